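"""Synthetic training cohort with planted similarity and learning structure.

The generator emulates an 18-participant box-trainer study — three sessions,
five trials per task per session, two hands, four muscles per arm, surface
EMG at 2000 Hz — with the statistical structure the downstream analysis
assumes, so every stage of the pipeline is testable without access to raw
recordings:

* participants are assigned to planted similarity blocks; all members of a
  block share the same muscle-activation envelope templates, so their
  extracted features correlate perfectly as noise vanishes;
* a designated subset of *learners* has non-dominant-hand envelopes that are
  a convex mixture of their own block's template and the best-performer
  block's template, with mixing weight growing across sessions — their
  activation pattern migrates toward the best performers as they practise;
* a designated subset of *best performers* has the lowest completion-time
  asymptotes, so selection by the final trial of the final session recovers
  them;
* NASA-TLX scores follow an additive group-effect model: learners and best
  performers report higher physical demand and effort and lower mental
  demand, effort additionally tracks each participant's planned improvement,
  and frustration carries no group effect.

Raw EMG is amplitude-modulated band-limited noise: a slow non-negative
envelope (the block template, scaled by participant strength) multiplies a
60-150 Hz carrier of unit RMS, plus white noise of standard deviation
``noise_sd``.  The carrier lives inside the 20-300 Hz analysis passband and
is shared by all participants within one (session, trial, hand, task,
muscle), so at ``noise_sd = 0`` same-block participants produce identical
signals.  Participant strength multiplies both the signal and the recorded
MVC, which is exactly the inter-subject scale that MVC normalisation is
meant to remove.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps

from .emg import DEFAULT_MUSCLES, EMGTrial, HANDS, TASKS
from .errors import ConfigurationError

#: Carrier band (Hz): strictly inside the 20-300 Hz filter passband so the
#: conditioning stage passes the signal essentially unchanged.
CARRIER_BAND_HZ = (60.0, 150.0)

#: Reference MVC amplitude for a participant of unit strength.
MVC_REFERENCE = 2.0

#: Exponential learning-curve parameters (asymptote a, gain b, in seconds)
#: per hand and participant group.  Non-dominant learners start slow and
#: drop ~46% of their mean time between sessions 1 and 3; best performers
#: have the lowest asymptotes on both hands; everyone else improves by well
#: under 20%, so the improvement rule separates planted learners.
TIME_CURVES = {
    "non_dominant": {"learner": (55.0, 90.0), "best": (40.0, 15.0), "other": (70.0, 12.0)},
    "dominant": {"learner": (55.0, 8.0), "best": (35.0, 6.0), "other": (55.0, 8.0)},
}

#: Additive NASA-TLX effect model: baseline per dimension plus group offsets
#: (scaled by ``tlx_effect_scale``).  Direction of effects: physical demand
#: and effort elevated for learners and best performers, mental demand
#: reduced; temporal demand, performance and frustration carry no effect.
TLX_BASELINES = {
    "mental": 5.5,
    "physical": 5.0,
    "temporal": 5.0,
    "performance": 5.0,
    "effort": 4.6,
    "frustration": 4.0,
}
TLX_GROUP_OFFSETS = {
    "mental": {"learner": -2.0, "best": -2.3},
    "physical": {"learner": 2.2, "best": 1.8},
}
#: Effort rises with the participant's planned relative improvement
#: (slope per unit of relative drop) plus a flat bonus for best performers.
TLX_EFFORT_IMPROVEMENT_SLOPE = 4.2
TLX_EFFORT_BEST_BONUS = 0.9


def default_participant_ids(n: int) -> list[str]:
    return [f"P{i:02d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and noise parameters of the synthetic cohort.

    Defaults reproduce the emulated study conditions: 18 participants split
    into two similarity blocks of nine, three planted learners in the
    non-best block, five planted best performers (ceil(0.25 x 18)) in the
    best block, 2000 Hz sampling, and the peg-transfer and wire-loop tasks.
    The seed fully determines every output.
    """

    n_participants: int = 18
    n_sessions: int = 3
    n_trials: int = 5
    hands: tuple[str, ...] = HANDS
    tasks: tuple[str, ...] = TASKS
    muscles: tuple[str, ...] = DEFAULT_MUSCLES
    sampling_rate: float = 2000.0
    trial_duration: float = 2.0
    community_assignment: Mapping[str, int] | None = None
    learner_ids: tuple[str, ...] | None = None
    best_ids: tuple[str, ...] | None = None
    noise_sd: float = 0.05
    learner_mix_max: float = 0.85
    time_noise_sd: float = 0.02
    tlx_noise_half_width: float = 1.2
    tlx_effect_scale: float = 1.0
    seed: int = 0

    def participants(self) -> list[str]:
        return default_participant_ids(self.n_participants)

    def blocks(self) -> dict[str, int]:
        """Planted block id per participant (two equal halves by default)."""
        ids = self.participants()
        if self.community_assignment is not None:
            blocks = dict(self.community_assignment)
            missing = [p for p in ids if p not in blocks]
            if missing:
                raise ConfigurationError(
                    f"community_assignment missing participants {missing}"
                )
            return {p: blocks[p] for p in ids}
        half = math.ceil(len(ids) / 2)
        return {p: (0 if i < half else 1) for i, p in enumerate(ids)}

    def resolved_best_ids(self) -> tuple[str, ...]:
        if self.best_ids is not None:
            return tuple(self.best_ids)
        ids = self.participants()
        blocks = self.blocks()
        block1 = [p for p in ids if blocks[p] == max(blocks.values())]
        n_best = min(math.ceil(0.25 * len(ids)), len(block1))
        return tuple(block1[:n_best])

    def resolved_learner_ids(self) -> tuple[str, ...]:
        if self.learner_ids is not None:
            return tuple(self.learner_ids)
        ids = self.participants()
        blocks = self.blocks()
        best_block = self.best_block()
        non_best = [p for p in ids if blocks[p] != best_block]
        return tuple(non_best[:3])

    def best_block(self) -> int:
        blocks = self.blocks()
        best = self.resolved_best_ids() if self.best_ids is not None else None
        if best:
            if best[0] not in blocks:
                raise ConfigurationError(
                    f"best_ids outside the roster: {best[0]!r}"
                )
            return blocks[best[0]]
        return max(blocks.values())

    def validate(self) -> None:
        if self.n_participants < 3:
            raise ConfigurationError("need at least 3 participants")
        if self.trial_duration <= 0:
            raise ConfigurationError(
                f"non-positive trial duration {self.trial_duration}"
            )
        if self.sampling_rate <= 0:
            raise ConfigurationError(
                f"non-positive sampling rate {self.sampling_rate}"
            )
        if self.n_sessions < 1 or self.n_trials < 1:
            raise ConfigurationError("need at least one session and one trial")
        if self.noise_sd < 0:
            raise ConfigurationError(f"negative noise_sd {self.noise_sd}")
        if not (0.0 <= self.learner_mix_max <= 1.0):
            raise ConfigurationError("learner_mix_max must be in [0, 1]")
        unknown_hands = set(self.hands) - set(HANDS)
        if unknown_hands:
            raise ConfigurationError(f"unknown hands {sorted(unknown_hands)}")
        unknown_tasks = set(self.tasks) - set(TASKS)
        if unknown_tasks:
            raise ConfigurationError(f"unknown tasks {sorted(unknown_tasks)}")
        ids = set(self.participants())
        for name, subset in (
            ("learner_ids", self.resolved_learner_ids()),
            ("best_ids", self.resolved_best_ids()),
        ):
            stray = set(subset) - ids
            if stray:
                raise ConfigurationError(f"{name} outside the roster: {sorted(stray)}")


@dataclass
class SyntheticCohort:
    """Generated cohort: EMG trials plus the three tabular records."""

    emg_trials: list[EMGTrial]
    mvc_table: pd.DataFrame
    kinematics: pd.DataFrame
    tlx: pd.DataFrame
    config: CohortConfig | None = None


def _envelope_template(rng: np.random.Generator, tau: np.ndarray) -> np.ndarray:
    """Random smooth non-negative activation profile on normalised time:
    a low baseline plus a few Gaussian activation bursts."""
    env = np.full_like(tau, 0.1)
    for _ in range(4):
        height = rng.uniform(0.2, 1.2)
        center = rng.uniform(0.1, 0.9)
        width = rng.uniform(0.04, 0.12)
        env += height * np.exp(-0.5 * ((tau - center) / width) ** 2)
    return env


def _carrier(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS band-limited noise carrier inside the analysis passband."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, CARRIER_BAND_HZ, btype="bandpass", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(band**2))
    return band / rms if rms > 0 else band


def _learning_mix(session: int, n_sessions: int, w_max: float) -> float:
    if n_sessions == 1:
        return 0.0
    return w_max * (session - 1) / (n_sessions - 1)


def _group_of(p: str, learners: set[str], best: set[str]) -> str:
    if p in best:
        return "best"
    if p in learners:
        return "learner"
    return "other"


def expected_relative_improvement(
    config: CohortConfig, group: str, hand: str = "non_dominant"
) -> float:
    """Noise-free relative drop in mean completion time, session 1 -> last,
    implied by the learning-curve parameters."""
    a, b = TIME_CURVES[hand][group]
    t = np.arange(config.n_trials) / config.n_trials
    first = a + b * np.mean(np.exp(-t))
    last = a + b * np.mean(np.exp(-(config.n_sessions - 1 + t)))
    return float((first - last) / first)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort.  Bit-identical for a fixed config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ids = config.participants()
    blocks = config.blocks()
    learners = set(config.resolved_learner_ids())
    best = set(config.resolved_best_ids())
    best_block = config.best_block()
    n = int(round(config.trial_duration * config.sampling_rate))
    tau = np.linspace(0.0, 1.0, n)
    t_sec = np.arange(n) / config.sampling_rate

    # 1) block templates, fixed generation order for determinism
    block_ids = sorted(set(blocks.values()))
    templates: dict[tuple, np.ndarray] = {}
    for block in block_ids:
        for task in config.tasks:
            for hand in config.hands:
                for muscle in config.muscles:
                    templates[(block, task, hand, muscle)] = _envelope_template(rng, tau)

    # 2) participant strength scales signal and MVC alike
    strength = {
        (p, m): float(rng.lognormal(mean=0.0, sigma=0.25))
        for p in ids
        for m in config.muscles
    }
    mvc_table = pd.DataFrame(
        [
            {
                "participant_id": p,
                "muscle": m,
                "mvc_amplitude": MVC_REFERENCE * strength[(p, m)],
            }
            for p in ids
            for m in config.muscles
        ]
    )

    # 3) carriers shared across participants within a trial slot
    carriers: dict[tuple, np.ndarray] = {}
    for session in range(1, config.n_sessions + 1):
        for trial in range(1, config.n_trials + 1):
            for hand in config.hands:
                for task in config.tasks:
                    for muscle in config.muscles:
                        carriers[(session, trial, hand, task, muscle)] = _carrier(
                            rng, n, config.sampling_rate
                        )

    # 4) EMG trials
    trials: list[EMGTrial] = []
    for p in ids:
        own_block = blocks[p]
        for session in range(1, config.n_sessions + 1):
            w = _learning_mix(session, config.n_sessions, config.learner_mix_max)
            for trial in range(1, config.n_trials + 1):
                for hand in config.hands:
                    for task in config.tasks:
                        channels = {}
                        for muscle in config.muscles:
                            env = templates[(own_block, task, hand, muscle)]
                            if p in learners and hand == "non_dominant" and w > 0:
                                target = templates[(best_block, task, hand, muscle)]
                                env = (1.0 - w) * env + w * target
                            noise = rng.normal(0.0, config.noise_sd, n)
                            channels[muscle] = (
                                env
                                * strength[(p, muscle)]
                                * carriers[(session, trial, hand, task, muscle)]
                                + noise
                            )
                        trials.append(
                            EMGTrial(
                                participant_id=p,
                                session=session,
                                trial=trial,
                                hand=hand,
                                task=task,
                                sampling_rate=config.sampling_rate,
                                channels=channels,
                            )
                        )

    # 5) completion times: exponential-decay learning curves
    asym_jitter = {
        (p, hand): float(rng.normal(1.0, 0.03))
        for p in ids
        for hand in config.hands
    }
    kin_rows = []
    for p in ids:
        group = _group_of(p, learners, best)
        for hand in config.hands:
            a, b = TIME_CURVES[hand][group]
            a = a * asym_jitter[(p, hand)]
            for session in range(1, config.n_sessions + 1):
                for trial in range(1, config.n_trials + 1):
                    for task in config.tasks:
                        x = (session - 1) + (trial - 1) / config.n_trials
                        noise = math.exp(rng.normal(0.0, config.time_noise_sd))
                        kin_rows.append(
                            {
                                "participant_id": p,
                                "session": session,
                                "trial": trial,
                                "hand": hand,
                                "task": task,
                                "completion_time_s": (a + b * math.exp(-x)) * noise,
                            }
                        )
    kinematics = pd.DataFrame(kin_rows)

    # 6) NASA-TLX: additive group effects + uniform noise, clipped to [0, 10]
    scale = config.tlx_effect_scale
    tlx_rows = []
    for p in ids:
        group = _group_of(p, learners, best)
        planned = expected_relative_improvement(config, group)
        means = dict(TLX_BASELINES)
        for dim, offsets in TLX_GROUP_OFFSETS.items():
            means[dim] += scale * offsets.get(group, 0.0)
        means["effort"] += scale * (
            TLX_EFFORT_IMPROVEMENT_SLOPE * planned
            + (TLX_EFFORT_BEST_BONUS if group == "best" else 0.0)
        )
        for session in range(1, config.n_sessions + 1):
            for task in config.tasks:
                row = {"participant_id": p, "session": session, "task": task}
                for dim, mu in means.items():
                    score = mu + rng.uniform(
                        -config.tlx_noise_half_width, config.tlx_noise_half_width
                    )
                    row[dim] = float(np.clip(score, 0.0, 10.0))
                tlx_rows.append(row)
    tlx = pd.DataFrame(tlx_rows)

    return SyntheticCohort(
        emg_trials=trials,
        mvc_table=mvc_table,
        kinematics=kinematics,
        tlx=tlx,
        config=config,
    )


def cohort_emg_frame(cohort: SyntheticCohort) -> pd.DataFrame:
    """Long-format EMG table (one row per sample per muscle)."""
    frames = []
    for tr in cohort.emg_trials:
        n = tr.n_samples
        t_sec = np.arange(n) / tr.sampling_rate
        for muscle, series in tr.channels.items():
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": tr.participant_id,
                        "session": tr.session,
                        "trial": tr.trial,
                        "hand": tr.hand,
                        "task": tr.task,
                        "muscle": muscle,
                        "t_sec": t_sec,
                        "amplitude": series,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=[
                "participant_id",
                "session",
                "trial",
                "hand",
                "task",
                "muscle",
                "t_sec",
                "amplitude",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict:
    """Write the cohort as the four CSV tables plus a manifest.

    Returns the manifest: file paths, trial counts per task, and the config
    as plain key-value text (also written to ``config.txt``).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    emg = cohort_emg_frame(cohort)
    paths = {
        "emg": directory / "emg.csv",
        "mvc": directory / "mvc.csv",
        "kinematics": directory / "kinematics.csv",
        "tlx": directory / "tlx.csv",
    }
    emg.to_csv(paths["emg"], index=False)
    cohort.mvc_table.to_csv(paths["mvc"], index=False)
    cohort.kinematics.to_csv(paths["kinematics"], index=False)
    cohort.tlx.to_csv(paths["tlx"], index=False)

    n_trials: dict[str, int] = {}
    for tr in cohort.emg_trials:
        n_trials[tr.task] = n_trials.get(tr.task, 0) + 1

    if cohort.config is not None:
        lines = []
        for key, value in asdict(cohort.config).items():
            lines.append(f"{key} = {value}")
        (directory / "config.txt").write_text("\n".join(lines) + "\n")

    manifest = {
        "files": {k: str(v) for k, v in paths.items()},
        "n_trial_recordings": n_trials,
        "n_participants": int(cohort.mvc_table["participant_id"].nunique())
        if not cohort.mvc_table.empty
        else 0,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
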