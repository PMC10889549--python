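"""Surface-EMG conditioning and feature extraction.

Each raw trial is reduced to a smooth muscle-activation profile in three
steps — zero-phase band-pass filtering, moving-window RMS, and normalisation
to the participant's maximal voluntary contraction (MVC) — and each
participant/hand/session/task is then summarised by one fixed-length feature
vector: the trial-averaged, time-normalised %MVC envelope of every muscle,
concatenated in a fixed muscle order.  Pearson correlation between these
vectors is what the similarity networks are built from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import (
    CalibrationError,
    ConfigurationError,
    InputError,
    SamplingError,
    SchemaError,
)

#: Muscles recorded on each arm, in the fixed concatenation order used for
#: feature vectors.
DEFAULT_MUSCLES: tuple[str, ...] = (
    "biceps_brachii",
    "triceps_brachii",
    "extensor_digitorum",
    "flexor_carpi_radialis",
)

HANDS: tuple[str, ...] = ("dominant", "non_dominant")
TASKS: tuple[str, ...] = ("peg_transfer", "wire_loop")

#: Band-pass cutoffs (Hz) and RMS window (ms) used throughout.
BANDPASS_LOW_HZ = 20.0
BANDPASS_HIGH_HZ = 300.0
RMS_WINDOW_MS = 150.0
FEATURE_POINTS = 100


@dataclass
class EMGTrial:
    """One trial's raw multi-channel surface-EMG recording.

    ``channels`` maps muscle name to the raw amplitude series; all channels
    must have equal length and the sampling rate must satisfy the Nyquist
    condition for the band-pass high cutoff.
    """

    participant_id: str
    session: int
    trial: int
    hand: str
    task: str
    sampling_rate: float
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise SchemaError(f"non-positive sampling rate {self.sampling_rate}")
        lengths = {m: len(v) for m, v in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise SchemaError(f"unequal channel lengths: {lengths}")

    @property
    def n_samples(self) -> int:
        return 0 if not self.channels else len(next(iter(self.channels.values())))

    def require_muscles(self, muscles: Sequence[str]) -> None:
        missing = [m for m in muscles if m not in self.channels]
        if missing:
            raise SchemaError(
                f"trial ({self.participant_id}, s{self.session}, t{self.trial}, "
                f"{self.hand}, {self.task}) missing muscle channel(s): {missing}"
            )


@dataclass
class FeatureVector:
    """Fixed-length descriptor of one participant-hand-session-task."""

    participant_id: str
    session: int
    hand: str
    task: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise SchemaError(
                f"non-finite feature values for {self.participant_id}"
            )


def bandpass(
    x: np.ndarray,
    fs: float,
    low: float = BANDPASS_LOW_HZ,
    high: float = BANDPASS_HIGH_HZ,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass.

    ``order`` is the per-direction section order of the low/high prototype;
    the default gives a 4th-order band-pass, applied forward and backward
    (``sosfiltfilt``) for zero phase lag.

    Parameters
    ----------
    x : array
        Raw amplitude series.
    fs : float
        Sampling rate in Hz; must exceed twice the high cutoff.
    low, high : float
        Passband edges in Hz.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InputError("empty signal")
    if fs <= 2.0 * high:
        raise SamplingError(
            f"sampling rate {fs} Hz too low for a {high} Hz cutoff (need > {2 * high})"
        )
    if not (0 < low < high):
        raise ConfigurationError(f"invalid band edges low={low}, high={high}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    # sosfiltfilt pads with 3 * (2 * n_sections + 1) samples per end by default
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.size <= padlen:
        raise InputError(
            f"signal of {x.size} samples shorter than filter warm-up ({padlen})"
        )
    return sps.sosfiltfilt(sos, x)


def rms_envelope(
    x: np.ndarray, fs: float, window_ms: float = RMS_WINDOW_MS
) -> np.ndarray:
    """Moving-window RMS with a centred window, truncated at the edges.

    ``out[i] = sqrt(mean(x[j]**2 for j in window centred at i))`` where the
    window is clipped to the signal extent, so the output has the same length
    as the input and no phase lag.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InputError("empty signal")
    if window_ms <= 0:
        raise InputError(f"non-positive RMS window {window_ms} ms")
    w = max(int(round(window_ms * 1e-3 * fs)), 1)
    half_lo = (w - 1) // 2
    half_hi = w // 2
    sq = np.concatenate([[0.0], np.cumsum(x * x)])
    idx = np.arange(x.size)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi, x.size - 1)
    total = sq[hi + 1] - sq[lo]
    count = hi - lo + 1
    return np.sqrt(total / count)


def normalize_mvc(envelope: np.ndarray, mvc: float) -> np.ndarray:
    """Express an RMS envelope as percent of maximal voluntary contraction."""
    if mvc <= 0:
        raise CalibrationError(f"MVC must be positive, got {mvc}")
    return 100.0 * np.asarray(envelope, dtype=float) / mvc


def time_normalize(envelope: np.ndarray, n_points: int) -> np.ndarray:
    """Resample an envelope onto ``n_points`` equally spaced points of
    normalised time by linear interpolation.  Invariant to uniform time
    stretching of the input by construction."""
    envelope = np.asarray(envelope, dtype=float)
    if envelope.size == 0:
        raise InputError("empty envelope")
    if n_points < 2:
        raise InputError(f"need at least 2 resample points, got {n_points}")
    if envelope.size == 1:
        return np.full(n_points, envelope[0])
    src = np.linspace(0.0, 1.0, envelope.size)
    dst = np.linspace(0.0, 1.0, n_points)
    return np.interp(dst, src, envelope)


def _mvc_lookup(mvc_table, participant_id: str, muscle: str) -> float:
    if isinstance(mvc_table, pd.DataFrame):
        rows = mvc_table[
            (mvc_table["participant_id"] == participant_id)
            & (mvc_table["muscle"] == muscle)
        ]
        if rows.empty:
            raise SchemaError(f"no MVC value for ({participant_id}, {muscle})")
        return float(rows["mvc_amplitude"].iloc[0])
    return float(mvc_table[(participant_id, muscle)])


def trial_envelope(
    trial: EMGTrial,
    mvc_table,
    muscles: Sequence[str] = DEFAULT_MUSCLES,
    window_ms: float = RMS_WINDOW_MS,
    low: float = BANDPASS_LOW_HZ,
    high: float = BANDPASS_HIGH_HZ,
) -> dict[str, np.ndarray]:
    """Condition one trial: band-pass, RMS envelope, %MVC per muscle."""
    trial.require_muscles(muscles)
    out: dict[str, np.ndarray] = {}
    for m in muscles:
        filtered = bandpass(trial.channels[m], trial.sampling_rate, low, high)
        env = rms_envelope(filtered, trial.sampling_rate, window_ms)
        mvc = _mvc_lookup(mvc_table, trial.participant_id, m)
        out[m] = normalize_mvc(env, mvc)
    return out


def extract_features(
    trials: Iterable[EMGTrial],
    mvc_table,
    muscles: Sequence[str] = DEFAULT_MUSCLES,
    n_points: int = FEATURE_POINTS,
    window_ms: float = RMS_WINDOW_MS,
    low: float = BANDPASS_LOW_HZ,
    high: float = BANDPASS_HIGH_HZ,
) -> FeatureVector:
    """Reduce one participant-hand-session-task to a single feature vector.

    Per trial each muscle channel is band-pass filtered, enveloped by moving
    RMS, normalised to %MVC and linearly resampled to ``n_points`` of
    normalised time; the per-muscle profiles are averaged pointwise across
    the session's trials and concatenated in ``muscles`` order, giving a
    vector of length ``len(muscles) * n_points``.
    """
    trials = list(trials)
    if not trials:
        raise InputError("extract_features requires at least one trial")
    key = (trials[0].participant_id, trials[0].session, trials[0].hand, trials[0].task)
    for t in trials:
        if (t.participant_id, t.session, t.hand, t.task) != key:
            raise SchemaError(
                "all trials passed to extract_features must share "
                "participant/session/hand/task; got "
                f"{(t.participant_id, t.session, t.hand, t.task)} vs {key}"
            )
    per_trial = []
    for t in trials:
        env = trial_envelope(t, mvc_table, muscles, window_ms, low, high)
        per_trial.append(
            np.concatenate([time_normalize(env[m], n_points) for m in muscles])
        )
    values = np.mean(per_trial, axis=0)
    return FeatureVector(
        participant_id=key[0], session=key[1], hand=key[2], task=key[3], values=values
    )


def features_to_frame(features: Iterable[FeatureVector]) -> pd.DataFrame:
    """Tabulate feature vectors as one row per participant-hand-session-task
    with columns ``f_0001 ... f_NNNN``."""
    rows = []
    for fv in features:
        row = {
            "participant_id": fv.participant_id,
            "session": fv.session,
            "hand": fv.hand,
            "task": fv.task,
        }
        row.update(
            {f"f_{i + 1:04d}": v for i, v in enumerate(fv.values)}
        )
        rows.append(row)
    return pd.DataFrame(rows)
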