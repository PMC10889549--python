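"""File formats, pipeline configuration, logging, and the full pipeline run.

All tabular inputs are plain long-format CSV (one documented dialect per
table); networks are interchanged as GraphML (node attributes carry the
best/improved/other labels and their display colours) or as a minimal
tab-separated edge list; derived statistics are JSON.  Machine-readable
outputs are never mixed with logs, which go to stderr with stage-scoped
logger names.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .emg import (
    BANDPASS_HIGH_HZ,
    BANDPASS_LOW_HZ,
    DEFAULT_MUSCLES,
    EMGTrial,
    FEATURE_POINTS,
    FeatureVector,
    RMS_WINDOW_MS,
    extract_features,
    features_to_frame,
)
from .errors import ConfigurationError, SchemaError
from .metrics import (
    NetworkMetrics,
    compare_sessions,
    network_metrics,
)
from .network import (
    DEFAULT_THRESHOLD_K,
    SimilarityNetwork,
    pairwise_correlation,
    threshold_network,
)
from .progression import (
    LABEL_COLORS,
    LabelAssignment,
    identify_best,
    identify_improved,
    label_nodes,
    validate_performance_table,
)
from .tlx import enrichment_report, validate_tlx_table

logger = logging.getLogger("skillnet")

EMG_COLUMNS = [
    "participant_id",
    "session",
    "trial",
    "hand",
    "task",
    "muscle",
    "t_sec",
    "amplitude",
]


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("skillnet")
    root.handlers[:] = [handler]
    root.setLevel(level.upper())


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# readers


def read_emg_csv(
    path: str | Path,
    muscles: Sequence[str] = DEFAULT_MUSCLES,
    expected_rate: float | None = None,
) -> list[EMGTrial]:
    """Parse the long-format EMG table into per-trial objects.

    The sampling rate is inferred from the ``t_sec`` spacing of each trial
    and cross-checked for consistency across trials and against
    ``expected_rate`` when given.  Non-monotone time or mixed rates raise a
    schema error with the offending trial's key.
    """
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("EMG file %s is empty; returning no trials", path)
        return []
    missing = [c for c in EMG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"EMG file {path} missing columns {missing}")
    trials: list[EMGTrial] = []
    rates: set[float] = set()
    key_cols = ["participant_id", "session", "trial", "hand", "task"]
    for key, group in df.groupby(key_cols, sort=True):
        channels: dict[str, np.ndarray] = {}
        rate = None
        for muscle, chan in group.groupby("muscle"):
            t = chan["t_sec"].to_numpy(dtype=float)
            if len(t) < 2:
                raise SchemaError(f"trial {key}: muscle {muscle} has < 2 samples")
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise SchemaError(f"trial {key}: non-monotone t_sec for {muscle}")
            if np.ptp(dt) > 1e-6 * np.mean(dt) + 1e-12:
                raise SchemaError(f"trial {key}: non-uniform t_sec for {muscle}")
            rate = round(1.0 / float(np.mean(dt)), 6)
            channels[muscle] = chan["amplitude"].to_numpy(dtype=float)
        rates.add(rate)
        trial = EMGTrial(
            participant_id=str(key[0]),
            session=int(key[1]),
            trial=int(key[2]),
            hand=str(key[3]),
            task=str(key[4]),
            sampling_rate=rate,
            channels=channels,
        )
        trial.require_muscles(muscles)
        trials.append(trial)
    if len(rates) > 1:
        raise SchemaError(f"mixed sampling rates across trials: {sorted(rates)}")
    if expected_rate is not None and rates:
        (inferred,) = rates
        if abs(inferred - expected_rate) > 0.01 * expected_rate:
            raise SchemaError(
                f"inferred rate {inferred} Hz differs from configured "
                f"{expected_rate} Hz"
            )
    return trials


def read_mvc_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("participant_id", "muscle", "mvc_amplitude") if c not in df.columns]
    if missing:
        raise SchemaError(f"MVC file {path} missing columns {missing}")
    if (df["mvc_amplitude"] <= 0).any():
        raise SchemaError(f"MVC file {path} contains non-positive amplitudes")
    return df


def read_kinematics_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_performance_table(df)


def read_tlx_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_tlx_table(df)


# ---------------------------------------------------------------------------
# graph and matrix writers


def write_cm_csv(cm, path: str | Path) -> None:
    """Correlation matrix as CSV with participant ids as header row/column."""
    pd.DataFrame(cm.rho, index=cm.participants, columns=cm.participants).to_csv(path)


def write_graphml(net: SimilarityNetwork, path: str | Path) -> None:
    g = net.to_networkx()
    if net.node_labels:
        colors = {p: LABEL_COLORS[lab] for p, lab in net.node_labels.items()}
        nx.set_node_attributes(g, colors, name="color")
    nx.write_graphml(g, path)


def read_graphml(path: str | Path) -> SimilarityNetwork:
    return SimilarityNetwork.from_networkx(nx.read_graphml(path))


def write_edgelist(net: SimilarityNetwork, path: str | Path) -> None:
    """Tab-separated edge list; a leading comment preserves the roster so
    isolated nodes survive a round trip."""
    lines = ["# nodes:\t" + "\t".join(net.participants)]
    lines += [f"{u}\t{v}" for u, v in sorted(net.edges)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edgelist(path: str | Path) -> SimilarityNetwork:
    lines = Path(path).read_text().splitlines()
    participants: list[str] = []
    edges = set()
    for line in lines:
        if line.startswith("# nodes:"):
            participants = line.split("\t")[1:]
            continue
        if not line.strip() or line.startswith("#"):
            continue
        u, v = line.split("\t")
        edges.add((u, v))
    if not participants:
        participants = sorted({x for e in edges for x in e})
    return SimilarityNetwork(participants=participants, edges=edges)


def draw_network(net: SimilarityNetwork, path: str | Path, seed: int = 0) -> None:
    """Minimal rendering helper: spring layout, nodes coloured by label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = net.to_networkx()
    colors = [
        LABEL_COLORS.get((net.node_labels or {}).get(p, "other"), "grey")
        for p in g.nodes
    ]
    fig, ax = plt.subplots(figsize=(6, 6))
    pos = nx.spring_layout(g, seed=seed)
    nx.draw_networkx(g, pos=pos, ax=ax, node_color=colors, edgecolors="black")
    ax.set_axis_off()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _metrics_payload(m: NetworkMetrics) -> dict:
    payload = asdict(m)
    if m.partition is not None:
        communities: dict[int, list[str]] = {}
        for node, c in m.partition.items():
            communities.setdefault(c, []).append(node)
        payload["communities"] = [sorted(v) for _, v in sorted(communities.items())]
    else:
        payload["communities"] = None
    return payload


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs, in one validated record."""

    emg_csv: str = "emg.csv"
    mvc_csv: str = "mvc.csv"
    kinematics_csv: str = "kinematics.csv"
    tlx_csv: str = "tlx.csv"
    out_dir: str = "out"
    threshold_k: float = DEFAULT_THRESHOLD_K
    threshold_mode: str = "value"
    feature_points: int = FEATURE_POINTS
    bandpass_low: float = BANDPASS_LOW_HZ
    bandpass_high: float = BANDPASS_HIGH_HZ
    window_ms: float = RMS_WINDOW_MS
    muscles: tuple[str, ...] = DEFAULT_MUSCLES
    best_fraction: float = 0.25
    min_improvement: float = 0.20
    clustering_variant: str = "average"
    correlation_method: str = "spearman"
    expected_rate: float | None = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not (0.0 <= self.threshold_k <= 1.0):
            raise ConfigurationError(f"threshold_k out of [0, 1]: {self.threshold_k}")
        if self.threshold_mode not in ("value", "percentile"):
            raise ConfigurationError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.feature_points < 2:
            raise ConfigurationError("feature_points must be >= 2")
        if not (0 < self.bandpass_low < self.bandpass_high):
            raise ConfigurationError("require 0 < bandpass_low < bandpass_high")
        if self.window_ms <= 0:
            raise ConfigurationError("window_ms must be positive")
        if not (0.0 < self.best_fraction <= 1.0):
            raise ConfigurationError("best_fraction must be in (0, 1]")
        if self.min_improvement < 0:
            raise ConfigurationError("min_improvement must be >= 0")
        if self.clustering_variant not in ("average", "transitivity"):
            raise ConfigurationError(
                f"unknown clustering_variant {self.clustering_variant!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config {path} is not a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "muscles" in raw:
            raw["muscles"] = tuple(raw["muscles"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class RunManifest:
    config: dict
    input_checksums: dict[str, str]
    outputs: dict[str, str]
    version: str = __version__
    started: str = ""
    finished: str = ""

    def write(self, path: str | Path) -> None:
        write_json(asdict(self), path)


# ---------------------------------------------------------------------------
# pipeline


def compute_session_features(
    trials: Iterable[EMGTrial],
    mvc_table: pd.DataFrame,
    config: PipelineConfig,
) -> list[FeatureVector]:
    """Group trials by participant/session/hand/task and extract one feature
    vector per group."""
    groups: dict[tuple, list[EMGTrial]] = {}
    for tr in trials:
        groups.setdefault(
            (tr.participant_id, tr.session, tr.hand, tr.task), []
        ).append(tr)
    return [
        extract_features(
            grp,
            mvc_table,
            muscles=config.muscles,
            n_points=config.feature_points,
            window_ms=config.window_ms,
            low=config.bandpass_low,
            high=config.bandpass_high,
        )
        for _, grp in sorted(groups.items())
    ]


def build_networks(
    features: Iterable[FeatureVector], config: PipelineConfig
) -> dict[tuple[str, str], dict[int, tuple]]:
    """Per (task, hand): per session, the (CM, SM) pair."""
    by_slot: dict[tuple, list[FeatureVector]] = {}
    for fv in features:
        by_slot.setdefault((fv.task, fv.hand, fv.session), []).append(fv)
    out: dict[tuple[str, str], dict[int, tuple]] = {}
    for (task, hand, session), feats in sorted(by_slot.items()):
        cm = pairwise_correlation(feats, session=session, hand=hand, task=task)
        net = threshold_network(cm, k=config.threshold_k, mode=config.threshold_mode)
        out.setdefault((task, hand), {})[session] = (cm, net)
    return out


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis: conditioning, features, networks, metrics,
    session comparisons, labelling, and TLX enrichment.

    Every artifact is written under ``config.out_dir``; any stage failure
    aborts with the stage name attached to the exception message.
    """
    config.validate()
    setup_logging(config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()

    stage = "read"
    try:
        log = logging.getLogger("skillnet.read")
        trials = read_emg_csv(config.emg_csv, config.muscles, config.expected_rate)
        mvc = read_mvc_csv(config.mvc_csv)
        perf = read_kinematics_csv(config.kinematics_csv)
        tlx = read_tlx_csv(config.tlx_csv)
        log.info("read %d trials", len(trials))

        stage = "features"
        log = logging.getLogger("skillnet.features")
        features = compute_session_features(trials, mvc, config)
        features_path = out_dir / "features.csv"
        features_to_frame(features).to_csv(features_path, index=False)
        log.info("extracted %d feature vectors", len(features))

        stage = "networks"
        log = logging.getLogger("skillnet.networks")
        networks = build_networks(features, config)
        net_dir = out_dir / "networks"
        net_dir.mkdir(exist_ok=True)
        n_networks = 0
        for (task, hand), per_session in networks.items():
            for session, (cm, net) in per_session.items():
                stem = f"{task}_{hand}_s{session}"
                write_cm_csv(cm, net_dir / f"{stem}_cm.csv")
                write_edgelist(net, net_dir / f"{stem}.edgelist.tsv")
                n_networks += 1
        log.info("built %d networks", n_networks)

        stage = "labels"
        log = logging.getLogger("skillnet.labels")
        sessions_present = sorted(perf["session"].unique())
        trials_present = sorted(perf["trial"].unique())
        sel_session, sel_trial = sessions_present[-1], trials_present[-1]
        labels_by_slot: dict[tuple[str, str], LabelAssignment] = {}
        label_frames = []
        for (task, hand), per_session in networks.items():
            nets = {s: net for s, (_, net) in per_session.items()}
            best = identify_best(
                perf,
                task,
                hand,
                session=sel_session,
                trial=sel_trial,
                fraction=config.best_fraction,
            )
            improved = identify_improved(
                perf, nets, task, hand, best, min_improvement=config.min_improvement
            )
            roster = nets[max(nets)].participants
            assignment = label_nodes(
                best,
                improved,
                roster,
                criteria={
                    "selection_session": int(sel_session),
                    "selection_trial": int(sel_trial),
                    "best_fraction": config.best_fraction,
                    "min_improvement": config.min_improvement,
                },
            )
            labels_by_slot[(task, hand)] = assignment
            label_frames.append(assignment.to_frame(task=task, hand=hand))
            for session, (_, net) in per_session.items():
                net.node_labels = dict(assignment.labels)
                write_graphml(net, net_dir / f"{task}_{hand}_s{session}.graphml")
        labels_path = out_dir / "labels.csv"
        pd.concat(label_frames, ignore_index=True).to_csv(labels_path, index=False)
        log.info("labelled %d (task, hand) slots", len(labels_by_slot))

        stage = "metrics"
        log = logging.getLogger("skillnet.metrics")
        metrics_payload = {}
        comparisons_payload = {}
        for (task, hand), per_session in networks.items():
            nets = {s: net for s, (_, net) in per_session.items()}
            metrics_payload[f"{task}/{hand}"] = {
                str(s): _metrics_payload(
                    network_metrics(net, config.clustering_variant)
                )
                for s, net in nets.items()
            }
            comparisons_payload[f"{task}/{hand}"] = [
                {
                    "sessions": list(c.pair),
                    "jaccard": c.jaccard,
                    "shared_edges": c.shared_edges,
                    "union_edges": c.union_edges,
                    "percent_difference": c.percent_difference,
                }
                for c in compare_sessions(nets)
            ]
        metrics_path = out_dir / "metrics.json"
        comparisons_path = out_dir / "comparisons.json"
        write_json(metrics_payload, metrics_path)
        write_json(comparisons_payload, comparisons_path)
        log.info("metrics written")

        stage = "enrichment"
        log = logging.getLogger("skillnet.enrichment")
        enrichment_payload = {
            f"{task}/{hand}": enrichment_report(
                tlx,
                perf,
                labels_by_slot[(task, hand)],
                task,
                hand,
                method=config.correlation_method,
            )
            for (task, hand) in networks
        }
        enrichment_path = out_dir / "enrichment.json"
        write_json(enrichment_payload, enrichment_path)
        log.info("enrichment written")
    except Exception as exc:
        try:
            wrapped = type(exc)(f"[stage: {stage}] {exc}")
        except Exception:
            wrapped = RuntimeError(f"[stage: {stage}] {exc}")
        raise wrapped from exc

    manifest = RunManifest(
        config=asdict(config),
        input_checksums={
            name: sha256_of(getattr(config, name))
            for name in ("emg_csv", "mvc_csv", "kinematics_csv", "tlx_csv")
        },
        outputs={
            "features": str(features_path),
            "networks": str(net_dir),
            "labels": str(labels_path),
            "metrics": str(metrics_path),
            "comparisons": str(comparisons_path),
            "enrichment": str(enrichment_path),
        },
        started=started,
        finished=datetime.now(timezone.utc).isoformat(),
    )
    manifest.write(out_dir / "manifest.json")
    return manifest
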