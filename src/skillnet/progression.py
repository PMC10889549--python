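"""Performance labelling: best performers, improvers, and everyone else.

Best performers are the fastest participants in a designated late trial
(by default the fifth trial of the third session, where skill has
stabilised).  Improvers are participants outside the best set whose mean
completion time dropped by at least a relative threshold from the first to
the last session AND who are linked to at least one best performer in the
final-session similarity network — i.e. they got faster and their muscle
activation pattern converged on the best performers'.  Best performers are
not required to be connected: an outperformer can sit isolated in the
network because their muscle pattern differs from everyone else's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import IncompleteDataError, RosterMismatchError, SchemaError
from .network import SimilarityNetwork

PERF_COLUMNS = [
    "participant_id",
    "session",
    "trial",
    "hand",
    "task",
    "completion_time_s",
]

LABEL_COLORS = {"best": "yellow", "improved": "green", "other": "grey"}


def validate_performance_table(perf: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PERF_COLUMNS if c not in perf.columns]
    if missing:
        raise SchemaError(f"performance table missing columns {missing}")
    if (perf["completion_time_s"] <= 0).any():
        bad = perf.loc[perf["completion_time_s"] <= 0, "participant_id"].tolist()
        raise SchemaError(f"non-positive completion times for {sorted(set(bad))}")
    key = ["participant_id", "session", "trial", "hand", "task"]
    if perf.duplicated(subset=key).any():
        raise SchemaError("duplicate (participant, session, trial, hand, task) rows")
    return perf


@dataclass
class LabelAssignment:
    """Total labelling of the roster into best / improved / other."""

    labels: dict[str, str]
    criteria: dict = field(default_factory=dict)

    def group(self, name: str) -> set[str]:
        return {p for p, lab in self.labels.items() if lab == name}

    def counts(self) -> dict[str, int]:
        out = {"best": 0, "improved": 0, "other": 0}
        for lab in self.labels.values():
            out[lab] += 1
        return out

    def colors(self) -> dict[str, str]:
        return {p: LABEL_COLORS[lab] for p, lab in self.labels.items()}

    def to_frame(self, task: str | None = None, hand: str | None = None) -> pd.DataFrame:
        rows = [
            {"participant_id": p, "label": lab, "task": task, "hand": hand}
            for p, lab in sorted(self.labels.items())
        ]
        return pd.DataFrame(rows)


def identify_best(
    perf: pd.DataFrame,
    task: str,
    hand: str,
    session: int = 3,
    trial: int = 5,
    fraction: float = 0.25,
) -> set[str]:
    """Participants with the lowest completion time in the selection trial.

    Takes ``ceil(fraction * N)`` participants; ties are broken toward the
    lower participant id.
    """
    validate_performance_table(perf)
    sub = perf[(perf["task"] == task) & (perf["hand"] == hand)]
    roster = sorted(sub["participant_id"].unique())
    if not roster:
        raise IncompleteDataError(f"no rows for task={task}, hand={hand}")
    sel = sub[(sub["session"] == session) & (sub["trial"] == trial)]
    present = set(sel["participant_id"])
    absent = [p for p in roster if p not in present]
    if absent:
        raise IncompleteDataError(
            f"no session {session} trial {trial} row for participants {absent}"
        )
    n_best = math.ceil(fraction * len(roster))
    ranked = sel.sort_values(["completion_time_s", "participant_id"])
    return set(ranked["participant_id"].head(n_best))


def session_mean_times(
    perf: pd.DataFrame, task: str, hand: str
) -> pd.DataFrame:
    sub = perf[(perf["task"] == task) & (perf["hand"] == hand)]
    return (
        sub.groupby(["participant_id", "session"])["completion_time_s"]
        .mean()
        .unstack("session")
    )


def relative_improvement(
    perf: pd.DataFrame, task: str, hand: str
) -> pd.Series:
    """Relative drop in mean completion time from the first to the last
    session: (t_first - t_last) / t_first, per participant."""
    means = session_mean_times(perf, task, hand)
    if means.shape[1] < 2:
        raise IncompleteDataError("need at least two sessions to assess improvement")
    first, last = means.columns.min(), means.columns.max()
    if means[[first, last]].isna().any().any():
        bad = means.index[means[[first, last]].isna().any(axis=1)].tolist()
        raise IncompleteDataError(f"missing session {first}/{last} rows for {bad}")
    return (means[first] - means[last]) / means[first]


def identify_improved(
    perf: pd.DataFrame,
    nets: Mapping[int, SimilarityNetwork],
    task: str,
    hand: str,
    best: set[str],
    min_improvement: float = 0.20,
) -> set[str]:
    """Participants (outside ``best``) who both got at least
    ``min_improvement`` relatively faster between the first and last session
    and are adjacent to a best performer in the last-session network."""
    impr = relative_improvement(perf, task, hand)
    last_session = max(nets)
    net = nets[last_session]
    roster = set(net.participants)
    if set(impr.index) != roster:
        raise RosterMismatchError(
            f"performance roster {sorted(impr.index)} != network roster "
            f"{sorted(roster)}"
        )
    improved = set()
    for p, drop in impr.items():
        if p in best:
            continue
        if drop >= min_improvement and net.neighbors(p) & best:
            improved.add(p)
    return improved


def label_nodes(
    best: Iterable[str],
    improved: Iterable[str],
    roster: Iterable[str],
    criteria: dict | None = None,
) -> LabelAssignment:
    """Total labelling with best taking precedence over improved."""
    roster = list(roster)
    best, improved = set(best), set(improved)
    stray = (best | improved) - set(roster)
    if stray:
        raise SchemaError(f"labels for participants outside the roster: {sorted(stray)}")
    labels = {}
    for p in roster:
        if p in best:
            labels[p] = "best"
        elif p in improved:
            labels[p] = "improved"
        else:
            labels[p] = "other"
    return LabelAssignment(labels=labels, criteria=dict(criteria or {}))
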