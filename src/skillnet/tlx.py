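"""NASA-TLX enrichment: subjective workload versus labels and improvement.

The NASA Task Load Index scores six workload dimensions (mental, physical
and temporal demand, performance, effort, frustration) on a 0-10 scale after
each task.  The enrichment relates those scores to the network-derived
participant groups (best / improved / other) via group means, and to
learning progression via the rank correlation between each dimension's
per-participant mean and the relative completion-time improvement.

Spearman is the default association measure (TLX scores are ordinal-like);
p-values are two-sided, by exact pairing permutation when N <= 10 and by the
asymptotic t approximation otherwise, and are descriptive: no correction is
applied across the six dimensions.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import IncompleteDataError, SchemaError
from .progression import LabelAssignment, relative_improvement

TLX_DIMENSIONS = [
    "mental",
    "physical",
    "temporal",
    "performance",
    "effort",
    "frustration",
]

TLX_COLUMNS = ["participant_id", "session", "task"] + TLX_DIMENSIONS

#: Above this sample size the exact permutation null is replaced by the
#: asymptotic approximation.
EXACT_PERMUTATION_MAX_N = 10


def validate_tlx_table(tlx: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TLX_COLUMNS if c not in tlx.columns]
    if missing:
        raise SchemaError(f"TLX table missing columns {missing}")
    for dim in TLX_DIMENSIONS:
        col = tlx[dim]
        if ((col < 0) | (col > 10)).any():
            raise SchemaError(f"TLX dimension {dim!r} outside [0, 10]")
    if tlx.duplicated(subset=["participant_id", "session", "task"]).any():
        raise SchemaError("duplicate (participant, session, task) TLX rows")
    return tlx


def group_means(
    tlx: pd.DataFrame, labels: LabelAssignment, task: str
) -> dict[str, dict[str, float]]:
    """Mean TLX score per label group and dimension, sessions pooled."""
    validate_tlx_table(tlx)
    sub = tlx[tlx["task"] == task]
    present = set(sub["participant_id"])
    absent = sorted(set(labels.labels) - present)
    if absent:
        raise IncompleteDataError(
            f"labelled participants with no TLX rows for task={task}: {absent}"
        )
    out: dict[str, dict[str, float]] = {}
    for group in ("best", "improved", "other"):
        members = labels.group(group)
        if not members:
            continue
        rows = sub[sub["participant_id"].isin(members)]
        out[group] = {dim: float(rows[dim].mean()) for dim in TLX_DIMENSIONS}
    return out


@dataclass
class CorrelationResult:
    rho: float | None
    p_value: float | None
    n: int
    method: str
    note: str | None = None


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


@functools.lru_cache(maxsize=4)
def _permutation_matrix(n: int) -> np.ndarray:
    """All n! permutations of range(n) as an (n!, n) int8 array."""
    count = math.factorial(n)
    flat = np.fromiter(
        itertools.chain.from_iterable(itertools.permutations(range(n))),
        dtype=np.int8,
        count=count * n,
    )
    return flat.reshape(count, n)


def _exact_spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided permutation p for the Spearman statistic.

    Enumerates all pairings of x against y; the p-value is the fraction of
    permutations whose |rho| reaches the observed one (the identity
    permutation is part of the null set, so p >= 1/n!).
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = _spearman_rho(x, y)
    perms = _permutation_matrix(len(x))
    ryc = ry - ry.mean()
    sy = float((ryc**2).sum())
    n_extreme = 0
    chunk = 500_000
    for start in range(0, perms.shape[0], chunk):
        rxp = rx[perms[start : start + chunk]]
        rxc = rxp - rxp.mean(axis=1, keepdims=True)
        rhos = (rxc @ ryc) / np.sqrt((rxc**2).sum(axis=1) * sy)
        n_extreme += int(np.sum(np.abs(rhos) >= abs(obs) - 1e-12))
    return float(obs), n_extreme / perms.shape[0]


def spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    n = len(x)
    if n <= EXACT_PERMUTATION_MAX_N:
        rho, p = _exact_spearman(np.asarray(x, float), np.asarray(y, float))
        return rho, p, "spearman-exact"
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue), "spearman-asymptotic"


def correlate_improvement(
    tlx: pd.DataFrame,
    perf: pd.DataFrame,
    task: str,
    hand: str,
    method: str = "spearman",
) -> dict[str, CorrelationResult]:
    """Correlate each TLX dimension with relative completion-time improvement.

    Per participant, each dimension is averaged over sessions for the task,
    and improvement is the relative session-1 to session-3 drop in mean
    completion time for the given hand.  ``method='pearson'`` switches the
    association measure.  Dimensions with constant scores are flagged with
    ``rho=None`` rather than raising, so one degenerate dimension does not
    abort the report.
    """
    validate_tlx_table(tlx)
    if method not in ("spearman", "pearson"):
        raise SchemaError(f"unknown correlation method {method!r}")
    impr = relative_improvement(perf, task, hand)
    if len(impr) < 4:
        raise IncompleteDataError(
            f"need at least 4 participants, got {len(impr)}"
        )
    sub = tlx[tlx["task"] == task]
    dim_means = sub.groupby("participant_id")[TLX_DIMENSIONS].mean()
    absent = sorted(set(impr.index) - set(dim_means.index))
    if absent:
        raise IncompleteDataError(f"no TLX rows for participants {absent}")
    dim_means = dim_means.loc[impr.index]
    y = impr.to_numpy(dtype=float)
    out: dict[str, CorrelationResult] = {}
    for dim in TLX_DIMENSIONS:
        x = dim_means[dim].to_numpy(dtype=float)
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            out[dim] = CorrelationResult(
                rho=None,
                p_value=None,
                n=len(x),
                method=method,
                note="undefined: constant input",
            )
            continue
        if method == "pearson":
            res = stats.pearsonr(x, y)
            out[dim] = CorrelationResult(
                rho=float(res.statistic),
                p_value=float(res.pvalue),
                n=len(x),
                method="pearson",
            )
        else:
            rho, p, how = spearman_with_p(x, y)
            out[dim] = CorrelationResult(rho=rho, p_value=p, n=len(x), method=how)
    return out


def enrichment_report(
    tlx: pd.DataFrame,
    perf: pd.DataFrame,
    labels: LabelAssignment,
    task: str,
    hand: str,
    method: str = "spearman",
) -> dict:
    """Group means plus improvement correlations, JSON-serialisable."""
    means = group_means(tlx, labels, task)
    corrs = correlate_improvement(tlx, perf, task, hand, method=method)
    return {
        "task": task,
        "hand": hand,
        "group_means": means,
        "improvement_correlation": {
            dim: {
                "rho": r.rho,
                "p_value": r.p_value,
                "n": r.n,
                "method": r.method,
                **({"note": r.note} if r.note else {}),
            }
            for dim, r in corrs.items()
        },
    }
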