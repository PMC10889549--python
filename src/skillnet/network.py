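"""Correlation-threshold similarity networks over participants.

A correlation matrix (CM) holds the Pearson correlation between every pair
of participants' EMG feature vectors; thresholding it at a similarity
criterion ``k`` yields a binary significance matrix (SM) that is the
adjacency matrix of the participant network: an edge links two participants
iff their feature correlation is at least ``k``.  Negative correlations
never create edges (the criterion is one-sided).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np

from .emg import FeatureVector
from .errors import (
    ConfigurationError,
    RosterMismatchError,
    SchemaError,
    UndefinedCorrelationError,
)

DEFAULT_THRESHOLD_K = 0.9

Edge = tuple[str, str]


def _norm_edge(u: str, v: str) -> Edge:
    return (u, v) if u <= v else (v, u)


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over an ordered roster."""

    participants: list[str]
    rho: np.ndarray
    session: int | None = None
    hand: str | None = None
    task: str | None = None

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        n = len(self.participants)
        if self.rho.shape != (n, n):
            raise SchemaError(
                f"rho shape {self.rho.shape} does not match roster of {n}"
            )
        if not np.allclose(self.rho, self.rho.T, atol=1e-10):
            raise SchemaError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.rho), 1.0, atol=1e-10):
            raise SchemaError("correlation matrix diagonal is not 1")
        if np.any(np.abs(self.rho) > 1.0 + 1e-12):
            raise SchemaError("correlation magnitude exceeds 1")

    def value(self, a: str, b: str) -> float:
        i, j = self.participants.index(a), self.participants.index(b)
        return float(self.rho[i, j])


@dataclass
class SimilarityNetwork:
    """Thresholded participant network (the SM as a graph).

    Isolated nodes are kept: the network is always over the full roster.
    ``node_labels`` optionally maps participants to best/improved/other.
    """

    participants: list[str]
    edges: set[Edge] = field(default_factory=set)
    threshold_k: float | None = None
    session: int | None = None
    hand: str | None = None
    task: str | None = None
    node_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        roster = set(self.participants)
        norm: set[Edge] = set()
        for u, v in self.edges:
            if u == v:
                raise SchemaError(f"self-loop on {u}")
            if u not in roster or v not in roster:
                raise SchemaError(f"edge ({u}, {v}) leaves the roster")
            norm.add(_norm_edge(u, v))
        self.edges = norm

    @property
    def n_nodes(self) -> int:
        return len(self.participants)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node: str) -> int:
        return sum(node in e for e in self.edges)

    def neighbors(self, node: str) -> set[str]:
        out = set()
        for u, v in self.edges:
            if u == node:
                out.add(v)
            elif v == node:
                out.add(u)
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.participants)
        g.add_edges_from(self.edges)
        if self.node_labels:
            nx.set_node_attributes(g, self.node_labels, name="label")
        for key in ("threshold_k", "session", "hand", "task"):
            val = getattr(self, key)
            if val is not None:
                g.graph[key] = val
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "SimilarityNetwork":
        labels = nx.get_node_attributes(g, "label") or None
        return cls(
            participants=sorted(g.nodes),
            edges={_norm_edge(u, v) for u, v in g.edges},
            threshold_k=g.graph.get("threshold_k"),
            session=g.graph.get("session"),
            hand=g.graph.get("hand"),
            task=g.graph.get("task"),
            node_labels=labels,
        )


def pairwise_correlation(
    features: Iterable[FeatureVector],
    session: int | None = None,
    hand: str | None = None,
    task: str | None = None,
) -> CorrelationMatrix:
    """Pearson correlation between every pair of participants' features.

    Raises
    ------
    UndefinedCorrelationError
        If any participant's feature vector is constant (zero variance),
        naming the offending participant.
    """
    feats = sorted(features, key=lambda f: f.participant_id)
    if len(feats) < 2:
        raise SchemaError("need at least 2 participants for a correlation matrix")
    lengths = {f.values.size for f in feats}
    if len(lengths) != 1:
        raise SchemaError(f"feature vectors have differing lengths: {lengths}")
    if lengths.pop() < 2:
        raise SchemaError("feature vectors must have length >= 2")
    for f in feats:
        if np.ptp(f.values) == 0.0:
            raise UndefinedCorrelationError(
                f"constant feature vector for participant {f.participant_id}; "
                "Pearson correlation is undefined"
            )
    mat = np.vstack([f.values for f in feats])
    rho = np.corrcoef(mat)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    meta = feats[0]
    return CorrelationMatrix(
        participants=[f.participant_id for f in feats],
        rho=rho,
        session=session if session is not None else meta.session,
        hand=hand if hand is not None else meta.hand,
        task=task if task is not None else meta.task,
    )


def threshold_network(
    cm: CorrelationMatrix,
    k: float = DEFAULT_THRESHOLD_K,
    mode: str = "value",
) -> SimilarityNetwork:
    """Build the similarity network by thresholding a correlation matrix.

    ``mode='value'`` (default) links i and j iff rho(i, j) >= k, the direct
    reading of the similarity criterion; ``mode='percentile'`` instead treats
    ``k`` as a quantile level of the off-diagonal correlation distribution
    and links pairs at or above that quantile.  Ties at the threshold always
    produce an edge.
    """
    if not (0.0 <= k <= 1.0):
        raise ConfigurationError(f"threshold k must be in [0, 1], got {k}")
    if mode not in ("value", "percentile"):
        raise ConfigurationError(f"unknown threshold mode {mode!r}")
    n = len(cm.participants)
    iu = np.triu_indices(n, k=1)
    offdiag = cm.rho[iu]
    cut = float(np.quantile(offdiag, k)) if mode == "percentile" else k
    edges = {
        _norm_edge(cm.participants[i], cm.participants[j])
        for i, j in zip(*iu)
        if cm.rho[i, j] >= cut
    }
    return SimilarityNetwork(
        participants=list(cm.participants),
        edges=edges,
        threshold_k=k,
        session=cm.session,
        hand=cm.hand,
        task=cm.task,
    )


def require_same_roster(a: SimilarityNetwork, b: SimilarityNetwork) -> None:
    if set(a.participants) != set(b.participants):
        raise RosterMismatchError(
            f"rosters differ: {sorted(set(a.participants) ^ set(b.participants))}"
        )
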