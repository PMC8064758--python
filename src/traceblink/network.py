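"""Trial-wise co-occurrence matrices and functional network maps.

The 600 ms tone-puff window holds only 12 samples at 20 Hz, too few for
pairwise correlation, so network structure is measured by co-activity
instead: on each trial, cells with a calcium event onset in the 1 s
after tone onset get a 1 in a binary response vector, and the outer
product of that vector with itself is the single-trial co-occurrence
matrix.  Summing single-trial matrices over a trial set counts, for each
cell pair, the trials on which both responded.  Networks place the
responsive cells at their ROI centroids and draw an edge wherever the
summed matrix is non-zero between two responsive cells; edge sets are
compared between sessions with a Jaccard index, and 2x2 proportion
contrasts use Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import fisher_exact
from sklearn.cluster import SpectralBiclustering

from .detect import EventTrain
from .synthetic import TrialSchedule

__all__ = ["CoOccurrenceMatrix", "NetworkMap", "EdgeOverlap",
           "trial_response_vector", "cooccurrence", "bicluster",
           "build_network", "network_density", "network_degree",
           "edge_overlap", "compare_proportions", "plot_network_map"]

log = logging.getLogger(__name__)


@dataclass
class CoOccurrenceMatrix:
    """Symmetric cell x cell count of joint tone-window activation."""

    A: np.ndarray
    trial_ids: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("co-occurrence matrix must be square")


@dataclass
class NetworkMap:
    """Graph of responsive cells at their anatomical positions."""

    graph: nx.Graph

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def m(self) -> int:
        return self.graph.number_of_edges()

    @property
    def edges(self) -> set[tuple[int, int]]:
        return {tuple(sorted(e)) for e in self.graph.edges}


@dataclass
class EdgeOverlap:
    """Shared/unique edge bookkeeping between two network maps."""

    Ei1: int
    Ei2: int
    Es: int
    Et: int = field(init=False)
    pct_individual_1: float = field(init=False)
    pct_individual_2: float = field(init=False)
    pct_shared: float = field(init=False)

    def __post_init__(self) -> None:
        if self.Es > min(self.Ei1, self.Ei2):
            raise ValueError("shared edges exceed an individual edge count")
        self.Et = self.Ei1 + self.Ei2 - self.Es
        if self.Et == 0:
            raise ValueError("no edges in either network")
        self.pct_individual_1 = 100.0 * self.Ei1 / self.Et
        self.pct_individual_2 = 100.0 * self.Ei2 / self.Et
        self.pct_shared = 100.0 * self.Es / self.Et

    @property
    def jaccard_pct(self) -> float:
        return self.pct_shared


def trial_response_vector(trains: list[EventTrain] | list[np.ndarray],
                          schedule: TrialSchedule, trial: int) -> np.ndarray:
    """Binary vector over cells: 1 iff the cell has an event onset in the
    half-open window [tone, tone + 1 s) of the given trial."""
    a, b = schedule.response_window(trial)
    vec = np.zeros(len(trains), dtype=np.uint8)
    for i, tr in enumerate(trains):
        onsets = tr.onsets if isinstance(tr, EventTrain) else np.asarray(tr)
        if len(onsets) and np.any((onsets >= a) & (onsets < b)):
            vec[i] = 1
    return vec


def cooccurrence(vectors: list[np.ndarray],
                 trial_ids: np.ndarray | None = None) -> CoOccurrenceMatrix:
    """Sum of single-trial outer products v v^T over a set of trials."""
    if not len(vectors):
        raise ValueError("no response vectors")
    V = np.asarray(vectors, dtype=np.int64)  # (n_trials, n_cells)
    if V.ndim != 2:
        raise ValueError("response vectors must share a length")
    A = V.T @ V
    if trial_ids is None:
        trial_ids = np.arange(V.shape[0])
    return CoOccurrenceMatrix(A=A, trial_ids=np.asarray(trial_ids))


def bicluster(matrix: CoOccurrenceMatrix, n_clusters: tuple[int, int] = (3, 3),
              seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Spectral biclustering into a 3x3 checkerboard, for display of
    co-modulated cell groups.

    Returns (row_order, col_order, row_labels, col_labels); an all-zero
    matrix gets the identity ordering with a warning.
    """
    A = matrix.A.astype(float)
    n = A.shape[0]
    if not A.any():
        log.warning("all-zero co-occurrence matrix; returning identity order")
        ident = np.arange(n)
        zeros = np.zeros(n, dtype=int)
        return ident, ident, zeros, zeros
    model = SpectralBiclustering(n_clusters=n_clusters, method="log",
                                 random_state=seed)
    model.fit(A)
    row_order = np.argsort(model.row_labels_, kind="stable")
    col_order = np.argsort(model.column_labels_, kind="stable")
    return row_order, col_order, model.row_labels_, model.column_labels_


def build_network(matrix: CoOccurrenceMatrix, responsive_union: set[int],
                  centroids: np.ndarray | None = None) -> NetworkMap:
    """Network over the responsive union: an (i, j) edge wherever the
    lower-triangle count A[i, j] is non-zero and both cells are in the
    union; no self-loops.  Node positions come from ROI centroids."""
    g = nx.Graph()
    for i in sorted(responsive_union):
        pos = tuple(centroids[i]) if centroids is not None else None
        g.add_node(int(i), pos=pos)
    A = matrix.A
    members = sorted(responsive_union)
    for ai, i in enumerate(members):
        for j in members[ai + 1:]:
            if A[j, i] > 0:  # lower triangle of the symmetric matrix
                g.add_edge(int(i), int(j), count=int(A[j, i]))
    return NetworkMap(graph=g)


def network_density(netmap: NetworkMap) -> float:
    """2m / (n (n-1)): observed edges over possible edges."""
    if netmap.n < 2:
        raise ValueError("density undefined for fewer than two nodes")
    return float(nx.density(netmap.graph))


def network_degree(netmap: NetworkMap) -> float:
    """2m / n: average degree per node."""
    if netmap.n == 0:
        raise ValueError("degree undefined for an empty graph")
    return float(2.0 * netmap.m / netmap.n)


def edge_overlap(map1: NetworkMap, map2: NetworkMap) -> EdgeOverlap:
    """Shared-edge bookkeeping between two networks on a common cell universe."""
    e1, e2 = map1.edges, map2.edges
    return EdgeOverlap(Ei1=len(e1), Ei2=len(e2), Es=len(e1 & e2))


def compare_proportions(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table
    [[k1, n1-k1], [k2, n2-k2]]."""
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    _, p = fisher_exact([[k1, n1 - k1], [k2, n2 - k2]], alternative="two-sided")
    return float(p)


def plot_network_map(netmap: NetworkMap, ax=None, node_color="tab:red",
                     edge_color="0.4"):
    """Draw the network at its anatomical node positions (ROI centroids)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    pos = nx.get_node_attributes(netmap.graph, "pos")
    if not pos or any(v is None for v in pos.values()):
        pos = nx.spring_layout(netmap.graph, seed=0)
    nx.draw_networkx(netmap.graph, pos=pos, ax=ax, with_labels=False,
                     node_size=20, node_color=node_color, edge_color=edge_color)
    ax.set_aspect("equal")
    return ax
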