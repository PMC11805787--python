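"""Functional-connectivity networks: correlation, thresholding, modularity.

Pipeline mirroring a resting-state connectivity analysis: per-run Pearson
correlation matrices over node time series, run-averaging, proportional
thresholding at a fixed edge density followed by binarization, and
Newman-style modularity maximization of the resulting binary graph.

Modularity of a partition is

    M = (1/2e) * sum_modules sum_{i,j in module} (A_ij - a_i a_j / 2e)

summed over ordered node pairs including i = j, where ``A`` is the binary
adjacency, ``a_i`` node degree and ``e`` the edge count.  The optimizer is
greedy agglomeration on the modularity-gain matrix with node-move
(Kernighan-Lin style) refinement and seeded random restarts; it is
validated against exhaustive partition enumeration on small graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np

__all__ = [
    "WeightedNetwork",
    "BinaryGraph",
    "ModularityResult",
    "connectivity_from_timeseries",
    "average_networks",
    "threshold_binarize",
    "modularity",
    "optimize_partition",
    "network_pipeline",
    "expected_edge_count",
]


@dataclass
class WeightedNetwork:
    """Symmetric weighted connectivity matrix; the diagonal is ignored."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, equal_nan=True):
            raise ValueError("weights must be symmetric")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class BinaryGraph:
    """Binarized graph: 0/1 symmetric adjacency with zero diagonal."""

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T) or a.ndim != 2:
            raise ValueError("adjacency must be square and symmetric")
        if not np.isin(a, (0, 1)).all() or np.diag(a).any():
            raise ValueError("adjacency must be 0/1 with zero diagonal")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    @property
    def n_edges(self) -> int:
        return int(self.degrees.sum()) // 2


@dataclass
class ModularityResult:
    M: float
    partition: np.ndarray          # node -> contiguous module label from 0
    density: float
    n_edges: int

    @property
    def n_modules(self) -> int:
        return int(self.partition.max()) + 1 if self.partition.size else 0


def connectivity_from_timeseries(values: np.ndarray) -> list[WeightedNetwork]:
    """Per-run Pearson-correlation networks from a runs x nodes x time array."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[None]
    if values.shape[-1] < 2:
        raise ValueError("need at least 2 timepoints per run")
    nets = []
    for run in values:
        if np.any(run.std(axis=1) == 0):
            raise ValueError("constant node time series: correlation undefined")
        c = np.corrcoef(run)
        np.fill_diagonal(c, 1.0)
        nets.append(WeightedNetwork((c + c.T) / 2))
    return nets


def average_networks(nets: list[WeightedNetwork]) -> WeightedNetwork:
    """Elementwise arithmetic mean of connectivity matrices (raw r scale)."""
    if not nets:
        raise ValueError("no networks to average")
    shape = nets[0].weights.shape
    if any(n.weights.shape != shape for n in nets):
        raise ValueError("dimension mismatch across networks")
    return WeightedNetwork(np.mean([n.weights for n in nets], axis=0))


def expected_edge_count(n_nodes: int, density: float) -> int:
    """Edges retained at a proportional threshold: ceil(density * C(n,2))."""
    return ceil(density * n_nodes * (n_nodes - 1) / 2)


def threshold_binarize(net: WeightedNetwork, density: float,
                       *, ranking: str = "signed") -> BinaryGraph:
    """Keep the k strongest edges (k = ceil(density * C(n,2))) and binarize.

    ``ranking='signed'`` ranks by the raw correlation (default);
    ``'absolute'`` ranks by |r|.  Ties at the cut are broken in
    lexicographic (i, j) order for reproducibility.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    n = net.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    w = net.weights[iu, ju]
    if ranking == "absolute":
        w = np.abs(w)
    elif ranking != "signed":
        raise ValueError("ranking must be 'signed' or 'absolute'")
    finite = np.isfinite(w)
    k = expected_edge_count(n, density)
    if k > finite.sum():
        raise ValueError(f"cannot retain {k} edges: only {finite.sum()} finite weights")
    # stable sort on (-w, i, j): deterministic under ties
    order = np.lexsort((ju, iu, -np.where(finite, w, -np.inf)))
    keep = order[:k]
    if k < w.size and np.isclose(w[order[k - 1]], w[order[k]]):
        warnings.warn("tie at the threshold weight; broken lexicographically")
    a = np.zeros((n, n), dtype=np.int8)
    a[iu[keep], ju[keep]] = 1
    return BinaryGraph(a + a.T)


def _as_labels(partition, n: int) -> np.ndarray:
    labels = np.asarray(partition)
    if labels.shape != (n,):
        raise ValueError("partition must assign a label to every node")
    _, contiguous = np.unique(labels, return_inverse=True)
    return contiguous


def modularity(graph: BinaryGraph, partition) -> float:
    """Evaluate M for a given node->module assignment.

    The double sum runs over ordered pairs within each module including
    i = j (A_ii = 0, but the -a_i^2/(2e) null term is kept), so a partition
    into singletons is strictly negative on any graph with edges.
    """
    a = graph.adjacency.astype(float)
    deg = graph.degrees.astype(float)
    two_e = deg.sum()
    if two_e == 0:
        raise ValueError("graph has no edges")
    labels = _as_labels(partition, graph.n_nodes)
    m = 0.0
    for mod in np.unique(labels):
        idx = np.flatnonzero(labels == mod)
        m += a[np.ix_(idx, idx)].sum() - deg[idx].sum() ** 2 / two_e
    return float(m / two_e)


def _move_refine(a, deg, two_e, labels, rng) -> np.ndarray:
    """Repeatedly move single nodes to the best neighboring module (KL style)."""
    n = a.shape[0]
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            current = labels[i]
            # links from i to each module (plus one empty candidate module,
            # so the sweep can also split communities), and degree sums
            n_mod = labels.max() + 2
            links = np.bincount(labels, weights=a[i], minlength=n_mod)
            degsum = np.bincount(labels, weights=deg, minlength=n_mod)
            degsum[current] -= deg[i]
            links_self = links[current]
            # gain of moving i from `current` to module c
            gain = (links - links_self) / two_e * 2 - 2 * deg[i] * (degsum - degsum[current]) / two_e**2
            gain[current] = 0.0
            best = int(np.argmax(gain))
            if gain[best] > 1e-12:
                labels[i] = best
                _, labels = np.unique(labels, return_inverse=True)
                improved = True
    return labels


def _gains_for_node(a, deg, two_e, labels, i):
    """Modularity change for moving node i to every module (one empty extra)."""
    current = labels[i]
    n_mod = labels.max() + 2
    links = np.bincount(labels, weights=a[i], minlength=n_mod)
    degsum = np.bincount(labels, weights=deg, minlength=n_mod)
    degsum[current] -= deg[i]
    gain = (links - links[current]) / two_e * 2 \
        - 2 * deg[i] * (degsum - degsum[current]) / two_e**2
    gain[current] = 0.0
    return gain


def _kl_pass(a, deg, two_e, labels, rng):
    """One Kernighan-Lin pass: move every node once (best move each step,
    accepting temporary losses), then revert to the best prefix."""
    n = a.shape[0]
    work = labels.copy()
    locked = np.zeros(n, dtype=bool)
    history = []
    cumulative = 0.0
    for _ in range(n):
        best_gain, best_move = -np.inf, None
        for i in np.flatnonzero(~locked):
            gain = _gains_for_node(a, deg, two_e, work, i)
            c = int(np.argmax(gain))
            if gain[c] > best_gain:
                best_gain, best_move = gain[c], (i, c)
        i, c = best_move
        work[i] = c
        _, work = np.unique(work, return_inverse=True)
        locked[i] = True
        cumulative += best_gain
        history.append((cumulative, work.copy()))
    best_cum, best_state = max(history, key=lambda h: h[0])
    if best_cum > 1e-12:
        return best_state, True
    return labels, False


def _greedy_agglomerate(a, deg, two_e, labels, rng) -> np.ndarray:
    """Merge the community pair with the largest positive modularity gain."""
    while True:
        n_mod = labels.max() + 1
        if n_mod == 1:
            break
        onehot = np.equal.outer(np.arange(n_mod), labels).astype(float)
        e_cc = onehot @ a @ onehot.T          # inter-community edge weight sums
        degsum = onehot @ deg
        gain = 2 * e_cc / two_e - 2 * np.outer(degsum, degsum) / two_e**2
        np.fill_diagonal(gain, -np.inf)
        best = gain.max()
        if best <= 1e-12:
            break
        # random tie-break among maximal pairs
        cands = np.argwhere(gain >= best - 1e-15)
        r, c = cands[rng.integers(len(cands))]
        labels = labels.copy()
        labels[labels == max(r, c)] = min(r, c)
        _, labels = np.unique(labels, return_inverse=True)
    return labels


def optimize_partition(graph: BinaryGraph, *, seed: int = 0,
                       restarts: int = 20, density: float | None = None) -> ModularityResult:
    """Maximize modularity by greedy agglomeration with node-move refinement.

    Starts from singleton modules, merges the best community pair while any
    merge increases M, then refines with single-node moves; the
    merge/refine cycle repeats until neither step improves.  ``restarts``
    seeded random restarts (random tie-breaks and sweep orders) guard
    against local optima; isolated nodes end up as singleton modules.
    """
    if graph.n_edges < 1:
        raise ValueError("graph must have at least one edge")
    a = graph.adjacency.astype(float)
    deg = graph.degrees.astype(float)
    two_e = deg.sum()
    rng = np.random.default_rng(seed)

    n = graph.n_nodes
    best_labels, best_m = None, -np.inf
    for attempt in range(max(1, restarts)):
        if attempt == 0:
            labels = np.arange(n)
        else:
            # diversified restart: random partition at any granularity
            _, labels = np.unique(rng.integers(0, n, size=n), return_inverse=True)
        while True:
            labels = _greedy_agglomerate(a, deg, two_e, labels, rng)
            labels = _move_refine(a, deg, two_e, labels.copy(), rng)
            labels, improved = _kl_pass(a, deg, two_e, labels, rng)
            if not improved:
                break
        m = modularity(graph, labels)
        if m > best_m + 1e-12:
            best_m, best_labels = m, labels
    return ModularityResult(
        M=best_m,
        partition=_as_labels(best_labels, graph.n_nodes),
        density=density if density is not None else 2 * graph.n_edges / (graph.n_nodes * (graph.n_nodes - 1)),
        n_edges=graph.n_edges,
    )


def network_pipeline(values: np.ndarray, density: float, *, seed: int = 0,
                     ranking: str = "signed", restarts: int = 20) -> ModularityResult:
    """Full pipeline: per-run correlation -> average -> threshold -> optimize."""
    nets = connectivity_from_timeseries(values)
    mean_net = average_networks(nets)
    graph = threshold_binarize(mean_net, density, ranking=ranking)
    return optimize_partition(graph, seed=seed, restarts=restarts, density=density)
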