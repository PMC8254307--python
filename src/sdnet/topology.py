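"""Descriptive network statistics and reference random networks.

All operations act on a trimmed simple ``networkx.Graph`` (an
:class:`sdnet.network.SDNetwork` passes its ``.graph``).  The component
spectrum — the multiset of connected-component sizes together with their
edge counts — is the central summary reused by the growth-model loss, the
ABC rejection step and the cross-species comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "ComponentSpectrum",
    "BinnedDensity",
    "GCStats",
    "component_spectrum",
    "log_binned_density",
    "fit_loglog_slope",
    "component_size_slope",
    "giant_component_stats",
    "reference_network",
    "detect_modules",
    "edge_class_fractions",
    "plot_component_spectrum",
]


def _as_graph(network) -> nx.Graph:
    return network.graph if hasattr(network, "graph") and isinstance(
        getattr(network, "graph"), nx.Graph) else network


# ---------------------------------------------------------------------------
# component spectrum
# ---------------------------------------------------------------------------

@dataclass
class ComponentSpectrum:
    """Connected-component decomposition: per-component node and edge counts.

    A component with N nodes and E edges is denoted C(N, E).
    """

    sizes: np.ndarray        # node count N per component
    edge_counts: np.ndarray  # edge count E per component

    def __post_init__(self):
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.edge_counts = np.asarray(self.edge_counts, dtype=int)

    @property
    def n_components(self) -> int:
        return len(self.sizes)

    @property
    def n_nodes(self) -> int:
        return int(self.sizes.sum())

    @property
    def n_edges(self) -> int:
        return int(self.edge_counts.sum())

    def size_histogram(self) -> dict:
        sizes, counts = np.unique(self.sizes, return_counts=True)
        return dict(zip(sizes.tolist(), counts.tolist()))

    def mean_edges_by_size(self, include_largest=True) -> dict:
        """E̅(N): average edge count over components of each size."""
        sizes, edges = self.sizes, self.edge_counts
        if not include_largest and len(sizes) > 1:
            drop = int(np.argmax(sizes))
            keep = np.ones(len(sizes), dtype=bool)
            keep[drop] = False
            sizes, edges = sizes[keep], edges[keep]
        out = {}
        for n in np.unique(sizes):
            out[int(n)] = float(edges[sizes == n].mean())
        return out

    def sorted_sizes(self, descending=True) -> np.ndarray:
        return np.sort(self.sizes)[::-1] if descending else np.sort(self.sizes)

    def motif_label_counts(self) -> dict:
        """Counts of C(N, E) labels, e.g. {(2, 1): 13, (3, 3): 2, ...}."""
        out = {}
        for n, e in zip(self.sizes.tolist(), self.edge_counts.tolist()):
            out[(n, e)] = out.get((n, e), 0) + 1
        return out


def component_spectrum(network) -> ComponentSpectrum:
    """Exact connected-component decomposition with per-component (N, E)."""
    g = _as_graph(network)
    sizes, edges = [], []
    for comp in nx.connected_components(g):
        sizes.append(len(comp))
        edges.append(g.subgraph(comp).number_of_edges())
    return ComponentSpectrum(np.array(sizes, dtype=int),
                             np.array(edges, dtype=int))


# ---------------------------------------------------------------------------
# log binning and slope fits
# ---------------------------------------------------------------------------

@dataclass
class BinnedDensity:
    """Logarithmically binned density: per bin i, n_i / (N * b_i), where n_i
    is the bin count, N the total number of observations and b_i the bin
    width (growing geometrically)."""

    edges: np.ndarray
    counts: np.ndarray
    density: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    def nonempty(self):
        mask = self.counts > 0
        return self.centers[mask], self.density[mask]


def log_binned_density(values, bins_per_decade=8) -> BinnedDensity:
    """Histogram on geometric bins; density n_i/(N b_i) damps the shot noise
    of heavy tails on log-log plots."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("no values to bin")
    if np.any(values < 1):
        raise ValueError("log binning requires values >= 1")
    lo = 1.0
    hi = values.max()
    n_bins = max(1, int(math.ceil(math.log10(hi / lo) * bins_per_decade)))
    # extend the last edge slightly so the maximum falls inside
    edges = lo * (10.0 ** (np.arange(n_bins + 1) / bins_per_decade))
    edges[-1] = max(edges[-1], hi * (1 + 1e-9))
    counts, _ = np.histogram(values, bins=edges)
    widths = np.diff(edges)
    density = counts / (len(values) * widths)
    return BinnedDensity(edges=edges, counts=counts, density=density)


def fit_loglog_slope(x, y, weights=None):
    """Ordinary (or weighted) least squares of log(y) on log(x).

    Returns ``(slope, intercept, stderr)`` where the intercept is in log10
    units and the slope is the power-law exponent.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("x and y must be positive")
    lx, ly = np.log10(x), np.log10(y)
    if np.allclose(lx, lx[0]):
        raise ValueError("degenerate x values (all equal)")
    if weights is None:
        from scipy import stats
        res = stats.linregress(lx, ly)
        return float(res.slope), float(res.intercept), float(res.stderr)
    w = np.asarray(weights, dtype=float)
    W = np.diag(w)
    X = np.column_stack([lx, np.ones_like(lx)])
    beta, *_ = np.linalg.lstsq(np.sqrt(W) @ X, np.sqrt(w) * ly, rcond=None)
    resid = ly - X @ beta
    dof = max(len(x) - 2, 1)
    s2 = float(w @ resid**2) / dof
    cov = s2 * np.linalg.inv(X.T @ W @ X)
    return float(beta[0]), float(beta[1]), float(math.sqrt(cov[0, 0]))


def component_size_slope(sizes, bins_per_decade=8, size_range=(2.0, None),
                         exclude_largest=0):
    """Power-law exponent of the component-size distribution p(N).

    Log-bins the sizes and fits a line to the nonempty bins on a log-log
    scale.  ``size_range`` restricts the fit to the power-law bulk (the
    giant component shows up as a detached peak and is excluded either via
    the upper bound or with ``exclude_largest`` components dropped).
    """
    sizes = np.sort(np.asarray(sizes, dtype=float))
    if exclude_largest:
        sizes = sizes[:len(sizes) - exclude_largest]
    dens = log_binned_density(sizes, bins_per_decade=bins_per_decade)
    x, y = dens.nonempty()
    lo, hi = size_range
    mask = np.ones(len(x), dtype=bool)
    if lo is not None:
        mask &= x >= lo
    if hi is not None:
        mask &= x <= hi
    slope, intercept, stderr = fit_loglog_slope(x[mask], y[mask])
    return slope, stderr


# ---------------------------------------------------------------------------
# giant component
# ---------------------------------------------------------------------------

@dataclass
class GCStats:
    clustering: float
    path_length: float
    n_nodes: int
    n_edges: int


def giant_component_stats(network) -> GCStats:
    """Mean clustering coefficient and exact average shortest path length of
    the largest connected component.

    The per-node clustering coefficient of a node with degree < 2 is defined
    as 0 and included in the mean.  The path length is the mean over all
    unordered node pairs of the BFS shortest-path length (computed in C via
    igraph; exact, no sampling).
    """
    g = _as_graph(network)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    gc_nodes = max(nx.connected_components(g), key=len)
    gc = g.subgraph(gc_nodes)
    cbar = float(np.mean(list(nx.clustering(gc).values())))
    if gc.number_of_nodes() < 2:
        path_len = 0.0
    else:
        import igraph as ig
        idx = {n: i for i, n in enumerate(gc.nodes())}
        h = ig.Graph(n=len(idx),
                     edges=[(idx[u], idx[v]) for u, v in gc.edges()])
        path_len = float(h.average_path_length(directed=False))
    return GCStats(clustering=cbar, path_length=path_len,
                   n_nodes=gc.number_of_nodes(), n_edges=gc.number_of_edges())


# ---------------------------------------------------------------------------
# reference random networks
# ---------------------------------------------------------------------------

def reference_network(kind, params, seed=None) -> nx.Graph:
    """Random comparison networks.

    ``er`` — G(n, m), a uniform random graph with exactly n nodes and m
    edges; ``ba`` — Barabási–Albert preferential attachment adding k edges
    per new node; ``config`` — configuration model realising a degree
    sequence, with self-loops and parallel edges erased.
    """
    if kind == "er":
        n, m = params
        return nx.gnm_random_graph(int(n), int(m), seed=seed)
    if kind == "ba":
        n, k = params
        return nx.barabasi_albert_graph(int(n), int(k), seed=seed)
    if kind == "config":
        degree_sequence = [int(d) for d in params]
        if sum(degree_sequence) % 2 != 0:
            raise ValueError("infeasible degree sequence (odd sum)")
        multi = nx.configuration_model(degree_sequence, seed=seed)
        g = nx.Graph(multi)
        g.remove_edges_from(nx.selfloop_edges(g))
        return g
    raise ValueError(f"unknown reference network kind: {kind!r}")


# ---------------------------------------------------------------------------
# modules and edge classes
# ---------------------------------------------------------------------------

def plot_component_spectrum(spectrum, bins_per_decade=8, ax=None):
    """Log-log component-size distribution with logarithmic binning."""
    import matplotlib
    if ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    dens = log_binned_density(spectrum.sizes,
                              bins_per_decade=bins_per_decade)
    x, y = dens.nonempty()
    ax.loglog(x, y, "o")
    ax.set_xlabel("component size N")
    ax.set_ylabel("density p(N)")
    return ax


def detect_modules(network, seed=None) -> dict:
    """Asynchronous label propagation; returns node → module label."""
    g = _as_graph(network)
    labels = {}
    for module_id, nodes in enumerate(
            nx.algorithms.community.asyn_lpa_communities(g, seed=seed)):
        for node in nodes:
            labels[node] = module_id
    return labels


def edge_class_fractions(network, tandem_dist=500_000):
    """Fractions of intrachromosomal and tandem edges.

    An edge is intrachromosomal when both regions lie on one chromosome and
    tandem when, in addition, the gap between the nearest region boundaries
    is < ``tandem_dist`` bp.
    """
    g = _as_graph(network)
    n_edges = g.number_of_edges()
    if n_edges == 0:
        return 0.0, 0.0
    intra = tandem = 0
    for u, v in g.edges():
        try:
            cu, cv = g.nodes[u]["chrom"], g.nodes[v]["chrom"]
            su, eu = g.nodes[u]["start"], g.nodes[u]["end"]
            sv, ev = g.nodes[v]["start"], g.nodes[v]["end"]
        except KeyError as exc:
            raise ValueError(f"edge ({u}, {v}) lacks coordinates") from exc
        if cu != cv:
            continue
        intra += 1
        gap = max(su, sv) - min(eu, ev)
        if gap < tandem_dist:
            tandem += 1
    return intra / n_edges, tandem / n_edges
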