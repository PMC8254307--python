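"""Kinetic Monte Carlo simulation of SD-network growth.

Two copying models grow a network from nothing:

* process 1 — a new two-node component C(2,1) is added with rate π
  (a fresh duplication that overlaps nothing that came before);
* process 2 — an existing "mother" node i is duplicated with rate δ_i;
  the "daughter" always gains the mother–daughter edge and inherits each
  mother–neighbor edge independently with probability f.

The Uniform Copying Model (UCM) uses δ_i = δ; the Preferential Copying
Model (PCM) uses δ_i = δ·k_i with k_i the current node degree, so regions
with many copies duplicate proportionally more often.  Events are drawn by
exact kinetic Monte Carlo: event i is chosen with probability r_i/Σr and
the waiting time is Δt = −ln(u)/Σr with u ~ Uniform(0, 1].  Only the ratio
δ/π matters, so π = 1 throughout.  Growth stops when the node count
reaches a target.  Optionally every edge is removed with probability r
after each event (an edge-loss robustness knob).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .topology import ComponentSpectrum, component_spectrum

__all__ = [
    "GrowthModelParams",
    "EventLog",
    "PooledResult",
    "rates_vector",
    "kmc_draw",
    "duplicate_node",
    "apply_edge_loss",
    "simulate_growth",
    "pool_simulations",
]


@dataclass(frozen=True)
class GrowthModelParams:
    """Parameters of a copying-model simulation.

    ``delta`` is the per-node duplication rate scale (per unit of the
    component-addition rate π, which is fixed at 1); ``f`` is the
    edge-inheritance probability; ``edge_loss_r`` removes each edge with
    that probability after every event; growth stops at ``target_nodes``.
    """

    model: str = "pcm"
    delta: float = 5.1e-4
    f: float = 0.47
    pi: float = 1.0
    edge_loss_r: float = 0.0
    target_nodes: int = 6656
    seed: int | None = None

    def __post_init__(self):
        if self.model not in ("ucm", "pcm"):
            raise ValueError(f"unknown model: {self.model!r}")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must lie in [0, 1]")
        if not 0.0 <= self.edge_loss_r < 1.0:
            raise ValueError("edge_loss_r must lie in [0, 1)")
        if self.target_nodes < 2:
            raise ValueError("target_nodes must be >= 2")


@dataclass
class EventLog:
    """Ordered record of simulated events.

    ``events`` rows are ``(time, type, mother, daughter, inherited)`` where
    type is "add" (mother is None, daughter the tuple of the two new node
    ids, inherited the single new edge) or "duplicate" (inherited lists the
    daughter's edges, always including the mother–daughter edge).
    """

    events: list = field(default_factory=list)
    total_time: float = 0.0

    def append(self, time, etype, mother, daughter, inherited):
        self.events.append((time, etype, mother, daughter, tuple(inherited)))
        self.total_time = time

    @property
    def n_additions(self) -> int:
        return sum(1 for e in self.events if e[1] == "add")

    @property
    def n_duplications(self) -> int:
        return sum(1 for e in self.events if e[1] == "duplicate")


# ---------------------------------------------------------------------------
# elementary moves
# ---------------------------------------------------------------------------

def rates_vector(network, params: GrowthModelParams) -> np.ndarray:
    """Rate of every possible process: element 0 is π (component addition),
    element i ≥ 1 is the duplication rate of the i-th node of the graph
    (δ for the UCM, δ·k_i for the PCM), in ``list(network.nodes())`` order.
    """
    g = network
    n = g.number_of_nodes()
    rates = np.empty(n + 1)
    rates[0] = params.pi
    if params.model == "ucm":
        rates[1:] = params.delta
    else:
        rates[1:] = params.delta * np.fromiter(
            (g.degree[v] for v in g.nodes()), dtype=float, count=n)
    return rates


def kmc_draw(rates, rng):
    """Pick an event index with probability r_i/Σr and draw the exponential
    waiting time Δt = −ln(u)/Σr, u ~ Uniform(0, 1]."""
    rates = np.asarray(rates, dtype=float)
    total = rates.sum()
    if total <= 0:
        raise ValueError("all rates are zero")
    cum = np.cumsum(rates)
    idx = int(np.searchsorted(cum, rng.random() * total, side="right"))
    idx = min(idx, len(rates) - 1)
    u = 1.0 - rng.random()  # uniform on (0, 1]
    dt = -np.log(u) / total
    return idx, dt


def duplicate_node(network, mother, f, rng):
    """Duplicate ``mother``: the daughter gets the mother–daughter edge plus
    each mother neighbor independently with probability f.  Returns the
    daughter id (max node id + 1)."""
    g = network
    daughter = (max(g.nodes()) + 1) if g.number_of_nodes() else 0
    neighbors = list(g.neighbors(mother))
    g.add_node(daughter)
    g.add_edge(mother, daughter)
    if neighbors and f > 0:
        keep = rng.random(len(neighbors)) < f
        for nbr, k in zip(neighbors, keep):
            if k:
                g.add_edge(daughter, nbr)
    return daughter


def apply_edge_loss(network, r, rng):
    """Remove each current edge independently with probability r; isolated
    nodes are retained.  Returns the list of removed edges."""
    if not 0.0 <= r < 1.0:
        raise ValueError("r must lie in [0, 1)")
    if r == 0.0:
        return []
    edges = list(network.edges())
    if not edges:
        return []
    drop = rng.random(len(edges)) < r
    removed = [e for e, d in zip(edges, drop) if d]
    network.remove_edges_from(removed)
    return removed


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

def simulate_growth(params: GrowthModelParams, rng=None):
    """Grow a network by kinetic Monte Carlo until ``target_nodes`` nodes.

    Returns ``(graph, event_log)``.  Node ids are consecutive integers in
    order of appearance.  Degrees (hence PCM rates) are maintained
    incrementally and agree exactly with :func:`rates_vector` recomputed
    from scratch.  Identical parameters and seed give an identical log.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    g = nx.Graph()
    log = EventLog()
    pcm = params.model == "pcm"
    delta, pi, f, r = params.delta, params.pi, params.f, params.edge_loss_r

    # incremental degree bookkeeping (node i at index i)
    capacity = params.target_nodes + 2
    degs = np.zeros(capacity, dtype=float)
    n = 0
    t = 0.0

    while n < params.target_nodes:
        rates = np.empty(n + 1)
        rates[0] = pi
        if n:
            rates[1:] = delta * degs[:n] if pcm else delta
        total = rates.sum()
        cum = np.cumsum(rates)
        idx = int(np.searchsorted(cum, rng.random() * total, side="right"))
        idx = min(idx, n)
        t += -np.log(1.0 - rng.random()) / total

        if idx == 0:
            a, b = n, n + 1
            g.add_edge(a, b)
            degs[a] = degs[b] = 1.0
            n += 2
            log.append(t, "add", None, (a, b), [(a, b)])
        else:
            mother = idx - 1
            daughter = n
            neighbors = list(g.neighbors(mother))
            g.add_node(daughter)
            g.add_edge(mother, daughter)
            inherited = [(mother, daughter)]
            degs[mother] += 1
            degs[daughter] = 1.0
            if neighbors and f > 0:
                keep = rng.random(len(neighbors)) < f
                for nbr, k in zip(neighbors, keep):
                    if k:
                        g.add_edge(daughter, nbr)
                        degs[nbr] += 1
                        degs[daughter] += 1
                        inherited.append((nbr, daughter))
            n += 1
            log.append(t, "duplicate", mother, daughter, inherited)

        if r > 0.0:
            removed = apply_edge_loss(g, r, rng)
            for u, v in removed:
                degs[u] -= 1
                degs[v] -= 1

    return g, log


@dataclass
class PooledResult:
    """Aggregate of replicate simulations: concatenated component spectra,
    pooled node degrees and per-replicate largest-component sizes."""

    spectrum: ComponentSpectrum
    degrees: np.ndarray
    largest_component_sizes: np.ndarray
    n_reps: int

    def degree_histogram(self) -> dict:
        vals, counts = np.unique(self.degrees, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def pool_simulations(params: GrowthModelParams, n_reps=500) -> PooledResult:
    """Run ``n_reps`` independent simulations (seeds spawned from
    ``params.seed``) and aggregate their networks, as if they were one big
    pooled network."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seeds = np.random.SeedSequence(params.seed).spawn(n_reps)
    sizes, edges, degrees, largest = [], [], [], []
    for child in seeds:
        g, _ = simulate_growth(params, rng=np.random.default_rng(child))
        spec = component_spectrum(g)
        sizes.append(spec.sizes)
        edges.append(spec.edge_counts)
        degrees.append(np.array([d for _, d in g.degree()], dtype=int))
        largest.append(int(spec.sizes.max()))
    return PooledResult(
        spectrum=ComponentSpectrum(np.concatenate(sizes),
                                   np.concatenate(edges)),
        degrees=np.concatenate(degrees),
        largest_component_sizes=np.array(largest, dtype=int),
        n_reps=n_reps,
    )
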