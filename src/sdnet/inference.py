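"""Inference of the preferential-copying-model parameters (f, δ, t).

Three independent routes:

1. **Regression** — in the PCM the average number of edges in a component
   of N nodes grows as E ∝ N^(1+f) for large N, so the slope of
   log E̅(N) vs log N minus one estimates f.
2. **ABC rejection** — δ is inferred by simulating the PCM over a uniform
   prior and accepting draws whose sorted top component-size vector is
   within a Bray–Curtis tolerance of the observed one.
3. **ODE loss fit** — the expected counts of the small motifs C(2,1),
   C(3,2), C(3,3) and C(>3,∗) follow a linear ODE system with closed-form
   solution; Nelder–Mead minimisation of a weighted city-block distance
   between expected and observed counts yields (f, δ, t) jointly.

A fourth helper places the observed giant component within the simulated
distribution of largest components (empirical p-value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import braycurtis as _braycurtis

from .growth import GrowthModelParams, simulate_growth
from .topology import component_spectrum, fit_loglog_slope

__all__ = [
    "MotifCounts",
    "ABCResult",
    "FitResult",
    "motif_counts",
    "estimate_f_regression",
    "ode_motif_counts",
    "loss_L",
    "minimize_loss",
    "bray_curtis",
    "spectrum_vector",
    "abc_delta",
    "giant_component_pvalue",
]


# ---------------------------------------------------------------------------
# motif counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifCounts:
    """Counts of the small-component motifs C(2,1), C(3,2), C(3,3) and of
    all components with more than three nodes, C(>3,∗).  Observed counts
    are integers; ODE-expected counts are real-valued."""

    n21: float
    n32: float
    n33: float
    n_gt3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.n21, self.n32, self.n33, self.n_gt3],
                        dtype=float)


def motif_counts(network) -> MotifCounts:
    """Exact motif counts of a trimmed simple graph (or spectrum)."""
    from .topology import ComponentSpectrum
    spec = network if isinstance(network, ComponentSpectrum) \
        else component_spectrum(network)
    n21 = n32 = n33 = n_gt3 = 0
    for n, e in zip(spec.sizes, spec.edge_counts):
        if n == 2:
            n21 += 1
        elif n == 3 and e == 2:
            n32 += 1
        elif n == 3 and e == 3:
            n33 += 1
        elif n > 3:
            n_gt3 += 1
    return MotifCounts(n21, n32, n33, n_gt3)


# ---------------------------------------------------------------------------
# f from the E(N) power law
# ---------------------------------------------------------------------------

def estimate_f_regression(mean_edges_by_size):
    """f̂ = slope of log E̅(N) ~ log N minus 1.

    ``mean_edges_by_size`` is a mapping N → E̅(N) (one point per observed
    component size, as produced by
    :meth:`sdnet.topology.ComponentSpectrum.mean_edges_by_size`).
    Returns ``(f_hat, stderr)``.
    """
    if isinstance(mean_edges_by_size, dict):
        items = sorted(mean_edges_by_size.items())
        x = np.array([n for n, _ in items], dtype=float)
        y = np.array([e for _, e in items], dtype=float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in mean_edges_by_size)
    slope, _, stderr = fit_loglog_slope(x, y)
    return slope - 1.0, stderr


# ---------------------------------------------------------------------------
# motif ODE system
# ---------------------------------------------------------------------------

def ode_motif_counts(f, delta, t) -> MotifCounts:
    """Expected motif counts at time t under the PCM.

    The expected counts obey (with π = 1)

        dn(2,1)/dt  = 1 − 2δ n(2,1)
        dn(3,2)/dt  = 2δ(1−f) n(2,1) − 4δ n(3,2)
        dn(3,3)/dt  = 2δ f n(2,1) − 6δ n(3,3)
        dn(>3,∗)/dt = 4δ n(3,2) + 6δ n(3,3)

    whose solution from empty initial conditions is evaluated in closed
    form.  Note the count of components larger than three nodes grows
    linearly in t once the small motifs saturate.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if t < 0:
        raise ValueError("t must be >= 0")
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must lie in [0, 1]")
    e2 = np.exp(-2.0 * delta * t)
    e4 = np.exp(-4.0 * delta * t)
    e6 = np.exp(-6.0 * delta * t)
    n21 = (1.0 - e2) / (2.0 * delta)
    n32 = (1.0 - f) * (1.0 - 2.0 * e2 + e4) / (4.0 * delta)
    n33 = f * (1.0 - 1.5 * e2 + 0.5 * e6) / (6.0 * delta)
    n_gt3 = t + (f - 9.0 + 3.0 * (4.0 - f) * e2
                 - 3.0 * (1.0 - f) * e4 - f * e6) / (12.0 * delta)
    return MotifCounts(n21, n32, n33, n_gt3)


def loss_L(n_t: MotifCounts, n_sd: MotifCounts) -> float:
    """Weighted city-block distance L = Σ_i |n_t,i − n_sd,i| / n_sd,i over
    the four motif classes."""
    expected = n_t.as_array()
    observed = n_sd.as_array()
    if np.any(observed <= 0):
        raise ValueError("all observed motif counts must be positive")
    return float(np.sum(np.abs(expected - observed) / observed))


@dataclass
class FitResult:
    f: float
    delta: float
    t: float
    loss: float
    converged: bool


def _unpack(theta):
    logit_f, log_delta, log_t = theta
    f = 1.0 / (1.0 + np.exp(-logit_f))
    return f, np.exp(log_delta), np.exp(log_t)


def minimize_loss(n_sd: MotifCounts, n_restarts=5, seed=0,
                  x0=(0.5, 1e-3 * np.exp(-1.0), 1e3)) -> FitResult:
    """Nelder–Mead minimisation of :func:`loss_L` over (f, δ, t).

    The search runs in transformed coordinates (logit f, log δ, log t) so
    the box constraints hold implicitly.  ``n_restarts`` jittered restarts
    around the default start are attempted and the best minimum kept.
    """
    rng = np.random.default_rng(seed)
    f0, d0, t0 = x0
    base = np.array([np.log(f0 / (1.0 - f0)), np.log(d0), np.log(t0)])

    def objective(theta):
        f, delta, t = _unpack(theta)
        return loss_L(ode_motif_counts(f, delta, t), n_sd)

    best = None
    for i in range(max(1, n_restarts)):
        start = base if i == 0 else base + rng.normal(scale=0.5, size=3)
        res = minimize(objective, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    f, delta, t = _unpack(best.x)
    return FitResult(f=float(f), delta=float(delta), t=float(t),
                     loss=float(best.fun), converged=bool(best.success))


# ---------------------------------------------------------------------------
# ABC rejection for delta
# ---------------------------------------------------------------------------

def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity Σ|x_i − y_i| / Σ(x_i + y_i) ∈ [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("vectors must be nonnegative")
    if x.sum() + y.sum() == 0:
        raise ValueError("both vectors are all-zero")
    return float(_braycurtis(x, y))


def spectrum_vector(sizes, top_n=500) -> np.ndarray:
    """Sorted-descending component-size vector of fixed length ``top_n``
    (zero-padded; simulations stop on node count, so the component count is
    not guaranteed)."""
    sizes = np.sort(np.asarray(sizes, dtype=float))[::-1]
    out = np.zeros(top_n)
    k = min(top_n, len(sizes))
    out[:k] = sizes[:k]
    return out


@dataclass
class ABCResult:
    accepted: np.ndarray       # accepted δ draws
    point_estimate: float      # posterior mean
    interval: tuple            # central 95% credible interval
    tolerance: float
    n_sims: int
    prior: tuple
    acceptance_rate: float


def abc_delta(observed_sizes, f=0.47, prior=(5e-5, 9e-4), n_sims=5000,
              tolerance=0.2, top_n=500, target_nodes=6656,
              seed=None) -> ABCResult:
    """Rejection-ABC posterior for δ at fixed f.

    Draw δ ~ Uniform(prior), simulate the PCM to ``target_nodes`` nodes and
    accept the draw when the Bray–Curtis dissimilarity between the sorted
    top-``top_n`` component-size vectors of simulation and observation is
    below ``tolerance``.  The point estimate is the posterior mean; the
    interval the 2.5/97.5 posterior percentiles.
    """
    lo, hi = prior
    if not (0 < lo < hi):
        raise ValueError("prior interval must be positive and ordered")
    observed_vec = spectrum_vector(observed_sizes, top_n=top_n)
    rng = np.random.default_rng(seed)
    accepted = []
    for _ in range(n_sims):
        delta = rng.uniform(lo, hi)
        params = GrowthModelParams(model="pcm", delta=delta, f=f,
                                   target_nodes=target_nodes)
        g, _ = simulate_growth(params, rng=rng)
        sim_vec = spectrum_vector(component_spectrum(g).sizes, top_n=top_n)
        if bray_curtis(sim_vec, observed_vec) < tolerance:
            accepted.append(delta)
    if not accepted:
        raise RuntimeError(
            "ABC accepted no simulations; increase the tolerance or widen "
            "the prior")
    accepted = np.array(accepted)
    return ABCResult(
        accepted=accepted,
        point_estimate=float(accepted.mean()),
        interval=(float(np.percentile(accepted, 2.5)),
                  float(np.percentile(accepted, 97.5))),
        tolerance=tolerance,
        n_sims=n_sims,
        prior=tuple(prior),
        acceptance_rate=len(accepted) / n_sims,
    )


# ---------------------------------------------------------------------------
# giant-component placement
# ---------------------------------------------------------------------------

def giant_component_pvalue(observed, simulated, two_sided=True) -> float:
    """Empirical p-value of the observed giant-component size within the
    simulated distribution of largest-component sizes.

    Two-sided (default): p = 2·min(F̂(x), 1−F̂(x⁻)) capped at 1, where F̂ is
    the empirical CDF.  One-sided: upper-tail probability.
    """
    simulated = np.asarray(simulated, dtype=float)
    if len(simulated) < 100:
        warnings.warn("fewer than 100 simulated values; the empirical "
                      "p-value has low resolution")
    n = len(simulated)
    le = float(np.sum(simulated <= observed)) / n   # F̂(x)
    ge = float(np.sum(simulated >= observed)) / n   # 1 − F̂(x⁻)
    if not two_sided:
        return ge
    return min(1.0, 2.0 * min(le, ge))
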