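"""Motif ODEs, loss minimisation, Bray-Curtis, ABC and the GC p-value."""

import networkx as nx
import numpy as np
import pytest
from scipy.integrate import solve_ivp

from sdnet import (
    GrowthModelParams,
    MotifCounts,
    abc_delta,
    bray_curtis,
    component_spectrum,
    estimate_f_regression,
    giant_component_pvalue,
    loss_L,
    minimize_loss,
    motif_counts,
    ode_motif_counts,
    simulate_growth,
    spectrum_vector,
)


# ---------------------------------------------------------------------------
# motif counts
# ---------------------------------------------------------------------------

def test_motif_counts_basic():
    g = nx.disjoint_union_all([nx.path_graph(3), nx.complete_graph(3)])
    mc = motif_counts(g)
    assert (mc.n21, mc.n32, mc.n33, mc.n_gt3) == (0, 1, 1, 0)


def test_motif_counts_mixture():
    g = nx.disjoint_union_all([nx.path_graph(2)] * 3 + [nx.complete_graph(4)])
    mc = motif_counts(g)
    assert mc.as_array().tolist() == [3, 0, 0, 1]


# ---------------------------------------------------------------------------
# ODE closed forms
# ---------------------------------------------------------------------------

def _rhs(t, y, f, delta):
    n21, n32, n33, ngt3 = y
    return [1 - 2 * delta * n21,
            2 * delta * (1 - f) * n21 - 4 * delta * n32,
            2 * delta * f * n21 - 6 * delta * n33,
            4 * delta * n32 + 6 * delta * n33]


@pytest.mark.parametrize("f,delta,t", [
    (0.47, 5.1e-4, 1320.0),
    (0.2, 1e-3, 400.0),
    (0.8, 2e-4, 5000.0),
    (0.5, 5e-3, 100.0),
])
def test_closed_forms_match_numerical_integration(f, delta, t):
    sol = solve_ivp(_rhs, (0, t), [0.0] * 4, args=(f, delta),
                    rtol=1e-11, atol=1e-12, dense_output=True)
    expected = sol.y[:, -1]
    got = ode_motif_counts(f, delta, t).as_array()
    assert np.allclose(got, expected, rtol=1e-8)


def test_closed_forms_at_zero():
    assert np.allclose(ode_motif_counts(0.4, 1e-3, 0.0).as_array(), 0.0)


def test_closed_forms_small_motif_saturation():
    f, delta = 0.3, 1e-3
    mc = ode_motif_counts(f, delta, 1e7)
    assert mc.n21 == pytest.approx(1 / (2 * delta), rel=1e-6)
    assert mc.n32 == pytest.approx((1 - f) / (4 * delta), rel=1e-6)
    assert mc.n33 == pytest.approx(f / (6 * delta), rel=1e-6)


def test_closed_forms_ode_residual_grid():
    # finite-difference residual of the printed ODE system
    h = 1e-4
    for f in (0.1, 0.5, 0.9):
        for delta in (1e-4, 1e-3):
            for t in (100.0, 1000.0, 5000.0):
                y = ode_motif_counts(f, delta, t).as_array()
                yp = ode_motif_counts(f, delta, t + h).as_array()
                ym = ode_motif_counts(f, delta, t - h).as_array()
                deriv = (yp - ym) / (2 * h)
                rhs = np.array(_rhs(t, y, f, delta))
                assert np.allclose(deriv, rhs, atol=1e-6)


def test_ode_rejects_bad_delta():
    with pytest.raises(ValueError):
        ode_motif_counts(0.5, 0.0, 10.0)


# ---------------------------------------------------------------------------
# loss and minimisation
# ---------------------------------------------------------------------------

def test_loss_zero_at_equality():
    mc = MotifCounts(10, 5, 3, 2)
    assert loss_L(mc, mc) == 0.0


def test_loss_hand_value():
    n_t = MotifCounts(2, 1, 1, 1)
    n_sd = MotifCounts(1, 1, 2, 2)
    assert loss_L(n_t, n_sd) == pytest.approx(1 / 1 + 0 + 1 / 2 + 1 / 2)


def test_loss_rejects_zero_observed():
    with pytest.raises(ValueError):
        loss_L(MotifCounts(1, 1, 1, 1), MotifCounts(1, 0, 1, 1))


def test_minimize_recovers_planted_parameters():
    truth = (0.5, 4e-4, 1000.0)
    n_sd = ode_motif_counts(*truth)
    fit = minimize_loss(n_sd, seed=1)
    assert fit.loss < 1e-6
    assert fit.f == pytest.approx(truth[0], rel=0.01)
    assert fit.delta == pytest.approx(truth[1], rel=0.01)
    assert fit.t == pytest.approx(truth[2], rel=0.01)


def test_minimize_restart_stability():
    n_sd = ode_motif_counts(0.35, 6e-4, 800.0)
    fits = [minimize_loss(n_sd, seed=s) for s in range(3)]
    fs = [fit.f for fit in fits]
    assert max(fs) - min(fs) < 1e-3


# ---------------------------------------------------------------------------
# f regression
# ---------------------------------------------------------------------------

def test_f_regression_exact_powerlaw():
    sizes = np.array([2.0, 3, 5, 10, 50, 200])
    f_hat, _ = estimate_f_regression(dict(zip(sizes, sizes ** 1.5)))
    assert f_hat == pytest.approx(0.5, abs=1e-12)


def test_f_regression_needs_enough_points():
    with pytest.raises(ValueError):
        estimate_f_regression({2: 1.0, 3: 2.0})


# ---------------------------------------------------------------------------
# Bray-Curtis and spectrum vectors
# ---------------------------------------------------------------------------

def test_bray_curtis_identity_and_hand_values():
    assert bray_curtis([3, 2, 1], [3, 2, 1]) == 0.0
    assert bray_curtis([3, 2, 1], [1, 2, 3]) == pytest.approx(1 / 3)
    assert bray_curtis([1, 0], [0, 1]) == 1.0


def test_bray_curtis_symmetry_and_bounds(rng):
    for _ in range(20):
        x = rng.integers(0, 50, size=10)
        y = rng.integers(0, 50, size=10)
        if x.sum() + y.sum() == 0:
            continue
        d = bray_curtis(x, y)
        assert d == bray_curtis(y, x)
        assert 0.0 <= d <= 1.0
        if not np.array_equal(x, y):
            assert (d == 0.0) == np.array_equal(x, y)


def test_bray_curtis_length_mismatch():
    with pytest.raises(ValueError):
        bray_curtis([1, 2], [1, 2, 3])


def test_spectrum_vector_pads_and_sorts():
    v = spectrum_vector([3, 7, 2], top_n=5)
    assert v.tolist() == [7, 3, 2, 0, 0]
    assert spectrum_vector([5] * 10, top_n=3).tolist() == [5, 5, 5]


# ---------------------------------------------------------------------------
# ABC
# ---------------------------------------------------------------------------

def test_abc_tolerance_one_returns_prior():
    g, _ = simulate_growth(GrowthModelParams(
        model="pcm", delta=3e-4, f=0.47, target_nodes=400, seed=1))
    obs = component_spectrum(g).sizes
    res = abc_delta(obs, f=0.47, prior=(1e-4, 9e-4), n_sims=300,
                    tolerance=1.0, top_n=100, target_nodes=400, seed=2)
    assert res.acceptance_rate == 1.0
    assert res.point_estimate == pytest.approx(5e-4, rel=0.1)
    lo, hi = res.interval
    assert lo < res.point_estimate < hi


def test_abc_zero_acceptance_raises():
    with pytest.raises(RuntimeError, match="tolerance"):
        abc_delta(np.array([1000]), f=0.47, prior=(1e-4, 2e-4), n_sims=5,
                  tolerance=1e-9, top_n=50, target_nodes=100, seed=3)


# ---------------------------------------------------------------------------
# GC p-value
# ---------------------------------------------------------------------------

def test_pvalue_at_median_is_one(rng):
    sims = rng.normal(1000, 100, size=501)
    assert giant_component_pvalue(np.median(sims), sims) == pytest.approx(
        1.0, abs=0.01)


def test_pvalue_beyond_maximum(rng):
    sims = rng.normal(1000, 100, size=500)
    p = giant_component_pvalue(sims.max() + 1000, sims)
    assert p <= 2 / 500
    assert giant_component_pvalue(sims.max() + 1000, sims,
                                  two_sided=False) == 0.0
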