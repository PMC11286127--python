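"""Tests for the continuum solvers, parameter maps and closed-form oracles."""
import math

import numpy as np
import pytest

import cellfronts as cf
from cellfronts.response import constant_response


GRID = cf.Grid1D(300.0, 300)


# ---------------------------------------------------------------------------
# parameter maps
# ---------------------------------------------------------------------------

def test_discrete_to_continuum_map():
    p = cf.map_discrete_to_continuum(P=1.0, Q=1 / 500, Gamma=0.1,
                                     delta=20.0, tau=24.0 / 500.0)
    assert p.D == pytest.approx(1.0 * 20.0 ** 2 / (4 * 24.0 / 500.0))  # 2083.3
    assert p.lam == pytest.approx(1.0 / 24.0)
    assert p.gamma == pytest.approx(0.1 * 500.0 / 24.0)
    assert p.units == "physical"
    assert cf.map_discrete_to_continuum(0.0, 0, 0, 1, 1).D == 0.0


def test_map_rejects_bad_scales():
    with pytest.raises(ValueError):
        cf.map_discrete_to_continuum(1, 0, 0, delta=0.0, tau=1.0)
    with pytest.raises(ValueError):
        cf.map_discrete_to_continuum(1, 0, 0, delta=1.0, tau=-1.0)


def test_doubling_time_ratio():
    r = cf.doubling_time_ratio(delta=20.0, D=2100.0, t_d=16.0)
    assert r == pytest.approx(20.0 ** 2 * math.log(2) / (4 * 2100.0 * 16.0))
    assert r == pytest.approx(0.00206, abs=1e-5)
    # no-proliferation limit: ratio -> 0 as the doubling time diverges
    assert cf.doubling_time_ratio(20.0, 2100.0, 1e12) < 1e-12
    with pytest.raises(ValueError):
        cf.doubling_time_ratio(0.0, 2100.0, 16.0)


def test_doubling_time_to_rate():
    # lambda = ln2 / t_d at t_d = 16 h
    assert math.log(2) / 16.0 == pytest.approx(0.0433, abs=1e-4)
    p = cf.ContinuumParams(D=1.0, lam=math.log(2) / 16.0)
    assert p.doubling_time == pytest.approx(16.0)


def test_match_diffusivity():
    assert cf.match_diffusivity(2100.0) == 4200.0
    assert cf.match_diffusivity(0.0) == 0.0
    assert cf.match_diffusivity(3.7) == pytest.approx(2 * 3.7)


# ---------------------------------------------------------------------------
# coupled 1D solver
# ---------------------------------------------------------------------------

def test_uniform_density_stays_uniform_with_closed_form_substrate():
    c, gamma = 0.4, 0.02
    params = cf.ContinuumParams(D=0.25, gamma=gamma)
    ic = cf.Field1D(np.full(300, c), np.zeros(300))
    for fld, t in zip(cf.solve_coupled_1d(params, GRID, ic, [10.0, 200.0]),
                      [10.0, 200.0]):
        assert np.allclose(fld.u, c, atol=1e-13)
        assert np.allclose(fld.s, min(gamma * c * t, 1.0), atol=1e-12)


def test_uniform_logistic_recovers_closed_form():
    params = cf.ContinuumParams(D=0.25, lam=1 / 500, gamma=0.0)
    ic = cf.Field1D(np.full(300, 0.3), np.ones(300))
    fld = cf.solve_coupled_1d(params, GRID, ic, [2000.0])[0]
    exact = cf.logistic_solution(0.3, 1 / 500, 2000.0)
    assert np.abs(fld.u - exact).max() < 1e-12


def test_mass_conserved_without_proliferation():
    params = cf.ContinuumParams(D=0.25, gamma=0.1)
    ic = cf.step_ic(GRID, 150.0)
    mass0 = ic.u.sum() * GRID.h
    flds = cf.solve_coupled_1d(params, GRID, ic, [500.0, 2000.0])
    for fld in flds:
        assert abs(fld.u.sum() * GRID.h - mass0) / mass0 < 1e-8


def test_substrate_monotone_and_clamped():
    params = cf.ContinuumParams(D=0.25, gamma=0.05)
    flds = cf.solve_coupled_1d(params, GRID, cf.step_ic(GRID, 150.0),
                               [200.0, 600.0, 1200.0])
    prev = np.zeros(300)
    for fld in flds:
        assert fld.s.max() <= 1.0 and fld.s.min() >= 0.0
        assert (fld.s >= prev - 1e-15).all()
        prev = fld.s


def test_constant_g_reduces_to_linear_diffusion():
    """g = 1 kills the advective term: identical update to the saturated
    (s0=1) identity-response run, and both match the Fourier series."""
    ic0 = cf.step_ic(GRID, 150.0, s0=0.0)
    ic1 = cf.step_ic(GRID, 150.0, s0=1.0)
    a = cf.solve_coupled_1d(
        cf.ContinuumParams(D=0.25, gamma=0.3, response=constant_response(1.0)),
        GRID, ic0, [1500.0])[0]
    b = cf.solve_coupled_1d(
        cf.ContinuumParams(D=0.25, gamma=0.3), GRID, ic1, [1500.0])[0]
    assert np.array_equal(a.u, b.u)
    exact = cf.linear_diffusion_profile(GRID.centers, 1500.0, 0.25, 300.0, 150.0)
    assert np.abs(a.u - exact).max() < 1e-3


def test_fast_deposition_approaches_linear_diffusion():
    """gamma -> infinity proxy: substrate saturates immediately behind the
    front and the solution collapses onto linear diffusion."""
    params = cf.ContinuumParams(D=0.25, gamma=100.0)
    fld = cf.solve_coupled_1d(params, GRID, cf.step_ic(GRID, 150.0),
                              [2000.0])[0]
    exact = cf.linear_diffusion_profile(GRID.centers, 2000.0, 0.25, 300.0,
                                        150.0)
    assert np.abs(fld.u - exact).max() < 0.01


def test_unstable_step_raises():
    params = cf.ContinuumParams(D=0.25, gamma=0.1)
    with pytest.raises(RuntimeError, match="reduce dt"):
        cf.solve_coupled_1d(params, GRID, cf.step_ic(GRID, 150.0), [100.0],
                            dt=10.0)


def test_times_validated():
    params = cf.ContinuumParams(D=0.25)
    with pytest.raises(ValueError):
        cf.solve_coupled_1d(params, GRID, cf.step_ic(GRID, 150.0),
                            [100.0, 50.0])


def test_refinement_order_behind_interface():
    """Halving h (with dt ~ h^2) changes the smooth Region-1 solution at
    second order or better; the moving interface itself is excluded since
    max-norm convergence is impossible across the emergent sharp edge."""
    params = cf.ContinuumParams(D=0.25, gamma=1.0)
    sols = {}
    for n in (300, 600, 1200):
        g = cf.Grid1D(300.0, n)
        sols[n] = (g, cf.solve_coupled_1d(params, g, cf.step_ic(g, 150.0),
                                          [2000.0])[0])
    x = sols[300][0].centers
    u300 = sols[300][1].u
    u600 = np.interp(x, sols[600][0].centers, sols[600][1].u)
    u1200 = np.interp(x, sols[1200][0].centers, sols[1200][1].u)
    eta = cf.front_locations(x, u300, sols[300][1].s).eta
    mask = x < eta - 2.0
    e1 = np.abs(u300 - u600)[mask].max()
    e2 = np.abs(u600 - u1200)[mask].max()
    assert math.log2(e1 / e2) >= 1.8


def test_region1_maximum_principle():
    """Behind the saturated interface the dynamics are linear diffusion of a
    step, so the profile is monotone non-increasing there."""
    params = cf.ContinuumParams(D=0.25, gamma=0.1)
    flds = cf.solve_coupled_1d(params, GRID, cf.step_ic(GRID, 150.0),
                               [500.0, 1000.0, 1500.0, 2000.0])
    eta_early = cf.front_locations(GRID.centers, flds[0].u, flds[0].s).eta
    region1 = GRID.centers < eta_early
    for fld in flds[1:]:
        du = np.diff(fld.u[region1])
        assert (du <= 1e-12).all()


# ---------------------------------------------------------------------------
# flux decomposition
# ---------------------------------------------------------------------------

def test_uniform_substrate_has_no_advective_flux():
    params = cf.ContinuumParams(D=0.25)
    fld = cf.Field1D(np.linspace(1, 0, 300), np.full(300, 0.7))
    fx = cf.flux_decomposition(fld, params, GRID)
    assert np.allclose(fx.Ja, 0.0)
    assert np.all(fx.Jd[1:-1] > 0)


def test_advective_flux_maximal_at_half_density():
    # u(1-u) weighting: zero at u in {0,1}, maximal at u = 1/2
    grid = cf.Grid1D(5.0, 5)
    s = np.linspace(1.0, 0.6, 5)           # fixed negative slope
    params = cf.ContinuumParams(D=1.0)
    mags = {}
    for u0 in (0.0, 0.5, 1.0):
        fld = cf.Field1D(np.full(5, u0), s)
        mags[u0] = np.abs(cf.flux_decomposition(fld, params, grid).Ja).max()
    assert mags[0.0] == pytest.approx(0.0)
    assert mags[1.0] == pytest.approx(0.0)
    assert mags[0.5] > 0


def test_flux_hand_computed_on_ramps():
    # 5 cells, h=1: u = 1, .8, .6, .4, .2 ; s = .2, .4, .6, .8, 1
    grid = cf.Grid1D(5.0, 5)
    u = np.array([1.0, 0.8, 0.6, 0.4, 0.2])
    s = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
    params = cf.ContinuumParams(D=2.0)
    fx = cf.flux_decomposition(cf.Field1D(u, s), params, grid)
    # face between cells 0,1: sf=0.3, du=-0.2 -> Jd = -2*0.3*(-0.2) = 0.12
    assert fx.Jd[1] == pytest.approx(0.12)
    # phi = u(1-u) = 0, .16, .24, .24, .16; face mean .08; ds=+0.2
    # Ja = -2 * 1 * 0.08 * 0.2 = -0.032
    assert fx.Ja[1] == pytest.approx(-0.032)
    assert fx.Jd[0] == fx.Jd[-1] == 0.0
    assert np.allclose(fx.J, fx.Jd + fx.Ja)


# ---------------------------------------------------------------------------
# 2D reference solvers and oracles
# ---------------------------------------------------------------------------

def test_zero_diffusivity_is_static():
    g2 = cf.Grid2D(10.0, 41)
    ic = cf.disc_ic(g2, 3.0)
    out = cf.solve_reference_2d("linear", 0.0, g2, ic, [5.0])[0]
    assert np.array_equal(out, ic)


def test_linear_2d_matches_heat_kernel():
    g2 = cf.Grid2D(10.0, 101)
    X, Y = g2.mesh()
    r = np.hypot(X, Y)
    ic = cf.gaussian_profile_2d(r, 0.0, 1.0, 1.0)
    sol = cf.solve_reference_2d("linear", 1.0, g2, ic, [0.5])[0]
    exact = cf.gaussian_profile_2d(r, 0.5, 1.0, 1.0)
    assert np.abs(sol - exact).max() < 2e-3
    assert abs(sol.sum() - ic.sum()) <= 1e-8 * ic.sum()


def test_degenerate_2d_conserves_mass_and_keeps_compact_support():
    g2 = cf.Grid2D(10.0, 81)
    X, Y = g2.mesh()
    r = np.hypot(X, Y)
    ic = cf.barenblatt_profile(r, 1.0, 2.0, math.pi)
    sol = cf.solve_reference_2d("degenerate", 2.0, g2, ic, [1.0])[0]
    assert abs(sol.sum() - ic.sum()) <= 1e-8 * ic.sum()
    assert sol[0, 0] == 0.0 and sol[-1, -1] == 0.0   # corners stay empty


def test_reference_2d_validation():
    g2 = cf.Grid2D(10.0, 21)
    with pytest.raises(ValueError):
        cf.solve_reference_2d("cubic", 1.0, g2, cf.disc_ic(g2, 3.0), [1.0])
    with pytest.raises(ValueError):
        cf.solve_reference_2d("linear", 1.0, g2, np.ones((5, 5)), [1.0])


def test_barenblatt_mass_and_front():
    # closed form self-checks: mass integral and support radius
    D, mass, t = 2.0, math.pi, 3.0
    r = np.linspace(0, 10, 20001)
    u = cf.barenblatt_profile(r, t, D, mass)
    integral = np.trapezoid(u * 2 * math.pi * r, r)
    assert integral == pytest.approx(mass, rel=1e-6)
    rf = cf.barenblatt_front_radius(t, D, mass)
    assert u[r > rf].max() == 0.0
    assert u[r < rf - 1e-3].min() > 0.0
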