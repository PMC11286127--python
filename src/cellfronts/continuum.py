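"""Coarse-grained continuum limit of the substrate-mediated migration model.

The ensemble-averaged occupancy u(x,t) and substrate s(x,t) of the lattice
model satisfy, in the limit of fine lattices with ``delta**2 / tau`` fixed,

    du/dt = D d/dx [ g(s) du/dx + g'(s) u(1-u) ds/dx ] + lambda u(1-u),
    ds/dt = gamma u   while s < 1,   ds/dt = 0 once s = 1,

with D = P delta**2 / (4 tau), gamma = Gamma / tau, lambda = Q / tau, and
g(s) = s by default.  The flux splits into a substrate-weighted diffusive part
Jd = -D g(s) du/dx and a crowding-limited advective part
Ja = -D g'(s) u(1-u) ds/dx that acts only where the substrate is still
unsaturated — the mechanism behind sharp, sometimes non-monotonic fronts.

Solvers here are cell-centred conservative finite volumes with zero-flux
boundaries and explicit time stepping; the saturation rule for s is realised
as an unclamped increment followed by a clamp at 1, so the moving interface
between saturated and unsaturated substrate emerges without explicit
tracking.  The logistic source is applied by Lie splitting with the exact
logistic map over each time step, which keeps spatially uniform solutions
exact.  Reference two-dimensional solvers for linear (J = -D grad u) and
degenerate (J = -D u**n grad u) diffusion are provided for the barrier-assay
geometry, together with closed-form oracles (Fourier series, heat kernel,
Barenblatt) used for validation.

By default everything is in *lattice units* (h = 1 site, time in steps), so
PDE cells align one-to-one with lattice columns: D = P/4, gamma = Gamma,
lambda = Q per step.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .response import IDENTITY, MotilityResponse, as_response

__all__ = [
    "ContinuumParams", "Grid1D", "Grid2D", "Field1D", "FluxDecomposition",
    "map_discrete_to_continuum", "doubling_time_ratio", "match_diffusivity",
    "step_ic", "solve_coupled_1d", "flux_decomposition",
    "disc_ic", "solve_reference_2d",
    "linear_diffusion_profile", "gaussian_profile_2d",
    "barenblatt_profile", "barenblatt_front_radius", "logistic_solution",
]

_BOUND_TOL = 1e-6


@dataclass(frozen=True)
class ContinuumParams:
    """Continuum-limit parameters.

    D : diffusivity (length^2 / time); lam : proliferation rate (1/time);
    gamma : substrate deposition rate (1/time); response : g and dg/ds;
    units : "lattice" (sites/steps) or "physical".
    """

    D: float
    lam: float = 0.0
    gamma: float = 0.0
    response: MotilityResponse = IDENTITY
    units: str = "lattice"

    def __post_init__(self):
        if self.D < 0 or self.lam < 0 or self.gamma < 0:
            raise ValueError("D, lambda and gamma must be >= 0")
        object.__setattr__(self, "response", as_response(self.response))

    @property
    def doubling_time(self) -> float:
        """t_d = ln 2 / lambda (inf when lambda = 0)."""
        return math.inf if self.lam == 0 else math.log(2.0) / self.lam


def map_discrete_to_continuum(P: float, Q: float, Gamma: float,
                              delta: float, tau: float,
                              response: MotilityResponse | None = None,
                              ) -> ContinuumParams:
    """Discrete -> continuum parameter map.

    D = P delta^2 / (4 tau), lambda = Q / tau, gamma = Gamma / tau.
    """
    if delta <= 0 or tau <= 0:
        raise ValueError("delta and tau must be positive")
    units = "lattice" if (delta == 1.0 and tau == 1.0) else "physical"
    return ContinuumParams(D=P * delta * delta / (4.0 * tau),
                           lam=Q / tau, gamma=Gamma / tau,
                           response=as_response(response), units=units)


def doubling_time_ratio(delta: float, D: float, t_d: float) -> float:
    """Q/P = delta^2 ln2 / (4 D t_d): proliferation-to-motility probability
    ratio that reproduces a doubling time t_d at diffusivity D; tau-free."""
    if delta <= 0 or D <= 0 or t_d <= 0:
        raise ValueError("delta, D and t_d must be positive")
    return delta * delta * math.log(2.0) / (4.0 * D * t_d)


def match_diffusivity(D1: float) -> float:
    """D2 with int_0^1 D1 du = int_0^1 D2 u du, i.e. D2 = 2 D1.

    Matches the total spreading capacity of degenerate diffusion (flux
    -D2 u grad u) to linear diffusion (flux -D1 grad u).
    """
    if D1 < 0:
        raise ValueError("D1 must be >= 0")
    return 2.0 * D1


@dataclass(frozen=True)
class Grid1D:
    """Uniform cell-centred grid on [0, length] with zero-flux end faces."""

    length: float
    n_cells: int

    def __post_init__(self):
        if self.length <= 0 or self.n_cells < 1:
            raise ValueError("need length > 0 and n_cells >= 1")

    @property
    def h(self) -> float:
        return self.length / self.n_cells

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_cells) + 0.5) * self.h

    @property
    def faces(self) -> np.ndarray:
        return np.arange(self.n_cells + 1) * self.h


@dataclass
class Field1D:
    """Density u, substrate s (cell-centred) and the time they refer to."""

    u: np.ndarray
    s: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.u.shape != self.s.shape:
            raise ValueError("u and s must share a grid")

    def copy(self) -> "Field1D":
        return Field1D(self.u.copy(), self.s.copy(), self.t)


@dataclass(frozen=True)
class FluxDecomposition:
    """Face-centred fluxes: total J = Jd + Ja, zero at boundary faces."""

    Jd: np.ndarray
    Ja: np.ndarray

    @property
    def J(self) -> np.ndarray:
        return self.Jd + self.Ja


def step_ic(grid: Grid1D, edge: float, s0: float = 0.0) -> Field1D:
    """Heaviside initial condition: u = 1 for cell centres x <= edge."""
    u = (grid.centers <= edge).astype(float)
    s = np.full(grid.n_cells, float(s0))
    return Field1D(u, s, 0.0)


def _interior_fluxes(u: np.ndarray, s: np.ndarray, h: float,
                     params: ContinuumParams):
    g, dg = params.response.g, params.response.dg
    sf = 0.5 * (s[:-1] + s[1:])
    phi = u * (1.0 - u)
    phif = 0.5 * (phi[:-1] + phi[1:])
    du = np.diff(u) / h
    ds = np.diff(s) / h
    Jd = -params.D * g(sf) * du
    Ja = -params.D * dg(sf) * phif * ds
    return Jd, Ja


def default_dt(grid: Grid1D, params: ContinuumParams,
               safety: float = 0.25) -> float:
    """Explicit stability bound dt = safety * h^2 / (D max(1, max g))."""
    gmax = max(1.0, params.response.max_value())
    if params.D <= 0:
        return grid.h  # no diffusion: any O(h) step resolves the ODE parts
    return safety * grid.h * grid.h / (params.D * gmax)


def solve_coupled_1d(params: ContinuumParams, grid: Grid1D, ic: Field1D,
                     times: Sequence[float], dt: float | None = None,
                     safety: float = 0.25) -> list[Field1D]:
    """March the coupled u-s system, returning fields at the requested times.

    Conservative update (total mass of u exact to round-off when lam = 0),
    exact logistic substep for the source, Euler-then-clamp for s.  Raises
    if u leaves [-1e-6, 1 + 1e-6], which indicates the time step is too
    large for the supplied response.
    """
    times = [float(t) for t in times]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("times must be non-decreasing")
    if times and times[0] < ic.t:
        raise ValueError("times must not precede the initial condition")
    if ic.u.shape[0] != grid.n_cells:
        raise ValueError("initial condition does not match the grid")
    if dt is None:
        dt = default_dt(grid, params, safety)
    h = grid.h
    u = ic.u.copy()
    s = np.clip(ic.s.copy(), 0.0, 1.0)
    t = ic.t
    out: list[Field1D] = []
    for target in times:
        while t < target - 1e-12 * max(1.0, abs(target)):
            ddt = min(dt, target - t)
            Jd, Ja = _interior_fluxes(u, s, h, params)
            J = np.concatenate(([0.0], Jd + Ja, [0.0]))
            u_new = u - (ddt / h) * np.diff(J)
            if params.lam > 0.0:
                e = math.exp(params.lam * ddt)
                u_new = u_new * e / (1.0 + u_new * (e - 1.0))
            if params.gamma > 0.0:
                s = np.minimum(1.0, s + ddt * params.gamma * u)
            u = u_new
            t += ddt
            if u.min() < -_BOUND_TOL or u.max() > 1.0 + _BOUND_TOL:
                raise RuntimeError(
                    f"density left [0,1] beyond tolerance at t={t:g} "
                    f"(min={u.min():g}, max={u.max():g}); reduce dt")
        out.append(Field1D(u.copy(), s.copy(), target))
    return out


def flux_decomposition(fld: Field1D, params: ContinuumParams,
                       grid: Grid1D) -> FluxDecomposition:
    """Diffusive and advective flux profiles at cell faces.

    Uses the same arithmetic-mean face values as the solver, so the
    decomposition is exactly consistent with the computed evolution.
    """
    if fld.u.shape[0] != grid.n_cells:
        raise ValueError("field does not match the grid")
    Jd, Ja = _interior_fluxes(fld.u, fld.s, grid.h, params)
    z = np.zeros(1)
    return FluxDecomposition(Jd=np.concatenate((z, Jd, z)),
                             Ja=np.concatenate((z, Ja, z)))


# ---------------------------------------------------------------------------
# reference two-dimensional solvers (barrier-assay geometry)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid2D:
    """Uniform square grid: n x n cells on [-length/2, length/2]^2."""

    length: float
    n: int

    @property
    def h(self) -> float:
        return self.length / self.n

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n) + 0.5) * self.h - self.length / 2.0

    def mesh(self):
        c = self.centers
        return np.meshgrid(c, c, indexing="ij")


def disc_ic(grid: Grid2D, radius: float, density: float = 1.0) -> np.ndarray:
    """u = density inside a centred disc, 0 elsewhere."""
    X, Y = grid.mesh()
    return np.where(X * X + Y * Y <= radius * radius, float(density), 0.0)


def solve_reference_2d(model: str, D: float, grid: Grid2D, ic: np.ndarray,
                       times: Sequence[float], n_exponent: float = 1.0,
                       safety: float = 0.2) -> list[np.ndarray]:
    """Five-point conservative solver for du/dt = div(D_eff grad u).

    model="linear": D_eff = D; model="degenerate": D_eff at each face is
    D times the arithmetic mean of u**n on the two adjacent cells (default
    n=1, the porous-medium case).  Zero-flux boundaries; no source, so mass
    is conserved to round-off.
    """
    if model not in ("linear", "degenerate"):
        raise ValueError("model must be 'linear' or 'degenerate'")
    if D < 0:
        raise ValueError("D must be >= 0")
    u = np.asarray(ic, dtype=float).copy()
    if u.shape != (grid.n, grid.n):
        raise ValueError("initial condition does not match the grid")
    h = grid.h
    times = [float(t) for t in times]
    t = 0.0
    out: list[np.ndarray] = []
    for target in times:
        while t < target - 1e-12 * max(1.0, target):
            if model == "linear":
                dmax = D
            else:
                dmax = D * max(float(np.max(u)), 0.0) ** n_exponent
            if dmax <= 0:
                t = target
                break
            ddt = min(safety * h * h / dmax, target - t)
            if model == "linear":
                Fx = -D * np.diff(u, axis=0) / h
                Fy = -D * np.diff(u, axis=1) / h
            else:
                un = np.maximum(u, 0.0) ** n_exponent
                Fx = -D * 0.5 * (un[:-1, :] + un[1:, :]) * np.diff(u, axis=0) / h
                Fy = -D * 0.5 * (un[:, :-1] + un[:, 1:]) * np.diff(u, axis=1) / h
            zx = np.zeros((1, grid.n))
            zy = np.zeros((grid.n, 1))
            divx = np.diff(np.concatenate((zx, Fx, zx), axis=0), axis=0) / h
            divy = np.diff(np.concatenate((zy, Fy, zy), axis=1), axis=1) / h
            u = u - ddt * (divx + divy)
            t += ddt
            if u.min() < -1e-3 or u.max() > np.max(ic) * (1 + 1e-3) + 1e-3:
                raise RuntimeError(
                    f"2D solution left its bounds at t={t:g}; reduce safety")
        out.append(u.copy())
    return out


# ---------------------------------------------------------------------------
# closed-form reference solutions (validation oracles)
# ---------------------------------------------------------------------------

def linear_diffusion_profile(x: np.ndarray, t: float, D: float, L: float,
                             edge: float, u0: float = 1.0,
                             n_terms: int = 2000) -> np.ndarray:
    """Fourier cosine series for du/dt = D d2u/dx2 on [0, L], zero flux,
    with initial step u = u0 on [0, edge]."""
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, u0 * edge / L)
    if t == 0:
        return np.where(x <= edge, u0, 0.0)
    for k in range(1, n_terms + 1):
        decay = math.exp(-D * (k * math.pi / L) ** 2 * t)
        if decay < 1e-18:
            break
        out += (2.0 * u0 / (k * math.pi) * math.sin(k * math.pi * edge / L)
                * np.cos(k * math.pi * x / L) * decay)
    return out


def logistic_solution(u0: float, lam: float, t) -> np.ndarray:
    """u(t) = u0 e^{lam t} / (1 + u0 (e^{lam t} - 1))."""
    e = np.exp(lam * np.asarray(t, dtype=float))
    return u0 * e / (1.0 + u0 * (e - 1.0))


def gaussian_profile_2d(r: np.ndarray, t: float, D: float, sigma0: float,
                        amplitude: float = 1.0) -> np.ndarray:
    """Linear 2D diffusion of an isotropic Gaussian of s.d. sigma0."""
    var = sigma0 * sigma0 + 2.0 * D * t
    return (amplitude * sigma0 * sigma0 / var
            * np.exp(-np.asarray(r, dtype=float) ** 2 / (2.0 * var)))


def _barenblatt_C(mass: float) -> float:
    return math.sqrt(mass / (8.0 * math.pi))


def barenblatt_profile(r: np.ndarray, t: float, D: float,
                       mass: float) -> np.ndarray:
    """Self-similar source solution of du/dt = D div(u grad u) in 2D.

    With tp = D t / 2:  u = tp^{-1/2} (C - r^2 tp^{-1/2} / 16)_+ where
    C = sqrt(mass / (8 pi)); total mass is conserved and the support is the
    disc r < 4 sqrt(C) tp^{1/4}.
    """
    tp = D * t / 2.0
    if tp <= 0:
        raise ValueError("need D > 0 and t > 0")
    C = _barenblatt_C(mass)
    prof = (C - np.asarray(r, dtype=float) ** 2 / (16.0 * math.sqrt(tp)))
    return np.maximum(prof, 0.0) / math.sqrt(tp)


def barenblatt_front_radius(t: float, D: float, mass: float) -> float:
    """Support radius of the 2D Barenblatt solution at time t."""
    tp = D * t / 2.0
    if tp <= 0:
        raise ValueError("need D > 0 and t > 0")
    return 4.0 * math.sqrt(_barenblatt_C(mass)) * tp ** 0.25
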