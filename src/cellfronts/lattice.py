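"""Stochastic lattice model of collective cell migration with substrate deposition.

The model is a two-dimensional exclusion process: each site of a W x H square
lattice holds at most one agent (a cell of diameter ``delta``).  Each site also
carries a non-dimensional substrate density ``S in [0,1]`` representing locally
deposited extracellular material.  Time advances in steps of duration ``tau``
via a random sequential update:

1. **Motility phase** — N agents (N = count at phase start) are drawn uniformly
   with replacement; a drawn agent on substrate S attempts a move with
   probability ``P * g(S)`` to a uniformly chosen nearest neighbour, succeeding
   iff the target is vacant.  Boundaries are reflecting (an off-lattice target
   aborts the move).
2. **Proliferation phase** (optional, ``Q > 0``) — another N draws with
   replacement; a drawn agent divides with probability Q, placing a daughter on
   a uniformly chosen nearest neighbour iff vacant.  Daughters become
   selectable only from the next step.
3. **Deposition phase** — every occupied site gains substrate ``Gamma``,
   capped at the saturation density 1.

With ``g(s) = s`` (the default) agent motility is proportional to local
substrate; the coarse-grained limit of this mechanism is the coupled PDE
system solved in :mod:`cellfronts.continuum`, with ``D = P * delta**2 / (4 tau)``,
``gamma = Gamma / tau`` and ``lambda = Q / tau``.

Reproducibility contract: each realization owns one ``numpy.random.Generator``
and consumes, per phase, exactly three arrays in a fixed order — agent
indices, attempt uniforms, direction codes.  Phases that cannot act (no
agents, or ``Q = 0``) consume no randomness.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Callable, Iterable, Sequence

import numpy as np

from ._kernels import motility_kernel, proliferation_kernel
from .response import MotilityResponse, as_response

__all__ = [
    "LatticeConfig", "SimState", "EnsembleResult",
    "init_disc", "init_strip", "disc_site_count", "rounded_disc_area",
    "motility_phase", "proliferation_phase", "deposition_phase",
    "step", "run", "column_average", "run_ensemble",
]

_G_TABLE_SIZE = 4097


@dataclass
class LatticeConfig:
    """Geometry, rates and seed for one simulation setup.

    Parameters
    ----------
    width, height
        Lattice dimensions in sites (W columns, H rows).
    delta
        Lattice spacing, i.e. cell diameter (μm); 1.0 for lattice units.
    tau
        Duration of one time step (h); 1.0 for lattice units.
    P
        Probability that an isolated agent on saturated substrate attempts a
        move when selected.
    Q
        Probability that a selected agent attempts to divide.
    Gamma
        Substrate deposited per occupied site per step (non-dimensional).
    g
        Motility response; ``None`` means the identity g(s) = s.
    seed
        Base RNG seed (realization m uses ``seed + m``).
    """

    width: int
    height: int
    delta: float = 1.0
    tau: float = 1.0
    P: float = 1.0
    Q: float = 0.0
    Gamma: float = 0.0
    g: MotilityResponse | Callable | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("lattice dimensions must be >= 1")
        if self.delta <= 0 or self.tau <= 0:
            raise ValueError("delta and tau must be positive")
        if not 0.0 <= self.P <= 1.0:
            raise ValueError("P must lie in [0,1]")
        if not 0.0 <= self.Q <= 1.0:
            raise ValueError("Q must lie in [0,1]")
        if self.Gamma < 0:
            raise ValueError("Gamma must be >= 0")
        self.g = as_response(self.g)  # validates bounds/monotonicity

    @cached_property
    def g_table(self) -> np.ndarray:
        return self.g.table(_G_TABLE_SIZE)

    @property
    def steps_per_day(self) -> float:
        """Number of time steps per 24 h of physical time."""
        return 24.0 / self.tau


@dataclass
class SimState:
    """Mutable state of one realization.

    ``occupancy`` is a uint8 W x H grid (1 = occupied); ``substrate`` holds
    the non-dimensional substrate density in [0,1]; ``positions[:n]`` are the
    (i, j) sites of the n agents, consistent with ``occupancy`` at all times.
    """

    occupancy: np.ndarray
    substrate: np.ndarray
    positions: np.ndarray
    n: int
    step_count: int = 0

    @property
    def agents(self) -> np.ndarray:
        """(n, 2) array of agent sites (a view; do not mutate)."""
        return self.positions[:self.n]

    def copy(self) -> "SimState":
        return SimState(self.occupancy.copy(), self.substrate.copy(),
                        self.positions.copy(), self.n, self.step_count)

    def validate(self) -> None:
        """Assert the exclusion/consistency invariants (used in tests)."""
        occ = self.occupancy
        if not np.isin(occ, (0, 1)).all():
            raise AssertionError("occupancy must be binary")
        if int(occ.sum()) != self.n:
            raise AssertionError("agent count inconsistent with occupancy")
        ag = self.positions[:self.n]
        if self.n and not (occ[ag[:, 0], ag[:, 1]] == 1).all():
            raise AssertionError("agent list inconsistent with occupancy")
        if self.n != len({(int(i), int(j)) for i, j in ag}):
            raise AssertionError("duplicate agents on one site")
        if self.substrate.min() < 0.0 or self.substrate.max() > 1.0:
            raise AssertionError("substrate out of [0,1]")


def _state_from_occupancy(occ: np.ndarray, s0: float) -> SimState:
    pos = np.ascontiguousarray(np.argwhere(occ == 1), dtype=np.int64)
    sub = np.full(occ.shape, float(s0))
    return SimState(occupancy=np.ascontiguousarray(occ, dtype=np.uint8),
                    substrate=sub, positions=pos, n=pos.shape[0])


def disc_site_count(radius: int) -> int:
    """Exact number of integer lattice offsets with di**2 + dj**2 <= radius**2."""
    r = int(radius)
    d = np.arange(-r, r + 1)
    return int(np.count_nonzero(d[:, None] ** 2 + d[None, :] ** 2 <= r * r))


def rounded_disc_area(radius: float) -> int:
    """Continuum disc area rounded to the nearest site count, round(pi r^2)."""
    return int(round(math.pi * radius * radius))


def _centre(n: int) -> int:
    # central site, 1-based round((n+1)/2), returned 0-based
    return (n - 1) // 2


def init_disc(config: LatticeConfig, radius_sites: int, occupancy_prob: float,
              s0: float = 0.0, rng: np.random.Generator | None = None) -> SimState:
    """Seed a circular barrier-assay population.

    Each site within ``radius_sites`` of the central site is occupied
    independently with probability ``occupancy_prob``; substrate is set to
    ``s0`` everywhere.
    """
    if not 0.0 <= occupancy_prob <= 1.0:
        raise ValueError("occupancy_prob must lie in [0,1]")
    if not 0.0 <= s0 <= 1.0:
        raise ValueError("s0 must lie in [0,1]")
    W, H = config.width, config.height
    ic, jc = _centre(W), _centre(H)
    r = int(radius_sites)
    if ic - r < 0 or jc - r < 0 or ic + r >= W or jc + r >= H:
        raise ValueError(f"disc of radius {r} does not fit a {W}x{H} lattice")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    di = np.arange(W) - ic
    dj = np.arange(H) - jc
    mask = di[:, None] ** 2 + dj[None, :] ** 2 <= r * r
    occ = np.zeros((W, H), dtype=np.uint8)
    occ[mask] = rng.random(int(mask.sum())) < occupancy_prob
    return _state_from_occupancy(occ, s0)


def init_strip(config: LatticeConfig, occupied_columns: int,
               s0: float = 0.0) -> SimState:
    """Deterministically occupy every site in columns i <= occupied_columns."""
    W, H = config.width, config.height
    c = int(occupied_columns)
    if not 0 <= c <= W:
        raise ValueError(f"occupied_columns must lie in [0, {W}]")
    if not 0.0 <= s0 <= 1.0:
        raise ValueError("s0 must lie in [0,1]")
    occ = np.zeros((W, H), dtype=np.uint8)
    occ[:c, :] = 1
    return _state_from_occupancy(occ, s0)


def motility_phase(state: SimState, config: LatticeConfig,
                   rng: np.random.Generator) -> SimState:
    """Attempt N motility events (N fixed at phase start); in place."""
    n = state.n
    if n == 0 or config.P == 0.0:
        return state
    idx = rng.integers(0, n, size=n)
    att = rng.random(n)
    dirs = rng.integers(0, 4, size=n)
    motility_kernel(state.occupancy, state.substrate, state.positions,
                    float(config.P), config.g_table, idx, att, dirs)
    return state


def proliferation_phase(state: SimState, config: LatticeConfig,
                        rng: np.random.Generator) -> SimState:
    """Attempt N proliferation events; daughters appended, N updated at end."""
    n = state.n
    if n == 0 or config.Q == 0.0:
        return state
    if state.positions.shape[0] < 2 * n:  # each of the n draws can add one
        grown = np.zeros((2 * n, 2), dtype=np.int64)
        grown[:n] = state.positions[:n]
        state.positions = grown
    idx = rng.integers(0, n, size=n)
    att = rng.random(n)
    dirs = rng.integers(0, 4, size=n)
    state.n = int(proliferation_kernel(state.occupancy, state.positions, n,
                                       float(config.Q), idx, att, dirs))
    return state


def deposition_phase(state: SimState, config: LatticeConfig) -> SimState:
    """Every occupied site gains Gamma, capped at saturation 1; deterministic."""
    if config.Gamma > 0.0 and state.n:
        occ = state.occupancy.view(bool)
        state.substrate[occ] = np.minimum(1.0, state.substrate[occ] + config.Gamma)
    return state


def step(state: SimState, config: LatticeConfig,
         rng: np.random.Generator) -> SimState:
    """Advance one time step: motility, proliferation (if Q>0), deposition."""
    motility_phase(state, config, rng)
    if config.Q > 0.0:
        proliferation_phase(state, config, rng)
    deposition_phase(state, config)
    state.step_count += 1
    return state


def run(state: SimState, config: LatticeConfig, n_steps: int,
        record_at: Sequence[int] | None = None,
        rng: np.random.Generator | None = None) -> list[SimState]:
    """Advance ``n_steps`` steps, returning deep-copied snapshots.

    ``record_at`` is a collection of step indices in [0, n_steps] (default:
    final step only).  With ``rng=None`` a fresh generator is seeded from
    ``config.seed`` so that (initial state, config, seed) fixes the trajectory.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    record = sorted({int(k) for k in record_at}) if record_at is not None else [n_steps]
    if record and (record[0] < 0 or record[-1] > n_steps):
        raise ValueError(f"record_at must lie within [0, {n_steps}]")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    snapshots: list[SimState] = []
    want = set(record)
    if state.step_count in want:
        snapshots.append(state.copy())
    start = state.step_count
    for _ in range(n_steps):
        step(state, config, rng)
        if state.step_count in want:
            snapshots.append(state.copy())
    return snapshots


def column_average(grids, M: int | None = None, H: int | None = None) -> np.ndarray:
    """Column-averaged density <U_i> = (1/(H M)) sum_m sum_j U^m_{i,j}.

    ``grids`` is one W x H grid or a stack of M of them (occupancy or
    substrate).  Returns a length-W profile in [0,1] for binary input.
    """
    arr = np.asarray(grids, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("expected one grid or a stack of equally shaped grids")
    if M is not None and arr.shape[0] != M:
        raise ValueError(f"expected M={M} grids, got {arr.shape[0]}")
    if H is not None and arr.shape[2] != H:
        raise ValueError(f"expected height H={H}, got {arr.shape[2]}")
    return arr.mean(axis=(0, 2))


@dataclass
class EnsembleResult:
    """Column-averaged output of M identically prepared realizations.

    ``u_columns[m, k]`` holds realization m's column sums of occupancy at the
    k-th recorded step (so ``u_columns / H`` is that realization's column
    average); ``u_mean``/``s_mean`` are the ensemble averages over M and H.
    """

    M: int
    W: int
    H: int
    record_steps: np.ndarray          # (T,)
    tau: float
    u_columns: np.ndarray             # (M, T, W) column sums of occupancy
    s_columns: np.ndarray             # (M, T, W) column means of substrate
    n_agents: np.ndarray              # (M, T)
    mean_occupancy: np.ndarray | None = None   # (T, W, H) if requested
    isolated_counts: np.ndarray | None = None  # (M, T) if requested

    @property
    def times_hours(self) -> np.ndarray:
        return self.record_steps * self.tau

    @property
    def times_days(self) -> np.ndarray:
        return self.record_steps * self.tau / 24.0

    @property
    def u_mean(self) -> np.ndarray:
        """<U_i> per recorded time, shape (T, W)."""
        return self.u_columns.mean(axis=0) / self.H

    @property
    def s_mean(self) -> np.ndarray:
        return self.s_columns.mean(axis=0)

    def u_sem(self) -> np.ndarray:
        """Monte-Carlo standard error of <U_i>, shape (T, W)."""
        if self.M < 2:
            return np.zeros_like(self.u_mean)
        return (self.u_columns / self.H).std(axis=0, ddof=1) / math.sqrt(self.M)


def _isolated_count(occ: np.ndarray) -> int:
    """Occupied sites whose 4 nearest neighbours are all vacant."""
    p = np.pad(occ, 1)
    nbrs = p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:]
    return int(np.count_nonzero((occ == 1) & (nbrs == 0)))


def run_ensemble(config: LatticeConfig,
                 init: Callable[[LatticeConfig, np.random.Generator], SimState],
                 n_steps: int, record_at: Sequence[int], M: int,
                 base_seed: int | None = None,
                 keep_mean_grid: bool = False,
                 track_isolated: bool = False) -> EnsembleResult:
    """Run M realizations (seeds base_seed + m) and collect column statistics.

    ``init`` builds the initial state from (config, rng); the same generator
    then drives that realization, so stochastic initial conditions are part
    of the reproducible stream.
    """
    base = config.seed if base_seed is None else int(base_seed)
    record = sorted({int(k) for k in record_at})
    if record[0] < 0 or record[-1] > n_steps:
        raise ValueError(f"record_at must lie within [0, {n_steps}]")
    T = len(record)
    W, H = config.width, config.height
    u_cols = np.empty((M, T, W))
    s_cols = np.empty((M, T, W))
    n_agents = np.empty((M, T), dtype=np.int64)
    mean_occ = np.zeros((T, W, H)) if keep_mean_grid else None
    iso = np.zeros((M, T), dtype=np.int64) if track_isolated else None
    want = set(record)
    index = {k: idx for idx, k in enumerate(record)}
    for m in range(M):
        rng = np.random.default_rng(base + m)
        state = init(config, rng)
        for k in range(n_steps + 1):
            if k in want:
                t = index[k]
                u_cols[m, t] = state.occupancy.sum(axis=1)
                s_cols[m, t] = state.substrate.mean(axis=1)
                n_agents[m, t] = state.n
                if keep_mean_grid:
                    mean_occ[t] += state.occupancy
                if track_isolated:
                    iso[m, t] = _isolated_count(state.occupancy)
            if k < n_steps:
                step(state, config, rng)
    if keep_mean_grid:
        mean_occ /= M
    return EnsembleResult(M=M, W=W, H=H,
                          record_steps=np.asarray(record), tau=config.tau,
                          u_columns=u_cols, s_columns=s_cols,
                          n_agents=n_agents, mean_occupancy=mean_occ,
                          isolated_counts=iso)
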