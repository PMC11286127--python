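"""In-silico experiment recipes tying the simulator, solver and front analysis.

Two geometries are used throughout:

* a barrier assay: a 500 x 500 lattice with agents seeded at random inside a
  disc of radius 150 sites (expected population 30 000, matching ~30 000
  fibroblasts inside a 3 mm barrier at 20 μm cell diameter), and
* a strip: a 300 x 20 lattice with every site in columns i <= 150 occupied,
  whose column averages are compared against the one-dimensional PDE.

Physical calibration in both: P = 1 and tau = 24/500 h, so 500 steps equal
one day and D = P delta^2 / (4 tau) = 2083 μm^2/h for delta = 20 μm;
proliferative variants use Q = 1/500 (lambda = 1/24 per hour, doubling time
~16.6 h).  The recipe names follow the package's own figure registry:
"disc" / "disc-proliferative" for the barrier assay, "strip" for single
realizations, "strip-averaged" / "strip-proliferative" for continuum-discrete
comparisons, "reference-2d" for the linear vs degenerate diffusion baseline.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import lattice as lat
from . import continuum as cont
from . import fronts as fr

__all__ = ["Recipe", "RecipeResult", "make_recipe", "run_recipe",
           "compare_profiles", "comparison_report", "strip_comparison",
           "isolated_agent_count", "EXPECTED_BARRIER_POPULATION",
           "BARRIER_RADIUS_SITES", "BARRIER_OCCUPANCY_PROB",
           "STEPS_PER_DAY", "TAU_HOURS", "DELTA_UM"]

# barrier-assay calibration
DELTA_UM = 20.0
TAU_HOURS = 24.0 / 500.0
STEPS_PER_DAY = 500
BARRIER_RADIUS_SITES = 150
EXPECTED_BARRIER_POPULATION = 30_000
BARRIER_OCCUPANCY_PROB = EXPECTED_BARRIER_POPULATION / lat.rounded_disc_area(
    BARRIER_RADIUS_SITES)
Q_PROLIFERATIVE = 1.0 / 500.0
D1_UM2_PER_H = 2100.0  # typical fibroblast diffusivity for the 2D reference

_DISC_NAMES = {"disc", "disc-proliferative", "fig2", "fig7"}
_STRIP_SINGLE = {"strip", "fig3"}
_STRIP_AVG = {"strip-averaged", "strip-proliferative", "fig4", "fig8"}
_REFERENCE = {"reference-2d", "fig1-reference"}
_ALIASES = {"fig2": "disc", "fig7": "disc-proliferative", "fig3": "strip",
            "fig4": "strip-averaged", "fig8": "strip-proliferative",
            "fig1-reference": "reference-2d"}


@dataclass(frozen=True)
class Recipe:
    name: str
    geometry: str                      # disc | strip | reference-2d
    config: lat.LatticeConfig | None
    s0: float
    M: int
    base_seed: int
    record_days: tuple[int, ...]
    radius_sites: int = BARRIER_RADIUS_SITES
    occupancy_prob: float = BARRIER_OCCUPANCY_PROB
    occupied_columns: int = 150
    steps_per_day: int = STEPS_PER_DAY
    with_pde: bool = False

    @property
    def record_steps(self) -> tuple[int, ...]:
        return tuple(d * self.steps_per_day for d in self.record_days)

    @property
    def n_steps(self) -> int:
        return max(self.record_steps)


def make_recipe(name: str, Gamma: float = 0.1, s0: float = 0.0,
                M: int | None = None, base_seed: int = 0,
                record_days: Sequence[int] | None = None,
                fast: bool = False) -> Recipe:
    """Build a named experiment recipe.

    ``fast`` shrinks the ensemble (M = 20) for quick runs; the full
    continuum-discrete comparisons use M = 100.
    """
    key = _ALIASES.get(name, name)
    proliferative = key in ("disc-proliferative", "strip-proliferative")
    Q = Q_PROLIFERATIVE if proliferative else 0.0
    if key in ("disc", "disc-proliferative"):
        cfg = lat.LatticeConfig(width=500, height=500, delta=DELTA_UM,
                                tau=TAU_HOURS, P=1.0, Q=Q, Gamma=Gamma,
                                seed=base_seed)
        days = tuple(record_days) if record_days else (0, 1, 2, 3)
        return Recipe(name=key, geometry="disc", config=cfg, s0=s0,
                      M=M if M is not None else 1, base_seed=base_seed,
                      record_days=days)
    if key in ("strip", "strip-averaged", "strip-proliferative"):
        cfg = lat.LatticeConfig(width=300, height=20, delta=DELTA_UM,
                                tau=TAU_HOURS, P=1.0, Q=Q, Gamma=Gamma,
                                seed=base_seed)
        days = tuple(record_days) if record_days else (0, 1, 2, 3, 4)
        averaged = key != "strip"
        default_M = 1 if not averaged else (20 if fast else 100)
        return Recipe(name=key, geometry="strip", config=cfg, s0=s0,
                      M=M if M is not None else default_M,
                      base_seed=base_seed, record_days=days,
                      with_pde=averaged)
    if key in _REFERENCE:
        days = tuple(record_days) if record_days else (0, 3)
        return Recipe(name="reference-2d", geometry="reference-2d",
                      config=None, s0=s0, M=1, base_seed=base_seed,
                      record_days=days)
    raise ValueError(f"unknown recipe {name!r}")


@dataclass
class RecipeResult:
    recipe: Recipe
    ensemble: lat.EnsembleResult | None = None
    pde: list[cont.Field1D] | None = None
    report: pd.DataFrame | None = None
    fronts: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def compare_profiles(a: np.ndarray, b: np.ndarray,
                     metric: str = "max") -> float:
    """Discrepancy between two profiles on a common grid: max-abs or RMS."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must share a grid")
    d = np.abs(a - b)
    if metric == "max":
        return float(d.max())
    if metric == "rms":
        return float(math.sqrt(np.mean(d * d)))
    raise ValueError("metric must be 'max' or 'rms'")


def comparison_report(ens: lat.EnsembleResult, pde: list[cont.Field1D],
                      tolerance: float = 0.05) -> pd.DataFrame:
    """Per-time max-abs and RMS discrepancy between <U_i> and u(x_i, t)."""
    rows = []
    for k, day in enumerate(ens.times_days):
        u_avg = ens.u_mean[k]
        u_pde = pde[k].u
        rows.append({"t_days": float(day),
                     "max_abs": compare_profiles(u_avg, u_pde, "max"),
                     "rms": compare_profiles(u_avg, u_pde, "rms"),
                     "tolerance": tolerance})
    df = pd.DataFrame(rows)
    df["passed"] = df["max_abs"] <= df["tolerance"]
    return df


def matched_pde(recipe: Recipe, grid: cont.Grid1D | None = None,
                ) -> tuple[cont.ContinuumParams, cont.Grid1D, cont.Field1D]:
    """Continuum setup aligned column-for-cell with a strip recipe.

    Lattice units: D = P/4, gamma = Gamma and lambda = Q per step, one cell
    per lattice column, step initial condition at the occupied edge.
    """
    cfg = recipe.config
    params = cont.map_discrete_to_continuum(cfg.P, cfg.Q, cfg.Gamma,
                                            1.0, 1.0, response=cfg.g)
    if grid is None:
        grid = cont.Grid1D(length=float(cfg.width), n_cells=cfg.width)
    ic = cont.step_ic(grid, edge=float(recipe.occupied_columns), s0=recipe.s0)
    return params, grid, ic


def strip_comparison(Gamma: float, Q: float = 0.0, M: int = 20,
                     base_seed: int = 0, s0: float = 0.0,
                     record_days: Sequence[int] = (1, 2, 3, 4),
                     tolerance: float = 0.05):
    """Run the strip ensemble and the matched PDE; return (ens, pde, report)."""
    name = "strip-proliferative" if Q > 0 else "strip-averaged"
    recipe = make_recipe(name, Gamma=Gamma, M=M, base_seed=base_seed,
                         record_days=record_days, s0=s0)
    ens = lat.run_ensemble(recipe.config, _strip_init(recipe),
                           recipe.n_steps, recipe.record_steps, recipe.M,
                           base_seed=recipe.base_seed)
    params, grid, ic = matched_pde(recipe)
    pde = cont.solve_coupled_1d(params, grid, ic,
                                [float(s) for s in recipe.record_steps])
    return ens, pde, comparison_report(ens, pde, tolerance)


def isolated_agent_count(occupancy: np.ndarray) -> int:
    """Number of occupied sites with all four nearest neighbours vacant
    (off-lattice neighbours count as vacant)."""
    return lat._isolated_count(np.asarray(occupancy))


def _strip_init(recipe: Recipe):
    def init(config, rng):
        return lat.init_strip(config, recipe.occupied_columns, recipe.s0)
    return init


def _disc_init(recipe: Recipe):
    def init(config, rng):
        return lat.init_disc(config, recipe.radius_sites,
                             recipe.occupancy_prob, recipe.s0, rng=rng)
    return init


def run_recipe(recipe: Recipe, out_dir: str | Path | None = None,
               tolerance: float = 0.05) -> RecipeResult:
    """Execute a recipe end to end and (optionally) write its artifact bundle.

    Outputs, when ``out_dir`` is given: ``profiles.csv`` (column averages),
    ``comparison.csv`` and ``fronts.csv`` for averaged strip recipes,
    ``snapshots.npz`` (first realization's grids) and ``manifest.json``
    with the config hash and seeds.
    """
    if recipe.geometry == "reference-2d":
        result = _run_reference_2d(recipe)
    else:
        init = _disc_init(recipe) if recipe.geometry == "disc" else _strip_init(recipe)
        ens = lat.run_ensemble(recipe.config, init, recipe.n_steps,
                               recipe.record_steps, recipe.M,
                               base_seed=recipe.base_seed,
                               track_isolated=(recipe.geometry == "disc"))
        result = RecipeResult(recipe=recipe, ensemble=ens)
        if recipe.with_pde:
            params, grid, ic = matched_pde(recipe)
            result.pde = cont.solve_coupled_1d(
                params, grid, ic, [float(s) for s in recipe.record_steps])
            result.report = comparison_report(ens, result.pde, tolerance)
            result.fronts = _front_table(ens, result.pde, grid)
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


def _front_table(ens: lat.EnsembleResult, pde: list[cont.Field1D],
                 grid: cont.Grid1D) -> pd.DataFrame:
    eps_stoch = fr.stochastic_eps_u(ens.H, ens.M)
    rows = []
    for k, day in enumerate(ens.times_days):
        if float(day) == 0.0:
            continue
        fm_p = fr.front_locations(grid.centers, pde[k].u, pde[k].s)
        fm_d = fr.front_locations(grid.centers, ens.u_mean[k], ens.s_mean[k],
                                  eps_u=eps_stoch, min_depth=0.02)
        for src, fm in (("pde", fm_p), ("discrete", fm_d)):
            rows.append({"t_days": float(day), "source": src, "eta": fm.eta,
                         "xi": fm.xi, "width": fm.width, "u_star": fm.u_star,
                         "dip_present": fm.dip.present,
                         "dip_depth": fm.dip.depth})
    return pd.DataFrame(rows)


def _run_reference_2d(recipe: Recipe) -> RecipeResult:
    """Linear vs spreading-matched degenerate diffusion in the barrier
    geometry: 10 mm square, 201 x 201 mesh, disc of radius 3 mm at density 1."""
    grid = cont.Grid2D(length=10.0, n=201)          # mm
    D1 = D1_UM2_PER_H * 1e-6                        # mm^2 / h
    D2 = cont.match_diffusivity(D1)
    ic = cont.disc_ic(grid, radius=3.0)
    hours = [24.0 * d for d in recipe.record_days]
    lin = cont.solve_reference_2d("linear", D1, grid, ic, hours)
    deg = cont.solve_reference_2d("degenerate", D2, grid, ic, hours,
                                  n_exponent=1.0)
    mid = grid.n // 2
    prof = pd.DataFrame({
        "x_mm": np.concatenate([grid.centers] * len(hours) * 2),
        "t_days": np.repeat(list(recipe.record_days) * 2, grid.n),
        "model": (["linear"] * grid.n * len(hours)
                  + ["degenerate"] * grid.n * len(hours)),
        "u": np.concatenate([f[:, mid] for f in lin]
                            + [f[:, mid] for f in deg]),
    })
    return RecipeResult(recipe=recipe,
                        extras={"D1": D1, "D2": D2, "d_ratio": D2 / D1,
                                "profiles": prof,
                                "linear": lin, "degenerate": deg,
                                "grid": grid})


def _dump_snapshots(recipe: Recipe, path: Path) -> None:
    """Re-run realization 0 and dump its grids with step/time metadata."""
    init = _disc_init(recipe) if recipe.geometry == "disc" else _strip_init(recipe)
    rng = np.random.default_rng(recipe.base_seed)
    state = init(recipe.config, rng)
    snaps = lat.run(state, recipe.config, recipe.n_steps,
                    record_at=recipe.record_steps, rng=rng)
    arrays = {}
    for snap in snaps:
        arrays[f"occupancy_step{snap.step_count}"] = snap.occupancy
        arrays[f"substrate_step{snap.step_count}"] = snap.substrate
    arrays["record_steps"] = np.asarray(recipe.record_steps)
    arrays["record_days"] = np.asarray(recipe.record_days, dtype=float)
    np.savez_compressed(path, **arrays)


def _config_dict(recipe: Recipe) -> dict:
    d = {f.name: getattr(recipe, f.name) for f in dataclasses.fields(recipe)
         if f.name != "config"}
    if recipe.config is not None:
        cfg = {f.name: getattr(recipe.config, f.name)
               for f in dataclasses.fields(recipe.config) if f.name != "g"}
        cfg["g"] = recipe.config.g.name
        d["config"] = cfg
    return d


def _write_bundle(result: RecipeResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    recipe = result.recipe
    if result.ensemble is not None:
        ens = result.ensemble
        frames = []
        for k, day in enumerate(ens.times_days):
            frames.append(pd.DataFrame({
                "x_site": np.arange(1, ens.W + 1),
                "t_days": float(day),
                "u_avg": ens.u_mean[k],
                "s_avg": ens.s_mean[k],
                "M": ens.M, "H": ens.H}))
        pd.concat(frames, ignore_index=True).to_csv(
            out_dir / "profiles.csv", index=False)
    if result.report is not None:
        result.report.to_csv(out_dir / "comparison.csv", index=False)
    if result.fronts is not None:
        result.fronts.to_csv(out_dir / "fronts.csv", index=False)
    if "profiles" in result.extras:
        result.extras["profiles"].to_csv(out_dir / "profiles.csv", index=False)
    if result.ensemble is not None and recipe.geometry in ("disc", "strip"):
        _dump_snapshots(recipe, out_dir / "snapshots.npz")
    cfg = _config_dict(recipe)
    payload = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "recipe": cfg,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seeds": list(range(recipe.base_seed, recipe.base_seed + recipe.M)),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
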