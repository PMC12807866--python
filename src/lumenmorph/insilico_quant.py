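"""Phenotyping of simulation outputs and the two in-silico experiments.

Per-snapshot phenotype: lumen count (8-connected components of the lumen
field above threshold), lumen occupancy (lumen area over organoid area, the
organoid being the hole-filled union of cells so enclosed lumina count), and
mean organoid radius sqrt(area/π).  On top of that, the ξ × τ_V phase-diagram
sweep and the paired division-arrest experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import sim_core
from .cell_cycle import CellCycleParams
from .sim_core import EnergyParams, GridSpec, SimState

__all__ = [
    "PhenotypeRow",
    "label_lumina",
    "phenotype",
    "sweep_phase_diagram",
    "arrest_experiment",
    "map_invitro_to_phase_diagram",
    "pressure_xi_calibration",
    "PAPER_TAU_V_LIST",
    "PAPER_XI_LIST",
]

# published sweep grids: τ_V ∈ {1, 10, 20, ..., 90}, ξ from 0.10 to 0.32
# in increments of 0.02 (10 × 12 = 120 combinations)
PAPER_TAU_V_LIST = (1.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0)
PAPER_XI_LIST = tuple(np.round(np.arange(0.10, 0.321, 0.02), 2))

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class PhenotypeRow:
    tau_v: float
    xi: float
    seed: int
    time: float
    n_cells: int
    n_lumina: int
    lumen_occupancy: float      # fraction in [0, 1]
    mean_radius: float          # simulation length units

    def __post_init__(self) -> None:
        if not 0.0 <= self.lumen_occupancy <= 1.0:
            raise ValueError("occupancy out of [0, 1]")
        if self.n_lumina < 0:
            raise ValueError("negative lumen count")


class UndefinedPhenotypeError(ValueError):
    """Zero organoid area: occupancy/radius undefined."""


def label_lumina(lumen_field: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Connected components of {w > threshold}, 8-connectivity, labelled
    1..K in deterministic raster order."""
    if not np.all(np.isfinite(lumen_field)):
        raise ValueError("non-finite lumen field")
    labels, _ = ndimage.label(lumen_field > threshold, structure=_EIGHT)
    return labels


def organoid_mask(state: SimState, threshold: float = 0.5) -> np.ndarray:
    """Union of supra-threshold cells and lumen, with holes filled so
    enclosed lumina count toward the organoid area."""
    mask = state.lumen_field > threshold
    if state.n_cells:
        mask = mask | (state.fields.max(axis=0) > threshold)
    return ndimage.binary_fill_holes(mask)


def phenotype(state: SimState, grid: GridSpec,
              tau_v: float = np.nan, xi: float = np.nan,
              seed: int = -1, threshold: float = 0.5) -> PhenotypeRow:
    """Measure one state: occupancy = A_lumen / A_organoid,
    mean_radius = sqrt(A_organoid / π)."""
    dx2 = grid.dx * grid.dx
    org = organoid_mask(state, threshold)
    a_org = org.sum() * dx2
    if a_org <= 0:
        raise UndefinedPhenotypeError("zero organoid area")
    lum = state.lumen_field > threshold
    a_lum = lum.sum() * dx2
    labels, n_lum = ndimage.label(lum, structure=_EIGHT)
    return PhenotypeRow(
        tau_v=tau_v, xi=xi, seed=seed, time=state.time,
        n_cells=state.n_cells, n_lumina=int(n_lum),
        lumen_occupancy=min(float(a_lum / a_org), 1.0),
        mean_radius=float(np.sqrt(a_org / np.pi)),
    )


# ---------------------------------------------------------------------------
# phase diagram sweep

DEFAULT_SWEEP_T_END = 60.0
DEFAULT_SWEEP_MAX_CELLS = 36


def sweep_phase_diagram(tau_v_list=PAPER_TAU_V_LIST, xi_list=PAPER_XI_LIST,
                        reps: int = 1, t_end: float = DEFAULT_SWEEP_T_END,
                        seed: int = 0, grid: GridSpec | None = None,
                        params: EnergyParams | None = None,
                        cycle: CellCycleParams | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One run per (τ_V, ξ, rep); returns (tidy rows, gridded summary).

    Individual run failures are recorded (column ``completed``) and the cell
    of the grid marked incomplete; the sweep continues.  Fully reproducible:
    the seed of run (τ_V, ξ, rep) is derived from ``seed`` and the indices.
    """
    if not len(tau_v_list) or not len(xi_list):
        raise ValueError("parameter lists must be non-empty")
    grid = grid or GridSpec()
    base_params = params or EnergyParams()
    base_cycle = cycle or CellCycleParams()

    rows = []
    for it, tau_v in enumerate(tau_v_list):
        for ix, xi in enumerate(xi_list):
            p = EnergyParams(**{**sim_core.params_to_dict(base_params),
                                "xi": float(xi)})
            c = CellCycleParams(**{**sim_core.params_to_dict(base_cycle),
                                   "tau_v": float(tau_v)})
            for rep in range(reps):
                run_seed = (seed * 1_000_003 + it * 10_007 + ix * 101
                            + rep) % (2**31 - 1)
                res = sim_core.run(p, grid, c, t_end=t_end,
                                   snapshot_interval=t_end or 1.0,
                                   seed=run_seed, keep_fields=False,
                                   max_cells=DEFAULT_SWEEP_MAX_CELLS)
                last = res.metrics.iloc[-1]
                rows.append({
                    "tau_v": tau_v, "xi": xi, "rep": rep, "seed": run_seed,
                    "time": last["time"], "n_cells": int(last["n_cells"]),
                    "n_lumina": int(last["n_lumina"]),
                    "lumen_occupancy": last["lumen_occupancy"],
                    "mean_radius": last["mean_radius"],
                    "completed": res.completed,
                })
    tidy = pd.DataFrame(rows)
    summary = (tidy.groupby(["tau_v", "xi"])
               .agg(n_lumina=("n_lumina", "mean"),
                    lumen_occupancy=("lumen_occupancy", "mean"),
                    n_cells=("n_cells", "mean"),
                    n_runs=("rep", "size"),
                    complete=("completed", "all"))
               .reset_index())
    return tidy, summary


# ---------------------------------------------------------------------------
# division-arrest experiment

ARREST_GRID = dict(nx=160, ny=160)   # roomier lattice than the sweep's


def arrest_experiment(tau_v: float = 40.0, xi: float = 0.12,
                      arrest_count: int = 32, reps: int = 10,
                      seed: int = 0, t_end: float = 200.0,
                      snapshot_interval: float = 5.0,
                      grid: GridSpec | None = None,
                      params: EnergyParams | None = None,
                      cycle: CellCycleParams | None = None,
                      max_cells: int = 40,
                      radius_bin_width: float = 0.25) -> dict:
    """Paired control/arrest runs (same seeds) and radius-binned curves.

    Returns a dict with tidy per-snapshot trajectories for both arms and
    moving-average curves of occupancy and lumen number against mean
    organoid radius (fixed-width radius bins).
    """
    if arrest_count < 2:
        raise ValueError("arrest_count must be >= 2")
    grid = grid or GridSpec(**ARREST_GRID)
    base_params = params or EnergyParams()
    base_cycle = cycle or CellCycleParams()
    p = EnergyParams(**{**sim_core.params_to_dict(base_params),
                        "xi": float(xi)})

    traj = []
    for rep in range(reps):
        run_seed = (seed * 1_000_003 + rep) % (2**31 - 1)
        for arm, arrest in (("control", None), ("arrest", arrest_count)):
            c = CellCycleParams(**{**sim_core.params_to_dict(base_cycle),
                                   "tau_v": float(tau_v),
                                   "arrest_count": arrest})
            res = sim_core.run(p, grid, c, t_end=t_end,
                               snapshot_interval=snapshot_interval,
                               seed=run_seed, keep_fields=False,
                               max_cells=max_cells)
            m = res.metrics.copy()
            m["arm"] = arm
            m["rep"] = rep
            m["completed"] = res.completed
            traj.append(m)
    if not traj:
        empty = pd.DataFrame()
        return {"trajectories": empty, "curves": empty, "pairs": empty}

    t = pd.concat(traj, ignore_index=True)
    t["radius_bin"] = (np.floor(t["mean_radius"] / radius_bin_width)
                       * radius_bin_width + radius_bin_width / 2.0)
    curves = (t.groupby(["arm", "radius_bin"])
              .agg(lumen_occupancy_mean=("lumen_occupancy", "mean"),
                   lumen_occupancy_std=("lumen_occupancy", "std"),
                   n_lumina_mean=("n_lumina", "mean"),
                   n_lumina_std=("n_lumina", "std"),
                   n_cells_mean=("n_cells", "mean"),
                   n=("rep", "size"))
              .reset_index())

    # per-replicate paired comparison over the common time window; the
    # occupancy is averaged over the final quarter of that window to smooth
    # slow inflation/reseal cycles of the relaxing lumen
    pairs = []
    for rep, sub in t.groupby("rep"):
        arms = {arm: s.sort_values("time") for arm, s in sub.groupby("arm")}
        if len(arms) < 2:
            continue
        t_common = min(s["time"].max() for s in arms.values())
        win = (max(0.75 * t_common, t_common - 0.25 * t_end), t_common)

        def tail(s):
            m = s[(s["time"] >= win[0]) & (s["time"] <= win[1])]
            return m if len(m) else s.tail(1)

        ca, cc_ = tail(arms["arrest"]), tail(arms["control"])
        arrest_at_common = arms["arrest"][arms["arrest"]["time"]
                                          <= t_common + 1e-9]
        pairs.append({
            "rep": rep,
            "t_common": t_common,
            "arrest_n_lumina": int(arrest_at_common.iloc[-1]["n_lumina"]),
            "control_n_lumina": int(arms["control"].iloc[-1]["n_lumina"]),
            "arrest_tail_occupancy": float(ca["lumen_occupancy"].mean()),
            "control_tail_occupancy": float(cc_["lumen_occupancy"].mean()),
            "arrest_higher": bool(ca["lumen_occupancy"].mean()
                                  > cc_["lumen_occupancy"].mean()),
        })
    return {"trajectories": t, "curves": curves, "pairs": pd.DataFrame(pairs)}


# ---------------------------------------------------------------------------
# pressure calibration: hydrostatic ΔP vs osmotic ξ

def pressure_xi_calibration(xi_list=(0.10, 0.16, 0.22, 0.28),
                            target_area: float = 8.0, n_shell: int = 8,
                            seed: int = 0, seed_area: float = 2.0,
                            max_t: float = 150.0,
                            grid: GridSpec | None = None,
                            params: EnergyParams | None = None) -> dict:
    """Hydrostatic pressure of matched-size single lumina across ξ.

    For each ξ a shell of ``n_shell`` non-dividing cells with a central
    lumen seed is relaxed until the lumen reaches ``target_area``; the
    mechanical pressure is then read with
    :func:`lumenmorph.sim_core.estimate_insilico_pressure`.  Matching the
    lumen size keeps the geometric (Laplace) contribution constant, so the
    ξ dependence of the estimate isolates the osmotically transmitted
    stress.  Returns the per-ξ table and the linear fit (slope, intercept,
    r_squared), which can feed
    :func:`map_invitro_to_phase_diagram` as ``dp_calibration``.
    """
    from scipy import stats

    from . import cell_cycle as cc

    if len(xi_list) < 2:
        raise ValueError("need at least two xi values")
    grid = grid or GridSpec()
    base = params or EnergyParams()
    rows = []
    for xi in xi_list:
        p = EnergyParams(**{**sim_core.params_to_dict(base),
                            "xi": float(xi)})
        st = sim_core.init_state(grid, n_shell, seed, params=p)
        centre = (grid.nx * grid.dx / 2.0, grid.ny * grid.dx / 2.0)
        cc.seed_micro_lumen(st, grid, p, centre, seed_area)
        while st.time < max_t:
            sim_core._advance(st, p, grid, 10)
            if sim_core.measure_volume(st.lumen_field, grid.dx) >= target_area:
                break
        ests = sim_core.estimate_insilico_pressure(st, p, grid)
        if not ests:
            rows.append({"xi": xi, "delta_p": np.nan, "area": 0.0,
                         "n_lumina": 0})
            continue
        big = max(ests, key=lambda e: e["area"])
        rows.append({"xi": xi, "delta_p": big["delta_p"],
                     "area": big["area"], "n_lumina": len(ests)})
    table = pd.DataFrame(rows).dropna()
    fit = stats.linregress(table["xi"], table["delta_p"])
    return {"table": table, "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "r_squared": float(fit.rvalue**2)}


# ---------------------------------------------------------------------------
# placing in vitro organoids on the diagram

def map_invitro_to_phase_diagram(xi_spherical: float, xi_branching: float,
                                 tau_spherical: float | None = None,
                                 tau_branching: float | None = None,
                                 dp_calibration: tuple[float, float] | None = None,
                                 ) -> dict:
    """ξ ratio of the two phenotype placements, optionally with the implied
    hydrostatic-pressure ratio from a linear ΔP(ξ) calibration.

    ``dp_calibration`` is (slope, intercept) of a linear fit of in-silico
    pressure estimates against ξ (see
    :func:`lumenmorph.sim_core.estimate_insilico_pressure`); when absent the
    ΔP ratio is omitted with a notice.
    """
    if xi_branching <= 0:
        raise ValueError("branching ξ placement must be > 0")
    out = {
        "xi_spherical": xi_spherical,
        "xi_branching": xi_branching,
        "tau_spherical": tau_spherical,
        "tau_branching": tau_branching,
        "xi_ratio": xi_spherical / xi_branching,
    }
    if dp_calibration is None:
        out["dp_ratio"] = None
        out["notice"] = "no ΔP(ξ) calibration supplied; ΔP ratio omitted"
    else:
        slope, intercept = dp_calibration
        dp_b = slope * xi_branching + intercept
        if dp_b <= 0:
            raise ValueError("calibration gives non-positive branching ΔP")
        out["dp_ratio"] = (slope * xi_spherical + intercept) / dp_b
    return out
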