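"""Cell growth rule, division trigger, cleavage geometry and micro-lumen seeding.

The target volume of every cell relaxes exponentially toward the asymptote
V̄ with characteristic time τ_V,

    τ_V dV_target,i/dt = V̄ − V_target,i(t),

so τ_V is the cell-cycle-duration control knob: a cell divides as soon as its
actual volume v_m(t) reaches the division volume V_d (no refractory period is
imposed).  At the end of each division a micro-lumen of fixed size is seeded
at the midpoint of the spindle poles (the parent centroid).  Divisions can be
arrested once the organoid reaches a configured cell count, which mimics a
proliferation-arrest (aphidicolin-type) experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sim_core import (EnergyParams, GridSpec, SimState, disc_profile,
                       interface_scale, lumen_interface_scale, measure_volume)

__all__ = [
    "CellCycleParams",
    "update_target_volumes",
    "check_divisions",
    "division_axis",
    "divide_cell",
    "seed_micro_lumen",
    "divisions_permitted",
    "apply_arrest",
]


@dataclass(frozen=True)
class CellCycleParams:
    """Growth/division parameters (simulation units).

    Defaults: V̄ = 3.0 and micro_lumen_size = 0.7 are the published model
    values; V_d = 2.0 is a calibration constant chosen so the inter-division
    interval scales as ≈ 0.69·τ_V.
    """

    tau_v: float = 40.0
    v_bar: float = 3.0
    v_d: float = 2.0
    micro_lumen_size: float = 0.7
    arrest_count: int | None = None

    def __post_init__(self) -> None:
        if self.tau_v <= 0:
            raise ValueError("tau_v must be > 0")
        if self.v_bar <= 0 or self.v_d <= 0:
            raise ValueError("v_bar and v_d must be > 0")
        if self.micro_lumen_size < 0:
            raise ValueError("micro_lumen_size must be >= 0")
        if self.arrest_count is not None and self.arrest_count < 1:
            raise ValueError("arrest_count must be positive when set")


def update_target_volumes(targets: np.ndarray, tau_v: float, v_bar: float,
                          dt: float) -> np.ndarray:
    """Advance targets by the exact exponential-integrator solution over dt.

    V_target(t+dt) = V̄ + (V_target(t) − V̄)·exp(−dt/τ_V); updates in place
    and returns the array.  Exact for any dt, hence monotone toward V̄.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not np.all(np.isfinite(targets)):
        raise ValueError("non-finite target volume")
    decay = np.exp(-dt / tau_v)
    targets *= decay
    targets += v_bar * (1.0 - decay)
    return targets


def check_divisions(state: SimState, v_d: float) -> list[int]:
    """Ids of cells whose actual volume has reached V_d (inclusive ≥)."""
    return [int(m) for m in np.flatnonzero(state.volumes >= v_d)]


def divisions_permitted(state: SimState, arrest_count: int | None) -> bool:
    """False once the live-cell count has reached ``arrest_count``.

    With no death in the model the count never decreases, so the flag
    stays false for the remainder of the run once tripped.
    """
    if arrest_count is None:
        return True
    return state.n_cells < arrest_count


#: division-permission flag for an arrest experiment (name used by callers
#: thinking in terms of applying an arrest protocol)
apply_arrest = divisions_permitted


CARVE_FACTOR = 1.0
TARGET_RESET_JITTER = 0.05

ISOTROPY_TOL = 0.05


def division_axis(cell_field: np.ndarray, dx: float,
                  rng: np.random.Generator | None = None,
                  threshold: float = 0.5) -> np.ndarray:
    """Cleavage-plane normal for one cell (unit 2-vector).

    Default policy is a Hertwig-rule proxy: the normal is the long axis of
    the supra-threshold region, from the eigen-decomposition of its second
    moments, so the cleavage plane cuts across the long axis.  A nearly
    isotropic cell draws a uniformly random axis from ``rng`` (deterministic
    per seed).  The policy is a plain function so a spindle-force model can
    be substituted by the caller.
    """
    mask = cell_field > threshold
    if not mask.any():
        raise ValueError("cell has no supra-threshold area")
    pts = np.argwhere(mask).astype(float) * dx
    c = pts.mean(axis=0)
    if len(pts) < 3:
        evals = np.zeros(2)
        evecs = np.eye(2)
    else:
        cov = np.cov((pts - c).T)
        evals, evecs = np.linalg.eigh(cov)      # ascending
    if evals[1] <= 0 or (evals[1] - evals[0]) / evals[1] < ISOTROPY_TOL:
        if rng is None:
            rng = np.random.default_rng(0)
        th = rng.uniform(0.0, np.pi)
        return np.array([np.cos(th), np.sin(th)])
    axis = evecs[:, 1]
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):   # canonical sign
        axis = -axis
    return axis / np.linalg.norm(axis)


def seed_micro_lumen(state: SimState, grid: GridSpec, params: EnergyParams,
                     centre: tuple[float, float], size: float) -> None:
    """Insert a smooth lumen bump of area ``size`` centred at ``centre``.

    The bump is merged into the lumen field by pointwise max, and the cell
    fields are locally suppressed underneath it: abscission displaces the
    membranes, creating the cavity.  The cells' volume constraint restores
    their lost volume by outward expansion during subsequent relaxation.
    """
    if size <= 0:
        return
    scale = lumen_interface_scale(grid, params)
    # calibrate the disc radius so that ∫h(bump) dx² equals `size`: the
    # soft profile carries substantial mass in its skirt
    radius = float(np.sqrt(size / np.pi))
    bump = disc_profile(grid, centre[0], centre[1], radius, scale)
    for _ in range(4):
        m = measure_volume(bump, grid.dx)
        if m <= 0:
            break
        radius = max(radius * np.sqrt(size / m), 0.5 * grid.dx)
        bump = disc_profile(grid, centre[0], centre[1], radius, scale)
    np.maximum(state.lumen_field, bump, out=state.lumen_field)
    # carve slightly wider than the seed so the nascent cavity is not
    # instantly re-invaded before pressure can establish
    carve = disc_profile(grid, centre[0], centre[1], CARVE_FACTOR * radius,
                         scale)
    state.fields *= (1.0 - carve)[None]
    for m in range(state.n_cells):
        state.volumes[m] = measure_volume(state.fields[m], grid.dx)


def divide_cell(state: SimState, cell_id: int, grid: GridSpec,
                params: EnergyParams, cycle: CellCycleParams,
                axis: np.ndarray | None = None) -> dict | None:
    """Split cell ``cell_id`` across the cleavage plane through its centroid.

    The parent field is multiplied by complementary logistic half-masks
    normal to ``axis`` (default: :func:`division_axis` on the parent), giving
    two daughters of ≈ half the parent volume each.  Daughter targets are
    reset to max(v_daughter, V_d/2) so growth resumes without instantaneous
    re-division.  A micro-lumen of area ``micro_lumen_size`` is seeded at the
    parent centroid (midpoint of the spindle poles).  Mutates ``state`` and
    returns an event record, or None when the cleavage would produce an
    empty daughter (division deferred).
    """
    u = state.fields[cell_id]
    mask = u > 0.5
    if not mask.any():
        return None                       # too diffuse to cleave: defer
    if axis is None:
        axis = division_axis(u, grid.dx, state.rng)
    pts = np.argwhere(mask).astype(float) * grid.dx
    c = pts.mean(axis=0)

    x = (np.arange(grid.nx) + 0.5) * grid.dx
    y = (np.arange(grid.ny) + 0.5) * grid.dx
    s = (x[:, None] - c[0]) * axis[0] + (y[None, :] - c[1]) * axis[1]
    # half the interface scale: the nonlinear volume interpolant loses mass
    # in the transition band, so the cut is kept narrow and relaxation
    # re-equilibrates the profiles
    scale = 0.5 * interface_scale(grid, params)
    with np.errstate(over="ignore"):
        half = 1.0 / (1.0 + np.exp(-s / scale))

    da = u * half
    db = u * (1.0 - half)
    va = measure_volume(da, grid.dx)
    vb = measure_volume(db, grid.dx)
    if min(va, vb) < 0.05 * (va + vb):
        return None                       # pathological shape: defer

    state.fields[cell_id] = da
    state.fields = np.concatenate([state.fields, db[None]], axis=0)
    state.volumes = np.concatenate([state.volumes, [vb]])
    state.volumes[cell_id] = va
    # small seeded jitter on the reset desynchronises lineages, standing in
    # for the cell-to-cell variability of real cycle durations
    ja, jb = 1.0 + TARGET_RESET_JITTER * state.rng.uniform(-1, 1, size=2)
    reset_a = max(va, cycle.v_d / 2.0) * ja
    reset_b = max(vb, cycle.v_d / 2.0) * jb
    state.target_volumes = np.concatenate([state.target_volumes, [reset_b]])
    state.target_volumes[cell_id] = reset_a

    seed_micro_lumen(state, grid, params, (c[0], c[1]),
                     cycle.micro_lumen_size)
    return {
        "parent_id": int(cell_id),
        "daughter_ids": (int(cell_id), state.n_cells - 1),
        "axis_x": float(axis[0]),
        "axis_y": float(axis[1]),
        "seed_x": float(c[0]),
        "seed_y": float(c[1]),
    }
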