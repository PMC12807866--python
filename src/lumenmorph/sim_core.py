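"""2D multicellular phase-field engine for organoid lumenogenesis.

Each cell ``m`` is a smooth scalar field ``u_m(x) ∈ [0, 1]`` and the lumen is a
single shared field ``w(x)``; organoid mechanics are encoded in a free energy

    F = Σ_m ∫ (ε²/2)|∇u_m|² + W u_m²(1−u_m)² dx          (interface tension)
      + Σ_m α (V_target,m(t) − V_m(t))²                   (volume constraint)
      + (β/2) ∫ H² − Σ_k h_k² dx,  H = Σ_m h(u_m) + h(w)  (mutual exclusion)
      + (η/2) [∫|∇S|² − Σ_k ∫|∇u_k|² − ∫|∇w|²]           (adhesion)
      − ξ V_lumen                                         (lumen osmotic pressure)

with ``h(u) = u²(3 − 2u)`` the volume interpolant, ``V_m = ∫ h(u_m) dx²`` and
``S = Σ u_m + w``.  All fields relax by non-conserved (Allen–Cahn) gradient
flow ``∂u/∂t = −M δF/δu`` integrated with explicit Euler on a regular lattice
with zero-flux (mirror) boundaries.  The lumen osmotic pressure ξ is one
constant shared by all lumina of an organoid; it enters linearly, so doubling
ξ doubles the pressure energy of a fixed state.

Everything is in dimensionless simulation units.  Cell growth and division
rules live in :mod:`lumenmorph.cell_cycle`; phenotyping in
:mod:`lumenmorph.insilico_quant`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "GridSpec",
    "EnergyParams",
    "SimState",
    "PlacementError",
    "IntegrationError",
    "NumericalStateError",
    "init_state",
    "free_energy",
    "interface_tension",
    "step",
    "run",
    "RunResult",
    "estimate_insilico_pressure",
    "save_snapshots_tiff",
    "save_run_hdf5",
    "write_manifest",
]

# Margin (in lattice sites) that must stay empty at the domain boundary;
# mirror boundaries would otherwise create interaction artefacts.
BOUNDARY_MARGIN = 4

# Field values are clamped-checked against this numerical tolerance.
FIELD_TOL = 0.05


class PlacementError(ValueError):
    """Domain too small to place the requested cells away from the margin."""


class IntegrationError(RuntimeError):
    """Explicit relaxation violated the energy-descent stability contract."""


class NumericalStateError(RuntimeError):
    """NaN/Inf contaminated a field."""


@dataclass(frozen=True)
class GridSpec:
    """Regular lattice and explicit-Euler time step.

    ``interface_width`` is the phase-field parameter ε; the equilibrium
    interface profile is a logistic of scale ε/√(2W).
    """

    nx: int = 128
    ny: int = 128
    dx: float = 0.11
    dt: float = 0.01
    interface_width: float = 0.22

    def __post_init__(self) -> None:
        if self.nx < 32 or self.ny < 32:
            raise ValueError("grid must be at least 32x32")
        if self.dx <= 0 or self.dt <= 0:
            raise ValueError("dx and dt must be positive")

    def stability_limit(self, mobility: float = 1.0) -> float:
        """Diffusive explicit-stability bound on dt (with safety factor 2)."""
        return self.dx**2 / (4.0 * mobility * self.interface_width**2) / 2.0


@dataclass(frozen=True)
class EnergyParams:
    """Coefficients of the free-energy functional (simulation units).

    alpha is the volume-constraint strength (default 1.0); xi the lumen
    osmotic pressure.  surface_coef is the double-well depth W; together with
    the interface width ε it sets the interface tension σ = ε√(2W)/6.
    exclusion/adhesion/mobility are calibration constants of the model family
    (not measured quantities).
    """

    alpha: float = 1.0
    surface_coef: float = 1.0
    lumen_surface_coef: float = 0.15
    exclusion_coef: float = 4.0
    lumen_exclusion_coef: float = 0.8
    lumen_adhesion_coef: float = 0.0
    adhesion_coef: float = 0.0
    xi: float = 0.0
    mobility: float = 1.0
    lumen_mobility: float = 0.3

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.xi < 0:
            raise ValueError("xi must be >= 0")
        for name in ("surface_coef", "lumen_surface_coef", "exclusion_coef",
                     "lumen_exclusion_coef", "lumen_adhesion_coef",
                     "adhesion_coef", "mobility", "lumen_mobility"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class SimState:
    """All per-cell fields, the lumen field, volumes and the clock."""

    fields: np.ndarray            # (n_cells, nx, ny)
    lumen_field: np.ndarray       # (nx, ny)
    volumes: np.ndarray           # (n_cells,)
    target_volumes: np.ndarray    # (n_cells,)
    time: float
    seed: int
    rng: np.random.Generator = field(repr=False, default=None)

    @property
    def n_cells(self) -> int:
        return self.fields.shape[0]

    def copy(self) -> "SimState":
        st = SimState(
            fields=self.fields.copy(),
            lumen_field=self.lumen_field.copy(),
            volumes=self.volumes.copy(),
            target_volumes=self.target_volumes.copy(),
            time=self.time,
            seed=self.seed,
        )
        st.rng = np.random.default_rng()
        st.rng.bit_generator.state = self.rng.bit_generator.state
        return st

    def validate(self) -> None:
        for arr in (self.fields, self.lumen_field):
            if not np.all(np.isfinite(arr)):
                raise NumericalStateError("non-finite field values")
        lo = min(self.fields.min(initial=0.0), self.lumen_field.min())
        hi = max(self.fields.max(initial=0.0), self.lumen_field.max())
        if lo < -FIELD_TOL or hi > 1.0 + FIELD_TOL:
            raise NumericalStateError(
                f"field out of [0,1] tolerance band: min={lo:.3g} max={hi:.3g}")


# ---------------------------------------------------------------------------
# helpers

def volume_interpolant(u: np.ndarray) -> np.ndarray:
    """h(u) = u²(3 − 2u): smooth volume fraction."""
    return u * u * (3.0 - 2.0 * u)


def measure_volume(u: np.ndarray, dx: float) -> float:
    return float(np.sum(volume_interpolant(u))) * dx * dx


def interface_tension(grid: GridSpec, params: EnergyParams) -> float:
    """Analytic line tension σ = ε√(2W)/6 of the equilibrium profile."""
    return grid.interface_width * np.sqrt(2.0 * params.surface_coef) / 6.0


def lumen_interface_tension(grid: GridSpec, params: EnergyParams) -> float:
    """σ of the lumen interface (its softer well)."""
    return (grid.interface_width
            * np.sqrt(2.0 * params.lumen_surface_coef) / 6.0)


def lumen_interface_scale(grid: GridSpec, params: EnergyParams) -> float:
    return grid.interface_width / np.sqrt(2.0 * params.lumen_surface_coef)


def interface_scale(grid: GridSpec, params: EnergyParams) -> float:
    """Logistic length scale ε/√(2W) of the equilibrium interface profile."""
    return grid.interface_width / np.sqrt(2.0 * params.surface_coef)


def disc_profile(grid: GridSpec, cx: float, cy: float, radius: float,
                 scale: float) -> np.ndarray:
    """Smooth disc: u = 1 at centre, logistic falloff of width ``scale``."""
    x = (np.arange(grid.nx) + 0.5) * grid.dx
    y = (np.arange(grid.ny) + 0.5) * grid.dx
    d = np.hypot(x[:, None] - cx, y[None, :] - cy)
    with np.errstate(over="ignore"):
        u = 1.0 / (1.0 + np.exp((d - radius) / scale))
    return u


def _mirror_laplacian(u: np.ndarray, dx: float) -> np.ndarray:
    """5-point Laplacian with zero-flux (mirror) boundaries."""
    up = np.pad(u, 1, mode="edge")
    return (up[:-2, 1:-1] + up[2:, 1:-1] + up[1:-1, :-2] + up[1:-1, 2:]
            - 4.0 * u) / (dx * dx)


def _grad_sq(u: np.ndarray, dx: float) -> np.ndarray:
    gx, gy = np.gradient(u, dx)
    return gx * gx + gy * gy


# ---------------------------------------------------------------------------
# initialisation

DEFAULT_INITIAL_VOLUME = 1.5


def init_state(grid: GridSpec, n_cells: int, seed: int,
               initial_volume: float = DEFAULT_INITIAL_VOLUME,
               params: EnergyParams | None = None) -> SimState:
    """Place ``n_cells`` relaxed disc profiles near the domain centre.

    Cells are laid out on a deterministic sunflower spiral with a small
    seeded jitter; the lumen field starts empty.  Raises
    :class:`PlacementError` when the discs cannot be kept clear of the
    boundary margin.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    params = params or EnergyParams()
    rng = np.random.default_rng(seed)
    scale = interface_scale(grid, params)
    r0 = float(np.sqrt(initial_volume / np.pi))

    lx, ly = grid.nx * grid.dx, grid.ny * grid.dx
    cx0, cy0 = lx / 2.0, ly / 2.0
    margin = (BOUNDARY_MARGIN + 2) * grid.dx + r0 + 3.0 * scale

    # ring packing around the centre (a micro-lumen can then be seeded at
    # the centre without gutting a cell), randomly oriented per seed
    centres = []
    if n_cells == 1:
        centres.append((cx0, cy0))
    else:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        ring_r = max(1.05 * r0 / np.sin(np.pi / n_cells), 1.1 * r0)
        for k in range(n_cells):
            th = phase + 2.0 * np.pi * k / n_cells
            centres.append((cx0 + ring_r * np.cos(th),
                            cy0 + ring_r * np.sin(th)))
    for cx, cy in centres:
        if (cx < margin or cx > lx - margin or cy < margin or cy > ly - margin):
            raise PlacementError(
                f"cannot place {n_cells} cells of radius {r0:.2f} on a "
                f"{grid.nx}x{grid.ny} grid without touching the margin")

    fields = np.stack([disc_profile(grid, cx, cy, r0, scale)
                       for cx, cy in centres])
    volumes = np.array([measure_volume(u, grid.dx) for u in fields])
    state = SimState(
        fields=fields,
        lumen_field=np.zeros((grid.nx, grid.ny)),
        volumes=volumes,
        target_volumes=volumes.copy(),
        time=0.0,
        seed=seed,
        rng=rng,
    )
    return state


# ---------------------------------------------------------------------------
# free energy

def free_energy(state: SimState, params: EnergyParams,
                grid: GridSpec) -> dict[str, float]:
    """Per-term energy breakdown plus ``total``.

    Components: interface (cells + lumen), volume_constraint, exclusion,
    adhesion, lumen_pressure (= −ξ·V_lumen, more negative for larger lumina).
    """
    state.validate()
    dx2 = grid.dx * grid.dx
    eps2 = grid.interface_width**2
    W = params.surface_coef

    interface = 0.0
    grad_sum = 0.0
    h_sq_sum = np.zeros_like(state.lumen_field)
    H = volume_interpolant(state.lumen_field)
    S = state.lumen_field.copy()
    for u in state.fields:
        g2 = _grad_sq(u, grid.dx)
        interface += np.sum(0.5 * eps2 * g2 + W * u * u * (1 - u) ** 2) * dx2
        grad_sum += np.sum(g2) * dx2
        h = volume_interpolant(u)
        H += h
        h_sq_sum += h * h
        S += u
    wl = state.lumen_field
    g2w = _grad_sq(wl, grid.dx)
    interface += np.sum(0.5 * eps2 * g2w
                        + params.lumen_surface_coef
                        * wl * wl * (1 - wl) ** 2) * dx2
    grad_sum += np.sum(g2w) * dx2

    volume_constraint = float(
        np.sum(params.alpha * (state.target_volumes - state.volumes) ** 2))
    hw = volume_interpolant(wl)
    Hc = H - hw          # cells only
    cell_cell = 0.5 * float(np.sum(Hc * Hc - h_sq_sum)) * dx2
    cell_lumen = float(np.sum(Hc * hw)) * dx2
    exclusion = (params.exclusion_coef * cell_cell
                 + params.lumen_exclusion_coef * cell_lumen)
    # apical adhesion couples the two interface zones: negative at contact
    gx_c, gy_c = np.gradient(Hc, grid.dx)
    gx_w, gy_w = np.gradient(hw, grid.dx)
    contact_adhesion = params.lumen_adhesion_coef * float(
        np.sum(gx_c * gx_w + gy_c * gy_w)) * dx2
    adhesion = 0.5 * params.adhesion_coef * (
        float(np.sum(_grad_sq(S, grid.dx))) * dx2 - grad_sum)
    lumen_volume = float(np.sum(volume_interpolant(wl))) * dx2
    lumen_pressure = -params.xi * lumen_volume

    terms = {
        "interface": float(interface),
        "volume_constraint": volume_constraint,
        "exclusion": float(exclusion),
        "adhesion": float(adhesion + contact_adhesion),
        "lumen_pressure": float(lumen_pressure),
    }
    terms["total"] = float(sum(terms.values()))
    return terms


# ---------------------------------------------------------------------------
# numba relaxation kernel

@njit(cache=True)
def _h(u):
    # volume interpolant, saturated outside [0, 1] so transient overshoots
    # cannot feed back into the force terms
    if u <= 0.0:
        return 0.0
    if u >= 1.0:
        return 1.0
    return u * u * (3.0 - 2.0 * u)


@njit(cache=True)
def _hp(u):
    # h'(u) = 6u(1−u), zero outside [0, 1] (see _h)
    if u <= 0.0 or u >= 1.0:
        return 0.0
    return 6.0 * u * (1.0 - u)


@njit(cache=True)
def _step_kernel(fields, w, bboxes, volumes, targets, n_steps,
                 dx, dt, eps2, W, Ww, alpha, beta, betw, acw, eta, xi, mob, mobw):
    # acw couples cell and lumen interfaces: F += acw ∫ ∇h_cells·∇h_lumen
    """``n_steps`` explicit Euler updates of all fields, in place.

    Cell updates run on per-cell bounding boxes (cells are compact); the
    lumen field updates on the full domain.  Mirror boundaries throughout.
    Returns nothing; ``volumes`` is refreshed each step.
    """
    n = fields.shape[0]
    nx, ny = w.shape
    dx2 = dx * dx
    inv_dx2 = 1.0 / dx2
    H = np.empty((nx, ny))
    HW = np.empty((nx, ny))
    lapH = np.empty((nx, ny))
    lapHW = np.empty((nx, ny))
    S = np.empty((nx, ny))
    lapS = np.empty((nx, ny))
    wnew = np.empty((nx, ny))

    for _ in range(n_steps):
        # totals over cells: H = Σ h(u), S = Σ u + w, HW = h(w)
        for i in range(nx):
            for j in range(ny):
                H[i, j] = 0.0
                S[i, j] = w[i, j]
                HW[i, j] = _h(w[i, j])
        for m in range(n):
            i0, i1, j0, j1 = bboxes[m]
            for i in range(i0, i1):
                for j in range(j0, j1):
                    uv = fields[m, i, j]
                    H[i, j] += _h(uv)
                    S[i, j] += uv
        # Laplacians of the totals (mirror boundaries)
        for i in range(nx):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < nx - 1 else nx - 1
            for j in range(ny):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < ny - 1 else ny - 1
                lapS[i, j] = (S[im, j] + S[ip, j] + S[i, jm] + S[i, jp]
                              - 4.0 * S[i, j]) * inv_dx2
                lapH[i, j] = (H[im, j] + H[ip, j] + H[i, jm] + H[i, jp]
                              - 4.0 * H[i, j]) * inv_dx2
                lapHW[i, j] = (HW[im, j] + HW[ip, j] + HW[i, jm]
                               + HW[i, jp] - 4.0 * HW[i, j]) * inv_dx2

        # cell updates
        for m in range(n):
            i0, i1, j0, j1 = bboxes[m]
            pnx, pny = i1 - i0, j1 - j0
            patch = np.empty((pnx, pny))
            # saturate the volume-constraint pressure so a freshly carved or
            # compressed cell cannot out-push exclusion and interpenetrate
            dv = 2.0 * alpha * (targets[m] - volumes[m])
            if dv > 1.2:
                dv = 1.2
            elif dv < -1.2:
                dv = -1.2
            for a in range(pnx):
                i = i0 + a
                im = i - 1 if i > 0 else 0
                ip = i + 1 if i < nx - 1 else nx - 1
                for b in range(pny):
                    j = j0 + b
                    jm = j - 1 if j > 0 else 0
                    jp = j + 1 if j < ny - 1 else ny - 1
                    uv = fields[m, i, j]
                    lapu = (fields[m, im, j] + fields[m, ip, j]
                            + fields[m, i, jm] + fields[m, i, jp]
                            - 4.0 * uv) * inv_dx2
                    hp = _hp(uv)
                    gp = 2.0 * uv * (1.0 - uv) * (1.0 - 2.0 * uv)
                    du = mob * (eps2 * lapu - W * gp
                                + dv * hp
                                - hp * (beta * (H[i, j] - _h(uv))
                                        + betw * HW[i, j])
                                + acw * hp * lapHW[i, j]
                                + eta * (lapS[i, j] - lapu))
                    patch[a, b] = uv + dt * du
            vol = 0.0
            for a in range(pnx):
                for b in range(pny):
                    uv = patch[a, b]
                    # projection onto the admissible band: the gradient flow
                    # is only meaningful for phase fractions in [0, 1]
                    if uv < -0.02:
                        uv = -0.02
                    elif uv > 1.02:
                        uv = 1.02
                    fields[m, i0 + a, j0 + b] = uv
                    vol += _h(uv)
            volumes[m] = vol * dx2

        # lumen update (full domain)
        for i in range(nx):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < nx - 1 else nx - 1
            for j in range(ny):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < ny - 1 else ny - 1
                wv = w[i, j]
                lapw = (w[im, j] + w[ip, j] + w[i, jm] + w[i, jp]
                        - 4.0 * wv) * inv_dx2
                hp = _hp(wv)
                gp = 2.0 * wv * (1.0 - wv) * (1.0 - 2.0 * wv)
                dw = mobw * (eps2 * lapw - Ww * gp
                             + xi * hp
                             - betw * hp * H[i, j]
                             + acw * hp * lapH[i, j]
                             + eta * (lapS[i, j] - lapw))
                wnew[i, j] = wv + dt * dw
        for i in range(nx):
            for j in range(ny):
                wv = wnew[i, j]
                if wv < -0.02:
                    wv = -0.02
                elif wv > 1.02:
                    wv = 1.02
                w[i, j] = wv


def _compute_bboxes(fields: np.ndarray, pad: int = 4,
                    tol: float = 1e-4) -> np.ndarray:
    """Tight per-cell bounding boxes padded for interface motion."""
    n, nx, ny = fields.shape
    out = np.zeros((n, 4), dtype=np.int64)
    for m in range(n):
        mask = fields[m] > tol
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        if rows.size == 0:
            out[m] = (0, 1, 0, 1)
            continue
        out[m] = (max(rows[0] - pad, 0), min(rows[-1] + pad + 1, nx),
                  max(cols[0] - pad, 0), min(cols[-1] + pad + 1, ny))
    return out


LEAK_RATE = 0.5          # decay rate of escaped lumen fluid, per time unit
LEAK_CLOSING_PX = 8      # closing radius: clefts/gaps up to ~2x this stay sealed


def _seal_state(state: SimState, grid: GridSpec) -> tuple[float, np.ndarray]:
    """Fraction of lumen fluid outside the sealed tissue region, and the
    outside mask.

    The sealed region is the morphological closing of the cell mask
    (bridging clefts and shell gaps up to about twice ``LEAK_CLOSING_PX``)
    plus every cavity it encloses.
    """
    from scipy import ndimage

    lum = state.lumen_field > 0.4
    if state.n_cells == 0 or not lum.any():
        return 0.0, np.zeros_like(lum)
    cells = state.fields.sum(axis=0) > 0.3
    if not cells.any():
        return 1.0, ~np.zeros_like(lum)
    closed = ndimage.binary_closing(
        cells, structure=ndimage.generate_binary_structure(2, 1),
        iterations=LEAK_CLOSING_PX)
    protect = ndimage.binary_fill_holes(closed)
    outside = ~protect
    total = lum.sum()
    f_out = float((lum & outside).sum() / total) if total else 0.0
    return f_out, outside


def _advance(state: SimState, params: EnergyParams, grid: GridSpec,
             n_steps: int, bboxes: np.ndarray | None = None) -> None:
    """Advance ``n_steps`` relaxation steps in place (no division logic)."""
    if bboxes is None:
        bboxes = _compute_bboxes(state.fields, pad=4 + (n_steps // 4))
    outside = None
    if params.xi > 0:
        _, outside = _seal_state(state, grid)
    _step_kernel(
        state.fields, state.lumen_field, bboxes,
        state.volumes, state.target_volumes, n_steps,
        grid.dx, grid.dt, grid.interface_width**2,
        params.surface_coef, params.lumen_surface_coef, params.alpha,
        params.exclusion_coef, params.lumen_exclusion_coef,
        params.lumen_adhesion_coef, params.adhesion_coef, params.xi,
        params.mobility, params.lumen_mobility)
    if outside is not None and outside.any():
        # fluid that escaped into the open medium slowly clears
        state.lumen_field[outside] *= np.exp(-LEAK_RATE * n_steps * grid.dt)
    state.time += n_steps * grid.dt


def step(state: SimState, params: EnergyParams, grid: GridSpec) -> SimState:
    """One explicit relaxation update of all fields down the energy gradient.

    Returns a new state; cell count is unchanged (division lives in
    :mod:`lumenmorph.cell_cycle`).
    """
    if grid.dt > grid.stability_limit(params.mobility) * 2.0:
        raise IntegrationError(
            f"dt={grid.dt} exceeds explicit stability bound "
            f"{grid.stability_limit(params.mobility) * 2.0:.4g}")
    state.validate()
    new = state.copy()
    if new.n_cells > 0 or np.any(new.lumen_field > 0):
        _advance(new, params, grid, 1)
    return new


# ---------------------------------------------------------------------------
# run orchestration

@dataclass
class RunResult:
    snapshots: list          # list of SimState
    metrics: "object"        # pandas.DataFrame
    events: "object"         # pandas.DataFrame of division events
    completed: bool
    failure: str | None = None


def _touches_margin(state: SimState, threshold: float = 0.5) -> bool:
    m = BOUNDARY_MARGIN
    occ = state.lumen_field.copy()
    if state.n_cells:
        occ = occ + state.fields.max(axis=0)
    return bool(
        occ[:m, :].max() > threshold or occ[-m:, :].max() > threshold
        or occ[:, :m].max() > threshold or occ[:, -m:].max() > threshold)


def run(params: EnergyParams, grid: GridSpec, cycle_params,
        t_end: float, snapshot_interval: float, seed: int,
        n_cells_init: int = 2, seed_initial_lumen: bool = True,
        energy_check_interval: int = 0, max_cells: int | None = None,
        keep_fields: bool = True) -> RunResult:
    """Full simulation: relaxation + growth/division + lumen dynamics.

    The default initial condition is two relaxed cells with one micro-lumen
    seeded between them — the state just after a first division.  Snapshots
    and one metrics row (time, n_cells, n_lumina, lumen_occupancy,
    mean_radius) are emitted every ``snapshot_interval`` time units.  Fully
    reproducible from (parameters, seed).
    """
    from . import cell_cycle as cc
    from . import insilico_quant as iq
    import pandas as pd

    state = init_state(grid, n_cells_init, seed, params=params)
    if seed_initial_lumen and cycle_params.micro_lumen_size > 0:
        centroid = _fields_centroid(state, grid)
        cc.seed_micro_lumen(state, grid, params, centroid,
                            cycle_params.micro_lumen_size)

    snapshots: list[SimState] = []
    rows = []
    events = []
    completed = True
    failure = None

    chunk = 10                      # kernel steps between control decisions
    n_total = max(int(round(t_end / grid.dt)), 0)
    next_snap = 0.0
    last_energy = None
    bad_energy_checks = 0
    divisions_allowed = True

    def snap():
        ph = iq.phenotype(state, grid)
        rows.append({"time": state.time, "n_cells": state.n_cells,
                     "n_lumina": ph.n_lumina,
                     "lumen_occupancy": ph.lumen_occupancy,
                     "mean_radius": ph.mean_radius})
        if keep_fields:
            snapshots.append(state.copy())

    snap()
    next_snap = snapshot_interval

    steps_done = 0
    while steps_done < n_total:
        n_now = min(chunk, n_total - steps_done)
        try:
            cc.update_target_volumes(
                state.target_volumes, cycle_params.tau_v,
                cycle_params.v_bar, n_now * grid.dt)
            _advance(state, params, grid, n_now)
            state.validate()
            if state.n_cells and state.volumes.max() > 4.0 * cycle_params.v_bar:
                raise IntegrationError("cell volume runaway: fields smeared")
        except (NumericalStateError, IntegrationError) as exc:  # flush partial
            completed, failure = False, f"{type(exc).__name__}: {exc}"
            break
        steps_done += n_now

        if divisions_allowed and not cc.divisions_permitted(
                state, cycle_params.arrest_count):
            divisions_allowed = False
        if divisions_allowed:
            due = cc.check_divisions(state, cycle_params.v_d)
            for cid in due:
                if not cc.divisions_permitted(state, cycle_params.arrest_count):
                    break
                ev = cc.divide_cell(state, cid, grid, params, cycle_params)
                if ev is not None:
                    ev["time"] = state.time
                    events.append(ev)

        if _touches_margin(state):
            completed, failure = False, "organoid reached the boundary margin"
            break
        if max_cells is not None and state.n_cells >= max_cells:
            break                      # domain capacity: stop cleanly
        if energy_check_interval and steps_done % energy_check_interval == 0:
            e = free_energy(state, params, grid)["total"]
            if last_energy is not None and e > last_energy + 1e-6:
                bad_energy_checks += 1
                if bad_energy_checks >= 3:
                    completed = False
                    failure = "energy increased on 3 consecutive checks"
                    break
            else:
                bad_energy_checks = 0
            last_energy = e

        if state.time >= next_snap - 1e-9:
            snap()
            next_snap += snapshot_interval

    if completed and (not rows or rows[-1]["time"] < state.time - 1e-9):
        snap()

    return RunResult(snapshots=snapshots, metrics=pd.DataFrame(rows),
                     events=pd.DataFrame(events), completed=completed,
                     failure=failure)


def _fields_centroid(state: SimState, grid: GridSpec) -> tuple[float, float]:
    tot = state.fields.sum(axis=0)
    m = tot.sum()
    xs = (np.arange(grid.nx) + 0.5) * grid.dx
    ys = (np.arange(grid.ny) + 0.5) * grid.dx
    return (float((tot.sum(axis=1) * xs).sum() / m),
            float((tot.sum(axis=0) * ys).sum() / m))


# ---------------------------------------------------------------------------
# in-silico pressure estimate

def _rest_energy(state: SimState, params: EnergyParams,
                 grid: GridSpec) -> float:
    """Free energy without the osmotic work term −ξ·V_lumen."""
    terms = free_energy(state, params, grid)
    return terms["total"] - terms["lumen_pressure"]


def estimate_insilico_pressure(state: SimState, params: EnergyParams,
                               grid: GridSpec, threshold: float = 0.5,
                               delta_px: float = 0.75) -> list[dict]:
    """Mechanical pressure estimate per connected lumen (simulation units).

    The hydrostatic excess of a lumen is the work the surrounding material
    extracts per unit of cavity growth: ΔP = dF_rest/dA under a virtual
    outward dilation of that lumen's boundary, where F_rest is the free
    energy without the osmotic term.  For a bare circular lumen this reduces
    exactly to the Laplace law σ_w/R; with an enclosing cell shell it adds
    the transmitted interface and exclusion stresses.  At force balance the
    estimate equals the applied osmotic pressure ξ, which is what makes the
    inferred ΔP linear in ξ across matched-size lumina.

    Returns one dict per lumen (label, area, radius, delta_p, confidence);
    a lumen whose boundary is mostly exposed to the medium (no closed shell)
    is flagged ``low`` confidence.  Empty lumen field → empty list.
    """
    from scipy import ndimage

    mask = state.lumen_field > threshold
    if not mask.any():
        return []
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    dx2 = grid.dx * grid.dx
    cells = (state.fields.sum(axis=0) > 0.3) if state.n_cells else None

    base_rest = _rest_energy(state, params, grid)
    base_area = measure_volume(state.lumen_field, grid.dx)

    gx, gy = np.gradient(state.lumen_field, grid.dx)
    grad_mag = np.hypot(gx, gy)

    out = []
    for lab in range(1, n + 1):
        comp = labels == lab
        area = float(comp.sum()) * dx2
        radius = float(np.sqrt(area / np.pi))
        # advect this component's interface outward by delta_px lattice units
        region = ndimage.binary_dilation(comp, iterations=6)
        bump = np.where(region, grad_mag * (delta_px * grid.dx), 0.0)
        pert = state.copy()
        pert.lumen_field = np.clip(state.lumen_field + bump, 0.0, 1.0)
        d_area = measure_volume(pert.lumen_field, grid.dx) - base_area
        if d_area <= 0:
            continue
        d_rest = _rest_energy(pert, params, grid) - base_rest
        # shell coverage of the one-pixel boundary ring → confidence
        if cells is not None:
            # the ring must clear the lumen's own soft skirt before probing
            # for cell material
            grown = ndimage.binary_dilation(comp, iterations=6)
            ring = grown & ~ndimage.binary_dilation(comp, iterations=3)
            coverage = (cells[ring].sum() / ring.sum()) if ring.any() else 0.0
        else:
            coverage = 0.0
        out.append({
            "label": int(lab),
            "area": area,
            "radius": radius,
            "delta_p": float(d_rest / d_area),
            "boundary_cell_coverage": float(coverage),
            "confidence": "ok" if coverage >= 0.5 else "low",
        })
    return out


# ---------------------------------------------------------------------------
# output writers

def save_snapshots_tiff(result: RunResult, path) -> None:
    """All fields of every snapshot as a multi-page 32-bit float TIFF."""
    import tifffile

    pages = []
    for st in result.snapshots:
        for u in st.fields:
            pages.append(u.astype(np.float32))
        pages.append(st.lumen_field.astype(np.float32))
    tifffile.imwrite(path, np.stack(pages) if pages else
                     np.zeros((1, 1, 1), np.float32))


def save_run_hdf5(result: RunResult, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for k, st in enumerate(result.snapshots):
            g = f.create_group(f"snapshot_{k:05d}")
            g.attrs["time"] = st.time
            g.create_dataset("cell_fields", data=st.fields,
                             compression="gzip")
            g.create_dataset("lumen_field", data=st.lumen_field,
                             compression="gzip")
            g.create_dataset("volumes", data=st.volumes)
            g.create_dataset("target_volumes", data=st.target_volumes)
        f.attrs["completed"] = result.completed


def write_manifest(path, config: dict, seed: int) -> dict:
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config_hash": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "package_version": __version__,
        "config": config,
    }
    with open(path, "w") as f:
        json.dump(manifest, f, indent=2, default=str)
    return manifest


def params_to_dict(obj) -> dict:
    return dataclasses.asdict(obj)
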