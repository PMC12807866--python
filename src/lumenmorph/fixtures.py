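"""Seeded synthetic-data generators with known ground truth.

Each generator is a forward model of exactly one inference path in the
package, so that path can be tested as an inverse problem: Brownian tracks
(→ MSD → diffusion → Stokes–Einstein viscosity), conduit-outflow ablation
records (→ flow rate → Hagen–Poiseuille ΔP), rasterized label volumes with
analytic volume/surface ground truth (→ morphometrics, duct filters) and
Gaussian-mixture intensity samples (→ KDE intersection threshold).  Every
output carries its ground truth and the seed that generated it.
"""

from __future__ import annotations

import numpy as np

from .biophysics import (BODY_TEMPERATURE_K, AblationRecord, TrajectorySet,
                         stokes_einstein_viscosity)
from .morphometrics import LabelVolume

__all__ = [
    "gen_brownian_tracks",
    "gen_label_volume",
    "gen_ablation_record",
    "gen_intensity_samples",
    "sphere_spec",
    "ellipsoid_spec",
]


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Brownian tracks

def gen_brownian_tracks(n_particles: int, frame_dt_s: float, n_frames: int,
                        d_um2_s: float | None = None,
                        viscosity_pa_s: float | None = None,
                        radius_um: float = 0.5,
                        temperature_k: float = BODY_TEMPERATURE_K,
                        localization_noise_sd_um: float = 0.0,
                        seed: int = 0) -> tuple[TrajectorySet, dict]:
    """3D random walks with per-axis increment variance 2·D·dt.

    Give either D directly or (viscosity, radius, temperature), in which
    case D follows from Stokes–Einstein.  Optional static Gaussian
    localization noise is added on top of the true positions (off by
    default).  Returns (TrajectorySet, ground truth dict).
    """
    if n_frames < 2:
        raise ValueError("need at least two frames")
    if d_um2_s is None:
        if viscosity_pa_s is None:
            raise ValueError("give d_um2_s or viscosity_pa_s")
        # invert μ = kT/(6πaD) for D (µm²/s)
        d_um2_s = (stokes_einstein_viscosity(1.0, radius_um, temperature_k)
                   / viscosity_pa_s)
    rng = _rng(seed)
    sd = np.sqrt(2.0 * d_um2_s * frame_dt_s)
    tracks = {}
    for pid in range(n_particles):
        steps = rng.normal(0.0, sd, size=(n_frames - 1, 3))
        pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        if localization_noise_sd_um > 0:
            pos = pos + rng.normal(0.0, localization_noise_sd_um,
                                   size=pos.shape)
        tracks[pid] = pos
    ts = TrajectorySet(tracks=tracks, frame_interval_s=frame_dt_s,
                       particle_radius_um=radius_um,
                       temperature_k=temperature_k)
    truth = {
        "d_um2_s": float(d_um2_s),
        "viscosity_pa_s": (stokes_einstein_viscosity(
            d_um2_s, radius_um, temperature_k) if d_um2_s > 0
            else float("inf")),
        "radius_um": radius_um,
        "temperature_k": temperature_k,
        "localization_noise_sd_um": localization_noise_sd_um,
        "seed": seed,
    }
    return ts, truth


# ---------------------------------------------------------------------------
# label volumes

def sphere_spec(centre, radius_um: float) -> dict:
    """Analytic sphere: V = 4πr³/3, SA = 4πr²."""
    r = float(radius_um)
    return {"kind": "sphere", "centre": tuple(centre), "radii": (r, r, r),
            "volume": 4.0 / 3.0 * np.pi * r**3,
            "surface_area": 4.0 * np.pi * r**2}


def ellipsoid_spec(centre, radii_um) -> dict:
    """Analytic ellipsoid; SA via the Knud Thomsen approximation (p=1.6075,
    relative error < 1.1%)."""
    a, b, c = (float(r) for r in radii_um)
    p = 1.6075
    sa = 4.0 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p)
                        / 3.0) ** (1.0 / p)
    return {"kind": "ellipsoid", "centre": tuple(centre), "radii": (a, b, c),
            "volume": 4.0 / 3.0 * np.pi * a * b * c, "surface_area": sa}


def gen_label_volume(shapes, shape_px=(64, 64, 64),
                     voxel_size=(1.0, 1.0, 1.0), seed: int = 0
                     ) -> tuple[LabelVolume, list[dict]]:
    """Rasterize analytic spheres/ellipsoids into an integer label volume.

    ``shapes`` is a list of :func:`sphere_spec` / :func:`ellipsoid_spec`
    dicts (centres in µm); labels are assigned 1..K in list order and the
    analytic ground truth is returned alongside.  Overlapping shapes are a
    generation error.
    """
    vs = np.asarray(voxel_size, dtype=float)
    labels = np.zeros(shape_px, dtype=np.int32)
    coords = np.meshgrid(*[(np.arange(n) + 0.5) * v
                           for n, v in zip(shape_px, vs)], indexing="ij")
    truths = []
    for k, spec in enumerate(shapes, start=1):
        c = np.asarray(spec["centre"], dtype=float)
        radii = np.asarray(spec["radii"], dtype=float)
        dist2 = sum(((g - ci) / ri) ** 2
                    for g, ci, ri in zip(coords, c, radii))
        mask = dist2 <= 1.0
        if np.any(labels[mask] > 0):
            raise ValueError(f"shape {k} overlaps a previously placed shape")
        labels[mask] = k
        t = dict(spec)
        t["label"] = k
        t["rasterized_volume"] = float(mask.sum()) * float(np.prod(vs))
        truths.append(t)
    return LabelVolume(labels, tuple(vs)), truths


def gen_duct_filter_scenario(volumes_um3=(100.0, 300.0, 400.0, 500.0, 600.0),
                             edge_touching: bool = False,
                             shape_px=(48, 96, 96),
                             voxel_size=(1.0, 1.0, 1.0), seed: int = 0
                             ) -> tuple[LabelVolume, list[dict]]:
    """Spheres with prescribed physical volumes on a grid layout, optionally
    plus one edge-touching sphere, for exercising the duct-label filters."""
    vs = np.asarray(voxel_size, dtype=float)
    extent = np.asarray(shape_px) * vs
    radii = [float(np.cbrt(3.0 * v / (4.0 * np.pi))) for v in volumes_um3]
    shapes = []
    n = len(radii)
    for i, r in enumerate(radii):
        cx = extent[0] / 2.0
        cy = extent[1] * (i + 1) / (n + 1)
        cz = extent[2] / 2.0
        shapes.append(sphere_spec((cx, cy, cz), r))
    if edge_touching:
        shapes.append(sphere_spec((2.0, extent[1] / 2.0, 2.0), 6.0))
    return gen_label_volume(shapes, shape_px, tuple(vs), seed)


# ---------------------------------------------------------------------------
# ablation records

def gen_ablation_record(dp_true_pa: float, viscosity_pa_s: float,
                        thickness_um: float, conduit_radius_um: float,
                        v0_um3: float, duration_s: float,
                        sample_dt_s: float, noise_sd_um3: float = 0.0,
                        laplace_coupled: bool = False,
                        seed: int = 0) -> tuple[AblationRecord, dict]:
    """Forward model of a post-cut lumen-volume series.

    Integrates dV/dt = −π r_c⁴ ΔP(t) / (8 μ L).  Default mode holds ΔP
    constant over the window; the Laplace-coupled mode lets ΔP decay with
    the shrinking radius (ΔP ∝ V^(−1/3)), mimicking tension-dominated
    deflation.  Optional additive Gaussian volume noise.
    """
    if duration_s < 2 * sample_dt_s:
        raise ValueError("duration shorter than two samples")
    for name, val in (("dp_true_pa", dp_true_pa),
                      ("viscosity_pa_s", viscosity_pa_s),
                      ("thickness_um", thickness_um),
                      ("conduit_radius_um", conduit_radius_um),
                      ("v0_um3", v0_um3)):
        if val < 0 or (val <= 0 and name != "dp_true_pa"):
            raise ValueError(f"{name} must be positive")
    rng = _rng(seed)
    coeff = (np.pi * conduit_radius_um**4
             / (8.0 * viscosity_pa_s * thickness_um))
    times = np.arange(0.0, duration_s + sample_dt_s / 2.0, sample_dt_s)
    vols = np.empty_like(times)
    v = v0_um3
    for i, _ in enumerate(times):
        vols[i] = v
        dp = dp_true_pa
        if laplace_coupled and v > 0:
            dp = dp_true_pa * (v / v0_um3) ** (-1.0 / 3.0)
        v = max(v - coeff * dp * sample_dt_s, 0.0)
    if noise_sd_um3 > 0:
        vols = vols + rng.normal(0.0, noise_sd_um3, size=vols.shape)
    rec = AblationRecord(times_s=times, volumes_um3=vols,
                         conduit_radius_um=conduit_radius_um,
                         epithelium_thickness_um=thickness_um,
                         viscosity_pa_s=viscosity_pa_s,
                         cut_time_s=0.0,
                         record_id=f"synthetic-{seed}")
    truth = {"dp_true_pa": dp_true_pa,
             "q_true_um3_s": coeff * dp_true_pa,
             "noise_sd_um3": noise_sd_um3, "seed": seed}
    return rec, truth


# ---------------------------------------------------------------------------
# intensity samples

def gen_intensity_samples(mean_a: float, sd_a: float, n_a: int,
                          mean_b: float, sd_b: float, n_b: int,
                          seed: int = 0) -> tuple[np.ndarray, np.ndarray, dict]:
    """Two Gaussian intensity samples for KDE-threshold testing."""
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("standard deviations must be positive")
    rng = _rng(seed)
    a = rng.normal(mean_a, sd_a, n_a)
    b = rng.normal(mean_b, sd_b, n_b)
    truth = {"mean_a": mean_a, "sd_a": sd_a, "mean_b": mean_b,
             "sd_b": sd_b, "seed": seed}
    return a, b, truth
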