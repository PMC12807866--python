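"""Lumen biophysics inference: Hagen–Poiseuille pressure and Stokes–Einstein
viscosity.

After a laser cut opens a conduit through the epithelium, luminal fluid is
expelled and the lumen volume decays; the outflow rate Q together with the
conduit radius r_c, the epithelium thickness L and the luminal viscosity μ
give the hydrostatic pressure excess via the Hagen–Poiseuille law

    ΔP = 8 μ L Q / (π r_c⁴).

The viscosity itself comes from particle tracking: the 3D time-averaged mean
squared displacement of luminal tracers is fitted as MSD = 6Dτ and the
Stokes–Einstein relation μ = k_B T / (6π a D) converts the diffusion
coefficient to a viscosity.  Units are µm / s / Pa throughout; conversions
to SI happen inside the two law evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AblationRecord",
    "TrajectorySet",
    "PressureEstimate",
    "flow_rate",
    "hagen_poiseuille_dp",
    "infer_pressure",
    "msd_3d",
    "fit_diffusion",
    "stokes_einstein_viscosity",
    "viscosity_pipeline",
    "size_matched_ratio",
    "BOLTZMANN_SI",
    "BODY_TEMPERATURE_K",
]

BOLTZMANN_SI = 1.380649e-23      # J/K
BODY_TEMPERATURE_K = 310.15      # 37 °C culture


@dataclass(frozen=True)
class AblationRecord:
    """Lumen-volume decay after one laser cut, plus conduit geometry.

    ``times_s``/``volumes_um3`` span pre and post cut; ``cut_time_s`` marks
    the opening of the conduit.  ``conduit_radius_um`` is the smallest
    radius measured along the conduit; ``epithelium_thickness_um`` its
    length; ``viscosity_pa_s`` is supplied (measured separately).
    """

    times_s: np.ndarray
    volumes_um3: np.ndarray
    conduit_radius_um: float
    epithelium_thickness_um: float
    viscosity_pa_s: float
    cut_time_s: float = 0.0
    record_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.volumes_um3, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "volumes_um3", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and volumes must be matching 1D arrays")
        if np.sum(t >= self.cut_time_s) < 2:
            raise ValueError("need at least two post-cut time points")
        for name in ("conduit_radius_um", "epithelium_thickness_um",
                     "viscosity_pa_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TrajectorySet:
    """Per-particle 3D tracks (µm) on a uniform frame interval (s)."""

    tracks: dict            # id -> (n_frames, 3) positions in µm
    frame_interval_s: float
    particle_radius_um: dict | float = 0.5
    temperature_k: float = BODY_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be positive")
        for tid, pos in self.tracks.items():
            p = np.asarray(pos, dtype=float)
            if p.ndim != 2 or p.shape[1] != 3:
                raise ValueError(f"track {tid}: positions must be (n, 3)")
            if not np.all(np.isfinite(p)):
                raise ValueError(f"track {tid}: non-finite positions")

    def radius_of(self, track_id) -> float:
        if isinstance(self.particle_radius_um, dict):
            return float(self.particle_radius_um[track_id])
        return float(self.particle_radius_um)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, frame_interval_s: float,
                       temperature_k: float = BODY_TEMPERATURE_K
                       ) -> "TrajectorySet":
        """Build from tidy CSV columns (track_id, frame, x_um, y_um, z_um
        and optionally radius_um)."""
        tracks, radii = {}, {}
        for tid, sub in df.sort_values("frame").groupby("track_id"):
            tracks[tid] = sub[["x_um", "y_um", "z_um"]].to_numpy(float)
            if "radius_um" in sub:
                radii[tid] = float(sub["radius_um"].iloc[0])
        return cls(tracks=tracks, frame_interval_s=frame_interval_s,
                   particle_radius_um=radii or 0.5,
                   temperature_k=temperature_k)


@dataclass(frozen=True)
class PressureEstimate:
    delta_p_pa: float
    flow_rate_um3_s: float
    record_id: str = ""
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# pressure pipeline

def flow_rate(record: AblationRecord, fit_window_s: float | None = None
              ) -> dict:
    """Outflow rate Q = −slope of the post-cut volume-vs-time linear fit.

    ``fit_window_s`` restricts the fit to the first window after the cut
    (default: all post-cut points).  Returns Q (µm³/s), fit R², number of
    points, and a ``no_outflow`` flag when the fitted slope is positive
    beyond its standard error (volume not decreasing: the cut senses no
    expulsion, so pressure does not exceed the exterior).
    """
    sel = record.times_s >= record.cut_time_s
    if fit_window_s is not None:
        sel &= record.times_s <= record.cut_time_s + fit_window_s
    t = record.times_s[sel]
    v = record.volumes_um3[sel]
    if t.size < 2:
        raise ValueError("fit window leaves fewer than two points")
    fit = stats.linregress(t, v)
    no_outflow = fit.slope > 0 and (fit.stderr == 0 or
                                    fit.slope > 2.0 * fit.stderr)
    return {
        "q_um3_s": max(-fit.slope, 0.0) if no_outflow else -fit.slope,
        "slope": fit.slope,
        "r_squared": fit.rvalue**2 if np.isfinite(fit.rvalue) else 1.0,
        "n_points": int(t.size),
        "no_outflow": bool(no_outflow),
    }


def hagen_poiseuille_dp(q_um3_s: float, viscosity_pa_s: float,
                        thickness_um: float, conduit_radius_um: float
                        ) -> float:
    """ΔP = 8 μ L Q / (π r_c⁴), in Pa.

    With L in µm, Q in µm³/s and r_c in µm the µm factors cancel
    (µm·µm³/µm⁴), so the result is μ[Pa·s] × [1/s] = Pa exactly.
    """
    if conduit_radius_um <= 0:
        raise ZeroDivisionError("conduit radius must be positive")
    if viscosity_pa_s <= 0 or thickness_um <= 0:
        raise ValueError("viscosity and thickness must be positive")
    return (8.0 * viscosity_pa_s * thickness_um * q_um3_s
            / (np.pi * conduit_radius_um**4))


def infer_pressure(record: AblationRecord,
                   fit_window_s: float | None = None) -> PressureEstimate:
    """Full record → ΔP: fit the outflow rate, apply Hagen–Poiseuille.

    A record flagged ``no_outflow`` reports ΔP = 0 (the method only senses
    expulsion, never negative pressure).
    """
    fr = flow_rate(record, fit_window_s)
    if fr["no_outflow"]:
        dp = 0.0
    else:
        dp = hagen_poiseuille_dp(fr["q_um3_s"], record.viscosity_pa_s,
                                 record.epithelium_thickness_um,
                                 record.conduit_radius_um)
    return PressureEstimate(delta_p_pa=float(dp),
                            flow_rate_um3_s=float(fr["q_um3_s"]),
                            record_id=record.record_id, diagnostics=fr)


# ---------------------------------------------------------------------------
# viscosity pipeline

def msd_3d(tracks: TrajectorySet, max_lag_fraction: float = 1.0
           ) -> tuple[dict, list]:
    """Time-averaged 3D MSD per track: MSD(τ) = ⟨|r(t+τ) − r(t)|²⟩ over all
    start times, at every integer lag up to ``max_lag_fraction`` of the
    track length.  Tracks shorter than 2 frames are skipped with an audit
    entry.  Returns ({track_id: (lags_s, msd_um2)}, audit list).
    """
    curves, audit = {}, []
    for tid, pos in tracks.tracks.items():
        pos = np.asarray(pos, dtype=float)
        n = len(pos)
        if n < 2:
            audit.append({"track_id": tid, "reason": "shorter than 2 frames"})
            continue
        max_lag = max(int((n - 1) * max_lag_fraction), 1)
        lags = np.arange(1, max_lag + 1)
        msd = np.empty(max_lag)
        for k, lag in enumerate(lags):
            d = pos[lag:] - pos[:-lag]
            msd[k] = np.mean(np.sum(d * d, axis=1))
        curves[tid] = (lags * tracks.frame_interval_s, msd)
    return curves, audit


def _linear_fit_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    fit = stats.linregress(x, y)
    r2 = fit.rvalue**2 if np.isfinite(fit.rvalue) else 1.0
    return fit.slope, fit.intercept, r2


def fit_diffusion(curves: dict, track_lengths: dict | None = None,
                  min_track_frames: int = 20, r2_min: float = 0.75,
                  fit_lag_fraction: float = 0.25) -> tuple[dict, pd.DataFrame]:
    """Per-particle diffusion coefficient D = slope/6 of MSD = 6Dτ.

    A particle survives only if its track is longer than
    ``min_track_frames`` frames and the linear fit over the first
    ``fit_lag_fraction`` of lags (at least 3) reaches R² > ``r2_min``.
    Returns ({track_id: D µm²/s}, audit table with pass/fail per particle).
    """
    out, audit = {}, []
    for tid, (lags, msd) in curves.items():
        n_frames = (track_lengths or {}).get(tid, len(lags) + 1)
        if n_frames <= min_track_frames:
            audit.append({"track_id": tid, "passed": False,
                          "reason": "track too short", "n_frames": n_frames,
                          "r_squared": np.nan, "d_um2_s": np.nan})
            continue
        n_fit = max(int(len(lags) * fit_lag_fraction), 3)
        slope, _, r2 = _linear_fit_r2(lags[:n_fit], msd[:n_fit])
        if r2 <= r2_min:
            audit.append({"track_id": tid, "passed": False,
                          "reason": "low linear fit R2", "n_frames": n_frames,
                          "r_squared": r2, "d_um2_s": np.nan})
            continue
        d = slope / 6.0
        if d <= 0:
            audit.append({"track_id": tid, "passed": False,
                          "reason": "non-positive slope",
                          "n_frames": n_frames, "r_squared": r2,
                          "d_um2_s": np.nan})
            continue
        out[tid] = float(d)
        audit.append({"track_id": tid, "passed": True, "reason": "",
                      "n_frames": n_frames, "r_squared": r2, "d_um2_s": d})
    return out, pd.DataFrame(audit)


def stokes_einstein_viscosity(d_um2_s: float, radius_um: float,
                              temperature_k: float = BODY_TEMPERATURE_K
                              ) -> float:
    """μ = k_B T / (6π a D), in Pa·s (D in µm²/s, a in µm)."""
    if d_um2_s <= 0 or radius_um <= 0 or temperature_k <= 0:
        raise ValueError("D, a and T must be positive")
    d_si = d_um2_s * 1e-12          # m²/s
    a_si = radius_um * 1e-6         # m
    return BOLTZMANN_SI * temperature_k / (6.0 * np.pi * a_si * d_si)


def viscosity_pipeline(tracks: TrajectorySet, min_track_frames: int = 20,
                       r2_min: float = 0.75,
                       fit_lag_fraction: float = 0.25) -> dict:
    """tracks → MSD → filtered D → per-particle μ, with median summary."""
    curves, skip_audit = msd_3d(tracks)
    lengths = {tid: len(pos) for tid, pos in tracks.tracks.items()}
    dvals, audit = fit_diffusion(curves, lengths, min_track_frames,
                                 r2_min, fit_lag_fraction)
    mus = {tid: stokes_einstein_viscosity(d, tracks.radius_of(tid),
                                          tracks.temperature_k)
           for tid, d in dvals.items()}
    return {
        "diffusion_um2_s": dvals,
        "viscosity_pa_s": mus,
        "median_viscosity_pa_s": (float(np.median(list(mus.values())))
                                  if mus else np.nan),
        "n_surviving": len(mus),
        "audit": audit,
        "skipped": skip_audit,
    }


# ---------------------------------------------------------------------------
# size-matched pressure comparison

def size_matched_ratio(group_a, group_b, n_bins: int = 5,
                       n_boot: int = 200, seed: int = 0) -> dict:
    """Pressure ratio of two groups after matching lumen size by binning.

    Each group is a sequence of (ΔP, lumen volume) pairs.  Shared log-spaced
    volume bins are built over the pooled volume range; the per-bin ratio of
    mean ΔP (A/B) is reported for bins populated in both groups, and the
    pooled ratio is the mean of per-bin ratios with a bootstrap standard
    deviation (resampling within each group).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")

    def pooled_ratio(a_arr, b_arr, edges):
        ia = np.clip(np.digitize(a_arr[:, 1], edges) - 1, 0, n_bins - 1)
        ib = np.clip(np.digitize(b_arr[:, 1], edges) - 1, 0, n_bins - 1)
        ratios = {}
        for k in range(n_bins):
            pa = a_arr[ia == k, 0]
            pb = b_arr[ib == k, 0]
            if pa.size and pb.size and pb.mean() > 0:
                ratios[k] = pa.mean() / pb.mean()
        return ratios

    lo = min(a[:, 1].min(), b[:, 1].min())
    hi = max(a[:, 1].max(), b[:, 1].max())
    # disjoint ranges leave no co-populated bin; detect after binning
    edges = np.geomspace(max(lo, 1e-12), hi * (1 + 1e-9), n_bins + 1)
    ratios = pooled_ratio(a, b, edges)
    if not ratios:
        raise ValueError("no volume bin is populated by both groups")
    pooled = float(np.mean(list(ratios.values())))

    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(n_boot):
        ra = a[rng.integers(0, len(a), len(a))]
        rb = b[rng.integers(0, len(b), len(b))]
        r = pooled_ratio(ra, rb, edges)
        if r:
            boot.append(np.mean(list(r.values())))
    return {
        "per_bin_ratio": ratios,
        "pooled_ratio": pooled,
        "bootstrap_sd": float(np.std(boot)) if boot else np.nan,
        "bootstrap_ci95": (tuple(np.percentile(boot, [2.5, 97.5]))
                           if boot else (np.nan, np.nan)),
        "bin_edges": edges,
    }
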