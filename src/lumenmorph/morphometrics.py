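"""Morphometric formulas on label volumes, meshes, counts and intensities.

These are the quantification rules applied to segmented organoid/lumen/duct
images: sphericity and scale-free surface-to-volume from mesh measures,
lumen occupancy, marker count ratios and population doubling time, the
Gaussian-KDE intersection threshold used to split marker-intensity
subpopulations, the three-step duct-label filter with its volumetric tile
density, the dextran lumen:cytoplasm ratio, and total skeleton length.
Segmentation and skeletonization themselves are upstream of this module: it
consumes integer label rasters with a physical voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.stats import gaussian_kde

__all__ = [
    "LabelVolume",
    "SurfaceMeasure",
    "CountPair",
    "sphericity",
    "occupancy",
    "midplane_slice",
    "surface_to_volume_scalefree",
    "marker_ratio",
    "doubling_time",
    "kde_intersection_threshold",
    "NoThresholdError",
    "filter_duct_labels",
    "tile_density",
    "dextran_ratio",
    "skeleton_total_length",
]


@dataclass(frozen=True)
class LabelVolume:
    """Integer-labelled 2D/3D raster with per-axis voxel size in µm."""

    labels: np.ndarray
    voxel_size: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.labels.ndim not in (2, 3):
            raise ValueError("labels must be 2D or 3D")
        if len(self.voxel_size) != self.labels.ndim:
            raise ValueError("voxel_size must match raster dimensionality")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def label_volumes(self) -> dict[int, float]:
        """Physical volume (µm³, or area in 2D) per non-zero label."""
        ids, counts = np.unique(self.labels[self.labels > 0],
                                return_counts=True)
        return {int(i): float(c) * self.voxel_volume
                for i, c in zip(ids, counts)}


@dataclass(frozen=True)
class SurfaceMeasure:
    """Mesh-derived volume (µm³) and surface area (µm²) of one object."""

    volume: float
    surface_area: float

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.surface_area <= 0:
            raise ValueError("volume and surface area must be positive")
        # the isoperimetric inequality SA³ ≥ 36πV² holds for any real
        # closed surface (equality iff sphere); small slack for meshes
        if self.surface_area**3 < 36.0 * np.pi * self.volume**2 * (1 - 1e-9):
            raise ValueError("isoperimetric inequality violated: "
                             "not a realizable surface")


@dataclass(frozen=True)
class CountPair:
    """Marker-positive vs total nuclei counts (e.g. EdU⁺ over DNA)."""

    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if self.numerator < 0 or self.denominator < 0:
            raise ValueError("counts must be non-negative")
        if self.numerator > self.denominator:
            raise ValueError("numerator cannot exceed denominator")


def sphericity(m: SurfaceMeasure) -> float:
    """Normalized sphericity Ψ = (36πV²)^(1/3) / SA ∈ (0, 1].

    Equals 1 for a perfect sphere and decreases as the shape departs from
    sphericity; invariant under uniform scaling.
    """
    return float((36.0 * np.pi * m.volume**2) ** (1.0 / 3.0)
                 / m.surface_area)


def _as_measure(obj) -> float:
    if isinstance(obj, SurfaceMeasure):
        return obj.volume
    if isinstance(obj, LabelVolume):
        return float((obj.labels > 0).sum()) * obj.voxel_volume
    return float(obj)


def midplane_slice(lv: LabelVolume) -> LabelVolume:
    """The 2D slice with the largest labelled area along the first axis
    (the z axis of a zxy raster) — the mid-plane rule for 2D read-outs."""
    if lv.labels.ndim != 3:
        raise ValueError("mid-plane extraction needs a 3D label volume")
    areas = (lv.labels > 0).sum(axis=(1, 2))
    k = int(np.argmax(areas))
    return LabelVolume(lv.labels[k], lv.voxel_size[1:])


def occupancy(lumen, organoid) -> float:
    """Lumen occupancy as a percentage: 100 · V_lumen / V_organoid.

    Accepts scalar measures, :class:`SurfaceMeasure` objects or
    :class:`LabelVolume` rasters (any non-zero label counts).  The 2D
    variant is the same ratio on mid-plane slices; use
    :func:`midplane_slice` to extract them by the largest-area rule.
    """
    v_l = _as_measure(lumen)
    v_o = _as_measure(organoid)
    if v_o <= 0:
        raise ValueError("organoid measure must be positive")
    if v_l < 0 or v_l > v_o:
        raise ValueError("lumen measure must lie in [0, organoid measure]")
    return 100.0 * v_l / v_o


def surface_to_volume_scalefree(m: SurfaceMeasure) -> float:
    """Dimensionless √SA / ∛V; ≈ 2.199 for every sphere."""
    return float(np.sqrt(m.surface_area) / np.cbrt(m.volume))


def marker_ratio(c: CountPair) -> float:
    """numerator / denominator ∈ [0, 1] (EdU:DNA, cleaved-caspase-3:DNA)."""
    if c.denominator == 0:
        raise ZeroDivisionError("denominator count is zero")
    return c.numerator / c.denominator


def doubling_time(n48: float, n96: float, interval_hours: float = 48.0) -> float:
    """Population doubling time: interval · ln2 / ln(N̄₉₆ / N̄₄₈), hours."""
    if n48 <= 0 or n96 <= 0:
        raise ValueError("mean counts must be positive")
    if n96 <= n48:
        raise ValueError("no growth between the two time points: "
                         "doubling time undefined")
    return interval_hours * np.log(2.0) / np.log(n96 / n48)


# ---------------------------------------------------------------------------
# KDE intersection threshold

class NoThresholdError(ValueError):
    """The two KDE curves never cross on the evaluation grid."""


def _silverman_kde(sample: np.ndarray) -> gaussian_kde:
    # rule-of-thumb bandwidth h ≈ 1.06 σ n^(−1/5): gaussian_kde multiplies
    # the factor by the sample std, so pass the 1.06·n^(−1/5) factor
    n = len(sample)
    return gaussian_kde(sample, bw_method=1.06 * n ** (-1.0 / 5.0))


def kde_intersection_threshold(sample_a, sample_b,
                               n_grid: int = 512) -> float:
    """First abscissa where the sign of KDE_a − KDE_b changes.

    Both samples get a Gaussian KDE with the Silverman rule-of-thumb
    bandwidth h ≈ 1.06 σ n^(−1/5); the difference is scanned ascending on
    ``n_grid`` points spanning the pooled range.  Symmetric in the sample
    order (the zero set of |difference| does not depend on it).  Raises
    :class:`NoThresholdError` when no sign change occurs.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    for s in (a, b):
        if s.size < 2 or np.std(s) == 0:
            raise ValueError("each sample needs n >= 2 and positive spread")
    grid = np.linspace(min(a.min(), b.min()), max(a.max(), b.max()), n_grid)
    diff = _silverman_kde(a)(grid) - _silverman_kde(b)(grid)
    sign = np.sign(diff)
    nz = sign != 0
    idx_nz = np.flatnonzero(nz)
    if idx_nz.size < 2:
        raise NoThresholdError("KDE difference has no sign structure")
    s = sign[idx_nz]
    changes = np.flatnonzero(s[1:] != s[:-1])
    if changes.size == 0:
        raise NoThresholdError("no sign change: samples indistinguishable "
                               "or fully separated beyond the grid")
    i0, i1 = idx_nz[changes[0]], idx_nz[changes[0] + 1]
    # linear interpolation of the zero crossing between the two grid points
    x0, x1, d0, d1 = grid[i0], grid[i1], diff[i0], diff[i1]
    return float(x0 + (x1 - x0) * d0 / (d0 - d1))


# ---------------------------------------------------------------------------
# duct-label filtering and tile density

DUCT_MIN_VOLUME_UM3 = 337.0


def _edge_labels(labels: np.ndarray) -> set[int]:
    faces = []
    for ax in range(labels.ndim):
        faces.append(np.take(labels, 0, axis=ax).ravel())
        faces.append(np.take(labels, -1, axis=ax).ravel())
    edge = np.unique(np.concatenate(faces))
    return set(int(v) for v in edge if v > 0)


def filter_duct_labels(lv: LabelVolume,
                       min_volume: float = DUCT_MIN_VOLUME_UM3) -> dict:
    """Three sequential duct-label filters with per-step audit counts.

    (1) remove labels touching the image edges; (2) remove labels smaller
    than ``min_volume`` µm³ (337 µm³ ↔ sphere-equivalent radius 4.31 µm);
    (3) select the "isolated" subset: labels strictly below the median
    volume of the post-step-2 distribution of the same image.

    Returns {filtered: LabelVolume after step 2, isolated: LabelVolume of
    the step-3 subset, audit: counts after each step, median_volume}.
    """
    labels = lv.labels
    vols0 = lv.label_volumes()
    n0 = len(vols0)

    edge = _edge_labels(labels)
    keep1 = [i for i in vols0 if i not in edge]

    keep2 = [i for i in keep1 if vols0[i] >= min_volume]

    if keep2:
        median = float(np.median([vols0[i] for i in keep2]))
        isolated_ids = [i for i in keep2 if vols0[i] < median]
    else:
        median = float("nan")
        isolated_ids = []

    def subset(ids):
        out = np.where(np.isin(labels, ids), labels, 0)
        return LabelVolume(out, lv.voxel_size)

    return {
        "filtered": subset(keep2),
        "isolated": subset(isolated_ids),
        "median_volume": median,
        "audit": {"input": n0, "after_edge_removal": len(keep1),
                  "after_volume_threshold": len(keep2),
                  "isolated": len(isolated_ids)},
    }


def duct_region_mask(lv: LabelVolume, radius_px: int = 50) -> np.ndarray:
    """'Virtual' epithelium+duct region: labels dilated then eroded by
    ``radius_px`` pixels and merged (morphological closing of the union)."""
    mask = lv.labels > 0
    structure = ndimage.generate_binary_structure(lv.labels.ndim, 1)
    closed = ndimage.binary_dilation(mask, structure, iterations=radius_px)
    closed = ndimage.binary_erosion(closed, structure, iterations=radius_px)
    return closed


def tile_density(isolated: LabelVolume, region_mask: np.ndarray,
                 tile_um: tuple[float, float, float] = (24.0, 88.5, 88.5),
                 overlap_min: float = 0.5) -> dict:
    """Mean isolated-lumen count per volumetric tile, per µm³.

    Tiles of physical size ``tile_um`` (z, x, y order matching the raster
    axes) are anchored at the region bounding-box origin; a tile qualifies
    when ≥ ``overlap_min`` of its volume lies inside ``region_mask``.  The
    density of a tile is (number of isolated-label centroids inside it) /
    (tile volume); the mean over qualifying tiles is returned.
    """
    if isolated.labels.ndim != len(tile_um):
        raise ValueError("tile size must match raster dimensionality")
    if not region_mask.any():
        raise ValueError("empty region mask: no qualifying tile")
    tile_px = [max(int(round(t / v)), 1)
               for t, v in zip(tile_um, isolated.voxel_size)]
    tile_volume = float(np.prod(tile_um))

    bbox = ndimage.find_objects(region_mask.astype(int))[0]
    origin = [s.start for s in bbox]
    extent = [s.stop for s in bbox]

    ids = [i for i in np.unique(isolated.labels) if i > 0]
    centroids = (ndimage.center_of_mass(isolated.labels > 0, isolated.labels,
                                        ids) if ids else [])

    densities = []
    starts = [range(o, e, t) for o, e, t in zip(origin, extent, tile_px)]
    import itertools
    for corner in itertools.product(*starts):
        sl = tuple(slice(c, c + t) for c, t in zip(corner, tile_px))
        inside = region_mask[sl].sum()
        if inside / float(np.prod(tile_px)) < overlap_min:
            continue
        count = 0
        for cen in centroids:
            if all(c <= x < c + t for x, c, t in zip(cen, corner, tile_px)):
                count += 1
        densities.append(count / tile_volume)
    if not densities:
        raise ValueError("no tile reaches the minimum region overlap")
    return {"mean_density": float(np.mean(densities)),
            "n_tiles": len(densities),
            "tile_volume_um3": tile_volume}


def dextran_ratio(lumen_intensities, cytoplasm_intensities) -> float:
    """mean(lumen) / mean(cytoplasm) dextran signal.

    Requires ≥ 2 lumen samples and an equal number of cytoplasm samples
    (intensities are taken in matched pairs from neighbouring cells).
    """
    lum = np.asarray(lumen_intensities, dtype=float)
    cyt = np.asarray(cytoplasm_intensities, dtype=float)
    if lum.size < 2:
        raise ValueError("need at least two lumen intensity samples")
    if lum.size != cyt.size:
        raise ValueError("lumen and cytoplasm sample counts must match")
    if cyt.mean() <= 0:
        raise ValueError("non-positive cytoplasm mean intensity")
    return float(lum.mean() / cyt.mean())


def skeleton_total_length(skeleton_voxels, voxel_size) -> float:
    """Total physical length (µm) of a skeleton given as voxel coordinates.

    Builds the 26-connected adjacency graph with Euclidean edge lengths in
    physical units and sums the edges of its minimum spanning forest, so
    every disjoint skeleton branch structure contributes additively.
    """
    pts = np.asarray(skeleton_voxels, dtype=float)
    if pts.size == 0:
        return 0.0
    if pts.ndim != 2:
        raise ValueError("skeleton_voxels must be an (n, ndim) array")
    vs = np.asarray(voxel_size, dtype=float)
    if vs.shape != (pts.shape[1],):
        raise ValueError("voxel_size must match coordinate dimensionality")
    phys = pts * vs
    n = len(pts)
    # adjacency: voxel pairs within one step along every axis (26-connected)
    rows, cols, dists = [], [], []
    index = {tuple(map(int, p)): i for i, p in enumerate(pts)}
    from itertools import product
    offsets = [o for o in product((-1, 0, 1), repeat=pts.shape[1])
               if any(o)]
    for i, p in enumerate(pts):
        key = tuple(map(int, p))
        for off in offsets:
            nb = tuple(k + o for k, o in zip(key, off))
            j = index.get(nb)
            if j is not None and j > i:
                rows.append(i)
                cols.append(j)
                dists.append(float(np.linalg.norm(phys[i] - phys[j])))
    graph = sparse.coo_matrix((dists, (rows, cols)), shape=(n, n))
    mst = minimum_spanning_tree(graph)
    return float(mst.sum())
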