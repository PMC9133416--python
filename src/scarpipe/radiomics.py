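"""Radiomic feature extraction on 2D masked regions.

Implements the 93-feature set used for scar/myocardium discrimination:
18 first-order statistics plus five gray-level texture-matrix families —
24 GLCM (co-occurrence), 14 GLDM (dependence), 16 GLSZM (size zone),
16 GLRLM (run length) and 5 NGTDM (neighbouring gray-tone difference).

Conventions (fixed so that independent brute-force oracles can reproduce
every value exactly):

* fixed-bin-width discretization anchored at the masked minimum,
  ``level = floor((x - min) / bin_width) + 1``;
* four 2D offsets/directions for GLCM and GLRLM, 8-connectivity for GLDM,
  GLSZM and NGTDM;
* co-occurrence and run matrices are summed over offsets/directions before
  features are computed;
* features that are undefined on a degenerate region (e.g. GLCM correlation
  at a single gray level) are returned as NaN and listed in
  ``FeatureVector.undefined`` rather than silently propagated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .slices import MIN_REGION_PIXELS, SliceMask, region_intensity_image

# four unique 2D directions (with symmetrization these cover all 8 neighbours)
OFFSETS_2D: tuple[tuple[int, int], ...] = ((0, 1), (1, 1), (1, 0), (1, -1))
NEIGHBOURS_8: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)
)
COARSENESS_CAP = 1e6

FIRSTORDER_NAMES = [
    "energy", "total_energy", "entropy", "minimum", "percentile_10",
    "percentile_90", "maximum", "mean", "median", "interquartile_range",
    "range", "mean_absolute_deviation", "robust_mean_absolute_deviation",
    "root_mean_squared", "skewness", "kurtosis", "variance", "uniformity",
]
GLCM_NAMES = [
    "autocorrelation", "joint_average", "cluster_prominence", "cluster_shade",
    "cluster_tendency", "contrast", "correlation", "difference_average",
    "difference_entropy", "difference_variance", "joint_energy",
    "joint_entropy", "imc1", "imc2", "idm", "idmn", "id", "idn",
    "inverse_variance", "maximum_probability", "sum_average", "sum_entropy",
    "sum_of_squares", "mcc",
]
GLDM_NAMES = [
    "small_dependence_emphasis", "large_dependence_emphasis",
    "gray_level_non_uniformity", "dependence_non_uniformity",
    "dependence_non_uniformity_normalized", "gray_level_variance",
    "dependence_variance", "dependence_entropy", "low_gray_level_emphasis",
    "high_gray_level_emphasis", "small_dependence_low_gray_level_emphasis",
    "small_dependence_high_gray_level_emphasis",
    "large_dependence_low_gray_level_emphasis",
    "large_dependence_high_gray_level_emphasis",
]
GLSZM_NAMES = [
    "small_area_emphasis", "large_area_emphasis",
    "gray_level_non_uniformity", "gray_level_non_uniformity_normalized",
    "size_zone_non_uniformity", "size_zone_non_uniformity_normalized",
    "zone_percentage", "gray_level_variance", "zone_variance", "zone_entropy",
    "low_gray_level_zone_emphasis", "high_gray_level_zone_emphasis",
    "small_area_low_gray_level_emphasis", "small_area_high_gray_level_emphasis",
    "large_area_low_gray_level_emphasis", "large_area_high_gray_level_emphasis",
]
GLRLM_NAMES = [
    "short_run_emphasis", "long_run_emphasis", "gray_level_non_uniformity",
    "gray_level_non_uniformity_normalized", "run_length_non_uniformity",
    "run_length_non_uniformity_normalized", "run_percentage",
    "gray_level_variance", "run_variance", "run_entropy",
    "low_gray_level_run_emphasis", "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis", "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis", "long_run_high_gray_level_emphasis",
]
NGTDM_NAMES = ["coarseness", "contrast", "busyness", "complexity", "strength"]

FAMILY_NAMES: dict[str, list[str]] = {
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "gldm": GLDM_NAMES,
    "glszm": GLSZM_NAMES,
    "glrlm": GLRLM_NAMES,
    "ngtdm": NGTDM_NAMES,
}
ALL_FEATURE_NAMES: list[str] = [
    f"{family}.{name}" for family, names in FAMILY_NAMES.items() for name in names
]
N_FEATURES = len(ALL_FEATURE_NAMES)  # 93


class EmptyRegionError(ValueError):
    pass


@dataclass(frozen=True)
class RadiomicsConfig:
    """Extraction settings: fixed bin width in HU, GLDM tolerance alpha,
    pixel volume used by first-order total energy (mm^3 per pixel)."""

    bin_width: float = 5.0
    alpha: int = 0
    pixel_volume: float = 1.0
    min_region_pixels: int = MIN_REGION_PIXELS


@dataclass
class DiscretizedRegion:
    """Masked image quantized to gray levels 1..n_levels."""

    gray_image: np.ndarray  # int levels; 0 outside the mask
    mask: np.ndarray
    n_levels: int
    bin_edges: np.ndarray

    @property
    def levels(self) -> np.ndarray:
        return self.gray_image[self.mask]


@dataclass
class FeatureVector:
    """The 93 named feature values for one region; NaN entries are listed in
    ``undefined`` and are meant to be imputed downstream."""

    values: dict[str, float]
    undefined: set[str] = field(default_factory=set)
    provenance: dict[str, float] = field(default_factory=dict)

    def as_array(self, names: Sequence[str] | None = None) -> np.ndarray:
        names = names or ALL_FEATURE_NAMES
        return np.array([self.values[n] for n in names])


def discretize(
    intensities: np.ndarray, mask: np.ndarray, bin_width: float, anchor: float | None = None
) -> DiscretizedRegion:
    """Fixed-bin-width quantization anchored at the masked minimum (or at an
    explicit ``anchor``, used to share bins across a multi-slice region)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError("empty mask")
    x = np.asarray(intensities, dtype=float)
    lo = float(x[mask].min()) if anchor is None else float(anchor)
    gray = np.zeros(x.shape, dtype=np.int64)
    gray[mask] = np.floor((x[mask] - lo) / bin_width).astype(np.int64) + 1
    n_levels = int(gray[mask].max())
    edges = lo + bin_width * np.arange(n_levels + 1)
    return DiscretizedRegion(gray, mask, n_levels, edges)


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------


def first_order(
    samples: np.ndarray, discretized: DiscretizedRegion, pixel_volume: float = 1.0
) -> tuple[dict[str, float], set[str]]:
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise EmptyRegionError("no samples")
    undefined: set[str] = set()
    mean = float(x.mean())
    m2 = float(np.mean((x - mean) ** 2))
    counts = np.bincount(discretized.levels)[1:]
    p = counts[counts > 0] / counts.sum()
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    energy = float(np.sum(x**2))
    vals = {
        "energy": energy,
        "total_energy": pixel_volume * energy,
        "entropy": float(-np.sum(p * np.log2(p))),
        "minimum": float(x.min()),
        "percentile_10": float(p10),
        "percentile_90": float(p90),
        "maximum": float(x.max()),
        "mean": mean,
        "median": float(np.median(x)),
        "interquartile_range": float(p75 - p25),
        "range": float(x.max() - x.min()),
        "mean_absolute_deviation": float(np.mean(np.abs(x - mean))),
        "robust_mean_absolute_deviation": float(
            np.mean(np.abs(robust - robust.mean())) if robust.size else 0.0
        ),
        "root_mean_squared": float(np.sqrt(np.mean(x**2))),
        "variance": m2,
        "uniformity": float(np.sum(p**2)),
    }
    if m2 > 0:
        m3 = float(np.mean((x - mean) ** 3))
        m4 = float(np.mean((x - mean) ** 4))
        vals["skewness"] = m3 / m2**1.5
        vals["kurtosis"] = m4 / m2**2
    else:
        vals["skewness"] = np.nan
        vals["kurtosis"] = np.nan
        undefined |= {"skewness", "kurtosis"}
    return {n: vals[n] for n in FIRSTORDER_NAMES}, undefined


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def glcm_matrix(
    d: DiscretizedRegion, offsets: Iterable[tuple[int, int]] = OFFSETS_2D
) -> np.ndarray:
    """Symmetrized co-occurrence counts summed over offsets, normalized to 1.

    Returns the all-zero matrix when no valid pixel pair exists (degenerate).
    """
    offsets = list(offsets)
    if not offsets or any(o == (0, 0) for o in offsets):
        raise ValueError("offsets must be nonzero and nonempty")
    ng = d.n_levels
    counts = np.zeros((ng, ng))
    g, m = d.gray_image, d.mask
    rows, cols = g.shape
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(rows, rows - dr)
        c0, c1 = max(0, -dc), min(cols, cols - dc)
        a = g[r0:r1, c0:c1]
        b = g[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = m[r0:r1, c0:c1] & m[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        if valid.any():
            np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1.0)
    counts = counts + counts.T  # symmetrize
    total = counts.sum()
    return counts / total if total > 0 else counts


def glcm_features(P: np.ndarray) -> tuple[dict[str, float], set[str]]:
    undefined: set[str] = set()
    ng = P.shape[0]
    if P.sum() <= 0:
        return {n: np.nan for n in GLCM_NAMES}, set(GLCM_NAMES)
    i = np.arange(1, ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(np.sum(px * i))
    mu_y = float(np.sum(py * i))
    sig_x = float(np.sqrt(np.sum(px * (i - mu_x) ** 2)))
    sig_y = float(np.sqrt(np.sum(py * (i - mu_y) ** 2)))

    # difference distribution p_{x-y}(k), k = 0..ng-1
    k_diff = np.arange(ng)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(I - J).ravel(), P.ravel())
    # sum distribution p_{x+y}(k), k = 2..2 ng
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (I + J - 2).ravel(), P.ravel())

    def ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-np.sum(q * np.log2(q)))

    da = float(np.sum(k_diff * p_diff))
    hxy = ent(P.ravel())
    pxy = np.outer(px, py)
    nz = (P > 0) & (pxy > 0)
    hxy1 = float(-np.sum(P[nz] * np.log2(pxy[nz])))
    hxy2 = ent(pxy.ravel())
    hx, hy = ent(px), ent(py)

    vals: dict[str, float] = {
        "autocorrelation": float(np.sum(P * I * J)),
        "joint_average": mu_x,
        "cluster_prominence": float(np.sum(P * (I + J - mu_x - mu_y) ** 4)),
        "cluster_shade": float(np.sum(P * (I + J - mu_x - mu_y) ** 3)),
        "cluster_tendency": float(np.sum(P * (I + J - mu_x - mu_y) ** 2)),
        "contrast": float(np.sum(P * (I - J) ** 2)),
        "difference_average": da,
        "difference_entropy": ent(p_diff),
        "difference_variance": float(np.sum(p_diff * (k_diff - da) ** 2)),
        "joint_energy": float(np.sum(P**2)),
        "joint_entropy": hxy,
        "idm": float(np.sum(p_diff / (1.0 + k_diff**2))),
        "idmn": float(np.sum(p_diff / (1.0 + (k_diff / ng) ** 2))),
        "id": float(np.sum(p_diff / (1.0 + k_diff))),
        "idn": float(np.sum(p_diff / (1.0 + k_diff / ng))),
        "inverse_variance": float(np.sum(p_diff[1:] / k_diff[1:] ** 2)) if ng > 1 else 0.0,
        "maximum_probability": float(P.max()),
        "sum_average": float(np.sum(k_sum * p_sum)),
        "sum_entropy": ent(p_sum),
        "sum_of_squares": float(np.sum(P * (I - mu_x) ** 2)),
    }
    if sig_x > 0 and sig_y > 0:
        vals["correlation"] = (float(np.sum(P * I * J)) - mu_x * mu_y) / (sig_x * sig_y)
    else:
        vals["correlation"] = np.nan
        undefined.add("correlation")
    if max(hx, hy) > 0:
        vals["imc1"] = (hxy - hxy1) / max(hx, hy)
        vals["imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    else:
        vals["imc1"] = np.nan
        vals["imc2"] = np.nan
        undefined |= {"imc1", "imc2"}
    present = px > 0
    if present.sum() >= 2:
        Pp = P[np.ix_(present, present)]
        pxp, pyp = px[present], py[present]
        Q = (Pp / pxp[:, None]) @ (Pp / pyp[None, :]).T
        eig = np.sort(np.real(np.linalg.eigvals(Q)))
        vals["mcc"] = float(np.sqrt(max(0.0, eig[-2])))
    else:
        vals["mcc"] = np.nan
        undefined.add("mcc")
    return {n: vals[n] for n in GLCM_NAMES}, undefined


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------


def gldm_matrix(d: DiscretizedRegion, alpha: int = 0) -> np.ndarray:
    """Dependence matrix P(g, j) with j-1 = number of 8-neighbours within
    ``alpha`` gray levels of the centre (masked neighbours only)."""
    g, m = d.gray_image, d.mask
    rows, cols = g.shape
    dep = np.zeros(g.shape, dtype=np.int64)
    for dr, dc in NEIGHBOURS_8:
        r0, r1 = max(0, -dr), min(rows, rows - dr)
        c0, c1 = max(0, -dc), min(cols, cols - dc)
        centre_m = m[r0:r1, c0:c1]
        nb_m = m[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        close = np.abs(
            g[r0:r1, c0:c1] - g[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ) <= alpha
        dep[r0:r1, c0:c1] += (centre_m & nb_m & close).astype(np.int64)
    P = np.zeros((d.n_levels, 9))
    np.add.at(P, (g[m] - 1, dep[m]), 1.0)
    return P[:, : dep[m].max() + 1] if m.any() else P


def gldm_features(
    d_or_matrix: DiscretizedRegion | np.ndarray, alpha: int = 0
) -> tuple[dict[str, float], set[str]]:
    P = (
        gldm_matrix(d_or_matrix, alpha)
        if isinstance(d_or_matrix, DiscretizedRegion)
        else np.asarray(d_or_matrix, dtype=float)
    )
    nz = float(P.sum())
    ng, nd = P.shape
    i = np.arange(1, ng + 1)
    j = np.arange(1, nd + 1)  # dependence size = neighbour count + 1
    I, J = np.meshgrid(i, j, indexing="ij")
    pg = P.sum(axis=1)
    pd = P.sum(axis=0)
    p = P / nz
    mu_g = float(np.sum(p.sum(axis=1) * i))
    mu_d = float(np.sum(p.sum(axis=0) * j))
    pn = p[p > 0]
    vals = {
        "small_dependence_emphasis": float(np.sum(P / J**2) / nz),
        "large_dependence_emphasis": float(np.sum(P * J**2) / nz),
        "gray_level_non_uniformity": float(np.sum(pg**2) / nz),
        "dependence_non_uniformity": float(np.sum(pd**2) / nz),
        "dependence_non_uniformity_normalized": float(np.sum(pd**2) / nz**2),
        "gray_level_variance": float(np.sum(p.sum(axis=1) * (i - mu_g) ** 2)),
        "dependence_variance": float(np.sum(p.sum(axis=0) * (j - mu_d) ** 2)),
        "dependence_entropy": float(-np.sum(pn * np.log2(pn))),
        "low_gray_level_emphasis": float(np.sum(P / I**2) / nz),
        "high_gray_level_emphasis": float(np.sum(P * I**2) / nz),
        "small_dependence_low_gray_level_emphasis": float(np.sum(P / (I**2 * J**2)) / nz),
        "small_dependence_high_gray_level_emphasis": float(np.sum(P * I**2 / J**2) / nz),
        "large_dependence_low_gray_level_emphasis": float(np.sum(P * J**2 / I**2) / nz),
        "large_dependence_high_gray_level_emphasis": float(np.sum(P * I**2 * J**2) / nz),
    }
    return {n: vals[n] for n in GLDM_NAMES}, set()


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_STRUCT_8 = np.ones((3, 3), dtype=bool)


def glszm_zones(d: DiscretizedRegion) -> list[tuple[int, int]]:
    """(gray level, zone size) for every 8-connected constant-level zone."""
    zones: list[tuple[int, int]] = []
    for level in range(1, d.n_levels + 1):
        blob = (d.gray_image == level) & d.mask
        if not blob.any():
            continue
        labelled, n = ndimage.label(blob, structure=_STRUCT_8)
        sizes = np.bincount(labelled.ravel())[1:]
        zones.extend((level, int(s)) for s in sizes)
    return zones


def glszm_matrix(d: DiscretizedRegion) -> np.ndarray:
    zones = glszm_zones(d)
    max_size = max(s for _, s in zones)
    P = np.zeros((d.n_levels, max_size))
    for level, size in zones:
        P[level - 1, size - 1] += 1.0
    return P


def _zone_family_features(
    P: np.ndarray, np_pixels: float, size_word: str
) -> dict[str, float]:
    """Shared size-zone / run-length feature formulas on a (level, size) matrix."""
    nz = float(P.sum())
    ng, ns = P.shape
    i = np.arange(1, ng + 1)
    s = np.arange(1, ns + 1)
    I, S = np.meshgrid(i, s, indexing="ij")
    pg = P.sum(axis=1)
    ps = P.sum(axis=0)
    p = P / nz
    mu_g = float(np.sum(p.sum(axis=1) * i))
    mu_s = float(np.sum(p.sum(axis=0) * s))
    pn = p[p > 0]
    return {
        f"small_{size_word}_emphasis": float(np.sum(P / S**2) / nz),
        f"large_{size_word}_emphasis": float(np.sum(P * S**2) / nz),
        "gray_level_non_uniformity": float(np.sum(pg**2) / nz),
        "gray_level_non_uniformity_normalized": float(np.sum(pg**2) / nz**2),
        "size_non_uniformity": float(np.sum(ps**2) / nz),
        "size_non_uniformity_normalized": float(np.sum(ps**2) / nz**2),
        "percentage": nz / np_pixels,
        "gray_level_variance": float(np.sum(p.sum(axis=1) * (i - mu_g) ** 2)),
        "size_variance": float(np.sum(p.sum(axis=0) * (s - mu_s) ** 2)),
        "entropy": float(-np.sum(pn * np.log2(pn))),
        "low_gray_level_emphasis": float(np.sum(P / I**2) / nz),
        "high_gray_level_emphasis": float(np.sum(P * I**2) / nz),
        f"small_{size_word}_low_gray_level_emphasis": float(np.sum(P / (I**2 * S**2)) / nz),
        f"small_{size_word}_high_gray_level_emphasis": float(np.sum(P * I**2 / S**2) / nz),
        f"large_{size_word}_low_gray_level_emphasis": float(np.sum(P * S**2 / I**2) / nz),
        f"large_{size_word}_high_gray_level_emphasis": float(np.sum(P * I**2 * S**2) / nz),
    }


def glszm_features(
    d_or_matrix: DiscretizedRegion | np.ndarray, np_pixels: float | None = None
) -> tuple[dict[str, float], set[str]]:
    if isinstance(d_or_matrix, DiscretizedRegion):
        P = glszm_matrix(d_or_matrix)
        np_pixels = float(d_or_matrix.mask.sum())
    else:
        P = np.asarray(d_or_matrix, dtype=float)
        assert np_pixels is not None
    raw = _zone_family_features(P, np_pixels, "area")
    vals = {
        "small_area_emphasis": raw["small_area_emphasis"],
        "large_area_emphasis": raw["large_area_emphasis"],
        "gray_level_non_uniformity": raw["gray_level_non_uniformity"],
        "gray_level_non_uniformity_normalized": raw["gray_level_non_uniformity_normalized"],
        "size_zone_non_uniformity": raw["size_non_uniformity"],
        "size_zone_non_uniformity_normalized": raw["size_non_uniformity_normalized"],
        "zone_percentage": raw["percentage"],
        "gray_level_variance": raw["gray_level_variance"],
        "zone_variance": raw["size_variance"],
        "zone_entropy": raw["entropy"],
        "low_gray_level_zone_emphasis": raw["low_gray_level_emphasis"],
        "high_gray_level_zone_emphasis": raw["high_gray_level_emphasis"],
        "small_area_low_gray_level_emphasis": raw["small_area_low_gray_level_emphasis"],
        "small_area_high_gray_level_emphasis": raw["small_area_high_gray_level_emphasis"],
        "large_area_low_gray_level_emphasis": raw["large_area_low_gray_level_emphasis"],
        "large_area_high_gray_level_emphasis": raw["large_area_high_gray_level_emphasis"],
    }
    return {n: vals[n] for n in GLSZM_NAMES}, set()


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


def _lines(arr: np.ndarray, direction: tuple[int, int]) -> list[np.ndarray]:
    rows, cols = arr.shape
    if direction == (0, 1):
        return [arr[r, :] for r in range(rows)]
    if direction == (1, 0):
        return [arr[:, c] for c in range(cols)]
    if direction == (1, 1):
        return [np.diagonal(arr, k) for k in range(-rows + 1, cols)]
    if direction == (1, -1):
        f = np.fliplr(arr)
        return [np.diagonal(f, k) for k in range(-rows + 1, cols)]
    raise ValueError(f"unsupported direction {direction}")


def glrlm_matrix(
    d: DiscretizedRegion, directions: Iterable[tuple[int, int]] = OFFSETS_2D
) -> np.ndarray:
    """Run-length counts summed over directions; runs break at mask gaps."""
    g = np.where(d.mask, d.gray_image, 0)
    runs: list[tuple[int, int]] = []
    for direction in directions:
        for line in _lines(g, direction):
            if len(line) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(line)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(line)]])
            for s, e in zip(starts, ends):
                if line[s] > 0:
                    runs.append((int(line[s]), int(e - s)))
    max_len = max(l for _, l in runs)
    P = np.zeros((d.n_levels, max_len))
    for level, length in runs:
        P[level - 1, length - 1] += 1.0
    return P


def glrlm_features(
    d_or_matrix: DiscretizedRegion | np.ndarray,
    directions: Iterable[tuple[int, int]] = OFFSETS_2D,
    np_pixels: float | None = None,
    n_directions: int | None = None,
) -> tuple[dict[str, float], set[str]]:
    if isinstance(d_or_matrix, DiscretizedRegion):
        directions = list(directions)
        P = glrlm_matrix(d_or_matrix, directions)
        np_pixels = float(d_or_matrix.mask.sum())
        n_directions = len(directions)
    else:
        P = np.asarray(d_or_matrix, dtype=float)
        assert np_pixels is not None and n_directions is not None
    raw = _zone_family_features(P, np_pixels * n_directions, "run")
    vals = {
        "short_run_emphasis": raw["small_run_emphasis"],
        "long_run_emphasis": raw["large_run_emphasis"],
        "gray_level_non_uniformity": raw["gray_level_non_uniformity"],
        "gray_level_non_uniformity_normalized": raw["gray_level_non_uniformity_normalized"],
        "run_length_non_uniformity": raw["size_non_uniformity"],
        "run_length_non_uniformity_normalized": raw["size_non_uniformity_normalized"],
        "run_percentage": raw["percentage"],
        "gray_level_variance": raw["gray_level_variance"],
        "run_variance": raw["size_variance"],
        "run_entropy": raw["entropy"],
        "low_gray_level_run_emphasis": raw["low_gray_level_emphasis"],
        "high_gray_level_run_emphasis": raw["high_gray_level_emphasis"],
        "short_run_low_gray_level_emphasis": raw["small_run_low_gray_level_emphasis"],
        "short_run_high_gray_level_emphasis": raw["small_run_high_gray_level_emphasis"],
        "long_run_low_gray_level_emphasis": raw["large_run_low_gray_level_emphasis"],
        "long_run_high_gray_level_emphasis": raw["large_run_high_gray_level_emphasis"],
    }
    return {n: vals[n] for n in GLRLM_NAMES}, set()


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------


def ngtdm_counts(d: DiscretizedRegion) -> tuple[np.ndarray, np.ndarray]:
    """(n_i, s_i) per gray level: pixel counts and summed absolute
    differences from the mean of the masked 8-neighbourhood.  Pixels with no
    masked neighbour are excluded."""
    g, m = d.gray_image, d.mask
    rows, cols = g.shape
    nb_sum = np.zeros(g.shape)
    nb_cnt = np.zeros(g.shape)
    for dr, dc in NEIGHBOURS_8:
        r0, r1 = max(0, -dr), min(rows, rows - dr)
        c0, c1 = max(0, -dc), min(cols, cols - dc)
        nb_m = m[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        nb_sum[r0:r1, c0:c1] += np.where(nb_m, g[r0 + dr : r1 + dr, c0 + dc : c1 + dc], 0)
        nb_cnt[r0:r1, c0:c1] += nb_m
    valid = m & (nb_cnt > 0)
    n = np.zeros(d.n_levels)
    s = np.zeros(d.n_levels)
    if valid.any():
        diffs = np.abs(g[valid] - nb_sum[valid] / nb_cnt[valid])
        np.add.at(n, g[valid] - 1, 1.0)
        np.add.at(s, g[valid] - 1, diffs)
    return n, s


def ngtdm_features(
    d_or_counts: DiscretizedRegion | tuple[np.ndarray, np.ndarray],
) -> tuple[dict[str, float], set[str]]:
    if isinstance(d_or_counts, DiscretizedRegion):
        n, s = ngtdm_counts(d_or_counts)
    else:
        n, s = d_or_counts
    nvp = float(n.sum())
    undefined: set[str] = set()
    if nvp == 0:
        return {k: np.nan for k in NGTDM_NAMES}, set(NGTDM_NAMES)
    p = n / nvp
    i = np.arange(1, len(n) + 1, dtype=float)
    present = p > 0
    ip, pp, sp = i[present], p[present], s[present]
    ngp = int(present.sum())
    denom_coarse = float(np.sum(pp * sp))
    vals: dict[str, float] = {}
    vals["coarseness"] = 1.0 / denom_coarse if denom_coarse > 0 else COARSENESS_CAP
    if ngp > 1:
        DI = ip[:, None] - ip[None, :]
        PPi = pp[:, None] * pp[None, :]
        vals["contrast"] = float(
            np.sum(PPi * DI**2) / (ngp * (ngp - 1)) * (s.sum() / nvp)
        )
        denom_busy = float(np.sum(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :])))
        vals["busyness"] = denom_coarse / denom_busy if denom_busy > 0 else 0.0
        PS = pp * sp
        vals["complexity"] = float(
            np.sum(np.abs(DI) * (PS[:, None] + PS[None, :]) / (pp[:, None] + pp[None, :]))
            / nvp
        )
        s_total = float(s.sum())
        vals["strength"] = (
            float(np.sum((pp[:, None] + pp[None, :]) * DI**2)) / s_total
            if s_total > 0
            else 0.0
        )
    else:
        vals["contrast"] = 0.0
        vals["busyness"] = 0.0
        vals["complexity"] = 0.0
        vals["strength"] = 0.0
    return {k: vals[k] for k in NGTDM_NAMES}, undefined


# ---------------------------------------------------------------------------
# full 93-feature extraction
# ---------------------------------------------------------------------------


def compute_features(
    intensity_images: Sequence[np.ndarray] | np.ndarray,
    masks: Sequence[np.ndarray] | np.ndarray,
    config: RadiomicsConfig = RadiomicsConfig(),
) -> FeatureVector:
    """All 93 features on one region, given as a single 2D (image, mask)
    pair or as a list of per-slice pairs (a multi-slice segment region).

    For multi-slice regions the gray-level bins are anchored at the pooled
    masked minimum, texture matrices are computed per slice and summed, and
    first-order statistics are computed on the pooled samples.
    """
    if isinstance(intensity_images, np.ndarray) and intensity_images.ndim == 2:
        intensity_images = [intensity_images]
        masks = [masks]  # type: ignore[list-item]
    pairs = [
        (np.asarray(img, dtype=float), np.asarray(mk, dtype=bool))
        for img, mk in zip(intensity_images, masks)
        if np.asarray(mk).any()
    ]
    if not pairs:
        raise EmptyRegionError("no masked pixels in any slice")
    anchor = min(float(img[mk].min()) for img, mk in pairs)
    regions = [discretize(img, mk, config.bin_width, anchor=anchor) for img, mk in pairs]
    ng = max(r.n_levels for r in regions)
    for r in regions:
        r.n_levels = ng

    samples = np.concatenate([img[mk] for img, mk in pairs])
    pooled_levels = np.concatenate([r.levels for r in regions])
    pooled = DiscretizedRegion(
        pooled_levels.reshape(1, -1), np.ones((1, len(pooled_levels)), dtype=bool),
        ng, regions[0].bin_edges,
    )

    values: dict[str, float] = {}
    undefined: set[str] = set()

    fo, fo_undef = first_order(samples, pooled, config.pixel_volume)
    values.update({f"firstorder.{k}": v for k, v in fo.items()})
    undefined |= {f"firstorder.{k}" for k in fo_undef}

    np_pixels = float(sum(r.mask.sum() for r in regions))

    glcm_sum = np.zeros((ng, ng))
    raw_pairs = 0.0
    for r in regions:
        raw = _glcm_counts(r)
        glcm_sum += raw
        raw_pairs += raw.sum()
    if raw_pairs > 0:
        fam, undef = glcm_features(glcm_sum / raw_pairs)
    else:
        fam, undef = {n: np.nan for n in GLCM_NAMES}, set(GLCM_NAMES)
    values.update({f"glcm.{k}": v for k, v in fam.items()})
    undefined |= {f"glcm.{k}" for k in undef}

    gldm_sum = _pad_sum([gldm_matrix(r, config.alpha) for r in regions])
    fam, undef = gldm_features(gldm_sum)
    values.update({f"gldm.{k}": v for k, v in fam.items()})
    undefined |= {f"gldm.{k}" for k in undef}

    glszm_sum = _pad_sum([glszm_matrix(r) for r in regions])
    fam, undef = glszm_features(glszm_sum, np_pixels)
    values.update({f"glszm.{k}": v for k, v in fam.items()})
    undefined |= {f"glszm.{k}" for k in undef}

    glrlm_sum = _pad_sum([glrlm_matrix(r) for r in regions])
    fam, undef = glrlm_features(
        glrlm_sum, np_pixels=np_pixels, n_directions=len(OFFSETS_2D)
    )
    values.update({f"glrlm.{k}": v for k, v in fam.items()})
    undefined |= {f"glrlm.{k}" for k in undef}

    n_tot = np.zeros(ng)
    s_tot = np.zeros(ng)
    for r in regions:
        n_i, s_i = ngtdm_counts(r)
        n_tot += n_i
        s_tot += s_i
    fam, undef = ngtdm_features((n_tot, s_tot))
    values.update({f"ngtdm.{k}": v for k, v in fam.items()})
    undefined |= {f"ngtdm.{k}" for k in undef}

    ordered = {name: values[name] for name in ALL_FEATURE_NAMES}
    return FeatureVector(
        ordered,
        undefined,
        provenance={"bin_width": config.bin_width, "n_levels": float(ng)},
    )


def _glcm_counts(d: DiscretizedRegion) -> np.ndarray:
    """Unnormalized symmetrized co-occurrence counts (all four offsets)."""
    ng = d.n_levels
    counts = np.zeros((ng, ng))
    g, m = d.gray_image, d.mask
    rows, cols = g.shape
    for dr, dc in OFFSETS_2D:
        r0, r1 = max(0, -dr), min(rows, rows - dr)
        c0, c1 = max(0, -dc), min(cols, cols - dc)
        a = g[r0:r1, c0:c1]
        b = g[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = m[r0:r1, c0:c1] & m[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        if valid.any():
            np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1.0)
    return counts + counts.T


def _pad_sum(matrices: list[np.ndarray]) -> np.ndarray:
    rows = max(m.shape[0] for m in matrices)
    cols = max(m.shape[1] for m in matrices)
    out = np.zeros((rows, cols))
    for m in matrices:
        out[: m.shape[0], : m.shape[1]] += m
    return out


def extract_features(
    volume,
    mask: SliceMask,
    region_label: int,
    config: RadiomicsConfig = RadiomicsConfig(),
) -> FeatureVector | None:
    """93 features for one slice region; returns None (skip signal) when the
    region has fewer than ``config.min_region_pixels`` pixels."""
    if not mask.region_valid(region_label, config.min_region_pixels):
        return None
    img, region = region_intensity_image(volume, mask, region_label)
    return compute_features(img, region, config)
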