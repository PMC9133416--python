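"""Short-axis reslicing of the LV and rasterization of myocardium/scar masks.

Sixty planes orthogonal to the endocardial long axis are spread evenly from
base to apex.  On each plane the endo/epi mesh cross-sections define the
myocardial ring and the registered scar mesh's cross-section defines the
scar footprint.  Scar is labelled *transmurally*: any wall location whose
in-plane angular position falls inside the scar silhouette gets the full
wall thickness labelled, which absorbs cardiac-phase differences between the
modalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
import trimesh
from shapely.geometry import Polygon

from .combine import ImageVolume
from .mesh import SurfaceMesh, principal_axis

BACKGROUND, MYOCARDIUM, SCAR = 0, 1, 2

#: minimum pixels for a region to support texture analysis
MIN_REGION_PIXELS = 16


@dataclass
class SliceMask:
    """One short-axis plane's label grid (0 background, 1 myocardium, 2 scar)."""

    slice_index: int
    plane_origin: np.ndarray
    plane_normal: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    grid_origin_uv: tuple[float, float]  # in-plane coords of pixel (0, 0) center
    pixel_grid: np.ndarray  # (rows, cols), rows along v, cols along u
    pixel_spacing: float
    valid: bool
    #: False when the plane is beyond the endocardial apex (apex-cap slice)
    has_cavity: bool = True

    @property
    def myocardium_pixels(self) -> int:
        return int(np.count_nonzero(self.pixel_grid == MYOCARDIUM))

    @property
    def scar_pixels(self) -> int:
        return int(np.count_nonzero(self.pixel_grid == SCAR))

    def region_mask(self, region_label: int) -> np.ndarray:
        if region_label == MYOCARDIUM:
            return self.pixel_grid == MYOCARDIUM
        if region_label == SCAR:
            return self.pixel_grid == SCAR
        raise ValueError("region_label must be 1 (non-scar myocardium) or 2 (scar)")

    def region_valid(self, region_label: int, min_region_pixels: int = MIN_REGION_PIXELS) -> bool:
        return int(self.region_mask(region_label).sum()) >= min_region_pixels

    def pixel_world(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        u0, v0 = self.grid_origin_uv
        u = u0 + np.asarray(cols) * self.pixel_spacing
        v = v0 + np.asarray(rows) * self.pixel_spacing
        return (
            self.plane_origin
            + np.outer(u, self.u_axis)
            + np.outer(v, self.v_axis)
        )


def short_axis_planes(
    endo: SurfaceMesh, n_slices: int = 60
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Evenly spaced (origin, normal) planes from base (index 0) to apex.

    End planes are inset by half a spacing so every slice cuts the shell.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    axis = principal_axis(endo)  # points base -> apex
    centroid = endo.centroid
    proj = (endo.vertices - centroid) @ axis
    lo, hi = float(proj.min()), float(proj.max())
    step = (hi - lo) / n_slices
    return [
        (centroid + (lo + (k + 0.5) * step) * axis, axis.copy())
        for k in range(n_slices)
    ]


def _section_points(mesh: SurfaceMesh, origin: np.ndarray, normal: np.ndarray) -> np.ndarray:
    if len(mesh.vertices) == 0:
        return np.zeros((0, 3))
    segments = trimesh.intersections.mesh_plane(mesh.to_trimesh(), normal, origin)
    if len(segments) == 0:
        return np.zeros((0, 3))
    return np.asarray(segments).reshape(-1, 3)


def _ordered_polygon(points_uv: np.ndarray) -> Polygon | None:
    """Close a star-shaped cross-section by angular ordering of its points."""
    if len(points_uv) < 3:
        return None
    center = points_uv.mean(axis=0)
    rel = points_uv - center
    order = np.argsort(np.arctan2(rel[:, 1], rel[:, 0]))
    poly = Polygon(points_uv[order])
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly if not poly.is_empty else None


def _plane_basis(
    normal: np.ndarray, origin: np.ndarray, rv_anterior: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    u = None
    if rv_anterior is not None:
        d = rv_anterior - origin
        d = d - (d @ n) * n
        if np.linalg.norm(d) > 1e-8:
            u = d / np.linalg.norm(d)
    if u is None:
        helper = np.array([1.0, 0.0, 0.0])
        if abs(n[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        u = np.cross(n, helper)
        u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def rasterize_slice(
    endo: SurfaceMesh,
    epi: SurfaceMesh,
    scar: SurfaceMesh | None,
    plane: tuple[np.ndarray, np.ndarray],
    spacing: float = 1.0,
    slice_index: int = 0,
    rv_anterior: np.ndarray | None = None,
    min_region_pixels: int = MIN_REGION_PIXELS,
) -> SliceMask:
    """Rasterize one plane: ring between epi and endo contours, scar by the
    transmural angular-footprint rule."""
    origin, normal = plane
    u, v = _plane_basis(normal, origin, rv_anterior)

    def to_uv(points: np.ndarray) -> np.ndarray:
        rel = points - origin
        return np.column_stack([rel @ u, rel @ v])

    epi_pts = _section_points(epi, origin, normal)
    empty = SliceMask(
        slice_index, origin, normal, u, v, (0.0, 0.0),
        np.zeros((1, 1), dtype=np.int8), spacing, valid=False, has_cavity=False,
    )
    epi_poly = _ordered_polygon(to_uv(epi_pts)) if len(epi_pts) else None
    if epi_poly is None:
        return empty
    endo_pts = _section_points(endo, origin, normal)
    endo_poly = _ordered_polygon(to_uv(endo_pts)) if len(endo_pts) else None

    minx, miny, maxx, maxy = epi_poly.bounds
    pad = 2 * spacing
    u0, v0 = minx - pad, miny - pad
    n_cols = int(np.ceil((maxx + pad - u0) / spacing)) + 1
    n_rows = int(np.ceil((maxy + pad - v0) / spacing)) + 1
    uu = u0 + np.arange(n_cols) * spacing
    vv = v0 + np.arange(n_rows) * spacing
    U, V = np.meshgrid(uu, vv)  # (rows, cols)

    inside_epi = shapely.contains_xy(epi_poly, U.ravel(), V.ravel()).reshape(U.shape)
    if endo_poly is not None:
        inside_endo = shapely.contains_xy(endo_poly, U.ravel(), V.ravel()).reshape(U.shape)
    else:
        inside_endo = np.zeros_like(inside_epi)
    grid = np.zeros(U.shape, dtype=np.int8)
    grid[inside_epi & ~inside_endo] = MYOCARDIUM

    if scar is not None and len(scar.vertices):
        scar_uv = to_uv(_section_points(scar, origin, normal))
        if len(scar_uv) >= 2:
            center = np.array(epi_poly.centroid.coords[0])
            rel = scar_uv - center
            ang = np.arctan2(rel[:, 1], rel[:, 0])
            mean_dir = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
            rel_ang = np.angle(np.exp(1j * (ang - mean_dir)))
            lo_a, hi_a = rel_ang.min(), rel_ang.max()
            pix_ang = np.angle(
                np.exp(1j * (np.arctan2(V - center[1], U - center[0]) - mean_dir))
            )
            in_wedge = (pix_ang >= lo_a) & (pix_ang <= hi_a)
            grid[(grid == MYOCARDIUM) & in_wedge] = SCAR

    nonscar = int(np.count_nonzero(grid == MYOCARDIUM))
    valid = nonscar >= min_region_pixels
    return SliceMask(
        slice_index, origin, normal, u, v, (float(u0), float(v0)),
        grid, spacing, valid, has_cavity=endo_poly is not None,
    )


def rasterize_stack(
    endo: SurfaceMesh,
    epi: SurfaceMesh,
    scar: SurfaceMesh | None,
    n_slices: int = 60,
    spacing: float = 1.0,
    rv_anterior: np.ndarray | None = None,
    min_region_pixels: int = MIN_REGION_PIXELS,
) -> list[SliceMask]:
    """All short-axis masks for one case, base (index 0) to apex."""
    planes = short_axis_planes(endo, n_slices)
    if rv_anterior is None:
        rv_anterior = endo.landmarks.get("rv_insertion_anterior")
    return [
        rasterize_slice(
            endo, epi, scar, plane, spacing, k, rv_anterior, min_region_pixels
        )
        for k, plane in enumerate(planes)
    ]


def stack_scar_volume(masks: list[SliceMask], endo: SurfaceMesh) -> float:
    """Scar volume estimate: scar pixels x pixel area x slice spacing (mm^3)."""
    if len(masks) < 2:
        raise ValueError("need at least 2 slices for a slice spacing")
    slice_spacing = float(
        np.linalg.norm(masks[1].plane_origin - masks[0].plane_origin)
    )
    area = masks[0].pixel_spacing ** 2
    return sum(m.scar_pixels for m in masks) * area * slice_spacing


def extract_region_intensities(
    volume: ImageVolume, mask: SliceMask, region_label: int
) -> np.ndarray:
    """Nearest-voxel intensities at the masked pixels, row-major order."""
    region = mask.region_mask(region_label)
    rows, cols = np.nonzero(region)
    if len(rows) == 0:
        return np.zeros(0)
    return volume.sample_nearest(mask.pixel_world(rows, cols))


def region_intensity_image(
    volume: ImageVolume, mask: SliceMask, region_label: int
) -> tuple[np.ndarray, np.ndarray]:
    """(intensity image, boolean mask) pair for texture analysis on a slice."""
    region = mask.region_mask(region_label)
    img = np.zeros(region.shape)
    rows, cols = np.nonzero(region)
    if len(rows):
        img[rows, cols] = volume.sample_nearest(mask.pixel_world(rows, cols))
    return img, region


def write_masks(masks: list[SliceMask], out_dir) -> None:
    """Write per-slice paletted PNG masks, a stacked NIfTI label volume on
    the slice grid, and a slice manifest CSV."""
    import csv
    from pathlib import Path

    import nibabel as nib
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    shape = (
        max(m.pixel_grid.shape[0] for m in masks),
        max(m.pixel_grid.shape[1] for m in masks),
    )
    stack = np.zeros((*shape, len(masks)), dtype=np.uint8)
    palette = [0, 0, 0, 160, 40, 40, 255, 255, 120] + [0] * (256 * 3 - 9)
    rows = []
    for k, m in enumerate(masks):
        img = Image.fromarray(m.pixel_grid.astype(np.uint8), mode="P")
        img.putpalette(palette)
        img.save(out / f"slice_{m.slice_index:02d}.png")
        h, w = m.pixel_grid.shape
        stack[:h, :w, k] = m.pixel_grid
        rows.append(
            {
                "slice_index": m.slice_index,
                "valid": m.valid,
                "myocardium_px": m.myocardium_pixels,
                "scar_px": m.scar_pixels,
            }
        )
    spacing = masks[0].pixel_spacing
    slice_gap = (
        float(np.linalg.norm(masks[1].plane_origin - masks[0].plane_origin))
        if len(masks) > 1
        else 1.0
    )
    affine = np.diag([spacing, spacing, slice_gap, 1.0])
    nib.save(nib.Nifti1Image(stack, affine), str(out / "labels.nii.gz"))
    with open(out / "slices.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
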