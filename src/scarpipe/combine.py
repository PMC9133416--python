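"""CT image volumes and combined-energy image synthesis.

Delayed-enhancement CT is acquired at more than one tube voltage; the lower
energy shows more iodine contrast but more noise.  A weighted (convex)
voxelwise combination of the co-registered volumes trades these off.  The
higher-energy volume is first rigidly registered to the lower-energy one,
resampled onto its grid, and then mixed as ``w * high + (1 - w) * low``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .mesh import RigidTransform

#: fill value for voxels resampled from outside the moving field of view
OUT_OF_FIELD_HU = -1024.0


class GeometryError(ValueError):
    """Voxel grids do not match where identical geometry is required."""


@dataclass
class ImageVolume:
    """3D scalar voxel grid with world geometry.

    ``voxels[i, j, k]`` sits at world position
    ``origin + orientation @ (spacing * (i, j, k))`` (mm); intensities in HU.
    """

    voxels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(3, 3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if not np.allclose(self.orientation.T @ self.orientation, np.eye(3), atol=1e-8):
            raise ValueError("orientation must be orthonormal")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return (idx * self.spacing) @ self.orientation.T + self.origin

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return ((pts - self.origin) @ self.orientation) / self.spacing

    def sample_nearest(self, points: np.ndarray) -> np.ndarray:
        """Nearest-voxel intensities at world points; out-of-bounds raises."""
        idx = np.rint(self.world_to_index(points)).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            raise IndexError("sample point outside volume bounds")
        return self.voxels[idx[:, 0], idx[:, 1], idx[:, 2]]

    def same_grid(self, other: "ImageVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.orientation, other.orientation)
        )

    # -- NIfTI I/O ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        affine = np.eye(4)
        affine[:3, :3] = self.orientation * self.spacing
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.voxels.astype(np.float32), affine), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "ImageVolume":
        img = nib.load(str(path))
        affine = img.affine
        M = affine[:3, :3]
        spacing = np.linalg.norm(M, axis=0)
        return cls(
            np.asarray(img.get_fdata(), dtype=float),
            spacing=spacing,
            origin=affine[:3, 3],
            orientation=M / spacing,
        )


# ---------------------------------------------------------------------------
# SimpleITK bridge
# ---------------------------------------------------------------------------


def _to_sitk(vol: ImageVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels.transpose(2, 1, 0)))
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(vol.origin))
    img.SetDirection(tuple(vol.orientation.ravel()))
    return img


def _from_sitk(img: sitk.Image) -> ImageVolume:
    return ImageVolume(
        sitk.GetArrayFromImage(img).transpose(2, 1, 0),
        spacing=np.array(img.GetSpacing()),
        origin=np.array(img.GetOrigin()),
        orientation=np.array(img.GetDirection()).reshape(3, 3),
    )


@dataclass
class VolumeRegistrationResult:
    transform: RigidTransform  # maps moving-frame geometry into the fixed frame
    converged: bool
    final_metric: float


def register_volumes(
    moving: ImageVolume,
    fixed: ImageVolume,
    max_iterations: int = 200,
) -> VolumeRegistrationResult:
    """Rigid intensity-based registration of ``moving`` onto ``fixed``.

    Mean-squared-error metric, regular-step gradient descent, linear
    interpolation (Euler 3D transform).  The returned rigid transform maps
    moving-frame coordinates into the fixed frame, so a volume whose content
    is the fixed content shifted by +d yields a translation of -d.
    """
    f_img = _to_sitk(fixed)
    m_img = _to_sitk(moving)

    # volumes come from the same acquisition session and share a world
    # frame: start at identity (rotation centered on the fixed volume)
    initial = sitk.Euler3DTransform()
    center = fixed.index_to_world((np.array(fixed.shape) - 1) / 2.0)[0]
    initial.SetCenter(tuple(center))
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-4,
        numberOfIterations=max_iterations,
        relaxationFactor=0.5,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(initial, inPlace=False)
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()

    try:
        fitted = reg.Execute(f_img, m_img)
        metric = float(reg.GetMetricValue())
    except RuntimeError:
        # e.g. no overlapping samples for disjoint fields of view
        return VolumeRegistrationResult(RigidTransform.identity(), False, float("inf"))

    euler = sitk.Euler3DTransform(
        sitk.CompositeTransform(fitted).GetNthTransform(0)
    )
    # SimpleITK's fitted transform maps fixed-domain points into the moving
    # domain; invert it to express moving geometry in the fixed frame.
    A = np.array(euler.GetMatrix()).reshape(3, 3)
    c = np.array(euler.GetCenter())
    t = np.array(euler.GetTranslation())
    fixed_to_moving = RigidTransform(A, c + t - A @ c)
    converged = np.isfinite(metric) and metric < np.var(fixed.voxels) + 1e-9
    return VolumeRegistrationResult(fixed_to_moving.inverse(), converged, metric)


def resample_to(
    moving: ImageVolume, fixed: ImageVolume, transform: RigidTransform
) -> ImageVolume:
    """Resample ``moving`` onto the grid of ``fixed``.

    ``transform`` maps moving-frame geometry into the fixed frame (the
    convention of :func:`register_volumes`); linear interpolation, voxels
    outside the moving field filled with ``OUT_OF_FIELD_HU``.
    """
    inv = transform.inverse()
    aff = sitk.AffineTransform(3)
    aff.SetMatrix(tuple(inv.rotation.ravel()))
    aff.SetTranslation(tuple(inv.translation))
    out = sitk.Resample(
        _to_sitk(moving),
        _to_sitk(fixed),
        aff,
        sitk.sitkLinear,
        OUT_OF_FIELD_HU,
    )
    return _from_sitk(out)


def combine(low: ImageVolume, high_registered: ImageVolume, w: float) -> ImageVolume:
    """Convex voxelwise combination with the high-energy image contributing
    fraction ``w``; geometry is copied from the low-energy grid."""
    if not 0.0 < w < 1.0:
        raise ValueError("w must lie in (0, 1)")
    if not low.same_grid(high_registered):
        raise GeometryError("low and registered high volumes must share a grid")
    return ImageVolume(
        w * high_registered.voxels + (1.0 - w) * low.voxels,
        spacing=low.spacing.copy(),
        origin=low.origin.copy(),
        orientation=low.orientation.copy(),
    )
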