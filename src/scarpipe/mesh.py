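"""Rigid registration of left-ventricle surface meshes.

The scar label lives on the MRI-derived anatomy while the texture analysis
runs on CT, so the MRI LV has to be mapped rigidly into the CT frame.
Registration is performed in three steps:

1. align the long (principal) axes of the two endocardial meshes,
2. rotate about the long axis so the right-ventricle insertion points match,
3. refine with point-to-point iterative closest point (ICP).

The composed transform is then applied to the scar mesh, which is a passive
passenger of the endocardium-driven registration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree


class DegenerateMeshError(ValueError):
    """Vertex cloud has no usable principal axis (or zero projected radius)."""


class LandmarkError(KeyError):
    """A required named landmark is missing from a mesh."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``v -> R v + t`` in mm."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotation_about(cls, rotation: np.ndarray, center: np.ndarray) -> "RigidTransform":
        """Rotation about an arbitrary center point."""
        center = np.asarray(center, dtype=float)
        return cls(rotation, center - rotation @ center)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out.reshape(np.shape(points))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply *other* first, then *self*."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_json_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))


@dataclass
class SurfaceMesh:
    """Triangulated surface with optional named landmarks (coordinates in mm)."""

    vertices: np.ndarray
    faces: np.ndarray
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")
        self.landmarks = {k: np.asarray(v, dtype=float) for k, v in self.landmarks.items()}

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    # -- I/O ---------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write PLY/STL (by extension) plus a JSON landmark sidecar."""
        path = Path(path)
        self.to_trimesh().export(path)
        if self.landmarks:
            sidecar = path.with_suffix(path.suffix + ".landmarks.json")
            sidecar.write_text(
                json.dumps({k: v.tolist() for k, v in self.landmarks.items()}, indent=1)
            )

    @classmethod
    def load(cls, path: str | Path) -> "SurfaceMesh":
        path = Path(path)
        tm = trimesh.load_mesh(path, process=False)
        landmarks: dict[str, np.ndarray] = {}
        sidecar = path.with_suffix(path.suffix + ".landmarks.json")
        if sidecar.exists():
            landmarks = {k: np.asarray(v) for k, v in json.loads(sidecar.read_text()).items()}
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), landmarks)


# ---------------------------------------------------------------------------
# Step 0: principal (long) axis
# ---------------------------------------------------------------------------

#: smallest admissible ratio of first to second covariance eigenvalue
_AXIS_EIGENRATIO_MIN = 1.0 + 1e-6


def principal_axis(mesh: SurfaceMesh) -> np.ndarray:
    """Unit vector along the dominant vertex-covariance direction.

    The sign is fixed to point from the base toward the apex.  If the mesh
    carries an ``apex`` landmark that decides the sign; otherwise the apex end
    is taken as the pointier one (smaller mean radial spread about the axis),
    which is robust for LV-shaped shells.
    """
    verts = mesh.vertices
    if len(verts) < 4:
        raise DegenerateMeshError("need at least 4 vertices for a principal axis")
    centered = verts - verts.mean(axis=0)
    cov = centered.T @ centered / len(verts)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[-1] < _AXIS_EIGENRATIO_MIN * evals[-2]:
        raise DegenerateMeshError(
            f"no unique major axis (eigenvalue ratio {evals[-1] / evals[-2]:.2e})"
        )
    axis = evecs[:, -1]

    if "apex" in mesh.landmarks:
        toward_apex = mesh.landmarks["apex"] - verts.mean(axis=0)
        if axis @ toward_apex < 0:
            axis = -axis
        return axis

    # pointedness heuristic: compare radial spread in the two end slabs
    proj = centered @ axis
    lo, hi = proj.min(), proj.max()
    slab = 0.15 * (hi - lo)
    radial = np.linalg.norm(centered - np.outer(proj, axis), axis=1)
    spread_hi = radial[proj > hi - slab].mean()
    spread_lo = radial[proj < lo + slab].mean()
    if spread_lo > spread_hi:  # pointy (apex) end sits at +proj already
        return axis
    return -axis


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal-angle rotation matrix mapping unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if c < -1.0 + 1e-12:  # anti-parallel: 180 deg about any orthogonal axis
        helper = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, helper)
        axis /= np.linalg.norm(axis)
        return _axis_angle(axis, np.pi)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


# ---------------------------------------------------------------------------
# Step 1: long-axis alignment
# ---------------------------------------------------------------------------


def align_major_axes(moving: SurfaceMesh, fixed: SurfaceMesh) -> RigidTransform:
    """Minimal rotation mapping the moving long axis onto the fixed one,
    plus the translation aligning the vertex centroids."""
    ax_m = principal_axis(moving)
    ax_f = principal_axis(fixed)
    R = _rotation_between(ax_m, ax_f)
    t = fixed.centroid - R @ moving.centroid
    return RigidTransform(R, t)


# ---------------------------------------------------------------------------
# Step 2: axial rotation from RV insertion points
# ---------------------------------------------------------------------------

RV_ANTERIOR = "rv_insertion_anterior"
RV_INFERIOR = "rv_insertion_inferior"


def _require_landmarks(mesh: SurfaceMesh, name: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        return mesh.landmarks[RV_ANTERIOR], mesh.landmarks[RV_INFERIOR]
    except KeyError as exc:
        raise LandmarkError(f"mesh '{name}' is missing RV insertion landmark {exc}") from None


def align_rv_insertions(
    moving: SurfaceMesh, fixed: SurfaceMesh, long_axis: np.ndarray
) -> RigidTransform:
    """Pure rotation about ``long_axis`` (through the fixed centroid) that
    best matches the RV insertion points in the plane orthogonal to the axis.

    The optimal angle is the 2D Procrustes solution on the projected
    landmark vectors.
    """
    n = np.asarray(long_axis, dtype=float)
    n = n / np.linalg.norm(n)
    lm_m = np.vstack(_require_landmarks(moving, "moving"))
    lm_f = np.vstack(_require_landmarks(fixed, "fixed"))
    center = fixed.centroid

    # in-plane orthonormal basis
    u = np.cross(n, [0.0, 0.0, 1.0])
    if np.linalg.norm(u) < 1e-8:
        u = np.cross(n, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(n, u)

    def project(points: np.ndarray) -> np.ndarray:
        rel = points - center
        return np.column_stack([rel @ u, rel @ v])

    pm, pf = project(lm_m), project(lm_f)
    if np.min(np.linalg.norm(pm, axis=1)) < 1e-9 or np.min(np.linalg.norm(pf, axis=1)) < 1e-9:
        raise DegenerateMeshError("RV insertion point lies on the long axis")
    # angle maximizing sum of dot(R2(theta) pm_i, pf_i)
    cos_sum = float(np.sum(pm * pf))
    sin_sum = float(np.sum(pm[:, 0] * pf[:, 1] - pm[:, 1] * pf[:, 0]))
    theta = np.arctan2(sin_sum, cos_sum)
    R = _axis_angle(n, theta)
    return RigidTransform.from_rotation_about(R, center)


# ---------------------------------------------------------------------------
# Step 3: ICP refinement
# ---------------------------------------------------------------------------


@dataclass
class ICPResult:
    transform: RigidTransform
    converged: bool
    n_iterations: int
    #: RMS nearest-neighbour distance after each iteration (index 0 = after init)
    history: list[float] = field(default_factory=list)


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid transform mapping src onto dst."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, cd - R @ cs)


def icp(
    moving: SurfaceMesh,
    fixed: SurfaceMesh,
    init: RigidTransform | None = None,
    max_iter: int = 100,
    tol: float = 1e-4,
    trim_fraction: float = 0.0,
) -> ICPResult:
    """Point-to-point ICP with nearest-vertex correspondences.

    Each iteration pairs every moving vertex with its nearest fixed vertex
    (k-d tree) and solves the closed-form SVD update; the RMS correspondence
    distance is therefore non-increasing.  Stops when the improvement drops
    below ``tol`` (mm) or after ``max_iter`` iterations.  The returned
    transform includes ``init``.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if init is None:
        init = RigidTransform.identity()
    tree = cKDTree(fixed.vertices)
    current = init
    pts = init.apply(moving.vertices)
    dist, idx = tree.query(pts)
    rms = float(np.sqrt(np.mean(dist**2)))
    history = [rms]
    converged = False
    n_keep = max(4, int(round((1.0 - trim_fraction) * len(pts))))
    for _ in range(max_iter):
        if trim_fraction > 0.0:
            keep = np.argsort(dist)[:n_keep]
            step = _kabsch(pts[keep], fixed.vertices[idx[keep]])
        else:
            step = _kabsch(pts, fixed.vertices[idx])
        current = step.compose(current)
        pts = step.apply(pts)
        dist, idx = tree.query(pts)
        new_rms = float(np.sqrt(np.mean(dist**2)))
        history.append(new_rms)
        if rms - new_rms < tol:
            rms = new_rms
            converged = True
            break
        rms = new_rms
    return ICPResult(current, converged, len(history) - 1, history)


# ---------------------------------------------------------------------------
# Full three-step registration
# ---------------------------------------------------------------------------


@dataclass
class RegistrationQC:
    """Automatic stand-in for visual registration checks."""

    apex_distance_mm: float
    base_centroid_distance_mm: float
    final_rms_mm: float
    passed: bool


def register_lv(
    moving_endo: SurfaceMesh,
    fixed_endo: SurfaceMesh,
    max_iter: int = 100,
    tol: float = 1e-4,
    qc_apex_mm: float = 5.0,
    qc_base_mm: float = 5.0,
) -> tuple[RigidTransform, RegistrationQC]:
    """Three-step registration of the moving (MRI) endocardium onto the
    fixed (CT) endocardium: long axes, RV insertions, then ICP."""
    try:
        t1 = align_major_axes(moving_endo, fixed_endo)
    except DegenerateMeshError as exc:
        raise DegenerateMeshError(f"major-axis step: {exc}") from exc
    moved1 = apply_transform(moving_endo, t1)
    axis = principal_axis(fixed_endo)
    try:
        t2 = align_rv_insertions(moved1, fixed_endo, axis)
    except (LandmarkError, DegenerateMeshError) as exc:
        raise type(exc)(f"rv-insertion step: {exc}") from exc
    init = t2.compose(t1)
    result = icp(moving_endo, fixed_endo, init=init, max_iter=max_iter, tol=tol)
    total = result.transform

    moved = apply_transform(moving_endo, total)
    qc = _registration_qc(moved, fixed_endo, result, qc_apex_mm, qc_base_mm)
    return total, qc


def _axis_extreme(mesh: SurfaceMesh, axis: np.ndarray, apex_end: bool) -> np.ndarray:
    proj = (mesh.vertices - mesh.centroid) @ axis
    if apex_end:
        return mesh.vertices[np.argmax(proj)]
    sel = proj < proj.min() + 0.05 * (proj.max() - proj.min()) + 1e-9
    return mesh.vertices[sel].mean(axis=0)


def _registration_qc(
    moved: SurfaceMesh,
    fixed: SurfaceMesh,
    icp_result: ICPResult,
    qc_apex_mm: float,
    qc_base_mm: float,
) -> RegistrationQC:
    axis = principal_axis(fixed)
    apex_d = float(
        np.linalg.norm(_axis_extreme(moved, axis, True) - _axis_extreme(fixed, axis, True))
    )
    base_d = float(
        np.linalg.norm(_axis_extreme(moved, axis, False) - _axis_extreme(fixed, axis, False))
    )
    return RegistrationQC(
        apex_distance_mm=apex_d,
        base_centroid_distance_mm=base_d,
        final_rms_mm=icp_result.history[-1],
        passed=apex_d <= qc_apex_mm and base_d <= qc_base_mm,
    )


def apply_transform(mesh: SurfaceMesh, t: RigidTransform) -> SurfaceMesh:
    """Map vertices and landmarks through a rigid transform; faces unchanged."""
    return SurfaceMesh(
        t.apply(mesh.vertices),
        mesh.faces.copy(),
        {k: t.apply(v) for k, v in mesh.landmarks.items()},
    )


def save_transform(t: RigidTransform, path: str | Path) -> None:
    Path(path).write_text(json.dumps(t.to_json_dict(), indent=1))


def load_transform(path: str | Path) -> RigidTransform:
    return RigidTransform.from_json_dict(json.loads(Path(path).read_text()))
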