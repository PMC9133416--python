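"""Synthetic left-ventricle phantom cohorts.

The patient images behind this analysis cannot be redistributed, so every
downstream stage is exercised on synthetic cases that reproduce the
statistical structure the method assumes:

* an LV modelled as a truncated half-ellipsoid myocardial shell (analytic
  volumes, so ground truths are exact),
* a contiguous transmural scar wedge occupying a known fraction of the
  myocardium,
* a second ("MRI") copy of the anatomy related to the CT copy by an unknown
  rigid misalignment plus vertex noise, with RV insertion-point landmarks,
* dual-energy CT-like volumes in which scar is brighter (retained contrast)
  and *more homogeneous* in texture than remote myocardium — the scar noise
  field is spatially smoothed, so its discretized gray-level diversity is
  strictly lower,
* per-patient variation of scar burden and scar location.

All randomness is driven by ``(seed, patient_index)`` so cohorts are exactly
reproducible.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .combine import ImageVolume
from .mesh import (
    RV_ANTERIOR,
    RV_INFERIOR,
    RigidTransform,
    SurfaceMesh,
    _axis_angle,
    save_transform,
)


class PhantomParamError(ValueError):
    """Invalid phantom parameter; the message names the offending field."""


@dataclass(frozen=True)
class PhantomParams:
    """Cohort-level generator settings (lengths mm, intensities HU).

    ``scar_texture_smoothing`` is the Gaussian correlation length (mm) of the
    scar noise field: larger values give a smoother, more homogeneous scar.
    ``noise_sd_per_energy`` / ``contrast_scale_per_energy`` encode the
    dual-energy trade-off: the low-energy (80 kV) image gets more iodine
    contrast but more noise.
    """

    n_patients: int = 15
    endo_radius: float = 20.0
    epi_radius: float = 30.0
    lv_length: float = 90.0
    scar_fraction_range: tuple[float, float] = (0.05, 0.20)
    scar_mean_shift: float = 25.0
    scar_texture_smoothing: float = 1.5
    #: per-patient range of the scar noise amplitude relative to remote
    #: myocardium (<1 means scar is more homogeneous; infarct texture varies
    #: between patients)
    scar_noise_scale_range: tuple[float, float] = (0.55, 0.9)
    #: relative sd of the smooth axial modulation of scar texture within a
    #: patient (infarct core/border-zone heterogeneity); 0 disables it
    scar_heterogeneity: float = 0.35
    noise_sd_per_energy: dict[str, float] = field(
        default_factory=lambda: {"80kV": 25.0, "100kV": 15.0}
    )
    contrast_scale_per_energy: dict[str, float] = field(
        default_factory=lambda: {"80kV": 1.25, "100kV": 1.0}
    )
    misalignment_max_rotation: float = 12.0  # degrees
    misalignment_max_translation: float = 8.0  # mm
    vertex_noise_sd: float = 0.5  # mm, on the "MRI" meshes
    voxel_spacing: float = 1.0  # mm, isotropic
    myocardium_hu: float = 80.0
    blood_pool_hu: float = 100.0  # plus 150 * contrast scale of iodine
    #: between-patient sd of the global tissue enhancement offset (HU),
    #: emulating contrast-timing and habitus variability
    patient_hu_sd: float = 12.0
    #: between-patient multiplicative range of the noise sd, emulating
    #: automatic tube-current modulation
    patient_noise_scale_range: tuple[float, float] = (0.75, 1.3)
    scar_z_band: tuple[float, float] = (0.25, 0.75)  # relative depth below base
    n_azimuth: int = 48
    n_latitude: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise PhantomParamError("n_patients must be >= 1")
        for name in ("endo_radius", "epi_radius", "lv_length", "voxel_spacing"):
            if getattr(self, name) <= 0:
                raise PhantomParamError(f"{name} must be > 0")
        if self.epi_radius <= self.endo_radius:
            raise PhantomParamError("epi_radius must exceed endo_radius")
        lo, hi = self.scar_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise PhantomParamError("scar_fraction_range must be within [0, 1]")
        for energy, sd in self.noise_sd_per_energy.items():
            if sd < 0:
                raise PhantomParamError(f"noise_sd_per_energy[{energy!r}] must be >= 0")
        if self.scar_texture_smoothing < 0:
            raise PhantomParamError("scar_texture_smoothing must be >= 0")
        s0, s1 = self.scar_noise_scale_range
        if not 0.0 <= s0 <= s1 <= 1.0:
            raise PhantomParamError("scar_noise_scale_range must be within [0, 1]")
        if self.scar_heterogeneity < 0:
            raise PhantomParamError("scar_heterogeneity must be >= 0")
        b0, b1 = self.scar_z_band
        if not (0.0 <= b0 < b1 <= 1.0):
            raise PhantomParamError("scar_z_band must be an increasing sub-interval of [0, 1]")

    @property
    def wall_thickness(self) -> float:
        return self.epi_radius - self.endo_radius

    @property
    def endo_length(self) -> float:
        return self.lv_length - self.wall_thickness

    @property
    def energies(self) -> list[str]:
        return sorted(self.noise_sd_per_energy)


@dataclass
class PhantomCase:
    """One synthetic patient; ground-truth fields exist for testing only."""

    patient_id: str
    ct_endo: SurfaceMesh
    ct_epi: SurfaceMesh
    mri_endo: SurfaceMesh
    mri_epi: SurfaceMesh
    scar_mesh_mri_frame: SurfaceMesh
    scar_empty: bool
    rv_insertions_ct: dict[str, np.ndarray]
    rv_insertions_mri: dict[str, np.ndarray]
    true_misalignment: RigidTransform  # maps the MRI frame into the CT frame
    volumes: dict[str, ImageVolume]
    true_scar_label: ImageVolume | None
    true_scar_fraction: float
    drawn_scar_fraction: float


# ---------------------------------------------------------------------------
# analytic geometry of the half-ellipsoid shell
# ---------------------------------------------------------------------------
# The LV sits with its base plane at z = 0 and the apex at z = -lv_length.
# The endocardial surface is the half-ellipsoid x^2/a^2 + y^2/a^2 + z^2/c^2 = 1
# (z < 0) with a = endo_radius, c = endo_length; the epicardium likewise with
# a = epi_radius, c = lv_length.


def _partial_ellipsoid_volume(a: float, c: float, z0: float, z1: float) -> float:
    """Volume of the solid half-ellipsoid between heights z0 < z1 (both <= 0)."""
    z0 = float(np.clip(z0, -c, 0.0))
    z1 = float(np.clip(z1, -c, 0.0))
    if z1 <= z0:
        return 0.0

    def antideriv(z: float) -> float:
        return z - z**3 / (3.0 * c**2)

    return np.pi * a**2 * (antideriv(z1) - antideriv(z0))


def shell_volume(params: PhantomParams, z0: float | None = None, z1: float | None = None) -> float:
    """Analytic myocardial shell volume, optionally restricted to a z band."""
    z0 = -params.lv_length if z0 is None else z0
    z1 = 0.0 if z1 is None else z1
    return _partial_ellipsoid_volume(
        params.epi_radius, params.lv_length, z0, z1
    ) - _partial_ellipsoid_volume(params.endo_radius, params.endo_length, z0, z1)


def _half_ellipsoid_mesh(a: float, c: float, n_az: int, n_lat: int) -> SurfaceMesh:
    """Lat-long triangulation of the half-ellipsoid, open at the base rim."""
    psis = np.pi / 2 + (np.pi / 2) * np.arange(n_lat) / n_lat  # base ring .. near apex
    phis = 2 * np.pi * np.arange(n_az) / n_az
    verts = []
    for psi in psis:
        sp, cp = np.sin(psi), np.cos(psi)
        for phi in phis:
            verts.append([a * sp * np.cos(phi), a * sp * np.sin(phi), c * cp])
    apex_index = len(verts)
    verts.append([0.0, 0.0, -c])
    faces = []
    for i in range(n_lat - 1):
        for j in range(n_az):
            j2 = (j + 1) % n_az
            v00, v01 = i * n_az + j, i * n_az + j2
            v10, v11 = (i + 1) * n_az + j, (i + 1) * n_az + j2
            faces.append([v00, v01, v11])
            faces.append([v00, v11, v10])
    last = (n_lat - 1) * n_az
    for j in range(n_az):
        faces.append([last + j, last + (j + 1) % n_az, apex_index])
    return SurfaceMesh(np.asarray(verts), np.asarray(faces))


def _radius_at(a: float, c: float, z: np.ndarray) -> np.ndarray:
    return a * np.sqrt(np.clip(1.0 - (z / c) ** 2, 0.0, None))


def _scar_wedge_mesh(
    params: PhantomParams,
    phi0: float,
    phi1: float,
    z0: float,
    z1: float,
    n_z: int = 24,
    n_phi: int = 24,
    n_r: int = 4,
) -> SurfaceMesh:
    """Watertight surface of the transmural scar wedge (CT frame).

    Built from six structured patches (inner, outer, two azimuthal walls,
    two z caps) whose shared boundary vertices coincide exactly, then merged.
    """
    zs = np.linspace(z0, z1, n_z)
    phis = np.linspace(phi0, phi1, n_phi)
    r_in = _radius_at(params.endo_radius, params.endo_length, zs)
    r_out = _radius_at(params.epi_radius, params.lv_length, zs)

    def ring(radii: np.ndarray, z: float, phi_vals: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [radii * np.cos(phi_vals), radii * np.sin(phi_vals), np.full(len(phi_vals), z)]
        )

    verts: list[np.ndarray] = []
    faces: list[list[int]] = []

    def add_grid(grid: np.ndarray) -> None:
        # grid shape (nu, nv, 3): quad strips triangulated
        nu, nv = grid.shape[:2]
        base = len(verts)
        for row in grid.reshape(-1, 3):
            verts.append(row)
        for i in range(nu - 1):
            for j in range(nv - 1):
                v00 = base + i * nv + j
                v01 = v00 + 1
                v10 = v00 + nv
                v11 = v10 + 1
                faces.append([v00, v01, v11])
                faces.append([v00, v11, v10])

    # inner and outer patches: rows over z, columns over phi
    add_grid(np.stack([ring(np.full(n_phi, r), z, phis) for r, z in zip(r_in, zs)]))
    add_grid(np.stack([ring(np.full(n_phi, r), z, phis) for r, z in zip(r_out, zs)]))
    # azimuthal walls: rows over z, columns over radius
    for phi in (phi0, phi1):
        wall = np.stack(
            [
                ring(np.linspace(ri, ro, n_r), z, np.full(n_r, phi))
                for ri, ro, z in zip(r_in, r_out, zs)
            ]
        )
        add_grid(wall)
    # z caps: rows over radius, columns over phi
    for k in (0, n_z - 1):
        cap = np.stack(
            [
                ring(np.full(n_phi, r), zs[k], phis)
                for r in np.linspace(r_in[k], r_out[k], n_r)
            ]
        )
        add_grid(cap)

    mesh = SurfaceMesh(np.asarray(verts), np.asarray(faces))
    tm = mesh.to_trimesh()
    tm.merge_vertices(digits_vertex=8)
    tm.update_faces(tm.nondegenerate_faces())
    tm.fix_normals()
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


# ---------------------------------------------------------------------------
# case generation
# ---------------------------------------------------------------------------


def _random_misalignment(params: PhantomParams, rng: np.random.Generator, center: np.ndarray) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, params.misalignment_max_rotation))
    R = _axis_angle(axis, angle)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    t = direction * rng.uniform(0.0, params.misalignment_max_translation)
    about_center = RigidTransform.from_rotation_about(R, center)
    return RigidTransform(about_center.rotation, about_center.translation + t)


def _grid_axes(params: PhantomParams, margin: float = 5.0):
    s = params.voxel_spacing
    r = params.epi_radius + margin
    xs = np.arange(-r, r + s / 2, s)
    zs = np.arange(-(params.lv_length + margin), margin + s / 2, s)
    return xs, xs.copy(), zs


def _inside_shell(params: PhantomParams, X, Y, Z):
    endo = (X / params.endo_radius) ** 2 + (Y / params.endo_radius) ** 2 + (
        Z / params.endo_length
    ) ** 2 <= 1.0
    endo &= Z <= 0
    epi = (X / params.epi_radius) ** 2 + (Y / params.epi_radius) ** 2 + (
        Z / params.lv_length
    ) ** 2 <= 1.0
    epi &= Z <= 0
    return epi & ~endo, endo


def _angle_in_wedge(phi: np.ndarray, phi0: float, phi1: float) -> np.ndarray:
    width = phi1 - phi0
    rel = np.mod(phi - phi0, 2 * np.pi)
    return rel <= width


def generate_case(
    params: PhantomParams, patient_index: int, include_volumes: bool = True
) -> PhantomCase:
    """Generate one synthetic patient, deterministic in (seed, patient_index)."""
    if patient_index >= params.n_patients:
        raise PhantomParamError("patient_index must be < n_patients")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, patient_index]))

    ct_endo = _half_ellipsoid_mesh(
        params.endo_radius, params.endo_length, params.n_azimuth, params.n_latitude
    )
    ct_epi = _half_ellipsoid_mesh(
        params.epi_radius, params.lv_length, params.n_azimuth, params.n_latitude
    )

    # RV insertion landmarks on the epicardium near the base; the inferior
    # insertion sits 120 deg from the anterior one, the arc between them
    # (in +phi direction) being the septum.
    z_lm = -0.15 * params.lv_length
    r_lm = _radius_at(params.epi_radius, params.lv_length, np.array([z_lm]))[0]
    phi_ant, phi_inf = 0.5, 0.5 + 2 * np.pi / 3
    landmarks_ct = {
        RV_ANTERIOR: np.array([r_lm * np.cos(phi_ant), r_lm * np.sin(phi_ant), z_lm]),
        RV_INFERIOR: np.array([r_lm * np.cos(phi_inf), r_lm * np.sin(phi_inf), z_lm]),
        "apex": np.array([0.0, 0.0, -params.lv_length]),
    }
    ct_endo.landmarks = {
        **{k: v.copy() for k, v in landmarks_ct.items()},
        "apex": np.array([0.0, 0.0, -params.endo_length]),
    }
    ct_epi.landmarks = {k: v.copy() for k, v in landmarks_ct.items()}

    # scar wedge: fraction drawn from the range, azimuthal extent solved
    # analytically so the wedge hits that fraction of the shell volume
    lo, hi = params.scar_fraction_range
    drawn_fraction = float(rng.uniform(lo, hi))
    z0 = -params.scar_z_band[1] * params.lv_length
    z1 = -params.scar_z_band[0] * params.lv_length
    z0 = max(z0, -0.95 * params.endo_length)  # keep the band inside the endo extent
    band_volume = shell_volume(params, z0, z1)
    total_volume = shell_volume(params)
    scar_empty = drawn_fraction <= 0.0 or band_volume <= 0.0
    phi_c = float(rng.uniform(0.0, 2 * np.pi))
    if scar_empty:
        scar_mesh_ct = SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        phi0 = phi1 = phi_c
        true_fraction = 0.0
    else:
        wedge_angle = 2 * np.pi * drawn_fraction * total_volume / band_volume
        if wedge_angle > 2 * np.pi:
            wedge_angle = 2 * np.pi
        phi0, phi1 = phi_c - wedge_angle / 2, phi_c + wedge_angle / 2
        scar_mesh_ct = _scar_wedge_mesh(params, phi0, phi1, z0, z1)
        true_fraction = wedge_angle / (2 * np.pi) * band_volume / total_volume

    # misalignment: the true transform maps MRI frame -> CT frame
    true_t = _random_misalignment(params, rng, ct_endo.centroid)
    inv = true_t.inverse()

    def to_mri(mesh: SurfaceMesh, noisy: bool) -> SurfaceMesh:
        moved = SurfaceMesh(
            inv.apply(mesh.vertices),
            mesh.faces.copy(),
            {k: inv.apply(v) for k, v in mesh.landmarks.items()},
        )
        if noisy and params.vertex_noise_sd > 0 and len(moved.vertices):
            moved.vertices = moved.vertices + rng.normal(
                0.0, params.vertex_noise_sd, moved.vertices.shape
            )
        return moved

    mri_endo = to_mri(ct_endo, noisy=True)
    mri_epi = to_mri(ct_epi, noisy=True)
    scar_mri = to_mri(scar_mesh_ct, noisy=False)
    rv_ct = {k: landmarks_ct[k].copy() for k in (RV_ANTERIOR, RV_INFERIOR)}
    rv_mri = {k: inv.apply(v) for k, v in rv_ct.items()}

    volumes: dict[str, ImageVolume] = {}
    label_volume: ImageVolume | None = None
    if include_volumes:
        xs, ys, zs = _grid_axes(params)
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        shell, endo_solid = _inside_shell(params, X, Y, Z)
        phi = np.arctan2(Y, X)
        scar_mask = (
            shell & (Z >= z0) & (Z <= z1) & _angle_in_wedge(phi, phi0, phi1)
            if not scar_empty
            else np.zeros_like(shell)
        )
        origin = np.array([xs[0], ys[0], zs[0]])
        spacing = np.full(3, params.voxel_spacing)
        label_volume = ImageVolume(scar_mask.astype(float), spacing, origin)
        patient_offset = (
            rng.normal(0.0, params.patient_hu_sd) if params.patient_hu_sd > 0 else 0.0
        )
        noise_scale = float(rng.uniform(*params.patient_noise_scale_range))
        scar_noise_scale = float(rng.uniform(*params.scar_noise_scale_range))
        # smooth axial profile of scar texture heterogeneity (shared by both
        # energies: it is a tissue property, not an acquisition one)
        prof = gaussian_filter(rng.normal(size=len(zs)), 8.0 / params.voxel_spacing)
        sd = prof.std()
        prof = prof / sd if sd > 0 else prof * 0.0
        axial_mod = np.clip(1.0 + params.scar_heterogeneity * prof, 0.3, 1.8)
        scar_scale_z = np.clip(scar_noise_scale * axial_mod, 0.05, 1.0)[None, None, :]
        for energy in params.energies:
            c = params.contrast_scale_per_energy.get(energy, 1.0)
            sd = params.noise_sd_per_energy[energy] * noise_scale
            base = np.zeros_like(X)
            base[endo_solid] = params.blood_pool_hu + 150.0 * c
            base[shell] = params.myocardium_hu
            base[scar_mask] = params.myocardium_hu + params.scar_mean_shift * c
            base[endo_solid | shell] += patient_offset
            noise = rng.normal(0.0, 1.0, X.shape)
            if params.scar_texture_smoothing > 0 and scar_mask.any():
                # scar noise is spatially correlated and amplitude-reduced:
                # renormalize the smoothed field to unit sd, then scale down
                smooth = gaussian_filter(
                    noise, params.scar_texture_smoothing / params.voxel_spacing
                )
                smooth_sd = smooth.std()
                if smooth_sd > 0:
                    smooth = smooth / smooth_sd * scar_scale_z
                noise = np.where(scar_mask, smooth, noise)
            volumes[energy] = ImageVolume(base + sd * noise, spacing, origin)

    return PhantomCase(
        patient_id=f"P{patient_index:03d}",
        ct_endo=ct_endo,
        ct_epi=ct_epi,
        mri_endo=mri_endo,
        mri_epi=mri_epi,
        scar_mesh_mri_frame=scar_mri,
        scar_empty=scar_empty,
        rv_insertions_ct=rv_ct,
        rv_insertions_mri=rv_mri,
        true_misalignment=true_t,
        volumes=volumes,
        true_scar_label=label_volume,
        true_scar_fraction=true_fraction,
        drawn_scar_fraction=drawn_fraction,
    )


def generate_cohort(params: PhantomParams, include_volumes: bool = True) -> list[PhantomCase]:
    """All patients of the cohort; per-case seeds derive from (seed, index)."""
    return [generate_case(params, i, include_volumes) for i in range(params.n_patients)]


def measured_scar_fraction(params: PhantomParams, case: PhantomCase) -> float:
    """Scar fraction from counting labelled voxels against the analytic shell."""
    if case.true_scar_label is None:
        raise ValueError("case was generated without volumes")
    voxel_volume = float(np.prod(case.true_scar_label.spacing))
    return float(case.true_scar_label.voxels.sum()) * voxel_volume / shell_volume(params)


def write_cohort(params: PhantomParams, out_dir: str | Path) -> Path:
    """Write meshes (PLY), volumes and labels (NIfTI), landmarks and true
    transforms (JSON sidecars), and a cohort manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for case in generate_cohort(params):
        d = out / case.patient_id
        d.mkdir(exist_ok=True)
        case.ct_endo.save(d / "ct_endo.ply")
        case.ct_epi.save(d / "ct_epi.ply")
        case.mri_endo.save(d / "mri_endo.ply")
        case.mri_epi.save(d / "mri_epi.ply")
        if not case.scar_empty:
            case.scar_mesh_mri_frame.save(d / "scar_mri.ply")
        for energy, vol in case.volumes.items():
            vol.save(d / f"ct_{energy}.nii.gz")
        if case.true_scar_label is not None:
            case.true_scar_label.save(d / "true_scar_label.nii.gz")
        save_transform(case.true_misalignment, d / "true_misalignment.json")
        (d / "landmarks.json").write_text(
            json.dumps(
                {
                    "ct": {k: v.tolist() for k, v in case.rv_insertions_ct.items()},
                    "mri": {k: v.tolist() for k, v in case.rv_insertions_mri.items()},
                },
                indent=1,
            )
        )
        manifest_rows.append(
            {
                "patient_id": case.patient_id,
                "path": str(d),
                "true_scar_fraction": f"{case.true_scar_fraction:.6f}",
                "scar_empty": case.scar_empty,
            }
        )
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(manifest_rows[0]))
        writer.writeheader()
        writer.writerows(manifest_rows)
    return manifest
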