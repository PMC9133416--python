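"""End-to-end orchestration: register, slice, extract, screen, classify.

Glue between the stage modules, operating on phantom cases (or any objects
with the same mesh/volume fields).  Produces the tidy per-slice feature
table, the screening results and the per-segment classification reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import combine as combine_mod
from .combine import ImageVolume
from .mesh import RV_ANTERIOR, RV_INFERIOR, RigidTransform, apply_transform, register_lv
from .phantom import PhantomCase
from .radiomics import ALL_FEATURE_NAMES, RadiomicsConfig, extract_features
from .screen import FeatureScreenResult, screen_features, select_top_k
from .segments import SegmentRecord, aha16_assign, segment_features
from .slices import MYOCARDIUM, SCAR, SliceMask, rasterize_stack


@dataclass
class CaseResult:
    patient_id: str
    transform: RigidTransform
    masks: list[SliceMask]
    aha_maps: list[np.ndarray]


def register_case(case: PhantomCase) -> RigidTransform:
    """Three-step registration of the case's MRI endocardium onto CT."""
    moving = case.mri_endo
    moving.landmarks.setdefault(RV_ANTERIOR, case.rv_insertions_mri[RV_ANTERIOR])
    moving.landmarks.setdefault(RV_INFERIOR, case.rv_insertions_mri[RV_INFERIOR])
    fixed = case.ct_endo
    fixed.landmarks.setdefault(RV_ANTERIOR, case.rv_insertions_ct[RV_ANTERIOR])
    fixed.landmarks.setdefault(RV_INFERIOR, case.rv_insertions_ct[RV_INFERIOR])
    transform, _qc = register_lv(moving, fixed)
    return transform


def slice_case(case: PhantomCase, n_slices: int = 60, spacing: float = 1.0) -> CaseResult:
    """Register the scar mesh into the CT frame and rasterize the slice stack."""
    transform = register_case(case)
    scar_ct = (
        None
        if case.scar_empty
        else apply_transform(case.scar_mesh_mri_frame, transform)
    )
    masks = rasterize_stack(
        case.ct_endo,
        case.ct_epi,
        scar_ct,
        n_slices=n_slices,
        spacing=spacing,
        rv_anterior=case.rv_insertions_ct[RV_ANTERIOR],
    )
    aha = aha16_assign(
        masks,
        case.rv_insertions_ct[RV_ANTERIOR],
        case.rv_insertions_ct[RV_INFERIOR],
    )
    return CaseResult(case.patient_id, transform, masks, aha)


def case_volume(case: PhantomCase, energy: str) -> ImageVolume:
    """Resolve an energy spec: a stored energy label, or ``combined<P>``
    for a convex mix with the higher energy contributing P percent."""
    if energy in case.volumes:
        return case.volumes[energy]
    if energy.startswith("combined"):
        w = float(energy.removeprefix("combined")) / 100.0
        low, high = case.volumes["80kV"], case.volumes["100kV"]
        if not low.same_grid(high):
            reg = combine_mod.register_volumes(high, low)
            high = combine_mod.resample_to(high, low, reg.transform)
        return combine_mod.combine(low, high, w)
    raise KeyError(f"unknown energy {energy!r}")


def feature_table(
    cases: list[PhantomCase],
    case_results: list[CaseResult],
    energy: str = "100kV",
    config: RadiomicsConfig = RadiomicsConfig(),
) -> pd.DataFrame:
    """Tidy per-(patient, slice, region) table of all 93 features.

    Non-scar myocardium rows come from every valid slice; scar rows only
    from slices whose scar region passes the minimum pixel count.
    """
    rows = []
    for case, res in zip(cases, case_results):
        volume = case_volume(case, energy)
        for mask in res.masks:
            if not mask.valid:
                continue
            for region_label, region_name in ((MYOCARDIUM, "nonscar"), (SCAR, "scar")):
                fv = extract_features(volume, mask, region_label, config)
                if fv is None:
                    continue
                row = {
                    "patient_id": case.patient_id,
                    "energy": energy,
                    "slice_index": mask.slice_index,
                    "region": region_name,
                    "bin_width": fv.provenance["bin_width"],
                    "n_levels": fv.provenance["n_levels"],
                }
                row.update(fv.values)
                rows.append(row)
    return pd.DataFrame(rows)


def screen_table(
    table: pd.DataFrame, k: int = 5, seed: int = 0, n_bootstrap: int = 1000
) -> tuple[list[FeatureScreenResult], list[str]]:
    results = screen_features(
        table, ALL_FEATURE_NAMES, k=k, seed=seed, n_bootstrap=n_bootstrap
    )
    return results, select_top_k(results, 10)


def segment_records(
    cases: list[PhantomCase],
    case_results: list[CaseResult],
    top10: list[str],
    energy: str = "100kV",
    config: RadiomicsConfig = RadiomicsConfig(),
) -> list[SegmentRecord]:
    records: list[SegmentRecord] = []
    for case, res in zip(cases, case_results):
        volume = case_volume(case, energy)
        records.extend(
            segment_features(
                volume, res.masks, res.aha_maps, top10, case.patient_id, energy, config
            )
        )
    return records
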