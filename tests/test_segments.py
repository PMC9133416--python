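"""AHA 16-segment assignment, segment labels, scaling, classification."""

import numpy as np
import pytest

from scarpipe.mesh import RV_ANTERIOR, RV_INFERIOR
from scarpipe.phantom import PhantomParams, generate_case
from scarpipe.segments import (
    SegmentRecord,
    UnitLengthScaler,
    aha16_assign,
    permutation_feature_importance,
    records_frame,
    scale_unit_length,
    segment_scar_fraction,
    train_eval,
)
from scarpipe.slices import rasterize_stack


@pytest.fixture(scope="module")
def aligned_stack():
    params = PhantomParams(
        n_patients=1, seed=17, misalignment_max_rotation=0.0,
        misalignment_max_translation=0.0, vertex_noise_sd=0.0,
    )
    case = generate_case(params, 0, include_volumes=False)
    masks = rasterize_stack(
        case.ct_endo, case.ct_epi, case.scar_mesh_mri_frame,
        rv_anterior=case.rv_insertions_ct[RV_ANTERIOR],
    )
    return params, case, masks


class TestAHAAssignment:
    def test_sixteen_segments_nonempty(self, aligned_stack):
        _, case, masks = aligned_stack
        maps = aha16_assign(
            masks, case.rv_insertions_ct[RV_ANTERIOR], case.rv_insertions_ct[RV_INFERIOR]
        )
        present = set()
        for m in maps:
            present |= set(np.unique(m)) - {0}
        assert present == set(range(1, 17))

    def test_basal_sector_angles(self, aligned_stack):
        """Each basal/mid segment subtends close to 60 degrees."""
        _, case, masks = aligned_stack
        maps = aha16_assign(
            masks, case.rv_insertions_ct[RV_ANTERIOR], case.rv_insertions_ct[RV_INFERIOR]
        )
        m, amap = masks[5], maps[5]  # a basal slice
        rows, cols = np.nonzero(amap)
        u0, v0 = m.grid_origin_uv
        ang = np.degrees(
            np.arctan2(v0 + rows * m.pixel_spacing, u0 + cols * m.pixel_spacing)
        )
        for seg in range(1, 7):
            spans = ang[amap[rows, cols] == seg]
            # angular extent of each sector (mod wraparound) close to 60 deg
            width = np.ptp(np.sort(np.mod(spans - spans.min(), 360.0)))
            assert 50.0 <= width <= 70.0

    def test_sector_table_fixture(self, aligned_stack):
        """Spot-check pixel positions against the standard AHA layout:
        just septal-ward of the anterior insertion is anteroseptal (2 basal,
        8 mid), 180 degrees away is inferolateral/anterolateral territory,
        and the apical third uses the 4-sector numbering 13-16."""
        _, case, masks = aligned_stack
        maps = aha16_assign(
            masks, case.rv_insertions_ct[RV_ANTERIOR], case.rv_insertions_ct[RV_INFERIOR]
        )

        def seg_at_angle(slice_idx, offset_deg):
            """Segment id at `offset_deg` from the anterior insertion,
            measured septum-ward (toward the inferior insertion)."""
            m, amap = masks[slice_idx], maps[slice_idx]
            ant = case.rv_insertions_ct[RV_ANTERIOR] - m.plane_origin
            inf = case.rv_insertions_ct[RV_INFERIOR] - m.plane_origin
            phi_ant = np.arctan2(ant @ m.v_axis, ant @ m.u_axis)
            phi_inf = np.arctan2(inf @ m.v_axis, inf @ m.u_axis)
            sign = 1.0 if np.angle(np.exp(1j * (phi_inf - phi_ant))) >= 0 else -1.0
            phi = phi_ant + sign * np.radians(offset_deg)
            rows, cols = np.nonzero(amap)
            u0, v0 = m.grid_origin_uv
            uu, vv = u0 + cols * m.pixel_spacing, v0 + rows * m.pixel_spacing
            ang = np.arctan2(vv, uu)
            d = np.abs(np.angle(np.exp(1j * (ang - phi))))
            return amap[rows[np.argmin(d)], cols[np.argmin(d)]]

        assert seg_at_angle(5, 10) == 2    # basal anteroseptal
        assert seg_at_angle(5, -10) == 1   # basal anterior
        assert seg_at_angle(5, 150) == 4   # basal inferior
        assert seg_at_angle(30, 10) == 8   # mid anteroseptal
        assert seg_at_angle(30, 210) == 11  # mid inferolateral
        assert seg_at_angle(45, 60) == 14  # apical septal
        assert seg_at_angle(45, 330) == 13  # apical anterior

    def test_insertion_rotation_permutes_segments(self, aligned_stack):
        """Rotating the insertion landmark by 60 degrees shifts each
        basal/mid ring id cyclically."""
        _, case, masks = aligned_stack
        ant = case.rv_insertions_ct[RV_ANTERIOR]
        inf = case.rv_insertions_ct[RV_INFERIOR]
        rot = np.array([[np.cos(np.pi / 3), -np.sin(np.pi / 3), 0],
                        [np.sin(np.pi / 3), np.cos(np.pi / 3), 0],
                        [0, 0, 1]])
        maps0 = aha16_assign(masks, ant, inf)
        maps1 = aha16_assign(masks, rot @ ant, rot @ inf)
        m0, m1 = maps0[10], maps1[10]
        sel = (m0 > 0) & (m1 > 0) & (m0 <= 6)
        # new id = old id shifted by one sector within the basal ring
        expected = (m0[sel] - 1 - 1) % 6 + 1
        frac = np.mean(m1[sel] == expected)
        alt = (m0[sel] - 1 + 1) % 6 + 1
        frac_alt = np.mean(m1[sel] == alt)
        assert max(frac, frac_alt) > 0.95

    def test_missing_landmark_error(self, aligned_stack):
        from scarpipe.mesh import LandmarkError

        _, _, masks = aligned_stack
        with pytest.raises(LandmarkError):
            aha16_assign(masks, None)


class TestSegmentScarFraction:
    def test_zero_scar(self, aligned_stack):
        _, case, _ = aligned_stack
        masks = rasterize_stack(case.ct_endo, case.ct_epi, None)
        maps = aha16_assign(
            masks, case.rv_insertions_ct[RV_ANTERIOR], case.rv_insertions_ct[RV_INFERIOR]
        )
        fractions = segment_scar_fraction(masks, maps)
        assert all(v == 0.0 for v in fractions.values())

    def test_fractions_bounded_and_conserved(self, aligned_stack):
        _, case, masks = aligned_stack
        maps = aha16_assign(
            masks, case.rv_insertions_ct[RV_ANTERIOR], case.rv_insertions_ct[RV_INFERIOR]
        )
        fractions = segment_scar_fraction(masks, maps)
        assert all(0.0 <= v <= 1.0 for v in fractions.values())
        # every scar pixel assigned to a segment is counted exactly once
        total_scar = sum(
            np.count_nonzero((mask.pixel_grid == 2) & (amap > 0))
            for mask, amap in zip(masks, maps)
        )
        counted = sum(
            fractions[seg]
            * sum(
                np.count_nonzero((amap == seg) & (mask.pixel_grid > 0))
                for mask, amap in zip(masks, maps)
            )
            for seg in fractions
        )
        assert counted == pytest.approx(total_scar, rel=1e-9)

    def test_wedge_concentrates_in_expected_ring(self, aligned_stack):
        """The mid-cavity band scar lands in mid segments, not basal tips."""
        _, case, masks = aligned_stack
        maps = aha16_assign(
            masks, case.rv_insertions_ct[RV_ANTERIOR], case.rv_insertions_ct[RV_INFERIOR]
        )
        fractions = segment_scar_fraction(masks, maps)
        mid = max(fractions[s] for s in range(7, 13))
        basal_max = max(fractions[s] for s in range(1, 7))
        assert mid > 0.5
        assert mid >= basal_max


class TestLabels:
    def test_threshold_monotonicity(self):
        rec = SegmentRecord("P0", "100kV", 3, 0.22, {})
        assert rec.label(0.10) and rec.label(0.20) and not rec.label(0.30)
        # positive at a high threshold implies positive at lower ones
        for frac in (0.05, 0.15, 0.25, 0.35):
            r = SegmentRecord("P0", "100kV", 1, frac, {})
            labels = [r.label(t) for t in (0.10, 0.20, 0.30)]
            assert labels == sorted(labels, reverse=True)


class TestUnitLengthScaler:
    def test_column_arithmetic(self):
        X = np.array([[3.0], [4.0]])
        scaled, scaler = scale_unit_length(X)
        np.testing.assert_allclose(scaled.ravel(), [0.6, 0.8])
        assert np.linalg.norm(scaled[:, 0]) == pytest.approx(1.0)

    def test_test_rows_use_train_norms(self):
        train = np.array([[3.0], [4.0]])
        test = np.array([[10.0]])
        scaler = UnitLengthScaler().fit(train)
        np.testing.assert_allclose(scaler.transform(test), [[2.0]])

    def test_zero_norm_column_flagged(self):
        X = np.array([[0.0, 1.0], [0.0, 2.0]])
        scaled, scaler = scale_unit_length(X)
        assert scaler.constant_columns_[0]
        assert np.all(scaled[:, 0] == 0.0)


def synthetic_records(rng, n_patients=12, margin=3.0):
    """Segment records with a two-feature signal of configurable margin."""
    records = []
    for p in range(n_patients):
        for seg in range(1, 17):
            positive = rng.random() < 0.3
            frac = rng.uniform(0.25, 0.8) if positive else rng.uniform(0.0, 0.15)
            f1 = rng.normal(margin if positive else 0.0, 1.0)
            f2 = rng.normal(-margin if positive else 0.0, 1.0)
            records.append(
                SegmentRecord(
                    f"P{p}", "100kV", seg, frac,
                    {"f1": f1, "f2": f2, "noise": rng.normal()},
                )
            )
    return records


class TestTrainEval:
    def test_separable_records_all_classifiers(self, rng):
        records = synthetic_records(rng, margin=50.0)
        for kind in ("svm", "logistic", "random_forest"):
            rep = train_eval(
                records, kind, 0.2, seed=0, n_bootstrap=100, importance_repeats=0
            )
            assert rep.auc == 1.0
            assert rep.sensitivity == 1.0
            assert rep.specificity == 1.0

    def test_label_permutation_null(self, rng):
        records = synthetic_records(rng, margin=0.0)
        rep = train_eval(
            records, "logistic", 0.2, seed=0, n_bootstrap=300, importance_repeats=0
        )
        assert rep.auc_ci_low <= 0.5 <= rep.auc_ci_high

    def test_margin_shrink_degrades_auc(self, rng):
        aucs = []
        for margin in (4.0, 1.0, 0.25):
            records = synthetic_records(np.random.default_rng(5), margin=margin)
            rep = train_eval(
                records, "svm", 0.2, seed=0, n_bootstrap=50, importance_repeats=0
            )
            aucs.append(rep.auc)
        assert aucs[0] > aucs[1] > aucs[2]

    def test_patient_leakage_guard(self, rng):
        """No patient contributes rows to both train and test of a fold."""
        from scarpipe.screen import patient_stratified_folds

        records = synthetic_records(rng)
        df = records_frame(records)
        pids = df["patient_id"].to_numpy()
        folds = patient_stratified_folds(pids, None, 5, np.random.default_rng(0))
        all_test = np.concatenate(folds)
        assert len(all_test) == len(pids)
        for f in folds:
            test_pids = set(pids[f])
            train_pids = set(pids[np.setdiff1d(np.arange(len(pids)), f)])
            assert test_pids.isdisjoint(train_pids)

    def test_single_class_raises(self, rng):
        records = synthetic_records(rng)
        for r in records:
            r.scar_volume_fraction = 0.0
        with pytest.raises(ValueError):
            train_eval(records, "svm", 0.2)


class TestPermutationImportance:
    def test_informative_vs_null_feature(self, rng):
        from sklearn.linear_model import LogisticRegression

        n = 400
        X = rng.normal(size=(n, 2))
        y = (X[:, 0] > 0).astype(int)
        model = LogisticRegression().fit(X, y)
        imp = permutation_feature_importance(
            model, X, y, ["signal", "noise"], n_repeats=20, seed=0
        )
        assert imp["signal"] > 0.3  # ~ baseline balanced accuracy - 0.5
        assert abs(imp["noise"]) < 0.05

    def test_row_order_invariance_in_expectation(self, rng):
        from sklearn.linear_model import LogisticRegression

        n = 300
        X = rng.normal(size=(n, 2))
        y = (X[:, 0] + 0.5 * rng.normal(size=n) > 0).astype(int)
        model = LogisticRegression().fit(X, y)
        imp1 = permutation_feature_importance(model, X, y, ["a", "b"], 30, seed=1)
        perm = rng.permutation(n)
        imp2 = permutation_feature_importance(model, X[perm], y[perm], ["a", "b"], 30, seed=1)
        assert imp1["a"] == pytest.approx(imp2["a"], abs=0.05)
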