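"""AHA 16-segment analysis and per-segment scar classification.

The LV is partitioned by the standard American Heart Association model:
basal/mid/apical thirds along the long axis (here by slice index), the basal
and mid rings into six 60-degree sectors and the apical ring into four
90-degree sectors, numbered from the anterior RV insertion point.  The
apex-cap segment of the 17-segment variant is excluded.

Each segment is labelled scar/non-scar by whether its scar volume fraction
reaches a threshold (10/20/30%), described by the screened top-10 radiomic
features recomputed on the whole segment region, and classified with SVM,
logistic-regression and random-forest models under patient-wise 5-fold
cross-validation with inner grid search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC

from .mesh import LandmarkError
from .radiomics import RadiomicsConfig, compute_features
from .screen import _roc_auc, patient_stratified_folds
from .slices import SCAR, SliceMask

SCAR_THRESHOLDS = (0.10, 0.20, 0.30)

#: hyperparameter grids (small, seeded, desk-scale)
DEFAULT_GRIDS: dict[str, dict] = {
    "svm": {"C": [0.1, 1.0, 10.0], "kernel": ["linear", "rbf"]},
    "logistic": {"C": [0.1, 1.0, 10.0]},
    "random_forest": {"n_estimators": [100, 300], "max_depth": [None, 8]},
}


@dataclass
class SegmentRecord:
    patient_id: str
    energy: str
    aha_id: int
    scar_volume_fraction: float
    features: dict[str, float]
    valid: bool = True

    def label(self, threshold: float) -> bool:
        return self.scar_volume_fraction >= threshold


@dataclass
class ClassifierReport:
    classifier_kind: str
    threshold: float
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    sensitivity: float
    specificity: float
    best_params: dict = field(default_factory=dict)
    permutation_importance: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# AHA assignment
# ---------------------------------------------------------------------------


def _ring_third(slice_index: int, n_slices: int) -> int:
    """0 basal, 1 mid, 2 apical, by slice index (base-to-apex ordering)."""
    return min(2, 3 * slice_index // n_slices)


def aha16_assign(
    mask_stack: list[SliceMask],
    rv_anterior_insertion: np.ndarray,
    rv_inferior_insertion: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Per-slice maps of AHA segment ids (0 = unassigned/apex cap).

    Sector angles are measured from the anterior RV insertion, increasing
    toward the septum.  If the inferior insertion is given it fixes that
    direction; otherwise the in-plane right-handed direction is used.
    Apex-cap slices (no endocardial cavity) are left unassigned.
    """
    if rv_anterior_insertion is None:
        raise LandmarkError("anterior RV insertion landmark required")
    n = len(mask_stack)
    maps = []
    for mask in mask_stack:
        out = np.zeros(mask.pixel_grid.shape, dtype=np.int8)
        if mask.myocardium_pixels + mask.scar_pixels == 0 or not mask.has_cavity:
            maps.append(out)
            continue
        third = _ring_third(mask.slice_index, n)
        rel = rv_anterior_insertion - mask.plane_origin
        ant_uv = np.array([rel @ mask.u_axis, rel @ mask.v_axis])
        if np.linalg.norm(ant_uv) < 1e-9:
            raise LandmarkError("anterior RV insertion projects onto the long axis")
        phi_ant = np.arctan2(ant_uv[1], ant_uv[0])
        sign = 1.0
        if rv_inferior_insertion is not None:
            rel_i = rv_inferior_insertion - mask.plane_origin
            inf_uv = np.array([rel_i @ mask.u_axis, rel_i @ mask.v_axis])
            delta = np.angle(
                np.exp(1j * (np.arctan2(inf_uv[1], inf_uv[0]) - phi_ant))
            )
            sign = 1.0 if delta >= 0 else -1.0

        myo = mask.pixel_grid > 0
        rows, cols = np.nonzero(myo)
        u0, v0 = mask.grid_origin_uv
        uu = u0 + cols * mask.pixel_spacing
        vv = v0 + rows * mask.pixel_spacing
        theta = np.mod(sign * (np.arctan2(vv, uu) - phi_ant), 2 * np.pi)
        deg = np.degrees(theta)
        if third < 2:  # basal or mid: 6 sectors of 60 deg from the insertion
            slot = np.clip(np.floor(deg / 60.0).astype(int), 0, 5)
            seg = np.array([2, 3, 4, 5, 6, 1])[slot] + 6 * third
        else:  # apical: 4 sectors of 90 deg, centres on the wall centres
            seg = np.full(deg.shape, 13, dtype=int)  # anterior
            seg[(deg >= 15) & (deg < 105)] = 14  # septal
            seg[(deg >= 105) & (deg < 195)] = 15  # inferior
            seg[(deg >= 195) & (deg < 285)] = 16  # lateral
        out[rows, cols] = seg
        maps.append(out)
    return maps


def segment_scar_fraction(
    masks: list[SliceMask], aha_maps: list[np.ndarray]
) -> dict[int, float]:
    """Scar volume fraction per segment (scar pixels over myocardium pixels;
    the constant pixel volume cancels).  Empty segments are dropped."""
    scar_px = np.zeros(17)
    myo_px = np.zeros(17)
    for mask, amap in zip(masks, aha_maps):
        for seg in range(1, 17):
            sel = amap == seg
            if not sel.any():
                continue
            labels = mask.pixel_grid[sel]
            myo_px[seg] += np.count_nonzero(labels > 0)
            scar_px[seg] += np.count_nonzero(labels == SCAR)
    fractions = {}
    for seg in range(1, 17):
        if myo_px[seg] == 0:
            warnings.warn(f"AHA segment {seg} is empty; dropped")
            continue
        fractions[seg] = float(scar_px[seg] / myo_px[seg])
    return fractions


def segment_features(
    volume,
    masks: list[SliceMask],
    aha_maps: list[np.ndarray],
    top10: list[str],
    patient_id: str,
    energy: str,
    config: RadiomicsConfig = RadiomicsConfig(),
) -> list[SegmentRecord]:
    """Top-10 features recomputed on each segment's full myocardial region
    (scar and non-scar pixels pooled across the segment's slices)."""
    fractions = segment_scar_fraction(masks, aha_maps)
    records = []
    for seg, frac in fractions.items():
        imgs, regs = [], []
        for mask, amap in zip(masks, aha_maps):
            sel = (amap == seg) & (mask.pixel_grid > 0)
            if not sel.any():
                continue
            rows, cols = np.nonzero(sel)
            img = np.zeros(sel.shape)
            img[rows, cols] = volume.sample_nearest(mask.pixel_world(rows, cols))
            imgs.append(img)
            regs.append(sel)
        n_px = int(sum(r.sum() for r in regs))
        if n_px < config.min_region_pixels:
            records.append(SegmentRecord(patient_id, energy, seg, frac, {}, valid=False))
            continue
        fv = compute_features(imgs, regs, config)
        feats = {name: fv.values[name] for name in top10}
        records.append(SegmentRecord(patient_id, energy, seg, frac, feats))
    return records


def records_frame(records: list[SegmentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        if not r.valid:
            continue
        row = {
            "patient_id": r.patient_id,
            "energy": r.energy,
            "aha_id": r.aha_id,
            "scar_volume_fraction": r.scar_volume_fraction,
        }
        row.update(r.features)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scaling and classification
# ---------------------------------------------------------------------------


class UnitLengthScaler:
    """Per-feature unit-Euclidean-norm scaling, fitted on training rows only.

    Zero-norm (constant-zero) columns are flagged and scaled to zeros.
    """

    def __init__(self) -> None:
        self.norms_: np.ndarray | None = None
        self.constant_columns_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "UnitLengthScaler":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 1:
            raise ValueError("need at least one row")
        self.norms_ = np.linalg.norm(X, axis=0)
        self.constant_columns_ = self.norms_ == 0
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        assert self.norms_ is not None
        X = np.asarray(X, dtype=float)
        safe = np.where(self.constant_columns_, 1.0, self.norms_)
        out = X / safe
        out[:, self.constant_columns_] = 0.0
        return out

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def scale_unit_length(feature_matrix: np.ndarray) -> tuple[np.ndarray, UnitLengthScaler]:
    scaler = UnitLengthScaler()
    return scaler.fit_transform(feature_matrix), scaler


def _make_classifier(kind: str, seed: int):
    if kind == "svm":
        return SVC(random_state=seed)
    if kind == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed)
    raise ValueError(f"unknown classifier kind {kind!r}")


def _scores_and_preds(model, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decision scores plus hard predictions at the model's native threshold."""
    if hasattr(model, "decision_function"):
        return model.decision_function(X), model.predict(X)
    return model.predict_proba(X)[:, 1], model.predict(X)


def train_eval(
    records: list[SegmentRecord] | pd.DataFrame,
    classifier_kind: str,
    threshold: float,
    feature_names: list[str] | None = None,
    grid: dict | None = None,
    k: int = 5,
    seed: int = 0,
    n_bootstrap: int = 1000,
    importance_repeats: int = 10,
) -> ClassifierReport:
    """Patient-wise 5-fold cross-validated evaluation of one classifier at
    one scar threshold, with pooled out-of-fold ROC, bootstrap 95% CI,
    native-threshold sensitivity/specificity, and permutation feature
    importance (mean balanced-accuracy drop, averaged over folds)."""
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    if feature_names is None:
        feature_names = [
            c
            for c in df.columns
            if c not in ("patient_id", "energy", "aha_id", "scar_volume_fraction")
        ]
    X = df[feature_names].to_numpy(dtype=float)
    if np.isnan(X).any():
        X = np.where(np.isnan(X), np.nanmedian(X, axis=0), X)
    y = (df["scar_volume_fraction"].to_numpy() >= threshold).astype(int)
    pids = df["patient_id"].to_numpy()
    if len(set(y)) < 2:
        raise ValueError("both classes must be present at this threshold")
    grid = grid if grid is not None else DEFAULT_GRIDS[classifier_kind]

    rng = np.random.default_rng(seed)
    prev = pd.DataFrame({"p": pids, "y": y}).groupby("p")["y"].mean()
    try:
        strata = pd.qcut(prev, q=2, labels=False, duplicates="drop").fillna(0).astype(int).to_dict()
    except ValueError:
        strata = {p: 0 for p in prev.index}
    folds = patient_stratified_folds(pids, strata, k, rng)

    scores = np.full(len(y), np.nan)
    preds = np.full(len(y), -1)
    importances: dict[str, list[float]] = {f: [] for f in feature_names}
    best_params: dict = {}
    pending: list[np.ndarray] = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        if pending:
            train_idx = np.setdiff1d(train_idx, np.concatenate(pending))
            test_idx = np.concatenate([test_idx] + pending)
            pending = []
        if len(set(y[train_idx])) < 2 or len(set(y[test_idx])) < 1:
            warnings.warn(f"fold {f} lacks a class; merged with the next fold")
            pending.append(test_idx)
            continue
        scaler = UnitLengthScaler().fit(X[train_idx])
        Xtr, Xte = scaler.transform(X[train_idx]), scaler.transform(X[test_idx])
        search = GridSearchCV(
            _make_classifier(classifier_kind, seed),
            grid,
            cv=min(5, np.bincount(y[train_idx]).min(), len(train_idx)),
            n_jobs=1,
        )
        search.fit(Xtr, y[train_idx])
        model = search.best_estimator_
        best_params = search.best_params_
        s, p = _scores_and_preds(model, Xte)
        scores[test_idx] = s
        preds[test_idx] = p
        if len(set(y[test_idx])) == 2 and importance_repeats > 0:
            imp = _sk_permutation_importance(
                model,
                Xte,
                y[test_idx],
                scoring="balanced_accuracy",
                n_repeats=importance_repeats,
                random_state=seed,
            )
            for name, mean_drop in zip(feature_names, imp.importances_mean):
                importances[name].append(float(mean_drop))

    ok = ~np.isnan(scores)
    auc = _roc_auc(scores[ok], y[ok])
    s_ok, y_ok, p_ok = scores[ok], y[ok], preds[ok]
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.integers(0, len(s_ok), len(s_ok))
        boots[b] = _roc_auc(s_ok[idx], y_ok[idx])
    boots = boots[~np.isnan(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    tp = np.sum((p_ok == 1) & (y_ok == 1))
    fn = np.sum((p_ok == 0) & (y_ok == 1))
    tn = np.sum((p_ok == 0) & (y_ok == 0))
    fp = np.sum((p_ok == 1) & (y_ok == 0))
    return ClassifierReport(
        classifier_kind=classifier_kind,
        threshold=threshold,
        auc=float(auc),
        auc_ci_low=float(lo),
        auc_ci_high=float(hi),
        sensitivity=float(tp / (tp + fn)) if tp + fn else float("nan"),
        specificity=float(tn / (tn + fp)) if tn + fp else float("nan"),
        best_params=best_params,
        permutation_importance={
            f: float(np.mean(v)) if v else float("nan") for f, v in importances.items()
        },
    )


def permutation_feature_importance(
    model,
    X_test: np.ndarray,
    y_test: np.ndarray,
    feature_names: list[str],
    n_repeats: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Mean balanced-accuracy drop when each feature column is shuffled."""
    imp = _sk_permutation_importance(
        model, X_test, y_test, scoring="balanced_accuracy",
        n_repeats=n_repeats, random_state=seed,
    )
    return {n: float(m) for n, m in zip(feature_names, imp.importances_mean)}


def report_grid(
    records: list[SegmentRecord] | pd.DataFrame,
    classifier_kinds: tuple[str, ...] = ("svm", "logistic", "random_forest"),
    thresholds: tuple[float, ...] = SCAR_THRESHOLDS,
    **kwargs,
) -> pd.DataFrame:
    """Classifier x threshold grid of AUC/sensitivity/specificity."""
    rows = []
    for kind in classifier_kinds:
        for thr in thresholds:
            rep = train_eval(records, kind, thr, **kwargs)
            rows.append(
                {
                    "classifier": kind,
                    "threshold": thr,
                    "auc": rep.auc,
                    "auc_ci_low": rep.auc_ci_low,
                    "auc_ci_high": rep.auc_ci_high,
                    "sensitivity": rep.sensitivity,
                    "specificity": rep.specificity,
                }
            )
    return pd.DataFrame(rows)
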