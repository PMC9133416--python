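"""Per-feature discrimination screening of scar vs. non-scar regions.

Each of the 93 features is screened two ways on the per-slice region table:

* a two-sided pooled-variance Student's t-test between scar-region and
  non-scar-region values, and
* an ROC AUC from out-of-fold scores of a univariate linear regression under
  patient-wise stratified 5-fold cross-validation, with a 95% percentile
  bootstrap confidence interval over 1,000 resamples of the pooled
  (score, label) pairs.

The 10 highest-AUC features feed the downstream segment classifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05
N_BOOTSTRAP = 1000


@dataclass
class FeatureScreenResult:
    feature_name: str
    t_statistic: float
    p_value: float
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    significant: bool
    degenerate: bool = False
    #: log10 of the t-test p-value computed in log space, so that ranking
    #: ties among extremely discriminative features are not decided by
    #: floating-point underflow of ``p_value``
    log10_p: float = 0.0


def t_test_two_sided(
    scar_values: np.ndarray, nonscar_values: np.ndarray
) -> tuple[float, float]:
    """Classical equal-variance two-sample t-test (two-sided p, df n1+n2-2).

    Raises ValueError on degenerate input (tiny groups or zero pooled
    variance), which callers flag rather than propagate.
    """
    a = np.asarray(scar_values, dtype=float)
    b = np.asarray(nonscar_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled_var = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    if pooled_var <= 0:
        raise ValueError("zero pooled variance")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def _roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with tie correction."""
    pos = labels.astype(bool)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def patient_stratified_folds(
    patient_ids: np.ndarray, patient_strata: dict | None, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Assign whole patients to k folds, balanced on a patient-level stratum
    (here: quantile of scar-slice fraction).  Returns row-index arrays."""
    patients = np.array(sorted(set(patient_ids)))
    if len(patients) < k:
        raise ValueError(f"need at least k={k} patients, got {len(patients)}")
    if patient_strata is None:
        patient_strata = {p: 0 for p in patients}
    order = []
    for stratum in sorted(set(patient_strata.values())):
        members = [p for p in patients if patient_strata[p] == stratum]
        order.extend(rng.permutation(members))
    fold_of_patient = {p: i % k for i, p in enumerate(order)}
    return [
        np.flatnonzero([fold_of_patient[p] == f for p in patient_ids])
        for f in range(k)
    ]


def _patient_strata(
    patient_ids: np.ndarray, labels: np.ndarray, n_quantiles: int = 2
) -> dict:
    """Stratify patients by quantile of their scar-row prevalence."""
    df = pd.DataFrame({"pid": patient_ids, "y": labels})
    prev = df.groupby("pid")["y"].mean()
    try:
        bins = pd.qcut(prev, q=n_quantiles, labels=False, duplicates="drop")
    except ValueError:
        bins = pd.Series(0, index=prev.index)
    return bins.fillna(0).astype(int).to_dict()


def per_feature_auc(
    values: np.ndarray,
    labels: np.ndarray,
    patient_ids: np.ndarray,
    k: int = 5,
    seed: int = 0,
    n_bootstrap: int = N_BOOTSTRAP,
) -> tuple[float, tuple[float, float]]:
    """Cross-validated univariate AUC with a percentile bootstrap 95% CI.

    A univariate linear regression of the binary label on the feature is fit
    on each set of training folds; because a monotone score only enters the
    ROC through its ranking, the pooled out-of-fold score is the feature
    itself under the orientation the training regressions vote for (majority
    slope sign, applied consistently so that scores pooled across folds
    remain comparable).  Folds are split by patient (no patient straddles a
    fold) and stratified on patient-level scar prevalence.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    patient_ids = np.asarray(patient_ids)
    rng = np.random.default_rng(seed)
    strata = _patient_strata(patient_ids, labels)
    folds = patient_stratified_folds(patient_ids, strata, k, rng)

    votes: list[float] = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(values)), test_idx)
        if len(set(labels[train_idx])) < 2 or len(test_idx) == 0:
            warnings.warn(f"fold {f} lacks a class in training; no orientation vote")
            continue
        x, y = values[train_idx], labels[train_idx]
        vx = x.var()
        slope = 0.0 if vx == 0 else np.cov(x, y, bias=True)[0, 1] / vx
        if slope != 0.0:
            votes.append(np.sign(slope))
    orientation = 1.0 if sum(votes) >= 0 else -1.0
    scores = orientation * values
    auc = _roc_auc(scores, labels)

    s, y = scores, labels
    n = len(s)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        boots[b] = _roc_auc(s[idx], y[idx])
    boots = boots[~np.isnan(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return auc, (float(lo), float(hi))


def screen_features(
    table: pd.DataFrame,
    feature_names: list[str],
    k: int = 5,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    adjust_fdr: bool = False,
    n_bootstrap: int = N_BOOTSTRAP,
) -> list[FeatureScreenResult]:
    """Screen every feature of a tidy per-(patient, slice, region) table.

    ``table`` needs columns ``patient_id``, ``region`` ('scar'/'nonscar')
    and one column per feature.  NaN feature values (degenerate regions) are
    imputed with the cohort median first.  ``adjust_fdr`` optionally applies
    Benjamini-Hochberg to the t-test p-values (off by default).
    """
    labels = (table["region"] == "scar").to_numpy()
    pids = table["patient_id"].to_numpy()
    results = []
    for name in feature_names:
        col = table[name].to_numpy(dtype=float)
        if np.isnan(col).any():
            col = np.where(np.isnan(col), np.nanmedian(col), col)
        degenerate = False
        try:
            t, p = t_test_two_sided(col[labels], col[~labels])
            df = len(col) - 2
            log10p = (np.log(2.0) + stats.t.logsf(abs(t), df)) / np.log(10.0)
        except ValueError:
            t, p, log10p, degenerate = 0.0, 1.0, 0.0, True
        auc, (lo, hi) = per_feature_auc(col, labels, pids, k=k, seed=seed,
                                        n_bootstrap=n_bootstrap)
        results.append(
            FeatureScreenResult(name, t, p, auc, lo, hi, p < alpha, degenerate, log10p)
        )
    if adjust_fdr:
        ps = np.array([r.p_value for r in results])
        m = len(ps)
        order = np.argsort(ps)
        adj = np.minimum.accumulate((ps[order] * m / (np.arange(m) + 1))[::-1])[::-1]
        for rank, idx in enumerate(order):
            results[idx].significant = bool(min(adj[rank], 1.0) < alpha)
    return results


def select_top_k(results: list[FeatureScreenResult], k: int = 10) -> list[str]:
    """k feature names by descending AUC; ties broken by smaller p-value,
    then lexicographically."""
    if len(results) < k:
        raise ValueError(f"need at least {k} screened features")
    ranked = sorted(
        results, key=lambda r: (-r.auc, r.log10_p, r.p_value, r.feature_name)
    )
    return [r.feature_name for r in ranked[:k]]


def results_frame(results: list[FeatureScreenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [r.feature_name for r in results],
            "t_statistic": [r.t_statistic for r in results],
            "p_value": [r.p_value for r in results],
            "auc": [r.auc for r in results],
            "auc_ci_low": [r.auc_ci_low for r in results],
            "auc_ci_high": [r.auc_ci_high for r in results],
            "significant": [r.significant for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )
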