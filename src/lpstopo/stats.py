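"""Group-level statistics: Mann-Whitney, AUC/AUPR, clinical correlations, FDR.

Scientific conventions used throughout:

* Group comparisons are two-sided Mann-Whitney U tests at alpha = 0.05; no
  multiple-testing correction is applied across whole-brain measures (no
  feature selection happens there), whereas nodal contrasts are
  Benjamini-Hochberg corrected across the 84 areas (a feature selection).
* AUC is reported for the "higher-in-group" orientation per measure: the
  positive class is the group with the larger mean, and the orientation is
  recorded on the result, so AUC >= 0.5 by construction and comparable
  across measures.
* AUPR uses the step-wise (non-interpolated) estimator; its chance level is
  the positive-class prevalence, not 0.5.
* Undefined measure values (NaN) are excluded pairwise with counts recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.multitest import multipletests

from .topology import NodalMetrics, TopologySummary

__all__ = [
    "mann_whitney",
    "auc_separation",
    "aupr_separation",
    "clinical_correlation",
    "bh_correct",
    "nodal_contrast",
    "whole_brain_comparison",
    "GroupComparison",
]

EXACT_MW_LIMIT = 400  # use the exact U distribution when n_x * n_y <= this


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (U for x) and p-value.

    Exact null distribution when the sample-size product is small and there
    are no ties; normal approximation with tie correction otherwise.  Two
    identical constant samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return float(len(x) * len(y) / 2.0), 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) * len(y) <= EXACT_MW_LIMIT and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _binary_labels(groups, positive_group: str) -> np.ndarray:
    labels = np.asarray([1 if g == positive_group else 0 for g in groups])
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("both groups must be non-empty")
    return labels


def auc_separation(scores, groups, positive_group: str) -> float:
    """Area under the ROC curve; equals U/(n1*n2) with ties counted half."""
    labels = _binary_labels(groups, positive_group)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def aupr_separation(scores, groups, positive_group: str) -> float:
    """Area under the precision-recall curve (step-wise estimator)."""
    labels = _binary_labels(groups, positive_group)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class CorrelationResult:
    pearson_rho: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n_used: int
    n_excluded: int


def clinical_correlation(values, crs_r) -> CorrelationResult:
    """Pearson and Spearman correlations of a measure against CRS-R.

    Pairs with undefined (NaN) measure values are excluded and counted; a
    zero-variance input yields NaN coefficients (undefined-flag).
    """
    values = np.asarray(values, dtype=float)
    crs_r = np.asarray(crs_r, dtype=float)
    if values.shape != crs_r.shape:
        raise ValueError("values and CRS-R must be paired")
    ok = np.isfinite(values) & np.isfinite(crs_r)
    n_excluded = int(np.count_nonzero(~ok))
    v, c = values[ok], crs_r[ok]
    if len(v) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(v) == 0 or np.ptp(c) == 0:
        return CorrelationResult(
            float("nan"), float("nan"), float("nan"), float("nan"),
            n_used=len(v), n_excluded=n_excluded,
        )
    pr = sps.pearsonr(v, c)
    sr = sps.spearmanr(v, c)
    return CorrelationResult(
        pearson_rho=float(pr.statistic), pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic), spearman_p=float(sr.pvalue),
        n_used=len(v), n_excluded=n_excluded,
    )


def bh_correct(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, boolean significant set)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


def nodal_contrast(
    group_a: list[NodalMetrics],
    group_b: list[NodalMetrics],
    metric: str = "degree",
    n_rois: int = 84,
    labels: list[str] | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-node group contrast: percent change (A-B)/B, MW p, BH-adjusted p.

    Nodes pruned from a subject's graph contribute NaN for that subject and
    are excluded pairwise.  Percent change is NaN where the B-group mean is 0.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 subjects per group")

    def stack(ms: list[NodalMetrics]) -> np.ndarray:
        out = np.full((len(ms), n_rois), np.nan)
        for s, m in enumerate(ms):
            out[s, np.asarray(m.roi_indices)] = getattr(m, metric)
        return out

    a = stack(group_a)
    b = stack(group_b)
    rows = []
    for node in range(n_rois):
        av = a[:, node][np.isfinite(a[:, node])]
        bv = b[:, node][np.isfinite(b[:, node])]
        if len(av) < 2 or len(bv) < 2:
            rows.append({"node": node, "pct_change": np.nan, "mw_p": np.nan})
            continue
        mean_b = bv.mean()
        pct = (av.mean() - mean_b) / mean_b * 100.0 if mean_b != 0 else np.nan
        _, p = mann_whitney(av, bv)
        rows.append({"node": node, "pct_change": pct, "mw_p": p})
    df = pd.DataFrame(rows)
    ok = df["mw_p"].notna()
    adjusted = np.full(len(df), np.nan)
    significant = np.zeros(len(df), dtype=bool)
    if ok.any():
        adj, rej = bh_correct(df.loc[ok, "mw_p"].to_numpy(), q=q)
        adjusted[ok.to_numpy()] = adj
        significant[ok.to_numpy()] = rej
    df["bh_p"] = adjusted
    df["significant"] = significant
    if labels is not None:
        df.insert(1, "label", [labels[i] for i in df["node"]])
    return df


@dataclass
class GroupComparison:
    """One whole-brain measure compared across groups, Table-2 style."""

    measure: str
    mean_a: float
    se_a: float
    mean_b: float
    se_b: float
    group_a: str
    group_b: str
    mw_u: float
    mw_p: float
    auc: float
    aupr: float
    positive_group: str  # orientation actually used for AUC/AUPR
    pearson_rho: float = float("nan")
    pearson_p: float = float("nan")
    spearman_rho: float = float("nan")
    spearman_p: float = float("nan")
    n_a: int = 0
    n_b: int = 0
    n_excluded: int = 0


_MEASURE_FIELDS = (
    "L", "E_glob", "E_loc", "ACC", "ANBC", "LCP_corr",
    "sw_omega", "sw_omega_eff", "q_modularity", "sigma_c",
)


def whole_brain_comparison(
    summaries: list[TopologySummary],
    cohort: pd.DataFrame,
    group_a: str = "UWS",
    group_b: str = "MCS",
    measures: tuple[str, ...] = _MEASURE_FIELDS,
) -> pd.DataFrame:
    """Assemble per-measure group comparisons with clinical correlations.

    One row per measure: group means +/- standard error, Mann-Whitney U/p,
    AUC and AUPR in the higher-mean orientation, and Pearson/Spearman
    correlations against CRS-R across all subjects.  Measures that are
    undefined (NaN) for some subjects are compared pairwise on the defined
    subjects, with the exclusion count reported.
    """
    by_id = {s.subject_id: s for s in summaries}
    missing = set(cohort["subject_id"]) - set(by_id)
    if missing:
        raise ValueError(f"missing topology summaries for subjects: {sorted(missing)}")
    rows = []
    for measure in measures:
        vals = np.array([getattr(by_id[s], measure) for s in cohort["subject_id"]])
        groups = cohort["group"].to_numpy()
        crs = cohort["crs_r"].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        a = vals[ok & (groups == group_a)]
        b = vals[ok & (groups == group_b)]
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"fewer than 2 defined values per group for {measure}")
        u, p = mann_whitney(a, b)
        positive = group_a if a.mean() >= b.mean() else group_b
        auc = auc_separation(vals[ok], groups[ok], positive)
        aupr = aupr_separation(vals[ok], groups[ok], positive)
        corr = clinical_correlation(vals, crs)
        rows.append(
            GroupComparison(
                measure=measure,
                mean_a=float(a.mean()),
                se_a=float(a.std(ddof=1) / np.sqrt(len(a))),
                mean_b=float(b.mean()),
                se_b=float(b.std(ddof=1) / np.sqrt(len(b))),
                group_a=group_a, group_b=group_b,
                mw_u=u, mw_p=p, auc=auc, aupr=aupr, positive_group=positive,
                pearson_rho=corr.pearson_rho, pearson_p=corr.pearson_p,
                spearman_rho=corr.spearman_rho, spearman_p=corr.spearman_p,
                n_a=len(a), n_b=len(b), n_excluded=int(np.count_nonzero(~ok)),
            )
        )
    return pd.DataFrame([vars(r) for r in rows])
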