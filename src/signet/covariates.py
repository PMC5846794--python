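"""Covariate screens on the biomarker panel: per-protein age regression by
group, treatment association among affected subjects, age-distribution
comparison, and the Benjamini-Hochberg correction used throughout.

All association tests operate on log2-scaled abundances and adjust p-values
within the submitted protein family only (by default the biomarker panel, not
the whole assay), mirroring how panel-level covariate screens are reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionDataset


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _restrict(dataset: ExpressionDataset, proteins) -> tuple[list[str], np.ndarray]:
    if proteins is None:
        return list(dataset.protein_ids), dataset.values
    col = {p: i for i, p in enumerate(dataset.protein_ids)}
    missing = [p for p in proteins if p not in col]
    if missing:
        raise ValueError(f"proteins absent from dataset: {missing[:5]}")
    idx = [col[p] for p in proteins]
    return list(proteins), dataset.values[:, idx]


def _ols_slope_test(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized OLS of each column of y on x: slope and two-sided slope p.

    Closed form: slope = Sxy/Sxx, se^2 = RSS/(n-2)/Sxx, t = slope/se with
    n-2 degrees of freedom.
    """
    n = len(x)
    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    yc = y - y.mean(axis=0)
    slope = xc @ yc / sxx
    rss = np.sum(yc**2, axis=0) - slope**2 * sxx
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / np.sqrt(sigma2 / sxx)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(p), 1.0, p)  # zero-residual exact fits and constants
    p = np.where(np.isinf(t), 0.0, p)  # perfect nonconstant linear fit
    return slope, p


def age_association(
    dataset: ExpressionDataset,
    group: str = "affected",
    proteins=None,
) -> pd.DataFrame:
    """OLS of log2(level) on age per protein within a group.

    ``group`` is "affected", "control" or "both-separately" (two regression
    lines, one table per group concatenated).  Returns a table with columns
    protein_id, slope (log2-units/year), p_value, q_value, group; q is BH
    within the submitted protein family, separately per group.
    """
    if group == "both-separately":
        return pd.concat(
            [age_association(dataset, g, proteins) for g in ("affected", "control")],
            ignore_index=True,
        )
    if group not in ("affected", "control"):
        raise ValueError("group must be 'affected', 'control' or 'both-separately'")
    mask = dataset.class_mask(group)
    if mask.sum() < 3:
        raise ValueError(f"need at least 3 subjects in group {group!r}")
    ages = dataset.ages[mask]
    if np.ptp(ages) == 0:
        raise ValueError("ages are constant; regression on age is undefined")
    ids, values = _restrict(dataset, proteins)
    y = np.log2(values[mask])
    slope, p = _ols_slope_test(y, ages)
    return pd.DataFrame(
        {
            "protein_id": ids,
            "slope": slope,
            "p_value": p,
            "q_value": bh_adjust(p),
            "group": group,
        }
    )


def treatment_association(dataset: ExpressionDataset, proteins=None) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum of treated vs untreated affected subjects.

    Exact enumeration for arm sizes <= 10 (tie-free), normal approximation
    with tie and continuity correction otherwise.  The location estimate is
    the difference of arm medians on the log2 scale.
    """
    aff = dataset.subset_subjects(dataset.class_mask("affected"))
    treated = aff.values[aff.treated]
    untreated = aff.values[~aff.treated]
    if len(treated) == 0 or len(untreated) == 0:
        raise ValueError("both treatment arms must be non-empty among affected subjects")
    ids, _ = _restrict(aff, proteins)
    col = {p: i for i, p in enumerate(aff.protein_ids)}
    idx = [col[p] for p in ids]
    a, b = treated[:, idx], untreated[:, idx]
    method = "exact" if max(len(a), len(b)) <= 10 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", axis=0, method=method)
    p = np.atleast_1d(res.pvalue)
    est = np.median(np.log2(a), axis=0) - np.median(np.log2(b), axis=0)
    return pd.DataFrame(
        {
            "protein_id": ids,
            "shift": est,
            "p_value": p,
            "q_value": bh_adjust(p),
            "group": "treated_vs_untreated",
        }
    )


def ks_age_compare(ages_case, ages_control) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of the age distributions."""
    a = np.asarray(list(ages_case), dtype=float)
    b = np.asarray(list(ages_control), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both age samples must be non-empty")
    res = stats.ks_2samp(a, b, method="auto")
    return float(res.statistic), float(res.pvalue)
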