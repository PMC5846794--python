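"""Tissue-specificity categorization and gene-set over-representation.

The tissue categorizer applies expression-ratio rules of the kind used by
large tissue atlases: a gene is *tissue enriched* when one tissue's mRNA level
is at least five times higher than every other tissue, *group enriched* when a
group of 2-7 tissues is at least five times higher than all the others,
*tissue enhanced* when some tissue is at least five times the mean level over
all tissues, *expressed in all* when detected everywhere, *not detected* when
detected nowhere, and *mixed* otherwise.  Rules are applied in that precedence
order, so every gene receives exactly one category.

Over-representation of a biomarker panel in a gene set is tested with the
upper-tail hypergeometric distribution against the assay background (the
genes the platform can measure), which is also exactly the one-sided
Fisher test used for per-tissue enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import bh_adjust
from .io_formats import GeneSetCollection, TissueExpressionTable

logger = logging.getLogger("signet")

FOLD = 5.0  # the "at least five times" ratio of all three specificity rules


@dataclass(frozen=True)
class TissueCategory:
    """One gene's specificity category and the tissue(s) defining it."""

    category: str
    tissues: tuple[str, ...] = ()


def _categorize_row(values: np.ndarray, tissues: list[str], thr: float) -> TissueCategory:
    detected = values >= thr
    if not detected.any():
        return TissueCategory("not_detected")
    order = np.argsort(-values, kind="stable")
    top = order[0]
    rest_max = values[order[1:]].max() if len(values) > 1 else 0.0
    if detected[top] and values[top] >= FOLD * rest_max:
        return TissueCategory("tissue_enriched", (tissues[top],))
    # smallest qualifying group of the top-g tissues, g = 2..7: if any group
    # is >= 5x all others, it must be a prefix of the descending order
    for g in range(2, min(7, len(values) - 1) + 1):
        grp = order[:g]
        out_max = values[order[g:]].max()
        if detected[grp].all() and values[grp].min() >= FOLD * out_max:
            return TissueCategory("group_enriched", tuple(sorted(tissues[i] for i in grp)))
    mean_all = values.mean()
    if detected[top] and values[top] >= FOLD * mean_all:
        return TissueCategory("tissue_enhanced", (tissues[top],))
    if detected.all():
        return TissueCategory("expressed_in_all")
    return TissueCategory("mixed")


def classify_tissue_specificity(table: TissueExpressionTable) -> dict[str, TissueCategory]:
    """Assign every gene exactly one specificity category (a partition)."""
    if len(table.tissues) < 2:
        raise ValueError("tissue categorization needs at least 2 tissues")
    thr = float(table.detection_threshold)
    return {
        gene: _categorize_row(table.values[i], table.tissues, thr)
        for i, gene in enumerate(table.genes)
    }


def fisher_tissue_enrichment(
    panel_genes,
    background_genes,
    categories: dict[str, TissueCategory],
) -> pd.DataFrame:
    """One-sided Fisher test of tissue-enriched genes in the panel, per tissue.

    For each tissue T the 2x2 table is (in panel / not) x (enriched in T /
    not) over the background; the one-sided (greater) exact p equals the
    hypergeometric upper tail.
    """
    panel = _clean_genes(panel_genes)
    background = _clean_genes(background_genes)
    offenders = sorted(set(panel) - set(background))
    if offenders:
        raise ValueError(f"panel genes absent from background: {offenders[:10]}")
    bg = set(background)
    enriched_by_tissue: dict[str, set[str]] = {}
    for gene, cat in categories.items():
        if cat.category == "tissue_enriched" and gene in bg:
            enriched_by_tissue.setdefault(cat.tissues[0], set()).add(gene)
    N, n = len(bg), len(set(panel))
    rows = []
    for tissue in sorted(enriched_by_tissue):
        enr = enriched_by_tissue[tissue]
        K = len(enr)
        k = len(enr & set(panel))
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "tissue": tissue,
                "panel_enriched": k,
                "background_enriched": K,
                "panel_size": n,
                "background_size": N,
                "p_value": p,
                "genes": ",".join(sorted(enr & set(panel))),
            }
        )
    return pd.DataFrame(rows, columns=[
        "tissue", "panel_enriched", "background_enriched", "panel_size",
        "background_size", "p_value", "genes",
    ])


def ora_hypergeometric(
    panel_genes,
    collection: GeneSetCollection,
    background_genes,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of the panel per gene set.

    Sets are intersected with the background before testing; p = P(X >= k)
    for k overlapping genes out of a panel of n against a set of K genes in a
    background of N.  q is BH across the tested collection; rows are sorted
    by (q, set name).  A set with empty background intersection is recorded
    with p = 1 and flagged.
    """
    panel = set(_clean_genes(panel_genes))
    background = set(_clean_genes(background_genes))
    offenders = sorted(panel - background)
    if offenders:
        raise ValueError(f"panel genes absent from background: {offenders[:10]}")
    N, n = len(background), len(panel)
    rows = []
    for name, members in collection:
        inset = members & background
        K = len(inset)
        overlap = sorted(inset & panel)
        k = len(overlap)
        if K == 0:
            p, flagged = 1.0, True
        else:
            p, flagged = float(stats.hypergeom.sf(k - 1, N, K, n)), False
        rows.append(
            {
                "set_name": name,
                "overlap_genes": ",".join(overlap),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": p,
                "empty_in_background": flagged,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q_value"] = bh_adjust(df["p_value"].to_numpy())
        df = df.sort_values(["q_value", "set_name"], kind="stable").reset_index(drop=True)
    else:
        df["q_value"] = []
    n_flagged = int(df["empty_in_background"].sum()) if len(df) else 0
    if n_flagged:
        logger.info("%d gene set(s) had no members in the background", n_flagged)
    return df


def _clean_genes(genes) -> list[str]:
    out: dict[str, None] = {}
    for g in genes:
        out.setdefault(str(g).upper(), None)
    return list(out)
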