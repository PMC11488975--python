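"""Differential abundance analysis of annotated phenotypes.

Per-sample cluster counts are summed over clusters sharing a terminal
phenotype label (leftover populations keep their ``*_remaining`` name and
are tested as phenotypes in their own right), converted to within-sample
proportions, and each phenotype is compared between every pair of sample
conditions with a two-sided Wilcoxon rank-sum (Mann–Whitney) test, followed
by a multiple-testing adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import (
    EmptyGroupError,
    RangeError,
    ValidationError,
    ZeroSampleError,
)

logger = logging.getLogger(__name__)

#: exact-p enumeration is used up to this combined sample size (no ties)
EXACT_CUTOFF = 25

ADJUSTMENT_METHODS = {
    "bonferroni": "bonferroni",
    "holm": "holm",
    "hochberg": "simes-hochberg",
    "fdr_bh": "fdr_bh",
    "none": None,
}

ADJUST_SCOPES = ("per_phenotype", "global")


@dataclass
class AbundanceTable:
    """Aggregated per-sample phenotype counts and proportions.

    Both frames are samples x phenotypes; each sample's proportions sum
    to 1 and its counts sum to the sample's input total.
    """

    counts: pd.DataFrame
    proportions: pd.DataFrame


def aggregate(labels: pd.Series, counts: pd.DataFrame) -> AbundanceTable:
    """Sum cluster counts by phenotype label and derive proportions.

    ``labels`` maps every cluster in ``counts`` to its terminal label.
    Samples with zero total cells have undefined proportions and are
    rejected.
    """
    labels = pd.Series(labels)
    missing = set(counts.index) - set(labels.index)
    if missing:
        raise ValidationError(
            f"clusters without a label: {sorted(missing)[:5]}"
        )
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ZeroSampleError(f"samples with zero cells: {list(zero.index)}")
    by_label = counts.groupby(labels.loc[counts.index]).sum()  # labels x samples
    agg_counts = by_label.T.sort_index(axis=1)  # samples x labels
    proportions = agg_counts.div(totals, axis=0)
    return AbundanceTable(counts=agg_counts, proportions=proportions)


def percentage_table(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample phenotype percentages, ready for export."""
    return table.proportions * 100.0


def aggregate_node(tree, labels: pd.Series, counts: pd.DataFrame, node_id: str) -> pd.Series:
    """Per-sample proportion of cells in one node's whole subtree.

    Aggregates every sub-phenotype (children, grandchildren, and the node's
    own leftover clusters) into the selected parent phenotype; the root
    yields 1 for every sample.
    """
    subtree = set(tree.descendants(node_id))
    clusters = [c for c, nid in tree.assignment.items() if nid in subtree and c in counts.index]
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ZeroSampleError(f"samples with zero cells: {list(zero.index)}")
    sub = counts.loc[clusters].sum(axis=0) if clusters else pd.Series(0, index=counts.columns)
    return sub / totals


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    The p-value is exact (full enumeration of the null rank-sum
    distribution) when the combined sample size is at most 25 and there are
    no ties; otherwise the normal approximation with tie and continuity
    corrections is used.  Returns ``(U, p)`` with U the first sample's
    statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EmptyGroupError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_CUTOFF and not ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def adjust_pvalues(p, method: str = "hochberg") -> np.ndarray:
    """Multiple-testing adjustment preserving input order.

    ``bonferroni`` multiplies by the family size (capped at 1); ``holm`` and
    ``hochberg`` are the step-down/step-up variants; ``fdr_bh`` is the
    Benjamini–Hochberg step-up false-discovery-rate procedure; ``none``
    returns the raw values.
    """
    p = np.asarray(p, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise RangeError("p-values must lie in [0, 1]")
    if method not in ADJUSTMENT_METHODS:
        raise ValidationError(
            f"unknown adjustment {method!r}; choose from {sorted(ADJUSTMENT_METHODS)}"
        )
    if p.size == 0 or method == "none":
        return p.copy()
    return multipletests(p, method=ADJUSTMENT_METHODS[method])[1]


def run_da(
    labels: pd.Series,
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    adjustment: str = "hochberg",
    scope: str = "per_phenotype",
) -> pd.DataFrame:
    """Test every phenotype for abundance differences between conditions.

    For each terminal label and each unordered pair of condition levels, a
    Wilcoxon rank-sum test compares the per-sample proportions.  With
    ``scope='per_phenotype'`` (mirroring R's ``pairwise.wilcox.test``) the
    adjustment is applied across the condition pairs of each phenotype;
    ``scope='global'`` additionally pools across phenotypes.

    Returns a frame with columns
    ``phenotype,group_a,group_b,n_a,n_b,statistic,p_raw,p_adjusted``,
    sorted by phenotype then pair.
    """
    if scope not in ADJUST_SCOPES:
        raise ValidationError(f"unknown scope {scope!r}; choose from {ADJUST_SCOPES}")
    samples = [s for s in counts.columns if s in metadata.index]
    if len(samples) < len(counts.columns):
        unknown = sorted(set(counts.columns) - set(metadata.index))
        raise ValidationError(f"samples without metadata: {unknown[:5]}")
    conditions = sorted(metadata.loc[samples, "condition"].unique())
    if len(conditions) < 2:
        raise ValidationError(
            f"need >=2 condition levels for differential abundance, got {conditions}"
        )
    table = aggregate(labels, counts)
    props = table.proportions
    groups = {
        c: [s for s in samples if metadata.loc[s, "condition"] == c]
        for c in conditions
    }

    rows = []
    for label in sorted(props.columns):
        for ga, gb in combinations(conditions, 2):
            va = props.loc[groups[ga], label].to_numpy()
            vb = props.loc[groups[gb], label].to_numpy()
            stat, p = wilcoxon_rank_sum(va, vb)
            rows.append(
                {
                    "phenotype": label,
                    "group_a": ga,
                    "group_b": gb,
                    "n_a": len(va),
                    "n_b": len(vb),
                    "statistic": stat,
                    "p_raw": p,
                }
            )
    result = pd.DataFrame(rows)
    if scope == "global":
        result["p_adjusted"] = adjust_pvalues(result["p_raw"].to_numpy(), adjustment)
    else:
        result["p_adjusted"] = np.nan
        for label, idx in result.groupby("phenotype").groups.items():
            result.loc[idx, "p_adjusted"] = adjust_pvalues(
                result.loc[idx, "p_raw"].to_numpy(), adjustment
            )
    logger.info(
        "differential abundance: %d tests (%d phenotypes x %d condition pairs)",
        len(result),
        props.shape[1],
        len(conditions) * (len(conditions) - 1) // 2,
    )
    return result
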