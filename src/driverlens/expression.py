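"""Expression calls, breadth classes and expressed-fraction statistics.

A gene is called expressed in a context when at least half of its
microarray probes have detection p-values below alpha (default 0.05).
Breadth of expression over a healthy-tissue panel separates housekeeping
genes (expressed in >= 98% of tissues) from tissue-selective genes
(expressed in < 25%). Group-level comparisons contrast the fraction of
expressed (or highly expressed) genes in a gene group against the rest,
with a 1-df chi-squared test and a log2 ratio of the two fractions — the
coordinates of a volcano plot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Set

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .records import (
    EXPRESSED,
    ExpressionCallMatrix,
    NO_DATA,
    NOT_EXPRESSED,
)


def call_expression(
    probes: pd.DataFrame,
    alpha: float = 0.05,
    levels: Optional[pd.DataFrame] = None,
    genes: Optional[Iterable[str]] = None,
    contexts: Optional[Iterable[str]] = None,
) -> ExpressionCallMatrix:
    """Ternary calls from a long probe detection table.

    A gene is expressed in a context iff the number of its probes with
    detection p strictly below ``alpha`` is at least half the number of
    probes ("at least half" read literally: 2 of 3 probes are required
    for n=3). Gene/context pairs without probes are no_data. ``genes``
    and ``contexts`` optionally extend the matrix axes beyond what the
    table covers (extra entries are all no_data).
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    extra_genes = set() if genes is None else set(genes)
    extra_contexts = set() if contexts is None else set(contexts)
    all_genes = sorted(set(probes["gene_id"]) | extra_genes)
    all_contexts = sorted(set(probes["context_id"]) | extra_contexts)
    calls = pd.DataFrame(NO_DATA, index=all_contexts, columns=all_genes, dtype=object)
    if len(probes):
        detected = probes["detection_p"] < alpha
        grouped = (
            probes.assign(_det=detected)
            .groupby(["context_id", "gene_id"], sort=True)["_det"]
            .agg(n_detected="sum", n_probes="size")
        )
        # count >= n/2 in exact arithmetic: 2*count >= n
        expressed = 2 * grouped["n_detected"] >= grouped["n_probes"]
        labelled = expressed.map({True: EXPRESSED, False: NOT_EXPRESSED})
        calls.update(labelled.unstack("gene_id"))
    level = None
    if levels is not None:
        level = levels.reindex(index=all_contexts, columns=all_genes)
    return ExpressionCallMatrix(calls=calls, level=level)


def classify_breadth(
    n_expressed: int,
    n_total: int,
    hk_frac: float = 0.98,
    ts_frac: float = 0.25,
) -> str:
    """Breadth class over a tissue panel.

    housekeeping iff n_expressed >= ceil(hk_frac * n_total); on a
    109-tissue panel the cut is 107. tissue_selective iff n_expressed is
    strictly below ts_frac * n_total; on 109 tissues the cut is 27.
    Everything else is intermediate.
    """
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    if not (0 <= n_expressed <= n_total):
        raise ValidationError("n_expressed must lie in [0, n_total]")
    if not (0.0 < ts_frac < hk_frac <= 1.0):
        raise ValidationError("need 0 < ts_frac < hk_frac <= 1")
    hk_cut = math.ceil(hk_frac * n_total)
    ts_cut = math.ceil(ts_frac * n_total) - 1  # largest integer strictly below
    if n_expressed >= hk_cut:
        return "housekeeping"
    if n_expressed <= ts_cut:
        return "tissue_selective"
    return "intermediate"


def breadth_cutoffs(n_total: int, hk_frac: float = 0.98, ts_frac: float = 0.25) -> dict:
    """The integer class boundaries implied by the fractions."""
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    return {
        "housekeeping_min": math.ceil(hk_frac * n_total),
        "tissue_selective_max": math.ceil(ts_frac * n_total) - 1,
    }


def chi2_2x2(table: np.ndarray, yates: bool = False) -> tuple:
    """1-df chi-squared on a 2x2 table, no continuity correction by default."""
    res = stats.chi2_contingency(np.asarray(table), correction=yates)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupExpressionComparison:
    """Expressed-fraction contrast of a gene group against the rest.

    ``counts`` is [[group_pos, group_neg], [rest_pos, rest_neg]] where
    "pos" means expressed (or highly expressed, depending on mode).
    ``log2ratio`` is None when either fraction is zero; ``defined`` is
    False when a group is empty after no_data exclusion.
    """

    f_group: Optional[float]
    f_rest: Optional[float]
    log2ratio: Optional[float]
    chi2_stat: Optional[float]
    p_value: Optional[float]
    counts: np.ndarray
    defined: bool
    mode: str = "expressed"


def expressed_fraction_comparison(
    group_genes: Set[str],
    rest_genes: Set[str],
    context: str,
    matrix: ExpressionCallMatrix,
    mode: str = "expressed",
    yates: bool = False,
) -> GroupExpressionComparison:
    """Compare the expressed fraction of two disjoint gene groups.

    Genes with no_data in this context are excluded from numerator and
    denominator alike. In ``highly_expressed`` mode a gene counts iff
    its level exceeds the context median over all genes with data.
    """
    if mode not in ("expressed", "highly_expressed"):
        raise ValidationError(f"unknown mode {mode!r}")
    if group_genes & rest_genes:
        raise ValidationError("group and rest must be disjoint")
    with_data = matrix.genes_with_data(context)
    if mode == "expressed":
        positive = matrix.expressed_genes(context)
    else:
        positive = matrix.highly_expressed_genes(context)
    group = group_genes & with_data
    rest = rest_genes & with_data
    a = len(group & positive)
    b = len(group) - a
    c = len(rest & positive)
    d = len(rest) - c
    counts = np.array([[a, b], [c, d]])
    if not group or not rest:
        return GroupExpressionComparison(
            None, None, None, None, None, counts, defined=False, mode=mode
        )
    f_group = a / len(group)
    f_rest = c / len(rest)
    log2ratio = None
    if f_group > 0 and f_rest > 0:
        log2ratio = math.log2(f_group / f_rest)
    if counts.sum(axis=0).min() == 0:
        # a zero column margin (all positive or all negative): chi2 degenerate
        chi2_stat, p_value = 0.0, 1.0
    else:
        chi2_stat, p_value = chi2_2x2(counts, yates=yates)
    return GroupExpressionComparison(
        f_group, f_rest, log2ratio, chi2_stat, p_value, counts, defined=True, mode=mode
    )


def class_enrichment_fisher(table) -> tuple:
    """Two-sided Fisher's exact test on a 2x2 class-membership table.

    Returns (conditional odds ratio or None, p). The conditional
    maximum-likelihood odds ratio is undefined when a margin is zero.
    Used for housekeeping / tissue-selective depletion contrasts, where
    counts can be too small for the chi-squared approximation.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("expected a non-negative 2x2 table")
    if t.sum() == 0:
        raise ValidationError("all-zero table")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    margins = np.concatenate([t.sum(axis=0), t.sum(axis=1)])
    odds = None
    if (margins > 0).all():
        odds = float(stats.contingency.odds_ratio(t).statistic)
    return odds, float(p)


def compare_breadth_distributions(group_a, group_b) -> dict:
    """Two-sided rank-sum comparison of two breadth-count distributions.

    Shapiro-Wilk normality p-values are reported for transparency and
    never used to switch tests. The rank-sum null is exact when the
    pooled values have no ties, tie-corrected normal otherwise.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("each group needs at least 3 values")
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    res = stats.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if no_ties else "asymptotic",
        use_continuity=False,
    )
    return {
        "wilcoxon_p": float(res.pvalue),
        "shapiro_p_a": float(stats.shapiro(a).pvalue),
        "shapiro_p_b": float(stats.shapiro(b).pvalue),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
    }


def volcano_rows(
    group_sets: dict,
    rest_genes: Set[str],
    contexts: Iterable[str],
    matrix: ExpressionCallMatrix,
    mode: str = "expressed",
    yates: bool = False,
) -> pd.DataFrame:
    """One volcano-plot row per (group, context): fractions, log2 ratio, chi2 p."""
    rows = []
    for name in sorted(group_sets):
        for context in contexts:
            cmp = expressed_fraction_comparison(
                group_sets[name], rest_genes, context, matrix, mode=mode, yates=yates
            )
            rows.append(
                {
                    "group": name,
                    "context": context,
                    "f_group": cmp.f_group,
                    "f_rest": cmp.f_rest,
                    "log2ratio": cmp.log2ratio,
                    "chi2": cmp.chi2_stat,
                    "p_value": cmp.p_value,
                    "defined": cmp.defined,
                }
            )
    return pd.DataFrame(rows)
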