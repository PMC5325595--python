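"""Neuron-group enrichment classification.

The rule chain: (1) an expression filter requiring a mean of at least
10 RPM in *each* of the two independent six-timepoint experiments of a
group; (2) fold changes between group means over all 12 samples, with a
2-fold pre-screen before statistics; (3) one-way ANOVA across the four
groups (p < 0.05), Benjamini-Hochberg correction of the gene-level ANOVA
p-values, and Tukey HSD post-hoc p < 0.05 for the specific pair; (4) class
rules — "common circadian": >= 5-fold over the dopaminergic outgroup in at
least 2 of the 3 circadian groups (groups failing the expression filter
are marked LR, low reads, and do not count); "group specific": > 5-fold
over one other circadian group and > 2-fold over the remaining one, all
pairs statistically significant.

Thresholds mirror their stated wording: the 10-RPM filter is inclusive
(">= 10", "at least"), the 5-RPM expressed definition strict ("> 5").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.libqsturng import psturng
from statsmodels.stats.multitest import multipletests

from neurocycle.io_formats import (
    CIRCADIAN_GROUPS,
    OUTGROUP,
    ExpressionMatrix,
    GeneModel,
)

logger = logging.getLogger(__name__)

ALPHA = 0.05
MIN_AVG_RPM_FILTER = 10.0
MIN_AVG_RPM_EXPRESSED = 5.0
FOLD_COMMON = 5.0
FOLD_SPECIFIC = (5.0, 2.0)
PRESCREEN_FOLD = 2.0
ZERO_DENOMINATOR_PSEUDO_RPM = 0.1


def expression_filter(
    matrix: ExpressionMatrix, group: str, min_avg: float = MIN_AVG_RPM_FILTER
) -> pd.Series:
    """True iff the gene averages >= min_avg RPM in *both* replicate sets."""
    matrix.require_complete_grid(group)
    m1 = matrix.group_values(group, replicate_set=1).mean(axis=1)
    m2 = matrix.group_values(group, replicate_set=2).mean(axis=1)
    return (m1 >= min_avg) & (m2 >= min_avg)


def is_expressed(
    matrix: ExpressionMatrix, group: str, min_avg: float = MIN_AVG_RPM_EXPRESSED
) -> pd.Series:
    """True iff the overall group mean is strictly above min_avg RPM."""
    return matrix.group_values(group).mean(axis=1) > min_avg


def group_means(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Mean RPM per gene per group over all 12 samples."""
    return pd.DataFrame(
        {g: matrix.group_values(g).mean(axis=1) for g in matrix.groups}
    )


def log2_fold(means: pd.DataFrame, a: str, b: str) -> pd.Series:
    """log2(mean_a / mean_b); a pseudo-value of 0.1 RPM replaces a zero
    denominator (logged per gene)."""
    denom = means[b].copy()
    zero = denom == 0
    if zero.any():
        logger.info(
            "log2_fold(%s,%s): %d genes with zero denominator, using %.3g RPM",
            a, b, int(zero.sum()), ZERO_DENOMINATOR_PSEUDO_RPM,
        )
        denom[zero] = ZERO_DENOMINATOR_PSEUDO_RPM
    with np.errstate(divide="ignore"):
        return np.log2(means[a] / denom)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in raw p)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def anova_tukey_bh(
    matrix: ExpressionMatrix,
    genes: Sequence[str] | None = None,
    groups: Sequence[str] | None = None,
    prescreen_fold: float | None = PRESCREEN_FOLD,
    alpha: float = ALPHA,
    compute_tukey: bool = True,
) -> pd.DataFrame:
    """One-way ANOVA across groups + BH correction + Tukey HSD per pair.

    Applied to the genes passing the fold-change pre-screen (max pairwise
    ratio of group means >= prescreen_fold; pass ``prescreen_fold=None``
    to test every requested gene).  Returns a DataFrame indexed by gene
    with columns ``anova_p``, ``bh_q`` and ``tukey_p:A|B`` for each
    unordered group pair; genes with zero within-group variance in every
    group get NA and are excluded from BH (logged).
    """
    if groups is None:
        groups = matrix.groups
    for g in groups:
        matrix.require_complete_grid(g)
    if genes is None:
        genes = list(matrix.genes)
    genes = pd.Index(genes)

    means = group_means(matrix).loc[genes, list(groups)]
    if prescreen_fold is not None:
        floor = means.clip(lower=ZERO_DENOMINATOR_PSEUDO_RPM)
        max_ratio = floor.max(axis=1) / floor.min(axis=1)
        genes = genes[max_ratio >= prescreen_fold]

    arrays = [matrix.group_values(g).loc[genes].to_numpy(dtype=float) for g in groups]
    with np.errstate(invalid="ignore", divide="ignore"):
        _f, anova_p = stats.f_oneway(*arrays, axis=1)
    anova_p = pd.Series(anova_p, index=genes, name="anova_p")

    degenerate = anova_p.isna()
    if degenerate.any():
        logger.info(
            "anova_tukey_bh: %d genes with undefined ANOVA p (zero variance) "
            "excluded: %s", int(degenerate.sum()),
            list(genes[degenerate][:10]),
        )
    tested = genes[~degenerate]

    bh_q = pd.Series(np.nan, index=genes, name="bh_q")
    if len(tested):
        bh_q.loc[tested] = bh_adjust(anova_p.loc[tested].to_numpy())

    out = pd.DataFrame({"anova_p": anova_p, "bh_q": bh_q})
    if not compute_tukey:
        return out
    pairs = [
        (groups[i], groups[j])
        for i in range(len(groups))
        for j in range(i + 1, len(groups))
    ]
    # Tukey HSD, vectorized over genes (equal group sizes): studentized
    # range q = |mean_a - mean_b| / sqrt(MSE / n); p from the range
    # distribution via the interpolation table statsmodels' Tukey uses.
    k = len(groups)
    n_per = arrays[0].shape[1]
    df_err = k * (n_per - 1)
    gmeans = np.column_stack([a.mean(axis=1) for a in arrays])
    mse = np.column_stack([a.var(axis=1, ddof=1) for a in arrays]).mean(axis=1)
    se = np.sqrt(mse / n_per)
    for pi, (a, b) in enumerate(pairs):
        ia, ib = groups.index(a), groups.index(b)
        with np.errstate(invalid="ignore", divide="ignore"):
            q = np.abs(gmeans[:, ia] - gmeans[:, ib]) / se
        p = np.full(len(genes), np.nan)
        ok = np.isfinite(q)
        if ok.any():
            p[ok] = np.asarray(psturng(q[ok], k, df_err), dtype=float)
        out[f"tukey_p:{a}|{b}"] = p
    out.loc[~out.index.isin(tested),
            [c for c in out.columns if c.startswith("tukey_p:")]] = np.nan
    return out


def pair_significant(
    stats_table: pd.DataFrame, a: str, b: str, alpha: float = ALPHA
) -> pd.Series:
    """A (a, b) pair is significant iff the BH-adjusted ANOVA criterion and
    the Tukey pairwise p both clear alpha."""
    col = f"tukey_p:{a}|{b}" if f"tukey_p:{a}|{b}" in stats_table else f"tukey_p:{b}|{a}"
    return (stats_table["bh_q"] < alpha) & (stats_table[col] < alpha)


def classify_common_circadian(
    log2_fold_vs_outgroup: pd.DataFrame,
    fold_threshold: float = FOLD_COMMON,
    passes_filter: pd.DataFrame | None = None,
    significant: pd.DataFrame | None = None,
    min_groups: int = 2,
) -> pd.Index:
    """Genes enriched over the outgroup in >= min_groups circadian groups.

    ``log2_fold_vs_outgroup`` has one column per circadian group; NaN marks
    LR (low reads) cells, which never qualify.  ``passes_filter`` /
    ``significant`` are optional boolean frames with the same shape; when
    omitted (e.g. applying the rule to a printed fold table whose rows are
    already significance-vetted) the corresponding gate is skipped.
    """
    qualifies = log2_fold_vs_outgroup >= math.log2(fold_threshold)
    qualifies &= log2_fold_vs_outgroup.notna()
    if passes_filter is not None:
        qualifies &= passes_filter.astype(bool)
    if significant is not None:
        qualifies &= significant.astype(bool)
    return log2_fold_vs_outgroup.index[qualifies.sum(axis=1) >= min_groups]


def classify_group_specific(
    means: pd.DataFrame,
    expressed: pd.DataFrame,
    significant_pairs: Mapping[tuple[str, str], pd.Series],
    circadian_groups: Sequence[str] = CIRCADIAN_GROUPS,
    fold_high: float = FOLD_SPECIFIC[0],
    fold_low: float = FOLD_SPECIFIC[1],
) -> pd.Series:
    """Assign genes specifically enriched in one circadian group.

    Gene specific to g iff expressed in g, > fold_high over one of the
    other circadian groups and > fold_low over the remaining one (strict,
    per the stated rule), with both pairs statistically significant.  The
    rule cannot be met for two groups at once (> 5-fold both directions is
    impossible); this is asserted.  Returns gene -> group (NaN if none).
    """
    floor = means.clip(lower=ZERO_DENOMINATOR_PSEUDO_RPM)
    label = pd.Series(pd.NA, index=means.index, dtype=object)
    for g in circadian_groups:
        others = [h for h in circadian_groups if h != g]
        folds = {h: floor[g] / floor[h] for h in others}
        sig = {
            h: significant_pairs.get((g, h), significant_pairs.get((h, g)))
            for h in others
        }
        for h in others:
            if sig[h] is None:
                raise KeyError(f"no significance series for pair ({g}, {h})")
        a, b = others
        rule = (
            expressed[g].astype(bool)
            & (
                ((folds[a] > fold_high) & (folds[b] > fold_low))
                | ((folds[b] > fold_high) & (folds[a] > fold_low))
            )
            & sig[a].reindex(means.index, fill_value=False).astype(bool)
            & sig[b].reindex(means.index, fill_value=False).astype(bool)
        )
        clash = rule & label.notna()
        if clash.any():
            raise AssertionError(
                f"genes specific to two groups (impossible under the rule): "
                f"{list(means.index[clash])}"
            )
        label[rule] = g
    return label


def flag_candidate_neuropeptide_genes(
    models: Sequence[GeneModel],
    enriched: set[str] | Sequence[str],
    max_length_bp: int = 2000,
    require_intronless: bool = True,
) -> set[str]:
    """Short (and optionally intronless) enriched genes — the structural
    pre-filter for candidate neuropeptide precursors."""
    enriched = set(enriched)
    out = set()
    for m in models:
        if m.gene_id not in enriched:
            continue
        if require_intronless and not m.is_intronless():
            continue
        max_tx = max(m.transcript_length(i) for i in range(len(m.isoforms)))
        if max_tx <= max_length_bp:
            out.add(m.gene_id)
    return out


@dataclass
class EnrichmentOutcome:
    """Full per-gene enrichment results plus class labels."""

    table: pd.DataFrame
    stats: pd.DataFrame
    common_circadian: pd.Index
    specific: pd.Series

    def summary(self) -> dict:
        labels = self.specific.dropna()
        return {
            "n_common_circadian": int(len(self.common_circadian)),
            "n_specific": {g: int((labels == g).sum()) for g in sorted(labels.unique())},
        }


def run_enrichment(
    matrix: ExpressionMatrix,
    outgroup: str = OUTGROUP,
    circadian_groups: Sequence[str] = CIRCADIAN_GROUPS,
    fold_common: float = FOLD_COMMON,
    fold_specific: tuple[float, float] = FOLD_SPECIFIC,
    alpha: float = ALPHA,
) -> EnrichmentOutcome:
    """Run the complete enrichment chain on an expression matrix."""
    groups = list(circadian_groups) + [outgroup]
    means = group_means(matrix)[groups]
    filt = pd.DataFrame({g: expression_filter(matrix, g) for g in groups})
    expr = pd.DataFrame({g: is_expressed(matrix, g) for g in groups})

    stats_table = anova_tukey_bh(matrix, groups=groups)
    sig = {}
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            sig[(a, b)] = pair_significant(stats_table, a, b, alpha)

    folds_vs_out = pd.DataFrame(
        {g: log2_fold(means, g, outgroup) for g in circadian_groups}
    )
    # LR convention: a circadian group failing its own expression filter (or
    # the outgroup failing its filter entirely) cannot qualify a cell
    lr = ~filt[list(circadian_groups)]
    folds_lr = folds_vs_out.mask(lr)
    sig_vs_out = pd.DataFrame(
        {
            g: sig[(g, outgroup) if (g, outgroup) in sig else (outgroup, g)]
            .reindex(matrix.genes, fill_value=False)
            for g in circadian_groups
        }
    )
    common = classify_common_circadian(
        folds_lr, fold_threshold=fold_common,
        significant=sig_vs_out, min_groups=2,
    )
    specific = classify_group_specific(
        means, expr, sig, circadian_groups=circadian_groups,
        fold_high=fold_specific[0], fold_low=fold_specific[1],
    )
    table = means.add_prefix("mean:")
    for g in groups:
        table[f"filter:{g}"] = filt[g]
    for g in circadian_groups:
        table[f"log2_fold:{g}|{outgroup}"] = folds_vs_out[g]
        table[f"LR:{g}"] = lr[g]
    table["common_circadian"] = table.index.isin(common)
    table["specific"] = specific
    return EnrichmentOutcome(table=table, stats=stats_table,
                             common_circadian=common, specific=specific)
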