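"""Phase-distribution summaries of cycling results across neuron groups.

Phase histograms (percent of cyclers per ZT bin, circular binning over
[0, 24)), the circular mean phase of the core clock genes (*vri*, *Pdp1*,
*per*, *tim*), cross-group overlap/intersection tables of cycler sets, and
the morning-vs-evening comparison of large-vs-small LNv expression ratios
(Welch two-sample t-test on log2 ratios; a ratio < 1 means higher
expression in s-LNvs).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CORE_CLOCK_GENES = ("vri", "Pdp1", "per", "tim")
MORNING_BIN_H = (3.0, 8.0)
EVENING_BIN_H = (14.0, 19.0)
PERIOD_H = 24.0


@dataclass(frozen=True)
class PhaseHistogram:
    group: str
    bin_edges: np.ndarray  # ZT hours, covers [0, 24)
    percent_per_bin: np.ndarray  # sums to 100 over cyclers with defined phase
    n_cyclers: int


def _select_confidence(cyclers: pd.DataFrame, confidence: str) -> pd.DataFrame:
    """confidence: 'HC' or 'HC+LC'."""
    if confidence == "HC":
        return cyclers[cyclers["confidence"] == "HC"]
    if confidence in ("HC+LC", "LC+HC"):
        return cyclers[cyclers["confidence"].isin(["HC", "LC"])]
    raise ValueError(f"unknown confidence selector {confidence!r}")


def phase_histogram(
    cyclers: pd.DataFrame,
    group: str,
    bin_width_h: float = 2.0,
    confidence: str = "HC",
) -> PhaseHistogram:
    """Histogram of peak phases for one group's cyclers.

    Bins are aligned to ZT0 and cover [0, 24) circularly: a phase of 23.9 h
    falls in the last bin, 0.1 h in the first (adjacent wrap-around bins,
    never pooled).  Percentages are over cyclers with a defined phase.
    """
    if not (0 < bin_width_h <= PERIOD_H) or (PERIOD_H / bin_width_h) % 1 != 0:
        raise ValueError("bin width must divide 24 h")
    edges = np.arange(0.0, PERIOD_H + bin_width_h, bin_width_h)
    sub = _select_confidence(cyclers[cyclers["group"] == group], confidence)
    phases = sub["phase"].dropna().to_numpy(dtype=float) % PERIOD_H
    counts, _ = np.histogram(phases, bins=edges)
    n = counts.sum()
    if n == 0:
        warnings.warn(f"no {confidence} cyclers with defined phase in {group!r}")
        percent = np.zeros(len(edges) - 1)
    else:
        percent = counts / n * 100.0
    return PhaseHistogram(group=group, bin_edges=edges,
                          percent_per_bin=percent, n_cyclers=int(n))


def circular_mean_phase(phases_h: Sequence[float], period: float = PERIOD_H) -> float:
    """Circular mean of phases in hours on [0, period)."""
    ph = np.asarray(phases_h, dtype=float)
    ang = 2 * np.pi * ph / period
    mean_ang = np.angle(np.mean(np.exp(1j * ang)))
    out = float(np.mod(mean_ang * period / (2 * np.pi), period))
    return 0.0 if out >= period else out  # guard float mod landing on period


def core_clock_phase(
    cyclers: pd.DataFrame,
    group: str,
    genes: Sequence[str] = CORE_CLOCK_GENES,
) -> float:
    """Circular mean phase (ZT hours) of the core clock genes in a group.

    Missing genes are skipped with a log entry; the mean is over the
    available subset.
    """
    sub = cyclers[(cyclers["group"] == group) & cyclers["gene_id"].isin(genes)]
    sub = sub[sub["phase"].notna()]
    found = set(sub["gene_id"])
    missing = [g for g in genes if g not in found]
    if missing:
        logger.info("core_clock_phase(%s): missing genes %s", group, missing)
    if sub.empty:
        raise ValueError(f"no core-clock phases available in group {group!r}")
    return circular_mean_phase(sub["phase"].to_numpy())


@dataclass(frozen=True)
class OverlapTable:
    """Cycler-set intersections across groups (inclusion-exclusion
    consistent by construction: all counts derive from the same sets)."""

    sets: Mapping[str, frozenset]
    pairwise: Mapping[tuple[str, str], int]
    threeway: Mapping[tuple[str, str, str], int]
    exactly_k: Mapping[int, int]
    not_expressed_elsewhere: Mapping[str, int] | None = None

    def to_summary(self) -> dict:
        out = {
            "per_group": {g: len(s) for g, s in self.sets.items()},
            "pairwise": {" & ".join(k): v for k, v in self.pairwise.items()},
            "threeway": {" & ".join(k): v for k, v in self.threeway.items()},
            "exactly_k_groups": {str(k): v for k, v in self.exactly_k.items()},
        }
        if self.not_expressed_elsewhere is not None:
            out["not_expressed_elsewhere"] = dict(self.not_expressed_elsewhere)
        return out


def overlap_analysis(
    cyclers: pd.DataFrame,
    groups: Sequence[str],
    confidence: str = "HC",
    expressed: pd.DataFrame | None = None,
) -> OverlapTable:
    """Intersections of per-group cycler sets.

    ``expressed`` (optional boolean genes x groups frame from the > 5 RPM
    definition) adds, per group, the count of that group's
    single-group cyclers not expressed in any of the other listed groups.
    """
    sets = {}
    for g in groups:
        sub = _select_confidence(cyclers[cyclers["group"] == g], confidence)
        sets[g] = frozenset(sub["gene_id"])
    pairwise = {
        (a, b): len(sets[a] & sets[b]) for a, b in combinations(groups, 2)
    }
    threeway = {
        trio: len(sets[trio[0]] & sets[trio[1]] & sets[trio[2]])
        for trio in combinations(groups, 3)
    }
    all_genes = frozenset().union(*sets.values()) if sets else frozenset()
    exactly_k: dict[int, int] = {k: 0 for k in range(1, len(groups) + 1)}
    membership = {gene: sum(gene in s for s in sets.values()) for gene in all_genes}
    for gene, k in membership.items():
        exactly_k[k] += 1
    nee = None
    if expressed is not None:
        nee = {}
        for g in groups:
            others = [h for h in groups if h != g]
            solo = {gene for gene in sets[g] if membership[gene] == 1}
            count = 0
            for gene in solo:
                if gene in expressed.index and not expressed.loc[gene, others].any():
                    count += 1
            nee[g] = count
    return OverlapTable(sets=sets, pairwise=pairwise, threeway=threeway,
                        exactly_k=exactly_k, not_expressed_elsewhere=nee)


def morning_evening_ratio_test(
    cyclers: pd.DataFrame,
    ratio_table: pd.DataFrame,
    group: str = "LNv",
    morning_bin: tuple[float, float] = MORNING_BIN_H,
    evening_bin: tuple[float, float] = EVENING_BIN_H,
    confidence: str = "HC",
    welch: bool = True,
) -> dict:
    """Compare l-LNv/s-LNv expression ratios of morning- vs evening-phase
    cyclers.

    Cyclers are assigned to the morning (ZT3-8, closed interval) or
    evening (ZT14-19) bin by peak phase; genes outside both bins are
    excluded.  Ratios are compared on the log2 scale with a two-sided
    two-sample t-test (Welch by default).  Returns the statistic, p-value
    and per-bin summaries (n, median, quartiles of the raw ratio).
    """
    sub = _select_confidence(cyclers[cyclers["group"] == group], confidence)
    sub = sub[sub["phase"].notna()]
    ratios = ratio_table.set_index("gene_id")["ls_ratio"] if "gene_id" in ratio_table \
        else ratio_table.iloc[:, 0]
    merged = sub.set_index("gene_id").join(ratios.rename("ls_ratio"), how="inner")
    if (merged["ls_ratio"] <= 0).any():
        raise ValueError("ratios must be positive")
    phase = merged["phase"]
    morning = merged[(phase >= morning_bin[0]) & (phase <= morning_bin[1])]
    evening = merged[(phase >= evening_bin[0]) & (phase <= evening_bin[1])]
    for name, bin_df in (("morning", morning), ("evening", evening)):
        if len(bin_df) < 2:
            raise ValueError(
                f"{name} bin has {len(bin_df)} genes; the t-test needs >= 2"
            )
    lm = np.log2(morning["ls_ratio"].to_numpy())
    le = np.log2(evening["ls_ratio"].to_numpy())
    t_stat, p = stats.ttest_ind(lm, le, equal_var=not welch)

    def _summ(x: np.ndarray) -> dict:
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return {"n": int(len(x)), "median": float(med),
                "q1": float(q1), "q3": float(q3)}

    return {
        "t": float(t_stat),
        "p": float(p),
        "welch": welch,
        "morning": _summ(morning["ls_ratio"].to_numpy()),
        "evening": _summ(evening["ls_ratio"].to_numpy()),
    }
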