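"""Synthetic time-course data with the statistical structure the pipeline
assumes: circadian cosine mean model, overdispersed low-input count noise,
group-restricted expression, 3'-biased read placement.

The default :class:`SimulationConfig` reproduces the study design — four
neuron groups (LNv, LNd, DN1 and the dopaminergic TH outgroup), two
independent replicate time courses per group, six timepoints at 4-h spacing
(the DN1 grid offset by +1 h) — so every downstream stage can be exercised
end-to-end without external data.

Mean model: a gene cycling with amplitude fold ``a`` (peak/trough) and peak
phase ``phi`` has mean expression

    m(t) = b * (1 + beta * cos(2*pi*(t - phi)/24)),   beta = (a-1)/(a+1)

so its time average is the baseline ``b`` and peak/trough equals ``a``
exactly.  Counts are drawn as gamma-Poisson (negative-binomial) mixtures at
the raw-count level and then normalized to reads per million, mimicking the
low reproducibility of small-cell-number libraries; pure Poisson noise
under-models that variance.  The dispersion default is a stand-in — the
real libraries' noise model is unknown (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from neurocycle.io_formats import (
    DEFAULT_ZT_GRIDS,
    ExpressionMatrix,
    GeneModel,
    ReadRecord,
    SampleMeta,
)

PERIOD_H = 24.0


@dataclass(frozen=True)
class PhaseDistribution:
    """Distribution of programmed peak phases over [0, 24).

    kind 'uniform' ignores the location parameters; 'unimodal' is a wrapped
    normal at `means[0]` with `sds[0]`; 'bimodal' a two-component wrapped
    normal mixture (the LNv-like morning/evening pattern).
    """

    kind: str = "uniform"
    means: tuple[float, ...] = (13.0,)
    sds: tuple[float, ...] = (2.0,)
    weights: tuple[float, ...] = (1.0,)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(0.0, PERIOD_H, size=n)
        if self.kind in ("unimodal", "bimodal"):
            comp = rng.choice(len(self.means), size=n,
                              p=np.asarray(self.weights) / np.sum(self.weights))
            draws = rng.normal(np.asarray(self.means)[comp],
                               np.asarray(self.sds)[comp])
            return np.mod(draws, PERIOD_H)
        raise ValueError(f"unknown phase distribution kind {self.kind!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters for the generator.

    dispersion is the negative-binomial overdispersion alpha (variance =
    mu + alpha*mu^2); at high expression the per-timepoint coefficient of
    variation approaches sqrt(alpha).  dispersion = 0 yields the noiseless
    mean model (no count sampling at all).
    """

    n_genes: int = 2000
    zt_grids: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ZT_GRIDS)
    )
    n_replicate_sets: int = 2
    frac_cyclers: float | Mapping[str, float] = 0.1
    amplitude_fold: float = 4.0
    phase_distribution: PhaseDistribution = field(default_factory=PhaseDistribution)
    baseline_log_mean: float = float(np.log(100.0))  # log-RPM scale
    baseline_log_sd: float = 1.2
    dispersion: float = 0.04
    frac_group_restricted: float = 0.2
    frac_low_expression: float = 0.1
    library_size: int = 1_000_000
    three_prime_decay_bp: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = [self.frac_group_restricted, self.frac_low_expression]
        if isinstance(self.frac_cyclers, Mapping):
            fracs.extend(self.frac_cyclers.values())
        else:
            fracs.append(self.frac_cyclers)
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if self.amplitude_fold < 1.0:
            raise ValueError("amplitude_fold must be >= 1")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for group, grid in self.zt_grids.items():
            if len(grid) != 6 or len(set(grid)) != 6:
                raise ValueError(
                    f"group {group!r}: ZT grid must have 6 distinct timepoints, "
                    f"got {tuple(grid)}"
                )

    def frac_cyclers_for(self, group: str) -> float:
        if isinstance(self.frac_cyclers, Mapping):
            return float(self.frac_cyclers.get(group, 0.0))
        return float(self.frac_cyclers)


@dataclass(frozen=True)
class GroupTruth:
    expressed: bool
    is_cycler: bool
    phase: float  # ZT hours of cosine peak; meaningful only if is_cycler
    amplitude_fold: float  # 1.0 for non-cyclers
    baseline: float  # expected RPM time average


@dataclass(frozen=True)
class TruthRecord:
    gene_id: str
    groups: Mapping[str, GroupTruth]


def cosine_mean_model(
    baseline: float, amplitude_fold: float, phase: float, t: np.ndarray | float
) -> np.ndarray | float:
    """Mean expression at ZT ``t`` for the circadian cosine model.

    Peak/trough ratio equals ``amplitude_fold`` exactly; the time average
    equals ``baseline``; the peak sits at ``phase``.
    """
    beta = (amplitude_fold - 1.0) / (amplitude_fold + 1.0)
    return baseline * (1.0 + beta * np.cos(2.0 * np.pi * (np.asarray(t) - phase) / PERIOD_H))


# expression-threshold anchors used when placing gene classes (RPM)
_LOW_EXPRESSION_RANGE = (1.0, 8.0)   # below the 10-RPM enrichment filter
_UNEXPRESSED_RANGE = (0.0, 2.0)      # below the 5-RPM "expressed" threshold


def _assign_gene_classes(config: SimulationConfig, rng: np.random.Generator):
    """Per gene and group: expressed flag, low-expression flag, baseline.

    A gene's abundance is drawn once and shared across the groups that
    express it (transcript abundance correlates across cell types); the
    group-restriction and low-expression flags impose the differential
    structure.  Within each group the expressed baselines are rescaled so
    the group's expected total is 1e6 RPM, so baselines read directly as
    expected reads per million.
    """
    n = config.n_genes
    groups = list(config.zt_grids)
    restricted = rng.random(n) < config.frac_group_restricted
    if len(groups) < 2:
        restricted[:] = False  # restriction needs >= 2 groups
    low_expr = rng.random(n) < config.frac_low_expression

    expressed = np.ones((n, len(groups)), dtype=bool)
    for i in np.flatnonzero(restricted):
        k = rng.integers(1, len(groups))  # expressed in 1..G-1 groups
        keep = rng.choice(len(groups), size=k, replace=False)
        expressed[i] = False
        expressed[i, keep] = True

    gene_level = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd,
                               size=n)
    gene_low = rng.uniform(*_LOW_EXPRESSION_RANGE, size=n)
    baselines = np.zeros((n, len(groups)))
    for j, _g in enumerate(groups):
        exp_j = expressed[:, j]
        normal = exp_j & ~low_expr
        low = exp_j & low_expr
        baselines[low, j] = gene_low[low]
        baselines[~exp_j, j] = rng.uniform(*_UNEXPRESSED_RANGE, size=(~exp_j).sum())
        raw = gene_level[normal]
        fixed_mass = baselines[:, j].sum()
        scale = max(1e6 - fixed_mass, 0.0) / raw.sum() if raw.sum() > 0 else 0.0
        baselines[normal, j] = raw * scale  # group totals sum to 1e6 RPM
    return groups, expressed, low_expr, baselines


def generate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, list[TruthRecord]]:
    """Simulate the full design and return (matrix, ground truth).

    Samples are ordered group-major, then replicate set, then ZT.  Values
    are reads-per-million (each sample sums to 1e6 before rounding).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]
    groups, expressed, _low, baselines = _assign_gene_classes(config, rng)

    is_cycler = np.zeros((n, len(groups)), dtype=bool)
    phases = np.zeros((n, len(groups)))
    amp = np.ones((n, len(groups)))
    for j, g in enumerate(groups):
        cand = expressed[:, j]
        is_cycler[:, j] = cand & (rng.random(n) < config.frac_cyclers_for(g))
        phases[:, j] = config.phase_distribution.sample(n, rng)
        amp[is_cycler[:, j], j] = config.amplitude_fold

    samples: list[SampleMeta] = []
    columns: list[np.ndarray] = []
    for j, g in enumerate(groups):
        beta = (amp[:, j] - 1.0) / (amp[:, j] + 1.0)
        for rep in range(1, config.n_replicate_sets + 1):
            for zt in config.zt_grids[g]:
                mean_rpm = baselines[:, j] * (
                    1.0 + beta * np.cos(2.0 * np.pi * (zt - phases[:, j]) / PERIOD_H)
                    * is_cycler[:, j]
                )
                total = mean_rpm.sum()
                mu = mean_rpm / total * config.library_size if total > 0 else mean_rpm
                if config.dispersion == 0.0:
                    counts = mu
                else:
                    lam = rng.gamma(shape=1.0 / config.dispersion,
                                    scale=mu * config.dispersion)
                    counts = rng.poisson(lam).astype(float)
                tot_counts = counts.sum()
                rpm = counts / tot_counts * 1e6 if tot_counts > 0 else counts
                samples.append(SampleMeta(f"{g}_r{rep}_zt{zt:g}", g, rep, float(zt)))
                columns.append(rpm)

    values = pd.DataFrame(
        np.column_stack(columns),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[s.sample_id for s in samples],
    )
    matrix = ExpressionMatrix(values, samples)

    truth = []
    for i, gid in enumerate(gene_ids):
        per_group = {}
        for j, g in enumerate(groups):
            per_group[g] = GroupTruth(
                expressed=bool(expressed[i, j]),
                is_cycler=bool(is_cycler[i, j]),
                phase=float(phases[i, j]) if is_cycler[i, j] else float("nan"),
                amplitude_fold=float(amp[i, j]),
                baseline=float(baselines[i, j]),
            )
        truth.append(TruthRecord(gene_id=gid, groups=per_group))
    return matrix, truth


def truth_to_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    """Flatten truth records to a tidy gene x group table."""
    rows = []
    for rec in truth:
        for g, t in rec.groups.items():
            rows.append(
                {
                    "gene_id": rec.gene_id,
                    "group": g,
                    "expressed": t.expressed,
                    "is_cycler": t.is_cycler,
                    "true_phase": t.phase,
                    "true_amplitude_fold": t.amplitude_fold,
                    "true_baseline": t.baseline,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gene models and 3'-biased reads
# ---------------------------------------------------------------------------

def generate_gene_models(
    n_genes: int,
    rng: np.random.Generator | int = 0,
    chrom: str = "chrS",
    max_exons: int = 3,
    exon_length_range: tuple[int, int] = (200, 800),
    intron_length_range: tuple[int, int] = (100, 500),
    intergenic_gap: int = 1000,
    frac_alt_utr: float = 0.2,
) -> list[GeneModel]:
    """Random non-overlapping gene models on a toy chromosome.

    A fraction of genes get a second isoform with an extended 3' UTR
    (exercising the distinct-3'-end window logic).  Strands alternate.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    models = []
    cursor = 1000
    for i in range(n_genes):
        n_exons = int(rng.integers(1, max_exons + 1))
        exons = []
        pos = cursor
        for k in range(n_exons):
            length = int(rng.integers(*exon_length_range))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(*intron_length_range))
        strand = "+" if i % 2 == 0 else "-"
        isoforms = [tuple(exons)]
        if rng.random() < frac_alt_utr:
            ext = int(rng.integers(100, 400))
            if strand == "+":
                s, e = exons[-1]
                isoforms.append(tuple(exons[:-1] + [(s, e + ext)]))
            else:
                s, e = exons[0]
                s2 = max(cursor - ext, exons[0][0] - ext, 0)
                isoforms.append(tuple([(s2, e)] + exons[1:]))
        gid = f"g{i:05d}"
        models.append(GeneModel(gid, chrom, strand, tuple(isoforms)))
        span_end = max(ex[-1][1] for ex in isoforms)
        cursor = span_end + intergenic_gap
    return models


def _place_positions(
    model: GeneModel, n_reads: int, decay_bp: float, rng: np.random.Generator
) -> np.ndarray:
    """Genomic 3'-terminal positions for n_reads of one gene: isoform chosen
    uniformly, distance from the isoform 3' end ~ Exponential(decay_bp)
    truncated at the transcript length, projected through exons."""
    iso_idx = rng.integers(0, len(model.isoforms), size=n_reads)
    positions = np.empty(n_reads, dtype=np.int64)
    for k, exons in enumerate(model.isoforms):
        mask = iso_idx == k
        m = int(mask.sum())
        if m == 0:
            continue
        lengths = np.array([e - s for s, e in exons])
        tx_len = int(lengths.sum())
        d = np.minimum(
            rng.exponential(decay_bp, size=m).astype(np.int64), tx_len - 1
        )
        # cumulative exon lengths counted from the 3' end of the transcript
        if model.strand == "+":
            rev = lengths[::-1]
            cum = np.concatenate([[0], np.cumsum(rev)])
            exon_of_d = np.searchsorted(cum, d, side="right") - 1
            within = d - cum[exon_of_d]
            ends = np.array([e for _s, e in exons])[::-1]
            positions[mask] = ends[exon_of_d] - 1 - within
        else:
            cum = np.concatenate([[0], np.cumsum(lengths)])
            exon_of_d = np.searchsorted(cum, d, side="right") - 1
            within = d - cum[exon_of_d]
            starts = np.array([s for s, _e in exons])
            positions[mask] = starts[exon_of_d] + within
    return positions


def generate_reads(
    models: Sequence[GeneModel],
    target_rpm: Mapping[str, float],
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> list[ReadRecord]:
    """Simulate 3'-biased read 3'-position records for one library.

    Expected read count per gene is proportional to its target RPM;
    ``config.library_size`` reads total.  Read 3' ends decay exponentially
    (scale ``config.three_prime_decay_bp``) upstream of a uniformly chosen
    isoform 3' end, so a short decay concentrates reads in the terminal
    300-bp windows as in oligo-dT-primed libraries.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    by_id = {m.gene_id: m for m in models}
    missing = [g for g in target_rpm if g not in by_id]
    if missing:
        raise ValueError(f"genes without a model: {sorted(missing)}")
    gene_ids = list(target_rpm)
    targets = np.array([max(float(target_rpm[g]), 0.0) for g in gene_ids])
    total = targets.sum()
    if total <= 0:
        return []
    counts = rng.multinomial(config.library_size, targets / total)
    reads: list[ReadRecord] = []
    for gid, n_reads in zip(gene_ids, counts):
        if n_reads == 0:
            continue
        model = by_id[gid]
        for pos in _place_positions(model, int(n_reads), config.three_prime_decay_bp, rng):
            reads.append(ReadRecord(model.chrom, model.strand, int(pos)))
    return reads


# ---------------------------------------------------------------------------
# l-LNv / s-LNv expression-ratio table
# ---------------------------------------------------------------------------

def generate_ls_ratio_table(
    truth: Sequence[TruthRecord],
    config: SimulationConfig,
    effect_log2: float = 1.0,
    sd_log2: float = 0.8,
    morning_bin: tuple[float, float] = (3.0, 8.0),
    evening_bin: tuple[float, float] = (14.0, 19.0),
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Per-gene large-vs-small LNv expression ratios with a programmed
    morning/evening effect.

    Ratios are positive; a value < 1 means higher expression in s-LNvs.
    LNv cyclers peaking in the morning bin get mean log2 ratio
    -effect_log2/2 (s-LNv biased), evening-bin cyclers +effect_log2/2,
    all other genes 0.  effect_log2 = 0 makes the two bins identical in
    expectation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    rows = []
    for rec in truth:
        t = rec.groups.get("LNv")
        mean = 0.0
        if t is not None and t.is_cycler and np.isfinite(t.phase):
            if morning_bin[0] <= t.phase <= morning_bin[1]:
                mean = -effect_log2 / 2.0
            elif evening_bin[0] <= t.phase <= evening_bin[1]:
                mean = +effect_log2 / 2.0
        rows.append({"gene_id": rec.gene_id,
                     "ls_ratio": float(2.0 ** rng.normal(mean, sd_log2))})
    return pd.DataFrame(rows)
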