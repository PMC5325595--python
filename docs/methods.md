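# Methods

This note documents the models, statistics and design choices behind
`neurocycle`, and what the synthetic-data tests do and do not establish
about real data.

## Study design assumed throughout

Four neuron groups — the circadian LNv, LNd and DN1 groups and a
dopaminergic (TH) outgroup — each profiled as **two independent replicate
time courses of six timepoints at 4-h spacing**. LNv, LNd and TH are
sampled at ZT2, 6, 10, 14, 18, 22; DN1 at ZT3, 7, 11, 15, 19, 23 (a +1-h
grid offset). Expression values are reads per million (RPM). Downstream
stages require the complete 2 × 6 grid per group and fail fast otherwise;
missing samples may be recorded as NA in tables but cannot enter the
statistics, because the tests below assume the full design. ZT is
recorded verbatim per group; phase estimates are expressed in absolute
ZT, so the DN1 offset needs no special reconciliation.

## 3'-end quantification

Low-input, oligo-dT-amplified libraries are strongly 3'-biased, so
expression is quantified from read **3'-terminal positions** in windows
anchored at transcript 3' ends rather than over whole gene bodies:

- one window of up to 300 bp per **distinct isoform 3' end**, extended
  upstream in transcript coordinates (projected through introns to one or
  more genomic intervals) and truncated at the transcript 5' end;
- overlapping windows of the same gene are merged, so a read can never be
  double-counted within a gene;
- a read counts for a gene iff its 3' position lies in one of the gene's
  windows on the matching strand. Reads inside windows of two different
  genes count once for each (the overlap is reported); unassigned reads
  are tallied and logged.

The terminal window is anchored, not scanned: the purpose of the window —
removing gene-length bias — is served by a fixed terminal window, and a
fixed anchor keeps counting deterministic and order-independent.
Duplicate reads are retained deliberately: 3'-anchored amplification
makes identical reads expected rather than artifactual, and removing them
would discard signal. RPM normalization divides by the per-sample total
of **window-assigned** reads (not all mapped reads); the choice is
self-contained and recorded in output metadata, and only rescales columns.
Distinct isoform 3' ends are all retained because alternative 3' UTRs of
the same gene can be cell-type specific.

## Enrichment rule chain

1. **Expression filter**: a gene is testable in a group iff its mean is
   ≥ 10 RPM in *each* of the two replicate time courses (inclusive ≥,
   following the rule's "at least" wording). Groups failing the filter are
   flagged LR ("low reads") and can never qualify in a comparison.
   Separately, "expressed" means overall group mean **strictly** > 5 RPM.
2. **Pre-screen**: only genes whose group means differ by ≥ 2-fold
   anywhere enter the statistics (means floored at 0.1 RPM for ratios).
3. **Statistics**: one-way ANOVA across the four groups on all 12 samples
   per group; Benjamini–Hochberg step-up over the gene-level ANOVA
   p-values of the pre-screened set; Tukey HSD per group pair. A pair is
   significant iff BH-adjusted q < 0.05 **and** Tukey p < 0.05 — the two
   corrections applied each at its natural level (BH across genes, Tukey
   across pairs). Genes with zero within-group variance everywhere are
   reported NA and excluded from BH, with a log entry.
4. **Class rules**: *common circadian* — log2 fold vs TH ≥ log2 5 in at
   least 2 of the 3 circadian groups, each qualifying group passing its
   expression filter and its (group, TH) pair significant. *Group
   specific* — expressed in the group, > 5-fold over one other circadian
   group and > 2-fold over the remaining one (strict >), both pairs
   significant; the rule cannot hold for two groups simultaneously and
   this is asserted. An alternative uniform > 2-fold reading of the
   specific rule exists in the literature on this design; the
   5-fold/2-fold form is implemented as primary and the thresholds are
   arguments, so the other reading is one call away.

Fold changes use group means over all 12 samples; a zero denominator is
replaced by 0.1 RPM and logged. Tukey p-values are computed vectorized
from the studentized-range distribution via the interpolation table used
by statsmodels' Tukey implementation; its p clipping at 0.001/0.9 is
immaterial for gating at 0.05.

The candidate-neuropeptide pre-filter is purely structural: enriched
genes that are short (spliced length ≤ a configurable cap, default
2,000 bp) and, optionally, single-exon. Sequence-based signal-peptide
scoring is out of scope.

## Cycling detection

Each gene/group series has 12 values ordered replicate-set-major. Each
6-point set is first divided by **its own maximum** (an all-zero set maps
to zeros), equalizing the two days' scales; the normalized series is then
treated as two consecutive 24-h days, i.e. a 48-h span sampled every 4 h.

**F24.** With `X` the DFT of the 12-point normalized series, the 24-h
component is harmonic 2 of 12, and

    F24 = |X₂|² / Σ_{k=1..6} |X_k|²  ∈ [0, 1].

A pure 24-h cosine gives F24 = 1, a pure 12-h cosine 0, a constant series
0 (defined as 0 when total AC power vanishes; the Nyquist harmonic k = 6
is counted once). Phase is the ZT at which the fitted 24-h cosine peaks,
read from the argument of the projection `Σ xₙ·e^(−2πi·ztₙ/24)` with
absolute sample ZTs, so grids with different offsets are directly
comparable. Phase is NA when the 24-h component vanishes. Amplitude is
peak/trough of the per-ZT means of the **unnormalized** series (the two
replicate values at each grid ZT averaged), with the trough floored at
0.1 RPM; a flat series has amplitude 1. Amplitude is measured before
max-normalization because normalization destroys cross-set amplitude
information; a fitted-cosine amplitude could be substituted but the
peak/trough of means is the plainest reading of "fold amplitude".

**Rank test.** Reference waveforms are 24-h cosines evaluated at the six
grid ZTs, one per lag on the 4-h lag grid. Each reference value appears
at least twice (two replicate sets) and cosine symmetry ties further grid
points, so references are heavily tied. The statistic is Kendall's
S = Σ sign(xⱼ−xᵢ)·sign(rⱼ−rᵢ) over reference-untied pairs. Under the
null (random ordering of distinct observed values) S = 2·JT − M where JT
is a Jonckheere–Terpstra-type statistic over the reference's tie groups
and M the number of untied pairs; the exact distribution of JT is
computed by convolving Gaussian-binomial coefficient polynomials
(integer-exact at this design size, cached per tie structure). Per-lag
two-sided p = min(1, 2·P(S ≥ |s|)). A lag+12 shift negates the cosine and
merely flips the sign of S, so reversed waveforms are collapsed; the
reported p is the minimum per-reference p multiplied by the number of
distinct references after collapse (3 on these grids) and capped at 1.
Observed ties contribute sign 0 (midrank-equivalent), so a constant
series has S = 0 and p = 1; with observed ties present the no-tie null is
slightly conservative. Because the statistic is a rank statistic, p is
invariant under strictly monotone transforms, so whether it is fed raw or
max-normalized values is immaterial.

**Consensus.** Fourier pass: F24 > 0.5 ∧ amplitude > 2 ∧ mean > 5 RPM.
Rank-test pass: p < 0.05 ∧ the same amplitude and mean cutoffs. Both →
HC, exactly one → LC, neither → none. The two methods are correlated, so
no independence assumption is made about the joint false-positive rate;
calibration is checked empirically (see below).

## Phase analysis

Histograms bin F24 phases into 2-h bins aligned to ZT0 over [0, 24)
(width configurable; it must divide 24). Binning is circular in the sense
that near-midnight phases fall in the first/last bins without pooling.
Percentages are over cyclers with defined phase and sum to 100. F24 phase
is used for all confidence classes, including LC cyclers detected only by
the rank test (the rank test's lag grid is coarser than the Fourier
phase). The core-clock summary is the circular mean (resultant-vector
angle) of the available subset of *vri*, *Pdp1*, *per*, *tim*, with
missing genes logged. Overlap tables are plain set arithmetic on gene
ids, so inclusion–exclusion identities hold exactly; an optional
annotation counts single-group cyclers not expressed (> 5 RPM) in the
other groups. The morning/evening comparison takes LNv cyclers with phase
in ZT [3, 8] or [14, 19] (closed intervals — a phase of exactly 8 h is
morning; genes outside both bins are excluded), and compares their
l-LNv/s-LNv ratios on the log2 scale (symmetric in the two subtypes) with
a two-sided Welch t-test (Student available via flag); a bin with fewer
than two genes is an error. Ratio semantics: < 1 means higher in s-LNvs.

## Synthetic-data generator

The generator's defaults are the study conditions: 2,000 genes, the
4-group × 2 × 6 design above, 10% cyclers per group at amplitude fold 4,
uniform phases (unimodal/bimodal wrapped-normal mixtures available), 20%
group-restricted genes, 10% low-expression genes, 10⁶ reads per library.

- **Mean model**: `m(t) = b·(1 + β·cos(2π(t−φ)/24))`, `β = (a−1)/(a+1)`,
  so the time average is the baseline `b` and peak/trough is exactly `a`;
  phase is the ZT of the cosine peak.
- **Abundance**: a gene's baseline is drawn once (log-normal, log-sd 1.2)
  and shared across the groups that express it, mirroring the cross-cell-
  type correlation of real transcript abundance; group-restricted genes
  are unexpressed (< 2 RPM) outside a random proper subset of groups;
  low-expression genes sit at 1–8 RPM, below the 10-RPM filter. Expressed
  baselines are rescaled per group so expected totals are 10⁶ RPM,
  making baselines read directly as expected RPM.
- **Noise**: gamma–Poisson (negative-binomial) counts with variance
  μ + α·μ², then RPM normalization. At high expression the per-timepoint
  CV ≈ √α; the default α = 0.04 (CV ≈ 0.2) is a **stand-in** — the noise
  model of real low-input libraries is not known, only that their
  replicate correlation is low — chosen because pure Poisson noise
  under-models that variability. Replicate sets are two independent days:
  identical mean model, independent noise. α = 0 yields the noiseless
  mean model with no count sampling.
- **RPM coupling**: per-sample normalization makes genes compete for the
  library, so a cycling gene's realized RPM ratio deviates from its
  programmed amplitude by the sample-total fluctuation (typically ~1%
  with uniform phases). The peak/trough = amplitude-fold identity is
  exact at the mean-model level (`cosine_mean_model`) and holds to ~1% on
  noiseless matrices.
- **Reads**: per-gene read counts are multinomial in the programmed RPM;
  each read picks an isoform uniformly and a 3'-end distance from the
  isoform 3' end ~ Exponential(decay length, default 100 bp; truncated at
  the transcript length), projected through exons. A decay length well
  below 300 bp concentrates ≥ 95% of reads in the terminal windows.
- **l/s-LNv ratios**: log2 ratios are normal with mean −e/2 for
  morning-phase LNv cyclers, +e/2 for evening-phase, 0 otherwise
  (programmed effect e, default 1 log2 unit, sd 0.8).

What the generator does **not** emulate: sequence-level artifacts
(adapters, rRNA, mapping errors), amplification jackpots, cell-number
variation between sorts, intra-group cell heterogeneity, and cross-gene
correlation beyond the RPM sum constraint. Tests passing on this
synthetic data therefore establish the correctness and calibration of the
statistics under the declared model, not performance on real libraries.

## Empirical guarantees exercised by the test suite

The acceptance tests (tests/test_acceptance.py) verify, at the study
design and scale above: the published worked example of the
common-enrichment rule (18 rows retained, distractor rejected); agreement
of the exact rank-test null with a 10⁵-draw permutation oracle over 50
random series and a ≤ 5% + 2 SE rejection rate on 2,000 simulated
non-cyclers; the F24 closed forms; HC sensitivity ≥ 0.8, HC
false-positive fraction ≤ 0.05 and phase recovery within 2 h for ≥ 90% of
detected cyclers; enrichment recovery of strongly programmed
group-specific genes (≥ 90% sensitivity, ≤ 5% false labels) with ANOVA
type-I error within 2 points of nominal; and quantifier rank correlation
≥ 0.95 at 10⁶ reads. Problem sizes (2,000 genes, 10⁵ permutation draws,
10⁶ reads) were chosen to make Monte-Carlo error small relative to the
asserted margins while keeping the suite quick to run.

## Numerical and degenerate-input conventions

- Coordinates are 0-based half-open internally; GTF's 1-based closed
  intervals are converted on read. GTF and BED12 encodings of the same
  gene yield identical models.
- Sample metadata lives in pipe-delimited column headers
  (`sample_id|group|replicate_set|zt`); a sidecar metadata TSV is also
  accepted.
- All-zero series: F24 = 0, phase NA, amplitude 1, rank-test p = 1.
- Floors: 0.1 RPM for fold-change denominators and amplitude troughs.
- Determinism: identical config + seed give byte-identical generator
  output; counting is order-independent; the exact-null cache is keyed by
  tie structure only.

## Known limitations

- The exact rank-test null assumes distinct observed values; with ties it
  is conservative. At RPM resolution ties are rare except for zeros.
- The Bonferroni factor over references makes the rank test conservative
  relative to its nominal level (observed null rejection ≈ 2% at
  α = 0.05); HC calibration is asserted directly rather than derived.
- Tukey p-values come from an interpolation table clipped to
  [0.001, 0.9]; exact tail values beyond the clip are not reported.
- The enrichment statistics treat RPM values as approximately normal
  within groups; at very low expression (near the 10-RPM filter) the
  count noise is markedly skewed and the ANOVA is only approximate.
- Phase resolution is limited by the 4-h grid; programmed-vs-recovered
  phase agreement is asserted at the ±2 h (one grid step) level.
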