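# neurocycle

Cell-type-resolved circadian RNA-seq analysis for time-course profiling of
small, sorted neuron populations — the *Drosophila* clock-neuron setting:
three circadian neuron groups (LNv, LNd, DN1) plus a dopaminergic (TH)
outgroup, each profiled as two independent six-timepoint circadian time
courses at 4-h spacing (LNv/LNd/TH at ZT2–ZT22, DN1 at ZT3–ZT23).

The package implements the full pipeline and a synthetic-data generator
that emulates the study design, so every stage is testable without any
sequencing data:

- **quantify3p** — 3'-end tag quantification: read 3' positions counted in
  300-bp windows anchored at every distinct isoform 3' end (spliced
  coordinates projected to the genome, overlapping windows merged),
  normalized to reads per million (RPM). Terminal windows remove
  gene-length bias in 3'-biased, oligo-dT-amplified low-input libraries.
- **enrichment** — differential expression between neuron groups:
  expression filter (mean ≥ 10 RPM in *both* replicate time courses),
  2-fold pre-screen, one-way ANOVA (p < 0.05) across the four groups,
  Benjamini–Hochberg correction, Tukey HSD post-hoc per pair; rule engine
  for "common circadian" transcripts (≥ 5-fold over TH in ≥ 2 of 3
  circadian groups) and "group-specific" transcripts (> 5-fold over one
  circadian group and > 2-fold over the other, all pairs significant),
  plus a structural pre-filter for candidate neuropeptide genes (short,
  intronless, enriched).
- **cycling** — dual-method rhythmicity detection on each 12-point series
  (two max-normalized 6-point sets, concatenated as two 24-h days):

  - *F24*: power at the 24-h Fourier harmonic over total non-DC power,
    `F24 = |X₂|² / Σₖ₌₁..₆ |Xₖ|²`, with peak phase from the 24-h
    component's argument in absolute ZT;
  - *JTK-style rank test*: Kendall's S between the observed series and
    lagged 24-h cosine references, with the exact null distribution of S
    for the tie-grouped references computed by Gaussian-binomial
    convolution; two-sided per-lag p, Bonferroni over distinct references.

  A transcript passes a method iff its score clears the cutoff (F24 > 0.5
  or exact p < 0.05) *and* peak/trough amplitude > 2 *and* mean > 5 RPM.
  Both methods → high-confidence (HC) cycler; exactly one → low-confidence
  (LC).
- **phase_analysis** — phase histograms with circular binning, circular
  mean phase of the core clock genes (*vri*, *Pdp1*, *per*, *tim*),
  cross-group overlap/intersection tables, and the Welch t-test comparing
  l-LNv/s-LNv expression ratios of morning-phase (ZT3–8) vs evening-phase
  (ZT14–19) cyclers (ratio < 1 ⇒ higher in s-LNvs).
- **synthetic_data** — the generator: cosine mean model
  `m(t) = b·(1 + β·cos(2π(t−φ)/24))` with `β = (a−1)/(a+1)` so peak/trough
  equals the amplitude fold `a` exactly; negative-binomial (gamma–Poisson)
  counts normalized to RPM; group-restricted and low-expression gene
  classes; exponential-decay 3'-biased read placement; programmed
  morning/evening l/s-LNv ratio effects.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (seed 1, 2,000 genes, 10% cyclers at amplitude fold 4, per-timepoint
CV ≈ 0.2):

```sh
python analysis/01_simulate.py
python analysis/02_quantify.py
python analysis/03_enrichment.py
python analysis/04_cycling.py
python analysis/05_phase.py
```

which prints, among other lines:

```
quantified 250 genes from 1000000 reads; Spearman rho (programmed vs quantified RPM) = 0.9995; column sum = 1000000.0
common-circadian transcripts: 77; group-specific: {'DN1': 53, 'LNd': 49, 'LNv': 55}
worked example: 18/19 published+distractor rows retained by the >=5-fold-in-two-groups rule (distractor rejected: True)
LNv: HC=168 LC=10 sensitivity=0.882 false-positive=0.0017 phase-within-2h=0.994
three-way HC intersection: 3; cycling in exactly one group: 404, two: 51, three: 3
morning vs evening l/s-LNv ratio: t=-5.41, p=7.13e-07 (morning median 0.65, evening median 1.48)
```

Reading the numbers: the quantifier recovers programmed abundances almost
perfectly from 3'-biased reads; the enrichment rule engine keeps all 18
published common-circadian rows and rejects a synthetic distractor; the
HC consensus detects ~88% of programmed cyclers with a false-positive
fraction well under 1% and phases within one grid step; most cycling is
group-specific; and the programmed s-LNv bias of morning-phase cyclers is
detected (medians on opposite sides of 1).

The same pipeline is available as a CLI:

```sh
neurocycle run-all --seed 1 --out-dir out/
neurocycle simulate|quantify|enrich|cycle|phase --help
```

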