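# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate, and
the numerical choices a maintainer should know about. No empirical claim is
made here beyond what the test suite and `scripts/acceptance.py` compute.

## Peptide tiling

Proteins are tiled into k-mers (default 15) stepped by a fixed offset
(default 3), the layout used when an epitope screen synthesises its peptide
library. Coordinates are 1-based inclusive and tiles are named
`<parent>_<start>-<end>`; trailing residues that cannot fill a complete
window are dropped, because fixed-length synthesis produces no short
terminal peptide. The tile count is therefore `floor((L−k)/offset)+1`.
Sequences are restricted to the 20 canonical residues plus X at parse time
— the synthesis alphabet. Binding cores are 9-mers placed at the leftmost
occurrence inside a tile (a repeated core triggers a warning, not an
error), and register positions P1–P9 carry absolute residue indices so a
structural register can be cross-referenced against the parent numbering.

## Epitope stability scoring

Two-timepoint binding reads are interpreted under one-phase dissociation
`Y = Y0·exp(−k·t)`, giving `k = −ln(Y/Y0)/t`, `t½ = ln2/k` and the
Stability Index `SI = t½·Y0/100`. Scores are percentages of a
positive-control epitope and may exceed 100.

Degenerate inputs are mapped, not rejected: a late read at or above the
initial read (k ≤ 0, where the half-life is undefined) is assigned the cap
`t_half_cap`, default **96 h** — four times the 24 h assay horizon — so the
ranking stays total; assay noise can inflate the late read, so growth is
treated the same as no decay. The cap also binds on *near-zero* positive
decay: without that, a peptide losing a fraction of a percent over 24 h
would be assigned an extrapolated half-life of hundreds of hours and
outrank a capped non-decayer, and the score would not be monotone in the
late read. With the cap binding everywhere, SI is non-increasing in Y24 at
fixed Y0 and proportional to Y0 at fixed decay ratio, which is exactly the
weighting intent: a weakly binding peptide cannot outrank a strong binder
of equal half-life. Ties in SI are broken by higher Y0, then name, so
ranking is deterministic.

The screen's "% binding" column is reported as Y0 (the 0 h read); whether a
published screen would use the 0 h, 24 h or maximum read is an assay
convention the data do not disclose, and the choice is flagged in the
output rather than hidden.

## Scatchard affinity estimation

The titration design is seven twofold serial dilutions from 5 nM plus a
0 nM well. Free ligand is approximated by the nominal staining
concentration — no depletion correction — matching how bound/free is
plotted in practice. If a 0 nM well exists its MFI is subtracted from all
points as background and the well is excluded from the fit; points whose
background-subtracted bound signal is ≤ 0 are dropped with a warning, and
at least 3 usable points are required. The fit is *unweighted* ordinary
least squares of bound/free on bound ("line of fit", no weighting), with
`K_D = −1/slope` and `B_max = −intercept/slope`; a non-negative slope
yields no estimate and a `non_binding` flag. On noiseless one-site data
the linearisation is exact — for any K_D, including ones far above the top
concentration — which is what the round-trip acceptance checks exploit.
Under multiplicative noise the Scatchard transform is known to bias
low-signal points; the tests therefore assert median recovery (within 15%
at CV 10% over 200 replicates), not unbiasedness.

## Clonotype aggregation

Contigs are kept when productive and high-confidence; within each
(barcode, chain) the highest-UMI contig wins, with ties resolved to the
lexicographically smallest nucleotide CDR3 so the rule is deterministic —
cells with two productive chains of one locus are resolved, not discarded.
Only cells retaining exactly one TRA and one TRB survive. Clonotype
identity is the paired (V gene, J gene, nucleotide CDR3) key — nucleotide
rather than amino-acid granularity, matching the common single-cell
convention. Ranking is by descending clone count with key-based
tie-breaks; frequencies are computed over paired cells, so counts are
conserved and the output is invariant to input row order.

## Negative binomial exact differential expression

The test is the classical exact construction for overdispersed counts:

1. **Equalization.** Library sizes are equalized by total-count scaling:
   each cell's counts are divided by its depth over the geometric-mean
   depth and rounded to integers. No quantile or trimmed-mean adjustment
   is applied.
2. **Pseudo-sums.** Each group's counts for a gene are collapsed to a sum;
   a sum of n iid NB(μ, α) variables is NB with mean nμ and dispersion
   α/n.
3. **Exact p-value.** Conditional on the observed grand total, the
   two-sided p-value sums the probabilities of all splits no more probable
   than the observed one (minimum-likelihood rule, with a 1e−10 relative
   tie guard). At dispersion 0 this reduces exactly to the two-sided
   binomial (Poisson) test, and for small totals it is checked against
   exhaustive enumeration.
4. **Dispersion.** Per gene, method of moments on normalized counts:
   `α = max(0, (var − mean)/mean²)` with the sample variance, 0 at the
   Poisson boundary. In the two-group pipeline the estimate is computed
   within each group and combined with degrees-of-freedom weights, so a
   real between-group difference is not absorbed into the dispersion. No
   shrinkage across genes is applied. Dispersions below 1e−10 are
   evaluated as Poisson: the distributions are numerically
   indistinguishable there and a size parameter of 1/α ≳ 10¹⁰ degrades the
   NB pmf.
5. **Multiplicity.** Benjamini–Hochberg step-up,
   `q(i) = min_{j≥i} m·p(j)/j` clipped at 1, returned in input order.

Known limitation: total-count equalization is subject to composition bias
— when a sizeable fraction of counts is truly differential, null genes
acquire a small apparent shift in the opposite direction, so the realized
false-discovery proportion in strongly perturbed simulations can exceed
the nominal BH level even though type-I error on fully null data is
calibrated (the packaged null simulation holds the p < 0.05 fraction in
[0.03, 0.07]). Equivalence with any particular vendor pipeline's volcano
plots is not claimed.

## Suppression and dose–response statistics

Percent suppression is `(alone − with)/alone × 100` on proliferation
percentages; it is scale-invariant, undefined at a zero baseline (error),
and negative values (enhancement) are reported as-is because clipping
would destroy information. A separately named variant,
`percent_suppression_mfi`, scores suppression as the relative *increase*
of proliferation-dye MFI over the no-Treg baseline — dye is retained when
division is suppressed — because both definitions are in circulation and
they differ. Potency ratios are plain folds of two suppression values.
Dose–response summaries group replicate MFI reads by (marker,
concentration), never pooling markers, report the sample SD (0 and a flag
for singletons), and carry log10 axis labels (−inf for the no-peptide
control).

## Renal-injury scoring

Per-glomerulus rules, all thresholds inclusive: segmental necrosis ⇔
PAS-positive fraction ≥ 0.5; crescent ⇔ ≥ 2 cell layers in Bowman's
space; mesangial proliferation ⇔ ≥ 3 clumped nuclei. Per-field (hpf)
tubulointerstitial injury scores 1 if any of infiltrate, tubular
dilation, necrosis or protein casts is present. Kidney summaries are
percentages over glomeruli / fields plus the mean cells per glomerular
cross-section; sampling below 20 glomeruli or 20 fields attaches QC flags
rather than rejecting the kidney, since the 20-unit minimum is a
data-collection guideline, not a computability constraint. The
tubulointerstitial summary is reported as % of fields scored 1 — the only
statistic computable from a per-field binary score, even where narrative
summaries phrase it as "% area affected". Selection of consecutive
equatorial glomeruli is the data collector's responsibility; only the
count is checked.

Dipstick proteinuria maps to the ordinal scale 0 (negative/trace),
1 (0.30 g/L), 2 (1 g/L), 3 (3 g/L), 4 (≥ 20 g/L). Numeric readings are
binned into half-open intervals with inclusive lower edges anchored at the
printed breakpoints, so each anchor maps to its own score and the mapping
is monotone.

## Synthetic-data generators

All generators draw from `numpy.random.default_rng(seed)` and are
byte-identical under a fixed seed and configuration.

* **Binding screen** — default 145 peptides (a typical three-protein
  15-mer/offset-3 library), half-lives lognormal with median 6 h and
  initial scores lognormal with median 20% of the positive control, so
  most tiles bind weakly as in a real screen; decay is exact
  `Y24 = Y0·2^(−24/h)` with optional multiplicative lognormal noise on the
  late read.
* **Titration** — one-site binding on the 8-point design; multiplicative
  lognormal noise (mean-one parameterisation) and optional additive
  background at all wells.
* **Repertoire** — planted clonotypes with specified cell counts (default
  59, 16, 13 — a dominant clone several-fold above the next two) plus 200
  background singletons; optional low-UMI duplicate chains, unpaired cells
  and non-productive contigs exercise every filtering rule without
  changing the planted counts.
* **Counts** — NB gene-by-cell counts, lognormal base means (median 5
  counts/cell), shared dispersion 0.15, 20 + 20 cells; planted
  fold-changes multiply group-A means on a named gene subset.
* **In vivo cohort** — per-glomerulus necrosis and mesangial events are
  Bernoulli with group-specific probabilities, expressed as PAS fractions
  / clump sizes on the correct side of the scoring thresholds; cell counts
  are Poisson; each hpf flags injury with a group probability; the ordinal
  proteinuria score is drawn as Binomial(4, mean/4), whose expectation is
  exactly the configured group mean, and emitted as the corresponding
  dipstick reading. The three disease groups (5 mice each) use the
  published week-8 group means — untreated 75.2% necrotic / 39.8
  cells/gcs / 62% mesangial / 50% tubulointerstitial / proteinuria 3.6;
  polyclonal-Treg 61.2 / 37.8 / 59% / 50% / 3.2; antigen-specific-Treg
  14.4 / 25.8 / 14% / 10% / 1.2 — and the healthy-control group (4 mice),
  whose histology means are not published, uses near-zero event rates
  (0.01), 20 cells/gcs and proteinuria mean 0.25. Crescents are not
  generated (Bowman layer count 1), matching their absence in the modelled
  disease course.

What the generators do **not** emulate: batch effects, plate-position and
spectral-spillover artefacts in fluorescence; doublet transcriptomes and
ambient RNA beyond simple duplicate-chain contamination; gene–gene
correlation and zero-inflation structure of real single-cell data;
antibody-mediated pathology in vivo (the modelled mouse strain does not
engraft B cells long-term). Passing tests therefore demonstrate that the
estimators recover the parameters of their own generating laws at the
study's design points — not that those laws capture every feature of real
assay data.

## Problem sizes and numerical choices

The packaged simulations use desk-scale sizes chosen to make Monte-Carlo
assertions sharp: 200 replicate titrations for noise-recovery medians,
2000 null genes for type-I calibration, 500 genes with 50 planted 4-fold
genes for power, cohorts of 5 mice × 50 (or 20) glomeruli for histology
recovery, asserted within 3 binomial/Poisson standard errors. Exact-test
enumeration is vectorised in log space (`logsumexp`); probability-tie
comparisons use a 1e−10 relative guard; the degenerate flat-MFI Scatchard
input short-circuits to a zero slope rather than a singular regression;
table sorts use stable mergesort so tie-breaks are reproducible.
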