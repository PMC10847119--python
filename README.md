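# immunoquant

Quantification stack for developing antigen-specific regulatory T-cell
(Treg) therapies for autoimmune disease — from autoantigen epitope
screening through T-cell receptor (TCR) selection to preclinical efficacy
readouts. It is aimed at translational immunologists who need the desk-side
numbers of such a pipeline to be reproducible: epitope stability scores,
apparent dextramer affinities, clonal-expansion rankings, differential
expression of clonotype-bearing cells, suppression-assay statistics and
semi-quantitative renal-injury scores.

Because the wet-lab inputs (plate reads, flow cytometry MFI exports,
single-cell contig tables, histology observations) are rarely shareable,
every stage ships with a seeded synthetic-data generator that emulates the
assay's statistical structure, so the whole pipeline is testable end to end
without downloads.

## What it computes

**Epitope stability.** MHC-II binding screens read a peptide–HLA binding
signal (as % of a positive-control epitope) at 0 h and 24 h. Under
one-phase dissociation Y = Y₀·e^(−kt),

    k = −ln(Y/Y₀)/t,   t½ = ln 2 / k,   Stability Index = t½ · Y₀ / 100,

ranking candidate epitopes while down-weighting weak binders.

**Apparent affinity.** Dextramer titrations (seven twofold dilutions from
5 nM plus a 0 nM background well) are fitted by Scatchard linearisation of
one-site binding B(c) = B_max·c/(K_D + c): ordinary least squares of
bound/free on bound gives K_D = −1/slope and B_max = −intercept/slope.

**Clonal expansion.** Single-cell V(D)J contigs are filtered to one
productive TRA and TRB per cell and aggregated into paired clonotypes
(V gene, J gene, nucleotide CDR3 on both chains), ranked by clone count.

**Differential expression.** Clonotype-vs-rest contrasts use a negative
binomial exact test on library-equalized pseudo-sums (method-of-moments
dispersion, minimum-likelihood two-sided rule), with Benjamini–Hochberg
correction.

**Functional readouts.** Percent suppression
(prolif_alone − prolif_with)/prolif_alone × 100, fold-potency ratios, and
dose–response summaries of activation-marker MFI; ordinal dipstick
proteinuria scoring and per-glomerulus/per-field renal histopathology
scoring (segmental necrosis, crescents, hypercellularity, mesangial
proliferation, tubulointerstitial injury).

## Worked example

```python
from immunoquant.simulate import gen_reveal_dataset, gen_titration
from immunoquant.stability import RevealMeasurement, rank_peptides
from immunoquant.affinity import fit_scatchard

# rank a synthetic 145-peptide screen by Stability Index
df = gen_reveal_dataset(seed=7, parent_id="SmBB")
ms = [RevealMeasurement(r.peptide_name, r.y0, r.y24, r.t) for r in df.itertuples()]
print(rank_peptides(ms, top_n=5).head(5)[
    ["peptide_name", "y0", "t_half", "stability_index", "rank", "selected"]
].to_string(index=False))

# recover a receptor's affinity from a noiseless titration
fit = fit_scatchard(gen_titration(seed=0, kd=0.3910, bmax=3157.0, label="TCR1"))
print(f"{fit.label}: KD = {fit.kd:.4f} nM, Bmax = {fit.bmax:.0f} MFI, r2 = {fit.r2:.6f}")
```

prints

```
peptide_name         y0    t_half  stability_index  rank  selected
SmBB_268-282 151.546614 10.117132        15.332172     1      True
SmBB_382-396 111.911001 11.811177        13.218006     2      True
SmBB_148-162  34.384852 29.728099        10.221963     3      True
SmBB_175-189  47.911300 18.964666         9.086218     4      True
SmBB_322-336  75.890546  8.901058         6.755061     5      True

TCR1: KD = 0.3910 nM, Bmax = 3157 MFI, r2 = 1.000000
```

The top table is the screen's shortlist: the five tiles (named
`<parent>_<start>-<end>`) whose peptide–HLA complexes combine strong
initial binding (y0, % of the positive control) with a long half-life
(t_half, hours). The titration fit recovers the generating affinity
exactly because Scatchard linearisation is exact on noiseless one-site
data — the round-trip validates the estimator, and r² = 1 confirms the
transform linearised the curve.

The same stages are available from a shell:

```bash
immunoquant simulate reveal --out sim --seed 7
immunoquant rank-epitopes sim/reveal.tsv --out ranked --top-n 5
immunoquant simulate repertoire --out rep --seed 42
immunoquant clonotypes rep/contigs.tsv --out clones
```

Each run writes its outputs as TSV plus a `manifest.json` recording the
tool version, seed and parameters.

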