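# epismoke

An integrative epigenomics pipeline for two-condition H3K27Ac ChIP-Seq peak
comparison coupled to time-course gene expression, built around the study
design of differentiated human bronchial epithelial (HBE) cells cultured at
air–liquid interface and exposed to cigarette smoke (CS) versus air. The
package is aimed at analysts who have peak lists with per-condition read
counts, a TSS annotation, an expression matrix with a repeated-measures
sample sheet, and want a tested, reproducible route from "which chromatin
regions changed" to "do early chromatin changes predict later expression
changes".

## What it computes

**Peak classification and normalization.** Peaks called in the two
conditions are classified by ≥1 bp interval overlap (BED half-open
convention) into *air-unique*, *smoke-unique* and *common* peaks; overlap
partners merge into the union interval with counts summed per condition.
For each peak, with pseudocount c = 0.5,

    M = log2((x_smoke + c) / (x_air + c)),
    A = ½ · log2((x_smoke + c) · (x_air + c)).

A robust (Huber IRLS) line M ~ a + b·A is fitted on common peaks only —
regions marked in both conditions should show no systematic difference, so
their M-on-A trend measures depth/intensity bias — and subtracted from every
peak's M (`M_norm`). Significance comes from an exact conditional binomial
test: after symmetric rescaling of the two counts by 2^(∓trend/2), their
split given the total is Binomial(n, ½) under an equal-rate Poisson null.

**Annotation.** Each peak is assigned to the nearest TSS by midpoint
distance, with signed distances (upstream negative relative to gene strand)
and proximity zones: proximal |d| ≤ 1 kb, distal 1–100 kb, remote > 100 kb.
Read-filtered external region sets (count > threshold in every sample) can
be intersected with the classified peaks.

**Enrichment.** Known-motif over-representation uses log-odds PWM scanning
with zero-or-one-occurrence-per-sequence (ZOOPS) counting against an
explicit background set, a one-sided hypergeometric test and BH FDR;
motifs are *selected* when present in ≥ 5% of target sequences with fold
change > 1.1 and q < 0.1. Gene-set over-representation uses the same exact
test against a supplied universe, with the display filters: set size
< 2000 members, BH-corrected p < 0.01, coverage (k/n) ≥ 10%.

**Expression statistics.** Per-gene location/scale batch adjustment; per-day
pooled-variance t-tests of smoke vs air; and a per-gene random-intercept
linear mixed model

    y_ij = β0i + β1·trt_i + β2·time_j + β3·trt_i·time_j + e_ij,
    β0i ~ N(0, σ²_subject),  time ∈ {1, 2, 4} days,

fitted by maximum likelihood with a 1-D profile over the variance ratio; the
treatment × time interaction β3 is tested by likelihood ratio (mapped to a
finite-sample F reference) with BH FDR at q < 0.1.

**Integration (meta-T).** For each day and peak class/zone, the per-day DE
t statistics of peak-associated genes are compared with those of all other
genes by a pooled two-sample t — the *meta-T*. A negative meta-T means the
peak-linked genes are more smoke-repressed than the rest of the
transcriptome that day.

A first-class synthetic-data module generates every input with planted
structure (peak classes, a planted motif, a planted day-1-repressed /
day-4-induced expression trajectory on smoke-unique-proximal genes) plus an
exhaustive ground truth, so the whole pipeline is testable end to end
without any downloads.

## Worked example

```python
import numpy as np
from epismoke.simulate import SimConfig, simulate_all
from epismoke import peaks as pk, annotate as ann, expression as expr, integrate as integ

data = simulate_all(SimConfig(seed=1))          # default study conditions
classified = pk.classify_peaks(data.air_peaks, data.smoke_peaks)
pk.annotate_ma(classified)
fit = pk.fit_ma_normalization([p for p in classified if p.label == "common"])
pk.normalize_and_score(classified, fit)

labels = [p.label for p in classified]
print(f"classes: {labels.count('air_unique')} air-unique, "
      f"{labels.count('smoke_unique')} smoke-unique, {labels.count('common')} common")
print(f"M-A fit: intercept={fit.intercept:.3f} slope={fit.slope:.4f}")
print(f"median M_norm (common): "
      f"{np.median([p.m_norm for p in classified if p.label == 'common']):.4f}")

assignments = ann.assign_nearest_tss(classified, data.annotation)
study = expr.batch_adjust(data.study)
de = {d: expr.per_day_de(study, d) for d in (1, 2, 4)}
sets = {z: integ.peak_gene_sets(assignments, classified, z)
        for z in ("proximal", "distal")}
grid = integ.integration_grid(de, sets)
sub = grid[(grid.peak_class == "smoke_unique") & (grid.zone == "proximal")]
print(sub[["day", "n_in", "meta_t", "p"]].to_string(index=False))
```

This prints (seed 1):

```
classes: 50 air-unique, 150 smoke-unique, 100 common
M-A fit: intercept=0.682 slope=-0.0231
median M_norm (common): -0.0035
 day  n_in     meta_t            p
   1    62 -13.640246 5.012796e-35
   2    62  -3.757867 1.970044e-04
   4    62  13.074002 9.559797e-33
```

All 300 planted peak classes are recovered; the fitted intercept absorbs the
simulated global depth offset, leaving the common peaks centred
(median M_norm ≈ 0); and the meta-T for smoke-unique proximal genes flips
sign from strongly negative on day 1 to strongly positive on day 4 — the
planted "early chromatin opening precedes later induction" trajectory.

The same pipeline is available from the shell:

```bash
epismoke run-all --config config.yaml --outdir out/
```

where the YAML config names the seed, simulation parameters and thresholds;
stage-wise subcommands (`simulate`, `classify-peaks`, `annotate`,
`motif-enrich`, `de-test`, `lmm-interaction`, `geneset-enrich`, `integrate`)
operate on the emitted TSV/FASTA/GMT files.

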