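# Methods

## Scope and data model

The pipeline links a two-condition (air vs cigarette smoke) H3K27Ac ChIP-Seq
peak comparison to a two-arm, three-timepoint (day 1/2/4) expression study
with repeated measures per subject. It starts from peak lists with
per-condition read counts (peak calling is upstream), a gene/TSS table, peak
and background sequences, PWMs, an expression matrix plus sample sheet
(subject, treatment, day, batch), and a gene-set catalog. All genomic
coordinates are BED-style 0-based half-open; two intervals overlap iff they
share at least one base. No raw-read handling, liftover or ontology-graph
expansion is implemented.

## Peak comparison

**Classification.** Each condition's peak list is first merged internally
(overlapping intervals union, counts summed). Across conditions, any
transitive chain of ≥1 bp overlaps collapses into a single *common* peak
spanning the union interval with counts summed per condition per member;
peaks with no cross-condition partner become *air-unique* / *smoke-unique*.
Union merging (rather than intersection trimming) was chosen because it
keeps the output a partition of the input: every input peak belongs to
exactly one output peak, so |air inputs| = |air-unique| + (air members of
common peaks), an accounting identity the tests enforce.

**M–A transform.** M = log2((x_smoke+c)/(x_air+c)),
A = ½·log2((x_smoke+c)(x_air+c)) with pseudocount c = 0.5 (avoids log 0;
exposed in the CLI).

**Normalization.** Robust line M ~ intercept + slope·A fitted on common
peaks only, by Huber IRLS: tuning constant 1.345, coefficient-change
tolerance 1e-8, at most 50 iterations, scale re-estimated each iteration as
1.4826·MAD of residuals. Two numerical guards matter in practice: an
exact-fit short-circuit (all residuals ≈ 0 relative to the response scale),
and a degenerate-MAD fallback — when more than half the points lie exactly
on one line the MAD is zero although outliers remain, so the scale falls
back to the normal-consistent mean absolute deviation and is then *frozen*
so the iteration remains a contraction. Requires ≥ 3 finite common-peak
points; non-convergence raises with the last coefficient change.

**Significance.** The fitted trend t(A) is removed symmetrically:
x̃_smoke = x_smoke·2^(−t/2), x̃_air = x_air·2^(+t/2), rounded to integers.
Under an equal-rate Poisson null the split of n = x̃_air + x̃_smoke is
Binomial(n, ½); the reported p is the exact two-sided tail (sum of outcome
probabilities no larger than the observed one; p = 1 when n = 0). Ranking
within a class orders by p ascending, then |M_norm| descending, then
coordinate.

## TSS annotation

The peak reference point is the interval midpoint, floor((start+end)/2) —
no summit information is required. The assigned gene minimizes |midpoint −
TSS| on the same chromosome; ties go to the lexicographically smaller gene
id (determinism). Distances are signed by gene strand so upstream is
negative. Zones: proximal |d| ≤ 1,000 bp, distal |d| ≤ 100,000 bp, remote
beyond; boundary values are inclusive in the nearer zone ("within" read as
≤). Peaks on chromosomes absent from the TSS table are reported with no
gene and zone *remote*, with a warning. Region-set comparison retains
regions with count strictly greater than the threshold (default 10) in
every sample of that set, then intersects by ≥1 bp and reports per-class
membership categories (both / single-set-only / neither) and percentages.

## Motif enrichment

PWMs are per-column probability matrices (count matrices are normalized on
read with pseudocount 0.5 per cell). Scanning scores every window on both
strands with log2 odds against the background composition (uniform by
default); N bases score 0. A sequence is a ZOOPS hit when its best window
reaches `score_fraction` (default 0.8) of the maximum attainable score —
with sharp PWMs this keeps the chance hit rate of a 200 bp sequence at a
few percent. Sequence-level hit counts feed a one-sided hypergeometric test
of the target set against the pooled target+background universe; BH FDR is
computed over exactly the PWMs tested in one run. Selection requires target
hit fraction ≥ 5%, fold change (target rate / background rate) > 1.1 and
q < 0.1. The background set is supplied explicitly (composition-matched in
the simulator); no genome-wide background sampling is implemented.

## Gene-set enrichment

One-sided hypergeometric over-representation of a query list within each
catalog set, against the supplied universe (the expression platform /
annotation table, not the genome). Fold enrichment follows the
annotation-tool convention (k/n)/(K/N) — note this differs from the motif
module's target-vs-background rate ratio, matching how each statistic is
conventionally reported. Display selection: total set size < 2000, BH
q < 0.01, and coverage ≥ 0.10 where coverage is k/n, the fraction of the
*query* annotated to the set (the alternative k/K reading is not used). An
optional EASE-style penalty (k−1 in the p-value) is provided for
comparability with hosted tools. `fisher_2x2` reports the exact two-sided p
(summing tables with probability ≤ observed at fixed margins) and the
sample odds ratio ad/bc, ∞ when bc = 0 with ad > 0 and 1 for fully
degenerate tables.

## Expression statistics

**Batch adjustment.** Per gene: within each batch, center to the batch mean
and rescale by pooled-sd/batch-sd, then restore the global gene mean. This
equalizes per-gene batch means and spreads, is idempotent, and is a
deliberate simplification of empirical-Bayes batch correction — with only a
handful of batches there is little to shrink toward, and the
location/scale step is exactly invertible and testable. Batches of one
sample are rejected; zero-variance gene/batch cells are centered only.

**Per-day differential expression.** Pooled-variance two-sample t of smoke
vs air columns of one day (replicates of both subjects pooled within
arm), two-sided p, sign positive when smoke mean is higher. The degenerate
all-equal case returns t = 0, p = 1.

**Interaction mixed model.** Per gene, y_ij = β0i + β1·trt + β2·time +
β3·trt·time + e_ij with a per-subject random intercept; treatment coded
0/1, time coded numerically in days {1, 2, 4}; technical replicates enter
as independent within-subject observations. ML fitting profiles the
likelihood over γ = σ²_subject/σ²_noise: for fixed γ the per-group
covariance I + γJ inverts in closed form, fixed effects come from GLS and
σ²_noise from the residual quadratic form; γ is optimized on a bounded log
grid (log γ ∈ [−12, 8], Brent, xatol 1e-5) with the γ = 0 boundary checked
explicitly (negative profile optima thus clamp to OLS). β3 is tested by the
likelihood ratio of the full vs no-interaction model, both re-profiled.
The LR statistic is referred not to χ²(1) but to its exact fixed-effects
analogue F = (exp(LR/N) − 1)·df with df = N − 4 − (g−1) degrees of freedom
(g subjects): at the default design (2 subjects × 2 replicates × 2 arms ×
3 days = 24 observations) the χ² reference is visibly anti-conservative
and inflates the realized FDR of the planted-gene recovery, while the F
mapping restores calibration (null P(p < 0.05) ≈ 0.04–0.05 at both 24 and
72 observations in the test suite) and is asymptotically identical to χ².
Interaction genes are declared significant at BH q < 0.1, the threshold
used throughout. With two sides of every subject observed in both arms the
design is balanced, so fixed-effect estimates coincide with OLS whatever γ̂
— the σ_subject = 0 oracle test exploits exactly this. Genes that fail to
fit are flagged and excluded from the FDR set.

The two-sided test follows "is β3 = 0 or not"; a one-sided (β3 < 0)
variant was considered and rejected because the planted biology (repression
then induction) makes the interaction positive when expression recovers.

## Integration

Peak-class gene sets collect, per class and zone, every gene with ≥1
assigned peak of that class (a gene may sit in several class sets; set
semantics deduplicate). The meta-T for one day and one gene set is the
pooled-variance two-sample t comparing the in-set genes' DE t statistics to
those of *all other* tested genes — the out-group deliberately includes
genes carrying other-class peaks, following the literal "all other genes"
reading; a Welch variant is available by flag. Genes without a t statistic
are excluded before the comparison. The full grid covers 3 days × classes ×
{proximal, distal}. DE-set overlap against an external gene list is a
2×2 Fisher exact test within a common universe.

## Synthetic data: what it emulates and what it does not

The generator plants, by default: 100 common, 50 air-unique and 150
smoke-unique peaks on one synthetic chromosome (20 Mb, 400 genes); class
zone shares (proximal/distal/remote) of 68/29/3, 24/55/21 and 46/43/11
percent respectively; Poisson read counts around gamma-distributed
intensities (mean 100 reads) with a global log2 depth offset of 0.5 split
symmetrically between conditions and near-background counts (mean 2) for
the absent condition of unique peaks; 200 bp target/background sequences of
matched composition with one consensus motif copy planted in half of the
targets on a random strand; an expression study of 2 subjects × 2 technical
replicates × 2 arms × days {1, 2, 4} with σ_subject = 0.3, σ_noise = 0.5,
batch confounded with subject (additive shift 0.5); and a treatment
trajectory of −1 (day 1) to +1 (day 4) log-expression units, linear in day,
on 80% of smoke-unique-proximal genes. Because the trajectory is linear in
day it corresponds exactly to β1 = −5/3, β3 = +2/3 in the mixed-model
coding, so interaction recovery has a well-defined truth.

Implementation notes. Genes occupy the first 80% of the chromosome with ≥4
kb between TSSs (so proximal placements are unambiguous); the trailing
TSS-free desert makes >100 kb "remote" placements realizable. Peak
envelopes never overlap across planted units (guard gap 150 bp), which is
what makes label recovery exact; when a gene's small proximal window is
blocked by an earlier placement the sampler falls back to a distal draw.
Ground-truth gene links and zones are recorded from the *realized* geometry
by an internal brute-force nearest-TSS scan, since a distal draw can land
nearer a neighbouring gene than its target. Planted motif instances are the
PWM consensus rather than stochastic draws, so a planting rate of 1.0
guarantees a scoring window in every target. All generators are
deterministic given the seed (independent child streams per stage).

What the simulation does not model — and hence what passing tests do not
establish about real data: fragment-size and nucleosome structure, GC and
mappability bias, overdispersed (non-Poisson) counts, multi-gene regulatory
domains, probe-level microarray noise, and empirical-Bayes batch structure
across many batches. Class-wise intensity distributions are chosen for
testability, not realism.

## Default problem sizes

The test suite and the acceptance script run entirely on synthetic data at
the sizes stated above, plus: 600 common peaks for the normalization check,
10,000 peaks × 1,000 TSS for the annotation oracle, 2,000 genes × 72
samples for mixed-model null calibration, 100 seeded runs of 150 target +
500 background sequences for motif recovery, and 1,000 replicates of
2,000-gene null meta-T comparisons. A full run completes in well under a
minute on one CPU.

## Known limitations

* Single-replicate-per-condition peak counts; no multi-replicate
  overdispersion modelling in the binomial significance.
* The conditional-binomial p is exact under its Poisson null but, like all
  count-split tests, anti-conservative under biological overdispersion.
* The mixed model fits a single random intercept; random slopes or
  AR-structured within-subject correlation are out of scope.
* The location/scale batch adjustment removes batch differences exactly but
  does not shrink across genes; with many small batches an empirical-Bayes
  method would be preferable.
* Motif scanning has no positional model and reports sequence-level hits
  only; background quality is entirely the caller's responsibility.
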