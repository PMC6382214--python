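# Methods

## Scientific setting

A single-nucleotide variant that sits inside or near a miRNA precursor
hairpin (stem-loop) in the intron of a protein-coding host gene can act as
a *cis*-eQTL on two molecules at once: the host mRNA and the mature miRNA,
both processed from one primary transcript. Because stem-loop cropping by
the Drosha–DGCR8 complex competes cotranscriptionally with splicing, such
a variant can push the two read-outs in *opposite* directions even though
their transcription is shared. Detecting this in multi-population cohorts
is complicated by population stratification: allele frequencies and
baseline expression both differ between populations, so pooled association
tests can be confounded or masked. This package implements the statistical
machinery for that setting, plus generators that construct the canonical
paradox datasets exactly.

## Association panel

All genotypes are modeled additively as alternate/risk-allele counts
(0/1/2); genotype-as-factor coding is out of scope. For one
(variant, feature) pair the panel computes:

- **SLR F-test** — `expression ~ genotype` ignoring population;
  F = (regression SS/1)/(residual SS/(n−2)).
- **One-way ANOVA** on the population label.
- **Type II ANCOVA** — `expression ~ genotype + population`
  (optionally `+ genotype:population`). Type II sums of squares are
  defined by marginality-respecting model comparison: the genotype SS is
  RSS(population-only) − RSS(main effects), and likewise for population;
  the interaction is tested against the main-effects model. All F-tests
  use the residual mean square of the largest fitted model. Implemented
  via statsmodels OLS + `anova_lm(typ=2)`; the test suite checks it
  against an independent explicit two-fit least-squares oracle to 1e-8.
- **Welch t-tests** for all pairwise genotype-group comparisons
  (Satterthwaite df; groups with fewer than 2 samples are excluded).
- **Random-intercept LMM** — `expression ~ genotype` with population as a
  random effect, fitted by REML (statsmodels `MixedLM`). The genotype
  effect is a type II Wald chi-square with 1 df, (slope/SE)², without
  small-sample df corrections. Non-convergence is reported as a flagged
  result rather than an exception.
- **Correlations** — plain Pearson, and the population-adjusted (partial)
  Pearson correlation: both variables are residualized on the population
  indicator matrix by least squares and the correlation of residuals is
  referred to t with n − 2 − (levels − 1) df. The df penalty is the
  standard partial-correlation convention; the adjustment itself is
  verified against an explicit projection-matrix oracle to 1e-10.

Missing genotype or expression values are removed pairwise per test and
the n actually used is recorded in every result. Significance is a fixed
α = 0.05 throughout; no multiple-testing correction is applied in the scan
(retention mirrors a nominal-significance rule), and a Benjamini–Hochberg
adjusted column can be added downstream by the caller if desired.

Analysis scale follows the data source: log2 microarray intensities are
analyzed in log2; RPKM and normalized miRNA counts are analyzed on the
linear scale as provided. Zero miRNA counts are retained as zeros, not
excluded. The scale tag travels with every `ExpressionTable` and is
recorded in results.

## Paradox taxonomy

Computed from statistics already in the panel, with population-adjusted
correlations feeding all detectors:

- **Simpson-like masking** — ANCOVA genotype p < α while SLR p ≥ α. The
  term covers associations that *disappear* on pooling; an actual
  *reversal* (pooled slope sign opposing the shared within-population
  sign) is reported as a separate category. These decision rules are a
  reconstruction from the published behavior of such analyses, stated
  explicitly here because the original counting rule was never written
  down formally.
- **Non-transitivity** — sign(r_miR,SNP) × sign(r_host,SNP) < 0 with
  r_miR,host > 0. The positive-coupling condition reflects the biology
  (the two molecules share a primary transcript); a switch drops it.
  A correlation of exactly 0 has no sign and never fires the detector.
- **Uncoupling** — |r_miR,SNP − r_host,SNP| strictly greater than 0.2.
  The score is symmetric and invariant to negating both correlations.

## Stem-loop scan

Biallelic single-nucleotide variants are kept when their 0-based position
p satisfies `start − flank ≤ p < end + flank` with flank = 25 — a closed
bound on the biological "within 25 bases" phrasing; indels and
multiallelic records are dropped and counted. The scan is restricted to
autosomes by default. Position labels are strand-aware: `P` inside the
precursor, `+k`/`−k` for k bases downstream/upstream in transcription
orientation (on minus-strand loops the genomic left flank is downstream).
Each retained (variant, mature miRNA) pair must clear the miRNA ANCOVA
genotype test at α; 5p and 3p mature products of one hairpin are tested
separately. miRNA↔host-gene pairing is taken as annotation input, not
recomputed. Internally all coordinates are 0-based half-open; BED6 is used
as is, GFF3 (1-based closed) and VCF positions (1-based) are converted at
the I/O boundary. Re-running the scan on identical inputs is bit-identical;
there is no hidden randomness.

## qPCR and reporter quantification

Undetected wells carry the detection floor Ct = 45 and any aggregate built
from ≥1 floored well is flagged "at detection limit" (floored values are
included, not dropped). Triplicates are aggregated by mean (cohort ΔCt
convention) or median (allele-comparison convention), configurable per
analysis. Relative expression is 2^−ΔCt scaled by a cosmetic factor of
1000; every downstream statistic is invariant to that factor. The allele
comparison uses ΔΔCt = (Ct_miR − Ct_refmiR) − (Ct_precursor − Ct_refgene)
and reports 2^−ΔΔCt, rescaled so an explicitly designated baseline
condition equals 1 (the baseline is an argument because different
displays fix different conditions to 1). Signed linear fold-changes invert
and negate ratios below 1, so |FC| ≥ 1 with the sign carrying direction.
Reporter assays average duplicate luminescence reads per well, form
GLuc/SEAP ratios, normalize to the control-3'UTR cotransfection, and
compare conditions by percent change and Welch t-tests across biological
replicates.

The miRNA/host **ratio eQTL** runs the same panel on the per-sample ratio
of linear-scale values (host strictly positive). The ratio is invariant to
any per-sample factor shared by the two transcripts, which is exactly why
it can expose a processing eQTL that neither single-molecule test detects.
The ×1000 ΔCt scaling cancels in the ratio and does not affect its F-test.

## Target-screen filtering

Differential-expression statistics are consumed from an external table
(the upstream array-processing and empirical-Bayes machinery is published
tooling and deliberately not reimplemented). The candidate rule is strict
p < 0.05 with inclusive fold-change ≤ −1.5. Prioritization requires
nominal downregulation at both time points — by default nominal
significance with any downregulation (fold-change < −1), with a strict
mode applying the full −1.5 cut at both times, since the published
wording is ambiguous — plus a control-condition mean log2 signal > 10
and, where provided, a hybridization minimum free energy ≤ −15 kcal/mol.
The consensus gate requires predictions from ≥6 of 12 algorithms, with
missing values conservatively counted as failures.

## Synthetic-data generators

**Simpson design.** Two populations, three genotype groups of 60. The
per-genotype mixing weight w solves w·m1g + (1−w)·m2g = pooled mean; the
default means (15,10,5)/(30,25,20) with pooled mean 18 give cell counts
(48,28,8) and (12,32,52), i.e. population totals 84 and 96 — the risk
allele is common in one population and rare in the other. In exact mode,
cell residuals are centered and rescaled (sample sd, ddof = 1) to the
nominal residual sd, so cell means are exact to ~1e-15, every pooled
genotype mean is exactly the pooled target and the pooled regression
slope is zero, hence F = 0 and p = 1 to floating precision. The published
illustration did not state its noise model or how the exact pooled means
were enforced; exact mode is this package's reconstruction of the stated
*outcome*, chosen so the headline quantities are deterministic without a
shared seed. residual sd defaults to 2.0, which makes the per-population
associations overwhelming (p < 1e-20) while keeping the cells visually
noisy. A noisy mode (plain Gaussian residuals) exists for power studies.

**Non-transitivity design.** Genotypes are fixed and balanced (20 per
group). The two RNA vectors are built in the orthonormal centered basis
(standardized genotype ĝ, a residual direction u1, a fresh direction u2):
RNA1* = r_g1·ĝ + √(1−r_g1²)·u1 and RNA2* = α·ĝ + β·u1 + γ·u2 with
α = r_g2, β = (r_12 − r_g1·r_g2)/√(1−r_g1²), γ = √(1−α²−β²). Because the
basis is centered and orthonormal, the empirical sample correlations equal
the targets exactly for any positive-definite target and any seed; γ² < 0
identifies an infeasible target. The default triple (0.472, 0.508,
−0.471) gives α = −0.471, β ≈ 0.8284, γ ≈ 0.3032. Display location/scale
(10 ± 2) are cosmetic.

**Cohort design.** Five populations of 92/95/96/93/89 samples with risk
allele frequencies 0.86 (the four European panels) and 0.40 (YRI),
genotypes drawn Binomial(2, freq) (Hardy–Weinberg within population).
Host and miRNA values share a per-sample multiplicative expression factor
(lognormal, σ = 0.25) that stands in for the common primary-transcript /
library-size variation — this is what makes the two molecules positively
correlated while the genotype pushes them in opposite directions —
plus independent Gaussian noise (sd 1.2 / 1.0). Default slopes are −1.0
(host) and +0.8 (miRNA) per risk allele: moderate effects that keep the
zero-inflated miRNA association near the significance boundary, matching
the character of real miR-eQTLs in RNA-seq panels. miRNA measurements are
simulated on the normalized-count scale (non-negative reals with exact
zeros, not integer reads): an independent Bernoulli dropout with
probability 0.403 zeroes samples, so ≈59.7% of samples have a detected
miRNA, and negative latent values are clipped to zero. Population
baselines differ (host 9.5–12.0, miRNA 2.8–3.6) to create the population
main effect that drives the masking phenomenon.

Three named variants of the design serve specific experiments:

- `null_cohort_design()` — zero slopes *and equal baselines*. Zero slopes
  alone leave the pooled SLR confounded (populations differ in both
  expression and allele frequency — the masking scenario itself), so test
  calibration must be assessed on the fully null design. There,
  SLR/ANCOVA/LMM p-values are uniform (KS) and the scan retains ≈5% of
  pairs at α = 0.05.
- `planted_scan_design()` — slopes −1.2/+2.0, all structure parameters at
  defaults. Chosen by a priori power analysis so the post-dropout
  population-adjusted miRNA correlation is ≈0.2 and the uncoupling score
  ≈0.45: a planted effect that a recovery experiment should find
  essentially always, rather than a boundary case.
- `pcr_cohort_design()` — no dropout (PCR-grade sensitivity detects every
  sample), weak opposite slopes (∓0.5) and a large shared factor
  (σ = 0.5): the regime in which the miRNA/host ratio out-powers both
  single-feature tests because the ratio cancels the shared factor
  exactly.

## What the generators do and do not emulate

The simulators reproduce: multi-population structure with realistic panel
sizes and allele frequencies, Hardy–Weinberg genotypes, opposite-sign
additive effects on two coupled transcripts, population baseline shifts,
and zero-inflated miRNA detection. They do not emulate: linkage
disequilibrium between variants (each simulated variant is independent),
read-level sequencing noise, batch/technical covariates beyond the shared
scaling factor, heavy-tailed expression distributions, or genotyping
error. Passing tests therefore demonstrate correctness of the statistical
machinery and detectability under idealized population structure, not
performance on real RNA-seq data with LD and complex covariance.

## Numerical choices and problem sizes

- Exact-mode tolerances: cell/pooled means to 1e-10, correlation targets
  to 1e-8 (limited only by floating-point accumulation).
- The pooled SLR p-value on exact Simpson data is 1 up to ~1e-16 of
  floating-point slack in the slope.
- Cells of size 1 cannot be centered-and-rescaled; exact mode rejects
  them with a pointer to noisy mode.
- LMM fits use REML with lbfgs (powell fallback); boundary variance
  estimates (random-intercept sd → 0) are returned as is.
- Degenerate inputs (constant genotype, single group, zero residual
  variance, rank-deficient designs) raise a dedicated error type rather
  than returning NaNs.
- Calibration experiments use 500 seeds of the n = 465 cohort (KS) and
  400 null pairs for scan retention; recovery uses 200 seeds. These sizes
  give binomial standard errors well below the asserted margins while
  keeping the default test run in tens of seconds.

## Known limitations

The Simpson "reversal" subcategory requires per-population slopes to
share a sign; loci with mixed within-population signs are classified as
masked only. The LMM Wald test is asymptotic and can be anticonservative
for very few populations (here: five). The partial-correlation df
convention, while standard, is one of several in use; comparisons across
tools should match conventions. The uncoupling threshold of 0.2 is an
operational cut inherited from the analysis this package reimplements,
not an estimated quantity.
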