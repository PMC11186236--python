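# Methods

## Scope and pipeline

`targetmr` implements a proteome-wide drug-target screen on GWAS summary
statistics. Per protein and per pQTL discovery source: cis-window extraction
(gene body ± 1 Mb, 1-based inclusive at both boundaries), instrument selection
at the source's significance threshold, allele harmonization against the
outcome, optional LD clumping / sentinel-only restriction, the Steiger
directionality filter, and two-sample MR (Wald ratio for one instrument,
fixed-effect IVW otherwise, MR-Egger attached as a pleiotropy diagnostic).
Benjamini–Hochberg FDR is applied within each source; proteins significant
(q < 0.05) in at least one source and estimated in at least two are combined
by fixed-effect inverse-variance meta-analysis, otherwise the most precise
single-source estimate is carried forward. Survivors are corroborated by SMR
+ HEIDI in each eQTL tissue, by ABF colocalization of the protein and outcome
regional signals, and by MR across a 17-outcome replication panel, then
graded: tier 1 = MR + SMR + coloc, tier 2 = MR plus exactly one, tier 3 = MR
only. Network/enrichment annotation, druggability lookup, and figure drawing
are outside the package's scope.

## Modeling choices and defaults

**Harmonization.** Same allele order kept; swapped alleles flip the outcome
beta and EAF; palindromic (A/T, C/G) variants are resolved by allele frequency
when both EAFs lie outside the ambiguous band 0.42–0.58 (window 0.5 ± 0.08,
config-exposed) and are dropped inside it or when either EAF is missing;
indels/multi-allelic records are dropped at read time. No strand inference
from a reference genome is attempted. Missing p-values are reconstructed from
the two-sided normal tail of beta/se; a supplied p disagreeing with |beta/se|
by more than two orders of magnitude warns but never drops (many sources round
p).

**Instruments.** The principal analysis uses all cis-pQTLs passing the source
threshold without clumping; greedy clumping (keep lowest p, discard neighbors
within the window with r² above the cutoff; defaults r² 0.01, 10,000 kb) and
sentinel-only are sensitivity switches. The Steiger pseudo-r² uses
t²/(t²+n−2) on both sides — exact for quantitative traits, an approximation on
the log-odds scale for binary ones; retention requires strict inequality
(ties drop, conservative).

**MR.** IVW is fixed-effect with a normal reference; Egger uses an estimated
residual scale and a t reference with k−2 df, after orienting exposure betas
nonnegative by joint sign flips. The Wald SE is first-order delta by default;
the second-order term is a flag. Both IVW and Egger assume (near-)independent
instruments: with correlated instruments the point estimate remains consistent
but the SE is understated, which is why the calibration experiments below
simulate unlinked instruments (rho = 0). Heterogeneity (Cochran's Q) is
always reported, never used to auto-exclude instruments.

**SMR / HEIDI.** Top-eQTL threshold 5e-8. HEIDI test SNPs: eQTL
p < 1.57e-3, LD r² against the top SNP in [0.05, 0.9], ranked by eQTL p,
3–20 SNPs (counts exclude the top SNP). The d-statistic covariance uses
first-order delta propagation with within-cohort LD covariance only (the eQTL
and outcome cohorts are independent). The null of Q_H = Σ z_d² is a weighted
sum of χ²₁ with weights the eigenvalues of the z_d correlation matrix; the
tail is computed by **Imhof's numerical inversion** of the characteristic
function (adaptive quadrature, result clipped to [0, 1]). A two-moment
Satterthwaite scaled-chi-square was evaluated first and rejected: its
worst-case absolute error against the exact tail is ≈ 0.06 on small random
instances, far outside the 0.005 accuracy this package tests to; the Imhof
integral is exact up to quadrature error at negligible cost. HEIDI p < 0.01
labels the signal linkage; "passes SMR" = SMR p below the configured
threshold (default raw 0.05; a Bonferroni flag per gene set is also emitted
by the CLI layer) and HEIDI p ≥ 0.01.

One behavior worth knowing: because the top SNP is chosen as the minimum-p
eQTL, winner's-curse selection shrinks the observed d statistics slightly,
so the full HEIDI procedure rejects *below* the nominal rate on
shared-causal loci (≈ 0.1–0.3% at nominal 1% in our calibration runs);
with the top SNP fixed to the true causal variant the test is exactly
calibrated (≈ 1.1% at 1% over 2,000 replicates). This conservatism is a
property of the top-SNP selection step itself and makes the linkage flag
slightly harder, not easier, to trigger.

**Colocalization.** Beta/SE parameterization only (one code path, exact
oracle comparability); prior effect SDs 0.15 (quantitative) and 0.2
(case-control); per-variant priors p1 = p2 = 1e-4, p12 = 1e-5. All mass
arithmetic is in log space; H3 is an explicit pairwise i ≠ j log-sum-exp (no
subtraction, hence no catastrophic cancellation). With a single shared
variant, H3 is undefined and posteriors renormalize over the remaining
hypotheses with a status note. "Passed coloc" for tiering means PPH4 > 0.5
(the moderate threshold), with the 0.8/0.5 level retained in the output.

## The synthetic-data generator

Summary-level (RSS-style) simulation: variants get AR(1) LD R_ij = rho^|i−j|
(default rho 0.9, m 200, 10 kb spacing); a trait with direct effect vector
beta has marginal effects b = R·beta and sampled estimates
b̂ ~ MVN(b, R/n_eff) with se = 1/√n_eff, p from two-sided normal tails
(floored at 1e-300 so extreme signals survive text round-trips). Binary
traits use the effective sample size 4/(1/ncase + 1/nctrl) on the log-odds
scale — an approximation that ignores case-control asymmetry beyond n_eff.
Architectures: null; causal/mediated (one variant drives protein and
expression; the outcome effect theta·a flows through the protein); linkage
(protein variant and a distinct outcome variant in LD); pleiotropy (direct
outcome effect at the protein variant); reverse (the variant drives the
outcome, the protein only via a back-effect theta·a — what Steiger should
remove).

Defaults emulate the study conditions of large published screens: pQTL
sources of n = 35,000 / 10,700 / 54,000 with thresholds 1.8e-9 / 1.004e-11 /
1.7e-11; blood eQTLs n = 30,000; principal binary outcome n_eff = 150,000
(≈ 41k cases / 439k controls); effects theta = 0.2 (log-OR per SD protein),
a = e = 0.3 (SD per allele), direct effect c = 0.05. The replication panel
has 17 outcomes (3 binary CKD-type, 2 continuous eGFR-type and 2 binary
decline-type, 4 continuous slope-type, 6 binary clinical-type) with declared
polarities (−1 where a negative beta means higher risk) and effective sample
sizes from 3,000 to 1,000,000.

Allele frequencies (uniform 0.05–0.5), a 10% palindromic-pair fraction, and
random per-table orientation flips (30%) exist solely to exercise
harmonization; they carry no effect-size information. The two designated
signal variants per locus are kept non-palindromic so a designed effect is
never silently lost to frequency ambiguity; the remaining variants still
exercise the palindromic-drop path. RNG sub-streams are derived from a single
integer seed via `SeedSequence.spawn`, so the same seed reproduces every
table byte-for-byte.

What the generator does **not** emulate: realistic MAF spectra and
MAF-dependent power, sample overlap between cohorts, imputation noise,
winner's-curse from discovery-stage selection in the real sources, and
population stratification. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the stated model, not
that real-data results are unbiased in the presence of those complications.

## Experiment sizes and numerical choices

Calibration experiments use 1,000 replicates (IVW and Egger-intercept type-I
error at alpha 0.05 on null loci with m = 10 unlinked variants and n = 10,000
per cohort; HEIDI at alpha 0.01 on shared-causal loci with m = 60, rho = 0.9),
judged against exact-binomial 99% intervals. Parameter recovery uses 500
replicates (m = 100); colocalization discrimination 200 replicates per
architecture (m = 100, n = 50,000 both traits; the distinct-variant scenario
places the two causal variants 60 lags apart, r² < 1e-5); Steiger removal 500
replicates; end-to-end tiering 100 panels of 10 loci (m = 200). These sizes
give Monte-Carlo error comfortably below each acceptance margin while keeping
the full suite in a few minutes on one core.

Ties in instrument selection and clumping break by (chrom, pos); top-eQTL
ties by larger |z| then position. Underflowed p-values are floored at 1e-300
before FDR. LD matrices are validated as symmetric with unit diagonal and
eigenvalues ≥ −1e-8; HEIDI eigenvalues are clipped at zero. Degenerate
inputs (zero exposure beta for a ratio, all-zero exposure betas for IVW,
duplicate protein ids in the evidence table, a candidate variant missing from
the LD matrix during clumping) are hard errors; soft failures (no instruments,
no top eQTL, insufficient HEIDI SNPs) degrade to status fields so a panel run
never aborts on one protein.

## Known limitations

* Fixed-effect IVW only (no random-effects inflation, no weighted median or
  mode, no MR-PRESSO, no multivariable MR).
* HEIDI relies on first-order delta variances; with a weak top eQTL the
  approximation degrades (mitigated by the p < 1.57e-3 inclusion rule).
* Single-causal-variant colocalization (no SuSiE-style multi-signal
  decomposition, no conditional analysis).
* The Steiger pseudo-r² on the log-odds scale is approximate; liability-scale
  conversion is not implemented.
* No LD estimation from genotype panels: LD is an input (or simulated).
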