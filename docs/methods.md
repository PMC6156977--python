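# Methods

This note documents the models, numerical choices and known limitations
of `twinmeth`.  It covers the synthetic twin-cohort generator, the QC
and deconvolution procedures, the similarity and twin-correlation
analyses, and the cis-mQTL scan with its permutation FDR.

## Synthetic twin cohort

The generator produces the data structure the analyses assume, with
every latent quantity recorded as ground truth.

**Cell mixture.** Each sample's β-profile is a convex combination of
nine cell-type profiles (epithelial, fibroblast, seven leukocyte
sub-types).  Epithelial fractions are drawn per pair from a Gaussian
copula on the logit scale: a bivariate normal with correlation
`epi_fraction_twin_corr` (default 0.51) pushed through
logistic(logit(0.796) + 0.5·z).  The defaults give a mean epithelial
fraction of ≈ 0.80 with a realistic 0.55–0.95 spread and the stated
co-twin correlation (mildly attenuated, < 0.02, by the logistic
transform).  Fibroblast fractions default to zero — buccal swabs contain
none, and recovering that structural zero is a deconvolution sanity
check.  The immune compartment is split by a Dirichlet draw
(concentration 50) around a neutrophil-dominated base composition
(Neutro 0.365, NK 0.167, B 0.158, CD4T 0.103, Mono 0.197, CD8T and
Eosino 0.005 each), matching microscopy-era reports for buccal tissue;
`immune_dirichlet_conc=None` freezes the composition for experiments
that need no cell variation.

**Reference profiles and signatures.** Signature CpGs are Hadamard-coded:
the cell types of a stage take rows 1..K of a Hadamard matrix mapped to
β ∈ {0.1, 0.9}, tiled across the signature.  Any two types then disagree
in exactly half the positions of each tile, so the pairwise mean |Δβ|
is 0.4 ≥ 0.3 deterministically, and together with the intercept the
reference columns are exactly linearly independent — noise-free mixtures
are identifiable.  On the immune-stage signature, epithelial and
fibroblast profiles sit at 0.5 so their contribution is absorbed by the
fit intercept.  Two stage-1 signature CpGs are named cg07380416
(epithelial-high: 0.95 vs 0.05) and cg20837735 (epithelial-low), hosting
the two-CpG estimator.  Bulk CpGs draw a bimodal base level from a
three-component mixture (30% U(0.03, 0.15), 40% U(0.15, 0.85),
30% U(0.85, 0.97)); a quarter of them carry independent N(0, 0.12)
epithelial-vs-immune offsets, which is what makes cell composition the
leading axis of genome-wide variation.  The mixture's floor at 0.03
keeps the additive-noise clipping bias on per-CpG twin correlations
small (≲ 0.01 on the mean) while preserving the bimodal marginal shape
of array data.

**Familial component and noise.** A pair-shared N(0, σ_f²(j)) deviation
is added per CpG with σ_f² = ρ/(1−ρ)·noise_sd², so the twin correlation
of the cell-free signal equals the configured ρ (`familial_corr`,
scalar or per-CpG; default 0.21).  ρ > 0 with zero noise, or ρ outside
[0, 1), is rejected as infeasible.  Measurement noise is i.i.d.
N(0, 0.03) per measurement; technical replicates re-measure the same
biological sample with fresh noise and fresh detection failures.

**Genotypes and mQTLs.** One hard genotype per pair is drawn under
Hardy–Weinberg proportions at an allele frequency uniform on
`maf_range` (default 0.05–0.5); both co-twins inherit it (MZ identity),
and per-individual dosages add N(0, 0.05) clipped to [0, 2], emulating
imputation error.  SNP metadata is computed, not asserted: MAF and MAC
over the analysis individuals (co-twins both counted, as in the real
design), the HWE chi-square on one hard call per pair (the independent
units), and imputation r² as the squared correlation of dosage with the
hard genotype.  `n_mqtl_cpgs` bulk CpGs (mid-range base level, so the
shift cannot clip) receive ±`mqtl_effect_size` per reference allele from
a SNP placed at a log-uniform distance in [1, 10⁶) bp — concentrating
causal SNPs near their CpGs as cis architecture does.  Everything lives
on one synthetic chromosome (default 20 Mb), which keeps cis-window
bookkeeping trivial.

**Scale used in the shipped studies.** The simulation studies run at
500 CpGs × 5,000 SNPs × 43 pairs (mQTL), 100–500 pairs (correlation
recovery) and 200 samples (deconvolution) — sizes chosen so each study
isolates its estimand with comfortable Monte-Carlo resolution while a
full run of the suite stays interactive.

**What the generator does not emulate:** raw-intensity artifacts and
normalization residue, probe cross-hybridization chemistry, linkage
disequilibrium between SNPs, population stratification, age/sex effects
on methylation, and epithelial sub-type heterogeneity.  Passing tests
demonstrate correct recovery under the stated generative model, not
robustness to those real-data complications.

## Quality control

Cell-level masking (intensity exactly zero, detection p > 0.01, bead
count < 3) precedes probe-level removal (multi-mapping, SNP/INDEL
overlap, success rate < 0.95 across samples — strict, so exactly 0.95
is retained — and non-autosomal), followed by a per-sample success-rate
check at the same bound.  The retained probe set is the complement of
the union of rule hits and therefore order-independent; the per-rule
report attributes each dropped probe to the first violated rule in the
fixed order multi-mapping → SNP overlap → success rate → non-autosomal.
β-values are only ever masked or removed, never altered.

## Deconvolution

`rpc_fit` is Huber-weighted iteratively reweighted least squares
(tuning constant 1.345, convergence when coefficients move < 1e-8, cap
100 iterations) of the sample's β on the reference columns over the
signature CpGs, with an intercept that is discarded before truncating
negative coefficients to zero and renormalizing to sum 1.  When the
ordinary least-squares fit is already exact (max residual < 1e-8) it is
used directly — the robust scale estimate degenerates at zero residuals
and OLS is the IRLS fixed point anyway.  Missing signature CpGs are
dropped; fewer than max(10, K+1) usable CpGs raises a coverage error,
rank deficiency a singularity error, and an all-zero truncated fit
returns uniform fractions with a warning.  The hierarchical estimator
multiplies stage-2 immune proportions (renormalized to 1) by the
stage-1 immune total, so the output simplex and the stage hierarchy are
exact by construction.

The two-CpG epithelial estimator is
clip(intercept + b1·β(cg07380416) + b2·β(cg20837735), 0, 1).  The
default coefficients (0.5, +1/1.8, −1/1.8) are synthetic stand-ins
derived analytically from this package's marker construction (each CpG
is an exact linear read-out of the epithelial fraction, and the default
averages the two); `calibrate_eipel` refits them on any cohort with
known fractions.  They do not reproduce the originally published
formula, which is not public.

## Profile similarity

Standardization is per CpG across samples (mean 0, sd 1, ddof = 1,
zero-variance rows flagged missing).  The direction matters: z-scoring
within a sample is an affine map of that sample and provably cannot
change any between-sample Pearson correlation, so only the per-CpG
reading yields a metric that distinguishes relatedness; the test suite
asserts this with a constructed counterexample.  The standardization
cohort is all samples in the supplied matrix.  Spearman uses average
ranks for ties.  Pairs sharing < 1,000 non-missing CpGs are flagged
unreliable (configurable).  Unrelated-pair enumeration uses one sample
per individual (the first measurement) and excludes co-twins, giving
C(2k, 2) − k pairs for k complete pairs.

## Twin analyses

Residualization fits per-CpG OLS (with intercept) of β on the supplied
covariates, excluding samples missing at that CpG; rows with fewer than
n_covariates + 2 usable samples come back all-missing, and collinear
designs raise an error naming the CpG.  The standard covariate set is
the six fractions that vary in buccal swabs (Epi, Neutro, B, NK, CD4T,
Mono); because estimated fractions can sum to ~1 exactly when the small
types truncate to zero, a full-rank reduction drops numerically
dependent columns first — harmless, since residuals depend only on the
column span.

Twin correlations are single-entry Pearson r per CpG (twin 1 vs twin 2
by sample-sheet role, pairwise-complete, ≥ 3 pairs or a missing value
with a reason code).  Single-entry r depends on the arbitrary co-twin
labeling; a double-entry variant (each pair in both orders, an
ICC-like quantity) is available behind a flag and is label-invariant,
which the suite demonstrates by flipping labels for half the pairs.

Within-pair differences use Δβ = twin1 − twin2 with a strict
|Δβ| > 0.3 exceedance rule (a difference of exactly 0.3 does not
count).  With two technical replicates per co-twin the 2×2
combinations give four difference measures; the reproducibility
summary reports the union of exceeding CpGs, counts per membership
pattern (Venn structure), the full-intersection count, and pairwise
Pearson correlations of the Δ vectors on the union set, labelling the
two comparisons that share no underlying measurement as independent.
BED-based CpG grouping converts the 1-based CpG position to the
0-based half-open convention before the overlap test.

## cis-mQTL analysis

SNPs must strictly exceed MAF 0.01, HWE p 1e-4, MAC 10 and imputation
r² 0.8 (first-violation attribution in the report; HWE optionally
recomputed from rounded dosages).  Methylation is residualized on the
cell fractions plus sex, age and the first ten genotype PCs (standard
eigendecomposition of the individual × individual Gram matrix of
per-SNP standardized dosages, sign-fixed for determinism), then
rank-normalized per CpG with the Blom offset (rank − 3/8)/(n + 1/4),
average ranks for ties.

The same covariates are projected out of the dosages before the scan
(Frisch–Waugh), so each reported slope equals the SNP coefficient of
the multiple regression including the covariates.  At realistic scale
this is a refinement; at simulation scale it is essential — ten PCs
over 43 independent pairs absorb a material share of any single SNP
vector, and adjusting only the methylation side biases slopes downward
by roughly 20%.

The scan computes, for every (CpG, SNP) pair on the same chromosome
with |pos difference| < 1 Mb (strict), the simple-regression slope, the
t statistic on n − 2 df and the two-sided p (natural-log p carried
alongside; p floored at 1e-300, with numerically perfect fits,
r² ≥ 1 − 1e-12, reported at the floor).  The n − 2 df ignores the
covariates already projected out; at n = 86 the difference to adjusted
df is immaterial and, more importantly, inference rests on the
permutation FDR, not on the raw p-values, which are anticonservative
under twin relatedness regardless.

**Permutation FDR.** The null reassigns whole genotype twin-pair blocks
to uniformly random methylation twin-pair blocks (role order preserved;
derangements not enforced — the identity draw belongs to the uniform
null and excluding it would bias it).  For every permutation the
complete analysis is repeated: the permuted matrix is re-residualized
on the covariates and re-rank-normalized before its scan.  This step
is what keeps the observed and permuted statistics exchangeable once
both data sides have been covariate-adjusted — without it, observed
pairs share a projection subspace the permuted pairs lack, and the
procedure anti-conservatively declares bulk significance (the shipped
null study exhibits ~18% false CpGs without the re-adjustment and
≈ 0.2% with it, against a 5% target).  Candidate thresholds are the
observed per-CpG minimum p-values (compared in log-p space); the
selected threshold is the largest candidate at which the mean permuted
count of significant CpGs divided by the observed count is ≤ the FDR
target; counting is per methylation site, and permuted counts are
averaged across the (default 10) permutations before the ratio.  If no
candidate qualifies the result carries an explicit no-threshold status.
Lowering the FDR target can only shrink the threshold, and enlarging
the window can only add scan records; both monotonicities are asserted
in the suite.

Effect sizes on the β-per-allele scale come from the same pipeline with
rank normalization disabled; the rank-normalized track is used for
detection.  Summaries report association/CpG/SNP counts, per-CpG and
per-SNP association-count distributions, and each significant CpG's
distance to its minimum-p SNP with ties broken toward the smaller
distance.

## Known limitations

* The reference profiles and Eipel coefficients are synthetic
  constructions; applying the deconvolution to real arrays requires
  real purified-cell references.
* The permutation null assumes complete twin pairs; incomplete pairs
  must be dropped before the mQTL analysis.
* No LD modelling: each planted mQTL has a single causal SNP, so power
  estimates ignore tagging.
* Raw scan p-values are intentionally left anticonservative under
  relatedness; only the permutation FDR is an inferential surface.
* The cis scan materializes one record per tested pair; at biobank
  scale the record table, not the computation, becomes the bottleneck.
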