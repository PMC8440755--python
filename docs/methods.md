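# Methods

## Model and procedure

The pipeline tests additive haplotype effects on quantitative traits using
individually phased genotypes, avoiding haplotype-frequency estimation (EM)
entirely: each individual contributes two observed chromosome-copy allele
strings per block.

**Genetic-map coordinates.** Each SNP receives a cM position by linear
interpolation between the two flanking map anchors (the local recombination
rate in cM/bp within that interval). SNPs before the first or after the
last anchor are extrapolated linearly with the *whole-chromosome* mean rate
(cM_last − cM_first)/(bp_last − bp_first), applied on both flanks; this is
one global rate rather than the local end-segment rates, which would be
noisier. Zero-length map segments (recombination deserts) interpolate flat.

**Block segmentation.** Blocks are maximal runs of consecutive SNPs whose
neighbouring cM gaps are all ≤ δ; a gap *strictly greater* than δ starts a
new block, so a gap exactly at δ stays inside. δ defaults to 0.001 cM, a
compromise between block length and phase reliability (switch errors
concentrate in high-recombination gaps, which are exactly the ones cut).
Runs below the minimum block size (2 SNPs) are dropped and counted; blocks
never span chromosomes. δ-monotonicity holds by construction: every
δ₁-block is contained in exactly one δ₂-block for δ₁ ≤ δ₂.

**Count matrix.** The reference haplotype h₀ is the most common string in
the block (ties broken by the lexicographically smallest string, for
deterministic output). The count matrix H is N × m over the alternatives in
descending-count order, entries 0/1/2; diploid conservation
h₀-dosage + rowsum(H) = 2 holds for every fully-observed individual.
Individuals with any missing allele inside a block are excluded from that
block only — per-block listwise deletion maximizes data use and keeps the
per-result n exact. Monomorphic blocks (m = 0) are flagged untestable. No
rare-haplotype filter is applied by default; a minimum-carrier-count option
exists for numerical stability and excludes the carriers rather than the
column, preserving conservation.

**Tests.** All three tests assume Ỹ = β₀ + Xβ + (dosages)γ + ε with ε
i.i.d. Gaussian. The block test is the exact F-test on the residual-sum
difference of the nested pair (intercept+X) vs (intercept+X+H), with
numerator df equal to the number of H columns surviving collinearity
pruning. The complete test reports per-coefficient two-sided t-tests from
the single full-model fit; the single test fits one dosage at a time for
j = 0..m, the reference entering through its dosage 2 − rowsum(H) (its
intercept then absorbs the mean effect of the remaining haplotypes). Fits
use QR decomposition; p-values come from exact F/t tails (no normal
approximation). Collinear dosage columns are detected by projecting each
column, in descending-frequency order, on the running orthonormal basis;
a column is dropped when its residual norm is below 1e-8 × the largest
singular value of the design, so the rarer member of a dependent set is
always the one removed.

**Multiple testing.** Bonferroni within each test family, with N_T the
count of statistics actually emitted (monomorphic, constant-dosage and
collinear candidates never enter N_T); p_corrected = min(1, p·N_T) and the
family threshold is α/N_T at α = 0.05.

**Phenotype preparation.** Per trait: (1) linear age/sex adjustment and
Tukey IQR fencing of the residuals (k = 1.5, the usual convention;
values exactly on a fence are kept); (2) Box-Cox transform of the surviving
*raw* values — not residuals, which violate positivity — with λ maximizing
the profile log-likelihood (λ−1)Σlog y − (n/2)·log σ̂²_λ on the grid
[−2, 2] step 0.01; (3) per-trait standardization (all test statistics are
affine-invariant, so this step is cosmetic). The transform uses the log
branch below |λ| < 1e-8. Traits missing in more than 25% of individuals
are dropped before testing. Non-positive traits are rejected with an
instruction to shift, never silently shifted. Note that fencing a skewed
trait on the raw scale trims its heavy tail, so the fitted λ of, e.g., a
log-normal trait sits somewhat above 0 after trimming; age and sex still
re-enter the association model as covariates.

**Permutation FPR audit.** Three nulls: (1) *per_block* — a fresh
permutation per block (inter-block LD destroyed, within-block structure
kept), run with the full covariate model, the same permutation order shared
across the selected phenotypes; (2) *genome* — one permutation per run
shared by all blocks (default 25 runs), run on covariate-residualized
phenotypes so the null fits need no covariates (the residualization is
exact: Ỹ* is orthogonal to the intercept and every covariate column);
(3) *pooled* — the genome-scenario statistics pooled over phenotypes,
FPR_T = N_FP/N_T, with a per-run exceedance flag FPR_T ≥ 1/N_T (equivalent
to "any false positive"; without inflation ~5% of runs should be flagged at
threshold α/N_T). In the per-block scenario the significance threshold can
be the per-phenotype α/N_{t,p} (default) or the family-wide α/N_T; both are
exposed because either reading is defensible. Randomness flows through
per-(run, block) `SeedSequence` substreams, so results are bit-identical
for a given plan even under parallel or reordered execution.

## Synthetic data: what it emulates, what it does not

`haploblock.synth` draws each individual's two chromosome copies i.i.d.
from a per-block haplotype pool with specified frequencies, builds a map
anchored at every SNP with intra-block gaps ≤ δ and inter-block gaps > δ
(so segmentation recovers the designed blocks exactly), simulates age
uniform on 45–73 and sex with 48% males (a typical mid-life cohort), and
generates traits y = β₀ + Xβ + Σγ·dosage + ε with unit Gaussian noise by
default. An inverse power warp (1 + λ₀y)^(1/λ₀) (exp at λ₀ = 0) produces
positive skewed traits to exercise the Box-Cox machinery; the warp refuses
non-positive arguments and asks for a location shift rather than clipping.
Defaults are 500 individuals and ten 3-SNP blocks with a
common/middling/rare pool (0.55/0.30/0.15).

Blocks are independent by default; an optional copy probability lets
consecutive blocks share draws to mimic inter-block LD for the
genome-permutation scenario. The generator does **not** model coalescent
history, recombination within blocks, switch errors in phasing, population
stratification, or the heavy inter-phenotype correlation of real imaging
traits — so passing calibration here demonstrates correctness of the
statistics under their stated assumptions, not robustness to those real
data features (the permutation audit is the tool for that on real data).

## Numerical choices and problem sizes

- Collinearity tolerance 1e-8 × largest singular value; deterministic,
  frequency-respecting drop order.
- Insufficient residual df (n ≤ 1 + p + m_eff) raises rather than returning
  a degenerate statistic; constant dosages are skipped and logged.
- Calibration suites pair every null statistic with its own freshly drawn
  trait and genotype block, so empirical sizes are exactly binomial and are
  checked against exact 95% binomial acceptance regions at α ∈ {0.05,
  0.001} over 12,000 statistics per family (n = 400 individuals per test).
- Box-Cox recovery is assessed at λ₀ ∈ {0, 0.2, 0.5, 0.8, 1}, n = 5000, 100
  replicates each, from a base normal with mean 3 and sd 1 (a relative
  spread at which λ is well identified); a negligible-mass truncation keeps
  the warp argument positive. λ is intrinsically weakly identified when the
  coefficient of variation is small — a nearly-normal trait with mean 10
  and sd 1 yields λ̂ scattered a few tenths around 1.
- Planted-effect detection uses 2000 individuals, ten blocks, one effect of
  0.5 noise-sd per copy on a frequency-0.2 haplotype, 100 replicates.

## Known limitations

- No mixed-model/kinship correction, burden tests, meta-analysis, or
  imputation; imputed-SNP comparisons enter only as externally supplied
  dosage vectors.
- Bonferroni over correlated blocks (small δ ⇒ higher inter-block LD) is
  conservative; effective-number corrections are out of scope.
- VCF region queries scan the file (no index requirement); adequate at the
  scales this package targets.
- Half-called genotypes are normalized to fully missing on read.
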