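# Methods

## The evaluation model

Both traits are analysed with single-trait animal models. Harvest weight:

    y_w = X b + Z u + W p + e,

where `b` contains the year × sex × pond interaction (coded as cell
means) and age as a linear covariate nested within sex; `u` is the
additive genetic effect of every pedigree animal with Var(u) = K σ²_u;
`p` is a common-environment effect shared by full sibs reared in the
same spawn tank before communal stocking, Var(p) = I σ²_p; and `e` is
the residual. Residual carcass weight replaces the age covariate with
body weight nested within the year × sex interaction, which turns raw
carcass weight into a measure of saleable-carcass proportion at a given
size; it is fitted exactly as that model, never as a precomputed
residual trait.

Pedigree BLUP uses K = A, the numerator relationship matrix; single-step
GBLUP (ssGBLUP) replaces A⁻¹ in Henderson's mixed-model equations with

    H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹],

where A22 is the pedigree relationship matrix of the genotyped animals
and G is the VanRaden genomic relationship matrix

    G = M D M' / (2 Σ_j p_j (1 − p_j)),

with M the dosage matrix centered by twice the current allele
frequencies and D diagonal SNP weights (identity for unweighted runs).
G built from current-sample frequencies is exactly singular (the
centered M annihilates the ones vector), so G is blended with 5% of A22
before inversion. Nothing else changes between BLUP and ssGBLUP, which
is the point of the single-step formulation: phenotypes of ungenotyped
animals flow to genotyped candidates through H.

### Solvers

The MME coefficient matrix is assembled sparse in λ-form
(λ_u = σ²_e/σ²_u on K⁻¹, λ_p = σ²_e/σ²_p on the spawn identity).
Three solve paths share one code path and are cross-checked in tests:
sparse LU when the matrix is sparse (pedigree-only models), dense
Cholesky up to 5000 equations, and Jacobi-preconditioned conjugate
gradients beyond that (relative residual 1e−8 by default). The dense
and PCG routes agree to ~1e−6 relative on mid-size systems.

### Variance components

EM-REML with the standard updates

    σ²_u ← (û'K⁻¹û + σ²_e tr(K⁻¹C^uu)) / q
    σ²_p ← (p̂'p̂ + σ²_e tr(C^pp)) / n_p
    σ²_e ← (y'y − θ̂'W'y) / (n − rank X).

Family-structured data make the restricted likelihood strongly ridged
in (σ²_u, σ²_p): between-family variance identifies only
0.5 σ²_u + σ²_p, and the components separate only through
cross-generation links (parents with own records, paternal half sibs
spread across spawn tanks). Plain EM creeps along that ridge slowly
enough that a change-based stopping rule can fire far from the optimum,
so the default estimator wraps the EM map in SQUAREM-style
extrapolation — two EM steps per cycle, a step length from the change
of the change, and a restricted-likelihood safeguard (evaluated cheaply
through a sparse LU of the coefficient matrix) that falls back to the
plain double step whenever extrapolation does not improve the
likelihood. The accelerated map reproduces a direct Nelder–Mead
maximization of the restricted likelihood to six decimals on test
problems, and the likelihood trace is non-decreasing. Components that
collapse below 1e−8 of the phenotypic variance are pinned and flagged.
EM rounds form a dense inverse of the coefficient matrix, so REML here
is a desk-scale tool; production-scale runs take fixed components
through the configuration, mirroring how the main evaluations are run.

### Validation designs and metrics

Four training/validation designs: (1) k-fold cross-validation (k = 5 or
10, replicated) over genotyped, phenotyped animals; (2) genotyped full
sibs halved within family (odd member to training; singleton families to
training); (3) as (2) with a random half of the genotyped training sibs
additionally de-phenotyped (rounding the masked count down); (4) as (2)
with every genotyped animal de-phenotyped, so genotyped candidates are
informed only through H. Predictive ability is the Pearson correlation
of (G)EBV with phenotypes adjusted for the fixed effects of the
full-data fit; inflation is the slope b₁ of adjusted phenotypes on
(G)EBV. Re-estimating variance components per training set (toggle)
changes b₁ but leaves predictive ability essentially unchanged, which
the tests assert to within 0.01.

One property of the b₁ metric worth knowing: the adjusted phenotype
still contains the common-environment effect, and a validation animal's
spawn mates sit in the training data, so b₁ carries a
+cov(p, û)/var(û) term on top of genuine dispersion. The term shrinks
with pedigree depth; under the six-cohort default structure it is a few
percent. Calibration proper is checked in tests by regressing *true*
breeding values on GEBV (slope ≈ 1 with true components).

### Weighted ssGBLUP GWAS

GEBV of genotyped animals are back-solved to SNP effects,
â = D M' G⁻¹ û / (2Σp(1−p)); with the unblended, invertible G this
reconstructs M â = û exactly (asserted in tests); production runs use
the blended G for stability. Nonlinear-A weights
d_j = 1.125^min(|â_j|/sd(â) − 2, 5) are applied iteratively (default 5
iterations): each iteration rebuilds the blended G with the current
weights, refits, and back-solves. The exponent cap bounds every weight
at 1.125⁵ ≈ 1.802. Held-out predictive ability and b₁ are recorded per
iteration; the reporting iteration is the one with the highest held-out
r, ties broken toward least |1 − b₁| and earliness. Association signal
is summarized as the percentage of SNP-captured additive variance in
non-overlapping windows of 20 adjacent SNPs within chromosome (trailing
shorter window kept; sliding windows available), using the
independent-locus sum Σ 2p q â² — LD covariance between SNPs inside a
window is deliberately ignored, and percentages are normalized by the
genome-wide SNP sum so they total exactly 100. Linear (â²2pq) weights
exist only as an experimental flag; they are known to diverge over
iterations for polygenic traits.

### Linkage disequilibrium and Ne

Genotypes are unphased, so r² between SNP pairs is the squared Pearson
correlation of dosages — under Hardy–Weinberg proportions
cov(g_A, g_B) = 2D and var(g) = 2pq, making it identical to the
haplotype-frequency form D²/(p_A q_A p_B q_B), which an exhaustive
phased-panel oracle verifies exactly; off HWE it remains in [0, 1].
Per-chromosome decay is fitted by nonlinear least squares of the Sved
curve E[r²] = 1/(1 + 4 Ne d) (distance in Morgan at a fixed 1 cM/Mb,
configurable); the closed-form route inverts the chromosome-mean r²,
Ne = (4 d̄)⁻¹[(r̄² − 1/N)⁻¹ − α] with α = 2 (mutation considered) and
the genotyped count N as sampling correction. Genome-wide Ne is the
unweighted mean of chromosome estimates (length-weighted available).
Interpretation note: r² at distance d reflects effective size roughly
1/(2d) generations back, so the marker spacing chosen for an Ne check
must match the age of the population — the constant-size drift checks
use ~0.05 M spacing (≈10 generations back) because denser maps would
probe the pre-founding, effectively infinite-Ne era and inflate Ne.
The third route is the inbreeding rate: ΔF = (F_n − F_{n−1})/(1 − F_{n−1}),
Ne_F = 1/(2ΔF), aggregated as the arithmetic mean of per-pair ΔF over
consecutive generations (last-pair mode available; generation = year
class when labels exist, else maximal ancestral depth).

## The synthetic-data generator

The generator emulates the structure of a US channel-catfish selection
program. Unrelated founder broodfish (haplotypes drawn at linkage
equilibrium from a uniform or U-shaped frequency spectrum with a 0.05
MAF floor) are mated to produce year-classes of full-sib families, each
family reared in its own spawn tank (one common-environment level per
family per year). Each sire serves up to two dams (paternal half-sib
families across tanks), full-sib matings are rejected, roughly 10% of
harvested fish are kept as broodfish with no more than 10% of the
selected set from any single family. Selection uses a standardized
two-trait *phenotype* index (the average of z-scored harvest and
carcass records); the real program selects on an EBV index, but an
in-generator evaluation would nest the whole machinery inside the data
generator — mass selection keeps the generator self-contained while
preserving directional selection and the inbreeding it causes.

Meiosis is simulated as a Markov phase switch between adjacent markers
with Haldane recombination fractions r = ½(1 − e^{−2d}), marginally
identical to a Poisson crossover process without interference; the
observed switch count per Morgan matches the map length in tests. True
breeding values are sums of QTL dosages times bivariate-normal effects
(genetic correlation 0.5 by default), rescaled so the founder-cohort
additive variance hits h²σ²_P exactly (h² = 0.27 harvest weight, 0.34
residual carcass weight; phenotypic SD 150 g and 40 g). The
common-environment fraction is 0.15 for both traits. Carcass weight is
generated as a body-weight regression plus its own genetic,
common-environment and residual parts and recorded on ~25% of fish,
mirroring partial slaughter; body weight doubles as the harvest-weight
record. A planted-QTL mode concentrates a chosen fraction of the
additive variance on one mid-frequency locus (mid-frequency so the MAF
filter cannot silently delete the signal) for GWAS power tests.

Default scale: 29 chromosomes of 1 Morgan, 5800 SNPs (a ~10× scaled
panel), 6 year-classes of 100 families × 30 tagged offspring, 10%
genotyped. Tests and the acceptance script use smaller explicit
configurations (hundreds of SNPs, tens of families, and ~2000-record
cohorts for variance-component work) chosen so each study still
identifies the quantity it measures; the multi-cohort depth matters
more than raw cohort size for separating σ²_u from the tank variance.

What the generator does *not* emulate: genotyping error and allele
miscalls, pedigree errors, age-dependent mortality, pond-by-year
environmental correlation beyond the fitted fixed effects,
genotype-by-environment interaction, and sequence-level variant
discovery. Passing tests therefore demonstrate correctness of the
evaluation machinery under the stated model, not robustness to
real-data pathologies.

## Numerical choices and edge cases

- QC order: animal call-rate filter first, then SNP filters computed on
  surviving animals; inequalities strict as stated (MAF < 0.05 removed,
  call rate < 0.90 removed); remaining missing dosages imputed to the
  SNP mean (2p̂) so centering leaves them neutral; allele frequencies
  are recomputed after animal removal.
- Unknown parents are unrelated, non-inbred founders; Mendelian
  sampling variance d_i = 0.5 − 0.25(F_s + F_d) with both parents
  known, 0.75 − 0.25 F with one, 1 with none.
- A22 is computed on the ancestral closure of the genotyped set, never
  on the full dense A.
- Fixed effects use cell-means coding of the single interaction factor
  plus nested covariate slopes — full rank by construction; a
  degenerate (collinear) system falls back to least squares.
- Blending fraction β ∈ [0, 1) enforced; β = 0.05 default. A singular
  blended G raises with advice to increase β.
- Ne from ΔF ≤ 0 is reported as missing (NaN), never infinity; Sved
  fits that fail to converge are flagged and the mean-r² route is the
  fallback.
- All randomness flows from one master seed through named blake2 -
  derived substreams (`_seeds.derive_seed`), making every table and
  file byte-reproducible; derived seeds stay below 2³¹.

## Known limitations

- EM-REML requires a dense inverse per round; practical up to a few
  thousand equations.
- Reliabilities/PEV are not computed beyond what the dense inverse
  would give; multi-trait MME, dominance, and G×E are out of scope.
- The GWAS variance attribution ignores within-window LD covariance;
  window percentages are a descriptive decomposition, not estimates of
  QTL variance.
- The GEBV decomposition into pedigree and genomic information shares
  (beyond the parent average) is not implemented; its weights are
  population-dependent and not derivable from the inputs used here.
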