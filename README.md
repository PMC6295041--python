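# ssgblup

Single-step genomic BLUP evaluation toolkit for family-based aquaculture
breeding programs — built around the kind of channel-catfish selection
program in which harvest weight and residual carcass weight are evaluated
on tens of thousands of pedigree records, a few thousand fish carry SNP
genotypes, and full sibs share a rearing tank before communal stocking.

## What it computes

For breeders and quantitative geneticists who want the whole evaluation
chain in one tested package:

- **Pedigree relationships** — Meuwissen–Luo inbreeding coefficients F,
  the tabular numerator relationship matrix A (oracle scale), Henderson's
  sparse A⁻¹ with inbreeding, the genotyped-block A₂₂ via ancestral
  subsets, and Ne from the rate of inbreeding, Ne_F = 1/(2ΔF) with
  ΔF = (F_n − F_{n−1})/(1 − F_{n−1}).
- **Genomic relationships** — SNP/animal QC (MAF < 0.05, call rate < 90%,
  monomorphic), the VanRaden matrix G = MDM′/2Σp_j(1−p_j), blending with
  5% A₂₂, and the single-step inverse
  H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A₂₂⁻¹].
- **Animal models** — y = Xb + Zu + Wp + e with a year–sex–pond
  interaction, nested covariates (age within sex; body weight within
  year–sex for residual carcass weight), a common-environment (spawn
  tank) effect, sparse/dense/PCG solvers for Henderson's MME, and
  accelerated EM-REML variance components.
- **Validation** — k-fold and full-sib training/validation designs with
  phenotype masking, predictive ability r = cor[(G)EBV, y*] against
  phenotypes adjusted for fixed effects, and the inflation slope b₁ of
  y* on (G)EBV.
- **GWAS** — weighted ssGBLUP: back-solving â = DM′G⁻¹û/2Σp(1−p),
  nonlinear-A weights d_j = 1.125^min(|â_j|/sd(â)−2, 5), iterated
  refits, and Manhattan tables of the % additive variance in 20-SNP
  windows.
- **LD and Ne** — composite r² from unphased dosages, Sved decay fits
  E[r²] = 1/(1+4Ne·d), and the closed form
  Ne = (4d̄)⁻¹[(r̄²−1/N)⁻¹−α], α = 2.
- **Gene-drop simulation** — a breeding-program generator (founders,
  year-classes of full-sib families, selection with family caps, Haldane
  recombination, two correlated traits with known truth) that feeds every
  other module's tests.

## Worked example

```python
from ssgblup import simulate as sim, validation as vl

cfg = sim.SimConfig(n_chromosomes=5, n_snps=800, n_qtl=300,
                    n_founders=200, families_per_year=20,
                    offspring_per_family=12, genotyped_fraction=0.4,
                    n_year_classes=6)
ds, truth, _ = sim.simulate_population(cfg, seed=100)

res = vl.run_validation(ds, traits=("hw",), strategies=(1, 2),
                        replicates=1, seed=0)
print(vl.summarize_validation(res)[
    ["trait", "strategy", "method", "r_mean", "b1_mean"]])
```

prints

```
  trait  strategy   method    r_mean   b1_mean
0    hw         1     blup  0.563542  1.145212
1    hw         1  ssgblup  0.578061  1.065903
2    hw         2     blup  0.596001  1.277711
3    hw         2  ssgblup  0.614830  1.158563
```

Read: on a six-cohort program with 40% of fish genotyped, single-step
GBLUP lifts the predictive ability of harvest-weight breeding values
(0.56 → 0.58 in the k-fold design, 0.60 → 0.61 in the full-sib design)
and its b₁ sits closer to 1 (less dispersion bias) than pedigree BLUP —
the expected value of genomic information in this family structure. The same
`Dataset` object drives the GWAS (`ssgblup.gwas.wssgblup`) and LD
(`ssgblup.popgen`) modules.

A `ssgblup` command-line tool wraps the pipeline
(`simulate | qc | relmat | fit | validate | gwas | ld | all`), driven by
a YAML config plus `--seed` and `--outdir`; every run writes tidy CSVs,
a JSON-lines log, and a manifest that reproduces it bit-for-bit.

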