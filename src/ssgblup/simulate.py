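"""Gene-drop simulation of a family-structured fish breeding program.

Founder haplotypes are drawn at linkage equilibrium with a configurable
allele-frequency spectrum, then dropped through a pedigree with Haldane
(no-interference) recombination. Phenotypes follow the same two animal
models that the evaluation fits: a growth trait (harvest weight) with a
year-sex-pond fixed interaction and age nested within sex, and a carcass
trait with body weight nested within year-sex, both with an additive
polygenic effect built from QTL dosages, a common-environment effect
shared by full sibs from the same spawn tank, and a Gaussian residual.

The generator emulates the structure of a channel-catfish selection
program: unrelated founder broodfish, 100-200 full-sib families per
year-class with ~30 tagged offspring each, mass selection of ~10% of
harvested fish with no more than 10% of broodfish from any single family,
no full-sib matings, heritabilities 0.27 (harvest weight) and 0.34
(carcass), a common-environment fraction of 0.15, and partial genotyping.
Marker density is scaled down relative to a commercial array; positions
map to base pairs at 1 cM/Mb.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import genotypes as gt
from . import model as md
from . import pedigree as pg
from .datasets import Dataset
from ._seeds import derive_seed

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_founders",
    "gene_drop",
    "simulate_phenotypes",
    "simulate_population",
    "drift_population",
    "write_dataset",
    "read_dataset",
]


@dataclass
class SimConfig:
    """Study-condition defaults for the synthetic breeding program."""

    n_chromosomes: int = 29
    chrom_length_morgan: float = 1.0
    n_snps: int = 5800
    n_qtl: int = 1000
    n_founders: int = 400
    n_year_classes: int = 6
    families_per_year: int = 100
    offspring_per_family: int = 30
    genotyped_fraction: float = 0.10
    carcass_fraction: float = 0.25
    h2: tuple = (0.27, 0.34)        # harvest weight, residual carcass weight
    c2: float = 0.15                # common-environment fraction, both traits
    genetic_corr: float = 0.5
    phen_sd: tuple = (150.0, 40.0)  # phenotypic SD in g
    trait_means: tuple = (650.0, 0.0)
    body_weight_slope: float = 0.32
    n_ponds: int = 4
    selection: bool = True
    selected_fraction: float = 0.10
    max_family_share: float = 0.10
    dams_per_sire: int = 2  # brood-pond male:female ratio up to 1:2
    founder_freq_spectrum: str = "uniform"  # or "ushaped"
    maf_floor: float = 0.05
    cm_per_mb: float = 1.0
    big_qtl_fraction: float = 0.0   # variance share of one planted QTL

    def __post_init__(self):
        if self.h2[0] + self.c2 >= 1.0 or self.h2[1] + self.c2 >= 1.0:
            raise ValueError("variance fractions must sum to < 1")
        for f in (self.genotyped_fraction, self.carcass_fraction,
                  self.selected_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must be in [0, 1]")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.blake2b(payload.encode(), digest_size=8).hexdigest()


@dataclass
class SimTruth:
    """Simulated ground truth for downstream recovery tests."""

    tbv: pd.DataFrame            # animal, tbv_hw, tbv_cc
    qtl: pd.DataFrame            # snp index, chrom, pos, effects
    vc: dict                     # trait -> true VarianceComponents
    realized_var_u: dict         # trait -> realized additive variance (founders)
    founder_freq: np.ndarray


def default_snp_map(cfg: SimConfig) -> gt.SnpMap:
    """Evenly spaced SNPs over cfg.n_chromosomes chromosomes."""
    per = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per[: cfg.n_snps % cfg.n_chromosomes] += 1
    chroms, poss = [], []
    bp_per_morgan = 1e8 / cfg.cm_per_mb
    for c in range(cfg.n_chromosomes):
        m = per[c]
        # 1 bp floor keeps map positions strictly increasing even for a
        # zero-length chromosome (recombination is then negligible)
        step = max(cfg.chrom_length_morgan * bp_per_morgan / m, 1.0)
        chroms.append(np.full(m, c + 1))
        poss.append((np.arange(m) * step + step / 2).astype(np.int64))
    snp_ids = np.array([f"snp{i+1}" for i in range(cfg.n_snps)])
    return gt.SnpMap(np.concatenate(chroms), np.concatenate(poss), snp_ids)


def simulate_founders(cfg: SimConfig, seed: int):
    """Founder haplotypes at linkage equilibrium.

    Returns (H, freqs): H of shape (2*n_founders, n_snps) in {0,1}, rows
    2i and 2i+1 belonging to founder i; freqs the sampled per-SNP allele
    frequencies, floored at cfg.maf_floor so downstream QC does not
    silently decimate the panel.
    """
    rng = np.random.default_rng(seed)
    lo, hi = cfg.maf_floor, 1.0 - cfg.maf_floor
    if cfg.founder_freq_spectrum == "uniform":
        freqs = rng.uniform(lo, hi, cfg.n_snps)
    elif cfg.founder_freq_spectrum == "ushaped":
        freqs = np.clip(rng.beta(0.5, 0.5, cfg.n_snps), lo, hi)
    else:
        raise ValueError(f"unknown spectrum {cfg.founder_freq_spectrum!r}")
    H = (rng.random((2 * cfg.n_founders, cfg.n_snps)) < freqs).astype(np.int8)
    return H, freqs


def _chrom_blocks(snp_map: gt.SnpMap, cm_per_mb: float):
    """Per-chromosome (column slice, adjacent recombination fractions)."""
    blocks = []
    morgan = snp_map.pos * (cm_per_mb / 1e8)
    for c in np.unique(snp_map.chrom):
        idx = np.nonzero(snp_map.chrom == c)[0]
        d = np.diff(morgan[idx])
        r = 0.5 * (1.0 - np.exp(-2.0 * d))  # Haldane
        blocks.append((idx, r))
    return blocks


def _gametes(H0, H1, parent_idx, blocks, rng, count_crossovers=False):
    """Sample one gamete per parent in parent_idx (vectorized).

    Recombination is a Markov phase switch between adjacent markers with
    Haldane fractions, equivalent marginally to a Poisson crossover
    process; the starting haplotype on each chromosome is random.
    """
    n = len(parent_idx)
    out = np.empty((n, H0.shape[1]), dtype=np.int8)
    xo = np.zeros(n)
    h0 = H0[parent_idx]
    h1 = H1[parent_idx]
    for idx, r in blocks:
        start = rng.integers(0, 2, size=(n, 1))
        if len(r):
            switches = (rng.random((n, len(r))) < r).astype(np.int8)
            phase = (start + np.cumsum(
                np.concatenate([np.zeros((n, 1), dtype=np.int8), switches], axis=1),
                axis=1)) % 2
            if count_crossovers:
                xo += switches.sum(axis=1)
        else:
            phase = np.broadcast_to(start, (n, len(idx)))
        cols = h0[:, idx]
        cols1 = h1[:, idx]
        out[:, idx] = np.where(phase == 0, cols, cols1)
    if count_crossovers:
        return out, xo
    return out


def gene_drop(
    ped: pg.Pedigree,
    founder_haplotypes: np.ndarray,
    snp_map: gt.SnpMap,
    seed: int,
    cm_per_mb: float = 1.0,
    return_haplotypes: bool = False,
):
    """Drop founder haplotypes through the pedigree.

    Founders (unknown-parent animals) receive haplotype rows (2i, 2i+1)
    of `founder_haplotypes` in pedigree order; every other animal gets
    one recombinant gamete from each parent. Returns a GenotypeMatrix of
    dosages for all pedigree animals (and the haplotype pair when
    `return_haplotypes`).
    """
    rng = np.random.default_rng(seed)
    n, S = ped.n, len(snp_map)
    blocks = _chrom_blocks(snp_map, cm_per_mb)
    H0 = np.zeros((n, S), dtype=np.int8)
    H1 = np.zeros((n, S), dtype=np.int8)

    founders = np.nonzero(ped.is_founder())[0]
    if 2 * len(founders) > founder_haplotypes.shape[0]:
        raise ValueError("not enough founder haplotypes for this pedigree")
    H0[founders] = founder_haplotypes[2 * np.arange(len(founders))]
    H1[founders] = founder_haplotypes[2 * np.arange(len(founders)) + 1]

    depth = np.zeros(n, dtype=np.int64)
    for i in range(n):
        ds = depth[ped.sire[i]] + 1 if ped.sire[i] >= 0 else 0
        dd = depth[ped.dam[i]] + 1 if ped.dam[i] >= 0 else 0
        depth[i] = max(ds, dd)
    for wave in range(1, depth.max() + 1):
        idx = np.nonzero(depth == wave)[0]
        if len(idx) == 0:
            continue
        H0[idx] = _gametes(H0, H1, ped.sire[idx], blocks, rng)
        H1[idx] = _gametes(H0, H1, ped.dam[idx], blocks, rng)

    geno = gt.GenotypeMatrix((H0 + H1).astype(float), ped.labels)
    if return_haplotypes:
        return geno, (H0, H1)
    return geno


def _qtl_effects(cfg: SimConfig, snp_map: gt.SnpMap, founder_dosages, rng):
    """Pick QTL among simulated SNPs and scale bivariate-normal effects so
    the founder-cohort additive variance hits the target for each trait.

    With big_qtl_fraction > 0, one QTL is planted to explain that share
    of the additive variance (for GWAS planted-signal tests)."""
    S = len(snp_map)
    qtl_idx = np.sort(rng.choice(S, size=min(cfg.n_qtl, S), replace=False))
    chol = np.linalg.cholesky(
        np.array([[1.0, cfg.genetic_corr], [cfg.genetic_corr, 1.0]])
    )
    eff = rng.standard_normal((len(qtl_idx), 2)) @ chol.T

    targets = [cfg.h2[0] * cfg.phen_sd[0] ** 2, cfg.h2[1] * cfg.phen_sd[1] ** 2]
    dos_q = founder_dosages[:, qtl_idx]
    big = None
    if cfg.big_qtl_fraction > 0:
        # plant at a mid-frequency locus so the signal is well tagged and
        # cannot be silently lost to the MAF filter
        freq_q = founder_dosages[:, qtl_idx].mean(axis=0) / 2.0
        big = int(np.argmin(np.abs(freq_q - 0.5)))
    for t in range(2):
        if big is not None:
            eff_t = eff[:, t].copy()
            eff_t[big] = 0.0
            tbv_bg = dos_q @ eff_t
            v_bg = np.var(tbv_bg)
            scale_bg = np.sqrt(targets[t] * (1 - cfg.big_qtl_fraction) / v_bg)
            eff[:, t] = eff_t * scale_bg
            pq = np.var(dos_q[:, big])
            eff[big, t] = np.sqrt(targets[t] * cfg.big_qtl_fraction / pq)
        else:
            tbv = dos_q @ eff[:, t]
            eff[:, t] *= np.sqrt(targets[t] / np.var(tbv))
    return qtl_idx, eff


def _true_vc(cfg: SimConfig) -> dict:
    out = {}
    for t, trait in enumerate(("hw", "cc")):
        sP2 = cfg.phen_sd[t] ** 2
        out[trait] = md.VarianceComponents(
            sigma2_u=cfg.h2[t] * sP2,
            sigma2_p=cfg.c2 * sP2,
            sigma2_e=(1.0 - cfg.h2[t] - cfg.c2) * sP2,
        )
    return out


def simulate_phenotypes(
    ped: pg.Pedigree,
    geno: gt.GenotypeMatrix,
    cfg: SimConfig,
    seed: int,
    snp_map: gt.SnpMap | None = None,
    qtl: tuple | None = None,
):
    """Phenotypes for all non-founder animals under the two trait models.

    geno must hold dosages for every pedigree animal (gene_drop output).
    Returns (PhenotypeTable, SimTruth). When `qtl` (qtl_idx, effects) is
    given it is reused, otherwise QTL are drawn afresh.
    """
    rng = np.random.default_rng(seed)
    if snp_map is None:
        snp_map = default_snp_map(cfg)
    founders = ped.is_founder()
    if qtl is None:
        qtl_idx, eff = _qtl_effects(cfg, snp_map, geno.dosages[founders], rng)
    else:
        qtl_idx, eff = qtl
    tbv = geno.dosages[:, qtl_idx] @ eff  # (n, 2)
    vc = _true_vc(cfg)

    rows = _phenotype_cohort(
        ped, np.nonzero(~founders)[0], tbv, cfg, vc,
        year=ped.generations(), rng=rng,
    )
    phenos = pd.DataFrame(rows)
    truth = SimTruth(
        tbv=pd.DataFrame(
            {"animal": ped.labels, "tbv_hw": tbv[:, 0], "tbv_cc": tbv[:, 1]}
        ),
        qtl=pd.DataFrame(
            {
                "snp_index": qtl_idx,
                "chrom": snp_map.chrom[qtl_idx],
                "pos": snp_map.pos[qtl_idx],
                "eff_hw": eff[:, 0],
                "eff_cc": eff[:, 1],
            }
        ),
        vc=vc,
        realized_var_u={
            "hw": float(np.var(tbv[founders, 0])),
            "cc": float(np.var(tbv[founders, 1])),
        },
        founder_freq=gt.allele_frequencies(
            gt.GenotypeMatrix(geno.dosages[founders], ped.labels[founders])
        ),
    )
    return phenos, truth


def _phenotype_cohort(ped, idx, tbv, cfg, vc, year, rng):
    """Phenotype records for the animals in idx (internal indices)."""
    n = len(idx)
    sex = rng.integers(0, 2, n)  # 0 = F, 1 = M
    pond = rng.integers(1, cfg.n_ponds + 1, n)
    age = np.clip(rng.normal(500.0, 35.0, n), 391, 620).round()

    # spawn group = full-sib family (sire, dam, year)
    fam_key = [
        (int(ped.sire[i]), int(ped.dam[i]), int(year[i])) for i in idx
    ]
    spawn_levels, spawn_codes = np.unique(
        np.array([f"{s}_{d}_{y}" for s, d, y in fam_key]), return_inverse=True
    )
    pe_hw = rng.normal(0.0, np.sqrt(vc["hw"].sigma2_p), len(spawn_levels))
    pe_cc = rng.normal(0.0, np.sqrt(vc["cc"].sigma2_p), len(spawn_levels))

    year_eff = {y: 25.0 * k for k, y in enumerate(np.unique(year[idx]))}
    pond_eff = {p: e for p, e in zip(
        range(1, cfg.n_ponds + 1), rng.normal(0, 20.0, cfg.n_ponds))}
    sex_eff = np.array([0.0, 40.0])
    age_slope = np.array([0.7, 0.8])  # g/day, F and M

    hw = (
        cfg.trait_means[0]
        + np.array([year_eff[y] for y in year[idx]])
        + sex_eff[sex]
        + np.array([pond_eff[p] for p in pond])
        + age_slope[sex] * (age - 500.0)
        + tbv[idx, 0]
        + pe_hw[spawn_codes]
        + rng.normal(0.0, np.sqrt(vc["hw"].sigma2_e), n)
    )
    body_weight = hw
    cc_full = (
        cfg.trait_means[1]
        + cfg.body_weight_slope * body_weight
        + np.array([pond_eff[p] for p in pond]) * 0.2
        + tbv[idx, 1]
        + pe_cc[spawn_codes]
        + rng.normal(0.0, np.sqrt(vc["cc"].sigma2_e), n)
    )
    has_cc = rng.random(n) < cfg.carcass_fraction
    cc = np.where(has_cc, cc_full, np.nan)

    return {
        "animal": ped.labels[idx],
        "hw": hw,
        "cc": cc,
        "year": year[idx],
        "sex": np.where(sex == 1, "M", "F"),
        "pond": pond,
        "age": age,
        "body_weight": body_weight,
        "spawn": spawn_levels[spawn_codes],
    }


def _select_broodfish(cands: pd.DataFrame, cfg: SimConfig, rng,
                      min_males: int = 0, min_females: int = 0):
    """Mass selection on the (standardized) phenotype index with a cap on
    the share of broodfish from any single full-sib family.

    Walks the ranking until the target count is reached and both sex
    quotas for the next mating design are filled.
    """
    df = cands.copy()
    z = (df["hw"] - df["hw"].mean()) / df["hw"].std()
    if df["cc"].notna().sum() >= 2:
        zc = (df["cc"] - df["cc"].mean()) / df["cc"].std()
        z = np.where(df["cc"].notna(), 0.5 * (z + zc), z)
    df["index"] = z
    n_keep = max(int(round(cfg.selected_fraction * len(df))), 20)
    cap = max(int(np.ceil(cfg.max_family_share * n_keep)), 2)
    chosen = []
    n_m = n_f = 0
    fam_counts: dict = {}
    for i in df.sort_values("index", ascending=False).index:
        fam = df.at[i, "spawn"]
        if fam_counts.get(fam, 0) >= cap:
            continue
        is_m = bool(df.at[i, "_sex01"])
        if len(chosen) >= n_keep:
            # past the nominal cut: only fill outstanding sex quotas
            if is_m and n_m >= min_males:
                continue
            if not is_m and n_f >= min_females:
                continue
        chosen.append(i)
        fam_counts[fam] = fam_counts.get(fam, 0) + 1
        n_m += is_m
        n_f += not is_m
        if len(chosen) >= n_keep and n_m >= min_males and n_f >= min_females:
            break
    return df.loc[chosen]


def simulate_population(cfg: SimConfig, seed: int):
    """End-to-end simulation of the breeding program.

    Returns (Dataset, SimTruth, full GenotypeMatrix). The Dataset holds
    post-QC genotypes for the genotyped subset only, mirroring partial
    genotyping of a real program; the full matrix is returned for
    oracle-style tests.
    """
    snp_map = default_snp_map(cfg)
    H_founder, freqs = simulate_founders(cfg, derive_seed(seed, "founders"))
    rng = np.random.default_rng(derive_seed(seed, "population"))
    blocks = _chrom_blocks(snp_map, cfg.cm_per_mb)
    vc = _true_vc(cfg)

    nf = cfg.n_founders
    sire = [-1] * nf
    dam = [-1] * nf
    year = [0] * nf
    sex_all = list(rng.integers(0, 2, nf))  # founders
    H0 = [H_founder[2 * i] for i in range(nf)]
    H1 = [H_founder[2 * i + 1] for i in range(nf)]

    founder_dos = np.array(
        [H_founder[2 * i] + H_founder[2 * i + 1] for i in range(nf)], dtype=float
    )
    qtl_idx, eff = _qtl_effects(cfg, snp_map, founder_dos, rng)

    pheno_frames = []
    prev_cohort: pd.DataFrame | None = None  # records of previous year-class
    prev_idx: np.ndarray | None = None
    tbv_rows = [founder_dos[:, qtl_idx] @ eff]

    H0a = np.array(H0, dtype=np.int8)
    H1a = np.array(H1, dtype=np.int8)

    for g in range(1, cfg.n_year_classes + 1):
        n_fam = cfg.families_per_year
        n_sires_needed = int(np.ceil(n_fam / cfg.dams_per_sire))
        if g == 1 or prev_cohort is None:
            pool_idx = np.arange(nf)
            pool_sex = np.array(sex_all[:nf])
        else:
            if cfg.selection:
                sel = _select_broodfish(prev_cohort, cfg, rng,
                                        min_males=n_sires_needed,
                                        min_females=n_fam)
            else:
                take = max(int(round(cfg.selected_fraction * len(prev_cohort))),
                           n_fam + n_sires_needed, 20)
                sel = prev_cohort.sample(n=min(take, len(prev_cohort)),
                                         random_state=int(rng.integers(2**31)))
            pool_idx = sel["_internal"].to_numpy()
            pool_sex = sel["_sex01"].to_numpy()

        males = pool_idx[pool_sex == 1]
        females = pool_idx[pool_sex == 0]
        if len(males) == 0 or len(females) == 0:
            raise RuntimeError("selection produced a single-sex broodfish pool")

        # each sire serves up to cfg.dams_per_sire dams (paternal half-sib
        # families across separate spawn tanks); no full-sib matings
        cur_sire = np.array(sire)
        cur_dam = np.array(dam)
        sire_pool = rng.permutation(males)
        if len(sire_pool) < n_sires_needed:
            sire_pool = males[rng.integers(len(males), size=n_sires_needed)]
        sire_seq = np.repeat(sire_pool[:n_sires_needed],
                             cfg.dams_per_sire)[:n_fam]

        def is_fullsib(a, b):
            return bool(
                cur_sire[a] >= 0
                and cur_sire[a] == cur_sire[b]
                and cur_dam[a] == cur_dam[b]
            )

        pairs = []
        used_dams: set = set()
        for s in sire_seq:
            s = int(s)
            d = None
            for _try in range(100):
                cand = int(females[rng.integers(len(females))])
                if not is_fullsib(s, cand) and cand not in used_dams:
                    d = cand
                    break
            if d is None:  # fall back to any non-full-sib female
                options = [int(f) for f in females if not is_fullsib(s, int(f))]
                if not options:
                    raise RuntimeError(
                        "cannot mate without full-sib pairing; broodfish "
                        "pool too narrow"
                    )
                d = options[int(rng.integers(len(options)))]
            used_dams.add(d)
            pairs.append((s, d))

        offs_sire = np.repeat([p[0] for p in pairs], cfg.offspring_per_family)
        offs_dam = np.repeat([p[1] for p in pairs], cfg.offspring_per_family)
        n_off = len(offs_sire)
        start = len(sire)
        sire += list(offs_sire)
        dam += list(offs_dam)
        year += [g] * n_off
        idx = np.arange(start, start + n_off)

        g0 = _gametes(H0a, H1a, offs_sire, blocks, rng)
        g1 = _gametes(H0a, H1a, offs_dam, blocks, rng)
        H0a = np.vstack([H0a, g0])
        H1a = np.vstack([H1a, g1])
        tbv_rows.append((g0 + g1)[:, qtl_idx].astype(float) @ eff)

        ped_now = pg.from_arrays(sire, dam, generation=year)
        tbv_now = np.vstack(tbv_rows)
        rows = _phenotype_cohort(
            ped_now, idx, tbv_now, cfg, vc, year=np.array(year), rng=rng
        )
        cohort = pd.DataFrame(rows)
        cohort["_internal"] = idx
        cohort["_sex01"] = (cohort["sex"] == "M").astype(int)
        pheno_frames.append(cohort)
        prev_cohort = cohort
        sex_all += list(cohort["_sex01"])

    ped = pg.from_arrays(sire, dam, generation=year)
    phenos = pd.concat(pheno_frames, ignore_index=True)
    tbv = np.vstack(tbv_rows)
    geno_all = gt.GenotypeMatrix((H0a + H1a).astype(float), ped.labels)

    offspring = np.nonzero(~ped.is_founder())[0]
    n_g = int(round(cfg.genotyped_fraction * len(offspring)))
    g_idx = np.sort(rng.choice(offspring, size=n_g, replace=False))
    geno_sub = gt.GenotypeMatrix(
        geno_all.dosages[g_idx].copy(), ped.labels[g_idx]
    )
    if n_g:
        geno_qc, map_qc, qc_report = gt.snp_qc(geno_sub, snp_map)
    else:
        geno_qc, map_qc, qc_report = None, snp_map, None

    specs = {
        "hw": md.ModelSpec(
            trait="hw", factors=["year", "sex", "pond"],
            covariates=[("age", ["sex"])], spawn_col="spawn",
        ),
        "cc": md.ModelSpec(
            trait="cc", factors=["year", "sex", "pond"],
            covariates=[("body_weight", ["year", "sex"])], spawn_col="spawn",
        ),
    }
    ds = Dataset(
        ped=ped,
        phenos=phenos.drop(columns=["_internal", "_sex01", "index"],
                           errors="ignore"),
        model_specs=specs,
        vc=vc,
        geno=geno_qc,
        snp_map=map_qc,
        qc_report=qc_report,
    )
    truth = SimTruth(
        tbv=pd.DataFrame(
            {"animal": ped.labels, "tbv_hw": tbv[:, 0], "tbv_cc": tbv[:, 1]}
        ),
        qtl=pd.DataFrame(
            {
                "snp_index": qtl_idx,
                "chrom": snp_map.chrom[qtl_idx],
                "pos": snp_map.pos[qtl_idx],
                "eff_hw": eff[:, 0],
                "eff_cc": eff[:, 1],
            }
        ),
        vc=vc,
        realized_var_u={
            "hw": float(np.var(tbv[: nf, 0])),
            "cc": float(np.var(tbv[: nf, 1])),
        },
        founder_freq=freqs,
    )
    return ds, truth, geno_all


def drift_population(
    census: int,
    n_generations: int,
    n_snps: int = 500,
    n_chromosomes: int = 5,
    chrom_length_morgan: float = 1.0,
    seed: int = 0,
    maf_floor: float = 0.05,
):
    """Closed random-mating population of constant census size.

    Every generation draws `census` offspring, each from a random sire and
    random dam of the previous generation (Poisson-like family sizes), so
    the expected effective size is close to the census size. Used as the
    simulation oracle for both inbreeding-based and LD-based Ne.

    Returns (Pedigree, GenotypeMatrix over all animals, SnpMap).
    """
    cfg = SimConfig(
        n_chromosomes=n_chromosomes,
        chrom_length_morgan=chrom_length_morgan,
        n_snps=n_snps,
        n_founders=census,
        maf_floor=maf_floor,
    )
    snp_map = default_snp_map(cfg)
    H_founder, _ = simulate_founders(cfg, derive_seed(seed, "drift-founders"))
    rng = np.random.default_rng(derive_seed(seed, "drift"))
    blocks = _chrom_blocks(snp_map, cfg.cm_per_mb)

    sire = [-1] * census
    dam = [-1] * census
    year = [0] * census
    sex = list(rng.integers(0, 2, census))
    while sum(sex[:census]) in (0, census):  # need both sexes
        sex = list(rng.integers(0, 2, census))
    H0a = H_founder[0::2][:census].copy()
    H1a = H_founder[1::2][:census].copy()

    prev = np.arange(census)
    for g in range(1, n_generations + 1):
        prev_sex = np.array([sex[i] for i in prev])
        males = prev[prev_sex == 1]
        females = prev[prev_sex == 0]
        offs_sire = males[rng.integers(len(males), size=census)]
        offs_dam = females[rng.integers(len(females), size=census)]
        start = len(sire)
        sire += list(offs_sire)
        dam += list(offs_dam)
        year += [g] * census
        new_sex = list(rng.integers(0, 2, census))
        while sum(new_sex) in (0, census):
            new_sex = list(rng.integers(0, 2, census))
        sex += new_sex
        g0 = _gametes(H0a, H1a, offs_sire, blocks, rng)
        g1 = _gametes(H0a, H1a, offs_dam, blocks, rng)
        H0a = np.vstack([H0a, g0])
        H1a = np.vstack([H1a, g1])
        prev = np.arange(start, start + census)

    ped = pg.from_arrays(sire, dam, generation=year)
    geno = gt.GenotypeMatrix((H0a + H1a).astype(float), ped.labels)
    return ped, geno, snp_map


def write_dataset(ds: Dataset, outdir, truth: SimTruth | None = None,
                  seed: int | None = None, cfg: SimConfig | None = None):
    """Write the dataset as plain-text files plus a manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pg.write_pedigree(ds.ped, out / "pedigree.csv")
    ds.phenos.to_csv(out / "phenotypes.csv", index=False)
    if ds.geno is not None:
        gdf = pd.DataFrame(ds.geno.dosages, columns=ds.snp_map.snp_ids)
        gdf.insert(0, "animal", ds.geno.animal_ids)
        gdf.to_csv(out / "genotypes.csv", index=False)
        ds.snp_map.to_frame().to_csv(out / "snp_map.csv", index=False)
    if truth is not None:
        truth.tbv.to_csv(out / "truth_tbv.csv", index=False)
        truth.qtl.to_csv(out / "truth_qtl.csv", index=False)
    manifest = {
        "seed": seed,
        "config": asdict(cfg) if cfg is not None else None,
        "config_hash": cfg.config_hash() if cfg is not None else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def read_dataset(indir, model_specs: dict | None = None,
                 vc: dict | None = None) -> Dataset:
    """Round-trip reader for write_dataset output."""
    ind = Path(indir)
    pdf = pd.read_csv(ind / "pedigree.csv")
    gen = pdf["year_class"].to_numpy() if "year_class" in pdf.columns else None
    ped = pg.from_arrays(
        pdf["sire"].to_numpy() - 1, pdf["dam"].to_numpy() - 1,
        labels=pdf["original_id"].to_numpy(), generation=gen,
    )
    phenos = pd.read_csv(ind / "phenotypes.csv")
    geno = snp_map = None
    if (ind / "genotypes.csv").exists():
        geno, snp_map = gt.read_dosage_matrix(
            ind / "genotypes.csv", ind / "snp_map.csv"
        )
    if model_specs is None:
        model_specs = {
            "hw": md.ModelSpec(trait="hw", factors=["year", "sex", "pond"],
                               covariates=[("age", ["sex"])], spawn_col="spawn"),
            "cc": md.ModelSpec(trait="cc", factors=["year", "sex", "pond"],
                               covariates=[("body_weight", ["year", "sex"])],
                               spawn_col="spawn"),
        }
    return Dataset(ped=ped, phenos=phenos, model_specs=model_specs,
                   vc=vc or {}, geno=geno, snp_map=snp_map)
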