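"""Linkage disequilibrium and effective population size.

LD between unphased genotypes uses the composite (Burrows-style)
disequilibrium D = cov(dosage_A, dosage_B) / 2, squared and normalized by
allele-frequency products:

    r^2 = D^2 / (p_A (1-p_A) p_B (1-p_B)).

Effective population size comes from three routes: a nonlinear
least-squares fit of the Sved decay curve E[r^2] = 1/(1 + 4 Ne d) to
per-pair r^2 against distance in Morgan; a closed-form inversion of the
chromosome-mean r^2, Ne = (4 d_t)^-1 [ (r^2 - 1/N)^-1 - alpha ] with the
sample-size correction 1/N and alpha = 2 when mutation is considered;
and (in the pedigree module) the per-generation rate of inbreeding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import genotypes as gt

__all__ = [
    "NeEstimate",
    "adjacent_r2",
    "pairwise_r2",
    "fit_sved_decay",
    "ne_from_mean_r2",
    "ld_summary",
]

DEFAULT_ALPHA = 2.0  # mutation considered


@dataclass
class NeEstimate:
    ne: float
    method: str
    chrom: int | None = None  # None = genome-wide
    converged: bool = True


def _composite_r2(dosA: np.ndarray, dosB: np.ndarray) -> float:
    """Composite-LD r^2 between two dosage vectors.

    Computed as the squared Pearson correlation of dosages (population
    moments). Under Hardy-Weinberg proportions cov(g_A, g_B) = 2D and
    var(g) = 2pq, so this equals D^2 / (p_A q_A p_B q_B) with the
    Burrows composite D; away from HWE it stays bounded by 1.
    """
    pA = dosA.mean() / 2.0
    pB = dosB.mean() / 2.0
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic SNP in LD computation; QC violation")
    vA = np.mean(dosA * dosA) - np.mean(dosA) ** 2
    vB = np.mean(dosB * dosB) - np.mean(dosB) ** 2
    cov = np.mean(dosA * dosB) - np.mean(dosA) * np.mean(dosB)
    return float(cov * cov / (vA * vB))


def _pair_frame(geno, snp_map, pairs_by_chrom, cm_per_mb):
    rows = []
    dos = geno.dosages
    for c, pairs in pairs_by_chrom:
        for i, j in pairs:
            d_morgan = abs(snp_map.pos[j] - snp_map.pos[i]) * cm_per_mb / 1e8
            rows.append(
                {
                    "chrom": int(c),
                    "snp_i": int(i),
                    "snp_j": int(j),
                    "dist_morgan": d_morgan,
                    "r2": _composite_r2(dos[:, i], dos[:, j]),
                }
            )
    return pd.DataFrame(rows)


def adjacent_r2(
    geno: gt.GenotypeMatrix, snp_map: gt.SnpMap, cm_per_mb: float = 1.0
) -> pd.DataFrame:
    """Composite r^2 for every within-chromosome adjacent SNP pair.

    Returns a tidy frame (chrom, snp_i, snp_j, dist_morgan, r2).
    """
    pairs_by_chrom = []
    for c in np.unique(snp_map.chrom):
        idx = np.nonzero(snp_map.chrom == c)[0]
        pairs_by_chrom.append((c, list(zip(idx[:-1], idx[1:]))))
    return _pair_frame(geno, snp_map, pairs_by_chrom, cm_per_mb)


def pairwise_r2(
    geno: gt.GenotypeMatrix,
    snp_map: gt.SnpMap,
    max_dist_bp: float = 20e6,
    cm_per_mb: float = 1.0,
    max_pairs_per_chrom: int | None = 20000,
    seed: int = 0,
) -> pd.DataFrame:
    """Composite r^2 for all within-chromosome pairs up to max_dist_bp
    (optionally subsampled), for decay curves beyond adjacent markers."""
    rng = np.random.default_rng(seed)
    pairs_by_chrom = []
    for c in np.unique(snp_map.chrom):
        idx = np.nonzero(snp_map.chrom == c)[0]
        pos = snp_map.pos[idx]
        pairs = [
            (idx[a], idx[b])
            for a in range(len(idx))
            for b in range(a + 1, len(idx))
            if pos[b] - pos[a] <= max_dist_bp
        ]
        if max_pairs_per_chrom is not None and len(pairs) > max_pairs_per_chrom:
            take = rng.choice(len(pairs), max_pairs_per_chrom, replace=False)
            pairs = [pairs[t] for t in sorted(take)]
        pairs_by_chrom.append((c, pairs))
    return _pair_frame(geno, snp_map, pairs_by_chrom, cm_per_mb)


def fit_sved_decay(records: pd.DataFrame, chrom: int | None = None) -> NeEstimate:
    """Nonlinear least squares of r^2 on the Sved curve 1/(1 + 4 Ne d).

    `records` is the output of adjacent_r2/pairwise_r2 (optionally
    restricted to one chromosome). Falls back to the mean-r^2 inversion
    flag when the fit fails to converge.
    """
    df = records if chrom is None else records[records["chrom"] == chrom]
    if len(df) < 10:
        raise ValueError("need >= 10 LD records with distance spread")
    d = df["dist_morgan"].to_numpy()
    r2 = df["r2"].to_numpy()

    def resid(log_ne):
        return 1.0 / (1.0 + 4.0 * np.exp(log_ne) * d) - r2

    r2m = np.clip(r2.mean(), 1e-6, 1 - 1e-6)
    ne0 = max((1.0 / r2m - 1.0) / (4.0 * max(d.mean(), 1e-9)), 1e-3)
    sol = least_squares(resid, x0=[np.log(ne0)], method="lm", xtol=1e-14,
                        ftol=1e-14)
    ne = float(np.exp(sol.x[0]))
    return NeEstimate(ne=ne, method="sved_fit", chrom=chrom,
                      converged=bool(sol.success))


def ne_from_mean_r2(
    r2_mean: float,
    d_t: float,
    n_genotyped: int | float = np.inf,
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Closed-form Ne from a chromosome-mean r^2.

    Ne = (4 d_t)^-1 [ (r2 - 1/N)^-1 - alpha ], with d_t the mean marker
    distance (Morgan) behind the mean r^2 and N the genotyped count.
    Returns NaN (flagged undefined) when r2 <= 1/N.
    """
    n_inv = 0.0 if np.isinf(n_genotyped) else 1.0 / n_genotyped
    if r2_mean <= n_inv:
        return float("nan")
    return float((1.0 / (4.0 * d_t)) * (1.0 / (r2_mean - n_inv) - alpha))


def ld_summary(
    records: pd.DataFrame,
    n_genotyped: int,
    alpha: float = DEFAULT_ALPHA,
    method: str = "mean_r2",
    weighting: str = "uniform",
) -> pd.DataFrame:
    """Per-chromosome mean adjacent r^2 and Ne, plus a genome-wide row.

    The genome-wide Ne is the unweighted mean of chromosome estimates by
    default; weighting="span" weights each chromosome by its covered map
    length (sum of pair distances).
    """
    rows = []
    for c, sub in records.groupby("chrom"):
        r2m = sub["r2"].mean()
        d_t = sub["dist_morgan"].mean()
        if method == "mean_r2":
            ne = ne_from_mean_r2(r2m, d_t, n_genotyped, alpha)
        elif method == "sved_fit":
            ne = fit_sved_decay(sub).ne
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"chrom": int(c), "mean_r2": r2m, "mean_dist_morgan": d_t,
                     "span_morgan": sub["dist_morgan"].sum(), "ne": ne})
    out = pd.DataFrame(rows)
    ok = out["ne"].notna()
    if weighting == "uniform":
        ne_genome = out.loc[ok, "ne"].mean()
    elif weighting == "span":
        w = out.loc[ok, "span_morgan"]
        ne_genome = float(np.average(out.loc[ok, "ne"], weights=w))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    genome = {
        "chrom": 0,
        "mean_r2": records["r2"].mean(),
        "mean_dist_morgan": records["dist_morgan"].mean(),
        "span_morgan": out["span_morgan"].sum(),
        "ne": ne_genome,
    }
    return pd.concat([out, pd.DataFrame([genome])], ignore_index=True)
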