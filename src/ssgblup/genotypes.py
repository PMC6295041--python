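"""Genomic relationships: SNP/animal quality control, allele frequencies,
the VanRaden genomic relationship matrix G, blending with the pedigree
submatrix A22, and assembly of the single-step H-inverse.

The central quantity is G = M D M' / (2 * sum_j p_j (1 - p_j)), where M
holds dosages centered by twice the current allele frequencies and D is a
diagonal matrix of SNP weights (identity for unweighted ssGBLUP). To keep
G invertible it is blended with a small fraction of A22. H-inverse is the
pedigree A-inverse with (G_blended^-1 - A22^-1) added into the genotyped
block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp

__all__ = [
    "GenotypeMatrix",
    "SnpMap",
    "QcReport",
    "HInverse",
    "snp_qc",
    "allele_frequencies",
    "build_G",
    "blend_G",
    "build_H_inverse",
    "read_dosage_matrix",
    "read_plink_raw",
]

MAX_DENSE_G = 20_000  # animals; memory guard for dense G


@dataclass
class SnpMap:
    """Per-SNP chromosome and physical position, sorted by (chrom, pos)."""

    chrom: np.ndarray
    pos: np.ndarray
    snp_ids: np.ndarray

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.snp_ids = np.asarray(self.snp_ids)
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(len(order))):
            raise ValueError("SNP map must be sorted by (chromosome, position)")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(
                    f"positions must be strictly increasing within chromosome {c}"
                )

    def __len__(self):
        return len(self.chrom)

    def subset(self, mask) -> "SnpMap":
        return SnpMap(self.chrom[mask], self.pos[mask], self.snp_ids[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp": self.snp_ids, "chrom": self.chrom, "pos": self.pos}
        )


@dataclass
class GenotypeMatrix:
    """Dosage matrix (animals x SNPs), values 0/1/2 with NaN for missing."""

    dosages: np.ndarray
    animal_ids: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.animal_ids = np.asarray(self.animal_ids)
        if self.dosages.shape[0] != len(self.animal_ids):
            raise ValueError("row count does not match animal_ids")

    @property
    def n_animals(self):
        return self.dosages.shape[0]

    @property
    def n_snps(self):
        return self.dosages.shape[1]

    def animal_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=1)

    def snp_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)


@dataclass
class QcReport:
    """Counts of animals/SNPs removed per filter."""

    n_animals_in: int
    n_snps_in: int
    animals_low_call: int = 0
    snps_low_call: int = 0
    snps_monomorphic: int = 0
    snps_low_maf: int = 0
    n_animals_out: int = 0
    n_snps_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("animals_in", self.n_animals_in),
            ("animals_removed_call_rate", self.animals_low_call),
            ("animals_out", self.n_animals_out),
            ("snps_in", self.n_snps_in),
            ("snps_removed_call_rate", self.snps_low_call),
            ("snps_removed_monomorphic", self.snps_monomorphic),
            ("snps_removed_maf", self.snps_low_maf),
            ("snps_out", self.n_snps_out),
        ]
        return pd.DataFrame(rows, columns=["filter", "count"])


def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Current allele frequencies p_j = mean dosage / 2 over non-missing calls."""
    return np.nanmean(geno.dosages, axis=0) / 2.0


def snp_qc(
    geno: GenotypeMatrix,
    snp_map: SnpMap | None = None,
    maf_min: float = 0.05,
    snp_call_min: float = 0.90,
    animal_call_min: float = 0.90,
    impute: bool = True,
):
    """Quality control on a raw dosage matrix.

    Animals with call rate < animal_call_min are removed first; SNP
    statistics (call rate, MAF, monomorphism) are then computed on the
    surviving animals. Inequalities are strict: a SNP at MAF exactly
    maf_min is retained. Remaining missing calls are imputed to the SNP
    mean dosage (2*p_j) so downstream centering leaves them neutral.

    Returns (GenotypeMatrix, SnpMap or None, QcReport).
    """
    report = QcReport(n_animals_in=geno.n_animals, n_snps_in=geno.n_snps)

    keep_animals = geno.animal_call_rate() >= animal_call_min
    report.animals_low_call = int(np.sum(~keep_animals))
    dos = geno.dosages[keep_animals].copy()
    ids = geno.animal_ids[keep_animals]

    call = 1.0 - np.mean(np.isnan(dos), axis=0) if len(dos) else np.zeros(geno.n_snps)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dos, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    low_call = call < snp_call_min
    mono = (p <= 0.0) | (p >= 1.0) | np.isnan(p)
    low_maf = (maf < maf_min) & ~mono
    keep_snps = ~(low_call | mono | low_maf)
    report.snps_low_call = int(np.sum(low_call))
    report.snps_monomorphic = int(np.sum(mono & ~low_call))
    report.snps_low_maf = int(np.sum(low_maf & ~low_call))

    if not np.any(keep_snps):
        raise ValueError(f"QC removed all SNPs: {report.to_frame().to_dict('records')}")

    dos = dos[:, keep_snps]
    if impute and np.any(np.isnan(dos)):
        col_mean = np.nanmean(dos, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(dos))
        dos[nan_r, nan_c] = col_mean[nan_c]

    report.n_animals_out = len(ids)
    report.n_snps_out = int(np.sum(keep_snps))
    out_map = snp_map.subset(keep_snps) if snp_map is not None else None
    return GenotypeMatrix(dos, ids), out_map, report


def build_G(
    geno: GenotypeMatrix,
    p: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """VanRaden genomic relationship matrix.

    G = M diag(D) M' / (2 * sum_j p_j (1-p_j)), M = dosages - 2p.
    `weights` (the diagonal of D) defaults to all ones.
    """
    if geno.n_animals > MAX_DENSE_G:
        raise MemoryError(f"dense G refused for {geno.n_animals} animals")
    if np.any(np.isnan(geno.dosages)):
        raise ValueError("missing dosages; run snp_qc with impute=True first")
    if p is None:
        p = allele_frequencies(geno)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("zero denominator: all SNPs monomorphic at given p")
    M = geno.dosages - 2.0 * p
    if weights is None:
        G = M @ M.T / denom
    else:
        weights = np.asarray(weights, dtype=float)
        G = (M * weights) @ M.T / denom
    return G


def blend_G(G: np.ndarray, A22: np.ndarray, beta: float = 0.05) -> np.ndarray:
    """Blend G with a fraction beta of A22: (1-beta)*G + beta*A22."""
    if not (0.0 <= beta < 1.0):
        raise ValueError(f"blending fraction must be in [0, 1), got {beta}")
    if G.shape != A22.shape:
        raise ValueError("G and A22 are not conformable")
    return (1.0 - beta) * G + beta * A22


@dataclass
class HInverse:
    """Single-step relationship inverse: sparse A-inverse plus the dense
    (G^-1 - A22^-1) correction in the genotyped block.

    `genotyped_index` holds 0-based positions of genotyped animals within
    the pedigree ordering.
    """

    A_inv: sp.spmatrix
    genotyped_index: np.ndarray
    correction: np.ndarray | None = None  # dense G^-1 - A22^-1 block
    _matrix: sp.csr_matrix | None = field(default=None, repr=False)

    @property
    def n(self):
        return self.A_inv.shape[0]

    def as_sparse(self) -> sp.csr_matrix:
        """Assemble the explicit sparse H-inverse matrix."""
        if self._matrix is None:
            H = self.A_inv.tocoo(copy=True)
            if self.correction is not None and len(self.genotyped_index):
                g = self.genotyped_index
                rows = np.repeat(g, len(g))
                cols = np.tile(g, len(g))
                corr = sp.coo_matrix(
                    (self.correction.ravel(), (rows, cols)), shape=H.shape
                )
                H = (H + corr).tocsr()
            else:
                H = H.tocsr()
            self._matrix = H
        return self._matrix


def build_H_inverse(
    A_inv: sp.spmatrix,
    A22: np.ndarray | None,
    G_blended: np.ndarray | None,
    genotyped_index,
) -> HInverse:
    """Assemble H-inverse from the pedigree inverse and the genomic block.

    With an empty genotyped set (or G_blended identical to A22) this
    reduces exactly to A-inverse.
    """
    genotyped_index = np.asarray(genotyped_index, dtype=np.int64)
    if len(genotyped_index) == 0:
        return HInverse(A_inv=sp.csr_matrix(A_inv), genotyped_index=genotyped_index)
    try:
        cF = la.cho_factor(G_blended)
        G_inv = la.cho_solve(cF, np.eye(G_blended.shape[0]))
    except la.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "blended G is singular; increase the A22 blending fraction"
        ) from err
    A22_inv = la.cho_solve(la.cho_factor(A22), np.eye(A22.shape[0]))
    corr = G_inv - A22_inv
    return HInverse(
        A_inv=sp.csr_matrix(A_inv),
        genotyped_index=genotyped_index,
        correction=corr,
    )


def read_dosage_matrix(geno_path, map_path=None):
    """Read a plain-text dosage matrix.

    Layout: header row of SNP ids, one row per animal, first column the
    animal id, remaining columns dosages 0/1/2 with NA or -9 for missing.
    Optional sidecar SNP map CSV with columns snp, chrom, pos.
    """
    df = pd.read_csv(geno_path, sep=None, engine="python")
    animal_ids = df.iloc[:, 0].to_numpy()
    dos = df.iloc[:, 1:].to_numpy(dtype=float)
    dos[dos == -9] = np.nan
    geno = GenotypeMatrix(dos, animal_ids)
    snp_map = None
    if map_path is not None:
        m = pd.read_csv(map_path)
        snp_map = SnpMap(m["chrom"].to_numpy(), m["pos"].to_numpy(), m["snp"].to_numpy())
    return geno, snp_map


def read_plink_raw(raw_path, map_path=None):
    """Read a PLINK .raw additive-coding file (and optional .map).

    .raw: whitespace-delimited with FID IID PAT MAT SEX PHENOTYPE then one
    column per SNP holding allele dosage or NA. .map: chrom, snp, cM, bp.
    """
    df = pd.read_csv(raw_path, sep=r"\s+")
    meta = {"FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"}
    snp_cols = [c for c in df.columns if c not in meta]
    dos = df[snp_cols].to_numpy(dtype=float)
    geno = GenotypeMatrix(dos, df["IID"].to_numpy())
    snp_map = None
    if map_path is not None:
        m = pd.read_csv(map_path, sep=r"\s+", header=None,
                        names=["chrom", "snp", "cm", "pos"])
        snp_map = SnpMap(m["chrom"].to_numpy(), m["pos"].to_numpy(), m["snp"].to_numpy())
    return geno, snp_map
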