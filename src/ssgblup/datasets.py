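"""Dataset bundle tying together pedigree, genotypes, phenotypes, and
model wiring, with lazily built relationship matrices.

Both simulated and file-based data flow through this container, so the
evaluation code downstream (fitting, validation, GWAS, LD) is agnostic
about where the data came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import genotypes as gt
from . import model as md
from . import pedigree as pg

__all__ = ["Dataset"]


@dataclass
class Dataset:
    ped: pg.Pedigree
    phenos: pd.DataFrame
    model_specs: dict  # trait -> ModelSpec
    vc: dict = field(default_factory=dict)  # trait -> VarianceComponents
    geno: gt.GenotypeMatrix | None = None
    snp_map: gt.SnpMap | None = None
    qc_report: gt.QcReport | None = None
    blend_beta: float = 0.05
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def genotyped_ids(self) -> np.ndarray:
        if self.geno is None:
            return np.array([], dtype=np.int64)
        return self.geno.animal_ids

    @property
    def genotyped_index(self) -> np.ndarray:
        """0-based pedigree positions of genotyped animals."""
        if self.geno is None:
            return np.array([], dtype=np.int64)
        return self.ped.internal(self.geno.animal_ids)

    # --- lazily built relationship structures -------------------------
    def F(self) -> np.ndarray:
        if "F" not in self._cache:
            self._cache["F"] = pg.compute_inbreeding(self.ped)
        return self._cache["F"]

    def A_inv(self) -> sp.csr_matrix:
        if "A_inv" not in self._cache:
            self._cache["A_inv"] = pg.build_A_inverse(self.ped, self.F())
        return self._cache["A_inv"]

    def A22(self) -> np.ndarray:
        if "A22" not in self._cache:
            self._cache["A22"] = pg.extract_A22(self.ped, self.genotyped_ids)
        return self._cache["A22"]

    def allele_freq(self) -> np.ndarray:
        if "p" not in self._cache:
            self._cache["p"] = gt.allele_frequencies(self.geno)
        return self._cache["p"]

    def G(self, weights: np.ndarray | None = None) -> np.ndarray:
        if weights is not None:
            return gt.build_G(self.geno, self.allele_freq(), weights)
        if "G" not in self._cache:
            self._cache["G"] = gt.build_G(self.geno, self.allele_freq())
        return self._cache["G"]

    def G_blended(self, weights: np.ndarray | None = None) -> np.ndarray:
        if weights is not None:
            return gt.blend_G(self.G(weights), self.A22(), self.blend_beta)
        if "G_blended" not in self._cache:
            self._cache["G_blended"] = gt.blend_G(
                self.G(), self.A22(), self.blend_beta
            )
        return self._cache["G_blended"]

    def H_inv(self, weights: np.ndarray | None = None) -> gt.HInverse:
        if self.geno is None or self.geno.n_animals == 0:
            # no genomic information: H-inverse degenerates to A-inverse
            return gt.build_H_inverse(self.A_inv(), None, None, [])
        if weights is not None:
            return gt.build_H_inverse(
                self.A_inv(), self.A22(), self.G_blended(weights),
                self.genotyped_index,
            )
        if "H_inv" not in self._cache:
            self._cache["H_inv"] = gt.build_H_inverse(
                self.A_inv(), self.A22(), self.G_blended(), self.genotyped_index
            )
        return self._cache["H_inv"]

    def relationship_inverse(self, method: str, weights=None) -> sp.spmatrix:
        """K-inverse for the requested evaluation method
        ("blup" -> A-inverse, "ssgblup" -> H-inverse)."""
        if method == "blup":
            return self.A_inv()
        if method == "ssgblup":
            return self.H_inv(weights).as_sparse()
        raise ValueError(f"unknown method {method!r}")

    def design(self, trait: str, phenos: pd.DataFrame | None = None) -> md.DesignMatrices:
        df = self.phenos if phenos is None else phenos
        return md.build_design(df, self.model_specs[trait], self.ped)

    def fit(
        self,
        trait: str,
        method: str = "blup",
        phenos: pd.DataFrame | None = None,
        vc: md.VarianceComponents | None = None,
        weights=None,
        **kwargs,
    ) -> md.Solutions:
        """One BLUP / ssGBLUP fit of a trait, optionally on masked
        phenotypes or with SNP weights (weighted ssGBLUP)."""
        dm = self.design(trait, phenos)
        K_inv = self.relationship_inverse(method, weights)
        use_vc = vc if vc is not None else self.vc[trait]
        return md.solve_mme(dm, K_inv, use_vc, **kwargs)
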