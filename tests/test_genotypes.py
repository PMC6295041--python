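import numpy as np
import pytest
import scipy.linalg as la
import scipy.sparse as sp

from ssgblup import genotypes as gt
from ssgblup import pedigree as pg
from conftest import random_pedigree


def make_geno(dos, ids=None):
    dos = np.asarray(dos, dtype=float)
    if ids is None:
        ids = np.arange(1, dos.shape[0] + 1)
    return gt.GenotypeMatrix(dos, ids)


class TestSnpQc:
    def test_monomorphic_snp_removed(self):
        dos = np.array(
            [[0, 1, 2, 2, 0], [1, 1, 2, 0, 1], [2, 0, 2, 1, 2], [0, 1, 2, 2, 1]]
        )
        out, _, rep = gt.snp_qc(make_geno(dos))
        assert out.n_snps == 4
        assert rep.snps_monomorphic == 1

    def test_maf_exactly_at_threshold_retained(self):
        # 10 animals, one SNP with exactly MAF 0.05 (one het in 10)
        dos = np.zeros((10, 2))
        dos[:, 0] = [0, 1, 2, 1, 0, 2, 1, 0, 1, 2]
        dos[0, 1] = 1  # p = 0.05
        out, _, rep = gt.snp_qc(make_geno(dos), maf_min=0.05)
        assert out.n_snps == 2
        # strictly below the threshold is removed
        dos[0, 1] = 0.0
        dos[1, 1] = 0.5  # p = 0.025 (synthetic fractional dosage)
        out, _, rep = gt.snp_qc(make_geno(dos), maf_min=0.05)
        assert out.n_snps == 1

    def test_matches_bruteforce_filter(self):
        rng = np.random.default_rng(3)
        dos = rng.integers(0, 3, size=(50, 100)).astype(float)
        dos[:, 0] = 2  # monomorphic
        dos[:45, 1] = np.nan  # low SNP call rate
        dos[2, 2:80] = np.nan  # low animal call rate
        lowmaf = rng.integers(0, 50, 3)
        dos[:, 5] = 0.0
        dos[lowmaf[0], 5] = 1  # MAF 0.01-ish

        out, _, rep = gt.snp_qc(make_geno(dos))

        # independent recount: animal filter first, then SNP stats
        keep_a = np.mean(np.isnan(dos), axis=1) <= 0.10
        sub = dos[keep_a]
        call = 1 - np.mean(np.isnan(sub), axis=0)
        p = np.nanmean(sub, axis=0) / 2
        maf = np.minimum(p, 1 - p)
        keep_s = (call >= 0.9) & (maf >= 0.05) & (p > 0) & (p < 1)
        assert out.n_animals == keep_a.sum()
        assert out.n_snps == keep_s.sum()

    def test_imputation_leaves_no_missing(self):
        rng = np.random.default_rng(1)
        dos = rng.integers(0, 3, size=(30, 20)).astype(float)
        dos[rng.random(dos.shape) < 0.05] = np.nan
        out, _, _ = gt.snp_qc(make_geno(dos))
        assert not np.any(np.isnan(out.dosages))

    def test_all_snps_removed_is_fatal(self):
        dos = np.full((4, 3), 2.0)
        with pytest.raises(ValueError, match="all SNPs"):
            gt.snp_qc(make_geno(dos))


class TestAlleleFrequencies:
    def test_all_homozygous_alt(self):
        assert gt.allele_frequencies(make_geno([[2, 2], [2, 2]])).tolist() == [1, 1]

    def test_balanced(self):
        p = gt.allele_frequencies(make_geno([[0], [1], [2]]))
        assert p[0] == pytest.approx(0.5)

    def test_matches_allele_counting(self):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(40, 25)).astype(float)
        p = gt.allele_frequencies(make_geno(dos))
        counts = dos.sum(axis=0) / (2 * dos.shape[0])
        np.testing.assert_allclose(p, counts)


class TestBuildG:
    def test_two_animal_worked_example(self):
        geno = make_geno([[2, 2], [0, 0]])
        G = gt.build_G(geno, p=np.array([0.5, 0.5]))
        np.testing.assert_allclose(G, [[2, -2], [-2, 2]])

    def test_identical_heterozygotes_give_zero(self):
        geno = make_geno(np.ones((4, 3)))
        G = gt.build_G(geno, p=np.full(3, 0.5))
        np.testing.assert_allclose(G, 0.0)

    def test_default_weights_are_identity(self):
        rng = np.random.default_rng(2)
        geno = make_geno(rng.integers(0, 3, (10, 30)))
        p = gt.allele_frequencies(geno)
        np.testing.assert_allclose(
            gt.build_G(geno, p), gt.build_G(geno, p, weights=np.ones(30))
        )

    def test_column_order_invariance(self):
        rng = np.random.default_rng(4)
        dos = rng.integers(0, 3, (12, 40)).astype(float)
        perm = rng.permutation(40)
        G1 = gt.build_G(make_geno(dos))
        G2 = gt.build_G(make_geno(dos[:, perm]))
        np.testing.assert_allclose(G1, G2, atol=1e-12)

    def test_hardy_weinberg_mean_diagonal_near_one(self):
        rng = np.random.default_rng(8)
        n, m = 200, 5000
        freqs = rng.uniform(0.05, 0.95, m)
        dos = rng.binomial(2, freqs, size=(n, m)).astype(float)
        G = gt.build_G(make_geno(dos))
        assert np.mean(np.diag(G)) == pytest.approx(1.0, abs=0.05)

    def test_zero_denominator_fatal(self):
        geno = make_geno([[2, 2], [2, 2]])
        with pytest.raises(ValueError, match="denominator"):
            gt.build_G(geno, p=np.array([1.0, 1.0]))


class TestBlendG:
    def test_beta_zero_unchanged(self):
        G = np.array([[1.0, 0.2], [0.2, 1.0]])
        np.testing.assert_array_equal(gt.blend_G(G, np.eye(2), 0.0), G)

    def test_G_equal_A22_fixed_point(self):
        A22 = np.array([[1.0, 0.5], [0.5, 1.0]])
        np.testing.assert_allclose(gt.blend_G(A22, A22, 0.3), A22)

    def test_worked_blend(self):
        G = np.array([[2.0, -2.0], [-2.0, 2.0]])
        out = gt.blend_G(G, np.eye(2), 0.05)
        np.testing.assert_allclose(out, [[1.95, -1.9], [-1.9, 1.95]])

    def test_invalid_beta_fatal(self):
        with pytest.raises(ValueError):
            gt.blend_G(np.eye(2), np.eye(2), 1.0)

    def test_blending_preserves_spd(self):
        rng = np.random.default_rng(9)
        dos = rng.binomial(2, rng.uniform(0.1, 0.9, 300), size=(40, 300))
        G = gt.build_G(make_geno(dos))
        ped = pg.from_arrays([-1] * 40, [-1] * 40)
        A22 = pg.extract_A22(ped, ped.labels)
        Gb = gt.blend_G(G, A22, 0.05)
        la.cholesky(Gb)  # raises if not positive definite
        np.testing.assert_allclose(Gb, Gb.T)


class TestHInverse:
    def test_empty_genotyped_set_reduces_to_A_inverse(self):
        ped = random_pedigree(30, 5, 0)
        A_inv = pg.build_A_inverse(ped)
        H = gt.build_H_inverse(A_inv, None, None, [])
        assert (H.as_sparse() != A_inv).nnz == 0

    def test_G_equal_A22_reduces_to_A_inverse(self):
        ped = random_pedigree(30, 5, 1)
        A_inv = pg.build_A_inverse(ped)
        gids = ped.labels[-8:]
        A22 = pg.extract_A22(ped, gids)
        H = gt.build_H_inverse(A_inv, A22, A22.copy(), ped.internal(gids))
        assert np.abs((H.as_sparse() - A_inv).toarray()).max() < 1e-8

    def test_matches_dense_H_oracle(self):
        # 10-animal pedigree, 4 genotyped: H assembled directly then inverted
        ped = random_pedigree(10, 4, 2)
        gids = ped.labels[-4:]
        gidx = ped.internal(gids)
        A = pg.tabular_A(ped)
        A22 = A[np.ix_(gidx, gidx)]
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, rng.uniform(0.2, 0.8, 50), size=(4, 50)).astype(float)
        G = gt.build_G(gt.GenotypeMatrix(dos, gids))
        Gb = gt.blend_G(G, A22, 0.05)

        # textbook construction: H = A + nonzero block adjustments
        A12 = np.delete(A[:, gidx], gidx, axis=0)
        A11 = np.delete(np.delete(A, gidx, 0), gidx, 1)
        A22i = np.linalg.inv(A22)
        H = A.copy()
        diff = Gb - A22
        H[np.ix_(gidx, gidx)] = Gb
        other = np.setdiff1d(np.arange(10), gidx)
        H[np.ix_(other, gidx)] = A12 @ A22i @ Gb
        H[np.ix_(gidx, other)] = (A12 @ A22i @ Gb).T
        H[np.ix_(other, other)] = A11 - A12 @ A22i @ A12.T + (
            A12 @ A22i @ Gb @ A22i @ A12.T
        )
        H_inv_oracle = np.linalg.inv(H)

        Hi = gt.build_H_inverse(pg.build_A_inverse(ped), A22, Gb, gidx)
        np.testing.assert_allclose(
            Hi.as_sparse().toarray(), H_inv_oracle, atol=1e-8
        )

    def test_singular_G_fatal(self):
        ped = random_pedigree(6, 3, 3)
        gids = ped.labels[:3]
        A22 = pg.extract_A22(ped, gids)
        G_sing = np.ones((3, 3))
        with pytest.raises(np.linalg.LinAlgError, match="blend"):
            gt.build_H_inverse(pg.build_A_inverse(ped), A22, G_sing,
                               ped.internal(gids))


class TestReaders:
    def test_dosage_matrix_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        dos = rng.integers(0, 3, (6, 4)).astype(float)
        dos[0, 1] = np.nan
        lines = ["animal," + ",".join(f"s{j}" for j in range(4))]
        for i in range(6):
            vals = ["NA" if np.isnan(v) else str(int(v)) for v in dos[i]]
            lines.append(f"{i+1}," + ",".join(vals))
        f = tmp_path / "geno.csv"
        f.write_text("\n".join(lines))
        m = tmp_path / "map.csv"
        m.write_text("snp,chrom,pos\n" + "\n".join(
            f"s{j},1,{(j+1)*1000}" for j in range(4)))
        geno, snp_map = gt.read_dosage_matrix(f, m)
        np.testing.assert_allclose(geno.dosages, dos)
        assert len(snp_map) == 4

    def test_plink_raw(self, tmp_path):
        f = tmp_path / "g.raw"
        f.write_text(
            "FID IID PAT MAT SEX PHENOTYPE snp1_A snp2_T\n"
            "0 101 0 0 1 -9 2 0\n"
            "0 102 0 0 2 -9 NA 1\n"
        )
        geno, _ = gt.read_plink_raw(f)
        assert geno.animal_ids.tolist() == [101, 102]
        assert np.isnan(geno.dosages[1, 0])
        assert geno.dosages[0, 0] == 2
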