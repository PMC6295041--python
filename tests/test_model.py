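import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ssgblup import model as md
from ssgblup import pedigree as pg
from ssgblup import validation as vl
from conftest import random_pedigree


def two_animal_setup(y, lam):
    """Mean + animal model on two unrelated phenotyped animals."""
    ped = pg.from_arrays([-1, -1], [-1, -1])
    df = pd.DataFrame({"animal": [1, 2], "y": y})
    spec = md.ModelSpec(trait="y", factors=[], covariates=[], spawn_col=None)
    dm = md.build_design(df, spec, ped)
    vc = md.VarianceComponents(sigma2_u=1.0 / lam, sigma2_p=0.0, sigma2_e=1.0)
    return dm, sp.identity(2, format="csr"), vc


class TestBuildDesign:
    def test_single_cell_plus_nested_age(self):
        ped = pg.from_arrays([-1, -1], [-1, -1])
        df = pd.DataFrame(
            {"animal": [1, 2], "y": [10.0, 12.0], "year": [1, 1],
             "sex": ["M", "M"], "pond": [1, 1], "age": [400.0, 410.0]}
        )
        spec = md.ModelSpec(trait="y", factors=["year", "sex", "pond"],
                            covariates=[("age", ["sex"])], spawn_col=None)
        dm = md.build_design(df, spec, ped)
        assert dm.X.shape == (2, 2)  # one cell column + one age-in-sex slope
        np.testing.assert_allclose(dm.X[:, 0], 1.0)
        np.testing.assert_allclose(dm.X[:, 1], [400.0, 410.0])

    def test_unphenotyped_animal_stays_in_equations(self):
        ped = pg.from_arrays([-1, -1, 0], [-1, -1, 1])
        df = pd.DataFrame({"animal": [1, 2], "y": [5.0, 6.0]})
        spec = md.ModelSpec(trait="y", factors=[], covariates=[], spawn_col=None)
        dm = md.build_design(df, spec, ped)
        assert dm.Z.shape == (2, 3)  # all three animals get equations
        vc = md.VarianceComponents(1.0, 0.0, 1.0)
        sol = md.solve_mme(dm, pg.build_A_inverse(ped), vc)
        assert len(sol.u) == 3

    def test_hand_built_dummy_coding(self):
        ped = pg.from_arrays([-1] * 4, [-1] * 4)
        df = pd.DataFrame(
            {"animal": [1, 2, 3, 4], "y": [1.0, 2, 3, 4],
             "grp": ["a", "a", "b", "b"], "x": [1.0, 2, 3, 4]}
        )
        spec = md.ModelSpec(trait="y", factors=["grp"],
                            covariates=[("x", ["grp"])], spawn_col=None)
        dm = md.build_design(df, spec, ped)
        X_hand = np.array(
            [[1, 0, 1, 0], [1, 0, 2, 0], [0, 1, 0, 3], [0, 1, 0, 4]], float
        )
        b = np.array([0.5, -0.5, 2.0, 1.0])
        np.testing.assert_allclose(dm.X @ b, X_hand @ b)

    def test_unknown_animal_fatal(self):
        ped = pg.from_arrays([-1], [-1])
        df = pd.DataFrame({"animal": [42], "y": [1.0]})
        spec = md.ModelSpec(trait="y", factors=[], covariates=[], spawn_col=None)
        with pytest.raises(pg.PedigreeError):
            md.build_design(df, spec, ped)


class TestSolveMme:
    def test_two_animal_closed_form(self):
        y = np.array([3.0, 7.0])
        lam = 2.5
        dm, K_inv, vc = two_animal_setup(y, lam)
        sol = md.solve_mme(dm, K_inv, vc)
        b_hat = sol.b[0]
        np.testing.assert_allclose(sol.u, (y - b_hat) / (1 + lam), atol=1e-10)

    def test_shrinkage_limit(self):
        y = np.array([3.0, 7.0])
        dm, K_inv, _ = two_animal_setup(y, 1.0)
        vc = md.VarianceComponents(1e-9, 0.0, 1.0)  # lambda -> 1e9
        sol = md.solve_mme(dm, K_inv, vc)
        assert np.abs(sol.u).max() < 1e-6
        assert sol.b[0] == pytest.approx(y.mean())

    def test_pcg_matches_direct(self, small_ds):
        ds, _, _ = small_ds
        d = ds.fit("hw", "ssgblup", solver="direct")
        p = ds.fit("hw", "ssgblup", solver="pcg", tol=1e-13)
        assert np.abs(d.u - p.u).max() < 1e-6 * max(np.abs(d.u).max(), 1.0)

    def test_record_order_invariance(self, small_ds):
        ds, _, _ = small_ds
        sol1 = ds.fit("hw", "blup")
        shuffled = ds.phenos.sample(frac=1.0, random_state=1).reset_index(drop=True)
        sol2 = ds.fit("hw", "blup", phenos=shuffled)
        np.testing.assert_allclose(sol1.u, sol2.u, atol=1e-8)

    def test_normal_equation_identity(self, small_ds):
        # X-weighted residuals vanish at the solution
        ds, _, _ = small_ds
        dm = ds.design("hw")
        sol = ds.fit("hw", "blup")
        fitted = dm.X @ sol.b + dm.Z @ sol.u + dm.W @ sol.pe
        resid = dm.y - fitted
        lhs = dm.X.T @ resid
        assert np.abs(lhs).max() < 1e-6 * np.abs(dm.X.T @ dm.y).max()


class TestSsgblupReductions:
    def test_no_genotypes_equals_blup(self, small_ds):
        import dataclasses

        ds, _, _ = small_ds
        ds2 = dataclasses.replace(ds, geno=None, snp_map=None, _cache={})
        sol_b = ds2.fit("hw", "blup")
        sol_s = ds2.fit("hw", "ssgblup")
        np.testing.assert_array_equal(sol_b.u, sol_s.u)

    def test_G_replaced_by_A22_equals_blup(self, small_ds):
        from ssgblup import genotypes as gt

        ds, _, _ = small_ds
        A22 = ds.A22()
        H = gt.build_H_inverse(ds.A_inv(), A22, A22.copy(), ds.genotyped_index)
        dm = ds.design("hw")
        sol_s = md.solve_mme(dm, H.as_sparse(), ds.vc["hw"])
        sol_b = md.solve_mme(dm, ds.A_inv(), ds.vc["hw"])
        np.testing.assert_allclose(sol_s.u, sol_b.u, atol=1e-6)


class TestEmReml:
    def test_null_signal_collapses_to_boundary(self):
        # iid noise on a family-structured pedigree: both the additive
        # and common-environment shares should collapse toward zero
        rng = np.random.default_rng(0)
        nf = 60
        sire = [-1] * nf
        dam = [-1] * nf
        spawn = []
        for fam in range(50):
            s, d = 2 * (fam % 30), 2 * (fam % 30) + 1
            for _ in range(8):
                sire.append(s)
                dam.append(d)
                spawn.append(fam)
        ped = pg.from_arrays(sire, dam)
        offs = np.arange(nf, ped.n)
        df = pd.DataFrame(
            {"animal": ped.labels[offs], "y": rng.normal(0, 1, len(offs)),
             "spawn": spawn}
        )
        spec = md.ModelSpec(trait="y", factors=[], covariates=[],
                            spawn_col="spawn")
        dm = md.build_design(df, spec, ped)
        vc, hist = md.em_reml(dm, pg.build_A_inverse(ped), max_rounds=80,
                              tol=1e-5)
        assert vc.h2 + vc.c2 < 0.12
        assert vc.sigma2_e == pytest.approx(1.0, rel=0.2)

    def test_loglik_grid_maximized_at_em_fixed_point(self):
        rng = np.random.default_rng(1)
        ped = random_pedigree(120, 20, 5)
        A = pg.tabular_A(ped)
        u = np.linalg.cholesky(A + 1e-10 * np.eye(ped.n)) @ rng.standard_normal(
            ped.n
        ) * np.sqrt(0.4)
        df = pd.DataFrame(
            {"animal": ped.labels,
             "y": 3.0 + u + rng.normal(0, np.sqrt(0.6), ped.n)}
        )
        spec = md.ModelSpec(trait="y", factors=[], covariates=[], spawn_col=None)
        dm = md.build_design(df, spec, ped)
        A_inv = pg.build_A_inverse(ped)
        vc, _ = md.em_reml(dm, A_inv, max_rounds=200, tol=1e-8)
        ll_hat = md.reml_loglik(dm, A_inv, vc)
        for scale in (0.7, 0.85, 1.2, 1.5):
            other = md.VarianceComponents(
                vc.sigma2_u * scale, vc.sigma2_p, vc.sigma2_e
            )
            assert md.reml_loglik(dm, A_inv, other) <= ll_hat + 1e-6

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(2)
        ped = random_pedigree(100, 20, 6)
        df = pd.DataFrame(
            {"animal": ped.labels, "y": rng.normal(10, 2, ped.n)}
        )
        spec = md.ModelSpec(trait="y", factors=[], covariates=[], spawn_col=None)
        dm = md.build_design(df, spec, ped)
        _, hist = md.em_reml(dm, pg.build_A_inverse(ped), max_rounds=30,
                             tol=1e-8, track_loglik=True)
        ll = np.array(hist["loglik"])
        assert np.all(np.diff(ll) >= -1e-6)


class TestAdjustedPhenotypes:
    def test_zero_effects(self):
        y = np.array([1.0, 2.0])
        X = np.ones((2, 1))
        np.testing.assert_array_equal(
            md.adjusted_phenotypes(y, X, np.zeros(1)), y
        )

    def test_intercept_only(self):
        y = np.array([4.0, 6.0])
        X = np.ones((2, 1))
        np.testing.assert_allclose(
            md.adjusted_phenotypes(y, X, np.array([5.0])), [-1.0, 1.0]
        )

    def test_manual_product(self):
        y = np.array([1.0, 2.0, 3.0])
        X = np.array([[1, 0.5], [1, 1.0], [1, 1.5]])
        b = np.array([0.5, 2.0])
        np.testing.assert_allclose(
            md.adjusted_phenotypes(y, X, b), y - X @ b
        )

    def test_dimension_mismatch_fatal(self):
        with pytest.raises(ValueError):
            md.adjusted_phenotypes(np.ones(3), np.ones((3, 2)), np.ones(3))


class TestParentAverage:
    def test_simple_average(self, trio_ped):
        pa = md.parent_average(np.array([2.0, 4.0, 0.0]), trio_ped)
        assert pa[2] == pytest.approx(3.0)

    def test_unknown_parents_give_zero(self, trio_ped):
        pa = md.parent_average(np.array([2.0, 4.0, 0.0]), trio_ped)
        assert pa[0] == 0.0 and pa[1] == 0.0

    def test_blup_fullsibs_collapse_to_pa_but_ssgblup_spreads(self, small_ds):
        # unphenotyped genotyped full sibs: identical EBV under pedigree
        # BLUP (parent average), distinct GEBV with genomic information
        ds, _, _ = small_ds
        fams = ds.ped.families()
        gset = set(ds.genotyped_ids.tolist())
        gen = ds.ped.generations()
        last = gen.max()
        target = None
        for fam, members in fams.items():
            g = [m for m in members if ds.ped.labels[m] in gset and gen[m] == last]
            if len(g) >= 4:
                target = members
                break
        assert target is not None
        labels = ds.ped.labels[target]
        masked = vl.masked_table(ds, "hw", labels)
        sol_b = ds.fit("hw", "blup", phenos=masked)
        sol_s = ds.fit("hw", "ssgblup", phenos=masked)
        u_b = sol_b.u[target]
        pa = md.parent_average(sol_b.u, ds.ped)[target]
        np.testing.assert_allclose(u_b, pa, atol=1e-6)
        g_members = [m for m in target if ds.ped.labels[m] in gset]
        assert np.std(sol_s.u[g_members]) > 1e-3


class TestSelectionIndex:
    def test_identical_traits_reduce_to_zscore(self):
        v = np.array([1.0, 2.0, 4.0])
        z = (v - v.mean()) / v.std()
        np.testing.assert_allclose(md.selection_index(v, v), z)

    def test_best_in_both_ranks_first(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=20)
        b = rng.normal(size=20)
        a[3] = a.max() + 1
        b[3] = b.max() + 1
        assert np.argmax(md.selection_index(a, b)) == 3

    def test_matches_hand_computation(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=15), rng.normal(size=15)
        za = (a - a.mean()) / a.std()
        zb = (b - b.mean()) / b.std()
        np.testing.assert_allclose(md.selection_index(a, b), (za + zb) / 2)

    def test_zero_variance_fatal(self):
        with pytest.raises(ValueError):
            md.selection_index(np.ones(5), np.arange(5.0))
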