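"""Animal-model machinery: design matrices, Henderson's mixed-model
equations (MME), EM-REML variance components, adjusted phenotypes, parent
averages, and the two-trait standardized selection index.

The model for a growth trait is

    y = Xb + Zu + Wp + e,

with b fixed effects (a year-sex-pond interaction plus nested linear
covariates, e.g. age within sex for harvest weight or body weight within
year-sex for residual carcass weight), u the additive genetic effect for
every pedigree animal with Var(u) = K * sigma2_u (K = A for pedigree BLUP
or H for single-step), p a common-environment effect shared by full sibs
reared in the same spawn tank with Var(p) = I * sigma2_p, and e the
residual.

Solving the MME with K-inverse = A-inverse gives pedigree BLUP; swapping
in H-inverse gives ssGBLUP. Nothing else changes, which is the point of
the single-step formulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .pedigree import Pedigree

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "Solutions",
    "DesignMatrices",
    "build_design",
    "solve_mme",
    "em_reml",
    "reml_loglik",
    "adjusted_phenotypes",
    "parent_average",
    "selection_index",
]

DENSE_SOLVE_MAX = 5000  # equations; above this use preconditioned CG


@dataclass
class ModelSpec:
    """Declarative wiring of one single-trait animal model.

    Parameters
    ----------
    trait : phenotype column name.
    factors : columns combined into one fixed interaction factor
        (e.g. ["year", "sex", "pond"]), coded as cell means.
    covariates : list of (covariate_column, nesting_columns or None);
        a nested covariate gets one slope per level of the nesting
        interaction (e.g. ("age", ["sex"]) or ("body_weight",
        ["year", "sex"])).
    spawn_col : column defining the common-environment (full-sib spawn)
        group, or None to omit the term.
    """

    trait: str
    factors: list = field(default_factory=list)
    covariates: list = field(default_factory=list)
    spawn_col: str | None = "spawn"


@dataclass
class VarianceComponents:
    """Additive, common-environment, and residual variances (trait units^2)."""

    sigma2_u: float
    sigma2_p: float
    sigma2_e: float

    def __post_init__(self):
        if self.sigma2_e <= 0:
            raise ValueError("residual variance must be > 0")
        if self.sigma2_u < 0 or self.sigma2_p < 0:
            raise ValueError("variance components must be >= 0")

    @property
    def h2(self) -> float:
        return self.sigma2_u / (self.sigma2_u + self.sigma2_p + self.sigma2_e)

    @property
    def c2(self) -> float:
        return self.sigma2_p / (self.sigma2_u + self.sigma2_p + self.sigma2_e)


@dataclass
class DesignMatrices:
    y: np.ndarray
    X: np.ndarray
    Z: sp.csr_matrix
    W: sp.csr_matrix | None
    fixed_names: list
    spawn_levels: np.ndarray | None
    record_animals: np.ndarray  # internal pedigree index per record


@dataclass
class Solutions:
    """One MME solve: fixed effects, breeding values for every pedigree
    animal (phenotyped or not), and common-environment effects."""

    b: np.ndarray
    u: np.ndarray
    pe: np.ndarray | None
    fixed_names: list
    residual_norm: float
    method: str
    n_iter: int = 0

    def ebv_frame(self, ped: Pedigree) -> pd.DataFrame:
        return pd.DataFrame({"animal": ped.labels, "ebv": self.u})


def _interaction_codes(df: pd.DataFrame, cols) -> tuple[np.ndarray, list]:
    key = df[cols[0]].astype(str)
    for c in cols[1:]:
        key = key + ":" + df[c].astype(str)
    levels, codes = np.unique(key.to_numpy(), return_inverse=True)
    return codes, list(levels)


def build_design(
    phenos: pd.DataFrame,
    spec: ModelSpec,
    ped: Pedigree,
    animal_col: str = "animal",
) -> DesignMatrices:
    """Build y, X, Z, W for one trait.

    Records with a missing trait value are dropped from y (but their
    animals remain in the equations via the relationship matrix). The
    fixed interaction factor is coded as cell means (one column per
    observed cell, no intercept), which is full rank by construction;
    nested covariates contribute one slope column per nesting level.
    """
    df = phenos.loc[phenos[spec.trait].notna()].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no records with non-missing {spec.trait!r}")
    y = df[spec.trait].to_numpy(dtype=float)
    n = len(df)

    blocks, names = [], []
    if spec.factors:
        codes, levels = _interaction_codes(df, spec.factors)
        Xf = np.zeros((n, len(levels)))
        Xf[np.arange(n), codes] = 1.0
        blocks.append(Xf)
        names += [f"{'x'.join(spec.factors)}={lv}" for lv in levels]
    else:
        blocks.append(np.ones((n, 1)))
        names.append("intercept")

    for cov, nest in spec.covariates:
        x = df[cov].to_numpy(dtype=float)
        if nest:
            codes, levels = _interaction_codes(df, list(nest))
            Xc = np.zeros((n, len(levels)))
            Xc[np.arange(n), codes] = x
            blocks.append(Xc)
            names += [f"{cov}@{'x'.join(nest)}={lv}" for lv in levels]
        else:
            blocks.append(x[:, None])
            names.append(cov)

    X = np.hstack(blocks)

    animals = ped.internal(df[animal_col].to_numpy())
    Z = sp.csr_matrix(
        (np.ones(n), (np.arange(n), animals)), shape=(n, ped.n)
    )

    W = None
    spawn_levels = None
    if spec.spawn_col is not None and spec.spawn_col in df.columns:
        spawn_levels, codes = np.unique(
            df[spec.spawn_col].to_numpy(), return_inverse=True
        )
        W = sp.csr_matrix(
            (np.ones(n), (np.arange(n), codes)), shape=(n, len(spawn_levels))
        )
        counts = np.bincount(codes)
        if np.any(counts == 1):
            warnings.warn(
                f"{int(np.sum(counts == 1))} spawn groups have a single record",
                stacklevel=2,
            )

    return DesignMatrices(
        y=y, X=X, Z=Z, W=W, fixed_names=names,
        spawn_levels=spawn_levels, record_animals=animals,
    )


def _assemble_mme(dm: DesignMatrices, K_inv: sp.spmatrix, vc: VarianceComponents):
    """Coefficient matrix (lambda form) and right-hand side, sparse."""
    lam_u = vc.sigma2_e / vc.sigma2_u
    X = sp.csr_matrix(dm.X)
    Z, W = dm.Z, dm.W
    parts = [X, Z] + ([W] if W is not None else [])
    Wfull = sp.hstack(parts).tocsr()
    p = X.shape[1]
    q = Z.shape[1]
    C = (Wfull.T @ Wfull).tocsr()
    Ku = sp.csr_matrix(K_inv) * lam_u
    pad_pre = sp.csr_matrix((p, p))
    diag_parts = [pad_pre, Ku]
    if W is not None:
        lam_p = vc.sigma2_e / vc.sigma2_p
        diag_parts.append(sp.identity(W.shape[1], format="csr") * lam_p)
    C = C + sp.block_diag(diag_parts, format="csr")
    rhs = Wfull.T @ dm.y
    return C, rhs, p, q


def solve_mme(
    dm: DesignMatrices,
    K_inv: sp.spmatrix,
    vc: VarianceComponents,
    solver: str = "auto",
    tol: float = 1e-8,
    maxiter: int = 20000,
) -> Solutions:
    """Solve Henderson's MME.

    solver "direct" uses a dense Cholesky factorization; "sparse" a
    sparse LU; "pcg" a Jacobi-preconditioned conjugate gradient; "auto"
    picks sparse LU when the coefficient matrix is sparse enough and a
    dense factorization below DENSE_SOLVE_MAX equations otherwise. The
    relative residual of the normal equations is checked against `tol`.
    """
    if vc.sigma2_u <= 0:
        raise ValueError("sigma2_u must be > 0 to solve the MME")
    C, rhs, p, q = _assemble_mme(dm, K_inv, vc)
    n_eq = C.shape[0]
    if solver == "auto":
        density = C.nnz / n_eq**2
        if density < 0.02:
            solver = "sparse"
        elif n_eq <= DENSE_SOLVE_MAX:
            solver = "direct"
        else:
            solver = "pcg"

    n_iter = 0
    if solver == "direct":
        Cd = C.toarray()
        try:
            sol = la.cho_solve(la.cho_factor(Cd), rhs)
        except la.LinAlgError:
            sol, *_ = la.lstsq(Cd, rhs)
    elif solver == "sparse":
        sol = spla.splu(sp.csc_matrix(C)).solve(rhs)
    elif solver == "pcg":
        diag = C.diagonal()
        M = sp.diags(1.0 / np.where(diag > 0, diag, 1.0))
        it_count = [0]

        def _cb(xk):
            it_count[0] += 1

        sol, info = spla.cg(C, rhs, rtol=tol, maxiter=maxiter, M=M, callback=_cb)
        n_iter = it_count[0]
        if info != 0:
            raise RuntimeError(
                f"PCG did not converge in {maxiter} iterations "
                f"(residual {np.linalg.norm(C @ sol - rhs):.3e})"
            )
    else:
        raise ValueError(f"unknown solver {solver!r}")

    res = float(np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300))
    b = sol[:p]
    u = sol[p : p + q]
    pe = sol[p + q :] if dm.W is not None else None
    return Solutions(
        b=b, u=u, pe=pe, fixed_names=dm.fixed_names,
        residual_norm=res, method=solver, n_iter=n_iter,
    )


def _logdet_sparse(K_inv: sp.spmatrix) -> float:
    lu = spla.splu(sp.csc_matrix(K_inv).astype(float))
    d = lu.U.diagonal()
    return float(np.sum(np.log(np.abs(d))))


def reml_loglik(
    dm: DesignMatrices,
    K_inv: sp.spmatrix,
    vc: VarianceComponents,
    logdet_K_inv: float | None = None,
) -> float:
    """Restricted log-likelihood (up to an additive constant) of the
    animal model at the given variance components.

    Uses a sparse LU factorization of the coefficient matrix, so single
    evaluations are cheap even at tens of thousands of equations.
    """
    C, rhs, p, q = _assemble_mme(dm, K_inv, vc)
    lu = spla.splu(sp.csc_matrix(C))
    sol = lu.solve(rhs)
    n = len(dm.y)
    n_eq = C.shape[0]
    yPy = (dm.y @ dm.y - sol @ rhs) / vc.sigma2_e
    # log|C*| for the unscaled (R^-1) form of the MME; C is SPD so the
    # LU determinant is positive
    logdet_C = float(
        np.sum(np.log(np.abs(lu.U.diagonal())))
    ) - n_eq * np.log(vc.sigma2_e)
    if logdet_K_inv is None:
        logdet_K_inv = _logdet_sparse(K_inv)
    logdet_Gcov = q * np.log(vc.sigma2_u) - logdet_K_inv
    if dm.W is not None:
        logdet_Gcov += dm.W.shape[1] * np.log(vc.sigma2_p)
    m2l = n * np.log(vc.sigma2_e) + logdet_Gcov + logdet_C + yPy
    return -0.5 * m2l


def _em_step(dm, K, vc, rank_X, floor):
    """One EM-REML update of the three variance components."""
    n = len(dm.y)
    has_pe = dm.W is not None
    C, rhs, p, q = _assemble_mme(dm, K, vc)
    Cd = C.toarray()
    # dense inverse via Cholesky (dpotrf + dpotri touches only a triangle)
    cf, info = la.lapack.dpotrf(Cd, lower=1, overwrite_a=False)
    if info != 0:
        raise la.LinAlgError("MME coefficient matrix not positive definite")
    Cinv, info = la.lapack.dpotri(cf, lower=1)
    if info != 0:
        raise la.LinAlgError("inversion of the MME coefficient matrix failed")
    ix = np.triu_indices(Cinv.shape[0], 1)
    Cinv[ix] = Cinv.T[ix]  # fill the upper triangle
    sol = Cinv @ rhs
    u = sol[p : p + q]

    # trace(K_inv @ C^uu) over the sparse pattern of K_inv
    Cuu = Cinv[p : p + q, p : p + q]
    Kcoo = K.tocoo()
    tr_KCuu = float(np.sum(Kcoo.data * Cuu[Kcoo.row, Kcoo.col]))
    new_u = (u @ (K @ u) + vc.sigma2_e * tr_KCuu) / q

    if has_pe:
        pe = sol[p + q :]
        Cpp = Cinv[p + q :, p + q :]
        new_p = (pe @ pe + vc.sigma2_e * np.trace(Cpp)) / len(pe)
    else:
        new_p = 0.0
    new_e = (dm.y @ dm.y - sol @ rhs) / (n - rank_X)

    pinned = []
    if new_u < floor:
        new_u, pinned = floor, pinned + ["sigma2_u"]
    if has_pe and new_p < floor:
        new_p, pinned = floor, pinned + ["sigma2_p"]
    return VarianceComponents(new_u, new_p, new_e), pinned


def em_reml(
    dm: DesignMatrices,
    K_inv: sp.spmatrix,
    init: VarianceComponents | None = None,
    max_rounds: int = 200,
    tol: float = 1e-5,
    accelerate: bool = True,
    track_loglik: bool = False,
) -> tuple[VarianceComponents, dict]:
    """EM-REML for the three-component animal model.

    Each EM round solves the MME at the current components, forms the
    dense inverse of the coefficient matrix, and applies the
    expectation-maximization updates

        sigma2_u <- (u' K^-1 u + sigma2_e tr(K^-1 C^uu)) / q
        sigma2_p <- (p' p     + sigma2_e tr(C^pp))       / n_p
        sigma2_e <- (y'y - b'X'y - u'Z'y - p'W'y) / (n - rank X)

    Family-structured data give a strongly ridged likelihood in
    (sigma2_u, sigma2_p), on which plain EM creeps; with
    `accelerate=True` (default) the EM map is extrapolated SQUAREM-style
    (two EM steps per cycle, step length from the change in the change),
    with a restricted-likelihood safeguard that falls back to the plain
    double step whenever extrapolation does not improve the likelihood.

    Stops when the largest relative parameter change over a cycle falls
    below `tol`. Components collapsing below 1e-8 of the phenotypic
    variance are pinned at that boundary and flagged in the diagnostics.

    Test-scale only: each EM round forms a dense inverse of the
    coefficient matrix.
    """
    var_y = float(np.var(dm.y))
    if init is None:
        init = VarianceComponents(var_y / 3, var_y / 3, var_y / 3)
    vc = VarianceComponents(init.sigma2_u, init.sigma2_p, init.sigma2_e)
    rank_X = np.linalg.matrix_rank(dm.X)
    K = sp.csr_matrix(K_inv)
    floor = 1e-8 * var_y
    history = {"vc": [], "loglik": [], "pinned": [], "converged": False,
               "rounds": 0, "em_steps": 0}
    logdet_K_inv = _logdet_sparse(K) if (accelerate or track_loglik) else None

    def theta(v):
        return np.array([v.sigma2_u, v.sigma2_p, v.sigma2_e])

    def from_theta(t):
        return VarianceComponents(max(t[0], floor), max(t[1], 0.0),
                                  max(t[2], floor))

    def loglik(v):
        return reml_loglik(dm, K, v, logdet_K_inv=logdet_K_inv)

    def record(v, pinned):
        history["vc"].append(v)
        history["pinned"] = pinned
        if track_loglik:
            history["loglik"].append(loglik(v))

    rel_change = lambda a, b: float(
        np.max(np.abs(theta(a) - theta(b)) / np.maximum(theta(b), floor))
    )

    rounds = 0
    while rounds < max_rounds:
        if not accelerate:
            new_vc, pinned = _em_step(dm, K, vc, rank_X, floor)
            history["em_steps"] += 1
            record(new_vc, pinned)
            rounds += 1
            done = rel_change(new_vc, vc) < tol
            vc = new_vc
            if done:
                history["converged"] = True
                break
            continue

        # SQUAREM cycle: two EM steps, then extrapolate
        v1, pin1 = _em_step(dm, K, vc, rank_X, floor)
        v2, pin2 = _em_step(dm, K, v1, rank_X, floor)
        history["em_steps"] += 2
        t0, t1, t2 = theta(vc), theta(v1), theta(v2)
        r = t1 - t0
        v = (t2 - t1) - r
        nv = np.linalg.norm(v)
        cand = v2
        pinned = pin2
        if nv > 0 and not (pin1 or pin2):
            alpha = -np.linalg.norm(r) / nv
            alpha = min(alpha, -1.0)  # never shorter than one EM step
            t_acc = t0 - 2.0 * alpha * r + alpha * alpha * v
            if np.all(t_acc[[0, 2]] > 0) and t_acc[1] >= 0:
                v_acc = from_theta(t_acc)
                # safeguard: accept only if the restricted likelihood
                # does not decrease relative to the plain double step
                if loglik(v_acc) >= loglik(v2) - 1e-8:
                    cand = v_acc
        record(cand, pinned)
        rounds += 1
        done = rel_change(cand, vc) < tol
        vc = cand
        history["rounds"] = rounds
        if done:
            history["converged"] = True
            break
    history["rounds"] = rounds
    return vc, history


def adjusted_phenotypes(y: np.ndarray, X: np.ndarray, b_full: np.ndarray) -> np.ndarray:
    """Phenotypes adjusted for fixed effects, y* = y - X b.

    `b_full` must come from the full-data fit, not a training fit.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.shape != (len(y), len(b_full)):
        raise ValueError("dimension mismatch between y, X, and b_full")
    return y - X @ b_full


def parent_average(u: np.ndarray, ped: Pedigree) -> np.ndarray:
    """Parent-average breeding value 0.5*u_sire + 0.5*u_dam; an unknown
    parent contributes zero (founder mean)."""
    us = np.where(ped.sire >= 0, u[np.maximum(ped.sire, 0)], 0.0)
    ud = np.where(ped.dam >= 0, u[np.maximum(ped.dam, 0)], 0.0)
    return 0.5 * us + 0.5 * ud


def selection_index(ebv_trait1: np.ndarray, ebv_trait2: np.ndarray) -> np.ndarray:
    """Average of the z-standardized EBV of two traits across candidates."""
    out = []
    for v in (np.asarray(ebv_trait1, float), np.asarray(ebv_trait2, float)):
        s = v.std()
        if s == 0:
            raise ValueError("zero EBV variance; index undefined")
        out.append((v - v.mean()) / s)
    return 0.5 * (out[0] + out[1])
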