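"""Training/validation designs for comparing pedigree BLUP and ssGBLUP.

Four strategies mirror how a fish breeding program can structure its
reference data:

1. random k-fold cross-validation among genotyped, phenotyped animals
   (k = 5 or 10, replicated);
2. full-sib validation: genotyped full sibs halved within family into
   training and validation;
3. like strategy 2, but only a random half of the training full sibs keep
   phenotypes (fewer slaughtered, genotyped fish);
4. like strategy 2, but no genotyped animal keeps a phenotype — genotyped
   candidates are connected to ungenotyped phenotyped relatives only
   through the pedigree/H matrix.

Predictive ability is the Pearson correlation between (G)EBV of
validation animals and their phenotypes adjusted for fixed effects from
the full-data fit; inflation is the slope of adjusted phenotypes
regressed on (G)EBV (slope < 1 means over-dispersed predictions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import model as md
from .datasets import Dataset
from ._seeds import derive_seed

__all__ = [
    "SplitPlan",
    "kfold_split",
    "fullsib_split",
    "mask_phenotypes",
    "masked_table",
    "predictive_ability",
    "inflation_regression",
    "run_validation",
    "summarize_validation",
]


@dataclass
class SplitPlan:
    """One training/validation partition.

    For strategy 1 `folds` maps fold number -> validation id array; for
    strategies 2-4 `validation` holds the validation ids and
    `train_unphenotyped` the training ids whose phenotypes are masked on
    top of the validation set (strategies 3-4).
    """

    strategy: int
    replicate: int = 0
    seed: int = 0
    folds: dict = field(default_factory=dict)
    validation: np.ndarray | None = None
    train_unphenotyped: np.ndarray | None = None


def kfold_split(ids, k: int = 5, replicates: int = 5, seed: int = 0):
    """Random partition of ids into k near-equal folds, replicated.

    Returns a list of SplitPlan, one per replicate. Same seed, same plan.
    """
    ids = np.asarray(ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds {len(ids)} animals")
    plans = []
    for rep in range(replicates):
        rng = np.random.default_rng(derive_seed(seed, "kfold", k, rep))
        perm = rng.permutation(ids)
        plans.append(
            SplitPlan(
                strategy=1,
                replicate=rep,
                seed=seed,
                folds={f: np.sort(part) for f, part in
                       enumerate(np.array_split(perm, k))},
            )
        )
    return plans


def _genotyped_families(ds: Dataset) -> dict:
    """Full-sib families (>= 1 genotyped member) -> genotyped ids."""
    fams: dict = {}
    gset = set(ds.genotyped_ids.tolist())
    for (s, d), members in ds.ped.families().items():
        gmem = [ds.ped.labels[i] for i in members if ds.ped.labels[i] in gset]
        if gmem:
            fams[(s, d)] = gmem
    return fams


def fullsib_split(ds: Dataset, seed: int = 0, mode: str = "family") -> SplitPlan:
    """Strategy 2: split genotyped full sibs into training and validation.

    mode "family" (default) halves every genotyped full-sib family; an
    odd member goes to training, singleton families are all-training.
    mode "global" halves the pooled genotyped full sibs irrespective of
    family.
    """
    rng = np.random.default_rng(derive_seed(seed, "fullsib"))
    fams = sorted(_genotyped_families(ds).items())
    if mode == "family":
        validation = []
        for fam, members in fams:
            members = np.asarray(members)
            if len(members) < 2:
                continue  # to training
            perm = rng.permutation(members)
            n_val = len(members) // 2  # extra member to training
            validation += list(perm[:n_val])
    elif mode == "global":
        pool = np.concatenate([np.asarray(m) for _, m in fams])
        perm = rng.permutation(pool)
        validation = list(perm[: len(pool) // 2])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SplitPlan(strategy=2, seed=seed, validation=np.sort(np.array(validation)))


def mask_phenotypes(
    plan: SplitPlan, ds: Dataset, strategy: int, seed: int = 0
) -> SplitPlan:
    """Derive the strategy-3 or strategy-4 plan from a strategy-2 plan.

    The validation set is unchanged. Strategy 3 additionally masks a
    random half of the genotyped training full sibs per family; strategy
    4 masks every genotyped animal not already in validation.
    """
    if plan.strategy != 2:
        raise ValueError("strategies 3-4 derive from a strategy-2 plan")
    if strategy == 3:
        rng = np.random.default_rng(derive_seed(seed, "strategy3"))
        val = set(plan.validation.tolist())
        masked = []
        for fam, members in sorted(_genotyped_families(ds).items()):
            train = [m for m in members if m not in val]
            n_mask = len(train) // 2  # keep ceil(half) phenotyped
            if n_mask:
                masked += list(rng.permutation(np.asarray(train))[:n_mask])
        extra = np.sort(np.array(masked))
    elif strategy == 4:
        val = set(plan.validation.tolist())
        extra = np.sort(np.array([g for g in ds.genotyped_ids if g not in val]))
    else:
        raise ValueError("strategy must be 3 or 4")
    return SplitPlan(
        strategy=strategy, seed=plan.seed,
        validation=plan.validation.copy(), train_unphenotyped=extra,
    )


def masked_table(ds: Dataset, trait: str, masked_ids) -> pd.DataFrame:
    """Phenotype table with `trait` set missing for masked_ids."""
    out = ds.phenos.copy()
    out.loc[out["animal"].isin(np.asarray(masked_ids)), trait] = np.nan
    return out


def predictive_ability(u_validation, y_star_validation) -> float:
    """Pearson correlation of (G)EBV with adjusted phenotypes."""
    u = np.asarray(u_validation, float)
    y = np.asarray(y_star_validation, float)
    if len(u) < 3:
        raise ValueError("need at least 3 validation animals")
    if u.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; predictive ability undefined")
    return float(np.corrcoef(u, y)[0, 1])


def inflation_regression(y_star_validation, u_validation):
    """OLS of adjusted phenotypes on (G)EBV; returns (b0, b1). b1 < 1
    indicates inflated (over-dispersed) breeding values."""
    u = np.asarray(u_validation, float)
    y = np.asarray(y_star_validation, float)
    if u.std() == 0:
        raise ValueError("zero EBV variance; inflation undefined")
    b1 = float(np.cov(y, u, ddof=1)[0, 1] / np.var(u, ddof=1))
    b0 = float(y.mean() - b1 * u.mean())
    return b0, b1


def _evaluate_split(
    ds: Dataset,
    trait: str,
    validation_ids,
    masked_train_ids,
    method: str,
    vc: md.VarianceComponents,
    y_star_by_animal: dict,
    solver_kwargs: dict,
):
    masked = (
        list(validation_ids)
        if masked_train_ids is None
        else list(validation_ids) + list(masked_train_ids)
    )
    table = masked_table(ds, trait, masked)
    sol = ds.fit(trait, method, phenos=table, vc=vc, **solver_kwargs)
    idx = ds.ped.internal(validation_ids)
    u_val = sol.u[idx]
    ys = np.array([y_star_by_animal.get(a, np.nan) for a in validation_ids])
    keep = ~np.isnan(ys)
    r = predictive_ability(u_val[keep], ys[keep])
    _, b1 = inflation_regression(ys[keep], u_val[keep])
    return r, b1, int(keep.sum())


def run_validation(
    ds: Dataset,
    traits=("hw",),
    strategies=(1, 2),
    methods=("blup", "ssgblup"),
    vc_mode: str = "fixed",
    k: int = 5,
    replicates: int = 5,
    seed: int = 0,
    reml_kwargs: dict | None = None,
    solver_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Run the requested validation strategies and return a tidy table
    (trait, strategy, method, vc_mode, replicate, fold, r, b1, n).

    Adjusted phenotypes always come from the full-data fixed effects per
    method; with vc_mode="reestimated" the variance components are
    re-estimated by EM-REML on every training set before prediction,
    otherwise the dataset's components are used throughout.
    """
    solver_kwargs = solver_kwargs or {}
    reml_kwargs = reml_kwargs or {}
    rows = []
    for trait in traits:
        dm_full = ds.design(trait)
        pheno_animals = ds.phenos.loc[
            ds.phenos[trait].notna(), "animal"
        ].to_numpy()
        gset = set(ds.genotyped_ids.tolist())
        gp_ids = np.array([a for a in pheno_animals if a in gset])
        for method in methods:
            sol_full = ds.fit(trait, method, **solver_kwargs)
            y_star = md.adjusted_phenotypes(dm_full.y, dm_full.X, sol_full.b)
            y_star_by_animal = dict(zip(pheno_animals, y_star))

            def vc_for(masked_ids):
                if vc_mode == "fixed":
                    return ds.vc[trait]
                table = masked_table(ds, trait, masked_ids)
                dm_train = md.build_design(table, ds.model_specs[trait], ds.ped)
                K_inv = ds.relationship_inverse(method)
                vc_est, _ = md.em_reml(dm_train, K_inv, **reml_kwargs)
                return vc_est

            for strat in strategies:
                if strat == 1:
                    if len(gp_ids) < k:
                        raise ValueError(
                            f"strategy 1 needs >= {k} genotyped phenotyped animals"
                        )
                    for plan in kfold_split(gp_ids, k=k, replicates=replicates,
                                            seed=seed):
                        for fold, val_ids in plan.folds.items():
                            vc_use = vc_for(val_ids)
                            r, b1, nv = _evaluate_split(
                                ds, trait, val_ids, None, method, vc_use,
                                y_star_by_animal, solver_kwargs,
                            )
                            rows.append(
                                (trait, strat, method, vc_mode,
                                 plan.replicate, fold, r, b1, nv)
                            )
                else:
                    plan2 = fullsib_split(ds, seed=seed)
                    if strat == 2:
                        plan = plan2
                    else:
                        plan = mask_phenotypes(plan2, ds, strategy=strat,
                                               seed=seed)
                    masked = (
                        list(plan.validation)
                        + list(plan.train_unphenotyped
                               if plan.train_unphenotyped is not None else [])
                    )
                    vc_use = vc_for(masked)
                    r, b1, nv = _evaluate_split(
                        ds, trait, plan.validation, plan.train_unphenotyped,
                        method, vc_use, y_star_by_animal, solver_kwargs,
                    )
                    rows.append((trait, strat, method, vc_mode, 0, 0, r, b1, nv))
    return pd.DataFrame(
        rows,
        columns=["trait", "strategy", "method", "vc_mode", "replicate",
                 "fold", "r", "b1", "n_validation"],
    )


def summarize_validation(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error (over replicates) per trait/strategy/method,
    mirroring the usual presentation of replicated cross-validation."""
    per_rep = (
        results.groupby(["trait", "strategy", "method", "vc_mode", "replicate"])
        [["r", "b1"]].mean().reset_index()
    )

    def agg(g):
        n = len(g)
        return pd.Series({
            "r_mean": g["r"].mean(),
            "r_se": g["r"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            "b1_mean": g["b1"].mean(),
            "b1_se": g["b1"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            "replicates": n,
        })

    return (
        per_rep.groupby(["trait", "strategy", "method", "vc_mode"])
        .apply(agg, include_groups=False)
        .reset_index()
    )
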