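"""Family-based (CVF) and individual-based (CVR) 4-fold cross-validation.

In CVF whole paternal half-sib families are assigned to folds (two of the
eight families per fold), so test birds share no sibs with the training
set — a deliberately distant test-training relationship. In CVR individual
birds are assigned at random, so test birds keep sibs in training. Test
birds' phenotypes are masked, not excluded: every individual stays in the
random effect and receives a breeding value through the relationship
matrix, while only training records enter the data vector.

Accuracy is measured two ways: the correlation between predicted breeding
values and corrected phenotypes divided by sqrt(h2), and the model-based
theoretical accuracy from the inverted mixed-model coefficient matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import RelationshipMatrix
from .mixed_model import (MMESolution, VarComp, build_mme, design_matrix,
                          incidence_matrix, solve_mme)


class CVError(ValueError):
    pass


@dataclass
class CVDesign:
    """Per-repeat fold assignments; ``folds[r][f]`` is the test-id array."""

    scenario: str
    n_folds: int
    n_repeats: int
    seed: int
    folds: list = field(repr=False)

    def validate(self, all_ids=None) -> None:
        for rep in self.folds:
            ids = np.concatenate(rep)
            if len(ids) != len(set(ids)):
                raise CVError("folds are not disjoint")
            if all_ids is not None and set(ids) != set(all_ids):
                raise CVError("folds do not exhaust the unit list")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r, rep in enumerate(self.folds):
            for f, test in enumerate(rep):
                rows.extend({"repeat": r, "fold": f, "id": i} for i in test)
        return pd.DataFrame(rows)


def make_folds_family(families: pd.Series, n_folds: int = 4,
                      n_repeats: int = 10, seed: int = 0) -> CVDesign:
    """Random partition of whole families into folds, per repeat.

    ``families`` maps bird id (index) to family label. The family count
    must divide evenly by ``n_folds`` (the 8-family design gives two
    families per fold); test sets contain whole families only.
    """
    families = pd.Series(families)
    fams = np.array(sorted(families.unique()))
    if len(fams) % n_folds != 0:
        raise CVError(f"{len(fams)} families not divisible by {n_folds} folds")
    per_fold = len(fams) // n_folds
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(n_repeats):
        order = rng.permutation(fams)
        rep = []
        for f in range(n_folds):
            chunk = set(order[f * per_fold:(f + 1) * per_fold])
            rep.append(families.index[families.isin(chunk)].to_numpy())
        folds.append(rep)
    return CVDesign("CVF", n_folds, n_repeats, seed, folds)


def make_folds_random(ids, n_folds: int = 4, n_repeats: int = 50,
                      seed: int = 0) -> CVDesign:
    """Uniformly random near-equal partition of individuals, per repeat."""
    ids = np.asarray(list(ids))
    if ids.size == 0:
        raise CVError("empty id list")
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(n_repeats):
        order = rng.permutation(ids)
        folds.append([chunk for chunk in np.array_split(order, n_folds)])
    return CVDesign("CVR", n_folds, n_repeats, seed, folds)


def accuracy_correlation(gebv_test, yc_test, h2: float) -> float:
    """Pearson correlation of predictions with corrected phenotypes,
    divided by sqrt(h2). May legitimately exceed 1. NaN (fold skipped)
    when either vector is degenerate."""
    if not (0.0 < h2 <= 1.0):
        raise CVError("h2 must lie in (0, 1]")
    g = np.asarray(gebv_test, dtype=float)
    y = np.asarray(yc_test, dtype=float)
    mask = np.isfinite(g) & np.isfinite(y)
    if mask.sum() < 3:
        raise CVError("need at least 3 finite test records")
    g, y = g[mask], y[mask]
    if g.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(g, y)[0, 1] / np.sqrt(h2))


def accuracy_theoretical(solution: MMESolution, test_ids,
                         sigma_a2: float) -> float:
    """Mean over test birds of sqrt(1 - PEV_i / sigma_a^2)."""
    if sigma_a2 <= 0:
        raise CVError("sigma_a2 must be positive")
    pev = solution.pev.loc[list(test_ids)].to_numpy()
    return float(np.mean(np.sqrt(np.clip(1.0 - pev / sigma_a2, 0.0, 1.0))))


def run_cv(design: CVDesign, traits: pd.DataFrame, yc: pd.DataFrame,
           varcomps: dict, trait_names, K_gen: RelationshipMatrix = None,
           K_ped: RelationshipMatrix = None,
           fixed_effects: dict | None = None,
           h2_scaling: dict | None = None) -> pd.DataFrame:
    """Run the cross-validation for each trait and relationship matrix.

    Parameters
    ----------
    traits:
        Post-QC trait table (index bird id) with trait columns plus
        ``sex``/``hatch``.
    yc:
        Corrected phenotypes, one column per trait.
    varcomps:
        ``{(model, trait): VarComp}`` estimated once on the full data and
        held fixed across folds.
    trait_names:
        Traits to evaluate (e.g. FCR, RFI, ADG, ADFI).
    K_gen / K_ped:
        Stabilized relationship matrices whose ids cover (at least) the
        phenotyped birds; all their individuals enter the random effect.
    fixed_effects:
        ``{trait: tuple-of-factors}``; default sex+hatch, RFI intercept-only.
    h2_scaling:
        One heritability per trait for the r_cor denominator, shared by all
        models so their correlation accuracies are directly comparable.
        Defaults to the GBLUP estimate when present (the relationship-based
        estimate of the trait's heritability), else the model's own.

    Returns a tidy detail DataFrame (scenario, model, trait, repeat, fold,
    n_test, r_cor, r_theo); aggregate with :func:`summarize_cv`.
    """
    if fixed_effects is None:
        fixed_effects = {t: (() if t == "RFI" else ("sex", "hatch"))
                         for t in trait_names}
    if h2_scaling is None:
        h2_scaling = {}
        for t in trait_names:
            if ("GBLUP", t) in varcomps:
                h2_scaling[t] = varcomps[("GBLUP", t)].h2
    models = {}
    if K_gen is not None:
        models["GBLUP"] = K_gen
    if K_ped is not None:
        models["PBLUP"] = K_ped
    if not models:
        raise CVError("provide at least one relationship matrix")

    bird_ids = list(traits.index)
    k_inv_cache = {}
    from scipy import linalg as _sl
    for name, K in models.items():
        k_inv_cache[name] = _sl.cho_solve(_sl.cho_factor(K.values),
                                          np.eye(len(K.ids)))
    rows = []
    for model_name, K in models.items():
        K_ids = list(K.ids)
        K_inv = k_inv_cache[model_name]
        for trait in trait_names:
            if (model_name, trait) not in varcomps:
                raise CVError(f"missing variance components for "
                              f"({model_name}, {trait})")
            vc: VarComp = varcomps[(model_name, trait)]
            h2_acc = h2_scaling.get(trait, vc.h2)
            y_all = traits[trait].astype(float)
            X_all, names = design_matrix(traits, fixed_effects[trait])
            for r, rep in enumerate(design.folds):
                for f, test in enumerate(rep):
                    test = [str(i) for i in test]
                    train_mask = ~traits.index.isin(test)
                    train_ids = [i for i, m in zip(bird_ids, train_mask) if m]
                    X_tr = X_all[train_mask.nonzero()[0]]
                    from .mixed_model import full_rank_columns
                    keep = full_rank_columns(X_tr)
                    X_tr = X_tr[:, keep]
                    Z_tr = incidence_matrix(train_ids, K_ids)
                    mme = build_mme(y_all[train_mask].to_numpy(), X_tr, Z_tr,
                                    K.values, vc.sigma_a2, vc.sigma_e2,
                                    K_inv=K_inv, random_ids=K_ids,
                                    fixed_names=[names[k] for k in keep])
                    sol = solve_mme(mme)
                    gebv = sol.u.loc[test].to_numpy()
                    yct = yc[trait].loc[test].to_numpy()
                    rows.append({
                        "scenario": design.scenario, "model": model_name,
                        "trait": trait, "repeat": r, "fold": f,
                        "n_test": len(test),
                        "r_cor": accuracy_correlation(gebv, yct, h2_acc),
                        "r_theo": accuracy_theoretical(sol, test,
                                                       vc.sigma_a2),
                    })
    return pd.DataFrame(rows)


def summarize_cv(detail: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracies: equal fold weights within repeat, then over repeats."""
    per_rep = (detail.groupby(["scenario", "model", "trait", "repeat"])
               [["r_cor", "r_theo"]].mean())
    return (per_rep.groupby(["scenario", "model", "trait"]).mean()
            .reset_index())


def accuracy_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Wide per-trait table: r_cor/r_theo for GBLUP and r_ped for PBLUP,
    split by scenario (the conventional reporting layout)."""
    rows = {}
    for _, rec in summary.iterrows():
        key = rec["trait"]
        rows.setdefault(key, {})
        suffix = rec["scenario"]
        if rec["model"] == "GBLUP":
            rows[key][f"r_cor_{suffix}"] = rec["r_cor"]
            rows[key][f"r_theo_{suffix}"] = rec["r_theo"]
        else:
            rows[key][f"r_ped_{suffix}"] = rec["r_cor"]
    out = pd.DataFrame(rows).T
    out.index.name = "trait"
    mean_row = out.mean(axis=0)
    out.loc["Mean"] = mean_row
    return out
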