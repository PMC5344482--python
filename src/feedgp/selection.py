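"""Ranking birds on (G)EBV and comparing efficient vs inefficient groups.

For feed-efficiency traits a *lower* breeding value means a more efficient
bird, so the top group is the k birds with the lowest GEBV. Group trait
means are compared with a pooled-variance two-sample Student's t-test.
Genetic correlations between the efficiency traits and carcass traits come
from bivariate AI-REML fits on the whole data, with a Wald test (estimate
over delta-method SE against a standard normal) for significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kinship import RelationshipMatrix
from .mixed_model import (CovComp, aireml_bivariate, design_matrix,
                          incidence_matrix)


class SelectionError(ValueError):
    pass


@dataclass
class SelectionGroups:
    """Most and least efficient k birds by ranking GEBV ascending."""

    trait: str
    top_ids: list[str]       # lowest GEBV = most efficient
    bottom_ids: list[str]
    k: int = 50


def rank_select(gebv: pd.Series, k: int = 50, trait: str = "",
                direction: str = "ascending") -> SelectionGroups:
    """Select the k extreme birds at each end of the GEBV ranking.

    Ties are broken by bird id (lexicographic), so the selection is
    deterministic and invariant to input order.
    """
    gebv = pd.Series(gebv).astype(float)
    if len(gebv) < 2 * k:
        raise SelectionError(f"need at least {2 * k} birds, got {len(gebv)}")
    if direction not in ("ascending", "descending"):
        raise SelectionError("direction must be 'ascending' or 'descending'")
    order = sorted(gebv.index, key=lambda i: (gebv[i], str(i)))
    if direction == "descending":
        order = order[::-1]
    return SelectionGroups(trait=trait, top_ids=[str(i) for i in order[:k]],
                           bottom_ids=[str(i) for i in order[-k:]], k=k)


def overlap(set_a, set_b) -> int:
    """Number of ids shared by two selection groups."""
    return len(set(map(str, set_a)) & set(map(str, set_b)))


def group_compare(traits: pd.DataFrame, groups: SelectionGroups,
                  compare_traits=("ADG", "ADFI", "EP", "BMP", "LMP")
                  ) -> pd.DataFrame:
    """Per-trait group means +- SD with a pooled-variance Student's t-test.

    Returns one row per trait: efficient/inefficient mean and SD, t,
    two-sided p and a significance flag at alpha = 0.05.
    """
    if len(groups.top_ids) < 2 or len(groups.bottom_ids) < 2:
        raise SelectionError("each group needs at least 2 birds")
    top = traits.loc[groups.top_ids]
    bottom = traits.loc[groups.bottom_ids]
    rows = []
    for t in compare_traits:
        a = top[t].to_numpy(dtype=float)
        b = bottom[t].to_numpy(dtype=float)
        tt = stats.ttest_ind(a, b, equal_var=True)
        rows.append({
            "trait": t,
            "efficient_mean": a.mean(), "efficient_sd": a.std(ddof=1),
            "inefficient_mean": b.mean(), "inefficient_sd": b.std(ddof=1),
            "t": float(tt.statistic), "p": float(tt.pvalue),
            "significant_0.05": bool(tt.pvalue < 0.05),
        })
    return pd.DataFrame(rows).set_index("trait")


DEFAULT_PAIRS = (("FCR", "EP"), ("FCR", "BMP"), ("FCR", "LMP"),
                 ("RFI", "EP"), ("RFI", "BMP"), ("RFI", "LMP"))


def genetic_correlation_table(traits: pd.DataFrame, K: RelationshipMatrix,
                              pairs=DEFAULT_PAIRS,
                              fixed_effects: dict | None = None
                              ) -> pd.DataFrame:
    """Bivariate AI-REML genetic correlations for trait pairs on full data.

    Each pair is fitted independently; a pair whose fit fails is reported
    with NaN rather than aborting the table. Significance is a Wald z-test
    of r_g against zero at alpha = 0.05.
    """
    rows = []
    ids = list(traits.index)
    Z = incidence_matrix(ids, list(K.ids))
    for t1, t2 in pairs:
        fx1 = (fixed_effects or {}).get(
            t1, () if t1 == "RFI" else ("sex", "hatch"))
        fx2 = (fixed_effects or {}).get(
            t2, () if t2 == "RFI" else ("sex", "hatch"))
        X1, _ = design_matrix(traits, fx1)
        X2, _ = design_matrix(traits, fx2)
        try:
            fit: CovComp = aireml_bivariate(
                traits[t1].to_numpy(float), traits[t2].to_numpy(float),
                X1, X2, Z, Z, K.values)
            z = fit.r_g / fit.se_rg if fit.se_rg > 0 else np.nan
            p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append({"trait_1": t1, "trait_2": t2, "r_g": fit.r_g,
                         "se": fit.se_rg, "wald_z": z, "p": p,
                         "significant_0.05": bool(p < 0.05)
                         if np.isfinite(p) else False,
                         "converged": fit.converged})
        except Exception as exc:  # propagate per pair, non-fatally
            rows.append({"trait_1": t1, "trait_2": t2, "r_g": np.nan,
                         "se": np.nan, "wald_z": np.nan, "p": np.nan,
                         "significant_0.05": False, "converged": False,
                         "error": str(exc)})
    return pd.DataFrame(rows)
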