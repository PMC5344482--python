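"""End-to-end analysis: simulate -> QC -> derive -> REML -> predict -> CV.

The pipeline reproduces the whole evaluation workflow on a synthetic
intercross: variance components per trait on the full post-QC data
(genomic and pedigree relationship matrices separately), full-data BLUP /
GBLUP breeding values, family- and individual-sampling cross-validation,
efficient/inefficient group comparison and bivariate genetic correlations
between feed-efficiency and carcass traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .cross_validation import (accuracy_table, make_folds_family,
                               make_folds_random, run_cv, summarize_cv)
from .efficiency import corrected_phenotype, derive_traits
from .kinship import (RelationshipMatrix, genomic_relationship,
                      pedigree_relationship, stabilize)
from .mixed_model import (aireml, build_mme, design_matrix, incidence_matrix,
                          solve_mme)
from .qc import filter_phenotypes, filter_snps
from .selection import (genetic_correlation_table, group_compare, overlap,
                        rank_select)
from .simulate import SimulatedDataset, simulate_dataset

logger = logging.getLogger(__name__)

#: Traits whose variance components populate the genetic-parameter table.
ALL_TRAITS = ("FCR", "RFI", "ADG", "ADFI", "EP", "BMP", "LMP")


@dataclass
class PipelineResult:
    """Everything the reporting stage writes out."""

    config: fio.RunConfig
    data: SimulatedDataset
    snp_report: object
    pheno_report: object
    traits: pd.DataFrame              # post-QC with MBW/FCR/RFI
    rfi_fit: object
    A: RelationshipMatrix
    G: RelationshipMatrix
    varcomps: dict                    # {(model, trait): VarComp}
    yc: pd.DataFrame
    gebv_full: dict                   # {(model, trait): MMESolution}
    cv_detail: pd.DataFrame
    cv_summary: pd.DataFrame
    cv_table: pd.DataFrame
    selection_groups: dict = field(default_factory=dict)
    group_tables: dict = field(default_factory=dict)
    overlaps: dict = field(default_factory=dict)
    rg_table: pd.DataFrame | None = None


def fit_varcomps(traits, K, trait_names, model_name):
    """Univariate AIREML per trait on the full post-QC data."""
    out = {}
    ids = list(traits.index)
    K_sub = K.subset(ids)
    Z = np.eye(len(ids))
    for t in trait_names:
        factors = () if t == "RFI" else ("sex", "hatch")
        X, _ = design_matrix(traits, factors)
        vc = aireml(traits[t].to_numpy(float), X, Z, K_sub.values)
        out[(model_name, t)] = vc
        logger.info("%s %s: sa2=%.4g se2=%.4g h2=%.3f(%.3f)", model_name, t,
                    vc.sigma_a2, vc.sigma_e2, vc.h2, vc.se_h2)
    return out


def full_data_solutions(traits, K, varcomps, trait_names, model_name):
    """Full-data (G)BLUP breeding values for every individual in K."""
    out = {}
    ids = list(traits.index)
    Z = incidence_matrix(ids, list(K.ids))
    for t in trait_names:
        factors = () if t == "RFI" else ("sex", "hatch")
        X, names = design_matrix(traits, factors)
        vc = varcomps[(model_name, t)]
        mme = build_mme(traits[t].to_numpy(float), X, Z, K.values,
                        vc.sigma_a2, vc.sigma_e2, random_ids=list(K.ids),
                        fixed_names=names)
        out[(model_name, t)] = solve_mme(mme)
    return out


def run_pipeline(config: fio.RunConfig | None = None,
                 seed: int | None = None) -> PipelineResult:
    """Run the full analysis on a freshly simulated dataset."""
    if config is None:
        config = fio.RunConfig()
    if seed is not None:
        config.seed = seed
    config.simulation.seed = config.seed

    logger.info("simulating dataset (seed=%d)", config.seed)
    data = simulate_dataset(config.simulation)

    geno_qc, snp_report = filter_snps(
        data.genotypes, data.panel, config.qc.call_rate_min,
        config.qc.quality_min, config.qc.maf_min)
    traits_qc, pheno_report = filter_phenotypes(
        data.traits, config.qc.check_traits, config.qc.sd_threshold)
    logger.info("QC: %s; %s", snp_report.to_text().replace("\n", " | "),
                pheno_report.to_text().replace("\n", " | "))

    traits, rfi_fit = derive_traits(traits_qc)

    A = stabilize(pedigree_relationship(data.pedigree))
    G = stabilize(genomic_relationship(geno_qc))

    cv_traits = list(config.cv.traits)
    varcomps = {}
    varcomps.update(fit_varcomps(traits, G, ALL_TRAITS, "GBLUP"))
    varcomps.update(fit_varcomps(traits, A, cv_traits, "PBLUP"))

    yc = pd.DataFrame({
        t: corrected_phenotype(traits[t], traits["sex"], traits["hatch"], t)
        for t in cv_traits}, index=traits.index)

    gebv_full = {}
    gebv_full.update(full_data_solutions(traits, G, varcomps,
                                         ["FCR", "RFI"], "GBLUP"))

    fams = traits["family"]
    seeds = np.random.SeedSequence(config.seed).generate_state(2) % (2 ** 31)
    design_f = make_folds_family(fams, config.cv.n_folds,
                                 config.cv.cvf_repeats, int(seeds[0]))
    design_r = make_folds_random(traits.index, config.cv.n_folds,
                                 config.cv.cvr_repeats, int(seeds[1]))
    logger.info("cross-validation: CVF %d repeats, CVR %d repeats",
                config.cv.cvf_repeats, config.cv.cvr_repeats)
    detail = pd.concat([
        run_cv(design_f, traits, yc, varcomps, cv_traits, K_gen=G, K_ped=A),
        run_cv(design_r, traits, yc, varcomps, cv_traits, K_gen=G, K_ped=A),
    ], ignore_index=True)
    summary = summarize_cv(detail)
    cv_table = accuracy_table(summary)

    result = PipelineResult(
        config=config, data=data, snp_report=snp_report,
        pheno_report=pheno_report, traits=traits, rfi_fit=rfi_fit, A=A, G=G,
        varcomps=varcomps, yc=yc, gebv_full=gebv_full, cv_detail=detail,
        cv_summary=summary, cv_table=cv_table)

    k = config.selection_k
    bird_ids = list(traits.index)
    for t in ("FCR", "RFI"):
        gebv = gebv_full[("GBLUP", t)].u.loc[bird_ids]
        groups = rank_select(gebv, k=k, trait=t)
        result.selection_groups[t] = groups
        result.group_tables[t] = group_compare(traits, groups)
    result.overlaps = {
        "efficient": overlap(result.selection_groups["FCR"].top_ids,
                             result.selection_groups["RFI"].top_ids),
        "inefficient": overlap(result.selection_groups["FCR"].bottom_ids,
                               result.selection_groups["RFI"].bottom_ids),
    }
    logger.info("top-%d overlap FCR/RFI: %s", k, result.overlaps)

    result.rg_table = genetic_correlation_table(traits, G.subset(bird_ids))
    return result


def varcomp_frame(varcomps: dict) -> pd.DataFrame:
    rows = []
    for (model, trait), vc in varcomps.items():
        rows.append({"model": model, "trait": trait,
                     "sigma_a2": vc.sigma_a2, "sigma_e2": vc.sigma_e2,
                     "h2": vc.h2, "se_h2": vc.se_h2, "loglik": vc.loglik,
                     "n_iter": vc.n_iter, "converged": vc.converged})
    return pd.DataFrame(rows)


def write_outputs(result: PipelineResult, outdir) -> Path:
    """Write the full set of result files (CSV + YAML manifest)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fio.write_pedigree(result.data.pedigree, out / "pedigree.csv")
    fio.write_phenotypes(result.traits, out / "phenotypes_derived.csv")
    fio.write_panel(result.data.panel, out / "snp_panel.csv")
    pd.concat([result.snp_report.to_frame().assign(kind="snp"),
               result.pheno_report.to_frame().assign(kind="phenotype")]
              ).to_csv(out / "qc_report.csv", index=False)
    result.rfi_fit.coef.rename("estimate").to_csv(out / "rfi_fit.csv")
    varcomp_frame(result.varcomps).to_csv(out / "variance_components.csv",
                                          index=False)
    result.cv_detail.to_csv(out / "cv_detail.csv", index=False)
    result.cv_summary.to_csv(out / "cv_summary.csv", index=False)
    result.cv_table.to_csv(out / "cv_accuracy_table.csv",
                           float_format="%.3f")
    gebv = pd.DataFrame({f"{m}_{t}": sol.u
                         for (m, t), sol in result.gebv_full.items()})
    gebv.index.name = "id"
    gebv.to_csv(out / "gebv_full_data.csv", float_format="%.6g")
    for t, table in result.group_tables.items():
        table.to_csv(out / f"group_comparison_{t}.csv", float_format="%.4g")
    if result.rg_table is not None:
        result.rg_table.to_csv(out / "genetic_correlations.csv", index=False,
                               float_format="%.4g")
    pd.Series(result.overlaps).rename("n_shared").to_csv(
        out / "selection_overlap.csv")
    result.config.to_yaml(out / "run_manifest.yaml")
    return out
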