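"""Synthetic F2 intercross generator: pedigree, SNP genotypes, and traits.

The generator emulates the data-generating process the downstream analysis
assumes: two divergent founder lines (a fast-growing broiler line crossed
with a slow-growing indigenous line), an F1 of selected breeders, and an F2
of paternal half-sib families in which every bird is genotyped but only F2
birds are phenotyped. Markers segregate independently (gene dropping without
a linkage map); linkage disequilibrium arises from family structure and
line divergence, which is all the downstream methods exploit.

Traits are simulated additively: a random subset of markers acts as QTL,
per-QTL effect vectors carry the genetic correlation structure, and residual
variance is set from the target heritabilities. Feed conversion ratio and
residual feed intake are deliberately *not* simulated — they are derived
later from ADG/ADFI/body weight, so their heritabilities are emergent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree

#: Traits simulated directly in "bird" mode (FCR and RFI are derived later).
BIRD_TRAITS = ("ADG", "ADFI", "EP", "BMP", "LMP")

#: Per-trait phenotypic means (g/day for ADG/ADFI, % for carcass traits).
DEFAULT_TRAIT_MEANS = {"ADG": 29.34, "ADFI": 102.36, "EP": 66.60,
                       "BMP": 17.40, "LMP": 23.72}
#: Per-trait phenotypic standard deviations on the same scales.
DEFAULT_TRAIT_SDS = {"ADG": 5.82, "ADFI": 14.41, "EP": 1.81,
                     "BMP": 1.44, "LMP": 2.58}
#: Target narrow-sense heritabilities.
DEFAULT_H2 = {"ADG": 0.49, "ADFI": 0.53, "EP": 0.39, "BMP": 0.34, "LMP": 0.52}

#: Genetic correlations among the simulated base traits (order BIRD_TRAITS).
#: ADG and ADFI are strongly positively correlated (bigger gainers eat more).
#: The ADG/ADFI x carcass entries are back-solved from the target *emergent*
#: genetic correlations of the derived efficiency traits with carcass yield
#: (FCR x EP/BMP/LMP ~ -0.43/-0.16/-0.34, RFI x EP/BMP/LMP ~
#: -0.32/-0.40/-0.35), using the linearized genetic values of FCR and RFI;
#: carcass traits hang together moderately.
DEFAULT_GENETIC_CORR = np.array([
    [1.00, 0.75, 0.24, -0.18, 0.10],
    [0.75, 1.00, -0.06, -0.39, -0.17],
    [0.24, -0.06, 1.00, 0.30, 0.30],
    [-0.18, -0.39, 0.30, 1.00, 0.30],
    [0.10, -0.17, 0.30, 0.30, 1.00],
])

#: Residual correlations: feed intake and gain share environment (pen,
#: appetite); carcass residuals treated as independent.
DEFAULT_RESIDUAL_CORR = np.array([
    [1.00, 0.60, 0.00, 0.00, 0.00],
    [0.60, 1.00, 0.00, 0.00, 0.00],
    [0.00, 0.00, 1.00, 0.00, 0.00],
    [0.00, 0.00, 0.00, 1.00, 0.00],
    [0.00, 0.00, 0.00, 0.00, 1.00],
])

#: Days on test (start of week 7 to end of week 12).
TEST_DAYS = 42


class SimulationError(ValueError):
    """Raised for infeasible simulation configurations."""


def _check_corr(mat: np.ndarray, name: str, k: int) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (k, k):
        raise SimulationError(f"{name} must be {k}x{k}, got {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise SimulationError(f"{name} is not symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-12):
        raise SimulationError(f"{name} must have unit diagonal")
    if np.linalg.eigvalsh(mat).min() < -1e-10:
        raise SimulationError(f"{name} is not positive semi-definite")
    return mat


@dataclass
class SimulationConfig:
    """Study-design parameters of the simulated intercross.

    Defaults reproduce the population structure of the target design:
    6 sires + 14 dams in F0, 8 sires + 43 dams in F1, 511 F2 birds in
    8 paternal half-sib families, with trait means/SDs, heritabilities and
    genetic correlations at the analysis targets.
    """

    # population structure
    n_f0_males: int = 6
    n_f0_females: int = 14
    n_f1_males: int = 8
    n_f1_females: int = 43
    n_f2: int = 511
    family_sizes: list[int] | None = None  # default: near-equal split

    # marker panel
    n_markers: int = 5000
    n_qtl: int = 200
    qtl_in_panel: bool = True  # False drops QTL columns from the marker panel

    # founder allele frequencies: common base frequency p0 ~ U(low, high),
    # per-line frequency ~ Beta centred on p0 with spread set by divergence
    founder_freq_low: float = 0.1
    founder_freq_high: float = 0.9
    divergence: float = 0.3  # in [0, 1); 0 = identical lines
    line_a_freqs: np.ndarray | None = None  # explicit overrides, in [0, 1]
    line_b_freqs: np.ndarray | None = None

    # traits
    trait_means: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_MEANS))
    trait_sds: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_SDS))
    target_h2: dict = field(default_factory=lambda: dict(DEFAULT_H2))
    genetic_corr: np.ndarray = field(
        default_factory=lambda: DEFAULT_GENETIC_CORR.copy())
    residual_corr: np.ndarray = field(
        default_factory=lambda: DEFAULT_RESIDUAL_CORR.copy())
    sex_effect_sd: float = 0.4    # male-female gap, units of phenotypic SD
    hatch_effect_sd: float = 0.25  # extreme hatch offsets, units of SD
    n_hatches: int = 3
    bw_start_mean: float = 900.0  # g at start of test (week 7)
    bw_start_sd: float = 60.0     # residual spread of start weight
    bw_start_adg_slope: float = 1.5  # g start weight per g/day ADG deviation

    # direct (single generic trait) mode
    direct_h2: float = 0.5
    direct_sd: float = 1.0
    direct_mean: float = 0.0

    # genotype quality metadata
    missing_rate: float = 0.01
    fail_fraction: float = 0.05
    quality_pass_range: tuple = (0.65, 1.0)
    quality_fail_range: tuple = (0.0, 0.55)

    # phenotype outlier planting (emulates deviant records removed by QC)
    n_planted_outliers: int = 7

    seed: int = 1

    def validate(self) -> None:
        counts = (self.n_f0_males, self.n_f0_females, self.n_f1_males,
                  self.n_f1_females, self.n_f2, self.n_markers, self.n_qtl,
                  self.n_hatches)
        if any(int(c) <= 0 for c in counts):
            raise SimulationError("all population/marker counts must be positive")
        if self.n_qtl > self.n_markers:
            raise SimulationError("n_qtl cannot exceed n_markers")
        if not (0.0 <= self.divergence < 1.0):
            raise SimulationError("divergence must lie in [0, 1)")
        if not (0.0 < self.founder_freq_low < self.founder_freq_high < 1.0):
            raise SimulationError(
                "founder base frequencies must satisfy 0 < low < high < 1")
        for line in (self.line_a_freqs, self.line_b_freqs):
            if line is not None:
                arr = np.asarray(line, dtype=float)
                if arr.shape != (self.n_markers,):
                    raise SimulationError("explicit line frequencies must have "
                                          "length n_markers")
                if np.any(arr < 0) or np.any(arr > 1):
                    raise SimulationError("explicit line frequencies must lie "
                                          "in [0, 1]")
        for t, h2 in self.target_h2.items():
            if not (0.0 <= h2 < 1.0):
                raise SimulationError(f"target h2 for {t} must be in [0, 1)")
        if not (0.0 <= self.direct_h2 < 1.0):
            raise SimulationError("direct_h2 must be in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise SimulationError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.fail_fraction < 1.0):
            raise SimulationError("fail_fraction must be in [0, 1)")
        k = len(BIRD_TRAITS)
        _check_corr(self.genetic_corr, "genetic_corr", k)
        _check_corr(self.residual_corr, "residual_corr", k)
        if self.family_sizes is not None:
            if len(self.family_sizes) != self.n_f1_males:
                raise SimulationError("family_sizes must have one entry per "
                                      "F1 sire")
            if sum(self.family_sizes) != self.n_f2:
                raise SimulationError("family_sizes must sum to n_f2")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("genetic_corr", "residual_corr", "line_a_freqs",
                    "line_b_freqs"):
            if d[key] is not None:
                d[key] = np.asarray(d[key]).tolist()
        return d


@dataclass
class TrueValues:
    """Ground truth of a trait simulation, for parameter-recovery tests."""

    tbv: pd.DataFrame                 # individuals x traits, true breeding values
    qtl_snp_ids: list[str]
    qtl_effects: pd.DataFrame         # QTL x traits allele-substitution effects
    tbv_offset: pd.Series             # additive centering constant per trait
    genetic_var: pd.Series            # realized var(TBV) over phenotyped birds
    residual_var: pd.Series           # residual variance used in simulation
    realized_h2: pd.Series


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

def simulate_founders(config: SimulationConfig, rng: np.random.Generator):
    """Draw two divergent founder lines and their genotypes.

    Sires come from line A (the selected broiler line), dams from line B
    (the indigenous line). Per-marker allele frequencies share a base draw
    ``p0 ~ U(low, high)``; each line's frequency is Beta-distributed around
    p0 with concentration ``(1 - divergence) / divergence``, so divergence 0
    collapses both lines onto p0 and divergence near 1 fixes alternative
    alleles.

    Returns
    -------
    (Pedigree, GenotypeMatrix, dict)
        The frequency dict holds ``p0``, ``line_a`` and ``line_b`` arrays so
        that the sampling law is checkable downstream.
    """
    config.validate()
    m = config.n_markers
    p0 = rng.uniform(config.founder_freq_low, config.founder_freq_high, m)
    if config.divergence == 0.0:
        p_a = p0.copy()
        p_b = p0.copy()
    else:
        conc = (1.0 - config.divergence) / config.divergence
        p_a = rng.beta(p0 * conc, (1.0 - p0) * conc)
        p_b = rng.beta(p0 * conc, (1.0 - p0) * conc)
    if config.line_a_freqs is not None:
        p_a = np.asarray(config.line_a_freqs, dtype=float)
    if config.line_b_freqs is not None:
        p_b = np.asarray(config.line_b_freqs, dtype=float)

    males = [f"F0_M{i + 1:02d}" for i in range(config.n_f0_males)]
    females = [f"F0_F{i + 1:02d}" for i in range(config.n_f0_females)]
    rows = []
    for i in males:
        rows.append(dict(id=i, sire=None, dam=None, generation="F0", sex="M",
                         hatch=None, family=None, line="A"))
    for i in females:
        rows.append(dict(id=i, sire=None, dam=None, generation="F0", sex="F",
                         hatch=None, family=None, line="B"))
    ped = Pedigree(pd.DataFrame.from_records(rows))

    geno_a = rng.binomial(2, p_a, size=(len(males), m)).astype(float)
    geno_b = rng.binomial(2, p_b, size=(len(females), m)).astype(float)
    snp_ids = [f"SNP{j + 1:05d}" for j in range(m)]
    geno = GenotypeMatrix(males + females, snp_ids,
                          np.vstack([geno_a, geno_b]))
    freqs = {"p0": p0, "line_a": p_a, "line_b": p_b}
    return ped, geno, freqs


# ---------------------------------------------------------------------------
# crossing / gene dropping
# ---------------------------------------------------------------------------

def _mate(g_sire: np.ndarray, g_dam: np.ndarray,
          rng: np.random.Generator) -> np.ndarray:
    """One offspring dosage vector by independent Mendelian sampling."""
    a_s = rng.random(g_sire.shape) < g_sire / 2.0
    a_d = rng.random(g_dam.shape) < g_dam / 2.0
    return (a_s.astype(float) + a_d.astype(float))


def simulate_cross(founder_ped: Pedigree, founder_geno: GenotypeMatrix,
                   config: SimulationConfig, rng: np.random.Generator):
    """Produce F1 and F2 generations by gene dropping.

    F1 birds come from line-A sire x line-B dam matings. The F1 males become
    the sires of the F2 paternal half-sib families; the F1 females are split
    into disjoint dam groups, one group per sire, so families contain a mix
    of full and half sibs.
    """
    config.validate()
    f0_males = founder_ped.table.query("sex == 'M'")["id"].tolist()
    f0_females = founder_ped.table.query("sex == 'F'")["id"].tolist()
    if not f0_males or not f0_females:
        raise SimulationError("founder generation needs both sexes")
    n_f1 = config.n_f1_males + config.n_f1_females
    if config.n_f1_females < config.n_f1_males:
        raise SimulationError(
            "mating design infeasible: each F1 sire needs at least one dam "
            f"({config.n_f1_males} sires > {config.n_f1_females} dams)")

    index = {i: k for k, i in enumerate(founder_geno.ids)}
    dos = founder_geno.dosages
    rows = list(founder_ped.table.to_dict("records"))
    genos = [dos]

    # F1: random F0 pairings, fixed sex counts
    f1_ids, f1_rows = [], []
    f1_geno = np.empty((n_f1, config.n_markers))
    sexes = ["M"] * config.n_f1_males + ["F"] * config.n_f1_females
    for k in range(n_f1):
        s = f0_males[rng.integers(len(f0_males))]
        d = f0_females[rng.integers(len(f0_females))]
        sex = sexes[k]
        iid = (f"F1_M{k + 1:02d}" if sex == "M"
               else f"F1_F{k - config.n_f1_males + 1:02d}")
        f1_ids.append(iid)
        f1_rows.append(dict(id=iid, sire=s, dam=d, generation="F1", sex=sex,
                            hatch=None, family=None, line=None))
        f1_geno[k] = _mate(dos[index[s]], dos[index[d]], rng)
    rows.extend(f1_rows)
    genos.append(f1_geno)
    f1_index = {i: k for k, i in enumerate(f1_ids)}

    # F2: one half-sib family per F1 sire, disjoint dam groups
    sires = [i for i, r in zip(f1_ids, f1_rows) if r["sex"] == "M"]
    dams = [i for i, r in zip(f1_ids, f1_rows) if r["sex"] == "F"]
    dam_groups = [list(g) for g in
                  np.array_split(rng.permutation(dams), len(sires))]
    if config.family_sizes is not None:
        fam_sizes = list(config.family_sizes)
    else:
        base, extra = divmod(config.n_f2, len(sires))
        fam_sizes = [base + (1 if k < extra else 0) for k in range(len(sires))]

    f2_rows = []
    f2_geno = np.empty((config.n_f2, config.n_markers))
    k = 0
    for sire, group, size in zip(sires, dam_groups, fam_sizes):
        for _ in range(size):
            dam = group[rng.integers(len(group))]
            iid = f"F2_{k + 1:04d}"
            sex = "M" if rng.random() < 0.5 else "F"
            hatch = f"H{rng.integers(config.n_hatches) + 1}"
            f2_rows.append(dict(id=iid, sire=sire, dam=dam, generation="F2",
                                sex=sex, hatch=hatch, family=sire, line=None))
            f2_geno[k] = _mate(f1_geno[f1_index[sire]],
                               f1_geno[f1_index[dam]], rng)
            k += 1
    rows.extend(f2_rows)
    genos.append(f2_geno)

    ped = Pedigree(pd.DataFrame.from_records(rows))
    all_ids = [r["id"] for r in rows]
    geno = GenotypeMatrix(all_ids, list(founder_geno.snp_ids),
                          np.vstack(genos))
    return ped, geno


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def _standardized_genetic_values(qtl_dosages: np.ndarray, target_cov: np.ndarray,
                                 phen_rows: np.ndarray,
                                 rng: np.random.Generator):
    """QTL effect matrix whose TBVs realize ``target_cov`` over phen_rows.

    Effects are drawn i.i.d. multivariate normal per QTL and then linearly
    transformed so the realized covariance of the breeding values across the
    phenotyped individuals equals the target exactly. The transform acts on
    the effect matrix, so breeding values stay strictly linear in genotype
    dosage (Mendelian transmission consistency is preserved).
    """
    n_qtl, n_traits = qtl_dosages.shape[1], target_cov.shape[0]
    active = np.diag(target_cov) > 0
    effects = np.zeros((n_qtl, n_traits))
    if active.any():
        sub_cov = target_cov[np.ix_(active, active)]
        k = int(active.sum())
        raw = rng.standard_normal((n_qtl, k))
        tbv_raw = qtl_dosages[phen_rows] @ raw
        realized = np.cov(tbv_raw, rowvar=False, ddof=1).reshape(k, k)
        try:
            l_real = np.linalg.cholesky(realized)
            l_target = np.linalg.cholesky(sub_cov)
        except np.linalg.LinAlgError as exc:
            raise SimulationError(
                "degenerate realized genetic covariance; increase n_qtl or "
                "marker diversity") from exc
        transform = np.linalg.solve(l_real.T, l_target.T)
        effects[:, active] = raw @ transform
    tbv = qtl_dosages @ effects
    offset = -tbv[phen_rows].mean(axis=0)
    return effects, tbv + offset, offset


def simulate_generic_traits(pedigree: Pedigree, genotypes: GenotypeMatrix,
                            h2: np.ndarray, sds: np.ndarray,
                            corr: np.ndarray, n_qtl: int,
                            rng: np.random.Generator,
                            residual_corr: np.ndarray | None = None,
                            trait_names: list[str] | None = None,
                            means: np.ndarray | None = None):
    """Simulate T additive traits with given h2 / SD / genetic correlations.

    Returns (phenotypes DataFrame over phenotyped ids, TrueValues). The
    phenotyped set is the F2 generation when present, otherwise everyone.
    """
    h2 = np.atleast_1d(np.asarray(h2, dtype=float))
    sds = np.atleast_1d(np.asarray(sds, dtype=float))
    n_traits = h2.size
    corr = _check_corr(np.atleast_2d(corr), "genetic correlation matrix",
                       n_traits)
    if residual_corr is None:
        residual_corr = np.eye(n_traits)
    residual_corr = _check_corr(np.atleast_2d(residual_corr),
                                "residual correlation matrix", n_traits)
    if trait_names is None:
        trait_names = [f"T{k + 1}" for k in range(n_traits)]
    if means is None:
        means = np.zeros(n_traits)

    ids = genotypes.ids
    try:
        phen_ids = pedigree.generation("F2") or ids
    except Exception:
        phen_ids = ids
    row_of = {i: k for k, i in enumerate(ids)}
    phen_rows = np.array([row_of[i] for i in phen_ids])

    qtl_idx = np.sort(rng.choice(genotypes.n_snps, size=n_qtl, replace=False))
    qtl_dos = genotypes.dosages[:, qtl_idx]
    if np.any(~np.isfinite(qtl_dos)):
        raise SimulationError("QTL genotypes must be complete (simulate traits "
                              "before injecting missingness)")

    gsd = np.sqrt(h2) * sds
    target_cov = np.outer(gsd, gsd) * corr
    effects, tbv, offset = _standardized_genetic_values(
        qtl_dos, target_cov, phen_rows, rng)

    esd = np.sqrt(1.0 - h2) * sds
    res_cov = np.outer(esd, esd) * residual_corr
    # eigendecomposition tolerates PSD-but-singular residual structure
    w, v = np.linalg.eigh(res_cov)
    factor = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    resid = rng.standard_normal((len(phen_rows), n_traits)) @ factor.T

    pheno = means + tbv[phen_rows] + resid
    pheno_df = pd.DataFrame(pheno, index=phen_ids, columns=trait_names)

    gvar = pd.Series(np.var(tbv[phen_rows], axis=0, ddof=1),
                     index=trait_names)
    rvar = pd.Series(np.diag(res_cov), index=trait_names)
    truth = TrueValues(
        tbv=pd.DataFrame(tbv, index=ids, columns=trait_names),
        qtl_snp_ids=[genotypes.snp_ids[j] for j in qtl_idx],
        qtl_effects=pd.DataFrame(effects, index=[genotypes.snp_ids[j]
                                                 for j in qtl_idx],
                                 columns=trait_names),
        tbv_offset=pd.Series(offset, index=trait_names),
        genetic_var=gvar,
        residual_var=rvar,
        realized_h2=gvar / (gvar + rvar),
    )
    return pheno_df, truth


def simulate_traits(pedigree: Pedigree, genotypes: GenotypeMatrix,
                    config: SimulationConfig, rng: np.random.Generator,
                    mode: str = "bird"):
    """Simulate phenotypes for the phenotyped (F2) birds.

    ``bird`` mode produces ADG, ADFI, EP, BMP, LMP with the configured
    genetic correlation structure plus sex/hatch fixed effects and derives
    start/end body weights from ADG. ``direct`` mode produces one generic
    trait at ``config.direct_h2`` with no fixed effects, for parameter
    recovery experiments.

    Returns (TraitTable DataFrame indexed by bird id, TrueValues).
    """
    config.validate()
    if mode == "direct":
        pheno, truth = simulate_generic_traits(
            pedigree, genotypes, np.array([config.direct_h2]),
            np.array([config.direct_sd]), np.eye(1), config.n_qtl, rng,
            trait_names=["trait"], means=np.array([config.direct_mean]))
        table = _attach_factors(pheno, pedigree)
        return table, truth

    if mode != "bird":
        raise SimulationError(f"unknown trait simulation mode {mode!r}")

    names = list(BIRD_TRAITS)
    h2 = np.array([config.target_h2[t] for t in names])
    sds = np.array([config.trait_sds[t] for t in names])
    means = np.array([config.trait_means[t] for t in names])
    pheno, truth = simulate_generic_traits(
        pedigree, genotypes, h2, sds, config.genetic_corr, config.n_qtl, rng,
        residual_corr=config.residual_corr, trait_names=names, means=means)
    table = _attach_factors(pheno, pedigree)

    # additive fixed effects, centered so trait means stay at target
    sex_sign = np.where(table["sex"] == "M", 0.5, -0.5)
    hatch_levels = sorted(table["hatch"].dropna().unique())
    offsets = (np.linspace(-1.0, 1.0, len(hatch_levels))
               if len(hatch_levels) > 1 else np.zeros(1))
    hatch_of = dict(zip(hatch_levels, offsets))
    hatch_sign = table["hatch"].map(hatch_of).fillna(0.0).to_numpy()
    for t, sd in zip(names, sds):
        table[t] = (table[t].to_numpy()
                    + config.sex_effect_sd * sd * sex_sign
                    + config.hatch_effect_sd * sd * hatch_sign)

    adg = table["ADG"].to_numpy()
    bw_start = (config.bw_start_mean
                + config.bw_start_adg_slope * (adg - adg.mean())
                + rng.normal(0.0, config.bw_start_sd, len(table)))
    table.insert(3, "BW_start", bw_start)
    table.insert(4, "BW_end", bw_start + TEST_DAYS * adg)
    return table, truth


def _attach_factors(pheno: pd.DataFrame, pedigree: Pedigree) -> pd.DataFrame:
    ped = pedigree.table.set_index("id")
    out = pheno.copy()
    for k, col in enumerate(("sex", "hatch", "family")):
        out.insert(k, col, ped.loc[out.index, col])
    return out


# ---------------------------------------------------------------------------
# genotype quality metadata
# ---------------------------------------------------------------------------

def attach_quality_metadata(genotypes: GenotypeMatrix,
                            config: SimulationConfig,
                            rng: np.random.Generator):
    """Inject missing calls and per-SNP quality scores; compute QC metrics.

    A ``fail_fraction`` of SNPs is planted to fail QC deterministically:
    roughly half get a quality score below 0.6, the rest get enough missing
    calls to push the call rate below 95%. Passing SNPs receive quality in
    ``quality_pass_range`` and at most 4% missing calls, so they can never
    fail those two criteria by chance. Low-MAF SNPs can still arise from the
    allele-frequency draws; the returned panel's ``expected_fail`` column is
    computed from the realized metrics and covers them.

    Returns (GenotypeMatrix with missingness, SNPPanel DataFrame).
    """
    config.validate()
    n, m = genotypes.n_individuals, genotypes.n_snps
    dos = genotypes.dosages.copy()

    n_fail = int(round(config.fail_fraction * m))
    planted = rng.choice(m, size=n_fail, replace=False)
    n_quality = n_fail // 2
    quality_fail = planted[:n_quality]
    callrate_fail = planted[n_quality:]

    quality = rng.uniform(*config.quality_pass_range, size=m)
    quality[quality_fail] = rng.uniform(*config.quality_fail_range,
                                        size=quality_fail.size)

    max_pass_missing = int(np.floor(0.04 * n))
    if config.missing_rate > 0:
        n_missing = np.minimum(rng.binomial(n, config.missing_rate, size=m),
                               max_pass_missing)
    else:
        n_missing = np.zeros(m, dtype=int)
    n_missing[callrate_fail] = int(np.ceil(0.08 * n))
    for j in np.nonzero(n_missing)[0]:
        rows = rng.choice(n, size=n_missing[j], replace=False)
        dos[rows, j] = np.nan

    call_rate = 1.0 - n_missing / n
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dos, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)

    panel = pd.DataFrame({
        "snp_id": genotypes.snp_ids,
        "call_rate": call_rate,
        "quality_score": quality,
        "maf": maf,
    })
    panel["planted_fail"] = np.isin(np.arange(m), planted)
    panel["expected_fail"] = ((call_rate <= 0.95) | (quality <= 0.6)
                              | (maf <= 0.01))
    out = GenotypeMatrix(list(genotypes.ids), list(genotypes.snp_ids), dos)
    return out, panel


def plant_phenotype_outliers(traits: pd.DataFrame, n_outliers: int = 7,
                             check_traits=("ADG", "ADFI"),
                             magnitude: float = 12.0, clip: float = 3.5,
                             rng: np.random.Generator | None = None):
    """Plant deviant records that a 3-SD screen removes exactly.

    Clean values of the check traits are first clipped to ``clip`` input SDs,
    then ``n_outliers`` birds get one check trait set ``magnitude`` SDs from
    the mean (alternating trait and sign). With the defaults and n >= 100 the
    contaminated SD is below ``sqrt(1 + n_outliers * magnitude**2 / n)`` ~
    1.9 input SDs, so planted birds sit beyond 6 contaminated SDs while clean
    birds stay within 2.1 — the 3-SD rule recovers the planted set exactly.

    Returns (contaminated TraitTable copy, list of planted bird ids).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    out = traits.copy()
    stats = {}
    for t in check_traits:
        x = out[t].to_numpy(dtype=float)
        mu, sd = x.mean(), x.std(ddof=1)
        out[t] = np.clip(x, mu - clip * sd, mu + clip * sd)
        stats[t] = (mu, sd)
    birds = rng.choice(len(out), size=n_outliers, replace=False)
    planted_ids = []
    for k, row in enumerate(birds):
        t = check_traits[k % len(check_traits)]
        mu, sd = stats[t]
        sign = 1.0 if k % 2 == 0 else -1.0
        out.iloc[row, out.columns.get_loc(t)] = mu + sign * magnitude * sd
        planted_ids.append(out.index[row])
    return out, planted_ids


# ---------------------------------------------------------------------------
# one-call orchestrator
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """Everything the downstream pipeline consumes."""

    config: SimulationConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix          # with injected missingness
    panel: pd.DataFrame                # per-SNP QC metadata
    traits: pd.DataFrame               # F2 phenotypes (with planted outliers)
    truth: TrueValues
    line_freqs: dict
    planted_outlier_ids: list[str]


def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int | None = None) -> SimulatedDataset:
    """Run the full generator: founders -> cross -> traits -> QC metadata.

    All randomness derives from one seed via independent child streams, so
    the same seed yields a bit-identical dataset.
    """
    if config is None:
        config = SimulationConfig()
    if seed is not None:
        config.seed = seed
    config.validate()
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(config.seed).spawn(5)]
    ped0, geno0, freqs = simulate_founders(config, streams[0])
    ped, geno = simulate_cross(ped0, geno0, config, streams[1])
    traits, truth = simulate_traits(ped, geno, config, streams[2], mode="bird")
    geno_qc, panel = attach_quality_metadata(geno, config, streams[3])
    planted: list[str] = []
    if config.n_planted_outliers > 0:
        traits, planted = plant_phenotype_outliers(
            traits, n_outliers=config.n_planted_outliers, rng=streams[4])
    if not config.qtl_in_panel:
        keep = [s for s in geno_qc.snp_ids if s not in set(truth.qtl_snp_ids)]
        geno_qc = geno_qc.subset_snps(keep)
        panel = panel[panel["snp_id"].isin(keep)].reset_index(drop=True)
    return SimulatedDataset(config, ped, geno_qc, panel, traits, truth,
                            freqs, planted)
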