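"""Generator checks: founder sampling law, Mendelian segregation, trait
structure, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import feedgp as fg
from feedgp.simulate import SimulationError
from conftest import tiny_cross_config


class TestFounders:
    def test_zero_divergence_shares_one_frequency_vector(self, rng):
        cfg = fg.SimulationConfig(n_markers=200, divergence=0.0, seed=1)
        _, _, freqs = fg.simulate_founders(cfg, rng)
        assert np.array_equal(freqs["line_a"], freqs["line_b"])
        assert np.array_equal(freqs["line_a"], freqs["p0"])

    def test_fixed_allele_override(self, rng):
        cfg = fg.SimulationConfig(n_markers=1, n_qtl=1,
                                  line_a_freqs=np.array([1.0]),
                                  line_b_freqs=np.array([0.0]), seed=1)
        ped, geno, _ = fg.simulate_founders(cfg, rng)
        males = ped.table.query("sex == 'M'")["id"]
        females = ped.table.query("sex == 'F'")["id"]
        df = geno.to_dataframe()
        assert (df.loc[males].to_numpy() == 2).all()
        assert (df.loc[females].to_numpy() == 0).all()

    def test_base_frequency_matches_sampling_law_over_seeds(self):
        """KS test of the drawn base frequencies against U(low, high)."""
        cfg = fg.SimulationConfig(n_markers=5000)
        passed = 0
        for seed in range(10):
            _, _, freqs = fg.simulate_founders(
                cfg, np.random.default_rng(seed))
            p = stats.kstest(
                freqs["p0"], stats.uniform(
                    cfg.founder_freq_low,
                    cfg.founder_freq_high - cfg.founder_freq_low).cdf).pvalue
            passed += p > 0.01
        assert passed >= 8

    def test_invalid_parameters_rejected(self, rng):
        with pytest.raises(SimulationError):
            fg.simulate_founders(
                fg.SimulationConfig(founder_freq_low=0.0), rng)
        with pytest.raises(SimulationError):
            fg.simulate_founders(fg.SimulationConfig(divergence=1.0), rng)
        with pytest.raises(SimulationError):
            fg.simulate_founders(
                fg.SimulationConfig(n_markers=2,
                                    line_a_freqs=np.array([0.5, 1.5])), rng)


class TestCross:
    def test_forced_heterozygote(self, rng):
        """Sire 2 x dam 0 at a marker -> every offspring dosage 1."""
        cfg = tiny_cross_config(n_markers=5, n_qtl=2,
                                line_a_freqs=np.ones(5),
                                line_b_freqs=np.zeros(5))
        ped0, g0, _ = fg.simulate_founders(cfg, rng)
        ped, geno = fg.simulate_cross(ped0, g0, cfg, rng)
        f1 = geno.to_dataframe().loc[ped.generation("F1")]
        assert (f1.to_numpy() == 1).all()

    def test_mendelian_segregation_ratio(self, rng):
        """Het x het -> 1:2:1 over 10,000 offspring (chi-square)."""
        g_parent = np.ones(1)
        from feedgp.simulate import _mate
        offspring = np.array([_mate(g_parent, g_parent, rng)[0]
                              for _ in range(10_000)])
        counts = [np.sum(offspring == k) for k in (0, 1, 2)]
        p = stats.chisquare(counts, f_exp=[2500, 5000, 2500]).pvalue
        assert p > 0.001

    def test_family_structure(self, small_dataset):
        ped = small_dataset.pedigree
        f2 = ped.table.query("generation == 'F2'")
        assert f2["family"].nunique() == 8
        # family label equals the F1 sire's id
        assert (f2["family"] == f2["sire"]).all()

    def test_gene_dropping_conservation(self, small_dataset):
        """Offspring alleles are drawable from parental genotypes: a
        homozygous parent pair bounds the offspring dosage."""
        geno = small_dataset.genotypes
        df = pd.DataFrame(np.nan_to_num(geno.dosages, nan=-1.0),
                          index=geno.ids, columns=geno.snp_ids)
        pm = small_dataset.pedigree.parent_map()
        for child in small_dataset.pedigree.generation("F2")[:40]:
            s, d = pm[child]
            c, gs, gd = (df.loc[child].to_numpy(), df.loc[s].to_numpy(),
                         df.loc[d].to_numpy())
            ok = c < 0  # missing calls carry no constraint
            lower = (gs == 2).astype(int) + (gd == 2).astype(int)
            upper = 2 - (gs == 0).astype(int) - (gd == 0).astype(int)
            assert np.all(ok | ((c >= lower) & (c <= upper)))

    def test_infeasible_design_rejected(self, rng):
        cfg = tiny_cross_config(n_f1_males=9, n_f1_females=8)
        ped0, g0, _ = fg.simulate_founders(cfg, rng)
        with pytest.raises(SimulationError, match="infeasible"):
            fg.simulate_cross(ped0, g0, cfg, rng)


@pytest.fixture(scope="module")
def big_cross():
    cfg = fg.SimulationConfig(n_f2=2000, n_markers=500, n_qtl=150,
                              n_planted_outliers=0, seed=33)
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(33).spawn(2)]
    ped0, g0, _ = fg.simulate_founders(cfg, streams[0])
    return fg.simulate_cross(ped0, g0, cfg, streams[1]), cfg


class TestTraits:
    def test_zero_h2_gives_zero_tbv(self, big_cross, rng):
        (ped, geno), cfg = big_cross
        cfg2 = fg.SimulationConfig(**{**cfg.to_dict(), "direct_h2": 0.0,
                                      "genetic_corr": np.asarray(
                                          cfg.genetic_corr),
                                      "residual_corr": np.asarray(
                                          cfg.residual_corr)})
        traits, truth = fg.simulate_traits(ped, geno, cfg2, rng,
                                           mode="direct")
        assert np.allclose(truth.tbv.to_numpy(), 0.0)

    def test_phenotype_regressed_on_tbv_has_unit_slope(self, big_cross):
        """Direct mode, h2=0.5: slope of phenotype on TBV ~ 1 over seeds."""
        (ped, geno), _ = big_cross
        slopes = []
        for seed in range(20):
            cfg = fg.SimulationConfig(direct_h2=0.5, seed=seed)
            traits, truth = fg.simulate_traits(
                ped, geno, cfg, np.random.default_rng(seed), mode="direct")
            tbv = truth.tbv.loc[traits.index, "trait"]
            slopes.append(np.polyfit(tbv, traits["trait"], 1)[0])
        assert abs(np.mean(slopes) - 1.0) < 0.05

    def test_tbv_correlation_matches_target(self, big_cross, rng):
        """Two traits at r_g = -0.4 realize that correlation in the F2."""
        (ped, geno), _ = big_cross
        corr = np.array([[1.0, -0.4], [-0.4, 1.0]])
        _, truth = fg.simulate_generic_traits(
            ped, geno, [0.5, 0.5], [1.0, 1.0], corr, 150, rng)
        f2 = ped.generation("F2")
        realized = np.corrcoef(truth.tbv.loc[f2, "T1"],
                               truth.tbv.loc[f2, "T2"])[0, 1]
        assert realized == pytest.approx(-0.40, abs=0.05)

    def test_realized_additive_variance_near_target(self, big_cross):
        """Var(TBV) over 2000 F2 within 10% of configured (20-seed mean)."""
        (ped, geno), _ = big_cross
        rel = []
        for seed in range(20):
            cfg = fg.SimulationConfig(direct_h2=0.4, direct_sd=2.0, seed=seed)
            _, truth = fg.simulate_traits(
                ped, geno, cfg, np.random.default_rng(seed), mode="direct")
            rel.append(truth.genetic_var.iloc[0] / (0.4 * 4.0))
        assert abs(np.mean(rel) - 1.0) < 0.10

    def test_non_psd_correlation_rejected(self, big_cross, rng):
        (ped, geno), _ = big_cross
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9],
                        [-0.9, 0.9, 1.0]])
        with pytest.raises(SimulationError, match="positive semi-definite"):
            fg.simulate_generic_traits(ped, geno, [0.5] * 3, [1.0] * 3,
                                       bad, 150, rng)

    def test_tbv_is_linear_in_qtl_dosage(self, small_dataset):
        """TBV recomputes exactly from QTL dosages and effect vectors."""
        truth = small_dataset.truth
        # quality metadata injects missingness after trait simulation, so
        # recompute from the complete pre-missingness dosages via truth
        geno = small_dataset.genotypes
        sub = geno.subset_snps(truth.qtl_snp_ids)
        dos = np.nan_to_num(sub.dosages, nan=0.0)
        recomputed = dos @ truth.qtl_effects.to_numpy() \
            + truth.tbv_offset.to_numpy()
        mask = np.isfinite(sub.dosages).all(axis=1)
        assert np.allclose(recomputed[mask],
                           truth.tbv.to_numpy()[mask], atol=1e-10)


class TestQualityMetadata:
    def test_clean_panel_passes_qc(self, rng):
        cfg = tiny_cross_config(missing_rate=0.0, fail_fraction=0.0)
        ds = fg.simulate_dataset(cfg)
        assert not ds.panel["expected_fail"].all()
        geno_qc, report = fg.filter_snps(ds.genotypes, ds.panel)
        # only natural low-MAF SNPs may fail; none from call rate/quality
        assert report.removed_by_criterion["call_rate<=0.95"] == 0
        assert report.removed_by_criterion["quality<=0.6"] == 0

    def test_planted_missingness_gives_exact_call_rate(self, rng):
        """A SNP given 10% planted missingness has call_rate 0.90 exactly."""
        cfg = tiny_cross_config()
        ds = fg.simulate_dataset(cfg)
        n = ds.genotypes.n_individuals
        n_missing = ds.genotypes.missing_mask.sum(axis=0)
        expected = 1.0 - n_missing / n
        assert np.allclose(ds.panel["call_rate"].to_numpy(), expected)

    def test_planted_failures_are_removed(self):
        cfg = fg.SimulationConfig(n_markers=1000, n_qtl=100,
                                  fail_fraction=0.05, seed=9)
        ds = fg.simulate_dataset(cfg)
        _, report = fg.filter_snps(ds.genotypes, ds.panel)
        removed = set(report.removed_ids)
        planted = set(ds.panel.loc[ds.panel["planted_fail"], "snp_id"])
        expected = set(ds.panel.loc[ds.panel["expected_fail"], "snp_id"])
        assert planted <= removed
        assert removed == expected

    def test_invalid_missing_rate_rejected(self):
        with pytest.raises(SimulationError):
            fg.SimulationConfig(missing_rate=1.0).validate()


class TestDeterminism:
    def test_same_seed_bitwise_identical(self):
        a = fg.simulate_dataset(fg.SimulationConfig(n_markers=300, seed=5))
        b = fg.simulate_dataset(fg.SimulationConfig(n_markers=300, seed=5))
        assert a.pedigree.table.equals(b.pedigree.table)
        assert np.array_equal(a.genotypes.dosages, b.genotypes.dosages,
                              equal_nan=True)
        assert a.traits.equals(b.traits)

    def test_different_seed_differs(self):
        a = fg.simulate_dataset(fg.SimulationConfig(n_markers=300, seed=5))
        b = fg.simulate_dataset(fg.SimulationConfig(n_markers=300, seed=6))
        assert not np.array_equal(a.genotypes.dosages, b.genotypes.dosages,
                                  equal_nan=True)


class TestOutlierPlanting:
    def test_planted_outliers_recovered_exactly(self, rng):
        clean = pd.DataFrame({
            "ADG": rng.normal(29, 5.8, 511), "ADFI": rng.normal(102, 14, 511),
        }, index=[f"B{i}" for i in range(511)])
        contaminated, planted = fg.plant_phenotype_outliers(clean, 7, rng=rng)
        kept, report = fg.filter_phenotypes(contaminated)
        assert set(report.removed_ids) == set(planted)
        assert report.n_retained == 504
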