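"""Mixed-model machinery: closed forms, GLS oracle, SNP-BLUP equivalence,
REML ascent and parameter recovery."""

import numpy as np
import pytest

import feedgp as fg
from feedgp.mixed_model import (ModelError, aireml, aireml_bivariate,
                                build_mme, design_matrix, full_rank_columns,
                                incidence_matrix, solve_mme)
from conftest import tiny_cross_config


def simulate_direct(cfg, seed):
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(seed).spawn(3)]
    ped0, g0, _ = fg.simulate_founders(cfg, streams[0])
    ped, geno = fg.simulate_cross(ped0, g0, cfg, streams[1])
    traits, truth = fg.simulate_traits(ped, geno, cfg, streams[2],
                                       mode="direct")
    ids = list(traits.index)
    G = fg.stabilize(fg.genomic_relationship(geno.subset_individuals(ids)))
    return traits, truth, G


class TestBuildSolve:
    def test_scalar_closed_form(self, rng):
        """K=I, lambda=1, one record per animal: u_i = (y_i - ybar) / 2."""
        n = 8
        y = rng.normal(10, 2, n)
        sol = solve_mme(build_mme(y, np.ones((n, 1)), np.eye(n), np.eye(n),
                                  1.0, 1.0))
        assert sol.fixed_effects.iloc[0] == pytest.approx(y.mean())
        assert np.allclose(sol.u, (y - y.mean()) / 2.0)

    def test_infinite_shrinkage_limit(self, rng):
        n = 6
        y = rng.normal(0, 1, n)
        sol = solve_mme(build_mme(y, np.ones((n, 1)), np.eye(n), np.eye(n),
                                  1e-9, 1.0))
        assert np.all(np.abs(sol.u) < 1e-6)

    def test_structure(self, rng):
        n, q, p = 7, 9, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        Z = incidence_matrix([f"i{k % q}" for k in range(n)],
                             [f"i{k}" for k in range(q)])
        mme = build_mme(rng.normal(size=n), X, Z, np.eye(q), 1.0, 2.0)
        assert mme.C.shape == (p + q, p + q)
        assert np.allclose(mme.C, mme.C.T)

    def test_solution_satisfies_equations(self, rng):
        n = 12
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        mme = build_mme(y, X, np.eye(n), np.eye(n), 1.5, 0.7)
        sol = solve_mme(mme)
        full = np.concatenate([sol.fixed_effects, sol.u])
        resid = np.linalg.norm(mme.C @ full - mme.rhs)
        assert resid / np.linalg.norm(mme.rhs) < 1e-10

    def test_pev_endpoints(self):
        """PEV=0 -> accuracy 1; PEV=sigma_a^2 -> accuracy 0."""
        sa2 = 2.0
        pev = np.array([0.0, sa2])
        r = np.sqrt(1.0 - np.clip(pev, 0, sa2) / sa2)
        assert r[0] == 1.0 and r[1] == 0.0

    def test_gls_oracle_equivalence(self):
        """u and PEV from the MME match direct GLS on the joint covariance
        for a 30-animal pedigree."""
        cfg = tiny_cross_config(n_f2=30)
        ds = fg.simulate_dataset(cfg)
        A = fg.pedigree_relationship(ds.pedigree)
        ids = list(ds.traits.index)
        K = A.subset(ids).values
        n = len(ids)
        y = ds.traits["ADG"].to_numpy()
        X = np.ones((n, 1))
        sa2, se2 = 12.0, 18.0
        sol = solve_mme(build_mme(y, X, np.eye(n), K, sa2, se2))
        V = K * sa2 + np.eye(n) * se2
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u = sa2 * K @ Vi @ (y - X @ b)
        P = Vi - Vi @ X @ np.linalg.solve(X.T @ Vi @ X, X.T @ Vi)
        pev = np.diag(sa2 * K - sa2 * K @ P @ K * sa2)
        assert np.allclose(sol.u, u, atol=1e-8)
        assert np.allclose(sol.pev, pev, atol=1e-8)

    def test_snp_blup_equivalence(self, rng):
        """GEBVs from GBLUP equal marker-ridge predictions (50 x 200)."""
        n, m = 50, 200
        p = rng.uniform(0.1, 0.9, m)
        M = rng.binomial(2, p, (n, m)).astype(float)
        W = M - 2 * p                    # fixed frequencies -> full-rank G
        c = 2 * np.sum(p * (1 - p))
        G = W @ W.T / c
        sa2, se2 = 1.2, 2.3
        y = rng.normal(0, 2, n)
        X = np.ones((n, 1))
        sol = solve_mme(build_mme(y, X, np.eye(n), G, sa2, se2))
        lam = se2 * c / sa2              # per-marker variance sa2 / c
        Cm = np.block([[X.T @ X, X.T @ W],
                       [W.T @ X, W.T @ W + lam * np.eye(m)]])
        a = np.linalg.solve(Cm, np.concatenate([X.T @ y, W.T @ y]))
        assert np.max(np.abs(W @ a[1:] - sol.u.to_numpy())) < 1e-8

    def test_dimension_errors(self, rng):
        with pytest.raises(ModelError):
            build_mme(rng.normal(size=4), np.ones((4, 1)), np.eye(4),
                      np.eye(3), 1.0, 1.0)


class TestDesignHelpers:
    def test_full_rank_columns_drops_aliased(self, rng):
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        X = np.column_stack([X, X[:, 0] + X[:, 1], np.zeros(10)])
        keep = full_rank_columns(X)
        assert len(keep) == 2


class TestAireml:
    def test_null_heritability_pinned_at_boundary(self):
        """Data simulated with sigma_a^2 = 0: median h2-hat <= 0.02."""
        ests = []
        for seed in range(20):
            cfg = tiny_cross_config(n_f2=150, n_markers=300, n_qtl=60,
                                    direct_h2=0.0, seed=seed)
            traits, _, G = simulate_direct(cfg, seed)
            n = len(traits)
            vc = aireml(traits["trait"].to_numpy(), np.ones((n, 1)),
                        np.eye(n), G.values, max_iter=100)
            ests.append(vc.h2)
        assert np.median(ests) <= 0.02

    def test_balanced_half_sib_closed_form(self, rng):
        """s sires x k progeny: REML equals the ANOVA estimator when
        interior."""
        s, k = 30, 8
        sig_s2, sig_e2 = 2.0, 6.0
        sire_effects = rng.normal(0, np.sqrt(sig_s2), s)
        y = (sire_effects.repeat(k)
             + rng.normal(0, np.sqrt(sig_e2), s * k) + 50.0)
        sire_ids = [f"s{j}" for j in range(s)]
        Z = incidence_matrix([f"s{j}" for j in range(s) for _ in range(k)],
                             sire_ids)
        vc = aireml(y, np.ones((s * k, 1)), Z, np.eye(s), tol=1e-12)
        ybar_i = y.reshape(s, k).mean(axis=1)
        msb = k * np.sum((ybar_i - y.mean()) ** 2) / (s - 1)
        msw = np.sum((y.reshape(s, k) - ybar_i[:, None]) ** 2) / (s * (k - 1))
        assert vc.sigma_a2 == pytest.approx((msb - msw) / k, abs=1e-4)
        assert vc.sigma_e2 == pytest.approx(msw, abs=1e-4)

    def test_loglik_nondecreasing(self):
        cfg = tiny_cross_config(n_f2=120, n_markers=300, n_qtl=60,
                                direct_h2=0.4, seed=3)
        traits, _, G = simulate_direct(cfg, 3)
        n = len(traits)
        vc = aireml(traits["trait"].to_numpy(), np.ones((n, 1)), np.eye(n),
                    G.values)
        ll = vc.loglik_trace
        assert all(ll[i + 1] >= ll[i] - 1e-8 for i in range(len(ll) - 1))

    def test_h2_recovery_small(self):
        """Mean h2-hat near truth over a few fast replicates (the full-size
        recovery runs in the acceptance suite)."""
        ests = []
        for seed in range(6):
            cfg = tiny_cross_config(n_f2=250, n_markers=400, n_qtl=100,
                                    direct_h2=0.5, seed=seed)
            traits, _, G = simulate_direct(cfg, seed)
            n = len(traits)
            vc = aireml(traits["trait"].to_numpy(), np.ones((n, 1)),
                        np.eye(n), G.values)
            ests.append(vc.h2)
        assert np.mean(ests) == pytest.approx(0.5, abs=0.10)

    def test_founder_only_identity_matches_shrinkage(self, rng):
        """With K = I the BLUPs reduce to the simple shrinkage form."""
        n = 40
        y = rng.normal(5, 2, n)
        sa2, se2 = 1.0, 3.0
        sol = solve_mme(build_mme(y, np.ones((n, 1)), np.eye(n), np.eye(n),
                                  sa2, se2))
        lam = se2 / sa2
        shrunk = (y - y.mean()) / (1 + lam)
        assert np.allclose(sol.u, shrunk, atol=1e-8)


class TestBivariate:
    def test_duplicate_trait_correlation_near_one(self):
        cfg = tiny_cross_config(n_f2=200, n_markers=300, n_qtl=80,
                                direct_h2=0.5, seed=8)
        traits, _, G = simulate_direct(cfg, 8)
        n = len(traits)
        y = traits["trait"].to_numpy()
        X = np.ones((n, 1))
        fit = aireml_bivariate(y, y.copy(), X, X, np.eye(n), np.eye(n),
                               G.values)
        assert fit.r_g >= 0.99

    def test_structural_invariants(self):
        cfg = tiny_cross_config(n_f2=200, n_markers=300, n_qtl=80, seed=9)
        streams = [np.random.default_rng(s)
                   for s in np.random.SeedSequence(9).spawn(3)]
        ped0, g0, _ = fg.simulate_founders(cfg, streams[0])
        ped, geno = fg.simulate_cross(ped0, g0, cfg, streams[1])
        corr = np.array([[1.0, -0.4], [-0.4, 1.0]])
        ph, _ = fg.simulate_generic_traits(ped, geno, [0.5, 0.5], [1.0, 1.0],
                                           corr, 80, streams[2])
        ids = list(ph.index)
        G = fg.stabilize(fg.genomic_relationship(
            geno.subset_individuals(ids)))
        n = len(ids)
        X = np.ones((n, 1))
        fit = aireml_bivariate(ph["T1"].to_numpy(), ph["T2"].to_numpy(),
                               X, X, np.eye(n), np.eye(n), G.values)
        assert np.allclose(fit.genetic_cov, fit.genetic_cov.T)
        assert abs(fit.r_g) <= 1.0
        assert fit.r_g < 0  # sign recovered

    def test_zero_variance_trait_rejected(self):
        with pytest.raises(ModelError):
            aireml_bivariate(np.ones(10), np.arange(10.0), np.ones((10, 1)),
                             np.ones((10, 1)), np.eye(10), np.eye(10),
                             np.eye(10))


class TestCalibration:
    def test_theoretical_accuracy_calibrated_when_markers_are_causal(self):
        """Mean cor(GEBV, TBV) over 50 masked-fold replicates matches mean
        r_theo within 0.05 when the marker panel is exactly the causal set
        and true variance components are used."""
        accs, rths = [], []
        for seed in range(50):
            cfg = tiny_cross_config(n_f2=200, n_markers=300, n_qtl=300,
                                    direct_h2=0.5, seed=seed)
            traits, truth, G = simulate_direct(cfg, seed)
            ids = list(traits.index)
            n = len(ids)
            sa2 = float(truth.genetic_var.iloc[0])
            se2 = float(truth.residual_var.iloc[0])
            rng = np.random.default_rng(1000 + seed)
            test = rng.choice(n, size=n // 2, replace=False)
            train = np.setdiff1d(np.arange(n), test)
            Z = np.zeros((train.size, n))
            Z[np.arange(train.size), train] = 1.0
            sol = solve_mme(build_mme(traits["trait"].to_numpy()[train],
                                      np.ones((train.size, 1)), Z, G.values,
                                      sa2, se2, random_ids=ids))
            tbv = truth.tbv["trait"].loc[ids].to_numpy()
            accs.append(np.corrcoef(sol.u.to_numpy()[test], tbv[test])[0, 1])
            rths.append(sol.r_theo.to_numpy()[test].mean())
        assert abs(np.mean(accs) - np.mean(rths)) < 0.05
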