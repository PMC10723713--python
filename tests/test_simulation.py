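"""Data-generating schemes: LD models, genotypes, ground truth, harness."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import fnclasso as fl
from fnclasso import (
    InvalidInputError,
    SimScheme,
    make_sigma,
    run_experiment,
    simulate_genotypes,
    simulate_nested,
    simulate_nonnested,
)


class TestMakeSigma:
    def test_independent_is_identity(self):
        sig = make_sigma("independent", 5)
        np.testing.assert_array_equal(sig.to_dense(), np.eye(5))

    def test_ar1_entries(self):
        sig = make_sigma(("ar1", 0.5), 4)
        dense = sig.to_dense()
        assert dense[0, 1] == pytest.approx(0.5)
        assert dense[0, 3] == pytest.approx(0.125)
        np.testing.assert_allclose(np.diag(dense), 1.0)

    def test_blocks_are_psd_and_block_diagonal(self):
        sig = make_sigma(("blocks", 4, 0.6), 10)
        dense = sig.to_dense()
        assert np.linalg.eigvalsh(dense).min() >= -1e-10
        assert dense[0, 4] == 0.0  # across blocks
        assert dense[0, 3] == pytest.approx(0.6**3)  # within block

    def test_explicit_matrix_validated(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # not PSD / |corr|>1
        with pytest.raises(InvalidInputError):
            make_sigma(bad, 2)
        good = np.array([[1.0, 0.3], [0.3, 1.0]])
        sig = make_sigma(good, 2)
        np.testing.assert_allclose(sig.to_dense(), good, atol=1e-8)

    def test_matvec_agrees_with_dense(self, rng):
        for spec in ["independent", ("ar1", 0.7), ("blocks", 3, 0.4)]:
            sig = make_sigma(spec, 11)
            v = rng.standard_normal(11)
            np.testing.assert_allclose(
                sig.matvec(v), sig.to_dense() @ v, atol=1e-10
            )

    def test_sample_covariance_converges(self):
        sig = make_sigma(("blocks", 5, 0.5), 10)
        X = sig.sample(200_000, np.random.default_rng(0))
        emp = np.corrcoef(X.T)
        np.testing.assert_allclose(emp, sig.to_dense(), atol=0.02)


class TestGenotypes:
    def test_gaussian_standardized_unit_variance(self, rng):
        sig = make_sigma("independent", 50)
        X = simulate_genotypes(5000, sig, "gaussian", seed=rng)
        sd = X.std(axis=0)
        # 3 standard errors of the sample SD at n = 5000
        assert np.all(np.abs(sd - 1.0) < 3 / np.sqrt(2 * 5000))

    def test_dosage_matches_hwe(self):
        sig = make_sigma("independent", 1)
        rng = np.random.default_rng(5)
        n = 20000
        # fix the MAF by narrowing the range
        X = simulate_genotypes(n, sig, "dosage", maf_range=(0.3, 0.3), seed=rng)
        f = 0.3
        expected = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        counts = np.array([(X == k).sum() for k in (0, 1, 2)]) / n
        # binomial error margin
        assert np.all(np.abs(counts - expected) < 4 * np.sqrt(expected * (1 - expected) / n))

    def test_bad_maf_rejected(self):
        sig = make_sigma("independent", 3)
        with pytest.raises(InvalidInputError):
            simulate_genotypes(10, sig, "dosage", maf_range=(0.0, 0.6))


class TestNestedScheme:
    def test_overlap_counts_and_nesting(self):
        for delta in (0.3, 0.5, 0.7, 1.0):
            ds = simulate_nested(
                SimScheme(m=500, n=50, s_plus=50, delta=delta, seed=1)
            )
            S, Sp = ds.truth["S"], ds.truth["S_plus"]
            assert len(Sp) == 50
            assert len(S) == round(delta * 50)
            assert set(S) <= set(Sp)

    def test_effects_in_declared_range(self):
        ds = simulate_nested(SimScheme(m=200, n=50, s_plus=20, delta=0.5, seed=2))
        beta_nz = ds.truth["beta"][ds.truth["S"]]
        assert np.all((beta_nz >= 0.05) & (beta_nz <= 0.15))
        mu_nz = ds.truth["mu_plus"][ds.truth["S_plus"]]
        assert np.all((mu_nz >= 0.05) & (mu_nz <= 0.15))

    def test_determinism(self):
        a = simulate_nested(SimScheme(m=100, n=40, s_plus=10, seed=7))
        b = simulate_nested(SimScheme(m=100, n=40, s_plus=10, seed=7))
        np.testing.assert_array_equal(a.target.X, b.target.X)
        np.testing.assert_array_equal(a.target.y, b.target.y)
        np.testing.assert_array_equal(
            a.sumstats.table["p"], b.sumstats.table["p"]
        )

    def test_degenerate_overlap_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate_nested(SimScheme(m=100, n=40, s_plus=10, delta=0.01, seed=0))

    def test_h2_concentrates_at_closed_form(self):
        # independent standardized genotypes: h2 -> s E[b^2]/(s E[b^2] + 1)
        # with E[b^2] = (a^2 + ab + b^2)/3 for Uniform(a, b) effects
        scheme = SimScheme(
            m=400, n=2000, s_plus=40, delta=1.0,
            sigma_spec="independent", seed=0,
        )
        h = fl.mean_realized_h2(scheme, n_replicates=40)
        a, b = 0.05, 0.15
        eb2 = (a * a + a * b + b * b) / 3
        expected = 40 * eb2 / (40 * eb2 + 1)
        assert h == pytest.approx(expected, abs=0.02)

    def test_summary_stat_covariance(self):
        # sqrt(n0) (Z - mu+) has covariance Sigma across replicates
        m = 20
        scheme = SimScheme(
            m=m, n=5, n0=400, s_plus=3, delta=1.0,
            sigma_spec=("blocks", 5, 0.5), seed=0,
        )
        sig = make_sigma(scheme.sigma_spec, m).to_dense()
        devs = []
        for s in range(2000):
            ds = simulate_nested(dataclasses.replace(scheme, seed=s))
            z = ds.sumstats.table["effect"].to_numpy()
            devs.append(np.sqrt(scheme.n0) * (z - ds.truth["mu_plus"]))
        emp = np.cov(np.array(devs).T)
        assert np.abs(emp - sig).max() < 0.15


class TestNonNestedScheme:
    def test_overlap_exact(self):
        for ds_star in (0.3, 0.5, 0.7):
            ds = simulate_nonnested(
                SimScheme(m=500, n=50, s_plus=50, scheme="nonnested",
                          delta_star=ds_star, seed=3)
            )
            S = set(ds.truth["S"])
            Spb = set(ds.truth["S_plus_beta"])
            assert len(S) == len(Spb) == 50
            assert len(S & Spb) == round(ds_star * 50)

    def test_shared_effect_correlation(self):
        # empirical correlation of (beta+, beta) on shared variants -> rho
        pairs = []
        for s in range(300):
            ds = simulate_nonnested(
                SimScheme(m=200, n=5, s_plus=20, scheme="nonnested",
                          delta_star=1.0, rho=0.9, seed=s)
            )
            sh = ds.truth["shared"]
            pairs.append(
                np.column_stack([ds.truth["beta_plus"][sh], ds.truth["beta"][sh]])
            )
        P = np.vstack(pairs)
        r = np.corrcoef(P.T)[0, 1]
        assert r == pytest.approx(0.9, abs=0.05)

    def test_mean_uses_ld(self):
        # mu+ = Sigma beta+ spreads signal onto LD partners
        ds = simulate_nonnested(
            SimScheme(m=100, n=5, s_plus=5, scheme="nonnested",
                      delta_star=1.0, sigma_spec=("blocks", 10, 0.8), seed=4)
        )
        mu, bp = ds.truth["mu_plus"], ds.truth["beta_plus"]
        sig = make_sigma(("blocks", 10, 0.8), 100)
        np.testing.assert_allclose(mu, sig.matvec(bp), atol=1e-10)
        assert np.count_nonzero(np.abs(mu) > 1e-12) > np.count_nonzero(bp)


class TestHarness:
    def test_single_replicate_table(self):
        scheme = SimScheme(m=60, n=120, s_plus=6, delta=1.0,
                           effect_low=0.2, effect_high=0.4, seed=5)
        res = run_experiment(scheme, ["fnc", "lasso"], n_replicates=1,
                             cv_folds=4)
        assert len(res) == 2
        assert set(res["method"]) == {"fnc_lasso", "lasso"}
        assert set(res.columns) >= {"replicate", "method", "r2", "aic", "q"}

    def test_fixed_seed_reproducible(self):
        scheme = SimScheme(m=40, n=100, s_plus=4, delta=1.0,
                           effect_low=0.3, effect_high=0.5, seed=6)
        a = run_experiment(scheme, ["sis"], n_replicates=2, cv_folds=4)
        b = run_experiment(scheme, ["sis"], n_replicates=2, cv_folds=4)
        assert a.equals(b)

    def test_unknown_method_rejected(self):
        with pytest.raises(InvalidInputError):
            run_experiment(SimScheme(m=20, n=40, s_plus=2, seed=0), ["nope"], 1)

    def test_external_scores_hook(self):
        scheme = SimScheme(m=30, n=80, s_plus=3, delta=1.0,
                           effect_low=0.3, effect_high=0.5, seed=8)

        def oracle_score(rep, test):
            return test.X @ np.ones(test.m) * 0.0 + test.y, 3

        res = run_experiment(scheme, [], n_replicates=1,
                             external_scores={"oracle": oracle_score})
        assert set(res["method"]) == {"oracle"}
        assert res["r2"].iloc[0] == pytest.approx(1.0)

    def test_replicate_seeds_fit_in_int32(self):
        from fnclasso.simulation import _replicate_seeds

        seeds = _replicate_seeds(12345, 1000)
        assert seeds.min() >= 0
        assert seeds.max() < 2**31
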