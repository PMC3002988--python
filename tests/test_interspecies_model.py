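import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from orthoarray._design import build_design
from orthoarray._lmm import fit_random_intercept
from orthoarray.interspecies_model import (
    NonIdentifiableDesignError,
    bh_fdr,
    fit_gene_mixed_model,
    fit_species_differences,
    lrt_species_difference,
)
from orthoarray.synthetic_data import SimulationConfig, simulate_dataset

from conftest import SPECIES3, manual_gene_dataset

STRATUM = ("NS", 4)


def _obs_arrays(ds, gene="g1", stratum=STRATUM):
    """Flatten a one-gene dataset stratum to (y, species, probe, group)."""
    from orthoarray.interspecies_model import _gene_observations
    return _gene_observations(ds, gene, stratum)


class TestEstimation:
    def test_species_means_recovered_within_monte_carlo_bound(self):
        mu = {"human": 8.0, "chimpanzee": 8.5, "rhesus": 9.0}
        sigma_ind, sigma_noise, n_ind, n_probes = 0.2, 0.3, 20, 3
        kappa = {(s, r): -0.5 for r in range(n_probes) for s in SPECIES3
                 if s != SPECIES3[r % 3]}
        # analytic SE of a species mean from n individual-level means
        se = np.sqrt((sigma_ind ** 2 + sigma_noise ** 2 / n_probes) / n_ind)
        errs = []
        for seed in range(8):
            ds = manual_gene_dataset(
                mu, pi=[0.4, -0.1, -0.3], kappa=kappa, n_ind=n_ind,
                sigma_ind=sigma_ind, sigma_noise=sigma_noise,
                rng=np.random.default_rng(seed))
            fit = fit_gene_mixed_model(ds, "g1", STRATUM, "alt")
            for s, est in zip(fit.species, fit.mu_hat):
                assert est == pytest.approx(mu[s], abs=3.5 * se)
                errs.append(est - mu[s])
        # estimates are unbiased: mean error well inside its own 3 SEs
        assert abs(np.mean(errs)) < 3 * se / np.sqrt(len(errs))

    def test_probe_relabeling_is_a_symmetry(self):
        ds = manual_gene_dataset({"human": 8, "chimpanzee": 8, "rhesus": 8},
                                 pi=[0.5, 0.0, -0.5], n_ind=5,
                                 sigma_noise=0.2,
                                 rng=np.random.default_rng(3))
        fit1 = fit_gene_mixed_model(ds, "g1", STRATUM, "alt")
        # reverse probe row order (annotation follows, so data is unchanged)
        ints = ds.intensities.iloc[::-1]
        probes = ds.probes.iloc[::-1]
        from orthoarray.study_data import ProbeLevelDataset
        ds2 = ProbeLevelDataset(ints, probes, ds.samples)
        fit2 = fit_gene_mixed_model(ds2, "g1", STRATUM, "alt")
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-8)
        np.testing.assert_allclose(fit1.mu_hat, fit2.mu_hat, atol=1e-8)
        np.testing.assert_allclose(fit1.pi_hat, fit2.pi_hat[::-1], atol=1e-8)

    def test_zero_individual_variance_matches_ols(self):
        ds = manual_gene_dataset({"human": 8, "chimpanzee": 9, "rhesus": 7},
                                 pi=[0.3, -0.3, 0.0], n_ind=4,
                                 sigma_noise=0.4,
                                 rng=np.random.default_rng(5))
        y, species, probe, group, origin, sp_names, _ = _obs_arrays(ds)
        info = build_design(species, probe, origin, sp_names)
        fit = fit_random_intercept(y, info.X, group,
                                   fixed_variances=(1e-12, 1.0))
        beta_ols = np.linalg.lstsq(info.X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-8)

    def test_fixed_variance_fit_matches_explicit_gls(self):
        ds = manual_gene_dataset({"human": 8, "chimpanzee": 8.4, "rhesus": 8},
                                 pi=[0.2, -0.2, 0.1, -0.1], n_ind=6,
                                 sigma_ind=0.2, sigma_noise=0.3,
                                 rng=np.random.default_rng(8))
        y, species, probe, group, origin, sp_names, _ = _obs_arrays(ds)
        info = build_design(species, probe, origin, sp_names)
        s2g, s2e = 0.04, 0.09
        fit = fit_random_intercept(y, info.X, group,
                                   fixed_variances=(s2g, s2e))
        # independent oracle: assemble the full covariance and solve the
        # generalized normal equations directly
        n = y.size
        V = s2e * np.eye(n)
        for g in np.unique(group):
            idx = np.where(group == g)[0]
            V[np.ix_(idx, idx)] += s2g
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(info.X.T @ Vi @ info.X, info.X.T @ Vi @ y)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-6)

    def test_all_probes_from_one_species_not_identifiable(self):
        ds = manual_gene_dataset({"human": 8, "chimpanzee": 8, "rhesus": 8},
                                 pi=[0.0], n_ind=4,
                                 rng=np.random.default_rng(0))
        # single probe has human origin -> chimp/rhesus means unanchored
        with pytest.raises(NonIdentifiableDesignError, match="chimpanzee"):
            fit_gene_mixed_model(ds, "g1", STRATUM, "alt")


class TestLikelihoodRatioTest:
    def make_fits(self, mu, seed=0, n_ind=6, sigma_noise=0.1):
        ds = manual_gene_dataset(
            dict(zip(SPECIES3, mu)), pi=[0.2, -0.2, 0.0], n_ind=n_ind,
            sigma_ind=0.1, sigma_noise=sigma_noise,
            rng=np.random.default_rng(seed))
        alt = fit_gene_mixed_model(ds, "g1", STRATUM, "alt")
        null = fit_gene_mixed_model(ds, "g1", STRATUM, "null")
        return ds, alt, null

    def test_lrt_nonnegative_and_p_in_unit_interval(self):
        for seed in range(5):
            _, alt, null = self.make_fits((8, 8, 8), seed=seed)
            lrt, p = lrt_species_difference(alt, null)
            assert lrt >= 0
            assert 0 < p <= 1
            assert alt.loglik >= null.loglik - 1e-6

    def test_strong_species_signal_gives_tiny_p(self):
        _, alt, null = self.make_fits((0.0, 3.0, 6.0), seed=1)
        _, p = lrt_species_difference(alt, null)
        assert p < 1e-6

    def test_lrt_matches_generic_likelihood_optimizer(self):
        # independent oracle: maximize the same Gaussian likelihood with a
        # generic quasi-Newton optimizer over (beta, log-variances)
        ds, alt, null = self.make_fits((8.0, 8.6, 8.2), seed=2, n_ind=4)
        y, species, probe, group, origin, sp_names, _ = _obs_arrays(ds)

        def neg_ll(params, X):
            beta, ls2g, ls2e = params[:-2], params[-2], params[-1]
            s2g, s2e = np.exp(ls2g), np.exp(ls2e)
            e = y - X @ beta
            ll = 0.0
            for g in np.unique(group):
                eg = e[group == g]
                m = eg.size
                V = s2e * np.eye(m) + s2g
                sign, logdet = np.linalg.slogdet(V)
                ll -= 0.5 * (m * np.log(2 * np.pi) + logdet
                             + eg @ np.linalg.solve(V, eg))
            return -ll

        for hypo, ours in (("alt", alt), ("null", null)):
            info = build_design(species, probe, origin, sp_names,
                                common_mean=(hypo == "null"))
            x0 = np.r_[np.linalg.lstsq(info.X, y, rcond=None)[0], -2.0, -2.0]
            res = optimize.minimize(neg_ll, x0, args=(info.X,),
                                    method="Nelder-Mead",
                                    options={"maxiter": 20000,
                                             "xatol": 1e-10, "fatol": 1e-12})
            assert ours.loglik == pytest.approx(-res.fun, abs=1e-4)

    def test_mismatched_fits_rejected(self):
        _, alt, _ = self.make_fits((8, 8, 8), seed=3)
        _, _, null_other = self.make_fits((8, 8, 8), seed=4)
        with pytest.raises(ValueError, match="same data"):
            lrt_species_difference(alt, null_other)


class TestProbeShiftInvariance:
    def test_constant_added_to_one_probe_moves_only_its_pi(self):
        ds = manual_gene_dataset({"human": 8, "chimpanzee": 8, "rhesus": 8},
                                 pi=[0.1, -0.1, 0.0], n_ind=5,
                                 sigma_ind=0.1, sigma_noise=0.2,
                                 rng=np.random.default_rng(12))
        fit0 = fit_gene_mixed_model(ds, "g1", STRATUM, "alt")
        c = 0.7
        ds.intensities.iloc[0] += c
        fit1 = fit_gene_mixed_model(ds, "g1", STRATUM, "alt")
        R = 3
        # sum-to-zero recentring: pi_r gains c(1-1/R), others lose c/R,
        # every species mean gains c/R, attenuation unchanged
        assert fit1.pi_hat[0] - fit0.pi_hat[0] == pytest.approx(
            c * (1 - 1 / R), abs=1e-7)
        np.testing.assert_allclose(fit1.pi_hat[1:] - fit0.pi_hat[1:],
                                   -c / R, atol=1e-7)
        np.testing.assert_allclose(fit1.mu_hat - fit0.mu_hat, c / R,
                                   atol=1e-7)
        for k in fit0.kappa_hat:
            assert fit1.kappa_hat[k] == pytest.approx(fit0.kappa_hat[k],
                                                      abs=1e-7)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_matches_brute_force_oracle_on_random_vectors(self):
        def step_up(p):
            p = np.asarray(p)
            m = p.size
            order = np.argsort(p)
            adj = p[order] * m / np.arange(1, m + 1)
            adj = np.minimum.accumulate(adj[::-1])[::-1]
            out = np.empty(m)
            out[order] = np.minimum(adj, 1.0)
            return out

        rng = np.random.default_rng(2024)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), step_up(p), atol=1e-12)
            adj = bh_fdr(p)
            assert (np.diff(adj[np.argsort(p)]) >= -1e-12).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            bh_fdr([0.1, np.nan])


def test_batch_driver_nesting_and_fdr_columns():
    cfg = SimulationConfig(n_genes=12, n_individuals=5, time_points=(4,),
                           seed=31, attenuation_sd=0.0)
    ds, _ = simulate_dataset(cfg)
    res = fit_species_differences(ds, STRATUM)
    assert res["converged"].all()
    assert (res["lrt"] >= 0).all()
    assert res["fdr"].between(0, 1).all()
    # FDR is the BH transform of the p column
    np.testing.assert_allclose(res["fdr"].values,
                               bh_fdr(res["p_value"].values), atol=1e-12)
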