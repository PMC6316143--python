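"""Inference checks: the joint posterior density against a term-wise
textbook oracle, sampler determinism, prior-only sampling, and agreement
with deterministic grid integration."""

import numpy as np
import pytest
from scipy.stats import binom, expon, kstest, uniform

from conftest import alignment_with_mismatches
from mscrate.distance import GammaPrior
from mscrate.infer import (
    MSCModelSpec,
    PairData,
    grid_posterior,
    locus_sufficient_stats,
    log_posterior,
    pair_data_from_loci,
    run_mcmc,
)
from mscrate.simulate import simulate_pair_counts
from mscrate.substitution import jc69_mismatch_probability


@pytest.fixture(scope="module")
def small_data() -> PairData:
    x, n, _ = simulate_pair_counts(0.00473, 0.00304, 5, 500, np.random.default_rng(11))
    return PairData(x, n)


class TestSufficientStats:
    def test_identical_and_fully_different(self):
        aln = alignment_with_mismatches(0, 100)
        assert locus_sufficient_stats(aln) == (0, 100)
        aln = alignment_with_mismatches(100, 100)
        assert locus_sufficient_stats(aln) == (100, 100)

    def test_agrees_with_per_site_comparison(self):
        rng = np.random.default_rng(0)
        from mscrate.simulate import LocusAlignment

        codes = rng.integers(0, 4, size=(4, 321), dtype=np.int8)
        aln = LocusAlignment("r", ("Homo", "Pan", "Gorilla", "Pongo"), codes)
        x, n = locus_sufficient_stats(aln, ("Homo", "Pongo"))
        brute = sum(
            a != b for a, b in zip(aln.sequence("Homo"), aln.sequence("Pongo"))
        )
        assert (x, n) == (brute, 321)

    def test_pair_data_validation(self):
        with pytest.raises(ValueError):
            PairData(np.array([5]), np.array([4]))  # x > n
        with pytest.raises(ValueError):
            PairData(np.array([]), np.array([]))


class TestLogPosterior:
    def test_matches_termwise_textbook_oracle(self, small_data):
        spec = MSCModelSpec()
        tau, theta = 0.004, 0.003
        heights = tau + np.linspace(1e-4, 3e-3, small_data.n_loci)

        def oracle(tau_, theta_, h_):
            # exponential waiting times + binomial mismatch counts + priors,
            # assembled term by term from scipy distributions
            total = uniform.logpdf(tau_, 0, spec.tau_upper)
            total += GammaPrior(2.0, 200.0).logpdf(theta_)
            for hi, xi, ni in zip(h_, small_data.x, small_data.n):
                total += expon.logpdf(hi - tau_, scale=theta_ / 2.0)
                total += binom.logpmf(xi, ni, jc69_mismatch_probability(2 * hi))
            return float(total)

        # binomial coefficients are omitted in the implementation, so
        # compare differences between two states (constants cancel)
        ours = log_posterior(tau, theta, heights, small_data, spec)
        ours2 = log_posterior(0.0045, 0.002, heights + 5e-4, small_data, spec)
        ref = oracle(tau, theta, heights)
        ref2 = oracle(0.0045, 0.002, heights + 5e-4)
        assert np.isclose(ours - ours2, ref - ref2, atol=1e-8)

    def test_outside_support_is_minus_inf(self, small_data):
        spec = MSCModelSpec()
        h = np.full(small_data.n_loci, 0.005)
        assert log_posterior(-0.001, 0.003, h, small_data, spec) == -np.inf
        assert log_posterior(0.004, -0.1, h, small_data, spec) == -np.inf
        assert log_posterior(0.006, 0.003, h, small_data, spec) == -np.inf  # h < tau
        assert log_posterior(0.02, 0.003, h + 0.02, small_data, spec) == -np.inf

    def test_likelihood_monotone_decreasing_for_zero_mismatches(self):
        data = PairData(np.array([0]), np.array([500]))
        spec = MSCModelSpec()
        values = [
            log_posterior(1e-4, 0.003, np.array([h]), data, spec)
            for h in (0.001, 0.002, 0.004, 0.008)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestMCMC:
    def test_fixed_seed_is_bit_identical(self, small_data):
        a = run_mcmc(small_data, n_samples=50, thin=2, n_chains=2, seed=123)
        b = run_mcmc(small_data, n_samples=50, thin=2, n_chains=2, seed=123)
        for ca, cb in zip(a.chains, b.chains):
            assert np.array_equal(ca["tau"], cb["tau"])
            assert np.array_equal(ca["theta"], cb["theta"])

    def test_samples_respect_support(self, small_data):
        post = run_mcmc(small_data, n_samples=200, thin=2, seed=3)
        tau = post.pooled("tau")
        theta = post.pooled("theta")
        assert (tau > 0).all() and (theta > 0).all()
        s = post.summary
        assert (s["q2.5"] <= s["mean"]).all() and (s["mean"] <= s["q97.5"]).all()

    def test_prior_only_sampling_reproduces_priors(self):
        # likelihood switched off: marginals must match Gamma(2,200) for
        # theta and Uniform(0, tau_max) for tau
        data = PairData(np.array([0]), np.array([1]))
        spec = MSCModelSpec(tau_max=0.013)
        post = run_mcmc(
            data, spec, n_samples=1500, thin=20, n_chains=2, seed=9,
            sample_prior_only=True,
        )
        theta = post.pooled("theta")
        tau = post.pooled("tau")
        assert kstest(theta, "gamma", args=(2.0, 0.0, 1 / 200.0)).pvalue > 0.001
        assert kstest(tau, "uniform", args=(0.0, 0.013)).pvalue > 0.001

    def test_agrees_with_grid_integration(self, small_data):
        post = run_mcmc(small_data, n_samples=1500, thin=20, n_chains=2, seed=5)
        grid = grid_posterior(small_data)
        for name in ("tau", "theta"):
            mc_mean = post.summary.loc[name, "mean"]
            mc_sd = post.summary.loc[name, "sd"]
            ess = post.ess[name].sum()
            mcse = mc_sd / np.sqrt(ess)
            assert abs(mc_mean - grid.loc[name, "mean"]) < 2 * mcse + 1e-6
            assert np.isclose(mc_sd, grid.loc[name, "sd"], rtol=0.15)

    def test_posterior_mean_height_tracks_empirical_half_distance(self):
        rng = np.random.default_rng(21)
        x, n, _ = simulate_pair_counts(0.00473, 0.00304, 300, 1000, rng)
        data = PairData(x, n)
        post = run_mcmc(data, n_samples=500, thin=10, seed=6)
        pooled_p = x.sum() / n.sum()
        pooled_half = -0.375 * np.log(1 - 4 * pooled_p / 3)
        implied = (
            post.summary.loc["tau", "mean"] + post.summary.loc["theta", "mean"] / 2
        )
        se = post.summary.loc["mean_height", "sd"]
        assert abs(implied - pooled_half) < 3 * max(se, 1e-5)

    def test_invalid_settings_rejected(self, small_data):
        with pytest.raises(ValueError):
            run_mcmc(small_data, n_samples=1)
        with pytest.raises(ValueError):
            run_mcmc(small_data, thin=0)


def test_pair_data_from_loci_roundtrip():
    alns = [alignment_with_mismatches(k, 200) for k in (0, 5, 11)]
    data = pair_data_from_loci(alns)
    assert data.x.tolist() == [0, 5, 11]
    assert data.n.tolist() == [200, 200, 200]
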