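"""Tests for concordance, DIME values, thresholds, accuracy, and MC oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import dblquad, quad
from scipy.stats import multivariate_normal, norm

from dimix import (
    GaussianComponent,
    StructuredMixture,
    accuracy,
    concordance,
    dime_summary,
    dime_values,
    gaussian_concordance,
    make_scenario,
    mc_classification_rates,
    posterior_summary,
    thresholds,
)
from dimix.fit import PosteriorDraws

from conftest import random_mixture


def quadrature_concordance_1d(a, b):
    fa = norm(a.mean[0], np.sqrt(a.cov[0, 0])).pdf
    fb = norm(b.mean[0], np.sqrt(b.cov[0, 0])).pdf
    lo = min(a.mean[0], b.mean[0]) - 12 * max(np.sqrt(a.cov[0, 0]), np.sqrt(b.cov[0, 0]))
    hi = max(a.mean[0], b.mean[0]) + 12 * max(np.sqrt(a.cov[0, 0]), np.sqrt(b.cov[0, 0]))
    val, _ = quad(lambda x: fa(x) * fb(x), lo, hi, limit=200)
    return val


def quadrature_concordance_2d(a, b):
    fa = multivariate_normal(a.mean, a.cov).pdf
    fb = multivariate_normal(b.mean, b.cov).pdf
    r = 14.0
    c0 = 0.5 * (a.mean + b.mean)
    val, _ = dblquad(
        lambda y, x: fa([x, y]) * fb([x, y]),
        c0[0] - r, c0[0] + r,
        lambda x: c0[1] - r, lambda x: c0[1] + r,
        epsabs=1e-12, epsrel=1e-10,
    )
    return val


class TestGaussianConcordance:
    def test_standard_normal_self_concordance(self):
        c = GaussianComponent([0.0], [[1.0]], 1.0)
        assert gaussian_concordance(c, c) == pytest.approx(1 / (2 * np.sqrt(np.pi)), abs=1e-9)

    def test_separated_pair_matches_quadrature(self):
        a = GaussianComponent([0.0], [[5.0]], 1.0)
        b = GaussianComponent([5.0], [[5.0]], 1.0)
        assert gaussian_concordance(a, b) == pytest.approx(0.036145, abs=1e-6)
        assert gaussian_concordance(a, b) == pytest.approx(
            quadrature_concordance_1d(a, b), abs=1e-10
        )

    @given(st.integers(0, 10**6))
    @settings(max_examples=20, deadline=None)
    def test_matches_quadrature_on_random_1d_pairs(self, seed):
        rng = np.random.default_rng(seed)
        a = GaussianComponent([rng.normal(0, 3)], [[0.2 + rng.random() * 3]], 1.0)
        b = GaussianComponent([rng.normal(0, 3)], [[0.2 + rng.random() * 3]], 1.0)
        assert gaussian_concordance(a, b) == pytest.approx(
            quadrature_concordance_1d(a, b), abs=1e-8
        )
        assert gaussian_concordance(a, b) == pytest.approx(gaussian_concordance(b, a))

    def test_extreme_separation_stays_finite_in_log(self):
        from dimix.dime import log_gaussian_concordance

        a = GaussianComponent([0.0], [[1.0]], 1.0)
        b = GaussianComponent([200.0], [[1.0]], 1.0)
        lg = log_gaussian_concordance(a, b)
        assert np.isfinite(lg) and lg < -9000

    def test_dimension_mismatch_rejected(self):
        a = GaussianComponent([0.0], [[1.0]], 1.0)
        b = GaussianComponent([0.0, 0.0], np.eye(2), 1.0)
        with pytest.raises(ValueError):
            gaussian_concordance(a, b)


class TestMixtureConcordance:
    def test_single_gaussian_parts_reduce_to_closed_form(self, benchmark_mixture):
        from dimix import marginalize

        m = marginalize(benchmark_mixture, [8])
        direct = gaussian_concordance(m.components[0], m.components[1])
        assert concordance(benchmark_mixture, 1, 2, [8]) == pytest.approx(direct, rel=1e-12)

    def test_independent_blocks_factorize(self):
        # block-diagonal covariances, block-wise mean differences:
        # delta over h1+h2 equals delta(h1) * delta(h2)
        mean_a = np.array([0.0, 0.0, 1.0])
        mean_b = np.array([2.0, 1.0, -1.0])
        cov = np.diag([1.0, 2.0, 1.5])
        mix = StructuredMixture(
            [GaussianComponent(mean_a, cov, 0.5), GaussianComponent(mean_b, cov, 0.5)]
        )
        full = concordance(mix, 1, 2, [1, 2, 3])
        split = concordance(mix, 1, 2, [1]) * concordance(mix, 1, 2, [2, 3])
        assert full == pytest.approx(split, rel=1e-10)

    def test_benchmark_component1_concordances_on_var8(self, benchmark_mixture):
        # on variable 8, f_1 = N(5,5) and the complement collapses to N(0,5)
        assert concordance(benchmark_mixture, 1, 1, [8]) == pytest.approx(0.126157, abs=1e-6)
        assert concordance(benchmark_mixture, 1, (2, 3, 4), [8]) == pytest.approx(
            0.036145, abs=1e-6
        )

    def test_no_complement_error(self):
        mix = random_mixture(3, p=1, n_components=2)
        with pytest.raises(ValueError, match="complement"):
            dime_values(mix, (1, 2))


class TestDimeValues:
    def test_identical_densities_give_unity(self):
        comps = [
            GaussianComponent([1.0], [[2.0]], 0.4),
            GaussianComponent([1.0], [[2.0]], 0.6),
        ]
        mix = StructuredMixture(comps)
        d_c, d_nc = dime_values(mix, 1)
        assert d_c == pytest.approx(1.0, rel=1e-10)
        assert d_nc == pytest.approx(1.0, rel=1e-10)

    def test_benchmark_closed_form_on_var8(self, benchmark_mixture):
        # equal-variance 1-D pair: Delta = exp(-d^2/(4 v)) = exp(-25/20)
        d_c, d_nc = dime_values(benchmark_mixture, 1, [8])
        assert d_c == pytest.approx(np.exp(-1.25), rel=1e-9)
        assert d_nc == pytest.approx(np.exp(-1.25), rel=1e-9)

    def test_decreasing_in_separation(self):
        prev = np.inf
        for d in np.linspace(0.5, 10, 12):
            mix = make_scenario("overlap-grid", separation=float(d)).to_mixture()
            d_c, _ = dime_values(mix, 1)
            assert d_c < prev
            prev = d_c

    def test_overlap_grid_closed_form(self):
        for d, v in [(1.0, 1.0), (3.0, 2.0), (5.0, 0.5)]:
            mix = make_scenario("overlap-grid", separation=d, variance=v).to_mixture()
            d_c, _ = dime_values(mix, 1)
            assert d_c == pytest.approx(np.exp(-(d**2) / (4 * v)), rel=1e-9)

    @given(st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None)
    def test_product_bounded_by_one(self, seed):
        mix = random_mixture(seed, p=2, n_components=4)
        d_c, d_nc = dime_values(mix, 1)
        assert d_c * d_nc <= 1.0 + 1e-10

    @given(st.integers(0, 10**6))
    @settings(max_examples=15, deadline=None)
    def test_affine_invariance(self, seed):
        # invertible affine transform of the variables leaves all DIME
        # quantities unchanged, so standardization cannot alter conclusions
        mix = random_mixture(seed, p=2, n_components=3)
        rng = np.random.default_rng(seed + 1)
        a = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        while abs(np.linalg.det(a)) < 0.1:
            a = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        b = rng.normal(size=2)
        mapped = StructuredMixture(
            [
                GaussianComponent(a @ c.mean + b, a @ c.cov @ a.T, c.weight)
                for c in mix.components
            ],
            mix.partition,
        )
        s0 = dime_summary(mix, 1)
        s1 = dime_summary(mapped, 1)
        for f in ("delta_c", "delta_neg_c", "tau_plus", "tau_minus", "accuracy"):
            assert getattr(s0, f) == pytest.approx(getattr(s1, f), abs=1e-8)

    def test_irrelevant_variable_changes_nothing(self):
        spec2 = make_scenario("irrelevant-variable", separation=2.5, alpha=0.4)
        mix2 = spec2.to_mixture()
        d_with, _ = dime_values(mix2, 1, [1, 2])
        d_without, _ = dime_values(mix2, 1, [1])
        assert d_with == pytest.approx(d_without, rel=1e-12)


class TestThresholdsAndAccuracy:
    def test_symmetric_no_information_case(self):
        tp, tm = thresholds(0.5, 1.0, 1.0)
        assert tp == pytest.approx(0.5)
        assert tm == pytest.approx(0.5)

    def test_alpha_validated(self):
        with pytest.raises(ValueError):
            thresholds(1.2, 0.1, 0.1)
        with pytest.raises(ValueError):
            accuracy(0.0, 0.5, 0.5)

    def test_monotonicity_in_dime(self):
        taus = [thresholds(0.3, d, 0.1)[0] for d in (0.01, 0.1, 1.0)]
        assert taus[0] > taus[1] > taus[2]
        tms = [thresholds(0.3, 0.1, d)[1] for d in (0.01, 0.1, 1.0)]
        assert tms[0] < tms[1] < tms[2]

    def test_perfect_discrimination_accuracy(self):
        assert accuracy(0.3, 1.0, 0.0) == 1.0

    def test_no_information_accuracy(self):
        for a in (0.2, 0.5, 0.7):
            tp, tm = thresholds(a, 1.0, 1.0)
            assert accuracy(a, tp, tm) == pytest.approx(a**2 + (1 - a) ** 2)

    def test_substitution_chain(self):
        # alpha=0.3, Delta_c=0.013, Delta_-c=0.022 pushed through the
        # threshold and accuracy formulas
        tp, tm = thresholds(0.3, 0.013, 0.022)
        assert accuracy(0.3, tp, tm) == pytest.approx(0.98462, abs=5e-5)

    def test_tau_sign_property(self):
        # E[V|f_c] > 0 iff tau < tau_c+ ; E[V|f_-c] < 0 iff tau > tau_c-
        mix = make_scenario("overlap-grid", separation=2.0, alpha=0.35).to_mixture()
        a = 0.35
        dcc = concordance(mix, 1, 1)
        dcn = concordance(mix, 1, 2)
        dnn = concordance(mix, 2, 2)
        tp, tm = thresholds(a, dcn / dcc, dcn / dnn)
        for eps in (-1e-4, 1e-4):
            e_pos = a * (1 - (tp + eps)) * dcc - (1 - a) * (tp + eps) * dcn
            assert (e_pos > 0) == (eps < 0)
            e_neg = a * (1 - (tm + eps)) * dcn - (1 - a) * (tm + eps) * dnn
            assert (e_neg < 0) == (eps > 0)


class TestMonteCarloRates:
    def test_identical_components_recover_alpha(self):
        comps = [
            GaussianComponent([0.0], [[1.0]], 0.3),
            GaussianComponent([0.0], [[1.0]], 0.7),
        ]
        mix = StructuredMixture(comps)
        r = mc_classification_rates(mix, 1, n=20_000, seed=1)
        assert r.alpha_plus_hat == pytest.approx(0.3, abs=3 * r.se_plus + 1e-9)
        assert r.alpha_minus_hat == pytest.approx(0.3, abs=3 * r.se_minus + 1e-9)

    def test_well_separated_pair_is_nearly_perfect(self):
        mix = make_scenario("overlap-grid", separation=20.0).to_mixture()
        r = mc_classification_rates(mix, 1, n=10_000, seed=2)
        assert r.alpha_plus_hat >= 0.999
        assert r.alpha_minus_hat <= 0.001

    def test_reproducible_by_seed(self, benchmark_mixture):
        r1 = mc_classification_rates(benchmark_mixture, 1, h=[8], n=5000, seed=9)
        r2 = mc_classification_rates(benchmark_mixture, 1, h=[8], n=5000, seed=9)
        assert r1 == r2

    def test_minimum_sample_size_enforced(self, benchmark_mixture):
        with pytest.raises(ValueError, match="1000"):
            mc_classification_rates(benchmark_mixture, 1, n=10, seed=0)


class TestPosteriorSummary:
    def test_single_draw_equals_plugin_summary(self, benchmark_mixture):
        draws = PosteriorDraws(draws=[benchmark_mixture], aligned=True)
        ps = posterior_summary(draws, 1, [8])
        direct = dime_summary(benchmark_mixture, 1, [8])
        assert ps.mean.accuracy == pytest.approx(direct.accuracy, rel=1e-12)
        assert ps.mean.delta_c == pytest.approx(direct.delta_c, rel=1e-12)

    def test_duplicated_draws_have_zero_width_intervals(self, benchmark_mixture):
        draws = PosteriorDraws(draws=[benchmark_mixture] * 5, aligned=True)
        ps = posterior_summary(draws, 1, [8])
        assert ps.lower.accuracy == pytest.approx(ps.upper.accuracy, abs=1e-14)

    def test_tight_posterior_brackets_truth(self, benchmark_mixture):
        # jitter the benchmark parameters slightly to mimic a tight posterior
        rng = np.random.default_rng(4)
        draws = []
        for _ in range(40):
            comps = [
                GaussianComponent(
                    c.mean + rng.normal(0, 0.02, size=8), c.cov, c.weight
                )
                for c in benchmark_mixture.components
            ]
            draws.append(StructuredMixture(comps))
        ps = posterior_summary(PosteriorDraws(draws=draws, aligned=True), 1, [8])
        truth = dime_summary(benchmark_mixture, 1, [8])
        assert ps.lower.accuracy <= truth.accuracy <= ps.upper.accuracy

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            posterior_summary(PosteriorDraws(draws=[]), 1)
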