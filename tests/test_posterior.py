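"""The closed-form posterior against an independent brute-force Bayes oracle."""

import numpy as np
import pytest
from scipy import stats

from baynorm import (
    CaptureEfficiencies,
    CountMatrix,
    GenePriors,
    RunConfig,
    lost_count_params,
    marginal_pmf,
    normalize,
    posterior_map,
    posterior_mean,
    posterior_pmf,
    posterior_sample,
    posterior_var,
    scale_non_umi,
)


def brute_force_posterior(n_max, x, mu, phi, beta):
    """Independent oracle: binomial likelihood x NB prior, normalized over a
    truncated support.  Never uses the shifted-NB closed form."""
    n = np.arange(n_max)
    prior = stats.nbinom.pmf(n, phi, phi / (phi + mu))
    likelihood = stats.binom.pmf(x, n, beta)
    post = prior * likelihood
    return post / post.sum()


class TestLostCountParams:
    def test_worked_values(self):
        pp = lost_count_params(1, 10.0, 2.0, 0.1)
        assert pp.zeta_mean == pytest.approx(9.0)
        assert pp.zeta_size == pytest.approx(3.0)
        pp0 = lost_count_params(0, 10.0, 2.0, 0.5)
        assert pp0.zeta_mean == pytest.approx(10.0 / 7.0)
        assert pp0.zeta_size == pytest.approx(2.0)

    def test_full_capture_loses_nothing(self):
        for x in (0, 3, 100):
            assert lost_count_params(x, 5.0, 1.0, 1.0).zeta_mean == 0.0

    def test_size_is_x_plus_phi(self):
        assert lost_count_params(7, 3.0, 1.5, 0.4).zeta_size == 8.5

    def test_domain_errors(self):
        for bad in [(-1, 1, 1, 0.5), (1, 0, 1, 0.5), (1, 1, 0, 0.5), (1, 1, 1, 0.0), (1, 1, 1, 1.1)]:
            with pytest.raises(ValueError):
                lost_count_params(*bad)


class TestMoments:
    def test_worked_mean_and_variance(self):
        assert posterior_mean(1, 10.0, 2.0, 0.1) == pytest.approx(10.0)
        assert posterior_var(1, 10.0, 2.0, 0.1) == pytest.approx(36.0)
        assert posterior_mean(0, 10.0, 2.0, 0.1) == pytest.approx(6.0)
        assert posterior_var(0, 10.0, 2.0, 0.1) == pytest.approx(24.0)

    def test_full_capture_degenerate(self):
        assert posterior_mean(5, 10.0, 2.0, 1.0) == 5.0
        assert posterior_var(5, 10.0, 2.0, 1.0) == 0.0

    def test_mean_equals_x_plus_zeta_mean(self, param_grid):
        for x, mu, phi, beta in param_grid:
            pp = lost_count_params(x, mu, phi, beta)
            assert posterior_mean(x, mu, phi, beta) == pytest.approx(x + pp.zeta_mean, rel=1e-12)

    def test_mean_nonincreasing_in_beta(self, param_grid):
        betas = np.linspace(0.01, 1.0, 50)
        for x, mu, phi, _ in param_grid:
            means = posterior_mean(np.full_like(betas, x), mu, phi, betas)
            assert np.all(np.diff(means) <= 1e-12)

    def test_mean_at_least_observed(self, param_grid):
        for x, mu, phi, beta in param_grid:
            assert posterior_mean(x, mu, phi, beta) >= x


class TestPosteriorPmf:
    def test_zero_below_observed_count(self):
        assert posterior_pmf(2, 5, 10.0, 2.0, 0.3) == 0.0

    def test_full_capture_point_mass(self):
        assert posterior_pmf(4, 4, 10.0, 2.0, 1.0) == pytest.approx(1.0)
        assert posterior_pmf(5, 4, 10.0, 2.0, 1.0) == 0.0

    def test_matches_brute_force_oracle_on_grid(self, param_grid):
        n = np.arange(501)
        worst = 0.0
        for x, mu, phi, beta in param_grid:
            oracle = brute_force_posterior(3000, x, mu, phi, beta)[:501]
            mine = posterior_pmf(n, x, mu, phi, beta)
            worst = max(worst, float(np.abs(oracle - mine).max()))
        assert worst < 1e-10

    def test_normalizes_to_one(self, param_grid):
        for x, mu, phi, beta in param_grid:
            n = np.arange(x, x + 5000)
            total = posterior_pmf(n, x, mu, phi, beta).sum()
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_numerical_moments_match_closed_forms(self, param_grid):
        for x, mu, phi, beta in param_grid:
            n = np.arange(x, x + 20000)
            p = posterior_pmf(n, x, mu, phi, beta)
            m1 = (n * p).sum()
            m2 = ((n - m1) ** 2 * p).sum()
            assert m1 == pytest.approx(posterior_mean(x, mu, phi, beta), rel=1e-8)
            if beta < 1.0:
                assert m2 == pytest.approx(posterior_var(x, mu, phi, beta), rel=1e-8)


class TestMarginalPmf:
    def test_worked_values(self):
        assert marginal_pmf(0, 10.0, 2.0, 0.1) == pytest.approx(4.0 / 9.0)
        assert marginal_pmf(1, 10.0, 2.0, 0.1) == pytest.approx(8.0 / 27.0)

    def test_full_capture_equals_prior(self):
        for x in range(10):
            prior = stats.nbinom.pmf(x, 2.0, 2.0 / 12.0)
            assert marginal_pmf(x, 10.0, 2.0, 1.0) == pytest.approx(prior, rel=1e-12)

    def test_normalizes_to_one(self, param_grid):
        x = np.arange(5000)
        for _, mu, phi, beta in param_grid:
            assert marginal_pmf(x, mu, phi, beta).sum() == pytest.approx(1.0, abs=1e-8)

    def test_thinned_sample_mean_matches_marginal_mean(self):
        rng = np.random.default_rng(2024)
        mu, phi, beta = 10.0, 2.0, 0.1
        x0 = rng.negative_binomial(phi, phi / (phi + mu), size=50_000)
        x = rng.binomial(x0, beta)
        se = np.sqrt((mu * beta + (mu * beta) ** 2 / phi) / x.size)
        assert abs(x.mean() - mu * beta) < 4 * se


class TestPosteriorMap:
    def test_worked_modes(self):
        assert posterior_map(2, 10.0, 2.0, 0.3) == 6
        assert posterior_map(0, 10.0, 2.0, 0.5) == 0
        assert posterior_map(7, 10.0, 2.0, 1.0) == 7

    def test_matches_argmax_of_pmf_with_low_tie_break(self, param_grid):
        for x, mu, phi, beta in param_grid:
            n = np.arange(x, x + 3000)
            p = posterior_pmf(n, x, mu, phi, beta)
            # ties at exact integer ratio crossings break to the smaller count
            top = n[p >= p.max() * (1.0 - 1e-9)].min()
            assert posterior_map(x, mu, phi, beta) == top

    def test_at_least_observed(self, param_grid):
        for x, mu, phi, beta in param_grid:
            assert posterior_map(x, mu, phi, beta) >= x


class TestPosteriorSample:
    def test_full_capture_returns_x(self, rng):
        draws = posterior_sample(4, 10.0, 2.0, 1.0, size=100, rng=rng)
        assert np.all(draws == 4)

    def test_moments_match_closed_forms(self):
        rng = np.random.default_rng(99)
        draws = posterior_sample(1, 10.0, 2.0, 0.1, size=100_000, rng=rng)
        se = np.sqrt(36.0 / draws.size)
        assert abs(draws.mean() - 10.0) < 3 * se
        assert draws.var(ddof=1) == pytest.approx(36.0, rel=0.05)

    def test_support_at_least_observed(self, rng):
        draws = posterior_sample(3, 5.0, 1.0, 0.2, size=10_000, rng=rng)
        assert draws.min() >= 3

    def test_total_variation_against_pmf(self):
        rng = np.random.default_rng(7)
        x, mu, phi, beta = 1, 10.0, 2.0, 0.1
        draws = posterior_sample(x, mu, phi, beta, size=100_000, rng=rng)
        kmax = int(draws.max())
        emp = np.bincount(draws, minlength=kmax + 1) / draws.size
        theo = posterior_pmf(np.arange(kmax + 1), x, mu, phi, beta)
        tv = 0.5 * np.abs(emp - theo).sum() + 0.5 * (1.0 - theo[: kmax + 1].sum())
        assert tv < 0.01

    def test_reproducible_under_seed(self):
        a = posterior_sample(1, 10.0, 2.0, 0.1, size=50, rng=np.random.default_rng(5))
        b = posterior_sample(1, 10.0, 2.0, 0.1, size=50, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


def _setup_matrix(values, beta, mu, phi):
    values = np.asarray(values)
    p, q = values.shape
    cm = CountMatrix(values, [f"g{i}" for i in range(p)], [f"c{j}" for j in range(q)])
    ce = CaptureEfficiencies(np.asarray(beta, dtype=float), float(np.mean(beta)))
    priors = GenePriors(mu=np.asarray(mu, dtype=float), phi=np.asarray(phi, dtype=float))
    return cm, ce, priors


class TestNormalize:
    def test_full_capture_map_is_identity(self, rng):
        values = rng.integers(0, 50, size=(6, 5))
        cm, _, priors = _setup_matrix(values, [0.5] * 5, [5.0] * 6, [2.0] * 6)
        ce = CaptureEfficiencies(np.ones(5), 0.5)  # exact full capture
        rc = normalize(cm, ce, priors, RunConfig(beta_bar=0.5, mode="map"))
        np.testing.assert_array_equal(rc.values, values)

    def test_mean_mode_zero_matrix_closed_form(self):
        mu, phi, beta = 10.0, 2.0, 0.1
        cm, ce, priors = _setup_matrix(np.zeros((3, 4), dtype=int), [beta] * 4, [mu] * 3, [phi] * 3)
        rc = normalize(cm, ce, priors, RunConfig(beta_bar=beta, mode="mean"))
        expected = mu * phi * (1 - beta) / (mu * beta + phi)
        np.testing.assert_allclose(rc.values, expected)

    def test_small_phi_limit_tends_to_x_over_beta(self, rng):
        values = rng.integers(1, 30, size=(4, 6))
        beta = rng.uniform(0.05, 0.5, 6)
        cm, ce, priors = _setup_matrix(values, beta, [10.0] * 4, [1e-3] * 4)
        rc = normalize(cm, ce, priors, RunConfig(beta_bar=0.2, mode="mean"))
        np.testing.assert_allclose(rc.values, values / beta[np.newaxis, :], rtol=5e-3)

    def test_flagged_genes_pass_through_as_zeros(self):
        values = np.array([[0, 0, 0], [3, 1, 2]])
        cm, ce, priors = _setup_matrix(values, [0.1] * 3, [1.0, 5.0], [1.0, 2.0])
        priors.mu[0] = 0.0
        priors.flagged[0] = True
        for mode in ("mean", "map", "samples"):
            rc = normalize(cm, ce, priors, RunConfig(beta_bar=0.1, mode=mode, n_samples=2))
            out0 = rc.values[0] if mode != "samples" else rc.values[0, :, 0]
            np.testing.assert_array_equal(out0, 0)

    def test_local_priors_applied_per_group(self):
        values = np.array([[2, 2, 2, 2]])
        cm = CountMatrix(values, ["g0"], [f"c{j}" for j in range(4)], groups=["A", "A", "B", "B"])
        ce = CaptureEfficiencies(np.full(4, 0.1), 0.1)
        from baynorm import GroupedPriors

        gp = GroupedPriors(by_group={
            "A": GenePriors(mu=np.array([5.0]), phi=np.array([2.0]), scope="local", group="A"),
            "B": GenePriors(mu=np.array([20.0]), phi=np.array([2.0]), scope="local", group="B"),
        })
        rc = normalize(cm, ce, gp, RunConfig(beta_bar=0.1, mode="mean"))
        want_a = posterior_mean(2, 5.0, 2.0, 0.1)
        want_b = posterior_mean(2, 20.0, 2.0, 0.1)
        np.testing.assert_allclose(rc.values[0], [want_a, want_a, want_b, want_b])

    def test_samples_first_slices_stable_as_s_grows(self, rng):
        values = rng.integers(0, 20, size=(5, 4))
        cm, ce, priors = _setup_matrix(values, [0.2] * 4, [8.0] * 5, [2.0] * 5)
        rc3 = normalize(cm, ce, priors, RunConfig(beta_bar=0.2, mode="samples", n_samples=3, seed=9))
        rc8 = normalize(cm, ce, priors, RunConfig(beta_bar=0.2, mode="samples", n_samples=8, seed=9))
        np.testing.assert_array_equal(rc3.values, rc8.values[:, :, :3])

    def test_samples_dominate_observed(self, rng):
        values = rng.integers(0, 20, size=(5, 4))
        cm, ce, priors = _setup_matrix(values, [0.2] * 4, [8.0] * 5, [2.0] * 5)
        rc = normalize(cm, ce, priors, RunConfig(beta_bar=0.2, mode="samples", n_samples=4, seed=1))
        assert np.all(rc.values >= values[:, :, np.newaxis])


class TestScaleNonUmi:
    def test_identity_at_one(self, small_cm):
        np.testing.assert_array_equal(scale_non_umi(small_cm, 1.0).dense(), small_cm.dense())

    @pytest.mark.parametrize("x,amp,want", [(10, 5, 2), (7, 2, 4), (1, 2, 1), (0, 3, 0)])
    def test_round_half_up(self, x, amp, want):
        cm = CountMatrix([[x]], ["g0"], ["c0"])
        assert scale_non_umi(cm, amp).dense()[0, 0] == want

    def test_rejects_amplification_below_one(self, small_cm):
        with pytest.raises(ValueError):
            scale_non_umi(small_cm, 0.5)
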