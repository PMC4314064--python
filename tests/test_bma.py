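import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import gammaln

from blubbercort.bma import (
    BMAConfig,
    build_design,
    enumerate_models_oracle,
    run_bma,
    summarize_coefficients,
)
from blubbercort.data_model import CovariateMatrix, normalize_covariates

from conftest import make_record


def matrix_from_values(values):
    """Standardize a raw matrix into a CovariateMatrix for direct model input."""
    values = np.asarray(values, dtype=float)
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    return CovariateMatrix(
        values=(values - means) / sds,
        factor_names=tuple(f"f{j}" for j in range(values.shape[1])),
        column_means=means,
        column_sds=sds,
        n_dropped=0,
        kept_indices=np.arange(values.shape[0]),
    )


def toy_dataset(n=40, p=3, effect=None, seed=0):
    rng = np.random.default_rng(seed)
    X = matrix_from_values(rng.normal(size=(n, p)))
    beta = np.zeros(p)
    if effect:
        for j, b in effect.items():
            beta[j] = b
    y = 1.0 + X.values @ beta + rng.normal(0.0, 0.6, size=n)
    return y, X


def chain_se(posterior, j):
    """Monte-Carlo SE of an inclusion probability from the chain spread."""
    means = posterior.chain_gamma_means[:, j]
    m = len(means)
    return float(means.std(ddof=1) / math.sqrt(m))


# ---------------------------------------------------------------------------
# Independent brute-force oracle: direct numerical integration over sigma^2
# using dense-covariance Gaussian densities (different code path from the
# package's eigenvalue/Simpson enumeration).
# ---------------------------------------------------------------------------

def brute_force_inclusion(y, X, config):
    n, p = X.values.shape
    assert p <= 3

    def log_marginal(mask):
        cols = X.values[:, mask]
        Xt = np.hstack([np.ones((n, 1)), cols])
        D = np.diag(
            [config.intercept_prior_variance] + [config.slope_prior_variance] * cols.shape[1]
        )
        K = Xt @ D @ Xt.T
        a0, b0 = config.sigma_prior_shape, config.sigma_prior_rate

        def log_f(s2):
            if s2 <= 1e-10:
                return -math.inf
            cov = s2 * np.eye(n) + K
            _, logdet = np.linalg.slogdet(cov)
            loglike = (
                -0.5 * n * math.log(2 * math.pi)
                - 0.5 * logdet
                - 0.5 * float(y @ np.linalg.solve(cov, y))
            )
            lp = a0 * math.log(b0) - gammaln(a0) - (a0 + 1) * math.log(s2) - b0 / s2
            return loglike + lp

        scan = np.exp(np.linspace(-15, 15, 400))
        ref = max(log_f(s) for s in scan)
        total = 0.0
        cuts = [0.0, 1e-4, 1e-2, 0.1, 1.0, 10.0, 100.0, 1e4, np.inf]
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            val, _ = quad(lambda s2: math.exp(log_f(s2) - ref), lo, hi, limit=300)
            total += val
        return ref + math.log(total)

    psel = config.selection_prior_p
    weights = {}
    for m in range(2**p):
        mask = np.array([(m >> j) & 1 for j in range(p)], dtype=bool)
        k = int(mask.sum())
        weights[m] = (
            k * math.log(psel) + (p - k) * math.log1p(-psel) + log_marginal(mask)
        )
    shift = max(weights.values())
    total = sum(math.exp(w - shift) for w in weights.values())
    probs = {}
    for j in range(p):
        num = sum(
            math.exp(w - shift) for m, w in weights.items() if (m >> j) & 1
        )
        probs[X.factor_names[j]] = num / total
    return probs


class TestBuildDesign:
    def test_full_mode_shape(self, default_cohort):
        y, X = build_design(default_cohort, "full")
        assert X.values.shape == (63, 8)
        assert y.shape == (63,)
        np.testing.assert_allclose(
            y, np.log([r.cortisol for r in default_cohort]), atol=1e-12
        )

    def test_bycatch_only_filters_and_drops_factors(self, default_cohort):
        y, X = build_design(default_cohort, "bycatch_only")
        assert X.values.shape == (40, 6)
        assert "fatality_type" not in X.factor_names
        assert "condition" not in X.factor_names

    def test_degenerate_cohort_errors(self):
        recs = [
            make_record(i, sex="male", maturity=("mature" if i % 2 else "immature"),
                        pregnancy=None, lactation="no", total_length=100.0 + i,
                        adrenal_mass=2.0 + 0.1 * i, cortisol=3.0 + 0.1 * i)
            for i in range(10)
        ]
        with pytest.raises(ValueError, match="zero variance"):
            build_design(recs, "bycatch_only")

    def test_bad_mode(self, default_cohort):
        with pytest.raises(ValueError, match="mode"):
            build_design(default_cohort, "both")


class TestConfig:
    def test_burn_in_validation(self):
        with pytest.raises(ValueError):
            BMAConfig(n_iterations=100, burn_in=100)

    def test_selection_prior_validation(self):
        with pytest.raises(ValueError):
            BMAConfig(selection_prior_p=0.0)
        BMAConfig(selection_prior_p=1.0)  # degenerate but allowed

    def test_large_slab_variance_warns(self):
        with pytest.warns(UserWarning, match="1000"):
            BMAConfig(slope_prior_variance=5000.0)


class TestOracle:
    def test_matches_brute_force_quadrature(self):
        y, X = toy_dataset(n=15, p=2, effect={0: 0.8}, seed=4)
        config = BMAConfig()
        exact = enumerate_models_oracle(y, X, config)
        brute = brute_force_inclusion(y, X, config)
        for name in X.factor_names:
            assert exact[name] == pytest.approx(brute[name], abs=1e-6)

    def test_uninformative_factor_penalized_below_half(self):
        # vague slab + no signal: the marginal-likelihood penalty keeps the
        # factor out more often than the 0.5 prior (Lindley direction)
        rng = np.random.default_rng(9)
        X = matrix_from_values(rng.normal(size=(30, 1)))
        y = rng.normal(size=30)
        probs = enumerate_models_oracle(y, X, BMAConfig())
        assert probs["f0"] < 0.5

    def test_label_permutation_equivariance(self):
        y, X = toy_dataset(n=25, p=3, effect={1: 0.7}, seed=7)
        probs = enumerate_models_oracle(y, X, BMAConfig())
        perm = [2, 0, 1]
        Xp = CovariateMatrix(
            values=X.values[:, perm],
            factor_names=tuple(X.factor_names[j] for j in perm),
            column_means=X.column_means[perm],
            column_sds=X.column_sds[perm],
            n_dropped=0,
            kept_indices=X.kept_indices,
        )
        probs_p = enumerate_models_oracle(y, Xp, BMAConfig())
        for name in X.factor_names:
            assert probs_p[name] == pytest.approx(probs[name], rel=1e-9)

    def test_p_too_large(self):
        y, X = toy_dataset(n=20, p=2)
        X13 = matrix_from_values(np.random.default_rng(0).normal(size=(20, 13)))
        with pytest.raises(ValueError, match="enumerate"):
            enumerate_models_oracle(np.zeros(20), X13, BMAConfig())


class TestRunBma:
    CFG = dict(n_iterations=8000, burn_in=2000, n_chains=4)

    def test_agrees_with_oracle_on_noise(self):
        y, X = toy_dataset(n=60, p=3, effect=None, seed=11)
        config = BMAConfig(seed=5, **self.CFG)
        posterior = run_bma(y, X, config)
        exact = enumerate_models_oracle(y, X, config)
        for j, name in enumerate(X.factor_names):
            tol = 3.0 * chain_se(posterior, j) + 0.004
            assert posterior.inclusion_probability[j] == pytest.approx(exact[name], abs=tol)

    def test_agrees_with_oracle_with_signal(self):
        y, X = toy_dataset(n=60, p=3, effect={0: 0.9, 2: 0.3}, seed=13)
        config = BMAConfig(seed=6, **self.CFG)
        posterior = run_bma(y, X, config)
        exact = enumerate_models_oracle(y, X, config)
        for j, name in enumerate(X.factor_names):
            tol = 3.0 * chain_se(posterior, j) + 0.004
            assert posterior.inclusion_probability[j] == pytest.approx(exact[name], abs=tol)

    def test_parameter_recovery_single_strong_factor(self):
        rng = np.random.default_rng(21)
        X = matrix_from_values(rng.normal(size=(63, 1)))
        y = 2.0 + 0.9 * X.values[:, 0] + rng.normal(0.0, 0.5, size=63)
        posterior = run_bma(y, X, BMAConfig(seed=2, **self.CFG))
        assert posterior.inclusion_probability[0] > 0.95
        lo, _, hi = posterior.coefficient_quantiles["f0"]
        assert lo < 0.9 < hi

    def test_reduces_to_bayesian_regression_when_prior_p_one(self):
        y, X = toy_dataset(n=40, p=2, effect={0: 0.6}, seed=17)
        config = BMAConfig(seed=3, selection_prior_p=1.0, **self.CFG)
        posterior = run_bma(y, X, config)
        assert np.all(posterior.inclusion_probability == 1.0)
        expected = conjugate_posterior_means(y, X, config)
        draws = posterior.beta_draws
        for j in range(2):
            se = 3.0 * draws[:, j].std(ddof=1) / math.sqrt(500)  # conservative ESS
            assert draws[:, j].mean() == pytest.approx(expected[j + 1], abs=se + 0.01)

    def test_two_seeds_agree(self):
        y, X = toy_dataset(n=50, p=3, effect={1: 0.8}, seed=23)
        p1 = run_bma(y, X, BMAConfig(seed=101, **self.CFG))
        p2 = run_bma(y, X, BMAConfig(seed=202, **self.CFG))
        for j in range(3):
            tol = 3.0 * (chain_se(p1, j) + chain_se(p2, j)) + 0.005
            assert p1.inclusion_probability[j] == pytest.approx(
                p2.inclusion_probability[j], abs=tol
            )

    def test_draw_count_and_rhat(self):
        y, X = toy_dataset(n=30, p=2, seed=1)
        config = BMAConfig(n_iterations=2000, burn_in=500, n_chains=3, seed=0)
        posterior = run_bma(y, X, config)
        assert posterior.n_draws == 1500 * 3
        assert set(posterior.rhat) >= {"intercept", "log_sigma2"}
        assert all(
            not math.isfinite(v) or v < 1.2 for v in posterior.rhat.values()
        )

    def test_n_less_than_p_rejected(self):
        X = matrix_from_values(np.random.default_rng(0).normal(size=(4, 5)))
        with pytest.raises(ValueError, match="n > p"):
            run_bma(np.zeros(4), X, BMAConfig(n_iterations=100, burn_in=10))

    def test_active_and_null_recovery_over_replicates(self):
        # one active factor (standardized effect 0.9) + six nulls, n = 63:
        # the active factor should be supported and every null unsupported
        # in nearly all replicate fits
        active_ok = 0
        nulls_ok = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            X = matrix_from_values(rng.normal(size=(63, 7)))
            y = 1.5 + 0.9 * X.values[:, 0] + rng.normal(0.0, 1.0, size=63)
            post = run_bma(
                y, X, BMAConfig(n_iterations=3000, burn_in=1000, n_chains=2, seed=rep)
            )
            if post.inclusion_probability[0] > 0.95:
                active_ok += 1
            if np.all(post.inclusion_probability[1:] < 0.5):
                nulls_ok += 1
        assert active_ok >= 18
        assert nulls_ok >= 18


def conjugate_posterior_means(y, X, config):
    """Posterior mean of (intercept, betas) for the always-included model,
    integrating sigma^2 on a dense grid — independent of the Gibbs code."""
    n, p = X.values.shape
    Xt = np.hstack([np.ones((n, 1)), X.values])
    prior_prec = np.diag(
        [1.0 / config.intercept_prior_variance] + [1.0 / config.slope_prior_variance] * p
    )
    a0, b0 = config.sigma_prior_shape, config.sigma_prior_rate
    D = np.diag(
        [config.intercept_prior_variance] + [config.slope_prior_variance] * p
    )
    K = Xt @ D @ Xt.T
    us = np.linspace(-8, 8, 2000)
    log_post = np.empty_like(us)
    means = np.zeros((us.size, p + 1))
    for i, u in enumerate(us):
        s2 = math.exp(u)
        cov = s2 * np.eye(n) + K
        sign, logdet = np.linalg.slogdet(cov)
        sol = np.linalg.solve(cov, y)
        log_post[i] = (
            -0.5 * logdet - 0.5 * y @ sol - a0 * u - b0 / s2
        )
        A = Xt.T @ Xt / s2 + prior_prec
        means[i] = np.linalg.solve(A, Xt.T @ y / s2)
    w = np.exp(log_post - log_post.max())
    w /= w.sum()
    return w @ means


class TestSummarizeCoefficients:
    def _posterior(self, gamma, beta, names=("a", "b")):
        from blubbercort.bma import BMAPosterior

        gamma = np.asarray(gamma)
        beta = np.asarray(beta)
        quantiles = {}
        for j, name in enumerate(names):
            sel = gamma[:, j] == 1
            if sel.any():
                q = np.percentile(beta[sel, j], [2.5, 50, 97.5])
                quantiles[name] = tuple(q)
            else:
                quantiles[name] = None
        return BMAPosterior(
            factor_names=tuple(names),
            inclusion_probability=gamma.mean(axis=0),
            coefficient_quantiles=quantiles,
            intercept_summary=(0, 0, 0),
            sigma_summary=(1, 1, 1),
            rhat={},
            n_draws=gamma.shape[0],
            gamma_draws=gamma,
            beta_draws=beta,
        )

    def test_constant_selected_coefficient(self):
        post = self._posterior(np.ones((100, 2)), np.full((100, 2), 0.7))
        table = summarize_coefficients(post)
        assert (table["median"] == 0.7).all()
        assert (table["2.50%"] == 0.7).all()

    def test_symmetric_draws_have_zero_median(self, rng):
        b = rng.normal(0.0, 1.0, size=(20001, 1))
        b = np.concatenate([b, -b])  # exactly symmetric
        post = self._posterior(np.ones_like(b), b, names=("x",))
        table = summarize_coefficients(post)
        assert table.loc[0, "median"] == pytest.approx(0.0, abs=1e-9)

    def test_never_selected_factor_noted(self):
        gamma = np.column_stack([np.ones(50), np.zeros(50)])
        beta = np.random.default_rng(0).normal(size=(50, 2))
        table = summarize_coefficients(self._posterior(gamma, beta))
        row = table[table["factor"] == "b"].iloc[0]
        assert math.isnan(row["median"])
        assert "never" in row["note"]

    def test_sorted_by_selection(self):
        gamma = np.column_stack([np.ones(50), (np.arange(50) % 2)])
        beta = np.random.default_rng(0).normal(size=(50, 2))
        table = summarize_coefficients(self._posterior(gamma, beta))
        assert list(table["factor"]) == ["a", "b"]
        assert table["%selected"].is_monotonic_decreasing


class TestFullCohortFit:
    def test_fatality_dominates_synthetic_cohort(self, default_cohort):
        y, X = build_design(default_cohort, "full")
        config = BMAConfig(n_iterations=6000, burn_in=1000, n_chains=2, seed=42)
        posterior = run_bma(y, X, config)
        by_name = dict(zip(posterior.factor_names, posterior.inclusion_probability))
        assert by_name["fatality_type"] > 0.999
        assert all(v < 0.05 for k, v in by_name.items() if k != "fatality_type")
        assert posterior.supported_factors() == ["fatality_type"]
        table = summarize_coefficients(posterior)
        assert table.loc[0, "factor"] == "fatality_type"
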