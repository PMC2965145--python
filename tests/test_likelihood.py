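import math

import numpy as np
import pytest
from scipy import stats

from fragfit.candidate_models import enumerate_candidates
from fragfit.likelihood import (
    FitData,
    OptimizerConfig,
    fit_model,
    mean_function,
    model_nll,
    nll_negbin,
    nll_poisson,
)

LANDSCAPES = ("L50", "L30", "L10")


def make_data(y, x=None, lids=None, offset=1.0):
    y = np.asarray(y, dtype=float)
    x = np.zeros_like(y) if x is None else np.asarray(x, dtype=float)
    lids = tuple(lids) if lids is not None else ("L50",) * len(y)
    return FitData(
        site_ids=tuple(f"s{i}" for i in range(len(y))),
        y=y, log10_area=x, landscape_ids=lids, offset=offset,
    )


def models(response):
    return {m.model_id: m for m in enumerate_candidates(LANDSCAPES, response)}


class TestMeanFunction:
    def test_constant_inverts_log_link(self):
        assert mean_function("constant", [math.log(5)], 0.0) == pytest.approx(5.0)

    def test_linear_log_link(self):
        assert mean_function("linear", [0.0, 1.0], 2.0) == pytest.approx(
            7.389056, abs=1e-6
        )

    def test_offset_is_multiplicative(self):
        for form, coefs in (("constant", [1.3]), ("linear", [0.2, 0.7])):
            one = mean_function(form, coefs, 1.5, offset=1)
            two = mean_function(form, coefs, 1.5, offset=2)
            assert two == pytest.approx(2 * one)

    def test_identity_link_floors_at_epsilon(self):
        assert mean_function("linear", [1.0, 2.0], 0.5,
                             link="identity") == pytest.approx(2.0)
        assert mean_function("linear", [-5.0, 0.0], 1.0, link="identity") > 0


class TestLikelihoodKernels:
    def test_poisson_hand_values(self):
        assert nll_poisson([0], [1.0]) == pytest.approx(1.0)
        assert nll_poisson([2], [2.0]) == pytest.approx(2 - 2 * math.log(2) + math.log(2))
        assert nll_poisson([], []) == 0.0

    def test_poisson_matches_scipy_pmf(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(4.0, size=20)
        mu = rng.uniform(0.5, 8.0, size=20)
        expected = -stats.poisson.logpmf(y, mu).sum()
        assert nll_poisson(y, mu) == pytest.approx(expected, rel=1e-12)

    def test_negbin_hand_values(self):
        assert nll_negbin([0], [1.0], 1.0) == pytest.approx(math.log(2))
        # k=1 is geometric: P(3) = (1/3)(2/3)^3 = 8/81
        assert nll_negbin([3], [2.0], 1.0) == pytest.approx(math.log(81 / 8))

    def test_negbin_matches_scipy_pmf(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(3.0, size=15)
        mu = rng.uniform(0.5, 6.0, size=15)
        k = 2.5
        expected = -stats.nbinom.logpmf(y, k, k / (k + mu)).sum()
        assert nll_negbin(y, mu, k) == pytest.approx(expected, rel=1e-10)

    def test_negbin_poisson_limit(self):
        y = np.array([0, 1, 2, 3])
        mu = np.full(4, 2.0)
        assert nll_negbin(y, mu, 1e8) == pytest.approx(nll_poisson(y, mu), abs=1e-4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            nll_poisson([1], [0.0])
        with pytest.raises(ValueError):
            nll_negbin([1], [1.0], 0.0)


class TestModelNLL:
    def test_single_component_reduces_to_poisson(self):
        m = models("richness")["A"]
        data = make_data([1, 2, 3], lids=["L50", "L30", "L10"], offset=2.0)
        c = 0.3
        mus = np.full(3, 2.0 * math.exp(c))
        assert model_nll(m, np.array([c]), data) == pytest.approx(
            nll_poisson(data.y, mus)
        )

    def test_additivity_over_components(self):
        m = models("richness")["C"]
        y = [4, 4, 9, 9, 1, 2]
        lids = ["L50", "L50", "L30", "L30", "L10", "L10"]
        data = make_data(y, lids=lids, offset=1.0)
        params = np.log([4.0, 9.0, 1.5])
        total = model_nll(m, params, data)
        parts = 0.0
        for lid, c in zip(LANDSCAPES, params):
            mask = np.array([l == lid for l in lids])
            parts += nll_poisson(data.y[mask], np.full(mask.sum(), math.exp(c)))
        assert total == pytest.approx(parts, rel=1e-12)

    def test_site_order_invariance(self):
        m = models("richness")["F"]
        rng = np.random.default_rng(3)
        y = rng.poisson(5, 9)
        x = rng.uniform(0.3, 2.5, 9)
        lids = ["L50", "L30", "L10"] * 3
        params = np.array([1.0, 0.5, 0.4, 0.8])
        data = make_data(y, x, lids)
        perm = rng.permutation(9)
        data_p = make_data(y[perm], x[perm], [lids[i] for i in perm])
        assert model_nll(m, params, data) == pytest.approx(
            model_nll(m, params, data_p), rel=1e-12
        )

    def test_wrong_parameter_length_rejected(self):
        m = models("abundance")["A"]  # negbin: mean + log k
        with pytest.raises(ValueError):
            model_nll(m, np.array([0.1]), make_data([1, 2]))


class TestFitModel:
    def test_constant_poisson_mle_is_sample_mean(self):
        m = models("richness")["A"]  # Poisson constant
        data = make_data([1, 2, 3], lids=["L50", "L30", "L10"], offset=1.0)
        fit = fit_model(m, data)
        assert math.exp(fit.params[0]) == pytest.approx(2.0, abs=1e-8)
        assert fit.converged

    def test_per_group_constant_means(self):
        m = models("richness")["C"]
        data = make_data(
            [4, 4, 9, 9, 7, 7],
            lids=["L50", "L50", "L30", "L30", "L10", "L10"],
        )
        fit = fit_model(m, data)
        mus = np.exp(fit.params)
        assert mus == pytest.approx([4.0, 9.0, 7.0], abs=1e-8)

    def test_negbin_constant_mean_is_sample_mean(self):
        m = models("abundance")["A"]
        rng = np.random.default_rng(5)
        y = rng.negative_binomial(2, 2 / (2 + 6.0), size=60)
        data = make_data(y, lids=tuple(LANDSCAPES[i % 3] for i in range(60)))
        fit = fit_model(m, data)
        assert math.exp(fit.params[0]) == pytest.approx(float(np.mean(y)), abs=1e-6)

    def test_richness_offset_recovers_per_year_rate(self):
        # response = 2 x mean yearly richness, offset 2: exp(c) is per-year
        m = models("richness")["A"]
        data = make_data([4, 6, 8], lids=list(LANDSCAPES), offset=2.0)
        fit = fit_model(m, data)
        assert math.exp(fit.params[0]) == pytest.approx(3.0, abs=1e-8)

    def test_fitted_loglik_nonpositive(self):
        rng = np.random.default_rng(11)
        y = rng.poisson(6, 12)
        x = rng.uniform(0.3, 2.5, 12)
        lids = tuple(LANDSCAPES[i % 3] for i in range(12))
        data = make_data(y, x, lids)
        for m in models("richness").values():
            assert fit_model(m, data).logL <= 0.0

    def test_nesting_monotonicity(self):
        """Larger nested parameter spaces never fit worse (same distribution)."""
        rng = np.random.default_rng(7)
        y = rng.poisson(5, 18)
        x = rng.uniform(0.3, 2.5, 18)
        lids = tuple(LANDSCAPES[i % 3] for i in range(18))
        data = make_data(y, x, lids)
        logL = {
            mid: fit_model(m, data, OptimizerConfig(seed=2)).logL
            for mid, m in models("richness").items()
        }
        tol = 1e-6
        assert logL["D2"] >= logL["D"] - tol >= logL["B"] - 2 * tol
        assert logL["D2"] >= logL["C"] - tol >= logL["A"] - 2 * tol
        assert logL["D2"] >= logL["E2"] - tol >= logL["E"] - 2 * tol
        assert logL["E2"] >= logL["F"] - tol  # F fixes the lowest-cover slope at 0

    def test_linear_component_needs_two_distinct_areas(self):
        m = models("richness")["B"]
        data = make_data([1, 2, 3], x=[1.0, 1.0, 1.0], lids=list(LANDSCAPES))
        with pytest.raises(ValueError):
            fit_model(m, data)

    def test_all_zero_component_flagged_degenerate(self):
        m = models("richness")["C"]
        data = make_data([0, 0, 3, 4, 5, 6],
                         lids=["L50", "L50", "L30", "L30", "L10", "L10"])
        fit = fit_model(m, data)
        assert fit.degenerate
        assert math.exp(fit.params[1]) == pytest.approx(3.5, abs=1e-8)
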