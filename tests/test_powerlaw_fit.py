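"""Discrete power-law MLE, KS distance, xmin scan and bootstrap p-value."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special

from readzipf.powerlaw_fit import (
    DivergentMLEError,
    FitConfigurationError,
    InsufficientDataError,
    convert_exponents,
    estimate_beta,
    fit_power_law,
    goodness_of_fit,
    ks_distance,
    model_tail,
    sample_discrete_power_law,
)


def grid_search_beta(sample, xmin, lo=1.01, hi=6.0, step=1e-4):
    """Independent oracle: maximise the discrete log-likelihood on a grid."""
    x = np.asarray(sample)
    x = x[x >= xmin]
    betas = np.arange(lo, hi + step / 2, step)
    loglik = -betas * np.log(x).sum() - x.size * np.log(special.zeta(betas, xmin))
    return betas[np.argmax(loglik)]


def brute_force_ks(sample, xmin, beta):
    """Independent oracle: enumerate every integer in [xmin+1, max]."""
    x = np.asarray(sample)
    x = x[x >= xmin]
    best = 0.0
    for v in range(int(xmin) + 1, max(int(x.max()), int(xmin) + 1) + 1):
        S = np.mean(x >= v)
        P = special.zeta(beta, v) / special.zeta(beta, xmin)
        best = max(best, abs(S - P))
    return best


class TestConvertExponents:
    @pytest.mark.parametrize(
        "value, given, expected",
        [
            (1.0, "k", (1.0, 2.0, 1.0)),
            (2.0, "alpha", (2.0, 1.5, 0.5)),
            (1.94, "beta", (1 / 0.94, 1.94, 0.94)),
        ],
    )
    def test_known_triples(self, value, given, expected):
        triple = convert_exponents(value, given)
        assert triple == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=0.05, max_value=20.0, allow_nan=False))
    def test_roundtrip_identity(self, alpha):
        a1, b, k = convert_exponents(alpha, "alpha")
        a2, _, _ = convert_exponents(b, "beta")
        a3, _, _ = convert_exponents(k, "k")
        assert a1 == pytest.approx(alpha, rel=1e-12)
        assert a2 == pytest.approx(alpha, rel=1e-12)
        assert a3 == pytest.approx(alpha, rel=1e-12)

    @pytest.mark.parametrize("value, given", [(0.9, "beta"), (-1, "alpha"), (0, "k")])
    def test_domain_errors(self, value, given):
        with pytest.raises(ValueError):
            convert_exponents(value, given)


class TestEstimateBeta:
    def test_matches_grid_oracle_on_fixture(self):
        sample = [1, 1, 1, 1, 2, 2, 3, 5]
        assert estimate_beta(sample, 1) == pytest.approx(grid_search_beta(sample, 1), abs=1e-3)

    def test_divergent_when_zero_log_spread(self):
        with pytest.raises(DivergentMLEError):
            estimate_beta([3, 3, 3, 3], 3)

    def test_insufficient_tail(self):
        with pytest.raises(InsufficientDataError):
            estimate_beta([1, 1, 1, 9], 8)

    def test_recovers_known_exponent(self):
        rng = np.random.default_rng(11)
        sample = sample_discrete_power_law(2.5, 1, 5000, rng)
        assert 2.4 <= estimate_beta(sample, 1) <= 2.6


class TestKSDistance:
    def test_hand_computed_zeta2_case(self):
        # sample {1,1,2}, beta=2: model tail at 2 is 1 - 6/pi^2; empirical 1/3
        expected = abs(1 / 3 - (1 - 6 / np.pi**2))
        assert ks_distance([1, 1, 2], 1, 2.0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.0588, abs=5e-4)

    def test_single_value_sample(self):
        # all mass at xmin: D is the model mass strictly above xmin
        beta = 2.0
        expected = special.zeta(beta, 2) / special.zeta(beta, 1)
        assert ks_distance([1, 1, 1], 1, beta) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(10):
            sample = rng.integers(1, 60, size=rng.integers(5, 40))
            beta = float(rng.uniform(1.3, 3.5))
            assert ks_distance(sample, 1, beta) == pytest.approx(
                brute_force_ks(sample, 1, beta), abs=1e-12
            )

    def test_model_tail_is_valid(self):
        xs = np.arange(3, 5000)
        P = model_tail(xs, 3, 1.8)
        assert P[0] == pytest.approx(1.0)
        assert np.all(np.diff(P) < 0)
        assert P[-1] < 0.01


class TestFitPowerLaw:
    def test_fixed_reproduces_composition(self):
        rng = np.random.default_rng(5)
        sample = sample_discrete_power_law(2.0, 1, 500, rng)
        fit = fit_power_law(sample, xmin_strategy="fixed", xmin=2)
        assert fit.beta == pytest.approx(estimate_beta(sample, 2))
        assert fit.D == pytest.approx(ks_distance(sample, 2, fit.beta))
        assert fit.n_tail == int((sample >= 2).sum())

    def test_scan_recovers_beta_and_small_xmin(self):
        rng = np.random.default_rng(17)
        sample = sample_discrete_power_law(2.0, 1, 5000, rng)
        fit = fit_power_law(sample)
        assert fit.xmin <= 3
        assert fit.beta == pytest.approx(2.0, abs=0.1)

    def test_corrupted_head_pushes_xmin_up(self):
        # power law above 3, flat uniform noise on {1, 2}: the scan must
        # place the cutoff above the corrupted head
        rng = np.random.default_rng(23)
        sample = np.concatenate([
            sample_discrete_power_law(2.0, 3, 3000, rng),
            rng.integers(1, 3, size=2000),
        ])
        fit = fit_power_law(sample)
        assert fit.xmin > 2

    def test_exponent_triple_identity(self):
        rng = np.random.default_rng(2)
        fit = fit_power_law(sample_discrete_power_law(1.8, 1, 800, rng))
        assert fit.beta == pytest.approx(1 + fit.k, abs=1e-12)
        assert fit.alpha == pytest.approx(1 / fit.k, rel=1e-12)

    def test_no_admissible_candidate(self):
        with pytest.raises(InsufficientDataError):
            fit_power_law([1, 2, 3], min_tail=10)

    def test_serialisation_roundtrip(self):
        import json
        rng = np.random.default_rng(3)
        fit = fit_power_law(sample_discrete_power_law(2.2, 1, 300, rng))
        doc = json.loads(fit.to_json())
        assert doc["xmin"] == fit.xmin and doc["beta"] == fit.beta
        assert doc["p_value"] is None and doc["plausible"] is None


class TestSampler:
    def test_matches_model_tail(self):
        rng = np.random.default_rng(29)
        sample = sample_discrete_power_law(2.3, 2, 20000, rng)
        assert sample.min() >= 2
        for x in (2, 3, 5, 10, 30):
            emp = np.mean(sample >= x)
            assert emp == pytest.approx(model_tail(x, 2, 2.3), abs=0.012)

    def test_deterministic_in_seed(self):
        s1 = sample_discrete_power_law(2.0, 1, 100, np.random.default_rng(1))
        s2 = sample_discrete_power_law(2.0, 1, 100, np.random.default_rng(1))
        assert np.array_equal(s1, s2)


class TestGoodnessOfFit:
    def test_p_definition_and_determinism(self):
        rng = np.random.default_rng(31)
        sample = sample_discrete_power_law(2.2, 1, 400, rng)
        fit = fit_power_law(sample)
        p1 = goodness_of_fit(sample, fit, n_boot=40, seed=6)
        p2 = goodness_of_fit(sample, fit, n_boot=40, seed=6)
        assert p1 == p2
        assert 0.0 <= p1 <= 1.0
        assert (p1 * 40) == pytest.approx(round(p1 * 40))  # exact fraction of replicates

    def test_n_boot_floor(self):
        rng = np.random.default_rng(37)
        sample = sample_discrete_power_law(2.2, 1, 100, rng)
        fit = fit_power_law(sample)
        with pytest.raises(FitConfigurationError):
            goodness_of_fit(sample, fit, n_boot=10, seed=0)

    def test_plausible_flag_requires_p(self):
        rng = np.random.default_rng(41)
        fit = fit_power_law(sample_discrete_power_law(2.2, 1, 200, rng))
        with pytest.raises(ValueError):
            _ = fit.plausible
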