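import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from parage import (
    AgeBandScheme,
    AgeCrossTab,
    ModelSpec,
    RW1Prior,
    binomial_loglik,
    linear_predictor,
    rw1_logdensity,
    rw1_structure_matrix,
    sd_hyperprior_logdensity,
)
from parage.crosstab import MarginalAgeTab


class TestBinomialLoglik:
    def test_single_cell_closed_form(self):
        tab = MarginalAgeTab(ages=[20], births=[10], cases=[5], parent="maternal")
        expected = np.log(252.0) - 10.0 * np.log(2.0)
        assert binomial_loglik(tab, np.array([0.5])) == pytest.approx(expected, rel=1e-12)

    def test_empty_table_contributes_zero(self):
        tab = MarginalAgeTab(ages=[20, 21], births=[0, 0], cases=[0, 0], parent="maternal")
        assert binomial_loglik(tab, np.array([0.0, 1.0])) == 0.0

    def test_matches_cellwise_pmf_oracle(self, tiny_tab):
        rng = np.random.default_rng(0)
        mu = rng.uniform(0.01, 0.4, size=tiny_tab.shape)
        oracle = binom.logpmf(tiny_tab.cases, tiny_tab.births, mu).sum()
        assert binomial_loglik(tiny_tab, mu) == pytest.approx(oracle, rel=1e-10)

    def test_mle_maximises(self, tiny_tab):
        mu_hat = tiny_tab.cases / np.maximum(tiny_tab.births, 1)
        mu_hat = np.clip(mu_hat, 1e-9, 1 - 1e-9)
        best = binomial_loglik(tiny_tab, mu_hat)
        rng = np.random.default_rng(1)
        for _ in range(20):
            other = np.clip(mu_hat + rng.normal(0, 0.02, mu_hat.shape), 1e-9, 1 - 1e-9)
            assert binomial_loglik(tiny_tab, other) <= best + 1e-9

    def test_rejects_bad_mu(self, tiny_tab):
        with pytest.raises(ValueError):
            binomial_loglik(tiny_tab, np.full(tiny_tab.shape, 1.5))
        with pytest.raises(ValueError):
            binomial_loglik(tiny_tab, np.zeros(tiny_tab.shape))


class TestRW1:
    def test_frozen_example(self):
        # effects (0, 1, -1), tau=2: ((3-1)/2) log 2 - (2/2)(1 + 4)
        assert rw1_logdensity([0.0, 1.0, -1.0], 2.0) == pytest.approx(np.log(2.0) - 5.0)

    def test_constant_vector_only_normalisation_term(self):
        L, tau = 6, 3.7
        val = rw1_logdensity(np.full(L, 2.3), tau)
        assert val == pytest.approx(0.5 * (L - 1) * np.log(tau))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(shift=st.floats(-50, 50), seed=st.integers(0, 100))
    def test_level_shift_invariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        e = rng.normal(size=8)
        assert rw1_logdensity(e + shift, 1.3) == pytest.approx(
            rw1_logdensity(e, 1.3), rel=1e-9, abs=1e-9
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 200), L=st.integers(2, 60))
    def test_quadratic_form_matches_structure_matrix(self, seed, L):
        rng = np.random.default_rng(seed)
        e = rng.normal(size=L)
        tau = float(rng.uniform(0.1, 5.0))
        Q = rw1_structure_matrix(L)
        expected = 0.5 * (L - 1) * np.log(tau) - 0.5 * tau * float(e @ Q @ e)
        assert rw1_logdensity(e, tau) == pytest.approx(expected, rel=1e-10, abs=1e-10)

    def test_doubling_differences_quadratic_penalty(self):
        e = np.array([0.0, 0.5, -0.2, 0.9])
        tau = 2.0
        d2 = float(np.sum(np.diff(e) ** 2))
        base = rw1_logdensity(e, tau)
        doubled = rw1_logdensity(e[0] + 2 * np.cumsum(np.r_[0, np.diff(e)]), tau)
        assert doubled - base == pytest.approx(-1.5 * tau * d2)

    def test_structure_matrix_shape(self):
        Q = rw1_structure_matrix(5)
        assert Q[0, 0] == 1 and Q[-1, -1] == 1 and Q[2, 2] == 2 and Q[1, 2] == -1
        assert np.allclose(Q.sum(axis=1), 0)  # rank deficiency in the level


class TestHyperprior:
    @pytest.mark.parametrize("sd, finite", [(5.0, True), (9.99, True), (10.5, False),
                                            (0.0, False), (-1.0, False), (10.0, False)])
    def test_uniform_support_open_interval(self, sd, finite):
        prior = RW1Prior(length=35)
        val = sd_hyperprior_logdensity(sd, prior)
        assert (val == 0.0) if finite else (val == -np.inf)

    def test_prior_validation(self):
        with pytest.raises(ValueError):
            RW1Prior(length=1)
        with pytest.raises(ValueError):
            RW1Prior(length=5, sd_lower=10.0, sd_upper=10.0)


class TestLinearPredictor:
    def test_all_zero_params_gives_even_odds(self):
        spec = ModelSpec.preset("model3")
        params = {"alpha": 0.0, "maternal": np.zeros(35), "paternal": np.zeros(51)}
        assert linear_predictor(spec, params, (30, 40)) == 0.0

    def test_car_additivity_across_other_parent(self):
        spec = ModelSpec.preset("model3")
        m = np.zeros(35)
        m[45 - 15] = np.log(2.0)
        rng = np.random.default_rng(2)
        p = rng.normal(size=51)
        params = {"alpha": -7.0, "maternal": m, "paternal": p}
        for k in (15, 33, 65):
            hi = linear_predictor(spec, params, (45, k))
            lo = linear_predictor(spec, params, (15, k))
            assert hi - lo == pytest.approx(np.log(2.0))

    def test_curvilinear_hand_value(self):
        # maternal centred at 32: 0.1*(30-32) + 0.01*(30-32)^2 = -0.16
        spec = ModelSpec(maternal_form="curvilinear", paternal_form="none")
        params = {"alpha": 0.0, "maternal": np.array([0.1, 0.01])}
        assert linear_predictor(spec, params, (30, 40)) == pytest.approx(-0.16)

    def test_category5_piecewise_constant(self):
        spec = ModelSpec(maternal_form="none", paternal_form="category5")
        coefs = np.arange(9, dtype=float) / 10  # non-reference bands
        params = {"alpha": 0.0, "paternal": coefs}
        assert linear_predictor(spec, params, (30, 50)) == linear_predictor(
            spec, params, (30, 54)
        )
        assert linear_predictor(spec, params, (30, 15)) == 0.0  # reference band
        assert linear_predictor(spec, params, (30, 60)) == linear_predictor(
            spec, params, (30, 65)
        )  # last band spans 60-65

    def test_age_out_of_range_rejected(self):
        spec = ModelSpec.preset("model3")
        params = {"alpha": 0.0, "maternal": np.zeros(35), "paternal": np.zeros(51)}
        with pytest.raises(ValueError, match="outside"):
            linear_predictor(spec, params, (51, 40))


class TestSpecs:
    def test_band_edges_match_design(self):
        assert AgeBandScheme("maternal").band_edges == [
            (15, 19), (20, 24), (25, 29), (30, 34), (35, 39), (40, 44), (45, 49)]
        assert AgeBandScheme("paternal").band_edges[-3:] == [(50, 54), (55, 59), (60, 65)]

    def test_presets(self):
        m1 = ModelSpec.preset("model1")
        assert (m1.maternal_form, m1.paternal_form) == ("car", "none")
        m2 = ModelSpec.preset("model2")
        assert (m2.maternal_form, m2.paternal_form) == ("none", "car")
        m3 = ModelSpec.preset("model3")
        assert (m3.maternal_form, m3.paternal_form) == ("car", "car")
        assert ModelSpec.preset("linear").intercept_prior == "normal"
        with pytest.raises(ValueError):
            ModelSpec.preset("model4")

    def test_yaml_roundtrip(self):
        spec = ModelSpec.preset("curvilinear", outcome="DS")
        assert ModelSpec.from_yaml(spec.to_yaml()) == spec
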