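"""Rheological models, the global complex fit and model selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from derheo.rheology import (DynamicModulus, PowerLawParams, RheologyModel,
                             crossing_frequency, distance_measures,
                             eval_model, fit_modulus, population_summary,
                             select_model)


TRUTH = {"A": 1000.0, "B": 50.0, "alpha": 0.1, "beta": 0.9}


def noisy(data, sigma, seed):
    rng = np.random.default_rng(seed)
    return DynamicModulus(
        data.frequencies,
        data.E_prime * rng.lognormal(0, sigma, data.frequencies.size),
        data.E_dprime * rng.lognormal(0, sigma, data.frequencies.size),
    )


class TestEvalModel:
    def test_alpha_zero_term_is_purely_elastic(self, f_grid):
        m = eval_model("double_pl", {"A": 500.0, "B": 0.0, "alpha": 0.0,
                                     "beta": 0.5}, f_grid)
        np.testing.assert_allclose(m.E_prime, 500.0, rtol=1e-12)
        np.testing.assert_allclose(m.E_dprime, 0.0, atol=1e-10)

    def test_alpha_one_is_newtonian(self, f_grid):
        m = eval_model("double_pl", {"A": 100.0, "B": 0.0, "alpha": 1.0,
                                     "beta": 1.0}, f_grid)
        np.testing.assert_allclose(m.E_prime, 0.0, atol=1e-9)
        np.testing.assert_allclose(m.E_dprime, 100.0 * f_grid / 1000.0,
                                   rtol=1e-12)

    def test_double_pl_reference_values_at_f0(self):
        m = eval_model("double_pl", TRUTH, [1000.0])
        # direct evaluation of the cos/sin split
        ep = (1000 * math.cos(0.05 * math.pi)
              + 50 * math.cos(0.45 * math.pi))
        edp = (1000 * math.sin(0.05 * math.pi)
               + 50 * math.sin(0.45 * math.pi))
        assert m.E_prime[0] == pytest.approx(ep, rel=1e-12)  # ~995.5
        assert m.E_dprime[0] == pytest.approx(edp, rel=1e-12)  # ~205.8

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(A=st.floats(1, 1e4), B=st.floats(0, 1e3),
           alpha=st.floats(0, 1), beta=st.floats(0, 1),
           x=st.floats(0.1, 100.0))
    def test_complex_eval_matches_cos_sin_split(self, A, B, alpha, beta, x):
        # the implementation uses i^a = exp(i pi a / 2); the real/imaginary
        # split with cos/sin prefactors is the independent form
        f0 = 1000.0
        m = eval_model("double_pl",
                       {"A": A, "B": B, "alpha": alpha, "beta": beta},
                       [x * f0])
        ep = (A * math.cos(math.pi * alpha / 2) * x**alpha
              + B * math.cos(math.pi * beta / 2) * x**beta)
        edp = (A * math.sin(math.pi * alpha / 2) * x**alpha
               + B * math.sin(math.pi * beta / 2) * x**beta)
        assert m.E_prime[0] == pytest.approx(ep, rel=1e-12, abs=1e-12)
        assert m.E_dprime[0] == pytest.approx(edp, rel=1e-12, abs=1e-12)

    def test_unknown_model_rejected(self, f_grid):
        from derheo.io import ValidationError
        with pytest.raises(ValidationError, match="unknown"):
            eval_model("kelvin_voigt", {}, f_grid)


class TestDistanceMeasures:
    def test_perfect_fit_is_zero(self, f_grid):
        m = eval_model("double_pl", TRUTH, f_grid)
        assert distance_measures(m, m) == (0.0, 0.0)

    def test_single_residual_values(self):
        f = np.array([1e3, 2e3])
        a = DynamicModulus(f, [1.0, 0.0], [1.0, 0.0])
        b = DynamicModulus(f, [0.0, 0.0], [0.0, 0.0])
        l1, l2 = distance_measures(a, b)
        assert l1 == pytest.approx(2.0)
        assert l2 == pytest.approx(math.sqrt(2.0))

    def test_l2star_squared_equals_stacked_residual(self, f_grid):
        data = noisy(eval_model("double_pl", TRUTH, f_grid), 0.02, 21)
        fit = fit_modulus(data, "double_pl")
        resid = data.complex - fit.eval(f_grid).complex
        ss = float(np.sum(resid.real**2) + np.sum(resid.imag**2))
        assert fit.l2star**2 == pytest.approx(ss, rel=1e-10)


class TestCrossingFrequency:
    def test_closed_form_crossing(self):
        # A cos_a x^a + B cos_b x^b = A sin_a x^a + B sin_b x^b
        #   => x = [A(cos_a - sin_a) / (B(sin_b - cos_b))]^{1/(b-a)}
        a, b = 0.1, 0.9
        num = TRUTH["A"] * (math.cos(math.pi * a / 2)
                            - math.sin(math.pi * a / 2))
        den = TRUTH["B"] * (math.sin(math.pi * b / 2)
                            - math.cos(math.pi * b / 2))
        oracle = (num / den) ** (1 / (b - a)) * 1000.0
        got = crossing_frequency(PowerLawParams(**TRUTH))
        assert got == pytest.approx(oracle, abs=2.0)
        assert oracle == pytest.approx(42294.85, abs=1.0)

    def test_half_exponent_single_power_law_degenerate(self):
        got = crossing_frequency(PowerLawParams(1000.0, 0.0, 0.5, 0.5))
        assert got == "degenerate"

    def test_no_crossing_below_half_exponent(self):
        assert crossing_frequency(PowerLawParams(1000.0, 0.0, 0.3, 0.3)) \
            is None


class TestFitModulus:
    def test_noiseless_self_fit_is_exact(self, f_grid):
        data = eval_model("double_pl", TRUTH, f_grid)
        fit = fit_modulus(data, "double_pl")
        med = np.median(np.abs(data.complex))
        assert fit.l2star < 1e-6 * med
        for k, v in TRUTH.items():
            assert fit.params[k] == pytest.approx(v, rel=1e-5)

    def test_recovery_at_2pct_noise_within_5pct(self, f_grid):
        data = noisy(eval_model("double_pl", TRUTH, f_grid), 0.02, 42)
        fit = fit_modulus(data, "double_pl")
        for k, v in TRUTH.items():
            assert fit.params[k] == pytest.approx(v, rel=0.05)

    def test_nested_model_has_larger_residual(self, f_grid):
        data = noisy(eval_model("double_pl", TRUTH, f_grid), 0.02, 1)
        single = fit_modulus(data, "single_pl")
        double = fit_modulus(data, "double_pl")
        assert single.l2star > double.l2star

    def test_exponent_ordering_enforced(self, f_grid):
        data = eval_model("double_pl", TRUTH, f_grid)
        fit = fit_modulus(data, "double_pl",
                          init={"A": 40.0, "B": 900.0, "alpha": 0.8,
                                "beta": 0.15})
        assert fit.params["alpha"] <= fit.params["beta"]

    def test_frequency_unit_rescaling_invariance(self, f_grid):
        data = noisy(eval_model("double_pl", TRUTH, f_grid), 0.01, 4)
        fit_hz = fit_modulus(data, "double_pl", f0=1000.0)
        khz = DynamicModulus(data.frequencies / 1000.0, data.E_prime,
                             data.E_dprime)
        fit_khz = fit_modulus(khz, "double_pl", f0=1.0)
        for k in TRUTH:
            assert fit_khz.params[k] == pytest.approx(fit_hz.params[k],
                                                      rel=1e-6)

    def test_too_few_points_rejected(self):
        from derheo.io import ValidationError
        f = np.linspace(1e3, 5e3, 10)
        data = eval_model("double_pl", TRUTH, f)
        with pytest.raises(ValidationError, match="points"):
            fit_modulus(data, "double_pl")


class TestModelSelection:
    def test_generating_model_selected(self, f_grid):
        generators = {
            "single_pl": {"A": 1000.0, "alpha": 0.2},
            "double_pl": TRUTH,
            "structural_damping": {"A": 1000.0, "alpha": 0.15, "mu": 20.0},
            "maxwell": {"E": 2000.0, "f_r": 10e3},
        }
        for mid, prm in generators.items():
            data = noisy(eval_model(mid, prm, f_grid), 0.02, 77)
            best, fits = select_model(data)
            assert best.model_id == mid, (mid, {k: v.l2star
                                                for k, v in fits.items()})

    def test_double_pl_ranked_first_on_double_pl_data(self, f_grid):
        data = noisy(eval_model("double_pl", TRUTH, f_grid), 0.02, 3)
        _, fits = select_model(data)
        ranked = sorted(fits, key=lambda m: fits[m].l2star)
        assert ranked[0] == "double_pl"


class TestPopulationSummary:
    def _fit(self, alpha, f_grid):
        p = dict(TRUTH, alpha=alpha)
        return fit_modulus(eval_model("double_pl", p, f_grid), "double_pl")

    def test_identical_fits_zero_sd(self, f_grid):
        fits = [self._fit(0.1, f_grid)] * 3
        out = population_summary(fits)
        assert out["alpha"]["sd"] == pytest.approx(0.0, abs=1e-12)

    def test_two_cell_hand_arithmetic(self, f_grid):
        fits = [self._fit(0.1, f_grid), self._fit(0.3, f_grid)]
        out = population_summary(fits)
        assert out["alpha"]["mean"] == pytest.approx(0.2, abs=1e-4)
        assert out["alpha"]["sd"] == pytest.approx(0.1414, abs=1e-3)

    def test_mixed_models_rejected(self, f_grid):
        from derheo.io import ValidationError
        a = self._fit(0.1, f_grid)
        b = fit_modulus(eval_model("maxwell", {"E": 2000.0, "f_r": 1e4},
                                   f_grid), "maxwell")
        with pytest.raises(ValidationError, match="mixed"):
            population_summary([a, b])

    def test_population_means_recovered_within_2se(self, f_grid):
        from derheo.pipeline import synthetic_population
        pop = synthetic_population(10, seed=5)
        fits = []
        for p in pop["params"]:
            data = eval_model("double_pl", p, f_grid)
            fits.append(fit_modulus(data, "double_pl"))
        out = population_summary(fits)
        gm = pop["generator_means"]
        for name, spread in [("A", 1000 * 0.2), ("B", 50 * 0.2),
                             ("alpha", 0.02), ("beta", 0.02)]:
            se = spread / math.sqrt(10)
            assert abs(out[name]["mean"] - gm[name]) < 2.5 * se


class TestModelResultsAPI:
    def test_summary_contains_parameters_and_distances(self, f_grid):
        data = noisy(eval_model("double_pl", TRUTH, f_grid), 0.01, 8)
        res = RheologyModel(data, "double_pl").fit()
        text = res.summary()
        assert "double_pl" in text and "l2*" in text and "alpha" in text
        assert set(res.params) == {"A", "B", "alpha", "beta"}
        assert all(np.isfinite(v) for v in res.bse.values())

    def test_predict_on_new_grid(self, f_grid):
        data = eval_model("double_pl", TRUTH, f_grid)
        res = RheologyModel(data, "double_pl").fit()
        new = res.predict(np.array([500.0, 1500.0]))
        assert len(new) == 2
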