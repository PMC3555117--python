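"""Least-squares parameter recovery, scenario comparison and sigmoid fits."""

import numpy as np
import pytest

from oracles import recursion_amplitudes
from schaffer.fitting import (
    FitFailureError,
    FitSpec,
    SigmoidFit,
    compare_scenarios,
    fit_sigmoid,
    fit_stp,
    model_curve,
)
from schaffer.stp import STPParams

SHARED_TAUS = {"tau_in": 1.0, "tau_rec": 50.0, "tau_facil": 200.0}


def synthetic_observations(U, frequencies=(100.0,), n_pulses=5, noise_sd=0.0, rng=None):
    params = STPParams(U=U, **SHARED_TAUS)
    obs = []
    for f in frequencies:
        curve = model_curve(params, f, n_pulses)
        if noise_sd:
            curve = curve + rng.normal(0.0, noise_sd, size=curve.size)
        obs.append((f, curve))
    return obs


class TestFitStp:
    @pytest.mark.parametrize("U_true", [0.15, 0.36])
    def test_recovers_release_probability_from_noiseless_curve(self, U_true):
        spec = FitSpec(
            free_parameters=("U",), fixed=SHARED_TAUS,
            observations=synthetic_observations(U_true),
        )
        result = fit_stp(spec)
        assert result.params["U"] == pytest.approx(U_true, abs=0.005)
        assert result.sse < 1e-10

    @pytest.mark.parametrize("name, true", [("tau_rec", 50.0), ("tau_facil", 200.0)])
    def test_recovers_time_constants_within_one_percent(self, name, true):
        fixed = {"U": 0.15, **SHARED_TAUS}
        del fixed[name]
        spec = FitSpec(
            free_parameters=(name,), fixed=fixed,
            observations=synthetic_observations(0.15, frequencies=(5.0, 40.0, 100.0), n_pulses=10),
        )
        result = fit_stp(spec)
        assert result.params[name] == pytest.approx(true, rel=0.01)

    def test_noisy_curves_give_small_bias(self):
        rng = np.random.default_rng(42)
        estimates = []
        for _ in range(10):
            spec = FitSpec(
                free_parameters=("U",), fixed=SHARED_TAUS,
                observations=synthetic_observations(0.15, noise_sd=0.05, rng=rng),
            )
            estimates.append(fit_stp(spec).params["U"])
        assert abs(np.mean(estimates) - 0.15) < 0.02

    def test_single_point_single_parameter_exact_fit(self):
        spec = FitSpec(
            free_parameters=("U",), fixed=SHARED_TAUS,
            observations=[(100.0, np.array([1.0]))],
        )
        assert fit_stp(spec).sse == pytest.approx(0.0, abs=1e-12)

    def test_nested_free_sets_do_not_increase_sse(self):
        obs = synthetic_observations(0.25, frequencies=(40.0, 100.0), n_pulses=8)
        noisy = [(f, a + 0.03 * np.sin(np.arange(a.size))) for f, a in obs]
        sse = {}
        for free in (("U",), ("U", "tau_rec"), ("U", "tau_rec", "tau_facil")):
            fixed = {k: v for k, v in {"U": 0.25, **SHARED_TAUS}.items() if k not in free}
            sse[free] = fit_stp(FitSpec(free_parameters=free, fixed=fixed, observations=noisy)).sse
        assert sse[("U", "tau_rec")] <= sse[("U",)] + 1e-9
        assert sse[("U", "tau_rec", "tau_facil")] <= sse[("U", "tau_rec")] + 1e-9

    def test_underdetermined_or_empty_specs_rejected(self):
        with pytest.raises(ValueError):
            FitSpec(free_parameters=("Q",), fixed=SHARED_TAUS)
        with pytest.raises(ValueError):
            fit_stp(FitSpec(free_parameters=("U", "tau_rec"),
                            fixed={"tau_in": 1.0, "tau_facil": 200.0},
                            observations=[(100.0, np.array([1.0]))]))


class TestCompareScenarios:
    def test_reduced_facilitation_scenario_approximates_abeta_curve(self):
        # a 15% lower release probability with ~10x faster facilitation decay
        # reproduces the increased-release curve to within 0.1
        reference = synthetic_observations(0.36)
        oracle = np.abs(
            recursion_amplitudes(0.30, 50.0, 20.0, 5, 100.0)
            - recursion_amplitudes(0.36, 50.0, 200.0, 5, 100.0)
        ).max()
        assert oracle == pytest.approx(0.067, abs=0.005)
        scen = FitSpec(
            free_parameters=("tau_facil",),
            fixed={"U": 0.30, "tau_in": 1.0, "tau_rec": 50.0},
            label="reduced p0 + free facilitation",
        )
        table = compare_scenarios(reference, [scen])
        fitted = STPParams(
            U=0.30, tau_in=1.0, tau_rec=50.0, tau_facil=float(table.loc[0, "tau_facil"])
        )
        diff = np.abs(model_curve(fitted, 100.0, 5) - reference[0][1]).max()
        assert diff <= 0.1

    def test_generator_scenario_ranks_first_with_zero_sse(self):
        reference = synthetic_observations(0.36)
        exact = FitSpec(free_parameters=(), fixed={"U": 0.36, **SHARED_TAUS}, label="generator")
        wrong = FitSpec(free_parameters=(), fixed={"U": 0.2, **SHARED_TAUS}, label="wrong")
        table = compare_scenarios(reference, [wrong, exact]).set_index("scenario")
        assert table.loc["generator", "sse"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["wrong", "sse"] > 0
        assert table.loc["generator", "rank"] == 1


class TestFitSigmoid:
    def test_recovers_exact_sigmoid_parameters(self):
        truth = SigmoidFit(a=90.0, b=50.0, c=0.15)
        x = np.linspace(5.0, 80.0, 12)
        fit = fit_sigmoid(x, truth(x))
        assert fit.a == pytest.approx(90.0, rel=0.01)
        assert fit.b == pytest.approx(50.0, rel=0.01)
        assert fit.c == pytest.approx(0.15, rel=0.01)

    def test_fixed_asymptote_mode(self):
        truth = SigmoidFit(a=90.0, b=30.0, c=0.2)
        x = np.linspace(2.0, 60.0, 8)
        fit = fit_sigmoid(x, truth(x), a_fixed=90.0)
        assert fit.a == 90.0
        assert fit.b == pytest.approx(30.0, rel=0.01)
        assert fit.c == pytest.approx(0.2, rel=0.01)

    def test_constant_probabilities_flagged_degenerate(self):
        with pytest.raises(FitFailureError):
            fit_sigmoid(np.array([1.0, 2.0, 3.0]), np.array([90.0, 90.0, 90.0]))

    def test_curve_tends_to_asymptote(self):
        fit = SigmoidFit(a=90.0, b=50.0, c=0.15)
        assert fit(1e6) == pytest.approx(90.0)
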