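"""Melting-curve preprocessing and two-state fitting."""

import numpy as np
import pytest

from duplexkit import synth
from duplexkit.errors import (
    FitRejectedError,
    FormatError,
    IdentifiabilityError,
    NoTransitionError,
)
from duplexkit.meltfit import (
    BaselinePair,
    MeltingCurve,
    derivative_tm,
    fit_melting_curve,
    hypochromicity,
    merge_ramps,
    model_absorbance,
    preprocess_curve,
)
from duplexkit.thermo import StrandConcentration

from conftest import make_noiseless


def _curve(temps, vals, ref=None, ct_uM=20.0, **kw):
    return MeltingCurve(
        temperatures=np.asarray(temps, float),
        absorbances=np.asarray(vals, float),
        reference_absorbances=None if ref is None else np.asarray(ref, float),
        ct=StrandConcentration.from_micromolar(ct_uM),
        **kw,
    )


@pytest.fixture
def nful_curve(noiseless_cfg, ct20):
    curve, truth = synth.gen_melting_curve(noiseless_cfg, ct20)
    return curve, truth


class TestPreprocess:
    def test_zero_reference_is_identity(self):
        t = np.arange(5.0, 95.0, 1.0)
        v = np.linspace(0.8, 1.0, len(t))
        out = preprocess_curve(_curve(t, v, ref=np.zeros_like(t)))
        np.testing.assert_array_equal(out.absorbances, v)
        assert out.reference_absorbances is None

    def test_descending_input_sorted(self):
        t = np.arange(95.0, 5.0, -1.0)
        v = np.linspace(1.0, 0.8, len(t))
        out = preprocess_curve(_curve(t, v))
        assert np.all(np.diff(out.temperatures) > 0)
        np.testing.assert_allclose(
            np.interp(50.0, out.temperatures, out.absorbances),
            np.interp(50.0, t[::-1], v[::-1]),
        )

    def test_constant_reference_subtracted(self):
        t = np.arange(5.0, 95.0, 1.0)
        v = np.linspace(0.8, 1.0, len(t))
        out = preprocess_curve(_curve(t, v, ref=np.full_like(t, 0.05)))
        np.testing.assert_allclose(out.absorbances, v - 0.05)

    def test_duplicate_temperatures_averaged(self):
        out = preprocess_curve(_curve([10.0, 10.0, 20.0], [0.8, 0.9, 1.0]))
        np.testing.assert_allclose(out.temperatures, [10.0, 20.0])
        np.testing.assert_allclose(out.absorbances, [0.85, 1.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(FormatError):
            _curve([1.0, 2.0], [0.5])

    def test_merge_ramps_flags_hysteresis(self, noiseless_cfg, ct20):
        heat, _ = synth.gen_melting_curve(noiseless_cfg, ct20)
        shifted = MeltingCurve(
            temperatures=heat.temperatures + 3.0,
            absorbances=heat.absorbances,
            ct=ct20,
            ramp="cooling",
        )
        with pytest.warns(UserWarning, match="hysteresis"):
            merged = merge_ramps(heat, shifted)
        assert merged.hysteresis_flag


class TestModelAbsorbance:
    def test_baseline_limits_and_midpoint(self, nful_params, ct20):
        baselines = BaselinePair(m_ds=1e-4, b_ds=0.85, m_ss=2e-4, b_ss=0.99)
        low = model_absorbance(nful_params, baselines, ct20, 5.0)
        high = model_absorbance(nful_params, baselines, ct20, 95.0)
        assert low == pytest.approx(baselines.duplex(5.0), abs=1e-6)
        assert high == pytest.approx(baselines.single_strand(95.0), abs=1e-4)
        from duplexkit.thermo import predict_tm

        tm = predict_tm(nful_params, ct20)
        mid = model_absorbance(nful_params, baselines, ct20, tm)
        expected = (baselines.duplex(tm) + baselines.single_strand(tm)) / 2.0
        assert mid == pytest.approx(expected, abs=1e-12)

    def test_model_between_baselines_everywhere(self, nful_params, ct20):
        baselines = BaselinePair(m_ds=1e-4, b_ds=0.85, m_ss=2e-4, b_ss=0.99)
        temps = np.arange(5.0, 95.0, 0.5)
        vals = model_absorbance(nful_params, baselines, ct20, temps)
        assert np.all(vals >= baselines.duplex(temps) - 1e-12)
        assert np.all(vals <= baselines.single_strand(temps) + 1e-12)


class TestDerivativeTm:
    def test_matches_fit_on_noiseless_curve(self, nful_curve):
        # The dA/dT maximum of a bimolecular melt sits slightly ABOVE the
        # theta = 1/2 temperature (theta(T) is asymmetric); for these
        # parameters the offset is ~1 degC, which is why derivative_tm is
        # an initializer/QC value, not the reported Tm.
        curve, truth = nful_curve
        est = derivative_tm(curve)
        assert est == pytest.approx(truth["tm_C"], abs=1.25)
        assert est >= truth["tm_C"] - 0.25

    def test_monotone_linear_trace_rejected(self):
        t = np.arange(5.0, 95.0, 1.0)
        with pytest.raises(NoTransitionError):
            derivative_tm(_curve(t, 0.8 + 0.002 * t))

    def test_symmetric_sigmoid_centered(self):
        t = np.arange(5.0, 95.5, 0.5)
        v = 0.9 + 0.1 / (1.0 + np.exp(-(t - 50.0) / 4.0))
        assert derivative_tm(_curve(t, v)) == pytest.approx(50.0, abs=0.5)


class TestFit:
    def test_noiseless_round_trip(self, nful_curve):
        curve, truth = nful_curve
        fit = fit_melting_curve(curve)
        assert fit.tm == pytest.approx(truth["tm_C"], abs=0.05)
        assert fit.params.dH_kcal == pytest.approx(truth["dH_kcal"], rel=0.005)
        assert fit.ssr < 1e-12
        assert fit.converged
        assert fit.hypochromicity == pytest.approx(
            truth["hypochromicity_pct"], abs=0.05
        )

    def test_init_at_truth_converges_immediately(self, nful_curve):
        curve, truth = nful_curve
        b = truth["baselines"]
        init = np.array(
            [truth["tm_C"], truth["dH_kcal"], b.m_ds, b.b_ds, b.m_ss, b.b_ss]
        )
        fit = fit_melting_curve(curve, init=init, n_restarts=1)
        assert fit.ssr < 1e-18

    def test_refit_of_own_prediction_is_idempotent(self, nful_curve):
        curve, _ = nful_curve
        fit1 = fit_melting_curve(curve)
        clean = model_absorbance(fit1.params, fit1.baselines, curve.ct,
                                 curve.temperatures)
        refit = fit_melting_curve(
            MeltingCurve(curve.temperatures, clean, ct=curve.ct)
        )
        assert refit.tm == pytest.approx(fit1.tm, rel=1e-6)
        assert refit.params.dH == pytest.approx(fit1.params.dH, rel=1e-6)

    def test_noisy_recovery_small_batch(self, ct20):
        errs = []
        for seed in range(5):
            cfg = synth.GeneratorConfig(seed=seed, scenario="nFluL",
                                        melting_sigma=0.002)
            curve, truth = synth.gen_melting_curve(cfg, ct20)
            fit = fit_melting_curve(curve)
            errs.append(abs(fit.tm - truth["tm_C"]))
        assert np.median(errs) < 0.3

    def test_fitted_model_between_fitted_baselines(self, nful_curve):
        curve, _ = nful_curve
        fit = fit_melting_curve(curve)
        temps = curve.temperatures
        vals = model_absorbance(fit.params, fit.baselines, curve.ct, temps)
        assert np.all(vals >= fit.baselines.duplex(temps) - 1e-10)
        assert np.all(vals <= fit.baselines.single_strand(temps) + 1e-10)

    def test_too_few_points_rejected(self, nful_params, ct20):
        t = np.linspace(5.0, 95.0, 12)
        baselines = BaselinePair(1e-4, 0.85, 2e-4, 0.99)
        v = model_absorbance(nful_params, baselines, ct20, t)
        with pytest.raises(IdentifiabilityError):
            fit_melting_curve(_curve(t, v))

    def test_narrow_span_rejected(self, nful_params, ct20):
        t = np.linspace(45.0, 65.0, 41)
        baselines = BaselinePair(1e-4, 0.85, 2e-4, 0.99)
        v = model_absorbance(nful_params, baselines, ct20, t)
        with pytest.raises(IdentifiabilityError):
            fit_melting_curve(_curve(t, v))

    def test_non_sigmoidal_trace_rejected(self):
        t = np.arange(5.0, 95.0, 1.0)
        with pytest.raises(FitRejectedError):
            fit_melting_curve(_curve(t, 0.8 + 0.002 * t))

    def test_tm_within_measured_range(self, nful_curve):
        curve, _ = nful_curve
        fit = fit_melting_curve(curve)
        assert curve.temperatures.min() < fit.tm < curve.temperatures.max()


class TestHypochromicity:
    def test_forced_by_baselines(self, nful_params, ct20):
        # A_ss(Tm) = 1.000, A_ds(Tm) = 0.8525 -> 14.75%
        from duplexkit.meltfit import MeltFitResult

        result = MeltFitResult(
            params=nful_params,
            baselines=BaselinePair(m_ds=0.0, b_ds=0.8525, m_ss=0.0, b_ss=1.0),
            tm=55.0, hypochromicity=0.0, ssr=0.0, converged=True,
            n_restarts_used=1, ct=ct20,
        )
        assert hypochromicity(result) == pytest.approx(14.75)
        result.baselines = BaselinePair(0.0, 0.7785, 0.0, 0.9)
        assert hypochromicity(result) == pytest.approx(13.5)
        result.baselines = BaselinePair(0.0, 1.0, 0.0, 1.0)
        assert hypochromicity(result) == 0.0


@pytest.mark.parametrize("scenario,expected_h", [
    ("NM", 14.75), ("nFluL", 13.5), ("nFluS", 14.3),
])
def test_scenario_hypochromicities_recovered(scenario, expected_h, ct20):
    """Noiseless scenario curves refit to their preset hypochromicity."""
    curve, _ = synth.gen_melting_curve(make_noiseless(scenario), ct20)
    fit = fit_melting_curve(curve)
    assert fit.hypochromicity == pytest.approx(expected_h, abs=0.05)
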