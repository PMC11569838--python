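"""Excision time-course normalization, efficiency ratios, replicate stats."""

import math

import numpy as np
import pytest

from duplexkit import synth
from duplexkit.errors import (
    EmptySignalError,
    FormatError,
    InputError,
    InsufficientDataError,
)
from duplexkit.excision import (
    ExcisionTimecourse,
    efficiency_ratio,
    normalize_timecourse,
    replicate_sd,
)


def _tc(times, intensities, substrate="s", rep="1"):
    return ExcisionTimecourse(
        substrate=substrate,
        times=np.asarray(times, float),
        intensities=np.asarray(intensities, float),
        replicate_id=rep,
    )


class TestTimecourse:
    def test_missing_time_zero_rejected(self):
        with pytest.raises(FormatError):
            _tc([5.0, 10.0], [1.0, 2.0])

    def test_negative_intensity_rejected(self):
        with pytest.raises(FormatError):
            _tc([0.0, 5.0], [1.0, -2.0])


class TestNormalize:
    def test_zero_background_identity(self):
        tc = normalize_timecourse(_tc([0, 10, 20], [0.0, 0.5, 1.0]))
        np.testing.assert_allclose(tc.intensities, [0.0, 0.5, 1.0])

    def test_subtraction_and_rescale(self):
        tc = _tc([0, 10, 20], [10.0, 30.0, 50.0])
        out = normalize_timecourse(tc)
        np.testing.assert_allclose(out.intensities, [0.0, 20.0, 40.0])
        out2 = normalize_timecourse(tc, rescale=True)
        np.testing.assert_allclose(out2.intensities, [0.0, 0.5, 1.0])

    def test_constant_series_is_empty_signal(self):
        with pytest.raises(EmptySignalError):
            normalize_timecourse(_tc([0, 10, 20], [10.0, 10.0, 10.0]))

    def test_below_background_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            out = normalize_timecourse(_tc([0, 10, 20], [10.0, 8.0, 30.0]))
        np.testing.assert_allclose(out.intensities, [0.0, 0.0, 20.0])


class TestEfficiencyRatio:
    def _normalized_pair(self, num_scale=1.0):
        times = [0, 10, 20, 30]
        base = [0.0, 20.0, 40.0, 60.0]
        num = [normalize_timecourse(_tc(times, [num_scale * b for b in base],
                                        "num", str(i))) for i in range(2)]
        den = [normalize_timecourse(_tc(times, base, "den", str(i)))
               for i in range(2)]
        return num, den

    def test_identical_courses_give_unit_ratios(self):
        num, den = self._normalized_pair(1.0)
        result = efficiency_ratio(num, den, n_boot=100, seed=0)
        np.testing.assert_allclose(result.ratio_per_time, 1.0)
        assert result.summary_ratio == 1.0

    def test_unnormalized_input_rejected(self):
        num, den = self._normalized_pair()
        with pytest.raises(InputError):
            efficiency_ratio([_tc([0, 10, 20, 30], [0, 1, 2, 3])], den)

    def test_time_zero_excluded(self):
        num, den = self._normalized_pair(2.0)
        result = efficiency_ratio(num, den, n_boot=100, seed=0)
        assert 0.0 not in result.times

    def test_swap_inverts_every_ratio_exactly(self):
        courses, _ = synth.gen_excision_timecourses(
            synth.GeneratorConfig(seed=3)
        )
        num = [normalize_timecourse(tc) for tc in courses["nFluS"]]
        den = [normalize_timecourse(tc) for tc in courses["nFluL"]]
        fwd = efficiency_ratio(num, den, n_boot=50, seed=0)
        rev = efficiency_ratio(den, num, n_boot=50, seed=0)
        np.testing.assert_allclose(fwd.ratio_per_time * rev.ratio_per_time, 1.0,
                                   rtol=1e-12)

    def test_zero_denominator_rejected(self):
        times = [0, 10, 20]
        num = [normalize_timecourse(_tc(times, [0.0, 1.0, 2.0], "num"))]
        den_raw = _tc(times, [5.0, 5.0, 6.0], "den")
        den = [normalize_timecourse(den_raw)]
        # only t=20 is non-zero in the denominator -> that point remains
        result = efficiency_ratio(num, den, n_boot=50, seed=0)
        assert result.times.tolist() == [20.0]
        # disjoint grids -> no common points at all
        num2 = [normalize_timecourse(_tc([0, 7, 13], [0.0, 1.0, 2.0], "num"))]
        with pytest.raises(InputError):
            efficiency_ratio(num2, den, n_boot=50, seed=0)

    def test_bootstrap_is_seed_reproducible(self):
        courses, _ = synth.gen_excision_timecourses(synth.GeneratorConfig(seed=5))
        num = [normalize_timecourse(tc) for tc in courses["nFluS"]]
        den = [normalize_timecourse(tc) for tc in courses["nFluL"]]
        a = efficiency_ratio(num, den, n_boot=500, seed=42)
        b = efficiency_ratio(num, den, n_boot=500, seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_interval_stabilizes_with_more_draws(self):
        courses, _ = synth.gen_excision_timecourses(synth.GeneratorConfig(seed=8))
        num = [normalize_timecourse(tc) for tc in courses["nFluS"]]
        den = [normalize_timecourse(tc) for tc in courses["nFluL"]]
        small = efficiency_ratio(num, den, n_boot=2000, seed=1)
        large = efficiency_ratio(num, den, n_boot=10000, seed=1)
        w_small = small.ci_high - small.ci_low
        w_large = large.ci_high - large.ci_low
        assert abs(w_large - w_small) / w_small < 0.05

    def test_summary_within_per_time_range(self):
        courses, _ = synth.gen_excision_timecourses(synth.GeneratorConfig(seed=2))
        num = [normalize_timecourse(tc) for tc in courses["nFluS"]]
        den = [normalize_timecourse(tc) for tc in courses["nFluL"]]
        r = efficiency_ratio(num, den, n_boot=50, seed=0)
        assert r.ratio_per_time.min() <= r.summary_ratio <= r.ratio_per_time.max()

    def test_summary_ratio_matches_study_band(self):
        """Rate-ratio-2 courses over the sampled window show per-time signal
        ratios of ~1.5-2 and a summary inside [1.5, 2.5] in >=95% of runs."""
        hits = 0
        n_runs = 30
        for seed in range(n_runs):
            courses, _ = synth.gen_excision_timecourses(
                synth.GeneratorConfig(seed=seed)
            )
            num = [normalize_timecourse(tc) for tc in courses["nFluS"]]
            den = [normalize_timecourse(tc) for tc in courses["nFluL"]]
            r = efficiency_ratio(num, den, n_boot=200, seed=seed)
            if 1.5 <= r.summary_ratio <= 2.5:
                hits += 1
        assert hits / n_runs >= 0.95

    def test_noiseless_equal_rates_give_unit_ratio(self):
        times = np.array([0.0, 10.0, 20.0, 40.0])
        k = 0.05
        signal = 100.0 * (1.0 - np.exp(-k * times))
        num = [normalize_timecourse(_tc(times, signal, "a"))]
        den = [normalize_timecourse(_tc(times, signal, "b"))]
        r = efficiency_ratio(num, den, n_boot=50, seed=0)
        np.testing.assert_allclose(r.ratio_per_time, 1.0, rtol=1e-12)

    def test_noiseless_rate_ratio_closed_form(self):
        """With k_num = 2*k_den and equal plateaus, the per-time signal
        ratio is exactly 1 + exp(-k_den * t): near 2 early, toward 1 late."""
        times = np.array([0.0, 5.0, 20.0, 60.0, 200.0])
        k = 0.0116
        num_sig = 100.0 * (1.0 - np.exp(-2 * k * times))
        den_sig = 100.0 * (1.0 - np.exp(-k * times))
        num = [normalize_timecourse(_tc(times, num_sig, "a"))]
        den = [normalize_timecourse(_tc(times, den_sig, "b"))]
        r = efficiency_ratio(num, den, n_boot=50, seed=0)
        np.testing.assert_allclose(
            r.ratio_per_time, 1.0 + np.exp(-k * times[1:]), rtol=1e-12
        )
        assert r.ratio_per_time[0] > 1.9
        assert r.ratio_per_time[-1] < 1.1


class TestReplicateSD:
    def test_constant_data_is_zero(self):
        assert replicate_sd([3.0, 3.0, 3.0]) == 0.0

    def test_hand_computed_values(self):
        assert replicate_sd([1.0, 2.0, 3.0]) == pytest.approx(1.0)
        assert replicate_sd([0.0, 2.0]) == pytest.approx(math.sqrt(2.0))

    def test_single_value_rejected(self):
        with pytest.raises(InsufficientDataError):
            replicate_sd([1.0])
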