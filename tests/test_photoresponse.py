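import numpy as np
import pytest

import chronoluc as cl
from chronoluc.errors import AnalysisError
from conftest import make_traceset


def pulse_trace(levels, dt=0.25):
    t = np.arange(len(levels)) * dt
    return t, np.asarray(levels, dtype=float)


class TestAcuteSensitivity:
    def test_no_response_gives_zero(self):
        t, y = pulse_trace([100.0] * 20)
        assert cl.acute_sensitivity(t, y, pulse_start_h=1.0) == 0.0

    def test_drop_to_40_gives_60(self):
        y = [100.0] * 5 + [80.0, 60.0, 40.0, 55.0, 70.0] + [80.0] * 10
        t, y = pulse_trace(y)
        assert cl.acute_sensitivity(t, y, pulse_start_h=1.0) == pytest.approx(60.0)

    def test_rise_after_pulse_clamped_to_zero(self):
        y = [100.0] * 5 + [110.0, 120.0, 115.0] + [120.0] * 12
        t, y = pulse_trace(y)
        assert cl.acute_sensitivity(t, y, pulse_start_h=1.0) == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        y = 50.0 + rng.uniform(0, 30, 30)
        t = np.arange(30) * 0.25
        s1 = cl.acute_sensitivity(t, y, 2.0)
        s2 = cl.acute_sensitivity(t, 17.3 * y, 2.0)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_window_past_record_end_rejected(self):
        t, y = pulse_trace([100.0] * 8)
        with pytest.raises(AnalysisError, match="past"):
            cl.acute_sensitivity(t, y, pulse_start_h=1.0, search_window_h=5.0)

    def test_sensitivity_monotone_in_degradation_rate(self, wt):
        reg = cl.pulse_protocol(3.0, 5 / 60, 660, 0.5, 3.0)
        sens = []
        for dmax in (0.0, 5.0, 15.0, 25.0, 60.0):
            t, y = cl.simulate_roc15_trace(wt.with_(delta_max=dmax), reg, 0.25)
            sens.append(cl.acute_sensitivity(t, y, 3.0))
        assert all(a <= b + 1e-9 for a, b in zip(sens, sens[1:]))


class TestAcuteResponseLevel:
    def test_flat_trace_stays_100(self):
        t, y = pulse_trace([50.0] * 40)
        assert cl.acute_response_level(t, y, 2.0, 6.0) == pytest.approx(100.0)

    def test_fall_to_20_percent(self):
        y = [50.0] * 10 + [10.0] * 30
        t, y = pulse_trace(y)
        assert cl.acute_response_level(t, y, 2.0, 6.0) == pytest.approx(20.0)

    def test_shorter_window_can_miss_the_minimum(self):
        y = [100.0] * 10 + list(np.linspace(95, 30, 30))
        t, y = pulse_trace(y)
        full = cl.acute_response_level(t, y, 2.0, 7.0)
        early = cl.acute_response_level(t, y, 2.0, 2.0)
        assert early > full


class TestComplementationCall:
    @pytest.mark.parametrize(
        "level,expected", [(25.0, True), (29.9, True), (30.0, False), (100.0, False)]
    )
    def test_strict_threshold_at_30(self, level, expected):
        assert cl.complementation_call(level) is expected


class TestActionSpectrum:
    def _plate(self, strain, noise=0.0, n_rep=3, seed=0):
        wells = []
        for lam in cl.DEFAULT_WAVELENGTHS:
            reg = cl.pulse_protocol(3.0, 5 / 60, lam, 0.5, 3.0)
            for r in range(n_rep):
                wells.append(cl.WellSpec(f"{strain.name}-{lam}-{r}", strain, reg, r))
        design = cl.PlateDesign(tuple(wells), 1 / 3, noise, 0.0, 1.0, seed)
        return cl.simulate_plate(design)

    def test_dark_control_wells_give_zero_spectrum(self, wt):
        reg = cl.constant_darkness(6.5)
        wells = tuple(cl.WellSpec(f"d{r}", wt, reg, r) for r in range(3))
        ts = cl.simulate_plate(cl.PlateDesign(wells, 1 / 3))
        spec = cl.build_action_spectrum(ts, 3.0, 2.0)
        assert spec.wavelengths_nm == ("dark",)
        assert spec.sensitivity[0] == pytest.approx(0.0, abs=1e-6)

    def test_wt_spectrum_peaks_at_660(self, wt):
        spec = cl.build_action_spectrum(self._plate(wt), 3.0, 2.0)
        best = spec.wavelengths_nm[int(np.argmax(spec.sensitivity))]
        assert best == 660

    def test_csl_red_response_below_10pct_of_wt(self, wt, csl):
        swt = cl.build_action_spectrum(self._plate(wt), 3.0, 2.0)
        scsl = cl.build_action_spectrum(self._plate(csl), 3.0, 2.0)
        assert scsl.at(660) < 0.1 * swt.at(660)

    def test_missing_wavelength_annotation_rejected(self):
        t = np.arange(0, 6.25, 0.25)
        ts = make_traceset(t, {"w": np.full(t.size, 50.0)})
        with pytest.raises(AnalysisError, match="wavelength"):
            cl.build_action_spectrum(ts, 3.0, 2.0)


class TestDifferenceSpectrum:
    def _spec(self, values, sd=None, n=4):
        lams = tuple(cl.DEFAULT_WAVELENGTHS[: len(values)])
        sd = sd or tuple(0.0 for _ in values)
        return cl.SensitivitySpectrum(lams, tuple(values), tuple(sd), tuple(n for _ in values), {})

    def test_identical_spectra_give_zeros(self):
        a = self._spec([30, 40, 50])
        out = cl.pathway_difference_spectrum(a, a)
        assert out.sensitivity == (0.0, 0.0, 0.0)

    def test_negative_differences_clamped_to_zero(self):
        wt = self._spec([30.0])
        mut = self._spec([35.0])
        assert cl.pathway_difference_spectrum(wt, mut).sensitivity == (0.0,)

    def test_hand_arithmetic(self):
        wt = self._spec([80.0])
        mut = self._spec([5.0])
        assert cl.pathway_difference_spectrum(wt, mut).sensitivity == (75.0,)

    def test_sd_combines_in_quadrature_and_n_is_min(self):
        wt = cl.SensitivitySpectrum((660,), (80.0,), (3.0,), (6,), {})
        mut = cl.SensitivitySpectrum((660,), (5.0,), (4.0,), (4,), {})
        out = cl.pathway_difference_spectrum(wt, mut)
        assert out.sd[0] == pytest.approx(5.0)
        assert out.n[0] == 4

    def test_grid_mismatch_rejected(self):
        with pytest.raises(AnalysisError, match="grids differ"):
            cl.pathway_difference_spectrum(self._spec([1, 2]), self._spec([1, 2, 3]))

    def test_difference_bounded_by_wild_type(self, wt, csl):
        plate = TestActionSpectrum()
        swt = cl.build_action_spectrum(plate._plate(wt, 0.05, 3, 2), 3.0, 2.0)
        scsl = cl.build_action_spectrum(plate._plate(csl, 0.05, 3, 3), 3.0, 2.0)
        diff = cl.pathway_difference_spectrum(swt, scsl)
        assert all(0.0 <= d <= w + 1e-9 for d, w in zip(diff.sensitivity, swt.sensitivity))
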