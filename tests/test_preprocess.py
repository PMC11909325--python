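"""Correction pipeline: referencing, report points, blanks, solvent curve."""

import numpy as np
import pytest

from ndscreen import (
    ReportPoint,
    Sensorgram,
    apply_solvent_correction,
    blank_correct,
    default_report_window,
    extract_report_point,
    fit_solvent_correction,
    reference_subtract,
)
from ndscreen.exceptions import (
    AlignmentError,
    ConfigError,
    FitError,
    ValidationError,
)


def make_trace(level=0.0, pulse=0.0, baseline=10.0, contact=20.0, diss=40.0,
               dt=0.5, cycle=1, channel="ch2", tail=5.0):
    """Square-pulse sensorgram: `level` everywhere, +`pulse` during injection."""
    t = np.arange(0.0, baseline + contact + diss + tail + dt / 2, dt)
    r = np.full_like(t, level)
    inj = (t >= baseline) & (t < baseline + contact)
    r[inj] += pulse
    return Sensorgram(cycle, channel, t, r, baseline, baseline + contact,
                      baseline + contact + diss)


class TestReferenceSubtract:
    def test_self_subtraction_is_zero(self):
        sg = make_trace(level=3.0, pulse=7.0)
        out = reference_subtract(sg, sg)
        assert np.all(out.response == 0.0)

    def test_zero_reference_leaves_active(self):
        active = make_trace(pulse=10.0)
        ref = make_trace(pulse=0.0, channel="ch1")
        out = reference_subtract(active, ref)
        np.testing.assert_array_equal(out.response, active.response)

    def test_square_pulse_difference(self):
        active = make_trace(pulse=10.0)
        ref = make_trace(pulse=4.0, channel="ch1")
        out = reference_subtract(active, ref)
        rp = extract_report_point(out, (15.0, 19.0))
        assert rp.value == pytest.approx(6.0, abs=1e-12)

    def test_interpolates_mismatched_grids(self):
        active = make_trace(pulse=10.0, dt=0.5)
        ref = make_trace(pulse=4.0, dt=0.7, channel="ch1")
        out = reference_subtract(active, ref)
        assert out.time.size == active.time.size
        rp = extract_report_point(out, (15.0, 19.0))
        assert rp.value == pytest.approx(6.0, abs=1e-9)

    def test_mismatched_cycles_rejected(self):
        with pytest.raises(AlignmentError):
            reference_subtract(make_trace(cycle=1), make_trace(cycle=2))

    def test_disjoint_spans_rejected(self):
        active = make_trace()
        ref = Sensorgram(1, "ch1", active.time + 1000.0, active.response,
                         1010.0, 1030.0, 1070.0)
        with pytest.raises(AlignmentError):
            reference_subtract(active, ref)

    def test_linearity_of_correction(self):
        # subtracting then reading is linear in the trace
        a = make_trace(pulse=5.0, level=1.0)
        b = make_trace(pulse=3.0, level=-0.5)
        ref = make_trace(pulse=2.0, channel="ch1")
        summed = Sensorgram(1, "ch2", a.time, a.response + b.response,
                            a.t_inject_start, a.t_inject_end, a.t_diss_end)
        rp_sum = extract_report_point(reference_subtract(summed, ref),
                                      (15.0, 19.0))
        rp_a = extract_report_point(reference_subtract(a, ref), (15.0, 19.0))
        rp_b = extract_report_point(reference_subtract(b, ref), (15.0, 19.0))
        # the shared reference is subtracted twice on the left, once each on
        # the right; correct for it to state strict additivity of the reads
        assert rp_sum.value == pytest.approx(rp_a.value + rp_b.value + 2.0,
                                             abs=1e-12)


class TestReportPoint:
    def test_plateau_minus_zero_baseline(self):
        sg = make_trace(pulse=10.0)
        assert extract_report_point(sg, (15.0, 19.0)).value == pytest.approx(
            10.0)

    def test_baseline_anchoring(self):
        sg = make_trace(level=2.0, pulse=10.0)
        assert extract_report_point(sg, (15.0, 19.0)).value == pytest.approx(
            10.0)

    def test_default_window_geometry(self):
        assert default_report_window(20.0) == (15.0, 19.0)

    def test_window_outside_contact_rejected(self):
        sg = make_trace(contact=20.0)
        with pytest.raises(ValidationError):
            extract_report_point(sg, (18.0, 25.0))

    def test_noise_averages_down(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(40):
            sg = make_trace()
            sg.response = sg.response + rng.normal(0, 0.1, sg.response.size)
            if abs(extract_report_point(sg, (15.0, 19.0)).value) < 0.1:
                hits += 1
        assert hits >= 36  # ~95% of seeds under the SEM bound


class TestBlankCorrect:
    def _rp(self, cycle, value):
        return ReportPoint(cycle, "ch2", value, (15.0, 19.0))

    def test_zero_blanks_change_nothing(self):
        samples = [self._rp(2, 5.0), self._rp(3, -1.0)]
        out = blank_correct(samples, [self._rp(1, 0.0), self._rp(4, 0.0)])
        assert [rp.value for rp in out] == [5.0, -1.0]

    def test_linear_interpolation_midpoint(self):
        out = blank_correct([self._rp(6, 10.0)],
                            [self._rp(1, 2.0), self._rp(11, 4.0)])
        assert out[0].value == pytest.approx(10.0 - 3.0)

    def test_single_blank_subtracts_constant(self):
        out = blank_correct([self._rp(2, 5.0), self._rp(9, 1.0)],
                            [self._rp(5, 2.0)])
        assert [rp.value for rp in out] == [3.0, -1.0]

    def test_no_blanks_is_config_error(self):
        with pytest.raises(ConfigError):
            blank_correct([self._rp(1, 1.0)], [])


class TestSolventCorrection:
    def test_recovers_known_quadratic(self):
        x = np.array([-2.0, -1.0, 0.5, 1.5, 3.0])
        y = 0.3 * x ** 2 - 1.1 * x + 0.25
        curve = fit_solvent_correction(list(zip(x, y)))
        assert curve.coefficients == pytest.approx((0.3, -1.1, 0.25),
                                                   abs=1e-9)
        assert curve.residual_norm < 1e-9

    def test_zero_ordinates_give_zero_curve(self):
        pts = [(x, 0.0) for x in (-2.0, -1.0, 0.0, 1.0, 2.0)]
        curve = fit_solvent_correction(pts)
        assert curve(1.7) == pytest.approx(0.0, abs=1e-12)

    def test_collinear_points_nested_linear(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        curve = fit_solvent_correction(list(zip(x, 2.0 * x + 1.0)))
        assert curve.coefficients[0] == pytest.approx(0.0, abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_solvent_correction([(0.0, 0.0)] * 4)

    def test_duplicate_abscissae_rejected(self):
        with pytest.raises(FitError):
            fit_solvent_correction([(1.0, 0.0), (1.0, 1.0), (2.0, 0.0),
                                    (3.0, 0.0), (3.0, 1.0)])

    def test_apply_identity_curve(self):
        curve = fit_solvent_correction(
            [(x, x) for x in (-2.0, -1.0, 0.0, 1.0, 2.0)])
        rp = ReportPoint(1, "ch2", 10.0, (15.0, 19.0))
        assert apply_solvent_correction(rp, curve, 1.5).value == \
            pytest.approx(8.5, abs=1e-10)

    def test_out_of_range_warns_and_extrapolates(self):
        curve = fit_solvent_correction(
            [(x, x) for x in (-2.0, -1.0, 0.0, 1.0, 2.0)])
        rp = ReportPoint(1, "ch2", 10.0, (15.0, 19.0))
        with pytest.warns(UserWarning, match="outside calibration range"):
            out = apply_solvent_correction(rp, curve, 5.0)
        assert out.value == pytest.approx(5.0, abs=1e-9)
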