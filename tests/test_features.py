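"""Stance feature extraction and the normality screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from footstrike import (
    ForceTrace,
    InputError,
    StanceWindow,
    extract_features,
    impulse,
    normality_screen,
    segment_stance,
    synthesize_trace,
)
from footstrike.errors import DegenerateStanceError
from footstrike.features import FEATURE_COLUMNS
from footstrike.simulate import pulse_integral

from _reference import CLASS_FEATURE_STATS, CLASS_FSA


def make_trace(fore, aft, fs=100.0):
    fore = np.asarray(fore, dtype=float)
    aft = np.asarray(aft, dtype=float)
    t = np.arange(fore.size) / fs
    return ForceTrace(t, fore, aft, fore + aft)


class TestImpulse:
    def test_rectangle(self):
        """Constant 50 N over 0.2 s integrates to 10 N*s."""
        trace = make_trace(np.full(30, 25.0), np.full(30, 25.0))
        assert impulse(trace, StanceWindow(4, 24), "total") == pytest.approx(10.0)

    def test_triangle(self):
        """A linear ramp 0 -> 100 N over 0.1 s integrates to 5 N*s."""
        ramp = np.linspace(0.0, 100.0, 11)
        trace = make_trace(ramp, np.zeros(11))
        assert impulse(trace, StanceWindow(0, 10), "fore") == pytest.approx(5.0)

    def test_raised_cosine_matches_closed_form(self):
        """Trapezoidal integration agrees with the analytic pulse integral."""
        u = np.linspace(0.0, 1.0, 101)  # 1 s stance at 100 Hz
        amp, c, w = 300.0, 0.5, 0.35
        arg = (u - c) / w
        pulse = np.where(np.abs(arg) <= 1, 0.5 * amp * (1 + np.cos(np.pi * arg)), 0.0)
        trace = make_trace(pulse, np.zeros_like(pulse))
        got = impulse(trace, StanceWindow(0, 100), "fore")
        assert got == pytest.approx(pulse_integral(amp, w), rel=1e-3)

    def test_empty_window_rejected(self):
        trace = make_trace(np.ones(10), np.ones(10))
        with pytest.raises(InputError):
            impulse(trace, StanceWindow(3, 12), "total")


class TestExtractFeatures:
    def test_identical_sensors_are_symmetric(self):
        y = np.concatenate([[0, 0], 100 * np.sin(np.linspace(0, np.pi, 26)) ** 2, [0, 0]])
        trace = make_trace(y, y)
        fv = extract_features(trace, StanceWindow(2, 27))
        assert fv.ir_fore == pytest.approx(0.5)
        assert fv.ir_aft == pytest.approx(0.5)
        assert fv.pf_fore == pytest.approx(fv.pf_aft)
        assert fv.rfd_fore == pytest.approx(fv.rfd_aft)
        assert fv.ln_pct_rfd_fore == pytest.approx(fv.ln_pct_rfd_aft)

    def test_silent_aft_sensor(self):
        y = np.concatenate([[0, 0], 100 * np.sin(np.linspace(0, np.pi, 26)) ** 2, [0, 0]])
        fv = extract_features(make_trace(y, np.zeros_like(y)), StanceWindow(2, 27))
        assert fv.ir_fore == pytest.approx(1.0)
        assert fv.ir_aft == pytest.approx(0.0)
        assert fv.pf_aft == pytest.approx(0.0)

    @settings(max_examples=25, derandomize=True)
    @given(k=st.floats(min_value=1e-3, max_value=1e3),
           fsa=st.floats(min_value=-25.0, max_value=35.0))
    def test_scale_invariance(self, quiet_cfg, k, fsa):
        """Multiplying both sensors by k > 0 leaves every feature unchanged."""
        trace, _ = synthesize_trace(fsa, quiet_cfg)
        w = segment_stance(trace)
        scaled = ForceTrace(trace.time, k * trace.force_fore, k * trace.force_aft,
                            k * trace.force_total)
        a = extract_features(trace, w).as_array()
        b = extract_features(scaled, w).as_array()
        np.testing.assert_allclose(a, b, rtol=1e-9)

    @pytest.mark.parametrize("fsa", [-18.0, -3.0, 5.0, 14.0, 31.0])
    def test_impulse_ratio_complementarity(self, sim_cfg, fsa):
        trace, _ = synthesize_trace(fsa, sim_cfg)
        fv = extract_features(trace, segment_stance(trace))
        assert fv.ir_fore + fv.ir_aft == pytest.approx(1.0, abs=1e-12)
        assert fv.ir_fore_0_33 + fv.ir_aft_0_33 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("label", ["FF", "MF", "RF"])
    def test_class_mean_envelope(self, quiet_cfg, label):
        """A noiseless step at each class-mean FSA lands inside the published
        mean +/- 2 SD envelope for all ten variables."""
        fsa = CLASS_FSA[label][0]
        trace, _ = synthesize_trace(fsa, quiet_cfg)
        fv = extract_features(trace, segment_stance(trace)).as_dict()
        for key in FEATURE_COLUMNS:
            mean, sd = CLASS_FEATURE_STATS[label][key]
            assert mean - 2 * sd <= fv[key] <= mean + 2 * sd, (
                f"{label}/{key}: {fv[key]:.3f} outside {mean}±{2 * sd:.3f}"
            )

    def test_zero_stance_is_degenerate(self):
        trace = make_trace(np.zeros(30), np.zeros(30))
        with pytest.raises(DegenerateStanceError):
            extract_features(trace, StanceWindow(5, 25))


class TestNormalityScreen:
    def test_gaussian_columns_pass(self, rng):
        table = pd.DataFrame(rng.standard_normal((5000, 3)),
                             columns=["ir_fore", "ir_aft", "pf_fore"])
        report = normality_screen(table, columns=("ir_fore", "ir_aft", "pf_fore"))
        assert report.flagged == []

    def test_exponential_column_flagged(self, rng):
        """Exp(1) skewness z is far beyond the 2.58 critical value at n=2000."""
        table = pd.DataFrame({
            "ir_fore": rng.standard_normal(2000),
            "rfd_aft": rng.exponential(1.0, 2000),
        })
        report = normality_screen(table, columns=("ir_fore", "rfd_aft"))
        assert report.flagged == ["rfd_aft"]
        assert report.skew_z["rfd_aft"] > 2.58

    def test_constant_column_flagged(self):
        table = pd.DataFrame({"ir_fore": np.ones(100)})
        report = normality_screen(table, columns=("ir_fore",))
        assert report.flagged == ["ir_fore"]
        assert np.isnan(report.skew_z["ir_fore"])

    def test_too_few_rows_rejected(self):
        with pytest.raises(InputError):
            normality_screen(pd.DataFrame({"ir_fore": np.ones(4)}))
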