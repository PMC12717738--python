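"""Interval arithmetic, QTc formulas, voltages, low-voltage rule."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tripecg.ecg_io import LEADS
from tripecg.fiducials import FiducialSet
from tripecg.measures import (
    MeasureError,
    low_voltage_flag,
    measure_intervals,
    qtc,
    round_half_away,
    sokolow,
    wave_amplitudes,
)
from tripecg.representative import RepresentativeBeat


FIDS = FiducialSet(p_onset_ms=240.0, qrs_onset_ms=400.0,
                   qrs_offset_ms=490.0, t_offset_ms=780.0)


class TestIntervals:
    def test_worked_example(self):
        out = measure_intervals(FIDS, mean_rr=800.0)
        assert out["pr_ms"] == 160.0
        assert out["qrs_ms"] == 90.0
        assert out["qt_ms"] == 380.0
        assert out["hr_bpm"] == pytest.approx(75.0)

    def test_absent_p_gives_absent_pr(self):
        fids = FiducialSet(qrs_onset_ms=400.0, qrs_offset_ms=490.0,
                           t_offset_ms=780.0)
        out = measure_intervals(fids, mean_rr=1000.0)
        assert out["pr_ms"] is None
        assert out["qrs_ms"] == 90.0
        assert out["hr_bpm"] == pytest.approx(60.0)

    def test_invalid_mean_rr(self):
        with pytest.raises(MeasureError):
            measure_intervals(FIDS, mean_rr=0.0)


class TestQtc:
    @pytest.mark.parametrize("formula", ["fridericia", "bazett"])
    def test_identity_at_rr_1000(self, formula):
        assert qtc(400.0, 1000.0, formula) == pytest.approx(400.0)

    def test_fridericia_cube_root(self):
        assert qtc(350.0, 512.0, "fridericia") == pytest.approx(437.5)

    def test_bazett_square_root(self):
        assert qtc(400.0, 640.0, "bazett") == pytest.approx(500.0)

    def test_exponent_ordering_over_grid(self):
        for rr in np.arange(400.0, 1600.0, 50.0):
            f, b = qtc(400.0, rr, "fridericia"), qtc(400.0, rr, "bazett")
            if rr < 1000:
                assert f <= b
            elif rr > 1000:
                assert f >= b

    def test_invalid_inputs(self):
        with pytest.raises(MeasureError):
            qtc(0.0, 1000.0)
        with pytest.raises(MeasureError):
            qtc(400.0, -5.0)
        with pytest.raises(MeasureError):
            qtc(400.0, 1000.0, "hodges")


def _rep_from(data):
    return RepresentativeBeat(data=data, sampling_rate=1000.0,
                              r_offset_ms=400.0, n_beats=10, mean_rr_ms=1000.0)


class TestWaveAmplitudes:
    def test_r_wave_above_baseline(self, base_template):
        t_rel = np.arange(-400, 800, dtype=float)
        rep = _rep_from(base_template.waveform(t_rel))
        fids = FiducialSet(qrs_onset_ms=400 + base_template.qrs_onset_ms,
                           qrs_offset_ms=400 + base_template.qrs_offset_ms)
        amps = wave_amplitudes(rep, fids)
        v5 = LEADS.index("V5")
        assert amps["r_amp"]["V5"] == pytest.approx(
            base_template.r_amp_true_uv[v5], abs=10)

    def test_monophasic_qs_has_zero_r(self):
        data = np.zeros((12, 1200))
        t = np.arange(1200, dtype=float)
        qs = -800.0 * np.exp(-0.5 * ((t - 400) / 10.0) ** 2)
        data[LEADS.index("V1")] = qs
        rep = _rep_from(data)
        fids = FiducialSet(qrs_onset_ms=360.0, qrs_offset_ms=450.0)
        amps = wave_amplitudes(rep, fids)
        assert amps["s_amp"]["V1"] == pytest.approx(800.0, abs=1)
        assert amps["r_amp"]["V1"] == 0.0

    def test_all_zero_lead(self):
        rep = _rep_from(np.zeros((12, 1200)))
        fids = FiducialSet(qrs_onset_ms=360.0, qrs_offset_ms=450.0)
        amps = wave_amplitudes(rep, fids)
        assert amps["r_amp"]["II"] == 0.0
        assert amps["s_amp"]["II"] == 0.0
        assert amps["peak_to_peak"]["II"] == 0.0


class TestSokolow:
    def test_formula(self):
        amps = {"r_amp": {"V5": 1400.0, "V6": 1000.0},
                "s_amp": {"V1": 800.0}}
        assert sokolow(amps) == (2200.0, 1800.0)

    def test_zero_s_reduces_to_r(self):
        amps = {"r_amp": {"V5": 1400.0, "V6": 1000.0}, "s_amp": {"V1": 0.0}}
        assert sokolow(amps)[0] == 1400.0

    def test_missing_lead(self):
        with pytest.raises(MeasureError):
            sokolow({"r_amp": {"V5": 1.0}, "s_amp": {}})


class TestLowVoltage:
    def _p2p(self, frontal, precordial):
        out = {l: frontal for l in LEADS[:6]}
        out.update({l: precordial for l in LEADS[6:]})
        return out

    def test_frontal_branch(self):
        assert low_voltage_flag(self._p2p(400.0, 1200.0)) is True

    def test_both_branches_fail(self):
        p2p = self._p2p(400.0, 1100.0)
        p2p["II"] = 600.0  # one frontal lead above 500
        assert low_voltage_flag(p2p) is False

    def test_degenerate_all_zero(self):
        assert low_voltage_flag(self._p2p(0.0, 0.0)) is True

    @pytest.mark.parametrize("frontal,precordial,expected", [
        (500.0, 1200.0, True),    # frontal boundary inclusive
        (500.001, 1200.0, False),
        (600.0, 1000.0, True),    # precordial boundary inclusive
        (600.0, 1000.001, False),
    ])
    def test_exact_boundaries(self, frontal, precordial, expected):
        assert low_voltage_flag(self._p2p(frontal, precordial)) is expected

    def test_missing_lead(self):
        p2p = self._p2p(400.0, 900.0)
        del p2p["V4"]
        with pytest.raises(MeasureError, match="V4"):
            low_voltage_flag(p2p)


@pytest.mark.parametrize("x,d,expected", [
    (0.5, 0, 1.0), (1.5, 0, 2.0), (2.5, 0, 3.0),   # ties away from zero
    (-0.5, 0, -1.0), (-2.5, 0, -3.0),
    (0.25, 1, 0.3), (-0.25, 1, -0.3),              # exact binary ties
    (437.2, 0, 437.0), (379.04, 1, 379.0),
])
def test_round_half_away_from_zero(x, d, expected):
    assert round_half_away(x, d) == expected


@given(st.floats(-1e6, 1e6, allow_nan=False), st.integers(0, 3))
def test_round_half_away_is_within_half_step_and_odd_symmetric(x, d):
    step = 10.0**-d
    assert abs(round_half_away(x, d) - x) <= step / 2 + 1e-9 * abs(x)
    assert round_half_away(-x, d) == -round_half_away(x, d)
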