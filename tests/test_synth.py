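"""Generator contracts: exact intervals, determinism, PVC bookkeeping."""

import numpy as np
import pytest

from tripecg.ecg_io import LEADS
from tripecg.synth import (
    DEFAULT_AMPLITUDES,
    NoiseSpec,
    SynthError,
    inject_pvc,
    make_template,
    random_template,
    synth_record,
    synth_triplicate,
)


class TestMakeTemplate:
    def test_requested_intervals_are_exact(self):
        tpl = make_template(pr=160, qrs=90, qt=380)
        assert tpl.qrs_onset_ms - tpl.p_onset_ms == pytest.approx(160)
        assert tpl.qrs_offset_ms - tpl.qrs_onset_ms == pytest.approx(90)
        assert tpl.t_offset_ms - tpl.qrs_onset_ms == pytest.approx(380)

    def test_fiducial_ordering_invariant(self, rng):
        for _ in range(20):
            tpl = random_template(rng)
            assert (tpl.p_onset_ms < tpl.qrs_onset_ms < 0
                    < tpl.qrs_offset_ms < tpl.t_offset_ms)

    def test_requested_sokolow_voltages(self):
        amps = {k: list(v) for k, v in DEFAULT_AMPLITUDES.items()}
        amps["S"][LEADS.index("V1")] = -800
        amps["R"][LEADS.index("V5")] = 1400
        tpl = make_template(pr=160, qrs=90, qt=380, lead_amplitudes=amps)
        # numeric truth includes small inter-lobe overlap corrections
        assert tpl.soko_v5_true_uv == pytest.approx(2200, abs=10)

    def test_infeasible_intervals_rejected(self):
        with pytest.raises(SynthError):
            make_template(pr=160, qrs=90, qt=80)  # qt <= qrs
        with pytest.raises(SynthError):
            make_template(pr=60, qrs=90, qt=380)  # pr below range
        with pytest.raises(SynthError):
            make_template(pr=160, qrs=300, qt=380)  # qrs above range

    def test_wave_mass_inside_labelled_segment(self):
        """>= 99% of each QRS lobe's area lies inside [qrs_onset, qrs_offset]."""
        tpl = make_template(pr=160, qrs=90, qt=380)
        t = np.arange(-300.0, 500.0, 0.05)
        for w in tpl.waves:
            if w.name not in ("Q", "R", "S"):
                continue
            shape = w.shape(t)
            inside = (t >= tpl.qrs_onset_ms) & (t <= tpl.qrs_offset_ms)
            assert shape[inside].sum() / shape.sum() >= 0.99


class TestSynthRecord:
    def test_jitterless_beat_train_is_regular(self, base_template):
        _, truth = synth_record(base_template, duration_s=10, mean_rr=1000, seed=0)
        assert len(truth.r_peak_times_ms) == 10
        assert np.all(np.diff(truth.r_peak_times_ms) == 1000.0)

    def test_same_seed_is_bit_identical(self, base_template):
        noise = NoiseSpec(baseline_wander_uv=30, mains_uv=10, broadband_sd_uv=15)
        r1, t1 = synth_record(base_template, noise=noise, rr_jitter_sd=20, seed=42)
        r2, t2 = synth_record(base_template, noise=noise, rr_jitter_sd=20, seed=42)
        assert np.array_equal(r1.data, r2.data)
        assert np.array_equal(t1.r_peak_times_ms, t2.r_peak_times_ms)
        r3, _ = synth_record(base_template, noise=noise, rr_jitter_sd=20, seed=43)
        assert not np.array_equal(r1.data, r3.data)

    def test_empirical_rr_jitter_matches_request(self, base_template):
        # ~215 beats at RR 600; SD of the sample SD is sigma/sqrt(2n) ~ 1 ms
        _, truth = synth_record(base_template, duration_s=130, mean_rr=600,
                                rr_jitter_sd=20, seed=7)
        rr = np.diff(truth.r_peak_times_ms)
        assert rr.size >= 200
        se = 20.0 / np.sqrt(2 * rr.size)
        assert abs(np.std(rr, ddof=1) - 20.0) < 3 * se + 0.5  # +quantization

    def test_noiseless_beat_window_equals_template(self, base_template, clean_record):
        rec, truth = clean_record
        r = truth.r_peak_times_ms[5]
        t_rel = np.arange(-400, 800, dtype=float)
        idx = (r + t_rel).astype(int)
        # the window spans more than one RR interval: neighbouring beats
        # contribute at its edges (e.g. the next beat's P wave)
        expected = sum(base_template.waveform(t_rel - k * 1000.0)
                       for k in (-1, 0, 1))
        # the renderer truncates each lobe's sub-0.1 µV tails at the beat
        # support edge; everything above that agrees exactly
        np.testing.assert_allclose(rec.data[:, idx], expected, atol=0.1)

    def test_truth_invariant_to_noise(self, base_template):
        _, t_clean = synth_record(base_template, seed=5)
        _, t_noisy = synth_record(base_template, seed=5,
                                  noise=NoiseSpec(broadband_sd_uv=50))
        assert t_clean.pr_ms == t_noisy.pr_ms
        assert t_clean.qt_ms == t_noisy.qt_ms
        assert np.array_equal(t_clean.r_peak_times_ms, t_noisy.r_peak_times_ms)

    def test_preconditions(self, base_template):
        with pytest.raises(SynthError):
            synth_record(base_template, duration_s=0)
        with pytest.raises(SynthError):
            synth_record(base_template, mean_rr=250)


class TestInjectPvc:
    def test_bookkeeping(self, clean_record):
        rec, truth = clean_record
        rec2, truth2 = inject_pvc(rec, truth, prematurity=0.55, widened_qrs=160)
        assert len(truth2.r_peak_times_ms) == len(truth.r_peak_times_ms) + 1
        assert truth2.beat_labels.count("pvc") == 1
        # sinus schedule and truth intervals untouched
        assert np.array_equal(truth2.sinus_times_ms, truth.r_peak_times_ms)
        assert truth2.qt_ms == truth.qt_ms

    def test_widened_qrs_supported(self, clean_record):
        rec, truth = clean_record
        rec2, truth2 = inject_pvc(rec, truth, widened_qrs=160)
        t_pvc = truth2.r_peak_times_ms[list(truth2.beat_labels).index("pvc")]
        delta = rec2.data - rec.data
        active = np.abs(delta).max(axis=0) > 0.035 * np.abs(delta).max()
        span = np.flatnonzero(active)
        width_ms = (span[-1] - span[0]) * 1000.0 / rec.sampling_rate
        assert width_ms == pytest.approx(160, abs=12)
        assert abs(span[0] + (span[-1] - span[0]) / 2 - t_pvc) < 5

    def test_overlap_with_existing_beat_rejected(self, clean_record):
        rec, truth = clean_record
        with pytest.raises(SynthError, match="overlap"):
            inject_pvc(rec, truth, times_ms=[float(truth.r_peak_times_ms[4])])


class TestSynthTriplicate:
    def test_reproducible_and_shared_truth(self, base_template):
        t1, g1 = synth_triplicate(base_template, seed=11)
        t2, g2 = synth_triplicate(base_template, seed=11)
        for a, b in zip(t1.records, t2.records):
            assert np.array_equal(a.data, b.data)
        assert len(t1.records) == 3
        # template-determined truth identical across the three members
        assert len({g.soko_v5_uv for g in g1}) == 1
        assert len({g.qt_ms for g in g1}) == 1

    def test_members_differ_only_by_realization(self, base_template):
        trip, _ = synth_triplicate(base_template, mean_rr=1000, seed=3)
        # noiseless and jitterless: all three members are identical signals
        assert np.array_equal(trip.records[0].data, trip.records[1].data)
        assert np.array_equal(trip.records[1].data, trip.records[2].data)
        noisy, _ = synth_triplicate(base_template, mean_rr=1000, seed=3,
                                    noise=NoiseSpec(broadband_sd_uv=20))
        assert not np.array_equal(noisy.records[0].data, noisy.records[1].data)
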