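"""Biomarker extraction: beats, APDs, rates, and affine invariance."""

import numpy as np
import pytest

from calreg.biomarkers import (
    apd,
    beat_rate,
    biomarker_table,
    compute_biomarkers,
    detect_beats,
)
from calreg.cell_model import Trace
from calreg.errors import InvalidParameterError
from calreg.synthetic import SynthTraceSpec, synth_optical_trace


def square_pulse_trace(width_ms=300.0, period_ms=1000.0, n_beats=5, dt=2.0):
    t = np.arange(0.0, n_beats * period_ms, dt)
    v = ((t % period_ms) < width_ms).astype(float)
    return Trace(time_ms=t, voltage=v)


class TestDetectBeats:
    def test_constant_trace_is_quiescent(self):
        tr = Trace(time_ms=np.arange(0, 8000, 20.0), voltage=np.zeros(400))
        ups, flags = detect_beats(tr)
        assert ups.size == 0
        assert "quiescent" in flags

    def test_sixty_bpm_eight_seconds_gives_eight_upstrokes(self):
        spec = SynthTraceSpec(beat_rate_bpm=60.0, duration_s=8.0, phase_ms=40.0)
        tr, _ = synth_optical_trace(spec)
        ups, _ = detect_beats(tr)
        assert ups.size == 8

    def test_upstrokes_near_ground_truth(self):
        spec = SynthTraceSpec(beat_rate_bpm=75.0, noise_sd=0.02, seed=3)
        tr, truth = synth_optical_trace(spec)
        ups, _ = detect_beats(tr, smoothing_window=5)
        truth_ups = np.array([b.upstroke_ms for b in truth.per_beat])
        assert ups.size == truth_ups.size
        # within one frame interval (20 ms at 50 fps)
        assert np.max(np.abs(ups - truth_ups)) <= 20.0

    def test_too_short_trace_rejected(self):
        tr = Trace(time_ms=np.arange(5.0), voltage=np.zeros(5))
        with pytest.raises(InvalidParameterError):
            detect_beats(tr)


class TestApd:
    def test_square_pulse_apd_equals_width_for_any_fraction(self):
        tr = square_pulse_trace(width_ms=300.0)
        ups, _ = detect_beats(tr, min_amplitude=0.5)
        for f in (0.2, 0.5, 0.8):
            durations, flags = apd(tr, ups, f)
            good = [d for d in durations if d is not None]
            assert len(good) >= 4
            assert np.allclose(good, 300.0, atol=4.0)

    def test_apd80_geq_apd50_beatwise(self):
        spec = SynthTraceSpec(beat_rate_bpm=50.0, apd50_ms=280.0, apd80_ms=340.0)
        tr, _ = synth_optical_trace(spec)
        ups, _ = detect_beats(tr)
        a50, _ = apd(tr, ups, 0.5)
        a80, _ = apd(tr, ups, 0.8)
        for d50, d80 in zip(a50, a80):
            if d50 is not None and d80 is not None:
                assert d80 >= d50

    def test_template_apd50_recovered_within_interpolation_error(self):
        spec = SynthTraceSpec(apd50_ms=300.0, apd80_ms=370.0, noise_sd=0.0)
        tr, _ = synth_optical_trace(spec)
        bm = compute_biomarkers(tr, fps_mode="optical", smoothing_window=0)
        assert bm.apd50_ms == pytest.approx(300.0, abs=10.0)
        assert bm.apd80_ms == pytest.approx(370.0, abs=10.0)

    def test_invalid_fraction_rejected(self):
        tr = square_pulse_trace()
        ups, _ = detect_beats(tr, min_amplitude=0.5)
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(InvalidParameterError):
                apd(tr, ups, bad)


class TestBeatRate:
    def test_one_second_intervals(self):
        assert beat_rate([0.0, 1000.0, 2000.0]) == pytest.approx(60.0)

    def test_800ms_intervals(self):
        assert beat_rate([0.0, 800.0, 1600.0, 2400.0]) == pytest.approx(75.0)

    def test_single_upstroke_missing(self):
        assert beat_rate([500.0]) is None


class TestAffineInvariance:
    @pytest.mark.parametrize("scale,offset", [(3.7, 12.0), (0.004, -5.0), (250.0, 0.0)])
    def test_rescaled_trace_same_biomarkers(self, scale, offset):
        spec = SynthTraceSpec(noise_sd=0.01, seed=11)
        tr, _ = synth_optical_trace(spec)
        bm0 = compute_biomarkers(tr, fps_mode="optical")
        tr2 = Trace(time_ms=tr.time_ms, voltage=scale * tr.voltage + offset)
        bm2 = compute_biomarkers(tr2, fps_mode="optical")
        assert bm2.apd50_ms == pytest.approx(bm0.apd50_ms, abs=1e-9)
        assert bm2.apd80_ms == pytest.approx(bm0.apd80_ms, abs=1e-9)
        assert bm2.beat_rate_bpm == pytest.approx(bm0.beat_rate_bpm, abs=1e-9)

    def test_inverted_polarity_same_biomarkers(self):
        spec = SynthTraceSpec(noise_sd=0.01, seed=4, invert=True)
        tr_inv, truth = synth_optical_trace(spec)
        bm = compute_biomarkers(tr_inv, fps_mode="optical")
        assert bm.apd50_ms == pytest.approx(truth.apd50_ms, abs=20.0)
        assert bm.beat_rate_bpm == pytest.approx(truth.beat_rate_bpm, abs=2.0)


class TestBiomarkerTable:
    def test_one_row_per_trace_sorted(self):
        traces = {}
        for i, rate in enumerate((50.0, 60.0, 70.0)):
            tr, _ = synth_optical_trace(SynthTraceSpec(beat_rate_bpm=rate, seed=i))
            traces[f"well_{i}"] = tr
        table = biomarker_table(traces, fps_mode="optical")
        assert list(table["label"]) == sorted(traces)
        assert len(table) == 3

    def test_identical_traces_identical_rows(self):
        tr, _ = synth_optical_trace(SynthTraceSpec(seed=9))
        table = biomarker_table({"a": tr, "b": tr}, fps_mode="optical")
        assert table.iloc[0]["apd50_ms"] == table.iloc[1]["apd50_ms"]
        assert table.iloc[0]["beat_rate_bpm"] == table.iloc[1]["beat_rate_bpm"]

    def test_quiescent_trace_row_flagged_with_missing_rate(self):
        flat = Trace(time_ms=np.arange(0, 8000, 20.0), voltage=np.zeros(400))
        table = biomarker_table({"flat": flat}, fps_mode="optical")
        import pandas as pd

        row = table.iloc[0]
        assert pd.isna(row["beat_rate_bpm"])
        assert "quiescent" in row["flags"]


class TestRecoveryAcrossConditions:
    def test_biomarkers_recovered_on_seeded_trace_suite(self):
        """APDs within one 20 ms frame and rate within 2 bpm on 50+ traces
        spanning 30-120 bpm, APD50 150-500 ms, noise up to 5 % amplitude."""
        rng = np.random.default_rng(1234)
        n_ok = 0
        specs = []
        for i in range(55):
            rate = float(rng.uniform(30.0, 120.0))
            period = 60_000.0 / rate
            apd50 = float(rng.uniform(150.0, min(500.0, 0.6 * period)))
            # the template needs plateau > 0 and the waveform inside the
            # period, which caps the APD80-APD50 spread
            apd80 = apd50 + float(
                rng.uniform(30.0, min(120.0, 0.3 * apd50, 0.2 * period))
            )
            specs.append(
                SynthTraceSpec(
                    beat_rate_bpm=rate,
                    apd50_ms=apd50,
                    apd80_ms=apd80,
                    noise_sd=float(rng.uniform(0.0, 0.05)),
                    drift_per_s=float(rng.uniform(-0.01, 0.01)),
                    phase_ms=float(rng.uniform(0, 400.0)),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
        for spec in specs:
            tr, truth = synth_optical_trace(spec)
            bm = compute_biomarkers(tr, fps_mode="optical")
            assert bm.apd50_ms is not None
            assert abs(bm.apd50_ms - truth.apd50_ms) <= 20.0, spec
            assert abs(bm.apd80_ms - truth.apd80_ms) <= 20.0, spec
            assert abs(bm.beat_rate_bpm - truth.beat_rate_bpm) <= 2.0, spec
            n_ok += 1
        assert n_ok >= 50
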