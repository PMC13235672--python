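"""HRV/EDA/skin-temperature feature-extraction tests.

The time-domain HRV oracle is the direct formula applied to the raw
interval arrays; the SCR oracle is the analytic linear-rise /
exponential-decay pulse whose amplitude, rise and 63%-recovery are
known in closed form.
"""

import numpy as np
import pytest

from walkscape.physio import (
    PHYSIO_INDICATORS,
    PhysioSession,
    detect_scrs,
    eda_decompose,
    eda_smooth,
    hrv_windows,
    lf_hf_ratio,
    qc_session,
    summarize_trip,
    extract_trip_indicators,
)

FS = 4.0


def make_session(duration_s=300.0, ibi_ms=None, eda_level=2.0, temp_c=33.0,
                 trip_id="T1"):
    if ibi_ms is None:
        n = int(duration_s / 0.8)
        ibi_ms = np.full(n, 800.0)
    ibi_ms = np.asarray(ibi_ms, dtype=float)
    ibi_t = np.cumsum(ibi_ms) / 1000.0
    n_samp = int(duration_s * FS)
    return PhysioSession(
        trip_id=trip_id, ibi_t=ibi_t, ibi_ms=ibi_ms,
        eda_raw=np.full(n_samp, eda_level), skin_temp=np.full(n_samp, temp_c),
        fs_eda=FS, fs_temp=FS, duration_s=duration_s,
    )


def analytic_pulse(t, t0, amp=1.0, rise=2.0, tau=3.0):
    y = np.zeros_like(t)
    m = (t >= t0) & (t < t0 + rise)
    y[m] = amp * (t[m] - t0) / rise
    m2 = t >= t0 + rise
    y[m2] = amp * np.exp(-(t[m2] - t0 - rise) / tau)
    return y


class TestQcGate:
    @pytest.mark.parametrize(
        "duration,has_ibi,temp,eda,accepted,reason",
        [
            (119.0, True, 33.0, 2.0, False, "duration"),
            (300.0, True, 31.0, 0.01, True, None),   # temp-only contact
            (300.0, True, 28.0, 2.0, True, None),    # EDA-only contact
            (300.0, True, 28.0, 0.04, False, "contact"),
            (300.0, False, 33.0, 2.0, False, "ibi"),
        ],
    )
    def test_gate_rule(self, duration, has_ibi, temp, eda, accepted, reason):
        s = make_session(duration_s=duration, eda_level=eda, temp_c=temp)
        if not has_ibi:
            s.ibi_t = np.array([])
            s.ibi_ms = np.array([])
        qc = qc_session(s)
        assert qc.accepted is accepted
        assert qc.reason == reason

    def test_monotone_in_duration(self):
        s = make_session(duration_s=300.0)
        assert qc_session(s).accepted
        s.duration_s = 100.0
        assert not qc_session(s).accepted


class TestHrvWindows:
    def test_constant_series(self):
        ibi = np.full(12, 800.0)
        out = hrv_windows(np.cumsum(ibi) / 1000.0, ibi)
        assert out[0].rmssd_ms == 0.0
        assert out[0].pnn50_pct == 0.0
        assert out[0].mean_hr_bpm == pytest.approx(75.0)

    def test_hand_rmssd(self):
        ibi = np.array([800.0, 850.0, 800.0])
        out = hrv_windows(np.array([0.8, 1.65, 2.45]), ibi)
        assert out[0].rmssd_ms == pytest.approx(50.0)

    def test_pnn50_strict_boundary(self):
        # successive diffs 50, 60, 10 -> only the 60 counts (strict > 50)
        ibi = np.array([800.0, 850.0, 910.0, 920.0])
        out = hrv_windows(np.array([0.8, 1.65, 2.56, 3.48]), ibi)
        assert out[0].pnn50_pct == pytest.approx(100.0 / 3.0)

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError):
            hrv_windows(np.array([0.8, 1.6]), np.array([800.0, -1.0]))

    def test_sparse_window_skipped(self):
        # one interval in [0, 10): skipped
        out = hrv_windows(np.array([5.0, 12.0, 13.0]),
                          np.array([800.0, 820.0, 790.0]))
        assert all(w.window_start_s != 0.0 for w in out)

    def test_matches_bruteforce_oracle(self):
        """Windowed extractor vs direct formulas on 1,000 random windows."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(3, 16)
            ibi = rng.uniform(500.0, 1200.0, n)
            t = np.cumsum(ibi) / 1000.0
            t = t - t[0] + rng.uniform(0, 1)  # keep inside one 20-s window
            out = hrv_windows(t, ibi, window_s=20.0)
            w = [x for x in out if x.window_start_s == 0.0][0]
            d = np.diff(ibi)
            assert w.rmssd_ms == pytest.approx(np.sqrt(np.mean(d**2)), abs=1e-9)
            assert w.pnn50_pct == pytest.approx(
                100.0 * np.sum(np.abs(d) > 50.0) / len(d), abs=1e-9)
            assert w.mean_hr_bpm == pytest.approx(60000.0 / np.mean(ibi), abs=1e-9)


class TestLfHf:
    def _modulated_ibi(self, f_mod, duration=300.0, depth=50.0):
        t, ibi = [0.0], []
        while t[-1] < duration:
            iv = 800.0 + depth * np.sin(2 * np.pi * f_mod * t[-1])
            t.append(t[-1] + iv / 1000.0)
            ibi.append(iv)
        return np.array(t[1:]), np.array(ibi)

    def test_lf_tone_dominates(self):
        t, ibi = self._modulated_ibi(0.10)
        assert lf_hf_ratio(t, ibi) >= 10.0

    def test_hf_tone_dominates(self):
        t, ibi = self._modulated_ibi(0.25)
        assert lf_hf_ratio(t, ibi) <= 0.1

    def test_white_noise_bandwidth_ratio(self):
        """Flat-spectrum oracle: ratio ~ LF width / HF width = 0.44."""
        rng = np.random.default_rng(7)
        ratios = []
        for _ in range(100):
            ibi = 800.0 + rng.normal(0, 30.0, 300)
            t = np.cumsum(ibi) / 1000.0
            ratios.append(lf_hf_ratio(t, ibi))
        mean_ratio = np.mean(ratios)
        assert 0.5 * 0.44 <= mean_ratio <= 1.5 * 0.44

    def test_short_series_missing(self):
        ibi = np.full(20, 800.0)
        assert np.isnan(lf_hf_ratio(np.cumsum(ibi) / 1000.0, ibi))


class TestEdaPipeline:
    def test_constant_input_dc_rejection(self):
        x = np.full(400, 1.0)
        sm = eda_smooth(x, fs=FS)
        tonic, phasic = eda_decompose(sm, fs=FS)
        np.testing.assert_allclose(tonic, 1.0, atol=1e-9)
        np.testing.assert_allclose(phasic, 0.0, atol=1e-9)

    def test_conservation(self):
        rng = np.random.default_rng(1)
        x = 2.0 + np.cumsum(rng.normal(0, 0.01, 800))
        sm = eda_smooth(x, fs=FS)
        tonic, phasic = eda_decompose(sm, fs=FS)
        np.testing.assert_allclose(tonic + phasic, sm, atol=1e-9)

    def test_slow_drift_rejected(self):
        t = np.arange(0, 400, 1 / FS)
        drift = np.sin(2 * np.pi * 0.005 * t)  # 0.005 Hz
        sm = eda_smooth(2.0 + drift, fs=FS)
        _, phasic = eda_decompose(sm, fs=FS)
        interior = phasic[int(60 * FS): -int(60 * FS)]
        assert np.max(np.abs(interior)) < 0.05  # < 5% of unit drift amplitude

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            eda_smooth(np.ones(3), fs=FS)

    def test_injected_pulse_recovered(self):
        t = np.arange(0, 300, 1 / FS)
        x = 2.0 + analytic_pulse(t, 150.0, amp=0.8)
        sm = eda_smooth(x, fs=FS)
        _, phasic = eda_decompose(sm, fs=FS)
        events = detect_scrs(phasic, fs=FS, amp_threshold_uS=0.05)
        assert len(events) == 1
        assert events[0].amplitude_uS == pytest.approx(0.8, rel=0.10)


class TestScrDetection:
    def test_flat_phasic_no_events(self):
        assert detect_scrs(np.zeros(200), fs=FS) == []

    def test_analytic_pulse_shape(self):
        t = np.arange(0, 300, 1 / FS)
        x = 2.0 + analytic_pulse(t, 150.0, amp=1.0, rise=2.0, tau=3.0)
        sm = eda_smooth(x, fs=FS)
        _, phasic = eda_decompose(sm, fs=FS)
        events = detect_scrs(phasic, fs=FS, amp_threshold_uS=0.1)
        assert len(events) == 1
        ev = events[0]
        assert ev.amplitude_uS == pytest.approx(1.0, rel=0.05)
        assert ev.rise_time_s == pytest.approx(2.0, abs=0.25)
        assert ev.recovery63_s == pytest.approx(3.0, abs=0.3)

    def test_two_pulses_ordered(self):
        t = np.arange(0, 300, 1 / FS)
        x = 2.0 + analytic_pulse(t, 100.0, amp=0.7) + analytic_pulse(t, 130.0, amp=0.5)
        sm = eda_smooth(x, fs=FS)
        _, phasic = eda_decompose(sm, fs=FS)
        events = detect_scrs(phasic, fs=FS, amp_threshold_uS=0.1)
        assert len(events) == 2
        assert events[0].peak_s < events[1].peak_s
        assert events[0].amplitude_uS > events[1].amplitude_uS

    def test_amplitude_scaling_equivariance(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 400, 1 / FS)
        x = 2.0 + sum(analytic_pulse(t, t0, amp=a) for t0, a in
                      [(60, 0.5), (150, 0.9), (260, 0.3)])
        x = x + rng.normal(0, 0.002, len(t))
        for c in (0.5, 3.0):
            sm1 = eda_smooth(x, fs=FS)
            sm2 = eda_smooth(c * x, fs=FS)
            _, p1 = eda_decompose(sm1, fs=FS)
            _, p2 = eda_decompose(sm2, fs=FS)
            e1 = detect_scrs(p1, fs=FS, amp_threshold_uS=0.05)
            e2 = detect_scrs(p2, fs=FS, amp_threshold_uS=0.05 * c)
            assert len(e1) == len(e2)
            for a, b in zip(e1, e2):
                assert b.amplitude_uS == pytest.approx(c * a.amplitude_uS, rel=1e-9)
                assert b.rise_time_s == pytest.approx(a.rise_time_s, abs=1e-9)
                if np.isfinite(a.recovery63_s):
                    assert b.recovery63_s == pytest.approx(a.recovery63_s, abs=1e-6)


class TestTripSummary:
    def test_indicator_count_and_names(self):
        s = make_session()
        ind = extract_trip_indicators(s)
        assert set(ind) == set(PHYSIO_INDICATORS)
        assert len(PHYSIO_INDICATORS) == 27

    def test_qc_failed_rejected(self):
        s = make_session(duration_s=60.0)
        with pytest.raises(ValueError, match="QC"):
            extract_trip_indicators(s)

    def test_empty_events_conventions(self):
        s = make_session()
        windows = hrv_windows(s.ibi_t, s.ibi_ms)
        out = summarize_trip(s, windows, events=[])
        assert out["scr_count"] == 0.0
        assert out["scr_rate_per_min"] == 0.0
        assert np.isnan(out["scr_amp_mean"])
        assert np.isnan(out["scr_rise_mean_s"])

    def test_single_window_sd_zero(self):
        ibi = np.full(10, 800.0)
        s = make_session(duration_s=130.0, ibi_ms=ibi)
        windows = hrv_windows(s.ibi_t, s.ibi_ms)
        assert len(windows) == 1
        out = summarize_trip(s, windows, events=[])
        assert out["rmssd_sd"] == 0.0
        assert out["hr_sd"] == 0.0
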