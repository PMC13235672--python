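"""Wearable-session quality control and trip-level physiological indicators.

Input is one synchronized session per walking trip: interbeat intervals
(IBI, ms), electrodermal activity (EDA, µS, uniformly sampled, 4 Hz by
default) and skin temperature (°C). The module gates sessions on a
signal-validity rule (duration >= 2 min, non-empty IBI, and sensor
contact evidenced by skin temperature >= 30 °C or raw EDA >= 0.05 µS),
computes heart-rate-variability metrics in 10-s windows, decomposes EDA
into tonic and phasic components, characterises skin conductance
responses (SCRs), and summarises everything into the canonical set of 27
trip-level indicators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal

__all__ = [
    "PhysioSession",
    "QcResult",
    "HrvWindowMetrics",
    "ScrEvent",
    "PHYSIO_INDICATORS",
    "qc_session",
    "hrv_windows",
    "lf_hf_ratio",
    "eda_smooth",
    "eda_decompose",
    "detect_scrs",
    "summarize_trip",
    "extract_trip_indicators",
]

#: Canonical trip-level physiological indicator names (27 fields).
PHYSIO_INDICATORS = (
    "rmssd_mean", "rmssd_sd",
    "pnn50_mean", "pnn50_sd",
    "hr_mean", "hr_sd",
    "bpm_min", "bpm_max",
    "lf_hf_ratio",
    "scr_amp_mean", "scr_amp_min", "scr_amp_max", "scr_amp_sd",
    "scr_rise_mean_s", "scr_rise_sd_s",
    "scr_rise_mean_npoints", "scr_rise_sd_npoints",
    "scr_recovery_mean_s", "scr_recovery_sd_s",
    "scr_count", "scr_rate_per_min",
    "tonic_mean", "tonic_sd",
    "temp_mean", "temp_min", "temp_max", "temp_sd",
)


@dataclass
class PhysioSession:
    """Synchronized IBI/EDA/temperature record for one trip."""

    trip_id: str
    ibi_t: np.ndarray       # beat times, s from session start
    ibi_ms: np.ndarray      # interbeat intervals, ms
    eda_raw: np.ndarray     # µS
    skin_temp: np.ndarray   # °C
    fs_eda: float = 4.0     # Hz
    fs_temp: float = 4.0    # Hz
    duration_s: float = None

    def __post_init__(self):
        self.ibi_t = np.asarray(self.ibi_t, dtype=float)
        self.ibi_ms = np.asarray(self.ibi_ms, dtype=float)
        self.eda_raw = np.asarray(self.eda_raw, dtype=float)
        self.skin_temp = np.asarray(self.skin_temp, dtype=float)
        if self.duration_s is None:
            candidates = [0.0]
            if len(self.eda_raw):
                candidates.append(len(self.eda_raw) / self.fs_eda)
            if len(self.ibi_t):
                candidates.append(float(self.ibi_t[-1]))
            self.duration_s = max(candidates)


@dataclass(frozen=True)
class QcResult:
    accepted: bool
    reason: str | None = None  # first failing gate, None when accepted

    def __bool__(self):
        return self.accepted


def qc_session(
    session: PhysioSession,
    min_duration_s: float = 120.0,
    temp_contact_c: float = 30.0,
    eda_contact_us: float = 0.05,
) -> QcResult:
    """Apply the session quality gate.

    Accepted iff duration >= 2 min AND the IBI array is non-empty AND
    sensor contact holds (mean skin temperature >= 30 °C OR mean raw EDA
    >= 0.05 µS). Rejections carry the first failing gate in order
    duration, ibi, contact.
    """
    if session.duration_s < min_duration_s:
        return QcResult(False, "duration")
    if len(session.ibi_ms) == 0:
        return QcResult(False, "ibi")
    temp_ok = len(session.skin_temp) > 0 and float(np.mean(session.skin_temp)) >= temp_contact_c
    eda_ok = len(session.eda_raw) > 0 and float(np.mean(session.eda_raw)) >= eda_contact_us
    if not (temp_ok or eda_ok):
        return QcResult(False, "contact")
    return QcResult(True)


@dataclass(frozen=True)
class HrvWindowMetrics:
    window_start_s: float
    rmssd_ms: float
    pnn50_pct: float
    mean_hr_bpm: float


def hrv_windows(ibi_t, ibi_ms, window_s: float = 10.0) -> list[HrvWindowMetrics]:
    """Windowed HRV metrics over consecutive ``window_s`` windows.

    Within each window: RMSSD is the root mean square of successive
    interval differences, pNN50 the percentage of successive differences
    strictly exceeding 50 ms, and mean HR is 60000 / mean interval (bpm).
    Windows holding fewer than two intervals are skipped.
    """
    ibi_t = np.asarray(ibi_t, dtype=float)
    ibi_ms = np.asarray(ibi_ms, dtype=float)
    if np.any(ibi_ms <= 0):
        raise ValueError("interbeat intervals must be positive")
    if len(ibi_t) == 0:
        return []
    out = []
    t_end = ibi_t[-1]
    n_win = int(math.ceil(max(t_end, window_s) / window_s))
    for k in range(n_win):
        lo, hi = k * window_s, (k + 1) * window_s
        mask = (ibi_t >= lo) & (ibi_t < hi)
        iv = ibi_ms[mask]
        if len(iv) < 2:
            continue
        dif = np.diff(iv)
        rmssd = float(np.sqrt(np.mean(dif**2)))
        pnn50 = float(100.0 * np.sum(np.abs(dif) > 50.0) / len(dif))
        hr = float(60_000.0 / np.mean(iv))
        out.append(HrvWindowMetrics(lo, rmssd, pnn50, hr))
    return out


def lf_hf_ratio(
    ibi_t,
    ibi_ms,
    resample_hz: float = 4.0,
    lf_band=(0.04, 0.15),
    hf_band=(0.15, 0.40),
) -> float:
    """LF/HF spectral power ratio of the heart-period series.

    The irregular IBI series is cubic-interpolated onto an evenly spaced
    tachogram (4 Hz), its power spectral density is estimated with
    Welch's method, and band powers are integrated over the LF
    (0.04-0.15 Hz) and HF (0.15-0.40 Hz) bands. Returns NaN when HF
    power is zero or the series is too short (< 120 s usable IBI).
    """
    ibi_t = np.asarray(ibi_t, dtype=float)
    ibi_ms = np.asarray(ibi_ms, dtype=float)
    if len(ibi_t) < 4 or (ibi_t[-1] - ibi_t[0]) < 120.0:
        return float("nan")
    f_interp = interpolate.interp1d(ibi_t, ibi_ms, kind="cubic", assume_sorted=True)
    tt = np.arange(ibi_t[0], ibi_t[-1], 1.0 / resample_hz)
    tach = f_interp(tt)
    tach = tach - np.mean(tach)
    nperseg = min(len(tach), int(256 * resample_hz / 4.0))
    freqs, psd = signal.welch(tach, fs=resample_hz, nperseg=nperseg)
    df = freqs[1] - freqs[0]
    lf = float(np.sum(psd[(freqs >= lf_band[0]) & (freqs < lf_band[1])]) * df)
    hf = float(np.sum(psd[(freqs >= hf_band[0]) & (freqs < hf_band[1])]) * df)
    if hf <= 0:
        return float("nan")
    return lf / hf


def eda_smooth(eda_raw, fs: float = 4.0, window_s: float = 1.0, polyorder: int = 3):
    """Savitzky-Golay smoothing of the raw EDA series (length-preserving)."""
    x = np.asarray(eda_raw, dtype=float)
    win = int(round(window_s * fs))
    if win % 2 == 0:
        win += 1
    if len(x) < win:
        raise ValueError(f"series shorter than filter window ({len(x)} < {win})")
    return signal.savgol_filter(x, window_length=win, polyorder=polyorder)


def eda_decompose(smoothed, fs: float = 4.0, cutoff_hz: float = 0.015, order: int = 4):
    """Split smoothed EDA into tonic and phasic components.

    The tonic component is a zero-phase (forward-backward) Butterworth
    low-pass of the smoothed signal; the phasic component is the
    complementary high-pass residual, so ``tonic + phasic == smoothed``
    identically and a constant input yields zero phasic response.

    The default fourth-order filter at 0.015 Hz keeps slow tonic drift
    (< ~0.005 Hz) out of the phasic channel while distorting the
    amplitude and recovery shape of a typical SCR pulse by only a few
    percent; a shallower first-order rolloff cannot do both at once.
    """
    x = np.asarray(smoothed, dtype=float)
    if len(x) < 16:
        raise ValueError("series too short to decompose")
    b, a = signal.butter(order, cutoff_hz, btype="lowpass", fs=fs)
    tonic = signal.filtfilt(b, a, x)
    phasic = x - tonic
    return tonic, phasic


@dataclass(frozen=True)
class ScrEvent:
    """One skin conductance response."""

    onset_s: float
    peak_s: float
    amplitude_uS: float
    rise_time_s: float
    rise_npoints: int
    recovery63_s: float  # NaN when the next event (or the record) cuts recovery short


def detect_scrs(
    phasic,
    fs: float = 4.0,
    amp_threshold_uS: float = 0.01,
    recovery_fraction: float = 0.63,
    min_rise_s: float = 0.5,
) -> list[ScrEvent]:
    """Detect SCRs on the phasic component.

    Each candidate peak is paired with the local phasic minimum
    preceding it; the onset level is the phasic value at that minimum
    and the amplitude is peak minus onset level. The onset *time* is
    refined with the tangent method — the maximal-slope tangent of the
    rising limb extrapolated down to the onset level — which is
    unbiased under symmetric smoothing and gives sub-sample rise times.
    Recovery time runs from the peak until the phasic signal has
    declined by ``recovery_fraction`` (63% by default, the exponential
    time-constant convention) of the amplitude, with linear
    interpolation between samples; it is missing (NaN) when the next
    event or the end of the record arrives first. Events below
    ``amp_threshold_uS``, or rising faster than ``min_rise_s`` (two
    samples at 4 Hz -- unresolvable, hence sensor noise), are
    discarded.
    """
    p = np.asarray(phasic, dtype=float)
    if len(p) < 3:
        return []
    # width >= 2 samples at half prominence: a genuine SCR spans seconds,
    # single-sample spikes are sensor noise
    peaks, _ = signal.find_peaks(p, prominence=amp_threshold_uS, width=2)
    if len(peaks) == 0:
        return []
    minima, _ = signal.find_peaks(-p)
    slope = np.gradient(p) * fs
    events = []
    for pk in peaks:
        prior = minima[minima < pk]
        onset_idx = int(prior[-1]) if len(prior) else 0
        base = p[onset_idx]
        amp = p[pk] - base
        if amp < amp_threshold_uS:
            continue
        events.append((onset_idx, int(pk), float(amp)))
    out = []
    for i, (onset_idx, pk, amp) in enumerate(events):
        base = p[onset_idx]
        # sub-sample peak: quadratic through the three samples around the
        # maximum (the true peak rarely falls on the 4-Hz grid)
        t_pk, v_pk = _refine_peak(p, pk, fs)
        amp = v_pk - base
        # tangent-method onset: extrapolate the steepest rising slope to base level
        ms = onset_idx + int(np.argmax(slope[onset_idx : pk + 1]))
        if slope[ms] > 0:
            t_on = ms / fs - (p[ms] - base) / slope[ms]
            t_on = float(np.clip(t_on, onset_idx / fs, t_pk))
        else:
            t_on = onset_idx / fs
        stop = events[i + 1][0] if i + 1 < len(events) else len(p) - 1
        target = v_pk - recovery_fraction * amp
        rec = float("nan")
        for j in range(pk + 1, stop + 1):
            if p[j] <= target:
                frac = (p[j - 1] - target) / (p[j - 1] - p[j]) if p[j - 1] > p[j] else 1.0
                rec = (j - 1 + frac) / fs - t_pk
                break
        rise_s = t_pk - t_on
        if rise_s < min_rise_s:
            continue
        out.append(
            ScrEvent(
                onset_s=t_on,
                peak_s=t_pk,
                amplitude_uS=amp,
                rise_time_s=rise_s,
                rise_npoints=int(round(rise_s * fs)),
                recovery63_s=rec,
            )
        )
    return out


def _refine_peak(p: np.ndarray, pk: int, fs: float):
    """Sub-sample peak time/height via a parabola through 3 samples."""
    if pk <= 0 or pk >= len(p) - 1:
        return pk / fs, float(p[pk])
    a, b, c = p[pk - 1], p[pk], p[pk + 1]
    denom = a - 2 * b + c
    if denom >= 0:  # not locally concave; keep the grid value
        return pk / fs, float(b)
    delta = 0.5 * (a - c) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    height = b - 0.25 * (a - c) * delta
    return (pk + delta) / fs, float(height)


def _mean_sd(values, single_sd=0.0):
    """Mean and dispersion with the single-observation SD-of-0 convention."""
    v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
    if len(v) == 0:
        return float("nan"), float("nan")
    if len(v) == 1:
        return float(v[0]), single_sd
    return float(np.mean(v)), float(np.std(v))


def summarize_trip(
    session: PhysioSession,
    windows: list[HrvWindowMetrics],
    events: list[ScrEvent],
    tonic: np.ndarray = None,
    ratio: float = None,
) -> dict:
    """Trip-level summary: the 27 canonical physiological indicators.

    SDs of a single observation are 0 by convention. With no SCR events
    the count fields are 0 and the amplitude/time fields missing (NaN).
    The session must have passed QC.
    """
    qc = qc_session(session)
    if not qc:
        raise ValueError(f"session failed QC ({qc.reason}); cannot summarize")
    out = {}
    rmssd = [w.rmssd_ms for w in windows]
    pnn = [w.pnn50_pct for w in windows]
    hr = [w.mean_hr_bpm for w in windows]
    out["rmssd_mean"], out["rmssd_sd"] = _mean_sd(rmssd)
    out["pnn50_mean"], out["pnn50_sd"] = _mean_sd(pnn)
    out["hr_mean"], out["hr_sd"] = _mean_sd(hr)
    out["bpm_min"] = float(np.min(hr)) if hr else float("nan")
    out["bpm_max"] = float(np.max(hr)) if hr else float("nan")
    if ratio is None:
        ratio = lf_hf_ratio(session.ibi_t, session.ibi_ms)
    out["lf_hf_ratio"] = float(ratio)
    amps = [e.amplitude_uS for e in events]
    if amps:
        out["scr_amp_mean"], out["scr_amp_sd"] = _mean_sd(amps)
        out["scr_amp_min"] = float(np.min(amps))
        out["scr_amp_max"] = float(np.max(amps))
    else:
        out["scr_amp_mean"] = out["scr_amp_sd"] = float("nan")
        out["scr_amp_min"] = out["scr_amp_max"] = float("nan")
    out["scr_rise_mean_s"], out["scr_rise_sd_s"] = _mean_sd([e.rise_time_s for e in events])
    out["scr_rise_mean_npoints"], out["scr_rise_sd_npoints"] = _mean_sd(
        [e.rise_npoints for e in events]
    )
    out["scr_recovery_mean_s"], out["scr_recovery_sd_s"] = _mean_sd(
        [e.recovery63_s for e in events]
    )
    out["scr_count"] = float(len(events))
    out["scr_rate_per_min"] = float(len(events) / (session.duration_s / 60.0))
    if tonic is None:
        sm = eda_smooth(session.eda_raw, fs=session.fs_eda)
        tonic, _ = eda_decompose(sm, fs=session.fs_eda)
    out["tonic_mean"] = float(np.mean(tonic))
    out["tonic_sd"] = float(np.std(tonic)) if len(tonic) > 1 else 0.0
    st = session.skin_temp
    out["temp_mean"] = float(np.mean(st)) if len(st) else float("nan")
    out["temp_min"] = float(np.min(st)) if len(st) else float("nan")
    out["temp_max"] = float(np.max(st)) if len(st) else float("nan")
    out["temp_sd"] = (float(np.std(st)) if len(st) > 1 else 0.0) if len(st) else float("nan")
    assert set(out) == set(PHYSIO_INDICATORS)
    return out


def extract_trip_indicators(
    session: PhysioSession,
    window_s: float = 10.0,
    sg_window_s: float = 1.0,
    sg_polyorder: int = 3,
    hp_cutoff_hz: float = 0.015,
    hp_order: int = 4,
    amp_threshold_uS: float = 0.01,
) -> dict:
    """Full per-trip extraction: QC -> HRV windows -> EDA pipeline -> summary.

    Raises ValueError when the session fails QC.
    """
    qc = qc_session(session)
    if not qc:
        raise ValueError(f"session failed QC ({qc.reason})")
    windows = hrv_windows(session.ibi_t, session.ibi_ms, window_s=window_s)
    smoothed = eda_smooth(session.eda_raw, fs=session.fs_eda, window_s=sg_window_s,
                          polyorder=sg_polyorder)
    tonic, phasic = eda_decompose(smoothed, fs=session.fs_eda,
                                  cutoff_hz=hp_cutoff_hz, order=hp_order)
    events = detect_scrs(phasic, fs=session.fs_eda, amp_threshold_uS=amp_threshold_uS)
    ratio = lf_hf_ratio(session.ibi_t, session.ibi_ms)
    return summarize_trip(session, windows, events, tonic=tonic, ratio=ratio)
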