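"""Waveform filtering and per-beat feature extraction for ECG/SCG/RPPG.

Raw channels are band-limited with zero-phase Kaiser-window FIR filters
(0.5-40 Hz ECG, 1-40 Hz SCG, 0.5-10 Hz RPPG).  R peaks anchor each beat;
the seismocardiogram supplies the aortic-opening (AO) and aortic-closing
(AC) fiducials that define the pre-ejection period PEP = AO - R and the
left ventricular ejection time LVET = AC - AO; the photoplethysmogram foot
defines the pulse arrival time PAT = foot - R and pulse transit time
PTT = foot - AO.  Beats where a fiducial cannot be located are marked NaN
and excluded downstream — never silently zeroed.

Fiducial search windows, HRV spectral bands, the nPAT definition and the
PVI window are under-determined by convention alone; the defaults here are
standard choices and every one is a keyword argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sg

from .features import FEATURES_12
from .synthetic import WaveformRecord

__all__ = [
    "FilterSpec",
    "ECG_FILTER",
    "SCG_FILTER",
    "RPPG_FILTER",
    "bandpass_zero_phase",
    "detect_r_peaks",
    "hr_and_hrv",
    "scg_fiducials",
    "ppg_features",
    "extract_feature_table",
]


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Kaiser-window FIR band-pass specification."""

    low_hz: float
    high_hz: float
    transition_width_hz: float = 1.0
    ripple_db: float = 60.0  # stopband attenuation of the one-pass design

    def design(self, fs_hz: float) -> np.ndarray:
        if not (0 < self.low_hz < self.high_hz < fs_hz / 2):
            raise ValueError(
                f"need 0 < low ({self.low_hz}) < high ({self.high_hz}) "
                f"< Nyquist ({fs_hz / 2})"
            )
        numtaps, beta = sg.kaiserord(self.ripple_db, self.transition_width_hz / (fs_hz / 2))
        numtaps |= 1  # odd length -> exactly linear phase, integer group delay
        return sg.firwin(
            numtaps, [self.low_hz, self.high_hz],
            window=("kaiser", beta), pass_zero=False, fs=fs_hz,
        )


ECG_FILTER = FilterSpec(0.5, 40.0)
SCG_FILTER = FilterSpec(1.0, 40.0)
RPPG_FILTER = FilterSpec(0.5, 10.0)


def bandpass_zero_phase(x: np.ndarray, fs_hz: float, spec: FilterSpec) -> np.ndarray:
    """Forward-backward (zero net phase) band-pass filtering.

    The two-pass application squares the magnitude response, so the effective
    stopband attenuation doubles relative to ``spec.ripple_db``.
    """
    x = np.asarray(x, dtype=float)
    taps = spec.design(fs_hz)
    if len(x) <= 3 * len(taps):
        raise ValueError(
            f"series too short: length {len(x)} must exceed 3 x filter order ({3 * len(taps)})"
        )
    return sg.filtfilt(taps, [1.0], x)


def detect_r_peaks(
    ecg: np.ndarray, fs_hz: float, refractory_s: float = 0.2, threshold_frac: float = 0.3
) -> np.ndarray:
    """R-peak indices via a smoothed derivative-energy transform.

    The squared derivative is smoothed over 80 ms; candidate maxima above
    ``threshold_frac`` of the transform's peak are accepted greedily by
    descending ECG amplitude under a 200 ms refractory period, then each
    detection is refined to the local ECG maximum.  Returns a strictly
    increasing index array; empty for flat or too-short input.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 3 or np.ptp(ecg) == 0:
        return np.array([], dtype=int)
    d = np.gradient(ecg)
    energy = d * d
    win = max(int(0.08 * fs_hz), 1)
    smooth = np.convolve(energy, np.ones(win) / win, mode="same")
    thr = threshold_frac * smooth.max()
    if thr <= 0:
        return np.array([], dtype=int)
    cand, _ = sg.find_peaks(smooth, height=thr, distance=max(int(0.05 * fs_hz), 1))
    if len(cand) == 0:
        return np.array([], dtype=int)
    # refine candidates to the nearby ECG maximum
    half = max(int(0.05 * fs_hz), 1)
    refined = []
    for c in cand:
        lo, hi = max(c - half, 0), min(c + half + 1, len(ecg))
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = np.unique(refined)
    # amplitude-priority acceptance under the refractory period
    order = np.argsort(ecg[refined])[::-1]
    accepted: list[int] = []
    min_gap = refractory_s * fs_hz
    for idx in refined[order]:
        if all(abs(idx - a) >= min_gap for a in accepted):
            accepted.append(int(idx))
    return np.array(sorted(accepted), dtype=int)


def hr_and_hrv(
    r_peaks: np.ndarray,
    fs_hz: float,
    lf_band: tuple[float, float] = (0.04, 0.15),
    hf_band: tuple[float, float] = (0.15, 0.40),
    resample_hz: float = 4.0,
    min_span_s: float = 30.0,
) -> dict[str, float]:
    """HR and the three HRV summaries over one window of beats.

    HR = 60/mean(RR); SDRR = sample SD of RR; the Poincare ratio uses
    SD1 = SD of successive RR differences / sqrt(2) and
    SD2 = sqrt(2 Var(RR) - SD1^2); LF/HF is the band-power ratio of a Welch
    periodogram of the RR series evenly resampled at ``resample_hz``.
    Quantities that are not estimable from the window are NaN.
    """
    r_peaks = np.asarray(r_peaks)
    out = {"HR": np.nan, "SDRR": np.nan, "SD1_SD2": np.nan, "LF_HF": np.nan}
    if len(r_peaks) < 2:
        return out
    rr = np.diff(r_peaks) / fs_hz
    out["HR"] = 60.0 / rr.mean()
    if len(rr) >= 2:
        out["SDRR"] = float(np.std(rr, ddof=1))
        sd1 = float(np.std(np.diff(rr) / math.sqrt(2.0), ddof=1)) if len(rr) >= 3 else np.nan
        if np.isfinite(sd1):
            sd2_sq = 2.0 * np.var(rr, ddof=1) - sd1**2
            sd2 = math.sqrt(sd2_sq) if sd2_sq > 0 else 0.0
            out["SD1_SD2"] = sd1 / sd2 if sd2 > 0 else np.nan
    span = (r_peaks[-1] - r_peaks[1]) / fs_hz
    if span >= min_span_s and len(rr) >= 4 and np.ptp(rr) > 0:
        t_beats = r_peaks[1:] / fs_hz  # RR assigned to its ending beat
        t_even = np.arange(t_beats[0], t_beats[-1], 1.0 / resample_hz)
        rr_even = np.interp(t_even, t_beats, rr)
        rr_even = rr_even - rr_even.mean()
        nperseg = min(len(rr_even), 256)
        freqs, psd = sg.welch(rr_even, fs=resample_hz, nperseg=nperseg)
        lf = np.trapezoid(psd[(freqs >= lf_band[0]) & (freqs < lf_band[1])],
                          freqs[(freqs >= lf_band[0]) & (freqs < lf_band[1])])
        hf = np.trapezoid(psd[(freqs >= hf_band[0]) & (freqs < hf_band[1])],
                          freqs[(freqs >= hf_band[0]) & (freqs < hf_band[1])])
        out["LF_HF"] = lf / hf if hf > 0 else np.nan
    return out


def scg_fiducials(
    scg: np.ndarray,
    r_peaks: np.ndarray,
    fs_hz: float,
    ao_window_s: tuple[float, float] = (0.0, 0.160),
    ac_window_s: tuple[float, float] = (0.150, 0.450),
) -> pd.DataFrame:
    """Aortic-opening/closing fiducials and PEP, LVET, PEP/LVET per beat.

    AO is the maximum SCG deflection in (R, R + 160 ms]; AC the maximum in
    (AO + 150 ms, AO + 450 ms].  Beats whose search windows are empty or
    violate R < AO < AC are marked NaN.
    """
    scg = np.asarray(scg, dtype=float)
    rows = []
    for r in np.asarray(r_peaks, dtype=int):
        ao = ac = np.nan
        pep = lvet = np.nan
        lo = r + max(int(round(ao_window_s[0] * fs_hz)), 1)
        hi = min(r + int(round(ao_window_s[1] * fs_hz)) + 1, len(scg))
        if hi > lo:
            ao = lo + int(np.argmax(scg[lo:hi]))
            lo2 = ao + max(int(round(ac_window_s[0] * fs_hz)), 1)
            hi2 = min(ao + int(round(ac_window_s[1] * fs_hz)) + 1, len(scg))
            if hi2 > lo2:
                ac = lo2 + int(np.argmax(scg[lo2:hi2]))
        if np.isfinite(ao) and np.isfinite(ac) and r < ao < ac:
            pep = (ao - r) / fs_hz
            lvet = (ac - ao) / fs_hz
        else:
            ao = ac = np.nan
        rows.append({"r_peak_idx": r, "ao_idx": ao, "ac_idx": ac,
                     "PEP": pep, "LVET": lvet,
                     "PEP_LVET": pep / lvet if np.isfinite(pep) and lvet > 0 else np.nan})
    return pd.DataFrame(rows)


def _pulse_foot(seg: np.ndarray, peak: int) -> int | None:
    """Latest pre-peak sample at the segment minimum (the pulse onset)."""
    if peak <= 0:
        return None
    pre = seg[: peak + 1]
    lo = pre.min()
    eps = 1e-9 * max(seg[peak] - lo, 1.0)
    at_min = np.nonzero(pre <= lo + eps)[0]
    return int(at_min[-1]) if len(at_min) else None


def ppg_features(
    rppg: np.ndarray,
    r_peaks: np.ndarray,
    ao_idx: np.ndarray,
    fs_hz: float,
    pvi_window_s: float = 8.0,
    min_amplitude: float = 1e-9,
) -> pd.DataFrame:
    """Per-beat PPGamp, PAT, nPAT, PTT and the windowed PVI.

    The pulse peak is the RPPG maximum between successive R peaks; the foot
    is the latest pre-peak minimum.  PAT = (foot - R)/fs, nPAT = PAT / RR,
    PTT = (foot - AO)/fs, PPGamp = peak - foot amplitude.  PVI is
    100 (Amax - Amin)/Amax over the beats within +/- ``pvi_window_s``/2 of
    each beat.  Beats without a usable pulse are NaN throughout.
    """
    rppg = np.asarray(rppg, dtype=float)
    r_peaks = np.asarray(r_peaks, dtype=int)
    n_beats = len(r_peaks)
    cols = {k: np.full(n_beats, np.nan) for k in ("PPGamp", "PAT", "nPAT", "PTT", "PVI")}
    if n_beats == 0:
        return pd.DataFrame(cols)
    rr_med = np.median(np.diff(r_peaks)) if n_beats >= 2 else int(0.8 * fs_hz)
    for i, r in enumerate(r_peaks):
        end = r_peaks[i + 1] if i + 1 < n_beats else min(int(r + rr_med), len(rppg))
        seg = rppg[r:end]
        if len(seg) < 3:
            continue
        peak = int(np.argmax(seg))
        amp_span = seg[peak] - seg.min()
        if amp_span < min_amplitude:
            continue  # flat / corrupted pulse -> undefined
        foot = _pulse_foot(seg, peak)
        if foot is None or foot <= 0:
            continue
        cols["PPGamp"][i] = seg[peak] - seg[foot]
        pat = foot / fs_hz  # foot index is relative to R
        cols["PAT"][i] = pat
        if i + 1 < n_beats:
            cols["nPAT"][i] = pat / ((r_peaks[i + 1] - r) / fs_hz)
        if i < len(ao_idx) and np.isfinite(ao_idx[i]):
            cols["PTT"][i] = (r + foot - ao_idx[i]) / fs_hz
    # sliding-window pleth variability index over pulse amplitudes
    t = r_peaks / fs_hz
    half = pvi_window_s / 2.0
    amp = cols["PPGamp"]
    for i in range(n_beats):
        in_win = np.abs(t - t[i]) <= half
        a = amp[in_win]
        a = a[np.isfinite(a)]
        if len(a) >= 2 and a.max() > 0:
            cols["PVI"][i] = 100.0 * (a.max() - a.min()) / a.max()
    return pd.DataFrame(cols)


def extract_feature_table(
    record: WaveformRecord,
    prefilter: bool = True,
    hrv_kwargs: dict | None = None,
    scg_kwargs: dict | None = None,
    ppg_kwargs: dict | None = None,
) -> pd.DataFrame:
    """One row per detected beat with the 12 features of the analysis.

    HRV features (HR, SDRR, SD1/SD2, LF/HF) are computed once over the whole
    record and broadcast to its beats; beat-timing features come from the SCG
    and RPPG fiducials.  With ``prefilter`` the channels are band-passed with
    the per-channel default specs first; pass ``False`` for data that are
    already band-limited (e.g. clean synthetic records, where filtering would
    only smear the constructed fiducials).
    """
    if not record.channels or all(len(v) == 0 for v in record.channels.values()):
        raise ValueError("empty waveform record")
    fs = record.fs_hz
    ecg = np.asarray(record.channels["ecg"], dtype=float)
    scg = np.asarray(record.channels.get("scg", np.zeros_like(ecg)), dtype=float)
    rppg = np.asarray(record.channels.get("rppg", np.zeros_like(ecg)), dtype=float)
    if prefilter:
        ecg = bandpass_zero_phase(ecg, fs, ECG_FILTER)
        scg = bandpass_zero_phase(scg, fs, SCG_FILTER)
        if np.ptp(rppg) > 0:
            rppg = bandpass_zero_phase(rppg, fs, RPPG_FILTER)

    r_peaks = detect_r_peaks(ecg, fs)
    hrv = hr_and_hrv(r_peaks, fs, **(hrv_kwargs or {}))
    scg_df = scg_fiducials(scg, r_peaks, fs, **(scg_kwargs or {}))
    ppg_df = ppg_features(rppg, r_peaks, scg_df["ao_idx"].to_numpy(), fs, **(ppg_kwargs or {}))

    n = len(r_peaks)
    table = pd.DataFrame({
        "subject_id": record.subject_id,
        "beat": np.arange(n),
        "r_peak_idx": r_peaks,
        "t_s": r_peaks / fs,
    })
    for k in ("HR", "SDRR", "SD1_SD2", "LF_HF"):
        table[k] = hrv[k]
    for k in ("PEP", "LVET", "PEP_LVET"):
        table[k] = scg_df[k].to_numpy() if n else np.nan
    for k in ("PPGamp", "PAT", "PTT", "nPAT", "PVI"):
        table[k] = ppg_df[k].to_numpy() if n else np.nan
    return table[["subject_id", "beat", "r_peak_idx", "t_s", *FEATURES_12]]
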