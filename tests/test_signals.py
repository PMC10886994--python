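import numpy as np
import pytest

from abvs import CohortConfig, generate_cohort, simulate_waveforms
from abvs.signals import (
    ECG_FILTER,
    RPPG_FILTER,
    SCG_FILTER,
    FilterSpec,
    bandpass_zero_phase,
    detect_r_peaks,
    extract_feature_table,
    hr_and_hrv,
    ppg_features,
    scg_fiducials,
)
from abvs.synthetic import WaveformRecord

FS = 2000.0


@pytest.fixture(scope="module")
def profile():
    return generate_cohort(CohortConfig(seed=4))[0]


@pytest.fixture(scope="module")
def clean_record(profile):
    return simulate_waveforms(profile, abvs_level=0.0, duration_s=15.0, fs_hz=FS, seed=2)


class TestBandpassZeroPhase:
    def test_in_band_sinusoid_passes_unchanged(self):
        t = np.arange(int(15 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        y = bandpass_zero_phase(x, FS, ECG_FILTER)
        mid = slice(len(x) // 4, 3 * len(x) // 4)
        assert abs(y[mid].max() - 1.0) < 0.01
        lag = np.argmax(np.correlate(y[mid], x[mid], mode="full")) - (len(x[mid]) - 1)
        assert lag == 0

    def test_dc_offset_removed(self):
        x = np.full(int(15 * FS), 3.7)
        y = bandpass_zero_phase(x, FS, ECG_FILTER)
        assert abs(y.mean()) < 1e-3

    def test_out_of_band_attenuation(self):
        t = np.arange(int(15 * FS)) / FS
        x = np.sin(2 * np.pi * 60.0 * t)
        y = bandpass_zero_phase(x, FS, ECG_FILTER)
        mid = slice(len(x) // 4, 3 * len(x) // 4)
        atten_db = -20 * np.log10(np.abs(y[mid]).max())
        assert atten_db >= 20

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_zero_phase(np.zeros(100_000), 60.0, FilterSpec(0.5, 40.0))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            bandpass_zero_phase(np.zeros(100), FS, ECG_FILTER)

    @pytest.mark.parametrize("spec, band", [
        (ECG_FILTER, (0.5, 40.0)), (SCG_FILTER, (1.0, 40.0)), (RPPG_FILTER, (0.5, 10.0)),
    ])
    def test_channel_default_passbands(self, spec, band):
        assert (spec.low_hz, spec.high_hz) == band


class TestDetectRPeaks:
    def test_recovers_known_qrs_positions(self, clean_record):
        got = detect_r_peaks(clean_record.channels["ecg"], FS)
        want = clean_record.ground_truth["r_peak_idx"].astype(int)
        assert len(got) == len(want)
        assert np.abs(got - want).max() <= 2

    def test_flat_line_gives_empty(self):
        assert len(detect_r_peaks(np.zeros(5000), FS)) == 0

    def test_refractory_merges_close_peaks(self):
        t = np.arange(int(2 * FS)) / FS
        x = np.exp(-0.5 * ((t - 1.0) / 0.008) ** 2) + 0.9 * np.exp(
            -0.5 * ((t - 1.1) / 0.008) ** 2
        )
        peaks = detect_r_peaks(x, FS)
        assert len(peaks) == 1

    def test_indices_strictly_increasing(self, clean_record):
        got = detect_r_peaks(clean_record.channels["ecg"], FS)
        assert np.all(np.diff(got) > 0)


class TestHrAndHrv:
    def test_constant_rr_closed_form(self):
        peaks = np.arange(0, 20) * int(0.75 * FS)
        out = hr_and_hrv(peaks, FS)
        assert np.isclose(out["HR"], 80.0)
        assert out["SDRR"] == 0.0
        assert np.isnan(out["SD1_SD2"])  # 0/0 Poincare ratio

    def test_alternating_rr_is_pure_short_term_variability(self):
        # perfectly alternating two-value RR: 2 Var(RR) = SD1^2 exactly, so
        # SD2 = 0 and the Poincare ratio is undefined
        rr = np.tile([0.70, 0.80], 10)
        peaks = (np.concatenate([[0], np.cumsum(rr)]) * FS).astype(int)
        out = hr_and_hrv(peaks, FS)
        assert np.isclose(out["HR"], 80.0)
        assert np.isnan(out["SD1_SD2"])

    def test_varied_rr_matches_hand_calculation(self):
        rr0 = [0.70, 0.80, 0.74, 0.77, 0.71, 0.79, 0.73, 0.76, 0.72, 0.78]
        peaks = (np.concatenate([[0], np.cumsum(rr0)]) * FS).astype(int)
        rr = np.diff(peaks) / FS  # quantized intervals the extractor sees
        out = hr_and_hrv(peaks, FS)
        # independent arithmetic on the defining sums
        n = len(rr)
        mean_rr = rr.sum() / n
        var_rr = ((rr - mean_rr) ** 2).sum() / (n - 1)
        d = (rr[:-1] - rr[1:]) / np.sqrt(2)
        sd1 = np.sqrt(((d - d.sum() / len(d)) ** 2).sum() / (len(d) - 1))
        sd2 = np.sqrt(2 * var_rr - sd1**2)
        assert np.isclose(out["HR"], 60.0 / mean_rr)
        assert np.isclose(out["SDRR"], np.sqrt(var_rr))
        assert np.isclose(out["SD1_SD2"], sd1 / sd2)

    def test_slow_modulation_dominates_lf(self):
        # 0.1 Hz RR modulation -> essentially all variability in the LF band
        n = 120
        base, mod = 0.75, 0.05
        rr, t = [], 0.0
        for _ in range(n):
            rr.append(base + mod * np.sin(2 * np.pi * 0.1 * t))
            t += rr[-1]
        peaks = (np.concatenate([[0], np.cumsum(rr)]) * FS).astype(int)
        out = hr_and_hrv(peaks, FS)
        assert out["LF_HF"] > 10

    def test_insufficient_beats_give_nan_not_zero(self):
        out = hr_and_hrv(np.array([100]), FS)
        assert all(np.isnan(v) for v in out.values())


class TestScgFiducials:
    def test_round_trip_recovery(self, clean_record):
        gt = clean_record.ground_truth
        peaks = gt["r_peak_idx"].astype(int)
        out = scg_fiducials(clean_record.channels["scg"], peaks, FS)
        assert np.nanmax(np.abs(out["PEP"] - gt["pep_s"])) <= 1.0 / FS
        assert np.nanmax(np.abs(out["LVET"] - gt["lvet_s"])) <= 1.0 / FS + 1e-12
        np.testing.assert_allclose(out["PEP_LVET"], out["PEP"] / out["LVET"])

    def test_sampling_rate_invariance_of_seconds(self, profile):
        out = {}
        for fs in (2000.0, 4000.0):
            rec = simulate_waveforms(profile, 0.0, 10.0, fs, seed=3)
            peaks = rec.ground_truth["r_peak_idx"].astype(int)
            out[fs] = scg_fiducials(rec.channels["scg"], peaks, fs)["PEP"].mean()
        assert abs(out[2000.0] - out[4000.0]) <= 1.0 / 2000

    def test_empty_window_marks_undefined(self):
        scg = np.zeros(1000)
        out = scg_fiducials(scg, np.array([990]), FS)
        assert np.isnan(out["PEP"]).all()

    def test_amplitude_scale_invariance(self, clean_record):
        peaks = clean_record.ground_truth["r_peak_idx"].astype(int)
        a = scg_fiducials(clean_record.channels["scg"], peaks, FS)
        b = scg_fiducials(3.5 * clean_record.channels["scg"], peaks, FS)
        np.testing.assert_array_equal(a["PEP"], b["PEP"])
        np.testing.assert_array_equal(a["LVET"], b["LVET"])


class TestPpgFeatures:
    def _fiducials(self, record):
        peaks = record.ground_truth["r_peak_idx"].astype(int)
        scg_df = scg_fiducials(record.channels["scg"], peaks, FS)
        return peaks, scg_df["ao_idx"].to_numpy()

    def test_pat_round_trip(self, clean_record):
        peaks, ao = self._fiducials(clean_record)
        out = ppg_features(clean_record.channels["rppg"], peaks, ao, FS)
        gt = clean_record.ground_truth["pat_s"]
        assert np.nanmax(np.abs(out["PAT"] - gt)) <= 1.0 / FS

    def test_pat_decomposes_into_pep_plus_ptt(self, clean_record):
        peaks, ao = self._fiducials(clean_record)
        out = ppg_features(clean_record.channels["rppg"], peaks, ao, FS)
        resid = out["PAT"] - (out["PTT"] + (ao - peaks) / FS)
        assert np.nanmax(np.abs(resid)) <= 2.0 / FS

    def test_constant_amplitude_gives_zero_pvi(self, profile):
        rec = simulate_waveforms(profile, 0.0, 12.0, FS, seed=5, amp_modulation=0.0)
        peaks, ao = self._fiducials(rec)
        out = ppg_features(rec.channels["rppg"], peaks, ao, FS)
        assert np.nanmax(np.abs(out["PVI"])) < 1e-6

    def test_flat_channel_marks_all_undefined(self, clean_record):
        peaks, ao = self._fiducials(clean_record)
        out = ppg_features(np.zeros_like(clean_record.channels["rppg"]), peaks, ao, FS)
        for col in ("PPGamp", "PAT", "nPAT", "PTT", "PVI"):
            assert np.isnan(out[col]).all()


class TestExtractFeatureTable:
    def test_clean_record_round_trip_no_undefined(self, clean_record):
        table = extract_feature_table(clean_record, prefilter=False)
        gt = clean_record.ground_truth
        core = table[["HR", "PEP", "LVET", "PEP_LVET", "PAT", "PPGamp"]]
        assert core.notna().all().all()
        assert np.abs(table["PEP"] - gt["pep_s"]).max() <= 1.0 / FS
        assert np.abs(table["PAT"] - gt["pat_s"]).max() <= 1.0 / FS
        hr_true = 60.0 / gt["rr_s"].mean()
        assert abs(table["HR"].iloc[0] - hr_true) < 0.5

    def test_flat_rppg_leaves_ecg_scg_features_intact(self, clean_record):
        rec = WaveformRecord(
            subject_id=clean_record.subject_id, fs_hz=FS,
            channels={"ecg": clean_record.channels["ecg"],
                      "scg": clean_record.channels["scg"],
                      "rppg": np.zeros_like(clean_record.channels["ecg"])},
        )
        table = extract_feature_table(rec, prefilter=False)
        assert table[["PPGamp", "PAT", "PTT", "nPAT", "PVI"]].isna().all().all()
        assert table[["HR", "PEP", "LVET"]].notna().all().all()

    def test_one_beat_record_leaves_hr_undefined(self):
        t = np.arange(int(2 * FS)) / FS
        ecg = np.exp(-0.5 * ((t - 1.0) / 0.008) ** 2)
        rec = WaveformRecord(subject_id="x", fs_hz=FS,
                             channels={"ecg": ecg, "scg": np.zeros_like(ecg),
                                       "rppg": np.zeros_like(ecg)})
        table = extract_feature_table(rec, prefilter=False)
        assert len(table) == 1 and np.isnan(table["HR"].iloc[0])

    def test_empty_record_rejected(self):
        rec = WaveformRecord(subject_id="x", fs_hz=FS,
                             channels={"ecg": np.array([])})
        with pytest.raises(ValueError):
            extract_feature_table(rec, prefilter=False)

    def test_prefiltered_extraction_still_recovers_timing(self, profile):
        rec = simulate_waveforms(profile, 0.0, 15.0, FS, seed=6, noise_sd=0.005)
        table = extract_feature_table(rec, prefilter=True)
        gt = rec.ground_truth
        assert abs(np.nanmedian(table["PEP"]) - gt["pep_s"][0]) < 0.01
        assert abs(np.nanmedian(table["LVET"]) - gt["lvet_s"][0]) < 0.02
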