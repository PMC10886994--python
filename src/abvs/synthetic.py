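"""Seeded synthetic cohorts emulating porcine hemorrhage feature data.

The generator produces the two kinds of data the analysis pipeline consumes:

* an *ABVS cohort* — six swine by default, each hemorrhaged in equal steps of
  its tolerable blood volume until decompensation, with per-heartbeat features
  recorded at baseline and after each post-step stabilization period;
* an *external cohort* — a larger baseline-only group (default 18 subjects,
  emulating a myocardial-infarction study in which only baseline data were
  usable and RPPG features could not be extracted), which supplies the global
  normalization statistics for the external-reference methods.

The statistical structure is deliberately simple and fully documented:
subject baselines are log-normal around population means (guaranteeing
positivity of ratio-scaled features), each feature responds linearly in the
ABVS fraction with a per-subject multiplicative sensitivity, and beat-level
noise is additive Gaussian with SD proportional to the subject's baseline
mean.  ``simulate_waveforms`` additionally renders ECG/SCG/RPPG waveforms
with known fiducial timings for testing the signal-feature extractor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURES_4, FEATURES_12, META_COLUMNS
from .labeling import assign_labels

__all__ = [
    "SubjectProfile",
    "CohortConfig",
    "WaveformRecord",
    "generate_cohort",
    "simulate_feature_table",
    "simulate_external_table",
    "simulate_waveforms",
    "read_feature_table",
    "write_feature_table",
    "write_waveform_record",
    "read_waveform_record",
]

# Population anchors for a juvenile Yorkshire swine cohort.  Means are typical
# resting values in feature units; effect sizes are the fractional change of
# each feature at full decompensation (ABVS = 100%), signed by the expected
# physiological direction during progressive hemorrhage (sympathetic HR rise,
# shortened ejection with reduced preload, vasoconstriction-lengthened pulse
# transit, damped peripheral pulse).  Magnitudes are calibration choices of
# this generator, not measured values.
POPULATION_MEANS: dict[str, float] = {
    "HR": 75.0,       # beats/min
    "SDRR": 0.025,    # s
    "SD1_SD2": 0.40,  # dimensionless
    "LF_HF": 2.0,     # dimensionless
    "PEP": 0.080,     # s
    "LVET": 0.300,    # s
    "PEP_LVET": 0.267,
    "PPGamp": 1.0,    # signal units
    "PAT": 0.150,     # s
    "PTT": 0.070,     # s
    "nPAT": 0.19,
    "PVI": 12.0,      # percent
}

EFFECT_SIZES: dict[str, float] = {
    "HR": 0.45,
    "SDRR": -0.30,
    "SD1_SD2": -0.25,
    "LF_HF": 0.50,
    "PEP": 0.30,
    "LVET": -0.25,
    "PEP_LVET": 0.73,
    "PPGamp": -0.50,
    "PAT": 0.20,
    "PTT": 0.30,
    "nPAT": 0.40,
    "PVI": 0.60,
}


@dataclass(frozen=True)
class SubjectProfile:
    """One animal's demographics and latent feature-response parameters."""

    subject_id: str
    sex: str                      # "CM" (castrated male) or "F"
    age_days: int
    weight_kg: float
    n_bleed_steps: int
    baseline_means: dict[str, float]
    sensitivities: dict[str, float]

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValueError("weight_kg must be positive")
        if self.sex not in ("CM", "F"):
            raise ValueError(f"sex must be 'CM' or 'F', got {self.sex!r}")
        if self.age_days <= 0:
            raise ValueError("age_days must be positive")


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    ``population_feature_cv`` is the between-subject coefficient of variation
    of the log-normal baseline means; ``noise_cv`` is the within-subject
    beat-level CV of the additive Gaussian noise; ``effect_sizes`` are
    population-mean sensitivities, individualized with a mild between-subject
    spread (``sensitivity_cv``).  ``step_count_distribution`` mirrors the
    six-animal study composition (one animal with 2 steps, three with 3, two
    with 4).
    """

    n_subjects: int = 6
    beats_per_level: int = 60
    population_feature_means: dict[str, float] = field(
        default_factory=lambda: dict(POPULATION_MEANS)
    )
    population_feature_cv: dict[str, float] = field(
        default_factory=lambda: {f: 0.10 for f in FEATURES_12}
    )
    effect_sizes: dict[str, float] = field(default_factory=lambda: dict(EFFECT_SIZES))
    noise_cv: dict[str, float] = field(
        default_factory=lambda: {f: 0.05 for f in FEATURES_12}
    )
    step_count_distribution: dict[int, float] = field(
        default_factory=lambda: {2: 1 / 6, 3: 3 / 6, 4: 2 / 6}
    )
    sensitivity_cv: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.beats_per_level < 1:
            raise ValueError("beats_per_level must be >= 1")
        probs = np.array(list(self.step_count_distribution.values()), dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("step_count_distribution probabilities must be >= 0 and sum to 1")
        if any(k not in (2, 3, 4) for k in self.step_count_distribution):
            raise ValueError("step counts must lie in {2, 3, 4}")
        for name, cvs in (("population_feature_cv", self.population_feature_cv),
                          ("noise_cv", self.noise_cv)):
            if any(v < 0 for v in cvs.values()):
                raise ValueError(f"{name} values must be >= 0")


@dataclass
class WaveformRecord:
    """Synchronous multi-channel waveforms with generator ground truth."""

    subject_id: str
    fs_hz: float
    channels: dict[str, np.ndarray]
    ground_truth: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have identical length")


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child generators so cohort/table/external draws decouple."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _lognormal_around(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Log-normal draws with the requested arithmetic mean and CV."""
    if cv == 0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def generate_cohort(config: CohortConfig) -> list[SubjectProfile]:
    """Draw ``config.n_subjects`` subject profiles, deterministically in seed."""
    config.validate()
    rng = _streams(config.seed, 3)[0]
    features = list(config.population_feature_means)

    steps = list(config.step_count_distribution)
    probs = [config.step_count_distribution[k] for k in steps]
    n = config.n_subjects

    step_counts = rng.choice(steps, size=n, p=probs)
    sexes = rng.choice(["CM", "F"], size=n)
    ages = rng.integers(110, 155, size=n)
    weights = _lognormal_around(rng, 63.0, 0.08, n)
    base = {f: _lognormal_around(rng, config.population_feature_means[f],
                                 config.population_feature_cv.get(f, 0.0), n)
            for f in features}
    sens_mult = (
        1.0 + config.sensitivity_cv * rng.standard_normal((n, len(features)))
        if config.sensitivity_cv > 0 else np.ones((n, len(features)))
    )

    profiles = []
    for i in range(n):
        profiles.append(
            SubjectProfile(
                subject_id=f"pig{i + 1:02d}",
                sex=str(sexes[i]),
                age_days=int(ages[i]),
                weight_kg=float(weights[i]),
                n_bleed_steps=int(step_counts[i]),
                baseline_means={f: float(base[f][i]) for f in features},
                sensitivities={
                    f: float(config.effect_sizes.get(f, 0.0) * sens_mult[i, j])
                    for j, f in enumerate(features)
                },
            )
        )
    return profiles


def simulate_feature_table(
    profiles: list[SubjectProfile], config: CohortConfig
) -> pd.DataFrame:
    """Per-heartbeat feature table over each subject's ABVS levels.

    For subject p at level ``l`` (percent), feature f is drawn as

        x = m_pf * (1 + s_pf * l/100) + eps,   eps ~ N(0, (noise_cv_f * m_pf)^2)

    with ``m_pf`` the subject baseline mean and ``s_pf`` its sensitivity.
    Only baseline (l = 0) and post-step stabilization beats are emitted; the
    transient beats during the blood draws themselves are not part of the
    analysis and are never generated.
    """
    if not profiles:
        raise ValueError("profiles must be nonempty")
    config.validate()
    rng = _streams(config.seed, 3)[1]
    features = list(config.population_feature_means)
    nb = config.beats_per_level

    blocks = []
    for p in profiles:
        if p.n_bleed_steps not in (2, 3, 4):
            raise ValueError(
                f"subject {p.subject_id}: step count {p.n_bleed_steps} outside {{2,3,4}}"
            )
        scheme = assign_labels(p.n_bleed_steps)
        for step_idx, level in enumerate(scheme.labels):
            block = {
                "subject_id": p.subject_id,
                "phase": "baseline" if step_idx == 0 else "stabilization",
                "step_index": step_idx,
                "abvs_label": level,
                "weight_kg": p.weight_kg,
            }
            df = pd.DataFrame(block, index=range(nb))
            for f in features:
                m = p.baseline_means[f]
                det = m * (1.0 + p.sensitivities[f] * level / 100.0)
                sd = config.noise_cv.get(f, 0.0) * m
                df[f] = det + sd * rng.standard_normal(nb)
            blocks.append(df)
    table = pd.concat(blocks, ignore_index=True)
    return table[list(META_COLUMNS) + ["weight_kg"] + features]


def simulate_external_table(
    n_subjects: int = 18, config: CohortConfig | None = None
) -> pd.DataFrame:
    """Baseline-only external cohort restricted to the ECG/SCG feature set.

    Emulates a separate study whose subjects never underwent blood loss and
    whose optical (RPPG) channel was unusable, leaving HR, PEP, LVET and
    PEP/LVET as the only shared features.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    config = config if config is not None else CohortConfig()
    config.validate()
    rng = _streams(config.seed, 3)[2]
    nb = config.beats_per_level

    blocks = []
    for i in range(n_subjects):
        row = {
            "subject_id": f"mi{i + 1:02d}",
            "phase": "baseline",
            "step_index": 0,
            "abvs_label": 0.0,
        }
        df = pd.DataFrame(row, index=range(nb))
        for f in FEATURES_4:
            m = _lognormal_around(
                rng, config.population_feature_means[f],
                config.population_feature_cv.get(f, 0.0), 1,
            )[0]
            sd = config.noise_cv.get(f, 0.0) * m
            df[f] = m + sd * rng.standard_normal(nb)
        blocks.append(df)
    table = pd.concat(blocks, ignore_index=True)
    return table[list(META_COLUMNS) + list(FEATURES_4)]


def _gaussian_bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def simulate_waveforms(
    profile: SubjectProfile,
    abvs_level: float,
    duration_s: float,
    fs_hz: float = 2000.0,
    seed: int = 0,
    rr_jitter_s: float = 0.0,
    noise_sd: float = 0.0,
    resp_hz: float = 0.25,
    amp_modulation: float = 0.10,
) -> WaveformRecord:
    """Render ECG/SCG/RPPG waveforms with known per-beat fiducial timings.

    The ECG is a train of Gaussian QRS complexes; the SCG carries an
    aortic-opening deflection at R + PEP and a smaller aortic-closing
    deflection at R + PEP + LVET; the RPPG is a squared-half-sine pulse whose
    foot sits exactly at R + PAT, with amplitude modulated at the respiratory
    rate (driving the pleth variability index).  ``ground_truth`` holds the
    per-beat RR/PEP/LVET/PAT values and R-peak sample indices used for
    construction; PTT is PAT - PEP by construction.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs_hz < 200:
        raise ValueError("fs_hz must be >= 200")
    rng = np.random.default_rng(seed)
    frac = abvs_level / 100.0

    def level_value(f: str) -> float:
        return profile.baseline_means[f] * (1.0 + profile.sensitivities.get(f, 0.0) * frac)

    hr = level_value("HR")
    pep = level_value("PEP")
    lvet = level_value("LVET")
    pat = level_value("PAT")
    ppg_amp = level_value("PPGamp")
    rr_mean = 60.0 / hr

    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    ecg = np.zeros(n)
    scg = np.zeros(n)
    rppg = np.zeros(n)

    r_times, rr_list = [], []
    tr = 0.1  # first R peak at 100 ms
    while tr < duration_s - max(pat + 0.4, pep + lvet + 0.1):
        r_times.append(tr)
        rr = rr_mean + (rr_jitter_s * rng.standard_normal() if rr_jitter_s > 0 else 0.0)
        rr = max(rr, 0.3)
        rr_list.append(rr)
        tr += rr
    r_times = np.asarray(r_times)
    rr_arr = np.asarray(rr_list)
    r_idx = np.round(r_times * fs_hz).astype(int)

    for i, tri in enumerate(r_idx / fs_hz):
        ecg += _gaussian_bump(t, tri, 0.008)
        scg += 1.0 * _gaussian_bump(t, tri + pep, 0.005)
        scg += 0.6 * _gaussian_bump(t, tri + pep + lvet, 0.005)
        # RPPG pulse: zero at the foot sample, strictly positive afterwards.
        foot = np.round((tri + pat) * fs_hz) / fs_hz
        amp = ppg_amp * (1.0 + amp_modulation * np.sin(2 * np.pi * resp_hz * foot))
        width = 0.30
        mask = (t > foot) & (t < foot + width)
        rppg[mask] += amp * np.sin(np.pi * (t[mask] - foot) / width) ** 2

    if noise_sd > 0:
        ecg += noise_sd * rng.standard_normal(n)
        scg += noise_sd * rng.standard_normal(n)
        rppg += noise_sd * rng.standard_normal(n)

    nb = len(r_idx)
    ground_truth = {
        "r_peak_idx": r_idx.astype(float),
        "rr_s": rr_arr,
        "pep_s": np.full(nb, pep),
        "lvet_s": np.full(nb, lvet),
        "pat_s": np.full(nb, pat),
    }
    return WaveformRecord(
        subject_id=profile.subject_id,
        fs_hz=fs_hz,
        channels={"ecg": ecg, "scg": scg, "rppg": rppg},
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# plain-text I/O

def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    table["subject_id"] = table["subject_id"].astype(str)
    return table


def write_waveform_record(record: WaveformRecord, path: str | Path) -> None:
    """Waveforms as multi-column CSV with a JSON metadata sidecar."""
    path = Path(path)
    n = len(next(iter(record.channels.values())))
    df = pd.DataFrame({"t_s": np.arange(n) / record.fs_hz, **record.channels})
    df.to_csv(path, index=False)
    meta = {"subject_id": record.subject_id, "fs_hz": record.fs_hz}
    path.with_suffix(".meta.json").write_text(json.dumps(meta))


def read_waveform_record(path: str | Path) -> WaveformRecord:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    channels = {c: df[c].to_numpy() for c in df.columns if c != "t_s"}
    return WaveformRecord(
        subject_id=str(meta["subject_id"]), fs_hz=float(meta["fs_hz"]), channels=channels
    )
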