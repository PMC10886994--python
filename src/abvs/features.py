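"""Canonical feature names and table schema shared across the package.

A *feature table* is a pandas DataFrame with one row per heartbeat and the
mandatory metadata columns ``subject_id``, ``phase``, ``step_index`` and
``abvs_label`` followed by feature columns named as below.  ``abvs_label`` is
the discrete absolute blood-volume status (ABVS) of the beat in percent of the
subject's tolerable blood loss (0 = euvolemic baseline, 100 = decompensation).
"""

from __future__ import annotations

import pandas as pd

#: The full 12-feature set extracted from ECG, SCG and RPPG waveforms.
FEATURES_12: tuple[str, ...] = (
    "HR",        # heart rate, beats/min
    "SDRR",      # SD of RR intervals, s
    "SD1_SD2",   # Poincare short/long axis ratio, dimensionless
    "LF_HF",     # low/high frequency RR power ratio, dimensionless
    "PEP",       # pre-ejection period, s
    "LVET",      # left ventricular ejection time, s
    "PEP_LVET",  # PEP/LVET, dimensionless
    "PPGamp",    # PPG pulse amplitude, signal units
    "PAT",       # pulse arrival time, s
    "PTT",       # pulse transit time, s
    "nPAT",      # PAT normalized by the concurrent RR interval
    "PVI",       # pleth variability index, percent
)

#: The reduced ECG+SCG feature set used by the default estimation model.
FEATURES_4: tuple[str, ...] = ("HR", "PEP", "LVET", "PEP_LVET")

#: Metadata columns every feature table carries ahead of the features.
META_COLUMNS: tuple[str, ...] = ("subject_id", "phase", "step_index", "abvs_label")

#: Phases whose beats enter normalization statistics (post-bleed beats are
#: recorded only after cardiovascular stabilization; mid-bleed data are never
#: emitted by the simulator and are excluded from real recordings upstream).
NORMALIZATION_PHASES: tuple[str, ...] = ("baseline", "stabilization")


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature columns present in ``table``, in canonical order."""
    return [f for f in FEATURES_12 if f in table.columns]


def validate_feature_table(table: pd.DataFrame) -> None:
    """Raise ``ValueError`` if mandatory schema columns are missing."""
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing mandatory columns: {missing}")
    if not feature_columns(table):
        raise ValueError("feature table contains no recognized feature columns")
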