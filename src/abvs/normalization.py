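"""Feature normalization: individual-baseline, LOSO, external-reference, and
the three common normalizers, plus the Spearman comparison procedure.

The scientific question these transforms address is whether blood-volume
status can be estimated *without* a subject's own pre-injury baseline.  The
reference transform is individual-baseline normalization (IBN),

    x' = (x - mu_b,p) / mu_b,p,

the fractional change of each feature from the subject's own baseline mean
mu_b,p.  The seven baseline-free alternatives replace mu_b,p with statistics
that are available without the subject's history:

=========  =================================================================
Method 1   z-score with leave-one-subject-out (LOSO) statistics:
           (x - mu_loso) / sigma_loso, where mu/sigma pool the *other*
           subjects' beats.
Method 2   z-score with global statistics of an external (non-hemorrhage)
           cohort: (x - mu_p) / sigma_p.
Method 3   fractional change from the LOSO mean: (x - mu_loso) / mu_loso.
Method 4   fractional change from the external global mean: (x - mu_p)/mu_p.
Method 5   Method 1 divided by the subject's weight (kg).
Method 6   Method 3 divided by the subject's weight (kg).
Method 7   feature-specific: Method 3 multiplied by weight for HR and LVET;
           Method 6 for PEP and PEP/LVET.
=========  =================================================================

Normalization statistics are computed over baseline + post-step stabilization
beats only.  LOSO statistics pool all held-in beats (not a mean of subject
means); sample (n-1) standard deviations are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import NORMALIZATION_PHASES, feature_columns

__all__ = [
    "NormalizationParams",
    "MethodSpec",
    "METHOD_IDS",
    "baseline_means",
    "apply_ibn",
    "loso_stats",
    "external_global_stats",
    "apply_method",
    "normalize_features",
    "common_normalizers",
    "spearman_compare",
]

METHOD_IDS = ("none", "ibn", "m1", "m2", "m3", "m4", "m5", "m6", "m7",
              "zscore", "minmax", "decimal")
_LOSO_METHODS = ("m1", "m3", "m5", "m6", "m7")
_EXTERNAL_METHODS = ("m2", "m4")
_WEIGHTED_METHODS = ("m5", "m6", "m7")

#: Default feature-specific assignment for Method 7 (only these four features
#: are shared with the external cohort, so Method 7 is defined on them).
M7_DEFAULT_ASSIGNMENT = {
    "HR": "m3_times_weight",
    "LVET": "m3_times_weight",
    "PEP": "m6",
    "PEP_LVET": "m6",
}


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature location/scale statistics with provenance."""

    mu: pd.Series
    sigma: pd.Series
    source: str  # individual_baseline | loso_held_in | external_global
    held_out_subject: str | None = None
    weight_kg: float | None = None


@dataclass(frozen=True)
class MethodSpec:
    """A normalization method identifier plus Method-7's feature assignment."""

    method_id: str
    feature_assignment: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.method_id not in METHOD_IDS:
            raise ValueError(f"unknown method {self.method_id!r}; valid: {METHOD_IDS}")

    def assignment_for(self, features: list[str]) -> dict[str, str]:
        assignment = self.feature_assignment or M7_DEFAULT_ASSIGNMENT
        missing = [f for f in features if f not in assignment]
        if missing:
            raise ValueError(f"method 7 assignment does not cover features {missing}")
        return assignment


def _stat_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Rows eligible for normalization statistics (stabilized periods only)."""
    if "phase" in table.columns:
        return table[table["phase"].isin(NORMALIZATION_PHASES)]
    return table


def baseline_means(
    table: pd.DataFrame, features: list[str] | None = None
) -> dict[str, NormalizationParams]:
    """Per-subject baseline means mu_b,p over each subject's own baseline beats."""
    features = features or feature_columns(table)
    out: dict[str, NormalizationParams] = {}
    for sid, grp in table.groupby("subject_id", sort=False):
        base = grp[grp["phase"] == "baseline"]
        if len(base) == 0:
            raise ValueError(f"subject {sid!r} has no baseline-phase rows")
        mu = base[features].mean()
        sigma = base[features].std(ddof=1)
        out[str(sid)] = NormalizationParams(mu=mu, sigma=sigma, source="individual_baseline")
    return out


def apply_ibn(
    table: pd.DataFrame,
    baselines: dict[str, NormalizationParams] | None = None,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Individual-baseline normalization x' = (x - mu_b,p) / mu_b,p."""
    features = features or feature_columns(table)
    baselines = baselines if baselines is not None else baseline_means(table, features)
    out = table.copy()
    for sid, grp_idx in table.groupby("subject_id", sort=False).groups.items():
        params = baselines[str(sid)]
        mu = params.mu[features]
        if (mu == 0).any():
            bad = list(mu.index[mu == 0])
            raise ValueError(f"subject {sid!r}: zero baseline mean for {bad}")
        out.loc[grp_idx, features] = (table.loc[grp_idx, features] - mu) / mu
    return out


def loso_stats(
    table: pd.DataFrame, held_out: str, features: list[str] | None = None
) -> NormalizationParams:
    """Pooled mean/SD of every *other* subject's stabilized beats.

    The held-out subject's rows contribute nothing (the leakage contract on
    which LOSO evaluation rests).
    """
    features = features or feature_columns(table)
    subjects = table["subject_id"].astype(str).unique()
    if len(subjects) < 2:
        raise ValueError("loso_stats requires at least 2 subjects")
    if str(held_out) not in subjects:
        raise ValueError(f"held-out subject {held_out!r} not in table")
    held_in = _stat_rows(table[table["subject_id"].astype(str) != str(held_out)])
    return NormalizationParams(
        mu=held_in[features].mean(),
        sigma=held_in[features].std(ddof=1),
        source="loso_held_in",
        held_out_subject=str(held_out),
    )


def external_global_stats(
    external_table: pd.DataFrame, features: list[str] | None = None
) -> NormalizationParams:
    """Global mean/SD pooled over all beats of the external cohort."""
    if len(external_table) == 0:
        raise ValueError("external table is empty")
    features = features or feature_columns(external_table)
    rows = _stat_rows(external_table)
    return NormalizationParams(
        mu=rows[features].mean(),
        sigma=rows[features].std(ddof=1),
        source="external_global",
    )


def _check_nonzero(values: pd.Series, what: str) -> None:
    bad = list(values.index[(values == 0) | values.isna()])
    if bad:
        raise ValueError(f"{what} is zero/undefined for features {bad}")


def _transform(
    x: pd.DataFrame,
    method_id: str,
    params: NormalizationParams,
    weight: float | None,
    assignment: dict[str, str] | None,
) -> pd.DataFrame:
    features = list(x.columns)
    mu, sigma = params.mu[features], params.sigma[features]
    if method_id in ("m1", "m2", "m5"):
        _check_nonzero(sigma, "sigma")
        out = (x - mu) / sigma
    elif method_id in ("m3", "m4", "m6"):
        _check_nonzero(mu, "mu")
        out = (x - mu) / mu
    elif method_id == "m7":
        _check_nonzero(mu, "mu")
        out = (x - mu) / mu
        assert assignment is not None
        for f in features:
            if assignment[f] == "m3_times_weight":
                out[f] = out[f] * weight
            elif assignment[f] == "m6":
                out[f] = out[f] / weight
            else:
                raise ValueError(f"unknown m7 sub-method {assignment[f]!r} for {f}")
        return out
    else:  # pragma: no cover
        raise ValueError(method_id)
    if method_id in ("m5", "m6"):
        out = out / weight
    return out


def apply_method(
    table: pd.DataFrame,
    spec: MethodSpec | str,
    params: NormalizationParams | dict[str, NormalizationParams] | None = None,
    weights: dict[str, float] | None = None,
    external_table: pd.DataFrame | None = None,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Apply one normalization method to every feature cell of ``table``.

    LOSO-based methods (1, 3, 5, 6, 7) transform each subject with parameters
    computed from the other subjects; external methods (2, 4) apply one fixed
    per-feature affine map to all subjects.  ``params`` may be supplied
    (a per-subject dict for LOSO/IBN methods, a single ``NormalizationParams``
    for external methods) or is computed from ``table``/``external_table``.
    ``weights`` maps subject_id to weight in kg (required for methods 5-7;
    taken from a ``weight_kg`` column if present).
    """
    if isinstance(spec, str):
        spec = MethodSpec(spec)
    mid = spec.method_id
    features = features or feature_columns(table)

    if mid == "none":
        return table.copy()
    if mid in ("zscore", "minmax", "decimal"):
        return common_normalizers(table, mid, features)
    if mid == "ibn":
        return apply_ibn(table, params, features)  # type: ignore[arg-type]

    if mid in _WEIGHTED_METHODS and weights is None:
        if "weight_kg" not in table.columns:
            raise ValueError(f"method {mid} requires subject weights")
        weights = (
            table.groupby("subject_id", sort=False)["weight_kg"].first().astype(float).to_dict()
        )

    out = table.copy()
    assignment = spec.assignment_for(features) if mid == "m7" else None

    if mid in _EXTERNAL_METHODS:
        if params is None:
            if external_table is None:
                raise ValueError(f"method {mid} requires an external table or params")
            params = external_global_stats(external_table, features)
        out[features] = _transform(table[features], mid, params, None, None)
        return out

    # LOSO-based methods: each subject gets its own held-out parameters.
    for sid, grp_idx in table.groupby("subject_id", sort=False).groups.items():
        sid = str(sid)
        p = params[sid] if isinstance(params, dict) else loso_stats(table, sid, features)
        w = None
        if mid in _WEIGHTED_METHODS:
            if sid not in weights:  # type: ignore[operator]
                raise ValueError(f"missing weight for subject {sid!r}")
            w = float(weights[sid])  # type: ignore[index]
        out.loc[grp_idx, features] = _transform(
            table.loc[grp_idx, features], mid, p, w, assignment
        ).to_numpy()
    return out


def normalize_features(
    table: pd.DataFrame,
    method: str,
    external_table: pd.DataFrame | None = None,
    weights: dict[str, float] | None = None,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Convenience wrapper: compute whatever statistics ``method`` needs and
    apply it (see :func:`apply_method`)."""
    return apply_method(
        table, MethodSpec(method), weights=weights,
        external_table=external_table, features=features,
    )


def common_normalizers(
    table: pd.DataFrame, kind: str, features: list[str] | None = None
) -> pd.DataFrame:
    """Whole-table z-score, min-max, or decimal-scaling normalization."""
    if kind not in ("zscore", "minmax", "decimal"):
        raise ValueError(f"kind must be zscore|minmax|decimal, got {kind!r}")
    features = features or feature_columns(table)
    out = table.copy()
    x = table[features]
    if kind == "zscore":
        sigma = x.std(ddof=1)
        _check_nonzero(sigma, "sigma")
        out[features] = (x - x.mean()) / sigma
    elif kind == "minmax":
        lo, hi = x.min(), x.max()
        span = hi - lo
        _check_nonzero(span, "max - min")
        out[features] = (x - lo) / span
    else:  # decimal scaling: x / 10^k with k the smallest int making max|x| < 1
        maxabs = x.abs().max()
        k = pd.Series(0, index=maxabs.index, dtype=int)
        pos = maxabs > 0
        k[pos] = np.floor(np.log10(maxabs[pos])).astype(int) + 1
        # guard against log10 edge cases at exact powers of ten
        for f in features:
            while maxabs[f] / 10.0 ** k[f] >= 1.0:
                k[f] += 1
            while k[f] > 0 and maxabs[f] / 10.0 ** (k[f] - 1) < 1.0:
                k[f] -= 1
        out[features] = x / np.power(10.0, k)
    return out


def spearman_compare(
    table_a: pd.DataFrame, table_b: pd.DataFrame, features: list[str] | None = None
) -> pd.DataFrame:
    """Per-feature Spearman rank correlation between two aligned tables.

    Returns a DataFrame indexed by feature with columns ``rho`` and
    ``p_value`` (two-sided).  Because Spearman correlation depends only on
    ranks, any strictly increasing per-feature transform of ``table_b``
    leaves every rho unchanged — which is why the z-score, min-max and
    decimal-scaling rows of the comparison are identical.
    """
    features = features or [f for f in feature_columns(table_a) if f in table_b.columns]
    if len(table_a) != len(table_b):
        raise ValueError("tables must have equal row counts (aligned rows)")
    rows = []
    for f in features:
        a = np.asarray(table_a[f], dtype=float)
        b = np.asarray(table_b[f], dtype=float)
        if np.all(a == a[0]) or np.all(b == b[0]):
            rho, p = np.nan, np.nan
        else:
            rho, p = sps.spearmanr(a, b)
        rows.append({"feature": f, "rho": rho, "p_value": p})
    return pd.DataFrame(rows).set_index("feature")
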