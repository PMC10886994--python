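"""Discrete ABVS labels, the decompensation binary label, and class weights.

Each subject tolerates a different number of equal blood-loss steps before
cardiovascular collapse, so its discrete ABVS labels are the equally spaced
grid 100*i/n_steps for i = 0..n_steps: a subject with 2 steps is labeled
{0, 50, 100}, with 3 steps {0, 33.3, 66.7, 100}, with 4 steps
{0, 25, 50, 75, 100}.  Training always uses the exact (unrounded) values;
rounding to integer percent is display-only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LabelScheme", "assign_labels", "decompensation_binary", "class_weights"]

_LABEL_TOL = 1e-9


@dataclass(frozen=True)
class LabelScheme:
    """The ordered discrete ABVS labels for one subject."""

    n_steps: int
    labels: tuple[float, ...]

    def rounded(self) -> tuple[int, ...]:
        """Labels rounded to the nearest integer percent (display only)."""
        return tuple(int(round(v)) for v in self.labels)


def assign_labels(n_steps: int) -> LabelScheme:
    """Equally spaced ABVS labels for a subject tolerating ``n_steps`` steps.

    Parameters
    ----------
    n_steps : int
        Number of blood-loss steps tolerated before decompensation (>= 1).

    Returns
    -------
    LabelScheme
        ``n_steps + 1`` strictly increasing labels from 0 to 100 percent.
    """
    if not isinstance(n_steps, (int, np.integer)) or n_steps < 1:
        raise ValueError(f"n_steps must be an integer >= 1, got {n_steps!r}")
    labels = tuple(100.0 * i / n_steps for i in range(n_steps + 1))
    return LabelScheme(n_steps=int(n_steps), labels=labels)


def decompensation_binary(label: float) -> int:
    """1 if ``label`` is the fully decompensated state (100%), else 0."""
    if not (-_LABEL_TOL <= label <= 100.0 + _LABEL_TOL):
        raise ValueError(f"ABVS label must lie in [0, 100], got {label!r}")
    return int(abs(label - 100.0) <= 1e-6)


def class_weights(table: pd.DataFrame) -> pd.Series:
    """Per-row weights equalizing (subject, ABVS level) group influence.

    Every (subject_id, abvs_label) group receives equal total weight and the
    weights sum to the number of rows, so groups with many beats are
    down-weighted relative to sparse ones.  The overall scale is a convention;
    any positive rescaling is equivalent for the learner.
    """
    for col in ("subject_id", "abvs_label"):
        if col not in table.columns:
            raise ValueError(f"class_weights requires column {col!r}")
    if len(table) == 0:
        return pd.Series(dtype=float, name="sample_weight")
    group_sizes = table.groupby(["subject_id", "abvs_label"], sort=False)[
        "abvs_label"
    ].transform("size")
    n_groups = len(table[["subject_id", "abvs_label"]].drop_duplicates())
    const = len(table) / n_groups
    weights = const / group_sizes.astype(float)
    weights.name = "sample_weight"
    return weights
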