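"""Model/Results interface for ABVS estimation.

``ABVSForest`` bundles a feature table, a normalization method and the
forest/evaluation configuration; ``fit`` runs the repeated class-weighted
LOSO-CV evaluation and returns an ``ABVSForestResults`` carrying per-trial
and aggregate metrics, pooled out-of-fold predictions and a ``summary()``
table.
"""

from __future__ import annotations

import pandas as pd

from .evaluation import (
    AggregateMetrics,
    ModelConfig,
    compare_methods,
    loso_predict,
    run_trials,
)
from .features import validate_feature_table
from .normalization import MethodSpec

__all__ = ["ABVSForest", "ABVSForestResults"]


class ABVSForest:
    """Random-forest ABVS estimator evaluated by leave-one-subject-out CV.

    Parameters
    ----------
    table : DataFrame
        Per-heartbeat feature table (see :mod:`abvs.features` for the schema).
    method : str or MethodSpec
        Normalization method: ``none``, ``ibn``, ``m1`` ... ``m7``, or one of
        the common normalizers.
    config : ModelConfig, optional
        Forest size/depth, feature set, trial count and base seed.
    external_table : DataFrame, optional
        Baseline-only external cohort (required for methods 2 and 4).
    weights : mapping subject_id -> kg, optional
        Subject weights (required for methods 5-7 unless the table carries a
        ``weight_kg`` column).

    Examples
    --------
    >>> from abvs import ABVSForest, CohortConfig, generate_cohort, simulate_feature_table
    >>> cfg = CohortConfig(seed=1)
    >>> table = simulate_feature_table(generate_cohort(cfg), cfg)
    >>> res = ABVSForest(table, method="m3").fit()
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(
        self,
        table: pd.DataFrame,
        method: str | MethodSpec = "none",
        config: ModelConfig | None = None,
        external_table: pd.DataFrame | None = None,
        weights: dict[str, float] | None = None,
    ) -> None:
        validate_feature_table(table)
        self.table = table
        self.spec = MethodSpec(method) if isinstance(method, str) else method
        self.config = config or ModelConfig()
        self.config.validate(table)
        self.external_table = external_table
        self.weights = weights

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ABVSForest":
        return cls(df, **kwargs)

    def fit(self) -> "ABVSForestResults":
        """Run the repeated LOSO-CV evaluation."""
        agg, trials = run_trials(
            self.table, self.spec, self.config, self.external_table, self.weights
        )
        preds = loso_predict(
            self.table, self.spec, self.config, self.config.base_seed % (2**31),
            self.external_table, self.weights,
        )
        return ABVSForestResults(self, agg, trials, preds)

    def compare(self, methods: list[str | MethodSpec]) -> pd.DataFrame:
        """Aggregate metrics for several normalization methods on this data."""
        return compare_methods(
            self.table, methods, self.config, self.external_table, self.weights
        )


class ABVSForestResults:
    """Evaluation results: per-trial metrics, aggregates and predictions."""

    def __init__(
        self,
        model: ABVSForest,
        aggregate: AggregateMetrics,
        trials: pd.DataFrame,
        predictions: pd.Series,
    ) -> None:
        self.model = model
        self.aggregate = aggregate
        self.trials = trials
        #: pooled out-of-fold predictions of the first trial, indexed by row
        self.predictions = predictions

    @property
    def r2(self) -> float:
        return self.aggregate.r2_mean

    @property
    def auc(self) -> float:
        return self.aggregate.auc_mean

    @property
    def rmse(self) -> float:
        return self.aggregate.rmse_mean

    def as_row(self) -> dict[str, object]:
        return self.aggregate.as_row()

    def summary(self) -> str:
        a = self.aggregate
        lines = [
            "ABVS random-forest LOSO-CV evaluation",
            "=" * 53,
            f"normalization method : {a.method_id}",
            f"features             : {', '.join(a.feature_set)}",
            f"subjects             : {self.model.table['subject_id'].nunique()}",
            f"beats                : {len(self.predictions)}",
            f"trees x depth        : {self.model.config.n_trees} x {self.model.config.max_depth}",
            f"trials               : {a.n_trials}",
            "-" * 53,
            f"{'metric':<8}{'mean':>12}{'SD':>14}",
            f"{'R2':<8}{a.r2_mean:>12.3f}{a.r2_sd:>14.2e}",
            f"{'AUC':<8}{a.auc_mean:>12.3f}{a.auc_sd:>14.2e}",
            f"{'RMSE(%)':<8}{a.rmse_mean:>12.2f}{a.rmse_sd:>14.2e}",
            "=" * 53,
        ]
        return "\n".join(lines)

    def plot_predictions(self, ax=None):
        """Box plot of pooled predictions per true ABVS level (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y_true = self.model.table.loc[self.predictions.index, "abvs_label"]
        levels = sorted(y_true.unique())
        ax.boxplot(
            [self.predictions[y_true == lv] for lv in levels],
            tick_labels=[f"{lv:.0f}" for lv in levels],
        )
        ax.set_xlabel("true ABVS (%)")
        ax.set_ylabel("predicted ABVS (%)")
        ax.set_title(f"LOSO predictions ({self.aggregate.method_id})")
        return ax
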