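"""Model-object interface: a tunable fuzzy k-NN diagnostic model.

:class:`FuzzyKnnTuner` is the entry point most users want: build it from a
feature table and binary labels (or straight from a DataFrame with a label
column), call :meth:`~FuzzyKnnTuner.fit` to let the bacterial-foraging
optimizer pick the neighborhood size ``k`` and fuzzy strength ``m`` on an
inner cross-validation, and use the returned results object to predict,
inspect the selected hyperparameters and print a summary.  Unbiased
generalization estimates come from :meth:`~FuzzyKnnTuner.cross_validate`,
which runs the full nested scheme (tuning repeated inside every outer
training split).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cbfo, fknn, selection
from .datasets import scale_minmax
from .exceptions import ContractError

__all__ = ["FuzzyKnnTuner", "FuzzyKnnResults", "NestedCvResults"]


class FuzzyKnnTuner:
    """Fuzzy k-NN model with foraging-optimized hyperparameters.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Binary class labels (the positive class defaults to 1).
    exog : array-like, shape (n, d)
        Real-valued feature matrix.
    config : CbfoConfig, optional
        Optimizer settings; defaults to the small tuning profile
        (swarm of 8, 150 chemotaxis passes).
    k_max : int, optional
        Upper bound of the neighborhood-size search (default
        ``min(50, n - 1)``).
    m_range : tuple, optional
        Search interval for the fuzzy strength, default ``(1.01, 10)``.
    inner_folds : int
        Stratified folds of the tuning objective (default 5).
    scale : bool
        Min-max scale features to [0, 1] before fitting (default True).
    """

    def __init__(self, endog, exog, config: cbfo.CbfoConfig | None = None,
                 k_max: int | None = None, m_range=(1.0 + selection.M_EPSILON, 10.0),
                 inner_folds: int = 5, scale: bool = True, positive_label=1,
                 feature_names=None):
        self.endog = np.asarray(endog)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or len(self.endog) != self.exog.shape[0]:
            raise ContractError("endog/exog shapes are inconsistent")
        if len(np.unique(self.endog)) != 2:
            raise ContractError("expected a two-class problem")
        self.config = config or cbfo.CbfoConfig.tuning_default()
        self.k_max = k_max
        self.m_range = m_range
        self.inner_folds = inner_folds
        self.scale = scale
        self.positive_label = positive_label
        self.feature_names = (
            list(feature_names) if feature_names is not None
            else [f"x{i}" for i in range(self.exog.shape[1])]
        )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, label_col: str = "status",
                       **kwargs) -> "FuzzyKnnTuner":
        """Build a tuner from a DataFrame with a label column."""
        if label_col not in data.columns:
            raise ContractError(f"label column {label_col!r} not found")
        y = data[label_col].to_numpy()
        X = data.drop(columns=[label_col]).select_dtypes("number")
        return cls(y, X.to_numpy(dtype=float), feature_names=list(X.columns),
                   **kwargs)

    def fit(self, seed=None) -> "FuzzyKnnResults":
        """Tune ``(k, m)`` on the full data and fit the final classifier."""
        if self.scale:
            X, scaler = scale_minmax(self.exog)
        else:
            X, scaler = self.exog, None
        k, m, err = selection.tune_fold(
            X, self.endog, config=self.config, k_max=self.k_max,
            m_range=self.m_range, seed=seed, inner_folds=self.inner_folds,
        )
        model = fknn.fit(X, self.endog, k=k, m=m)
        return FuzzyKnnResults(model=self, fitted=model, scaler=scaler,
                               k=k, m=m, inner_error=err, seed=seed)

    def cross_validate(self, outer_folds: int = 10, seed=None,
                       ) -> "NestedCvResults":
        """Nested stratified CV: tuning inside every outer training split."""
        res = selection.nested_cv(
            self.exog, self.endog, config=self.config,
            outer_folds=outer_folds, inner_folds=self.inner_folds,
            k_max=self.k_max, m_range=self.m_range, seed=seed,
            positive_label=self.positive_label,
        )
        return NestedCvResults(model=self, result=res, seed=seed)


@dataclass
class FuzzyKnnResults:
    """Fitted tuned-FKNN results: selected hyperparameters + predictor."""

    model: FuzzyKnnTuner
    fitted: fknn.FknnModel
    scaler: object
    k: int
    m: float
    inner_error: float
    seed: object = None

    @property
    def params(self) -> pd.Series:
        return pd.Series({"k": self.k, "m": self.m})

    def _prepare(self, X):
        X = np.asarray(X, dtype=float)
        return self.scaler.transform(X) if self.scaler is not None else X

    def predict(self, exog) -> np.ndarray:
        """Crisp class predictions for new samples."""
        return fknn.classify(self.fitted, self._prepare(exog))

    def predict_memberships(self, exog) -> np.ndarray:
        """Fuzzy per-class membership vectors for new samples."""
        return fknn.predict_memberships(self.fitted, self._prepare(exog))

    def summary(self) -> str:
        n, d = self.model.exog.shape
        lines = [
            "Fuzzy k-NN (bacterial-foraging tuned)",
            "=" * 46,
            f"{'No. observations:':<28}{n}",
            f"{'No. features:':<28}{d}",
            f"{'Classes:':<28}{np.asarray(self.fitted.classes_).tolist()}",
            f"{'Selected k:':<28}{self.k}",
            f"{'Selected m:':<28}{self.m:.4f}",
            f"{'Inner CV error rate:':<28}{self.inner_error:.4f}",
            f"{'Inner CV accuracy (%):':<28}{100 * (1 - self.inner_error):.2f}",
            f"{'Optimizer:':<28}swarm {self.model.config.swarm_size}, "
            f"{self.model.config.total_passes} passes",
            "=" * 46,
        ]
        return "\n".join(lines)


@dataclass
class NestedCvResults:
    """Nested cross-validation results with a printable fold table."""

    model: FuzzyKnnTuner
    result: selection.NestedCvResult
    seed: object = None

    @property
    def records(self):
        return self.result.records

    @property
    def mean_acc(self) -> float:
        return self.result.mean_acc

    @property
    def mean_auc(self) -> float:
        return self.result.mean_auc

    def to_dataframe(self, include_mean: bool = True) -> pd.DataFrame:
        return self.result.to_dataframe(include_mean=include_mean)

    def summary(self) -> str:
        df = self.to_dataframe()
        with pd.option_context("display.float_format", lambda v: f"{v:0.4f}"):
            table = df.to_string(index=False)
        header = [
            "Nested stratified CV of the tuned fuzzy k-NN",
            "=" * 52,
        ]
        footer = [
            "=" * 52,
            f"{'Mean ACC (%):':<20}{self.mean_acc:.2f}",
            f"{'Mean AUC:':<20}{self.mean_auc:.4f}",
        ]
        return "\n".join(header + [table] + footer)
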