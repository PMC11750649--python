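"""Scikit-learn-style estimators wrapping the sensor pipeline.

``FogIndexExtractor`` is a (stateless) transformer mapping a sequence of
:class:`~fogturn.io.IMUTrial` recordings to the four trial-level FOG-index
metrics plus the turn count, ready for downstream model selection.
``KSCutoffClassifier`` is a one-dimensional threshold classifier that learns
the Kolmogorov-Smirnov-optimal cutoff on a score and classifies "freezer"
where the score is at or above it.  Both follow the fit/transform/predict
and get_params/set_params conventions so they compose with sklearn
pipelines and cross-validation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import IMUTrial
from .spectral import SpectralConfig, fog_index
from .turns import TurnConfig, count_turns
from .validation import roc_analysis

METRIC_COLUMNS = ("AP_Mean", "AP_Max", "ML_Mean", "ML_Max")


class FogIndexExtractor(TransformerMixin, BaseEstimator):
    """Transform IMU trials into FOG-index features.

    Parameters
    ----------
    window_s, overlap_fraction, squared_ratio, pool_shins
        Spectral windowing knobs, see :class:`~fogturn.spectral.SpectralConfig`.
    lowpass_hz, reversal_dwell_s
        Turn-counting knobs, see :class:`~fogturn.turns.TurnConfig`.

    ``transform`` returns a DataFrame with columns AP_Mean, AP_Max, ML_Mean,
    ML_Max and n_turns, one row per trial.  Trials with zero completed turns
    have an undefined FOG-index and raise unless ``on_zero_turns="drop"``,
    in which case the row is NaN and callers must handle the exclusion.
    """

    def __init__(
        self,
        window_s: float = 3.0,
        overlap_fraction: float = 0.5,
        squared_ratio: bool = False,
        pool_shins: bool = True,
        lowpass_hz: float | None = 1.5,
        reversal_dwell_s: float = 0.5,
        on_zero_turns: str = "raise",
    ):
        self.window_s = window_s
        self.overlap_fraction = overlap_fraction
        self.squared_ratio = squared_ratio
        self.pool_shins = pool_shins
        self.lowpass_hz = lowpass_hz
        self.reversal_dwell_s = reversal_dwell_s
        self.on_zero_turns = on_zero_turns

    def _spectral_config(self) -> SpectralConfig:
        return SpectralConfig(
            window_s=self.window_s,
            overlap_fraction=self.overlap_fraction,
            squared_ratio=self.squared_ratio,
            pool_shins=self.pool_shins,
        ).validate()

    def _turn_config(self) -> TurnConfig:
        return TurnConfig(lowpass_hz=self.lowpass_hz, reversal_dwell_s=self.reversal_dwell_s)

    def fit(self, X, y=None):
        """Stateless; validates configuration and returns self."""
        if self.on_zero_turns not in ("raise", "drop"):
            raise ValueError("on_zero_turns must be 'raise' or 'drop'")
        self._spectral_config()
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> pd.DataFrame:
        """Compute metrics for a sequence of :class:`IMUTrial` objects."""
        check_is_fitted(self)
        sconf = self._spectral_config()
        tconf = self._turn_config()
        rows = []
        index = []
        for trial in X:
            if not isinstance(trial, IMUTrial):
                raise TypeError(f"expected IMUTrial, got {type(trial).__name__}")
            turn_res = count_turns(
                trial.lumbar_gyro["yaw"], trial.sample_rate_hz, tconf
            )
            index.append(trial.subject_id)
            if turn_res.n_complete_turns == 0:
                if self.on_zero_turns == "raise":
                    raise ValueError(
                        f"subject {trial.subject_id}: zero completed turns, FOG-index undefined"
                    )
                rows.append({c: np.nan for c in METRIC_COLUMNS} | {"n_turns": 0})
                continue
            res = fog_index(trial, turn_res.n_complete_turns, sconf)
            rows.append(res.as_dict() | {"n_turns": res.n_turns})
        return pd.DataFrame(rows, index=pd.Index(index, name="subject_id"))

    def get_feature_names_out(self, input_features=None):
        return np.asarray(list(METRIC_COLUMNS) + ["n_turns"], dtype=object)


class KSCutoffClassifier(ClassifierMixin, BaseEstimator):
    """Univariate threshold classifier at the KS-optimal ROC cutoff.

    Fit on a single score column and boolean labels; learns ``cutoff_`` (the
    threshold maximizing sensitivity + specificity - 1) and classifies
    positive where score >= cutoff.  Fitted attributes expose the full ROC
    summary (``auc_``, ``accuracy_rate_``, ``sens_at_cutoff_``, ...).
    """

    def __init__(self, metric: str | None = None):
        self.metric = metric

    def _score_column(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            col = self.metric if self.metric is not None else X.columns[0]
            return X[col].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            return X
        if X.ndim == 2 and X.shape[1] == 1:
            return X[:, 0]
        raise ValueError("X must be a single score column (1-D, (n,1) or a DataFrame)")

    def fit(self, X, y):
        scores = self._score_column(X)
        y = np.asarray(y, dtype=bool)
        roc = roc_analysis(scores, y)
        self.classes_ = np.array([False, True])
        self.roc_result_ = roc
        self.cutoff_ = roc.cutoff
        self.auc_ = roc.auc
        self.auc_p_ = roc.auc_p
        self.accuracy_rate_ = roc.accuracy_rate
        self.sens_at_cutoff_ = roc.sens_at_cutoff
        self.spec_at_cutoff_ = roc.spec_at_cutoff
        self.ks_statistic_ = roc.ks_statistic
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self)
        return self._score_column(X) >= self.cutoff_

    def decision_function(self, X):
        check_is_fitted(self)
        return self._score_column(X) - self.cutoff_
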