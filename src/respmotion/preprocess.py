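"""Feature scaling for the two pipelines.

The classification pipeline standardizes features to zero mean / unit SD;
the regression pipeline min-max scales features and the displacement target
to [0, 1] (matching the ReLU output range), with exact inverse transforms.
Scalers are fitted on the training partition only.
"""

from __future__ import annotations

import numpy as np
from sklearn.preprocessing import MinMaxScaler as _SkMinMax
from sklearn.preprocessing import StandardScaler as _SkStandard

__all__ = ["Standardizer", "MinMaxScaler"]


def _as_matrix(data) -> np.ndarray:
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("expected a 1-D or 2-D feature array")
    return X


def _check_fitted(obj, attr: str) -> None:
    if not hasattr(obj, attr):
        raise RuntimeError(f"{type(obj).__name__} must be fitted before use")


class Standardizer:
    """Per-feature z-scoring: (x - mean) / sd, with sd the population SD.

    Rejects constant features at fit time (their SD is zero, so the z-score
    is undefined), naming the offending column.
    """

    def fit(self, data) -> "Standardizer":
        X = _as_matrix(data)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit a Standardizer")
        sd = X.std(axis=0)
        bad = np.flatnonzero(sd == 0)
        if len(bad):
            raise ValueError(f"constant feature column(s) {bad.tolist()}: SD is zero")
        self._scaler = _SkStandard().fit(X)
        self.mean_ = self._scaler.mean_
        self.scale_ = self._scaler.scale_
        return self

    def transform(self, data) -> np.ndarray:
        _check_fitted(self, "mean_")
        return self._scaler.transform(_as_matrix(data))

    def inverse_transform(self, data) -> np.ndarray:
        _check_fitted(self, "mean_")
        return self._scaler.inverse_transform(_as_matrix(data))

    def fit_transform(self, data) -> np.ndarray:
        return self.fit(data).transform(data)

    @classmethod
    def from_params(cls, mean, scale) -> "Standardizer":
        """Rebuild a fitted scaler from stored moments (bit-exact reload)."""
        mean = np.asarray(mean, dtype=float)
        scale = np.asarray(scale, dtype=float)
        if np.any(scale <= 0):
            raise ValueError("scale must be positive")
        self = cls()
        sk = _SkStandard()
        sk.mean_ = mean
        sk.scale_ = scale
        sk.var_ = scale**2
        sk.n_features_in_ = mean.shape[0]
        sk.n_samples_seen_ = 2
        self._scaler = sk
        self.mean_ = mean
        self.scale_ = scale
        return self


class MinMaxScaler:
    """Per-feature scaling to [0, 1]: (x - min) / (max - min).

    Values outside the fitted range map outside [0, 1]; that is allowed
    (test data may exceed the training extrema) but the fit itself rejects
    features whose max equals their min.
    """

    def fit(self, data) -> "MinMaxScaler":
        X = _as_matrix(data)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit a MinMaxScaler")
        span = X.max(axis=0) - X.min(axis=0)
        bad = np.flatnonzero(span == 0)
        if len(bad):
            raise ValueError(f"constant feature column(s) {bad.tolist()}: max equals min")
        self._scaler = _SkMinMax(clip=False).fit(X)
        self.data_min_ = self._scaler.data_min_
        self.data_max_ = self._scaler.data_max_
        return self

    def transform(self, data) -> np.ndarray:
        _check_fitted(self, "data_min_")
        return self._scaler.transform(_as_matrix(data))

    def inverse_transform(self, data) -> np.ndarray:
        _check_fitted(self, "data_min_")
        return self._scaler.inverse_transform(_as_matrix(data))

    def fit_transform(self, data) -> np.ndarray:
        return self.fit(data).transform(data)

    @classmethod
    def from_params(cls, data_min, data_max) -> "MinMaxScaler":
        """Rebuild a fitted scaler from stored extrema (bit-exact reload)."""
        data_min = np.asarray(data_min, dtype=float)
        data_max = np.asarray(data_max, dtype=float)
        if np.any(data_max <= data_min):
            raise ValueError("data_max must exceed data_min")
        self = cls()
        sk = _SkMinMax(clip=False)
        data_range = data_max - data_min
        # the derived attributes follow sklearn's own fit arithmetic exactly
        sk.data_min_ = data_min
        sk.data_max_ = data_max
        sk.data_range_ = data_range
        sk.scale_ = (1.0 - 0.0) / data_range
        sk.min_ = 0.0 - data_min * sk.scale_
        sk.n_features_in_ = data_min.shape[0]
        sk.n_samples_seen_ = 2
        self._scaler = sk
        self.data_min_ = data_min
        self.data_max_ = data_max
        return self
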