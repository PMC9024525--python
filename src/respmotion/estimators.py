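"""scikit-learn style estimators wrapping the time-lagged network.

``TimeLaggedPhaseClassifier`` standardizes the 33 windowed features and
trains the Softmax head against one-hot phase targets;
``TimeLaggedDisplacementRegressor`` min-max scales features and the
displacement target to [0, 1], trains the ReLU head, and inverse-transforms
predictions back to millimetres.  Both compose with sklearn model selection
(get_params/set_params, fitted attributes with trailing underscores).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

from . import network
from .preprocess import MinMaxScaler, Standardizer

__all__ = ["TimeLaggedPhaseClassifier", "TimeLaggedDisplacementRegressor"]


def _validate_X(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 33:
        raise ValueError(
            f"X must be (n_samples, 33): three 11-feature time steps; got {X.shape}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    return X


def _one_hot(y: np.ndarray) -> np.ndarray:
    out = np.zeros((len(y), 10))
    out[np.arange(len(y)), y] = 1.0
    return out


class _TimeLaggedBase(BaseEstimator):
    _head: str

    def __init__(
        self,
        learning_rate: float = 0.1,
        max_epochs: int = 1000,
        l1_lambda: float = 1e-4,
        patience: int = 25,
        random_state: int = 0,
        joint_normalization: bool = False,
    ):
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.l1_lambda = l1_lambda
        self.patience = patience
        self.random_state = random_state
        self.joint_normalization = joint_normalization

    def _training_config(self) -> network.TrainingConfig:
        return network.TrainingConfig(
            head=self._head,
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            l1_lambda=self.l1_lambda,
            patience=self.patience,
            seed=self.random_state,
        )

    def _check_is_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError(f"{type(self).__name__} is not fitted yet")


class TimeLaggedPhaseClassifier(_TimeLaggedBase, ClassifierMixin):
    """10-phase respiratory classifier (standardized inputs, Softmax head).

    ``fit`` accepts an optional held-out partition used for the
    divergence-based early stop; without one, the training loss is monitored
    (which effectively disables early stopping on a descending curve).
    """

    _head = "classifier"

    def fit(self, X, y, X_val=None, y_val=None) -> "TimeLaggedPhaseClassifier":
        X = _validate_X(X)
        y = np.asarray(y, dtype=int)
        if y.shape != (X.shape[0],):
            raise ValueError("y must be a 1-D phase-index array matching X")
        if y.min() < 0 or y.max() > 9:
            raise ValueError("phase indices must lie in 0..9")

        if X_val is not None:
            X_val = _validate_X(X_val)
            y_val = np.asarray(y_val, dtype=int)
            fit_block = np.vstack([X, X_val]) if self.joint_normalization else X
        else:
            fit_block = X
        self.scaler_ = Standardizer().fit(fit_block)
        Xs = self.scaler_.transform(X)
        Y = _one_hot(y)
        if X_val is not None:
            Xv, Yv = self.scaler_.transform(X_val), _one_hot(y_val)
        else:
            Xv, Yv = Xs, Y

        self.params_, self.history_ = network.train(
            Xs, Y, Xv, Yv, self._training_config()
        )
        self.classes_ = np.arange(10)
        self.n_features_in_ = 33
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._check_is_fitted()
        Xs = self.scaler_.transform(_validate_X(X))
        return network.forward(self.params_, Xs).output

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


class TimeLaggedDisplacementRegressor(_TimeLaggedBase, RegressorMixin):
    """Longitudinal tumor-displacement regressor (min-max inputs, ReLU head).

    Targets are scaled to [0, 1] for training; ``predict`` returns
    millimetres via the inverse transform.
    """

    _head = "regressor"

    def __init__(
        self,
        learning_rate: float = 0.1,
        max_epochs: int = 5000,
        l1_lambda: float = 1e-4,
        patience: int = 25,
        random_state: int = 0,
        joint_normalization: bool = False,
    ):
        super().__init__(
            learning_rate=learning_rate,
            max_epochs=max_epochs,
            l1_lambda=l1_lambda,
            patience=patience,
            random_state=random_state,
            joint_normalization=joint_normalization,
        )

    def fit(self, X, y, X_val=None, y_val=None) -> "TimeLaggedDisplacementRegressor":
        X = _validate_X(X)
        y = np.asarray(y, dtype=float)
        if y.shape != (X.shape[0],):
            raise ValueError("y must be a 1-D displacement array matching X")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite values")

        if X_val is not None:
            X_val = _validate_X(X_val)
            y_val = np.asarray(y_val, dtype=float)
            if self.joint_normalization:
                x_block = np.vstack([X, X_val])
                y_block = np.concatenate([y, y_val])
            else:
                x_block, y_block = X, y
        else:
            x_block, y_block = X, y
        self.x_scaler_ = MinMaxScaler().fit(x_block)
        self.y_scaler_ = MinMaxScaler().fit(y_block[:, None])

        Xs = self.x_scaler_.transform(X)
        Ys = self.y_scaler_.transform(y[:, None])
        if X_val is not None:
            Xv = self.x_scaler_.transform(X_val)
            Yv = self.y_scaler_.transform(y_val[:, None])
        else:
            Xv, Yv = Xs, Ys

        self.params_, self.history_ = network.train(
            Xs, Ys, Xv, Yv, self._training_config()
        )
        self.n_features_in_ = 33
        return self

    def predict_normalized(self, X) -> np.ndarray:
        """ReLU-head output on the [0, 1] training scale."""
        self._check_is_fitted()
        Xs = self.x_scaler_.transform(_validate_X(X))
        return network.predict_displacement(self.params_, Xs)

    def predict(self, X) -> np.ndarray:
        """Predicted longitudinal displacement in millimetres."""
        yn = self.predict_normalized(X)
        return self.y_scaler_.inverse_transform(yn[:, None]).ravel()
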