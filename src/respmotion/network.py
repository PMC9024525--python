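"""The time-lagged shared-weight feed-forward network.

Seven tanh hidden layers of widths (8, 10, 8, 10, 8, 10, 5).  The three
time-step feature vectors are injected through ONE shared 11x8 weight matrix:
T-2 enters hidden layer 1 (with the shared bias), T-1 and T0 are added to
the pre-activations of hidden layers 3 and 5 (no extra bias).  The output
head is Softmax over the 10 respiratory phases (classifier) or a single
ReLU unit (regressor).  Training is plain full-batch gradient descent with
an L1 weight penalty and divergence-based early stopping; backpropagation is
explicit so the shared-injection gradient (the sum of the three sites'
contributions) is under direct test via finite differences.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "HIDDEN_WIDTHS",
    "N_STEP_FEATURES",
    "NetworkParams",
    "TrainingConfig",
    "ForwardTrace",
    "TrainingDivergedError",
    "init_params",
    "forward",
    "loss",
    "backward",
    "train",
    "predict_phases",
    "predict_displacement",
    "params_to_vector",
    "vector_to_params",
]

HIDDEN_WIDTHS = (8, 10, 8, 10, 8, 10, 5)
N_STEP_FEATURES = 11
#: hidden layers (0-based indices) receiving the shared input injection
_INJECTION_LAYERS = {0: slice(0, 11), 2: slice(11, 22), 4: slice(22, 33)}
_HEADS = {"classifier": 10, "regressor": 1}
_LOG_CLAMP = 1e-12


@dataclass
class NetworkParams:
    """All weights/biases of one head.

    ``w_in``/``b_in`` is the single shared input projection; the same array
    object serves hidden layers 1, 3 and 5 (mutating it mutates every
    injection site by construction).  ``hidden_w[k]`` maps hidden layer k to
    k+1; ``w_out`` maps the 5-node layer to the head.
    """

    head: str
    w_in: np.ndarray  # (11, 8)
    b_in: np.ndarray  # (8,)
    hidden_w: list[np.ndarray] = field(default_factory=list)  # 6 inter-layer maps
    hidden_b: list[np.ndarray] = field(default_factory=list)
    w_out: np.ndarray = None  # (5, 10) or (5, 1)
    b_out: np.ndarray = None

    def copy(self) -> "NetworkParams":
        return copy.deepcopy(self)

    def weight_arrays(self) -> list[np.ndarray]:
        """Weight matrices subject to the L1 penalty (shared w_in once)."""
        return [self.w_in, *self.hidden_w, self.w_out]

    def all_arrays(self) -> list[np.ndarray]:
        out = [self.w_in, self.b_in]
        for w, b in zip(self.hidden_w, self.hidden_b):
            out.extend([w, b])
        out.extend([self.w_out, self.b_out])
        return out


@dataclass
class TrainingConfig:
    """Gradient-descent hyperparameters (defaults follow the published runs:
    learning rate 0.1 with 1000 epochs for the classifier, 5000 for the
    regressor)."""

    head: str = "classifier"
    learning_rate: float = 0.1
    max_epochs: int = 1000
    l1_lambda: float = 1e-4
    patience: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.head not in _HEADS:
            raise ValueError(f"head must be one of {sorted(_HEADS)}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.l1_lambda < 0:
            raise ValueError("l1_lambda must be >= 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class ForwardTrace:
    """Per-layer pre-activations and activations of one forward pass."""

    z: list[np.ndarray]
    a: list[np.ndarray]
    z_out: np.ndarray
    output: np.ndarray


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite; carries the history so far."""

    def __init__(self, message: str, history: dict):
        super().__init__(message)
        self.history = history


def init_params(head: str, seed: int) -> NetworkParams:
    """Symmetric uniform fan-based (Glorot) initialization, seeded.

    Keeps tanh pre-activations in the non-saturated regime.  Biases start at
    zero except the regressor output bias, which starts at 0.5 — the middle
    of the min-max-scaled target range — so the ReLU unit is initially live.
    The regressor's output weights start at 0.2x the fan-based limit: the
    initial prediction then sits near the bias, keeping the first full-batch
    steps small enough not to overshoot the ReLU into the dead (all-negative
    pre-activation) region, from which plain gradient descent cannot recover.
    """
    if head not in _HEADS:
        raise ValueError(f"head must be one of {sorted(_HEADS)}")
    rng = np.random.default_rng(seed)

    def glorot(fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    w_in = glorot(N_STEP_FEATURES, HIDDEN_WIDTHS[0])
    b_in = np.zeros(HIDDEN_WIDTHS[0])
    hidden_w = [
        glorot(HIDDEN_WIDTHS[k], HIDDEN_WIDTHS[k + 1])
        for k in range(len(HIDDEN_WIDTHS) - 1)
    ]
    hidden_b = [np.zeros(HIDDEN_WIDTHS[k + 1]) for k in range(len(HIDDEN_WIDTHS) - 1)]
    n_out = _HEADS[head]
    w_out = glorot(HIDDEN_WIDTHS[-1], n_out)
    if head == "regressor":
        w_out *= 0.2
        b_out = np.full(n_out, 0.5)
    else:
        b_out = np.zeros(n_out)
    return NetworkParams(
        head=head, w_in=w_in, b_in=b_in,
        hidden_w=hidden_w, hidden_b=hidden_b, w_out=w_out, b_out=b_out,
    )


def _split_steps(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != 3 * N_STEP_FEATURES:
        raise ValueError(
            f"expected {3 * N_STEP_FEATURES} features "
            f"(three {N_STEP_FEATURES}-vectors), got {X.shape[1]}"
        )
    return X[:, 0:11], X[:, 11:22], X[:, 22:33]


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def forward(params: NetworkParams, X: np.ndarray) -> ForwardTrace:
    """Run the shared-injection forward pass on an (n, 33) batch.

    Hidden layer 1 sees ``x(T-2) W_in + B_in``; layers 3 and 5 add
    ``x(T-1) W_in`` and ``x(T0) W_in`` to their affine pre-activation (no
    second bias); all hidden activations are tanh.
    """
    x_tm2, x_tm1, x_t0 = _split_steps(X)
    injections = {0: x_tm2, 2: x_tm1, 4: x_t0}

    zs, acts = [], []
    z = injections[0] @ params.w_in + params.b_in
    zs.append(z)
    acts.append(np.tanh(z))
    for k in range(1, len(HIDDEN_WIDTHS)):
        z = acts[-1] @ params.hidden_w[k - 1] + params.hidden_b[k - 1]
        if k in injections:
            z = z + injections[k] @ params.w_in
        zs.append(z)
        acts.append(np.tanh(z))
    z_out = acts[-1] @ params.w_out + params.b_out
    if params.head == "classifier":
        output = _softmax(z_out)
    else:
        output = np.maximum(z_out, 0.0)
    return ForwardTrace(z=zs, a=acts, z_out=z_out, output=output)


def _check_targets(params: NetworkParams, Y: np.ndarray, n: int) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if params.head == "classifier":
        Y = np.atleast_2d(Y)
        if Y.shape != (n, 10):
            raise ValueError(f"classifier targets must be one-hot (n, 10); got {Y.shape}")
    else:
        Y = Y.reshape(n, 1)
    return Y


def loss(
    params: NetworkParams,
    X: np.ndarray,
    Y: np.ndarray,
    l1_lambda: float = 0.0,
    trace: Optional[ForwardTrace] = None,
) -> float:
    """Data loss (cross-entropy or MSE, batch mean) plus the L1 weight penalty.

    Classifier: ``J = -1/N sum_n y_n . log(p_n)`` with probabilities clamped
    at 1e-12 inside the log only.  Regressor: ``MSE = 1/n sum (y - yhat)^2``
    on the normalized scale.  Biases are excluded from the penalty; the
    shared input matrix is penalized once.
    """
    if np.size(X) == 0:
        raise ValueError("batch must be non-empty")
    trace = trace or forward(params, X)
    n = trace.output.shape[0]
    Y = _check_targets(params, Y, n)
    if params.head == "classifier":
        p = np.clip(trace.output, _LOG_CLAMP, None)
        data = -float(np.sum(Y * np.log(p))) / n
    else:
        data = float(np.mean((Y - trace.output) ** 2))
    penalty = l1_lambda * sum(float(np.abs(w).sum()) for w in params.weight_arrays())
    return data + penalty


def backward(
    params: NetworkParams,
    X: np.ndarray,
    Y: np.ndarray,
    l1_lambda: float = 0.0,
    trace: Optional[ForwardTrace] = None,
) -> NetworkParams:
    """Analytic gradients of :func:`loss`, shaped like the parameters.

    The shared ``w_in`` gradient is the sum of the contributions from its
    three injection sites (layers 1, 3, 5); ``b_in`` only accumulates from
    layer 1, where it is applied.
    """
    x_tm2, x_tm1, x_t0 = _split_steps(X)
    injections = {0: x_tm2, 2: x_tm1, 4: x_t0}
    trace = trace or forward(params, X)
    n = trace.output.shape[0]
    Y = _check_targets(params, Y, n)

    if params.head == "classifier":
        d_z_out = (trace.output - Y) / n
    else:
        d_z_out = 2.0 * (trace.output - Y) / n * (trace.z_out > 0)

    g = NetworkParams(
        head=params.head,
        w_in=np.zeros_like(params.w_in),
        b_in=np.zeros_like(params.b_in),
        hidden_w=[np.zeros_like(w) for w in params.hidden_w],
        hidden_b=[np.zeros_like(b) for b in params.hidden_b],
        w_out=np.zeros_like(params.w_out),
        b_out=np.zeros_like(params.b_out),
    )
    g.w_out = trace.a[-1].T @ d_z_out
    g.b_out = d_z_out.sum(axis=0)
    d_a = d_z_out @ params.w_out.T
    for k in range(len(HIDDEN_WIDTHS) - 1, 0, -1):
        d_z = d_a * (1.0 - trace.a[k] ** 2)
        g.hidden_w[k - 1] = trace.a[k - 1].T @ d_z
        g.hidden_b[k - 1] = d_z.sum(axis=0)
        if k in injections:
            g.w_in += injections[k].T @ d_z
        d_a = d_z @ params.hidden_w[k - 1].T
    d_z0 = d_a * (1.0 - trace.a[0] ** 2)
    g.w_in += injections[0].T @ d_z0
    g.b_in = d_z0.sum(axis=0)

    if l1_lambda > 0:
        for w, gw in zip(params.weight_arrays(), g.weight_arrays()):
            gw += l1_lambda * np.sign(w)
    return g


def train(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_test: np.ndarray,
    Y_test: np.ndarray,
    config: TrainingConfig,
    params: Optional[NetworkParams] = None,
) -> tuple[NetworkParams, dict]:
    """Full-batch gradient descent with divergence-based early stopping.

    Per-epoch train and test losses are recorded.  Training stops once the
    test loss has sat above its running minimum for ``patience`` consecutive
    epochs (the train/test divergence signal); the returned parameters are
    the snapshot at the test-loss minimum.
    """
    if np.size(X_train) == 0 or np.size(X_test) == 0:
        raise ValueError("both partitions must be non-empty")
    params = params.copy() if params is not None else init_params(config.head, config.seed)
    history: dict = {"train_loss": [], "test_loss": []}
    best_loss, best_params, best_epoch, bad = np.inf, params.copy(), 0, 0

    for epoch in range(config.max_epochs):
        tr = forward(params, X_train)
        train_loss = loss(params, X_train, Y_train, config.l1_lambda, trace=tr)
        test_loss = loss(params, X_test, Y_test, config.l1_lambda)
        history["train_loss"].append(train_loss)
        history["test_loss"].append(test_loss)
        if not (np.isfinite(train_loss) and np.isfinite(test_loss)):
            raise TrainingDivergedError(
                f"non-finite loss at epoch {epoch}", history
            )
        if test_loss < best_loss:
            best_loss, best_params, best_epoch, bad = test_loss, params.copy(), epoch, 0
        else:
            bad += 1
            if bad >= config.patience:
                break
        grads = backward(params, X_train, Y_train, config.l1_lambda, trace=tr)
        for p, gr in zip(params.all_arrays(), grads.all_arrays()):
            p -= config.learning_rate * gr

    history["best_epoch"] = best_epoch
    history["n_epochs"] = len(history["train_loss"])
    return best_params, history


def predict_phases(params: NetworkParams, X: np.ndarray) -> np.ndarray:
    """Argmax phase decision; ties break toward the lower phase index."""
    if params.head != "classifier":
        raise ValueError("predict_phases requires a classifier head")
    return np.argmax(forward(params, X).output, axis=1)


def predict_displacement(params: NetworkParams, X: np.ndarray) -> np.ndarray:
    """Raw (normalized-scale) displacement output of the regressor head."""
    if params.head != "regressor":
        raise ValueError("predict_displacement requires a regressor head")
    return forward(params, X).output.ravel()


def params_to_vector(params: NetworkParams) -> np.ndarray:
    return np.concatenate([a.ravel() for a in params.all_arrays()])


def vector_to_params(vec: np.ndarray, template: NetworkParams) -> NetworkParams:
    out = template.copy()
    offset = 0
    for a in out.all_arrays():
        a[...] = vec[offset:offset + a.size].reshape(a.shape)
        offset += a.size
    if offset != vec.size:
        raise ValueError("vector length does not match parameter count")
    return out
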