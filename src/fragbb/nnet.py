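"""Self-normalizing feed-forward regression networks.

A small fully connected architecture: one or more hidden layers sized as a
fraction of the input width, SELU activations, optional alpha dropout (the
dropout variant that preserves the self-normalizing mean/variance property
of SELU) between hidden layers, and a single linear output unit.  Training
minimizes mean squared error with the Adam optimizer; a disjoint stop set
is monitored every epoch and the weights from the best stop-set epoch are
restored (early termination with patience).

Everything — forward pass, backpropagation, and the analytic gradient of
the output with respect to the inputs used for fragment-contribution
analysis — is implemented directly in NumPy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

# SELU constants (fixed-point of the self-normalizing map)
_LAMBDA = 1.0507009873554804934193349852946
_ALPHA = 1.6732632423543772848170429916717
_ALPHA_PRIME = -_LAMBDA * _ALPHA  # saturation value used by alpha dropout


def selu(z: np.ndarray) -> np.ndarray:
    return _LAMBDA * np.where(z > 0, z, _ALPHA * (np.exp(np.minimum(z, 0.0)) - 1.0))


def selu_grad(z: np.ndarray) -> np.ndarray:
    return _LAMBDA * np.where(z > 0, 1.0, _ALPHA * np.exp(np.minimum(z, 0.0)))


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture specification.

    ``hidden_ratios`` gives each hidden layer's width as a fraction of the
    input width (each in [0.2, 0.6] in the searched space); widths round to
    at least one unit.
    """

    n_inputs: int
    hidden_ratios: tuple[float, ...] = (0.3,)
    dropout_p: float = 0.0

    def __post_init__(self):
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        if not 0.0 <= self.dropout_p <= 0.5:
            raise ValueError("dropout_p must be in [0, 0.5]")
        if not self.hidden_ratios:
            raise ValueError("need at least one hidden layer")

    @property
    def hidden_sizes(self) -> tuple[int, ...]:
        return tuple(
            max(1, int(round(r * self.n_inputs))) for r in self.hidden_ratios
        )

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.n_inputs, *self.hidden_sizes, 1)


def init_weights(spec: NetworkSpec, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """LeCun-normal initialization (variance 1/fan-in), appropriate for SELU."""
    rng = np.random.default_rng(seed)
    sizes = spec.layer_sizes
    params = []
    for fan_in, fan_out in zip(sizes, sizes[1:]):
        W = rng.normal(0.0, np.sqrt(1.0 / fan_in), size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        params.append((W, b))
    return params


def _forward_cached(params, X):
    """Forward pass returning pre-activations for backprop; SELU on hidden
    layers, identity on the output layer."""
    a = X
    zs, activations = [], [a]
    n_layers = len(params)
    for li, (W, b) in enumerate(params):
        z = a @ W + b
        zs.append(z)
        a = selu(z) if li < n_layers - 1 else z
        activations.append(a)
    return zs, activations


def forward(params, X: np.ndarray) -> np.ndarray:
    """Deterministic inference output (dropout disabled), shape (n,)."""
    return _forward_cached(params, X)[1][-1][:, 0]


def gradient_input(params, X: np.ndarray) -> np.ndarray:
    """Analytic ∂output/∂input for each row of X, shape like X."""
    zs, _ = _forward_cached(params, X)
    n_layers = len(params)
    # backpropagate a unit output sensitivity
    g = params[-1][0].T  # (1, hidden_last)
    g = np.repeat(g, X.shape[0], axis=0)
    for li in range(n_layers - 2, -1, -1):
        g = g * selu_grad(zs[li])
        g = g @ params[li][0].T
    return g


def _alpha_dropout(a: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Alpha dropout: drop to the SELU saturation value, then rescale so the
    layer keeps zero mean / unit variance under self-normalization."""
    if p <= 0:
        return a
    q = 1.0 - p
    keep = rng.random(a.shape) < q
    scale = (q + _ALPHA_PRIME**2 * q * p) ** -0.5
    shift = -scale * p * _ALPHA_PRIME
    return scale * np.where(keep, a, _ALPHA_PRIME) + shift


class SELUNetRegressor(BaseEstimator, RegressorMixin):
    """SELU feed-forward regressor trained with Adam and early stopping.

    Parameters
    ----------
    hidden_ratios : hidden layer widths as fractions of the input width.
    dropout_p : alpha-dropout probability between hidden layers (0 = off).
    learning_rate, batch_size : Adam settings.
    max_epochs : training epoch cap.
    patience : epochs without stop-set improvement before early termination.
    seed : controls initialization, batch shuffling and dropout masks.

    ``fit`` accepts an optional ``stop_set=(X_stop, y_stop)``; when given,
    the stop-set MSE is monitored every epoch and the best-epoch weights
    are restored.  Inputs and the endpoint are expected already scaled.
    """

    def __init__(
        self,
        hidden_ratios: tuple[float, ...] = (0.3,),
        dropout_p: float = 0.0,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 1000,
        patience: int = 20,
        seed: int = 0,
    ):
        self.hidden_ratios = hidden_ratios
        self.dropout_p = dropout_p
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed

    def fit(self, X, y, stop_set: tuple[np.ndarray, np.ndarray] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        spec = NetworkSpec(X.shape[1], tuple(self.hidden_ratios), self.dropout_p)
        params = init_weights(spec, self.seed)
        rng = np.random.default_rng(self.seed + 1)
        self.spec_ = spec
        self.n_features_in_ = X.shape[1]
        self.training_log_ = []
        self.stopped_epoch_ = 0

        if self.max_epochs == 0:
            self.params_ = params
            return self

        has_stop = stop_set is not None
        if has_stop:
            X_stop = np.asarray(stop_set[0], dtype=float)
            y_stop = np.asarray(stop_set[1], dtype=float).ravel()

        # Adam state
        m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
        v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        best_loss = np.inf
        best_params = [(W.copy(), b.copy()) for W, b in params]
        best_epoch = 0
        n = X.shape[0]
        n_layers = len(params)

        for epoch in range(1, self.max_epochs + 1):
            perm = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = perm[start:start + self.batch_size]
                Xb, yb = X[idx], y[idx]
                # forward with dropout
                a = Xb
                zs, acts = [], [a]
                for li, (W, b) in enumerate(params):
                    z = a @ W + b
                    zs.append(z)
                    if li < n_layers - 1:
                        a = selu(z)
                        if self.dropout_p > 0:
                            a = _alpha_dropout(a, self.dropout_p, rng)
                    else:
                        a = z
                    acts.append(a)
                pred = acts[-1][:, 0]
                if not np.all(np.isfinite(pred)):
                    raise FloatingPointError(
                        f"non-finite network output at epoch {epoch}"
                    )
                # backprop of MSE
                delta = (2.0 / len(yb)) * (pred - yb)[:, None]
                grads = [None] * n_layers
                for li in range(n_layers - 1, -1, -1):
                    gW = acts[li].T @ delta
                    gb = delta.sum(axis=0)
                    grads[li] = (gW, gb)
                    if li > 0:
                        delta = (delta @ params[li][0].T) * selu_grad(zs[li - 1])
                # Adam update
                t += 1
                corr1 = 1 - beta1**t
                corr2 = 1 - beta2**t
                for li in range(n_layers):
                    W, b = params[li]
                    for k, (p_arr, g_arr) in enumerate(
                        zip((W, b), grads[li])
                    ):
                        m_arr = m[li][k]
                        v_arr = v[li][k]
                        m_arr *= beta1
                        m_arr += (1 - beta1) * g_arr
                        v_arr *= beta2
                        v_arr += (1 - beta2) * g_arr**2
                        p_arr -= self.learning_rate * (
                            (m_arr / corr1) / (np.sqrt(v_arr / corr2) + eps)
                        )

            train_loss = float(np.mean((forward(params, X) - y) ** 2))
            if has_stop:
                stop_loss = float(np.mean((forward(params, X_stop) - y_stop) ** 2))
            else:
                stop_loss = train_loss
            if not np.isfinite(train_loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            self.training_log_.append((train_loss, stop_loss))
            if stop_loss < best_loss:
                best_loss = stop_loss
                best_params = [(W.copy(), b.copy()) for W, b in params]
                best_epoch = epoch
            elif epoch - best_epoch >= self.patience:
                break

        self.params_ = best_params
        self.stopped_epoch_ = epoch
        self.best_epoch_ = best_epoch
        self.best_stop_loss_ = best_loss
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return forward(self.params_, X)

    def gradient_input(self, X) -> np.ndarray:
        """Analytic gradient of the (scaled) output w.r.t. each (scaled) input."""
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return gradient_input(self.params_, X)
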