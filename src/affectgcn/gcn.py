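"""Graph-level binary classification of 6-node affect networks.

A small dense graph convolutional network: node features are propagated
over a normalized adjacency matrix with self-loops,

    H^(l+1) = act( A_hat H^(l) W^(l) + b^(l) ),

followed by mean readout over the six nodes and a sigmoid output head.
Affect networks are signed and directed (VAR coefficients), so the
default normalization keeps signs and divides each row by its absolute
sum (``signed_rownorm``); absolute row normalization and the textbook
symmetric normalization of |A_hat| are available.

Training minimizes binary cross-entropy by mini-batch RMSprop
(lr 0.001 by default) with manual backpropagation — at 6 nodes per graph
dense numpy is ample.  The estimator follows scikit-learn conventions and
accepts the flat ``(n, 42)`` sample layout of :mod:`affectgcn.samples`
(36 adjacency entries + 6 node features), so it composes with sklearn
model selection.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .samples import FLAT_DIM, N_NODES

__all__ = ["normalize_adjacency", "GCNGraphClassifier"]

ADJACENCY_MODES = ("signed_rownorm", "abs_rownorm", "sym_norm")


def normalize_adjacency(matrix: np.ndarray, mode: str = "signed_rownorm") -> np.ndarray:
    """Add self-loops and normalize a (possibly signed) adjacency matrix.

    signed_rownorm : row j of A+I divided by its absolute sum (signs kept).
    abs_rownorm    : same on |A+I|.
    sym_norm       : D^{-1/2} |A+I| D^{-1/2}, D = diag of row sums of |A+I|.

    An all-zero row of A normalizes to its self-loop alone.
    """
    a = np.asarray(matrix, dtype=float)
    if a.shape[-2:] != (N_NODES, N_NODES):
        raise ValueError("adjacency must be 6x6 (or a batch of 6x6)")
    if not np.all(np.isfinite(a)):
        raise ValueError("adjacency contains non-finite entries")
    if mode not in ADJACENCY_MODES:
        raise ValueError(f"unknown adjacency mode {mode!r}; choose from {ADJACENCY_MODES}")
    ahat = a + np.eye(N_NODES)
    absum = np.abs(ahat).sum(axis=-1, keepdims=True)
    absum = np.where(absum == 0, 1.0, absum)  # degenerate exact cancellation
    if mode == "signed_rownorm":
        return ahat / absum
    if mode == "abs_rownorm":
        return np.abs(ahat) / absum
    d = np.sqrt(absum)
    return np.abs(ahat) / d / np.swapaxes(d, -1, -2)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _RMSProp:
    """Elementwise RMSprop: cache = rho*cache + (1-rho)*g^2; step = lr*g/sqrt(cache+eps)."""

    def __init__(self, params: list[np.ndarray], lr: float, rho: float = 0.9, eps: float = 1e-8):
        self.params = params
        self.lr, self.rho, self.eps = lr, rho, eps
        self.cache = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, c in zip(self.params, grads, self.cache):
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(c) + self.eps)


class GCNGraphClassifier(ClassifierMixin, BaseEstimator):
    """GCN binary classifier over flattened 6-node graph samples.

    Parameters
    ----------
    n_layers : int, default 2
        Number of graph-convolution layers.
    hidden_dim : int, default 16
        Width of each hidden layer.
    learning_rate : float, default 0.001
        RMSprop learning rate.
    epochs : int, default 200
        Passes over the training set.
    batch_size : int, default 32
    adjacency_mode : {"signed_rownorm", "abs_rownorm", "sym_norm"}
    hidden_activation : {"sigmoid", "relu"}, default "sigmoid"
        Hidden-layer nonlinearity; the output head is always a sigmoid.
    feature_scaling : {"likert", "zscore", "none"}, default "likert"
        How node features are rescaled before propagation.  "likert" maps
        the 1-7 scale affinely to [0, 1] (fixed, data-independent);
        "zscore" centers and scales by the training set's global
        mean/SD — note that centering near-constant features leaves the
        propagation step with almost no signal to spread, so "likert" is
        the default.  Both act globally, so node permutations are
        unaffected.
    random_state : int, default 0
        Seeds parameter initialization and batch shuffling.

    Attributes
    ----------
    coefs_, intercepts_ : per-layer weights/biases.
    readout_coef_, readout_intercept_ : output head.
    loss_trace_ : mean training BCE per epoch.
    classes_ : array([0, 1]).
    """

    def __init__(
        self,
        n_layers: int = 2,
        hidden_dim: int = 16,
        learning_rate: float = 0.001,
        epochs: int = 200,
        batch_size: int = 32,
        adjacency_mode: str = "signed_rownorm",
        hidden_activation: str = "sigmoid",
        feature_scaling: str = "likert",
        random_state: int = 0,
    ):
        self.n_layers = n_layers
        self.hidden_dim = hidden_dim
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.adjacency_mode = adjacency_mode
        self.hidden_activation = hidden_activation
        self.feature_scaling = feature_scaling
        self.random_state = random_state

    # ------------------------------------------------------------------ utils

    def _split(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if X.shape[1] != FLAT_DIM:
            raise ValueError(f"expected {FLAT_DIM} columns (36 edges + 6 features), got {X.shape[1]}")
        a = X[:, : N_NODES * N_NODES].reshape(-1, N_NODES, N_NODES)
        feats = X[:, N_NODES * N_NODES:]
        return normalize_adjacency(a, self.adjacency_mode), feats

    def _act(self, z: np.ndarray) -> np.ndarray:
        if self.hidden_activation == "relu":
            return np.maximum(z, 0.0)
        return _sigmoid(z)

    def _act_grad(self, z: np.ndarray, h: np.ndarray) -> np.ndarray:
        if self.hidden_activation == "relu":
            return (z > 0).astype(float)
        return h * (1.0 - h)

    def _forward(self, ahat: np.ndarray, feats: np.ndarray, cache: bool = False):
        h = ((feats - self.feature_mean_) / self.feature_scale_)[:, :, None]
        zs, hs, ms = [], [h], []
        for w, b in zip(self.coefs_, self.intercepts_):
            m = ahat @ h
            z = m @ w + b
            h = self._act(z)
            if cache:
                ms.append(m)
                zs.append(z)
                hs.append(h)
        pooled = h.mean(axis=1)
        logit = pooled @ self.readout_coef_ + self.readout_intercept_
        prob = _sigmoid(logit)
        if cache:
            return prob, pooled, ms, zs, hs
        return prob

    # ------------------------------------------------------------------ sklearn API

    def fit(self, X, y) -> "GCNGraphClassifier":
        X, y = check_X_y(X, y, dtype=float)
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.hidden_activation not in ("sigmoid", "relu"):
            raise ValueError("hidden_activation must be 'sigmoid' or 'relu'")
        y = np.asarray(y)
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        y = y.astype(float)
        if len(np.unique(y)) < 2:
            warnings.warn("training set contains a single class; model will predict it everywhere")

        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)

        feats_raw = X[:, N_NODES * N_NODES:]
        if self.feature_scaling == "likert":
            self.feature_mean_, self.feature_scale_ = 1.0, 6.0
        elif self.feature_scaling == "zscore":
            self.feature_mean_ = float(feats_raw.mean())
            scale = float(feats_raw.std())
            self.feature_scale_ = scale if scale > 0 else 1.0
        elif self.feature_scaling == "none":
            self.feature_mean_, self.feature_scale_ = 0.0, 1.0
        else:
            raise ValueError("feature_scaling must be 'likert', 'zscore' or 'none'")

        ahat, feats = self._split(X)

        dims = [1] + [self.hidden_dim] * self.n_layers
        self.coefs_, self.intercepts_ = [], []
        for din, dout in zip(dims[:-1], dims[1:]):
            limit = np.sqrt(6.0 / (din + dout))
            self.coefs_.append(rng.uniform(-limit, limit, (din, dout)))
            self.intercepts_.append(np.zeros(dout))
        limit = np.sqrt(6.0 / (dims[-1] + 1))
        self.readout_coef_ = rng.uniform(-limit, limit, dims[-1])
        self.readout_intercept_ = 0.0

        params = [*self.coefs_, *self.intercepts_, self.readout_coef_]
        opt = _RMSProp(params, lr=self.learning_rate)
        bias_cache = 0.0  # scalar readout bias handled alongside

        n = X.shape[0]
        batch = min(self.batch_size, n)
        self.loss_trace_ = []
        eps = 1e-12
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                a_b, f_b, y_b = ahat[idx], feats[idx], y[idx]
                prob, pooled, ms, zs, hs = self._forward(a_b, f_b, cache=True)
                p = np.clip(prob, eps, 1.0 - eps)
                epoch_loss -= float(np.sum(y_b * np.log(p) + (1.0 - y_b) * np.log(1.0 - p)))

                bsz = len(idx)
                dlogit = (prob - y_b) / bsz
                g_wout = pooled.T @ dlogit
                g_bout = float(dlogit.sum())
                dh = (dlogit[:, None] * self.readout_coef_[None, :])[:, None, :] / N_NODES
                dh = np.broadcast_to(dh, hs[-1].shape).copy()
                g_w, g_b = [], []
                for layer in range(self.n_layers - 1, -1, -1):
                    dz = dh * self._act_grad(zs[layer], hs[layer + 1])
                    g_w.append(np.einsum("bnd,bne->de", ms[layer], dz))
                    g_b.append(dz.sum(axis=(0, 1)))
                    if layer > 0:
                        dm = dz @ self.coefs_[layer].T
                        dh = np.swapaxes(a_b, 1, 2) @ dm
                grads = [*reversed(g_w), *reversed(g_b), g_wout]
                opt.step(grads)
                # readout bias shares the RMSprop rule
                bias_cache = 0.9 * bias_cache + 0.1 * g_bout * g_bout
                self.readout_intercept_ -= self.learning_rate * g_bout / (np.sqrt(bias_cache) + 1e-8)
            self.loss_trace_.append(epoch_loss / n)
        self.loss_trace_ = np.asarray(self.loss_trace_)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "coefs_")
        X = check_array(X, dtype=float)
        ahat, feats = self._split(X)
        p1 = self._forward(ahat, feats)
        return np.column_stack([1.0 - p1, p1])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        """Label 1 iff the predicted probability strictly exceeds 0.5 (ties -> 0)."""
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)
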