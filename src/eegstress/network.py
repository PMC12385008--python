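"""Hybrid stress classifier: parallel CNN, BiLSTM and DBN feature branches.

The classifier consumes one multi-domain feature vector per trial (527
values per selected channel) and routes it through three branches:

* a 1-D deep CNN — three blocks of (3x1 convolution, batch normalization,
  ReLU, /2 max-pooling) with 64/128/256 filters — over the flat vector;
* a 2-layer bidirectional LSTM with 50 units per direction, sequencing over
  channels (one 527-long step per selected channel);
* a deep belief network of three stacked sigmoid layers (200/150/100 units)
  whose weights are pretrained greedily as restricted Boltzmann machines by
  one-step contrastive divergence (CD-1), Gaussian-Bernoulli at the bottom.

Branch outputs are concatenated, passed through dropout and one fully
connected layer, and a softmax head yields calm/stress probabilities. The
whole network is trained end to end by mini-batch gradient descent with
momentum and weight decay under the cross-entropy loss.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from ._autodiff import (
    Tensor,
    batch_norm,
    concat,
    conv1d,
    maxpool1d,
    softmax_cross_entropy,
)

__all__ = ["HybridStressClassifier", "pretrain_dbn", "RBMStack"]


def _glorot(rng: np.random.Generator, *shape) -> np.ndarray:
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[0], shape[-1]
    if len(shape) == 3:  # conv kernels (out, in, k)
        fan_in = shape[1] * shape[2]
        fan_out = shape[0] * shape[2]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class _Param(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class _BatchNorm1d:
    """Per-channel batch normalization over (batch, channels, length).

    Training uses batch statistics and keeps an exponential running
    average. After training the estimator recomputes inference statistics
    by pooling batch moments over the whole training set (``calibrate``
    mode), which removes the warm-up bias of the running average when the
    number of gradient steps is small.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.scale = _Param(np.ones((1, channels, 1)))
        self.offset = _Param(np.zeros((1, channels, 1)))
        self.running_mean = np.zeros((1, channels, 1))
        self.running_var = np.ones((1, channels, 1))
        self.eps = eps
        self.momentum = momentum
        self._calib = None

    def __call__(self, x: Tensor, mode: str) -> Tensor:
        if mode in ("train", "calibrate"):
            mu = x.data.mean(axis=(0, 2), keepdims=True)
            var = x.data.var(axis=(0, 2), keepdims=True)
            if mode == "train":
                self.running_mean += self.momentum * (mu - self.running_mean)
                self.running_var += self.momentum * (var - self.running_var)
            else:
                n = x.data.shape[0] * x.data.shape[2]
                if self._calib is None:
                    self._calib = [0.0, 0.0, 0.0]
                self._calib[0] += n
                self._calib[1] += n * mu
                self._calib[2] += n * (var + mu**2)
            return batch_norm(
                x, self.scale, self.offset, mu, var, self.eps, batch_stats=True
            )
        return batch_norm(
            x,
            self.scale,
            self.offset,
            self.running_mean,
            self.running_var,
            self.eps,
            batch_stats=False,
        )

    def finalize_calibration(self) -> None:
        n, s1, s2 = self._calib
        self.running_mean = s1 / n
        self.running_var = s2 / n - self.running_mean**2
        self._calib = None

    def parameters(self):
        return [self.scale, self.offset]


class _ConvBlock:
    def __init__(self, rng, c_in: int, c_out: int, kernel: int):
        self.w = _Param(_glorot(rng, c_out, c_in, kernel))
        self.b = _Param(np.zeros(c_out))
        self.bn = _BatchNorm1d(c_out)
        self.pad = kernel // 2

    def __call__(self, x: Tensor, mode: str) -> Tensor:
        return maxpool1d(self.bn(conv1d(x, self.w, self.b, self.pad), mode).relu())

    def parameters(self):
        return [self.w, self.b] + self.bn.parameters()


class _LSTMDirection:
    def __init__(self, rng, d_in: int, units: int):
        self.units = units
        self.wx = _Param(_glorot(rng, d_in, 4 * units))
        self.wh = _Param(_glorot(rng, units, 4 * units))
        b = np.zeros(4 * units)
        b[units : 2 * units] = 1.0  # forget-gate bias
        self.b = _Param(b)

    def __call__(self, steps: list[Tensor]) -> list[Tensor]:
        batch = steps[0].shape[0]
        h = Tensor(np.zeros((batch, self.units)))
        c = Tensor(np.zeros((batch, self.units)))
        out = []
        u = self.units
        for x_t in steps:
            z = x_t @ self.wx + h @ self.wh + self.b
            i = z.narrow(1, 0, u).sigmoid()
            f = z.narrow(1, u, u).sigmoid()
            g = z.narrow(1, 2 * u, u).tanh()
            o = z.narrow(1, 3 * u, u).sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            out.append(h)
        return out

    def parameters(self):
        return [self.wx, self.wh, self.b]


class _BiLSTMLayer:
    def __init__(self, rng, d_in: int, units: int):
        self.fwd = _LSTMDirection(rng, d_in, units)
        self.bwd = _LSTMDirection(rng, d_in, units)

    def __call__(self, steps: list[Tensor]) -> list[Tensor]:
        hf = self.fwd(steps)
        hb = self.bwd(steps[::-1])[::-1]
        return [concat([f, b], axis=1) for f, b in zip(hf, hb)]

    def parameters(self):
        return self.fwd.parameters() + self.bwd.parameters()


class RBMStack:
    """Greedily pretrained restricted-Boltzmann-machine weights."""

    def __init__(self, weights: list[np.ndarray], hidden_biases: list[np.ndarray]):
        self.weights = weights
        self.hidden_biases = hidden_biases

    def propagate(self, v: np.ndarray) -> np.ndarray:
        for w, c in zip(self.weights, self.hidden_biases):
            v = expit(c + v @ w)
        return v


def pretrain_dbn(
    features: np.ndarray,
    layer_sizes: tuple[int, ...] = (200, 150, 100),
    epochs: int = 10,
    learning_rate: float = 0.05,
    batch_size: int = 16,
    rng: np.random.Generator | None = None,
) -> RBMStack:
    """Greedy layer-wise CD-1 pretraining of a sigmoid stack.

    ``features`` must already be scaled to [0, 1]; the first machine treats
    them as Gaussian visible units (mean-field reconstruction), upper
    machines are Bernoulli-Bernoulli. Constant feature columns carry no
    information for the energy model and trigger a warning.
    """
    rng = rng or np.random.default_rng()
    v_data = np.asarray(features, dtype=float)
    if v_data.shape[0] < 2:
        raise ValueError("pretraining needs at least 2 feature vectors")
    constant = np.ptp(v_data, axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature column(s) carry no "
            "contrastive signal during pretraining"
        )
    weights, hidden_biases = [], []
    for layer, n_hidden in enumerate(layer_sizes):
        n_visible = v_data.shape[1]
        w = rng.normal(0.0, 0.01, size=(n_visible, n_hidden))
        b = np.zeros(n_visible)
        c = np.zeros(n_hidden)
        gaussian_visible = layer == 0
        n = v_data.shape[0]
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                v0 = v_data[order[start : start + batch_size]]
                ph0 = expit(c + v0 @ w)
                h0 = (rng.random(ph0.shape) < ph0).astype(float)
                if gaussian_visible:
                    v1 = b + h0 @ w.T  # mean-field Gaussian reconstruction
                else:
                    v1 = expit(b + h0 @ w.T)
                ph1 = expit(c + v1 @ w)
                m = v0.shape[0]
                w += learning_rate * (v0.T @ ph0 - v1.T @ ph1) / m
                b += learning_rate * (v0 - v1).mean(axis=0)
                c += learning_rate * (ph0 - ph1).mean(axis=0)
        weights.append(w)
        hidden_biases.append(c)
        v_data = expit(c + v_data @ w)
    return RBMStack(weights, hidden_biases)


class HybridStressClassifier(ClassifierMixin, BaseEstimator):
    """CNN + BiLSTM + DBN hybrid classifier with a softmax head.

    Scikit-learn estimator over a feature matrix X of shape
    (n_trials, n_features). When ``n_features`` is a multiple of
    ``step_size`` (default 527, one block per channel) the BiLSTM sequences
    over channel blocks; otherwise it sees the whole vector as one step.

    Parameters follow the published configuration: conv filters 64/128/256
    with 3x1 kernels, two BiLSTM layers of 50 units, RBM sizes 200/150/100,
    dropout 0.5, initial learning rate 1e-3, mini-batches of 16. ``epochs``
    defaults to 200; scale it down for quick experiments. ``momentum`` and
    ``weight_decay`` are the knobs the hyper-parameter tuner adjusts.
    """

    def __init__(
        self,
        conv_filters=(64, 128, 256),
        conv_kernel=3,
        bilstm_layers=2,
        bilstm_units=50,
        rbm_units=(200, 150, 100),
        dropout=0.5,
        learning_rate=0.001,
        momentum=0.9,
        weight_decay=1e-4,
        batch_size=16,
        epochs=200,
        pretrain=True,
        pretrain_epochs=10,
        step_size=527,
        random_state=None,
    ):
        self.conv_filters = conv_filters
        self.conv_kernel = conv_kernel
        self.bilstm_layers = bilstm_layers
        self.bilstm_units = bilstm_units
        self.rbm_units = rbm_units
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.pretrain = pretrain
        self.pretrain_epochs = pretrain_epochs
        self.step_size = step_size
        self.random_state = random_state

    # -- construction ------------------------------------------------------

    def _build(self, n_features: int, n_classes: int, rng: np.random.Generator):
        self._conv_blocks = []
        c_in = 1
        length = n_features
        for c_out in self.conv_filters:
            self._conv_blocks.append(_ConvBlock(rng, c_in, c_out, self.conv_kernel))
            c_in = c_out
            length //= 2
        self._cnn_out = c_in * length

        if n_features % self.step_size == 0 and n_features > self.step_size:
            self._n_steps = n_features // self.step_size
        else:
            self._n_steps = 1
        d_in = n_features // self._n_steps
        self._bilstm = []
        for _ in range(self.bilstm_layers):
            self._bilstm.append(_BiLSTMLayer(rng, d_in, self.bilstm_units))
            d_in = 2 * self.bilstm_units

        self._dbn_weights = []
        self._dbn_biases = []
        d = n_features
        for h in self.rbm_units:
            self._dbn_weights.append(_Param(rng.normal(0.0, 0.01, size=(d, h))))
            self._dbn_biases.append(_Param(np.zeros(h)))
            d = h

        fused = self._cnn_out + 2 * self.bilstm_units + self.rbm_units[-1]
        self._fc_w = _Param(_glorot(rng, fused, n_classes))
        self._fc_b = _Param(np.zeros(n_classes))

    def _parameters(self) -> list[_Param]:
        params = []
        for blk in self._conv_blocks:
            params += blk.parameters()
        for layer in self._bilstm:
            params += layer.parameters()
        params += self._dbn_weights + self._dbn_biases
        params += [self._fc_w, self._fc_b]
        return params

    def _forward(
        self, x: np.ndarray, mode: str, rng: np.random.Generator | None = None
    ) -> Tensor:
        batch, n_features = x.shape
        xt = Tensor(x)

        h = xt.reshape(batch, 1, n_features)
        for blk in self._conv_blocks:
            h = blk(h, mode)
        cnn = h.reshape(batch, self._cnn_out)

        steps = [
            xt.narrow(1, s * (n_features // self._n_steps), n_features // self._n_steps)
            for s in range(self._n_steps)
        ]
        for layer in self._bilstm:
            steps = layer(steps)
        # final forward state (last step) and final backward state (first step)
        u = self.bilstm_units
        rnn = concat([steps[-1].narrow(1, 0, u), steps[0].narrow(1, u, u)], axis=1)

        dbn = xt
        for w, b in zip(self._dbn_weights, self._dbn_biases):
            dbn = (dbn @ w + b).sigmoid()

        fused = concat([cnn, rnn, dbn], axis=1)
        if mode == "train" and self.dropout > 0:
            mask = (rng.random(fused.shape) >= self.dropout) / (1.0 - self.dropout)
            fused = fused * mask
        return fused @ self._fc_w + self._fc_b

    # -- sklearn API ---------------------------------------------------------

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes, y_idx = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("training set must contain at least 2 classes")
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)

        # min-max scaling to [0, 1]; constant columns map to 0
        self._x_min = X.min(axis=0)
        span = X.max(axis=0) - self._x_min
        self._x_span = np.where(span == 0, 1.0, span)
        xs = (X - self._x_min) / self._x_span

        self._build(X.shape[1], classes.size, rng)
        if self.pretrain:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stack = pretrain_dbn(
                    xs,
                    tuple(self.rbm_units),
                    epochs=self.pretrain_epochs,
                    batch_size=self.batch_size,
                    rng=rng,
                )
            for w_param, b_param, w, c in zip(
                self._dbn_weights, self._dbn_biases, stack.weights, stack.hidden_biases
            ):
                w_param.data = w.copy()
                b_param.data = c.copy()

        params = self._parameters()
        velocity = [np.zeros_like(p.data) for p in params]
        n = xs.shape[0]
        trace = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = self._forward(xs[idx], mode="train", rng=rng)
                loss, _ = softmax_cross_entropy(logits, y_idx[idx])
                for p in params:
                    p.grad = None
                loss.backward()
                for p, v in zip(params, velocity):
                    g = (p.grad if p.grad is not None else 0.0) + self.weight_decay * p.data
                    v *= self.momentum
                    v -= self.learning_rate * g
                    p.data += v
                losses.append(float(loss.data))
            trace.append(float(np.mean(losses)))
        # pooled full-training-set batch-norm statistics for inference
        for start in range(0, n, max(self.batch_size, 2)):
            self._forward(xs[start : start + max(self.batch_size, 2)], mode="calibrate")
        for blk in self._conv_blocks:
            blk.bn.finalize_calibration()
        self.loss_trace_ = np.asarray(trace)
        return self

    def _scaled(self, X) -> np.ndarray:
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        # clip: features outside the training range would otherwise reach the
        # network far outside the [0, 1] box the branches were trained on
        return np.clip((X - self._x_min) / self._x_span, 0.0, 1.0)

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "loss_trace_")
        logits = self._forward(self._scaled(X), mode="eval")
        return logits.data

    def predict_proba(self, X) -> np.ndarray:
        logits = self.decision_function(X)
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        if not np.isfinite(probs).all():
            raise ValueError("model produced non-finite probabilities")
        return probs

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]  # ties -> lower class index
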