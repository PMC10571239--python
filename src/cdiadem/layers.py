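"""Minimal feed-forward layer primitives with hand-written backpropagation.

Only what the dual-input classifier needs: dense and mask-constrained dense
layers, a length-preserving 1D convolution, batch normalization, a
position-wise embedding expansion, reshape/flatten, and Adam.  All arithmetic
is float64 numpy; forward passes cache what backward needs, so a layer
instance is not reentrant across interleaved forward calls.

Weight initialization is Glorot-uniform from a caller-supplied generator, so
a fixed seed gives bit-identical parameters and (single-threaded) training.
"""

from __future__ import annotations

import numpy as np


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    name: str = "layer"

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def output_shape(self, input_shape):
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Input(Layer):
    """Bookkeeping-only layer so manifests count inputs the way keras does."""

    def __init__(self, width: int, name: str = "input"):
        self.width = width
        self.name = name

    def forward(self, x, training=False):
        if x.shape[1] != self.width:
            raise ValueError(f"{self.name}: expected width {self.width}, got {x.shape[1]}")
        return x

    def backward(self, grad):
        return grad

    def output_shape(self, input_shape):
        return (self.width,)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str = "relu", name: str = "dense"):
        if activation not in ("relu", "linear"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.W = glorot_uniform(rng, n_in, n_out, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.activation = activation
        self.name = name

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training=False):
        self._x = x
        z = x @ self.W + self.b
        self._z = z
        return np.maximum(z, 0.0) if self.activation == "relu" else z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * (self._z > 0)
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


class MaskedDense(Dense):
    """Dense layer whose weight matrix is multiplied elementwise by a fixed
    binary mask on every forward pass: 0-bit connections contribute exactly
    zero regardless of the stored weight value, and stay zero under training
    because the gradient is masked identically."""

    def __init__(self, mask: np.ndarray, rng: np.random.Generator,
                 activation: str = "relu", name: str = "pathway_dense"):
        n_in, n_out = mask.shape
        super().__init__(n_in, n_out, rng, activation=activation, name=name)
        self.mask = np.asarray(mask, dtype=float)

    def forward(self, x, training=False):
        self._x = x
        z = x @ (self.W * self.mask) + self.b
        self._z = z
        return np.maximum(z, 0.0) if self.activation == "relu" else z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * (self._z > 0)
        self.dW[...] = (self._x.T @ grad) * self.mask
        self.db[...] = grad.sum(axis=0)
        return grad @ (self.W * self.mask).T


class Reshape(Layer):
    def __init__(self, shape: tuple, name: str = "reshape"):
        self.shape = shape
        self.name = name

    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.reshape((x.shape[0], *self.shape))

    def backward(self, grad):
        return grad.reshape(self._in_shape)

    def output_shape(self, input_shape):
        return self.shape


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        self.name = name

    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)

    def output_shape(self, input_shape):
        return (int(np.prod(input_shape)),)


class Conv1D(Layer):
    """Stride-1, length-preserving ("same" padding) 1D convolution.

    For kernel size k the input is padded with (k-1)//2 zeros on the left and
    k//2 on the right, so the output length equals the input length.
    """

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 rng: np.random.Generator, activation: str = "relu", name: str = "conv1d"):
        fan_in, fan_out = kernel * in_channels, kernel * filters
        self.W = glorot_uniform(rng, fan_in, fan_out, (kernel, in_channels, filters))
        self.b = np.zeros(filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel = kernel
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel // 2
        self.activation = activation
        self.name = name

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training=False):
        # x: (batch, length, channels)
        B, L, C = x.shape
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        self._xp, self._L = xp, L
        z = np.zeros((B, L, self.W.shape[2]))
        for k in range(self.kernel):
            z += xp[:, k:k + L, :] @ self.W[k]
        z += self.b
        self._z = z
        return np.maximum(z, 0.0) if self.activation == "relu" else z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * (self._z > 0)
        L = self._L
        dxp = np.zeros_like(self._xp)
        for k in range(self.kernel):
            seg = self._xp[:, k:k + L, :]
            self.dW[k] = np.einsum("blc,blf->cf", seg, grad)
            dxp[:, k:k + L, :] += grad @ self.W[k].T
        self.db[...] = grad.sum(axis=(0, 1))
        return dxp[:, self.pad_left:self.pad_left + L, :]


class BatchNorm(Layer):
    """Per-feature batch normalization with running statistics.

    Training uses batch moments and updates the running mean/variance as
    running = momentum * running + (1 - momentum) * batch; inference uses the
    running statistics.
    """

    def __init__(self, width: int, momentum: float = 0.99, eps: float = 1e-3,
                 name: str = "batch_norm"):
        self.gamma = np.ones(width)
        self.beta = np.zeros(width)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(width)
        self.running_var = np.ones(width)
        self.momentum = momentum
        self.eps = eps
        self.name = name

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        self.dgamma[...] = (grad * self._xhat).sum(axis=0)
        self.dbeta[...] = grad.sum(axis=0)
        gx = grad * self.gamma
        if not self._training:
            return gx / self._std
        B = grad.shape[0]
        return (gx - gx.mean(axis=0) - self._xhat * (gx * self._xhat).mean(axis=0)) / self._std


class PositionwiseExpansion(Layer):
    """Embedding-style transform x (width n) -> (n, k): out[:, i, j] = x[:, i] * W[i, j].

    Each input unit gets k trainable scalars, mirroring an embedding table of
    shape (n, k) applied multiplicatively to a continuous input.
    """

    def __init__(self, width: int, depth: int, rng: np.random.Generator,
                 name: str = "embedding"):
        self.W = glorot_uniform(rng, 1, depth, (width, depth))
        self.dW = np.zeros_like(self.W)
        self.name = name

    @property
    def params(self):
        return [self.W]

    @property
    def grads(self):
        return [self.dW]

    def forward(self, x, training=False):
        self._x = x
        return x[:, :, None] * self.W[None, :, :]

    def backward(self, grad):
        self.dW[...] = np.einsum("bi,bij->ij", self._x, grad)
        return np.einsum("bij,ij->bi", grad, self.W)


class Adam:
    def __init__(self, layers: list[Layer], learning_rate: float = 0.005,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.layers = [l for l in layers if l.params]
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.v = [[np.zeros_like(p) for p in l.params] for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m *= self.beta1
                m += (1 - self.beta1) * g
                v *= self.beta2
                v += (1 - self.beta2) * g * g
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, one_hot_targets: np.ndarray) -> float:
    p = np.clip(probs, 1e-12, 1.0)
    return float(-(one_hot_targets * np.log(p)).sum(axis=1).mean())
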