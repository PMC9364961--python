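"""Numpy neural-network primitives for the sleep-staging model.

Two kinds of code live here.  The reference operations ``conv1d_valid``,
``lstm_cell_step`` and ``attention_pool`` are direct float64 transcriptions
of the model's defining equations (valid cross-correlation, the
gated-recurrence LSTM cell, softmax-weighted hidden-state pooling); they are
single-example, oracle-checkable, and intentionally simple.  The layer
classes below them are the batched float32 forward/backward implementations
the trainable model is built from; the test suite cross-checks the fused
layers against the reference operations.

Conventions: batches are leading axes; temporal convolution uses no padding
and stride 1; pooling is max with stride equal to the pool size and floor
division of the length; dropout is "inverted" (activations scaled by
1/(1-p) during training, identity at inference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LSTMCellParams",
    "conv1d_valid",
    "lstm_cell_step",
    "attention_pool",
    "relu",
    "softmax",
    "softmax_cross_entropy",
]

_F32 = np.float32


# ---------------------------------------------------------------------------
# reference operations (float64, single example)
# ---------------------------------------------------------------------------

def relu(x: np.ndarray) -> np.ndarray:
    """Rectified linear unit, f(x) = max(0, x)."""
    return np.maximum(x, 0)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax along ``axis``."""
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def conv1d_valid(
    x: np.ndarray, kernels: np.ndarray, bias: np.ndarray | None = None
) -> np.ndarray:
    """Valid-mode 1-D cross-correlation of a multichannel series.

    ``x`` is (L, C), ``kernels`` is (K, C, F), ``bias`` is (F,).  Returns
    (L-K+1, F) with ``out[t, f] = bias[f] + sum_{m,c} x[t+m, c] *
    kernels[m, c, f]`` — the sliding weighted sum with no kernel flip, as
    convolutional networks compute it.
    """
    x = np.asarray(x, dtype=np.float64)
    kernels = np.asarray(kernels, dtype=np.float64)
    if x.ndim != 2 or kernels.ndim != 3:
        raise ValueError("x must be (L, C) and kernels (K, C, F)")
    L, C = x.shape
    K, Ck, F = kernels.shape
    if Ck != C:
        raise ValueError(f"channel mismatch: input has {C}, kernels expect {Ck}")
    if K > L:
        raise ValueError(f"kernel length {K} exceeds input length {L}")
    windows = np.lib.stride_tricks.sliding_window_view(x, K, axis=0)  # (L-K+1, C, K)
    cols = windows.transpose(0, 2, 1).reshape(L - K + 1, K * C)
    out = cols @ kernels.reshape(K * C, F)
    if bias is not None:
        bias = np.asarray(bias, dtype=np.float64)
        if bias.shape != (F,):
            raise ValueError(f"bias must have shape ({F},)")
        out = out + bias
    return out


@dataclass
class LSTMCellParams:
    """Per-gate LSTM parameters (forget f, input i, output o, candidate c).

    ``W_*`` act on the input x_t, ``U_*`` on the previous hidden state
    h_{t-1}, ``b_*`` are biases; all gates share the hidden width.
    """

    W_f: np.ndarray
    W_i: np.ndarray
    W_o: np.ndarray
    W_c: np.ndarray
    U_f: np.ndarray
    U_i: np.ndarray
    U_o: np.ndarray
    U_c: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    def __post_init__(self) -> None:
        units, in_dim = self.W_f.shape
        for name in ("W_i", "W_o", "W_c"):
            if getattr(self, name).shape != (units, in_dim):
                raise ValueError(f"{name} must have shape {(units, in_dim)}")
        for name in ("U_f", "U_i", "U_o", "U_c"):
            if getattr(self, name).shape != (units, units):
                raise ValueError(f"{name} must have shape {(units, units)}")
        for name in ("b_f", "b_i", "b_o", "b_c"):
            if getattr(self, name).shape != (units,):
                raise ValueError(f"{name} must have shape {(units,)}")

    @property
    def units(self) -> int:
        return self.W_f.shape[0]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def lstm_cell_step(
    params: LSTMCellParams,
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One step of the gated LSTM recurrence.

    f = sigmoid(W_f x + U_f h + b_f), i, o likewise; candidate
    c~ = tanh(W_c x + U_c h + b_c); state c = f*c_prev + i*c~; output
    h = o * tanh(c) (elementwise products throughout).
    """
    x_t = np.asarray(x_t, dtype=np.float64)
    h_prev = np.asarray(h_prev, dtype=np.float64)
    c_prev = np.asarray(c_prev, dtype=np.float64)
    units = params.units
    if x_t.shape != (params.W_f.shape[1],):
        raise ValueError(f"x_t must have shape ({params.W_f.shape[1]},)")
    if h_prev.shape != (units,) or c_prev.shape != (units,):
        raise ValueError(f"h_prev and c_prev must have shape ({units},)")
    f = _sigmoid(params.W_f @ x_t + params.U_f @ h_prev + params.b_f)
    i = _sigmoid(params.W_i @ x_t + params.U_i @ h_prev + params.b_i)
    c_tilde = np.tanh(params.W_c @ x_t + params.U_c @ h_prev + params.b_c)
    c_t = f * c_prev + i * c_tilde
    o = _sigmoid(params.W_o @ x_t + params.U_o @ h_prev + params.b_o)
    h_t = o * np.tanh(c_t)
    return h_t, c_t


def attention_pool(h_sequence: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Softmax-weighted pooling of a hidden-state sequence.

    alpha = softmax(scores); returns sum_i alpha_i * h_i for ``h_sequence``
    of shape (T, U) and ``scores`` of shape (T,).
    """
    h_sequence = np.asarray(h_sequence, dtype=np.float64)
    scores = np.asarray(scores, dtype=np.float64)
    if h_sequence.ndim != 2 or scores.shape != (h_sequence.shape[0],):
        raise ValueError("h_sequence must be (T, U) with one score per step")
    alpha = softmax(scores)
    return alpha @ h_sequence


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy of softmax(logits) against integer labels.

    Returns (loss, probabilities, dlogits) with dlogits already averaged
    over the batch.
    """
    probs = softmax(logits.astype(np.float64), axis=1)
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-np.mean(np.log(probs[np.arange(n), labels] + eps)))
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return loss, probs, dlogits


# ---------------------------------------------------------------------------
# batched trainable layers (float32)
# ---------------------------------------------------------------------------

class Layer:
    """Minimal layer interface: params/grads dicts + forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k, p in self.params.items():
            self.grads[k] = np.zeros_like(p)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_F32)


class Dense(Layer):
    """Fully connected layer, optionally ReLU-activated."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 activation: str = "linear", zero_init: bool = False) -> None:
        super().__init__()
        if activation not in ("linear", "relu"):
            raise ValueError("activation must be 'linear' or 'relu'")
        self.activation = activation
        if zero_init:
            self.params["W"] = np.zeros((in_dim, out_dim), dtype=_F32)
        else:
            self.params["W"] = _glorot(rng, (in_dim, out_dim), in_dim, out_dim)
        self.params["b"] = np.zeros(out_dim, dtype=_F32)
        self.zero_grads()

    def forward(self, x, training=False, rng=None):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._mask = z > 0
            z = np.maximum(z, 0)
        return z

    def backward(self, dout):
        if self.activation == "relu":
            dout = dout * self._mask
        self.grads["W"] += self._x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


class Conv1D(Layer):
    """Valid-mode temporal convolution over (B, L, C) batches."""

    def __init__(self, in_channels: int, filters: int, kernel_len: int,
                 rng: np.random.Generator,
                 needs_input_grad: bool = True) -> None:
        super().__init__()
        self.kernel_len = kernel_len
        self.needs_input_grad = needs_input_grad
        fan_in = kernel_len * in_channels
        self.params["W"] = _glorot(
            rng, (kernel_len, in_channels, filters), fan_in, filters
        )
        self.params["b"] = np.zeros(filters, dtype=_F32)
        self.zero_grads()

    def forward(self, x, training=False, rng=None):
        B, L, C = x.shape
        K = self.kernel_len
        if K > L:
            raise ValueError(f"kernel length {K} exceeds input length {L}")
        windows = np.lib.stride_tricks.sliding_window_view(x, K, axis=1)
        cols = np.ascontiguousarray(windows.transpose(0, 1, 3, 2)).reshape(
            B * (L - K + 1), K * C
        )
        self._cols = cols
        self._in_shape = (B, L, C)
        F = self.params["b"].size
        out = cols @ self.params["W"].reshape(K * C, F) + self.params["b"]
        return out.reshape(B, L - K + 1, F)

    def backward(self, dout):
        B, L, C = self._in_shape
        K = self.kernel_len
        F = self.params["b"].size
        Lout = L - K + 1
        dflat = dout.reshape(B * Lout, F)
        self.grads["W"] += (self._cols.T @ dflat).reshape(K, C, F)
        self.grads["b"] += dflat.sum(axis=0)
        if not self.needs_input_grad:
            return None
        dx = np.zeros((B, L, C), dtype=dout.dtype)
        W = self.params["W"]
        for k in range(K):
            dx[:, k:k + Lout, :] += dout @ W[k].T
        return dx


class BatchNorm1D(Layer):
    """Per-feature batch normalization over the batch and time axes."""

    def __init__(self, n_features: int, momentum: float = 0.9,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(n_features, dtype=_F32)
        self.params["beta"] = np.zeros(n_features, dtype=_F32)
        self.running_mean = np.zeros(n_features, dtype=_F32)
        self.running_var = np.ones(n_features, dtype=_F32)
        self.zero_grads()

    def forward(self, x, training=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(_F32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(_F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std.astype(x.dtype), axes,
                       int(np.prod([x.shape[a] for a in axes])))
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        xhat, inv_std, axes, n = self._cache
        self.grads["gamma"] += (dout * xhat).sum(axis=axes)
        self.grads["beta"] += dout.sum(axis=axes)
        g = self.params["gamma"]
        dxhat = dout * g
        dx = (inv_std / n) * (
            n * dxhat
            - dxhat.sum(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True)
        )
        return dx.astype(dout.dtype)


class ReLULayer(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def forward(self, x, training=False, rng=None):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        # 8-bit mask resolution: keep probability is quantized to the
        # nearest 1/256 (exact for p = 0.5, off by 8e-4 for p = 0.2); the
        # inverted-dropout scale uses the realized keep probability, so
        # activations stay unbiased.
        threshold = int(round(self.p * 256))
        keep = (256 - threshold) / 256.0
        draw = rng.integers(0, 256, size=x.shape, dtype=np.uint8)
        self._mask = (draw >= threshold).astype(x.dtype) / x.dtype.type(keep)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class MaxPool1D(Layer):
    """Max pooling with stride = pool size; trailing remainder dropped."""

    def __init__(self, pool_size: int) -> None:
        super().__init__()
        if pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        self.pool = pool_size

    def forward(self, x, training=False, rng=None):
        B, L, F = x.shape
        Lp = L // self.pool
        windows = x[:, : Lp * self.pool, :].reshape(B, Lp, self.pool, F)
        # running max with first-occurrence winner indices (an explicit
        # comparison chain is several times faster than argmax here)
        mx = windows[:, :, 0].copy()
        idx = np.zeros((B, Lp, F), dtype=np.uint8)
        for k in range(1, self.pool):
            wk = windows[:, :, k]
            better = wk > mx
            idx = np.where(better, np.uint8(k), idx)
            np.maximum(mx, wk, out=mx)
        self._winner = idx
        self._in_shape = (B, L, F)
        return mx

    def backward(self, dout):
        B, L, F = self._in_shape
        Lp = L // self.pool
        dx = np.zeros((B, Lp, self.pool, F), dtype=dout.dtype)
        np.put_along_axis(
            dx, self._winner.astype(np.intp)[:, :, None, :],
            dout[:, :, None, :], axis=2,
        )
        dx = dx.reshape(B, Lp * self.pool, F)
        if Lp * self.pool == L:
            return dx
        return np.concatenate(
            [dx, np.zeros((B, L - Lp * self.pool, F), dtype=dout.dtype)],
            axis=1,
        )


try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False


if _HAVE_NUMBA:
    # Fused non-transcendental LSTM step arithmetic.  tanh/sigmoid stay in
    # vectorized numpy (scalar libm calls would be far slower here); these
    # kernels fuse the cheap elementwise work between the matrix products.

    @_njit(cache=True, fastmath=True)
    def _step_pre(g_t, xp_t):  # pragma: no cover - via LSTMLayer
        """g_t = (g_t + xp_t), with the i,f,o blocks halved for the
        tanh-based sigmoid that follows."""
        B, W = g_t.shape
        U3 = 3 * (W // 4)
        for b in range(B):
            for k in range(U3):
                g_t[b, k] = (g_t[b, k] + xp_t[b, k]) * np.float32(0.5)
            for k in range(U3, W):
                g_t[b, k] = g_t[b, k] + xp_t[b, k]

    @_njit(cache=True, fastmath=True)
    def _step_cell(g_t, c_prev, c_out):  # pragma: no cover
        """Finish the sigmoids (0.5 * tanh + 0.5) in place and compute the
        new cell state c = f * c_prev + i * g."""
        B, W = g_t.shape
        U = W // 4
        half = np.float32(0.5)
        for b in range(B):
            for u in range(U):
                i = half * g_t[b, u] + half
                f = half * g_t[b, U + u] + half
                o = half * g_t[b, 2 * U + u] + half
                g_t[b, u] = i
                g_t[b, U + u] = f
                g_t[b, 2 * U + u] = o
                c_out[b, u] = f * c_prev[b, u] + i * g_t[b, 3 * U + u]

    @_njit(cache=True, fastmath=True)
    def _step_back(g_t, tc, c_prev, dHt_t, dh, dc, dz, has_prev):  # pragma: no cover
        """One BPTT step of cell/gate derivatives (no transcendentals)."""
        B, W = g_t.shape
        U = W // 4
        one = np.float32(1.0)
        for b in range(B):
            for u in range(U):
                i = g_t[b, u]
                f = g_t[b, U + u]
                o = g_t[b, 2 * U + u]
                g = g_t[b, 3 * U + u]
                tcv = tc[b, u]
                dhv = dh[b, u] + dHt_t[b, u]
                do = dhv * tcv
                dcv = dhv * o * (one - tcv * tcv) + dc[b, u]
                dz[b, u] = dcv * g * i * (one - i)
                if has_prev:
                    dz[b, U + u] = dcv * c_prev[b, u] * f * (one - f)
                else:
                    dz[b, U + u] = np.float32(0.0)
                dz[b, 2 * U + u] = do * o * (one - o)
                dz[b, 3 * U + u] = dcv * i * (one - g * g)
                dc[b, u] = dcv * f


if _HAVE_NUMBA:
    from scipy.linalg.blas import sgemm as _sgemm


class LSTMLayer(Layer):
    """Fused batched LSTM with full backpropagation through time.

    Gate order in the fused parameter blocks is (i, f, o, g).  The input
    projection for all timesteps is one matrix product written straight
    into the time-major gate buffer; each recurrent step accumulates
    ``h @ U`` into that buffer with a beta=1 BLAS call on transposed
    (Fortran-order) views, so no intermediate projection array is ever
    materialized.  The i/f/o columns of the parameter copies used in the
    forward pass are pre-scaled by 1/2, turning all three sigmoids plus
    the candidate tanh into a single whole-row tanh
    (sigmoid(v) = (1 + tanh(v/2)) / 2); gradients are taken with respect
    to the original parameters, so the scaling never appears in backward.
    Cheap elementwise step arithmetic is numba-compiled; transcendentals
    stay in vectorized numpy.  A pure-numpy fallback implements the same
    contract when numba is unavailable.

    ``time_major_in``/``time_major_out`` let stacked layers chain without
    transposing the 3-D activations; batch-major callers see (B, T, U).
    ``needs_input_grad=False`` skips the input-gradient product for a
    layer that sits directly on the network input.
    """

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator,
                 time_major_in: bool = False, time_major_out: bool = False,
                 needs_input_grad: bool = True) -> None:
        super().__init__()
        self.units = units
        self.time_major_in = time_major_in
        self.time_major_out = time_major_out
        self.needs_input_grad = needs_input_grad
        U = units
        self.params["W"] = _glorot(rng, (in_dim, 4 * U), in_dim, U)
        self.params["U"] = _glorot(rng, (U, 4 * U), U, U)
        b = np.zeros(4 * U, dtype=_F32)
        b[U: 2 * U] = 1.0  # forget-gate bias starts open (standard practice)
        self.params["b"] = b
        self.zero_grads()
        # column scaling folding the i/f/o sigmoids into one whole-row tanh
        self._col_scale = np.concatenate(
            [np.full(3 * U, 0.5, _F32), np.ones(U, _F32)])
        self._post_mul = self._col_scale.copy()
        self._post_add = np.concatenate(
            [np.full(3 * U, 0.5, _F32), np.zeros(U, _F32)])

    def _shape_in(self, x):
        if self.time_major_in:
            T, B, D = x.shape
            return x.reshape(T * B, D), (B, T, D)
        B, T, D = x.shape
        xT = np.ascontiguousarray(x.transpose(1, 0, 2)).reshape(T * B, D)
        return xT, (B, T, D)

    def forward(self, x, training=False, rng=None):
        if _HAVE_NUMBA:
            return self._forward_fast(x)
        return self._forward_numpy(x)

    def backward(self, dH):
        if _HAVE_NUMBA:
            return self._backward_fast(dH)
        return self._backward_numpy(dH)

    # -- fast path ---------------------------------------------------------

    def _buffer(self, name: str, shape: tuple[int, ...]) -> np.ndarray:
        """Persistent scratch array, reused across batches of equal shape."""
        store = getattr(self, "_bufs", None)
        if store is None:
            store = self._bufs = {}
        arr = store.get(name)
        if arr is None or arr.shape != shape:
            arr = store[name] = np.empty(shape, dtype=_F32)
        return arr

    def _forward_fast(self, x):
        U = self.units
        xT, (B, T, D) = self._shape_in(x)
        W_s = self.params["W"] * self._col_scale
        Ur_s = self.params["U"] * self._col_scale
        b_s = self.params["b"] * self._col_scale
        gates = self._buffer("gates", (T, B, 4 * U))
        flat = gates.reshape(T * B, 4 * U)
        np.dot(xT, W_s, out=flat)
        flat += b_s
        C = self._buffer("C", (T, B, U))
        H = self._buffer("H", (T, B, U))
        tc = np.empty((B, U), dtype=_F32)
        h = np.zeros((B, U), dtype=_F32)
        c = np.zeros((B, U), dtype=_F32)
        for t in range(T):
            g_t = gates[t]
            # g_t += h @ Ur_s, in place on Fortran-order transposed views
            _sgemm(1.0, Ur_s.T, h.T, 1.0, g_t.T, overwrite_c=1)
            np.tanh(g_t, out=g_t)
            _step_cell(g_t, c, C[t])
            c = C[t]
            np.tanh(c, out=tc)
            np.multiply(g_t[:, 2 * U:3 * U], tc, out=H[t])
            h = H[t]
        self._cache = (xT, gates, C, None, H, (B, T, D))
        if self.time_major_out:
            return H
        return np.ascontiguousarray(H.transpose(1, 0, 2))

    def _backward_fast(self, dH):
        xT, gates, C, _, H, (B, T, D) = self._cache
        U = self.units
        W, Ur = self.params["W"], self.params["U"]
        UrT = np.ascontiguousarray(Ur.T)
        WT = np.ascontiguousarray(W.T) if self.needs_input_grad else None
        dHt = dH if self.time_major_out else np.ascontiguousarray(
            dH.transpose(1, 0, 2))
        dW, dUr, db = self.grads["W"], self.grads["U"], self.grads["b"]
        dx = (self._buffer("dx", (T, B, D))
              if self.needs_input_grad else None)
        dz = np.empty((B, 4 * U), dtype=_F32)
        dh = np.zeros((B, U), dtype=_F32)
        dc = np.zeros((B, U), dtype=_F32)
        tc = np.empty((B, U), dtype=_F32)
        zeros_c = np.zeros((B, U), dtype=_F32)
        for t in range(T - 1, -1, -1):
            np.tanh(C[t], out=tc)
            c_prev = C[t - 1] if t > 0 else zeros_c
            _step_back(gates[t], tc, c_prev, dHt[t], dh, dc, dz, t > 0)
            if t > 0:
                # dUr += H[t-1]^T dz  (transposed-view BLAS accumulate)
                _sgemm(1.0, dz.T, H[t - 1].T, 1.0, dUr.T,
                       trans_b=1, overwrite_c=1)
            x_t = xT[t * B:(t + 1) * B]
            _sgemm(1.0, dz.T, x_t.T, 1.0, dW.T, trans_b=1, overwrite_c=1)
            db += dz.sum(axis=0)
            if dx is not None:
                np.dot(dz, WT, out=dx[t])
            np.dot(dz, UrT, out=dh)
        if dx is None:
            return None
        if self.time_major_in:
            return dx
        return np.ascontiguousarray(dx.transpose(1, 0, 2))

    # -- reference numpy path ---------------------------------------------

    def _forward_numpy(self, x):
        U = self.units
        W, Ur, b = self.params["W"], self.params["U"], self.params["b"]
        xT, (B, T, D) = self._shape_in(x)
        xp = (xT @ W + b).reshape(T, B, 4 * U)
        gates = np.empty((T, B, 4 * U), dtype=_F32)  # post-activation i,f,o,g
        C = np.empty((T, B, U), dtype=_F32)
        tanh_c = np.empty((T, B, U), dtype=_F32)
        H = np.empty((T, B, U), dtype=_F32)
        tmp = np.empty((B, U), dtype=_F32)
        h = np.zeros((B, U), dtype=_F32)
        c = np.zeros((B, U), dtype=_F32)
        for t in range(T):
            g_t = gates[t]
            np.dot(h, Ur, out=g_t)
            g_t += xp[t]
            g_t *= self._col_scale
            np.tanh(g_t, out=g_t)
            g_t *= self._post_mul
            g_t += self._post_add
            i, f = g_t[:, :U], g_t[:, U:2 * U]
            o, g = g_t[:, 2 * U:3 * U], g_t[:, 3 * U:]
            c_new = C[t]
            np.multiply(f, c, out=c_new)
            np.multiply(i, g, out=tmp)
            c_new += tmp
            np.tanh(c_new, out=tanh_c[t])
            np.multiply(o, tanh_c[t], out=H[t])
            h = H[t]
            c = c_new
        self._cache = (xT, gates, C, tanh_c, H, (B, T, D))
        if self.time_major_out:
            return H
        return np.ascontiguousarray(H.transpose(1, 0, 2))

    def _backward_numpy(self, dH):
        xT, gates, C, tanh_c, H, (B, T, D) = self._cache
        U = self.units
        Ur = self.params["U"]
        UrT = np.ascontiguousarray(Ur.T)
        dHt = dH if self.time_major_out else np.ascontiguousarray(
            dH.transpose(1, 0, 2))
        dz_all = np.empty((T, B, 4 * U), dtype=_F32)
        dh = np.zeros((B, U), dtype=_F32)
        dc = np.zeros((B, U), dtype=_F32)
        dcv = np.empty((B, U), dtype=_F32)
        tmp = np.empty((B, U), dtype=_F32)
        t2 = np.empty((B, U), dtype=_F32)
        dUr = np.zeros_like(Ur)
        for t in range(T - 1, -1, -1):
            g_t = gates[t]
            i, f = g_t[:, :U], g_t[:, U:2 * U]
            o, g = g_t[:, 2 * U:3 * U], g_t[:, 3 * U:]
            tc = tanh_c[t]
            dh += dHt[t]
            np.multiply(dh, o, out=dcv)
            np.multiply(tc, tc, out=t2)
            np.subtract(1.0, t2, out=t2)
            dcv *= t2
            dcv += dc
            dz = dz_all[t]
            np.multiply(dcv, g, out=tmp)       # input gate
            np.subtract(1.0, i, out=t2)
            t2 *= i
            tmp *= t2
            dz[:, :U] = tmp
            if t > 0:                          # forget gate
                np.multiply(dcv, C[t - 1], out=tmp)
                np.subtract(1.0, f, out=t2)
                t2 *= f
                tmp *= t2
                dz[:, U:2 * U] = tmp
            else:
                dz[:, U:2 * U] = 0.0
            np.multiply(dh, tc, out=tmp)       # output gate
            np.subtract(1.0, o, out=t2)
            t2 *= o
            tmp *= t2
            dz[:, 2 * U:3 * U] = tmp
            np.multiply(dcv, i, out=tmp)       # candidate
            np.multiply(g, g, out=t2)
            np.subtract(1.0, t2, out=t2)
            tmp *= t2
            dz[:, 3 * U:] = tmp
            np.multiply(dcv, f, out=dc)
            if t > 0:
                dUr += H[t - 1].T @ dz
            np.dot(dz, UrT, out=dh)
        flat_dz = dz_all.reshape(T * B, 4 * U)
        self.grads["W"] += xT.T @ flat_dz
        self.grads["U"] += dUr
        self.grads["b"] += flat_dz.sum(axis=0)
        if not self.needs_input_grad:
            return None
        dx = (flat_dz @ self.params["W"].T).reshape(T, B, D)
        if self.time_major_in:
            return dx
        return np.ascontiguousarray(dx.transpose(1, 0, 2))


class AttentionPool(Layer):
    """Learned softmax pooling over an LSTM hidden sequence (B, T, U)."""

    def __init__(self, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["w"] = _glorot(rng, (units,), units, 1)
        self.zero_grads()

    def forward(self, x, training=False, rng=None):
        scores = x @ self.params["w"]                       # (B, T)
        alpha = softmax(scores, axis=1).astype(x.dtype)     # (B, T)
        self._cache = (x, alpha)
        return np.einsum("bt,btu->bu", alpha, x)

    def backward(self, dout):
        x, alpha = self._cache
        dalpha = np.einsum("bu,btu->bt", dout, x)
        # softmax Jacobian applied rowwise
        dscores = alpha * (dalpha - np.sum(alpha * dalpha, axis=1, keepdims=True))
        self.grads["w"] += np.einsum("bt,btu->u", dscores, x)
        dx = alpha[:, :, None] * dout[:, None, :]
        dx += dscores[:, :, None] * self.params["w"][None, None, :]
        return dx.astype(dout.dtype)
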