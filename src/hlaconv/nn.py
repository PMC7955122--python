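"""Minimal feed-forward autodiff layers for the multitask haplotype CNN.

The imputation network is small (two 1-D convolutions, batch normalisation,
max-pooling, one shared fully-connected layer and per-gene softmax heads), so
the layers are implemented directly in numpy with hand-written backward
passes.  This keeps inference differentiable end-to-end, which the
sensitivity-map and Monte-Carlo-dropout diagnostics rely on, and makes every
source of randomness an explicit ``numpy.random.Generator``.

Also hosts the multiple-gradient-descent (MGDA-UB) task-weighting solver: the
min-norm point of the convex hull of per-task gradients, found by
Frank-Wolfe iteration with an analytic two-point line search.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Layer:
    """Base layer: parameters and their gradients are parallel lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train: bool, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padded 1-D convolution over (batch, channels, length)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.kernel = kernel
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, kernel))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng=None):
        k = self.kernel
        p_left = (k - 1) // 2
        p_right = k - 1 - p_left
        xp = np.pad(x, ((0, 0), (0, 0), (p_left, p_right)))
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
        self._win, self._pad, self._L = win, (p_left, p_right), x.shape[2]
        return np.einsum("bilk,oik->bol", win, self.W, optimize=True) + self.b[None, :, None]

    def backward(self, dy):
        self.grads[0][...] = np.einsum("bol,bilk->oik", dy, self._win, optimize=True)
        self.grads[1][...] = dy.sum(axis=(0, 2))
        p_left, p_right = self._pad
        L = self._L
        dxp = np.zeros((dy.shape[0], self.W.shape[1], L + p_left + p_right))
        for t in range(self.kernel):
            dxp[:, :, t : t + L] += np.einsum("bol,oi->bil", dy, self.W[:, :, t], optimize=True)
        return dxp[:, :, p_left : p_left + L]


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over (batch, channels, length)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train, rng=None):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._xhat, self._inv, self._train = xhat, inv, train
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dy):
        self.grads[0][...] = (dy * self._xhat).sum(axis=(0, 2))
        self.grads[1][...] = dy.sum(axis=(0, 2))
        g = self.gamma[None, :, None] * self._inv[None, :, None]
        if not self._train:  # inference-mode gradient (diagnostics)
            return dy * g
        N = dy.shape[0] * dy.shape[2]
        dxhat = dy * self.gamma[None, :, None]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * self._xhat).sum(axis=(0, 2), keepdims=True)
        return (self._inv[None, :, None] / N) * (N * dxhat - s1 - self._xhat * s2)


class ReLU(Layer):
    def forward(self, x, train, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; active whenever a generator is supplied."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng=None):
        if rng is None or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class MaxPool1d(Layer):
    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x, train, rng=None):
        B, C, L = x.shape
        Lo = L // self.size
        xv = x[:, :, : Lo * self.size].reshape(B, C, Lo, self.size)
        self._arg = xv.argmax(axis=3)
        self._shape = x.shape
        return xv.max(axis=3)

    def backward(self, dy):
        B, C, L = self._shape
        Lo = dy.shape[2]
        dx = np.zeros((B, C, Lo, self.size))
        b, c, o = np.ogrid[:B, :C, :Lo]
        dx[b, c, o, self._arg] = dy
        dx = dx.reshape(B, C, Lo * self.size)
        if Lo * self.size < L:
            dx = np.pad(dx, ((0, 0), (0, 0), (0, L - Lo * self.size)))
        return dx


class Flatten(Layer):
    def forward(self, x, train, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_out, n_in))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng=None):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.grads[0][...] = dy.T @ self._x
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, target: np.ndarray, mask: np.ndarray | None = None):
    """Mean categorical cross-entropy and its gradient w.r.t. the logits.

    ``mask`` selects the rows that carry a label; unlabeled rows contribute
    zero loss and zero gradient.
    """
    p = softmax(logits)
    n = logits.shape[0]
    sel = np.ones(n, dtype=bool) if mask is None else mask
    eff = max(int(sel.sum()), 1)
    eps = 1e-12
    loss = -np.log(p[sel, target[sel]] + eps).sum() / eff
    dlogits = np.zeros_like(logits)
    dlogits[sel] = p[sel]
    dlogits[sel, target[sel]] -= 1.0
    dlogits /= eff
    return loss, dlogits


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# MGDA-UB task weighting
# ---------------------------------------------------------------------------


def _min_norm_exact(M: np.ndarray) -> np.ndarray | None:
    """Exact min-norm point over the simplex by active-set enumeration.

    For each support subset S, the equality-constrained minimiser is
    w_S proportional to M_S^{-1} 1; the best feasible (w >= 0) candidate is
    the global optimum of this convex QP.  Practical for small task counts.
    """
    from itertools import combinations

    T = M.shape[0]
    best_w, best_obj = None, np.inf
    for size in range(1, T + 1):
        for S in combinations(range(T), size):
            MS = M[np.ix_(S, S)]
            try:
                sol = np.linalg.solve(MS + 1e-12 * np.eye(size), np.ones(size))
            except np.linalg.LinAlgError:
                continue
            ssum = sol.sum()
            if ssum <= 0 or np.any(sol < -1e-10):
                continue
            w = np.zeros(T)
            w[list(S)] = np.clip(sol / ssum, 0.0, None)
            w /= w.sum()
            obj = float(w @ M @ w)
            if obj < best_obj - 1e-15:
                best_obj, best_w = obj, w
    return best_w


def mgda_ub_weights(
    task_gradients: list[np.ndarray],
    max_iter: int = 250,
    tol: float = 1e-10,
) -> np.ndarray:
    """Min-norm simplex weights over per-task shared-representation gradients.

    Solves ``argmin_{w in simplex} || sum_t w_t g_t ||^2`` by Frank-Wolfe.
    For two tasks the line search is analytic and exact.  All-zero gradients
    return uniform weights.
    """
    G = np.stack([np.asarray(g, dtype=float).ravel() for g in task_gradients])
    T = G.shape[0]
    if T == 1:
        return np.array([1.0])
    norms = np.linalg.norm(G, axis=1)
    if np.all(norms == 0.0):
        return np.full(T, 1.0 / T)
    M = G @ G.T
    if T == 2:
        # argmin_gamma ||(1-gamma) g1 + gamma g2||^2, clipped to [0, 1]
        den = M[0, 0] - 2.0 * M[0, 1] + M[1, 1]
        gamma = 0.5 if den <= 0.0 else float(np.clip((M[0, 0] - M[0, 1]) / den, 0.0, 1.0))
        return np.array([1.0 - gamma, gamma])
    if T <= 6:
        w = _min_norm_exact(M)
        if w is not None:
            return w
    w = np.full(T, 1.0 / T)
    for _ in range(max_iter):
        v = M @ w
        t = int(np.argmin(v))
        wMw = float(w @ v)
        den = wMw - 2.0 * v[t] + M[t, t]
        if den <= tol:
            break
        gamma = float(np.clip((wMw - v[t]) / den, 0.0, 1.0))
        w_new = (1.0 - gamma) * w
        w_new[t] += gamma
        if np.abs(w_new - w).max() < tol:
            w = w_new
            break
        w = w_new
    w = np.clip(w, 0.0, None)
    return w / w.sum()
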