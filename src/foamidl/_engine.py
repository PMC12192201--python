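"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set needed by the patch-level 3D CNN, the
attention blocks and the global classifier: broadcast arithmetic, matmul,
elementwise nonlinearities, axis reductions, reshape/concatenate, 3D
convolution (stride 1, arbitrary odd kernel, zero padding) and 2x2x2 max
pooling.  Gradients for conv/pool are hand-derived; everything else composes
from primitives.  Single-threaded numpy keeps runs bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Parameter",
    "concatenate",
    "conv3d",
    "maxpool3d",
    "log_softmax",
    "Module",
    "Conv3d",
    "Linear",
    "BatchNorm3d",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._prev = _prev

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.result_type(self.data, np.float32))
        self.grad = self.grad + g

    def backward(self, grad=None) -> None:
        """Reverse-mode sweep from this (typically scalar) tensor."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _lift(self, x) -> "Tensor":
        # python scalars adopt this tensor's dtype so float32 graphs stay float32
        if isinstance(x, Tensor):
            return x
        return Tensor(np.asarray(x, dtype=self.data.dtype))

    def _needs(self, *others) -> bool:
        return self.requires_grad or any(o.requires_grad for o in others)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, self._needs(other), (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, self._needs(other), (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, self._needs(other), (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = bw
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, self._needs(other), (self, other))

        def bw(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    self._accumulate(np.outer(g, other.data) if g.ndim else g * other.data)
                else:
                    self._accumulate(g @ other.data.T)
            if other.requires_grad:
                if self.data.ndim == 1:
                    other._accumulate(np.outer(self.data, g))
                else:
                    other._accumulate(self.data.T @ g)

        out._backward = bw
        return out

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bw
        return out

    def sigmoid(self):
        # clipped into the open interval: the mathematical sigmoid never
        # reaches 0/1, but float arithmetic saturates beyond |x| ~ 37
        s = np.clip(1.0 / (1.0 + np.exp(-self.data)),
                    np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
        out = Tensor(s, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = bw
        return out

    def softplus(self):
        """log(1 + exp(x)), numerically stable; gradient is sigmoid(x)."""
        x = self.data
        out_data = np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x)))
        out = Tensor(out_data, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / (1.0 + np.exp(-x)))

        out._backward = bw
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * e)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bw
        return out

    # -- reductions / shaping --------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        idx = np.argmax(self.data, axis=axis)
        m = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        out_data = m if keepdims else np.squeeze(m, axis=axis)
        out = Tensor(out_data, self.requires_grad, (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            gx = np.zeros_like(self.data)
            np.put_along_axis(gx, np.expand_dims(idx, axis), g, axis=axis)
            self._accumulate(gx)

        out._backward = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = bw
        return out


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def concatenate(tensors, axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(
        np.concatenate(datas, axis=axis),
        any(t.requires_grad for t in tensors),
        tuple(tensors),
    )
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


def _im2col(arr: np.ndarray, k: int, pad: int) -> tuple[np.ndarray, tuple]:
    """(N, C, D, H, W) -> contiguous (N*Do*Ho*Wo, C*k^3) column matrix."""
    xp = np.pad(arr, ((0, 0), (0, 0)) + ((pad, pad),) * 3) if pad else arr
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))  # N,C,Do,Ho,Wo,k,k,k
    n, c, do, ho, wo = win.shape[:5]
    col = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
        n * do * ho * wo, c * k**3
    )
    return col, (n, do, ho, wo)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int = 1) -> Tensor:
    """3D cross-correlation, stride 1, symmetric zero padding.

    x: (N, Cin, D, H, W); w: (Cout, Cin, k, k, k); b: (Cout,) or None.
    Output spatial size is D+2*pad-k+1 per axis.  Implemented as im2col +
    GEMM; the column matrix is kept for the weight-gradient GEMM.
    """
    k = w.shape[-1]
    c_out = w.shape[0]
    w_mat = w.data.reshape(c_out, -1)
    col, (n, do, ho, wo) = _im2col(x.data, k, pad)
    out_data = (col @ w_mat.T).reshape(n, do, ho, wo, c_out)
    out_data = np.ascontiguousarray(out_data.transpose(0, 4, 1, 2, 3))
    if b is not None:
        out_data += b.data[None, :, None, None, None]
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, any(t.requires_grad for t in prev), prev)

    def bw(g):
        g_col = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(-1, c_out)
        if w.requires_grad:
            w._accumulate((g_col.T @ col).reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g_col.sum(axis=0))
        if x.requires_grad:
            # full correlation of the output gradient with the flipped kernel
            wf = np.ascontiguousarray(
                w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            ).reshape(x.shape[1], -1)
            gc, (n2, d2, h2, w2) = _im2col(g, k, k - 1 - pad)
            dx = (gc @ wf.T).reshape(n2, d2, h2, w2, x.shape[1])
            x._accumulate(np.ascontiguousarray(dx.transpose(0, 4, 1, 2, 3)))

    out._backward = bw
    return out


def maxpool3d(x: Tensor) -> Tensor:
    """2x2x2 max pooling, stride 2; trailing odd voxels are dropped."""
    N, C, D, H, W = x.shape
    D2, H2, W2 = D // 2, H // 2, W // 2
    xc = x.data[:, :, : D2 * 2, : H2 * 2, : W2 * 2]
    xv = xc.reshape(N, C, D2, 2, H2, 2, W2, 2)
    xw = np.ascontiguousarray(xv.transpose(0, 1, 2, 4, 6, 3, 5, 7)).reshape(
        N, C, D2, H2, W2, 8
    )
    idx = np.argmax(xw, axis=-1)
    out = Tensor(
        np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0],
        x.requires_grad,
        (x,),
    )

    def bw(g):
        if not x.requires_grad:
            return
        gw = np.zeros((N, C, D2, H2, W2, 8), dtype=g.dtype)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gv = gw.reshape(N, C, D2, H2, W2, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        gx = np.zeros_like(x.data)
        gx[:, :, : D2 * 2, : H2 * 2, : W2 * 2] = gv.reshape(
            N, C, D2 * 2, H2 * 2, W2 * 2
        )
        x._accumulate(gx)

    out._backward = bw
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    # shift by a constant (max) for stability; the shift has zero net gradient
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


# ---------------------------------------------------------------------------
# layers


class Module:
    """Base class: recursive parameter collection and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def _submodules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                yield from (m for m in v if isinstance(m, Module))

    def train(self):
        self.training = True
        for m in self._submodules():
            m.train()
        return self

    def eval(self):
        self.training = False
        for m in self._submodules():
            m.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # checkpointing -------------------------------------------------------
    def state_arrays(self) -> list:
        """All arrays defining the module state (parameters + buffers), in order."""
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v.data)
            elif isinstance(v, Module):
                out.extend(v.state_arrays())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.state_arrays())
                    elif isinstance(item, Parameter):
                        out.append(item.data)
        for name in getattr(self, "_buffers", ()):
            out.append(getattr(self, name))
        return out

    def load_state_arrays(self, arrays: list) -> None:
        it = iter(arrays)

        def fill(mod):
            for key, v in mod.__dict__.items():
                if isinstance(v, Parameter):
                    v.data = np.asarray(next(it), dtype=v.data.dtype).reshape(v.shape)
                elif isinstance(v, Module):
                    fill(v)
                elif isinstance(v, (list, tuple)):
                    for item in v:
                        if isinstance(item, Module):
                            fill(item)
                        elif isinstance(item, Parameter):
                            item.data = np.asarray(next(it), dtype=item.data.dtype).reshape(item.shape)
            for name in getattr(mod, "_buffers", ()):
                setattr(mod, name, np.asarray(next(it)).copy())

        fill(self)


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int = 3, pad: int = 1,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel**3
        bound = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        self.weight = Parameter(
            rng.normal(0.0, bound, size=(c_out, c_in, kernel, kernel, kernel)).astype(dtype)
        )
        self.bias = Parameter(np.zeros(c_out, dtype=dtype))
        self.pad = pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, pad=self.pad)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bound = np.sqrt(1.0 / n_in)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(n_out, n_in)).astype(dtype))
        self.bias = Parameter(np.zeros(n_out, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        out = Tensor(
            x.data @ w.data.T + b.data,
            x.requires_grad or w.requires_grad or b.requires_grad,
            (x, w, b),
        )

        def bw(g):
            g2 = g.reshape(-1, g.shape[-1])
            x2 = x.data.reshape(-1, x.data.shape[-1])
            if w.requires_grad:
                w._accumulate(g2.T @ x2)
            if b.requires_grad:
                b._accumulate(g2.sum(axis=0))
            if x.requires_grad:
                x._accumulate((g2 @ w.data).reshape(x.shape))

        out._backward = bw
        return out


class BatchNorm3d(Module):
    """Per-channel batch normalisation over (N, D, H, W).

    Train mode normalises with batch statistics and updates running moments;
    eval mode uses the running moments (deterministic inference).
    """

    _buffers = ("running_mean", "running_var")

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float64):
        super().__init__()
        self.gamma = Parameter(np.ones(c, dtype=dtype))
        self.beta = Parameter(np.zeros(c, dtype=dtype))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3, 4)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.data.reshape(-1)
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var.data.reshape(-1)
            )
            inv = (var + self.eps) ** -0.5
            xhat = xc * inv
        else:
            shape = (1, -1, 1, 1, 1)
            mu = self.running_mean.reshape(shape)
            inv = 1.0 / np.sqrt(self.running_var.reshape(shape) + self.eps)
            xhat = (x - Tensor(mu)) * Tensor(inv)
        g = self.gamma.reshape(1, -1, 1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1, 1)
        return xhat * g + b


class Adam:
    """Adam with decoupled weight decay (AdamW) and optional per-group lr.

    ``params`` is a list of Parameters or of (parameter_list, lr_multiplier)
    groups.  ``weight_decay`` is skipped for parameters listed in
    ``no_decay`` (normalisation affines, biases).
    """

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0, no_decay=()):
        if params and isinstance(params[0], tuple):
            groups = [(list(ps), float(mult)) for ps, mult in params]
        else:
            groups = [(list(params), 1.0)]
        self.params = [p for ps, _ in groups for p in ps]
        self.mults = [m for ps, m in groups for _ in ps]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._no_decay = {id(p) for p in no_decay}
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            lr = self.lr * self.mults[i]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and id(p) not in self._no_decay:
                p.data = p.data - lr * self.weight_decay * p.data
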