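"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The generative models in this package are small multilayer perceptrons.  This
module provides the tensor/graph machinery to train them: a :class:`Tensor`
wrapping a ``float64`` ndarray, a set of differentiable primitives, and a
:func:`grad` routine.  Backward rules are themselves expressed with the same
primitives, so gradients are graph nodes too and :func:`grad` can be nested —
that second-order capability is what the Wasserstein-GAN gradient penalty
(a loss on the norm of an input gradient) requires.

Only what the models need is implemented: elementwise arithmetic, matmul,
reductions, shape ops, tanh/exp/log/sqrt, leaky-ReLU and a numerically stable
softmax.  Piecewise-linear activations have zero second derivative almost
everywhere, so treating their masks as constants during double backprop is
exact.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "grad",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "matmul",
    "pow_const",
    "exp",
    "log",
    "sqrt",
    "tanh",
    "leaky_relu",
    "relu",
    "sum_",
    "mean",
    "reshape",
    "transpose",
    "concat",
    "slice_cols",
    "broadcast_to",
    "softmax",
    "Linear",
    "Adam",
]


class Tensor:
    """A node in the computation graph holding a float64 array."""

    __slots__ = ("data", "requires_grad", "parents", "vjp")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        vjp: Callable[["Tensor"], tuple] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        if not requires_grad:
            for p in parents:
                if p.requires_grad:
                    requires_grad = True
                    break
        self.requires_grad = requires_grad
        self.parents = parents if self.requires_grad else ()
        self.vjp = vjp if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # Operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __rsub__(self, other):
        return sub(_wrap(other), self)

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __pow__(self, k):
        return pow_const(self, k)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    @property
    def T(self):
        return transpose(self)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# --------------------------------------------------------------------------
# Broadcasting helpers
# --------------------------------------------------------------------------


def _sum_to_shape(g: Tensor, shape: tuple) -> Tensor:
    """Reduce a broadcast gradient back to ``shape`` (the reverse of
    NumPy broadcasting)."""
    if g.shape == shape:
        return g
    # Leading added axes
    extra = len(g.shape) - len(shape)
    out = g
    if extra > 0:
        out = sum_(out, axis=tuple(range(extra)), keepdims=False)
    # Axes broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and out.shape[i] != 1)
    if axes:
        out = sum_(out, axis=axes, keepdims=True)
    return reshape(out, shape)


def broadcast_to(x: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    out = np.broadcast_to(x.data, shape)
    return Tensor(out.copy(), parents=(x,), vjp=lambda g: (_sum_to_shape(g, x.shape),))


# --------------------------------------------------------------------------
# Primitives
# --------------------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data + b.data,
        parents=(a, b),
        vjp=lambda g: (_sum_to_shape(g, a.shape), _sum_to_shape(g, b.shape)),
    )


def sub(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data - b.data,
        parents=(a, b),
        vjp=lambda g: (_sum_to_shape(g, a.shape), _sum_to_shape(neg(g), b.shape)),
    )


def mul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data * b.data,
        parents=(a, b),
        vjp=lambda g: (
            _sum_to_shape(mul(g, b), a.shape),
            _sum_to_shape(mul(g, a), b.shape),
        ),
    )


def div(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data / b.data,
        parents=(a, b),
        vjp=lambda g: (
            _sum_to_shape(div(g, b), a.shape),
            _sum_to_shape(neg(div(mul(g, a), mul(b, b))), b.shape),
        ),
    )


def neg(a: Tensor) -> Tensor:
    return Tensor(-a.data, parents=(a,), vjp=lambda g: (neg(g),))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data @ b.data,
        parents=(a, b),
        vjp=lambda g: (matmul(g, transpose(b)), matmul(transpose(a), g)),
    )


def pow_const(a: Tensor, k: float) -> Tensor:
    return Tensor(
        a.data ** k,
        parents=(a,),
        vjp=lambda g: (mul(g, mul(Tensor(float(k)), pow_const(a, k - 1))),),
    )


def exp(a: Tensor) -> Tensor:
    out = Tensor(np.exp(a.data), parents=(a,), vjp=None)
    out.vjp = lambda g: (mul(g, out),)
    return out


def log(a: Tensor) -> Tensor:
    return Tensor(np.log(a.data), parents=(a,), vjp=lambda g: (div(g, a),))


def sqrt(a: Tensor) -> Tensor:
    out = Tensor(np.sqrt(a.data), parents=(a,), vjp=None)
    out.vjp = lambda g: (div(g, mul(Tensor(2.0), out)),)
    return out


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)
    out = Tensor(t, parents=(a,), vjp=None)
    out.vjp = lambda g: (mul(g, sub(Tensor(1.0), mul(out, out))),)
    return out


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    # mask is data-dependent but piecewise constant: second derivative is
    # zero a.e., so holding it fixed during double backprop is exact
    mask = np.where(a.data > 0, 1.0, slope)
    return Tensor(a.data * mask, parents=(a,), vjp=lambda g: (mul(g, Tensor(mask)),))


def relu(a: Tensor) -> Tensor:
    return leaky_relu(a, slope=0.0)


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g: Tensor):
        gd = g
        if not keepdims and axis is not None:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            shp = list(a.shape)
            for ax in sorted(ax % len(a.shape) for ax in axes):
                shp[ax] = 1
            gd = reshape(gd, tuple(shp))
        return (broadcast_to(gd, a.shape),)

    return Tensor(out_data, parents=(a,), vjp=vjp)


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = 1
        for ax in axes:
            n *= a.shape[ax]
    return mul(sum_(a, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


def reshape(a: Tensor, shape) -> Tensor:
    shape = tuple(shape) if isinstance(shape, (tuple, list)) else (shape,)
    return Tensor(
        a.data.reshape(shape), parents=(a,), vjp=lambda g: (reshape(g, a.shape),)
    )


def transpose(a: Tensor) -> Tensor:
    return Tensor(a.data.T, parents=(a,), vjp=lambda g: (transpose(g),))


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g: Tensor):
        return tuple(
            _take_along_axis(g, int(offsets[i]), int(offsets[i + 1]), axis)
            for i in range(len(tensors))
        )

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        vjp=vjp,
    )


def _take_along_axis(a: Tensor, start: int, stop: int, axis: int) -> Tensor:
    idx = [slice(None)] * len(a.shape)
    idx[axis] = slice(start, stop)
    idx = tuple(idx)

    def vjp(g: Tensor):
        def scatter(gg: Tensor):
            z = np.zeros(a.shape)
            z[idx] = gg.data
            return Tensor(z, parents=(gg,), vjp=lambda h: (_take(h, idx),))

        return (scatter(g),)

    return Tensor(a.data[idx], parents=(a,), vjp=vjp)


def _take(a: Tensor, idx) -> Tensor:
    return Tensor(a.data[idx], parents=(a,), vjp=lambda g: (_scatter_like(g, a.shape, idx),))


def _scatter_like(g: Tensor, shape, idx) -> Tensor:
    z = np.zeros(shape)
    z[idx] = g.data
    return Tensor(z, parents=(g,), vjp=lambda h: (_take(h, idx),))


def slice_cols(a: Tensor, start: int, stop: int) -> Tensor:
    """Column slice of a 2-D tensor, differentiable."""
    return _take_along_axis(a, start, stop, axis=1)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shift = a.data.max(axis=axis, keepdims=True)  # constant shift, grad-free
    e = exp(sub(a, Tensor(shift)))
    return div(e, sum_(e, axis=axis, keepdims=True))


# --------------------------------------------------------------------------
# Reverse accumulation
# --------------------------------------------------------------------------


def grad(
    output: Tensor,
    inputs: Iterable[Tensor],
    create_graph: bool = False,
) -> list[Tensor]:
    """Gradients of a scalar ``output`` with respect to ``inputs``.

    With ``create_graph=True`` the returned tensors remain connected to the
    graph, so they can appear in further differentiated expressions.
    """
    inputs = list(inputs)
    if output.data.size != 1:
        raise ValueError("grad expects a scalar output")

    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(output, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))

    grads: dict[int, Tensor] = {id(output): Tensor(np.ones_like(output.data))}
    for node in reversed(topo):
        g = grads.get(id(node))
        if g is None or node.vjp is None:
            continue
        for parent, pg in zip(node.parents, node.vjp(g)):
            if pg is None or not parent.requires_grad:
                continue
            cur = grads.get(id(parent))
            grads[id(parent)] = pg if cur is None else add(cur, pg)

    out = []
    for t in inputs:
        g = grads.get(id(t))
        if g is None:
            g = Tensor(np.zeros_like(t.data))
        out.append(g if create_graph else g.detach())
    return out


# --------------------------------------------------------------------------
# Layers and optimizer
# --------------------------------------------------------------------------


class Linear:
    """Dense layer with the uniform fan-in initialization common for MLPs."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_in)
        self.W = Tensor(rng.uniform(-bound, bound, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(rng.uniform(-bound, bound, size=(1, n_out)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.W), self.b)

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class BatchNorm:
    """Batch normalization over axis 0 with learnable scale/shift.

    Always uses the current batch's statistics (the convention of tabular
    GAN generators, which sample in training mode), so behaviour is a pure
    function of the input batch and the parameters.
    """

    def __init__(self, n: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, n)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, n)), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = mean(x, axis=0, keepdims=True)
        xc = sub(x, mu)
        var = mean(mul(xc, xc), axis=0, keepdims=True)
        norm = div(xc, sqrt(add(var, Tensor(self.eps))))
        return add(mul(norm, self.gamma), self.beta)

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class Adam:
    """Adaptive moment estimation over a fixed parameter list."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads: Sequence[Tensor]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(self.params, grads)):
            gd = g.data + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * gd
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * gd * gd
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state(self) -> dict:
        return {"t": self.t, "m": [m.copy() for m in self.m], "v": [v.copy() for v in self.v]}

    def load_state(self, s: dict) -> None:
        self.t = s["t"]
        self.m = [m.copy() for m in s["m"]]
        self.v = [v.copy() for v in s["v"]]
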