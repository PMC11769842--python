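"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model stack needs exact derivatives twice over: forces are gradients of
the energy with respect to positions, and training on a force loss needs
gradients of those gradients with respect to parameters.  To make that
possible every primitive's vector-Jacobian product is itself written in
terms of the primitives below, so :func:`grad` can be applied to a graph
produced by a previous call to :func:`grad`.

Values are computed eagerly (each op holds its numpy result); only the
parent links and VJP closures are retained for the backward pass.  The
engine is deliberately small: elementwise arithmetic, a restricted
``einsum``, reductions, reshapes, gather/scatter along the first axis, and
basic slicing — exactly what an atom-centred potential needs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "astensor", "grad",
    "tsum", "reshape", "broadcast_to", "transpose", "einsum",
    "concatenate", "stack", "take", "scatter_add", "tslice",
    "exp", "log", "sin", "cos", "sqrt", "tanh", "sigmoid", "silu", "square",
]


class Tensor:
    """A node in the computation graph: a numpy value plus backward closure."""

    __slots__ = ("value", "parents", "vjp")

    def __init__(self, value, parents=(), vjp=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.parents = parents
        self.vjp = vjp  # callable: adjoint Tensor -> tuple of adjoint Tensors

    # -- conveniences -------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def __repr__(self):
        return f"Tensor(shape={self.value.shape})"

    # -- operator overloads -------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __neg__(self):
        return neg(self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, key):
        return tslice(self, key)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _is_const(t: Tensor) -> bool:
    return t.vjp is None and not t.parents


# ----------------------------------------------------------------------
# broadcasting helpers (built from primitives, hence differentiable)
# ----------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce adjoint ``g`` back down to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = tsum(g, axis=0)
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return g


# ----------------------------------------------------------------------
# elementwise arithmetic
# ----------------------------------------------------------------------

def add(a, b):
    a, b = astensor(a), astensor(b)
    sa, sb = a.shape, b.shape
    return Tensor(a.value + b.value, (a, b),
                  lambda g: (_unbroadcast(g, sa), _unbroadcast(g, sb)))


def sub(a, b):
    a, b = astensor(a), astensor(b)
    sa, sb = a.shape, b.shape
    return Tensor(a.value - b.value, (a, b),
                  lambda g: (_unbroadcast(g, sa), _unbroadcast(neg(g), sb)))


def neg(a):
    a = astensor(a)
    return Tensor(-a.value, (a,), lambda g: (neg(g),))


def mul(a, b):
    a, b = astensor(a), astensor(b)
    sa, sb = a.shape, b.shape
    return Tensor(a.value * b.value, (a, b),
                  lambda g: (_unbroadcast(mul(g, b), sa), _unbroadcast(mul(g, a), sb)))


def div(a, b):
    a, b = astensor(a), astensor(b)
    sa, sb = a.shape, b.shape
    out = Tensor(a.value / b.value, (a, b), None)
    out.vjp = lambda g: (_unbroadcast(div(g, b), sa),
                         _unbroadcast(neg(mul(g, div(out, b))), sb))
    return out


def power(a, p):
    """Elementwise a**p for a *constant* exponent p."""
    a = astensor(a)
    p = float(p)
    return Tensor(a.value ** p, (a,),
                  lambda g: (mul(g, mul(p, power(a, p - 1.0))),))


def square(a):
    a = astensor(a)
    return mul(a, a)


def exp(a):
    a = astensor(a)
    out = Tensor(np.exp(a.value), (a,), None)
    out.vjp = lambda g: (mul(g, out),)
    return out


def log(a):
    a = astensor(a)
    return Tensor(np.log(a.value), (a,), lambda g: (div(g, a),))


def sin(a):
    a = astensor(a)
    return Tensor(np.sin(a.value), (a,), lambda g: (mul(g, cos(a)),))


def cos(a):
    a = astensor(a)
    return Tensor(np.cos(a.value), (a,), lambda g: (neg(mul(g, sin(a))),))


def sqrt(a):
    a = astensor(a)
    out = Tensor(np.sqrt(a.value), (a,), None)
    out.vjp = lambda g: (div(g, mul(2.0, out)),)
    return out


def tanh(a):
    a = astensor(a)
    out = Tensor(np.tanh(a.value), (a,), None)
    out.vjp = lambda g: (mul(g, sub(1.0, mul(out, out))),)
    return out


def sigmoid(a):
    a = astensor(a)
    out = Tensor(1.0 / (1.0 + np.exp(-a.value)), (a,), None)
    out.vjp = lambda g: (mul(g, mul(out, sub(1.0, out))),)
    return out


def silu(a):
    a = astensor(a)
    return mul(a, sigmoid(a))


# ----------------------------------------------------------------------
# shape ops
# ----------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = astensor(a)
    shape = a.shape
    out_val = np.sum(a.value, axis=axis, keepdims=keepdims)

    def vjp(g):
        gv = g
        if axis is not None and not keepdims:
            axes = (axis,) if isinstance(axis, int) else axis
            newshape = list(out_val.shape)
            for ax in sorted(ax % len(shape) for ax in axes):
                newshape.insert(ax, 1)
            gv = reshape(gv, tuple(newshape))
        elif axis is None and not keepdims:
            gv = reshape(gv, (1,) * len(shape))
        return (broadcast_to(gv, shape),)

    return Tensor(out_val, (a,), vjp)


def mean(a, axis=None, keepdims=False):
    a = astensor(a)
    n = a.value.size if axis is None else np.prod(
        [a.shape[ax] for ax in ((axis,) if isinstance(axis, int) else axis)])
    return div(tsum(a, axis=axis, keepdims=keepdims), float(n))


def reshape(a, shape):
    a = astensor(a)
    old = a.shape
    return Tensor(a.value.reshape(shape), (a,), lambda g: (reshape(g, old),))


def broadcast_to(a, shape):
    a = astensor(a)
    old = a.shape
    return Tensor(np.broadcast_to(a.value, shape), (a,),
                  lambda g: (_unbroadcast(g, old),))


def transpose(a, axes):
    a = astensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return Tensor(np.transpose(a.value, axes), (a,), lambda g: (transpose(g, inv),))


def concatenate(tensors, axis=0):
    tensors = [astensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def vjp(g):
        outs = []
        for k in range(len(tensors)):
            key = [slice(None)] * tensors[k].ndim
            key[axis] = slice(int(offsets[k]), int(offsets[k + 1]))
            outs.append(tslice(g, tuple(key)))
        return tuple(outs)

    return Tensor(np.concatenate([t.value for t in tensors], axis=axis),
                  tuple(tensors), vjp)


def stack(tensors, axis=0):
    nd = astensor(tensors[0]).ndim
    axis = axis % (nd + 1)
    expanded = []
    for t in tensors:
        t = astensor(t)
        shape = list(t.shape)
        shape.insert(axis, 1)
        expanded.append(reshape(t, tuple(shape)))
    return concatenate(expanded, axis=axis)


# ----------------------------------------------------------------------
# gather / scatter along the leading axis
# ----------------------------------------------------------------------

def take(a, indices):
    """a[indices] along axis 0 (indices: constant int array)."""
    a = astensor(a)
    indices = np.asarray(indices, dtype=np.intp)
    n = a.shape[0]
    return Tensor(a.value[indices], (a,),
                  lambda g: (scatter_add(g, indices, n),))


def scatter_add(data, indices, n):
    """out[indices[e]] += data[e]; out has leading dimension n."""
    data = astensor(data)
    indices = np.asarray(indices, dtype=np.intp)
    out_val = np.zeros((n,) + data.shape[1:], dtype=np.float64)
    np.add.at(out_val, indices, data.value)
    return Tensor(out_val, (data,), lambda g: (take(g, indices),))


def tslice(a, key):
    """Basic (non-advanced) indexing a[key]."""
    a = astensor(a)
    shape = a.shape

    def vjp(g):
        return (_unslice(g, key, shape),)

    return Tensor(a.value[key], (a,), vjp)


def _unslice(g, key, shape):
    g = astensor(g)
    out_val = np.zeros(shape, dtype=np.float64)
    out_val[key] = g.value
    return Tensor(out_val, (g,), lambda gg: (tslice(gg, key),))


# ----------------------------------------------------------------------
# einsum (restricted: no repeated index within an operand; every index of
# each operand must occur in the output or another operand)
# ----------------------------------------------------------------------

def einsum(subscripts, *operands):
    operands = [astensor(o) for o in operands]
    in_part, out_sub = subscripts.replace(" ", "").split("->")
    in_subs = in_part.split(",")
    if len(in_subs) != len(operands):
        raise ValueError("einsum: operand count mismatch")
    for s in in_subs:
        if len(set(s)) != len(s):
            raise ValueError("einsum: repeated index within one operand unsupported")

    def vjp(g):
        grads = []
        for k, sk in enumerate(in_subs):
            others = [in_subs[j] for j in range(len(in_subs)) if j != k]
            avail = set(out_sub).union(*[set(s) for s in others]) if others else set(out_sub)
            if not set(sk) <= avail:
                raise ValueError("einsum: index summed within a single operand unsupported")
            sub = out_sub + "".join(others) + "->" + sk
            args = [g] + [operands[j] for j in range(len(operands)) if j != k]
            grads.append(einsum(",".join([out_sub] + others) + "->" + sk, *args))
        return tuple(grads)

    value = np.einsum(subscripts, *[o.value for o in operands], optimize=True)
    return Tensor(value, tuple(operands), vjp)


# ----------------------------------------------------------------------
# reverse pass
# ----------------------------------------------------------------------

def _topo(root: Tensor):
    order, seen = [], set()
    stack_ = [(root, False)]
    while stack_:
        node, done = stack_.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack_.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack_.append((p, False))
    return order


def _grad_impl(output: Tensor, wrt_list, seed: Tensor):
    adjoint = {id(output): seed}
    wanted = {id(w) for w in wrt_list}
    results = {}
    for node in reversed(_topo(output)):
        g = adjoint.pop(id(node), None)
        if g is None:
            continue
        if id(node) in wanted:
            results[id(node)] = g
        if node.vjp is None:
            continue
        for parent, pg in zip(node.parents, node.vjp(g)):
            if pg is None:
                continue
            prev = adjoint.get(id(parent))
            adjoint[id(parent)] = pg if prev is None else add(prev, pg)
    out = []
    for w in wrt_list:
        out.append(results.get(id(w), Tensor(np.zeros(w.shape))))
    return out


def grad(output: Tensor, wrt, seed=None):
    """Adjoints of ``output`` with respect to each tensor in ``wrt``.

    Returns Tensors (zeros for inputs the output does not depend on); the
    returned graph is itself differentiable, enabling higher-order
    derivatives such as parameter gradients of forces.
    """
    single = isinstance(wrt, Tensor)
    wrt_list = [wrt] if single else list(wrt)
    if seed is None:
        if output.value.ndim != 0:
            raise ValueError("grad of non-scalar output requires a seed adjoint")
        seed = Tensor(1.0)
    else:
        seed = astensor(seed)
    res = _grad_impl(output, wrt_list, seed)
    return res[0] if single else res
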