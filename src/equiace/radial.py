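"""Radial features on edges: Bessel basis, smooth polynomial cutoff, and the
learnable radial maps (element-agnostic MLP and element-dependent linear).

All functions accept either plain numpy arrays or autodiff Tensors, so the
same code serves analysis and the differentiable model graph.  The cutoff
envelope is always applied multiplicatively to the Bessel features *before*
any learnable map, and no learnable map carries an output bias, so every
radial variant vanishes identically for r >= r_cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad

RADIAL_MODES = ("fixed-orthogonal", "agnostic-mlp", "element-dependent")


@dataclass
class RadialConfig:
    r_cut: float = 5.0           # Angstrom
    n_basis: int = 8
    p: int = 6                   # cutoff polynomial power
    mode: str = "element-dependent"
    mlp_widths: tuple = (64, 64, 64)
    n_paths: int = 1             # number of (l1, l2, L) combinations served

    def __post_init__(self):
        if self.r_cut <= 0:
            raise ValueError("r_cut must be positive")
        if self.n_basis < 1:
            raise ValueError("n_basis must be >= 1")
        if self.p < 1:
            raise ValueError("cutoff power must be >= 1")
        if self.mode not in RADIAL_MODES:
            raise ValueError(f"mode must be one of {RADIAL_MODES}")
        self.mlp_widths = tuple(int(w) for w in self.mlp_widths)


def _is_tensor(x) -> bool:
    return isinstance(x, ad.Tensor)


def bessel_basis(r, n_basis: int, r_cut: float):
    """Spherical-Bessel-type functions sqrt(2/r_cut) sin(n pi r / r_cut) / r.

    The n = 1..n_basis functions are orthonormal on [0, r_cut] with weight
    r^2; the cutoff envelope is *not* included here.  Output shape
    ``r.shape + (n_basis,)``.
    """
    n = np.arange(1, n_basis + 1, dtype=float)
    pref = np.sqrt(2.0 / r_cut)
    if _is_tensor(r):
        if np.any(r.value <= 0):
            raise ValueError("bessel_basis requires r > 0")
        rr = ad.reshape(r, r.shape + (1,))
        return pref * ad.sin(rr * (n * np.pi / r_cut)) / rr
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("bessel_basis requires r > 0")
    rr = r[..., None]
    return pref * np.sin(rr * (n * np.pi / r_cut)) / rr


def polynomial_cutoff(r, r_cut: float, p: int = 6):
    """Smooth envelope: 1 at r=0, 0 at r>=r_cut with two vanishing derivatives.

    f(u) = 1 - (p+1)(p+2)/2 u^p + p(p+2) u^(p+1) - p(p+1)/2 u^(p+2), u = r/r_cut.
    """
    a = (p + 1) * (p + 2) / 2.0
    b = float(p * (p + 2))
    c = p * (p + 1) / 2.0
    if _is_tensor(r):
        u = r * (1.0 / r_cut)
        inside = (r.value < r_cut).astype(float)
        poly = 1.0 - a * u ** p + b * u ** (p + 1) - c * u ** (p + 2)
        return poly * ad.Tensor(inside)
    u = np.asarray(r, dtype=float) / r_cut
    poly = 1.0 - a * u ** p + b * u ** (p + 1) - c * u ** (p + 2)
    return np.where(u < 1.0, poly, 0.0)


def enveloped_bessel(r, cfg: RadialConfig):
    """Bessel features times the cutoff envelope, shape (..., n_basis)."""
    B = bessel_basis(r, cfg.n_basis, cfg.r_cut)
    f = polynomial_cutoff(r, cfg.r_cut, cfg.p)
    if _is_tensor(r):
        return B * ad.reshape(f, f.shape + (1,))
    return B * f[..., None]


# ----------------------------------------------------------------------
# learnable radial maps (autodiff Tensors)
# ----------------------------------------------------------------------

def init_agnostic_params(cfg: RadialConfig, n_channels: int,
                         rng: np.random.Generator) -> dict:
    """Fan-in-scaled Gaussian MLP weights; the output layer has no bias."""
    widths = [cfg.n_basis, *cfg.mlp_widths, n_channels * cfg.n_paths]
    params = {}
    for i, (nin, nout) in enumerate(zip(widths[:-1], widths[1:])):
        params[f"W{i}"] = ad.Tensor(rng.normal(size=(nin, nout)) / np.sqrt(nin))
        if i < len(widths) - 2:
            params[f"b{i}"] = ad.Tensor(np.zeros(nout))
    return params


def element_agnostic_radial(r, params: dict, cfg: RadialConfig,
                            n_channels: int, nonlinearity: str = "silu"):
    """MLP on enveloped Bessel features -> (n_edges, n_channels, n_paths).

    Independent of the chemical elements; the zero of the envelope is
    preserved because hidden biases feed through activations with
    act(0) = 0 only approximately — exact vanishing beyond r_cut instead
    comes from re-multiplying by the envelope at the output.
    """
    if cfg.mode != "agnostic-mlp":
        raise ValueError("config mode is not agnostic-mlp")
    act = {"silu": ad.silu, "tanh": ad.tanh, "none": lambda t: t}.get(nonlinearity)
    if act is None:
        raise ValueError(f"unknown nonlinearity {nonlinearity!r}")
    h = enveloped_bessel(r, cfg)
    n_layers = 1 + len(cfg.mlp_widths)
    for i in range(n_layers):
        W = params[f"W{i}"]
        if W.shape[0] != h.shape[-1]:
            raise ValueError("radial MLP parameter shape mismatch")
        h = ad.einsum("eb,bo->eo", h, W)
        if i < n_layers - 1:
            h = act(h + params[f"b{i}"])
    envelope = polynomial_cutoff(r, cfg.r_cut, cfg.p)
    h = h * ad.reshape(envelope, envelope.shape + (1,))
    return ad.reshape(h, (h.shape[0], n_channels, cfg.n_paths))


def init_element_dependent_params(cfg: RadialConfig, n_channels: int,
                                  n_elements: int, rng: np.random.Generator) -> dict:
    W = rng.normal(size=(n_elements, n_channels, cfg.n_basis, cfg.n_paths))
    return {"W": ad.Tensor(W / np.sqrt(cfg.n_basis))}


def element_dependent_radial(r, sender_element_index, params: dict,
                             cfg: RadialConfig):
    """Per-sender-element linear combination of enveloped Bessel features.

    R_{k,path}(r_e) = sum_n W[z_j(e), k, n, path] R_n(r_e) f_cut(r_e),
    returning (n_edges, n_channels, n_paths).
    """
    if cfg.mode != "element-dependent":
        raise ValueError("config mode is not element-dependent")
    idx = np.asarray(sender_element_index, dtype=np.intp)
    W = params["W"]
    if idx.min(initial=0) < 0 or (idx.size and idx.max() >= W.shape[0]):
        raise ValueError("sender element index outside the element table")
    feats = enveloped_bessel(r, cfg)                      # (E, n_basis)
    We = ad.take(W, idx)                                  # (E, K, n_basis, P)
    return ad.einsum("eb,ekbp->ekp", feats, We)


def fixed_orthogonal_radial(r, cfg: RadialConfig):
    """The raw enveloped Bessel features (delta / linear-ACE mode)."""
    return enveloped_bessel(r, cfg)


def distance_transform(r, z_i, z_j, params: dict | None = None):
    """Optional element-pair monotone rescaling applied before the basis.

    ``params['scale']`` is a per-element-pair positive factor; identity when
    params is None.  A non-positive scale would break monotonicity and is a
    configuration error.
    """
    if params is None:
        return r
    scale = np.asarray(params["scale"], dtype=float)
    if np.any(scale <= 0):
        raise ValueError("distance transform must be strictly monotone (scale > 0)")
    s = scale[np.asarray(z_i, dtype=np.intp), np.asarray(z_j, dtype=np.intp)]
    if _is_tensor(r):
        return r * ad.Tensor(s)
    return r * s
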