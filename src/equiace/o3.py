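"""O(3) symmetry kernel: real spherical harmonics, Wigner-D matrices, and
ordinary/generalized Clebsch–Gordan coupling.

Conventions (fixed once, everything downstream relies on them):

* Real **orthonormal** spherical harmonics without the Condon–Shortley
  phase, components ordered ``m = -l .. +l``; negative ``m`` carries the
  ``sin(|m| phi)`` part, positive ``m`` the ``cos(m phi)`` part, so for a
  unit vector ``(x, y, z)`` the ``l = 1`` block is
  ``sqrt(3/4pi) * (y, z, x)``.
* A degree-``l`` harmonic has parity ``(-1)**l``; parities multiply under
  coupling.  An improper operation acts as the rotation part times the
  feature's parity.
* Wigner-D matrices are defined *functionally* through the harmonics:
  ``Y_l(Q v) = D_l(Q) Y_l(v)``.
* Coupling tensors satisfy ``(D_l1 x ... x D_lv) C = C D_L`` exactly; each
  eta path of a generalized coupling is normalized to unit Frobenius norm
  (the nu = 1 degenerate path is the identity on m).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from functools import lru_cache
from math import factorial, pi, sqrt
from typing import Sequence

import numpy as np

from . import autodiff as ad

CACHE_FORMAT_VERSION = "v1"

_disk_cache_dir: str | None = None


def set_cache_dir(path: str | None) -> None:
    """Enable (or disable with None) on-disk caching of coupling tensors.

    Layout: ``<path>/v1/gc_<degrees>_<L>_<parity>.npz``, one file per
    generalized-coupling request, all eta paths stacked.
    """
    global _disk_cache_dir
    _disk_cache_dir = None if path is None else os.path.join(str(path), CACHE_FORMAT_VERSION)
    if _disk_cache_dir is not None:
        os.makedirs(_disk_cache_dir, exist_ok=True)


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class IrrepSpec:
    """Ordered block layout of an equivariant feature vector."""

    blocks: tuple  # of (multiplicity, degree L, parity)

    def __post_init__(self):
        blocks = tuple((int(m), int(L), int(p)) for m, L, p in self.blocks)
        for mult, L, p in blocks:
            if mult <= 0 or L < 0 or p not in (-1, 1):
                raise ValueError(f"invalid irrep block {(mult, L, p)}")
        object.__setattr__(self, "blocks", tuple(sorted(blocks, key=lambda b: (b[1], -b[2]))))

    @property
    def total_dim(self) -> int:
        return sum(m * (2 * L + 1) for m, L, _ in self.blocks)


@dataclass(frozen=True)
class RotationOperation:
    """An element of O(3): a 3x3 orthogonal matrix plus its improper flag."""

    matrix: np.ndarray
    improper: bool = False

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3) or np.abs(m.T @ m - np.eye(3)).max() > 1e-12:
            raise ValueError("matrix is not orthogonal to 1e-12")
        det = np.linalg.det(m)
        improper = det < 0
        if improper != bool(self.improper):
            raise ValueError("improper flag inconsistent with determinant sign")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "improper", bool(improper))

    @classmethod
    def from_matrix(cls, matrix) -> "RotationOperation":
        m = np.asarray(matrix, dtype=float)
        return cls(m, np.linalg.det(m) < 0)


@dataclass(frozen=True)
class CouplingScheme:
    """One sequential left-to-right binary coupling path (l1..lv) -> L."""

    degrees: tuple
    L: int
    intermediates: tuple  # k_2 .. k_{v-1}; empty for v <= 2
    path_index: int


@dataclass
class CouplingCoefficients:
    """All eta paths coupling ``degrees`` to the target (L, parity)."""

    degrees: tuple
    L: int
    parity: int
    schemes: list = field(default_factory=list)
    tensors: list = field(default_factory=list)  # each (2l1+1, ..., 2lv+1, 2L+1)

    @property
    def n_paths(self) -> int:
        return len(self.tensors)


# ----------------------------------------------------------------------
# real spherical harmonics
# ----------------------------------------------------------------------

def _double_factorial(n: int) -> float:
    out = 1.0
    for k in range(n, 0, -2):
        out *= k
    return out


@lru_cache(maxsize=None)
def _sh_norm(l: int, m: int) -> float:
    K = sqrt((2 * l + 1) / (4 * pi) * factorial(l - m) / factorial(l + m))
    return K * sqrt(2.0) if m > 0 else K


def _sh_from_xyz(x, y, z, l_max: int, stack_fn):
    """Shared harmonic recursion; works on ndarrays and autodiff Tensors.

    Azimuthal part: C_m = sin^m(theta) cos(m phi), S_m likewise with sin,
    built by the complex-multiplication recursion; polar part: associated
    Legendre with the sin^m factor removed (polynomial in z, singularity
    free).  Everything is polynomial in (x, y, z), hence differentiable.
    """
    one = x * 0.0 + 1.0
    C = [one]
    S = [x * 0.0]
    for m in range(1, l_max + 1):
        C.append(x * C[m - 1] - y * S[m - 1])
        S.append(x * S[m - 1] + y * C[m - 1])
    Q = {}
    for m in range(0, l_max + 1):
        Q[(m, m)] = _double_factorial(2 * m - 1) * one
        if m + 1 <= l_max:
            Q[(m + 1, m)] = (2 * m + 1) * (z * Q[(m, m)])
        for l in range(m + 2, l_max + 1):
            Q[(l, m)] = ((2 * l - 1) * (z * Q[(l - 1, m)]) - (l + m - 1) * Q[(l - 2, m)]) \
                * (1.0 / (l - m))
    out = []
    for l in range(l_max + 1):
        comps = [None] * (2 * l + 1)
        for m in range(0, l + 1):
            K = _sh_norm(l, m)
            comps[l + m] = K * (Q[(l, m)] * C[m])
            if m > 0:
                comps[l - m] = K * (Q[(l, m)] * S[m])
        out.append(stack_fn(comps))
    return out


def spherical_harmonics(direction, l_max: int):
    """Real orthonormal spherical harmonics of unit vector(s).

    Parameters
    ----------
    direction : array, shape (..., 3)
        Unit vector(s); a deviation of |v| from 1 beyond 1e-8 is an error.
    l_max : int

    Returns
    -------
    list of arrays, element ``l`` with shape ``(..., 2l+1)``, m = -l..+l.
    """
    v = np.asarray(direction, dtype=float)
    if v.shape[-1] != 3:
        raise ValueError("direction must have trailing dimension 3")
    if l_max < 0:
        raise ValueError("l_max must be >= 0")
    norms = np.linalg.norm(v, axis=-1)
    if np.any(norms < 1e-12):
        raise ValueError("zero vector has no direction")
    if norms.size and np.abs(norms - 1.0).max() > 1e-8:
        raise ValueError("direction vectors must be unit length (|1 - |v|| <= 1e-8)")
    return _sh_from_xyz(v[..., 0], v[..., 1], v[..., 2], l_max,
                        lambda comps: np.stack(comps, axis=-1))


def spherical_harmonics_ad(x: ad.Tensor, y: ad.Tensor, z: ad.Tensor, l_max: int):
    """Differentiable harmonics on already-normalized Tensor components."""
    return _sh_from_xyz(x, y, z, l_max, lambda comps: ad.stack(comps, axis=-1))


# ----------------------------------------------------------------------
# Wigner-D
# ----------------------------------------------------------------------

@lru_cache(maxsize=None)
def _sample_frame(L: int):
    """Fixed generic unit vectors and the pseudo-inverse of their harmonics."""
    rng = np.random.default_rng(1234 + L)
    pts = rng.normal(size=(2 * L + 1 + 8, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    Y = spherical_harmonics(pts, L)[L]
    return pts, np.linalg.pinv(Y)


def _rotation_D(R: np.ndarray, L: int) -> np.ndarray:
    """D_L for a *proper* rotation, via Y_L(R v) = D_L(R) Y_L(v)."""
    if L == 0:
        return np.ones((1, 1))
    pts, Ypinv = _sample_frame(L)
    YR = spherical_harmonics(pts @ R.T, L)[L]
    return (Ypinv @ YR).T


def wigner_D(rotation: RotationOperation, L: int, parity: int = None) -> np.ndarray:
    """Real representation matrix of an O(3) element on a (L, parity) irrep.

    For improper operations the result is ``parity * D(rotation part)``;
    ``parity`` defaults to the spherical-harmonic parity ``(-1)**L``.
    """
    if L < 0:
        raise ValueError("L must be >= 0")
    if parity is None:
        parity = (-1) ** L
    if parity not in (-1, 1):
        raise ValueError("parity must be +1 or -1")
    Q = rotation.matrix
    if rotation.improper:
        return parity * _rotation_D(-Q, L)
    return _rotation_D(Q, L)


def random_rotation(rng: np.random.Generator) -> RotationOperation:
    """Haar-uniform element of SO(3)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, [0, 1]] = Q[:, [1, 0]]
    return RotationOperation(Q, False)


def random_o3(rng: np.random.Generator, improper_fraction: float = 0.5) -> RotationOperation:
    """Haar-uniform element of O(3) (reflections via a fixed mirror)."""
    rot = random_rotation(rng)
    if rng.random() < improper_fraction:
        mirror = np.diag([1.0, 1.0, -1.0])
        return RotationOperation(rot.matrix @ mirror, True)
    return rot


# ----------------------------------------------------------------------
# Clebsch-Gordan coupling
# ----------------------------------------------------------------------

@lru_cache(maxsize=None)
def _real_to_complex(l: int) -> np.ndarray:
    """Unitary U with Y_real = U @ Y_complex (Condon-Shortley complex SH)."""
    d = 2 * l + 1
    U = np.zeros((d, d), dtype=complex)
    U[l, l] = 1.0
    for m in range(1, l + 1):
        U[l + m, l - m] = 1 / np.sqrt(2)
        U[l + m, l + m] = (-1) ** m / np.sqrt(2)
        U[l - m, l - m] = 1j / np.sqrt(2)
        U[l - m, l + m] = -1j * (-1) ** m / np.sqrt(2)
    return U


@lru_cache(maxsize=None)
def _complex_cg(l1: int, l2: int, L: int) -> np.ndarray:
    """Exact <l1 m1 l2 m2 | L M> tensor (sympy, evaluated to float64)."""
    from sympy.physics.quantum.cg import CG as _CG

    C = np.zeros((2 * l1 + 1, 2 * l2 + 1, 2 * L + 1))
    for i, m1 in enumerate(range(-l1, l1 + 1)):
        for j, m2 in enumerate(range(-l2, l2 + 1)):
            M = m1 + m2
            if abs(M) <= L:
                C[i, j, L + M] = float(_CG(l1, m1, l2, m2, L, M).doit())
    return C


@lru_cache(maxsize=None)
def clebsch_gordan(l1: int, l2: int, L: int) -> np.ndarray:
    """Real-basis coupling tensor of shape (2l1+1, 2l2+1, 2L+1).

    Satisfies ``(D_l1 x D_l2) C = C D_L`` for every rotation; the all-zero
    tensor when the triangle rule |l1-l2| <= L <= l1+l2 fails; unit
    Frobenius norm otherwise.
    """
    if min(l1, l2, L) < 0:
        raise ValueError("degrees must be non-negative")
    if L < abs(l1 - l2) or L > l1 + l2:
        return np.zeros((2 * l1 + 1, 2 * l2 + 1, 2 * L + 1))
    Cc = _complex_cg(l1, l2, L)
    U1, U2, UL = _real_to_complex(l1), _real_to_complex(l2), _real_to_complex(L)
    Cr = np.einsum("ab,cd,bdM,NM->acN", U1, U2, Cc, UL.conj())
    # a single global phase makes the tensor real in this basis
    idx = np.unravel_index(np.argmax(np.abs(Cr)), Cr.shape)
    Cr = Cr / (Cr[idx] / abs(Cr[idx]))
    if np.abs(Cr.imag).max() > 1e-10:
        raise RuntimeError("real CG construction left an imaginary residue")
    Cr = Cr.real
    Cr.flags.writeable = False
    nrm = np.linalg.norm(Cr)
    out = Cr / nrm
    out.flags.writeable = False
    return out


def _intermediate_sequences(degrees: Sequence[int], L: int):
    """All lexicographic sequences of intermediate degrees for the
    left-to-right coupling tree (l1 l2)->k2, (k2 l3)->k3, ..., ending at L."""
    nu = len(degrees)
    if nu == 1:
        return [()] if degrees[0] == L else []
    seqs = []

    def rec(pos, k, acc):
        if pos == nu - 1:
            if abs(k - degrees[pos]) <= L <= k + degrees[pos]:
                seqs.append(tuple(acc))
            return
        for knext in range(abs(k - degrees[pos]), k + degrees[pos] + 1):
            rec(pos + 1, knext, acc + [knext])

    rec(1, degrees[0], [])
    # acc holds k2..k_{nu-1}; lexicographic by construction
    return seqs


_gc_memory_cache: dict = {}


def generalized_coupling(degrees, L: int, parity: int = None) -> CouplingCoefficients:
    """Generalized coupling coefficients for ``degrees = (l1, .., lv) -> L``.

    Each eta path is the sequential contraction of ordinary CG tensors
    along the left-to-right binary tree; eta enumerates the admissible
    intermediate-degree sequences in lexicographic order.  ``parity``
    defaults to the natural harmonic parity ``prod (-1)**l``; requesting
    the opposite parity yields an empty result (no admissible path).
    """
    degrees = tuple(int(l) for l in degrees)
    if len(degrees) < 1:
        raise ValueError("need at least one degree (nu >= 1)")
    natural_parity = (-1) ** sum(degrees)
    if parity is None:
        parity = natural_parity
    key = (degrees, int(L), int(parity))
    if key in _gc_memory_cache:
        return _gc_memory_cache[key]
    result = CouplingCoefficients(degrees, int(L), int(parity))
    if parity == natural_parity:
        loaded = _disk_load(key)
        if loaded is not None:
            result = loaded
        else:
            for eta, inter in enumerate(_intermediate_sequences(degrees, L)):
                result.schemes.append(CouplingScheme(degrees, L, inter, eta))
                result.tensors.append(_path_tensor(degrees, L, inter))
            _disk_store(key, result)
    _gc_memory_cache[key] = result
    return result


def _path_tensor(degrees, L, intermediates) -> np.ndarray:
    nu = len(degrees)
    if nu == 1:
        return np.eye(2 * L + 1)
    chain = list(intermediates) + [L]
    T = clebsch_gordan(degrees[0], degrees[1], chain[0])  # (m1, m2, k2)
    for pos in range(2, nu):
        C = clebsch_gordan(chain[pos - 2], degrees[pos], chain[pos - 1])
        T = np.einsum("...k,kmM->...mM", T, C)
    nrm = np.linalg.norm(T)
    return T / nrm if nrm > 0 else T


def _disk_key_path(key) -> str:
    degrees, L, parity = key
    name = "gc_" + "-".join(map(str, degrees)) + f"_L{L}_p{'m' if parity < 0 else 'p'}.npz"
    return os.path.join(_disk_cache_dir, name)


def _disk_load(key):
    if _disk_cache_dir is None:
        return None
    path = _disk_key_path(key)
    if not os.path.exists(path):
        return None
    with np.load(path, allow_pickle=False) as data:
        degrees, L, parity = key
        result = CouplingCoefficients(degrees, L, parity)
        n = int(data["n_paths"])
        for eta in range(n):
            inter = tuple(int(v) for v in data[f"inter_{eta}"])
            result.schemes.append(CouplingScheme(degrees, L, inter, eta))
            result.tensors.append(data[f"tensor_{eta}"])
    return result


def _disk_store(key, result: CouplingCoefficients) -> None:
    if _disk_cache_dir is None:
        return
    payload = {"n_paths": np.array(result.n_paths)}
    for eta, (scheme, tensor) in enumerate(zip(result.schemes, result.tensors)):
        payload[f"inter_{eta}"] = np.array(scheme.intermediates, dtype=int)
        payload[f"tensor_{eta}"] = tensor
    np.savez(_disk_key_path(key), **payload)


def coupling_path_count(degrees, L: int) -> int:
    return len(_intermediate_sequences(tuple(degrees), L))
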