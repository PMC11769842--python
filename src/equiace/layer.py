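"""One equivariant ACE layer: one-particle basis on edges, density-trick
pooling to the atomic (A) basis, tensor products to the product basis,
generalized Clebsch-Gordan symmetrization to the B basis, and weighted
message formation.

Two engines live here:

* the *uncoupled-channel* convolution (correlation order nu = 1), the
  workhorse of the message-passing presets, where the (l1, l2) -> L
  coupling collapses to an ordinary Clebsch-Gordan contraction;
* the *generic* engine, which forms explicit products of pooled A-basis
  factors and contracts them with generalized coupling tensors — the full
  construction for arbitrary nu, also used in discrete-element ("delta")
  mode where it reproduces classic linear ACE.

Features are dictionaries mapping an irrep key ``(L, parity)`` to a Tensor
of shape ``(n_atoms, n_channels, 2L+1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np

from . import autodiff as ad
from . import o3

Features = dict  # {(L, parity): Tensor [n_atoms, K, 2L+1]}


def features_irrep_spec(h: Features, n_channels: int) -> o3.IrrepSpec:
    return o3.IrrepSpec(tuple((n_channels, L, p) for (L, p) in sorted(h.keys())))


# ----------------------------------------------------------------------
# embedding
# ----------------------------------------------------------------------

def initial_embedding(one_hot: np.ndarray, weights: ad.Tensor | None) -> Features:
    """Scalar chemical-element embedding h^(0) = one_hot @ W.

    ``weights`` of shape (n_elements, n_channels); None means delta mode,
    where the one-hot rows themselves are the initial (discrete) features.
    """
    oh = ad.Tensor(np.asarray(one_hot, dtype=float))
    if weights is None:
        h0 = oh
    else:
        if weights.shape[0] != oh.shape[1]:
            raise ValueError("embedding weight rows must match n_elements")
        h0 = ad.einsum("nz,zk->nk", oh, weights)
    return {(0, 1): ad.reshape(h0, h0.shape + (1,))}


# ----------------------------------------------------------------------
# path enumeration for the nu = 1 convolution
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ConvPath:
    """(l1, sender irrep, L) combination admissible under the triangle rule."""

    l1: int
    l2: int
    p2: int
    L: int

    @property
    def parity(self) -> int:
        return (-1) ** self.l1 * self.p2


def enumerate_paths(sender_irreps, l_max: int, L_max: int):
    """Deterministic list of (l1, l2, p2, L) paths with |l1-l2| <= L <= l1+l2."""
    paths = []
    for l2, p2 in sorted(sender_irreps):
        for l1 in range(l_max + 1):
            for L in range(abs(l1 - l2), min(l1 + l2, L_max) + 1):
                paths.append(ConvPath(l1, l2, p2, L))
    return paths


# ----------------------------------------------------------------------
# one-particle basis, pooling, products, symmetrization
# ----------------------------------------------------------------------

def one_particle_basis(paths, radial_values: ad.Tensor, Y, h: Features,
                       senders: np.ndarray) -> list:
    """Edge basis phi = R(r) * Y_l1(rhat) * h_sender per path.

    ``radial_values``: (n_edges, K, n_paths) aligned with ``paths``;
    ``Y``: per-degree harmonic Tensors (n_edges, 2l+1).  Returns one Tensor
    of shape (n_edges, K, 2l1+1, 2l2+1) per path — the sender-feature index
    c = (l2, m2) is kept uncontracted; symmetrization happens later.
    """
    out = []
    for idx, path in enumerate(paths):
        R = radial_values[:, :, idx]
        hj = ad.take(h[(path.l2, path.p2)], senders)
        out.append(ad.einsum("ek,ea,ekb->ekab", R, Y[path.l1], hj))
    return out


def pool_atomic_basis(edge_basis: list, receivers: np.ndarray, n_atoms: int,
                      lam: float) -> list:
    """Density-trick pooling A_i = (1/lambda) sum_{j in N(i)} phi(i, j)."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return [ad.scatter_add(phi, receivers, n_atoms) * (1.0 / lam)
            for phi in edge_basis]


def symmetrize_pair(A: ad.Tensor, l1: int, l2: int, L: int) -> ad.Tensor:
    """nu = 1 symmetrization: contract the (m1, m2) pair with ordinary CG."""
    C = o3.clebsch_gordan(l1, l2, L)
    return ad.einsum("nkab,abM->nkM", A, ad.Tensor(C))


def nequip_convolution(paths, radial_values: ad.Tensor, Y, h: Features,
                       receivers: np.ndarray, senders: np.ndarray,
                       n_atoms: int, lam: float) -> dict:
    """The nu = 1 message basis: per-(L, parity) stacks over paths.

    m-basis B[(L,P)] has shape (n_atoms, K, n_paths_LP, 2L+1); contracting
    the Clebsch-Gordan tensor directly on edges is algebraically identical
    to pool -> product -> symmetrize at nu = 1 but cheaper.
    """
    per_key: dict = {}
    for idx, path in enumerate(paths):
        C = o3.clebsch_gordan(path.l1, path.l2, path.L)
        R = radial_values[:, :, idx]
        hj = ad.take(h[(path.l2, path.p2)], senders)
        edge = ad.einsum("ek,ea,ekb,abM->ekM", R, Y[path.l1], hj, ad.Tensor(C))
        pooled = ad.scatter_add(edge, receivers, n_atoms) * (1.0 / lam)
        per_key.setdefault((path.L, path.parity), []).append(pooled)
    return {key: ad.stack(vals, axis=2) for key, vals in per_key.items()}


def form_message(basis: dict, weights: dict, element_index: np.ndarray) -> Features:
    """m_{i,kLM} = sum_eta w_{k eta L}(theta_i) B_{i,k eta,LM}.

    The per-atom weight of the central equation is realized as an
    element-conditioned shared weight: ``weights[(L,P)]`` has shape
    (n_elements, K, n_paths_LP) and is gathered by the central atom's
    element.
    """
    idx = np.asarray(element_index, dtype=np.intp)
    out: Features = {}
    for key, B in basis.items():
        w = ad.take(weights[key], idx)
        out[key] = ad.einsum("nkp,nkpM->nkM", w, B)
    return out


# ----------------------------------------------------------------------
# generic engine: explicit products + generalized coupling
# ----------------------------------------------------------------------

def product_basis(A_factors: list, tuples: list) -> list:
    """Tensor products of A-basis factors: the density-trick product basis.

    ``A_factors[f]`` has shape (n_atoms, K, d_1(f), d_2(f)) (d_2 may be 1);
    ``tuples`` are index tuples (f_1 <= ... <= f_nu).  The uncoupled channel
    k is never multiplied with itself across factors — products are taken
    elementwise in k, outer in the m indices.
    """
    out = []
    letters = "abcdefghij"
    for tup in tuples:
        if len(tup) < 1:
            raise ValueError("correlation order nu must be >= 1")
        subs, ops = [], []
        used = 0
        for f in tup:
            A = A_factors[f]
            nd = A.ndim - 2
            subs.append("nk" + letters[used:used + nd])
            ops.append(A)
            used += nd
        spec = ",".join(subs) + "->nk" + letters[:used]
        out.append(ad.einsum(spec, *ops) if len(ops) > 1 else ops[0])
    return out


def symmetrize(prod: ad.Tensor, coupling: o3.CouplingCoefficients) -> ad.Tensor:
    """B_{i,k,eta,LM} = sum_v C^{LM}_{eta,v} Abold_{i,k,v}.

    ``prod`` has one trailing m axis per coupled degree; returns shape
    (n_atoms, K, n_paths, 2L+1).
    """
    nd = prod.ndim - 2
    if nd != len(coupling.degrees):
        raise ValueError("product rank does not match coupling degrees")
    for d, l in zip(prod.shape[2:], coupling.degrees):
        if d != 2 * l + 1:
            raise ValueError("product m-dimensions do not match coupling degrees")
    letters = "abcdefghij"[:nd]
    outs = [ad.einsum(f"nk{letters},{letters}M->nkM", prod, ad.Tensor(T))
            for T in coupling.tensors]
    if not outs:
        return ad.Tensor(np.zeros((prod.shape[0], prod.shape[1], 0, 2 * coupling.L + 1)))
    return ad.stack(outs, axis=2)


# ----------------------------------------------------------------------
# discrete-element (delta / full-coupling) atomic basis: linear ACE
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class DeltaTuple:
    """A canonical nu-tuple of coupled (element, radial n, degree l) indices."""

    entries: tuple      # of (z_index, n_index, l), sorted
    L: int
    eta: int


def delta_atomic_basis(bessel_env: ad.Tensor, Y, receivers: np.ndarray,
                       sender_element_index: np.ndarray, n_atoms: int,
                       n_elements: int, l_max: int, lam: float) -> dict:
    """A_{i, z n l m}: density projection with discrete element channels.

    Returns {l: Tensor (n_atoms, n_elements, n_basis, 2l+1)}.
    """
    comb = receivers * n_elements + np.asarray(sender_element_index, dtype=np.intp)
    n_basis = bessel_env.shape[1]
    A = {}
    for l in range(l_max + 1):
        edge = ad.einsum("en,em->enm", bessel_env, Y[l])
        pooled = ad.scatter_add(edge, comb, n_atoms * n_elements)
        A[l] = ad.reshape(pooled, (n_atoms, n_elements, n_basis, 2 * l + 1)) * (1.0 / lam)
    return A


def enumerate_delta_tuples(n_elements: int, n_basis: int, l_max: int,
                           nu_max: int, max_poly_degree: int, L: int = 0,
                           parity: int = 1) -> list:
    """Canonical invariant/equivariant tuple list for full coupling.

    Tuples are multisets of (z, n, l) with total polynomial degree
    sum(n_xi + l_xi) <= max_poly_degree (n is 1-based), one entry per
    admissible eta coupling path to the target (L, parity).
    """
    singles = [(z, n, l) for l in range(l_max + 1)
               for n in range(n_basis) for z in range(n_elements)]
    out = []
    for nu in range(1, nu_max + 1):
        for combo in combinations_with_replacement(range(len(singles)), nu):
            entries = tuple(sorted(singles[c] for c in combo))
            degree = sum((n + 1) + l for _, n, l in entries)
            if degree > max_poly_degree:
                continue
            degrees = tuple(l for _, _, l in entries)
            coup = o3.generalized_coupling(degrees, L, parity)
            for eta in range(coup.n_paths):
                out.append(DeltaTuple(entries, L, eta))
    return out


def delta_symmetrized_basis(A: dict, tuples: list) -> ad.Tensor:
    """Stack of B_{i, (tuple, eta), L M} values, shape (n_atoms, n_feat, 2L+1)."""
    letters = "abcdefghij"
    feats = []
    for tup in tuples:
        degrees = tuple(l for _, _, l in tup.entries)
        coup = o3.generalized_coupling(degrees, tup.L)
        T = coup.tensors[tup.eta]
        subs, ops = [], []
        for pos, (z, n, l) in enumerate(tup.entries):
            subs.append("n" + letters[pos])
            ops.append(A[l][:, z, n, :])
        ms = letters[:len(tup.entries)]
        spec = ",".join(subs) + f",{ms}M->nM"
        feats.append(ad.einsum(spec, *(ops + [ad.Tensor(T)])))
    return ad.stack(feats, axis=1)


# ----------------------------------------------------------------------
# update-side linear algebra (shared with model assembly)
# ----------------------------------------------------------------------

def linear_update(message: Features, W: dict) -> Features:
    """h_{kLM} = sum_k' W_{kk'L} m_{k'LM}; structurally block-diagonal in L, M."""
    out: Features = {}
    for key, m in message.items():
        Wb = W[key]
        if Wb.shape[0] != m.shape[1] or Wb.shape[1] != m.shape[1]:
            raise ValueError("update weight block shape mismatch")
        out[key] = ad.einsum("kq,nqM->nkM", Wb, m)
    return out


def self_connection(updated: Features, previous: Features, S: dict,
                    element_index: np.ndarray) -> Features:
    """Element-conditioned residual: h <- updated + S(theta_i) h_prev."""
    idx = np.asarray(element_index, dtype=np.intp)
    out = dict(updated)
    for key, hprev in previous.items():
        if key not in S:
            continue
        Se = ad.take(S[key], idx)  # (n, K, K)
        term = ad.einsum("nkq,nqM->nkM", Se, hprev)
        out[key] = out[key] + term if key in out else term
    return out
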