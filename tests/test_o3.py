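"""Symmetry kernel: harmonics against an independent implementation,
Wigner-D as a representation, coupling tensors against null-space
extraction, and the path combinatorics."""

from math import pi, sqrt

import numpy as np
import pytest
from scipy.special import sph_harm_y

from equiace import o3


def _unit(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


# ----------------------------------------------------------------------
# spherical harmonics
# ----------------------------------------------------------------------

def test_l0_and_pole_closed_forms(rng):
    v = _unit(rng, 4)
    Y = o3.spherical_harmonics(v, 1)
    assert np.allclose(Y[0], 1.0 / (2 * sqrt(pi)))
    Yz = o3.spherical_harmonics(np.array([0.0, 0.0, 1.0]), 1)
    assert np.allclose(Yz[1], [0.0, sqrt(3 / (4 * pi)), 0.0], atol=1e-14)


def test_against_scipy_complex_harmonics(rng):
    """Independent oracle: rebuild the real basis from the Condon-Shortley
    complex harmonics and compare value-for-value."""
    v = _unit(rng, 25)
    theta = np.arccos(v[:, 2])
    phi = np.arctan2(v[:, 1], v[:, 0])
    Y = o3.spherical_harmonics(v, 3)
    for l in range(4):
        Yc = np.stack([sph_harm_y(l, m, theta, phi) for m in range(-l, l + 1)], axis=-1)
        ref = np.zeros((len(v), 2 * l + 1))
        ref[:, l] = Yc[:, l].real
        for m in range(1, l + 1):
            ref[:, l + m] = ((Yc[:, l - m] + (-1) ** m * Yc[:, l + m]) / np.sqrt(2)).real
            ref[:, l - m] = ((1j * (Yc[:, l - m] - (-1) ** m * Yc[:, l + m])) / np.sqrt(2)).real
        assert np.abs(Y[l] - ref).max() < 1e-12


def test_orthonormality_by_spherical_quadrature():
    # Gauss-Legendre x uniform-phi product rule is exact for band-limited
    # integrands, so the Gram matrix must be the identity to machine precision
    l_max = 3
    xg, wg = np.polynomial.legendre.leggauss(2 * l_max + 2)
    n_phi = 4 * l_max + 4
    phis = 2 * np.pi * np.arange(n_phi) / n_phi
    ct, ph = np.meshgrid(xg, phis, indexing="ij")
    st = np.sqrt(1 - ct ** 2)
    vecs = np.stack([st * np.cos(ph), st * np.sin(ph), ct], axis=-1).reshape(-1, 3)
    w = np.broadcast_to(wg[:, None], ct.shape).reshape(-1) * (2 * np.pi / n_phi)
    Y = o3.spherical_harmonics(vecs, l_max)
    flat = np.concatenate(Y, axis=-1)
    gram = np.einsum("p,pa,pb->ab", w, flat, flat)
    assert np.abs(gram - np.eye(flat.shape[1])).max() < 1e-12


def test_rotation_equivariance_of_harmonics(rng):
    v = _unit(rng, 10)
    for _ in range(100):
        Q = o3.random_o3(rng)
        Y = o3.spherical_harmonics(v, 3)
        YQ = o3.spherical_harmonics(v @ Q.matrix.T, 3)
        for l in range(4):
            D = o3.wigner_D(Q, l)
            assert np.abs(YQ[l] - Y[l] @ D.T).max() < 1e-10


def test_input_validation():
    with pytest.raises(ValueError):
        o3.spherical_harmonics(np.array([0.0, 0.0, 0.0]), 1)
    with pytest.raises(ValueError):
        o3.spherical_harmonics(np.array([1.0, 1.0, 0.0]), 1)


# ----------------------------------------------------------------------
# Wigner-D
# ----------------------------------------------------------------------

def test_wigner_identity_and_scalar(rng):
    ident = o3.RotationOperation(np.eye(3))
    for L in range(4):
        assert np.allclose(o3.wigner_D(ident, L), np.eye(2 * L + 1), atol=1e-12)
    Q = o3.random_rotation(rng)
    assert o3.wigner_D(Q, 0) == pytest.approx(1.0)


def test_wigner_is_a_representation(rng):
    for _ in range(50):
        Q1, Q2 = o3.random_rotation(rng), o3.random_rotation(rng)
        Q12 = o3.RotationOperation(Q1.matrix @ Q2.matrix)
        for L in (1, 2, 3):
            err = np.abs(o3.wigner_D(Q12, L)
                         - o3.wigner_D(Q1, L) @ o3.wigner_D(Q2, L)).max()
            assert err < 1e-10


def test_wigner_L1_is_rotation_matrix_permuted(rng):
    # m = (-1, 0, +1) components of Y_1 are proportional to (y, z, x)
    P = np.zeros((3, 3))
    P[0, 1] = P[1, 2] = P[2, 0] = 1.0
    for _ in range(5):
        Q = o3.random_rotation(rng)
        assert np.abs(o3.wigner_D(Q, 1) - P @ Q.matrix @ P.T).max() < 1e-12


def test_improper_operations_carry_parity(rng):
    mirror = o3.RotationOperation(np.diag([1.0, 1.0, -1.0]), improper=True)
    for L in range(3):
        D_natural = o3.wigner_D(mirror, L)               # parity (-1)^L
        D_even = o3.wigner_D(mirror, L, parity=1)
        assert np.abs(D_natural - (-1) ** L * D_even).max() < 1e-12


def test_rotation_operation_validation():
    with pytest.raises(ValueError):
        o3.RotationOperation(np.eye(3) * 1.001)
    with pytest.raises(ValueError):
        o3.RotationOperation(np.eye(3), improper=True)


# ----------------------------------------------------------------------
# Clebsch-Gordan
# ----------------------------------------------------------------------

def test_cg_trivial_cases():
    assert o3.clebsch_gordan(0, 0, 0)[0, 0, 0] == pytest.approx(1.0)
    assert np.all(o3.clebsch_gordan(1, 2, 4) == 0.0)  # selection rule
    C = o3.clebsch_gordan(1, 1, 0)[:, :, 0]
    assert np.abs(C - np.eye(3) / sqrt(3)).max() < 1e-12


def _nullspace_cg(l1, l2, L, rng):
    """Independent oracle: the coupling tensor as the null space of the
    equivariance constraint stacked over random rotations."""
    d1, d2, dL = 2 * l1 + 1, 2 * l2 + 1, 2 * L + 1
    rows = []
    for _ in range(6):
        Q = o3.random_rotation(rng)
        D1, D2, DL = (o3.wigner_D(Q, l) for l in (l1, l2, L))
        op = np.einsum("ab,cd->acbd", D1, D2).reshape(d1 * d2, d1 * d2)
        # (D1 x D2) C - C DL = 0 as a linear map on vec(C)
        M = np.kron(op, np.eye(dL)) - np.kron(np.eye(d1 * d2), DL.T)
        rows.append(M)
    A = np.vstack(rows)
    _, s, vt = np.linalg.svd(A)
    null = vt[s.size - 1:]
    assert s[-2] > 1e-6  # the copy of L in l1 x l2 is unique
    return null[0].reshape(d1, d2, dL)


@pytest.mark.parametrize("l1,l2,L", [(1, 1, 0), (1, 1, 1), (1, 1, 2), (2, 1, 2), (2, 2, 0)])
def test_cg_matches_nullspace_oracle(l1, l2, L, rng):
    C = o3.clebsch_gordan(l1, l2, L)
    N = _nullspace_cg(l1, l2, L, rng)
    N /= np.linalg.norm(N)
    sign = np.sign(np.sum(C * N))
    assert np.abs(C - sign * N).max() < 1e-9


def test_cg_equivariance_identity(rng):
    for (l1, l2, L) in [(1, 1, 1), (2, 1, 2), (2, 2, 2), (1, 2, 3)]:
        C = o3.clebsch_gordan(l1, l2, L)
        for _ in range(20):
            Q = o3.random_o3(rng)
            D1, D2 = o3.wigner_D(Q, l1), o3.wigner_D(Q, l2)
            DL = o3.wigner_D(Q, L, parity=(-1) ** (l1 + l2))
            lhs = np.einsum("ab,cd,bdM->acM", D1, D2, C)
            rhs = np.einsum("acN,NM->acM", C, DL)
            assert np.abs(lhs - rhs).max() < 1e-10


# ----------------------------------------------------------------------
# generalized coupling
# ----------------------------------------------------------------------

def _brute_path_count(degrees, L):
    """Independent enumeration of intermediate-degree sequences."""
    states = {degrees[0]: 1}
    for l in degrees[1:]:
        nxt = {}
        for k, c in states.items():
            for k2 in range(abs(k - l), k + l + 1):
                nxt[k2] = nxt.get(k2, 0) + c
        states = nxt
    return states.get(L, 0)


@pytest.mark.parametrize("degrees,L", [
    ((1,), 1), ((1, 1), 2), ((1, 1, 1), 0), ((1, 1, 1), 1),
    ((2, 1, 1), 0), ((2, 2, 2), 0), ((1, 2, 2, 1), 0), ((2, 1, 2), 3),
])
def test_path_count_matches_brute_force(degrees, L):
    assert o3.coupling_path_count(degrees, L) == _brute_path_count(degrees, L)


def test_generalized_coupling_degenerate_cases():
    one = o3.generalized_coupling((2,), 2)
    assert one.n_paths == 1 and np.allclose(one.tensors[0], np.eye(5))
    pair = o3.generalized_coupling((1, 2), 2)
    assert pair.n_paths == 1
    assert np.abs(pair.tensors[0] - o3.clebsch_gordan(1, 2, 2)).max() < 1e-12
    assert o3.generalized_coupling((1, 1, 1), 0).n_paths == 1
    assert o3.generalized_coupling((1, 1, 1), 0, parity=1).n_paths == 0


def test_generalized_coupling_equivariance_and_independence(rng):
    coup = o3.generalized_coupling((1, 2, 1), 1)
    assert coup.n_paths > 1
    flat = np.stack([T.ravel() for T in coup.tensors])
    gram = flat @ flat.T
    assert np.abs(gram - np.eye(coup.n_paths)).max() < 1e-10  # orthonormal paths
    for T in coup.tensors:
        for _ in range(10):
            Q = o3.random_o3(rng)
            Ds = [o3.wigner_D(Q, l) for l in coup.degrees]
            DL = o3.wigner_D(Q, 1, parity=(-1) ** sum(coup.degrees))
            lhs = np.einsum("ab,cd,ef,bdfM->aceM", *Ds, T)
            rhs = np.einsum("aceN,NM->aceM", T, DL)
            assert np.abs(lhs - rhs).max() < 1e-10


def test_disk_cache_roundtrip(tmp_path):
    o3.set_cache_dir(tmp_path)
    try:
        o3._gc_memory_cache.clear()
        first = o3.generalized_coupling((1, 1, 2), 0)
        o3._gc_memory_cache.clear()
        second = o3.generalized_coupling((1, 1, 2), 0)
        assert first.n_paths == second.n_paths
        for a, b in zip(first.tensors, second.tensors):
            assert np.array_equal(a, b)
        assert any(p.name.startswith("gc_") for p in (tmp_path / o3.CACHE_FORMAT_VERSION).iterdir())
    finally:
        o3.set_cache_dir(None)


def test_irrep_spec_invariants():
    spec = o3.IrrepSpec(((2, 1, -1), (3, 0, 1)))
    assert spec.total_dim == 3 * 1 + 2 * 3
    assert spec.blocks[0][1] == 0  # canonical ordering by degree
    with pytest.raises(ValueError):
        o3.IrrepSpec(((1, -1, 1),))
    with pytest.raises(ValueError):
        o3.IrrepSpec(((1, 0, 2),))
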