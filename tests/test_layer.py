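"""The phi -> A -> product -> B ladder and message formation."""

import numpy as np
import pytest

from equiace import autodiff as ad
from equiace import layer as lay
from equiace import models as md
from equiace import o3
from equiace import radial as rd
from equiace.structures import build_neighbour_list, one_hot_attributes


def _layer_inputs(config, model, l_max=2):
    nl = build_neighbour_list(config, model.config.r_cut)
    pos = ad.Tensor(config.positions)
    d = ad.take(pos, nl.senders) - ad.take(pos, nl.receivers)
    r = ad.sqrt(ad.tsum(d * d, axis=1))
    inv = 1.0 / r
    Y = o3.spherical_harmonics_ad(d[:, 0] * inv, d[:, 1] * inv, d[:, 2] * inv, l_max)
    z_idx = model.element_index(config.atomic_numbers)
    return nl, r, Y, z_idx


def _small_model(elements=(1, 6, 8), **kw):
    kw.setdefault("n_channels", 3)
    kw.setdefault("n_basis", 4)
    kw.setdefault("r_cut", 4.0)
    return md.assemble_model(md.preset_config("botnet", elements, **kw))


def test_initial_embedding_cases(rng):
    oh = one_hot_attributes([1, 6, 6], [1, 6]).one_hot
    ident = lay.initial_embedding(oh, ad.Tensor(np.eye(2)))
    assert np.array_equal(ident[(0, 1)].value[:, :, 0], oh)
    assert np.array_equal(lay.initial_embedding(oh, None)[(0, 1)].value[:, :, 0], oh)
    zeros = lay.initial_embedding(oh, ad.Tensor(np.zeros((2, 5))))
    assert np.all(zeros[(0, 1)].value == 0)
    w = ad.Tensor(rng.normal(size=(2, 4)))
    h = lay.initial_embedding(oh, w)[(0, 1)].value
    assert np.array_equal(h[1], h[2])  # same element, same embedding
    with pytest.raises(ValueError):
        lay.initial_embedding(oh, ad.Tensor(np.zeros((3, 4))))


def test_pooling_contracts(cluster_factory):
    model = _small_model()
    c = cluster_factory(n_atoms=5)
    # add an isolated atom far away: its A basis must be exactly zero
    pos = np.vstack([c.positions, [50.0, 0, 0]])
    z = np.append(c.atomic_numbers, 1)
    from equiace.structures import AtomicConfiguration
    c2 = AtomicConfiguration(pos, z)
    nl, r, Y, z_idx = _layer_inputs(c2, model)
    h = lay.initial_embedding(one_hot_attributes(z, model.element_table).one_hot,
                              model.params["embedding"])
    paths = model.layer_paths[0]
    rcfg = rd.RadialConfig(mode="element-dependent", n_paths=len(paths),
                           r_cut=4.0, n_basis=4)
    R = rd.element_dependent_radial(r, z_idx[nl.senders],
                                    {"W": model.params["rad0_W"]}, rcfg)
    phi = lay.one_particle_basis(paths, R, Y, h, nl.senders)
    lam = 2.0
    A = lay.pool_atomic_basis(phi, nl.receivers, len(c2), lam)
    for a in A:
        assert np.all(a.value[-1] == 0.0)  # atom with no neighbours
    # single-neighbour atom: A = phi / lambda
    dimer = AtomicConfiguration([[0, 0, 0], [1.2, 0, 0]], [1, 6])
    nl, r, Y, z_idx = _layer_inputs(dimer, model)
    h = lay.initial_embedding(one_hot_attributes(dimer.atomic_numbers,
                                                 model.element_table).one_hot,
                              model.params["embedding"])
    R = rd.element_dependent_radial(r, z_idx[nl.senders],
                                    {"W": model.params["rad0_W"]}, rcfg)
    phi = lay.one_particle_basis(paths, R, Y, h, nl.senders)
    A = lay.pool_atomic_basis(phi, nl.receivers, 2, lam)
    for p, a in zip(phi, A):
        assert np.allclose(a.value[0], p.value[0] / lam)
    with pytest.raises(ValueError):
        lay.pool_atomic_basis(phi, nl.receivers, 2, 0.0)


def test_product_basis_reductions(rng):
    # nu = 1 slice equals the atomic basis; nu = 2 diagonal is the square
    A = [ad.Tensor(rng.normal(size=(4, 2, 1, 1)))]
    prod1 = lay.product_basis(A, [(0,)])[0]
    assert np.array_equal(prod1.value, A[0].value)
    prod2 = lay.product_basis(A, [(0, 0)])[0]
    assert np.allclose(prod2.value[..., 0, 0, 0, 0],
                       A[0].value[..., 0, 0] ** 2)


def test_symmetrize_identity_and_rotation(rng, cluster_factory):
    model = _small_model()
    c = cluster_factory(n_atoms=5)

    def invariants(config):
        nl, r, Y, z_idx = _layer_inputs(config, model)
        h = lay.initial_embedding(one_hot_attributes(config.atomic_numbers,
                                                     model.element_table).one_hot,
                                  model.params["embedding"])
        paths = model.layer_paths[0]
        rcfg = rd.RadialConfig(mode="element-dependent", n_paths=len(paths),
                               r_cut=4.0, n_basis=4)
        R = rd.element_dependent_radial(r, z_idx[nl.senders],
                                        {"W": model.params["rad0_W"]}, rcfg)
        phi = lay.one_particle_basis(paths, R, Y, h, nl.senders)
        A = lay.pool_atomic_basis(phi, nl.receivers, len(config), 1.0)
        # nu = 2 product of the two l1 = 1 factors, coupled to L = 0
        idx = [k for k, p in enumerate(model.layer_paths[0]) if p.l1 == 1][0]
        prod = lay.product_basis([A[idx]], [(0, 0)])[0]
        coup = o3.generalized_coupling((1, 0, 1, 0), 0)
        return lay.symmetrize(prod, coup).value

    base = invariants(c)
    assert base.shape[2] == 1  # single eta path for (1,0,1,0) -> 0
    Q = o3.random_o3(np.random.default_rng(3))
    from equiace.structures import AtomicConfiguration
    rot = AtomicConfiguration(c.positions @ Q.matrix.T, c.atomic_numbers)
    assert np.abs(invariants(rot) - base).max() < 1e-10

    # nu = 1, L = l coupling is the identity: B = A
    A1 = ad.Tensor(rng.normal(size=(3, 2, 3)))
    coup1 = o3.generalized_coupling((1,), 1)
    B1 = lay.symmetrize(A1, coup1)
    assert np.array_equal(B1.value[:, :, 0, :], A1.value)


def test_symmetrize_shape_validation(rng):
    prod = ad.Tensor(rng.normal(size=(2, 2, 3, 3)))
    with pytest.raises(ValueError):
        lay.symmetrize(prod, o3.generalized_coupling((2, 2), 0))


def test_form_message_weighting(rng):
    B = {(0, 1): ad.Tensor(rng.normal(size=(4, 2, 3, 1)))}
    zeros = {(0, 1): ad.Tensor(np.zeros((2, 2, 3)))}
    z_idx = np.array([0, 1, 0, 1])
    out = lay.form_message(B, zeros, z_idx)
    assert np.all(out[(0, 1)].value == 0)
    w = np.zeros((2, 2, 3))
    w[:, :, 1] = 2.0  # single eta path selected
    out = lay.form_message(B, {(0, 1): ad.Tensor(w)}, z_idx)
    assert np.allclose(out[(0, 1)].value, 2.0 * B[(0, 1)].value[:, :, 1, :])


def test_linear_update_block_structure(rng):
    m = {(0, 1): ad.Tensor(rng.normal(size=(3, 2, 1))),
         (1, -1): ad.Tensor(rng.normal(size=(3, 2, 3)))}
    ident = {k: ad.Tensor(np.eye(2)) for k in m}
    out = lay.linear_update(m, ident)
    for k in m:
        assert np.array_equal(out[k].value, m[k].value)
    # zeroing the L=1 block changes only L=1 outputs
    W = {(0, 1): ad.Tensor(np.eye(2)), (1, -1): ad.Tensor(np.zeros((2, 2)))}
    out = lay.linear_update(m, W)
    assert np.array_equal(out[(0, 1)].value, m[(0, 1)].value)
    assert np.all(out[(1, -1)].value == 0)
    with pytest.raises(ValueError):
        lay.linear_update(m, {k: ad.Tensor(np.eye(3)) for k in m})


def test_self_connection_cases(rng):
    h = {(0, 1): ad.Tensor(rng.normal(size=(3, 2, 1)))}
    m = {(0, 1): ad.Tensor(rng.normal(size=(3, 2, 1)))}
    z_idx = np.array([0, 0, 1])
    S0 = {(0, 1): ad.Tensor(np.zeros((2, 2, 2)))}
    assert np.array_equal(lay.self_connection(m, h, S0, z_idx)[(0, 1)].value,
                          m[(0, 1)].value)
    Sid = {(0, 1): ad.Tensor(np.tile(np.eye(2), (2, 1, 1)))}
    zero_m = {(0, 1): ad.Tensor(np.zeros((3, 2, 1)))}
    carried = lay.self_connection(zero_m, h, Sid, z_idx)
    assert np.array_equal(carried[(0, 1)].value, h[(0, 1)].value)


def test_delta_mode_reproduces_discrete_one_particle_basis(rng, cluster_factory):
    """The delta / element-selector basis equals the explicit discrete form."""
    c = cluster_factory(n_atoms=5, elements=(1, 6))
    nl = build_neighbour_list(c, 4.0)
    table = (1, 6)
    z_idx = np.array([table.index(z) for z in c.atomic_numbers])
    rcfg = rd.RadialConfig(r_cut=4.0, n_basis=3, mode="fixed-orthogonal")
    r = ad.Tensor(nl.distances)
    env = rd.enveloped_bessel(r, rcfg)
    Y = [ad.Tensor(y) for y in
         o3.spherical_harmonics(nl.displacements / nl.distances[:, None], 2)]
    A = lay.delta_atomic_basis(env, Y, nl.receivers, z_idx[nl.senders],
                               len(c), 2, 2, 1.0)
    for i in range(len(c)):
        for zi, n, l in [(0, 1, 1), (1, 2, 2)]:
            expected = np.zeros(2 * l + 1)
            for e in range(nl.n_edges):
                if nl.receivers[e] == i and z_idx[nl.senders[e]] == zi:
                    expected += env.value[e, n] * Y[l].value[e]
            assert np.abs(A[l].value[i, zi, n] - expected).max() < 1e-13
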