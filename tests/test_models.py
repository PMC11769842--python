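"""Assembled potentials: presets, symmetries, forces, persistence."""

import numpy as np
import pytest

from equiace import autodiff as ad
from equiace import models as md
from equiace import o3
from equiace.structures import AtomicConfiguration


def _model(preset="botnet", elements=(1, 6, 8), **kw):
    kw.setdefault("n_channels", 3)
    kw.setdefault("n_basis", 4)
    kw.setdefault("r_cut", 4.0)
    return md.assemble_model(md.preset_config(preset, elements, **kw))


def test_preset_invariants():
    ace = md.preset_config("linear_ace", (1, 6))
    assert ace.T == 1 and ace.embedding == "delta" and ace.coupling == "full" \
        and ace.L_max == 0
    bot = md.preset_config("botnet", (1,))
    assert bot.nu == 1 and bot.nonlinearity == "none" \
        and bot.readout == "nonlinear-final"
    neq = md.preset_config("nequip_like", (1,))
    assert neq.nu == 1 and neq.l_max == neq.L_max >= 1 and neq.nonlinearity == "silu"
    sch = md.preset_config("schnet_like", (1,))
    assert sch.l_max == 0 and sch.L_max == 0 and sch.nu == 1


def test_inconsistent_design_point_rejected():
    with pytest.raises(ValueError, match="delta embedding"):
        md.ModelConfig(elements=(1,), embedding="delta", coupling="uncoupled")
    with pytest.raises(ValueError):
        md.ModelConfig(elements=(1,), nonlinearity="relu")


@pytest.mark.parametrize("preset", ["botnet", "nequip_like", "schnet_like",
                                    "linear_ace"])
def test_energy_invariance_and_force_equivariance(preset, rng, cluster_factory):
    kw = {} if preset == "linear_ace" else {"n_channels": 3}
    model = _model(preset, (1, 6, 8), n_basis=4, **kw)
    c = cluster_factory(n_atoms=5)
    res = md.total_energy(model, c)
    for _ in range(4):
        Q = o3.random_o3(rng)
        moved = AtomicConfiguration(c.positions @ Q.matrix.T + rng.normal(size=3),
                                    c.atomic_numbers)
        res2 = md.total_energy(model, moved)
        assert abs(res2.energy - res.energy) <= 1e-10
        assert np.abs(res2.forces - res.forces @ Q.matrix.T).max() <= 1e-10


def test_energy_decomposition_consistency(cluster_factory):
    model = _model("botnet")
    c = cluster_factory(n_atoms=6)
    res = md.total_energy(model, c)
    assert sum(res.contributions.values()) == pytest.approx(res.energy, abs=1e-10)
    assert res.site_energies.sum() == pytest.approx(res.energy, abs=1e-10)
    assert set(res.contributions) == {"E0", "layer_1", "layer_2", "E_rest"}
    # site energies are binding energies: interaction terms vanish exactly
    # for an isolated atom
    lone = md.total_energy(model, AtomicConfiguration([[0, 0, 0]], [1]),
                           need_forces=False)
    assert all(v == 0.0 for k, v in lone.contributions.items() if k != "E0")


def test_isolated_atom_is_a_position_independent_one_body_constant():
    model = _model("botnet", (6,), n_channels=2)
    model.params["E0"] = ad.Tensor(np.array([-7.5]))
    res = md.total_energy(model, AtomicConfiguration([[0, 0, 0]], [6]))
    assert np.all(res.forces == 0.0)
    # binding-energy convention: a free atom's energy is exactly its E0
    assert res.energy == pytest.approx(-7.5, abs=1e-12)
    shifted = md.total_energy(model, AtomicConfiguration([[3.0, -1.0, 2.0]], [6]),
                              need_forces=False)
    assert shifted.energy == res.energy


def test_size_extensivity(cluster_factory):
    model = _model("botnet")
    c = cluster_factory(n_atoms=5)
    double = AtomicConfiguration(
        np.vstack([c.positions, c.positions + 100.0]),
        np.concatenate([c.atomic_numbers] * 2))
    e1 = md.total_energy(model, c, need_forces=False).energy
    e2 = md.total_energy(model, double, need_forces=False).energy
    assert e2 == pytest.approx(2 * e1, abs=1e-10)


@pytest.mark.parametrize("preset", ["botnet", "nequip_like", "linear_ace"])
def test_forces_match_finite_differences(preset, rng, cluster_factory):
    model = _model(preset, (1, 6))
    c = cluster_factory(n_atoms=4, elements=(1, 6))
    forces = md.compute_forces(model, c)
    assert np.abs(forces.sum(axis=0)).max() < 1e-10  # translation invariance
    eps = 1e-5
    for _ in range(4):
        i, a = rng.integers(len(c)), rng.integers(3)
        pp, pm = c.positions.copy(), c.positions.copy()
        pp[i, a] += eps
        pm[i, a] -= eps
        fd = -(md.total_energy(model, AtomicConfiguration(pp, c.atomic_numbers),
                               need_forces=False).energy
               - md.total_energy(model, AtomicConfiguration(pm, c.atomic_numbers),
                                 need_forces=False).energy) / (2 * eps)
        assert abs(fd - forces[i, a]) < 1e-6


def test_overlapping_atoms_rejected():
    model = _model("botnet", (1,), n_channels=2)
    pair = AtomicConfiguration([[0, 0, 0], [1e-8, 0, 0]], [1, 1])
    with pytest.raises(ValueError, match="overlapping"):
        md.total_energy(model, pair)


def test_unknown_element_rejected(cluster_factory):
    model = _model("botnet", (1, 6), n_channels=2)
    c = AtomicConfiguration([[0, 0, 0], [1.5, 0, 0]], [1, 8])
    with pytest.raises(ValueError):
        md.total_energy(model, c)


def test_gated_nonlinearity_contracts(rng):
    h = {(0, 1): ad.Tensor(rng.normal(size=(3, 2, 1))),
         (1, -1): ad.Tensor(rng.normal(size=(3, 2, 3)))}
    assert md.gated_nonlinearity(h, "none") is h
    gates = {(1, -1): ad.Tensor(rng.normal(size=(2, 2)))}
    out = md.gated_nonlinearity(h, "silu", gates)
    scal = h[(0, 1)].value[:, :, 0]
    assert np.allclose(out[(0, 1)].value[:, :, 0], scal / (1 + np.exp(-scal)) * 1.0,
                       atol=1e-12)
    sq = md.gated_nonlinearity(h, "square", gates)
    assert np.allclose(sq[(0, 1)].value[:, :, 0], scal ** 2)
    with pytest.raises(ValueError):
        md.gated_nonlinearity(h, "silu")  # missing gate weights
    with pytest.raises(ValueError):
        md.gated_nonlinearity(h, "bogus", gates)


@pytest.mark.parametrize("kind", ["silu", "tanh", "square"])
def test_gated_nonlinearity_preserves_equivariance(kind, rng, cluster_factory):
    model = _model("nequip_like", (1, 6), nonlinearity=kind, n_channels=3)
    c = cluster_factory(n_atoms=5, elements=(1, 6))
    res = md.total_energy(model, c)
    Q = o3.random_o3(rng)
    res2 = md.total_energy(model, AtomicConfiguration(c.positions @ Q.matrix.T,
                                                      c.atomic_numbers))
    assert abs(res2.energy - res.energy) <= 1e-10
    assert np.abs(res2.forces - res.forces @ Q.matrix.T).max() <= 1e-10


def test_zero_readout_weights_zero_sites(cluster_factory):
    model = _model("botnet", (6,), readout="linear", n_channels=2)
    for name in list(model.params):
        if name.startswith("ro") or name == "E0":
            model.params[name] = ad.Tensor(np.zeros(model.params[name].shape))
    c = cluster_factory(n_atoms=4, elements=(6,))
    res = md.total_energy(model, c, need_forces=False)
    assert np.abs(res.site_energies).max() == 0.0


def test_save_load_round_trip(tmp_path, cluster_factory):
    model = _model("botnet", (1, 6))
    model.lam = 3.5
    c = cluster_factory(n_atoms=5, elements=(1, 6))
    e0 = md.total_energy(model, c, need_forces=False).energy
    md.save_model(model, tmp_path / "m")
    back = md.load_model(tmp_path / "m")
    assert back.lam == 3.5
    assert md.total_energy(back, c, need_forces=False).energy == pytest.approx(e0, abs=0)
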