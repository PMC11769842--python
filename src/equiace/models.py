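"""Full interatomic potentials assembled from equivariant ACE layers.

A model is ``embedding -> T x (one-particle basis -> pool -> product ->
symmetrize -> message -> linear update [+ self-connection, + gated
nonlinearity]) -> readouts``; site energies from per-layer linear readouts
(plus an optional nonlinear final readout) are summed with per-element
reference energies into the total.  Forces are exact negative gradients of
the energy, obtained by reverse-mode differentiation of the same graph.

Presets mark out the familiar corners of the design space:

* ``linear_ace`` — one layer, discrete-element (delta) embedding, full
  index coupling, invariant readout: classic body-ordered linear ACE.
* ``botnet`` — nu = 1 per layer, element-dependent linear radial, *no*
  nonlinear activations in the updates, per-layer linear readouts and a
  nonlinear final readout carrying the body-order remainder.
* ``nequip_like`` — nu = 1, element-agnostic MLP radial, gated nonlinear
  updates, l_max = L_max >= 1.
* ``schnet_like`` — scalar features only (l_max = L_max = 0).
"""

from __future__ import annotations


import os
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from . import autodiff as ad
from . import layer as lay
from . import o3
from . import radial as rd
from .structures import AtomicConfiguration, build_neighbour_list, one_hot_attributes

PRESETS = ("linear_ace", "botnet", "nequip_like", "schnet_like")
NONLINEARITIES = ("none", "silu", "tanh", "square")


@dataclass
class ModelConfig:
    """Design-space coordinates of one model."""

    elements: tuple = (1,)
    preset: str | None = None
    T: int = 2                       # number of message-passing layers
    nu: int = 1                      # correlation order per layer
    l_max: int = 2                   # spherical-harmonic degree on edges
    L_max: int = 2                   # max degree passed between layers
    n_channels: int = 8
    embedding: str = "learned"       # learned | delta
    coupling: str = "uncoupled"      # uncoupled | full
    radial_mode: str = "element-dependent"
    n_basis: int = 8
    mlp_widths: tuple = (64, 64, 64)
    cutoff_power: int = 6
    r_cut: float = 5.0               # Angstrom
    nonlinearity: str = "none"       # update nonlinearity
    readout: str = "linear"          # linear | nonlinear-final
    readout_mlp_widths: tuple = (16, 16)
    lambda_mode: str = "avg"         # avg | sqrt_avg
    lam: float = 1.0
    final_invariant_only: bool = True  # last layer emits only L=0 (readouts use scalars)
    max_poly_degree: int = 12        # full-coupling tuple bound on sum(n + l)
    seed: int = 0

    def __post_init__(self):
        self.elements = tuple(sorted(int(z) for z in self.elements))
        if self.nonlinearity not in NONLINEARITIES:
            raise ValueError(f"nonlinearity must be one of {NONLINEARITIES}")
        if self.embedding not in ("learned", "delta"):
            raise ValueError("embedding must be 'learned' or 'delta'")
        if self.coupling not in ("uncoupled", "full"):
            raise ValueError("coupling must be 'uncoupled' or 'full'")
        if self.embedding == "delta" and self.coupling != "full":
            raise ValueError("delta embedding requires full coupling (inconsistent design point)")
        if self.coupling == "full" and self.T != 1:
            raise ValueError("full coupling is a single-layer (T = 1) design point")
        if self.T < 1 or self.nu < 1 or self.l_max < 0 or self.L_max < 0:
            raise ValueError("T, nu >= 1 and l_max, L_max >= 0 required")
        if self.preset is not None and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")


def preset_config(name: str, elements, **overrides) -> ModelConfig:
    """A ModelConfig at one of the named design points."""
    base = dict(elements=tuple(elements), preset=name)
    if name == "linear_ace":
        base.update(T=1, nu=2, l_max=2, L_max=0, embedding="delta", coupling="full",
                    radial_mode="fixed-orthogonal", nonlinearity="none",
                    readout="linear", n_basis=6, max_poly_degree=8)
    elif name == "botnet":
        base.update(T=2, nu=1, l_max=2, L_max=2, embedding="learned",
                    coupling="uncoupled", radial_mode="element-dependent",
                    nonlinearity="none", readout="nonlinear-final")
    elif name == "nequip_like":
        base.update(T=2, nu=1, l_max=2, L_max=2, embedding="learned",
                    coupling="uncoupled", radial_mode="agnostic-mlp",
                    nonlinearity="silu", readout="linear")
    elif name == "schnet_like":
        base.update(T=2, nu=1, l_max=0, L_max=0, embedding="learned",
                    coupling="uncoupled", radial_mode="agnostic-mlp",
                    nonlinearity="silu", readout="linear")
    else:
        raise ValueError(f"unknown preset {name!r}")
    base.update(overrides)
    cfg = ModelConfig(**base)
    _check_preset_invariants(cfg)
    return cfg


def _check_preset_invariants(cfg: ModelConfig) -> None:
    if cfg.preset == "linear_ace":
        assert cfg.T == 1 and cfg.embedding == "delta" and cfg.coupling == "full" \
            and cfg.L_max == 0
    elif cfg.preset == "botnet":
        assert cfg.nu == 1 and cfg.nonlinearity == "none"
    elif cfg.preset == "nequip_like":
        assert cfg.nu == 1 and cfg.nonlinearity != "none" and cfg.l_max == cfg.L_max >= 1
    elif cfg.preset == "schnet_like":
        assert cfg.l_max == 0 and cfg.L_max == 0 and cfg.nu == 1


@dataclass
class EnergyResult:
    """Body-order-auditable energy decomposition plus forces."""

    energy: float                    # eV
    site_energies: np.ndarray        # (n,) eV
    contributions: dict              # name -> eV, summing to energy
    forces: np.ndarray | None = None  # (n, 3) eV/A


# ----------------------------------------------------------------------
# the model object
# ----------------------------------------------------------------------

class Model:
    """A parameterized potential: config + parameter Tensors + lambda."""

    def __init__(self, config: ModelConfig, params: dict, lam: float = None):
        self.config = config
        self.params = params
        self.lam = float(lam if lam is not None else config.lam)
        self.element_table = config.elements
        if config.coupling == "full":
            self.tuples = lay.enumerate_delta_tuples(
                len(config.elements), config.n_basis, config.l_max,
                config.nu, config.max_poly_degree)
        else:
            self.layer_keys, self.layer_paths = _plan_layers(config)

    # -- parameter utilities ------------------------------------------
    def parameter_names(self):
        return sorted(self.params)

    def set_flat(self, names, values):
        for name, v in zip(names, values):
            self.params[name] = ad.Tensor(np.asarray(v))

    def element_index(self, atomic_numbers) -> np.ndarray:
        table = {z: i for i, z in enumerate(self.element_table)}
        try:
            return np.array([table[int(z)] for z in atomic_numbers], dtype=np.intp)
        except KeyError as exc:
            raise ValueError(f"element {exc} not in model table {self.element_table}") from None


def _plan_layers(cfg: ModelConfig):
    """Irrep keys entering each layer and the conv paths used by it."""
    keys = [((0, 1),)]
    paths = []
    for t in range(cfg.T):
        L_max_t = 0 if (t == cfg.T - 1 and cfg.final_invariant_only) else cfg.L_max
        p = lay.enumerate_paths(keys[-1], cfg.l_max, L_max_t)
        paths.append(p)
        keys.append(tuple(sorted({(q.L, q.parity) for q in p})))
    return keys, paths


def assemble_model(config: ModelConfig) -> Model:
    """Seeded deterministic initialization of every parameter block."""
    rng = np.random.default_rng(config.seed)
    nz = len(config.elements)
    K = config.n_channels
    params: dict = {"E0": ad.Tensor(np.zeros(nz))}
    if config.coupling == "full":
        model = Model(config, params)
        nfeat = len(model.tuples)
        params["readout_w"] = ad.Tensor(rng.normal(size=(nz, nfeat)) / np.sqrt(max(nfeat, 1)))
        return model

    params["embedding"] = ad.Tensor(rng.normal(size=(nz, K)))
    model = Model(config, params)
    rcfg_base = dict(r_cut=config.r_cut, n_basis=config.n_basis, p=config.cutoff_power,
                     mlp_widths=config.mlp_widths)
    for t in range(config.T):
        pths = model.layer_paths[t]
        rcfg = rd.RadialConfig(mode=config.radial_mode, n_paths=len(pths), **rcfg_base)
        if config.radial_mode == "element-dependent":
            params.update({f"rad{t}_{k}": v for k, v in
                           rd.init_element_dependent_params(rcfg, K, nz, rng).items()})
        elif config.radial_mode == "agnostic-mlp":
            params.update({f"rad{t}_{k}": v for k, v in
                           rd.init_agnostic_params(rcfg, K, rng).items()})
        else:
            raise ValueError("uncoupled models need a learnable radial mode")
        per_key_counts: dict = {}
        for q in pths:
            per_key_counts[(q.L, q.parity)] = per_key_counts.get((q.L, q.parity), 0) + 1
        for key, n_paths in per_key_counts.items():
            L, p = key
            params[f"msg{t}_{L}_{p}"] = ad.Tensor(
                rng.normal(size=(nz, K, n_paths)) / np.sqrt(n_paths))
            params[f"upd{t}_{L}_{p}"] = ad.Tensor(rng.normal(size=(K, K)) / np.sqrt(K))
        for key in model.layer_keys[t]:
            if key in per_key_counts:
                L, p = key
                params[f"self{t}_{L}_{p}"] = ad.Tensor(
                    rng.normal(size=(nz, K, K)) / np.sqrt(K))
        if config.nonlinearity != "none":
            for key in per_key_counts:
                if key != (0, 1):
                    L, p = key
                    params[f"gate{t}_{L}_{p}"] = ad.Tensor(rng.normal(size=(K, K)) / np.sqrt(K))
        params[f"ro{t}"] = ad.Tensor(rng.normal(size=(nz, K)) / np.sqrt(K))
    if config.readout == "nonlinear-final":
        widths = [K, *config.readout_mlp_widths, 1]
        for i, (nin, nout) in enumerate(zip(widths[:-1], widths[1:])):
            params[f"fro_W{i}"] = ad.Tensor(rng.normal(size=(nin, nout)) / np.sqrt(nin))
            if i < len(widths) - 2:
                params[f"fro_b{i}"] = ad.Tensor(np.zeros(nout))
    return model


# ----------------------------------------------------------------------
# nonlinearities and readouts
# ----------------------------------------------------------------------

def gated_nonlinearity(h: lay.Features, kind: str, gate_weights: dict = None) -> lay.Features:
    """Equivariance-preserving nonlinearity.

    Scalars (L=0, even) pass through the chosen pointwise function; every
    other block is multiplied by a scalar gate computed from the scalar
    channels.  ``square`` squares the invariants and uses a *linear* gate,
    keeping the Taylor expansion finite so body order doubles rather than
    becoming infinite.
    """
    if kind == "none":
        return h
    if kind not in NONLINEARITIES:
        raise ValueError(f"unknown nonlinearity kind {kind!r}")
    scal = h[(0, 1)][:, :, 0]
    out: lay.Features = {}
    for key, block in h.items():
        if key == (0, 1):
            if kind == "silu":
                new = ad.silu(scal)
            elif kind == "tanh":
                new = ad.tanh(scal)
            else:  # square
                new = scal * scal
            out[key] = ad.reshape(new, new.shape + (1,))
        else:
            if gate_weights is None or key not in gate_weights:
                raise ValueError("gated nonlinearity needs gate weights for equivariant blocks")
            pre = ad.einsum("nq,qk->nk", scal, gate_weights[key])
            gate = pre if kind == "square" else ad.sigmoid(pre)
            out[key] = block * ad.reshape(gate, gate.shape + (1,))
    return out


def readout_linear(h: lay.Features, weights: ad.Tensor, element_index) -> ad.Tensor:
    """Per-atom linear readout on the invariant channels only."""
    scal = h[(0, 1)][:, :, 0]
    w = ad.take(weights, np.asarray(element_index, dtype=np.intp))
    return ad.einsum("nk,nk->n", w, scal)


def readout_mlp(h: lay.Features, params: dict, n_hidden: int) -> ad.Tensor:
    """Nonlinear final readout (the body-order remainder E_rest)."""
    x = h[(0, 1)][:, :, 0]
    for i in range(n_hidden + 1):
        x = ad.einsum("nk,ko->no", x, params[f"fro_W{i}"])
        if i < n_hidden:
            x = ad.silu(x + params[f"fro_b{i}"])
    return x[:, 0]


# ----------------------------------------------------------------------
# forward evaluation
# ----------------------------------------------------------------------

class _Batch:
    """Concatenated frames with a shared position Tensor."""

    def __init__(self, configs, r_cut: float):
        self.configs = list(configs)
        offsets = np.concatenate([[0], np.cumsum([len(c) for c in self.configs])])
        self.n_atoms = int(offsets[-1])
        self.frame_index = np.concatenate(
            [np.full(len(c), f, dtype=np.intp) for f, c in enumerate(self.configs)])
        self.positions = ad.Tensor(np.concatenate([c.positions for c in self.configs]))
        recv, send, cellshift = [], [], []
        for f, c in enumerate(self.configs):
            nl = build_neighbour_list(c, r_cut)
            recv.append(nl.receivers + offsets[f])
            send.append(nl.senders + offsets[f])
            if c.cell is not None:
                cellshift.append(nl.shifts @ c.cell)
            else:
                cellshift.append(np.zeros((nl.n_edges, 3)))
        self.receivers = np.concatenate(recv)
        self.senders = np.concatenate(send)
        self.shift_vectors = np.concatenate(cellshift)
        self.atomic_numbers = np.concatenate([c.atomic_numbers for c in self.configs])

    def edge_geometry(self, l_max: int):
        d = ad.take(self.positions, self.senders) - ad.take(self.positions, self.receivers)
        d = d + ad.Tensor(self.shift_vectors)
        r = ad.sqrt(ad.tsum(d * d, axis=1))
        inv = 1.0 / r
        Y = o3.spherical_harmonics_ad(d[:, 0] * inv, d[:, 1] * inv, d[:, 2] * inv, l_max)
        return d, r, Y


def forward(model: Model, configs, need_forces: bool = True,
            collect: dict = None):
    """Evaluate a list of configurations in one batched graph.

    Returns (per-frame total energies Tensor, per-atom site energies Tensor,
    contributions dict of Tensors, forces Tensor or None, batch).  The
    returned Tensors stay connected to the parameters, so training can
    differentiate through the result (including through the forces).  A
    mutable ``collect`` dict, if given, receives the final feature blocks
    under "features" (for feature-level certification).
    """
    cfg = model.config
    if isinstance(configs, AtomicConfiguration):
        configs = [configs]
    batch = _Batch(configs, cfg.r_cut)
    z_idx = model.element_index(batch.atomic_numbers)
    one_hot = one_hot_attributes(batch.atomic_numbers, model.element_table).one_hot
    n_frames = len(batch.configs)
    contributions: dict = {}
    _, r, Y = batch.edge_geometry(cfg.l_max)
    if batch.senders.size and float(np.min(r.value)) < 1e-6:
        raise ValueError("overlapping atoms (r < 1e-6 A)")
    E0_site = ad.take(model.params["E0"], z_idx)
    site = E0_site
    contributions["E0"] = ad.scatter_add(E0_site, batch.frame_index, n_frames)

    if cfg.coupling == "full":
        env = rd.enveloped_bessel(r, rd.RadialConfig(
            r_cut=cfg.r_cut, n_basis=cfg.n_basis, p=cfg.cutoff_power,
            mode="fixed-orthogonal"))
        A = lay.delta_atomic_basis(env, Y, batch.receivers, z_idx[batch.senders],
                                   batch.n_atoms, len(cfg.elements), cfg.l_max,
                                   model.lam)
        B = lay.delta_symmetrized_basis(A, model.tuples)[:, :, 0]
        if collect is not None:
            collect["features"] = {"B": B}
            collect["batch"] = batch
        w = ad.take(model.params["readout_w"], z_idx)
        term = ad.einsum("nf,nf->n", w, B)
        site = site + term
        contributions["layer_1"] = ad.scatter_add(term, batch.frame_index, n_frames)
    else:
        emb = model.params["embedding"] if cfg.embedding == "learned" else None
        h = lay.initial_embedding(one_hot, emb)
        # isolated-atom baseline: the same layer stack with zero messages,
        # one virtual atom per element; subtracting its readouts makes site
        # energies binding energies relative to free atoms and removes the
        # energy-flat one-body directions from the parameter space
        nz = len(cfg.elements)
        iso_idx = np.arange(nz, dtype=np.intp)
        h_iso = lay.initial_embedding(np.eye(nz), emb)
        if collect is not None:
            collect["layers"] = []
        rcfg_base = dict(r_cut=cfg.r_cut, n_basis=cfg.n_basis, p=cfg.cutoff_power,
                         mlp_widths=cfg.mlp_widths)
        for t in range(cfg.T):
            pths = model.layer_paths[t]
            rcfg = rd.RadialConfig(mode=cfg.radial_mode, n_paths=len(pths), **rcfg_base)
            if cfg.radial_mode == "element-dependent":
                R = rd.element_dependent_radial(
                    r, z_idx[batch.senders], {"W": model.params[f"rad{t}_W"]}, rcfg)
            else:
                rparams = {k[len(f"rad{t}_"):]: v for k, v in model.params.items()
                           if k.startswith(f"rad{t}_")}
                R = rd.element_agnostic_radial(
                    r, rparams, rcfg, cfg.n_channels,
                    cfg.nonlinearity if cfg.nonlinearity in ("silu", "tanh") else "silu")
            B = lay.nequip_convolution(pths, R, Y, h, batch.receivers, batch.senders,
                                       batch.n_atoms, model.lam)
            msg_w = {key: model.params[f"msg{t}_{key[0]}_{key[1]}"] for key in B}
            m = lay.form_message(B, msg_w, z_idx)
            upd_w = {key: model.params[f"upd{t}_{key[0]}_{key[1]}"] for key in m}
            h_new = lay.linear_update(m, upd_w)
            S = {key: model.params[f"self{t}_{key[0]}_{key[1]}"]
                 for key in h if f"self{t}_{key[0]}_{key[1]}" in model.params}
            h = lay.self_connection(h_new, h, S, z_idx)
            zero_msg = {key: ad.Tensor(np.zeros((nz, cfg.n_channels, 2 * key[0] + 1)))
                        for key in m}
            h_iso = lay.self_connection(zero_msg, h_iso, S, iso_idx)
            if cfg.nonlinearity != "none":
                gates = {key: model.params[f"gate{t}_{key[0]}_{key[1]}"]
                         for key in h if key != (0, 1)}
                h = gated_nonlinearity(h, cfg.nonlinearity, gates)
                h_iso = gated_nonlinearity(h_iso, cfg.nonlinearity, gates)
            if collect is not None:
                collect["layers"].append(h)
            term = readout_linear(h, model.params[f"ro{t}"], z_idx) \
                - ad.take(readout_linear(h_iso, model.params[f"ro{t}"], iso_idx), z_idx)
            site = site + term
            contributions[f"layer_{t + 1}"] = ad.scatter_add(term, batch.frame_index, n_frames)
        if collect is not None:
            collect["features"] = h
            collect["batch"] = batch
        if cfg.readout == "nonlinear-final":
            rest = readout_mlp(h, model.params, len(cfg.readout_mlp_widths)) \
                - ad.take(readout_mlp(h_iso, model.params,
                                      len(cfg.readout_mlp_widths)), z_idx)
            site = site + rest
            contributions["E_rest"] = ad.scatter_add(rest, batch.frame_index, n_frames)

    totals = ad.scatter_add(site, batch.frame_index, n_frames)
    forces = None
    if need_forces:
        g = ad.grad(ad.tsum(totals), batch.positions)
        forces = ad.neg(g)
    return totals, site, contributions, forces, batch


def total_energy(model: Model, config: AtomicConfiguration,
                 need_forces: bool = True) -> EnergyResult:
    """Energy, per-atom site energies, body-order contributions, forces.

    ``contributions`` holds the per-element reference term E0 plus one
    *interaction* term per layer (and the nonlinear remainder if present):
    site energies are binding energies relative to free atoms, so every
    non-E0 term vanishes identically for an isolated atom.
    """
    totals, site, contribs, forces, _ = forward(model, [config], need_forces)
    return EnergyResult(
        energy=float(totals.value[0]),
        site_energies=site.value.copy(),
        contributions={k: float(v.value[0]) for k, v in contribs.items()},
        forces=None if forces is None else forces.value.copy())


def compute_forces(model: Model, config: AtomicConfiguration) -> np.ndarray:
    """Exact forces F = -dE/dr (reverse-mode, not finite differences)."""
    return total_energy(model, config, need_forces=True).forces


def site_energies(model: Model, config: AtomicConfiguration) -> np.ndarray:
    return total_energy(model, config, need_forces=False).site_energies


# ----------------------------------------------------------------------
# persistence (plain-text friendly: YAML config + NPZ parameters)
# ----------------------------------------------------------------------

def save_model(model: Model, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "config.yaml"), "w") as fh:
        yaml.safe_dump({**asdict(model.config), "lam": model.lam}, fh)
    np.savez(os.path.join(directory, "parameters.npz"),
             **{k: v.value for k, v in model.params.items()})


def load_model(directory: str) -> Model:
    with open(os.path.join(directory, "config.yaml")) as fh:
        raw = yaml.safe_load(fh)
    for key in ("elements", "mlp_widths", "readout_mlp_widths"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    cfg = ModelConfig(**raw)
    model = assemble_model(cfg)
    with np.load(os.path.join(directory, "parameters.npz")) as data:
        for k in data.files:
            model.params[k] = ad.Tensor(data[k])
    model.lam = float(raw.get("lam", cfg.lam))
    return model
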