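"""Executable certificates for the symmetry and body-order contracts.

Each check turns one defining property of an equivariant atom-centred
potential into a seeded, deterministic numerical test with a
machine-readable report: O(3) equivariance of features/energies/forces,
permutation invariance, explicit body order via the inclusion-exclusion
functional, the density-trick identity against an explicit cluster sum,
Monte-Carlo evaluation of the symmetrization integral, locality of the
receptive field, and smoothness across the cutoff.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np

from . import o3
from .structures import AtomicConfiguration


@dataclass
class VerificationReport:
    name: str
    max_deviation: float
    tolerance: float
    passed: bool
    claimed_body_order: int | None = None
    n_samples: int = 0
    seed: int = 0
    details: dict = field(default_factory=dict)

    @classmethod
    def from_deviation(cls, name, dev, tol, **kw):
        return cls(name=name, max_deviation=float(dev), tolerance=float(tol),
                   passed=bool(dev <= tol), **kw)


def _transform_config(config: AtomicConfiguration, Q: o3.RotationOperation,
                      translation=0.0) -> AtomicConfiguration:
    return AtomicConfiguration(config.positions @ Q.matrix.T + translation,
                               config.atomic_numbers, cell=config.cell,
                               pbc=config.pbc)


# ----------------------------------------------------------------------
# equivariance
# ----------------------------------------------------------------------

def check_equivariance(fn, configs, irreps=None, n_rotations: int = 20,
                       include_reflections: bool = True, seed: int = 0,
                       tolerance: float = 1e-8) -> VerificationReport:
    """Blockwise O(3) equivariance of ``fn`` over sampled group elements.

    Two calling modes:

    * ``irreps is None`` — ``fn(config) -> (energy, forces)``; energies
      must be invariant, forces must rotate as (proper) vectors.
    * ``irreps`` given as a list of (L, parity) keys — ``fn(config)`` must
      return a dict of feature blocks ``(n_atoms, ..., 2L+1)`` which
      transform by the corresponding Wigner-D matrices.
    """
    rng = np.random.default_rng(seed)
    dev = 0.0
    n_ops = 0
    for config in configs:
        base = fn(config)
        ops = [o3.random_rotation(rng) for _ in range(n_rotations)]
        if include_reflections:
            ops += [o3.random_o3(rng, improper_fraction=1.0)
                    for _ in range(max(1, n_rotations // 5))]
        for Q in ops:
            n_ops += 1
            shifted = _transform_config(config, Q, translation=rng.normal(size=3))
            out = fn(shifted)
            if irreps is None:
                e0, f0 = base
                e1, f1 = out
                dev = max(dev, abs(e1 - e0))
                if f0 is not None:
                    det = -1.0 if Q.improper else 1.0
                    # forces are proper vectors: F(Qx) = Q F(x) for all of O(3)
                    dev = max(dev, np.abs(f1 - f0 @ Q.matrix.T).max())
            else:
                for key in irreps:
                    L, p = key
                    D = o3.wigner_D(Q, L, p)
                    expected = np.einsum("MN,...N->...M", D, np.asarray(base[key]))
                    dev = max(dev, np.abs(np.asarray(out[key]) - expected).max())
    return VerificationReport.from_deviation(
        "equivariance", dev, tolerance, n_samples=n_ops, seed=seed)


def check_permutation_invariance(fn, config: AtomicConfiguration,
                                 n_shuffles: int = 8, seed: int = 0,
                                 tolerance: float = 1e-12) -> VerificationReport:
    """fn(config) -> (energy, per-atom array); invariance under relabeling."""
    rng = np.random.default_rng(seed)
    e0, site0 = fn(config)
    dev = 0.0
    for _ in range(n_shuffles):
        perm = rng.permutation(len(config))
        shuffled = AtomicConfiguration(config.positions[perm],
                                       config.atomic_numbers[perm],
                                       cell=config.cell, pbc=config.pbc)
        e1, site1 = fn(shuffled)
        dev = max(dev, abs(e1 - e0))
        if site0 is not None:
            dev = max(dev, np.abs(np.asarray(site1) - np.asarray(site0)[perm]).max())
    return VerificationReport.from_deviation(
        "permutation_invariance", dev, tolerance, n_samples=n_shuffles, seed=seed)


# ----------------------------------------------------------------------
# body order via inclusion-exclusion
# ----------------------------------------------------------------------

def check_body_order(site_energy_fn, centre, neighbour_pool, claimed_order: int,
                     tolerance: float = 1e-9, r_cut: float = None,
                     subset_sizes=None) -> VerificationReport:
    """Inclusion-exclusion certificate of the body order of a site energy.

    ``site_energy_fn(config) -> float`` must return the site energy of atom
    0; ``centre = (position, atomic_number)``; ``neighbour_pool`` an
    ``AtomicConfiguration`` whose atoms all lie within ``r_cut`` of the
    centre (otherwise the test is vacuous and an error is raised).

    u(S) = sum_{A subset of S} (-1)^{|S \\ A|} E_0(centre + A) must vanish
    for every tested subset with |S| >= claimed_order and be nonzero for
    some |S| = claimed_order - 1.  (claimed_order counts *all* atoms of an
    interaction term including the centre, so a pair potential has
    claimed_order 2 and u(S) = 0 for |S| >= 2 neighbours.)
    """
    cpos = np.asarray(centre[0], dtype=float).reshape(3)
    cz = int(centre[1])
    pool_pos = neighbour_pool.positions
    pool_z = neighbour_pool.atomic_numbers
    if r_cut is not None:
        d = np.linalg.norm(pool_pos - cpos, axis=1)
        if np.any(d >= r_cut):
            raise ValueError("neighbour pool atoms must lie within r_cut of the centre")
    n_pool = len(pool_z)
    if n_pool < claimed_order:
        raise ValueError("neighbour pool smaller than the claimed body order")

    cache: dict = {}

    def site_e(subset):
        key = tuple(sorted(subset))
        if key not in cache:
            pos = np.vstack([cpos[None], pool_pos[list(key)]]) if key else cpos[None]
            z = np.concatenate([[cz], pool_z[list(key)]]) if key else np.array([cz])
            cache[key] = float(site_energy_fn(AtomicConfiguration(pos, z)))
        return cache[key]

    def u(S):
        total = 0.0
        S = tuple(S)
        for k in range(len(S) + 1):
            for A in combinations(S, k):
                total += (-1) ** (len(S) - k) * site_e(A)
        return total

    sizes = subset_sizes or [claimed_order - 1, claimed_order]
    max_high = 0.0
    max_low = 0.0
    n_eval = 0
    for size in sizes:
        for S in combinations(range(n_pool), size):
            val = abs(u(S))
            n_eval += 1
            if size >= claimed_order:
                max_high = max(max_high, val)
            else:
                max_low = max(max_low, val)
    passed = max_high <= tolerance and max_low > tolerance
    return VerificationReport(
        name="body_order", max_deviation=float(max_high), tolerance=float(tolerance),
        passed=bool(passed), claimed_body_order=claimed_order, n_samples=n_eval,
        details={"max_u_below_order": float(max_low)})


# ----------------------------------------------------------------------
# density trick and symmetrization oracles
# ----------------------------------------------------------------------

def explicit_cluster_sum(phi_factors, nu: int = None) -> np.ndarray:
    """Sum over *ordered* neighbour tuples of products of one-particle values.

    ``phi_factors`` is a list of nu arrays, each ``(n_neighbours, d_xi)``;
    the result has shape ``(d_1, ..., d_nu)`` and equals the tensor product
    of neighbour sums (the density trick) exactly — here it is computed the
    slow, explicit way, as the independent oracle.
    """
    nu = len(phi_factors) if nu is None else nu
    if nu != len(phi_factors):
        raise ValueError("nu must match the number of factors")
    n_nb = phi_factors[0].shape[0]
    if nu > 4 or n_nb > 10:
        raise ValueError("combinatorial guard: nu <= 4 and <= 10 neighbours")
    shape = tuple(f.shape[1] for f in phi_factors)
    out = np.zeros(shape)
    for tup in product(range(n_nb), repeat=nu):
        term = phi_factors[0][tup[0]]
        for xi in range(1, nu):
            term = np.multiply.outer(term, phi_factors[xi][tup[xi]])
        out += term
    return out


def brute_force_symmetrize(product_fn, displacements: np.ndarray,
                           coupling: o3.CouplingCoefficients,
                           n_rotations: int = 10000, seed: int = 0,
                           include_reflections: bool = True):
    """Monte-Carlo estimate of the symmetrization integral.

    ``product_fn(displacements) -> ndarray`` over the m multi-index (one
    axis per coupled degree) for the local environment given by the
    neighbour displacement vectors.  For each O(3) sample Q the product
    basis of the rotated environment is projected onto each eta path and
    rotated back with ``D^L(Q)^-1``; the mean over samples estimates the
    symmetrized basis ``B_{eta, LM}``, with its standard error.

    Returns (estimates [n_paths, 2L+1], standard_errors [n_paths, 2L+1]).
    """
    if n_rotations < 1000:
        raise ValueError("use at least 10^3 rotations for a meaningful estimate")
    rng = np.random.default_rng(seed)
    L, parity = coupling.L, coupling.parity
    nd = len(coupling.degrees)
    letters = "abcdefghij"[:nd]
    samples = np.zeros((n_rotations, coupling.n_paths, 2 * L + 1))
    for s in range(n_rotations):
        Q = o3.random_o3(rng) if include_reflections else o3.random_rotation(rng)
        Aq = np.asarray(product_fn(displacements @ Q.matrix.T))
        D = o3.wigner_D(Q, L, parity)
        for eta, T in enumerate(coupling.tensors):
            proj = np.einsum(f"{letters},{letters}N->N", Aq, T)
            samples[s, eta] = D.T @ proj
    est = samples.mean(axis=0)
    se = samples.std(axis=0, ddof=1) / np.sqrt(n_rotations)
    return est, se


def direct_linear_ace_site_energies(model, config: AtomicConfiguration) -> np.ndarray:
    """Independent full-coupling (linear-ACE) evaluation.

    Plain Python loops over neighbours and coupled tuples — no pooled
    tensors, no shared graph machinery, no automatic differentiation —
    used as the cross-check oracle for the full-coupling model path.
    """
    from .radial import bessel_basis, polynomial_cutoff

    cfg = model.config
    table = model.element_table
    z_idx = [table.index(z) for z in config.atomic_numbers]
    pos = config.positions
    sites = []
    for i in range(len(config)):
        A: dict = {}
        for j in range(len(config)):
            if j == i:
                continue
            dvec = pos[j] - pos[i]
            r = np.linalg.norm(dvec)
            if r >= cfg.r_cut:
                continue
            Y = o3.spherical_harmonics(dvec / r, cfg.l_max)
            Rn = (bessel_basis(np.array([r]), cfg.n_basis, cfg.r_cut)[0]
                  * polynomial_cutoff(np.array([r]), cfg.r_cut,
                                      cfg.cutoff_power)[0])
            for n in range(cfg.n_basis):
                for l in range(cfg.l_max + 1):
                    key = (z_idx[j], n, l)
                    A[key] = A.get(key, np.zeros(2 * l + 1)) + Rn[n] * Y[l]
        site = model.params["E0"].value[z_idx[i]]
        for feat, tup in enumerate(model.tuples):
            degrees = tuple(l for _, _, l in tup.entries)
            T = o3.generalized_coupling(degrees, tup.L).tensors[tup.eta]
            value = T
            for (zz, n, l) in tup.entries:
                a = A.get((zz, n, l), np.zeros(2 * l + 1)) / model.lam
                value = np.tensordot(a, value, axes=([0], [0]))
            site += model.params["readout_w"].value[z_idx[i], feat] * value[0]
        sites.append(site)
    return np.array(sites)


# ----------------------------------------------------------------------
# locality and smoothness
# ----------------------------------------------------------------------

def _hop_distances(config: AtomicConfiguration, r_cut: float, source: int) -> np.ndarray:
    d = np.linalg.norm(config.positions[:, None] - config.positions[None], axis=-1)
    adj = (d < r_cut) & ~np.eye(len(config), dtype=bool)
    hops = np.full(len(config), np.inf)
    hops[source] = 0
    frontier = [source]
    level = 0
    while frontier:
        level += 1
        nxt = []
        for i in frontier:
            for j in np.nonzero(adj[i])[0]:
                if hops[j] > level:
                    hops[j] = level
                    nxt.append(int(j))
        frontier = nxt
    return hops


def check_locality(site_energy_fn, config: AtomicConfiguration, probe_atom: int,
                   displacement, T: int, r_cut: float) -> VerificationReport:
    """Receptive-field certificate: T message-passing layers see T hops.

    Displaces ``probe_atom`` and reports the per-atom site-energy change;
    passes iff the change is *exactly* zero for every atom farther than T
    hops from the probe (in both the original and displaced graphs) and
    nonzero for at least one atom within range.
    """
    site0 = np.asarray(site_energy_fn(config))
    moved = config.positions.copy()
    moved[probe_atom] += np.asarray(displacement, dtype=float)
    config1 = AtomicConfiguration(moved, config.atomic_numbers, cell=config.cell,
                                  pbc=config.pbc)
    site1 = np.asarray(site_energy_fn(config1))
    delta = np.abs(site1 - site0)
    hops = np.minimum(_hop_distances(config, r_cut, probe_atom),
                      _hop_distances(config1, r_cut, probe_atom))
    beyond = hops > T
    within = (hops <= T) & (np.arange(len(config)) != probe_atom)
    max_beyond = float(delta[beyond].max()) if beyond.any() else 0.0
    max_within = float(delta[within].max()) if within.any() else 0.0
    return VerificationReport(
        name="locality", max_deviation=max_beyond, tolerance=0.0,
        passed=bool(max_beyond == 0.0 and (not within.any() or max_within > 0.0)),
        n_samples=len(config),
        details={"hops": hops.tolist(), "delta": delta.tolist(),
                 "max_within": max_within})


def check_cutoff_smoothness(energy_fn, path_fn, t_start: float, t_stop: float,
                            step: float = 1e-4,
                            tolerance: float = 1e-8) -> VerificationReport:
    """Max energy jump along a path (in Angstrom) crossing the cutoff.

    ``path_fn(t) -> AtomicConfiguration``; the jump between adjacent
    samples must shrink linearly with the step for a C^1 potential, so the
    report includes the observed max jump and its ratio to the step
    (an effective slope bound).
    """
    ts = np.arange(t_start, t_stop + step / 2, step)
    energies = np.array([float(energy_fn(path_fn(t))) for t in ts])
    jumps = np.abs(np.diff(energies))
    max_jump = float(jumps.max()) if len(jumps) else 0.0
    return VerificationReport.from_deviation(
        "cutoff_smoothness", max_jump, tolerance, n_samples=len(ts),
        details={"slope_bound": max_jump / step})


# ----------------------------------------------------------------------
# mutation helpers (the testbench must detect the defects it claims to)
# ----------------------------------------------------------------------

@contextmanager
def perturbed_clebsch_gordan(scale: float = 1e-2, seed: int = 0):
    """Context manager corrupting the CG tensors seen by the layers."""
    original = o3.clebsch_gordan
    rng = np.random.default_rng(seed)
    cache = {}

    def corrupted(l1, l2, L):
        key = (l1, l2, L)
        if key not in cache:
            base = original(l1, l2, L)
            cache[key] = base + scale * rng.normal(size=base.shape)
        return cache[key]

    o3.clebsch_gordan = corrupted
    from . import layer as lay
    lay.o3.clebsch_gordan = corrupted
    try:
        yield
    finally:
        o3.clebsch_gordan = original
        lay.o3.clebsch_gordan = original
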