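"""Synthetic datasets labelled by analytic body-ordered toy potentials.

The generator emulates small molecular clusters (or periodic boxes) whose
energies come from a Morse pair potential, optionally plus an explicit
angular three-body term — functional forms chosen to have *exact* low body
order (2 and 3 respectively) so the body-order machinery has a sharp
target.  Forces are hand-derived analytic gradients; both terms are
multiplied by the same smooth polynomial envelope the models use, so the
labels share the models' smoothness assumptions at the cutoff.

Everything is seeded and reproducible; no external data is ever needed.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from .radial import polynomial_cutoff
from .structures import AtomicConfiguration, build_neighbour_list, write_extxyz


@dataclass
class ToyPotentialSpec:
    """Morse pair term, optional cos^2-angle three-body term, smooth cutoff."""

    kind: str = "morse_plus_three_body"   # morse | morse_plus_three_body
    D: float = 0.5        # eV, well depth
    a: float = 1.5        # 1/A, well width
    r0: float = 2.0       # A, equilibrium distance
    epsilon: float = 0.15  # eV, three-body strength
    r_cut: float = 4.0    # A, envelope cutoff
    p: int = 6            # envelope power

    def __post_init__(self):
        if self.kind not in ("morse", "morse_plus_three_body"):
            raise ValueError("kind must be 'morse' or 'morse_plus_three_body'")
        if min(self.D, self.a, self.r0, self.r_cut) <= 0:
            raise ValueError("D, a, r0, r_cut must be positive")


# ----------------------------------------------------------------------
# geometry generation
# ----------------------------------------------------------------------

def random_configurations(n_configs: int, n_atoms: int, elements=(6,),
                          mode: str = "cluster", min_separation: float = 1.6,
                          seed: int = 0, radius: float = 3.0,
                          box: float = 8.0) -> list:
    """Seeded random geometries with a minimum pair distance.

    ``cluster`` samples positions uniformly in a ball of the given radius;
    ``box`` samples in a periodic cubic cell.  Rejection sampling enforces
    ``min_separation``; an infeasible packing raises after bounded retries.
    """
    if min_separation <= 0:
        raise ValueError("min_separation must be positive")
    if mode not in ("cluster", "box"):
        raise ValueError("mode must be 'cluster' or 'box'")
    rng = np.random.default_rng(seed)
    configs = []
    for _ in range(n_configs):
        for attempt in range(500):
            if mode == "cluster":
                u = rng.normal(size=(n_atoms, 3))
                u /= np.linalg.norm(u, axis=1, keepdims=True)
                pos = u * (radius * rng.random((n_atoms, 1)) ** (1 / 3))
                d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
            else:
                pos = rng.random((n_atoms, 3)) * box
                frac = pos[:, None] - pos[None, :]
                frac -= box * np.round(frac / box)
                d = np.linalg.norm(frac, axis=-1)
            if (d + 1e9 * np.eye(n_atoms)).min() >= min_separation:
                break
        else:
            raise RuntimeError("could not place atoms with the requested min_separation")
        z = rng.choice(list(elements), size=n_atoms)
        if mode == "cluster":
            configs.append(AtomicConfiguration(pos, z))
        else:
            configs.append(AtomicConfiguration(pos, z, cell=np.eye(3) * box,
                                               pbc=[True] * 3))
    return configs


# ----------------------------------------------------------------------
# analytic labels
# ----------------------------------------------------------------------

def _envelope(r: np.ndarray, spec: ToyPotentialSpec):
    """f_env(r) and its derivative; reuses the models' polynomial cutoff."""
    f = polynomial_cutoff(r, spec.r_cut, spec.p)
    u = r / spec.r_cut
    p = spec.p
    a = (p + 1) * (p + 2) / 2.0
    b = float(p * (p + 2))
    c = p * (p + 1) / 2.0
    df = (-a * p * u ** (p - 1) + b * (p + 1) * u ** p
          - c * (p + 2) * u ** (p + 1)) / spec.r_cut
    df = np.where(u < 1.0, df, 0.0)
    return f, df


def morse_labels(config: AtomicConfiguration, spec: ToyPotentialSpec):
    """E = sum_{i<j} [D (1 - e^{-a(r - r0)})^2 - D] f_env(r), analytic forces."""
    nl = build_neighbour_list(config, spec.r_cut)
    if nl.n_edges and nl.distances.min() < 1e-6:
        raise ValueError("overlapping atoms")
    r = nl.distances
    ex = np.exp(-spec.a * (r - spec.r0))
    pair = spec.D * (1.0 - ex) ** 2 - spec.D
    dpair = 2.0 * spec.D * (1.0 - ex) * spec.a * ex
    f, df = _envelope(r, spec)
    # directed edges double-count i<j pairs
    energy = 0.5 * np.sum(pair * f)
    dEdr = 0.5 * (dpair * f + pair * df)
    forces = np.zeros_like(config.positions)
    # dE/dr_i from edge (i <- j): d r/d r_i = -rhat (rhat = displacement/r)
    rhat = nl.displacements / r[:, None]
    np.add.at(forces, nl.receivers, dEdr[:, None] * rhat)
    np.add.at(forces, nl.senders, -dEdr[:, None] * rhat)
    return float(energy), forces


def _three_body_terms(config: AtomicConfiguration, spec: ToyPotentialSpec):
    nl = build_neighbour_list(config, spec.r_cut)
    edges_by_center: dict = {}
    for e in range(nl.n_edges):
        edges_by_center.setdefault(int(nl.receivers[e]), []).append(e)
    return nl, edges_by_center


def three_body_labels(config: AtomicConfiguration, spec: ToyPotentialSpec):
    """E3 = sum_i sum_{j<k in N(i)} eps cos^2(theta_jik) g(r_ij) g(r_ik).

    Strictly three-body (each term involves one centre and two distinct
    neighbours); forces are the exact analytic gradient.
    """
    nl, by_center = _three_body_terms(config, spec)
    g_all, dg_all = _envelope(nl.distances, spec)
    energy = 0.0
    forces = np.zeros_like(config.positions)
    eps = spec.epsilon
    for i, edges in by_center.items():
        for aidx in range(len(edges)):
            for bidx in range(aidx + 1, len(edges)):
                ea, eb = edges[aidx], edges[bidx]
                u = nl.displacements[ea]
                v = nl.displacements[eb]
                ru, rv = nl.distances[ea], nl.distances[eb]
                c = float(u @ v) / (ru * rv)
                ga, gb = g_all[ea], g_all[eb]
                dga, dgb = dg_all[ea], dg_all[eb]
                energy += eps * c * c * ga * gb
                # gradients wrt u and v (displacements from centre i)
                dc_du = v / (ru * rv) - c * u / ru ** 2
                dc_dv = u / (ru * rv) - c * v / rv ** 2
                dE_du = eps * gb * (2 * c * ga * dc_du + c * c * dga * u / ru)
                dE_dv = eps * ga * (2 * c * gb * dc_dv + c * c * dgb * v / rv)
                ja, jb = int(nl.senders[ea]), int(nl.senders[eb])
                forces[ja] -= dE_du
                forces[i] += dE_du
                forces[jb] -= dE_dv
                forces[i] += dE_dv
    return float(energy), forces


def label_config(config: AtomicConfiguration, spec: ToyPotentialSpec) -> AtomicConfiguration:
    """Attach toy-potential energy and exact forces to a configuration."""
    e2, f2 = morse_labels(config, spec)
    if spec.kind == "morse_plus_three_body":
        e3, f3 = three_body_labels(config, spec)
        e2, f2 = e2 + e3, f2 + f3
    return AtomicConfiguration(config.positions, config.atomic_numbers,
                               cell=config.cell, pbc=config.pbc,
                               energy=e2, forces=f2)


def dimer_curve(element_pair=(6, 6), r_grid=None) -> list:
    """Two-atom frames along the x axis, one per grid distance."""
    if r_grid is None:
        r_grid = np.linspace(1.0, 6.0, 50)
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(r_grid <= 0) or np.any(np.diff(r_grid) <= 0):
        raise ValueError("r_grid must be positive and ascending")
    out = []
    for r in r_grid:
        out.append(AtomicConfiguration([[0.0, 0.0, 0.0], [r, 0.0, 0.0]],
                                       list(element_pair)))
    return out


def make_dataset(spec: ToyPotentialSpec, n_configs: int = 500, n_atoms: int = 8,
                 elements=(6,), split_fractions=(0.8, 0.1, 0.1), seed: int = 0,
                 out_dir: str | None = None, mode: str = "cluster",
                 min_separation: float = 1.6, radius: float = 3.0) -> dict:
    """Labelled, split dataset; optionally written as extxyz + manifest.

    Returns {"train": [...], "val": [...], "test": [...], "manifest": {...}}.
    """
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    configs = random_configurations(n_configs, n_atoms, elements, mode,
                                    min_separation, seed, radius=radius)
    labelled = [label_config(c, spec) for c in configs]
    n_train = int(round(split_fractions[0] * n_configs))
    n_val = int(round(split_fractions[1] * n_configs))
    splits = {"train": labelled[:n_train],
              "val": labelled[n_train:n_train + n_val],
              "test": labelled[n_train + n_val:]}
    manifest = {"spec": asdict(spec), "seed": seed, "n_configs": n_configs,
                "n_atoms": n_atoms, "elements": list(elements), "mode": mode,
                "min_separation": min_separation, "radius": radius,
                "split_fractions": list(split_fractions),
                "counts": {k: len(v) for k, v in splits.items()}}
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for name, frames in splits.items():
            write_extxyz(frames, os.path.join(out_dir, f"{name}.xyz"))
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
    return {**splits, "manifest": manifest}


def regenerate_from_manifest(manifest: dict) -> dict:
    """Rebuild the identical dataset from a manifest (reproducibility check)."""
    spec = ToyPotentialSpec(**manifest["spec"])
    return make_dataset(spec, manifest["n_configs"], manifest["n_atoms"],
                        tuple(manifest["elements"]),
                        tuple(manifest["split_fractions"]), manifest["seed"],
                        mode=manifest["mode"],
                        min_separation=manifest["min_separation"],
                        radius=manifest["radius"])
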