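"""Atomic configurations, extended-XYZ I/O, neighbour lists, element one-hots.

The only exchange format is extended XYZ in the common dialect
(``Lattice="..." Properties=species:S:1:pos:R:3[:forces:R:3] energy=...``),
positions in Angstrom, energies in eV, forces in eV/A.  Neighbour lists are
built by exact brute-force search with explicit periodic replication —
O(n^2) but correct by construction at the cluster/molecule scale this
package targets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

_SYMBOLS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg",
    "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Sc", "Ti", "V", "Cr",
    "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se", "Br", "Kr",
]
_NUMBERS = {s: i for i, s in enumerate(_SYMBOLS)}


def atomic_number(symbol: str) -> int:
    try:
        return _NUMBERS[symbol]
    except KeyError:
        raise ValueError(f"unknown element symbol {symbol!r}") from None


def chemical_symbol(z: int) -> str:
    if not 1 <= z < len(_SYMBOLS):
        raise ValueError(f"atomic number {z} outside supported range")
    return _SYMBOLS[z]


@dataclass
class AtomicConfiguration:
    """One frame: positions (A), atomic numbers, optional cell and labels."""

    positions: np.ndarray                 # (n, 3)
    atomic_numbers: np.ndarray            # (n,)
    cell: np.ndarray | None = None        # (3, 3), rows are lattice vectors
    pbc: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=bool))
    energy: float | None = None           # eV
    forces: np.ndarray | None = None      # (n, 3) eV/A

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=int).reshape(-1)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if np.any(self.atomic_numbers < 1):
            raise ValueError("atomic numbers must be >= 1")
        if len(self.atomic_numbers) != len(self.positions):
            raise ValueError("positions / atomic_numbers length mismatch")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float).reshape(3, 3)
        self.pbc = np.asarray(self.pbc, dtype=bool).reshape(3)
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
            if self.forces.shape != self.positions.shape:
                raise ValueError("forces shape must match positions")
        if self.energy is not None:
            self.energy = float(self.energy)

    def __len__(self):
        return len(self.atomic_numbers)


@dataclass
class NeighbourList:
    """Directed edges within r_cut, canonically sorted for reproducibility."""

    receivers: np.ndarray      # i
    senders: np.ndarray        # j
    displacements: np.ndarray  # r_j - r_i (+ lattice shift), (E, 3)
    distances: np.ndarray      # (E,)
    shifts: np.ndarray         # integer lattice shifts, (E, 3)
    r_cut: float

    @property
    def n_edges(self) -> int:
        return len(self.receivers)


@dataclass
class NodeAttributes:
    one_hot: np.ndarray        # (n, n_elements)
    element_table: tuple       # ascending atomic numbers


# ----------------------------------------------------------------------
# extended XYZ
# ----------------------------------------------------------------------

_KV_RE = re.compile(r'(\S+?)=(?:"([^"]*)"|(\S+))')


def _parse_comment(line: str) -> dict:
    return {m.group(1): m.group(2) if m.group(2) is not None else m.group(3)
            for m in _KV_RE.finditer(line)}


def read_extxyz(path) -> list:
    """Read every frame of an extended-XYZ file."""
    configs = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        frame += 1
        try:
            n = int(lines[pos].strip())
            comment = lines[pos + 1]
            fields = _parse_comment(comment)
            props = fields.get("Properties", "species:S:1:pos:R:3").split(":")
            cols, c = [], 0
            for name, kind, width in zip(props[0::3], props[1::3], props[2::3]):
                w = int(width)
                cols.append((name, c, w))
                c += w
            body = [lines[pos + 2 + k].split() for k in range(n)]
            symbols, positions, forces = [], [], []
            has_forces = any(name == "forces" for name, _, _ in cols)
            for row in body:
                for name, start, w in cols:
                    chunk = row[start:start + w]
                    if name == "species":
                        symbols.append(chunk[0])
                    elif name == "pos":
                        positions.append([float(v) for v in chunk])
                    elif name == "forces":
                        forces.append([float(v) for v in chunk])
            cell = None
            pbc = np.zeros(3, dtype=bool)
            if "Lattice" in fields:
                cell = np.array([float(v) for v in fields["Lattice"].split()]).reshape(3, 3)
                pbc = np.ones(3, dtype=bool)
            if "pbc" in fields:
                pbc = np.array([v in ("T", "True", "1") for v in fields["pbc"].split()])
            energy = float(fields["energy"]) if "energy" in fields else None
            configs.append(AtomicConfiguration(
                positions=np.array(positions),
                atomic_numbers=np.array([atomic_number(s) for s in symbols]),
                cell=cell, pbc=pbc, energy=energy,
                forces=np.array(forces) if has_forces else None))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed extended-XYZ frame {frame} in {path}: {exc}") from exc
        pos += 2 + n
    return configs


def write_extxyz(configs, path) -> None:
    """Write configurations as extended XYZ at full float64 precision."""
    with open(path, "w") as fh:
        for cfg in configs:
            fh.write(f"{len(cfg)}\n")
            parts = []
            if cfg.cell is not None:
                parts.append('Lattice="' + " ".join(f"{v:.17g}" for v in cfg.cell.ravel()) + '"')
            props = "species:S:1:pos:R:3"
            if cfg.forces is not None:
                props += ":forces:R:3"
            parts.append(f"Properties={props}")
            if cfg.energy is not None:
                parts.append(f"energy={cfg.energy:.17g}")
            parts.append('pbc="' + " ".join("T" if b else "F" for b in cfg.pbc) + '"')
            fh.write(" ".join(parts) + "\n")
            for a in range(len(cfg)):
                row = [f"{chemical_symbol(cfg.atomic_numbers[a]):2s}"]
                row += [f"{v:.17g}" for v in cfg.positions[a]]
                if cfg.forces is not None:
                    row += [f"{v:.17g}" for v in cfg.forces[a]]
                fh.write(" ".join(row) + "\n")


# ----------------------------------------------------------------------
# neighbour list
# ----------------------------------------------------------------------

def build_neighbour_list(config: AtomicConfiguration, r_cut: float) -> NeighbourList:
    """All directed pairs with distance strictly below r_cut.

    Periodic directions are handled by explicit cell replication out to the
    number of images r_cut requires; edges are sorted by (receiver, sender,
    shift) so downstream summation order is reproducible bit-for-bit.
    """
    if r_cut <= 0:
        raise ValueError("r_cut must be positive")
    pos = config.positions
    n = len(config)
    periodic = config.cell is not None and config.pbc.any()
    if periodic:
        inv = np.linalg.inv(config.cell)
        plane_spacing = 1.0 / np.linalg.norm(inv, axis=1)  # distance between lattice planes
        reps = np.where(config.pbc, np.ceil(r_cut / plane_spacing).astype(int), 0)
        if np.any(reps > 12):
            raise ValueError("cell too skewed or small: replication bound exceeded")
        ranges = [range(-int(r), int(r) + 1) for r in reps]
    else:
        ranges = [range(0, 1)] * 3

    recv, send, disp, shifts = [], [], [], []
    for sa in ranges[0]:
        for sb in ranges[1]:
            for sc in ranges[2]:
                shift = np.array([sa, sb, sc])
                offset = shift @ config.cell if periodic else np.zeros(3)
                # d[i, j] = (r_j + offset) - r_i
                d = (pos[None, :, :] + offset) - pos[:, None, :]
                dist = np.linalg.norm(d, axis=-1)
                mask = dist < r_cut
                if not shift.any():
                    np.fill_diagonal(mask, False)
                ii, jj = np.nonzero(mask)
                recv.append(ii)
                send.append(jj)
                disp.append(d[ii, jj])
                shifts.append(np.tile(shift, (len(ii), 1)))
    recv = np.concatenate(recv)
    send = np.concatenate(send)
    disp = np.concatenate(disp)
    shifts = np.concatenate(shifts)
    order = np.lexsort((shifts[:, 2], shifts[:, 1], shifts[:, 0], send, recv))
    recv, send, disp, shifts = recv[order], send[order], disp[order], shifts[order]
    return NeighbourList(receivers=recv, senders=send, displacements=disp,
                         distances=np.linalg.norm(disp, axis=1),
                         shifts=shifts, r_cut=float(r_cut))


def one_hot_attributes(atomic_numbers, element_table) -> NodeAttributes:
    """Deterministic one-hot rows ordered by the ascending element table."""
    table = tuple(sorted(int(z) for z in element_table))
    index = {z: k for k, z in enumerate(table)}
    z = np.asarray(atomic_numbers, dtype=int)
    unknown = sorted(set(z.tolist()) - set(table))
    if unknown:
        raise ValueError(f"atomic numbers {unknown} not in element table {table}")
    oh = np.zeros((len(z), len(table)))
    oh[np.arange(len(z)), [index[v] for v in z]] = 1.0
    return NodeAttributes(one_hot=oh, element_table=table)
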