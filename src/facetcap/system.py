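"""In-memory molecular system container and bonded topology.

A :class:`MolecularSystem` holds atoms (element, name, residue, charge, MM
type), Cartesian coordinates in Å, the covalent bond list, a fixed-atom
mask and an optional periodic cell.  The cell is periodic in its first two
lattice vectors only (slab geometry: open normal to the surface, +z).

Angles, proper dihedrals, planarity impropers and nonbonded exclusions are
derived from the bond graph by :class:`Topology` and cached on the system.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import element_mass

__all__ = ["MolecularSystem", "Topology", "merge_systems"]


@dataclass
class Topology:
    """Bonded terms and nonbonded exclusion bookkeeping.

    ``angles`` are (i, j, k) with j central; ``propers`` are paths
    (i, j, k, l); ``impropers`` are (i, j, c, l) with c the planar center.
    ``excluded`` holds 1-2 and 1-3 pairs (i < j); ``pairs14`` the 1-4
    pairs that are scaled rather than excluded.
    """

    bonds: np.ndarray
    angles: np.ndarray
    propers: np.ndarray
    impropers: np.ndarray
    excluded: set[tuple[int, int]]
    pairs14: set[tuple[int, int]]

    @classmethod
    def from_bonds(cls, bonds: np.ndarray, n_atoms: int, types: np.ndarray) -> "Topology":
        bonds = np.asarray(bonds, dtype=int).reshape(-1, 2)
        if bonds.size and (bonds.min() < 0 or bonds.max() >= n_atoms):
            raise IndexError("bond index out of range")
        adj: list[list[int]] = [[] for _ in range(n_atoms)]
        for i, j in bonds:
            adj[i].append(int(j))
            adj[j].append(int(i))
        adj = [sorted(a) for a in adj]

        angles = []
        for j in range(n_atoms):
            nb = adj[j]
            for a in range(len(nb)):
                for b in range(a + 1, len(nb)):
                    angles.append((nb[a], j, nb[b]))

        propers = []
        seen = set()
        for j, k in bonds:
            j, k = int(j), int(k)
            for i in adj[j]:
                if i == k:
                    continue
                for l in adj[k]:
                    if l == j or l == i:
                        continue
                    key = (i, j, k, l) if (j, k, i, l) <= (k, j, l, i) else (l, k, j, i)
                    if key not in seen:
                        seen.add(key)
                        propers.append(key)

        impropers = []
        for c in range(n_atoms):
            if len(adj[c]) != 3:
                continue
            t = types[c]
            planar = t in ("C", "CA") or (
                t == "N" and any(types[n] in ("C",) for n in adj[c])
            )
            if planar:
                a, b, d = adj[c]
                impropers.append((a, b, c, d))

        excluded: set[tuple[int, int]] = set()
        for i, j in bonds:
            excluded.add((min(i, j), max(i, j)))
        for i, _, k in angles:
            excluded.add((min(i, k), max(i, k)))
        pairs14: set[tuple[int, int]] = set()
        for i, _, _, l in propers:
            p = (min(i, l), max(i, l))
            if p not in excluded:
                pairs14.add(p)

        def arr(x, width):
            return np.asarray(x, dtype=int).reshape(-1, width)

        return cls(bonds, arr(angles, 3), arr(propers, 4), arr(impropers, 4),
                   excluded, pairs14)


@dataclass
class MolecularSystem:
    names: np.ndarray
    elements: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    segments: np.ndarray  # 'peptide' | 'slab' | 'water' | 'probe'
    types: np.ndarray
    charges: np.ndarray
    coords: np.ndarray
    bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    fixed: np.ndarray | None = None
    cell: np.ndarray | None = None  # (3, 3); periodic along rows 0 and 1
    masses: np.ndarray | None = None
    _topology: Topology | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        n = len(self.names)
        self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)
        self.charges = np.asarray(self.charges, dtype=float)
        self.resids = np.asarray(self.resids, dtype=int)
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        if self.fixed is None:
            self.fixed = np.zeros(n, dtype=bool)
        self.fixed = np.asarray(self.fixed, dtype=bool)
        if self.masses is None:
            self.masses = np.array([element_mass(e) for e in self.elements])
        for arr_name in ("names", "elements", "resnames", "segments", "types"):
            setattr(self, arr_name, np.asarray(getattr(self, arr_name)))

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def mobile(self) -> np.ndarray:
        return ~self.fixed

    def topology(self) -> Topology:
        if self._topology is None:
            self._topology = Topology.from_bonds(self.bonds, self.n_atoms, self.types)
        return self._topology

    def copy(self) -> "MolecularSystem":
        new = replace(self)
        new.coords = self.coords.copy()
        new.fixed = self.fixed.copy()
        new._topology = self._topology
        return new

    def with_coords(self, coords: np.ndarray) -> "MolecularSystem":
        new = self.copy()
        new.coords = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        return new

    def translate(self, shift) -> "MolecularSystem":
        return self.with_coords(self.coords + np.asarray(shift, dtype=float))

    def subset(self, mask: np.ndarray) -> "MolecularSystem":
        """New system from the masked atoms; bonds crossing the cut are dropped."""
        mask = np.asarray(mask, dtype=bool)
        index = np.full(self.n_atoms, -1, dtype=int)
        index[mask] = np.arange(mask.sum())
        keep = mask[self.bonds[:, 0]] & mask[self.bonds[:, 1]] if self.bonds.size else \
            np.zeros(0, dtype=bool)
        bonds = index[self.bonds[keep]] if self.bonds.size else self.bonds
        return MolecularSystem(
            names=self.names[mask], elements=self.elements[mask],
            resids=self.resids[mask], resnames=self.resnames[mask],
            segments=self.segments[mask], types=self.types[mask],
            charges=self.charges[mask], coords=self.coords[mask],
            bonds=bonds, fixed=self.fixed[mask], cell=self.cell,
            masses=self.masses[mask],
        )

    def select(self, segment: str) -> np.ndarray:
        return self.segments == segment


def merge_systems(a: MolecularSystem, b: MolecularSystem,
                  cell: np.ndarray | None = None) -> MolecularSystem:
    """Concatenate two systems (atom order: a then b). Residue ids of ``b``
    are shifted above ``a``'s so they stay unique."""
    offset = int(a.resids.max()) + 1 - int(b.resids.min()) if a.n_atoms and b.n_atoms else 0
    bonds = np.vstack([a.bonds, b.bonds + a.n_atoms]) if (a.bonds.size or b.bonds.size) \
        else np.empty((0, 2), dtype=int)
    if cell is None:
        cell = a.cell if a.cell is not None else b.cell
    return MolecularSystem(
        names=np.concatenate([a.names, b.names]),
        elements=np.concatenate([a.elements, b.elements]),
        resids=np.concatenate([a.resids, b.resids + offset]),
        resnames=np.concatenate([a.resnames, b.resnames]),
        segments=np.concatenate([a.segments, b.segments]),
        types=np.concatenate([a.types, b.types]),
        charges=np.concatenate([a.charges, b.charges]),
        coords=np.vstack([a.coords, b.coords]),
        bonds=bonds,
        fixed=np.concatenate([a.fixed, b.fixed]),
        cell=cell,
        masses=np.concatenate([a.masses, b.masses]),
    )
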