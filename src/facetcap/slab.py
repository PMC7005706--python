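"""FCC metal slabs exposing the (111) facet.

The (111) surface of an FCC crystal is a hexagonal close-packed plane;
successive planes follow ABC stacking with interlayer spacing a/√3 and
in-plane nearest-neighbour distance a/√2.  The slab is built with the
surface normal along +z, the top layer at z = 0 (adsorbate above), and is
periodic in the two in-plane lattice vectors only.  Slab atoms are fixed
by default: the metal is treated as a rigid substrate, which leaves the
adsorption configuration and interaction energy essentially unchanged for
a heavy metal while removing its internal dynamics from the problem.

The three lateral site classes of the hexagonal surface cell — ``top``
(above a first-layer atom), ``second`` (hollow above a second-layer atom,
the hcp site) and ``third`` (hollow above a third-layer atom, the fcc
site) — are exposed through :class:`SurfaceRegistry`, the geometric basis
of the lock-and-key analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .system import MolecularSystem

__all__ = ["Slab", "build_fcc_slab", "surface_registry", "SurfaceRegistry"]

SITE_CLASSES = ("top", "second", "third")


@dataclass
class Slab:
    """FCC(111) substrate: a rigid :class:`MolecularSystem` plus lattice
    metadata and per-atom layer indices (1 = top layer)."""

    system: MolecularSystem
    element: str
    lattice_constant: float
    miller: tuple[int, int, int]
    n_layers: int
    repeats: tuple[int, int]
    layer_index: np.ndarray
    surface_vectors: np.ndarray  # (2, 2): in-plane lattice vectors (xy)

    @property
    def coords(self) -> np.ndarray:
        return self.system.coords

    @property
    def interlayer_spacing(self) -> float:
        return self.lattice_constant / np.sqrt(3.0)

    @property
    def nn_distance(self) -> float:
        return self.lattice_constant / np.sqrt(2.0)

    @property
    def top_z(self) -> float:
        return float(self.coords[self.layer_index == 1, 2].max())

    def top_layer_xy(self) -> np.ndarray:
        return self.coords[self.layer_index == 1, :2]


def build_fcc_slab(element: str = "Au", a: float = 4.08,
                   miller: tuple[int, int, int] = (1, 1, 1),
                   n_layers: int = 6,
                   repeats: tuple[int, int] = (8, 8)) -> Slab:
    """Build an FCC ``miller`` slab of ``element`` with ``n_layers`` layers.

    Only the (111) facet is generated: the peptide capping candidates show
    no adsorption preference on the (100)/(110) facets, so those are
    rejected here.  The default lattice constant 4.08 Å is gold's.
    """
    if a <= 0:
        raise ValueError("lattice constant must be positive")
    if n_layers < 1:
        raise ValueError("need at least one layer")
    if tuple(miller) != (1, 1, 1):
        raise ValueError(
            f"unsupported Miller index {tuple(miller)}: only the (111) facet "
            "is modelled (capping peptides show no (100)/(110) preference)")
    nx, ny = repeats
    d = a / np.sqrt(2.0)            # in-plane nearest-neighbour distance
    dz = a / np.sqrt(3.0)           # (111) interlayer spacing
    a1 = d * np.array([1.0, 0.0])
    a2 = d * np.array([0.5, np.sqrt(3.0) / 2.0])
    # ABC stacking: each deeper layer shifts laterally by (a1 + a2)/3
    shift = (a1 + a2) / 3.0

    coords, layers = [], []
    for layer in range(1, n_layers + 1):
        off = (layer - 1) * shift
        z = -(layer - 1) * dz
        for i in range(nx):
            for j in range(ny):
                xy = i * a1 + j * a2 + off
                coords.append([xy[0], xy[1], z])
                layers.append(layer)
    coords = np.array(coords)
    layers = np.array(layers, dtype=int)

    cell = np.zeros((3, 3))
    cell[0, :2] = nx * a1
    cell[1, :2] = ny * a2
    cell[2, 2] = n_layers * dz + 100.0  # open direction, recorded as vacuum

    n = len(coords)
    el = element.upper()
    system = MolecularSystem(
        names=np.array([el] * n), elements=np.array([el] * n),
        resids=np.arange(1, n + 1), resnames=np.array(["SLB"] * n),
        segments=np.array(["slab"] * n), types=np.array([el] * n),
        charges=np.zeros(n), coords=coords,
        fixed=np.ones(n, dtype=bool), cell=cell,
    )
    return Slab(system=system, element=element, lattice_constant=a,
                miller=tuple(miller), n_layers=n_layers, repeats=(nx, ny),
                layer_index=layers,
                surface_vectors=np.vstack([nx * a1, ny * a2]))


@dataclass
class SurfaceRegistry:
    """Lateral site map of a (111) surface.

    Any in-plane point is assigned to the nearest of the three sublattices
    formed by the lateral positions of the first, second and third layers
    (classes ``top`` / ``second`` / ``third``); the map is invariant under
    translation by surface lattice vectors.
    """

    primitive: np.ndarray      # (2, 2) primitive surface vectors (rows)
    offsets: np.ndarray        # (3, 2) lateral offset of each site class

    def classify(self, xy) -> tuple[str, float]:
        """Site class and lateral distance (Å) to its nearest lattice point."""
        dists = [self.distance_to_class(xy, cls) for cls in SITE_CLASSES]
        k = int(np.argmin(dists))
        return SITE_CLASSES[k], float(dists[k])

    def distance_to_class(self, xy, site_class: str) -> float:
        k = SITE_CLASSES.index(site_class)
        d = np.asarray(xy, dtype=float)[:2] - self.offsets[k]
        frac = np.linalg.solve(self.primitive.T, d)
        frac -= np.round(frac)
        best = np.inf
        for s1 in (-1, 0, 1):
            for s2 in (-1, 0, 1):
                cand = (frac + [s1, s2]) @ self.primitive
                best = min(best, float(np.linalg.norm(cand)))
        return best


def surface_registry(slab: Slab) -> SurfaceRegistry:
    """Site map of ``slab``'s top surface; needs at least 3 layers to see
    the full ABC registry."""
    if slab.n_layers < 3:
        raise ValueError("surface registry needs >= 3 layers (ABC stacking)")
    d = slab.nn_distance
    a1 = d * np.array([1.0, 0.0])
    a2 = d * np.array([0.5, np.sqrt(3.0) / 2.0])
    shift = (a1 + a2) / 3.0
    # lateral offset of layer k is (k-1)*shift relative to the top layer
    offsets = np.array([0.0 * shift, 1.0 * shift, 2.0 * shift])
    return SurfaceRegistry(primitive=np.vstack([a1, a2]), offsets=offsets)
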