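"""Named synthetic fixtures with documented oracles.

Every fixture is generated programmatically and deterministically; where
an independent oracle value exists (closed form, brute-force grid, or a
well-known cluster minimum) it is attached to the fixture so tests and the
acceptance script compare search results against it rather than against
the implementation under test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .constants import ACC_CONV
from .peptide import build_conformation, parse_capped_sequence
from .slab import Slab, build_fcc_slab, surface_registry
from .system import MolecularSystem, merge_systems

__all__ = ["Fixture", "make_fixture", "available_fixtures",
           "DoubleWellProblem", "LJClusterProblem", "make_benzene_probe"]


@dataclass
class Fixture:
    name: str
    description: str
    oracle: dict
    payload: object
    seed: int = 0


# ---------------------------------------------------------------------------
# analytic / toy problems implementing the search-problem protocol
# ---------------------------------------------------------------------------

class DoubleWellProblem:
    """1-D asymmetric double well f(x) = (x² − 1)² + tilt·x.

    Two minima near ±1 with depths split by the tilt; the global minimum
    (negative-x well for positive tilt) is located independently by a
    brute-force grid scan at construction.
    """

    def __init__(self, tilt: float = 0.3, step: float = 0.7):
        self.tilt = tilt
        self.step = step
        grid = np.linspace(-2.5, 2.5, 20001)
        vals = self._f(grid)
        x0 = grid[np.argmin(vals)]
        res = optimize.minimize_scalar(
            self._f, bracket=(x0 - 1e-3, x0, x0 + 1e-3))
        self.global_min_x = float(res.x)
        self.global_min_f = float(res.fun)
        other = optimize.minimize_scalar(
            self._f, bracket=(0.5, 1.0, 1.5) if self.global_min_x < 0
            else (-1.5, -1.0, -0.5))
        self.other_min_f = float(other.fun)

    def _f(self, x):
        return (np.asarray(x) ** 2 - 1.0) ** 2 + self.tilt * np.asarray(x)

    def initial(self, rng) -> np.ndarray:
        return rng.uniform(-2.0, 2.0, size=1)

    def value(self, x) -> float:
        return float(self._f(x[0]))

    def minimize(self, x):
        res = optimize.minimize(lambda v: self._f(v[0]), np.asarray(x, dtype=float),
                                method="CG",
                                jac=lambda v: np.array(
                                    [4.0 * v[0] * (v[0] ** 2 - 1.0) + self.tilt]))
        return res.x, float(res.fun), bool(res.success)

    def perturb(self, x, rng) -> np.ndarray:
        return np.asarray(x) + self.step * rng.normal(size=1)


class LJClusterProblem:
    """Lennard-Jones n-cluster in reduced units (ε = σ = 1).

    Known global minima: −3ε (triangle, n=3), −6ε (tetrahedron, n=4),
    −9.103852ε (n=5), −12.712062ε (n=6).
    """

    KNOWN_MINIMA = {2: -1.0, 3: -3.0, 4: -6.0, 5: -9.103852,
                    6: -12.712062, 7: -16.505384}

    def __init__(self, n: int, step: float = 0.35):
        self.n = n
        self.step = step

    def initial(self, rng) -> np.ndarray:
        span = 1.1 * self.n ** (1.0 / 3.0)
        return rng.uniform(-span / 2, span / 2, size=(self.n, 3)).ravel()

    def _energy_grad(self, flat):
        x = flat.reshape(self.n, 3)
        d = x[:, None, :] - x[None, :, :]
        r2 = np.einsum("ijk,ijk->ij", d, d)
        np.fill_diagonal(r2, 1.0)
        inv6 = r2 ** -3
        iu = np.triu_indices(self.n, k=1)
        e = float(np.sum(4.0 * (inv6[iu] ** 2 - inv6[iu])))
        coef = 24.0 * (2.0 * inv6 ** 2 - inv6) / r2
        np.fill_diagonal(coef, 0.0)
        grad = -np.einsum("ij,ijk->ik", coef, d)
        return e, grad.ravel()

    def value(self, flat) -> float:
        return self._energy_grad(flat)[0]

    def minimize(self, flat):
        res = optimize.minimize(self._energy_grad, np.asarray(flat, dtype=float),
                                jac=True, method="CG",
                                options={"gtol": 1e-6, "maxiter": 2000})
        return res.x, float(res.fun), bool(res.success)

    def perturb(self, flat, rng) -> np.ndarray:
        return np.asarray(flat) + self.step * rng.normal(size=3 * self.n)


# ---------------------------------------------------------------------------
# molecular fixtures
# ---------------------------------------------------------------------------

def make_harmonic_dimer() -> tuple[MolecularSystem, dict]:
    """Two bonded carbon-like sites; the analytic vibration period of the
    harmonic bond E = k(r−r0)² is 2π √(μ / (2k·c)) with c the
    units-conversion factor."""
    from .forcefield import ForceFieldParams

    params = ForceFieldParams.default()
    k, r0 = params.bond_params("CT", "CT")
    system = MolecularSystem(
        names=np.array(["C1", "C2"]), elements=np.array(["C", "C"]),
        resids=np.array([1, 1]), resnames=np.array(["DIM", "DIM"]),
        segments=np.array(["probe", "probe"]),
        types=np.array(["CT", "CT"]), charges=np.zeros(2),
        coords=np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]]),
        bonds=np.array([[0, 1]]),
    )
    mu = system.masses[0] / 2.0
    omega = np.sqrt(2.0 * k * ACC_CONV / mu)  # rad/fs
    return system, {"bond_k": k, "bond_r0": r0, "period_fs": 2.0 * np.pi / omega}


def make_benzene_probe(placement: str = "flat", height: float = 3.5,
                       lateral_shift=None, slab: Slab | None = None,
                       with_hydrogens: bool = True
                       ) -> tuple[MolecularSystem, Slab, np.ndarray]:
    """Ideal benzene over a (111) slab: ``flat`` centers the ring over a
    top-layer atom with carbons pointing at the surrounding hollow sites;
    ``standup`` rotates it 90° about an in-plane axis.  Returns
    (combined system, slab, ring index array)."""
    slab = slab or build_fcc_slab(n_layers=4, repeats=(6, 6))
    reg = surface_registry(slab)
    # center over the top atom nearest the slab middle
    top_xy = slab.top_layer_xy()
    center = top_xy[np.argmin(np.linalg.norm(
        top_xy - top_xy.mean(axis=0), axis=1))]
    # ring vertices along the hollow-site directions (30° + k*60°)
    angles = np.radians(30.0 + 60.0 * np.arange(6))
    ring = np.stack([1.40 * np.cos(angles), 1.40 * np.sin(angles),
                     np.zeros(6)], axis=1)
    atoms = [ring]
    if with_hydrogens:
        atoms.append(np.stack([2.48 * np.cos(angles), 2.48 * np.sin(angles),
                               np.zeros(6)], axis=1))
    coords = np.vstack(atoms)
    if placement == "standup":
        # rotate 90° about an in-plane axis through the ring centroid
        rot = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]])
        coords = coords @ rot.T
    coords[:, :2] += center
    if lateral_shift is not None:
        coords[:, :2] += np.asarray(lateral_shift, dtype=float)
    coords[:, 2] += slab.top_z + height

    n_c, n_h = 6, 6 if with_hydrogens else 0
    bonds = [[i, (i + 1) % 6] for i in range(6)]
    bonds += [[i, 6 + i] for i in range(n_h)]
    probe = MolecularSystem(
        names=np.array([f"C{i+1}" for i in range(n_c)]
                       + [f"H{i+1}" for i in range(n_h)]),
        elements=np.array(["C"] * n_c + ["H"] * n_h),
        resids=np.ones(n_c + n_h, dtype=int),
        resnames=np.array(["BNZ"] * (n_c + n_h)),
        segments=np.array(["probe"] * (n_c + n_h)),
        types=np.array(["CA"] * n_c + ["HA"] * n_h),
        charges=np.zeros(n_c + n_h),
        coords=coords, bonds=np.array(bonds, dtype=int),
    )
    combined = merge_systems(probe, slab.system)
    del reg
    return combined, slab, np.arange(6)


def make_tripeptide_on_slab() -> tuple[MolecularSystem, Slab]:
    """Capped Ser-Phe-Ser over a small rigid (111) slab (≤ 200 atoms): the
    standard toy adsorption fixture for MD and search tests."""
    seq = parse_capped_sequence("Ac-SFS-NH2")
    pep = build_conformation(seq)
    slab = build_fcc_slab(n_layers=3, repeats=(7, 7))
    x = pep.coords - pep.coords.mean(axis=0)
    x[:, 2] += slab.top_z + 3.5 - x[:, 2].min()
    x[:, :2] += slab.surface_vectors.sum(axis=0) / 2.0
    pep = pep.with_coords(x)
    return merge_systems(pep, slab.system), slab


_FIXTURES = {}


def _register(name):
    def deco(fn):
        _FIXTURES[name] = fn
        return fn
    return deco


@_register("lj3")
def _lj3(seed):
    p = LJClusterProblem(3)
    return Fixture("lj3", "3-site Lennard-Jones cluster (equilateral triangle)",
                   {"global_min": -3.0}, p, seed)


@_register("lj4")
def _lj4(seed):
    p = LJClusterProblem(4)
    return Fixture("lj4", "4-site Lennard-Jones cluster (regular tetrahedron, "
                   "all 6 pairs at the pair minimum)",
                   {"global_min": -6.0}, p, seed)


@_register("lj5")
def _lj5(seed):
    return Fixture("lj5", "5-site Lennard-Jones cluster",
                   {"global_min": LJClusterProblem.KNOWN_MINIMA[5]},
                   LJClusterProblem(5), seed)


@_register("lj6")
def _lj6(seed):
    return Fixture("lj6", "6-site Lennard-Jones cluster",
                   {"global_min": LJClusterProblem.KNOWN_MINIMA[6]},
                   LJClusterProblem(6), seed)


@_register("lj7")
def _lj7(seed):
    return Fixture("lj7", "7-site Lennard-Jones cluster",
                   {"global_min": LJClusterProblem.KNOWN_MINIMA[7]},
                   LJClusterProblem(7), seed)


@_register("double_well")
def _dw(seed):
    p = DoubleWellProblem()
    return Fixture(
        "double_well",
        "1-D asymmetric double well with brute-force-located minima",
        {"global_min_x": p.global_min_x, "global_min_f": p.global_min_f,
         "other_min_f": p.other_min_f}, p, seed)


@_register("harmonic_dimer")
def _dimer(seed):
    system, oracle = make_harmonic_dimer()
    return Fixture("harmonic_dimer",
                   "bonded two-site oscillator with closed-form period",
                   oracle, system, seed)


@_register("tripeptide_on_slab")
def _tri(seed):
    system, slab = make_tripeptide_on_slab()
    return Fixture("tripeptide_on_slab",
                   "capped Ser-Phe-Ser above a rigid 3-layer (111) slab",
                   {"n_atoms": system.n_atoms}, {"system": system, "slab": slab},
                   seed)


@_register("benzene_flat_on_au")
def _bfa(seed):
    system, slab, ring = make_benzene_probe("flat")
    return Fixture("benzene_flat_on_au",
                   "flat-on benzene centered over a top-layer atom "
                   "(lock-and-key positive probe)",
                   {"lak": True, "orientation": "flat-on"},
                   {"system": system, "slab": slab, "ring": ring}, seed)


@_register("benzene_standup_on_au")
def _bsa(seed):
    system, slab, ring = make_benzene_probe("standup")
    return Fixture("benzene_standup_on_au",
                   "benzene rotated 90° about an in-plane axis (stand-up probe)",
                   {"lak": False, "orientation": "stand-up"},
                   {"system": system, "slab": slab, "ring": ring}, seed)


@_register("benzene_shifted_on_au")
def _bsh(seed):
    system, slab, ring = make_benzene_probe(
        "flat", lateral_shift=(0.5 * 4.08 / np.sqrt(2.0), 0.0))
    return Fixture("benzene_shifted_on_au",
                   "flat benzene displaced by half a lattice vector "
                   "(lock-and-key negative probe)",
                   {"lak": False, "orientation": "flat-on"},
                   {"system": system, "slab": slab, "ring": ring}, seed)


def available_fixtures() -> list[str]:
    return sorted(_FIXTURES)


def make_fixture(name: str, seed: int = 0) -> Fixture:
    """Instantiate a named fixture; unknown names raise listing what exists."""
    try:
        maker = _FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: "
                       f"{', '.join(available_fixtures())}") from None
    return maker(seed)
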