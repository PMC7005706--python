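"""NVT / NVE molecular dynamics for peptide-on-slab systems.

A velocity-Verlet integrator with a Nosé–Hoover thermostat (the production
choice) or a stochastic Langevin (BAOAB) thermostat as an explicitly
selected fallback for tiny systems where Nosé–Hoover ergodicity is poor.
Supports fixed-atom masks (the rigid slab), harmonic positional restraints
(E = k |r − r0|², the convention under which a single restrained atom has
mean-square displacement 3 k_B T / (2 k)), and explicit 3-site water with
stiff internal harmonics.

Units: fs, Å, kcal/mol, K.  All stochastic elements (velocity seeding,
Langevin noise, water placement) derive from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import ACC_CONV, KB, KE_PER_MV2
from .forcefield import Evaluator, ForceFieldParams, Restraints
from .system import MolecularSystem, merge_systems

__all__ = [
    "MDConfig", "Trajectory", "nvt_run", "nve_run", "restrained_relax",
    "solvate", "strip_water", "relative_energy_drift",
]

_WATER_NUMBER_DENSITY = 6.02214076e-1 / 18.015  # molecules/Å³ per (g/cm³)


@dataclass
class MDConfig:
    """Integration settings.  ``thermostat`` is ``"nose-hoover"``,
    ``"langevin"`` or ``None`` (NVE); ``coupling`` is the thermostat time
    constant in fs.  A 2 fs timestep is permitted only when explicitly
    requested (the high-temperature perturbation moves); the production
    default is 0.5 fs."""

    timestep: float = 0.5
    n_steps: int = 1000
    temperature: float = 300.0
    thermostat: str | None = "nose-hoover"
    coupling: float = 100.0
    seed: int = 0
    stride: int = 10
    restraints: Restraints | None = None
    store_velocities: bool = False

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.thermostat is not None and self.temperature <= 0:
            raise ValueError("NVT requires a positive target temperature")
        if self.thermostat not in (None, "nose-hoover", "langevin"):
            raise ValueError(f"unknown thermostat {self.thermostat!r}")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass
class Trajectory:
    """Frames plus per-frame energies/temperature and the run's config echo."""

    coords: np.ndarray          # (F, N, 3)
    times: np.ndarray           # fs
    epot: np.ndarray
    ekin: np.ndarray
    temperature: np.ndarray
    config: MDConfig
    seed: int
    final_velocities: np.ndarray
    velocities: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def etot(self) -> np.ndarray:
        return self.epot + self.ekin

    @property
    def final_coords(self) -> np.ndarray:
        return self.coords[-1]

    def mean_temperature(self, fraction: float = 0.5) -> float:
        """Time-averaged kinetic temperature over the trailing ``fraction``
        of the run (the production window)."""
        start = int(round((1.0 - fraction) * (self.n_frames - 1)))
        return float(self.temperature[start:].mean())


def _kinetic(masses, v) -> float:
    return 0.5 * KE_PER_MV2 * float(np.sum(masses[:, None] * v * v))


def _dof(system: MolecularSystem, config: MDConfig) -> int:
    n_mob = int(system.mobile.sum())
    translation_free = (not system.fixed.any() and config.restraints is None
                        and system.cell is None)
    return max(1, 3 * n_mob - (3 if translation_free else 0))


def _init_velocities(system, config, rng) -> np.ndarray:
    t = config.temperature if config.thermostat is not None else max(
        config.temperature, 1e-12)
    sigma = np.sqrt(KB * t / (system.masses * KE_PER_MV2))
    v = rng.normal(size=(system.n_atoms, 3)) * sigma[:, None]
    v[system.fixed] = 0.0
    if not system.fixed.any():
        mob = system.mobile
        p = (system.masses[mob, None] * v[mob]).sum(axis=0)
        v[mob] -= p / system.masses[mob].sum()
    return v


def run_md(system: MolecularSystem, config: MDConfig,
           params: ForceFieldParams | None = None,
           velocities: np.ndarray | None = None) -> Trajectory:
    """Integrate ``config.n_steps`` steps and return the trajectory.

    Fully deterministic for a given seed.  Aborts with the offending step
    index if forces become non-finite.
    """
    params = params or ForceFieldParams.default()
    ev = Evaluator(system, params, config.restraints)
    rng = np.random.default_rng(config.seed)
    masses = system.masses
    mob = system.mobile
    dt = config.timestep
    x = system.coords.copy()
    v = _init_velocities(system, config, rng) if velocities is None \
        else np.array(velocities, dtype=float)
    v[system.fixed] = 0.0

    nf = _dof(system, config)
    kt = KB * config.temperature
    q_nh = nf * kt * config.coupling ** 2  # Nosé–Hoover inertia
    vxi = 0.0
    gamma = 1.0 / config.coupling          # Langevin friction
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(np.clip(kt / (masses * KE_PER_MV2) * (1.0 - c1 * c1), 0.0, None))

    def nh_half(v):
        nonlocal vxi
        ke2 = 2.0 * _kinetic(masses[mob], v[mob])
        vxi += 0.25 * dt * (ke2 - nf * kt) / q_nh
        v[mob] *= np.exp(-0.5 * dt * vxi)
        ke2 = 2.0 * _kinetic(masses[mob], v[mob])
        vxi += 0.25 * dt * (ke2 - nf * kt) / q_nh
        return v

    br, f = ev.energy_forces(x)
    n_record = config.n_steps // config.stride + 1
    frames = np.empty((n_record, system.n_atoms, 3))
    vels = np.empty_like(frames) if config.store_velocities else None
    times = np.empty(n_record)
    epot = np.empty(n_record)
    ekin = np.empty(n_record)

    def record(slot, step):
        frames[slot] = x
        if vels is not None:
            vels[slot] = v
        times[slot] = step * dt
        epot[slot] = br.total
        ekin[slot] = _kinetic(masses[mob], v[mob])

    record(0, 0)
    slot = 1
    acc = ACC_CONV / masses[:, None]
    for step in range(1, config.n_steps + 1):
        if config.thermostat == "nose-hoover":
            v = nh_half(v)
        v[mob] += 0.5 * dt * (f * acc)[mob]
        if config.thermostat == "langevin":
            x[mob] += 0.5 * dt * v[mob]
            v[mob] = c1 * v[mob] + c2[mob, None] * rng.normal(
                size=(int(mob.sum()), 3))
            x[mob] += 0.5 * dt * v[mob]
        else:
            x[mob] += dt * v[mob]
        br, f = ev.energy_forces(x)
        if not np.isfinite(f).all():
            raise RuntimeError(f"non-finite forces at MD step {step}")
        v[mob] += 0.5 * dt * (f * acc)[mob]
        if config.thermostat == "nose-hoover":
            v = nh_half(v)
        if step % config.stride == 0:
            record(slot, step)
            slot += 1

    return Trajectory(coords=frames, times=times, epot=epot, ekin=ekin,
                      temperature=2.0 * ekin / (nf * KB),
                      config=config, seed=config.seed,
                      final_velocities=v, velocities=vels)


def nvt_run(system: MolecularSystem, config: MDConfig,
            params: ForceFieldParams | None = None,
            velocities: np.ndarray | None = None) -> Trajectory:
    """Constant-temperature run; velocities drawn from Maxwell–Boltzmann at
    the target temperature unless supplied."""
    if config.thermostat is None:
        config = replace(config, thermostat="nose-hoover")
    return run_md(system, config, params, velocities)


def nve_run(system: MolecularSystem, config: MDConfig,
            params: ForceFieldParams | None = None,
            velocities: np.ndarray | None = None) -> Trajectory:
    """Microcanonical run (thermostat off); used for integrator validation."""
    config = replace(config, thermostat=None)
    return run_md(system, config, params, velocities)


def relative_energy_drift(traj: Trajectory) -> float:
    """Max relative total-energy deviation per ps of simulated time."""
    e = traj.etot
    span = traj.times[-1] - traj.times[0]
    if span <= 0:
        return 0.0
    scale = max(abs(e[0]), 1e-12)
    return float(np.max(np.abs(e - e[0])) / scale / (span / 1000.0))


def restrained_relax(system: MolecularSystem, k: float = 10.0,
                     duration_fs: float = 1000.0,
                     config: MDConfig | None = None,
                     params: ForceFieldParams | None = None,
                     ) -> tuple[MolecularSystem, dict]:
    """Thermalize with all peptide atoms tethered to their input positions
    by harmonic springs of constant ``k`` kcal/mol/Å² (the standard
    conformation-preserving pre-equilibration stage), then release.

    Returns the relaxed system and a report with the peptide heavy-atom
    RMSD from the anchors.
    """
    config = config or MDConfig()
    pep = np.flatnonzero(system.segments == "peptide")
    if len(pep) == 0:
        raise ValueError("system has no peptide atoms to restrain")
    anchors = system.coords[pep].copy()
    restraints = Restraints(pep, anchors, k) if k > 0 else None
    n_steps = max(1, int(round(duration_fs / config.timestep)))
    run_cfg = replace(config, n_steps=n_steps, restraints=restraints)
    traj = nvt_run(system, run_cfg, params)
    out = system.with_coords(traj.final_coords)
    heavy = pep[system.elements[pep] != "H"]
    d = out.coords[heavy] - system.coords[heavy]
    rmsd = float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
    report = {"spring_k": k, "duration_fs": duration_fs,
              "heavy_atom_rmsd": rmsd, "n_restrained": len(pep)}
    return out, report


# ---------------------------------------------------------------------------
# explicit water
# ---------------------------------------------------------------------------

def _water_template(rng) -> np.ndarray:
    """One randomly oriented 3-site water (O at origin), 0.9572 Å / 104.52°."""
    r, half = 0.9572, np.radians(104.52 / 2.0)
    local = np.array([
        [0.0, 0.0, 0.0],
        [r * np.sin(half), 0.0, r * np.cos(half)],
        [-r * np.sin(half), 0.0, r * np.cos(half)],
    ])
    # uniform random rotation from a normalized quaternion
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, xq, yq, zq = q
    rot = np.array([
        [1 - 2 * (yq * yq + zq * zq), 2 * (xq * yq - zq * w), 2 * (xq * zq + yq * w)],
        [2 * (xq * yq + zq * w), 1 - 2 * (xq * xq + zq * zq), 2 * (yq * zq - xq * w)],
        [2 * (xq * zq - yq * w), 2 * (yq * zq + xq * w), 1 - 2 * (xq * xq + yq * yq)],
    ])
    return local @ rot.T


def solvate(system: MolecularSystem | None, box,
            count: int | None = None, density: float = 0.997,
            origin=(0.0, 0.0, 0.0), seed: int = 0,
            min_dist: float = 2.4) -> MolecularSystem:
    """Fill ``box`` (Å edge lengths) with 3-site waters around ``system``.

    Either an explicit ``count`` (error if the box cannot host it) or a
    target mass ``density`` in g/cm³.  No water oxygen is placed within
    ``min_dist`` of a solute heavy atom.  ``count=0`` returns the system
    unchanged.
    """
    box = np.asarray(box, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if count == 0:
        return system.copy() if system is not None else system
    rng = np.random.default_rng(seed)
    rho = _WATER_NUMBER_DENSITY * density
    n_target = count if count is not None else int(round(rho * np.prod(box)))
    spacing = rho ** (-1.0 / 3.0)
    n_side = np.maximum(1, np.round(box / spacing).astype(int))
    grids = [origin[d] + (np.arange(n_side[d]) + 0.5) * box[d] / n_side[d]
             for d in range(3)]
    sites = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, 3)

    if system is not None and system.n_atoms:
        heavy = system.coords[system.elements != "H"]
        d2 = ((sites[:, None, :] - heavy[None, :, :]) ** 2).sum(axis=-1)
        sites = sites[(d2 > min_dist ** 2).all(axis=1)]
    if len(sites) < n_target:
        if count is not None:
            raise ValueError(
                f"box too small: requested {count} waters, only {len(sites)} "
                "clash-free sites available")
        n_target = len(sites)  # shortfall: take what fits
    order = rng.permutation(len(sites))[:n_target]
    sites = sites[order]

    n_w = len(sites)
    coords = np.empty((3 * n_w, 3))
    for w, site in enumerate(sites):
        coords[3 * w:3 * w + 3] = site + _water_template(rng)
    start_resid = 1 if system is None else int(system.resids.max()) + 1
    bonds = np.array([[3 * w, 3 * w + 1] for w in range(n_w)]
                     + [[3 * w, 3 * w + 2] for w in range(n_w)], dtype=int)
    water = MolecularSystem(
        names=np.array(["O", "H1", "H2"] * n_w),
        elements=np.array(["O", "H", "H"] * n_w),
        resids=np.repeat(np.arange(start_resid, start_resid + n_w), 3),
        resnames=np.array(["HOH"] * (3 * n_w)),
        segments=np.array(["water"] * (3 * n_w)),
        types=np.array(["OW", "HW", "HW"] * n_w),
        charges=np.array([-0.834, 0.417, 0.417] * n_w),
        coords=coords, bonds=bonds,
    )
    if system is None:
        return water
    return merge_systems(system, water)


def strip_water(system: MolecularSystem) -> MolecularSystem:
    """Inverse of :func:`solvate`: drop every water atom."""
    return system.subset(system.segments != "water")
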