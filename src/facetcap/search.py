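"""STUN-BH global search for low-lying adsorption configurations.

The search couples basin hopping with stochastic tunneling: every proposal
is first relaxed to its local minimum by conjugate-gradient minimization;
a short high-temperature MD burst (500 K, 300 steps, 2 fs by default)
generates the next candidate; and Metropolis acceptance acts on the
tunneled surface

    f(E) = 1 − exp(−γ (E − E_ref)),     E_ref = best energy found so far,

which compresses all barriers above the running best into [0, 1) while
preserving the ordering and location of every local minimum (values below
E_ref map monotonically below 0).  The objective for a peptide-on-slab
system is the Eq.-style binding energy with a rigid slab; for the toy
benchmark problems it is the objective function itself.

The engine is generic over a small problem protocol (``value``,
``minimize``, ``perturb``, optional ``distance``), so the same code is
exercised by the analytic double-well and Lennard-Jones-cluster oracles
that validate it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .forcefield import Evaluator, ForceFieldParams
from .md import MDConfig, run_md
from .system import MolecularSystem, merge_systems

__all__ = [
    "StunBhConfig", "SearchResult", "stun_transform", "local_minimize",
    "perturb_move", "stunbh_iterate", "multistart_search", "multistart_plan",
    "AdsorptionProblem", "LocalMinimum",
]


def stun_transform(e, e_ref: float, gamma: float):
    """Stochastic-tunneling transform f = 1 − exp(−γ (E − E_ref)).

    Zero at the reference energy, strictly increasing in E for any γ > 0,
    and bounded above by 1 — so the ranking of local minima is preserved
    while barriers above E_ref are flattened.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return 1.0 - np.exp(-gamma * (np.asarray(e, dtype=float) - e_ref))


@dataclass
class StunBhConfig:
    """Search schedule and knobs.

    Defaults follow the published protocol: 1000 independent initial
    conformations × 200 STUN-BH iterations each (200,000 total), with
    500 K / 300-step / 2 fs MD perturbation moves.  ``gamma=None`` selects
    auto-calibration from the energy spread of the first iterations so a
    typical spread maps to f ≈ 0.9.
    """

    n_initial_conformations: int = 1000
    iterations_per_start: int = 200
    gamma: float | None = None
    metropolis_temperature: float = 0.15
    cg_tol: float = 1e-4
    cg_max_iter: int = 500
    perturb_md: MDConfig = field(default_factory=lambda: MDConfig(
        timestep=2.0, n_steps=300, temperature=500.0,
        thermostat="nose-hoover", coupling=50.0, stride=300))
    seed: int = 0
    placement_height: tuple[float, float] = (3.0, 8.0)
    dedup_energy_tol: float = 0.1
    dedup_rmsd_tol: float = 0.5
    calibration_window: int = 10

    def __post_init__(self):
        if self.n_initial_conformations < 1 or self.iterations_per_start < 1:
            raise ValueError("counts must be >= 1")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @property
    def planned_iterations(self) -> int:
        return self.n_initial_conformations * self.iterations_per_start


@dataclass
class LocalMinimum:
    """One distinct minimum: configuration, objective value, and how many
    starts converged onto it."""

    value: float
    coords: np.ndarray
    multiplicity: int = 1
    start_index: int = 0


@dataclass
class SearchResult:
    """Ranked outcome of a multistart STUN-BH search."""

    minima: list[LocalMinimum]
    best_per_start: list[float]
    acceptance_rate: float
    planned_iterations: int
    completed_iterations: int
    seed: int
    start_seeds: list[int]
    failures: list[tuple[int, str]]

    @property
    def best(self) -> LocalMinimum:
        return self.minima[0]


# ---------------------------------------------------------------------------
# problem adapters
# ---------------------------------------------------------------------------

class AdsorptionProblem:
    """Peptide-on-slab adsorption as a search problem.

    The state is the full coordinate array; CG minimizes the total
    potential energy of the mobile atoms and the reported objective is the
    single-point binding energy, which for a rigid uncharged-metal slab is
    exactly the peptide–surface interaction term.
    """

    def __init__(self, system: MolecularSystem,
                 params: ForceFieldParams | None = None,
                 cg_tol: float = 1e-4, cg_max_iter: int = 500,
                 perturb_md: MDConfig | None = None):
        self.system = system
        self.params = params or ForceFieldParams.default()
        self.evaluator = Evaluator(system, self.params)
        self.cg_tol = cg_tol
        self.cg_max_iter = cg_max_iter
        self.perturb_md = perturb_md or MDConfig(
            timestep=2.0, n_steps=300, temperature=500.0, stride=300)
        self.mobile = np.flatnonzero(system.mobile)

    def value(self, coords: np.ndarray) -> float:
        br, _ = self.evaluator.energy_forces(coords, want_forces=False)
        return br.e_peptide_surface

    def total_energy(self, coords: np.ndarray) -> float:
        br, _ = self.evaluator.energy_forces(coords, want_forces=False)
        return br.total

    def minimize(self, coords: np.ndarray):
        x_full = np.array(coords, dtype=float)
        mob = self.mobile

        def fun(flat):
            x_full[mob] = flat.reshape(-1, 3)
            br, f = self.evaluator.energy_forces(x_full)
            return br.total, -f[mob].ravel()

        res = optimize.minimize(
            fun, x_full[mob].ravel(), jac=True, method="CG",
            options={"gtol": self.cg_tol, "maxiter": self.cg_max_iter})
        x_full[mob] = res.x.reshape(-1, 3)
        converged = bool(np.max(np.abs(res.jac)) < self.cg_tol) or res.success
        return x_full, self.value(x_full), converged

    def perturb(self, coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        cfg = replace(self.perturb_md, seed=int(rng.integers(2 ** 31 - 1)))
        if cfg.n_steps == 0:
            return np.array(coords, dtype=float)
        traj = run_md(self.system.with_coords(coords), cfg, self.params)
        if not np.isfinite(traj.final_coords).all():
            cfg = replace(cfg, seed=int(rng.integers(2 ** 31 - 1)))
            traj = run_md(self.system.with_coords(coords), cfg, self.params)
            if not np.isfinite(traj.final_coords).all():
                raise RuntimeError("perturbation MD diverged twice")
        return traj.final_coords

    def distance(self, a: np.ndarray, b: np.ndarray) -> float:
        return superposed_rmsd(a[self.mobile], b[self.mobile])


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between two coordinate sets after optimal rigid superposition."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = a @ rot.T - b
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

@dataclass
class LocalMinResult:
    system: MolecularSystem
    energy: float
    converged: bool

    def __iter__(self):
        return iter((self.system, self.energy))


def local_minimize(system: MolecularSystem,
                   params: ForceFieldParams | None = None,
                   tol: float = 1e-4, max_iter: int = 500) -> LocalMinResult:
    """Conjugate-gradient relaxation of the mobile atoms.

    Returns the relaxed system and its objective value: the binding energy
    if the system contains a slab, the total potential energy otherwise.
    Non-convergence returns best-so-far with ``converged=False``.
    """
    problem = AdsorptionProblem(system, params, cg_tol=tol, cg_max_iter=max_iter)
    x, _, converged = problem.minimize(system.coords)
    has_slab = (system.segments == "slab").any()
    value = problem.value(x) if has_slab else problem.total_energy(x)
    return LocalMinResult(system.with_coords(x), value, converged)


def perturb_move(system: MolecularSystem, md_spec: MDConfig | None = None,
                 seed: int = 0,
                 params: ForceFieldParams | None = None) -> MolecularSystem:
    """High-temperature MD move generating the next candidate configuration
    (identity for a 0-step spec); the slab never moves."""
    md_spec = md_spec or MDConfig(timestep=2.0, n_steps=300, temperature=500.0,
                                  stride=300)
    problem = AdsorptionProblem(system, params, perturb_md=md_spec)
    rng = np.random.default_rng(seed)
    return system.with_coords(problem.perturb(system.coords, rng))


def stunbh_engine(problem, x0, config: StunBhConfig, rng: np.random.Generator):
    """Core STUN-BH loop on any problem object; returns
    (best_x, best_value, acceptance_rate, completed_iterations, trace)."""
    x, f_cur, _ = problem.minimize(x0)
    best_x, best_f = x, f_cur
    trace = [f_cur]
    gamma = config.gamma
    spread_samples: list[float] = []
    accepted = proposed = 0
    for _ in range(config.iterations_per_start - 1):
        cand = problem.perturb(x, rng)
        cand_x, f_cand, _ = problem.minimize(cand)
        trace.append(f_cand)
        if f_cand < best_f:
            best_x, best_f = cand_x, f_cand
        g = gamma
        if g is None:
            spread_samples.append(abs(f_cand - best_f))
            if len(spread_samples) >= config.calibration_window:
                spread = float(np.median(spread_samples))
                gamma = math.log(10.0) / max(spread, 1e-9)
                g = gamma
            else:
                g = math.log(10.0) / max(max(spread_samples), 1e-9)
        proposed += 1
        delta = float(stun_transform(f_cand, best_f, g)
                      - stun_transform(f_cur, best_f, g))
        if delta <= 0 or rng.random() < math.exp(
                -delta / config.metropolis_temperature):
            x, f_cur = cand_x, f_cand
            accepted += 1
    rate = accepted / proposed if proposed else 1.0
    return best_x, best_f, rate, config.iterations_per_start, trace


def stunbh_iterate(system: MolecularSystem, config: StunBhConfig,
                   params: ForceFieldParams | None = None,
                   seed: int | None = None) -> tuple[MolecularSystem, float]:
    """One STUN-BH start on a peptide/slab system: minimize → perturb →
    minimize → Metropolis-accept on the tunneled surface.  Returns the
    per-start best configuration and its binding energy."""
    problem = AdsorptionProblem(system, params, cg_tol=config.cg_tol,
                                cg_max_iter=config.cg_max_iter,
                                perturb_md=config.perturb_md)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    best_x, best_f, _, _, _ = stunbh_engine(problem, system.coords, config, rng)
    return system.with_coords(best_x), best_f


def multistart_plan(config: StunBhConfig) -> dict:
    """Schedule bookkeeping without executing anything: per-start seeds and
    the total planned iteration count."""
    seeds = [int(s.generate_state(1)[0] % (2 ** 31 - 1))
             for s in np.random.SeedSequence(config.seed).spawn(
                 config.n_initial_conformations)]
    return {
        "n_starts": config.n_initial_conformations,
        "iterations_per_start": config.iterations_per_start,
        "planned_iterations": config.planned_iterations,
        "start_seeds": seeds,
    }


def _random_placement(peptide: MolecularSystem, slab, config: StunBhConfig,
                      rng: np.random.Generator) -> MolecularSystem:
    """Random rigid orientation and lateral position, base height drawn in
    the configured window above the top layer; clashes resolved by lifting."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, xq, yq, zq = q
    rot = np.array([
        [1 - 2 * (yq ** 2 + zq ** 2), 2 * (xq * yq - zq * w), 2 * (xq * zq + yq * w)],
        [2 * (xq * yq + zq * w), 1 - 2 * (xq ** 2 + zq ** 2), 2 * (yq * zq - xq * w)],
        [2 * (xq * zq - yq * w), 2 * (yq * zq + xq * w), 1 - 2 * (xq ** 2 + yq ** 2)],
    ])
    x = peptide.coords - peptide.coords.mean(axis=0)
    x = x @ rot.T
    frac = rng.random(2)
    lateral = frac @ slab.surface_vectors
    lo, hi = config.placement_height
    height = lo + (hi - lo) * rng.random()
    x[:, :2] += lateral
    x[:, 2] += height + slab.top_z - x[:, 2].min()
    while True:
        dz = x[:, 2].min() - slab.top_z
        d2 = ((x[:, None, :] - slab.coords[None, :, :]) ** 2).sum(axis=-1)
        if d2.min() >= 4.0 or dz > hi:  # lift until nothing sits closer than 2 Å
            break
        x[:, 2] += 0.25
    return peptide.with_coords(x)


def multistart_search(peptide: MolecularSystem, slab,
                      config: StunBhConfig,
                      params: ForceFieldParams | None = None) -> SearchResult:
    """Full multistart STUN-BH search of a peptide over a slab.

    Runs ``n_initial_conformations`` independent starts with dedicated
    seed streams, deduplicates the per-start minima by energy (and RMSD
    when closer than the energy tolerance), and ranks them by ascending
    binding energy.  A failing start is recorded, not fatal.
    """
    plan = multistart_plan(config)
    minima: list[LocalMinimum] = []
    best_per_start: list[float] = []
    rates: list[float] = []
    completed = 0
    failures: list[tuple[int, str]] = []
    for start, start_seed in enumerate(plan["start_seeds"]):
        rng = np.random.default_rng(start_seed)
        try:
            placed = _random_placement(peptide, slab, config, rng)
            complex_system = merge_systems(placed, slab.system)
            problem = AdsorptionProblem(
                complex_system, params, cg_tol=config.cg_tol,
                cg_max_iter=config.cg_max_iter, perturb_md=config.perturb_md)
            best_x, best_f, rate, iters, _ = stunbh_engine(
                problem, complex_system.coords, config, rng)
        except Exception as exc:  # noqa: BLE001 - per-start isolation
            failures.append((start, f"{type(exc).__name__}: {exc}"))
            continue
        completed += iters
        rates.append(rate)
        best_per_start.append(best_f)
        _merge_minimum(minima, best_x, best_f, start, config, problem)
    minima.sort(key=lambda m: m.value)
    return SearchResult(
        minima=minima, best_per_start=best_per_start,
        acceptance_rate=float(np.mean(rates)) if rates else 0.0,
        planned_iterations=plan["planned_iterations"],
        completed_iterations=completed, seed=config.seed,
        start_seeds=plan["start_seeds"], failures=failures)


def _merge_minimum(minima, x, value, start, config, problem):
    for m in minima:
        if abs(m.value - value) < config.dedup_energy_tol:
            dist = problem.distance(m.coords, x) if hasattr(problem, "distance") \
                else 0.0
            if dist < config.dedup_rmsd_tol:
                m.multiplicity += 1
                return
    minima.append(LocalMinimum(value=value, coords=x, start_index=start))
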