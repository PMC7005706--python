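"""STUN transform properties, CG minimization, and global-search oracles."""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from facetcap.fixtures import make_fixture
from facetcap.md import MDConfig
from facetcap.search import (StunBhConfig, local_minimize, multistart_plan,
                             multistart_search, perturb_move, stun_transform,
                             stunbh_engine, stunbh_iterate)
from facetcap.system import MolecularSystem


def lj_trimer(params, perturbation=0.0, seed=0):
    eps, sigma = params.lj_params("CT")
    r = 2.0 ** (1.0 / 6.0) * sigma
    base = np.array([[0, 0, 0], [r, 0, 0], [r / 2, r * np.sqrt(3) / 2, 0]])
    if perturbation:
        base = base + perturbation * np.random.default_rng(seed).normal(
            size=base.shape)
    n = 3
    return MolecularSystem(
        names=np.array([f"X{i}" for i in range(n)]),
        elements=np.array(["C"] * n), resids=np.arange(1, n + 1),
        resnames=np.array(["BNZ"] * n), segments=np.array(["probe"] * n),
        types=np.array(["CT"] * n), charges=np.zeros(n), coords=base)


class TestStunTransform:
    def test_zero_at_reference(self):
        assert stun_transform(-12.5, -12.5, 0.7) == 0.0

    def test_half_at_log_two_over_gamma(self):
        gamma = 0.31
        assert stun_transform(np.log(2.0) / gamma, 0.0, gamma) == pytest.approx(
            0.5, rel=1e-12)

    @given(st.floats(-50, 50), st.floats(-50, 50), st.floats(0.01, 5.0))
    @settings(max_examples=100, deadline=None)
    def test_strictly_monotone_and_bounded(self, e1, e2, gamma):
        assume(abs(e1 - e2) > 1e-9)  # resolvable at double precision
        assume(gamma * max(e1, e2) < 30.0)  # below exp() saturation
        f1 = float(stun_transform(e1, 0.0, gamma))
        f2 = float(stun_transform(e2, 0.0, gamma))
        if e1 < e2:
            assert f1 < f2
        assert f1 < 1.0 and f2 < 1.0

    def test_order_preservation_of_minima(self):
        """Ranking minima by raw energy equals ranking by transformed
        energy for any reference and gamma."""
        energies = np.array([-20.0, -18.5, -12.0, -25.1])
        f = stun_transform(energies, energies.min(), 0.4)
        assert np.array_equal(np.argsort(energies), np.argsort(f))

    def test_rejects_nonpositive_gamma(self):
        with pytest.raises(ValueError):
            stun_transform(1.0, 0.0, 0.0)


class TestLocalMinimize:
    def test_lj_trimer_reaches_minus_three_eps(self, params):
        eps, _ = params.lj_params("CT")
        system = lj_trimer(params, perturbation=0.12, seed=3)
        relaxed, energy = local_minimize(system, params, tol=1e-7,
                                         max_iter=1000)
        assert energy == pytest.approx(-3 * eps, rel=1e-6)

    def test_start_at_minimum_is_stationary(self, params):
        system = lj_trimer(params)
        res = local_minimize(system, params, tol=1e-5, max_iter=100)
        assert res.converged
        assert np.abs(res.system.coords - system.coords).max() < 1e-4

    def test_energy_never_increases(self, tripeptide_complex, params):
        system, _ = tripeptide_complex
        from facetcap.forcefield import binding_energy
        e_in = binding_energy(system, params=params)
        _, e_out = local_minimize(system, params, tol=1e-3, max_iter=150)
        assert e_out <= e_in


class TestPerturbMove:
    def test_zero_steps_is_identity(self, tripeptide_complex):
        system, _ = tripeptide_complex
        spec = MDConfig(timestep=2.0, n_steps=0, temperature=500.0, stride=1)
        out = perturb_move(system, spec, seed=1)
        assert np.array_equal(out.coords, system.coords)

    def test_same_seed_same_candidate(self, tripeptide_complex):
        system, _ = tripeptide_complex
        spec = MDConfig(timestep=2.0, n_steps=50, temperature=500.0, stride=50)
        a = perturb_move(system, spec, seed=42)
        b = perturb_move(system, spec, seed=42)
        assert np.array_equal(a.coords, b.coords)

    def test_thermal_displacement_and_rigid_slab(self, tripeptide_complex):
        system, _ = tripeptide_complex
        out = perturb_move(system, seed=7)  # 500 K, 300 steps, 2 fs default
        heavy = (system.segments == "peptide") & (system.elements != "H")
        rmsd = np.sqrt(np.mean(np.sum(
            (out.coords[heavy] - system.coords[heavy]) ** 2, axis=1)))
        assert rmsd > 0.1
        assert np.array_equal(out.coords[system.fixed],
                              system.coords[system.fixed])


class TestSchedule:
    def test_paper_schedule_counts_200k(self):
        cfg = StunBhConfig(n_initial_conformations=1000,
                           iterations_per_start=200)
        assert cfg.planned_iterations == 200_000
        plan = multistart_plan(cfg)
        assert plan["planned_iterations"] == 200_000
        assert len(plan["start_seeds"]) == 1000
        assert all(0 <= s < 2 ** 31 for s in plan["start_seeds"])

    def test_plan_is_seed_deterministic(self):
        a = multistart_plan(StunBhConfig(n_initial_conformations=8, seed=5))
        b = multistart_plan(StunBhConfig(n_initial_conformations=8, seed=5))
        assert a == b

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            StunBhConfig(n_initial_conformations=0)


class TestEngineOracles:
    def test_double_well_global_minimum_rate(self):
        """The brute-force grid locates the global minimum; STUN-BH must
        find it in at least 95 % of 50 seeded runs."""
        fx = make_fixture("double_well")
        problem = fx.payload
        cfg = StunBhConfig(n_initial_conformations=1, iterations_per_start=30)
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            _, best_f, _, _, _ = stunbh_engine(problem, problem.initial(rng),
                                               cfg, rng)
            hits += abs(best_f - fx.oracle["global_min_f"]) < 1e-6
        assert hits >= 48  # >= 95 %

    @pytest.mark.parametrize("name,iters", [("lj3", 30), ("lj4", 40)])
    def test_lj_cluster_minima_found(self, name, iters):
        fx = make_fixture(name)
        problem = fx.payload
        cfg = StunBhConfig(n_initial_conformations=10,
                           iterations_per_start=iters)
        best = np.inf
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            _, f, _, _, _ = stunbh_engine(problem, problem.initial(rng), cfg,
                                          rng)
            best = min(best, f)
        assert best == pytest.approx(fx.oracle["global_min"], abs=1e-5)

    def test_best_never_worsens_with_more_iterations(self):
        fx = make_fixture("double_well")
        problem = fx.payload
        for seed in (3, 4):
            bests = {}
            for iters in (5, 25):
                cfg = StunBhConfig(n_initial_conformations=1,
                                   iterations_per_start=iters)
                rng = np.random.default_rng(seed)
                _, bests[iters], _, _, _ = stunbh_engine(
                    problem, problem.initial(rng), cfg, rng)
            assert bests[25] <= bests[5] + 1e-12

    def test_trace_running_best_monotone(self):
        fx = make_fixture("lj4")
        problem = fx.payload
        cfg = StunBhConfig(n_initial_conformations=1, iterations_per_start=25)
        rng = np.random.default_rng(0)
        _, _, _, _, trace = stunbh_engine(problem, problem.initial(rng), cfg,
                                          rng)
        running = np.minimum.accumulate(trace)
        assert np.all(np.diff(running) <= 0.0 + 1e-15)


class TestAdsorptionSearch:
    def test_single_iteration_equals_local_minimize(self, tripeptide_complex,
                                                    params):
        system, _ = tripeptide_complex
        cfg = StunBhConfig(n_initial_conformations=1, iterations_per_start=1,
                           cg_tol=1e-3, cg_max_iter=150)
        best, e_best = stunbh_iterate(system, cfg, params, seed=1)
        _, e_cg = local_minimize(system, params, tol=1e-3, max_iter=150)
        assert e_best == pytest.approx(e_cg, rel=1e-9)

    def test_multistart_reproducible_and_bookkept(self, tripeptide_complex,
                                                  params):
        system, slab = tripeptide_complex
        pep = system.subset(system.segments == "peptide")
        cfg = StunBhConfig(
            n_initial_conformations=2, iterations_per_start=2, seed=12,
            cg_tol=1e-3, cg_max_iter=60,
            perturb_md=MDConfig(timestep=2.0, n_steps=60, temperature=500.0,
                                stride=60))
        a = multistart_search(pep, slab, cfg, params)
        b = multistart_search(pep, slab, cfg, params)
        assert a.completed_iterations == cfg.planned_iterations == 4
        assert [m.value for m in a.minima] == [m.value for m in b.minima]
        assert a.best_per_start == b.best_per_start
        assert a.failures == []
        # ranked ascending; best bounded by every per-start best
        values = [m.value for m in a.minima]
        assert values == sorted(values)
        assert all(a.best.value <= v + 1e-12 for v in a.best_per_start)
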