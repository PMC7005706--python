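"""Energy terms, analytic forces, binding energy, and decomposition."""

import numpy as np
import pytest
from scipy import optimize

from facetcap.forcefield import (Evaluator, binding_energy,
                                 per_residue_binding, total_energy)
from facetcap.system import MolecularSystem
from conftest import finite_difference_force_error


def make_sites(types, coords, charges=None, segments=None, bonds=(),
               resids=None):
    n = len(types)
    return MolecularSystem(
        names=np.array([f"X{i}" for i in range(n)]),
        elements=np.array(["C"] * n),
        resids=np.arange(1, n + 1) if resids is None else np.array(resids),
        resnames=np.array(["SLB" if (segments or ["x"] * n)[i] == "slab"
                           else "BNZ" for i in range(n)]),
        segments=np.array(segments or ["probe"] * n),
        types=np.array(types),
        charges=np.zeros(n) if charges is None else np.array(charges, float),
        coords=np.array(coords, float),
        bonds=np.array(bonds, int).reshape(-1, 2),
    )


class TestLennardJones:
    def test_dimer_at_minimum_gives_minus_eps(self, params):
        eps, sigma = params.lj_params("CT")
        r = 2.0 ** (1.0 / 6.0) * sigma
        s = make_sites(["CT", "CT"], [[0, 0, 0], [r, 0, 0]])
        br = total_energy(s, params)
        assert br.e_lj == pytest.approx(-eps, rel=1e-12)
        assert br.total == pytest.approx(-eps, rel=1e-12)

    def test_beyond_cutoff_is_zero(self, params):
        s = make_sites(["CT", "CT"], [[0, 0, 0], [params.cutoff + 0.5, 0, 0]],
                       charges=[0.4, -0.4])
        assert total_energy(s, params).total == 0.0

    def test_tetrahedron_reaches_minus_six_eps(self, params):
        """Four LJ sites: the global minimum puts all six pairs at the pair
        minimum (regular tetrahedron).  Verified by an independent
        numerical minimization from a perturbed tetrahedron."""
        eps, sigma = params.lj_params("CT")
        r = 2.0 ** (1.0 / 6.0) * sigma
        base = r * np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
                             [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)]])
        s = make_sites(["CT"] * 4, base)
        assert total_energy(s, params).total == pytest.approx(-6 * eps, rel=1e-9)

        ev = Evaluator(s, params)

        def fun(flat):
            br, f = ev.energy_forces(flat.reshape(4, 3))
            return br.total, -f.ravel()

        rng = np.random.default_rng(1)
        x0 = (base + 0.15 * rng.normal(size=base.shape)).ravel()
        res = optimize.minimize(fun, x0, jac=True, method="CG")
        assert res.fun == pytest.approx(-6 * eps, rel=1e-6)

    def test_switching_window_continuous_and_monotone(self, params):
        eps, sigma = params.lj_params("CT")
        rs, rc = params.switch_start, params.cutoff

        def pair_energy(r):
            s = make_sites(["CT", "CT"], [[0, 0, 0], [r, 0, 0]],
                           charges=[0.2, -0.2])
            return total_energy(s, params).total

        # continuity at both window edges (tolerance covers the physical
        # slope over the probe interval)
        assert pair_energy(rs - 1e-7) == pytest.approx(pair_energy(rs + 1e-7),
                                                       abs=1e-6)
        assert pair_energy(rc - 1e-7) == pytest.approx(0.0, abs=1e-9)
        # |E| decreases monotonically to 0 across the window
        rr = np.linspace(rs, rc, 60)
        vals = np.abs([pair_energy(r) for r in rr])
        assert np.all(np.diff(vals) <= 1e-12)
        assert vals[-1] == pytest.approx(0.0, abs=1e-12)

    def test_missing_type_error_names_type(self, params):
        s = make_sites(["CT", "ZZ"], [[0, 0, 0], [3, 0, 0]])
        with pytest.raises(KeyError, match="ZZ"):
            total_energy(s, params)


class TestForces:
    def test_newton_third_law_dimer(self, params):
        s = make_sites(["CT", "CT"], [[0, 0, 0], [3.1, 0, 0]],
                       charges=[0.3, -0.3])
        _, f = Evaluator(s, params).energy_forces()
        assert np.allclose(f[0], -f[1], atol=1e-12)

    def test_forces_match_numerical_gradient(self, tripeptide_complex, params):
        system, _ = tripeptide_complex
        assert finite_difference_force_error(system, params) < 1e-4

    def test_force_vanishes_at_minimum(self, params):
        from facetcap.search import local_minimize
        eps, sigma = params.lj_params("CT")
        r = 2.0 ** (1.0 / 6.0) * sigma
        s = make_sites(["CT"] * 3,
                       [[0, 0, 0], [r, 0, 0], [r / 2, r * np.sqrt(3) / 2, 0]])
        relaxed, e = local_minimize(s, params, tol=1e-8, max_iter=500)
        _, f = Evaluator(relaxed, params).energy_forces()
        assert np.abs(f).max() < 1e-6

    def test_fixed_atoms_report_zero_force(self, tripeptide_complex, params):
        system, _ = tripeptide_complex
        _, f = Evaluator(system, params).energy_forces()
        assert np.all(f[system.fixed] == 0.0)


class TestInvariance:
    def test_rigid_translation_rotation(self, s7_peptide, params):
        e0 = total_energy(s7_peptide, params).total
        shifted = s7_peptide.translate([5.0, -3.0, 2.0])
        assert total_energy(shifted, params).total == pytest.approx(
            e0, rel=1e-8)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        rotated = s7_peptide.with_coords(s7_peptide.coords @ rot.T)
        assert total_energy(rotated, params).total == pytest.approx(
            e0, rel=1e-8)

    def test_breakdown_total_is_component_sum(self, tripeptide_complex, params):
        system, _ = tripeptide_complex
        br = total_energy(system, params)
        parts = (br.e_bond + br.e_angle + br.e_dihedral + br.e_improper
                 + br.e_lj + br.e_coulomb + br.e_restraint)
        assert br.total == pytest.approx(parts, rel=1e-12)


class TestBindingEnergy:
    def test_single_pair_oracle(self, params):
        """One probe LJ site at the mixed-pair minimum above one metal site:
        the binding energy is exactly −ε_mix."""
        eps_c, sig_c = params.lj_params("CT")
        eps_m, sig_m = params.lj_params("AU")
        eps_mix = np.sqrt(eps_c * eps_m)
        r = 2.0 ** (1.0 / 6.0) * 0.5 * (sig_c + sig_m)
        s = make_sites(["CT", "AU"], [[0, 0, r], [0, 0, 0]],
                       segments=["peptide", "slab"])
        s.resnames[0] = "BNZ"
        assert binding_energy(s, params=params) == pytest.approx(
            -eps_mix, rel=1e-9)

    def test_separated_fragments_give_exact_zero(self, tripeptide_complex,
                                                 params):
        system, _ = tripeptide_complex
        x = system.coords.copy()
        pep = system.segments == "peptide"
        x[pep, 2] += params.cutoff + 10.0
        assert binding_energy(system.with_coords(x), params=params) == 0.0

    def test_equals_surface_interaction_term(self, tripeptide_complex, params):
        """Single-point Eq.-1 arithmetic: complex minus fragments reduces to
        the peptide-surface nonbonded term for a rigid uncharged slab."""
        system, _ = tripeptide_complex
        br = total_energy(system, params)
        assert binding_energy(system, params=params) == pytest.approx(
            br.e_peptide_surface, rel=1e-9)

    def test_mismatched_components_rejected(self, tripeptide_complex, params):
        system, _ = tripeptide_complex
        pep = system.subset(system.segments == "peptide")
        sub = system.subset(system.segments == "slab")
        short = pep.subset(np.arange(pep.n_atoms) < pep.n_atoms - 1)
        with pytest.raises(ValueError):
            binding_energy(system, short, sub, params)


class TestPerResidueBinding:
    def test_profile_sums_to_surface_total(self, tripeptide_complex, params):
        system, _ = tripeptide_complex
        prof = per_residue_binding(system, params)
        br = total_energy(system, params)
        assert prof.total == pytest.approx(br.e_peptide_surface, rel=1e-8)
        assert len(prof) == 3  # caps folded into terminal residues

    def test_far_peptide_gives_zero_profile(self, tripeptide_complex, params):
        system, _ = tripeptide_complex
        x = system.coords.copy()
        x[system.segments == "peptide", 2] += 40.0
        prof = per_residue_binding(system.with_coords(x), params)
        assert np.allclose(prof.energies, 0.0)

    def test_two_group_toy_decomposition(self, params):
        """Only the second 'residue' touches the slab: the profile must be
        [0, E_peptide_surface]."""
        s = make_sites(
            ["CT", "CT", "AU"],
            [[0, 0, 40.0], [0, 0, 3.5], [0, 0, 0]],
            segments=["peptide", "peptide", "slab"], resids=[1, 2, 3])
        s.resnames[:2] = "BNZ"
        prof = per_residue_binding(s, params)
        br = total_energy(s, params)
        assert prof.energies[0] == 0.0
        assert prof.energies[1] == pytest.approx(br.e_peptide_surface, rel=1e-9)

    def test_unlabeled_complex_rejected(self, params):
        s = make_sites(["CT", "AU"], [[0, 0, 3], [0, 0, 0]],
                       segments=["probe", "slab"])
        with pytest.raises(ValueError):
            per_residue_binding(s, params)
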