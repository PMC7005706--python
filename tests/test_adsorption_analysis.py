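"""Ring orientation, lock-and-key registry, comparison tables, mobility."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from facetcap.analysis import (detect_lak, environment_comparison, mobility,
                               percent_difference, ring_orientation)
from facetcap.fixtures import make_benzene_probe, make_fixture
from facetcap.peptide import build_conformation, parse_capped_sequence
from facetcap.slab import build_fcc_slab
from facetcap.system import merge_systems


@pytest.fixture(scope="module")
def flat_probe():
    return make_fixture("benzene_flat_on_au").payload


class TestRingOrientation:
    def test_flat_benzene(self, flat_probe):
        coords = flat_probe["system"].coords[flat_probe["ring"]]
        orientation, tilt, height = ring_orientation(coords,
                                                     flat_probe["slab"])
        assert orientation == "flat-on"
        assert tilt == pytest.approx(0.0, abs=1e-6)
        assert height == pytest.approx(3.5, abs=1e-6)

    def test_rotated_ring_stands_up(self):
        fx = make_fixture("benzene_standup_on_au").payload
        coords = fx["system"].coords[fx["ring"]]
        orientation, tilt, _ = ring_orientation(coords, fx["slab"])
        assert orientation == "stand-up"
        assert tilt == pytest.approx(90.0, abs=1e-6)

    def test_high_ring_detached(self, flat_probe):
        coords = flat_probe["system"].coords[flat_probe["ring"]].copy()
        coords[:, 2] += 15.0
        orientation, _, height = ring_orientation(coords, flat_probe["slab"])
        assert orientation == "detached" and height > 15.0

    def test_nonplanar_ring_intermediate(self, flat_probe):
        coords = flat_probe["system"].coords[flat_probe["ring"]].copy()
        coords[::2, 2] += 0.8  # strong chair-like distortion
        orientation, _, _ = ring_orientation(coords, flat_probe["slab"])
        assert orientation == "intermediate"

    def test_wrong_ring_size_rejected(self, flat_probe):
        with pytest.raises(ValueError):
            ring_orientation(np.zeros((4, 3)), flat_probe["slab"])

    def test_orientation_classes_partition(self, flat_probe):
        """Every ring gets exactly one of the four classes."""
        rng = np.random.default_rng(0)
        slab = flat_probe["slab"]
        for _ in range(25):
            c = rng.normal(size=3) * [3, 3, 1]
            c[2] = abs(c[2]) + rng.uniform(2.0, 10.0) + slab.top_z
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ref = np.array([0.0, 0.0, 1.0])
            v = np.cross(ref, axis)
            s, cth = np.linalg.norm(v), float(ref @ axis)
            rot = np.eye(3) if s < 1e-12 else (
                np.eye(3) + _skew(v) + _skew(v) @ _skew(v) * (1 - cth) / s ** 2)
            ang = np.radians(60.0 * np.arange(6))
            ring = np.stack([1.4 * np.cos(ang), 1.4 * np.sin(ang),
                             np.zeros(6)], 1) @ rot.T + c
            orientation, tilt, _ = ring_orientation(ring, slab)
            assert orientation in ("flat-on", "stand-up", "intermediate",
                                   "detached")
            assert 0.0 <= tilt <= 90.0


def _skew(v):
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])


class TestLakDetection:
    def test_centered_flat_ring_is_lak(self, flat_probe):
        report = detect_lak(flat_probe["system"], flat_probe["slab"],
                            rings=[flat_probe["ring"]])
        rec = report.records[0]
        assert rec.lak and rec.orientation == "flat-on"
        # carbons alternate over second-/third-layer sites (the hexagonal
        # subsurface lattice the ring keys into)
        assert set(rec.atom_sites) == {"second", "third"}
        assert rec.atom_sites[::2] != rec.atom_sites[1::2]

    def test_half_lattice_shift_breaks_lak(self):
        fx = make_fixture("benzene_shifted_on_au").payload
        report = detect_lak(fx["system"], fx["slab"], rings=[fx["ring"]])
        assert report.records[0].orientation == "flat-on"
        assert not report.records[0].lak

    def test_standup_ring_not_lak(self):
        fx = make_fixture("benzene_standup_on_au").payload
        report = detect_lak(fx["system"], fx["slab"], rings=[fx["ring"]])
        assert not report.records[0].lak

    def test_ringless_peptide_empty_report(self):
        slab = build_fcc_slab(n_layers=3, repeats=(5, 5))
        pep = build_conformation(parse_capped_sequence("Ac-SS-NH2"))
        system = merge_systems(pep, slab.system)
        assert len(detect_lak(system, slab)) == 0

    def test_lattice_translation_invariance(self):
        base = make_fixture("benzene_flat_on_au").payload
        rec0 = detect_lak(base["system"], base["slab"],
                          rings=[base["ring"]]).records[0]
        d = base["slab"].nn_distance
        a1 = d * np.array([1.0, 0.0])
        a2 = d * np.array([0.5, np.sqrt(3) / 2])
        for shift in (a1, a2, 2 * a1 - a2):
            sys2, slab, ring = make_benzene_probe("flat", lateral_shift=shift)
            rec = detect_lak(sys2, slab, rings=[ring]).records[0]
            assert rec.lak == rec0.lak
            assert rec.orientation == rec0.orientation
            assert rec.atom_sites == rec0.atom_sites

    def test_sixty_degree_rotation_invariance(self, flat_probe):
        """A six-ring rotated 60° about its own centroid axis is the same
        lock-and-key geometry."""
        system = flat_probe["system"].copy()
        ring = flat_probe["ring"]
        coords = system.coords.copy()
        centroid = coords[ring].mean(axis=0)
        th = np.radians(60.0)
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        probe = system.segments == "probe"
        coords[probe] = (coords[probe] - centroid) @ rot.T + centroid
        rec = detect_lak(system.with_coords(coords), flat_probe["slab"],
                         rings=[ring]).records[0]
        assert rec.lak
        assert set(rec.atom_sites) == {"second", "third"}


class TestEnvironmentComparison:
    def test_printed_vacuum_contrast(self):
        """Vacuum adsorption energies −250.06 vs −252.84 kcal/mol differ by
        about 1.1 % (reference: the deeper configuration)."""
        pct = percent_difference(-250.06, -252.84)
        assert abs(pct) == pytest.approx(1.1, abs=0.05)

    def test_printed_water_contrast(self):
        """Water values −235.23 vs −210.26 kcal/mol: ≈11.9 % contrast (the
        printed energies carry ~0.01-point rounding)."""
        pct = percent_difference(-235.23, -210.26)
        assert abs(pct) == pytest.approx(11.89, abs=0.05)

    def test_identical_inputs_zero(self):
        assert percent_difference(-210.0, -210.0) == 0.0

    @given(st.floats(-400, -10), st.floats(-400, -10))
    @settings(max_examples=60, deadline=None)
    def test_reference_swap_identity(self, a, b):
        """(1 + p_ab/100)(1 + p_ba/100) = 1: antisymmetry up to the change
        of reference."""
        p_ab = percent_difference(a, b)
        p_ba = percent_difference(b, a)
        assert (1 + p_ab / 100) * (1 + p_ba / 100) == pytest.approx(1.0,
                                                                    rel=1e-9)

    def test_table_from_series_and_values(self):
        series = np.concatenate([np.full(50, -180.0), np.full(50, -235.23)])
        table = environment_comparison(
            {"S7-1": (-250.06, series), "S7-2": (-252.84, -210.26)})
        assert table.water[0] == pytest.approx(-235.23, rel=1e-3)
        assert abs(table.percent("S7-1", "S7-2", "vacuum")) == pytest.approx(
            1.1, abs=0.05)
        assert abs(table.percent("S7-1", "S7-2", "water")) == pytest.approx(
            11.89, abs=0.1)
        text = table.to_text()
        assert "S7-1" in text and "vacuum" in text

    def test_mismatched_profiles_rejected(self):
        with pytest.raises(ValueError):
            environment_comparison(
                {"a": (-1.0, -1.0), "b": (-2.0, -2.0)},
                profiles={"a": np.zeros(7), "b": np.zeros(8)})


class TestMobility:
    def _traj(self, coords_list):
        class T:
            coords = np.array(coords_list)
        return T()

    def test_static_trajectory_zero(self, tripeptide_complex):
        system, slab = tripeptide_complex
        traj = self._traj([system.coords] * 4)
        rep = mobility(traj, system, slab)
        assert np.allclose(rep.displacement, 0.0)

    def test_rigid_translation_pythagoras(self, tripeptide_complex):
        system, slab = tripeptide_complex
        moved = system.coords + np.array([3.0, 4.0, 0.0])
        rep = mobility(self._traj([system.coords, moved]), system, slab)
        assert rep.max == pytest.approx(5.0, abs=1e-9)

    def test_lattice_walk_unwraps(self, tripeptide_complex):
        """A gradual drift of one full surface lattice vector, with frames
        wrapped into the cell, must unwrap to the lattice-vector length."""
        system, slab = tripeptide_complex
        vec3 = np.array([*slab.surface_vectors[0], 0.0])
        frames = []
        inplane = slab.surface_vectors
        pep = system.segments == "peptide"
        masses = system.masses[pep]
        for t in np.linspace(0.0, 1.0, 9):
            x = system.coords + t * vec3
            com = masses @ x[pep, :2] / masses.sum()
            wrap = np.floor(np.linalg.solve(inplane.T, com))
            x[pep, :2] -= wrap @ inplane  # rigid wrap into the home cell
            frames.append(x)
        rep = mobility(self._traj(frames), system, slab)
        assert rep.displacement[-1] == pytest.approx(
            np.linalg.norm(vec3), rel=1e-6)
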