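import numpy as np
import pytest

from facetcap.forcefield import ForceFieldParams
from facetcap.md import MDConfig, nvt_run
from facetcap.peptide import build_conformation, parse_capped_sequence
from facetcap.fixtures import make_tripeptide_on_slab


@pytest.fixture(scope="session")
def params():
    return ForceFieldParams.default()


@pytest.fixture(scope="session")
def s7_peptide():
    """Built S7 conformation (Ac-SSFPQPN-NH2), relaxed, deterministic."""
    return build_conformation(parse_capped_sequence("Ac-SSFPQPN-NH2"))


@pytest.fixture(scope="session")
def tripeptide_complex():
    """Toy capped Ser-Phe-Ser on a rigid 3-layer (111) slab (198 atoms)."""
    return make_tripeptide_on_slab()


@pytest.fixture(scope="session")
def s7_nvt_trajectory(s7_peptide):
    """4 ps production-style NVT run of S7 in vacuum at 300 K
    (110 mobile atoms), shared by thermostat checks."""
    cfg = MDConfig(timestep=0.5, n_steps=8000, temperature=300.0,
                   thermostat="nose-hoover", coupling=50.0, seed=3, stride=20)
    return nvt_run(s7_peptide, cfg)


@pytest.fixture(scope="session")
def toy_nve(tripeptide_complex):
    """Warm-started 1 ps NVE run of the toy adsorption fixture at 0.5 fs."""
    from facetcap.md import nve_run

    system, _ = tripeptide_complex
    warm = nvt_run(system, MDConfig(timestep=0.5, n_steps=400,
                                    temperature=300.0, seed=1, stride=400))
    start = system.with_coords(warm.final_coords)
    traj = nve_run(start, MDConfig(timestep=0.5, n_steps=2000,
                                   thermostat=None, temperature=1.0, stride=10),
                   velocities=warm.final_velocities)
    return traj


def finite_difference_force_error(system, params, n_probes=12, seed=0):
    """Max relative error between analytic forces and central differences."""
    from facetcap.forcefield import Evaluator

    ev = Evaluator(system, params)
    _, f = ev.energy_forces()
    rng = np.random.default_rng(seed)
    mobile = np.flatnonzero(system.mobile)
    h = 1e-5
    worst = 0.0
    x = system.coords
    for _ in range(n_probes):
        i = int(rng.choice(mobile))
        d = int(rng.integers(3))
        xp = x.copy(); xp[i, d] += h
        xm = x.copy(); xm[i, d] -= h
        ep = ev.energy_forces(xp, want_forces=False)[0].total
        em = ev.energy_forces(xm, want_forces=False)[0].total
        num = -(ep - em) / (2 * h)
        worst = max(worst, abs(num - f[i, d]) / max(1.0, abs(num)))
    return worst
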