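# Methods

This note documents the models, parameters, numerical choices and known
limitations of `facetcap`.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Molecular model

**Residue alphabet.** Ser, Phe, Pro, Gln, Asn plus acetyl (ACE) and
C-terminal amide (NH2) caps — the alphabet of the S7/PF8/FS8 capping
candidates.  Each residue template carries atom names, elements, MM atom
types, partial charges, intra-residue bonds, ring membership (Phe six-ring,
Pro five-ring) and idealized reference coordinates taken from biotite's
bundled Chemical Component Dictionary geometry.

**Force field.** A reduced Amber-class table shipped as
`src/facetcap/data/forcefield.toml` (human-readable, versioned):

- harmonic bonds `E = k (r − r0)²` and angles `E = k (θ − θ0)²`;
- cosine proper torsions `E = k (1 + cos(nφ − φ0))` matched on the central
  bond, plus harmonic-cosine impropers (n = 2, φ0 = 180°) auto-generated
  for every three-coordinated sp² center (carbonyl C, aromatic C, amide N)
  to keep them planar;
- 12-6 Lennard-Jones with Lorentz–Berthelot combining and point-charge
  Coulomb (332.0637 q₁q₂/r kcal/mol); 1-2/1-3 pairs excluded, 1-4 pairs
  scaled by 1/2 (LJ) and 1/1.2 (Coulomb), the Amber convention;
- nonbonded cutoff 12 Å with a CHARMM-style C1 switching window starting
  at 10 Å, applied to both LJ and Coulomb (no Ewald: the model treats only
  short-range electrostatics, consistent with a neutral peptide over an
  uncharged metal);
- metal atoms are uncharged Lennard-Jones sites
  (ε = 5.29 kcal/mol, R_min/2 = 1.4745 Å for Au), the
  CHARMM-METAL-style dispersion-only surface term.

Partial charges follow the classic Amber fixed-charge assignments for
these residues and sum exactly to zero per residue.  The set reproduces
the *functional forms* of the published biomolecular force fields but is
deliberately reduced; absolute adsorption energies are therefore **not**
comparable with published multi-hundred-kcal/mol values, and no test or
acceptance quantity depends on them.  Orderings, decompositions,
invariants and printed-arithmetic checks are the validated surfaces.

**Binding energy.** `E_BE = E_complex − E_peptide − E_substrate`
evaluated single-point at shared coordinates.  All intra-fragment terms
cancel, so the implementation sums the switched nonbonded pair energies
that cross the substrate/adsorbate divide over one pair list — a form
that is algebraically identical and returns an exact 0.0 for fragments
beyond the cutoff.  Per-residue binding assigns each peptide–surface pair
energy to the residue of its peptide atom; ACE/NH2 cap contributions fold
into the adjacent terminal residue so the profile length equals the
sequence length, and the profile sums to the surface-interaction total to
1e-8 relative (asserted in code).

## Conformer construction

Chains are grown N→C with NeRF placement of each backbone frame
(C–N 1.335 Å, ω = 180°, φ/ψ from a named preset; Pro φ held at −75°),
rigid-fitting each CCD residue template onto its frame, then repositioning
the carbonyl O (trans to the next N) and amide H (trans to CA).  The
assembled structure is relaxed under the embedded force field with bond
springs stiffened 25×: Amber-style scaled 1-4 interactions shift the
unmodified force field's equilibrium backbone bond lengths by ~1.5% off
their reference values, and the builder's contract is to deliver bonds on
reference (<0.2%) with no nonbonded contact under 1 Å.  Construction is
deterministic; a clash that survives ψ-jitter retries raises.  Energy
evaluation and dynamics always use the unmodified parameters.

Molecular weights are computed atom-by-atom from the template
compositions with IUPAC average atomic weights (Table-style average
masses, not monoisotopic).  Computed from their printed sequences, the
PF8 (3 Pro/3 Phe/2 Ser ≈ 966.10 Da) and FS8 (4 Phe/4 Ser ≈ 996.09 Da)
masses are swapped relative to some tabulated listings; the package
always computes from sequence and does not force agreement.

## Slab and surface registry

FCC(111) only: the capping candidates show no (100)/(110) adsorption
preference, so other Miller indices are rejected explicitly.  Geometry:
hexagonal layers with in-plane nearest-neighbour distance a/√2 and ABC
stacking at spacing a/√3 (a = 4.08 Å for Au); surface normal +z, top
layer at z = 0, peptide above; periodic in-plane only.  The slab is rigid
(fixed mask) — the metal atoms are far heavier than the adsorbate's and a
rigid substrate leaves the adsorption configuration and interaction
energy essentially unchanged while removing the substrate's dynamics.
The default lateral extent is configurable; it must keep the peptide from
seeing its own periodic image inside the 12 Å cutoff (the 8×8 default
with a = 4.08 Å gives a 23 Å cell).

Minimum-image displacements in the skewed hexagonal cell are computed
exactly by scanning the 3×3 neighbour images of the rounded fractional
displacement; energies are invariant under lattice translations to
1e-6 kcal/mol (tested).

The registry map classifies any lateral point as `top`, `second` (hcp
hollow) or `third` (fcc hollow) by nearest sublattice; it underlies the
lock-and-key criterion.

## Molecular dynamics

Velocity Verlet at 0.5 fs (production) with a single-variable Nosé–Hoover
thermostat (inertia Q = N_f k_B T τ², τ = 100 fs default, integrated with
the standard quarter-step thermostat splitting).  A Langevin (BAOAB)
thermostat is available by explicit config choice for tiny systems where
Nosé–Hoover is non-ergodic (e.g. the single-restrained-atom equipartition
check).  Degrees of freedom subtract center-of-mass translation only when
nothing breaks translation invariance (no fixed atoms, restraints or
cell).  Velocities are Maxwell–Boltzmann at the target temperature from
the run seed; every stochastic element flows from one master seed, and
trajectories are bitwise reproducible.

Positional restraints are `E = k |r − anchor|²` with k in kcal/mol/Å²
(no ½ — under this convention a restrained atom's equilibrium MSD is
3 k_B T/(2k), which the tests verify).  The conformation-preserving
pre-equilibration stage restrains all peptide atoms at k = 10.

Water is a flexible 3-site model (0.9572 Å / 104.52°, charges
−0.834/+0.417 e) with stiff internal harmonics instead of rigid-body
constraints: at 0.5 fs the stiff springs are stable and a SHAKE/SETTLE
solver is avoided; this is a documented deviation from rigid 3-site
water.  Solvation fills a box on a density-derived lattice with seeded
random orientations, excludes sites within 2.4 Å of solute heavy atoms,
and reports shortfalls (or raises, when an explicit count was requested).
`strip_water` is its exact inverse.

The 2 fs timestep is used only for the high-temperature perturbation
moves of the search, where fidelity is irrelevant (the move only has to
land somewhere new); C–H vibrations put ω·dt ≈ 1.1, inside the stability
bound of the integrator but inaccurate — production dynamics stay at
0.5 fs.  Default run lengths in tests and examples are picoseconds, not
nanoseconds; full lengths are reachable through config.

Energy-conservation reporting uses the maximum relative deviation of the
total energy from its initial value per ps of simulated time — a strict
metric that includes the integrator's bounded sawtooth, not just the
secular slope.

## STUN-BH search

Per start: CG-minimize (scipy conjugate gradient on the mobile atoms'
total potential energy, gradient max-norm tolerance), then iterate
perturb (hot MD) → minimize → Metropolis accept on the transformed
surface `f(E) = 1 − exp(−γ(E − E_ref))` with `E_ref` the best-so-far.
The objective value reported, ranked and accepted on is the single-point
binding energy at each minimum; for a rigid slab this is the
peptide–surface interaction term, while CG itself descends the full
potential-energy surface, mirroring how the geometric optimization and
the adsorption-energy objective divide the work.  Values below `E_ref`
map monotonically below zero, so minimum ordering is always preserved
(property-tested).

γ defaults to auto-calibration: after the first 10 iterations it is set
to ln 10 / median(|E − E_best|), mapping a typical per-iteration energy
spread to f ≈ 0.9.  The Metropolis temperature on the transformed surface
is dimensionless (default 0.15).  Observed acceptance on the toy
double-well fixture is ~90% largely independent of that temperature:
basin-hopping proposals are pre-minimized, so most moves land in an
equal-or-lower basin and are accepted at Δf ≤ 0; the temperature only
gates genuinely uphill inter-basin hops.  A 40–60% acceptance regime is
not reachable on such a landscape by the temperature knob alone, so the
default is chosen for reliable barrier crossing instead.

Multistart: each of `n_initial_conformations` starts gets an independent
seed stream (spawned from the master seed, all below 2³¹); initial
placements are uniform random rigid rotations at a random lateral cell
position, base height 3–8 Å above the top layer, lifted in 0.25 Å steps
until no contact is closer than 2 Å.  `E_ref` is per-start (independent
starts).  Distinct minima are deduplicated at ΔE < 0.1 kcal/mol **and**
mobile-atom RMSD < 0.5 Å after optimal superposition, first-found kept;
failures are recorded per start, never fatal.  The default schedule is
1000 starts × 200 iterations = 200,000 planned iterations, and
`multistart_plan` exposes the bookkeeping without executing.  Dihedral
space is explored only through the MD moves — φ/ψ/χ combinations are
never enumerated.

The engine is generic over a small problem protocol and is validated
against independent oracles: a brute-force grid on a 1-D asymmetric
double well (global minimum found in ≥95% of 50 seeded runs) and the
known Lennard-Jones cluster minima (−3ε triangle, −6ε tetrahedron, −9.104ε,
−12.712ε for n = 5, 6).

Search in explicit water is out of scope by design: the vacuum search
supplies candidate configurations, whose stability is then probed by
water-phase MD — ranking by adsorption free energy is a non-goal.

## Adsorption analysis

Ring orientation: tilt = angle between the SVD ring-plane normal and the
surface normal, folded to [0°, 90°]; centroid height above the top layer.
Classes: `detached` (height > 6 Å), `flat-on` (tilt ≤ 20° at height
≤ 4.5 Å), `stand-up` (tilt ≥ 60° at contact), else `intermediate`; rings
whose planar RMS residual exceeds 0.25 Å (Pro envelopes pass, genuinely
bent rings do not) fall to `intermediate` with a warning.  **LAK** is the
operational criterion *flat-on ring whose centroid projects within 0.8 Å
of a top-layer atom*; reports include each ring atom's registry class
(the second/third-layer alternation of a keyed six-ring) and label the
criterion as interpretive — the underlying judgement is made visually in
structure figures, so all thresholds are config-exposed.

Environment comparison: vacuum values are single-point binding energies
of minimized configurations; water values average the trailing half of a
production time series (window configurable).  Percent contrasts are
100 × (E_a − E_b)/E_b with the reference stated per row; the identity
(1 + p_ab/100)(1 + p_ba/100) = 1 is property-tested.  From tabulated
adsorption energies of the two most stable S7 configurations
(−250.06/−252.84 vacuum, −235.23/−210.26 water) this machinery yields the
1.10% and 11.88% contrasts checked in the acceptance suite.

Mobility: in-plane center-of-mass displacement from the first frame with
minimum-image-corrected frame-to-frame increments (unwrapped convention —
a walk across the periodic boundary counts its true path length).

## Problem sizes and synthetic data

All test inputs are generated programmatically: LJ clusters and the
double well (with attached oracle values), a harmonic dimer with
closed-form period, benzene-on-slab probes constructed from the registry
geometry, and a capped Ser-Phe-Ser on a 3-layer 7×7 slab (198 atoms) as
the standard adsorption fixture.  The suites run at desk scale — searches
of tens of iterations over a few starts, MD of 1–4 ps — chosen so the
whole validation cycle completes in minutes on one core while every
property being checked (thermostat averages, drift, oracle equivalence)
is already resolvable at that scale.  What passing shows: the machinery
is correct against analytic and brute-force references and its invariants
hold.  What it does not show: force-field accuracy against experiment,
converged adsorption ensembles for the 7–8-residue candidates, or
free-energy-weighted rankings in water.

## Known limitations

- Reduced parameter set: absolute energies differ from published
  force-field combinations; only structure of the method is transferable.
- No Ewald/PME, no pressure coupling, no polarizable or image-charge
  metal response (a systematically parametrized polarizable gold model
  would be the natural upgrade).
- Rigid slab; no surface reconstruction, defects, or curved nanoparticle
  geometry.
- Flexible water in place of rigid 3-site water.
- The LAK criterion is geometric, not thermodynamic; residence times and
  free energies are out of scope.
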