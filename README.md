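# facetcap

Computer-aided design of **peptide capping agents** for FCC metal
nanoparticle facets.  A capping agent is a molecule that adsorbs
selectively on one crystallographic facet — here the close-packed (111)
face of gold — suppressing growth there and steering the nanoparticle
toward (111)-rich shapes.  Short capped peptides such as
**S7** (`Ac-SSFPQPN-NH2`), **PF8** (`Ac-PFSPFSPF-NH2`) and
**FS8** (`Ac-FSFSFSFS-NH2`) are attractive candidates because their
sequences can be tuned residue by residue.

`facetcap` implements the full in-silico screening pipeline for such
candidates:

1. **STUN-BH global search** for low-lying adsorption configurations of a
   capped peptide on a rigid Au(111) slab in vacuum.  Basin hopping
   (perturb → conjugate-gradient minimize → Metropolis accept) is combined
   with stochastic tunneling: acceptance acts on the transformed surface
   `f(E) = 1 − exp(−γ(E − E_ref))`, which flattens every barrier above the
   running best energy `E_ref` while preserving the ordering and location
   of all local minima.  Perturbation moves are short hot MD bursts
   (500 K, 300 steps, 2 fs).
2. **Binding energy** objective
   `E_BE = E_peptide/surface − E_peptide − E_substrate` (kcal/mol,
   single-point decomposition; more negative = more stable adsorption),
   with per-residue decomposition of the peptide–surface term.
3. **MD stability runs** (velocity Verlet, Nosé–Hoover NVT at 300 K,
   0.5 fs, 12 Å switched cutoff) in vacuum or explicit 3-site water, with
   the standard restrained pre-equilibration stage
   (k = 10 kcal/mol/Å² springs on all peptide atoms).
4. **Lock-and-key (LAK) analysis**: a flat-lying Phe six-ring or Pro
   five-ring can enclose a top-layer metal atom while its ring atoms align
   with second-/third-layer lattice sites — the geometric registry that
   strengthens dispersion contact.  `facetcap` classifies every ring
   (flat-on / stand-up / intermediate / detached), detects LAK registry,
   and builds vacuum-vs-water comparison tables and on-surface mobility
   summaries used to rank sequences.

The molecular-mechanics model is an embedded, reduced Amber-class
parameter set (harmonic bonds/angles, cosine torsions, LJ + Coulomb with
Lorentz–Berthelot combining and Amber 1-4 scaling) covering exactly the
residues Ser/Phe/Pro/Gln/Asn plus acetyl/amide caps, 3-site water, and
uncharged LJ metal sites for the surface term.  It follows the functional
forms of the standard biomolecular force fields but is **not** the
published Amber99sb-ILDN / CHARMM-METAL / TIP3P files; absolute energies
are not comparable with runs using those sets (see `docs/methods.md`).

## Worked example

```python
import facetcap as fc
from facetcap.fixtures import make_tripeptide_on_slab
from facetcap.md import MDConfig
from facetcap.search import StunBhConfig, stunbh_iterate

seq = fc.parse_capped_sequence("Ac-SSFPQPN-NH2")
print(seq.format(), len(seq), "residues,",
      round(fc.molecular_weight(seq), 2), "Da")

system, slab = make_tripeptide_on_slab()   # capped Ser-Phe-Ser on Au(111)
cfg = StunBhConfig(
    n_initial_conformations=1, iterations_per_start=5, seed=0,
    cg_tol=1e-3, cg_max_iter=200,
    perturb_md=MDConfig(timestep=2.0, n_steps=150, temperature=500.0,
                        stride=150))
best, e_be = stunbh_iterate(system, cfg, seed=0)
print("best E_BE:", round(e_be, 2), "kcal/mol")
for label, e in zip(*[fc.per_residue_binding(best).labels,
                      fc.per_residue_binding(best).energies]):
    print(f"  {label}  {e:8.2f} kcal/mol")
for r in fc.detect_lak(best, slab).records:
    print(f"  ring {r.resname}-{r.resid}: {r.orientation}, "
          f"tilt {r.tilt_deg:.0f} deg, height {r.height:.1f} A, LAK {r.lak}")
```

prints

```
Ac-SSFPQPN-NH2 7 residues, 816.87 Da
best E_BE: -66.43 kcal/mol
  SER     -3.66 kcal/mol
  PHE    -42.51 kcal/mol
  SER    -20.26 kcal/mol
  ring PHE-3: flat-on, tilt 1 deg, height 2.9 A, LAK False
```

The peptide's mass comes out at the tabulated 816.87 Da; after five
STUN-BH iterations on the toy Ser-Phe-Ser fixture, the Phe aromatic ring
has dropped flat onto the surface at 2.9 Å and dominates the binding
(−42.5 of −66.4 kcal/mol) — the flat-on ring contact that makes
Phe-containing sequences good (111) cappers.  Longer searches let the ring
also find top-atom registry (LAK).

## Command line

```bash
facetcap build "Ac-SSFPQPN-NH2" -o s7.pdb      # conformer + MW
facetcap slab --layers 6 --repeats 8 8         # Au(111) substrate
facetcap search --config run.toml              # multistart STUN-BH
facetcap md --config run.toml --structure min.pdb
facetcap analyze --structure complex.pdb       # LAK / ring report
facetcap report --vacuum vac.json --water wat.json
facetcap fixtures                              # synthetic test systems
```

Every run writes a JSON config echo and its seed, so any output can be
regenerated from the echo alone.  `run.toml` holds all physics constants
(lattice constant 4.08 Å, 6 layers, 12 Å cutoff, 300/500 K, 0.5/2 fs,
restraint spring 10 kcal/mol/Å², 1000 × 200 search schedule) as defaults.

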