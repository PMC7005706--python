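"""Capped peptide sequences: parsing, masses, and 3-D conformer building.

Sequences follow the capped notation used for facet-binding peptides, e.g.
``Ac-SSFPQPN-NH2`` (the S7 candidate): an optional N-terminal acetyl cap,
a body of one- or three-letter residue codes, and an optional C-terminal
amide cap.  Supported residues are Ser, Phe, Pro, Gln and Asn.

Conformers are assembled residue-by-residue along the backbone at a chosen
(φ, ψ) preset using idealized residue geometry, then relaxed briefly under
the embedded force field so bond lengths sit on their reference values and
small template clashes are resolved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .constants import ELEMENT_MASSES
from .residues import ONE_TO_THREE, THREE_TO_ONE, get_template
from .system import MolecularSystem

__all__ = [
    "PeptideSequence", "parse_capped_sequence", "molecular_weight",
    "build_conformation", "BACKBONE_PRESETS",
]

_N_CAPS = {"AC": "Ac", "ACE": "Ac"}
_C_CAPS = {"NH2": "NH2", "CONH2": "NH2", "NHE": "NH2"}

# (φ, ψ) in degrees
BACKBONE_PRESETS = {
    "extended": (-140.0, 135.0),
    "ppii": (-75.0, 145.0),
    "alpha": (-57.0, -47.0),
}


@dataclass(frozen=True)
class PeptideSequence:
    """Ordered capped residue list (one-letter codes, N→C)."""

    residues: tuple[str, ...]
    n_cap: str | None = "Ac"
    c_cap: str | None = "NH2"

    def __post_init__(self):
        if not self.residues:
            raise ValueError("empty peptide sequence")
        for code in self.residues:
            if code not in ONE_TO_THREE:
                raise ValueError(f"unsupported residue code {code!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def format(self) -> str:
        """Canonical text form, e.g. ``"Ac-SSFPQPN-NH2"``."""
        body = "".join(self.residues)
        parts = []
        if self.n_cap:
            parts.append(self.n_cap)
        parts.append(body)
        if self.c_cap:
            parts.append(self.c_cap)
        return "-".join(parts)

    def __str__(self) -> str:
        return self.format()


def parse_capped_sequence(text: str) -> PeptideSequence:
    """Parse ``"<cap>-<codes>-<cap>"`` (or bare codes) into a sequence.

    Accepts one-letter bodies (``Ac-SSFPQPN-NH2``) and dash-separated
    three-letter bodies (``Ac-Ser-Ser-Phe-Pro-Gln-Pro-Asn-NH2``).
    Unsupported residue codes are rejected by name.
    """
    if not isinstance(text, str) or not text.strip():
        raise ValueError("empty sequence string")
    tokens = [t for t in re.split(r"[-\s]+", text.strip()) if t]
    n_cap = c_cap = None
    if tokens and tokens[0].upper() in _N_CAPS:
        n_cap = _N_CAPS[tokens[0].upper()]
        tokens = tokens[1:]
    if tokens and tokens[-1].upper() in _C_CAPS:
        c_cap = _C_CAPS[tokens[-1].upper()]
        tokens = tokens[:-1]
    if not tokens:
        raise ValueError(f"sequence {text!r} has caps but no residue body")

    standard_aa = {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
    residues: list[str] = []
    for tok in tokens:
        up = tok.upper()
        if up in THREE_TO_ONE:
            residues.append(THREE_TO_ONE[up])
        elif all(c in ONE_TO_THREE for c in up):
            residues.extend(up)
        else:
            bad = up if up in standard_aa else next(
                c for c in up if c not in ONE_TO_THREE)
            raise ValueError(f"unsupported residue code {bad!r} in {text!r}")
    return PeptideSequence(tuple(residues), n_cap=n_cap, c_cap=c_cap)


def molecular_weight(seq: PeptideSequence) -> float:
    """Average molecular weight in Da of the capped peptide.

    Computed atom-by-atom from the residue templates with IUPAC average
    atomic weights: residue bodies, plus the acetyl cap (net +C2H2O over a
    free N-terminus' H) and the C-terminal amide (NH2 in place of OH).
    Free termini add H / OH instead of the cap atoms.
    """
    mass = 0.0
    for code in seq.residues:
        mass += get_template(ONE_TO_THREE[code]).mass
    mass += get_template("ACE").mass if seq.n_cap else ELEMENT_MASSES["H"]
    mass += get_template("NH2").mass if seq.c_cap else (
        ELEMENT_MASSES["O"] + ELEMENT_MASSES["H"])
    return mass


# ---------------------------------------------------------------------------
# conformer construction
# ---------------------------------------------------------------------------

def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          r: float, theta_deg: float, tau_deg: float) -> np.ndarray:
    """Place atom d bonded to ``a`` with angle d-a-b = theta and torsion
    d-a-b-c = tau (natural extension reference frame)."""
    theta = np.radians(theta_deg)
    tau = np.radians(tau_deg)
    ab = b - a
    bc = c - b
    n1 = ab / np.linalg.norm(ab)
    m = np.cross(bc, n1)
    m /= np.linalg.norm(m)
    n2 = np.cross(n1, m)
    d_local = r * np.array([
        -np.cos(theta),
        np.sin(theta) * np.cos(tau),
        np.sin(theta) * np.sin(tau),
    ])
    return a + d_local[0] * n1 + d_local[1] * n2 + d_local[2] * m


def _fit_rigid(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) mapping ``src`` points onto
    ``dst`` (Kabsch)."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, cd - r @ cs


def _chain_plan(seq: PeptideSequence) -> list[str]:
    plan = []
    if seq.n_cap:
        plan.append("ACE")
    plan.extend(ONE_TO_THREE[c] for c in seq.residues)
    if seq.c_cap:
        plan.append("NH2")
    return plan


def build_conformation(seq: PeptideSequence, backbone: str = "extended",
                       relax: bool = True) -> MolecularSystem:
    """Build an all-atom 3-D conformation with full MM topology.

    ``backbone`` selects a (φ, ψ) preset (see :data:`BACKBONE_PRESETS`);
    Pro φ is held at −75° by its ring.  Construction is deterministic:
    the same sequence and preset always give identical coordinates.
    Raises ``RuntimeError`` if steric clashes survive placement retries.
    """
    if backbone not in BACKBONE_PRESETS:
        raise KeyError(f"unknown backbone preset {backbone!r}; "
                       f"choose from {sorted(BACKBONE_PRESETS)}")
    phi0, psi0 = BACKBONE_PRESETS[backbone]
    for jitter in (0.0, 10.0, -10.0, 20.0):
        sys_ = _assemble(seq, phi0, psi0 + jitter)
        if relax:
            sys_ = _relax(sys_)
        if _min_nonbonded_distance(sys_) >= 1.0:
            return sys_
    raise RuntimeError(
        f"steric clash could not be resolved building {seq.format()!r}")


def _assemble(seq: PeptideSequence, phi0: float, psi0: float) -> MolecularSystem:
    plan = _chain_plan(seq)
    names, elements, types, charges, resnames, resids = [], [], [], [], [], []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    offsets: list[int] = []

    prev: dict[str, np.ndarray] | None = None  # frame atoms of previous unit
    prev_c_index = -1

    for ri, resname in enumerate(plan, start=1):
        tpl = get_template(resname)
        offset = len(names)
        offsets.append(offset)
        phi = -75.0 if resname == "PRO" else phi0
        psi = psi0

        if resname == "NH2":
            n = _nerf(prev["C"], prev["CA"], prev["N"], 1.335, 116.6, prev["psi"])
            h1 = _nerf(n, prev["C"], prev["CA"], 1.010, 119.8, 0.0)
            h2 = _nerf(n, prev["C"], prev["CA"], 1.010, 119.8, 180.0)
            placed = {"N": n, "HN1": h1, "HN2": h2}
            pos = np.array([placed[a] for a in tpl.atom_names])
        elif prev is None:
            # first unit sits at its template position
            pos = tpl.coords.copy()
        else:
            n = _nerf(prev["C"], prev["CA"], prev["N"], 1.335, 116.6, prev["psi"])
            ca = _nerf(n, prev["C"], prev["CA"], 1.449, 121.9, 180.0)
            c_target = _nerf(ca, n, prev["C"], 1.522, 110.1, phi)
            src = np.array([tpl.coords[tpl.index(a)] for a in ("N", "CA", "C")])
            rot, trans = _fit_rigid(src, np.array([n, ca, c_target]))
            pos = tpl.coords @ rot.T + trans
            # carbonyl O trans to the next backbone N; amide H trans to CA
            pos[tpl.index("O")] = _nerf(pos[tpl.index("C")], pos[tpl.index("CA")],
                                        pos[tpl.index("N")], 1.229, 120.4,
                                        psi + 180.0)
            if "H" in tpl.atom_names:
                pos[tpl.index("H")] = _nerf(n, prev["C"], prev["CA"],
                                            1.010, 119.8, 0.0)

        names.extend(tpl.atom_names)
        elements.extend(tpl.elements)
        types.extend(tpl.mm_types)
        charges.extend(tpl.charges)
        resnames.extend([resname] * tpl.n_atoms)
        resids.extend([ri] * tpl.n_atoms)
        coords.append(pos)
        for a, b in tpl.bonds:
            bonds.append((offset + tpl.index(a), offset + tpl.index(b)))
        if prev_c_index >= 0 and resname != "ACE":
            bonds.append((prev_c_index, offset + tpl.index("N")))

        if resname == "NH2":
            break
        anchor_ca = "CA" if "CA" in tpl.atom_names else "CH3"
        anchor_n = "N" if "N" in tpl.atom_names else "O"
        prev = {
            "N": pos[tpl.index(anchor_n)],
            "CA": pos[tpl.index(anchor_ca)],
            "C": pos[tpl.index("C")],
            "psi": 180.0 if resname == "ACE" else psi,
        }
        prev_c_index = offset + tpl.index("C")

    return MolecularSystem(
        names=np.array(names), elements=np.array(elements),
        resids=np.array(resids), resnames=np.array(resnames),
        segments=np.array(["peptide"] * len(names)),
        types=np.array(types), charges=np.array(charges),
        coords=np.vstack(coords), bonds=np.array(bonds, dtype=int),
    )


def _relax(system: MolecularSystem, max_iter: int = 2000) -> MolecularSystem:
    """Clean up the assembled geometry under the embedded force field.

    Bond springs are stiffened 25× during this construction-time pass:
    scaled 1-4 interactions shift the unmodified force field's equilibrium
    bond lengths by >1%, and the builder's contract is to deliver bonds on
    their reference values while angles and contacts relax.
    """
    from scipy import optimize

    from .forcefield import Evaluator, ForceFieldParams

    ev = Evaluator(system, ForceFieldParams.default())
    ev.b_k = ev.b_k * 25.0

    def fun(flat):
        br, f = ev.energy_forces(flat.reshape(-1, 3))
        return br.total, -f.ravel()

    res = optimize.minimize(fun, system.coords.ravel(), jac=True,
                            method="L-BFGS-B",
                            options={"maxiter": max_iter, "ftol": 1e-12,
                                     "gtol": 1e-6})
    return system.with_coords(res.x.reshape(-1, 3))


def _min_nonbonded_distance(system: MolecularSystem) -> float:
    top = system.topology()
    x = system.coords
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
    iu = np.triu_indices(system.n_atoms, k=1)
    skip = top.excluded | top.pairs14
    mask = np.array([(int(i), int(j)) not in skip for i, j in zip(*iu)])
    vals = d[iu][mask]
    return float(vals.min()) if vals.size else np.inf


def find_rings(system: MolecularSystem) -> list[np.ndarray]:
    """Index arrays of the template-defined rings (Phe 6-ring, Pro 5-ring)
    present in ``system``, in residue order."""
    rings = []
    for rid in np.unique(system.resids):
        mask = system.resids == rid
        resname = system.resnames[mask][0]
        try:
            tpl = get_template(str(resname))
        except KeyError:
            continue
        if not tpl.ring:
            continue
        idx = np.flatnonzero(mask)
        name_to_idx = {system.names[i]: i for i in idx}
        rings.append(np.array([name_to_idx[a] for a in tpl.ring], dtype=int))
    return rings
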