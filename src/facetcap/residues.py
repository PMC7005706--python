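"""Residue parameter templates for the supported capping-peptide residues.

Covers Ser, Phe, Pro, Gln, Asn plus the acetyl (ACE) and C-terminal amide
(NH2) caps — the full residue alphabet of the S7 / PF8 / FS8 capping
candidates.  Each template carries atom names, elements, MM atom types and
partial charges (a reduced Amber-class set; charges sum to the residue's
formal charge of zero), the intra-residue bond list, ring membership, and
idealized 3-D reference coordinates taken from biotite's bundled Chemical
Component Dictionary geometry.

The aromatic six-membered Phe ring and the five-membered Pro ring are the
two ring systems that drive the lock-and-key surface registry analysis, so
ring membership is recorded explicitly here.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .constants import element_mass

__all__ = [
    "ResidueTemplate", "get_template", "SUPPORTED_RESIDUES",
    "ONE_TO_THREE", "THREE_TO_ONE",
]

ONE_TO_THREE = {"S": "SER", "F": "PHE", "P": "PRO", "Q": "GLN", "N": "ASN"}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}
SUPPORTED_RESIDUES = tuple(ONE_TO_THREE) + ("ACE", "NH2")

# (mm_type, partial charge / e) per atom name; insertion order is the
# canonical atom order of the template.
_PARAMS: dict[str, dict[str, tuple[str, float]]] = {
    "SER": {
        "N": ("N", -0.4157), "H": ("H", 0.2719),
        "CA": ("CT", -0.0249), "HA": ("H1", 0.0843),
        "CB": ("CT", 0.2117), "HB2": ("H1", 0.0352), "HB3": ("H1", 0.0352),
        "OG": ("OH", -0.6546), "HG": ("HO", 0.4275),
        "C": ("C", 0.5973), "O": ("O", -0.5679),
    },
    "PHE": {
        "N": ("N", -0.4157), "H": ("H", 0.2719),
        "CA": ("CT", -0.0024), "HA": ("H1", 0.0978),
        "CB": ("CT", -0.0343), "HB2": ("HC", 0.0295), "HB3": ("HC", 0.0295),
        "CG": ("CA", 0.0118),
        "CD1": ("CA", -0.1256), "HD1": ("HA", 0.1330),
        "CD2": ("CA", -0.1256), "HD2": ("HA", 0.1330),
        "CE1": ("CA", -0.1704), "HE1": ("HA", 0.1430),
        "CE2": ("CA", -0.1704), "HE2": ("HA", 0.1430),
        "CZ": ("CA", -0.1072), "HZ": ("HA", 0.1297),
        "C": ("C", 0.5973), "O": ("O", -0.5679),
    },
    "PRO": {
        "N": ("N", -0.2548),
        "CD": ("CT", 0.0192), "HD2": ("H1", 0.0391), "HD3": ("H1", 0.0391),
        "CG": ("CT", 0.0189), "HG2": ("HC", 0.0213), "HG3": ("HC", 0.0213),
        "CB": ("CT", -0.0070), "HB2": ("HC", 0.0253), "HB3": ("HC", 0.0253),
        "CA": ("CT", -0.0266), "HA": ("H1", 0.0641),
        "C": ("C", 0.5896), "O": ("O", -0.5748),
    },
    "GLN": {
        "N": ("N", -0.4157), "H": ("H", 0.2719),
        "CA": ("CT", -0.0031), "HA": ("H1", 0.0850),
        "CB": ("CT", -0.0036), "HB2": ("HC", 0.0171), "HB3": ("HC", 0.0171),
        "CG": ("CT", -0.0645), "HG2": ("HC", 0.0352), "HG3": ("HC", 0.0352),
        "CD": ("C", 0.6951), "OE1": ("O", -0.6086),
        "NE2": ("N", -0.9407), "HE21": ("H", 0.4251), "HE22": ("H", 0.4251),
        "C": ("C", 0.5973), "O": ("O", -0.5679),
    },
    "ASN": {
        "N": ("N", -0.4157), "H": ("H", 0.2719),
        "CA": ("CT", 0.0143), "HA": ("H1", 0.1048),
        "CB": ("CT", -0.2041), "HB2": ("HC", 0.0797), "HB3": ("HC", 0.0797),
        "CG": ("C", 0.7130), "OD1": ("O", -0.5931),
        "ND2": ("N", -0.9191), "HD21": ("H", 0.4196), "HD22": ("H", 0.4196),
        "C": ("C", 0.5973), "O": ("O", -0.5679),
    },
    "ACE": {
        "CH3": ("CT", -0.3662),
        "H1": ("HC", 0.1123), "H2": ("HC", 0.1123), "H3": ("HC", 0.1123),
        "C": ("C", 0.5972), "O": ("O", -0.5679),
    },
    "NH2": {
        "N": ("N", -0.4630), "HN1": ("H", 0.2315), "HN2": ("H", 0.2315),
    },
}

_RINGS = {
    "PRO": ("N", "CA", "CB", "CG", "CD"),
    "PHE": ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),
}

# CCD atoms that belong to the free-monomer form only (charged termini /
# leaving groups), removed for in-chain use.
_LEAVING = {
    "SER": {"OXT", "HXT", "H2"}, "PHE": {"OXT", "HXT", "H2"},
    "PRO": {"OXT", "HXT", "H"}, "GLN": {"OXT", "HXT", "H2"},
    "ASN": {"OXT", "HXT", "H2"},
    "ACE": {"H"}, "NH2": set(),
}


@dataclass(frozen=True)
class ResidueTemplate:
    """In-chain residue building block with parameters and ideal geometry."""

    name: str
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    mm_types: tuple[str, ...]
    charges: tuple[float, ...]
    bonds: tuple[tuple[str, str], ...]
    ring: tuple[str, ...]
    coords: np.ndarray  # (n, 3) idealized reference geometry, Å

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def mass(self) -> float:
        """Average mass (Da) of the in-chain residue body."""
        return float(sum(element_mass(e) for e in self.elements))

    @property
    def formal_charge(self) -> float:
        return float(np.round(sum(self.charges), 6))

    def index(self, atom_name: str) -> int:
        return self.atom_names.index(atom_name)


@lru_cache(maxsize=None)
def get_template(resname: str) -> ResidueTemplate:
    """Template for ``resname`` (3-letter, e.g. ``"PRO"``); raises for
    residues outside the supported capping-peptide alphabet."""
    resname = resname.upper()
    if resname not in _PARAMS:
        raise KeyError(
            f"unsupported residue {resname!r}; supported: {', '.join(_PARAMS)}")
    import biotite.structure.info as struc_info

    ref = struc_info.residue(resname)
    ccd_coords = {n: ref.coord[i] for i, n in enumerate(ref.atom_name)}
    params = _PARAMS[resname]
    missing = [n for n in params if n not in ccd_coords]
    if missing:
        raise RuntimeError(f"CCD template {resname} lacks atoms {missing}")

    names = tuple(params)
    elements = tuple(
        str(ref.element[list(ref.atom_name).index(n)]).upper() for n in names)
    keep = set(names)
    bonds = tuple(
        (a, b) for (a, b) in struc_info.bonds_in_residue(resname)
        if a in keep and b in keep
    )
    coords = np.array([ccd_coords[n] for n in names], dtype=float)
    return ResidueTemplate(
        name=resname,
        atom_names=names,
        elements=elements,
        mm_types=tuple(params[n][0] for n in names),
        charges=tuple(params[n][1] for n in names),
        bonds=bonds,
        ring=_RINGS.get(resname, ()),
        coords=coords,
    )
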