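"""Molecular-mechanics energies, analytic forces, and binding energies.

Functional forms (Amber-class): harmonic bonds and angles, cosine proper
and improper torsions, 12-6 Lennard-Jones and point-charge Coulomb with a
12 Å cutoff and a C1 switching window, Lorentz–Berthelot combining, 1-2/1-3
exclusions and Amber 1-4 scaling.  Metal substrate atoms are uncharged
Lennard-Jones sites (CHARMM-METAL-style surface term).

The adsorption (binding) energy is the single-point decomposition

    E_BE = E_complex − E_peptide − E_substrate

evaluated at shared coordinates, so E_BE reduces exactly to the
peptide–surface interaction and vanishes when the fragments are separated
beyond the cutoff.  More negative E_BE means more stable adsorption.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .constants import COULOMB
from .system import MolecularSystem

__all__ = [
    "ForceFieldParams", "EnergyBreakdown", "BindingProfile", "Evaluator",
    "Restraints", "total_energy", "forces", "binding_energy",
    "per_residue_binding", "split_complex",
]

_SIGMA_FROM_RMIN2 = 2.0 / 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class ForceFieldParams:
    """Embedded reduced parameter table (see ``data/forcefield.toml``)."""

    name: str
    version: str
    lj: dict[str, tuple[float, float]]          # type -> (eps, sigma)
    bonds: dict[str, tuple[float, float]]       # "A-B" sorted -> (k, r0)
    angles: dict[str, tuple[float, float]]      # "A-B-C" -> (k, theta0 rad)
    dihedrals: dict[str, tuple[tuple[float, int, float], ...]]
    impropers: dict[str, tuple[float, int, float]]
    cutoff: float = 12.0
    switch_start: float = 10.0
    scale14_lj: float = 0.5
    scale14_coulomb: float = 1.0 / 1.2

    @staticmethod
    @lru_cache(maxsize=1)
    def default() -> "ForceFieldParams":
        path = resources.files("facetcap.data").joinpath("forcefield.toml")
        with path.open("rb") as fh:
            return ForceFieldParams.from_dict(tomllib.load(fh))

    @staticmethod
    def from_file(path) -> "ForceFieldParams":
        with open(path, "rb") as fh:
            return ForceFieldParams.from_dict(tomllib.load(fh))

    @staticmethod
    def from_dict(raw: dict) -> "ForceFieldParams":
        meta = raw.get("meta", {})
        lj = {}
        for t, entry in raw["atom_types"].items():
            eps, rmin2 = float(entry["eps"]), float(entry["rmin2"])
            if eps < 0 or rmin2 <= 0:
                raise ValueError(f"invalid LJ parameters for type {t!r}")
            lj[t] = (eps, rmin2 * _SIGMA_FROM_RMIN2)
        bonds = {_sort_key(k): (v[0], v[1]) for k, v in raw["bonds"].items()}
        angles = {k: (v[0], np.radians(v[1])) for k, v in raw["angles"].items()}
        dihedrals = {
            k: tuple((t[0], int(t[1]), np.radians(t[2])) for t in v)
            for k, v in raw["dihedrals"].items()
        }
        impropers = {
            k: (v[0], int(v[1]), np.radians(v[2]))
            for k, v in raw.get("impropers", {}).items()
        }
        return ForceFieldParams(
            name=meta.get("name", "unnamed"), version=str(meta.get("version", "0")),
            lj=lj, bonds=bonds, angles=angles, dihedrals=dihedrals,
            impropers=impropers,
            cutoff=float(meta.get("cutoff", 12.0)),
            switch_start=float(meta.get("switch_start", 10.0)),
            scale14_lj=float(meta.get("scale14_lj", 0.5)),
            scale14_coulomb=float(meta.get("scale14_coulomb", 1.0 / 1.2)),
        )

    # -- lookups ----------------------------------------------------------
    def lj_params(self, t: str) -> tuple[float, float]:
        try:
            return self.lj[t]
        except KeyError:
            raise KeyError(f"no Lennard-Jones parameters for atom type {t!r}") from None

    def bond_params(self, t1: str, t2: str) -> tuple[float, float]:
        key = _sort_key(f"{t1}-{t2}")
        try:
            return self.bonds[key]
        except KeyError:
            raise KeyError(f"no bond parameters for type pair {key!r}") from None

    def angle_params(self, t1: str, t2: str, t3: str) -> tuple[float, float]:
        for key in (f"{t1}-{t2}-{t3}", f"{t3}-{t2}-{t1}", f"X-{t2}-X"):
            if key in self.angles:
                return self.angles[key]
        raise KeyError(f"no angle parameters for type triple {t1}-{t2}-{t3!r}")

    def dihedral_terms(self, t1, t2, t3, t4):
        for key in (f"{t1}-{t2}-{t3}-{t4}", f"{t4}-{t3}-{t2}-{t1}",
                    f"X-{t2}-{t3}-X", f"X-{t3}-{t2}-X"):
            if key in self.dihedrals:
                return self.dihedrals[key]
        return ()

    def improper_term(self, center_type: str):
        return self.impropers.get(center_type)


def _sort_key(key: str) -> str:
    a, b = key.split("-")
    return f"{a}-{b}" if a <= b else f"{b}-{a}"


@dataclass
class EnergyBreakdown:
    """MM energy components, kcal/mol.  ``e_peptide_surface`` is the
    peptide↔slab share of the nonbonded terms (informational subset, not
    added again in the total)."""

    e_bond: float = 0.0
    e_angle: float = 0.0
    e_dihedral: float = 0.0
    e_improper: float = 0.0
    e_lj: float = 0.0
    e_coulomb: float = 0.0
    e_restraint: float = 0.0
    e_peptide_surface: float = 0.0

    @property
    def total(self) -> float:
        return (self.e_bond + self.e_angle + self.e_dihedral + self.e_improper
                + self.e_lj + self.e_coulomb + self.e_restraint)

    def as_dict(self) -> dict:
        return {
            "E_bond": self.e_bond, "E_angle": self.e_angle,
            "E_dihedral": self.e_dihedral, "E_improper": self.e_improper,
            "E_LJ": self.e_lj, "E_coulomb": self.e_coulomb,
            "E_restraint": self.e_restraint,
            "E_peptide_surface": self.e_peptide_surface,
            "E_total": self.total,
        }


@dataclass
class BindingProfile:
    """Per-residue binding energies (kcal/mol), ordered N→C.

    Each residue's value is the sum of peptide–surface nonbonded terms
    whose peptide atom belongs to that residue; cap (ACE / NH2)
    contributions are folded into the adjacent terminal residue so the
    profile length equals the residue count of the sequence.
    """

    labels: tuple[str, ...]
    energies: np.ndarray

    @property
    def total(self) -> float:
        return float(self.energies.sum())

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class Restraints:
    """Harmonic positional restraints E = k Σ |r_i − anchor_i|²
    (k in kcal/mol/Å², no 1/2 factor)."""

    indices: np.ndarray
    anchors: np.ndarray
    k: float

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        self.anchors = np.asarray(self.anchors, dtype=float).reshape(-1, 3)
        if len(self.indices) != len(self.anchors):
            raise ValueError("restraint indices and anchors differ in length")


class Evaluator:
    """Precompiled energy/force evaluator for one system.

    Pair lists, bonded parameter arrays and the (constant) contribution of
    pairs between fixed atoms are prepared once; ``energy`` and ``forces``
    then evaluate any coordinate set for that system.  Fixed atoms must
    keep the coordinates they had at construction.
    """

    def __init__(self, system: MolecularSystem, params: ForceFieldParams,
                 restraints: Restraints | None = None):
        self.system = system
        self.params = params
        self.restraints = restraints
        if restraints is not None and system.fixed[restraints.indices].any():
            raise ValueError("restrained atoms must not also be fixed")
        top = system.topology()
        types = system.types

        # bonded parameter arrays ----------------------------------------
        self.b_idx = top.bonds
        self.b_k = np.array([params.bond_params(types[i], types[j])[0]
                             for i, j in top.bonds])
        self.b_r0 = np.array([params.bond_params(types[i], types[j])[1]
                              for i, j in top.bonds])
        self.a_idx = top.angles
        self.a_k = np.array([params.angle_params(types[i], types[j], types[k])[0]
                             for i, j, k in top.angles])
        self.a_t0 = np.array([params.angle_params(types[i], types[j], types[k])[1]
                              for i, j, k in top.angles])

        d_idx, d_k, d_n, d_p = [], [], [], []
        for i, j, k, l in top.propers:
            for kk, nn, pp in params.dihedral_terms(types[i], types[j],
                                                    types[k], types[l]):
                if kk != 0.0:
                    d_idx.append((i, j, k, l))
                    d_k.append(kk); d_n.append(nn); d_p.append(pp)
        self.d_idx = np.asarray(d_idx, dtype=int).reshape(-1, 4)
        self.d_k = np.asarray(d_k); self.d_n = np.asarray(d_n, dtype=float)
        self.d_p = np.asarray(d_p)

        im_idx, im_k, im_n, im_p = [], [], [], []
        for a, b, c, d in top.impropers:
            term = params.improper_term(types[c])
            if term is not None and term[0] != 0.0:
                im_idx.append((a, b, c, d))
                im_k.append(term[0]); im_n.append(term[1]); im_p.append(term[2])
        self.im_idx = np.asarray(im_idx, dtype=int).reshape(-1, 4)
        self.im_k = np.asarray(im_k); self.im_n = np.asarray(im_n, dtype=float)
        self.im_p = np.asarray(im_p)

        # nonbonded pair lists -------------------------------------------
        n = system.n_atoms
        eps = np.array([params.lj_params(t)[0] for t in types])
        sig = np.array([params.lj_params(t)[1] for t in types])
        iu, ju = np.triu_indices(n, k=1)
        keep = np.ones(len(iu), dtype=bool)
        s_lj = np.ones(len(iu))
        s_cl = np.ones(len(iu))
        def pos(p):
            i, j = p
            return i * n - i * (i + 1) // 2 + (j - i - 1)

        for p in top.excluded:
            keep[pos(p)] = False
        for p in top.pairs14:
            s_lj[pos(p)] = params.scale14_lj
            s_cl[pos(p)] = params.scale14_coulomb
        iu, ju, s_lj, s_cl = iu[keep], ju[keep], s_lj[keep], s_cl[keep]

        frozen = system.fixed[iu] & system.fixed[ju]
        self.p_i, self.p_j = iu[~frozen], ju[~frozen]
        self.p_slj, self.p_scl = s_lj[~frozen], s_cl[~frozen]
        self.p_eps = np.sqrt(eps[self.p_i] * eps[self.p_j])
        self.p_sig = 0.5 * (sig[self.p_i] + sig[self.p_j])
        self.p_qq = COULOMB * system.charges[self.p_i] * system.charges[self.p_j]

        seg = system.segments
        pep_i = seg[self.p_i] == "peptide"
        pep_j = seg[self.p_j] == "peptide"
        slab_i = seg[self.p_i] == "slab"
        slab_j = seg[self.p_j] == "slab"
        self.p_surface = (pep_i & slab_j) | (pep_j & slab_i)
        # pairs crossing the slab / non-slab divide (adsorbate+solvent vs
        # substrate): their switched pair energies sum to the single-point
        # binding energy, exactly zero beyond the cutoff
        self.p_cross = slab_i ^ slab_j
        # residue id of the peptide atom in each peptide-surface pair
        self.p_surf_resid = np.where(pep_i, system.resids[self.p_i],
                                     system.resids[self.p_j])[self.p_surface]

        # constant contribution of fixed-fixed pairs (e.g. slab internal)
        fi, fj = iu[frozen], ju[frozen]
        if len(fi):
            e_lj, e_cl, _ = self._pair_terms(
                system.coords, fi, fj,
                np.sqrt(eps[fi] * eps[fj]), 0.5 * (sig[fi] + sig[fj]),
                COULOMB * system.charges[fi] * system.charges[fj],
                s_lj[frozen], s_cl[frozen], want_forces=False)
            self.frozen_lj = float(e_lj.sum())
            self.frozen_coulomb = float(e_cl.sum())
        else:
            self.frozen_lj = self.frozen_coulomb = 0.0

    # -- geometry helpers --------------------------------------------------
    def _displacements(self, coords, i, j):
        d = coords[j] - coords[i]
        cell = self.system.cell
        if cell is None:
            return d
        inplane = cell[:2, :2]
        frac = d[:, :2] @ np.linalg.inv(inplane)
        frac -= np.round(frac)
        # exact 2-D minimum image for skewed (hexagonal) cells
        best = None
        best_r2 = None
        for s1 in (-1.0, 0.0, 1.0):
            for s2 in (-1.0, 0.0, 1.0):
                cand = (frac + np.array([s1, s2])) @ inplane
                r2 = cand[:, 0] ** 2 + cand[:, 1] ** 2
                if best is None:
                    best, best_r2 = cand.copy(), r2
                else:
                    upd = r2 < best_r2
                    best[upd] = cand[upd]
                    best_r2 = np.where(upd, r2, best_r2)
        out = d.copy()
        out[:, :2] = best
        return out

    def _pair_terms(self, coords, i, j, eps, sig, qq, s_lj, s_cl,
                    want_forces=True):
        """Switched LJ + Coulomb pair energies (and optionally the force
        contribution array f_ij applied to atom j, -f_ij to atom i)."""
        rc, rs = self.params.cutoff, self.params.switch_start
        d = self._displacements(coords, i, j)
        r2 = np.einsum("ij,ij->i", d, d)
        mask = r2 < rc * rc
        e_lj = np.zeros(len(i)); e_cl = np.zeros(len(i))
        fvec = np.zeros((len(i), 3)) if want_forces else None
        if not mask.any():
            return e_lj, e_cl, fvec
        r2m = r2[mask]
        r = np.sqrt(r2m)
        inv_r2 = 1.0 / r2m
        sr2 = sig[mask] ** 2 * inv_r2
        sr6 = sr2 ** 3
        elj = 4.0 * eps[mask] * (sr6 * sr6 - sr6) * s_lj[mask]
        ecl = qq[mask] / r * s_cl[mask]
        # CHARMM-style switching, C1 at both window edges
        rc2, rs2 = rc * rc, rs * rs
        t = rc2 - r2m
        u3 = (rc2 - rs2) ** 3
        sw = np.where(r2m <= rs2, 1.0, t * t * (rc2 + 2.0 * r2m - 3.0 * rs2) / u3)
        e_lj[mask] = elj * sw
        e_cl[mask] = ecl * sw
        if want_forces:
            delj_dr = 4.0 * eps[mask] * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r * s_lj[mask]
            decl_dr = -qq[mask] * inv_r2 * s_cl[mask]
            dsw_dr2 = np.where(
                r2m <= rs2, 0.0,
                (2.0 * t * t - 2.0 * t * (rc2 + 2.0 * r2m - 3.0 * rs2)) / u3)
            dsw_dr = 2.0 * r * dsw_dr2
            dtot_dr = (delj_dr + decl_dr) * sw + (elj + ecl) * dsw_dr
            # force on atom j along +d
            fvec[mask] = (-dtot_dr / r)[:, None] * d[mask]
        return e_lj, e_cl, fvec

    # -- public evaluation -------------------------------------------------
    def energy_forces(self, coords=None, want_forces=True,
                      want_profile=False):
        sys_ = self.system
        x = sys_.coords if coords is None else np.asarray(coords).reshape(-1, 3)
        n = sys_.n_atoms
        f = np.zeros((n, 3)) if want_forces else None
        br = EnergyBreakdown(e_lj=self.frozen_lj, e_coulomb=self.frozen_coulomb)
        profile = None

        if len(self.b_idx):
            i, j = self.b_idx[:, 0], self.b_idx[:, 1]
            d = x[j] - x[i]
            r = np.linalg.norm(d, axis=1)
            dr = r - self.b_r0
            br.e_bond = float(np.sum(self.b_k * dr * dr))
            if want_forces:
                fij = (-2.0 * self.b_k * dr / r)[:, None] * d
                np.add.at(f, j, fij)
                np.add.at(f, i, -fij)

        if len(self.a_idx):
            i, j, k = self.a_idx.T
            u = x[i] - x[j]
            v = x[k] - x[j]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            cos_t = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
            theta = np.arccos(cos_t)
            dth = theta - self.a_t0
            br.e_angle = float(np.sum(self.a_k * dth * dth))
            if want_forces:
                sin_t = np.sqrt(np.clip(1.0 - cos_t * cos_t, 1e-12, None))
                dE = 2.0 * self.a_k * dth
                uh = u / nu[:, None]
                vh = v / nv[:, None]
                fi = (-dE / (nu * sin_t))[:, None] * (cos_t[:, None] * uh - vh)
                fk = (-dE / (nv * sin_t))[:, None] * (cos_t[:, None] * vh - uh)
                np.add.at(f, i, fi)
                np.add.at(f, k, fk)
                np.add.at(f, j, -(fi + fk))

        for idx, kk, nn, pp, slot in (
            (self.d_idx, self.d_k, self.d_n, self.d_p, "e_dihedral"),
            (self.im_idx, self.im_k, self.im_n, self.im_p, "e_improper"),
        ):
            if not len(idx):
                continue
            e_val = self._torsion(x, idx, kk, nn, pp, f if want_forces else None)
            setattr(br, slot, getattr(br, slot) + e_val)

        if len(self.p_i):
            e_lj, e_cl, fvec = self._pair_terms(
                x, self.p_i, self.p_j, self.p_eps, self.p_sig, self.p_qq,
                self.p_slj, self.p_scl, want_forces=want_forces)
            br.e_lj += float(e_lj.sum())
            br.e_coulomb += float(e_cl.sum())
            surf = e_lj[self.p_surface] + e_cl[self.p_surface]
            br.e_peptide_surface = float(surf.sum())
            if want_profile:
                profile = {}
                for rid in np.unique(self.p_surf_resid):
                    profile[int(rid)] = float(surf[self.p_surf_resid == rid].sum())
            if want_forces:
                np.add.at(f, self.p_j, fvec)
                np.add.at(f, self.p_i, -fvec)

        if self.restraints is not None:
            ridx = self.restraints.indices
            d = x[ridx] - self.restraints.anchors
            br.e_restraint = float(self.restraints.k * np.sum(d * d))
            if want_forces:
                f[ridx] += -2.0 * self.restraints.k * d

        if want_forces:
            f[sys_.fixed] = 0.0
        if want_profile:
            return br, f, (profile or {})
        return br, f

    def cross_interaction(self, coords=None) -> float:
        """Sum of nonbonded pair energies crossing the substrate / adsorbate
        divide — the single-point binding energy of Eq.-1 form, computed
        over one pair list so separated fragments give exactly zero."""
        x = self.system.coords if coords is None else np.asarray(coords).reshape(-1, 3)
        if not len(self.p_i):
            return 0.0
        e_lj, e_cl, _ = self._pair_terms(
            x, self.p_i, self.p_j, self.p_eps, self.p_sig, self.p_qq,
            self.p_slj, self.p_scl, want_forces=False)
        return float(np.sum(e_lj[self.p_cross]) + np.sum(e_cl[self.p_cross]))

    def _torsion(self, x, idx, kcoef, ncoef, p0, f):
        i, j, k, l = idx.T
        b1 = x[j] - x[i]
        b2 = x[k] - x[j]
        b3 = x[l] - x[k]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        m = np.cross(n1, b2 / nb2[:, None])
        xx = np.einsum("ij,ij->i", n1, n2)
        yy = np.einsum("ij,ij->i", m, n2)
        phi = np.arctan2(yy, xx)
        e = float(np.sum(kcoef * (1.0 + np.cos(ncoef * phi - p0))))
        if f is not None:
            dEdphi = -kcoef * ncoef * np.sin(ncoef * phi - p0)
            sn1 = np.clip(np.einsum("ij,ij->i", n1, n1), 1e-12, None)
            sn2 = np.clip(np.einsum("ij,ij->i", n2, n2), 1e-12, None)
            p = (np.einsum("ij,ij->i", b1, b2) / nb2 / sn1)[:, None] * n1
            q = (np.einsum("ij,ij->i", b3, b2) / nb2 / sn2)[:, None] * n2
            dphi_di = (nb2 / sn1)[:, None] * n1
            dphi_dl = (-nb2 / sn2)[:, None] * n2
            dphi_dj = -dphi_di - p - q
            dphi_dk = p + q - dphi_dl
            np.add.at(f, i, -dEdphi[:, None] * dphi_di)
            np.add.at(f, j, -dEdphi[:, None] * dphi_dj)
            np.add.at(f, k, -dEdphi[:, None] * dphi_dk)
            np.add.at(f, l, -dEdphi[:, None] * dphi_dl)
        return e


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def total_energy(system: MolecularSystem, params: ForceFieldParams | None = None,
                 restraints: Restraints | None = None) -> EnergyBreakdown:
    """Full MM energy breakdown of ``system`` (deterministic single point)."""
    params = params or ForceFieldParams.default()
    br, _ = Evaluator(system, params, restraints).energy_forces(want_forces=False)
    return br


def forces(system: MolecularSystem, params: ForceFieldParams | None = None,
           restraints: Restraints | None = None) -> np.ndarray:
    """Analytic per-atom forces (kcal/mol/Å); fixed atoms report zero."""
    params = params or ForceFieldParams.default()
    _, f = Evaluator(system, params, restraints).energy_forces()
    return f


def split_complex(complex_system: MolecularSystem
                  ) -> tuple[MolecularSystem, MolecularSystem]:
    """Split a peptide/substrate complex into its components by segment
    label, sharing the complex's coordinates (single-point convention)."""
    pep = complex_system.subset(complex_system.segments != "slab")
    sub = complex_system.subset(complex_system.segments == "slab")
    if pep.n_atoms == 0 or sub.n_atoms == 0:
        raise ValueError("complex must contain both peptide and slab atoms")
    return pep, sub


def binding_energy(complex_system: MolecularSystem,
                   peptide: MolecularSystem | None = None,
                   substrate: MolecularSystem | None = None,
                   params: ForceFieldParams | None = None) -> float:
    """Adsorption energy E_BE = E_complex − E_peptide − E_substrate
    (kcal/mol) at the complex's coordinates.  Lower is more stable.

    With the shared single-point coordinates every intra-fragment term
    cancels and E_BE reduces to the substrate↔adsorbate interaction, which
    is what gets evaluated (one pair list, so full separation gives an
    exact zero)."""
    params = params or ForceFieldParams.default()
    if peptide is None or substrate is None:
        peptide, substrate = split_complex(complex_system)
    if peptide.n_atoms + substrate.n_atoms != complex_system.n_atoms:
        raise ValueError("peptide + substrate atom counts do not match complex")
    comp_elems = np.sort(complex_system.elements)
    part_elems = np.sort(np.concatenate([peptide.elements, substrate.elements]))
    if not np.array_equal(comp_elems, part_elems):
        raise ValueError("peptide/substrate elements do not match the complex")
    return Evaluator(complex_system, params).cross_interaction()


def per_residue_binding(complex_system: MolecularSystem,
                        params: ForceFieldParams | None = None) -> BindingProfile:
    """Per-residue binding profile, N→C: residue r's value is the sum of
    peptide–surface nonbonded terms whose peptide atom belongs to r.  Cap
    contributions fold into the adjacent terminal residue.  The profile
    sums to the peptide–surface interaction total."""
    params = params or ForceFieldParams.default()
    pep_mask = complex_system.segments == "peptide"
    if not pep_mask.any():
        raise ValueError("complex has no atoms labelled as peptide")
    ev = Evaluator(complex_system, params)
    br, _, by_resid = ev.energy_forces(want_forces=False, want_profile=True)

    order = []
    resnames = {}
    for rid in np.unique(complex_system.resids[pep_mask]):
        resnames[int(rid)] = str(
            complex_system.resnames[complex_system.resids == rid][0])
        order.append(int(rid))
    body = [r for r in order if resnames[r] not in ("ACE", "NH2")] or order
    slot_of = {r: i for i, r in enumerate(body)}
    for r in order:
        if r not in slot_of:  # fold caps into the nearest body residue
            slot_of[r] = 0 if r < body[0] else len(body) - 1
    energies = np.zeros(len(body))
    for rid, e in by_resid.items():
        energies[slot_of[int(rid)]] += e
    total = float(energies.sum())
    if abs(total - br.e_peptide_surface) > 1e-8 * max(1.0, abs(total)):
        raise AssertionError("per-residue decomposition lost energy")
    return BindingProfile(
        labels=tuple(resnames[r] for r in body), energies=energies)
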