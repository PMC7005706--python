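"""Structure and trajectory I/O: PDB v3.3, XYZ, multi-frame XYZ, CSV.

Writers emit plain-text formats with 1-based atom/residue numbering (PDB
convention; internal indexing is 0-based).  The slab's in-plane periodic
cell is recorded in a CRYST1 record; the open surface-normal direction is
written as a large vacuum length along c.  Readers validate eagerly and
report the offending line number.
"""

from __future__ import annotations

import csv

import numpy as np

from .residues import ONE_TO_THREE, get_template
from .system import MolecularSystem

__all__ = [
    "write_pdb", "read_pdb", "write_xyz", "read_xyz",
    "write_trajectory_xyz", "write_energy_csv",
]

_SEGMENT_OF_RESNAME = {"HOH": "water", "SLB": "slab", "BNZ": "probe"}


def _cell_to_cryst1(cell: np.ndarray) -> str:
    a = float(np.linalg.norm(cell[0, :2]))
    b = float(np.linalg.norm(cell[1, :2]))
    c = float(cell[2, 2])
    gamma = float(np.degrees(np.arccos(
        np.dot(cell[0, :2], cell[1, :2]) / (a * b))))
    return (f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{gamma:7.2f} P 1           1\n")


def write_pdb(system: MolecularSystem, path) -> None:
    """Write ATOM/HETATM records (elements right-justified in columns
    77–78); slab atoms go out as HETATM."""
    with open(path, "w") as fh:
        if system.cell is not None:
            fh.write(_cell_to_cryst1(system.cell))
        serial = 0
        last_peptide_idx = np.flatnonzero(system.segments == "peptide")
        last_peptide_idx = last_peptide_idx[-1] if len(last_peptide_idx) else -1
        for i in range(system.n_atoms):
            serial += 1
            record = "HETATM" if system.segments[i] == "slab" else "ATOM  "
            name = str(system.names[i])
            pdb_name = f" {name:<3}" if len(name) < 4 else name[:4]
            x, y, z = system.coords[i]
            fh.write(
                f"{record}{serial:5d} {pdb_name} {str(system.resnames[i]):>3} "
                f"A{int(system.resids[i]):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{str(system.elements[i]).capitalize():>2}\n")
            if i == last_peptide_idx:
                serial += 1
                fh.write(f"TER   {serial:5d}      "
                         f"{str(system.resnames[i]):>3} A"
                         f"{int(system.resids[i]):4d}\n")
        fh.write("END\n")


class PdbFormatError(ValueError):
    pass


def read_pdb(path) -> MolecularSystem:
    """Read a PDB written by this package (or an equivalent single-model
    file restricted to the supported residues).  Malformed records and
    unknown residues raise with the line number."""
    names, elements, resids, resnames, coords = [], [], [], [], []
    cell = None
    known = (set(ONE_TO_THREE.values()) | {"ACE", "NH2"}
             | set(_SEGMENT_OF_RESNAME) | {"AU", "PT", "AG"})
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "CRYST1":
                try:
                    a, b, c = (float(line[6:15]), float(line[15:24]),
                               float(line[24:33]))
                    gamma = np.radians(float(line[47:54]))
                except ValueError as exc:
                    raise PdbFormatError(
                        f"{path}:{lineno}: malformed CRYST1 record") from exc
                cell = np.zeros((3, 3))
                cell[0, 0] = a
                cell[1, :2] = b * np.array([np.cos(gamma), np.sin(gamma)])
                cell[2, 2] = c
                continue
            if rec not in ("ATOM", "HETATM"):
                continue
            try:
                name = line[12:16].strip()
                resname = line[17:20].strip()
                resid = int(line[22:26])
                xyz = [float(line[30 + 8 * k:38 + 8 * k]) for k in range(3)]
            except (ValueError, IndexError) as exc:
                raise PdbFormatError(
                    f"{path}:{lineno}: malformed {rec} record") from exc
            if resname not in known:
                raise PdbFormatError(
                    f"{path}:{lineno}: unknown residue {resname!r}")
            element = line[76:78].strip().upper() or name[:1].upper()
            names.append(name)
            elements.append(element)
            resids.append(resid)
            resnames.append(resname)
            coords.append(xyz)
    if not names:
        raise PdbFormatError(f"{path}: no ATOM/HETATM records found")
    return _assemble_system(np.array(names), np.array(elements),
                            np.array(resids, dtype=int), np.array(resnames),
                            np.array(coords, dtype=float), cell, path)


def _assemble_system(names, elements, resids, resnames, coords, cell, path):
    """Recover segments, MM types/charges and bonds from residue identity."""
    n = len(names)
    segments = np.empty(n, dtype="U7")
    types = np.empty(n, dtype="U2")
    charges = np.zeros(n)
    fixed = np.zeros(n, dtype=bool)
    bonds: list[tuple[int, int]] = []
    prev_c = -1
    order = np.arange(n)
    for rid in dict.fromkeys(resids[order]):
        idx = np.flatnonzero(resids == rid)
        resname = str(resnames[idx[0]])
        if resname in ("SLB", "AU", "PT", "AG"):
            segments[idx] = "slab"
            types[idx] = elements[idx]
            fixed[idx] = True
            prev_c = -1
        elif resname == "HOH":
            segments[idx] = "water"
            for i in idx:
                types[i] = "OW" if elements[i] == "O" else "HW"
                charges[i] = -0.834 if elements[i] == "O" else 0.417
            o = idx[elements[idx] == "O"][0]
            for h in idx[elements[idx] == "H"]:
                bonds.append((o, h))
            prev_c = -1
        elif resname == "BNZ":
            segments[idx] = "probe"
            for i in idx:
                types[i] = "CA" if elements[i] == "C" else "HA"
            carbons = idx[elements[idx] == "C"]
            for k, c_i in enumerate(carbons):
                bonds.append((int(c_i), int(carbons[(k + 1) % len(carbons)])))
            prev_c = -1
        else:
            segments[idx] = "peptide"
            tpl = get_template(resname)
            name_to_idx = {}
            for i in idx:
                if names[i] not in tpl.atom_names:
                    raise PdbFormatError(
                        f"{path}: atom {names[i]!r} not in residue "
                        f"{resname} template")
                k = tpl.index(names[i])
                types[i] = tpl.mm_types[k]
                charges[i] = tpl.charges[k]
                name_to_idx[names[i]] = int(i)
            for a, b in tpl.bonds:
                if a in name_to_idx and b in name_to_idx:
                    bonds.append((name_to_idx[a], name_to_idx[b]))
            if prev_c >= 0 and "N" in name_to_idx and resname != "ACE":
                bonds.append((prev_c, name_to_idx["N"]))
            prev_c = name_to_idx.get("C", -1)
    return MolecularSystem(
        names=names, elements=elements, resids=resids, resnames=resnames,
        segments=segments, types=types, charges=charges, coords=coords,
        bonds=np.array(bonds, dtype=int).reshape(-1, 2), fixed=fixed,
        cell=cell)


def write_xyz(system: MolecularSystem, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{system.n_atoms}\n{comment}\n")
        for el, (x, y, z) in zip(system.elements, system.coords):
            fh.write(f"{str(el).capitalize():<2} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def read_xyz(path) -> tuple[np.ndarray, np.ndarray, str]:
    """Return (elements, coords, comment); a count/body mismatch raises
    with the header line number."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}:1: empty XYZ file")
    try:
        n = int(lines[0].strip())
    except ValueError as exc:
        raise ValueError(f"{path}:1: XYZ header is not an atom count") from exc
    body = [l for l in lines[2:2 + n]]
    if len(body) != n or any(len(l.split()) < 4 for l in body):
        raise ValueError(
            f"{path}:1: header declares {n} atoms but the body disagrees")
    elements = np.array([l.split()[0].upper() for l in body])
    coords = np.array([[float(v) for v in l.split()[1:4]] for l in body])
    comment = lines[1] if len(lines) > 1 else ""
    return elements, coords, comment


def write_trajectory_xyz(traj, system: MolecularSystem, path) -> None:
    """Multi-frame XYZ; the comment line carries step, potential energy and
    instantaneous temperature."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{system.n_atoms}\n")
            fh.write(f"step={int(round(traj.times[f] / traj.config.timestep))} "
                     f"time_fs={traj.times[f]:.2f} "
                     f"epot={traj.epot[f]:.6f} temp={traj.temperature[f]:.2f}\n")
            for el, (x, y, z) in zip(system.elements, traj.coords[f]):
                fh.write(f"{str(el).capitalize():<2} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def write_energy_csv(traj, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_fs", "epot_kcal_mol", "ekin_kcal_mol",
                    "etot_kcal_mol", "temperature_K"])
        for f in range(traj.n_frames):
            w.writerow([f"{traj.times[f]:.3f}", f"{traj.epot[f]:.6f}",
                        f"{traj.ekin[f]:.6f}", f"{traj.etot[f]:.6f}",
                        f"{traj.temperature[f]:.2f}"])
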