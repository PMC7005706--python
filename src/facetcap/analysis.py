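"""Post-hoc adsorption analysis: ring orientation, lock-and-key registry,
vacuum/water comparison tables, and on-surface mobility.

A flat-lying aromatic or pyrrolidine ring can sink into registry with the
(111) surface so that the ring encloses a top-layer metal atom while its
ring atoms line up with second-/third-layer lattice sites — the
lock-and-key (LAK) match that strengthens the dispersion contact.  The
numeric thresholds used to classify orientations are an interpretive
operationalization of what is judged visually in structure figures; they
are configuration-exposed and reported alongside every result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .peptide import find_rings
from .slab import Slab, surface_registry
from .system import MolecularSystem

__all__ = [
    "AnalysisThresholds", "RingRecord", "LakReport", "ring_orientation",
    "detect_lak", "percent_difference", "environment_comparison",
    "ComparisonTable", "mobility", "MobilityReport",
]

ORIENTATION_CLASSES = ("flat-on", "stand-up", "intermediate", "detached")


@dataclass(frozen=True)
class AnalysisThresholds:
    """Interpretive classification thresholds (all config-exposed).

    ``flat_tilt``/``stand_tilt`` split ring-plane tilt (° from the surface
    plane normal); ``contact_height`` / ``detach_height`` bound the ring
    centroid height above the top layer (Å); ``registry_tol`` is the
    lateral tolerance for a centroid to count as enclosing a top atom;
    ``planarity_rms`` flags distorted rings.
    """

    flat_tilt: float = 20.0
    stand_tilt: float = 60.0
    contact_height: float = 4.5
    detach_height: float = 6.0
    registry_tol: float = 0.8
    planarity_rms: float = 0.25


@dataclass
class RingRecord:
    """Classification of one ring against the surface."""

    resid: int
    resname: str
    ring_size: int
    orientation: str
    tilt_deg: float
    height: float
    lak: bool
    centroid_site: str
    centroid_site_distance: float
    atom_sites: tuple[str, ...]
    planarity_rms: float
    planarity_warning: bool = False


@dataclass
class LakReport:
    """Per-ring lock-and-key records for one configuration."""

    records: list[RingRecord] = field(default_factory=list)
    thresholds: AnalysisThresholds = field(default_factory=AnalysisThresholds)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def any_lak(self) -> bool:
        return any(r.lak for r in self.records)

    def as_dict(self) -> dict:
        return {
            "note": ("LAK here is an operational geometric criterion "
                     "(flat-on ring whose centroid sits over a top atom "
                     "within the registry tolerance), not a free-energy "
                     "statement"),
            "thresholds": vars(self.thresholds),
            "rings": [vars(r) for r in self.records],
        }


def _ring_geometry(ring_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    centroid = ring_coords.mean(axis=0)
    centered = ring_coords - centroid
    _, s, vt = np.linalg.svd(centered)
    normal = vt[2]
    rms = float(s[2] / np.sqrt(len(ring_coords)))
    return centroid, normal, rms


def ring_orientation(ring_coords: np.ndarray, slab: Slab,
                     thresholds: AnalysisThresholds | None = None
                     ) -> tuple[str, float, float]:
    """Orientation class, tilt (°) and centroid height (Å) of a ring.

    Tilt is the angle between the ring-plane normal and the surface
    normal, folded into [0°, 90°].  Flat-on requires small tilt at contact
    height; stand-up requires large tilt at contact; far rings are
    detached; everything else (including non-planar rings, with a warning
    upstream) is intermediate.
    """
    ring_coords = np.asarray(ring_coords, dtype=float)
    if ring_coords.shape[0] not in (5, 6):
        raise ValueError("a ring must have 5 or 6 atoms")
    th = thresholds or AnalysisThresholds()
    centroid, normal, rms = _ring_geometry(ring_coords)
    cos_t = abs(float(normal[2]) / np.linalg.norm(normal))
    tilt = float(np.degrees(np.arccos(np.clip(cos_t, 0.0, 1.0))))
    height = float(centroid[2] - slab.top_z)
    if height > th.detach_height:
        orientation = "detached"
    elif rms > th.planarity_rms:
        orientation = "intermediate"
    elif tilt <= th.flat_tilt and height <= th.contact_height:
        orientation = "flat-on"
    elif tilt >= th.stand_tilt and height <= th.contact_height:
        orientation = "stand-up"
    else:
        orientation = "intermediate"
    return orientation, tilt, height


def detect_lak(system: MolecularSystem, slab: Slab,
               rings: list[np.ndarray] | None = None,
               thresholds: AnalysisThresholds | None = None) -> LakReport:
    """Lock-and-key report for every ring of ``system``.

    Rings default to the template-defined ones (Phe six-ring, Pro
    five-ring); a ring is LAK-matched when it is flat-on and its centroid
    projects within the registry tolerance of a top-layer atom.  The
    per-atom site classes record the second-/third-layer registry of each
    ring atom.  Ring-free systems yield an empty report.
    """
    th = thresholds or AnalysisThresholds()
    registry = surface_registry(slab)
    if rings is None:
        rings = find_rings(system)
    report = LakReport(thresholds=th)
    for ring_idx in rings:
        coords = system.coords[ring_idx]
        orientation, tilt, height = ring_orientation(coords, slab, th)
        centroid, _, rms = _ring_geometry(coords)
        site, dist = registry.classify(centroid[:2])
        lak = (orientation == "flat-on"
               and registry.distance_to_class(centroid[:2], "top") <= th.registry_tol)
        atom_sites = tuple(registry.classify(system.coords[i][:2])[0]
                           for i in ring_idx)
        report.records.append(RingRecord(
            resid=int(system.resids[ring_idx[0]]),
            resname=str(system.resnames[ring_idx[0]]),
            ring_size=len(ring_idx), orientation=orientation,
            tilt_deg=tilt, height=height, lak=lak,
            centroid_site=site, centroid_site_distance=dist,
            atom_sites=atom_sites, planarity_rms=rms,
            planarity_warning=rms > th.planarity_rms))
    return report


# ---------------------------------------------------------------------------
# vacuum / water comparison
# ---------------------------------------------------------------------------

def percent_difference(e_a: float, e_b: float) -> float:
    """Relative contrast 100 × (E_a − E_b) / E_b with E_b the reference."""
    if e_b == 0:
        raise ZeroDivisionError("reference energy is zero")
    return 100.0 * (e_a - e_b) / e_b


@dataclass
class ComparisonTable:
    """Adsorption energies per configuration in vacuum and in water, plus
    pairwise percent differences (reference stated in each row)."""

    labels: tuple[str, ...]
    vacuum: np.ndarray
    water: np.ndarray
    profiles: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def percent(self, a: str, b: str, environment: str = "vacuum") -> float:
        vals = dict(zip(self.labels, self.vacuum if environment == "vacuum"
                        else self.water))
        return percent_difference(vals[a], vals[b])

    def as_dict(self) -> dict:
        rows = []
        for a in self.labels:
            for b in self.labels:
                if a == b:
                    continue
                for env in ("vacuum", "water"):
                    rows.append({"a": a, "b": b, "reference": b,
                                 "environment": env,
                                 "percent_difference": self.percent(a, b, env)})
        return {
            "labels": list(self.labels),
            "vacuum_kcal_mol": self.vacuum.tolist(),
            "water_kcal_mol": self.water.tolist(),
            "percent_differences": rows,
        }

    def to_text(self) -> str:
        lines = [f"{'configuration':>16} {'vacuum':>12} {'water':>12}"]
        for i, lab in enumerate(self.labels):
            lines.append(f"{lab:>16} {self.vacuum[i]:>12.2f} {self.water[i]:>12.2f}")
        for a in self.labels:
            for b in self.labels:
                if a >= b:
                    continue
                lines.append(
                    f"{a} vs {b} (ref {b}): vacuum "
                    f"{self.percent(a, b, 'vacuum'):+.2f}%  water "
                    f"{self.percent(a, b, 'water'):+.2f}%")
        return "\n".join(lines)


def environment_comparison(entries: dict[str, tuple[float, object]],
                           production_fraction: float = 0.5,
                           profiles: dict | None = None) -> ComparisonTable:
    """Build a vacuum-vs-water comparison table.

    ``entries`` maps a configuration label to ``(vacuum_E_BE, water)``,
    where ``water`` is either a single number or a time series whose
    trailing ``production_fraction`` is averaged (the production window).
    When per-residue profiles are supplied for several configurations they
    must share the residue ordering.
    """
    labels = tuple(entries)
    vacuum, water = [], []
    for lab in labels:
        vac, wat = entries[lab]
        vacuum.append(float(vac))
        arr = np.atleast_1d(np.asarray(wat, dtype=float))
        start = int(round((1.0 - production_fraction) * (len(arr) - 1)))
        water.append(float(arr[start:].mean()))
    profiles = profiles or {}
    lengths = {len(p) for p in profiles.values()}
    if len(lengths) > 1:
        raise ValueError("per-residue profiles have mismatched residue counts")
    return ComparisonTable(labels=labels, vacuum=np.array(vacuum),
                           water=np.array(water), profiles=profiles)


# ---------------------------------------------------------------------------
# on-surface mobility
# ---------------------------------------------------------------------------

@dataclass
class MobilityReport:
    """In-plane center-of-mass displacement from the first frame
    (minimum-image unwrapped), with summary statistics."""

    displacement: np.ndarray  # (F,)
    path: np.ndarray          # (F, 2) unwrapped COM positions

    @property
    def max(self) -> float:
        return float(self.displacement.max())

    @property
    def mean(self) -> float:
        return float(self.displacement.mean())


def mobility(trajectory, system: MolecularSystem, slab: Slab | None = None,
             mask: np.ndarray | None = None) -> MobilityReport:
    """Lateral COM drift of the peptide along a trajectory.

    Frame-to-frame COM increments are minimum-image corrected against the
    slab's surface cell and accumulated, so a walk across a periodic
    boundary counts its true path (unwrapped convention).
    """
    if mask is None:
        mask = system.segments == "peptide"
    masses = system.masses[mask]
    coords = trajectory.coords if hasattr(trajectory, "coords") else np.asarray(trajectory)
    com = np.einsum("fij,i->fj", coords[:, mask, :2], masses) / masses.sum()
    inplane = None
    if slab is not None:
        inplane = slab.surface_vectors
    elif system.cell is not None:
        inplane = system.cell[:2, :2]
    steps = np.diff(com, axis=0)
    if inplane is not None and len(steps):
        frac = steps @ np.linalg.inv(inplane)
        frac -= np.round(frac)
        steps = frac @ inplane
    path = np.vstack([com[:1], com[0] + np.cumsum(steps, axis=0)]) if len(steps) \
        else com[:1].copy()
    disp = np.linalg.norm(path - path[0], axis=1)
    return MobilityReport(displacement=disp, path=path)
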