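"""Geometric detection of the four noncovalent interaction classes.

Intermolecular contacts between solute molecules are classified as
hydrogen bonds (HB), π–π ring stacking (PIPI), C–H···O contacts (CHO)
and X–H···π contacts (CHPI for aromatic donors, OHPI for the hydroxyl
proton or the reverse aromatic-H-to-hydroxyl contact).  Distances are
measured under the minimum-image convention in an orthorhombic box;
distance cutoffs are strict upper bounds ("less than"), angle windows
are inclusive.

Default criteria: O···H < 2.6 Å with the O···H–O angle in [135°, 180°]
for hydrogen bonds; ring-carbon-centroid separation < 4.0 Å for π–π;
H···O < 2.8 Å with the C–H···O angle in [120°, 180°]; H···centroid
< 3.0 Å with the C–H···π angle in [120°, 180°] or the O–H···π angle in
[135°, 180°].  All angles are measured at the hydrogen atom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core_model import Frame, MoleculeSpec

HB = "HB"
PIPI = "PIPI"
CHO = "CHO"
CHPI = "CHPI"
OHPI = "OHPI"


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric thresholds for contact detection (Å, degrees)."""

    hb_max_dist: float = 2.6
    hb_angle: tuple[float, float] = (135.0, 180.0)
    pipi_max_dist: float = 4.0
    cho_max_dist: float = 2.8
    cho_angle: tuple[float, float] = (120.0, 180.0)
    xhpi_max_dist: float = 3.0
    chpi_angle: tuple[float, float] = (120.0, 180.0)
    ohpi_angle: tuple[float, float] = (135.0, 180.0)

    def __post_init__(self):
        for d in (self.hb_max_dist, self.pipi_max_dist,
                  self.cho_max_dist, self.xhpi_max_dist):
            if d <= 0:
                raise ValueError("distance cutoffs must be positive")
        for lo, hi in (self.hb_angle, self.cho_angle,
                       self.chpi_angle, self.ohpi_angle):
            if not (0 <= lo < hi <= 180):
                raise ValueError(f"bad angle window [{lo}, {hi}]")


@dataclass(frozen=True)
class InteractionRecord:
    """One detected contact between molecules i and j."""

    kind: str                 # HB | PIPI | CHO | CHPI | OHPI
    i: int
    j: int
    group_i: str              # "hydroxyl" | "ring"
    group_j: str
    distance: float           # Å
    angle: float | None = None  # deg, at the H atom where applicable


def minimum_image_displacement(a: np.ndarray, b: np.ndarray,
                               box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement b−a in an orthorhombic box.

    Each returned component has magnitude ≤ half the box edge; the
    exact half-box tie resolves to +L/2.
    """
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    # floor convention: maps to [-L/2, L/2), then the -L/2 edge flips to +L/2
    d -= box * np.floor(d / box + 0.5)
    d = np.where(np.isclose(d, -box / 2), box / 2, d)
    return d


def _mic_batch(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Vectorised minimum-image displacement for coordinate arrays."""
    d = b - a
    return d - box * np.floor(d / box + 0.5)


def ring_centroid(frame: Frame, molecule: int, spec: MoleculeSpec) -> np.ndarray:
    """Mass-weighted centroid of the six ring carbons.

    Equal carbon masses make this the arithmetic mean; ring hydrogens
    never contribute.
    """
    grp = spec.group("aromatic-ring")
    atoms = frame.molecule_atoms(molecule)[list(grp.atom_indices)]
    masses = np.array([spec.masses[i] for i in grp.atom_indices])
    ref = frame.coords[atoms[0]]
    # unwrap ring atoms around the first one before averaging (PBC safety)
    disp = _mic_batch(ref, frame.coords[atoms], frame.box)
    return ref + (masses[:, None] * disp).sum(0) / masses.sum()


def _angle_at_h(h: np.ndarray, x: np.ndarray, target: np.ndarray,
                box: np.ndarray) -> float:
    """Angle X–H···target at the H vertex, in degrees."""
    v1 = minimum_image_displacement(h, x, box)
    v2 = minimum_image_displacement(h, target, box)
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _candidate_pairs(pos_a, pos_b, box, cutoff):
    """Index pairs with min-image distance strictly below the cutoff.

    Returns (ia, ib, dist); full (len_a × len_b) distance matrix — fine
    at the molecule counts one snapshot holds.
    """
    if len(pos_a) == 0 or len(pos_b) == 0:
        return (np.empty(0, int),) * 2 + (np.empty(0),)
    d = _mic_batch(pos_a[:, None, :], pos_b[None, :, :], box)
    dist = np.sqrt((d ** 2).sum(-1))
    ia, ib = np.nonzero(dist < cutoff)
    return ia, ib, dist[ia, ib]


def _angles_deg(h, x, target, box):
    """Vectorised X–H···target angle at H, degrees."""
    v1 = _mic_batch(h, x, box)
    v2 = _mic_batch(h, target, box)
    c = (v1 * v2).sum(-1) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1))
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def detect_interactions(
    frame: Frame,
    specs: Mapping[str, MoleculeSpec],
    criteria: InteractionCriteria | None = None,
) -> list[InteractionRecord]:
    """All intermolecular contacts passing the geometric criteria.

    Species without functional-group definitions (solvent) are skipped.
    At most one record is emitted per (class, ordered group pair).
    Distance screens run on full numpy matrices; angles are evaluated
    only for the distance-passing candidates.
    """
    crit = criteria or InteractionCriteria()
    box = frame.box

    solute = [m for m in range(frame.n_molecules)
              if specs[frame.mol_species[m]].groups]
    if not solute:
        return []

    # Flat geometry tables over the solute molecules
    oh_mol, oh_hpos, oh_opos = [], [], []       # one hydroxyl per molecule
    ring_mol, centroids = [], []
    rh_mol, rh_hpos, rh_cpos = [], [], []       # ring H with its bonded C
    for m in solute:
        spec = specs[frame.mol_species[m]]
        atoms = frame.molecule_atoms(m)
        if spec.has_group("aromatic-ring"):
            ring_mol.append(m)
            centroids.append(ring_centroid(frame, m, spec))
        hydrox: set[int] = set()
        if spec.has_group("hydroxyl"):
            grp = spec.group("hydroxyl")
            hydrox = set(grp.atom_indices)
            oh_mol.append(m)
            for li in grp.atom_indices:
                (oh_opos if spec.elements[li] == "O" else oh_hpos).append(
                    frame.coords[atoms[li]])
        for li in spec.donor_hydrogens:
            if li in hydrox:
                continue
            hpos = frame.coords[atoms[li]]
            carbons = [a for a, le in zip(atoms, spec.elements) if le == "C"]
            dists = np.linalg.norm(
                _mic_batch(hpos, frame.coords[carbons], box), axis=1)
            rh_mol.append(m)
            rh_hpos.append(hpos)
            rh_cpos.append(frame.coords[carbons[int(np.argmin(dists))]])

    oh_mol = np.asarray(oh_mol, int)
    oh_hpos = np.asarray(oh_hpos, float).reshape(-1, 3)
    oh_opos = np.asarray(oh_opos, float).reshape(-1, 3)
    ring_mol = np.asarray(ring_mol, int)
    centroids = np.asarray(centroids, float).reshape(-1, 3)
    rh_mol = np.asarray(rh_mol, int)
    rh_hpos = np.asarray(rh_hpos, float).reshape(-1, 3)
    rh_cpos = np.asarray(rh_cpos, float).reshape(-1, 3)

    records: list[InteractionRecord] = []
    seen: set[tuple] = set()

    def emit(kind, i, j, gi, gj, dist, ang=None):
        key = (kind, int(i), int(j), gi, gj)
        if key not in seen:
            seen.add(key)
            records.append(InteractionRecord(
                kind, int(i), int(j), gi, gj, float(dist),
                None if ang is None else float(ang)))

    # --- hydrogen bonds: hydroxyl H (donor) to hydroxyl O (acceptor)
    ia, ib, dist = _candidate_pairs(oh_hpos, oh_opos, box, crit.hb_max_dist)
    keep = oh_mol[ia] != oh_mol[ib]
    ia, ib, dist = ia[keep], ib[keep], dist[keep]
    if len(ia):
        ang = _angles_deg(oh_hpos[ia], oh_opos[ia], oh_opos[ib], box)
        for a, b, r, t in zip(ia, ib, dist, ang):
            if crit.hb_angle[0] <= t <= crit.hb_angle[1]:
                emit(HB, oh_mol[a], oh_mol[b], "hydroxyl", "hydroxyl", r, t)

    # --- π–π: ring-centroid separation (i < j once)
    ia, ib, dist = _candidate_pairs(centroids, centroids, box, crit.pipi_max_dist)
    for a, b, r in zip(ia, ib, dist):
        if ring_mol[a] < ring_mol[b]:
            emit(PIPI, ring_mol[a], ring_mol[b], "ring", "ring", r)

    # --- C–H···O
    ia, ib, dist = _candidate_pairs(rh_hpos, oh_opos, box, crit.cho_max_dist)
    keep = rh_mol[ia] != oh_mol[ib]
    ia, ib, dist = ia[keep], ib[keep], dist[keep]
    if len(ia):
        ang = _angles_deg(rh_hpos[ia], rh_cpos[ia], oh_opos[ib], box)
        for a, b, r, t in zip(ia, ib, dist, ang):
            if crit.cho_angle[0] <= t <= crit.cho_angle[1]:
                emit(CHO, rh_mol[a], oh_mol[b], "ring", "hydroxyl", r, t)

    # --- C–H···π
    ia, ib, dist = _candidate_pairs(rh_hpos, centroids, box, crit.xhpi_max_dist)
    keep = rh_mol[ia] != ring_mol[ib]
    ia, ib, dist = ia[keep], ib[keep], dist[keep]
    if len(ia):
        ang = _angles_deg(rh_hpos[ia], rh_cpos[ia], centroids[ib], box)
        for a, b, r, t in zip(ia, ib, dist, ang):
            if crit.chpi_angle[0] <= t <= crit.chpi_angle[1]:
                emit(CHPI, rh_mol[a], ring_mol[b], "ring", "ring", r, t)

    # --- O–H···π
    ia, ib, dist = _candidate_pairs(oh_hpos, centroids, box, crit.xhpi_max_dist)
    keep = oh_mol[ia] != ring_mol[ib]
    ia, ib, dist = ia[keep], ib[keep], dist[keep]
    if len(ia):
        ang = _angles_deg(oh_hpos[ia], oh_opos[ia], centroids[ib], box)
        for a, b, r, t in zip(ia, ib, dist, ang):
            if crit.ohpi_angle[0] <= t <= crit.ohpi_angle[1]:
                emit(OHPI, oh_mol[a], ring_mol[b], "hydroxyl", "ring", r, t)

    return records
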