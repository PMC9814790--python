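"""Geometric analysis of the cation-in-aromatic-cage system.

Implements ring-substructure detection for tryptophan-like indoles (by
atom-name template, not graph perception), ring centroids, cation-ring
distances against the 5-membered ring, 6-membered ring or whole indole,
contact statistics at a geometric cutoff (6 A by convention) with
distance histograms, and closest methyl-H to ring-C contacts.

All outputs are invariant under rigid rotation and translation of the
whole frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .io import Structure, Trajectory
from .synthetic import FIVE_RING_NAMES, SIX_RING_NAMES

SUBSTRUCTURES = ("5MR", "6MR", "whole")


@dataclass(frozen=True)
class RingSystem:
    """An indole decomposed into its fused 5- and 6-membered rings.

    ``five_ring`` and ``six_ring`` intersect exactly in the two fusion
    atoms (CD2, CE2); ``all_heavy`` is their 9-atom union. Fluorine
    substituents are carried separately: they are not ring members and do
    not enter centroid geometry.
    """

    residue_id: int
    five_ring: tuple[int, ...]
    six_ring: tuple[int, ...]
    all_heavy: tuple[int, ...]
    fluorines: tuple[int, ...] = ()
    label: str = "other"

    def substructure(self, which: str) -> np.ndarray:
        if which == "5MR":
            return np.array(self.five_ring)
        if which == "6MR":
            return np.array(self.six_ring)
        if which == "whole":
            return np.array(self.all_heavy)
        raise ValueError(f"unknown substructure {which!r}; expected one of {SUBSTRUCTURES}")


def detect_indole_rings(structure: Structure,
                        residue_ids: list[int] | None = None) -> list[RingSystem]:
    """Find tryptophan-like indole ring systems by atom-name template.

    Every selected residue must carry the full Trp side-chain name set
    (CG, CD1, NE1, CE2, CD2, CE3, CZ3, CH2, CZ2); a residue that does not
    match raises with the residue named. The first two detected systems
    are labelled Trp18-like and Trp28-like in order of appearance.
    """
    if residue_ids is None:
        residue_ids = [rid for rid in structure.residue_ids()
                       if len(structure.select(residue_id=rid, names=FIVE_RING_NAMES)) > 0]
        if not residue_ids:
            raise ValueError("no residue in the structure matches the indole template")
    systems = []
    needed = set(FIVE_RING_NAMES) | set(SIX_RING_NAMES)
    for rid in residue_ids:
        names = {a.name: a.index for a in structure.atoms if a.residue_id == rid}
        missing = needed - set(names)
        if missing:
            raise ValueError(f"residue {rid} does not match the indole template "
                             f"(missing atoms: {sorted(missing)})")
        five = tuple(names[n] for n in FIVE_RING_NAMES)
        six = tuple(names[n] for n in SIX_RING_NAMES)
        heavy = tuple(sorted(set(five) | set(six)))
        fluor = tuple(int(i) for i in structure.select(residue_id=rid, element="F"))
        label = ("Trp18-like", "Trp28-like")[len(systems)] if len(systems) < 2 else "other"
        systems.append(RingSystem(residue_id=rid, five_ring=five, six_ring=six,
                                  all_heavy=heavy, fluorines=fluor, label=label))
    return systems


def centroid(frame: np.ndarray, atom_indices) -> np.ndarray:
    """Unweighted arithmetic mean of the selected atoms' coordinates."""
    atom_indices = np.asarray(atom_indices, dtype=int)
    if atom_indices.size == 0:
        raise ValueError("cannot take the centroid of an empty atom group")
    return np.asarray(frame, dtype=float)[atom_indices].mean(axis=0)


def cation_ring_distance(cation_point: np.ndarray, ring: RingSystem,
                         substructure: str, frame: np.ndarray) -> float:
    """Euclidean distance from the cation reference point to the chosen
    ring-substructure centroid."""
    c = centroid(frame, ring.substructure(substructure))
    return float(np.linalg.norm(np.asarray(cation_point, dtype=float) - c))


@dataclass
class ContactSeries:
    """Per-frame cation-ring distances with contact statistics.

    ``fraction`` is the share of frames with distance below ``cutoff``;
    the histogram's outermost bins absorb out-of-range distances so that
    counts always sum to the frame count.
    """

    distances: np.ndarray
    contact_flags: np.ndarray
    fraction: float
    cutoff: float
    substructure: str
    hist_counts: np.ndarray = field(repr=False)
    hist_edges: np.ndarray = field(repr=False)


def contact_series(trajectory: Trajectory, cation_indices, ring: RingSystem,
                   cutoff: float = 6.0, substructure: str = "whole",
                   bin_width: float = 0.25,
                   hist_range: tuple[float, float] = (2.0, 10.0)) -> ContactSeries:
    """Distance series between the cation reference point and a ring.

    The cation reference point each frame is the centroid of
    ``cation_indices`` — pass the single N index for the quaternary-N
    convention, or the heavy-atom indices for the NMe3 centroid
    convention.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    if trajectory.n_frames == 0:
        raise ValueError("empty trajectory")
    cation_indices = np.atleast_1d(np.asarray(cation_indices, dtype=int))
    sub = ring.substructure(substructure)
    cat = trajectory.coordinates[:, cation_indices, :].mean(axis=1)
    cen = trajectory.coordinates[:, sub, :].mean(axis=1)
    dist = np.linalg.norm(cat - cen, axis=1)
    flags = dist < cutoff
    edges = np.arange(hist_range[0], hist_range[1] + bin_width / 2, bin_width)
    # outermost bins absorb outliers: histogram mass equals the frame count
    clipped = np.clip(dist, edges[0], np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(clipped, bins=edges)
    return ContactSeries(distances=dist, contact_flags=flags,
                         fraction=float(flags.mean()), cutoff=cutoff,
                         substructure=substructure,
                         hist_counts=counts, hist_edges=edges)


def closest_methyl_carbon_distance(frame: np.ndarray, methyl_h_indices,
                                   ring: RingSystem, substructure: str = "whole",
                                   ) -> tuple[float, tuple[int, int]]:
    """Minimum distance over all (methyl H, ring C/N) pairs in one frame.

    Ties are broken deterministically in favour of the lowest (H, ring)
    index pair. Returns (distance, (h_index, ring_index)).
    """
    methyl_h_indices = np.asarray(methyl_h_indices, dtype=int)
    if methyl_h_indices.size == 0:
        raise ValueError("cation has no methyl hydrogens")
    ring_atoms = ring.substructure(substructure)
    frame = np.asarray(frame, dtype=float)
    d = cdist(frame[methyl_h_indices], frame[ring_atoms])
    flat = int(np.argmin(d))  # argmin returns the first minimum: lowest-index tie-break
    hi, ri = divmod(flat, d.shape[1])
    return float(d[hi, ri]), (int(methyl_h_indices[hi]), int(ring_atoms[ri]))
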