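"""Seeded toy systems with known ground truth.

Two generators stand in for expensive simulation inputs:

* :func:`make_cage_trajectory` — a tetramethylammonium (TMA) cation probe
  jittering between two rigid indole rings, the minimal model of a
  trimethyllysine ammonium group held in a two-tryptophan aromatic cage.
  Fluorinated variants keep the ring geometry (F simply replaces the
  designated ring hydrogen) and perturb only the charge set: the carbon
  bonded to each fluorine is shifted positive by exactly the charge it
  must absorb to conserve the residue's net charge.

* :func:`make_water_trajectory` — rigid three-site waters in a box: a
  uniform, uniformly-oriented bulk background plus planted localized
  hydration sites with Gaussian positions and concentration-parameterized
  dipole orientations. Ground-truth site membership is recorded so that
  downstream clustering and entropy estimators can be checked against
  what was planted.

Both generators are bit-deterministic under a fixed spec and seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (AtomRecord, ChargeTable, Structure, Trajectory,
                 write_charge_table, write_pdb, write_xyz_trajectory)

VARIANTS = ("WT", "5F", "6F", "56diF")

#: residue name used for each cage variant's indole fragments
VARIANT_RESNAME = {"WT": "TRP", "5F": "W5F", "6F": "W6F", "56diF": "WFF"}

#: ring hydrogens replaced by fluorine, per variant (position 5 = CZ3,
#: position 6 = CH2 in tryptophan side-chain naming)
VARIANT_FLUORINATION = {
    "WT": (),
    "5F": (("CZ3", "HZ3", "FZ3"),),
    "6F": (("CH2", "HH2", "FH2"),),
    "56diF": (("CZ3", "HZ3", "FZ3"), ("CH2", "HH2", "FH2")),
}

_BOND_CC = 1.39   # aromatic C-C, A
_BOND_CH = 1.08
_BOND_NH = 1.01
_BOND_CF = 1.34
_BOND_NC_TMA = 1.49
_BOND_CH_TMA = 1.09

_LJ_BY_ELEMENT = {  # (sigma A, epsilon kcal/mol)
    "C": (3.40, 0.086),
    "N": (3.25, 0.170),
    "H": (2.60, 0.015),
    "F": (3.00, 0.061),
    "O": (3.1507, 0.1521),
}

FIVE_RING_NAMES = ("CG", "CD1", "NE1", "CE2", "CD2")
SIX_RING_NAMES = ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")


# ---------------------------------------------------------------------------
# rigid templates
# ---------------------------------------------------------------------------

def indole_template() -> tuple[list[str], list[str], np.ndarray]:
    """Idealized planar indole fragment in the z=0 plane.

    Regular hexagon and pentagon of side 1.39 A fused on the CD2-CE2 edge,
    ring hydrogens placed radially outward, the 9-heavy-atom centroid at
    the origin. Returns (names, elements, coords).
    """
    s = _BOND_CC
    cd2 = np.array([0.0, -s / 2])
    ce2 = np.array([0.0, +s / 2])
    # hexagon: center one apothem to -x of the fusion edge
    c6 = np.array([-s * np.sqrt(3) / 2, 0.0])
    hexa = {}
    ang0 = np.arctan2(ce2[1] - c6[1], ce2[0] - c6[0])
    for k, name in enumerate(("CE2", "CZ2", "CH2", "CZ3", "CE3", "CD2")):
        ang = ang0 + k * np.pi / 3
        hexa[name] = c6 + s * np.array([np.cos(ang), np.sin(ang)])
    # pentagon: center one apothem to +x, vertices every 72 deg from CE2
    r5 = s / (2 * np.sin(np.pi / 5))
    c5 = np.array([s / (2 * np.tan(np.pi / 5)), 0.0])
    penta = {}
    ang0 = np.arctan2(ce2[1] - c5[1], ce2[0] - c5[0])
    for k, name in enumerate(("CE2", "NE1", "CD1", "CG", "CD2")):
        ang = ang0 - k * 2 * np.pi / 5
        penta[name] = c5 + r5 * np.array([np.cos(ang), np.sin(ang)])
    heavy = {**hexa, **penta}  # CE2/CD2 consistent: both lie on the shared edge
    heavy["CE2"], heavy["CD2"] = ce2, cd2

    order = ["CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2"]
    names = list(order)
    elements = ["N" if n.startswith("N") else "C" for n in order]
    coords = [heavy[n] for n in order]

    # hydrogens radially outward from the owning ring's center
    h_of = {"CG": ("HG", c5), "CD1": ("HD1", c5), "NE1": ("HE1", c5),
            "CE3": ("HE3", c6), "CZ3": ("HZ3", c6), "CH2": ("HH2", c6),
            "CZ2": ("HZ2", c6)}
    for hv, (hname, center) in h_of.items():
        p = heavy[hv]
        u = (p - center) / np.linalg.norm(p - center)
        bond = _BOND_NH if hv.startswith("N") else _BOND_CH
        names.append(hname)
        elements.append("H")
        coords.append(p + bond * u)

    xy = np.array(coords)
    xyz = np.column_stack([xy, np.zeros(len(xy))])
    xyz -= xyz[:9].mean(axis=0)  # 9-heavy centroid at origin
    return names, elements, xyz


def tma_template() -> tuple[list[str], list[str], np.ndarray]:
    """Tetramethylammonium cation: N at origin, 4 tetrahedral methyls."""
    dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
    dirs /= np.sqrt(3)
    names, elements, coords = ["N"], ["N"], [np.zeros(3)]
    theta = np.deg2rad(70.53)  # angle of C-H with the N->C axis
    for ci, a in enumerate(dirs, start=1):
        c = _BOND_NC_TMA * a
        names.append(f"C{ci}")
        elements.append("C")
        coords.append(c)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(a @ ref) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        e1 = np.cross(a, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(a, e1)
        for hi in range(3):
            phi = 2 * np.pi * hi / 3
            u = np.cos(theta) * a + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2)
            names.append(f"H{ci}{hi + 1}")
            elements.append("H")
            coords.append(c + _BOND_CH_TMA * u)
    return names, elements, np.array(coords)


@dataclass(frozen=True)
class RingPlacement:
    """Rigid placement of the canonical indole template.

    ``center`` receives the 9-heavy-atom centroid; ``normal`` is the ring
    plane normal; ``azimuth`` spins the template about that normal.
    """

    center: tuple[float, float, float]
    normal: tuple[float, float, float] = (0.0, 0.0, 1.0)
    azimuth: float = 0.0

    def transform(self, coords: np.ndarray) -> np.ndarray:
        n = np.asarray(self.normal, dtype=float)
        n = n / np.linalg.norm(n)
        ca, sa = np.cos(self.azimuth), np.sin(self.azimuth)
        rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]], dtype=float)
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(z, n)
        c = float(z @ n)
        if np.linalg.norm(v) < 1e-12:
            align = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            align = np.eye(3) + vx + vx @ vx / (1 + c)
        return coords @ (align @ rz).T + np.asarray(self.center, dtype=float)


def default_ring_placements(separation: float = 8.0) -> tuple[RingPlacement, RingPlacement]:
    """Two indoles face-to-face across the cation anchor, centroids
    ``separation`` A apart along z (4 A from the origin each by default)."""
    h = separation / 2
    return (RingPlacement(center=(0.0, 0.0, -h), normal=(0.0, 0.0, 1.0)),
            RingPlacement(center=(0.0, 0.0, +h), normal=(0.0, 0.0, -1.0)))


# ---------------------------------------------------------------------------
# cage generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CageSimSpec:
    """Conditions for one synthetic cage run.

    Defaults mirror the sampling of the reference analysis: 5000 frames at
    20 ps spacing (100 ns of emulated trajectory), cation anchored midway
    between two indoles whose centroids sit 4 A away.
    """

    n_frames: int = 5000
    frame_spacing_ps: float = 20.0
    cation_anchor: tuple[float, float, float] = (0.0, 0.0, 0.0)
    positional_sigma: float = 0.5
    ring_placements: tuple[RingPlacement, RingPlacement] = field(
        default_factory=default_ring_placements)
    variant: str = "WT"
    seed: int = 0
    fluorine_charge: float = -0.16

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.positional_sigma < 0:
            raise ValueError(f"positional_sigma must be >= 0, got {self.positional_sigma}")
        if self.frame_spacing_ps <= 0:
            raise ValueError(f"frame_spacing_ps must be > 0, got {self.frame_spacing_ps}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if len(self.ring_placements) != 2:
            raise ValueError("exactly two ring placements required")


def _cage_structure(spec: CageSimSpec) -> Structure:
    atoms: list[AtomRecord] = []
    tnames, tel, tcoords = tma_template()
    anchor = np.asarray(spec.cation_anchor, dtype=float)
    for n, e, xyz in zip(tnames, tel, tcoords + anchor):
        atoms.append(AtomRecord(index=len(atoms), name=n, element=e,
                                residue_name="TMA", residue_id=1,
                                coordinates=tuple(xyz)))
    inames, iel, icoords = indole_template()
    subs = VARIANT_FLUORINATION[spec.variant]
    resname = VARIANT_RESNAME[spec.variant]
    for ri, placement in enumerate(spec.ring_placements, start=2):
        placed = placement.transform(icoords)
        for n, e, xyz in zip(inames, iel, placed):
            name, element = n, e
            for cname, hname, fname in subs:
                if n == hname:
                    name, element = fname, "F"
                    # F sits on the C-H axis at C-F bond length
                    ci = inames.index(cname)
                    u = placed[inames.index(hname)] - placed[ci]
                    u /= np.linalg.norm(u)
                    xyz = placed[ci] + _BOND_CF * u
            atoms.append(AtomRecord(index=len(atoms), name=name, element=element,
                                    residue_name=resname, residue_id=ri,
                                    coordinates=tuple(xyz)))
    return Structure(atoms=atoms, title=f"synthetic {spec.variant} cage probe")


def variant_charge_table(structure: Structure, variant: str,
                         fluorine_charge: float = -0.16) -> ChargeTable:
    """Point charges for the cage system.

    TMA carries net +1 e (N 0.00, C -0.20, H +0.15); each indole is net
    neutral. On fluorination the replaced hydrogen's charge plus the
    difference to the fluorine charge is moved onto the bonded carbon, so
    the carbon acquires a net positive partial charge and the residue's
    net charge is conserved exactly.
    """
    base = {"N": 0.00, "C": -0.20, "H": 0.15}  # TMA by element
    indole = {"CG": -0.115, "CD1": -0.115, "NE1": -0.40, "CE2": 0.10,
              "CD2": -0.10, "CE3": -0.115, "CZ3": -0.115, "CH2": -0.115,
              "CZ2": -0.115, "HG": 0.115, "HD1": 0.115, "HE1": 0.40,
              "HE3": 0.115, "HZ3": 0.115, "HH2": 0.115, "HZ2": 0.115}
    subs = VARIANT_FLUORINATION[variant]
    ring = dict(indole)
    for cname, hname, fname in subs:
        q_h = ring.pop(hname)
        ring[fname] = fluorine_charge
        ring[cname] = ring[cname] + (q_h - fluorine_charge)
    rows = []
    for a in structure.atoms:
        if a.residue_name == "TMA":
            q = base[a.element]
        else:
            q = ring[a.name]
        sig, eps = _LJ_BY_ELEMENT[a.element]
        rows.append((a.index, a.name, a.residue_name, q, sig, eps))
    df = pd.DataFrame(rows, columns=["atom_index", "atom_name", "residue",
                                     "charge_e", "lj_sigma_A", "lj_epsilon_kcal"])
    return ChargeTable(table=df)


def make_cage_trajectory(spec: CageSimSpec) -> tuple[Structure, Trajectory, ChargeTable]:
    """Generate the cation-in-cage toy trajectory.

    The rings are rigid; the whole TMA probe translates by isotropic
    Gaussian jitter of ``positional_sigma`` about its anchor each frame.
    Same spec and seed give bit-identical output.
    """
    spec.validate()
    structure = _cage_structure(spec)
    rng = np.random.default_rng(spec.seed)
    jitter = rng.normal(scale=spec.positional_sigma, size=(spec.n_frames, 3)) \
        if spec.positional_sigma > 0 else np.zeros((spec.n_frames, 3))
    base = structure.coordinates
    tma = structure.select(residue_id=1)
    coords = np.broadcast_to(base, (spec.n_frames,) + base.shape).copy()
    coords[:, tma, :] += jitter[:, None, :]
    times = np.arange(spec.n_frames) * spec.frame_spacing_ps
    traj = Trajectory(times_ps=times, coordinates=coords)
    charges = variant_charge_table(structure, spec.variant, spec.fluorine_charge)
    return structure, traj, charges


def cage_ground_truth(spec: CageSimSpec, structure: Structure,
                      trajectory: Trajectory) -> dict:
    """Ground-truth sidecar: per-frame cation N position and ring centroids."""
    n_index = int(structure.select(residue_id=1, names=["N"])[0])
    ring_centroids = []
    inames, _, _ = indole_template()
    for ri in (2, 3):
        heavy = structure.select(residue_id=ri, names=FIVE_RING_NAMES + SIX_RING_NAMES)
        ring_centroids.append(structure.coordinates[heavy].mean(axis=0).tolist())
    return {
        "variant": spec.variant,
        "seed": spec.seed,
        "anchor": list(spec.cation_anchor),
        "positional_sigma": spec.positional_sigma,
        "ring_centroids": ring_centroids,
        "cation_n_positions": trajectory.coordinates[:, n_index, :].round(6).tolist(),
    }


def write_cage_run(spec: CageSimSpec, outdir: str | Path) -> dict[str, Path]:
    """Emit structure.pdb, trajectory.xyz, charges.tsv and the JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    structure, traj, charges = make_cage_trajectory(spec)
    paths = {"structure": outdir / "structure.pdb",
             "trajectory": outdir / "trajectory.xyz",
             "charges": outdir / "charges.tsv",
             "ground_truth": outdir / "ground_truth.json"}
    write_pdb(structure, paths["structure"])
    write_xyz_trajectory(structure, traj, paths["trajectory"])
    write_charge_table(charges, paths["charges"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump(cage_ground_truth(spec, structure, traj), fh, indent=1, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# water generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSite:
    """A localized hydration site to plant in the water box.

    Positions are Gaussian about the center, truncated at 3 sigma: an
    occupied site water is in the site by definition — excursions beyond
    that are exchange events, which the occupancy flag models instead.
    """

    center: tuple[float, float, float]
    positional_sigma: float = 0.3
    orientational_concentration: float = 10.0
    occupancy_probability: float = 0.9


@dataclass(frozen=True)
class WaterSimSpec:
    """Conditions for one synthetic water run.

    Defaults emulate a short solvated-pocket simulation: a 12 A box of
    bulk-density water over 2000 frames, with localized sites planted on
    top of the background.
    """

    box_lo: tuple[float, float, float] = (0.0, 0.0, 0.0)
    box_hi: tuple[float, float, float] = (12.0, 12.0, 12.0)
    n_frames: int = 2000
    frame_spacing_ps: float = 1.0
    bulk_density: float = 0.0334
    planted_sites: tuple[PlantedSite, ...] = ()
    seed: int = 0
    exclusion_radius: float = 2.4
    min_oo_distance: float = 2.6

    def validate(self) -> None:
        lo, hi = np.asarray(self.box_lo, float), np.asarray(self.box_hi, float)
        if np.any(hi <= lo):
            raise ValueError("box_hi must exceed box_lo on every axis")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.bulk_density <= 0:
            raise ValueError("bulk_density must be > 0")
        for s in self.planted_sites:
            c = np.asarray(s.center, float)
            if np.any(c < lo) or np.any(c > hi):
                raise ValueError(f"planted site center {s.center} lies outside the box")
            if not 0.0 <= s.occupancy_probability <= 1.0:
                raise ValueError("occupancy_probability must be in [0, 1]")
            if s.positional_sigma < 0:
                raise ValueError("positional_sigma must be >= 0")
        centers = np.array([s.center for s in self.planted_sites], float)
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                d = float(np.linalg.norm(centers[i] - centers[j]))
                if d < 2.0:
                    warnings.warn(f"planted sites {i} and {j} overlap "
                                  f"(centers {d:.2f} A apart)", stacklevel=2)

    @property
    def volume(self) -> float:
        lo, hi = np.asarray(self.box_lo, float), np.asarray(self.box_hi, float)
        return float(np.prod(hi - lo))


# rigid 3-site water in its canonical frame: O at origin, dipole along +z
_WATER_OH = 0.9572
_WATER_HOH = np.deg2rad(104.52)
_WATER_H = np.array([
    [+np.sin(_WATER_HOH / 2) * _WATER_OH, 0.0, np.cos(_WATER_HOH / 2) * _WATER_OH],
    [-np.sin(_WATER_HOH / 2) * _WATER_OH, 0.0, np.cos(_WATER_HOH / 2) * _WATER_OH],
])

TIP3P_CHARGES = {"O": -0.834, "H": 0.417}


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _random_quaternion(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def _sample_vmf_axis(rng: np.random.Generator, kappa: float) -> np.ndarray:
    """Direction on the sphere concentrated about +z (uniform at kappa=0)."""
    if kappa < 1e-12:
        u = rng.normal(size=3)
        return u / np.linalg.norm(u)
    u = rng.random()
    # inverse-CDF of the vMF polar angle, numerically stable form
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    phi = 2 * np.pi * rng.random()
    s = np.sqrt(max(0.0, 1.0 - w * w))
    return np.array([s * np.cos(phi), s * np.sin(phi), w])


def _rotation_dipole_to(axis: np.ndarray, spin: float) -> np.ndarray:
    """Rotation taking the canonical dipole (+z) to ``axis`` with the given
    spin about the dipole."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(z @ axis)
    if np.linalg.norm(v) < 1e-12:
        align = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        align = np.eye(3) + vx + vx @ vx / (1 + c)
    cs, sn = np.cos(spin), np.sin(spin)
    rz = np.array([[cs, -sn, 0], [sn, cs, 0], [0, 0, 1]])
    return align @ rz


def water_structure(n_waters: int) -> Structure:
    atoms = []
    for w in range(n_waters):
        for name, element in (("O", "O"), ("H1", "H"), ("H2", "H")):
            atoms.append(AtomRecord(index=len(atoms), name=name, element=element,
                                    residue_name="HOH", residue_id=w + 1,
                                    coordinates=(0.0, 0.0, 0.0)))
    return Structure(atoms=atoms, title=f"synthetic water box ({n_waters} waters)")


def water_charge_table(structure: Structure) -> ChargeTable:
    """TIP3P-like charges and LJ parameters (LJ on oxygen only)."""
    rows = []
    for a in structure.atoms:
        q = TIP3P_CHARGES[a.element]
        sig, eps = (3.1507, 0.1521) if a.element == "O" else (0.4, 0.0)
        rows.append((a.index, a.name, a.residue_name, q, sig, eps))
    return ChargeTable(table=pd.DataFrame(
        rows, columns=["atom_index", "atom_name", "residue",
                       "charge_e", "lj_sigma_A", "lj_epsilon_kcal"]))


def make_water_trajectory(spec: WaterSimSpec) -> tuple[Structure, Trajectory, dict]:
    """Generate the planted-site water ensemble.

    Waters 0..n_planted-1 are the planted-site waters; in frames where a
    site is unoccupied its water is resampled as an ordinary bulk water
    (emulating exchange with bulk, and keeping the per-frame atom count
    constant). Bulk waters avoid a hard-sphere shell of
    ``exclusion_radius`` around occupied planted centers and keep at
    least ``min_oo_distance`` between oxygens (a liquid-like hard core,
    so pair energies stay physical). The returned ground-truth dict
    records per-frame site occupancy.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo = np.asarray(spec.box_lo, float)
    hi = np.asarray(spec.box_hi, float)
    n_planted = len(spec.planted_sites)
    n_bulk = int(round(spec.bulk_density * spec.volume))
    n_waters = n_planted + n_bulk
    if n_waters == 0:
        raise ValueError("spec generates no waters (empty box and no planted sites)")
    structure = water_structure(n_waters)

    centers = np.array([s.center for s in spec.planted_sites], float).reshape(n_planted, 3)
    occupied = np.zeros((spec.n_frames, n_planted), dtype=bool)
    coords = np.empty((spec.n_frames, n_waters * 3, 3))

    def bulk_position(occupied_centers: np.ndarray, placed: list[np.ndarray]) -> np.ndarray:
        placed_arr = np.array(placed).reshape(-1, 3)
        for _ in range(500):
            p = lo + rng.random(3) * (hi - lo)
            if occupied_centers.size and \
                    np.min(np.linalg.norm(occupied_centers - p, axis=1)) < spec.exclusion_radius:
                continue
            if placed_arr.size and \
                    np.min(np.linalg.norm(placed_arr - p, axis=1)) < spec.min_oo_distance:
                continue
            return p
        return p  # pathological spec (over-dense box): accept the last draw

    for f in range(spec.n_frames):
        frame = np.empty((n_waters, 3, 3))
        occ_centers_list: list[np.ndarray] = []
        placed: list[np.ndarray] = []
        for si, site in enumerate(spec.planted_sites):
            occ = rng.random() < site.occupancy_probability
            occupied[f, si] = occ
            if occ:
                while True:
                    off = rng.normal(scale=site.positional_sigma, size=3) \
                        if site.positional_sigma > 0 else np.zeros(3)
                    if np.linalg.norm(off) <= 3.0 * site.positional_sigma:
                        break
                pos = np.asarray(site.center) + off
                axis = _sample_vmf_axis(rng, site.orientational_concentration)
                rot = _rotation_dipole_to(axis, 2 * np.pi * rng.random())
                occ_centers_list.append(np.asarray(site.center, float))
                placed.append(pos)
                frame[si, 0] = pos
                frame[si, 1:] = pos + _WATER_H @ rot.T
        occ_centers = np.array(occ_centers_list).reshape(-1, 3)
        for wi in range(n_waters):
            if wi < n_planted and occupied[f, wi]:
                continue
            pos = bulk_position(occ_centers, placed)
            placed.append(pos)
            rot = _quat_to_matrix(_random_quaternion(rng))
            frame[wi, 0] = pos
            frame[wi, 1:] = pos + _WATER_H @ rot.T
        coords[f] = frame.reshape(n_waters * 3, 3)

    times = np.arange(spec.n_frames) * spec.frame_spacing_ps
    traj = Trajectory(times_ps=times, coordinates=coords)
    truth = {
        "seed": spec.seed,
        "n_bulk": n_bulk,
        "planted_sites": [
            {"center": list(s.center), "positional_sigma": s.positional_sigma,
             "orientational_concentration": s.orientational_concentration,
             "occupancy_probability": s.occupancy_probability,
             "occupancy_observed": float(occupied[:, i].mean())}
            for i, s in enumerate(spec.planted_sites)
        ],
        "occupied": occupied.tolist(),
    }
    return structure, traj, truth


def write_water_run(spec: WaterSimSpec, outdir: str | Path) -> dict[str, Path]:
    """Emit waters.pdb, waters.xyz, charges.tsv and the ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    structure, traj, truth = make_water_trajectory(spec)
    paths = {"structure": outdir / "waters.pdb",
             "trajectory": outdir / "waters.xyz",
             "charges": outdir / "water_charges.tsv",
             "ground_truth": outdir / "water_ground_truth.json"}
    # frame-0 coordinates stand in for the (placeholder) reference geometry
    ref = Structure(atoms=[AtomRecord(index=a.index, name=a.name, element=a.element,
                                      residue_name=a.residue_name, residue_id=a.residue_id,
                                      coordinates=tuple(traj.coordinates[0, a.index]))
                           for a in structure.atoms], title=structure.title)
    write_pdb(ref, paths["structure"])
    write_xyz_trajectory(structure, traj, paths["trajectory"])
    write_charge_table(water_charge_table(structure), paths["charges"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths
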