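"""Hydration-site thermodynamics from water trajectories.

Water oxygens inside a region of interest are clustered into recurrently
occupied sites by greedy density clustering. Each site is then assigned,
relative to bulk:

* an enthalpy — the mean non-bonded (Coulomb + Lennard-Jones)
  interaction energy of the member water with the rest of the system,
  minus a bulk reference measured the same way;
* an excess entropy, as -T*dS — first-order (one-body) translational and
  orientational terms from nearest-neighbor (Kozachenko-Leonenko)
  estimators. The translational reference is a bulk water occupying its
  per-molecule cell volume uniformly; the orientational reference is the
  uniform distribution over orientation space (unit quaternions with
  antipodal identification, Haar volume pi^2). Localized sites therefore
  have -T*dS >= 0 up to estimator noise.

The free energy a binding ligand gains by expelling cage waters is
approximated as the sum of dG over the sites its heavy atoms overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from scipy.special import digamma

from .constants import BULK_WATER_DENSITY, DEFAULT_TEMPERATURE, K_COULOMB, R_KCAL
from .io import ChargeTable, Structure, Trajectory


@dataclass(frozen=True)
class Box:
    """Axis-aligned region of interest (A)."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        lo = np.asarray(self.lo, float)
        hi = np.asarray(self.hi, float)
        return np.all((p >= lo) & (p <= hi), axis=1)

    @property
    def volume(self) -> float:
        lo = np.asarray(self.lo, float)
        hi = np.asarray(self.hi, float)
        return float(np.prod(hi - lo))


@dataclass
class HydrationSite:
    """One localized water site and its thermodynamics relative to bulk."""

    center: np.ndarray
    occupancy: float
    member_frames: np.ndarray = field(repr=False)
    member_waters: np.ndarray = field(repr=False)
    member_positions: np.ndarray = field(repr=False)
    enthalpy: float | None = None        # dH_site, kcal/mol
    minus_t_entropy: float | None = None  # -T dS_site, kcal/mol

    @property
    def n_observations(self) -> int:
        return len(self.member_frames)

    @property
    def free_energy(self) -> float:
        """dG_site = dH_site + (-T dS_site); requires both terms assigned."""
        if self.enthalpy is None or self.minus_t_entropy is None:
            raise ValueError("site thermodynamics not yet assigned "
                             "(run site_enthalpy / site_entropy first)")
        return self.enthalpy + self.minus_t_entropy


@dataclass
class SolvationSummary:
    """Sites displaced by a ligand and their summed thermodynamics."""

    sites: list[HydrationSite]
    total_free_energy: float
    total_enthalpy: float
    total_minus_t_entropy: float
    n_high_energy: int
    high_energy_threshold: float

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def water_oxygen_indices(structure: Structure) -> np.ndarray:
    idx = structure.select(residue_name="HOH", names=["O"])
    if idx.size == 0:
        raise ValueError("structure contains no water (HOH) oxygens")
    return idx


def cluster_sites(trajectory: Trajectory, structure: Structure, region: Box,
                  radius: float = 1.0, min_occupancy: float = 0.5,
                  ) -> list[HydrationSite]:
    """Greedy density clustering of water oxygens into hydration sites.

    Repeatedly seeds a site at the observation whose ``radius``-ball
    contains the most unclaimed oxygen observations, claims them, and
    stops when no candidate reaches ``min_occupancy * n_frames``
    observations. Ties are broken by lexicographically smallest seed
    position, so the result does not depend on frame or water order.
    The site center is the mean of the claimed observations.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    oxy = water_oxygen_indices(structure)
    n_frames = trajectory.n_frames
    pts_list, frame_ids, water_ids = [], [], []
    resids = np.array([structure.atoms[i].residue_id for i in oxy])
    for f in range(n_frames):
        p = trajectory.coordinates[f, oxy, :]
        mask = region.contains(p)
        pts_list.append(p[mask])
        frame_ids.append(np.full(mask.sum(), f))
        water_ids.append(resids[mask])
    points = np.concatenate(pts_list) if pts_list else np.empty((0, 3))
    if len(points) == 0:
        return []
    frames = np.concatenate(frame_ids)
    waters = np.concatenate(water_ids)

    tree = cKDTree(points)
    neighbors = tree.query_ball_point(points, r=radius)
    neighbors = [np.array(nb, dtype=int) for nb in neighbors]
    active = np.ones(len(points), dtype=bool)
    counts = np.array([len(nb) for nb in neighbors])
    threshold = min_occupancy * n_frames
    sites: list[HydrationSite] = []
    while True:
        best = counts[active].max() if active.any() else 0
        if best < threshold:
            break
        cand = np.flatnonzero(active & (counts == best))
        # deterministic, permutation-robust tie-break on the seed position
        cand = cand[np.lexsort((points[cand, 2], points[cand, 1], points[cand, 0]))]
        seed = cand[0]
        members = neighbors[seed][active[neighbors[seed]]]
        sites.append(HydrationSite(
            center=points[members].mean(axis=0),
            occupancy=float(len(np.unique(frames[members])) / n_frames),
            member_frames=frames[members].copy(),
            member_waters=waters[members].copy(),
            member_positions=points[members].copy()))
        active[members] = False
        affected = np.unique(np.concatenate([neighbors[m] for m in members]))
        for i in affected:
            counts[i] = int(active[neighbors[i]].sum())
    return sites


# ---------------------------------------------------------------------------
# enthalpy
# ---------------------------------------------------------------------------

def _water_atom_indices(structure: Structure, water_resid: int) -> np.ndarray:
    return structure.select(residue_id=int(water_resid), residue_name="HOH")


def water_interaction_energy(frame: np.ndarray, water_atoms: np.ndarray,
                             charges: ChargeTable, all_atoms: np.ndarray | None = None,
                             ) -> float:
    """Coulomb + LJ energy (kcal/mol) between one water and all other atoms.

    Lorentz-Berthelot combining for LJ. Raises when LJ parameters are
    missing from the charge table.
    """
    frame = np.asarray(frame, dtype=float)
    if all_atoms is None:
        all_atoms = np.arange(len(frame))
    others = np.setdiff1d(all_atoms, water_atoms)
    qw = charges.charges(water_atoms)
    qo = charges.charges(others)
    sw, ew = charges.lj_params(water_atoms)
    so, eo = charges.lj_params(others)
    diff = frame[water_atoms][:, None, :] - frame[others][None, :, :]
    r = np.linalg.norm(diff, axis=2)
    if np.any(r == 0.0):
        raise ValueError("coincident atoms in water-environment energy")
    e_coul = K_COULOMB * np.sum(np.outer(qw, qo) / r)
    sig = 0.5 * (sw[:, None] + so[None, :])
    eps = np.sqrt(np.outer(ew, eo))
    sr6 = (sig / r) ** 6
    e_lj = np.sum(4.0 * eps * (sr6 ** 2 - sr6))
    return float(e_coul + e_lj)


def site_enthalpy(site: HydrationSite, structure: Structure,
                  charges: ChargeTable, trajectory: Trajectory,
                  bulk_reference: float = 0.0,
                  max_observations: int = 500) -> float:
    """Mean member-water non-bonded energy minus the bulk reference.

    At most ``max_observations`` member observations are evaluated, taken
    at a deterministic stride, and the result is stored on the site.
    """
    n = site.n_observations
    if n == 0:
        raise ValueError("site has no member observations")
    step = max(1, n // max_observations)
    sel = np.arange(0, n, step)
    energies = []
    for i in sel:
        f = int(site.member_frames[i])
        w = int(site.member_waters[i])
        watoms = _water_atom_indices(structure, w)
        energies.append(water_interaction_energy(
            trajectory.coordinates[f], watoms, charges))
    dh = float(np.mean(energies) - bulk_reference)
    site.enthalpy = dh
    return dh


def bulk_water_stats(trajectory: Trajectory, structure: Structure,
                     charges: ChargeTable, bulk_region: Box,
                     max_observations: int = 500) -> tuple[float, float]:
    """(number density, mean per-water interaction energy) in a bulk region.

    Measured from the trajectory itself so synthetic and real runs are
    self-consistent: "bulk" is whatever the data's background is.
    """
    oxy = water_oxygen_indices(structure)
    resids = np.array([structure.atoms[i].residue_id for i in oxy])
    obs: list[tuple[int, int]] = []
    count = 0
    for f in range(trajectory.n_frames):
        mask = bulk_region.contains(trajectory.coordinates[f, oxy, :])
        count += int(mask.sum())
        obs.extend((f, int(w)) for w in resids[mask])
    density = count / (trajectory.n_frames * bulk_region.volume)
    if not obs:
        raise ValueError("no waters found in the designated bulk region")
    step = max(1, len(obs) // max_observations)
    energies = [water_interaction_energy(trajectory.coordinates[f],
                                         _water_atom_indices(structure, w), charges)
                for f, w in obs[::step]]
    return float(density), float(np.mean(energies))


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------

_LN_SO3_VOLUME = float(np.log(np.pi ** 2))
_LN_C3 = float(np.log(4.0 * np.pi / 3.0))  # unit-ball volume, d = 3


def _kl_entropy_positions(points: np.ndarray, k: int = 1) -> float:
    """Kozachenko-Leonenko differential entropy (nats) of 3D samples."""
    n = len(points)
    tree = cKDTree(points)
    dist, _ = tree.query(points, k=k + 1)
    eps = dist[:, k]
    eps = np.maximum(eps, 1e-12)
    return float(digamma(n) - digamma(k) + _LN_C3 + 3.0 * np.mean(np.log(eps)))


def _kl_entropy_orientations(quats: np.ndarray, k: int = 1) -> float:
    """KL entropy (nats) on orientation space SO(3) = S^3 with antipodal
    identification, geodesic metric; uniform distribution has entropy
    ln(pi^2)."""
    n = len(quats)
    q = quats / np.linalg.norm(quats, axis=1, keepdims=True)
    doubled = np.vstack([q, -q])
    tree = cKDTree(doubled)
    # each query point matches itself and its antipode once in the doubled set
    dist, _ = tree.query(q, k=k + 1)
    chord = np.maximum(dist[:, k], 1e-12)
    geo = 2.0 * np.arcsin(np.minimum(chord / 2.0, 1.0))
    # ball volume ~ (4/3) pi r^3 for small geodesic radii on S^3
    return float(digamma(n) - digamma(k) + _LN_C3 + 3.0 * np.mean(np.log(geo)))


def water_orientations(trajectory: Trajectory, structure: Structure,
                       frames: np.ndarray, waters: np.ndarray) -> np.ndarray:
    """Unit quaternions of the listed (frame, water) observations.

    The water body frame has the dipole along +z and H1-H2 along +x.
    """
    quats = np.empty((len(frames), 4))
    cache: dict[int, np.ndarray] = {}
    for i, (f, w) in enumerate(zip(frames, waters)):
        watoms = cache.setdefault(int(w), _water_atom_indices(structure, int(w)))
        o, h1, h2 = trajectory.coordinates[int(f), watoms, :]
        zax = (h1 + h2) / 2 - o
        zax /= np.linalg.norm(zax)
        xax = h1 - h2
        xax -= (xax @ zax) * zax
        xax /= np.linalg.norm(xax)
        yax = np.cross(zax, xax)
        quats[i] = Rotation.from_matrix(np.column_stack([xax, yax, zax])).as_quat()
    return quats


def site_entropy(site: HydrationSite, trajectory: Trajectory, structure: Structure,
                 temperature: float = DEFAULT_TEMPERATURE,
                 bulk_density: float = BULK_WATER_DENSITY,
                 min_observations: int = 50, k: int = 1) -> float:
    """First-order excess entropy of a site, returned as -T dS (kcal/mol).

    Translational term: KL entropy of member positions against a bulk
    water's uniform cell, ln(m_bar / rho_bulk), where m_bar is the mean
    number of member observations per frame (so bulk-like member sets
    give zero excess). Orientational term: KL entropy of member
    orientations against the uniform distribution on orientation space.
    The result is stored on the site.
    """
    n = site.n_observations
    if n < min_observations:
        raise ValueError(f"only {n} member observations (< {min_observations}); "
                         "sample a longer trajectory for a stable entropy estimate")
    if bulk_density <= 0 or temperature <= 0:
        raise ValueError("bulk_density and temperature must be positive")
    m_bar = n / trajectory.n_frames
    h_tr = _kl_entropy_positions(site.member_positions, k=k)
    ds_tr = h_tr - float(np.log(m_bar / bulk_density))
    quats = water_orientations(trajectory, structure,
                               site.member_frames, site.member_waters)
    h_or = _kl_entropy_orientations(quats, k=k)
    ds_or = h_or - _LN_SO3_VOLUME
    minus_t_ds = -R_KCAL * temperature * (ds_tr + ds_or)
    site.minus_t_entropy = float(minus_t_ds)
    return site.minus_t_entropy


# ---------------------------------------------------------------------------
# displaced free energy
# ---------------------------------------------------------------------------

def displaced_free_energy(sites: list[HydrationSite], ligand_heavy_atoms: np.ndarray,
                          overlap_radius: float,
                          high_energy_threshold: float = 1.0) -> SolvationSummary:
    """Sum dG over the sites a ligand displaces.

    A site is displaced when its center lies within ``overlap_radius`` of
    any ligand heavy atom. ``high_energy_threshold`` (kcal/mol) counts
    the displaced sites whose dG relative to bulk exceeds it.
    """
    if overlap_radius <= 0:
        raise ValueError(f"overlap_radius must be > 0, got {overlap_radius}")
    lig = np.atleast_2d(np.asarray(ligand_heavy_atoms, dtype=float))
    displaced = [s for s in sites
                 if lig.size and np.min(np.linalg.norm(lig - s.center, axis=1)) <= overlap_radius]
    total_dg = float(sum(s.free_energy for s in displaced))
    total_dh = float(sum(s.enthalpy for s in displaced))
    total_tds = float(sum(s.minus_t_entropy for s in displaced))
    n_high = sum(1 for s in displaced if s.free_energy > high_energy_threshold)
    return SolvationSummary(sites=displaced, total_free_energy=total_dg,
                            total_enthalpy=total_dh, total_minus_t_entropy=total_tds,
                            n_high_energy=n_high,
                            high_energy_threshold=high_energy_threshold)
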