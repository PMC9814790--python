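"""Point-charge electrostatics between the cation probe and the pi-system.

The interaction energy between two disjoint atom sets is the exact
pairwise Coulomb sum (no cutoff, no switching), E = sum_ij K q_i q_j /
(eps r_ij) with K = 332.0636 kcal A mol^-1 e^-2 and a dielectric of 1 by
default. Trajectory averages are taken at a configurable sampling stride
(default 20 ps, one energy per saved frame of the emulated run).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import K_COULOMB
from .geometry import RingSystem
from .io import ChargeTable, Trajectory


def coulomb_energy(atoms_a, atoms_b, charges: ChargeTable, frame: np.ndarray,
                   dielectric: float = 1.0) -> float:
    """Pairwise Coulomb energy (kcal/mol) between two disjoint atom sets.

    Raises on overlapping sets and on coincident atom positions (the
    energy would be singular).
    """
    a = np.asarray(atoms_a, dtype=int)
    b = np.asarray(atoms_b, dtype=int)
    if np.intersect1d(a, b).size:
        raise ValueError("atom sets overlap; Coulomb energy requires disjoint sets")
    frame = np.asarray(frame, dtype=float)
    qa = charges.charges(a)
    qb = charges.charges(b)
    diff = frame[a][:, None, :] - frame[b][None, :, :]
    r = np.linalg.norm(diff, axis=2)
    if np.any(r == 0.0):
        raise ValueError("coincident atoms between the two sets (r = 0): singular geometry")
    return float(K_COULOMB / dielectric * np.sum(np.outer(qa, qb) / r))


def pi_system_atoms(ring: RingSystem, include_fluorines: bool = False) -> np.ndarray:
    """The ring's pi-system atom set: 9 indole heavy atoms, optionally
    extended by bonded fluorine substituents."""
    atoms = list(ring.all_heavy)
    if include_fluorines:
        atoms.extend(ring.fluorines)
    return np.array(atoms, dtype=int)


@dataclass
class EnergySeries:
    """Per-frame electrostatic energies between two named atom sets."""

    times_ps: np.ndarray
    energies: np.ndarray
    stride_ps: float
    set_a_label: str
    set_b_label: str
    include_fluorines: bool = False

    @property
    def mean(self) -> float:
        return float(self.energies.mean())

    @property
    def std(self) -> float:
        return float(self.energies.std())

    @property
    def n_samples(self) -> int:
        return len(self.energies)


def energy_series(trajectory: Trajectory, cation_set, pi_set,
                  charges: ChargeTable, stride_ps: float = 20.0,
                  dielectric: float = 1.0, set_a_label: str = "cation",
                  set_b_label: str = "pi-system",
                  include_fluorines: bool = False) -> EnergySeries:
    """Coulomb energy at every strided frame, plus its mean and spread.

    ``stride_ps`` must be a (positive integer) multiple of the trajectory
    frame spacing; single-frame trajectories are sampled as-is.
    """
    a = np.asarray(cation_set, dtype=int)
    b = np.asarray(pi_set, dtype=int)
    if trajectory.n_frames > 1:
        dt = trajectory.frame_spacing_ps
        if stride_ps < dt:
            raise ValueError(f"stride {stride_ps} ps is smaller than the frame spacing {dt} ps")
        ratio = stride_ps / dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(f"stride {stride_ps} ps is not a multiple of the frame spacing {dt} ps")
        step = int(round(ratio))
    else:
        step = 1
    idx = np.arange(0, trajectory.n_frames, step)
    if np.intersect1d(a, b).size:
        raise ValueError("atom sets overlap; Coulomb energy requires disjoint sets")
    qa = charges.charges(a)
    qb = charges.charges(b)
    frames = trajectory.coordinates[idx]
    diff = frames[:, a, None, :] - frames[:, None, b, :]
    r = np.linalg.norm(diff, axis=3)
    if np.any(r == 0.0):
        raise ValueError("coincident atoms between the two sets (r = 0): singular geometry")
    e = K_COULOMB / dielectric * np.sum(np.outer(qa, qb)[None, :, :] / r, axis=(1, 2))
    return EnergySeries(times_ps=trajectory.times_ps[idx], energies=e,
                        stride_ps=stride_ps, set_a_label=set_a_label,
                        set_b_label=set_b_label, include_fluorines=include_fluorines)


@dataclass
class TrendReport:
    """Ordering verdict over per-variant mean interaction energies.

    Attraction strength is the magnitude of a (negative) mean energy; the
    verdict states how it orders across progressive fluorination.
    """

    means: dict[str, float]
    order: tuple[str, ...]
    verdict: str
    strict_weakening: bool


VARIANT_ORDER = ("WT", "5F", "6F", "56diF")


def variant_trend_report(series: dict[str, EnergySeries],
                         order: tuple[str, ...] = VARIANT_ORDER) -> TrendReport:
    """Compare mean cation-pi electrostatic attraction across variants.

    Requires at least two variants computed on matched trajectories
    (equal sample counts). The expected physical ordering is a weakening
    of attraction with fluorine count: |E_WT| >= |E_monoF| >= |E_diF|.
    """
    present = [v for v in order if v in series]
    if len(present) < 2:
        raise ValueError("trend report requires at least two variants")
    counts = {v: series[v].n_samples for v in present}
    if len(set(counts.values())) != 1:
        raise ValueError(f"mismatched frame counts across variants: {counts}")
    means = {v: series[v].mean for v in present}
    attraction = {v: -means[v] for v in present}  # positive = attractive
    vals = [attraction[v] for v in present]
    if all(abs(x - vals[0]) < 1e-12 for x in vals):
        verdict = "no trend (all means equal)"
        strict = False
    else:
        rels = []
        strict = True
        for u, v in zip(present[:-1], present[1:]):
            if attraction[u] > attraction[v]:
                rels.append(f"{u} > {v}")
            elif attraction[u] == attraction[v]:
                rels.append(f"{u} = {v}")
                strict = False
            else:
                rels.append(f"{u} < {v}")
                strict = False
        verdict = ", ".join(rels)
    return TrendReport(means=means, order=tuple(present), verdict=verdict,
                       strict_weakening=strict)
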