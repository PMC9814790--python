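# Methods

This note records the models implemented in `fluorocage`, the parameters
that matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was genuinely open. Units
throughout: Å, kcal/mol, elementary charge, K, ps, Da.

## The scientific setting

A trimethyllysine side chain carries a permanent quaternary ammonium
cation that reader proteins recognize inside an "aromatic cage" of
electron-rich side chains — here, two tryptophan indoles. Fluorinating
the indole benzene ring at positions 5 and/or 6 withdraws electron
density, weakens the ring quadrupole and therefore the cation–π
attraction. The binding ledger nevertheless balances, because the
fluorinated cage also holds water of higher free energy whose expulsion
by the ligand is more favourable. The package implements the three
quantitative legs of that argument — contact geometry/electrostatics
from trajectories, hydration-site thermodynamics, and the
energy-decomposition / calorimetric identity bookkeeping — against
synthetic data with planted ground truth plus packaged reference tables.

## Synthetic cage trajectories

`CageSimSpec` defaults define the study conditions: 5000 frames at 20 ps
spacing (the sampling grid of a 100 ns run saved every 20 ps), a
tetramethylammonium (TMA) probe anchored midway between two rigid
indoles whose 9-heavy-atom centroids sit 4 Å away on either side, and
isotropic Gaussian jitter of σ = 0.5 Å applied to the rigid probe. The
anchor distance is a typical cation–π contact distance; the jitter
magnitude is a free knob of the emulation, not an estimate of the real
cation's distribution, which is why every geometric statistic derived
from it is validated against per-frame brute-force oracles rather than
against literature values.

The indole template is an idealized fused regular pentagon/hexagon of
side 1.39 Å (aromatic C–C), exactly planar, with ring hydrogens placed
radially (C–H 1.08, N–H 1.01, C–F 1.34 Å). Using TMA rather than a full
lysine side chain isolates the cage interaction from backbone
conformational noise.

Charge model. TMA: N 0.00, C −0.20, H +0.15 (net +1 e exactly). Indole:
benzene-like ±0.115 on aromatic C/H pairs, a −0.40/+0.40 N–H pair, and a
+0.10/−0.10 split across the fusion carbons, net 0. Fluorination is
purely electrostatic — geometry is held fixed apart from the H→F bond
length — with F at a configurable −0.16 e and the bonded carbon
absorbing exactly the difference (−0.115 → +0.16), so per-residue net
charge is conserved to machine precision and each fluorinated carbon
acquires a net positive partial charge. This construction makes the
weakening of cation–indole attraction with fluorine count provable at
matched geometry, which is what the trend tests assert; the absolute
energies are toy-scale (the 9-heavy-atom "π-system" set carries the
negative end of every C–H and N–H dipole) and are never compared to real
numbers.

## Synthetic water ensembles

`WaterSimSpec` generates rigid 3-site (TIP3P-geometry) waters in an
axis-aligned box: a uniform background at bulk density (default
0.0334 Å⁻³) with uniform orientations, plus planted sites whose waters
are Gaussian-distributed about the site center (default σ = 0.3 Å,
truncated at 3σ — an "occupied" site water is in the site by definition;
excursions are exchange events, modelled by the per-frame occupancy flag,
default 0.9) and whose dipole axes follow a von-Mises–Fisher
distribution (default concentration κ = 10) with uniform spin about the
dipole. One concentration parameter maps cleanly onto orientational
entropy ground truth.

Two liquid-like constraints keep pair energies physical: oxygens are
placed with a 2.6 Å hard core against each other, and bulk waters avoid
a 2.4 Å shell around occupied planted centers (a localized water
excludes others; this also makes the "exactly one oxygen within 1 Å of
the center" ground-truth check exact). When a planted site is unoccupied
its water is resampled as an ordinary bulk water that frame, keeping the
atom count constant as the trajectory container requires.

What the generator does *not* emulate: hydrogen-bond network structure,
pair correlations beyond the hard core, polarization, or protein
surfaces. Passing tests therefore demonstrate estimator and bookkeeping
correctness on data whose ground truth is known — not agreement with
real solvation free energies, which require force-field simulations of
the actual protein and are out of scope.

## Geometry

Ring systems are detected by the tryptophan side-chain atom-name
template (5-ring CG–CD1–NE1–CE2–CD2, 6-ring CD2–CE2–CZ2–CH2–CZ3–CE3),
not by graph perception; anything not matching the template is rejected
by residue. Fluorines are carried on the ring system but excluded from
centroid geometry (they are substituents, not ring members); they can be
included in the electrostatic atom set.

The cation–ring distance reference points are both configurable, because
convention does not pin them: cation side N⁺ (default) or NMe₃
heavy-atom centroid; ring side 5MR, 6MR or whole-indole 9-atom centroid
(default). The 6 Å contact criterion is likewise a conventional default,
not a constant. Histograms default to 0.25 Å bins over 2–10 Å, with the
outermost bins absorbing out-of-range distances so counts always sum to
the frame count. Closest-pair searches break ties toward the lowest atom
index. All geometric outputs are rigid-motion invariant to 1e-9 Å
(property-tested).

## Electrostatics

Exact pairwise Coulomb summation with k = 332.0636 kcal·Å·mol⁻¹·e⁻² and
dielectric 1.0, no cutoff or switching — chosen for reproducibility over
emulating any particular analysis plugin. The cation atom set defaults
to the full TMA group, with the lone-N convention available, since usage
varies between the two. Energies are reported per side chain to keep the
two rings' contributions separate. Trajectory averages sample at a
stride that must be a multiple of the frame spacing (default 20 ps);
the mean is over all sampled frames.

## Hydration-site thermodynamics

Clustering is greedy density clustering on pooled water-oxygen
observations: repeatedly seed at the observation whose 1.0 Å ball
(configurable) holds the most unclaimed observations, claim the ball,
stop when no candidate reaches `min_occupancy × n_frames` (default 0.5).
Because counts are computed on the aggregated point set and ties break
on the lexicographically smallest seed position, the result is
deterministic and independent of frame/water ordering. Site centers are
the means of claimed observations; occupancy is the fraction of distinct
frames contributing a member (clamped to [0,1] by construction).

Enthalpy: mean Coulomb + Lennard-Jones (Lorentz–Berthelot) energy
between the member water and all other atoms, minus a bulk reference.
Both the bulk reference energy and the bulk density are *measured from a
user-designated bulk region of the same trajectory* rather than taken
from literature, so synthetic and real runs are self-consistent — on
synthetic data "bulk" is whatever the generator produced.

Entropy: first-order (one-body) excess only, as −TΔS. The translational
term is a Kozachenko–Leonenko nearest-neighbor entropy estimate of the
member positions, referenced against ln(m̄/ρ_bulk) where m̄ is the mean
number of member observations per frame — i.e. a bulk water uniform in
its per-molecule cell volume 1/ρ, scaled to the site's mean occupancy.
This reference makes a bulk-like member set give exactly zero excess and
reduces, for a single localized water, to the closed-form
Gaussian-versus-uniform-cell entropy difference used as the estimator's
oracle. The orientational term uses the same estimator on orientation
space — unit quaternions with antipodal identification, geodesic metric,
uniform (Haar) reference of volume π² — a standard, metric-valid choice.
Higher-order (correlation) terms of the entropy expansion are out of
scope. The estimator needs a minimum number of observations (default
50); at 10⁴ observations it is accurate to well within ±0.2 kcal/mol
against the closed form, with small positive bias from boundary and
truncation effects.

Displaced free energy: a site is displaced when its center is within
`overlap_radius` of any ligand heavy atom; the summary sums ΔG, ΔH and
−TΔS over displaced sites exactly. "High-energy" sites are counted above
a configurable ΔG threshold (default 1.0 kcal/mol relative to bulk; no
standard definition exists, so it is configuration, not constant).
Temperature defaults to 298.15 K everywhere.

## Thermodynamic ledger

Energy-decomposition records hold the nine energies of the three-level
identity chain; `eda_compose` derives the three totals from the six
components exactly, and `eda_validate` checks stated records within a
tolerance. The default tolerance is 0.25 kcal/mol — the worst case for a
four-term identity whose five printed values were independently rounded
to one decimal. The packaged reference table indeed carries residuals of
up to 0.1 kcal/mol on the four-term decomposition for the two
mono-fluorinated columns while every other identity closes exactly;
whether the underlying unrounded values satisfied the identities exactly
is unknowable from the printed table, so tolerance-based validation is
the honest check.

ITC records validate ΔG° = ΔH° + (−TΔS°) and ΔG° = RT ln K_d (R =
1.98720425×10⁻³ kcal mol⁻¹ K⁻¹) within 0.15 kcal/mol. The measurement
temperature is not part of the packaged table's source and defaults to
298.15 K — the K_d↔ΔG° pairs are mutually consistent only near 25 °C,
so this is a documented inference, configurable per record.

Isodesmic reaction energies are plain stoichiometry-checked differences
with hartree→kcal/mol conversion at 627.5095; the quantum-chemical
inputs themselves are never computed here. Mass arithmetic uses the
average-mass H→F difference 17.9905 Da.

## Pipeline

`run_pipeline` executes simulate → contacts → energies → hydration →
ledger with stage toggles, at reduced default problem sizes (2000 cage
frames, 1500 water frames) chosen to keep a full run in the tens of
seconds while leaving every estimator comfortably above its minimum
sample requirements. Every report embeds the seed, package version and a
hash of the resolved configuration, and the resolved configuration
itself is written alongside the artifacts, because the scientific
conclusions depend on analysis parameters that are easy to leave
implicit. Reports round floats to 6 decimals; reruns under a fixed seed
are bit-identical.

## Known limitations

- The cage emulation is statistical (rigid bodies, Gaussian jitter): no
  forces, thermostats or Ewald electrostatics, and its energy magnitudes
  are not comparable to force-field or quantum-chemical values.
- The entropy estimator is first-order; water–water orientational
  correlations and translational–orientational coupling are ignored.
- Absolute hydration-site energies of real binding pockets are out of
  scope; only orderings and internal consistency are asserted.
- PDB support covers ATOM/HETATM fixed-width records (single chain, no
  altlocs, no mmCIF); trajectories are plain multi-frame XYZ only.
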