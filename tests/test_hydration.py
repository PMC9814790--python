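"""Hydration-site clustering, enthalpy oracles, entropy estimator checks
against closed forms, and displaced-site accounting."""

import numpy as np
import pandas as pd
import pytest

from fluorocage.constants import K_COULOMB, R_KCAL
from fluorocage.hydration import (Box, HydrationSite, bulk_water_stats,
                                  cluster_sites, displaced_free_energy,
                                  site_enthalpy, site_entropy,
                                  water_interaction_energy)
from fluorocage.io import ChargeTable, Trajectory
from fluorocage.synthetic import (PlantedSite, WaterSimSpec,
                                  make_water_trajectory, water_charge_table,
                                  water_structure)

KT = R_KCAL * 298.15


def _static_water_traj(o_positions, n_frames=10):
    """Waters frozen at given O positions, canonical orientation."""
    n = len(o_positions)
    structure = water_structure(n)
    frame = np.zeros((n * 3, 3))
    h_off = np.array([[0.7, 0.0, 0.6], [-0.7, 0.0, 0.6]])
    for i, o in enumerate(o_positions):
        frame[3 * i] = o
        frame[3 * i + 1] = o + h_off[0]
        frame[3 * i + 2] = o + h_off[1]
    coords = np.stack([frame] * n_frames)
    return structure, Trajectory(times_ps=np.arange(n_frames, dtype=float),
                                 coordinates=coords)


class TestClustering:
    def test_single_fixed_point_single_site(self):
        structure, traj = _static_water_traj([(5.0, 5.0, 5.0)])
        sites = cluster_sites(traj, structure, Box(lo=(0, 0, 0), hi=(10, 10, 10)))
        assert len(sites) == 1
        assert sites[0].occupancy == 1.0
        assert np.allclose(sites[0].center, (5.0, 5.0, 5.0), atol=1e-12)

    def test_uniform_bulk_yields_no_sites(self):
        spec = WaterSimSpec(n_frames=200, seed=17)
        structure, traj, _ = make_water_trajectory(spec)
        sites = cluster_sites(traj, structure,
                              Box(lo=(1, 1, 1), hi=(11, 11, 11)),
                              radius=1.0, min_occupancy=0.5)
        assert sites == []

    def test_two_planted_sites_recovered(self, water_run, water_spec):
        structure, traj, truth = water_run
        sites = cluster_sites(traj, structure, Box(lo=(2, 4, 4), hi=(10.5, 8, 8)))
        assert len(sites) == 2
        planted = np.array([s["center"] for s in truth["planted_sites"]])
        for s in sites:
            d = np.linalg.norm(planted - s.center, axis=1)
            i = int(np.argmin(d))
            assert d[i] < 1.0
            assert abs(s.occupancy
                       - truth["planted_sites"][i]["occupancy_observed"]) < 0.05

    def test_frame_permutation_leaves_centers_fixed(self, water_run):
        structure, traj, _ = water_run
        region = Box(lo=(2, 4, 4), hi=(10.5, 8, 8))
        a = cluster_sites(traj, structure, region)
        rev = Trajectory(times_ps=traj.times_ps, coordinates=traj.coordinates[::-1])
        b = cluster_sites(rev, structure, region)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            assert np.allclose(sa.center, sb.center, atol=1e-6)

    def test_empty_region_is_empty_not_error(self, water_run):
        structure, traj, _ = water_run
        assert cluster_sites(traj, structure,
                             Box(lo=(100, 100, 100), hi=(101, 101, 101))) == []

    def test_nonpositive_radius_rejected(self, water_run):
        structure, traj, _ = water_run
        with pytest.raises(ValueError, match="radius"):
            cluster_sites(traj, structure, Box(lo=(0, 0, 0), hi=(1, 1, 1)), radius=0)


class TestEnthalpy:
    def test_water_pair_matches_hand_summed_pairs(self):
        structure, traj = _static_water_traj([(0.0, 0.0, 0.0), (3.0, 0.0, 0.0)],
                                             n_frames=1)
        charges = water_charge_table(structure)
        e = water_interaction_energy(traj.coordinates[0], np.array([0, 1, 2]), charges)
        frame = traj.coordinates[0]
        q = charges.charges()
        sig, eps = charges.lj_params()
        oracle = 0.0
        for i in range(3):
            for j in range(3, 6):
                r = np.linalg.norm(frame[i] - frame[j])
                oracle += K_COULOMB * q[i] * q[j] / r
                s_ij = 0.5 * (sig[i] + sig[j])
                e_ij = np.sqrt(eps[i] * eps[j])
                oracle += 4 * e_ij * ((s_ij / r) ** 12 - (s_ij / r) ** 6)
        assert e == pytest.approx(oracle, abs=1e-9)

    def test_doubling_charges_quadruples_coulomb(self):
        structure, traj = _static_water_traj([(0.0, 0.0, 0.0), (3.0, 0.0, 0.0)],
                                             n_frames=1)
        base = water_charge_table(structure).table.copy()
        base["lj_epsilon_kcal"] = 0.0  # isolate the Coulomb part
        e1 = water_interaction_energy(traj.coordinates[0], np.array([0, 1, 2]),
                                      ChargeTable(table=base))
        doubled = base.copy()
        doubled["charge_e"] *= 2
        e2 = water_interaction_energy(traj.coordinates[0], np.array([0, 1, 2]),
                                      ChargeTable(table=doubled))
        assert e2 == pytest.approx(4 * e1, abs=1e-9)

    def test_missing_lj_fails(self):
        structure, traj = _static_water_traj([(0.0, 0.0, 0.0), (3.0, 0.0, 0.0)],
                                             n_frames=1)
        bare = water_charge_table(structure).table.drop(
            columns=["lj_sigma_A", "lj_epsilon_kcal"])
        with pytest.raises(Exception, match="Lennard-Jones"):
            water_interaction_energy(traj.coordinates[0], np.array([0, 1, 2]),
                                     ChargeTable(table=bare))

    def test_site_enthalpy_is_mean_member_energy_minus_bulk(self, water_run):
        structure, traj, _ = water_run
        charges = water_charge_table(structure)
        sites = cluster_sites(traj, structure, Box(lo=(2, 4, 4), hi=(10.5, 8, 8)))
        s = sites[0]
        dh = site_enthalpy(s, structure, charges, traj, bulk_reference=1.5,
                          max_observations=40)
        dh0 = site_enthalpy(s, structure, charges, traj, bulk_reference=0.0,
                            max_observations=40)
        assert dh == pytest.approx(dh0 - 1.5, abs=1e-12)


class TestEntropy:
    def test_bulk_like_waters_have_zero_excess(self):
        """Uniform positions at bulk density with uniform orientations give
        -T dS = 0 within estimator error at ~10^4 samples."""
        spec = WaterSimSpec(box_hi=(8.0, 8.0, 8.0), n_frames=600, seed=23)
        structure, traj, _ = make_water_trajectory(spec)
        oxy = structure.select(residue_name="HOH", names=["O"])
        resids = np.array([structure.atoms[i].residue_id for i in oxy])
        frames, waters, positions = [], [], []
        for f in range(traj.n_frames):
            p = traj.coordinates[f, oxy]
            frames.extend([f] * len(p))
            waters.extend(resids)
            positions.append(p)
        positions = np.concatenate(positions)
        site = HydrationSite(center=positions.mean(axis=0), occupancy=1.0,
                             member_frames=np.array(frames),
                             member_waters=np.array(waters),
                             member_positions=positions)
        assert site.n_observations > 9000
        density = site.n_observations / (traj.n_frames * spec.volume)
        mtds = site_entropy(site, traj, structure, bulk_density=density)
        assert abs(mtds) < 0.2

    def test_gaussian_site_matches_closed_form(self):
        """A sigma=0.3 A Gaussian site in rho=0.0334 bulk: -T dS equals the
        Gaussian-vs-uniform-cell differential-entropy difference."""
        sigma, rho = 0.3, 0.0334
        spec = WaterSimSpec(box_hi=(8.0, 8.0, 8.0), n_frames=10_000,
                            bulk_density=0.002,
                            planted_sites=(PlantedSite(center=(4.0, 4.0, 4.0),
                                                       positional_sigma=sigma,
                                                       orientational_concentration=0.0,
                                                       occupancy_probability=1.0),),
                            seed=5)
        structure, traj, _ = make_water_trajectory(spec)
        sites = cluster_sites(traj, structure, Box(lo=(3, 3, 3), hi=(5, 5, 5)))
        assert len(sites) == 1
        site = sites[0]
        m_bar = site.n_observations / traj.n_frames
        mtds = site_entropy(site, traj, structure, bulk_density=rho)
        h_gauss = 1.5 * np.log(2 * np.pi * np.e * sigma ** 2)
        expected = -KT * (h_gauss - np.log(m_bar / rho))
        assert mtds == pytest.approx(expected, abs=0.2)
        assert mtds > 0  # confinement always costs entropy

    def test_tighter_sigma_costs_more_entropy(self):
        results = []
        for sigma in (0.45, 0.2):
            spec = WaterSimSpec(box_hi=(8.0, 8.0, 8.0), n_frames=2000,
                                bulk_density=0.002,
                                planted_sites=(PlantedSite(center=(4.0, 4.0, 4.0),
                                                           positional_sigma=sigma,
                                                           occupancy_probability=1.0),),
                                seed=7)
            structure, traj, _ = make_water_trajectory(spec)
            site = cluster_sites(traj, structure, Box(lo=(2, 2, 2), hi=(6, 6, 6)))[0]
            results.append(site_entropy(site, traj, structure))
        assert results[1] > results[0]

    def test_too_few_observations_advises_more_sampling(self):
        structure, traj = _static_water_traj([(5.0, 5.0, 5.0)], n_frames=10)
        site = cluster_sites(traj, structure, Box(lo=(0, 0, 0), hi=(10, 10, 10)))[0]
        with pytest.raises(ValueError, match="longer trajectory"):
            site_entropy(site, traj, structure, min_observations=50)


def _dummy_site(center, dg_split=(1.0, 0.5)):
    dh, mtds = dg_split
    return HydrationSite(center=np.asarray(center, float), occupancy=1.0,
                         member_frames=np.zeros(1, int),
                         member_waters=np.ones(1, int),
                         member_positions=np.asarray([center], float),
                         enthalpy=dh, minus_t_entropy=mtds)


class TestDisplacedFreeEnergy:
    def test_far_ligand_displaces_nothing(self):
        sites = [_dummy_site((0, 0, 0)), _dummy_site((3, 0, 0))]
        s = displaced_free_energy(sites, np.array([[50.0, 0, 0]]), overlap_radius=2.0)
        assert s.n_sites == 0
        assert s.total_free_energy == 0.0

    def test_overlapping_ligand_sums_everything(self):
        sites = [_dummy_site((0, 0, 0), (1.0, 0.5)),
                 _dummy_site((3, 0, 0), (-0.4, 0.9))]
        lig = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        s = displaced_free_energy(sites, lig, overlap_radius=1.0)
        assert s.n_sites == 2
        assert s.total_free_energy == pytest.approx(sum(x.free_energy for x in sites))
        assert s.total_free_energy == pytest.approx(
            s.total_enthalpy + s.total_minus_t_entropy, abs=1e-12)

    def test_membership_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            sites = [_dummy_site(rng.uniform(0, 10, 3), (rng.normal(), rng.normal()))
                     for _ in range(6)]
            lig = rng.uniform(0, 10, (4, 3))
            r = rng.uniform(0.5, 4.0)
            s = displaced_free_energy(sites, lig, overlap_radius=r)
            expected = [x for x in sites
                        if min(np.linalg.norm(lig - x.center, axis=1)) <= r]
            assert len(s.sites) == len(expected)
            assert s.total_free_energy == pytest.approx(
                sum(x.free_energy for x in expected), abs=1e-9)

    def test_unassigned_thermodynamics_fail(self):
        site = _dummy_site((0, 0, 0))
        site.enthalpy = None
        with pytest.raises(ValueError, match="not yet assigned"):
            displaced_free_energy([site], np.zeros((1, 3)), overlap_radius=1.0)


def test_bulk_stats_measures_background_density(water_run, water_spec):
    structure, traj, _ = water_run
    charges = water_charge_table(structure)
    density, energy = bulk_water_stats(traj, structure, charges,
                                       Box(lo=(0.5, 0.5, 0.5), hi=(11.5, 3.0, 11.5)),
                                       max_observations=100)
    assert 0.5 * water_spec.bulk_density < density < 1.5 * water_spec.bulk_density
    assert np.isfinite(energy)
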