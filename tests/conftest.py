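import pytest

from fluorocage.synthetic import (VARIANTS, CageSimSpec, PlantedSite,
                                  WaterSimSpec, make_cage_trajectory,
                                  make_water_trajectory)


@pytest.fixture(scope="session")
def cage_runs():
    """One matched-seed cage run per variant: (structure, trajectory, charges)."""
    return {v: make_cage_trajectory(CageSimSpec(n_frames=800, variant=v, seed=11))
            for v in VARIANTS}


@pytest.fixture(scope="session")
def wt_run(cage_runs):
    return cage_runs["WT"]


@pytest.fixture(scope="session")
def water_spec():
    return WaterSimSpec(
        n_frames=800,
        planted_sites=(PlantedSite(center=(4.0, 6.0, 6.0)),
                       PlantedSite(center=(8.5, 6.0, 6.0))),
        seed=3)


@pytest.fixture(scope="session")
def water_run(water_spec):
    """(structure, trajectory, ground_truth) for a two-site water box."""
    return make_water_trajectory(water_spec)
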