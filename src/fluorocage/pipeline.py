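"""End-to-end orchestration: generate -> geometry -> electrostatics ->
hydration -> ledger -> consolidated report.

Every run is driven by a :class:`RunConfig` (plain key-value data, YAML
on disk) and is deterministic under a fixed seed; the resolved
configuration, its hash and the seed are echoed into every report so a
run can be reproduced from its own output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import electrostatics as el
from . import geometry as geom
from . import hydration as hyd
from . import ledger as led
from .synthetic import (VARIANTS, CageSimSpec, PlantedSite, WaterSimSpec,
                        make_cage_trajectory, make_water_trajectory,
                        water_charge_table, write_cage_run, write_water_run)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """All knobs of one pipeline run."""

    seed: int = 0
    outdir: str | None = None
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "contacts": True, "energies": True,
        "hydration": True, "ledger": True})
    # cage analysis
    cage_n_frames: int = 2000
    cage_sigma: float = 0.5
    contact_cutoff: float = 6.0
    histogram_bin_width: float = 0.25
    energy_stride_ps: float = 20.0
    include_fluorines: bool = False
    # hydration analysis
    water_n_frames: int = 1500
    clustering_radius: float = 1.0
    min_occupancy: float = 0.5
    temperature_K: float = 298.15
    overlap_radius: float = 2.0
    high_energy_threshold: float = 1.0
    # ledger validation
    eda_tolerance: float = led.DEFAULT_EDA_TOLERANCE
    itc_tolerance: float = led.DEFAULT_ITC_TOLERANCE

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, np.floating):
        return round(float(obj), ndigits)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def default_water_spec(config: RunConfig) -> WaterSimSpec:
    """The pipeline's standard hydration scenario: two localized sites in
    a bulk-density box, emulating cage waters over a solvated background."""
    return WaterSimSpec(
        box_lo=(0.0, 0.0, 0.0), box_hi=(12.0, 12.0, 12.0),
        n_frames=config.water_n_frames,
        planted_sites=(
            PlantedSite(center=(4.0, 6.0, 6.0), positional_sigma=0.3,
                        orientational_concentration=10.0, occupancy_probability=0.9),
            PlantedSite(center=(8.5, 6.0, 6.0), positional_sigma=0.3,
                        orientational_concentration=10.0, occupancy_probability=0.9),
        ),
        seed=config.seed + 1,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the report.

    A stage failure propagates with the stage named; artifacts written
    before the failure are retained.
    """
    report: dict = {
        "provenance": {"package": "fluorocage", "version": __version__,
                       "seed": config.seed, "config_hash": config.config_hash()},
        "config": asdict(config),
    }
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "resolved_config.yaml")

    cage_runs: dict[str, tuple] = {}
    stage = "simulate"
    try:
        if config.stages.get("simulate", True):
            for variant in VARIANTS:
                spec = CageSimSpec(n_frames=config.cage_n_frames,
                                   positional_sigma=config.cage_sigma,
                                   variant=variant, seed=config.seed)
                cage_runs[variant] = make_cage_trajectory(spec)
                if outdir:
                    write_cage_run(spec, outdir / f"cage_{variant}")
            wspec = default_water_spec(config)
            water_run = make_water_trajectory(wspec)
            if outdir:
                write_water_run(wspec, outdir / "water")
            report["simulate"] = {
                "variants": list(VARIANTS), "cage_frames": config.cage_n_frames,
                "water_frames": wspec.n_frames,
                "planted_sites": len(wspec.planted_sites)}

        stage = "contacts"
        if config.stages.get("contacts", True) and cage_runs:
            contacts = {}
            for variant, (structure, traj, _) in cage_runs.items():
                rings = geom.detect_indole_rings(structure)
                n_idx = structure.select(residue_id=1, names=["N"])
                per_ring = {}
                for ring in rings:
                    cs = geom.contact_series(traj, n_idx, ring,
                                             cutoff=config.contact_cutoff,
                                             bin_width=config.histogram_bin_width)
                    per_ring[ring.label] = {
                        "fraction": cs.fraction,
                        "mean_distance": float(cs.distances.mean()),
                        "cutoff": cs.cutoff}
                contacts[variant] = per_ring
            report["contacts"] = contacts

        stage = "energies"
        if config.stages.get("energies", True) and cage_runs:
            series = {}
            per_ring_means: dict[str, dict[str, float]] = {}
            for variant, (structure, traj, charges) in cage_runs.items():
                rings = geom.detect_indole_rings(structure)
                cation = structure.select(residue_id=1)
                ring_means = {}
                total, times = None, None
                for ring in rings:
                    pi = el.pi_system_atoms(ring, config.include_fluorines)
                    es = el.energy_series(traj, cation, pi, charges,
                                          stride_ps=config.energy_stride_ps,
                                          set_b_label=ring.label,
                                          include_fluorines=config.include_fluorines)
                    ring_means[ring.label] = es.mean
                    total = es.energies if total is None else total + es.energies
                    times = es.times_ps
                series[variant] = el.EnergySeries(
                    times_ps=times, energies=total,
                    stride_ps=config.energy_stride_ps,
                    set_a_label="cation", set_b_label="both rings",
                    include_fluorines=config.include_fluorines)
                per_ring_means[variant] = ring_means
            trend = el.variant_trend_report(series)
            report["energies"] = {
                "per_ring_means": per_ring_means,
                "mean_total": trend.means,
                "trend_verdict": trend.verdict,
                "strict_weakening": trend.strict_weakening}

        stage = "hydration"
        if config.stages.get("hydration", True):
            wspec = default_water_spec(config)
            structure, traj, truth = make_water_trajectory(wspec)
            charges = water_charge_table(structure)
            region = hyd.Box(lo=(2.0, 4.0, 4.0), hi=(10.5, 8.0, 8.0))
            bulk_region = hyd.Box(lo=(0.5, 0.5, 0.5), hi=(11.5, 3.0, 11.5))
            density, bulk_energy = hyd.bulk_water_stats(traj, structure, charges,
                                                        bulk_region,
                                                        max_observations=300)
            sites = hyd.cluster_sites(traj, structure, region,
                                      radius=config.clustering_radius,
                                      min_occupancy=config.min_occupancy)
            for s in sites:
                hyd.site_enthalpy(s, structure, charges, traj,
                                  bulk_reference=bulk_energy, max_observations=300)
                hyd.site_entropy(s, traj, structure,
                                 temperature=config.temperature_K,
                                 bulk_density=density)
            probe = np.array([s["center"] for s in truth["planted_sites"]])
            summary = hyd.displaced_free_energy(
                sites, probe, overlap_radius=config.overlap_radius,
                high_energy_threshold=config.high_energy_threshold)
            report["hydration"] = {
                "bulk_density": density, "bulk_energy": bulk_energy,
                "n_sites": len(sites),
                "sites": [{"center": s.center.tolist(), "occupancy": s.occupancy,
                           "enthalpy": s.enthalpy,
                           "minus_t_entropy": s.minus_t_entropy,
                           "free_energy": s.free_energy} for s in sites],
                "displaced": {"n_sites": summary.n_sites,
                              "total_free_energy": summary.total_free_energy,
                              "total_enthalpy": summary.total_enthalpy,
                              "total_minus_t_entropy": summary.total_minus_t_entropy,
                              "n_high_energy": summary.n_high_energy}}

        stage = "ledger"
        if config.stages.get("ledger", True):
            report["ledger"] = verify_reference_tables(config.eda_tolerance,
                                                   config.itc_tolerance)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = _round_floats(report)
    if outdir:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    return report


def verify_reference_tables(eda_tolerance: float = led.DEFAULT_EDA_TOLERANCE,
                        itc_tolerance: float = led.DEFAULT_ITC_TOLERANCE) -> dict:
    """Validate the packaged reference tables: the three decomposition
    identities on each of the four cage-complex columns, and the two ITC
    identities on each of the five binding rows."""
    out = {"eda": [], "itc": [], "tolerances": {"eda": eda_tolerance,
                                                "itc": itc_tolerance}}
    n_pass = 0
    records = led.load_reference_eda()
    for rec in records:
        v = led.eda_validate(rec, tolerance=eda_tolerance)
        out["eda"].append({"label": v.label, "residuals": v.residuals,
                           "passed": v.passed, "failed": v.failed_identities})
        n_pass += v.passed
    for rec in led.load_reference_itc():
        v = led.itc_validate(rec, tolerance=itc_tolerance)
        out["itc"].append({"label": v.label, "residuals": v.residuals,
                           "passed": v.passed, "failed": v.failed_identities})
        n_pass += v.passed
    out["n_pass"] = n_pass
    out["n_total"] = len(out["eda"]) + len(out["itc"])
    out["all_passed"] = n_pass == out["n_total"]
    return _round_floats(out)
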