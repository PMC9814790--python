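"""Thermodynamic bookkeeping for cage-binding energetics.

Three ledgers are implemented:

* the energy-decomposition ledger for an aromatic-cage/trimethyllysine
  complex: the aqueous bond energy splits into strain plus interaction,
  the aqueous interaction into desolvation plus intrinsic interaction,
  and the intrinsic interaction into electrostatic, Pauli, orbital and
  dispersion terms,

      dE(aq)     = dE(aq)_strain + dE(aq)_int
      dE(aq)_int = dE(desolv)_int + dE_int
      dE_int     = dV_elstat + dE_Pauli + dE_oi + dE_disp

  The component values are inputs (they come from quantum-chemical
  calculations outside this package); the ledger composes and validates
  the identities against printed, one-decimal-rounded tables.

* ITC binding records: dG = RT ln Kd and dG = dH + (-T dS), validated
  within rounding/propagation tolerances.

* small arithmetic utilities: isodesmic reaction energies (with
  hartree -> kcal/mol conversion) and fluorination mass-shift checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import F_MINUS_H_MASS, HARTREE_TO_KCAL, R_KCAL

#: worst-case residual of a four-term identity whose terms are rounded to
#: one decimal (5 values x 0.05)
DEFAULT_EDA_TOLERANCE = 0.25
DEFAULT_ITC_TOLERANCE = 0.15


@dataclass(frozen=True)
class EDARecord:
    """One complex's full energy-decomposition ledger (kcal/mol)."""

    label: str
    e_aq: float
    e_aq_strain: float
    e_aq_int: float
    e_desolv_int: float
    e_int: float
    e_pauli: float
    v_elstat: float
    e_oi: float
    e_disp: float
    d_hme_c6mr: float | None = None  # closest methyl-H to 6MR carbon, A
    d_hme_c5mr: float | None = None


@dataclass(frozen=True)
class ITCRecord:
    """One reader-peptide binding record (Kd in nM, energies kcal/mol)."""

    label: str
    kd_nM: float
    kd_err_nM: float
    delta_g: float
    delta_g_err: float
    delta_h: float
    delta_h_err: float
    minus_t_delta_s: float
    minus_t_delta_s_err: float
    temperature_K: float = 298.15


@dataclass(frozen=True)
class Species:
    """A species in a reaction, with a unit-tagged energy."""

    label: str
    energy: float
    unit: str = "kcal/mol"  # or "hartree"

    def energy_kcal(self) -> float:
        if self.unit == "kcal/mol":
            return self.energy
        if self.unit == "hartree":
            return self.energy * HARTREE_TO_KCAL
        raise ValueError(f"unknown energy unit {self.unit!r}")


@dataclass(frozen=True)
class IsodesmicReaction:
    """A balanced model reaction: species on each side must match by label
    multiset (bond types conserved)."""

    reactants: tuple[Species, ...]
    products: tuple[Species, ...]

    def validate_balance(self) -> None:
        def labels(side):
            out: dict[str, int] = {}
            for s in side:
                base = s.label.split("@")[0]  # "ring@complexed" vs "ring@free"
                out[base] = out.get(base, 0) + 1
            return out
        if labels(self.reactants) != labels(self.products):
            raise ValueError("isodesmic reaction is not stoichiometrically balanced: "
                             f"{labels(self.reactants)} vs {labels(self.products)}")


@dataclass
class ValidationResult:
    """Residuals of a record's internal identities."""

    label: str
    residuals: dict[str, float]
    tolerance: float
    passed: bool
    failed_identities: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# EDA operations
# ---------------------------------------------------------------------------

def eda_compose(label: str, strain: float, desolv: float, pauli: float,
                elstat: float, oi: float, disp: float,
                d_hme_c6mr: float | None = None,
                d_hme_c5mr: float | None = None) -> EDARecord:
    """Build a ledger record from its six independent components; the three
    derived energies follow from the identities exactly."""
    for name, v in (("strain", strain), ("desolv", desolv), ("pauli", pauli),
                    ("elstat", elstat), ("oi", oi), ("disp", disp)):
        if not np.isfinite(v):
            raise ValueError(f"non-finite component {name}")
    e_int = elstat + pauli + oi + disp
    e_aq_int = desolv + e_int
    e_aq = strain + e_aq_int
    return EDARecord(label=label, e_aq=e_aq, e_aq_strain=strain, e_aq_int=e_aq_int,
                     e_desolv_int=desolv, e_int=e_int, e_pauli=pauli,
                     v_elstat=elstat, e_oi=oi, e_disp=disp,
                     d_hme_c6mr=d_hme_c6mr, d_hme_c5mr=d_hme_c5mr)


def eda_residuals(record: EDARecord) -> dict[str, float]:
    """Signed residuals of the three ledger identities (stated minus
    recomputed)."""
    return {
        "bond_energy": record.e_aq - (record.e_aq_strain + record.e_aq_int),
        "desolvation_split": record.e_aq_int - (record.e_desolv_int + record.e_int),
        "decomposition": record.e_int - (record.v_elstat + record.e_pauli
                                         + record.e_oi + record.e_disp),
    }


def eda_validate(record: EDARecord,
                 tolerance: float = DEFAULT_EDA_TOLERANCE) -> ValidationResult:
    """Check the ledger identities to within ``tolerance`` (kcal/mol).

    The default tolerance is the worst-case residual when every printed
    value has been independently rounded to one decimal.
    """
    res = eda_residuals(record)
    failed = [k for k, v in res.items() if abs(v) > tolerance]
    return ValidationResult(label=record.label, residuals=res, tolerance=tolerance,
                            passed=not failed, failed_identities=failed)


def delta_vs_reference(records: list[EDARecord], reference_label: str,
                       fieldname: str) -> dict[str, float]:
    """field(record) - field(reference) for every record, e.g. the
    electrostatic weakening of each fluorinated cage against wild type."""
    by_label = {r.label: r for r in records}
    if reference_label not in by_label:
        raise ValueError(f"reference {reference_label!r} not among records "
                         f"{sorted(by_label)}")
    ref = getattr(by_label[reference_label], fieldname)
    return {r.label: getattr(r, fieldname) - ref for r in records}


# ---------------------------------------------------------------------------
# ITC operations
# ---------------------------------------------------------------------------

def gibbs_from_kd(kd_nM: float, temperature_K: float = 298.15) -> float:
    """Standard Gibbs energy of binding (kcal/mol) from a dissociation
    constant in nM: RT ln(Kd in M)."""
    if kd_nM <= 0:
        raise ValueError(f"Kd must be positive, got {kd_nM} nM")
    if temperature_K <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_K} K")
    return R_KCAL * temperature_K * float(np.log(kd_nM * 1e-9))


def itc_validate(record: ITCRecord,
                 tolerance: float = DEFAULT_ITC_TOLERANCE) -> ValidationResult:
    """Check dG = dH + (-T dS) and dG = RT ln Kd for one record."""
    res = {
        "hess": record.delta_g - (record.delta_h + record.minus_t_delta_s),
        "kd_consistency": record.delta_g - gibbs_from_kd(record.kd_nM,
                                                         record.temperature_K),
    }
    failed = [k for k, v in res.items() if abs(v) > tolerance]
    return ValidationResult(label=record.label, residuals=res, tolerance=tolerance,
                            passed=not failed, failed_identities=failed)


# ---------------------------------------------------------------------------
# isodesmic / mass arithmetic
# ---------------------------------------------------------------------------

def isodesmic_energy(reaction: IsodesmicReaction) -> float:
    """Reaction energy (kcal/mol): sum(products) - sum(reactants), with
    hartree-tagged inputs converted at 627.5095 kcal/mol per hartree."""
    reaction.validate_balance()
    return (sum(s.energy_kcal() for s in reaction.products)
            - sum(s.energy_kcal() for s in reaction.reactants))


def fluorination_mass_shift(wt_mass_Da: float, n_fluorines: int) -> float:
    """Expected mass after replacing ``n_fluorines`` aromatic hydrogens by
    fluorine (about +18 Da per fluorine)."""
    if n_fluorines < 0:
        raise ValueError("n_fluorines must be >= 0")
    return wt_mass_Da + n_fluorines * F_MINUS_H_MASS


def mass_difference(mass1_Da: float, mass2_Da: float) -> float:
    """Signed mass difference mass1 - mass2 (Da)."""
    return mass1_Da - mass2_Da


# ---------------------------------------------------------------------------
# table I/O and packaged fixtures
# ---------------------------------------------------------------------------

def read_eda_table(path: str | Path) -> list[EDARecord]:
    """Read a TSV of EDA ledgers, one row per complex; column names match
    the EDARecord field names."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        records.append(EDARecord(
            label=str(row["label"]), e_aq=row["e_aq"], e_aq_strain=row["e_aq_strain"],
            e_aq_int=row["e_aq_int"], e_desolv_int=row["e_desolv_int"],
            e_int=row["e_int"], e_pauli=row["e_pauli"], v_elstat=row["v_elstat"],
            e_oi=row["e_oi"], e_disp=row["e_disp"],
            d_hme_c6mr=row.get("d_hme_c6mr"), d_hme_c5mr=row.get("d_hme_c5mr")))
    return records


def read_itc_table(path: str | Path) -> list[ITCRecord]:
    df = pd.read_csv(path, sep="\t")
    return [ITCRecord(label=str(r["label"]), kd_nM=r["kd_nM"], kd_err_nM=r["kd_err_nM"],
                      delta_g=r["delta_g"], delta_g_err=r["delta_g_err"],
                      delta_h=r["delta_h"], delta_h_err=r["delta_h_err"],
                      minus_t_delta_s=r["minus_t_delta_s"],
                      minus_t_delta_s_err=r["minus_t_delta_s_err"],
                      temperature_K=r.get("temperature_K", 298.15))
            for _, r in df.iterrows()]


def packaged_table_path(name: str) -> Path:
    """Path to a packaged reference table ('eda' or 'itc')."""
    fname = {"eda": "eda_reference.tsv", "itc": "itc_reference.tsv"}[name]
    return Path(str(resources.files("fluorocage").joinpath("data", fname)))


def load_reference_eda() -> list[EDARecord]:
    """The packaged quantum-chemical ledger for the four cage variants."""
    return read_eda_table(packaged_table_path("eda"))


def load_reference_itc() -> list[ITCRecord]:
    """The packaged calorimetric binding table for the five reader-peptide
    pairs."""
    return read_itc_table(packaged_table_path("itc"))
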