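"""Carbon accounting: headspace gas moles, ATP-derived biomass, and a closed
carbon budget with extracellular polymeric substance (EPS) as the residual.

Degraded substrate carbon is attributed to four sinks — acetate, inorganic
carbonate, cell biomass, and EPS.  The first three are measured or estimated;
EPS is never measured directly and is defined by closure
(f_eps = 1 - f_acetate - f_carbonate - f_biomass).  A budget where the
residual is negative is flagged infeasible, never clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .data_model import (
    ATOMIC_MASS,
    BIOMASS_CARBON_FRACTION,
    R_GAS,
    AnalyteSpec,
    AtpCalibration,
    HeadspaceRecord,
    ValidationError,
)

__all__ = [
    "BiomassEstimate",
    "CarbonBudget",
    "headspace_moles",
    "headspace_total_mmol",
    "biomass_from_atp",
    "compute_budget",
    "biomass_yield",
    "biomass_carbon_from_dry_weight",
    "dry_weight_from_biomass_carbon",
]


def headspace_total_mmol(record: HeadspaceRecord) -> float:
    """Total gas in the headspace by the ideal gas law, in mmol."""
    return record.pressure * record.volume * 1e-3 / (R_GAS * record.temperature) * 1e3


def headspace_moles(record: HeadspaceRecord, gas: str) -> float:
    """mmol of one gas: n = y * PV/RT (volume in L converted to m^3)."""
    if gas not in record.mole_fractions:
        raise ValidationError(f"gas {gas!r} not present in record at t={record.time}")
    return record.mole_fractions[gas] * headspace_total_mmol(record)


def biomass_carbon_from_dry_weight(dry_weight_mg: float) -> float:
    """mmol C in ``dry_weight_mg`` of cells, assuming C5H7O2N composition
    (53.1% carbon by mass)."""
    return dry_weight_mg * BIOMASS_CARBON_FRACTION / ATOMIC_MASS["C"]


def dry_weight_from_biomass_carbon(carbon_mmol: float) -> float:
    """Inverse of :func:`biomass_carbon_from_dry_weight`, mg."""
    return carbon_mmol * ATOMIC_MASS["C"] / BIOMASS_CARBON_FRACTION


@dataclass(frozen=True)
class BiomassEstimate:
    """Whole-reactor biomass inferred from one ATP luminometry reading."""

    cfu_per_ml: float
    dry_weight: float  # mg, whole reactor
    carbon_mmol: float

    def __post_init__(self) -> None:
        if min(self.cfu_per_ml, self.dry_weight, self.carbon_mmol) < 0:
            raise ValidationError("biomass estimate fields must be non-negative")


def biomass_from_atp(rlu: float, cal: AtpCalibration, volume: float) -> BiomassEstimate:
    """Convert an RLU reading to CFU/mL, reactor dry weight and carbon.

    The calibration is a log10-log10 line against an *E. coli* K12 standard
    curve.  Readings outside the calibrated RLU range are extrapolated with a
    warning; non-positive readings are an error.
    """
    if rlu <= 0:
        raise ValidationError(f"RLU must be positive, got {rlu}")
    lo, hi = cal.valid_range
    if not lo <= rlu <= hi:
        warnings.warn(
            f"RLU {rlu} outside calibrated range [{lo}, {hi}]; extrapolating",
            stacklevel=2,
        )
    cfu_per_ml = cal.cfu_per_ml(rlu)
    dry_weight = cfu_per_ml * volume * 1e3 * cal.mass_per_cfu
    return BiomassEstimate(
        cfu_per_ml=cfu_per_ml,
        dry_weight=dry_weight,
        carbon_mmol=biomass_carbon_from_dry_weight(dry_weight),
    )


@dataclass(frozen=True)
class CarbonBudget:
    """Partition of degraded substrate carbon over the four sinks.

    Fractions sum to 1 exactly because f_eps is defined by closure; a
    negative residual (sinks exceeding degraded carbon) sets ``feasible``
    False and is reported, never hidden.  ``inorganic_mode`` records whether
    carbonate carbon was measured or estimated stoichiometrically.
    """

    degraded_c: float  # mmol C
    f_acetate: float
    f_carbonate: float
    f_biomass: float
    f_eps: float
    feasible: bool
    inorganic_mode: str = "measured"

    def as_percent(self) -> dict[str, float]:
        return {
            "acetate": 100 * self.f_acetate,
            "carbonate": 100 * self.f_carbonate,
            "biomass": 100 * self.f_biomass,
            "eps": 100 * self.f_eps,
        }


def compute_budget(
    substrate_consumed: dict[AnalyteSpec, float],
    acetate_c: float,
    inorganic_c: float | None,
    biomass_c: float,
) -> CarbonBudget:
    """Close the carbon budget over degraded substrate.

    ``substrate_consumed`` maps each substrate analyte to mmol degraded.
    ``inorganic_c`` may be None, in which case carbonate carbon is estimated
    as half the acetate carbon — the 2:1 acetate:bicarbonate carbon split of
    the equimolar fermentation closure — since dissolved inorganic carbon is
    often not quantified.  EPS is the closure residual.
    """
    degraded_c = sum(mmol * analyte.n_carbon for analyte, mmol in substrate_consumed.items())
    if degraded_c <= 0:
        raise ValidationError("no degraded substrate carbon: budget undefined")
    if inorganic_c is None:
        inorganic_c = acetate_c / 2
        mode = "estimated (half acetate carbon, equimolar closure)"
    else:
        mode = "measured"
    for name, value in (("acetate", acetate_c), ("inorganic", inorganic_c),
                        ("biomass", biomass_c)):
        if value < 0:
            raise ValidationError(f"negative {name} carbon sink: {value}")
    f_acetate = acetate_c / degraded_c
    f_carbonate = inorganic_c / degraded_c
    f_biomass = biomass_c / degraded_c
    f_eps = 1.0 - (f_acetate + f_carbonate + f_biomass)
    return CarbonBudget(
        degraded_c=degraded_c,
        f_acetate=f_acetate,
        f_carbonate=f_carbonate,
        f_biomass=f_biomass,
        f_eps=f_eps,
        feasible=f_eps >= 0,
        inorganic_mode=mode,
    )


def biomass_yield(dry_weight_produced: float, substrate_degraded: float) -> float:
    """Dry-cell yield in mg biomass per mg substrate degraded."""
    if substrate_degraded <= 0:
        raise ValidationError("substrate degraded must be positive")
    if dry_weight_produced < 0:
        raise ValidationError("dry weight produced must be non-negative")
    return dry_weight_produced / substrate_degraded
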