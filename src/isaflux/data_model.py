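"""Domain types, units and delimited-text I/O for microcosm measurement streams.

The package analyses continuously-stirred anaerobic microcosms fed with
cellulose degradation products (CDP) under alkaline conditions.  Three data
streams are handled:

* aqueous chemistry — isosaccharinic acids (alpha/beta-ISA, xylo-ISA) and
  acetate concentrations over time, replicated;
* headspace records — total pressure, gas volume, temperature and GC-TCD
  mole fractions;
* ATP luminometry — relative light units (RLU) calibrated against an
  *E. coli* K12 standard curve.

All concentrations are held internally in mM.  Input files are tidy
long-format CSV (UTF-8, '.' decimal).  Times are decimal days from the start
of the first waste/feed cycle (day 0 = a feed event).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

# ---------------------------------------------------------------------------
# Physical constants (shared across modules)
# ---------------------------------------------------------------------------

R_GAS = 8.314  # J mol^-1 K^-1
DEFAULT_TEMPERATURE_K = 293.15  # 20 degC incubation
ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}

#: Generic bacterial biomass formula C5H7O2N -> carbon mass fraction.
BIOMASS_CARBON_FRACTION = 5 * ATOMIC_MASS["C"] / (
    5 * ATOMIC_MASS["C"] + 7 * ATOMIC_MASS["H"] + 2 * ATOMIC_MASS["O"] + ATOMIC_MASS["N"]
)
#: Default dry mass of a single cell, mg per CFU.
DEFAULT_MASS_PER_CFU_MG = 2.8e-10


class ValidationError(ValueError):
    """Raised when an input file or record violates the data contract."""


# ---------------------------------------------------------------------------
# Analytes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalyteSpec:
    """Chemical identity of a measured aqueous species.

    ``formula`` maps element symbol to atom count; ``charge`` is the net
    charge (acetate is measured as the anion at pH 11).
    """

    name: str
    formula: dict[str, int] = field(hash=False)  # dicts are unhashable; hash by identity fields
    molar_mass: float = 0.0  # g mol^-1
    charge: int = 0

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValidationError(f"{self.name}: molar mass must be positive")
        computed = sum(ATOMIC_MASS[el] * n for el, n in self.formula.items())
        if abs(computed - self.molar_mass) > 0.05:
            raise ValidationError(
                f"{self.name}: molar mass {self.molar_mass} does not match "
                f"formula mass {computed:.3f} g/mol"
            )

    @property
    def n_carbon(self) -> int:
        return self.formula.get("C", 0)


#: ISA is the six-carbon sugar acid from cellulose (two diastereomers measured
#: separately); xylo-ISA the five-carbon analogue from hemicellulose.
ALPHA_ISA = AnalyteSpec("alpha_ISA", {"C": 6, "H": 12, "O": 6}, 180.16)
BETA_ISA = AnalyteSpec("beta_ISA", {"C": 6, "H": 12, "O": 6}, 180.16)
XYLO_ISA = AnalyteSpec("xylo_ISA", {"C": 5, "H": 10, "O": 5}, 150.13)
ACETATE = AnalyteSpec("acetate", {"C": 2, "H": 3, "O": 2}, 59.04, charge=-1)

ANALYTE_REGISTRY: dict[str, AnalyteSpec] = {
    a.name: a for a in (ALPHA_ISA, BETA_ISA, XYLO_ISA, ACETATE)
}
_ALIASES = {
    "a_isa": "alpha_ISA",
    "b_isa": "beta_ISA",
    "x_isa": "xylo_ISA",
    "xisa": "xylo_ISA",
    "isa_alpha": "alpha_ISA",
    "isa_beta": "beta_ISA",
}

ISA_ANALYTES = ("alpha_ISA", "beta_ISA", "xylo_ISA")


def get_analyte(name: str) -> AnalyteSpec:
    key = name.strip()
    canonical = key if key in ANALYTE_REGISTRY else _ALIASES.get(key.lower().replace("-", "_"))
    if canonical is None or canonical not in ANALYTE_REGISTRY:
        raise ValidationError(f"unknown analyte name: {name!r}")
    return ANALYTE_REGISTRY[canonical]


# ---------------------------------------------------------------------------
# Measurement records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeasurementRecord:
    """One aqueous concentration observation.

    ``below_detection`` marks a censored point; ``detection_limit`` (mM) then
    holds the limit the instrument reported, and ``concentration`` a
    substituted value (by default half that limit).
    """

    time: float  # days
    analyte: str
    concentration: float  # mM
    replicate: str = "r1"
    below_detection: bool = False
    detection_limit: float | None = None


@dataclass
class MeasurementSeries:
    """Replicated aqueous concentration time series, validated on build."""

    records: list[MeasurementRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        last: dict[tuple[str, str], float] = {}
        for i, rec in enumerate(self.records):
            if rec.time < 0:
                raise ValidationError(f"record {i}: negative time {rec.time}")
            if rec.concentration < 0 and not rec.below_detection:
                raise ValidationError(
                    f"record {i}: negative concentration {rec.concentration}"
                )
            key = (rec.replicate, rec.analyte)
            if key in last and rec.time <= last[key]:
                raise ValidationError(
                    f"record {i}: times not strictly increasing for "
                    f"replicate {rec.replicate!r}, analyte {rec.analyte!r}"
                )
            last[key] = rec.time

    def analytes(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.analyte, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_d": [r.time for r in self.records],
                "analyte": [r.analyte for r in self.records],
                "concentration_mm": [r.concentration for r in self.records],
                "replicate": [r.replicate for r in self.records],
                "below_detection": [r.below_detection for r in self.records],
            }
        )

    def pooled(self, analyte: str) -> list[tuple[float, float]]:
        """(time, mean concentration over replicates) for one analyte,
        censored points excluded."""
        df = self.to_frame()
        df = df[(df["analyte"] == analyte) & (~df["below_detection"])]
        g = df.groupby("time_d")["concentration_mm"].mean()
        return list(zip(g.index.to_list(), g.to_list()))


@dataclass(frozen=True)
class HeadspaceRecord:
    """Headspace state at one sampling time.

    Pressure is total absolute pressure (Pa); mole fractions come from
    GC-TCD and need not sum to 1 (undetected gases may be omitted).
    """

    time: float
    pressure: float  # Pa
    volume: float  # L
    temperature: float  # K
    mole_fractions: dict[str, float]

    def __post_init__(self) -> None:
        if self.pressure <= 0 or self.volume <= 0 or self.temperature <= 0:
            raise ValidationError("pressure, volume and temperature must be positive")
        total = sum(self.mole_fractions.values())
        if total > 1 + 1e-9:
            raise ValidationError(f"mole fractions sum to {total} > 1")
        if any(y < 0 for y in self.mole_fractions.values()):
            raise ValidationError("negative mole fraction")


@dataclass(frozen=True)
class AtpCalibration:
    """log10-log10 RLU -> CFU/mL calibration against an E. coli K12 curve."""

    slope: float
    intercept: float
    mass_per_cfu: float = DEFAULT_MASS_PER_CFU_MG  # mg CFU^-1
    valid_range: tuple[float, float] = (1.0, 1e9)  # RLU

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValidationError("calibration slope must be positive")
        if self.mass_per_cfu <= 0:
            raise ValidationError("mass per CFU must be positive")

    def cfu_per_ml(self, rlu: float) -> float:
        if rlu <= 0:
            raise ValidationError(f"RLU must be positive, got {rlu}")
        return 10 ** (self.slope * math.log10(rlu) + self.intercept)

    def rlu_from_cfu_per_ml(self, cfu_per_ml: float) -> float:
        """Inverse of the calibration line (used by the simulator)."""
        return 10 ** ((math.log10(cfu_per_ml) - self.intercept) / self.slope)


@dataclass(frozen=True)
class CycleSchedule:
    """Waste/feed regime: at each feed time, ``waste_fraction`` of the liquid
    (solutes and suspended flocs included) is replaced with fresh feed."""

    feed_times: tuple[float, ...]
    waste_fraction: float
    reactor_volume: float  # L
    feed_composition: dict[str, float] = field(default_factory=dict)  # analyte -> mM

    def __post_init__(self) -> None:
        if not all(b > a for a, b in zip(self.feed_times, self.feed_times[1:])):
            raise ValidationError("feed times must be strictly increasing")
        if not 0 <= self.waste_fraction < 1:
            raise ValidationError("waste fraction must lie in [0, 1)")
        if self.reactor_volume <= 0:
            raise ValidationError("reactor volume must be positive")


# ---------------------------------------------------------------------------
# Unit conversion
# ---------------------------------------------------------------------------


def to_mm(value: float, unit: str, analyte: AnalyteSpec) -> float:
    """Convert a concentration to mM. Supported units: mM, mg/L (== mg_l, mgl-1)."""
    u = unit.strip().lower().replace(" ", "")
    if u in ("mm", "mmol/l", "mmoll-1"):
        return value
    if u in ("mg/l", "mg_l", "mgl-1", "mgperl"):
        return value / analyte.molar_mass
    if u in ("m", "mol/l"):
        return value * 1e3
    raise ValidationError(f"unparseable concentration unit: {unit!r}")


def from_mm(value_mm: float, unit: str, analyte: AnalyteSpec) -> float:
    u = unit.strip().lower().replace(" ", "")
    if u in ("mm", "mmol/l", "mmoll-1"):
        return value_mm
    if u in ("mg/l", "mg_l", "mgl-1", "mgperl"):
        return value_mm * analyte.molar_mass
    if u in ("m", "mol/l"):
        return value_mm * 1e-3
    raise ValidationError(f"unparseable concentration unit: {unit!r}")


def carbon_moles(analyte: AnalyteSpec, concentration_mm: float, volume_l: float) -> float:
    """mmol of carbon held by ``analyte`` at ``concentration_mm`` in ``volume_l``."""
    if concentration_mm < 0 or volume_l < 0:
        raise ValidationError("concentration and volume must be non-negative")
    return concentration_mm * volume_l * analyte.n_carbon


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_SERIES_COLUMNS = ["time_d", "analyte", "concentration", "unit", "replicate"]


def read_series(path, bd_substitution: float = 0.5) -> MeasurementSeries:
    """Read a tidy chemistry CSV into a validated :class:`MeasurementSeries`.

    Required columns: ``time_d, analyte, concentration, unit, replicate``.
    A concentration written ``<X`` is treated as below-detection with limit X
    (in the row's unit); the stored value is ``bd_substitution * limit``.
    """
    df = pd.read_csv(path, dtype={"concentration": str, "replicate": str})
    missing = [c for c in _SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise ValidationError(f"{path}: no records")

    records: list[MeasurementRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        analyte = get_analyte(str(row.analyte))
        raw = str(row.concentration).strip()
        below = raw.startswith("<")
        try:
            value = float(raw[1:] if below else raw)
        except ValueError as exc:
            raise ValidationError(f"{path} row {i}: unparseable concentration {raw!r}") from exc
        if value < 0:
            raise ValidationError(f"{path} row {i}: negative concentration {value}")
        value_mm = to_mm(value, str(row.unit), analyte)
        records.append(
            MeasurementRecord(
                time=float(row.time_d),
                analyte=analyte.name,
                concentration=value_mm * bd_substitution if below else value_mm,
                replicate=str(row.replicate),
                below_detection=below,
                detection_limit=value_mm if below else None,
            )
        )
    try:
        return MeasurementSeries(records)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_series(series: MeasurementSeries, path) -> None:
    """Write a series back to the tidy CSV schema (mM, 6 significant figures)."""
    rows = []
    for r in series.records:
        value = r.detection_limit if r.below_detection else r.concentration
        conc = f"{'<' if r.below_detection else ''}{value:.6g}"
        rows.append((f"{r.time:.6g}", r.analyte, conc, "mM", r.replicate))
    pd.DataFrame(rows, columns=_SERIES_COLUMNS).to_csv(path, index=False)


def read_headspace(path) -> list[HeadspaceRecord]:
    """Read a headspace CSV: time_d, pressure_pa, volume_l, temperature_k,
    then one column per gas mole fraction."""
    df = pd.read_csv(path)
    required = ["time_d", "pressure_pa", "volume_l", "temperature_k"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    gas_cols = [c for c in df.columns if c not in required]
    out = []
    for row in df.itertuples(index=False):
        fractions = {g: float(getattr(row, g)) for g in gas_cols}
        out.append(
            HeadspaceRecord(
                time=float(row.time_d),
                pressure=float(row.pressure_pa),
                volume=float(row.volume_l),
                temperature=float(row.temperature_k),
                mole_fractions=fractions,
            )
        )
    return out


def write_headspace(records: list[HeadspaceRecord], path) -> None:
    gases = sorted({g for rec in records for g in rec.mole_fractions})
    rows = []
    for rec in records:
        row = {
            "time_d": rec.time,
            "pressure_pa": rec.pressure,
            "volume_l": rec.volume,
            "temperature_k": rec.temperature,
        }
        row.update({g: rec.mole_fractions.get(g, 0.0) for g in gases})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_atp(path) -> list[tuple[float, float]]:
    """Read an ATP luminometry CSV with columns time_d, rlu."""
    df = pd.read_csv(path)
    missing = [c for c in ("time_d", "rlu") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return [(float(t), float(r)) for t, r in zip(df["time_d"], df["rlu"])]


def write_atp(readings: list[tuple[float, float]], path) -> None:
    pd.DataFrame(readings, columns=["time_d", "rlu"]).to_csv(path, index=False)


def substitute_below_detection(
    series: MeasurementSeries, substitution: float = 0.5
) -> MeasurementSeries:
    """Return a copy with censored values re-substituted at
    ``substitution * detection_limit``."""
    records = [
        replace(r, concentration=substitution * r.detection_limit)
        if r.below_detection and r.detection_limit is not None
        else r
        for r in series.records
    ]
    return MeasurementSeries(records)
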