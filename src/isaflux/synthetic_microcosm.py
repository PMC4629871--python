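"""Seeded generator of complete synthetic microcosm datasets.

Emulates a continuously stirred, nitrogen-blanketed 250 mL alkaline reactor
fed with cellulose degradation products on a 10% waste/feed cycle every two
weeks: three isosaccharinic acid pools decay first-order, degraded carbon is
partitioned between EPS, cell biomass and fermentation (acetate +
bicarbonate + H2 per the balanced reaction), H2 accumulates in a fixed
75 mL headspace by the ideal gas law, and observations carry multiplicative
lognormal noise.  An inhibited (chloramphenicol-amended) control has zero
biological activity.

Every stream a real study would measure is emitted — replicated aqueous
chemistry, headspace pressure/composition, ATP luminometry — plus a
noiseless per-step carbon ledger used as a conservation oracle.  Feed-stream
ISA concentrations are synthetic choices (the CDP feedstock composition is
a free parameter), sized to give realistic mM-scale dynamics.

The update is discrete-time with the exact per-step decay factor, so
substrate trajectories and cumulative products are independent of the step
size; an ODE solver would add error without adding physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import (
    DEFAULT_TEMPERATURE_K,
    R_GAS,
    AtpCalibration,
    CycleSchedule,
    HeadspaceRecord,
    MeasurementRecord,
    MeasurementSeries,
    ValidationError,
    get_analyte,
)
from .carbon_flow import dry_weight_from_biomass_carbon
from .stoichiometry import balance_fermentation

__all__ = ["SimulationConfig", "SimulationOutput", "simulate", "paper_preset"]

STANDARD_PRESSURE_PA = 101325.0


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of one synthetic microcosm run.

    ``phi_eps`` and ``phi_biomass`` are the fractions of degraded substrate
    carbon diverted to EPS and to cells; the remainder is fermented.
    ``h2_recovery`` scales stoichiometric H2 reaching the headspace (dissolved
    H2 is ignored).  ``inhibited`` models a chloramphenicol control: no decay,
    no products.
    """

    rate_constants: dict[str, float]  # analyte -> day^-1
    initial_concentrations: dict[str, float]  # analyte -> mM (ISAs + acetate)
    schedule: CycleSchedule
    phi_eps: float = 0.0
    phi_biomass: float = 0.0
    feed_acetate: float = 0.0  # mM acetate in the feed stream
    headspace_volume: float = 0.075  # L
    temperature: float = DEFAULT_TEMPERATURE_K
    initial_pressure: float = STANDARD_PRESSURE_PA  # Pa, pure N2 at start
    noise_cv: float = 0.0
    h2_recovery: float = 1.0
    inhibited: bool = False
    seed: int = 0
    dt: float = 0.1  # days
    t_end: float | None = None  # default: one cycle past the last feed
    sample_interval: float = 2.0  # chemistry + headspace sampling, days
    atp_interval: float = 7.0  # luminometry sampling, days
    n_replicates: int = 1
    initial_biomass_c: float = 0.06  # mmol C
    calibration: AtpCalibration = field(default_factory=lambda: AtpCalibration(1.0, 2.0))

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if not 0 <= self.phi_eps < 1 or not 0 <= self.phi_biomass < 1:
            raise ValidationError("phi_eps and phi_biomass must lie in [0, 1)")
        if self.phi_eps + self.phi_biomass >= 1:
            raise ValidationError("phi_eps + phi_biomass must be < 1")
        if not 0 < self.h2_recovery <= 1:
            raise ValidationError("h2_recovery must lie in (0, 1]")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be non-negative")
        if self.n_replicates < 1:
            raise ValidationError("at least one replicate required")

    @property
    def end_time(self) -> float:
        if self.t_end is not None:
            return self.t_end
        feeds = self.schedule.feed_times
        period = feeds[-1] - feeds[-2] if len(feeds) > 1 else 14.0
        return feeds[-1] + period


@dataclass
class SimulationOutput:
    """Observed streams plus the noiseless truth ledger."""

    chemistry: MeasurementSeries
    headspace: list[HeadspaceRecord]
    atp: list[tuple[float, float]]  # (time_d, RLU)
    ledger: pd.DataFrame  # per-step carbon pools, mmol C
    config: SimulationConfig


def paper_preset(**overrides) -> SimulationConfig:
    """The reference alkaline CDP microcosm scenario.

    First-order rate constants 3.33e-2 (alpha-ISA), 9.36e-2 (beta-ISA) and
    6.78e-2 (xylo-ISA) per day; 63.7% of degraded carbon to EPS and 0.5% to
    biomass; two 14-day cycles of 10% waste/feed in a 0.25 L reactor with a
    0.075 L headspace at 293.15 K.  Initial and feed ISA concentrations are
    synthetic (see module docstring).
    """
    schedule = CycleSchedule(
        feed_times=(0.0, 14.0),
        waste_fraction=0.10,
        reactor_volume=0.25,
        feed_composition={
            "alpha_ISA": 20.0,
            "beta_ISA": 9.0,
            "xylo_ISA": 5.0,
            "acetate": 2.0,
        },
    )
    config = SimulationConfig(
        rate_constants={"alpha_ISA": 3.33e-2, "beta_ISA": 9.36e-2, "xylo_ISA": 6.78e-2},
        initial_concentrations={
            "alpha_ISA": 4.0,
            "beta_ISA": 1.2,
            "xylo_ISA": 0.8,
            "acetate": 4.0,
        },
        schedule=schedule,
        phi_eps=0.637,
        phi_biomass=0.005,
        feed_acetate=2.0,
        noise_cv=0.05,
    )
    return replace(config, **overrides) if overrides else config


def _time_grid(config: SimulationConfig) -> np.ndarray:
    end = config.end_time
    times = set(np.round(np.arange(0.0, end + 1e-9, config.dt), 9).tolist())
    times.update(t for t in config.schedule.feed_times if t <= end)
    times.update(np.round(np.arange(0.0, end, config.sample_interval), 9).tolist())
    times.update(np.round(np.arange(0.0, end + 1e-9, config.atp_interval), 9).tolist())
    times.add(float(end))
    return np.array(sorted(times))


def simulate(config: SimulationConfig) -> SimulationOutput:
    """Run the microcosm forward and emit observed streams plus the ledger.

    Per step of length h: each substrate pool decays by the exact factor
    e^(-k h); the degraded carbon splits phi_eps : phi_biomass : remainder,
    with the remainder fermented stoichiometrically; stoichiometric H2 times
    ``h2_recovery`` enters the fixed-volume headspace.  At each feed time,
    ``waste_fraction`` of the liquid — solutes and suspended flocs alike —
    is replaced with feed.  Observations multiply truth by lognormal noise
    with the configured CV; a single integer seed drives one generator.
    """
    rng = np.random.default_rng(config.seed)
    sched = config.schedule
    v_liq = sched.reactor_volume
    reactions = {name: balance_fermentation(get_analyte(name)) for name in config.rate_constants}

    conc = dict(config.initial_concentrations)  # mM
    conc.setdefault("acetate", 0.0)
    inorganic_c = 0.0  # mmol C
    biomass_c = config.initial_biomass_c
    eps_c = 0.0
    h2_mmol = 0.0
    n2_mmol = (
        config.initial_pressure * config.headspace_volume * 1e-3
        / (R_GAS * config.temperature) * 1e3
    )

    sigma = math.sqrt(math.log(1 + config.noise_cv**2)) if config.noise_cv > 0 else 0.0

    def noisy(x: float) -> float:
        if sigma == 0.0 or x == 0.0:
            return x
        return x * math.exp(sigma * rng.standard_normal())

    grid = _time_grid(config)
    feed_times = set(sched.feed_times)
    sample_times = set(np.round(np.arange(0.0, config.end_time, config.sample_interval), 9))
    atp_times = set(np.round(np.arange(0.0, config.end_time + 1e-9, config.atp_interval), 9))

    chem_records: list[MeasurementRecord] = []
    headspace: list[HeadspaceRecord] = []
    atp: list[tuple[float, float]] = []
    ledger_rows: list[dict[str, float]] = []

    def observe(t: float) -> None:
        if t in sample_times:
            for rep in range(config.n_replicates):
                for name in sorted(conc):
                    chem_records.append(
                        MeasurementRecord(
                            time=t, analyte=name,
                            concentration=noisy(conc[name]),
                            replicate=f"r{rep + 1}",
                        )
                    )
            total = n2_mmol + h2_mmol
            pressure = total * 1e-3 * R_GAS * config.temperature / (config.headspace_volume * 1e-3)
            y_h2 = min(noisy(h2_mmol / total), 1.0)
            headspace.append(
                HeadspaceRecord(
                    time=t, pressure=noisy(pressure),
                    volume=config.headspace_volume,
                    temperature=config.temperature,
                    mole_fractions={"h2": y_h2, "n2": 1.0 - y_h2},
                )
            )
        if t in atp_times:
            dw = dry_weight_from_biomass_carbon(biomass_c)
            cfu_per_ml = dw / config.calibration.mass_per_cfu / (v_liq * 1e3)
            rlu = config.calibration.rlu_from_cfu_per_ml(max(cfu_per_ml, 1e-12))
            atp.append((t, noisy(rlu)))

    def log_ledger(t: float, event: str) -> None:
        row = {"time_d": t, "event": event}
        substrate_c = 0.0
        for name in config.rate_constants:
            c_mmol = conc[name] * v_liq * get_analyte(name).n_carbon
            row[f"{name}_c"] = c_mmol
            substrate_c += c_mmol
        acetate_c = conc["acetate"] * v_liq * get_analyte("acetate").n_carbon
        row.update(
            substrate_c=substrate_c, acetate_c=acetate_c, inorganic_c=inorganic_c,
            biomass_c=biomass_c, eps_c=eps_c, h2_mmol=h2_mmol,
            total_c=substrate_c + acetate_c + inorganic_c + biomass_c + eps_c,
        )
        ledger_rows.append(row)

    for i, t in enumerate(grid):
        if i > 0:
            h = t - grid[i - 1]
            if not config.inhibited:
                ferm_frac = 1.0 - config.phi_eps - config.phi_biomass
                for name, k in config.rate_constants.items():
                    analyte = get_analyte(name)
                    decayed_mm = conc[name] * (1.0 - math.exp(-k * h))
                    conc[name] -= decayed_mm
                    decayed_mmol = decayed_mm * v_liq
                    carbon = decayed_mmol * analyte.n_carbon
                    eps_c += config.phi_eps * carbon
                    biomass_c += config.phi_biomass * carbon
                    fermented = decayed_mmol * ferm_frac
                    rxn = reactions[name]
                    conc["acetate"] += float(rxn.b) * fermented / v_liq
                    inorganic_c += float(rxn.c) * fermented  # 1 C per bicarbonate
                    h2_mmol += float(rxn.d) * fermented * config.h2_recovery
        if t in feed_times and t > grid[0]:
            log_ledger(t, "pre_feed")
            w = sched.waste_fraction
            for name in conc:
                feed_mm = sched.feed_composition.get(name, 0.0)
                if name == "acetate" and "acetate" not in sched.feed_composition:
                    feed_mm = config.feed_acetate
                conc[name] = (1 - w) * conc[name] + w * feed_mm
            inorganic_c *= 1 - w
            biomass_c *= 1 - w  # flocs are suspended and wasted with the liquid
            eps_c *= 1 - w
            log_ledger(t, "post_feed")
        else:
            log_ledger(t, "step")
        observe(float(t))

    return SimulationOutput(
        chemistry=MeasurementSeries(chem_records),
        headspace=headspace,
        atp=atp,
        ledger=pd.DataFrame(ledger_rows),
        config=config,
    )
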