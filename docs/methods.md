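# Methods

## Fermentation stoichiometry

An uncharged C/H/O substrate CₓH_yO_z ferments as

    substrate + a H2O -> b CH3COO- + c HCO3- + d H2 + e H+

Conservation of C (x = 2b + c), H (y + 2a = 3b + c + 2d + e),
O (z + a = 2b + 3c) and charge (e = b + c) leaves one degree of freedom.
The package resolves it with a **closure constraint**:

* `equimolar` (default): b = c, i.e. acetate and bicarbonate produced
  equimolar. This is the classical anaerobic carbohydrate split — two thirds
  of substrate carbon to acetate, one third to bicarbonate — and it gives
  the canonical equations for both the C₆ acid (a,b,c,d,e = 4,2,2,4,4) and
  the C₅ acid (10/3, 5/3, 5/3, 10/3, 10/3).
* `max-h2`: b = 0, the hydrogen-maximising limit with all carbon oxidised to
  bicarbonate.
* `fixed-acetate`: the acetate coefficient is imposed directly.

Coefficients are exact `fractions.Fraction`s; `verify_balance` recomputes
residuals by direct atom counting and any negative coefficient under a
closure raises an error naming the offending species. For any (CH₂O)ₙ
substrate the equimolar solution is the C₆ solution scaled by n/6 (a tested
invariant).

## First-order kinetics over waste/feed cycles

Within one feed-to-feed interval substrate decays as C(t) = C₀e^(−kt).
Records are assigned to half-open intervals [feed_i, feed_{i+1}); the sample
taken at a feed time opens that cycle, so a fit never crosses the
concentration step-up of a feed event. Replicates are pooled by mean at
each time point. Censored (below-detection) values are excluded from
fitting; at least 3 usable points are required per cycle.

k is estimated as minus the OLS slope of ln C on t — the standard,
reproducible small-n choice, exact on noiseless data — with the slope's
standard error. Negative point estimates (possible for flat, noisy data)
are truncated at zero and read as "no detectable degradation". A rate is
called significant when the pooled estimate exceeds twice its SE.

**Pooling.** Per-cycle estimates are pooled as their arithmetic mean. The
pooled SE is `max(SD_between/sqrt(n), sqrt(mean(se_i^2)/n))`: with only two
cycles the between-cycle sample SD has a single degree of freedom and is far
too unstable to set interval widths on its own (a ±2 SE interval built from
it covers the truth only ~70% of the time), so it is floored by the
propagated within-cycle regression error. With n = 1 the fit's own SE is
reported. A joint mode (one shared slope, per-cycle intercepts) is also
provided; on noiseless data the two agree exactly.

## Headspace gas accounting

Gas amounts follow the ideal gas law, n = y·PV/RT with R = 8.314 J mol⁻¹ K⁻¹
(at 101325 Pa, 75 mL and 293.15 K the headspace holds 3.118 mmol of gas).
Temperature defaults to 293.15 K (20 °C incubation) unless a record states
otherwise. Dissolved H₂ and carbonate speciation (CO₂/HCO₃⁻/CO₃²⁻) are not
modelled; at pH ~11 with no CO₂ or CH₄ detected in the headspace, inorganic
carbon is treated as a single aqueous pool.

## Biomass from ATP luminometry

The calibration is a log–log line, log₁₀(CFU mL⁻¹) = slope·log₁₀(RLU) +
intercept, of the kind obtained from an *E. coli* K12 dilution series.
Readings outside the calibrated RLU range are extrapolated with a warning;
non-positive readings are errors. Dry weight uses a per-cell mass of
2.8×10⁻¹⁰ mg CFU⁻¹ and biomass carbon the generic composition C₅H₇O₂N
(53.1% C by mass). Both are standard constants, exposed in configuration,
because measured values for an alkaliphilic floc community are generally
unavailable.

## Carbon budget

Degraded substrate carbon is partitioned over four sinks:

    f_acetate + f_carbonate + f_biomass + f_eps = 1

EPS is **defined by closure** — it is never measured — mirroring how floc
EPS production is inferred in such systems. A negative residual marks the
budget infeasible; fractions are reported as computed, never clipped.
If dissolved inorganic carbon was not measured, carbonate carbon is
estimated as half the acetate carbon (the exact 2:1 acetate:bicarbonate
carbon ratio of the equimolar closure); the mode used is recorded in the
output.

In the pipeline, substrate degraded and acetate produced are measured as
within-cycle first-to-last differences of the pooled series. This makes the
two sides of the budget share identical observation windows (so fractions
are unbiased even though the last sample of a cycle precedes the next feed
by up to one sampling interval) and automatically excludes acetate supplied
with the feed. The reported "predicted" H₂ and acetate are the
stoichiometric ceilings assuming all degraded substrate were fermented;
measured values below them indicate carbon diverted to EPS/biomass, and the
two are reported side by side, never forced to agree.

## Synthetic microcosm generator

The generator emulates a 250 mL continuously stirred, N₂-blanketed reactor
at 293.15 K with a 75 mL fixed-volume headspace, on a 10% waste/feed cycle
every 14 days, sampled every 2 days (chemistry, headspace) and every 7 days
(ATP):

1. each ISA pool decays by the exact factor e^(−k·dt) per step (zero when
   chloramphenicol-inhibited);
2. degraded carbon splits φ_eps : φ_biomass : remainder; the remainder is
   fermented per the substrate's balanced reaction;
3. stoichiometric H₂ × `h2_recovery` (default 1) accumulates in the
   headspace, raising pressure by the ideal gas law;
4. at each feed time the waste fraction of liquid — solutes and suspended
   flocs alike — is replaced by feed;
5. observations are truth × lognormal noise with the configured CV
   (median-parameterised, so log-scale noise is zero-mean), all drawn from
   one seeded generator.

Discrete time with exact per-step decay was chosen over an ODE solver
because the model is linear: substrate trajectories and cumulative products
are then independent of the step size, which both removes discretisation
error and makes closed-form oracles possible. A noiseless per-step carbon
ledger is emitted alongside the observations and conserves total carbon
between feed events to 1×10⁻⁹ relative (a tested invariant).

`paper_preset()` encodes the reference study conditions: rate constants
0.0333/0.0936/0.0678 day⁻¹ (α-ISA/β-ISA/xylo-ISA), φ_eps = 0.637,
φ_biomass = 0.005, two 14-day cycles of 10% exchange, 5% CV noise. Note
that these diversion fractions imply acetate and carbonate carbon fractions
of 23.9% and 11.9% — the fermented remainder split 2:1 — so the four-sink
partition is internally consistent by construction. Initial and feed ISA
concentrations (4/1.2/0.8 mM initial; 20/9/5 mM in the feed, plus 2 mM
acetate) are **synthetic choices**: CDP feedstock composition varies by
preparation and is not a measured constant here. They were sized once to
give mM-scale dynamics with roughly 1 mmol of H₂ and about 2 mmol of
accumulated acetate over two cycles, which is the realistic operating
regime for this reactor geometry.

What the generator does *not* emulate: biofilm/floc spatial structure, pH
drift and carbonate speciation, substrate-dependent (Monod) kinetics,
dissolved H₂, analytical drift or autocorrelated instrument error. Passing
recovery tests therefore shows the estimators are correct under the stated
noise model, not that real microcosm data meet that model.

## Numerical and design choices

* Concentrations are carried internally in mM; molar masses 180.16 (ISA),
  150.13 (xylo-ISA) and 59.04 g mol⁻¹ (acetate anion).
* Below-detection values are flagged and substituted at half the detection
  limit by default (configurable); they are excluded from log-linear fits.
* Test-scale problem sizes — 200 seeds for rate-recovery checks, 50 seeds
  for budget recovery — give medians and coverage rates stable to well
  under the tolerances being checked while keeping the suite fast.
* The budget pipeline reports biomass production as the sum of within-cycle
  increases of ATP-derived biomass carbon; with 7-day ATP sampling part of
  each first cycle's growth window is unobserved, biasing the biomass
  fraction slightly low (and the EPS residual correspondingly high) by a
  few tenths of a percentage point under preset conditions.

## Known limitations

* The dry-cell yield (mg biomass per mg substrate) and the biomass carbon
  fraction are reported independently; under the default composition
  constants they are not mutually derivable, and no reconciliation is
  attempted.
* The EPS sink inherits every error of the other three sinks (it is the
  closure residual); it should be read as "unaccounted carbon consistent
  with EPS production", not as a measurement.
* Fermentation chemistry is restricted to the acetate/bicarbonate/H₂/H⁺
  product set; no thermodynamic feasibility (ΔG) checks are made.
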