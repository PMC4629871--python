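"""First-order degradation kinetics across waste/feed cycles.

Substrate decay within one feed-to-feed interval follows C(t) = C0 e^(-kt).
The rate constant is estimated per cycle by ordinary least squares on
ln(concentration) versus time — exact on noiseless data and the standard
small-n choice — then pooled across cycles.  Feed events step concentrations
up, so fitting never crosses a feed boundary; segmentation handles that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import CycleSchedule, MeasurementSeries, ValidationError

__all__ = [
    "CycleSegment",
    "KineticsFit",
    "PooledRate",
    "InsufficientDataError",
    "segment_cycles",
    "fit_first_order",
    "fit_joint",
    "pool_rates",
    "fit_series",
]

MIN_POINTS = 3


class InsufficientDataError(ValueError):
    """Fewer than three usable points in a cycle segment."""


@dataclass(frozen=True)
class CycleSegment:
    """Pooled (time, concentration) points of one analyte within one cycle."""

    cycle: int
    analyte: str
    points: tuple[tuple[float, float], ...]  # (days, mM)


@dataclass(frozen=True)
class KineticsFit:
    """Per-cycle first-order fit: k = -slope of ln C on t, with its OLS
    standard error. Negative point estimates are truncated at zero (no
    detectable degradation)."""

    k: float  # day^-1
    se: float  # day^-1
    n_points: int
    analyte: str
    cycle: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.k) or self.se < 0:
            raise ValidationError("rate constant must be finite with se >= 0")


@dataclass(frozen=True)
class PooledRate:
    """Rate constant pooled over cycles.

    ``se`` is the between-cycle sample SD / sqrt(n), floored by the
    propagated within-cycle regression error sqrt(mean(se_i^2)/n); with only
    two cycles the between-cycle SD alone is too unstable a scale estimate.
    For a single cycle the fit's own se is reported.
    """

    analyte: str
    mean_k: float
    se: float
    n_cycles: int

    @property
    def significant(self) -> bool:
        """Degradation detectably above zero (point estimate > 2 SE)."""
        return self.mean_k > 0 and self.mean_k > 2 * self.se


def segment_cycles(series: MeasurementSeries, schedule: CycleSchedule) -> list[CycleSegment]:
    """Assign replicate-pooled points to half-open feed intervals
    [feed_i, feed_{i+1}); the sample taken at a feed time opens that cycle."""
    feeds = list(schedule.feed_times)
    if not feeds:
        raise ValidationError("schedule must contain at least one feed time")
    segments: list[CycleSegment] = []
    for analyte in series.analytes():
        points = series.pooled(analyte)
        if any(t < feeds[0] for t, _ in points):
            raise ValidationError(
                f"{analyte}: records before the first feed time {feeds[0]}"
            )
        for i, start in enumerate(feeds):
            end = feeds[i + 1] if i + 1 < len(feeds) else math.inf
            cycle_pts = tuple(p for p in points if start <= p[0] < end)
            if cycle_pts:
                segments.append(CycleSegment(cycle=i, analyte=analyte, points=cycle_pts))
    return segments


def _log_linear(points: list[tuple[float, float]]) -> tuple[float, float]:
    t = np.array([p[0] for p in points])
    lnc = np.log([p[1] for p in points])
    if np.ptp(lnc) == 0:  # constant concentration: slope 0, no residual
        return 0.0, 0.0
    res = stats.linregress(t, lnc)
    return float(res.slope), float(res.stderr)


def fit_first_order(segment: CycleSegment) -> KineticsFit:
    """OLS fit of ln(concentration) on time within one cycle.

    Non-positive concentrations (e.g. below-detection substitutions at zero)
    are excluded; at least three usable points are required.
    """
    usable = [p for p in segment.points if p[1] > 0]
    if len(usable) < MIN_POINTS:
        raise InsufficientDataError(
            f"{segment.analyte} cycle {segment.cycle}: "
            f"{len(usable)} usable points (< {MIN_POINTS})"
        )
    slope, stderr = _log_linear(usable)
    return KineticsFit(
        k=max(-slope, 0.0),
        se=stderr,
        n_points=len(usable),
        analyte=segment.analyte,
        cycle=segment.cycle,
    )


def fit_joint(segments: list[CycleSegment]) -> KineticsFit:
    """Joint fit across cycles: one shared slope, one intercept per cycle.

    Each cycle's times are re-zeroed to its first sample so the shared slope
    is identified from within-cycle decay only.
    """
    if not segments:
        raise InsufficientDataError("no segments supplied")
    analyte = segments[0].analyte
    if any(s.analyte != analyte for s in segments):
        raise ValidationError("joint fit requires segments of one analyte")
    t, lnc, groups = [], [], []
    for s in segments:
        usable = [p for p in s.points if p[1] > 0]
        t0 = min(p[0] for p in usable) if usable else 0.0
        for time, conc in usable:
            t.append(time - t0)
            lnc.append(math.log(conc))
            groups.append(s.cycle)
    if len(t) < MIN_POINTS + len(segments) - 1:
        raise InsufficientDataError("too few points for a joint fit")
    # design matrix: per-cycle intercept dummies + shared time column
    cycles = sorted(set(groups))
    X = np.zeros((len(t), len(cycles) + 1))
    for i, g in enumerate(groups):
        X[i, cycles.index(g)] = 1.0
    X[:, -1] = t
    y = np.asarray(lnc)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = len(t) - X.shape[1]
    if dof > 0 and float(resid @ resid) > 0:
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = math.sqrt(cov[-1, -1])
    else:
        se = 0.0
    return KineticsFit(
        k=max(-float(coef[-1]), 0.0), se=se, n_points=len(t),
        analyte=analyte, cycle=-1,
    )


def pool_rates(fits: list[KineticsFit]) -> PooledRate:
    """Pool per-cycle fits of one analyte into a mean rate with uncertainty."""
    if not fits:
        raise ValidationError("no fits to pool")
    analyte = fits[0].analyte
    if any(f.analyte != analyte for f in fits):
        raise ValidationError("cannot pool fits for different analytes")
    ks = np.array([f.k for f in fits])
    n = len(ks)
    if n == 1:
        return PooledRate(analyte=analyte, mean_k=float(ks[0]), se=fits[0].se, n_cycles=1)
    between = float(np.std(ks, ddof=1)) / math.sqrt(n)
    within = math.sqrt(sum(f.se**2 for f in fits) / n**2)
    return PooledRate(analyte=analyte, mean_k=float(ks.mean()),
                      se=max(between, within), n_cycles=n)


def fit_series(
    series: MeasurementSeries,
    schedule: CycleSchedule,
    analytes: list[str] | None = None,
    mode: str = "per-cycle",
) -> dict[str, PooledRate]:
    """Segment, fit and pool every requested analyte in one call.

    ``mode`` is ``"per-cycle"`` (default: independent cycle fits pooled by
    mean +/- SE) or ``"joint"`` (shared slope, per-cycle intercepts).
    Analytes without enough usable data are silently omitted.
    """
    segments = segment_cycles(series, schedule)
    wanted = analytes if analytes is not None else series.analytes()
    out: dict[str, PooledRate] = {}
    for analyte in wanted:
        segs = [s for s in segments if s.analyte == analyte]
        if not segs:
            continue
        try:
            if mode == "joint":
                fit = fit_joint(segs)
                out[analyte] = PooledRate(analyte=analyte, mean_k=fit.k,
                                          se=fit.se, n_cycles=len(segs))
            else:
                fits = [fit_first_order(s) for s in segs]
                out[analyte] = pool_rates(fits)
        except InsufficientDataError:
            continue
    return out
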