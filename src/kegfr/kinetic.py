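"""Kinetic estimated GFR (KeGFR) under non-steady-state conditions.

A single serum creatinine (sCr) or plasma cystatin C (pCysC) value only
estimates GFR at steady state. Immediately after kidney transplantation
concentrations are moving, and the kinetic estimate reconciles the
absolute level with its rate of change under one-compartment mass
balance:

    KeGFR = (Bc × eGFR) / MeanBc × (1 − 24·ΔBc / (Δt · MaxΔBc/d))

where ``Bc × eGFR`` is the anchor concentration multiplied by its
steady-state eGFR (proportional to daily marker production), ``MeanBc``
is the mean of two consecutive concentrations, ``ΔBc`` their difference
(later − earlier, so a rising marker lowers the estimate), ``Δt`` the
sampling interval in hours, and ``MaxΔBc/d`` the maximal theoretical
one-day rise of the marker at zero GFR (daily production / volume of
distribution). The factor 1.44 converts concentration × mL/min to an
amount per day (1440 min/day, 1000 mL/L). Negative estimates are
clamped to zero by default, with the pre-clamp value retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

from .gfr_equations import (
    Subject,
    ckd_epi_creatinine,
    ckd_epi_cystatin,
    cockcroft_gault,
)

__all__ = [
    "BiomarkerSeries",
    "KineticConfig",
    "KineticEstimate",
    "MINUTES_PER_DAY_FACTOR",
    "daily_production",
    "max_delta_per_day",
    "kegfr_interval",
    "series_kegfr",
]

logger = logging.getLogger(__name__)

#: Converts concentration × (mL/min) to amount/day: 1440 min/day ÷ 1000 mL/L.
MINUTES_PER_DAY_FACTOR = 1.44

Marker = Literal["creatinine", "cystatin_c"]

#: Default distribution-volume coefficients (L/kg): total body water for
#: creatinine, extracellular fluid for cystatin C.
DEFAULT_VD_COEFFICIENT = {"creatinine": 0.6, "cystatin_c": 0.2}

#: Default fixed MaxΔBc/d (concentration/day): a moderately high estimate
#: of the anuric one-day rise for each marker.
DEFAULT_FIXED_MAX_DELTA = {"creatinine": 235.0, "cystatin_c": 3.0}

ProductionMethod = Literal[
    "ckd_epi_backcalc",
    "cockcroft_gault",
    "sjostrom",
    "fixed_max_delta",
    "fixed_production",
]


@dataclass(frozen=True)
class BiomarkerSeries:
    """Timed concentrations of one filtration marker for one subject.

    ``samples`` is an ordered sequence of ``(time_h, concentration)``
    pairs with strictly increasing times and positive concentrations.
    Concentration units are μmol/L for creatinine, mg/L for cystatin C.
    """

    subject_id: str
    marker: Marker
    samples: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.marker not in ("creatinine", "cystatin_c"):
            raise ValueError(f"unknown marker {self.marker!r}")
        samples = tuple((float(t), float(c)) for t, c in self.samples)
        object.__setattr__(self, "samples", samples)
        times = [t for t, _ in samples]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("sample times must be strictly increasing")
        if any(c <= 0 for _, c in samples):
            raise ValueError("all concentrations must be positive")

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.samples)

    def concentration_at(self, time_h: float) -> float:
        for t, c in self.samples:
            if math.isclose(t, time_h, abs_tol=1e-9):
                return c
        raise KeyError(f"no sample at t={time_h} h for subject {self.subject_id}")


@dataclass(frozen=True)
class KineticConfig:
    """Estimator choices for the kinetic GFR computation.

    Parameters
    ----------
    anchor_time : float
        Sample time (hours) whose concentration anchors the production
        estimate; 4 h is the first study sample for both markers.
    vd_coefficient : float, optional
        Distribution volume per kg body weight (L/kg). Defaults to
        0.6 for creatinine and 0.2 for cystatin C when left None.
    production_method : str
        How daily marker production (hence MaxΔBc/d) is estimated:
        ``ckd_epi_backcalc`` (anchor concentration × CKD-EPI eGFR × 1.44),
        ``cockcroft_gault`` (× Cockcroft-Gault clearance, creatinine only),
        ``sjostrom`` (configured constant per 1.73 m², scaled by BSA/1.73),
        ``fixed_max_delta`` (bypass production; use the configured
        concentration/day directly), or ``fixed_production`` (use the
        supplied amount/day verbatim — a testing hook for simulations
        with known truth).
    fixed_max_delta : float, optional
        Concentration/day for ``fixed_max_delta``; defaults to 235
        μmol/L/d (creatinine) or 3 mg/L/d (cystatin C) when None.
    fixed_production, sjostrom_production : float, optional
        Amount/day (absolute) and amount/day/1.73m² respectively.
    clamp_negative : bool
        Report max(estimate, 0); the raw value is always retained.
    output_indexing : {"per_1p73m2", "absolute_ml_min"}
        Absolute output multiplies by BSA/1.73 and requires height.
    """

    anchor_time: float = 4.0
    vd_coefficient: float | None = None
    production_method: ProductionMethod = "ckd_epi_backcalc"
    fixed_max_delta: float | None = None
    fixed_production: float | None = None
    sjostrom_production: float | None = None
    clamp_negative: bool = True
    output_indexing: Literal["per_1p73m2", "absolute_ml_min"] = "per_1p73m2"

    def __post_init__(self) -> None:
        if self.vd_coefficient is not None and self.vd_coefficient <= 0:
            raise ValueError("vd_coefficient must be positive")
        if self.production_method not in (
            "ckd_epi_backcalc",
            "cockcroft_gault",
            "sjostrom",
            "fixed_max_delta",
            "fixed_production",
        ):
            raise ValueError(f"unknown production method {self.production_method!r}")

    def vd_for(self, marker: Marker, weight: float) -> float:
        coeff = self.vd_coefficient
        if coeff is None:
            coeff = DEFAULT_VD_COEFFICIENT[marker]
        return coeff * weight

    def fixed_max_delta_for(self, marker: Marker) -> float:
        if self.fixed_max_delta is not None:
            return self.fixed_max_delta
        return DEFAULT_FIXED_MAX_DELTA[marker]


@dataclass(frozen=True)
class KineticEstimate:
    """One kinetic GFR value for one sampling interval, with audit terms.

    ``kegfr`` is in mL/min/1.73m² (or mL/min under absolute indexing);
    ``pre_clamp_value`` is the same quantity before the zero clamp and
    may be negative. All intermediate terms of the formula are kept.
    """

    interval: tuple[float, float]
    kegfr: float
    pre_clamp_value: float
    mean_bc: float
    delta_bc: float
    delta_t: float
    daily_production: float
    max_delta_per_day: float
    anchor_egfr: float = float("nan")

    def __post_init__(self) -> None:
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")
        if self.mean_bc <= 0:
            raise ValueError("mean_bc must be positive")

    @property
    def time(self) -> float:
        """Label of the estimate: the later timepoint of its interval."""
        return self.interval[1]


def daily_production(anchor_concentration: float, anchor_egfr: float) -> float:
    """Daily circulating marker production from the anchor sample.

    production = Bc(anchor) × eGFR(anchor) × 1.44, in μmol/d/1.73m²
    (creatinine) or mg/d/1.73m² (cystatin C); absolute when the
    clearance estimate is absolute.
    """
    if anchor_concentration <= 0:
        raise ValueError("anchor concentration must be positive")
    if anchor_egfr <= 0:
        raise ValueError("anchor eGFR must be positive")
    return anchor_concentration * anchor_egfr * MINUTES_PER_DAY_FACTOR


def max_delta_per_day(production: float, vd: float) -> float:
    """Maximal theoretical one-day marker rise at zero GFR.

    MaxΔBc/d = daily production / Vd, in concentration/day.
    """
    if production <= 0:
        raise ValueError("daily production must be positive")
    if vd <= 0:
        raise ValueError("volume of distribution must be positive")
    return production / vd


def kegfr_interval(
    b1: float,
    b2: float,
    t1: float,
    t2: float,
    anchor_product: float,
    max_delta: float,
    clamp: bool = True,
    anchor_egfr: float = float("nan"),
) -> KineticEstimate:
    """Kinetic GFR for one pair of consecutive concentrations.

    Parameters
    ----------
    b1, b2 : float
        Concentrations at the earlier (t1) and later (t2) sample.
    anchor_product : float
        Bc(anchor) × eGFR(anchor), i.e. daily production / 1.44.
    max_delta : float
        MaxΔBc/d in concentration/day.
    clamp : bool
        Clamp negative estimates to 0 (the raw value is retained).
    """
    if b1 <= 0 or b2 <= 0:
        raise ValueError("concentrations must be positive")
    if t2 <= t1:
        raise ValueError(f"times must increase, got t1={t1}, t2={t2}")
    if max_delta <= 0:
        raise ValueError("max_delta must be positive")
    if anchor_product <= 0:
        raise ValueError("anchor_product must be positive")

    mean_bc = (b1 + b2) / 2.0
    delta_bc = b2 - b1
    delta_t = t2 - t1
    bracket = 1.0 - (24.0 * delta_bc) / (delta_t * max_delta)
    raw = (anchor_product / mean_bc) * bracket
    value = max(raw, 0.0) if clamp else raw
    return KineticEstimate(
        interval=(t1, t2),
        kegfr=value,
        pre_clamp_value=raw,
        mean_bc=mean_bc,
        delta_bc=delta_bc,
        delta_t=delta_t,
        daily_production=anchor_product * MINUTES_PER_DAY_FACTOR,
        max_delta_per_day=max_delta,
        anchor_egfr=anchor_egfr,
    )


def _anchor_steady_state(series: BiomarkerSeries, subject: Subject, anchor_conc: float):
    if series.marker == "creatinine":
        return ckd_epi_creatinine(anchor_conc, subject).value
    return ckd_epi_cystatin(anchor_conc, subject).value


def series_kegfr(
    series: BiomarkerSeries,
    subject: Subject,
    config: KineticConfig | None = None,
) -> list[KineticEstimate]:
    """Kinetic GFR estimates for every consecutive sample pair.

    Daily production is estimated once per series from the anchor sample
    (per ``config.production_method``) and shared by all intervals; each
    estimate is labelled by the later timepoint of its pair.
    """
    if config is None:
        config = KineticConfig()
    if len(series.samples) < 2:
        raise ValueError("at least two samples are required")

    needs_anchor = config.production_method in (
        "ckd_epi_backcalc",
        "cockcroft_gault",
        "fixed_max_delta",
    )
    anchor_conc = anchor_egfr = None
    if needs_anchor:
        try:
            anchor_conc = series.concentration_at(config.anchor_time)
        except KeyError as exc:
            raise ValueError(
                f"anchor sample at t={config.anchor_time} h required for "
                f"production method {config.production_method!r}"
            ) from exc

    method = config.production_method
    if method == "ckd_epi_backcalc":
        anchor_egfr = _anchor_steady_state(series, subject, anchor_conc)
        production = daily_production(anchor_conc, anchor_egfr)
        anchor_product = anchor_conc * anchor_egfr
        vd = config.vd_for(series.marker, subject.require_weight())
        max_delta = max_delta_per_day(production, vd)
    elif method == "cockcroft_gault":
        if series.marker != "creatinine":
            raise ValueError("Cockcroft-Gault production applies to creatinine only")
        anchor_egfr = cockcroft_gault(anchor_conc, subject).value
        production = daily_production(anchor_conc, anchor_egfr)
        anchor_product = anchor_conc * anchor_egfr
        vd = config.vd_for(series.marker, subject.require_weight())
        max_delta = max_delta_per_day(production, vd)
    elif method == "sjostrom":
        if config.sjostrom_production is None:
            raise ValueError(
                "production method 'sjostrom' requires sjostrom_production "
                "(amount/day/1.73m²) to be configured"
            )
        production = config.sjostrom_production * subject.bsa() / 1.73
        anchor_product = production / MINUTES_PER_DAY_FACTOR
        anchor_egfr = float("nan")
        vd = config.vd_for(series.marker, subject.require_weight())
        max_delta = max_delta_per_day(production, vd)
    elif method == "fixed_max_delta":
        anchor_egfr = _anchor_steady_state(series, subject, anchor_conc)
        anchor_product = anchor_conc * anchor_egfr
        max_delta = config.fixed_max_delta_for(series.marker)
    else:  # fixed_production
        if config.fixed_production is None:
            raise ValueError(
                "production method 'fixed_production' requires fixed_production"
            )
        production = config.fixed_production
        anchor_product = production / MINUTES_PER_DAY_FACTOR
        anchor_egfr = float("nan")
        vd = config.vd_for(series.marker, subject.require_weight())
        max_delta = max_delta_per_day(production, vd)

    scale = 1.0
    if config.output_indexing == "absolute_ml_min":
        scale = subject.bsa() / 1.73

    estimates = []
    for (t1, c1), (t2, c2) in zip(series.samples, series.samples[1:]):
        est = kegfr_interval(
            c1,
            c2,
            t1,
            t2,
            anchor_product=anchor_product,
            max_delta=max_delta,
            clamp=config.clamp_negative,
            anchor_egfr=anchor_egfr,
        )
        if scale != 1.0:
            est = replace(
                est,
                kegfr=est.kegfr * scale,
                pre_clamp_value=est.pre_clamp_value * scale,
            )
        if est.pre_clamp_value < 0:
            logger.info(
                "subject %s %s: negative kinetic GFR %.2f at %g h clamped to %g",
                series.subject_id,
                series.marker,
                est.pre_clamp_value,
                t2,
                est.kegfr,
            )
        estimates.append(est)
    return estimates
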