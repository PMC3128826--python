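"""Closed-form one-compartment PK relations on canonical units.

The body is treated as a single well-mixed volume with first-order
elimination (rate constant ``k_e``, 1/h).  Repeated bolus dosing at interval
τ accumulates to a steady state characterised by the accumulation ratio
AR = 1/(1 − e^(−k_e·τ)); oral doses are treated as boluses scaled by the
bioavailability F, which is adequate when absorption is much faster than
elimination (k_a ≳ 5·k_e).  Drugs that are genuinely two-compartmental can
be handled by substituting the terminal rate constant β for k_e and the
central volume V_c for V_d (:func:`two_compartment_alias`).

Two deliberate conventions, matching clinical usage:

* the average steady-state concentration uses clearance
  (Css,avg = F·Dose/(Cl·τ)), while the peak and trough use V_d and k_e —
  the tabulated Cl and k_e·V_d come from independent literature pools and
  are not reconciled internally;
* time to steady state is the 5-half-lives rule on the tabulated t_half.

No rounding happens here; practical rounding lives in :mod:`opioidpk.design`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import NotApplicableError, ValidationError
from .params import OpioidPKParams, Patient, TherapeuticWindow, total_clearance, total_volume

__all__ = [
    "DoseEvent",
    "Regimen",
    "SteadyStateSummary",
    "target_css",
    "dose_rate",
    "tau_max",
    "accumulation_ratio",
    "steady_state_summary",
    "conc_at_time",
    "loading_dose",
    "infusion_rate",
    "oral_bolus_approx_ok",
    "two_compartment_alias",
    "simulate_interval",
]

#: k_a/k_e ratio above which oral absorption is treated as instantaneous.
ORAL_BOLUS_KA_KE_RATIO = 5.0

_BOLUS_ROUTES = ("iv_bolus", "oral")


@dataclass(frozen=True)
class DoseEvent:
    """A single administered dose: mass (μg), bioavailability, and route."""

    dose: float
    f: float
    route: str = "iv_bolus"

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise ValidationError(f"dose must be positive, got {self.dose}")
        if not (0 < self.f <= 1):
            raise ValidationError(f"bioavailability must be in (0, 1], got {self.f}")
        if self.route not in (*_BOLUS_ROUTES, "infusion"):
            raise ValidationError(f"unknown route {self.route!r}")

    @classmethod
    def from_params(cls, dose: float, route: str, p: OpioidPKParams) -> "DoseEvent":
        return cls(dose=dose, f=p.bioavailability(route), route=route)


@dataclass(frozen=True)
class Regimen:
    """A repeating dosing schedule: route, dose (μg) and interval τ (h), or
    an infusion rate k0 (μg/h) for route 'infusion'."""

    route: str
    dose: float | None = None
    tau: float | None = None
    k0: float | None = None

    def __post_init__(self) -> None:
        if self.route == "infusion":
            if self.k0 is None or not self.k0 > 0:
                raise ValidationError("infusion regimen requires k0 > 0")
        else:
            if self.route not in _BOLUS_ROUTES:
                raise ValidationError(f"unknown route {self.route!r}")
            if self.dose is None or not self.dose > 0:
                raise ValidationError("bolus regimen requires dose > 0")
            if self.tau is None or not self.tau > 0:
                raise ValidationError("bolus regimen requires tau > 0")


@dataclass(frozen=True)
class SteadyStateSummary:
    """Steady-state profile of a repeated bolus regimen (all μg/L, h)."""

    css_avg: float
    cmax_ss: float
    cmin_ss: float
    ar: float
    t_ss: float
    warnings: tuple[str, ...] = ()


def target_css(window: TherapeuticWindow) -> float:
    """Target average steady-state concentration for a therapeutic window.

    Because a first-order drug declines exponentially, the time-average of a
    decline from c_max to c_min is the logarithmic mean
    (c_max − c_min)/ln(c_max/c_min), slightly below the arithmetic mean
    (33.7 μg/L for the morphine 10–80 μg/L window, not 45).
    """
    return (window.c_max - window.c_min) / math.log(window.c_max / window.c_min)


def dose_rate(css_target: float, cl_total: float, f: float) -> float:
    """Dosing rate Dose/τ (μg/h) sustaining ``css_target``: Css·Cl/F."""
    if css_target < 0:
        raise ValidationError("target concentration cannot be negative")
    if not cl_total > 0:
        raise ValidationError("clearance must be positive")
    if not (0 < f <= 1):
        raise ValidationError(f"bioavailability must be in (0, 1], got {f}")
    return css_target * cl_total / f


def tau_max(c_max: float, c_min: float, k_e: float) -> float:
    """Longest dosing interval keeping the decline inside (c_min, c_max):
    ln(c_max/c_min)/k_e."""
    if not (c_max > c_min > 0):
        raise ValidationError(f"need c_max > c_min > 0, got ({c_max}, {c_min})")
    if not k_e > 0:
        raise ValidationError("k_e must be positive")
    return math.log(c_max / c_min) / k_e


def accumulation_ratio(k_e: float, tau: float) -> float:
    """Steady-state accumulation ratio AR = 1/(1 − e^(−k_e·τ)) (≥ 1)."""
    if not k_e > 0 or not tau > 0:
        raise ValidationError("k_e and tau must be positive")
    return 1.0 / (-math.expm1(-k_e * tau))


def conc_at_time(c_start: float, k_e: float, t: float) -> float:
    """First-order decline from ``c_start`` after ``t`` hours."""
    if t < 0:
        raise ValidationError("time cannot be negative")
    if c_start < 0 or not k_e > 0:
        raise ValidationError("need c_start >= 0 and k_e > 0")
    return c_start * math.exp(-k_e * t)


def loading_dose(c_target: float, c_p: float, v_d_total: float, f: float) -> float:
    """Loading dose (μg) raising the level from ``c_p`` to ``c_target``:
    (C_target − C_p)·V_d/F."""
    if c_p < 0 or c_target < c_p:
        raise ValidationError(f"need c_target >= c_p >= 0, got ({c_target}, {c_p})")
    if not v_d_total > 0:
        raise ValidationError("distribution volume must be positive")
    if not (0 < f <= 1):
        raise ValidationError(f"bioavailability must be in (0, 1], got {f}")
    return (c_target - c_p) * v_d_total / f


def infusion_rate(c_target: float, cl_total: float) -> float:
    """Constant-infusion rate k0 (μg/h) holding ``c_target``: C_target·Cl."""
    if c_target < 0:
        raise ValidationError("target concentration cannot be negative")
    if not cl_total > 0:
        raise ValidationError("clearance must be positive")
    return c_target * cl_total


def oral_bolus_approx_ok(p: OpioidPKParams) -> tuple[bool, float]:
    """Whether absorption may be treated as instantaneous, plus k_a/k_e.

    True when k_a is at least 5 times k_e (absorption essentially complete
    within a small fraction of the elimination phase).
    """
    if p.k_a is None:
        raise NotApplicableError(f"{p.label}: no absorption rate constant on record")
    ratio = p.k_a / p.k_e
    return ratio >= ORAL_BOLUS_KA_KE_RATIO, ratio


def steady_state_summary(
    event: DoseEvent,
    tau: float,
    p: OpioidPKParams,
    patient: Patient,
) -> SteadyStateSummary:
    """Steady-state peak/trough/average for a repeated bolus regimen.

    Cmax,ss = (F·Dose/V_d)·AR, Cmin,ss = Cmax,ss·e^(−k_e·τ),
    Css,avg = F·Dose/(Cl·τ), T_ss = 5·t_half.
    """
    if event.route == "infusion":
        raise ValidationError(
            "steady_state_summary applies to bolus-type regimens; "
            "use infusion_rate/design_infusion for constant infusions"
        )
    if not tau > 0:
        raise ValidationError("tau must be positive")

    warnings: list[str] = []
    if event.route == "oral":
        try:
            ok, ratio = oral_bolus_approx_ok(p)
            if not ok:
                warnings.append(
                    f"oral-absorption-not-instantaneous: k_a/k_e = {ratio:.2f} < "
                    f"{ORAL_BOLUS_KA_KE_RATIO:g}; bolus approximation may overstate peaks"
                )
        except NotApplicableError:
            warnings.append("oral-absorption-rate-unknown: bolus approximation unchecked")

    v_d = total_volume(p, patient)
    cl = total_clearance(p, patient)
    ar = accumulation_ratio(p.k_e, tau)
    cmax = (event.f * event.dose / v_d) * ar
    cmin = cmax * math.exp(-p.k_e * tau)
    css = event.f * event.dose / (cl * tau)
    return SteadyStateSummary(
        css_avg=css,
        cmax_ss=cmax,
        cmin_ss=cmin,
        ar=ar,
        t_ss=5.0 * p.t_half,
        warnings=tuple(warnings),
    )


def two_compartment_alias(
    beta: float,
    v_c_per_kg: float,
    base: OpioidPKParams | None = None,
    name: str = "two-compartment alias",
) -> OpioidPKParams:
    """Parameter view for a two-compartment drug usable by every operation here.

    Substitutes the terminal (β) rate constant for k_e and the central
    compartment volume V_c for V_d; with ``base`` given, other fields
    (bioavailability, k_a, window) are inherited.
    """
    if not beta > 0 or not v_c_per_kg > 0:
        raise ValidationError("beta and v_c_per_kg must be positive")
    t_half = math.log(2.0) / beta
    if base is not None:
        return replace(
            base, k_e=beta, v_d_per_kg=v_c_per_kg, t_half=t_half,
            phase_label=base.phase_label,
        )
    return OpioidPKParams(
        name=name,
        t_half=t_half,
        k_e=beta,
        v_d_per_kg=v_c_per_kg,
        cl_per_kg=beta * v_c_per_kg,
        f_by_route={"iv": 1.0},
    )


def simulate_interval(
    p: OpioidPKParams,
    patient: Patient,
    event: DoseEvent,
    tau: float,
    dt: float = 0.25,
) -> pd.DataFrame:
    """Concentration-time series over one steady-state dosing interval.

    Samples Cmax,ss·e^(−k_e·t) on the grid t = 0, dt, …, τ; the first row is
    the peak and the last row the trough.  Columns: ``time_h``,
    ``concentration_ug_per_l``.
    """
    if not dt > 0:
        raise ValidationError("dt must be positive")
    summary = steady_state_summary(event, tau, p, patient)
    n = int(round(tau / dt))
    t = np.linspace(0.0, n * dt, n + 1)
    t = t[t <= tau + 1e-12]
    conc = summary.cmax_ss * np.exp(-p.k_e * t)
    return pd.DataFrame({"time_h": t, "concentration_ug_per_l": conc})
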