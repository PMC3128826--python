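"""Evaluation of existing regimens and forensic dose back-calculation.

Assessment places a prescribed bolus regimen's predicted steady state
against the therapeutic window and quantifies how much of each dosing
interval is spent below the analgesic threshold.  Back-calculation inverts
the average-steady-state relation Css = F·Dose/(Cl·τ) to recover the
administered dose consistent with a measured level — useful when a
postmortem or monitored concentration must be reconciled with a dosing
history.  The measured level is treated as the steady-state average and
postmortem redistribution is assumed absent, so the result is an
approximation and is labelled as such in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import ValidationError
from .params import OpioidPKParams, Patient, TherapeuticWindow, total_clearance
from .pk_core import DoseEvent, Regimen, SteadyStateSummary, steady_state_summary

__all__ = [
    "RegimenAssessment",
    "assess_regimen",
    "conc_after_dose",
    "back_calculate_dose",
    "css_from_total_daily_dose",
    "round_to_sig_figs",
]


@dataclass(frozen=True)
class RegimenAssessment:
    """Verdict on an existing regimen against a therapeutic window.

    ``time_below_threshold`` is hours per dosing interval spent under the
    analgesic threshold; the verdict classifies the average steady-state
    level against the closed window interval, with ``mixed`` reserved for
    regimens whose average is inside the window but whose fluctuation
    breaches both bounds.
    """

    summary: SteadyStateSummary
    threshold: float
    time_below_threshold: float
    fraction_of_interval_below: float
    verdict: str
    t_ss: float


def _verdict(summary: SteadyStateSummary, window: TherapeuticWindow) -> str:
    if summary.css_avg < window.c_min:
        return "subtherapeutic"
    if summary.css_avg > window.c_max:
        return "supratherapeutic"
    if summary.cmax_ss > window.c_max and summary.cmin_ss < window.c_min:
        return "mixed"
    return "within_window"


def assess_regimen(
    p: OpioidPKParams,
    patient: Patient,
    regimen: Regimen,
    window: TherapeuticWindow,
    threshold: float | None = None,
) -> RegimenAssessment:
    """Assess a bolus-type regimen against a therapeutic window.

    The sub-threshold time solves Cmax,ss·e^(−k_e·t) = threshold for t and
    clamps it to [0, τ]; a threshold above the peak means the whole interval
    is below.  The default threshold is the window's analgesic floor if
    present, else its lower bound.
    """
    if regimen.route == "infusion":
        raise ValidationError("assessment applies to bolus-type regimens")
    event = DoseEvent.from_params(regimen.dose, regimen.route, p)
    summary = steady_state_summary(event, regimen.tau, p, patient)

    thr = threshold
    if thr is None:
        thr = (
            window.analgesic_threshold
            if window.analgesic_threshold is not None
            else window.c_min
        )
    if thr <= 0:
        time_below = 0.0
    elif thr >= summary.cmax_ss:
        time_below = regimen.tau
    else:
        t_cross = math.log(summary.cmax_ss / thr) / p.k_e
        time_below = max(0.0, regimen.tau - min(t_cross, regimen.tau))
    return RegimenAssessment(
        summary=summary,
        threshold=thr,
        time_below_threshold=time_below,
        fraction_of_interval_below=time_below / regimen.tau,
        verdict=_verdict(summary, window),
        t_ss=summary.t_ss,
    )


def conc_after_dose(
    p: OpioidPKParams, patient: Patient, regimen: Regimen, t: float
) -> float:
    """Steady-state concentration ``t`` hours after a dose (0 ≤ t ≤ τ).

    At t = 0 this is Cmax,ss; at t = τ it is Cmin,ss (oral doses treated as
    boluses scaled by F).
    """
    if regimen.route == "infusion":
        raise ValidationError("conc_after_dose applies to bolus-type regimens")
    if not (0 <= t <= regimen.tau):
        raise ValidationError(f"t must lie in [0, tau={regimen.tau}], got {t}")
    event = DoseEvent.from_params(regimen.dose, regimen.route, p)
    summary = steady_state_summary(event, regimen.tau, p, patient)
    return summary.cmax_ss * math.exp(-p.k_e * t)


def back_calculate_dose(
    c_observed: float,
    p: OpioidPKParams,
    patient: Patient,
    tau: float,
    route: str,
) -> float:
    """Administered dose (μg) consistent with a measured steady-state level.

    Inverts Css,avg = F·Dose/(Cl·τ): Dose = C·Cl·τ/F.  The observed
    concentration is interpreted as the steady-state average, assuming no
    significant postmortem redistribution; the result is an approximation.
    """
    if c_observed < 0:
        raise ValidationError("observed concentration cannot be negative")
    if not tau > 0:
        raise ValidationError("tau must be positive")
    f = p.bioavailability(route)
    return c_observed * total_clearance(p, patient) * tau / f


def css_from_total_daily_dose(
    daily_dose: float, p: OpioidPKParams, patient: Patient, route: str = "oral"
) -> float:
    """Average steady-state concentration implied by a total daily dose:
    F·(daily_dose/24)/Cl."""
    if daily_dose < 0:
        raise ValidationError("daily dose cannot be negative")
    f = p.bioavailability(route)
    return f * (daily_dose / 24.0) / total_clearance(p, patient)


def round_to_sig_figs(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (used for forensic reporting,
    where doses are quoted at 2 s.f. in the ×0.001 scaled convention)."""
    if x == 0:
        return 0.0
    if sig < 1:
        raise ValidationError("need at least one significant figure")
    exponent = math.floor(math.log10(abs(x)))
    factor = 10.0 ** (exponent - sig + 1)
    return math.floor(abs(x) / factor + 0.5) * factor * (1 if x > 0 else -1)
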