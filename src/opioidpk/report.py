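"""Human-readable text rendering of plans, assessments and estimates.

Text reports use bedside units (doses in mg, concentrations in μg/L,
estimates as mean ± SD with the confidence interval in parentheses); the
JSON artifacts keep full precision in canonical units.
"""

from __future__ import annotations

from .design import RegimenPlan
from .evaluate import RegimenAssessment
from .params import ug_to_mg
from .popboot import BootstrapEstimate


def render_plan(plan: RegimenPlan) -> str:
    lines = [
        f"Regimen plan — {plan.opioid} [{plan.method}, route {plan.route}]",
        f"  patient: {plan.weight_kg:g} kg ({plan.sex})",
    ]
    if plan.c_target is not None:
        lines.append(f"  target Css,avg: {plan.c_target:.1f} ug/L")
    if plan.tau_max is not None:
        lines.append(f"  tau_max: {plan.tau_max:.1f} h")
    if plan.tau is not None:
        lines.append(f"  dosing interval: {plan.tau:g} h")
    if plan.loading_dose_rounded is not None:
        lines.append(
            f"  loading/starting dose: {ug_to_mg(plan.loading_dose_rounded):g} mg"
            f" (exact {ug_to_mg(plan.loading_dose_exact):.2f} mg)"
        )
    if plan.dose_rounded is not None:
        lines.append(
            f"  maintenance dose: {ug_to_mg(plan.dose_rounded):g} mg"
            f" (exact {ug_to_mg(plan.dose_exact):.2f} mg)"
        )
    if plan.infusion_rate_ug_per_h is not None:
        lines.append(
            f"  infusion rate: {plan.infusion_rate_ug_per_h / 1000.0:.1f} mg/h"
            f" ({plan.infusion_rate_ug_per_h:.1f} ug/h)"
        )
    if plan.post_bolus_conc is not None:
        lines.append(f"  post-bolus concentration: {plan.post_bolus_conc:.1f} ug/L")
    if plan.predicted is not None:
        s = plan.predicted
        lines.append(
            f"  predicted steady state: Cmax {s.cmax_ss:.1f} / Cavg {s.css_avg:.1f}"
            f" / Cmin {s.cmin_ss:.1f} ug/L (AR {s.ar:.2f})"
        )
        lines.append(f"  time to steady state: {s.t_ss:.1f} h")
    for w in plan.warnings:
        lines.append(f"  warning: {w}")
    return "\n".join(lines)


def render_assessment(a: RegimenAssessment, opioid: str) -> str:
    s = a.summary
    lines = [
        f"Regimen assessment — {opioid}",
        f"  predicted steady state: Cmax {s.cmax_ss:.1f} / Cavg {s.css_avg:.1f}"
        f" / Cmin {s.cmin_ss:.1f} ug/L (AR {s.ar:.2f})",
        f"  time to steady state: {a.t_ss:.1f} h",
        f"  verdict: {a.verdict}",
        f"  time below {a.threshold:g} ug/L: {a.time_below_threshold:.1f} h per "
        f"interval ({a.fraction_of_interval_below:.0%})",
    ]
    for w in s.warnings:
        lines.append(f"  warning: {w}")
    return "\n".join(lines)


def render_estimate(e: BootstrapEstimate, parameter: str, units: str = "") -> str:
    u = f" {units}" if units else ""
    return (
        f"{parameter}: {e.point:.4g} ± {e.sd:.3g}{u} "
        f"({e.ci_low:.4g}, {e.ci_high:.4g}) "
        f"[bootstrap N = {e.n_boot}, seed = {e.seed}]"
    )


def render_back_calculation(
    dose_ug: float, dose_scaled_2sf: float, tau: float, opioid: str
) -> str:
    """Forensic back-calculation line; the scaled figure applies the ×0.001
    convention with 2-significant-figure rounding used in bedside reports."""
    return (
        f"{opioid}: observed level is consistent with {dose_ug / 1000.0:.2f} mg "
        f"every {tau:g} h (scaled convention: {dose_scaled_2sf:g}); "
        "steady-state average assumed, no postmortem redistribution"
    )
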