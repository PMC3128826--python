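"""Dosing-regimen design: limited-fluctuation, target-concentration, infusion.

Three design strategies:

* **limited fluctuation** — pick the target average concentration from the
  therapeutic window (logarithmic mean), the longest practical interval not
  exceeding τ_max, and the maintenance dose sustaining the target;
* **target concentration** — given an explicit C_target and interval, the
  starting dose fills the distribution volume (D_S = C_target·V_d/F) and
  the maintenance dose replaces what clearance removes per interval
  (D_M = C_target·Cl·τ/F);
* **constant infusion** — k0 = C_target·Cl with an optional loading bolus
  D_L = C_target·V_d.

Exact values are kept at full precision; practical rounding (half-up to the
available strength granularity) is applied here and the predicted steady
state is recomputed from the *rounded* dose, so the plan reflects what would
actually be administered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import DesignInfeasibleError, ValidationError
from .params import (
    OpioidPKParams,
    Patient,
    TherapeuticWindow,
    total_clearance,
    total_volume,
    ug_to_mg,
)
from .pk_core import (
    DoseEvent,
    SteadyStateSummary,
    dose_rate,
    infusion_rate,
    loading_dose,
    steady_state_summary,
    target_css,
    tau_max,
)

__all__ = [
    "RegimenPlan",
    "PRACTICAL_TAU_GRID",
    "practical_tau",
    "round_dose",
    "default_granularity",
    "design_limited_fluctuation",
    "design_target_concentration",
    "design_infusion",
]

#: Practical dosing intervals (hours) a prescription can realistically use.
PRACTICAL_TAU_GRID = (2.0, 4.0, 6.0, 8.0, 12.0, 24.0)

#: Loading/starting doses are reported at 1 mg precision.
LOADING_DOSE_GRANULARITY_UG = 1_000.0

_ROUNDING_DRIFT_WARN = 0.05


def practical_tau(tau_maximum: float, grid: tuple[float, ...] = PRACTICAL_TAU_GRID) -> float:
    """Largest practical interval not exceeding τ_max.

    A practical τ above τ_max would let troughs fall through the window
    floor, so the grid is truncated at τ_max; if even the smallest grid
    interval is too long the bolus design is infeasible and a constant
    infusion (or a controlled-release formulation) is indicated.
    """
    if not grid:
        raise ValidationError("practical interval grid is empty")
    grid = tuple(sorted(grid))
    feasible = [g for g in grid if g <= tau_maximum + 1e-12]
    if not feasible:
        raise DesignInfeasibleError(
            f"tau_max {tau_maximum:.2f} h is shorter than the smallest practical "
            f"interval ({grid[0]:g} h); consider a constant infusion or a "
            "controlled-release formulation"
        )
    return feasible[-1]


def round_dose(dose_exact: float, strength_granularity: float) -> float:
    """Half-up rounding of a dose (μg) to the nearest multiple of the
    available strength granularity (μg)."""
    if not strength_granularity > 0:
        raise ValidationError("strength granularity must be positive")
    if dose_exact < 0:
        raise ValidationError("dose cannot be negative")
    return math.floor(dose_exact / strength_granularity + 0.5) * strength_granularity


def default_granularity(dose_exact: float) -> float:
    """Default strength granularity: 5 mg for doses of 10 mg and above,
    1 mg below."""
    return 5_000.0 if dose_exact >= 10_000.0 else 1_000.0


@dataclass(frozen=True)
class RegimenPlan:
    """A designed regimen with exact and practically rounded quantities.

    Doses in μg, intervals in hours, rates in μg/h, concentrations in μg/L.
    ``predicted`` is recomputed from ``dose_rounded`` (not ``dose_exact``)
    for bolus-type plans; infusion plans carry ``infusion_rate_ug_per_h``
    and the steady state it implies.
    """

    opioid: str
    method: str
    route: str
    weight_kg: float
    sex: str
    tau: float | None = None
    tau_max: float | None = None
    dose_exact: float | None = None
    dose_rounded: float | None = None
    granularity: float | None = None
    loading_dose_exact: float | None = None
    loading_dose_rounded: float | None = None
    infusion_rate_ug_per_h: float | None = None
    post_bolus_conc: float | None = None
    c_target: float | None = None
    window: TherapeuticWindow | None = None
    predicted: SteadyStateSummary | None = None
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        """JSON-ready representation (canonical units plus mg conveniences)."""
        d: dict = {
            "opioid": self.opioid,
            "method": self.method,
            "route": self.route,
            "patient": {"weight_kg": self.weight_kg, "sex": self.sex},
            "tau_h": self.tau,
            "tau_max_h": self.tau_max,
            "dose_exact_ug": self.dose_exact,
            "dose_rounded_ug": self.dose_rounded,
            "dose_rounded_mg": ug_to_mg(self.dose_rounded) if self.dose_rounded else None,
            "granularity_ug": self.granularity,
            "loading_dose_exact_ug": self.loading_dose_exact,
            "loading_dose_rounded_ug": self.loading_dose_rounded,
            "loading_dose_rounded_mg": (
                ug_to_mg(self.loading_dose_rounded)
                if self.loading_dose_rounded is not None
                else None
            ),
            "infusion_rate_ug_per_h": self.infusion_rate_ug_per_h,
            "infusion_rate_mg_per_h": (
                round(self.infusion_rate_ug_per_h / 1000.0, 1)
                if self.infusion_rate_ug_per_h is not None
                else None
            ),
            "post_bolus_conc_ug_per_l": self.post_bolus_conc,
            "c_target_ug_per_l": self.c_target,
            "warnings": list(self.warnings),
        }
        if self.window is not None:
            d["window"] = {
                "c_min": self.window.c_min,
                "c_max": self.window.c_max,
                "analgesic_threshold": self.window.analgesic_threshold,
            }
        if self.predicted is not None:
            d["predicted"] = {
                "css_avg_ug_per_l": self.predicted.css_avg,
                "cmax_ss_ug_per_l": self.predicted.cmax_ss,
                "cmin_ss_ug_per_l": self.predicted.cmin_ss,
                "accumulation_ratio": self.predicted.ar,
                "t_ss_h": self.predicted.t_ss,
            }
        return d


def _fluctuation_warnings(
    summary: SteadyStateSummary,
    window: TherapeuticWindow | None,
    k_e: float,
    tau: float,
) -> list[str]:
    """Window/threshold breach warnings for a predicted steady state."""
    notes: list[str] = list(summary.warnings)
    if window is None:
        return notes
    if summary.cmax_ss > window.c_max:
        notes.append(
            f"predicted-peak-above-window: Cmax,ss {summary.cmax_ss:.1f} > "
            f"{window.c_max:g} μg/L"
        )
    if summary.cmin_ss < window.c_min:
        notes.append(
            f"predicted-trough-below-window: Cmin,ss {summary.cmin_ss:.1f} < "
            f"{window.c_min:g} μg/L"
        )
    thr = window.analgesic_threshold
    if thr is not None and summary.cmin_ss < thr < summary.cmax_ss:
        t_cross = math.log(summary.cmax_ss / thr) / k_e
        notes.append(
            f"trough-below-analgesic-threshold: level falls below {thr:g} μg/L "
            f"about {t_cross:.1f} h into each {tau:g}-h interval; watch for "
            "breakthrough pain towards the end of the interval"
        )
    return notes


def design_limited_fluctuation(
    p: OpioidPKParams,
    patient: Patient,
    window: TherapeuticWindow,
    route: str = "iv_bolus",
    grid: tuple[float, ...] = PRACTICAL_TAU_GRID,
    granularity: float | None = None,
) -> RegimenPlan:
    """Design a bolus regimen keeping steady-state levels inside the window.

    The target average is the logarithmic mean of the window, the interval
    is the longest practical τ ≤ τ_max = ln(c_max/c_min)/k_e, and the
    maintenance dose is the dosing rate times τ, rounded to the strength
    granularity.  The predicted steady state is recomputed from the rounded
    dose and window breaches are attached as warnings.
    """
    f = p.bioavailability(route)
    cl = total_clearance(p, patient)
    css_t = target_css(window)
    rate = dose_rate(css_t, cl, f)
    t_max = tau_max(window.c_max, window.c_min, p.k_e)
    tau = practical_tau(t_max, grid)
    dose_exact = rate * tau
    gran = granularity if granularity is not None else default_granularity(dose_exact)
    dose_rounded = round_dose(dose_exact, gran)
    extra: list[str] = []
    if dose_rounded == 0.0:  # dose smaller than half the finest strength
        dose_rounded = dose_exact
        extra.append(
            f"dose-below-strength-granularity: exact dose {dose_exact:.1f} ug kept "
            "unrounded; no practical strength this small"
        )

    event = DoseEvent(dose=dose_rounded, f=f, route="oral" if route == "oral" else "iv_bolus")
    predicted = steady_state_summary(event, tau, p, patient)
    warnings = _fluctuation_warnings(predicted, window, p.k_e, tau) + extra
    if dose_exact > 0 and abs(dose_rounded - dose_exact) / dose_exact > _ROUNDING_DRIFT_WARN:
        warnings.append(
            f"rounding-drift: rounded dose differs from exact by "
            f"{abs(dose_rounded - dose_exact) / dose_exact:.0%}"
        )
    return RegimenPlan(
        opioid=p.label,
        method="limited_fluctuation",
        route=route,
        weight_kg=patient.weight,
        sex=patient.sex,
        tau=tau,
        tau_max=t_max,
        dose_exact=dose_exact,
        dose_rounded=dose_rounded,
        granularity=gran,
        c_target=css_t,
        window=window,
        predicted=predicted,
        warnings=tuple(warnings),
    )


def design_target_concentration(
    p: OpioidPKParams,
    patient: Patient,
    c_target: float,
    route: str,
    tau: float,
    granularity: float | None = None,
    window: TherapeuticWindow | None = None,
) -> RegimenPlan:
    """Design a regimen around an explicit target average concentration.

    Starting dose D_S = (C_target − C_p)·V_d/F (C_p from the patient's
    measured level, if any); maintenance dose D_M = C_target·Cl·τ/F.  The
    starting dose is reported at 1 mg precision, the maintenance dose at the
    strength granularity.
    """
    if not c_target > 0:
        raise ValidationError("c_target must be positive")
    if not tau > 0:
        raise ValidationError("tau must be positive")
    f = p.bioavailability(route)
    v_d = total_volume(p, patient)
    cl = total_clearance(p, patient)
    c_p = patient.measured_cp or 0.0
    d_start = loading_dose(c_target, c_p, v_d, f)
    d_maint = dose_rate(c_target, cl, f) * tau
    gran = granularity if granularity is not None else default_granularity(d_maint)
    d_maint_rounded = round_dose(d_maint, gran)
    d_start_rounded = round_dose(d_start, LOADING_DOSE_GRANULARITY_UG)

    event = DoseEvent(
        dose=d_maint_rounded, f=f, route="oral" if route == "oral" else "iv_bolus"
    )
    predicted = steady_state_summary(event, tau, p, patient)
    warnings = _fluctuation_warnings(predicted, window, p.k_e, tau)
    return RegimenPlan(
        opioid=p.label,
        method="target_concentration",
        route=route,
        weight_kg=patient.weight,
        sex=patient.sex,
        tau=tau,
        dose_exact=d_maint,
        dose_rounded=d_maint_rounded,
        granularity=gran,
        loading_dose_exact=d_start,
        loading_dose_rounded=d_start_rounded,
        c_target=c_target,
        window=window,
        predicted=predicted,
        warnings=tuple(warnings),
    )


def design_infusion(
    p: OpioidPKParams,
    patient: Patient,
    c_target: float,
    with_loading: bool = True,
) -> RegimenPlan:
    """Design a constant IV infusion holding ``c_target``.

    k0 = C_target·Cl; the optional loading bolus D_L = C_target·V_d brings
    the level near target immediately (``post_bolus_conc`` is computed from
    the *rounded* bolus, hence slightly off target).  The implied steady
    state k0/Cl equals C_target exactly.
    """
    if c_target < 0:
        raise ValidationError("c_target cannot be negative")
    cl = total_clearance(p, patient)
    v_d = total_volume(p, patient)
    k0 = infusion_rate(c_target, cl)
    d_l_exact = d_l_rounded = post_bolus = None
    if with_loading:
        d_l_exact = c_target * v_d
        d_l_rounded = round_dose(d_l_exact, LOADING_DOSE_GRANULARITY_UG)
        post_bolus = d_l_rounded / v_d
    return RegimenPlan(
        opioid=p.label,
        method="infusion",
        route="infusion",
        weight_kg=patient.weight,
        sex=patient.sex,
        loading_dose_exact=d_l_exact,
        loading_dose_rounded=d_l_rounded,
        infusion_rate_ug_per_h=k0,
        post_bolus_conc=post_bolus,
        c_target=c_target,
    )
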