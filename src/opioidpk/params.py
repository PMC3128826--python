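"""Opioid population PK parameter reference data, units, and patient scaling.

The bundled table carries, for 12 commonly prescribed opioids, the four
one-compartment disposition parameters pooled from the literature by
bootstrap resampling (elimination half-life ``t_half``, first-order
elimination rate constant ``k_e``, apparent volume of distribution per kg
``v_d_per_kg``, and systemic clearance per kg ``cl_per_kg``), together with
route-specific bioavailability fractions ``F`` and first-order absorption
rate constants ``k_a``.  Controlled-release oxycodone is represented as two
phase entries whose source values are reported per minute; the loader
canonicalizes every rate constant to 1/hour and every half-life to hours.

Canonical units throughout the package: mass in μg, volume in L, time in
hours, concentration in μg/L.  Milligrams appear only at I/O boundaries.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Sequence

from .exceptions import OpioidNotFoundError, ValidationError

__all__ = [
    "TherapeuticWindow",
    "Patient",
    "OpioidPKParams",
    "OpioidTable",
    "ConsistencyReport",
    "load_opioid_table",
    "total_clearance",
    "total_volume",
    "consistency_check",
    "DEFAULT_WEIGHT_KG",
    "MORPHINE_LITERATURE_WINDOW",
]

#: Average adult body weight by sex (kg), used when a patient weight is not given.
DEFAULT_WEIGHT_KG = {"male": 86.6, "female": 74.4}

#: Routes recognised in bioavailability maps.
ROUTES = ("iv", "oral", "buccal", "patch")

_MG_TO_UG = 1000.0


@dataclass(frozen=True)
class TherapeuticWindow:
    """Steady-state concentration window (μg/L) bounding a dosing design.

    ``c_min`` is the minimum effective concentration, ``c_max`` the
    toxic-boundary maximum; ``analgesic_threshold`` is an optional
    evidence-based floor inside the window (e.g. 20 μg/L for morphine
    analgesia in most cancer patients).
    """

    c_min: float
    c_max: float
    analgesic_threshold: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.c_min < self.c_max):
            raise ValidationError(
                f"therapeutic window requires 0 < c_min < c_max, got "
                f"({self.c_min}, {self.c_max})"
            )
        t = self.analgesic_threshold
        if t is not None and not (self.c_min <= t <= self.c_max):
            raise ValidationError(
                f"analgesic_threshold {t} outside window ({self.c_min}, {self.c_max})"
            )


#: Literature therapeutic range reported for morphine analgesia (ng/mL ≡ μg/L).
MORPHINE_LITERATURE_WINDOW = TherapeuticWindow(9.3, 80.0, analgesic_threshold=20.0)


@dataclass(frozen=True)
class Patient:
    """Patient descriptors used to scale per-kg parameters to whole-body values.

    If ``weight`` is omitted the population average for the stated sex is
    used (male 86.6 kg, female 74.4 kg); an unspecified sex requires an
    explicit weight.
    """

    weight: float | None = None
    sex: str = "unspecified"
    measured_cp: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unspecified"):
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.weight is None:
            if self.sex not in DEFAULT_WEIGHT_KG:
                raise ValidationError(
                    "patient weight required when sex is unspecified"
                )
            object.__setattr__(self, "weight", DEFAULT_WEIGHT_KG[self.sex])
        if not self.weight > 0:
            raise ValidationError(f"patient weight must be positive, got {self.weight}")
        if self.measured_cp is not None and self.measured_cp < 0:
            raise ValidationError("measured plasma concentration cannot be negative")


@dataclass(frozen=True)
class OpioidPKParams:
    """Population PK parameters for one opioid (or one release phase).

    All rate constants are stored in 1/hour, half-lives in hours, volumes in
    L/kg and clearances in L/h/kg, regardless of the units in the source
    file.  ``f_by_route`` maps route name ("iv", "oral", "buccal", "patch")
    to the bioavailability fraction; a reported oral range is kept as
    ``f_oral_range`` metadata while ``f_by_route["oral"]`` holds the working
    average.
    """

    name: str
    t_half: float
    k_e: float
    v_d_per_kg: float
    cl_per_kg: float
    f_by_route: Mapping[str, float] = field(default_factory=lambda: {"iv": 1.0})
    k_a: float | None = None
    window: TherapeuticWindow | None = None
    phase_label: str | None = None
    f_oral_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for attr in ("t_half", "k_e", "v_d_per_kg", "cl_per_kg"):
            v = getattr(self, attr)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ValidationError(f"{self.name}: {attr} must be positive, got {v}")
        for route, f in self.f_by_route.items():
            if not (0 < f <= 1):
                raise ValidationError(
                    f"{self.name}: bioavailability for route {route!r} must be in "
                    f"(0, 1], got {f}"
                )
        if self.k_a is not None and self.k_a <= 0:
            raise ValidationError(f"{self.name}: k_a must be positive, got {self.k_a}")

    @property
    def label(self) -> str:
        return f"{self.name} ({self.phase_label})" if self.phase_label else self.name

    def bioavailability(self, route: str) -> float:
        """F for a route; 'iv_bolus'/'infusion' alias to the IV value of 1."""
        key = {"iv_bolus": "iv", "infusion": "iv"}.get(route, route)
        try:
            return self.f_by_route[key]
        except KeyError:
            raise ValidationError(
                f"{self.label}: no bioavailability value for route {route!r}"
            ) from None


def total_clearance(p: OpioidPKParams, patient: Patient) -> float:
    """Whole-body systemic clearance, L/h (Cl per kg × body weight)."""
    return p.cl_per_kg * patient.weight


def total_volume(p: OpioidPKParams, patient: Patient) -> float:
    """Whole-body apparent volume of distribution, L (V_d per kg × weight)."""
    return p.v_d_per_kg * patient.weight


@dataclass(frozen=True)
class ConsistencyReport:
    """Result of the t_half vs k_e cross-check for one table entry."""

    name: str
    phase_label: str | None
    t_half: float
    t_half_from_k_e: float
    relative_deviation: float
    flagged: bool


def consistency_check(p: OpioidPKParams, tolerance: float = 0.10) -> ConsistencyReport:
    """Flag entries whose tabulated half-life disagrees with ln2/k_e.

    The pooled half-life and elimination rate constant are bootstrapped
    independently from overlapping but not identical study sets, so the
    identity t_half = ln2/k_e need not hold (morphine: 0.693/0.318 ≈ 2.18 h
    vs a tabulated 3.9 h).  This check never raises; it reports the relative
    deviation and whether it exceeds ``tolerance``.
    """
    implied = math.log(2.0) / p.k_e
    deviation = abs(implied - p.t_half) / p.t_half
    return ConsistencyReport(
        name=p.name,
        phase_label=p.phase_label,
        t_half=p.t_half,
        t_half_from_k_e=implied,
        relative_deviation=deviation,
        flagged=deviation > tolerance,
    )


# ---------------------------------------------------------------------------
# Table container and I/O

_CANONICAL_COLUMNS = [
    "name",
    "phase_label",
    "t_half_h",
    "k_e_per_h",
    "v_d_l_per_kg",
    "cl_l_per_h_per_kg",
    "f_iv",
    "f_oral",
    "f_buccal",
    "f_patch",
    "f_oral_lo",
    "f_oral_hi",
    "k_a_per_h",
    "window_min",
    "window_max",
    "analgesic_threshold",
]


class OpioidTable:
    """Ordered collection of :class:`OpioidPKParams` with lookup by name."""

    def __init__(self, entries: Sequence[OpioidPKParams], source: str = "bundled"):
        self._entries = list(entries)
        self.source = source

    def __iter__(self) -> Iterator[OpioidPKParams]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def names(self) -> list[str]:
        """Distinct opioid names in table order."""
        seen: dict[str, None] = {}
        for e in self._entries:
            seen.setdefault(e.name, None)
        return list(seen)

    def lookup(self, name: str, phase: str | None = None) -> OpioidPKParams:
        """Case-insensitive lookup; multiphase entries require ``phase``."""
        matches = [e for e in self._entries if e.name.lower() == name.strip().lower()]
        if not matches:
            raise OpioidNotFoundError(f"no opioid named {name!r} in table")
        if phase is not None:
            want = phase.strip().lower()
            phased = [
                e
                for e in matches
                if e.phase_label
                and (e.phase_label.lower() == want or e.phase_label.lower().endswith(want))
            ]
            if not phased:
                raise OpioidNotFoundError(f"{name!r} has no phase {phase!r}")
            return phased[0]
        if len(matches) > 1:
            phases = [e.phase_label for e in matches]
            raise OpioidNotFoundError(
                f"{name!r} has multiple phase entries {phases}; specify phase="
            )
        return matches[0]

    def check_consistency(self, tolerance: float = 0.10) -> list[ConsistencyReport]:
        return [consistency_check(e, tolerance) for e in self._entries]

    def to_csv(self, path: str | Path) -> None:
        """Write the table in canonical units; reloading is bit-exact."""
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=_CANONICAL_COLUMNS)
            w.writeheader()
            for e in self._entries:
                row = {
                    "name": e.name,
                    "phase_label": e.phase_label or "",
                    "t_half_h": repr(e.t_half),
                    "k_e_per_h": repr(e.k_e),
                    "v_d_l_per_kg": repr(e.v_d_per_kg),
                    "cl_l_per_h_per_kg": repr(e.cl_per_kg),
                    "k_a_per_h": repr(e.k_a) if e.k_a is not None else "",
                }
                for route in ROUTES:
                    f = e.f_by_route.get(route)
                    row[f"f_{route}"] = repr(f) if f is not None else ""
                if e.f_oral_range:
                    row["f_oral_lo"] = repr(e.f_oral_range[0])
                    row["f_oral_hi"] = repr(e.f_oral_range[1])
                if e.window:
                    row["window_min"] = repr(e.window.c_min)
                    row["window_max"] = repr(e.window.c_max)
                    if e.window.analgesic_threshold is not None:
                        row["analgesic_threshold"] = repr(e.window.analgesic_threshold)
                w.writerow({k: row.get(k, "") for k in _CANONICAL_COLUMNS})


def _num(row: Mapping[str, object], key: str) -> float | None:
    v = row.get(key)
    if v is None or v == "":
        return None
    return float(v)  # type: ignore[arg-type]


def _entry_from_row(row: Mapping[str, object]) -> OpioidPKParams:
    """Build one entry from a row, canonicalizing per-minute units (×60 for
    rates, ÷60 for half-lives)."""
    name = str(row["name"]).strip()

    def dual(hour_key: str, minute_key: str, rate: bool) -> float | None:
        h = _num(row, hour_key)
        if h is not None:
            return h
        m = _num(row, minute_key)
        if m is None:
            return None
        return m * 60.0 if rate else m / 60.0

    t_half = dual("t_half_h", "t_half_min", rate=False)
    k_e = dual("k_e_per_h", "k_e_per_min", rate=True)
    cl = dual("cl_l_per_h_per_kg", "cl_l_per_min_per_kg", rate=True)
    k_a = dual("k_a_per_h", "k_a_per_min", rate=True)
    v_d = _num(row, "v_d_l_per_kg")
    if t_half is None or k_e is None or cl is None or v_d is None:
        raise ValidationError(f"{name}: missing disposition parameter(s)")

    f_by_route = {}
    for route in ROUTES:
        f = _num(row, f"f_{route}")
        if f is not None:
            f_by_route[route] = f
    lo, hi = _num(row, "f_oral_lo"), _num(row, "f_oral_hi")
    f_range = (lo, hi) if lo is not None and hi is not None else None

    window = None
    wmin, wmax = _num(row, "window_min"), _num(row, "window_max")
    if wmin is not None and wmax is not None:
        window = TherapeuticWindow(wmin, wmax, _num(row, "analgesic_threshold"))

    phase = str(row.get("phase_label") or "").strip() or None
    return OpioidPKParams(
        name=name,
        t_half=t_half,
        k_e=k_e,
        v_d_per_kg=v_d,
        cl_per_kg=cl,
        f_by_route=f_by_route,
        k_a=k_a,
        window=window,
        phase_label=phase,
        f_oral_range=f_range,
    )


def load_opioid_table(source: str | Path | None = None) -> OpioidTable:
    """Load the bundled reference table, or a user CSV/JSON parameter file.

    CSV files use the canonical column names (``t_half_h``, ``k_e_per_h``,
    ``v_d_l_per_kg``, ``cl_l_per_h_per_kg``, ``f_<route>``, ``k_a_per_h``,
    ``window_min``, ``window_max``, ``analgesic_threshold``); ``*_min``
    variants holding per-minute values are converted on load.  JSON files
    hold a list of objects with the same keys.
    """
    if source is None:
        ref = resources.files("opioidpk.data") / "opioid_pk_parameters.csv"
        with ref.open("r", newline="") as fh:
            rows = list(csv.DictReader(fh))
        return OpioidTable([_entry_from_row(r) for r in rows], source="bundled")

    path = Path(source)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        if not isinstance(rows, list):
            raise ValidationError("JSON parameter file must be a list of objects")
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    return OpioidTable([_entry_from_row(r) for r in rows], source=str(path))


def mg_to_ug(mg: float) -> float:
    """Milligrams → canonical micrograms."""
    return mg * _MG_TO_UG


def ug_to_mg(ug: float) -> float:
    """Canonical micrograms → milligrams for display."""
    return ug / _MG_TO_UG
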