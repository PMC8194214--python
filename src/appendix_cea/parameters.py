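"""Model inputs for the appendicitis cost-effectiveness model.

Every scalar the decision model consumes lives in a :class:`ParameterSet`:
branch probabilities, relative risks (laparoscopic vs open complications),
health-state utilities with durations, resource quantities and unit tariffs
in Colombian pesos (COP), the discount rate, the time horizon, the
willingness-to-pay threshold and the currency conversion constants.

Costing follows the Colombian tariff logic: open (OA) and laparoscopic (LA)
appendectomy are valued as packages (the LA package is the OA package plus a
single disposable trocar); nonoperative management (NOM) and complication
episodes are valued per event as ``sum(quantity x unit tariff)``.  Tariff
totals in COP are adjusted upward by 30% for inflation, per the national
economic-evaluation guideline, and converted to US dollars at the
January-2021 exchange rate of 3478 COP per USD.

The default values defined here form a synthetic but internally consistent
baseline calibrated to publicly stated anchors (five-year NOM success of
72.7% from the APPAC trial, a 92.9% open-surgery share, ISS-tariff cost
scales).  The annotated template in ``configs/template.yaml`` flags each
field whose exact source value should be transcribed before using the model
for a real reimbursement decision.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

__all__ = [
    "ParameterError",
    "CostItem",
    "HealthState",
    "DistributionSpec",
    "ParameterSet",
    "convert_cost",
    "la_probability",
    "event_cost",
    "load_parameters",
    "save_parameters",
    "baseline_parameter_set",
    "baseline_distributions",
    "default_recurrence_schedule",
    "rescale_recurrence_schedule",
]

PROB_TOL = 1e-9


class ParameterError(ValueError):
    """A configuration failed validation.  ``errors`` names each offending field."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("invalid parameters: " + "; ".join(self.errors))


# --------------------------------------------------------------------------
# currency and probability primitives
# --------------------------------------------------------------------------

def convert_cost(amount_cop: float, fx: float = 3478.0, inflation: float = 1.30) -> float:
    """COP tariff -> USD: ``amount_cop * inflation / fx``, no intermediate rounding.

    ``fx`` is the exchange rate in COP per USD; ``inflation`` the guideline
    inflation-adjustment multiplier (>= 1).
    """
    errors = []
    if amount_cop < 0:
        errors.append(f"amount_cop must be >= 0, got {amount_cop}")
    if fx <= 0:
        errors.append(f"fx must be > 0, got {fx}")
    if inflation < 1:
        errors.append(f"inflation must be >= 1, got {inflation}")
    if errors:
        raise ParameterError(errors)
    return amount_cop * inflation / fx


def la_probability(p_oa: float, rr: float) -> float:
    """Laparoscopic complication probability: ``min(p_oa * rr, 1)``.

    Derived probabilities are clamped at certainty; the caller can detect a
    clamp by checking ``p_oa * rr > 1``.
    """
    errors = []
    if not 0.0 <= p_oa <= 1.0:
        errors.append(f"p_oa must lie in [0, 1], got {p_oa}")
    if rr < 0:
        errors.append(f"rr must be >= 0, got {rr}")
    if errors:
        raise ParameterError(errors)
    return min(p_oa * rr, 1.0)


@dataclass
class CostItem:
    """One resource line of a per-event costing: quantity x unit tariff (COP)."""

    resource: str
    quantity: float
    unit_cost_cop: float

    def validate(self, where: str = "") -> list[str]:
        errs = []
        if self.quantity < 0:
            errs.append(f"{where}{self.resource}: quantity must be >= 0, got {self.quantity}")
        if self.unit_cost_cop < 0:
            errs.append(f"{where}{self.resource}: unit_cost_cop must be >= 0, got {self.unit_cost_cop}")
        return errs


def event_cost(items: Sequence[CostItem], fx: float = 3478.0, inflation: float = 1.30) -> float:
    """Total USD cost of one event: sum of quantity x unit tariff, then converted."""
    errors = [e for item in items for e in item.validate()]
    if errors:
        raise ParameterError(errors)
    total_cop = sum(item.quantity * item.unit_cost_cop for item in items)
    return convert_cost(total_cop, fx=fx, inflation=inflation)


@dataclass
class HealthState:
    """Utility weight in [0, 1] and the episode duration in years."""

    utility: float
    duration_years: float

    def validate(self, name: str) -> list[str]:
        errs = []
        if not 0.0 <= self.utility <= 1.0:
            errs.append(f"utilities.{name}: utility must lie in [0, 1], got {self.utility}")
        if self.duration_years <= 0:
            errs.append(f"utilities.{name}: duration must be > 0, got {self.duration_years}")
        return errs


# --------------------------------------------------------------------------
# PSA distribution specifications
# --------------------------------------------------------------------------

_DIST_KINDS = {"beta", "dirichlet", "poisson", "uniform", "point"}


@dataclass
class DistributionSpec:
    """Second-order uncertainty for one ParameterSet field (or one simplex).

    kind:
        ``beta(alpha, beta)`` for probabilities and utilities;
        ``dirichlet(concentration=[...])`` for polytomous branch probabilities
        (``target`` is then a list of field paths, ``None`` marking the
        residual branch whose mass is implied);
        ``poisson(mean)`` for resource quantities;
        ``uniform(lower, upper)`` for unit tariffs and relative risks;
        ``point(value)`` for a degenerate (fixed) draw.
    target:
        dotted path into the ParameterSet, e.g. ``p_oa_ssi``,
        ``utilities.post_surgery_la``, ``cost_items.nom_initial.ertapenem_1g.quantity``.
    """

    kind: str
    parameters: dict
    target: Any

    def validate(self) -> list[str]:
        errs = []
        p = self.parameters
        if self.kind not in _DIST_KINDS:
            errs.append(f"{self.target}: unknown distribution kind {self.kind!r}")
            return errs
        if self.kind == "beta":
            if p.get("alpha", 0) <= 0 or p.get("beta", 0) <= 0:
                errs.append(f"{self.target}: beta requires alpha, beta > 0, got {p}")
        elif self.kind == "dirichlet":
            conc = p.get("concentration", [])
            if len(conc) < 2 or any(c <= 0 for c in conc):
                errs.append(f"{self.target}: dirichlet requires >= 2 positive concentrations, got {conc}")
            if not isinstance(self.target, (list, tuple)) or len(self.target) != len(conc):
                errs.append(f"{self.target}: dirichlet target must list one field per concentration")
        elif self.kind == "poisson":
            if p.get("mean", -1) < 0:
                errs.append(f"{self.target}: poisson requires mean >= 0, got {p}")
        elif self.kind == "uniform":
            if p.get("lower", 0) > p.get("upper", 0):
                errs.append(f"{self.target}: uniform requires lower <= upper, got {p}")
        elif self.kind == "point":
            if "value" not in p:
                errs.append(f"{self.target}: point requires a value")
        return errs


# --------------------------------------------------------------------------
# recurrence schedule helpers
# --------------------------------------------------------------------------

def default_recurrence_schedule(
    p_nom_success: float,
    p_nom_initial_failure: float = 0.0,
    horizon_years: int = 5,
    first_year_cumulative: float = 0.27,
) -> dict[int, float]:
    """Annual recurrence hazards after initial NOM success.

    Places 27% cumulative failure at year 1 (the share of antibiotic-treated
    patients who undergo appendectomy within the first year) and linearly
    interpolates cumulative failure up to the total implied by
    ``1 - p_nom_success`` at the horizon.  Returned values are conditional
    (per-year hazard) probabilities; the implied overall success probability,
    ``(1 - p_nom_initial_failure) * prod(1 - h_t)``, equals ``p_nom_success``.
    """
    if not 0.0 <= p_nom_success <= 1.0:
        raise ParameterError([f"p_nom_success must lie in [0, 1], got {p_nom_success}"])
    if not 0.0 <= p_nom_initial_failure < 1.0:
        raise ParameterError([f"p_nom_initial_failure must lie in [0, 1), got {p_nom_initial_failure}"])
    surv_initial = 1.0 - p_nom_initial_failure
    if p_nom_success > surv_initial + PROB_TOL:
        raise ParameterError(["p_nom_success cannot exceed 1 - p_nom_initial_failure"])
    total = 1.0 - min(p_nom_success / surv_initial, 1.0)  # conditional cumulative failure
    f1 = min(first_year_cumulative, total)
    cum = [0.0]
    for t in range(1, horizon_years + 1):
        if horizon_years == 1:
            cum.append(total)
        else:
            cum.append(f1 + (total - f1) * (t - 1) / (horizon_years - 1))
    schedule = {}
    for t in range(1, horizon_years + 1):
        surv = 1.0 - cum[t - 1]
        schedule[t] = 0.0 if surv <= 0 else (cum[t] - cum[t - 1]) / surv
    return schedule


def rescale_recurrence_schedule(
    schedule: Mapping[int, float],
    p_nom_success_new: float,
    p_nom_initial_failure: float = 0.0,
) -> dict[int, float]:
    """Rescale a hazard schedule so total failure tracks a new success probability.

    The cumulative-failure curve keeps its shape; its level is scaled so that
    the implied overall success equals ``p_nom_success_new``.  Used when a PSA
    draw perturbs ``p_nom_success``.
    """
    years = sorted(schedule)
    cum, surv = [], 1.0
    for t in years:
        surv *= 1.0 - schedule[t]
        cum.append(1.0 - surv)
    old_total = cum[-1] if cum else 0.0
    surv_initial = 1.0 - p_nom_initial_failure
    new_total = 1.0 - min(p_nom_success_new / surv_initial, 1.0)
    if new_total == old_total:  # exact no-op keeps degenerate draws bitwise stable
        return {t: schedule[t] for t in years}
    scale = 0.0 if old_total <= 0 else new_total / old_total
    if old_total <= 0 and new_total > 0:
        # degenerate old schedule: fall back to the default shape
        return default_recurrence_schedule(p_nom_success_new, p_nom_initial_failure, len(years) or 5)
    new_cum = [min(c * scale, 1.0) for c in cum]
    out, prev = {}, 0.0
    for t, c in zip(years, new_cum):
        s = 1.0 - prev
        out[t] = 0.0 if s <= 0 else (c - prev) / s
        prev = c
    return out


# --------------------------------------------------------------------------
# the parameter set
# --------------------------------------------------------------------------

def _baseline_utilities() -> dict[str, HealthState]:
    return {
        # background utility while free of any modelled episode
        "healthy": HealthState(0.998, 5.0),
        # convalescence after the index operation
        "post_surgery_la": HealthState(0.88, 1.0 / 12.0),
        "post_surgery_oa": HealthState(0.85, 2.0 / 12.0),
        # short-term surgical complications (ileus is cost-only, assumption V)
        "ssi": HealthState(0.82, 3.0 / 52.0),
        "abscess": HealthState(0.74, 0.10),
        # antibiotic treatment episode (in-hospital observation >= 72 h)
        "nom_initial": HealthState(0.90, 0.02),
        # complicated recurrent appendicitis episode
        "complicated_aa": HealthState(0.70, 0.15),
    }


def _baseline_cost_items() -> dict[str, list[CostItem]]:
    return {
        "nom_initial": [
            CostItem("hospital_day", 3, 80_000),
            CostItem("surgeon_evaluation", 2, 35_000),
            CostItem("iv_fluids", 6, 15_000),
            CostItem("analgesic_dose", 9, 3_000),
            CostItem("c_reactive_protein", 2, 25_000),
            CostItem("hemogram", 2, 20_000),
            CostItem("ertapenem_1g", 3, 90_000),
            CostItem("levofloxacin_500mg", 7, 6_000),
            CostItem("metronidazole_500mg", 21, 2_000),
        ],
        "ssi": [
            CostItem("cephalexin_500mg", 28, 2_000),
            CostItem("medical_evaluation", 2, 35_000),
            CostItem("wound_care_session", 8, 20_000),
            CostItem("analgesic_dose", 10, 3_000),
        ],
        "abscess": [
            CostItem("hospital_day", 4, 80_000),
            CostItem("percutaneous_drainage", 1, 250_000),
            CostItem("ceftriaxone_1g", 8, 12_000),
            CostItem("metronidazole_500mg", 24, 2_000),
            CostItem("c_reactive_protein", 2, 25_000),
            CostItem("hemogram", 2, 20_000),
            CostItem("surgeon_evaluation", 2, 35_000),
        ],
        "ileus": [
            CostItem("hospital_day", 4, 80_000),
            CostItem("iv_fluids", 8, 15_000),
            CostItem("analgesic_dose", 9, 3_000),
            CostItem("nasogastric_tube", 1, 40_000),
            CostItem("hemogram", 2, 20_000),
        ],
        "complicated_aa": [
            CostItem("hospital_day", 5, 80_000),
            CostItem("percutaneous_drainage", 1, 250_000),
            CostItem("ceftriaxone_1g", 10, 12_000),
            CostItem("metronidazole_500mg", 30, 2_000),
            CostItem("c_reactive_protein", 3, 25_000),
            CostItem("hemogram", 3, 20_000),
            CostItem("surgeon_evaluation", 3, 35_000),
        ],
    }


#: documented provenance per default, "assumed" where no public point value exists
PROVENANCE: dict[str, str] = {
    "p_oa_ssi": "assumed; surgical-site infection after open appendectomy, meta-analytic scale",
    "p_oa_abscess": "assumed; intra-abdominal abscess after open appendectomy",
    "p_oa_ileus": "assumed; postoperative ileus after open appendectomy",
    "rr_la_ssi": "assumed; LA-vs-OA wound infection RR, meta-analytic scale (LA protective)",
    "rr_la_abscess": "assumed; LA-vs-OA intra-abdominal abscess RR (LA harmful)",
    "rr_la_ileus": "assumed; LA-vs-OA ileus RR",
    "p_nom_success": "APPAC trial: 72.7% antibiotic success within 5 years",
    "p_nom_initial_failure": "assumed 0: initial 72-h failure folded into the year-1 hazard",
    "p_recur_complicated": "APPAC follow-up: ~10% of recurrences present complicated",
    "p_choose_oa": "Bogota 2013-2015 registry: 92.9% of appendectomies performed open",
    "p_complicated_medical": "assumed; share of complicated recurrences managed medically + interval appendectomy",
    "recurrence_schedule": "derived: 27% cumulative appendectomy at year 1, linear to 1-p_nom_success at year 5",
    "utilities": "assumed; Tufts CEA-registry scale for appendicitis states",
    "cost_items": "assumed; Manual Tarifario ISS / SISMED scale, transcribe exact tariffs",
    "package_cost_oa": "assumed; ISS package tariff scale for open appendectomy",
    "package_cost_la": "OA package plus one disposable trocar (15,000 COP assumed, ISS tariff scale)",
    "discount_rate": "Colombian EE guideline: 5% for costs and outcomes",
    "horizon_years": "5-year horizon (late NOM recurrences)",
    "wtp": "1 GDP per capita in Colombia: $6,667/QALY",
    "exchange_rate": "Banco de la Republica, January 2021: 3478 COP/USD",
    "inflation_factor": "Colombian EE guideline: +30% tariff inflation adjustment",
    "qaly_convention": "end-of-year annuity discounting of utility streams (mid/start selectable)",
}

#: 95% CIs backing the uniform relative-risk distributions (assumed, meta-analytic
#: scale, symmetric about the point estimates so the PSA mean equals the base case)
RR_CONFIDENCE_INTERVALS: dict[str, tuple[float, float]] = {
    "rr_la_ssi": (0.21, 0.49),
    "rr_la_abscess": (1.05, 2.49),
    "rr_la_ileus": (0.25, 0.55),
}

_PROB_FIELDS = (
    "p_oa_ssi", "p_oa_abscess", "p_oa_ileus",
    "p_nom_success", "p_nom_initial_failure",
    "p_recur_complicated", "p_choose_oa", "p_complicated_medical",
)
_RR_FIELDS = ("rr_la_ssi", "rr_la_abscess", "rr_la_ileus")
_QALY_CONVENTIONS = ("end", "mid", "start")


@dataclass
class ParameterSet:
    """Every scalar input of the appendicitis decision model.

    Defaults are the documented synthetic baseline (see module docstring and
    :data:`PROVENANCE`).  ``validate`` returns a report rather than raising;
    ``ensure_valid`` raises :class:`ParameterError` on any violation.
    """

    # short-term complication probabilities after open appendectomy
    p_oa_ssi: float = 0.10
    p_oa_abscess: float = 0.012
    p_oa_ileus: float = 0.05
    # relative risks, laparoscopic vs open
    rr_la_ssi: float = 0.35
    rr_la_abscess: float = 1.77
    rr_la_ileus: float = 0.40
    # nonoperative-management course
    p_nom_success: float = 0.727
    p_nom_initial_failure: float = 0.0
    p_recur_complicated: float = 0.10
    p_choose_oa: float = 0.929
    p_complicated_medical: float = 0.60
    recurrence_schedule: dict[int, float] | None = None
    # health states and per-event costing
    utilities: dict[str, HealthState] = field(default_factory=_baseline_utilities)
    cost_items: dict[str, list[CostItem]] = field(default_factory=_baseline_cost_items)
    package_cost_oa: float = 780_000.0  # COP
    package_cost_la: float = 795_000.0  # COP = OA package + one disposable trocar
    # analysis settings
    discount_rate: float = 0.05
    horizon_years: int = 5
    wtp: float = 6667.0           # USD per QALY, 1 GDP per capita
    exchange_rate: float = 3478.0  # COP per USD
    inflation_factor: float = 1.30
    qaly_convention: str = "end"

    def __post_init__(self) -> None:
        if self.recurrence_schedule is None:
            self.recurrence_schedule = default_recurrence_schedule(
                self.p_nom_success, self.p_nom_initial_failure, self.horizon_years
            )

    # -- derived quantities -------------------------------------------------

    def la_complication_probability(self, which: str) -> float:
        """Clamped LA probability for ``which`` in {'ssi', 'abscess', 'ileus'}."""
        return la_probability(getattr(self, f"p_oa_{which}"), getattr(self, f"rr_la_{which}"))

    def clamp_log(self) -> list[str]:
        """Which RR-derived probabilities were clamped at 1."""
        out = []
        for which in ("ssi", "abscess", "ileus"):
            raw = getattr(self, f"p_oa_{which}") * getattr(self, f"rr_la_{which}")
            if raw > 1.0:
                out.append(f"p_la_{which}: {raw:.6g} clamped to 1")
        return out

    def recurrence_probability(self, year: int) -> float:
        """Unconditional probability that the NOM recurrence occurs in ``year``."""
        if year not in self.recurrence_schedule:
            raise ParameterError([f"recurrence_schedule has no year {year}"])
        p = 1.0 - self.p_nom_initial_failure
        for t in sorted(self.recurrence_schedule):
            if t == year:
                return p * self.recurrence_schedule[t]
            p *= 1.0 - self.recurrence_schedule[t]
        raise AssertionError("unreachable")

    def cumulative_failure(self) -> float:
        """Total probability NOM ends in appendectomy within the horizon."""
        surv = 1.0 - self.p_nom_initial_failure
        for t in sorted(self.recurrence_schedule):
            surv *= 1.0 - self.recurrence_schedule[t]
        return 1.0 - surv

    def event_cost_usd(self, event: str) -> float:
        """Discounted-to-nothing USD cost of one named event (packages included)."""
        if event == "package_oa":
            cop = self.package_cost_oa
            return convert_cost(cop, self.exchange_rate, self.inflation_factor)
        if event == "package_la":
            return convert_cost(self.package_cost_la, self.exchange_rate, self.inflation_factor)
        if event not in self.cost_items:
            raise ParameterError([f"unknown cost event {event!r}"])
        return event_cost(self.cost_items[event], self.exchange_rate, self.inflation_factor)

    def known_events(self) -> list[str]:
        return ["package_oa", "package_la", *self.cost_items]

    # -- validation ----------------------------------------------------------

    def validate(self) -> list[str]:
        """Return every invariant violation (empty list == valid)."""
        errs: list[str] = []
        for f in _PROB_FIELDS:
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                errs.append(f"{f}: probability must lie in [0, 1], got {v}")
        for f in _RR_FIELDS:
            v = getattr(self, f)
            if v < 0:
                errs.append(f"{f}: relative risk must be >= 0, got {v}")
        for name, state in self.utilities.items():
            errs.extend(state.validate(name))
        for event, items in self.cost_items.items():
            for item in items:
                errs.extend(item.validate(f"cost_items.{event}."))
        if self.package_cost_oa < 0:
            errs.append(f"package_cost_oa must be >= 0, got {self.package_cost_oa}")
        if self.package_cost_la < 0:
            errs.append(f"package_cost_la must be >= 0, got {self.package_cost_la}")
        if self.discount_rate < 0:
            errs.append(f"discount_rate must be >= 0, got {self.discount_rate}")
        if self.horizon_years < 1:
            errs.append(f"horizon_years must be >= 1, got {self.horizon_years}")
        if self.wtp < 0:
            errs.append(f"wtp must be >= 0, got {self.wtp}")
        if self.exchange_rate <= 0:
            errs.append(f"exchange_rate must be > 0, got {self.exchange_rate}")
        if self.inflation_factor < 1:
            errs.append(f"inflation_factor must be >= 1, got {self.inflation_factor}")
        if self.qaly_convention not in _QALY_CONVENTIONS:
            errs.append(f"qaly_convention must be one of {_QALY_CONVENTIONS}, got {self.qaly_convention!r}")
        if "healthy" not in self.utilities:
            errs.append("utilities must define the background state 'healthy'")
        # complication branches must leave room for the no-complication branch
        if all(0 <= getattr(self, f) <= 1 for f in ("p_oa_ssi", "p_oa_abscess", "p_oa_ileus")):
            if self.p_oa_ssi + self.p_oa_abscess + self.p_oa_ileus > 1.0 + PROB_TOL:
                errs.append("p_oa_ssi + p_oa_abscess + p_oa_ileus must not exceed 1")
            try:
                la_sum = sum(self.la_complication_probability(w) for w in ("ssi", "abscess", "ileus"))
                if la_sum > 1.0 + PROB_TOL:
                    errs.append("derived LA complication probabilities must not exceed 1 in total")
            except ParameterError:
                pass
        # recurrence schedule: hazards in [0,1]; implied success == p_nom_success
        for t, h in self.recurrence_schedule.items():
            if not 0.0 <= h <= 1.0:
                errs.append(f"recurrence_schedule[{t}]: hazard must lie in [0, 1], got {h}")
        years = sorted(self.recurrence_schedule)
        if years != list(range(1, self.horizon_years + 1)):
            errs.append(
                f"recurrence_schedule must cover years 1..{self.horizon_years}, got {years}"
            )
        elif all(0.0 <= h <= 1.0 for h in self.recurrence_schedule.values()) and (
            0.0 <= self.p_nom_initial_failure <= 1.0
        ):
            implied_success = 1.0 - self.cumulative_failure()
            if 0.0 <= self.p_nom_success <= 1.0 and abs(implied_success - self.p_nom_success) > PROB_TOL:
                errs.append(
                    "recurrence_schedule implies success "
                    f"{implied_success:.12g} but p_nom_success is {self.p_nom_success:.12g}"
                )
        return errs

    def ensure_valid(self) -> "ParameterSet":
        errs = self.validate()
        if errs:
            raise ParameterError(errs)
        return self

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d: dict[str, Any] = {}
        for f in _PROB_FIELDS + _RR_FIELDS:
            d[f] = float(getattr(self, f))
        d["recurrence_schedule"] = {int(t): float(h) for t, h in self.recurrence_schedule.items()}
        d["utilities"] = {
            k: {"utility": float(v.utility), "duration_years": float(v.duration_years)}
            for k, v in self.utilities.items()
        }
        d["cost_items"] = {
            event: [
                {
                    "resource": str(i.resource),
                    "quantity": float(i.quantity),
                    "unit_cost_cop": float(i.unit_cost_cop),
                }
                for i in items
            ]
            for event, items in self.cost_items.items()
        }
        for f in (
            "package_cost_oa", "package_cost_la", "discount_rate",
            "wtp", "exchange_rate", "inflation_factor",
        ):
            d[f] = float(getattr(self, f))
        d["horizon_years"] = int(self.horizon_years)
        d["qaly_convention"] = str(self.qaly_convention)
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ParameterSet":
        known = set(cls.__dataclass_fields__)
        errs = [f"unknown field {k!r}" for k in data if k not in known and k != "provenance"]
        if errs:
            raise ParameterError(errs)
        kwargs: dict[str, Any] = {}
        for k, v in data.items():
            if k == "provenance":
                continue  # annotation block of the template config, ignored
            if k == "utilities":
                kwargs[k] = {
                    name: HealthState(float(s["utility"]), float(s["duration_years"]))
                    for name, s in v.items()
                }
            elif k == "cost_items":
                kwargs[k] = {
                    event: [
                        CostItem(str(i["resource"]), float(i["quantity"]), float(i["unit_cost_cop"]))
                        for i in items
                    ]
                    for event, items in v.items()
                }
            elif k == "recurrence_schedule":
                kwargs[k] = {int(t): float(h) for t, h in v.items()}
            else:
                kwargs[k] = v
        return cls(**kwargs)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def with_nom_success(self, p_nom_success: float) -> "ParameterSet":
        """Copy with a new success probability; the recurrence schedule is rescaled."""
        out = self.copy()
        out.p_nom_success = p_nom_success
        out.recurrence_schedule = rescale_recurrence_schedule(
            self.recurrence_schedule, p_nom_success, self.p_nom_initial_failure
        )
        return out


# --------------------------------------------------------------------------
# config IO
# --------------------------------------------------------------------------

def load_parameters(source: str | Path | Mapping[str, Any]) -> ParameterSet:
    """Load and validate a ParameterSet from a YAML/JSON file or a mapping.

    File dialect is chosen by extension (``.yaml``/``.yml`` vs ``.json``).
    Missing keys fall back to the documented baseline defaults; unknown keys,
    range violations and an inconsistent recurrence schedule raise
    :class:`ParameterError` naming each field.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        elif path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            raise ParameterError([f"unrecognized config extension {path.suffix!r} (use .yaml/.yml/.json)"])
    else:
        data = dict(source)
    if not isinstance(data, Mapping):
        raise ParameterError(["config document must be a mapping"])
    params = ParameterSet.from_dict(data)
    return params.ensure_valid()


def save_parameters(params: ParameterSet, path: str | Path) -> Path:
    """Serialize to YAML or JSON by extension; round-trips through ``load_parameters``."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    elif path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        raise ParameterError([f"unrecognized config extension {path.suffix!r} (use .yaml/.yml/.json)"])
    return path


def baseline_parameter_set() -> ParameterSet:
    """The documented synthetic baseline configuration."""
    return ParameterSet().ensure_valid()


def baseline_distributions(params: ParameterSet | None = None, ess: float = 100.0) -> list[DistributionSpec]:
    """Second-order distributions matching the baseline parameter set.

    beta for binomial probabilities and utilities (moment-matched at an
    effective sample size ``ess``), Dirichlet jointly over the four-way OA
    complication split, uniform over the RR 95% CIs and +/-25% around unit
    tariffs and package costs, Poisson for resource quantities.
    """
    p = params or baseline_parameter_set()
    specs: list[DistributionSpec] = []

    def beta_for(value: float, target: str) -> DistributionSpec:
        v = min(max(value, 1e-6), 1 - 1e-6)
        return DistributionSpec("beta", {"alpha": v * ess, "beta": (1 - v) * ess}, target)

    # polytomous OA complication split (residual = no complication)
    branch = [p.p_oa_ssi, p.p_oa_abscess, p.p_oa_ileus]
    conc = [max(1.0 - sum(branch), 1e-6) * ess] + [max(b, 1e-6) * ess for b in branch]
    specs.append(DistributionSpec(
        "dirichlet", {"concentration": conc},
        [None, "p_oa_ssi", "p_oa_abscess", "p_oa_ileus"],
    ))
    for f in ("p_nom_success", "p_recur_complicated", "p_choose_oa", "p_complicated_medical"):
        specs.append(beta_for(getattr(p, f), f))
    for name, state in p.utilities.items():
        specs.append(beta_for(state.utility, f"utilities.{name}"))
    for f, (lo, hi) in RR_CONFIDENCE_INTERVALS.items():
        specs.append(DistributionSpec("uniform", {"lower": lo, "upper": hi}, f))
    for f in ("package_cost_oa", "package_cost_la"):
        v = getattr(p, f)
        specs.append(DistributionSpec("uniform", {"lower": 0.75 * v, "upper": 1.25 * v}, f))
    for event, items in p.cost_items.items():
        for item in items:
            specs.append(DistributionSpec(
                "uniform",
                {"lower": 0.75 * item.unit_cost_cop, "upper": 1.25 * item.unit_cost_cop},
                f"cost_items.{event}.{item.resource}.unit_cost_cop",
            ))
            specs.append(DistributionSpec(
                "poisson", {"mean": item.quantity},
                f"cost_items.{event}.{item.resource}.quantity",
            ))
    for s in specs:
        bad = s.validate()
        if bad:
            raise ParameterError(bad)
    return specs
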