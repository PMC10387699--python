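"""Model inputs: drug definitions, natural history, economics, validation, file I/O.

The model compares sequences of disease-modifying treatments (DMTs) for
relapsing multiple sclerosis.  Each DMT carries two relative-efficacy
estimates from a network meta-analysis — an incidence rate ratio (IRR)
scaling the annualized relapse rate and a relative risk (RR) scaling the
hazard of 24-week confirmed disability progression — together with Dutch
annual list prices (first year vs. subsequent years).  Natural history is an
annual EDSS transition matrix (states 0–9, death handled separately through
a life table with EDSS-dependent hazard multipliers).  Economic inputs map
EDSS states to utilities and to healthcare/societal costs.

Parameter files are YAML mappings with five sections (``dmts``,
``natural_history``, ``economics``, ``grammar``, ``cohort``).  Unknown keys
are errors; every structural invariant is checked on load.  The transition
matrix may live in a sidecar delimited table (rows = from-EDSS, columns =
to-EDSS).  Readers accept ``dialect="comma"`` for decimal-comma files.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .grammar import GrammarRules

MAX_AGE = 100  # survivors are terminated at the life-table end

__all__ = [
    "Measure",
    "UNKNOWN",
    "EfficacyEstimate",
    "DMTDefinition",
    "NaturalHistoryParams",
    "EconomicParams",
    "CohortSettings",
    "ModelParameters",
    "Violation",
    "ParameterError",
    "table1_defaults",
    "validate_parameters",
    "load_model_parameters",
    "save_model_parameters",
    "model_parameters_to_dict",
]


class ParameterError(ValueError):
    """Raised when a parameter file or parameter set violates its schema."""


class Measure(str, enum.Enum):
    """Which hazard a relative-efficacy ratio scales."""

    IRR_ARR = "IRR_ARR"  # incidence rate ratio on the annualized relapse rate
    RR_CDP = "RR_CDP"    # relative risk of 24-week confirmed disability progression


class _Unknown:
    """Sentinel for an efficacy that trials did not identify (not 1.0).

    Deterministic runs refuse to use it; the threshold-analysis module
    supplies trial values instead.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "UNKNOWN"

    def __deepcopy__(self, memo):
        return self


UNKNOWN = _Unknown()


@dataclass(frozen=True)
class EfficacyEstimate:
    """A ratio versus placebo with its 95% confidence interval."""

    point: float
    ci_low: float
    ci_high: float
    measure: Measure

    @classmethod
    def certain(cls, point: float, measure: Measure) -> "EfficacyEstimate":
        """A degenerate estimate (no uncertainty), e.g. a trial value in a
        threshold search."""
        return cls(point, point, point, measure)

    @property
    def degenerate(self) -> bool:
        return self.ci_low == self.point == self.ci_high


@dataclass
class DMTDefinition:
    """One disease-modifying treatment: efficacy, cost schedule, eligibility.

    ``annual_cost_first_year``/``annual_cost_subsequent`` may be ``None`` for
    a drug whose list price is not yet known (ublituximab); such a drug can
    only be simulated through the threshold-analysis price search.
    ``synthetic`` flags filler values invented for testing, to prevent their
    accidental citation as published estimates.
    """

    name: str
    moa_class: str
    eligible_lines: frozenset
    efficacy_arr: EfficacyEstimate
    efficacy_cdp: Any  # EfficacyEstimate or UNKNOWN
    annual_cost_first_year: float | None
    annual_cost_subsequent: float | None
    admin_cost: float = 0.0
    monitoring_cost: float = 0.0
    ae_discontinuation_prob: float = 0.0
    synthetic: bool = False

    def with_cdp(self, rr: float) -> "DMTDefinition":
        """Copy with a trial RR of disability progression (threshold search)."""
        return dataclasses.replace(
            self, efficacy_cdp=EfficacyEstimate.certain(rr, Measure.RR_CDP)
        )

    def with_annual_price(
        self, first_year: float, subsequent: float | None = None
    ) -> "DMTDefinition":
        return dataclasses.replace(
            self,
            annual_cost_first_year=first_year,
            annual_cost_subsequent=first_year if subsequent is None else subsequent,
        )


@dataclass
class NaturalHistoryParams:
    """Untreated disease dynamics.

    ``transition_matrix`` is the annual probability matrix over EDSS states
    (row-stochastic; death is NOT an EDSS row).  ``life_table`` holds the
    background mortality hazard (per year) indexed by integer age 0..100;
    ``mortality_multiplier_by_edss`` scales that hazard per state.
    """

    transition_matrix: np.ndarray
    relapse_rate_by_edss: np.ndarray
    mortality_multiplier_by_edss: np.ndarray
    life_table: np.ndarray

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.relapse_rate_by_edss = np.asarray(self.relapse_rate_by_edss, dtype=float)
        self.mortality_multiplier_by_edss = np.asarray(
            self.mortality_multiplier_by_edss, dtype=float
        )
        self.life_table = np.asarray(self.life_table, dtype=float)

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]


@dataclass
class EconomicParams:
    """Utilities, state costs, relapse cost/disutility, discounting, WTP."""

    utility_by_edss: np.ndarray
    relapse_disutility: float
    state_cost_healthcare_by_edss: np.ndarray
    state_cost_societal_by_edss: np.ndarray
    relapse_cost: float
    wtp: float
    discount_rate_costs: float = 0.04
    discount_rate_effects: float = 0.015

    def __post_init__(self) -> None:
        self.utility_by_edss = np.asarray(self.utility_by_edss, dtype=float)
        self.state_cost_healthcare_by_edss = np.asarray(
            self.state_cost_healthcare_by_edss, dtype=float
        )
        self.state_cost_societal_by_edss = np.asarray(
            self.state_cost_societal_by_edss, dtype=float
        )


@dataclass
class CohortSettings:
    n_patients: int = 10_000
    start_age: int = 29
    baseline_edss_range: tuple = (0, 3)


@dataclass
class ModelParameters:
    """The full model input: DMT set, natural history, economics, grammar, cohort."""

    dmts: list
    natural_history: NaturalHistoryParams
    economics: EconomicParams
    grammar: GrammarRules
    cohort: CohortSettings = field(default_factory=CohortSettings)

    def dmt(self, name: str):
        for d in self.dmts:
            if d.name == name:
                return d
        raise KeyError(f"unknown DMT {name!r}; known: {[d.name for d in self.dmts]}")

    def dmt_names(self) -> list:
        return [d.name for d in self.dmts]

    def replace_dmt(self, dmt: DMTDefinition) -> "ModelParameters":
        """Copy of the parameter set with one DMT swapped in by name."""
        new = [dmt if d.name == dmt.name else d for d in self.dmts]
        if dmt.name not in [d.name for d in self.dmts]:
            new = new + [dmt]
        return dataclasses.replace(self, dmts=new)


# ---------------------------------------------------------------------------
# Printed defaults for the four anti-CD20 monoclonal antibodies
# ---------------------------------------------------------------------------

_ANTI_CD20_LINES = frozenset({"1a", "2"})


def table1_defaults() -> list:
    """The four anti-CD20 mAbs with their published NMA efficacy and 2022
    Dutch list prices.

    Ocrelizumab (OCR), ofatumumab (OFA), ublituximab (UBL, price not yet
    known) and rituximab (RIT, off-label; its effect on confirmed disability
    progression is considered unknown).  Administration/monitoring costs and
    adverse-event discontinuation probabilities are not part of the printed
    table and default to zero here; the synthetic generator fills plausible
    values.
    """

    def eff(point, lo, hi, measure):
        return EfficacyEstimate(point, lo, hi, measure)

    return [
        DMTDefinition(
            name="OCR",
            moa_class="anti-CD20",
            eligible_lines=_ANTI_CD20_LINES,
            efficacy_arr=eff(0.40, 0.30, 0.52, Measure.IRR_ARR),
            efficacy_cdp=eff(0.45, 0.31, 0.61, Measure.RR_CDP),
            annual_cost_first_year=22_437,
            annual_cost_subsequent=22_437,
        ),
        DMTDefinition(
            name="OFA",
            moa_class="anti-CD20",
            eligible_lines=_ANTI_CD20_LINES,
            efficacy_arr=eff(0.30, 0.22, 0.42, Measure.IRR_ARR),
            efficacy_cdp=eff(0.55, 0.34, 0.88, Measure.RR_CDP),
            annual_cost_first_year=23_434,
            annual_cost_subsequent=20_086,
        ),
        DMTDefinition(
            name="UBL",
            moa_class="anti-CD20",
            eligible_lines=_ANTI_CD20_LINES,
            efficacy_arr=eff(0.31, 0.21, 0.45, Measure.IRR_ARR),
            efficacy_cdp=eff(0.54, 0.27, 1.08, Measure.RR_CDP),
            annual_cost_first_year=None,
            annual_cost_subsequent=None,
        ),
        DMTDefinition(
            name="RIT",
            moa_class="anti-CD20",
            eligible_lines=_ANTI_CD20_LINES,
            efficacy_arr=eff(0.36, 0.20, 0.64, Measure.IRR_ARR),
            efficacy_cdp=UNKNOWN,
            annual_cost_first_year=3_802,
            annual_cost_subsequent=2_535,
        ),
    ]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    type_name: str
    field: str
    rule: str

    def __str__(self) -> str:
        return f"{self.type_name}.{self.field}: {self.rule}"


def validate_parameters(params: ModelParameters) -> list:
    """Check every structural invariant; return violations (never raises)."""
    v: list = []

    def bad(type_name, fld, rule):
        v.append(Violation(type_name, fld, rule))

    # --- DMTs -------------------------------------------------------------
    seen = set()
    for d in params.dmts:
        tn = f"DMTDefinition[{d.name}]"
        if d.name in seen:
            bad(tn, "name", "duplicate DMT name")
        seen.add(d.name)
        for attr in ("efficacy_arr", "efficacy_cdp"):
            est = getattr(d, attr)
            if est is UNKNOWN:
                if attr == "efficacy_arr":
                    bad(tn, attr, "relapse efficacy may not be UNKNOWN")
                continue
            if not (0 < est.ci_low <= est.point <= est.ci_high):
                bad(tn, attr, "requires 0 < ci_low <= point <= ci_high")
        if d.efficacy_arr is not UNKNOWN and d.efficacy_arr.measure is not Measure.IRR_ARR:
            bad(tn, "efficacy_arr", "measure must be IRR_ARR")
        if d.efficacy_cdp is not UNKNOWN and d.efficacy_cdp.measure is not Measure.RR_CDP:
            bad(tn, "efficacy_cdp", "measure must be RR_CDP")
        for attr in (
            "annual_cost_first_year",
            "annual_cost_subsequent",
            "admin_cost",
            "monitoring_cost",
        ):
            c = getattr(d, attr)
            if c is not None and c < 0:
                bad(tn, attr, "cost must be >= 0")
        if not (0.0 <= d.ae_discontinuation_prob <= 1.0):
            bad(tn, "ae_discontinuation_prob", "must lie in [0, 1]")
        if not d.eligible_lines:
            bad(tn, "eligible_lines", "must not be empty")

    # --- natural history --------------------------------------------------
    nh = params.natural_history
    T = nh.transition_matrix
    S = nh.n_states
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        bad("NaturalHistoryParams", "transition_matrix", "must be square")
    else:
        if (T < -1e-12).any():
            bad("NaturalHistoryParams", "transition_matrix", "entries must be >= 0")
        sums = T.sum(axis=1)
        for i, s in enumerate(sums):
            if abs(s - 1.0) > 1e-9:
                bad(
                    "NaturalHistoryParams",
                    "transition_matrix",
                    f"row {i} sums to {s:.12g}, expected 1 within 1e-9",
                )
    for fld, arr in (
        ("relapse_rate_by_edss", nh.relapse_rate_by_edss),
        ("mortality_multiplier_by_edss", nh.mortality_multiplier_by_edss),
    ):
        if arr.shape != (S,):
            bad("NaturalHistoryParams", fld, f"length must equal n_states={S}")
    if (nh.relapse_rate_by_edss < 0).any():
        bad("NaturalHistoryParams", "relapse_rate_by_edss", "rates must be >= 0")
    if (nh.mortality_multiplier_by_edss < 1.0 - 1e-12).any():
        bad("NaturalHistoryParams", "mortality_multiplier_by_edss", "multipliers must be >= 1")
    lt = nh.life_table
    if lt.shape != (MAX_AGE + 1,):
        bad("NaturalHistoryParams", "life_table", f"must hold ages 0..{MAX_AGE}")
    else:
        if (lt <= 0).any():
            bad("NaturalHistoryParams", "life_table", "hazards must be > 0")
        if (np.diff(lt[40:]) < -1e-15).any():
            bad("NaturalHistoryParams", "life_table", "hazards must be non-decreasing above age 40")

    # --- economics --------------------------------------------------------
    ec = params.economics
    if ec.utility_by_edss.shape != (S,):
        bad("EconomicParams", "utility_by_edss", f"length must equal n_states={S}")
    else:
        if (ec.utility_by_edss > 1.0).any():
            bad("EconomicParams", "utility_by_edss", "utilities must be <= 1")
        if (np.diff(ec.utility_by_edss) > 1e-12).any():
            bad("EconomicParams", "utility_by_edss", "must be non-increasing in EDSS")
    for fld in ("state_cost_healthcare_by_edss", "state_cost_societal_by_edss"):
        arr = getattr(ec, fld)
        if arr.shape != (S,):
            bad("EconomicParams", fld, f"length must equal n_states={S}")
            continue
        if (arr < 0).any():
            bad("EconomicParams", fld, "costs must be >= 0")
        if (np.diff(arr) < -1e-9).any():
            bad("EconomicParams", fld, "must be non-decreasing in EDSS")
    if ec.relapse_cost < 0:
        bad("EconomicParams", "relapse_cost", "must be >= 0")
    if ec.relapse_disutility < 0:
        bad("EconomicParams", "relapse_disutility", "must be >= 0")
    if not ec.wtp > 0:
        bad("EconomicParams", "wtp", "must be > 0")
    for fld in ("discount_rate_costs", "discount_rate_effects"):
        if getattr(ec, fld) < 0:
            bad("EconomicParams", fld, "must be >= 0")

    # --- grammar ----------------------------------------------------------
    names = {d.name for d in params.dmts}
    g = params.grammar
    for fld in ("first_line_escalation_set", "first_line_highefficacy_set", "last_resort_only"):
        unknown = set(getattr(g, fld)) - names
        if unknown:
            bad("GrammarRules", fld, f"unknown DMT names {sorted(unknown)}")
    if not (2 <= g.max_lines <= 5):
        bad("GrammarRules", "max_lines", "must lie in 2..5")

    # --- cohort -----------------------------------------------------------
    co = params.cohort
    if co.n_patients < 1:
        bad("CohortSettings", "n_patients", "must be >= 1")
    if not (0 <= co.start_age < MAX_AGE):
        bad("CohortSettings", "start_age", f"must lie in [0, {MAX_AGE})")
    lo, hi = co.baseline_edss_range
    if not (0 <= lo <= hi < S):
        bad("CohortSettings", "baseline_edss_range", "must be a state interval within 0..n_states-1")

    return v


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _efficacy_to_obj(est) -> Any:
    if est is UNKNOWN:
        return "unknown"
    return {
        "point": float(est.point),
        "ci_low": float(est.ci_low),
        "ci_high": float(est.ci_high),
    }


def _efficacy_from_obj(obj: Any, measure: Measure, where: str):
    if obj == "unknown" or obj is None:
        return UNKNOWN
    _require_keys(obj, {"point", "ci_low", "ci_high"}, where)
    return EfficacyEstimate(
        float(obj["point"]), float(obj["ci_low"]), float(obj["ci_high"]), measure
    )


def model_parameters_to_dict(params: ModelParameters) -> dict:
    """Plain-python mapping mirroring the parameter-file schema."""
    g = params.grammar
    return {
        "dmts": [
            {
                "name": d.name,
                "moa_class": d.moa_class,
                "eligible_lines": sorted(d.eligible_lines),
                "efficacy_arr": _efficacy_to_obj(d.efficacy_arr),
                "efficacy_cdp": _efficacy_to_obj(d.efficacy_cdp),
                "annual_cost_first_year": d.annual_cost_first_year,
                "annual_cost_subsequent": d.annual_cost_subsequent,
                "admin_cost": float(d.admin_cost),
                "monitoring_cost": float(d.monitoring_cost),
                "ae_discontinuation_prob": float(d.ae_discontinuation_prob),
                "synthetic": bool(d.synthetic),
            }
            for d in params.dmts
        ],
        "natural_history": {
            "transition_matrix": [
                [float(x) for x in row] for row in params.natural_history.transition_matrix
            ],
            "relapse_rate_by_edss": [float(x) for x in params.natural_history.relapse_rate_by_edss],
            "mortality_multiplier_by_edss": [
                float(x) for x in params.natural_history.mortality_multiplier_by_edss
            ],
            "life_table": [float(x) for x in params.natural_history.life_table],
        },
        "economics": {
            "utility_by_edss": [float(x) for x in params.economics.utility_by_edss],
            "relapse_disutility": float(params.economics.relapse_disutility),
            "state_cost_healthcare_by_edss": [
                float(x) for x in params.economics.state_cost_healthcare_by_edss
            ],
            "state_cost_societal_by_edss": [
                float(x) for x in params.economics.state_cost_societal_by_edss
            ],
            "relapse_cost": float(params.economics.relapse_cost),
            "wtp": float(params.economics.wtp),
            "discount_rate_costs": float(params.economics.discount_rate_costs),
            "discount_rate_effects": float(params.economics.discount_rate_effects),
        },
        "grammar": {
            "first_line_escalation_set": sorted(g.first_line_escalation_set),
            "first_line_highefficacy_set": sorted(g.first_line_highefficacy_set),
            "forbid_same_moa_consecutive": bool(g.forbid_same_moa_consecutive),
            "last_resort_only": sorted(g.last_resort_only),
            "max_lines": int(g.max_lines),
            "line1b_enabled": bool(g.line1b_enabled),
        },
        "cohort": {
            "n_patients": int(params.cohort.n_patients),
            "start_age": int(params.cohort.start_age),
            "baseline_edss_range": [int(x) for x in params.cohort.baseline_edss_range],
        },
    }


def save_model_parameters(params: ModelParameters, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(model_parameters_to_dict(params), sort_keys=False), encoding="utf-8"
    )


_DMT_KEYS = {
    "name",
    "moa_class",
    "eligible_lines",
    "efficacy_arr",
    "efficacy_cdp",
    "annual_cost_first_year",
    "annual_cost_subsequent",
    "admin_cost",
    "monitoring_cost",
    "ae_discontinuation_prob",
    "synthetic",
}
_DMT_REQUIRED = {"name", "moa_class", "eligible_lines", "efficacy_arr", "efficacy_cdp"}
_NH_KEYS = {
    "transition_matrix",
    "relapse_rate_by_edss",
    "mortality_multiplier_by_edss",
    "life_table",
}
_ECON_KEYS = {
    "utility_by_edss",
    "relapse_disutility",
    "state_cost_healthcare_by_edss",
    "state_cost_societal_by_edss",
    "relapse_cost",
    "wtp",
    "discount_rate_costs",
    "discount_rate_effects",
}
_ECON_REQUIRED = _ECON_KEYS - {"discount_rate_costs", "discount_rate_effects"}
_GRAMMAR_KEYS = {
    "first_line_escalation_set",
    "first_line_highefficacy_set",
    "forbid_same_moa_consecutive",
    "last_resort_only",
    "max_lines",
    "line1b_enabled",
}
_COHORT_KEYS = {"n_patients", "start_age", "baseline_edss_range"}


def _require_keys(obj: Mapping, required: set, where: str, allowed: set | None = None) -> None:
    if not isinstance(obj, Mapping):
        raise ParameterError(f"section {where!r} must be a mapping")
    missing = required - set(obj)
    if missing:
        raise ParameterError(f"{where}: missing required field(s) {sorted(missing)}")
    extra = set(obj) - (allowed if allowed is not None else required)
    if extra:
        raise ParameterError(f"{where}: unknown key(s) {sorted(extra)}")


def _coerce_number(x: Any, dialect: str) -> float:
    if isinstance(x, str):
        if dialect == "comma":
            x = x.replace(".", "").replace(",", ".")
        return float(x)
    return float(x)


def _coerce_seq(xs: Iterable, dialect: str) -> list:
    return [_coerce_number(x, dialect) for x in xs]


def load_model_parameters(path, dialect: str = "point") -> ModelParameters:
    """Read and fully validate a parameter file.

    ``dialect``: ``"point"`` (default) or ``"comma"`` for decimal-comma
    numbers written as strings (also applies to a sidecar transition table,
    which then uses ``;`` as delimiter).
    """
    if dialect not in ("point", "comma"):
        raise ParameterError(f"unknown dialect {dialect!r}; use 'point' or 'comma'")
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    _require_keys(
        raw, {"dmts", "natural_history", "economics", "grammar", "cohort"}, str(path)
    )

    dmts = []
    if not isinstance(raw["dmts"], Sequence):
        raise ParameterError("dmts: must be a list of DMT mappings")
    for i, obj in enumerate(raw["dmts"]):
        where = f"dmts[{i}]"
        _require_keys(obj, _DMT_REQUIRED, where, allowed=_DMT_KEYS)
        num = lambda k, default=0.0: (
            _coerce_number(obj[k], dialect) if k in obj and obj[k] is not None else default
        )
        cost = lambda k: (
            None
            if obj.get(k, None) is None
            else _coerce_number(obj[k], dialect)
        )
        dmts.append(
            DMTDefinition(
                name=str(obj["name"]),
                moa_class=str(obj["moa_class"]),
                eligible_lines=frozenset(str(x) for x in obj["eligible_lines"]),
                efficacy_arr=_efficacy_from_obj(obj["efficacy_arr"], Measure.IRR_ARR, where),
                efficacy_cdp=_efficacy_from_obj(obj["efficacy_cdp"], Measure.RR_CDP, where),
                annual_cost_first_year=cost("annual_cost_first_year"),
                annual_cost_subsequent=cost("annual_cost_subsequent"),
                admin_cost=num("admin_cost"),
                monitoring_cost=num("monitoring_cost"),
                ae_discontinuation_prob=num("ae_discontinuation_prob"),
                synthetic=bool(obj.get("synthetic", False)),
            )
        )

    nh_raw = raw["natural_history"]
    _require_keys(nh_raw, _NH_KEYS, "natural_history")
    tm = nh_raw["transition_matrix"]
    if isinstance(tm, Mapping):
        # sidecar delimited table: rows = from-EDSS, columns = to-EDSS
        _require_keys(tm, {"file"}, "natural_history.transition_matrix")
        sep = ";" if dialect == "comma" else ","
        decimal = "," if dialect == "comma" else "."
        sidecar = path.parent / str(tm["file"])
        matrix = pd.read_csv(sidecar, sep=sep, decimal=decimal, header=None).to_numpy(float)
    else:
        matrix = np.array([_coerce_seq(row, dialect) for row in tm], dtype=float)
    natural_history = NaturalHistoryParams(
        transition_matrix=matrix,
        relapse_rate_by_edss=_coerce_seq(nh_raw["relapse_rate_by_edss"], dialect),
        mortality_multiplier_by_edss=_coerce_seq(
            nh_raw["mortality_multiplier_by_edss"], dialect
        ),
        life_table=_coerce_seq(nh_raw["life_table"], dialect),
    )

    ec_raw = raw["economics"]
    _require_keys(ec_raw, _ECON_REQUIRED, "economics", allowed=_ECON_KEYS)
    economics = EconomicParams(
        utility_by_edss=_coerce_seq(ec_raw["utility_by_edss"], dialect),
        relapse_disutility=_coerce_number(ec_raw["relapse_disutility"], dialect),
        state_cost_healthcare_by_edss=_coerce_seq(
            ec_raw["state_cost_healthcare_by_edss"], dialect
        ),
        state_cost_societal_by_edss=_coerce_seq(
            ec_raw["state_cost_societal_by_edss"], dialect
        ),
        relapse_cost=_coerce_number(ec_raw["relapse_cost"], dialect),
        wtp=_coerce_number(ec_raw["wtp"], dialect),
        discount_rate_costs=_coerce_number(ec_raw.get("discount_rate_costs", 0.04), dialect),
        discount_rate_effects=_coerce_number(
            ec_raw.get("discount_rate_effects", 0.015), dialect
        ),
    )

    g_raw = raw["grammar"]
    _require_keys(g_raw, _GRAMMAR_KEYS, "grammar")
    grammar = GrammarRules(
        first_line_escalation_set=frozenset(str(x) for x in g_raw["first_line_escalation_set"]),
        first_line_highefficacy_set=frozenset(
            str(x) for x in g_raw["first_line_highefficacy_set"]
        ),
        forbid_same_moa_consecutive=bool(g_raw["forbid_same_moa_consecutive"]),
        last_resort_only=frozenset(str(x) for x in g_raw["last_resort_only"]),
        max_lines=int(g_raw["max_lines"]),
        line1b_enabled=bool(g_raw["line1b_enabled"]),
    )

    co_raw = raw["cohort"]
    _require_keys(co_raw, _COHORT_KEYS, "cohort")
    lo, hi = co_raw["baseline_edss_range"]
    cohort = CohortSettings(
        n_patients=int(co_raw["n_patients"]),
        start_age=int(co_raw["start_age"]),
        baseline_edss_range=(int(lo), int(hi)),
    )

    params = ModelParameters(
        dmts=dmts,
        natural_history=natural_history,
        economics=economics,
        grammar=grammar,
        cohort=cohort,
    )
    violations = validate_parameters(params)
    if violations:
        raise ParameterError(
            "invalid parameters:\n" + "\n".join(f"  - {x}" for x in violations)
        )
    return params
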