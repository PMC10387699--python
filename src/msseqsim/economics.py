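"""Cost and utility accrual, discounting, net health benefit, result tables.

Per annual cycle a living patient accrues

* drug acquisition cost (first-year price in the first cycle on a drug,
  subsequent-years price afterwards),
* other healthcare cost = administration + monitoring + EDSS-state
  healthcare cost + relapse cost x number of relapses,
* societal cost (productivity loss, caregiver time) from the EDSS state,
* utility = utility(EDSS) - relapse disutility x number of relapses
  (may go below zero after large decrements; no flooring).

Costs are discounted at 4%/yr and effects at 1.5%/yr by default (cycle 0
undiscounted).  Cost-effectiveness is summarized as net health benefit
NHB = QALYs - costs / lambda with lambda the willingness-to-pay per QALY.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .engine import CycleOutcome, PatientState
    from .parameters import DMTDefinition, EconomicParams

__all__ = [
    "CostBreakdown",
    "CohortResult",
    "annual_drug_cost",
    "accrue_cycle",
    "discount",
    "compute_nhb",
    "combine_by_dmt",
    "cost_reduction_percent",
    "results_table",
    "write_results_table",
]


@dataclass(frozen=True)
class CostBreakdown:
    """Discounted (or per-cycle) costs split the way the results tables are."""

    drug: float
    other_healthcare: float
    societal: float

    @property
    def total(self) -> float:
        return self.drug + self.other_healthcare + self.societal

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        return CostBreakdown(
            self.drug + other.drug,
            self.other_healthcare + other.other_healthcare,
            self.societal + other.societal,
        )

    def scaled(self, factor: float) -> "CostBreakdown":
        return CostBreakdown(
            self.drug * factor, self.other_healthcare * factor, self.societal * factor
        )


@dataclass(frozen=True)
class CohortResult:
    """Mean per-patient outcomes of one simulated cohort on one sequence."""

    costs: CostBreakdown
    qalys: float
    nhb: float
    lifetime_relapses: float
    time_to_edss6: float  # mean over patients reaching EDSS >= 6; nan if none
    fraction_reaching_edss6: float
    time_in_line1: float
    life_years: float


def annual_drug_cost(dmt, years_on_dmt: float) -> float:
    """List-price acquisition cost for one cycle on ``dmt``."""
    if years_on_dmt < 0:
        raise ValueError("years_on_dmt must be >= 0")
    cost = dmt.annual_cost_first_year if years_on_dmt < 1 else dmt.annual_cost_subsequent
    if cost is None:
        raise ValueError(
            f"{dmt.name} has no list price; supply one (e.g. via the threshold "
            "price search) before simulating"
        )
    return float(cost)


def accrue_cycle(state, outcome, dmt, econ) -> tuple:
    """Undiscounted (CostBreakdown, QALY) for one cycle.

    Uses the EDSS state occupied during the cycle (start-of-cycle state; no
    half-cycle correction).  ``dmt`` is ``None`` for off-treatment cycles.
    """
    k = outcome.n_relapses
    edss = state.edss
    if dmt is None:
        drug = 0.0
        fixed = 0.0
    else:
        drug = annual_drug_cost(dmt, state.years_on_current_dmt)
        fixed = dmt.admin_cost + dmt.monitoring_cost
    other = fixed + float(econ.state_cost_healthcare_by_edss[edss]) + econ.relapse_cost * k
    societal = float(econ.state_cost_societal_by_edss[edss])
    qaly = float(econ.utility_by_edss[edss]) - econ.relapse_disutility * k
    return CostBreakdown(drug, other, societal), qaly


def discount(value: float, rate: float, cycle_index: int) -> float:
    """``value / (1 + rate) ** cycle_index``; cycle 0 is undiscounted."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    return value / (1.0 + rate) ** cycle_index


def compute_nhb(qalys: float, total_costs: float, wtp: float) -> float:
    """Net health benefit in QALY units: ``qalys - total_costs / wtp``."""
    if wtp <= 0:
        raise ValueError("willingness-to-pay must be > 0")
    return qalys - total_costs / wtp


def combine_by_dmt(results: Sequence[CohortResult]) -> CohortResult:
    """Unweighted mean over sequences sharing an anchor drug.

    Every sequence is assumed equally likely in practice, so combined
    per-drug columns are plain arithmetic means of every field.
    """
    if not results:
        raise ValueError("combine_by_dmt needs at least one result")
    m = len(results)

    def mean(get):
        return sum(get(r) for r in results) / m

    return CohortResult(
        costs=CostBreakdown(
            mean(lambda r: r.costs.drug),
            mean(lambda r: r.costs.other_healthcare),
            mean(lambda r: r.costs.societal),
        ),
        qalys=mean(lambda r: r.qalys),
        nhb=mean(lambda r: r.nhb),
        lifetime_relapses=mean(lambda r: r.lifetime_relapses),
        time_to_edss6=mean(lambda r: r.time_to_edss6),
        fraction_reaching_edss6=mean(lambda r: r.fraction_reaching_edss6),
        time_in_line1=mean(lambda r: r.time_in_line1),
        life_years=mean(lambda r: r.life_years),
    )


def cost_reduction_percent(reference_total: float, candidate_total: float) -> float:
    """Percent cost reduction of a candidate versus a reference total."""
    if reference_total <= 0:
        raise ValueError("reference total must be > 0")
    return 100.0 * (reference_total - candidate_total) / reference_total


_TABLE_ROWS = (
    "Total costs (Euros)",
    "Drug costs (Euros)",
    "Other healthcare costs (Euros)",
    "Societal costs (Euros)",
    "Total QALYs",
    "NHB",
    "Lifetime relapses",
    "Time to EDSS 6 (years)",
    "Time in line 1 (years)",
)


def results_table(results: Mapping[str, CohortResult]) -> pd.DataFrame:
    """Publication-style table: one column per sequence, nine outcome rows.

    Euro amounts are rounded to integer Euros at reporting only; NHB is
    reported from unrounded internals.
    """
    cols = {}
    for label, r in results.items():
        cols[label] = [
            round(r.costs.total),
            round(r.costs.drug),
            round(r.costs.other_healthcare),
            round(r.costs.societal),
            round(r.qalys, 1),
            round(r.nhb, 2),
            round(r.lifetime_relapses, 1),
            round(r.time_to_edss6, 1) if not math.isnan(r.time_to_edss6) else float("nan"),
            round(r.time_in_line1, 1),
        ]
    return pd.DataFrame(cols, index=list(_TABLE_ROWS))


def write_results_table(results: Mapping[str, CohortResult], path) -> None:
    results_table(results).to_csv(Path(path), index_label="Outcome")
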