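"""Patient-level microsimulation of DMT sequences with annual cycles.

Each simulated patient starts treatment-naive at the cohort start age and is
followed in 1-year cycles until death (or the life-table end at age 100).
Within a cycle, events are resolved in a fixed order:

1. death, from the life-table hazard times the EDSS mortality multiplier
   (a patient who dies accrues nothing this cycle);
2. relapses, a Poisson count with the treatment-scaled annualized rate;
3. EDSS transition, from the natural-history row with the treatment's
   relative risk of confirmed disability progression applied to the
   aggregate worsening mass (conditional allocation among higher states
   keeps the natural-history proportions; improvement mass is untouched);
4. adverse event, a per-drug annual discontinuation probability;
5. switching: any relapse or EDSS progression advances the patient one
   treatment line (adverse events on line 1a route to the 1b branch when
   present); past the final line the patient follows natural history;
6. treatment-stopping rules: patients aged >= 50 with >= 5 event-free years
   on lines 1a/1b/2, or aged >= 70 with >= 10 event-free years on line 3,
   discontinue DMTs for good.

The relative risk scales the *rate* implied by an annual probability:
``p' = 1 - exp(RR * ln(1 - p))``, the exact annual-probability analogue of a
proportional-hazards effect.

Randomness: each cohort draws one uniform tensor ``U[patient, cycle, 4]``
(death, relapse, transition, adverse event) up front from the cohort seed,
with every patient and cycle allocated its draws whether used or not.
Patient ``i`` at cycle ``t`` therefore sees identical uniforms in every
compared arm — common random numbers for paired comparisons and threshold
searches.  Relapse counts come from the inverse Poisson CDF of a single
uniform, which makes treatment-effect comparisons monotone pathwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import economics as econmod
from .economics import CohortResult, CostBreakdown
from .grammar import SequenceSpec
from .parameters import (
    MAX_AGE,
    DMTDefinition,
    Measure,
    ModelParameters,
    UNKNOWN,
)

__all__ = [
    "OFF_TREATMENT",
    "NOT_REACHED",
    "EDSS_MILESTONE",
    "UnknownEfficacyError",
    "PatientState",
    "CycleOutcome",
    "CycleRecord",
    "Trajectory",
    "CohortDetail",
    "initialize_cohort",
    "effective_relapse_rate",
    "effective_progression_prob",
    "draw_cycle_outcome",
    "apply_switch_rules",
    "check_discontinuation",
    "simulate_patient",
    "simulate_cohort",
    "run_cohort_detail",
    "estimate_irr_from_cycles",
    "estimate_rr_cdp_from_cycles",
]

OFF_TREATMENT = -1
NOT_REACHED = float("nan")
EDSS_MILESTONE = 6  # walking-aid dependence, the model's disability milestone


class UnknownEfficacyError(ValueError):
    """A drug with unidentified progression efficacy entered a deterministic
    run; supply a trial relative risk via the threshold-analysis module."""


# ---------------------------------------------------------------------------
# Patient-level state
# ---------------------------------------------------------------------------


@dataclass
class PatientState:
    age: float
    edss: int
    alive: bool = True
    current_line_index: int = 0  # position in SequenceSpec.lines, or OFF_TREATMENT
    current_line_label: Optional[str] = None
    years_on_current_dmt: int = 0
    years_since_last_event: int = 0  # event = relapse or EDSS progression
    cumulative_relapses: int = 0
    time_to_edss6: float = NOT_REACHED
    time_in_line1: float = 0.0

    @property
    def on_treatment(self) -> bool:
        return self.alive and self.current_line_index != OFF_TREATMENT


@dataclass(frozen=True)
class CycleOutcome:
    n_relapses: int
    edss_progressed: bool
    edss_new: int
    adverse_event: bool
    died: bool


@dataclass(frozen=True)
class CycleRecord:
    cycle: int
    age: float
    edss: int
    line: Optional[str]
    costs: CostBreakdown  # discounted
    utility: float  # discounted QALY accrued this cycle


@dataclass
class Trajectory:
    records: list = field(default_factory=list)
    summary: Optional[CohortResult] = None


@dataclass
class CohortDetail:
    """Cohort summary plus the per-patient arrays behind it."""

    result: CohortResult
    qalys: np.ndarray
    cost_drug: np.ndarray
    cost_other: np.ndarray
    cost_societal: np.ndarray
    relapses: np.ndarray
    life_years: np.ndarray
    time_in_line1: np.ndarray
    time_to_edss6: np.ndarray  # nan where never reached
    drug_cost_by_position: np.ndarray  # mean discounted drug cost per line slot
    cycles: Optional[dict] = None

    @property
    def total_costs(self) -> np.ndarray:
        return self.cost_drug + self.cost_other + self.cost_societal


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def initialize_cohort(params: ModelParameters, n: int, seed: int = 0) -> list:
    """Treatment-naive patients at the start age, EDSS assigned round-robin
    over the baseline range so state counts differ by at most one.

    The assignment is deterministic; ``seed`` is accepted for interface
    symmetry and recorded nowhere else.
    """
    if n < 4:
        raise ValueError("cohort initialization needs n >= 4")
    lo, hi = params.cohort.baseline_edss_range
    states = _baseline_edss(params, n)
    return [
        PatientState(age=float(params.cohort.start_age), edss=int(s), current_line_label="1a")
        for s in states
    ]


def _baseline_edss(params: ModelParameters, n: int) -> np.ndarray:
    lo, hi = params.cohort.baseline_edss_range
    return lo + np.arange(n, dtype=np.int64) % (hi - lo + 1)


def effective_relapse_rate(base_rate: float, efficacy) -> float:
    """Annualized relapse rate scaled by an incidence rate ratio."""
    if base_rate < 0:
        raise ValueError("base relapse rate must be >= 0")
    if efficacy.measure is not Measure.IRR_ARR:
        raise ValueError("relapse scaling requires an IRR_ARR estimate")
    return base_rate * efficacy.point


def effective_progression_prob(base_annual_prob: float, efficacy) -> float:
    """Annual worsening probability under a relative risk of progression.

    Probability -> rate -> scale -> probability: ``1 - exp(RR * ln(1 - p))``.
    """
    if efficacy is UNKNOWN:
        raise UnknownEfficacyError(
            "progression efficacy is UNKNOWN; the threshold-analysis module "
            "must supply a trial relative risk"
        )
    if efficacy.measure is not Measure.RR_CDP:
        raise ValueError("progression scaling requires an RR_CDP estimate")
    if not (0.0 <= base_annual_prob < 1.0):
        raise ValueError("base annual probability must lie in [0, 1)")
    if base_annual_prob == 0.0:
        return 0.0
    return 1.0 - math.exp(efficacy.point * math.log1p(-base_annual_prob))


def _poisson_icdf(u, lam):
    """Inverse CDF of the Poisson law, vectorized.

    ``k = min{j : u < P(X <= j)}``.  Iterates the pmf recurrence; the loop
    runs ~``max(lam)`` + a few iterations (rates here are well below 1/yr).
    Cross-checked against scipy.stats.poisson.ppf in the test suite.
    """
    shape = np.broadcast(np.asarray(u), np.asarray(lam)).shape
    u = np.atleast_1d(np.asarray(u, dtype=float)).ravel()
    lam_b = np.broadcast_to(np.asarray(lam, dtype=float), shape)
    lam_b = np.atleast_1d(lam_b).ravel()
    if u.shape != lam_b.shape:
        u, lam_b = np.broadcast_arrays(u, lam_b)
        u, lam_b = u.ravel(), lam_b.ravel()
    out = np.zeros(u.shape, dtype=np.int64)
    pmf = np.exp(-lam_b)
    cdf = pmf.copy()
    active = u >= cdf
    k = 0
    while active.any():
        k += 1
        if k > 400:  # unreachable for the rates this model uses
            out[active] += 1
            break
        pmf = pmf * lam_b / k
        cdf = cdf + pmf
        out[active] += 1
        active = u >= cdf
    return out.reshape(shape) if shape else out[0]


def _adjusted_row(T: np.ndarray, s: int, rr: float) -> np.ndarray:
    """Natural-history transition row with RR applied to the worsening mass.

    The relative risk rescales the aggregate probability of any EDSS
    worsening (rate scaling); conditional on worsening, the allocation among
    higher states keeps the natural-history proportions.  The stay
    probability absorbs the difference; improvement mass is untouched.
    """
    row = np.asarray(T[s], dtype=float).copy()
    if rr == 1.0:
        return row
    w = row[s + 1 :].sum()
    if w <= 0.0:
        return row
    if w >= 1.0:
        w_new = 1.0
    else:
        w_new = 1.0 - math.exp(rr * math.log1p(-w))
    # guard: an RR > 1 may not push worsening beyond stay+worsen mass
    w_new = min(w_new, w + row[s])
    row[s + 1 :] *= w_new / w
    row[s] = max(0.0, 1.0 - row[:s].sum() - row[s + 1 :].sum())
    return row


def _transition_cum(params: ModelParameters, rr: float) -> np.ndarray:
    """Cumulative treated transition rows, one per EDSS state."""
    T = params.natural_history.transition_matrix
    S = T.shape[0]
    rows = np.empty((S, S))
    for s in range(S):
        rows[s] = _adjusted_row(T, s, rr)
    return np.cumsum(rows, axis=1)


def _dmt_rr(dmt: DMTDefinition) -> float:
    if dmt.efficacy_cdp is UNKNOWN:
        raise UnknownEfficacyError(
            f"{dmt.name}: relative risk of disability progression is UNKNOWN; "
            "use the threshold-analysis module to supply a trial value"
        )
    return dmt.efficacy_cdp.point


def draw_cycle_outcome(state: PatientState, dmt, params: ModelParameters, rng) -> CycleOutcome:
    """One patient-cycle: death, relapses, EDSS transition, adverse event.

    ``dmt=None`` means natural-history rates unscaled.  Consumes exactly four
    uniforms in the engine's fixed order, so scalar and vectorized paths see
    the same stream.
    """
    if not state.alive:
        raise ValueError("cannot draw a cycle for a dead patient")
    u = rng.random(4)
    nh = params.natural_history
    hazard = nh.life_table[min(int(state.age), MAX_AGE)] * nh.mortality_multiplier_by_edss[
        state.edss
    ]
    if u[0] < 1.0 - math.exp(-hazard):
        return CycleOutcome(0, False, state.edss, False, died=True)
    base = float(nh.relapse_rate_by_edss[state.edss])
    lam = base if dmt is None else effective_relapse_rate(base, dmt.efficacy_arr)
    k = int(_poisson_icdf(u[1], lam))
    rr = 1.0 if dmt is None else _dmt_rr(dmt)
    cum = np.cumsum(_adjusted_row(nh.transition_matrix, state.edss, rr))
    edss_new = int(np.searchsorted(cum, u[2], side="right"))
    edss_new = min(edss_new, nh.n_states - 1)
    ae = dmt is not None and u[3] < dmt.ae_discontinuation_prob
    return CycleOutcome(
        n_relapses=k,
        edss_progressed=edss_new > state.edss,
        edss_new=edss_new,
        adverse_event=ae,
        died=False,
    )


def apply_switch_rules(
    state: PatientState, outcome: CycleOutcome, seq: SequenceSpec, rules=None
) -> PatientState:
    """Advance the treatment line after a cycle's events (mutates ``state``).

    Relapse or EDSS progression advances one line (from 1a it skips the 1b
    branch).  An adverse event alone on line 1a enters line 1b when the
    sequence has one; elsewhere it advances one line.  Beyond the final line
    the patient is off treatment for good.
    """
    if not state.alive:
        raise ValueError("cannot switch a dead patient")
    efficacy_event = outcome.n_relapses > 0 or outcome.edss_progressed
    event = efficacy_event or outcome.adverse_event
    if efficacy_event:
        state.years_since_last_event = 0
    else:
        state.years_since_last_event += 1
    if state.current_line_index == OFF_TREATMENT:
        return state
    pos = state.current_line_index
    if not event:
        state.years_on_current_dmt += 1
        return state
    if seq.has_line1b and pos == 0:
        new = 1 if (outcome.adverse_event and not efficacy_event) else 2
    else:
        new = pos + 1
    state.current_line_index = new if new < len(seq.lines) else OFF_TREATMENT
    state.current_line_label = (
        seq.line_label(state.current_line_index)
        if state.current_line_index != OFF_TREATMENT
        else None
    )
    state.years_on_current_dmt = 0
    return state


def check_discontinuation(state: PatientState) -> bool:
    """Permanent DMT stop: age >= 50 with >= 5 event-free years on lines
    1a/1b/2, or age >= 70 with >= 10 event-free years on line 3."""
    if not state.alive or state.current_line_index == OFF_TREATMENT:
        return False
    label = state.current_line_label
    if label in ("1a", "1b", "2"):
        return state.age >= 50 and state.years_since_last_event >= 5
    if label == "3":
        return state.age >= 70 and state.years_since_last_event >= 10
    return False


# ---------------------------------------------------------------------------
# Scalar patient loop (reference path; the cohort loop below is vectorized)
# ---------------------------------------------------------------------------


def simulate_patient(
    seq: Optional[SequenceSpec], params: ModelParameters, rng, edss0: Optional[int] = None
) -> Trajectory:
    """Simulate one patient; deterministic given the generator state.

    Consumes uniforms in the same layout as the vectorized cohort loop, so a
    one-patient cohort with the same seed reproduces this trajectory.
    """
    n_cycles = MAX_AGE - params.cohort.start_age
    u = np.asarray(rng.random((n_cycles, 4)))
    return _simulate_patient_from_uniforms(seq, params, u, edss0=edss0)


class _ReplayStream:
    """Feed a fixed (n_cycles, 4) uniform block through the rng interface."""

    def __init__(self, u: np.ndarray):
        self._flat = np.asarray(u, dtype=float).ravel()
        self._i = 0

    def random(self, size=None):
        if size is None:
            size = 1
        k = int(np.prod(size))
        out = self._flat[self._i : self._i + k]
        self._i += k
        return out.reshape(size)


def _simulate_patient_from_uniforms(
    seq: Optional[SequenceSpec],
    params: ModelParameters,
    u: np.ndarray,
    edss0: Optional[int] = None,
) -> Trajectory:
    ec = params.economics
    start_age = params.cohort.start_age
    state = PatientState(
        age=float(start_age),
        edss=int(params.cohort.baseline_edss_range[0] if edss0 is None else edss0),
        current_line_index=0 if seq is not None and len(seq.lines) > 0 else OFF_TREATMENT,
    )
    if seq is not None and state.current_line_index == 0:
        state.current_line_label = seq.line_label(0)
    if state.edss >= EDSS_MILESTONE:
        state.time_to_edss6 = 0.0
    stream = _ReplayStream(u)
    traj = Trajectory()
    disc_costs = CostBreakdown(0.0, 0.0, 0.0)
    disc_qaly = 0.0
    life_years = 0.0
    n_cycles = MAX_AGE - start_age
    for t in range(n_cycles):
        dmt = (
            params.dmt(seq.lines[state.current_line_index])
            if seq is not None and state.current_line_index != OFF_TREATMENT
            else None
        )
        outcome = draw_cycle_outcome(state, dmt, params, stream)
        if outcome.died:
            state.alive = False
            break
        cost, qaly = econmod.accrue_cycle(state, outcome, dmt, ec)
        dcost = CostBreakdown(
            econmod.discount(cost.drug, ec.discount_rate_costs, t),
            econmod.discount(cost.other_healthcare, ec.discount_rate_costs, t),
            econmod.discount(cost.societal, ec.discount_rate_costs, t),
        )
        dq = econmod.discount(qaly, ec.discount_rate_effects, t)
        disc_costs = disc_costs + dcost
        disc_qaly += dq
        life_years += 1.0
        state.cumulative_relapses += outcome.n_relapses
        if state.current_line_label in ("1a", "1b"):
            state.time_in_line1 += 1.0
        traj.records.append(
            CycleRecord(t, state.age, state.edss, state.current_line_label, dcost, dq)
        )
        if math.isnan(state.time_to_edss6) and outcome.edss_new >= EDSS_MILESTONE:
            state.time_to_edss6 = float(t + 1)
        state.edss = outcome.edss_new
        state.age += 1.0
        if seq is not None:
            apply_switch_rules(state, outcome, seq)
            if check_discontinuation(state):
                state.current_line_index = OFF_TREATMENT
                state.current_line_label = None
        else:
            # natural history: still track event-free years for symmetry
            if outcome.n_relapses > 0 or outcome.edss_progressed:
                state.years_since_last_event = 0
            else:
                state.years_since_last_event += 1
    reached = not math.isnan(state.time_to_edss6)
    traj.summary = CohortResult(
        costs=disc_costs,
        qalys=disc_qaly,
        nhb=econmod.compute_nhb(disc_qaly, disc_costs.total, ec.wtp),
        lifetime_relapses=float(state.cumulative_relapses),
        time_to_edss6=state.time_to_edss6 if reached else NOT_REACHED,
        fraction_reaching_edss6=1.0 if reached else 0.0,
        time_in_line1=state.time_in_line1,
        life_years=life_years,
    )
    return traj


# ---------------------------------------------------------------------------
# Vectorized cohort loop
# ---------------------------------------------------------------------------


class _SeqTables:
    """Per-line-slot lookup tables; slot L (one past the last line) is
    off-treatment natural history."""

    def __init__(self, seq: Optional[SequenceSpec], params: ModelParameters):
        nh = params.natural_history
        S = nh.n_states
        lines = () if seq is None else seq.lines
        L = len(lines)
        self.L = L
        dmts = [params.dmt(name) for name in lines]
        labels = list(seq.line_labels()) if seq is not None else []
        self.lam = np.empty((L + 1, S))
        self.cum = np.empty((L + 1, S, S))
        self.ae = np.zeros(L + 1)
        self.cost_first = np.zeros(L + 1)
        self.cost_sub = np.zeros(L + 1)
        self.fixed = np.zeros(L + 1)
        base_rate = nh.relapse_rate_by_edss
        for j, d in enumerate(dmts):
            self.lam[j] = base_rate * d.efficacy_arr.point
            self.cum[j] = _transition_cum(params, _dmt_rr(d))
            self.ae[j] = d.ae_discontinuation_prob
            self.cost_first[j] = econmod.annual_drug_cost(d, 0)
            self.cost_sub[j] = econmod.annual_drug_cost(d, 1)
            self.fixed[j] = d.admin_cost + d.monitoring_cost
        self.lam[L] = base_rate
        self.cum[L] = _transition_cum(params, 1.0)
        labels_arr = labels + [None]
        self.is_line1 = np.array([lab in ("1a", "1b") for lab in labels_arr])
        self.disc_g1 = np.array([lab in ("1a", "1b", "2") for lab in labels_arr])
        self.disc_g3 = np.array([lab == "3" for lab in labels_arr])
        nxt_ev = np.arange(L + 1) + 1
        nxt_ae = nxt_ev.copy()
        if seq is not None and seq.has_line1b and L >= 1:
            nxt_ae[0] = 1
            nxt_ev[0] = 2
            if L >= 2:
                nxt_ev[1] = 2
                nxt_ae[1] = 2
        self.next_event = np.minimum(nxt_ev, L)
        self.next_ae = np.minimum(nxt_ae, L)
        self.next_event[L] = L
        self.next_ae[L] = L


def run_cohort_detail(
    seq: Optional[SequenceSpec],
    params: ModelParameters,
    n: Optional[int] = None,
    seed: int = 0,
    collect_cycles: bool = False,
) -> CohortDetail:
    """Simulate a cohort and keep per-patient outcome arrays.

    ``seq=None`` runs untreated natural history.  ``seed`` may be an int or
    a sequence of ints (entropy for the cohort's random stream).
    """
    nh = params.natural_history
    ec = params.economics
    S = nh.n_states
    if n is None:
        n = params.cohort.n_patients
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    start_age = params.cohort.start_age
    n_cycles = MAX_AGE - start_age
    tab = _SeqTables(seq, params)
    L = tab.L

    entropy = [int(seed)] if np.isscalar(seed) else [int(x) for x in seed]
    rng = np.random.default_rng(np.random.SeedSequence(entropy))
    U = rng.random((n, n_cycles, 4))

    # age x state death probability (hazard = life table x EDSS multiplier)
    ages = np.arange(start_age, MAX_AGE)
    p_death = 1.0 - np.exp(
        -nh.life_table[ages][:, None] * nh.mortality_multiplier_by_edss[None, :]
    )
    disc_c = (1.0 + ec.discount_rate_costs) ** -np.arange(n_cycles)
    disc_e = (1.0 + ec.discount_rate_effects) ** -np.arange(n_cycles)
    util = ec.utility_by_edss
    hc_cost = ec.state_cost_healthcare_by_edss
    soc_cost = ec.state_cost_societal_by_edss

    edss = _baseline_edss(params, n).astype(np.int64)
    pos = np.full(n, 0 if L > 0 else L, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    yrs_on = np.zeros(n, dtype=np.int64)
    yrs_since = np.zeros(n, dtype=np.int64)

    acc_drug = np.zeros(n)
    acc_other = np.zeros(n)
    acc_soc = np.zeros(n)
    acc_qaly = np.zeros(n)
    relapses = np.zeros(n, dtype=np.int64)
    life_years = np.zeros(n)
    time_line1 = np.zeros(n)
    t_edss6 = np.full(n, np.nan)
    t_edss6[edss >= EDSS_MILESTONE] = 0.0
    drug_by_pos = np.zeros(L + 1)

    cyc_patient: list = []
    cyc_t: list = []
    cyc_pos: list = []
    cyc_edss: list = []
    cyc_k: list = []
    cyc_prog: list = []

    for t in range(n_cycles):
        if not alive.any():
            break
        u0 = U[:, t, 0]
        u1 = U[:, t, 1]
        u2 = U[:, t, 2]
        u3 = U[:, t, 3]

        dies = alive & (u0 < p_death[t, edss])
        alive = alive & ~dies
        if not alive.any():
            break

        lam = tab.lam[pos, edss]
        k = _poisson_icdf(u1, lam)
        k[~alive] = 0

        cumrow = tab.cum[pos, edss]  # (n, S)
        new_edss = np.minimum((u2[:, None] >= cumrow).sum(axis=1), S - 1)
        new_edss = np.where(alive, new_edss, edss)
        progressed = new_edss > edss

        on_trt = pos < L
        ae = alive & on_trt & (u3 < tab.ae[pos])

        # ---- economics (state occupied during the cycle = start state) ----
        drug = np.where(
            alive & on_trt,
            np.where(yrs_on == 0, tab.cost_first[pos], tab.cost_sub[pos]),
            0.0,
        )
        other = np.where(alive, hc_cost[edss] + ec.relapse_cost * k, 0.0)
        other += np.where(alive & on_trt, tab.fixed[pos], 0.0)
        soc = np.where(alive, soc_cost[edss], 0.0)
        qaly = np.where(alive, util[edss] - ec.relapse_disutility * k, 0.0)

        acc_drug += disc_c[t] * drug
        acc_other += disc_c[t] * other
        acc_soc += disc_c[t] * soc
        acc_qaly += disc_e[t] * qaly
        if L > 0:
            drug_by_pos += disc_c[t] * np.bincount(
                pos, weights=drug, minlength=L + 1
            )
        life_years += alive
        time_line1 += alive & tab.is_line1[pos]
        relapses += k

        if collect_cycles:
            m = alive
            cyc_patient.append(np.flatnonzero(m))
            cyc_t.append(np.full(int(m.sum()), t, dtype=np.int32))
            cyc_pos.append(pos[m].astype(np.int16))
            cyc_edss.append(edss[m].astype(np.int16))
            cyc_k.append(k[m].astype(np.int32))
            cyc_prog.append(progressed[m])

        newly6 = alive & np.isnan(t_edss6) & (new_edss >= EDSS_MILESTONE)
        t_edss6[newly6] = t + 1

        # ---- switching and stopping rules ---------------------------------
        eff_event = (k > 0) | progressed
        any_event = eff_event | ae
        yrs_since = np.where(alive & eff_event, 0, yrs_since + alive.astype(np.int64))

        switch = alive & on_trt & any_event
        to_1b = switch & (pos == 0) & ae & ~eff_event
        if seq is None or not seq.has_line1b:
            to_1b &= False
        new_pos = pos.copy()
        new_pos[switch] = tab.next_event[pos[switch]]
        new_pos[to_1b] = tab.next_ae[pos[to_1b]]
        yrs_on = np.where(switch, 0, yrs_on + (alive & on_trt).astype(np.int64))

        age_next = start_age + t + 1
        still_on = new_pos < L
        stop = alive & still_on & (
            (tab.disc_g1[new_pos] & (age_next >= 50) & (yrs_since >= 5))
            | (tab.disc_g3[new_pos] & (age_next >= 70) & (yrs_since >= 10))
        )
        new_pos[stop] = L

        pos = new_pos
        edss = new_edss

    total = acc_drug + acc_other + acc_soc
    reached = ~np.isnan(t_edss6)
    result = CohortResult(
        costs=CostBreakdown(
            float(acc_drug.mean()), float(acc_other.mean()), float(acc_soc.mean())
        ),
        qalys=float(acc_qaly.mean()),
        nhb=econmod.compute_nhb(float(acc_qaly.mean()), float(total.mean()), ec.wtp),
        lifetime_relapses=float(relapses.mean()),
        time_to_edss6=float(t_edss6[reached].mean()) if reached.any() else NOT_REACHED,
        fraction_reaching_edss6=float(reached.mean()),
        time_in_line1=float(time_line1.mean()),
        life_years=float(life_years.mean()),
    )
    cycles = None
    if collect_cycles:
        cycles = {
            "patient": np.concatenate(cyc_patient) if cyc_patient else np.empty(0, np.int64),
            "cycle": np.concatenate(cyc_t) if cyc_t else np.empty(0, np.int32),
            "position": np.concatenate(cyc_pos) if cyc_pos else np.empty(0, np.int16),
            "edss": np.concatenate(cyc_edss) if cyc_edss else np.empty(0, np.int16),
            "n_relapses": np.concatenate(cyc_k) if cyc_k else np.empty(0, np.int32),
            "progressed": np.concatenate(cyc_prog) if cyc_prog else np.empty(0, bool),
        }
    return CohortDetail(
        result=result,
        qalys=acc_qaly,
        cost_drug=acc_drug,
        cost_other=acc_other,
        cost_societal=acc_soc,
        relapses=relapses.astype(float),
        life_years=life_years,
        time_in_line1=time_line1,
        time_to_edss6=t_edss6,
        drug_cost_by_position=drug_by_pos / n,
        cycles=cycles,
    )


def simulate_cohort(
    seq: Optional[SequenceSpec],
    params: ModelParameters,
    n: Optional[int] = None,
    seed: int = 0,
) -> CohortResult:
    """Mean discounted costs/QALYs/NHB and health outcomes for one sequence.

    Deterministic: identical (seq, params, n, seed) give a bit-identical
    result.
    """
    return run_cohort_detail(seq, params, n=n, seed=seed).result


# ---------------------------------------------------------------------------
# Effect recovery from pooled patient-cycles (model diagnostics)
# ---------------------------------------------------------------------------


def estimate_irr_from_cycles(
    cycles: dict, params: ModelParameters, position: int = 0
) -> tuple:
    """Recover the incidence rate ratio from on-line patient-cycles.

    Ratio of observed relapses to the natural-history expectation over the
    same cycles; 95% CI from the Poisson count.  Returns (irr, (lo, hi)).
    """
    m = cycles["position"] == position
    if not m.any():
        raise ValueError(f"no patient-cycles at line position {position}")
    k = float(cycles["n_relapses"][m].sum())
    expected = float(
        params.natural_history.relapse_rate_by_edss[cycles["edss"][m]].sum()
    )
    irr = k / expected
    half = 1.96 / math.sqrt(k) if k > 0 else float("inf")
    return irr, (irr * (1 - half), irr * (1 + half))


def estimate_rr_cdp_from_cycles(
    cycles: dict, params: ModelParameters, position: int = 0
) -> tuple:
    """Recover the relative risk of progression from on-line patient-cycles.

    Maximum likelihood under the engine's own hazard link: a cycle at state
    ``s`` worsens with probability ``1 - exp(-RR * r_s)`` where ``r_s`` is
    the natural-history worsening rate ``-ln(1 - w_s)``.  95% CI from the
    event count.  Returns (rr, (lo, hi)).
    """
    from scipy.optimize import brentq

    T = params.natural_history.transition_matrix
    S = T.shape[0]
    w = np.array([T[s, s + 1 :].sum() for s in range(S)])
    r_by_state = -np.log1p(-np.minimum(w, 1 - 1e-12))
    m = (cycles["position"] == position) & (r_by_state[cycles["edss"]] > 0)
    if not m.any():
        raise ValueError(f"no informative patient-cycles at line position {position}")
    r = r_by_state[cycles["edss"][m]]
    y = cycles["progressed"][m]
    n_events = int(y.sum())
    if n_events == 0:
        raise ValueError("no progression events observed; cannot estimate RR")

    def score(rr):
        e = np.exp(-rr * r[y])
        return float((r[y] * e / (1.0 - e)).sum() - r[~y].sum())

    rr_hat = brentq(score, 1e-4, 50.0)
    half = 1.96 / math.sqrt(n_events)
    return rr_hat, (rr_hat * (1 - half), rr_hat * (1 + half))
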