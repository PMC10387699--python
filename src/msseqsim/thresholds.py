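"""Threshold searches: cost-neutral price and efficacy-parity relative risk.

Two questions the deterministic model can answer by search:

* at which annual list price does a candidate drug's best sequence reach
  the same net health benefit (NHB) as a reference sequence? (a drug
  awaiting registration, whose price is unknown);
* at which relative risk of confirmed disability progression does a
  candidate whose progression efficacy is unidentified reach NHB parity?
  (an off-label drug priced far below the registered alternatives).

Parity is defined under common random numbers: the candidate and reference
cohorts reuse identical patient streams, otherwise Monte-Carlo noise swamps
the search.  The drug price enters the simulation only through linear cost
accrual — trajectories do not depend on it — so NHB(price) is exactly
affine under a fixed seed and one cohort run at unit price determines the
whole line; the bisection then runs on that exact function and its trace is
kept.  NHB(RR) does change the dynamics, so the RR search re-simulates at
every trial value.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

from .economics import CohortResult, CostBreakdown, compute_nhb
from .engine import run_cohort_detail
from .grammar import SequenceSpec, enumerate_sequences
from .parameters import DMTDefinition, ModelParameters, UNKNOWN

__all__ = [
    "ThresholdResult",
    "BracketError",
    "find_threshold_price",
    "find_threshold_rr",
    "round_price_to_hundred",
    "reference_nhb_for",
]

DEFAULT_TOL = 0.005  # NHB tolerance, QALY units


class BracketError(RuntimeError):
    """NHB parity is unreachable on the search bracket."""

    def __init__(self, message: str, trace):
        super().__init__(message)
        self.trace = trace


@dataclass
class ThresholdResult:
    variable: str  # "annual_price" or "rr_cdp"
    threshold_value: float
    rounded_value: float
    reference_nhb: float
    candidate_nhb_at_threshold: float
    candidate_summary: CohortResult
    search_trace: list = field(default_factory=list)  # (trial value, NHB)
    candidate_sequence: Optional[SequenceSpec] = None

    def report(self) -> str:
        unit = "EUR/yr" if self.variable == "annual_price" else ""
        lines = [
            f"threshold variable : {self.variable}",
            f"threshold value    : {self.threshold_value:.4f} {unit}".rstrip(),
            f"reported (rounded) : {self.rounded_value:g} {unit}".rstrip(),
            f"reference NHB      : {self.reference_nhb:.4f}",
            f"candidate NHB      : {self.candidate_nhb_at_threshold:.4f}",
            f"candidate drug costs (lifetime, discounted) : "
            f"{self.candidate_summary.costs.drug:,.0f}",
            f"candidate total costs (lifetime, discounted): "
            f"{self.candidate_summary.costs.total:,.0f}",
            f"candidate QALYs    : {self.candidate_summary.qalys:.2f}",
            "trace:",
        ]
        lines += [f"  {v:.6g} -> NHB {nhb:.5f}" for v, nhb in self.search_trace]
        return "\n".join(lines)


def round_price_to_hundred(price: float) -> float:
    """Prices are reported to the nearest 100 Euro."""
    return round(price / 100.0) * 100.0


def reference_nhb_for(
    seq: SequenceSpec, params: ModelParameters, n: Optional[int] = None, seed: int = 0
) -> float:
    """Deterministic NHB of a reference sequence (same seed policy as the
    searches: common random numbers)."""
    return run_cohort_detail(seq, params, n=n, seed=seed).result.nhb


def _pick_candidate_sequence(
    candidate: DMTDefinition,
    anchor_line: str,
    params: ModelParameters,
    n: Optional[int],
    seed: int,
    score_params: ModelParameters,
) -> SequenceSpec:
    """Highest-NHB enumerated sequence holding the candidate at the anchor
    line, scored under neutral candidate assumptions."""
    seqs = enumerate_sequences(
        candidate.name, anchor_line, score_params.dmts, score_params.grammar
    )
    if not seqs:
        raise ValueError(
            f"no valid sequence holds {candidate.name} at line {anchor_line}"
        )
    if len(seqs) == 1:
        return seqs[0]
    scored = [
        (run_cohort_detail(s, score_params, n=n, seed=seed).result.nhb, s.label, s)
        for s in seqs
    ]
    scored.sort(key=lambda x: (-x[0], x[1]))
    return scored[0][2]


def _bisect(f, lo: float, hi: float, tol: float, trace, max_iter: int = 60):
    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        raise BracketError(
            f"no NHB-parity sign change on bracket [{lo:g}, {hi:g}] "
            f"(f={f_lo:+.4f} / {f_hi:+.4f})",
            list(trace),
        )
    mid = 0.5 * (lo + hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if abs(f_mid) <= tol:
            return mid
        if f_lo * f_mid <= 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    return mid


def find_threshold_price(
    candidate: DMTDefinition,
    anchor_line: str,
    reference_nhb: float,
    params: ModelParameters,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
    *,
    n: Optional[int] = None,
    candidate_sequence: Optional[SequenceSpec] = None,
    reference_price: Optional[float] = None,
    flat_price: bool = False,
) -> ThresholdResult:
    """Annual first-year price at which the candidate's sequence matches the
    reference NHB.

    The candidate's first-year/subsequent-year cost ratio is preserved while
    the price scales (``flat_price=True`` applies one flat annual price
    instead).  The bracket is [0, 2 x reference price]; ``reference_price``
    defaults to the highest known first-year price among drugs of the
    candidate's mode-of-action class.  The rounded value reports the price
    to the nearest 100 Euro.
    """
    if candidate.efficacy_cdp is UNKNOWN:
        raise ValueError(
            f"{candidate.name}: progression efficacy must be specified for a "
            "price search (use find_threshold_rr for unidentified efficacy)"
        )
    if reference_price is None:
        peers = [
            d.annual_cost_first_year
            for d in params.dmts
            if d.moa_class == candidate.moa_class
            and d.name != candidate.name
            and d.annual_cost_first_year is not None
        ]
        if not peers:
            raise ValueError(
                "no priced drug of the same class found; pass reference_price"
            )
        reference_price = float(max(peers))

    if (
        flat_price
        or candidate.annual_cost_first_year in (None, 0)
        or candidate.annual_cost_subsequent is None
    ):
        ratio = 1.0
    else:
        ratio = candidate.annual_cost_subsequent / candidate.annual_cost_first_year

    unit_candidate = candidate.with_annual_price(1.0, ratio)
    trial_params = params.replace_dmt(unit_candidate)
    if candidate_sequence is None:
        score_params = params.replace_dmt(
            candidate.with_annual_price(reference_price, reference_price * ratio)
        )
        candidate_sequence = _pick_candidate_sequence(
            candidate, anchor_line, params, n, seed, score_params
        )

    detail = run_cohort_detail(candidate_sequence, trial_params, n=n, seed=seed)
    anchor_pos = candidate_sequence.lines.index(candidate.name)
    unit_drug_cost = float(detail.drug_cost_by_position[anchor_pos])
    base_cost = detail.result.costs.total - unit_drug_cost  # all but candidate drug
    qalys = detail.result.qalys
    wtp = params.economics.wtp

    trace: list = []

    def f(price: float) -> float:
        nhb = compute_nhb(qalys, base_cost + price * unit_drug_cost, wtp)
        trace.append((price, nhb))
        return nhb - reference_nhb

    threshold = _bisect(f, 0.0, 2.0 * reference_price, tol, trace)

    costs = CostBreakdown(
        drug=detail.result.costs.drug - unit_drug_cost + threshold * unit_drug_cost,
        other_healthcare=detail.result.costs.other_healthcare,
        societal=detail.result.costs.societal,
    )
    summary = dataclasses.replace(
        detail.result, costs=costs, nhb=compute_nhb(qalys, costs.total, wtp)
    )
    return ThresholdResult(
        variable="annual_price",
        threshold_value=threshold,
        rounded_value=round_price_to_hundred(threshold),
        reference_nhb=reference_nhb,
        candidate_nhb_at_threshold=summary.nhb,
        candidate_summary=summary,
        search_trace=trace,
        candidate_sequence=candidate_sequence,
    )


def find_threshold_rr(
    candidate: DMTDefinition,
    anchor_line: str,
    reference_nhb: float,
    params: ModelParameters,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
    *,
    n: Optional[int] = None,
    candidate_sequence: Optional[SequenceSpec] = None,
    bracket: tuple = (0.2, 1.2),
) -> ThresholdResult:
    """Relative risk of disability progression at which the candidate's
    sequence matches the reference NHB.

    Intended for drugs whose progression efficacy is unidentified but whose
    costs are known.  Bisection over the RR bracket under common random
    numbers; the threshold is reported to two decimals.
    """
    if candidate.annual_cost_first_year is None:
        raise ValueError(f"{candidate.name}: costs must be known for an RR search")

    trace: list = []
    last: dict = {}

    if candidate_sequence is None:
        mid_rr = 0.5 * (bracket[0] + bracket[1])
        score_params = params.replace_dmt(candidate.with_cdp(mid_rr))
        candidate_sequence = _pick_candidate_sequence(
            candidate, anchor_line, params, n, seed, score_params
        )

    def f(rr: float) -> float:
        trial = params.replace_dmt(candidate.with_cdp(rr))
        detail = run_cohort_detail(candidate_sequence, trial, n=n, seed=seed)
        last["detail"] = detail
        last["rr"] = rr
        trace.append((rr, detail.result.nhb))
        return detail.result.nhb - reference_nhb

    threshold = _bisect(f, bracket[0], bracket[1], tol, trace)
    if last.get("rr") != threshold:
        f(threshold)
    summary = last["detail"].result
    return ThresholdResult(
        variable="rr_cdp",
        threshold_value=threshold,
        rounded_value=round(threshold, 2),
        reference_nhb=reference_nhb,
        candidate_nhb_at_threshold=summary.nhb,
        candidate_summary=summary,
        search_trace=trace,
        candidate_sequence=candidate_sequence,
    )
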