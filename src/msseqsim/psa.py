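"""Probabilistic sensitivity analysis.

Input parameters are sampled from their uncertainty distributions —
simultaneously for both compared arms, so each iteration applies one joint
parameter draw — and the paired cohorts are run with common random numbers.

Distribution families (standard health-economic practice):

* ratio parameters (IRR of relapses, RR of progression): lognormal with
  median equal to the point estimate and ``sigma = (ln hi - ln lo) / (2 *
  1.96)`` so the 2.5/97.5 percentiles match the published 95% CI;
* utilities: beta, moment-matched to (mean, se):
  ``a + b = m (1 - m) / se^2 - 1``, ``a = m (a + b)`` (a normal fallback is
  used for states whose mean utility is outside (0, 1), where a beta law is
  undefined);
* costs and relapse rates: gamma, moment-matched via the coefficient of
  variation: ``shape = 1 / cv^2``, ``scale = mean * cv^2``.

Sampled utilities are re-sorted non-increasing and state costs
non-decreasing so each draw respects the model's structural monotonicity.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .economics import CohortResult, compute_nhb
from .engine import run_cohort_detail
from .grammar import SequenceSpec
from .parameters import (
    EfficacyEstimate,
    ModelParameters,
    UNKNOWN,
)

__all__ = [
    "PSAUncertainty",
    "PSAIteration",
    "PSAResult",
    "sample_efficacy",
    "collapse_uncertainty",
    "run_psa",
    "ce_probability",
    "export_ce_plane",
]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class PSAUncertainty:
    """Spread parameters for inputs whose CIs are not published."""

    utility_se: float = 0.03
    cost_cv: float = 0.10
    relapse_rate_cv: float = 0.10


def sample_efficacy(est: EfficacyEstimate, rng: np.random.Generator) -> float:
    """One lognormal draw with median = point and 95% range = [ci_low, ci_high]."""
    if est is UNKNOWN:
        raise ValueError("cannot sample an UNKNOWN efficacy estimate")
    if est.degenerate:
        return est.point
    sigma = (np.log(est.ci_high) - np.log(est.ci_low)) / (2.0 * _Z95)
    return float(np.exp(rng.normal(np.log(est.point), sigma)))


def _sample_beta(mean: float, se: float, rng: np.random.Generator) -> float:
    if se <= 0:
        return mean
    if not (0.0 < mean < 1.0):
        return float(rng.normal(mean, se))  # beta undefined; documented fallback
    var = min(se**2, mean * (1 - mean) * 0.99)
    ab = mean * (1 - mean) / var - 1.0
    a = mean * ab
    b = (1 - mean) * ab
    return float(rng.beta(a, b))


def _sample_gamma(mean: float, cv: float, rng: np.random.Generator) -> float:
    if cv <= 0 or mean <= 0:
        return mean
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, mean * cv**2))


def collapse_uncertainty(params: ModelParameters) -> ModelParameters:
    """Copy with every efficacy CI collapsed to its point estimate."""
    dmts = []
    for d in params.dmts:
        arr = EfficacyEstimate.certain(d.efficacy_arr.point, d.efficacy_arr.measure)
        cdp = (
            UNKNOWN
            if d.efficacy_cdp is UNKNOWN
            else EfficacyEstimate.certain(d.efficacy_cdp.point, d.efficacy_cdp.measure)
        )
        dmts.append(dataclasses.replace(d, efficacy_arr=arr, efficacy_cdp=cdp))
    return dataclasses.replace(params, dmts=dmts)


def _sample_params(
    params: ModelParameters, unc: PSAUncertainty, rng: np.random.Generator
) -> ModelParameters:
    """One joint draw of the model's uncertain inputs (shared by both arms)."""
    dmts = []
    for d in params.dmts:
        arr = EfficacyEstimate.certain(
            sample_efficacy(d.efficacy_arr, rng), d.efficacy_arr.measure
        )
        cdp = (
            UNKNOWN
            if d.efficacy_cdp is UNKNOWN
            else EfficacyEstimate.certain(
                sample_efficacy(d.efficacy_cdp, rng), d.efficacy_cdp.measure
            )
        )
        dmts.append(dataclasses.replace(d, efficacy_arr=arr, efficacy_cdp=cdp))

    ec = params.economics
    util = np.array([_sample_beta(m, unc.utility_se, rng) for m in ec.utility_by_edss])
    util = np.minimum(np.sort(util)[::-1], 1.0)  # keep non-increasing in EDSS
    hc = np.sort(
        [_sample_gamma(m, unc.cost_cv, rng) for m in ec.state_cost_healthcare_by_edss]
    )
    soc = np.sort(
        [_sample_gamma(m, unc.cost_cv, rng) for m in ec.state_cost_societal_by_edss]
    )
    econ = dataclasses.replace(
        ec,
        utility_by_edss=util,
        state_cost_healthcare_by_edss=np.asarray(hc),
        state_cost_societal_by_edss=np.asarray(soc),
        relapse_cost=_sample_gamma(ec.relapse_cost, unc.cost_cv, rng),
    )
    nh = dataclasses.replace(
        params.natural_history,
        relapse_rate_by_edss=np.array(
            [
                _sample_gamma(m, unc.relapse_rate_cv, rng)
                for m in params.natural_history.relapse_rate_by_edss
            ]
        ),
    )
    return dataclasses.replace(params, dmts=dmts, economics=econ, natural_history=nh)


@dataclass(frozen=True)
class PSAIteration:
    sampled_params_digest: str
    result_a: CohortResult
    result_b: CohortResult

    @property
    def delta_qaly(self) -> float:
        return self.result_a.qalys - self.result_b.qalys

    @property
    def delta_cost(self) -> float:
        return self.result_a.costs.total - self.result_b.costs.total


@dataclass
class PSAResult:
    iterations: list
    wtp: float
    seed: int
    cohort_n: int

    @property
    def delta_qalys(self) -> np.ndarray:
        return np.array([it.delta_qaly for it in self.iterations])

    @property
    def delta_costs(self) -> np.ndarray:
        return np.array([it.delta_cost for it in self.iterations])

    @property
    def p_a_more_qalys(self) -> float:
        d = self.delta_qalys
        return float(((d > 0).sum() + 0.5 * (d == 0).sum()) / d.size)

    def p_a_cost_effective_at(self, wtp: float) -> float:
        return ce_probability(self, wtp)

    def arm_summary(self, arm: str) -> dict:
        """Mean, binomial-free SE and 2.5/97.5 percentiles of costs and QALYs."""
        getter = (lambda it: it.result_a) if arm == "a" else (lambda it: it.result_b)
        costs = np.array([getter(it).costs.total for it in self.iterations])
        qalys = np.array([getter(it).qalys for it in self.iterations])
        out = {}
        for name, x in (("costs", costs), ("qalys", qalys)):
            out[name] = {
                "mean": float(x.mean()),
                "se": float(x.std(ddof=1)) if x.size > 1 else 0.0,
                "p2.5": float(np.percentile(x, 2.5)),
                "p97.5": float(np.percentile(x, 97.5)),
            }
        return out


def run_psa(
    seq_a: SequenceSpec,
    seq_b: SequenceSpec,
    params: ModelParameters,
    n_iterations: int = 500,
    cohort_n: int = 1_000,
    seed: int = 0,
    uncertainty: PSAUncertainty = PSAUncertainty(),
    common_random_numbers: bool = True,
    vary_cohort_streams: bool = True,
) -> PSAResult:
    """Paired PSA of two sequences.

    Per iteration one joint parameter draw is applied to both arms and both
    cohorts run with common random numbers (identical patient streams), so
    iteration-level differences isolate parameter uncertainty.
    ``common_random_numbers=False`` gives each arm an independent stream
    (used for null-calibration checks); ``vary_cohort_streams=False`` reuses
    the base seed's stream in every iteration.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    iterations = []
    for i in range(n_iterations):
        prng = np.random.default_rng(np.random.SeedSequence([int(seed), 101, i]))
        drawn = _sample_params(params, uncertainty, prng)
        digest = hashlib.sha1(
            repr(
                [(d.name, d.efficacy_arr.point, getattr(d.efficacy_cdp, "point", None))
                 for d in drawn.dmts]
            ).encode()
        ).hexdigest()[:12]
        cseed_a = [int(seed), 202, i] if vary_cohort_streams else [int(seed)]
        if common_random_numbers:
            cseed_b = cseed_a
        else:
            cseed_b = [int(seed), 203, i] if vary_cohort_streams else [int(seed), 203]
        ra = run_cohort_detail(seq_a, drawn, n=cohort_n, seed=cseed_a).result
        rb = run_cohort_detail(seq_b, drawn, n=cohort_n, seed=cseed_b).result
        iterations.append(PSAIteration(digest, ra, rb))
    return PSAResult(
        iterations=iterations,
        wtp=params.economics.wtp,
        seed=int(seed),
        cohort_n=cohort_n,
    )


def ce_probability(result: PSAResult, wtp: float) -> float:
    """Fraction of iterations where arm A has positive incremental net
    health benefit at ``wtp``; ties count one half."""
    if not result.iterations:
        raise ValueError("PSA result holds no iterations")
    if wtp <= 0:
        raise ValueError("willingness-to-pay must be > 0")
    inhb = result.delta_qalys - result.delta_costs / wtp
    return float(((inhb > 0).sum() + 0.5 * (inhb == 0).sum()) / inhb.size)


def ce_probability_se(result: PSAResult, wtp: float) -> float:
    """Binomial standard error of the acceptability estimate (no smoothing)."""
    p = ce_probability(result, wtp)
    m = len(result.iterations)
    return float(np.sqrt(p * (1 - p) / m))


def export_ce_plane(result: PSAResult, path) -> None:
    """Write the cost-effectiveness plane: a delimited table of incremental
    (QALY, cost) pairs plus a rendered scatter with the WTP line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    dq, dc = result.delta_qalys, result.delta_costs
    lines = ["delta_qaly,delta_cost"]
    lines += [f"{float(q)!r},{float(c)!r}" for q, c in zip(dq, dc)]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(dq, dc, s=8, alpha=0.5, color="tab:blue")
    span = max(1e-9, float(np.abs(dq).max()) * 1.1)
    xs = np.linspace(-span, span, 2)
    ax.plot(xs, result.wtp * xs, "k--", lw=1, label=f"WTP €{result.wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental costs (€)")
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    fig.savefig(path.with_suffix(".png"), dpi=150)
    plt.close(fig)
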