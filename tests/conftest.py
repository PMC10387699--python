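import dataclasses

import numpy as np
import pytest

from msseqsim.grammar import GrammarRules, SequenceSpec
from msseqsim.parameters import (
    CohortSettings,
    EconomicParams,
    ModelParameters,
    NaturalHistoryParams,
    MAX_AGE,
)
from msseqsim.synthetic import ScenarioSpec, generate_synthetic_params


@pytest.fixture(scope="session")
def default_params() -> ModelParameters:
    return generate_synthetic_params(ScenarioSpec())


@pytest.fixture(scope="session")
def ocr_first_line() -> SequenceSpec:
    return SequenceSpec(lines=("OCR", "CLA", "NAT", "ALE"))


@pytest.fixture(scope="session")
def ofa_first_line() -> SequenceSpec:
    return SequenceSpec(lines=("OFA", "CLA", "NAT", "ALE"))


def make_toy_params(
    start_age: int = 29,
    hazard: float = 0.01,
    relapse_rates=(0.5, 0.4, 0.3),
    worsen=(0.10, 0.08),
) -> ModelParameters:
    """Three-state natural-history-only model, small enough for an exact
    Markov-cohort computation."""
    T = np.array(
        [
            [1.0 - worsen[0], worsen[0] * 0.8, worsen[0] * 0.2],
            [0.02, 0.98 - worsen[1], worsen[1]],
            [0.0, 0.02, 0.98],
        ]
    )
    nh = NaturalHistoryParams(
        transition_matrix=T,
        relapse_rate_by_edss=np.array(relapse_rates),
        mortality_multiplier_by_edss=np.array([1.0, 1.2, 1.5]),
        life_table=np.full(MAX_AGE + 1, hazard),
    )
    econ = EconomicParams(
        utility_by_edss=np.array([0.9, 0.7, 0.5]),
        relapse_disutility=0.05,
        state_cost_healthcare_by_edss=np.array([1000.0, 2000.0, 4000.0]),
        state_cost_societal_by_edss=np.array([500.0, 1500.0, 3000.0]),
        relapse_cost=2000.0,
        wtp=50_000.0,
    )
    return ModelParameters(
        dmts=[],
        natural_history=nh,
        economics=econ,
        grammar=GrammarRules(),
        cohort=CohortSettings(n_patients=1000, start_age=start_age, baseline_edss_range=(0, 2)),
    )
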