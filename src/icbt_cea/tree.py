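"""Short-term decision tree: acceptance -> compliance -> program response.

Both strategies offer the same low-intensity CBT program; they differ in the
delivery channel (guided internet platform vs in-person sessions), hence in
acceptance, compliance, program cost, and — through a relative-effectiveness
multiplier — possibly in the treated recovery probability.  The tree is
resolved instantaneously at time zero and yields the state distribution
entering the Markov model plus the program cost incurred per student offered
the strategy.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .params import ModelConfig, ParameterSet

__all__ = ["Strategy", "InitialDistribution", "program_cost",
           "treatment_probability", "initial_distribution"]

_MASS_TOL = 1e-12


class Strategy(str, Enum):
    """The two delivery strategies under comparison."""

    INTERNET = "internet"
    IN_PERSON = "in_person"


@dataclass(frozen=True)
class InitialDistribution:
    """State probabilities entering the Markov model, plus program cost."""

    p_well: float
    p_mild: float
    p_moderate: float
    p_severe: float
    program_cost: float

    def __post_init__(self) -> None:
        masses = (self.p_well, self.p_mild, self.p_moderate, self.p_severe)
        if min(masses) < -_MASS_TOL:
            raise ValueError(f"negative state probability in {masses}")
        if abs(sum(masses) - 1.0) > 1e-9:
            raise ValueError(f"state probabilities sum to {sum(masses)!r}, not 1")
        if self.program_cost < 0:
            raise ValueError("negative program cost")

    def occupancy(self) -> np.ndarray:
        """Occupancy vector over (well, mild, moderate, severe, dead)."""
        return np.array([self.p_well, self.p_mild, self.p_moderate,
                         self.p_severe, 0.0])


def program_cost(strategy: Strategy, params: ParameterSet) -> float:
    """Per-participant cost of one low-intensity CBT course.

    In-person: sessions x session-hours x therapist hourly rate.  Internet:
    the same therapist cost scaled by the guided-CBT time share, plus the
    platform overhead.
    """
    in_person = params.sessions_low * (params.minutes_low / 60.0) * params.therapist_hourly
    if Strategy(strategy) is Strategy.IN_PERSON:
        return in_person
    return in_person * params.therapist_time_share_internet + params.platform_overhead


def treatment_probability(strategy: Strategy, params: ParameterSet) -> float:
    """Probability that an offered student accepts and completes the program."""
    if Strategy(strategy) is Strategy.INTERNET:
        return params.accept_internet * params.comply_internet
    return params.accept_inperson * params.comply_inperson


def _acceptance(strategy: Strategy, params: ParameterSet) -> float:
    return (params.accept_internet if Strategy(strategy) is Strategy.INTERNET
            else params.accept_inperson)


def initial_distribution(strategy: Strategy, params: ParameterSet,
                         config: ModelConfig | None = None) -> InitialDistribution:
    """Resolve the decision tree into a Markov entry distribution.

    Students who accept and comply receive the program outcome probabilities
    (recovery scaled by the relative-effectiveness multiplier in the internet
    arm, capped at 1); everyone else — decliners and non-compliers alike —
    receives the no-intervention outcomes.  Deteriorated mass splits between
    moderate and severe by ``prop_moderate_among_modsev``; the remainder of
    the non-recovered mass stays mild.  Program cost is charged per accepter
    (or per complier, by configuration), independent of outcome.
    """
    config = config or ModelConfig()
    strategy = Strategy(strategy)
    p_treat = treatment_probability(strategy, params)
    recovery_treated = params.recovery_low_cbt
    if strategy is Strategy.INTERNET:
        recovery_treated = min(recovery_treated * params.rel_effect_internet, 1.0)
    det_treated = min(params.deterioration_low_cbt, 1.0 - recovery_treated)

    p_well = p_treat * recovery_treated + (1.0 - p_treat) * params.recovery_none
    p_det = p_treat * det_treated + (1.0 - p_treat) * params.deterioration_none
    p_moderate = p_det * params.prop_moderate_among_modsev
    p_severe = p_det - p_moderate
    p_mild = 1.0 - p_well - p_det

    payers = (_acceptance(strategy, params)
              if config.program_cost_payers == "accepters" else p_treat)
    return InitialDistribution(
        p_well=p_well, p_mild=p_mild, p_moderate=p_moderate, p_severe=p_severe,
        program_cost=payers * program_cost(strategy, params))
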