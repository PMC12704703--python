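"""Individual-level Monte Carlo simulator of the identical decision model.

Simulates single students through the acceptance/compliance/response tree
and the monthly Markov transitions, with school-dropout event times and the
same accrual conventions as the cohort engine.  Serves as a brute-force
oracle: by the law of large numbers its sample means must agree with the
cohort engine's expectations within Monte Carlo error, for any valid
parameter set and any configuration — both engines read the same
:class:`~icbt_cea.params.ModelConfig`, so structural switches cannot drift
apart.

Hospitalization while severe is drawn as a Bernoulli event per cycle
(expected cost matches the cohort engine's per-cycle expectation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import HealthState, _transition_matrices, _utility_vector, discount_factor
from .params import ModelConfig, ParameterSet
from .tree import Strategy, initial_distribution, program_cost

__all__ = ["IndividualTrajectory", "MicrosimEstimates",
           "simulate_individual", "simulate_cohort"]


@dataclass(frozen=True)
class IndividualTrajectory:
    """One simulated student: state path, dropout time, discounted accruals."""

    states: np.ndarray          # (horizon+1,) HealthState codes
    dropout_cycle: int | None
    cost: float
    qaly: float

    def to_frame(self) -> pd.DataFrame:
        cycles = np.arange(self.states.shape[0])
        return pd.DataFrame({
            "cycle": cycles,
            "state": [HealthState(s).name.lower() for s in self.states],
            "in_school": (cycles < self.dropout_cycle) if self.dropout_cycle
            is not None else np.ones_like(cycles, dtype=bool),
        })


@dataclass(frozen=True)
class MicrosimEstimates:
    """Sample means with Monte Carlo standard errors for one strategy."""

    n: int
    mean_cost: float
    se_cost: float
    mean_qaly: float
    se_qaly: float
    dropout_fraction: float
    se_dropout: float
    final_state_counts: np.ndarray  # (5,) counts at the horizon


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    n = x.shape[0]
    se = float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return float(x.mean()), se


def _simulate(strategy: Strategy, params: ParameterSet, n: int,
              rng: np.random.Generator, config: ModelConfig,
              record_paths: bool = False):
    strategy = Strategy(strategy)
    horizon = int(round(params.horizon_months))
    rate = params.discount_annual
    pa = {k: np.atleast_1d(np.asarray(v, float)) for k, v in params.items()}
    matrix = _transition_matrices(pa, config)[0]
    cum_matrix = np.cumsum(matrix, axis=1)
    u_state = _utility_vector(pa, config)[0]

    # --- decision tree -----------------------------------------------------
    if strategy is Strategy.INTERNET:
        acc, comp = params.accept_internet, params.comply_internet
    else:
        acc, comp = params.accept_inperson, params.comply_inperson
    accepted = rng.random(n) < acc
    treated = accepted & (rng.random(n) < comp)

    init = initial_distribution(strategy, params, config)
    # branch-specific response probabilities (treated vs no-intervention)
    rec_t = params.recovery_low_cbt
    if strategy is Strategy.INTERNET:
        rec_t = min(rec_t * params.rel_effect_internet, 1.0)
    det_t = min(params.deterioration_low_cbt, 1.0 - rec_t)
    p_well = np.where(treated, rec_t, params.recovery_none)
    p_det = np.where(treated, det_t, params.deterioration_none)
    p_mod = p_det * params.prop_moderate_among_modsev
    u = rng.random(n)
    states = np.full(n, int(HealthState.MILD))
    states[u < p_well] = int(HealthState.WELL)
    well_or_mild = p_well + (1.0 - p_well - p_det)
    states[(u >= well_or_mild) & (u < well_or_mild + p_mod)] = int(HealthState.MODERATE)
    states[u >= well_or_mild + p_mod] = int(HealthState.SEVERE)

    payers = accepted if config.program_cost_payers == "accepters" else treated
    cost = np.where(payers, program_cost(strategy, params), 0.0)
    qaly = np.zeros(n)
    in_school = np.ones(n, dtype=bool)
    dropout_cycle = np.full(n, -1)

    hazard_by_state = np.array([params.dropout_monthly_well,
                                params.dropout_monthly_dep,
                                params.dropout_monthly_dep,
                                params.dropout_monthly_dep, 0.0])
    charged = np.zeros(5, dtype=bool)
    charged[[HealthState.MODERATE, HealthState.SEVERE]] = True
    if config.outpatient_states == "all_symptomatic":
        charged[HealthState.MILD] = True
    stepup = np.zeros(5, dtype=bool)
    stepup[[HealthState.MODERATE, HealthState.SEVERE]] = True
    if config.step_up_cbt_charge == "entries_all_symptomatic":
        stepup[HealthState.MILD] = True
    hi_course = (params.sessions_high * params.minutes_high / 60.0
                 * params.therapist_hourly)

    if record_paths:
        paths = np.empty((horizon + 1, n), dtype=np.int8)
        paths[0] = states

    def month_cost(st: np.ndarray, hosp_event: np.ndarray,
                   stepup_charge: np.ndarray) -> np.ndarray:
        return (params.outpatient_monthly * charged[st]
                + params.hosp_episode_cost * hosp_event + stepup_charge)

    for t in range(horizon):
        d0 = float(discount_factor(t, rate))
        d1 = float(discount_factor(t + 1, rate))
        prev_states = states
        if config.dropout_stops_accrual:
            active_start = in_school.copy()
        else:
            active_start = prev_states != int(HealthState.DEAD)

        # permanent school dropout (state-specific hazard; alive only —
        # the dead row hazard is zero)
        drops = in_school & (rng.random(n) < hazard_by_state[prev_states])
        dropout_cycle[drops] = t
        in_school = in_school & ~drops

        # monthly transition, sampled from the shared matrix rows
        u_t = rng.random(n)
        states = np.empty_like(prev_states)
        for s in range(5):
            mask = prev_states == s
            if mask.any():
                states[mask] = np.searchsorted(cum_matrix[s], u_t[mask],
                                               side="right")
        if config.dropout_stops_accrual:
            active_end = in_school
        else:
            active_end = states != int(HealthState.DEAD)

        if config.step_up_cbt_charge != "none":
            entered = stepup[states] & ~stepup[prev_states]
            if t == 0:
                entered = entered | stepup[prev_states]
            stepup_charge = hi_course * entered
        else:
            stepup_charge = np.zeros(n)
        hosp_start = ((prev_states == int(HealthState.SEVERE))
                      & (rng.random(n) < params.hosp_monthly_severe))
        hosp_end = ((states == int(HealthState.SEVERE))
                    & (rng.random(n) < params.hosp_monthly_severe))

        if config.accrual_timing == "cycle_start":
            c = month_cost(prev_states, hosp_start, stepup_charge)
            cost[active_start] += c[active_start] * d0
            qaly[active_start] += u_state[prev_states[active_start]] / 12.0 * d0
        elif config.accrual_timing == "cycle_end":
            c = month_cost(states, hosp_end, stepup_charge)
            cost[active_end] += c[active_end] * d1
            qaly[active_end] += u_state[states[active_end]] / 12.0 * d1
        else:  # half_cycle: average of the two accrual conventions
            c0 = month_cost(prev_states, hosp_start, stepup_charge)
            c1 = month_cost(states, hosp_end, np.zeros(n))
            cost[active_start] += 0.5 * c0[active_start] * d0
            cost[active_end] += 0.5 * c1[active_end] * d1
            qaly[active_start] += 0.5 * u_state[prev_states[active_start]] / 12.0 * d0
            qaly[active_end] += 0.5 * u_state[states[active_end]] / 12.0 * d1

        if record_paths:
            paths[t + 1] = states

    out = dict(cost=cost, qaly=qaly, dropped=dropout_cycle >= 0,
               dropout_cycle=dropout_cycle, final_states=states)
    if record_paths:
        out["paths"] = paths
    return out


def simulate_individual(strategy: Strategy, params: ParameterSet, seed: int,
                        config: ModelConfig | None = None) -> IndividualTrajectory:
    """Simulate a single student's trajectory; reproducible given ``seed``."""
    config = config or ModelConfig()
    rng = np.random.default_rng(seed)
    res = _simulate(strategy, params, 1, rng, config, record_paths=True)
    drop = int(res["dropout_cycle"][0])
    return IndividualTrajectory(states=res["paths"][:, 0].astype(int),
                                dropout_cycle=None if drop < 0 else drop,
                                cost=float(res["cost"][0]),
                                qaly=float(res["qaly"][0]))


def simulate_cohort(strategy: Strategy, params: ParameterSet, n: int,
                    seed: int | np.random.Generator,
                    config: ModelConfig | None = None) -> MicrosimEstimates:
    """Simulate ``n`` students and summarize with Monte Carlo standard errors.

    Uses one cohort-level random stream (vectorized across individuals), so
    results are reproducible given ``seed`` but individual k is not stable
    across different ``n``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    config = config or ModelConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    res = _simulate(strategy, params, n, rng, config)
    mean_cost, se_cost = _mean_se(res["cost"])
    mean_qaly, se_qaly = _mean_se(res["qaly"])
    dropped = res["dropped"].astype(float)
    frac, se_frac = _mean_se(dropped)
    counts = np.bincount(res["final_states"], minlength=5)
    return MicrosimEstimates(n=n, mean_cost=mean_cost, se_cost=se_cost,
                             mean_qaly=mean_qaly, se_qaly=se_qaly,
                             dropout_fraction=frac, se_dropout=se_frac,
                             final_state_counts=counts)
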