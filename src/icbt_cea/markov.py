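"""Monthly Markov cohort engine over a 5-year horizon.

Health states are well/remission, mild, moderate, and severe depressive
symptoms, and all-cause death (absorbing).  School dropout is a permanent
side event with a state-specific monthly hazard; the engine tracks the joint
(health state x in-school) occupancy exactly, so that cost/QALY accrual can
be restricted to students still enrolled without biasing the comparison
against an individual-level simulation.

All heavy lifting is done by a vectorized batch core that evaluates ``n``
parameter sets at once (used by the probabilistic and two-way sensitivity
analyses); the scalar API wraps the same code at ``n = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Mapping

import numpy as np
import pandas as pd

from .params import ModelConfig, ParameterSet
from .tree import InitialDistribution, Strategy, initial_distribution

__all__ = ["HealthState", "TransitionModel", "CohortTrace", "StrategyOutcome",
           "build_transition_model", "discount_factor", "run_cohort",
           "run_strategy", "run_strategy_batch"]

_ROW_TOL = 1e-12


class HealthState(IntEnum):
    WELL = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3
    DEAD = 4


_SYMPTOMATIC = (HealthState.MILD, HealthState.MODERATE, HealthState.SEVERE)


@dataclass(frozen=True)
class TransitionModel:
    """Row-stochastic monthly transition matrix over the five health states."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (5, 5):
            raise ValueError(f"transition matrix shape {m.shape}, expected (5, 5)")
        if np.any(m < -_ROW_TOL):
            raise ValueError("negative transition probability")
        if np.max(np.abs(m.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("transition matrix rows must sum to 1")
        if not np.allclose(m[HealthState.DEAD], np.eye(5)[HealthState.DEAD]):
            raise ValueError("death must be absorbing")

    def probability(self, src: HealthState, dst: HealthState) -> float:
        return float(self.matrix[src, dst])


@dataclass(frozen=True)
class StrategyOutcome:
    """Discounted totals for one strategy at one parameter set."""

    strategy: str
    total_cost: float
    total_qaly: float
    dropout_prob: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.total_cost, self.total_qaly, self.dropout_prob]).all():
            raise ValueError("non-finite strategy outcome")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError(f"dropout probability {self.dropout_prob} outside [0, 1]")


@dataclass(frozen=True)
class CohortTrace:
    """Cycle-by-cycle cohort history (cycles 0..horizon).

    ``occupancy`` covers the whole cohort (in school or not); ``in_school``
    is the sub-occupancy still enrolled; ``cum_dropout[t]`` is the
    probability of having permanently left university by the start of cycle
    t.  ``disc_cost``/``disc_qaly`` hold one discounted accrual per cycle.
    """

    occupancy: np.ndarray      # (horizon+1, 5)
    in_school: np.ndarray      # (horizon+1, 5)
    cum_dropout: np.ndarray    # (horizon+1,)
    disc_cost: np.ndarray      # (horizon,)
    disc_qaly: np.ndarray      # (horizon,)
    program_cost: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format export, one row per cycle."""
        horizon = self.disc_cost.shape[0]
        cols = {f"p_{s.name.lower()}": self.occupancy[:, s] for s in HealthState}
        cols.update({f"in_school_{s.name.lower()}": self.in_school[:, s]
                     for s in HealthState})
        frame = pd.DataFrame({"cycle": np.arange(horizon + 1), **cols,
                              "cum_dropout": self.cum_dropout})
        frame["disc_cost"] = np.concatenate([[self.program_cost], self.disc_cost])
        frame["disc_qaly"] = np.concatenate([[0.0], self.disc_qaly])
        return frame


def discount_factor(cycle: int | np.ndarray, annual_rate: float) -> float | np.ndarray:
    """Discount factor (1 + r)^(-cycle/12) for a monthly cycle index."""
    if annual_rate <= -1.0:
        raise ValueError(f"annual discount rate {annual_rate} must exceed -1")
    return (1.0 + annual_rate) ** (-np.asarray(cycle, dtype=float) / 12.0)


# ---------------------------------------------------------------------------
# Batch building blocks (leading axis = parameter draw)
# ---------------------------------------------------------------------------

def _as_arrays(params: Mapping[str, float]) -> dict[str, np.ndarray]:
    return {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in params.items()}


def _severity_mix(pa: Mapping[str, np.ndarray]) -> np.ndarray:
    """(n, 3) mild/moderate/severe composition of relapse (and of the
    redistributed symptomatic mass in ``relapse_proportions`` mode)."""
    mild = pa["prop_mild_relapse"]
    mod = (1.0 - mild) * pa["prop_moderate_among_modsev"]
    return np.stack([mild, mod, 1.0 - mild - mod], axis=-1)


def _transition_matrices(pa: Mapping[str, np.ndarray], config: ModelConfig) -> np.ndarray:
    n = pa["relapse_monthly"].shape[0]
    mix = _severity_mix(pa)
    mort_well = pa["mortality_monthly"]
    mort_dep = np.minimum(pa["mortality_monthly"] * pa["rr_mortality_depressed"], 1.0)
    relapse, remission = pa["relapse_monthly"], pa["remission_monthly"]

    m = np.zeros((n, 5, 5))
    stay_well = 1.0 - relapse - mort_well
    if np.any(stay_well < -_ROW_TOL):
        raise ValueError("relapse + mortality exceed 1 in the well state")
    m[:, HealthState.WELL, HealthState.WELL] = stay_well
    m[:, HealthState.WELL, HealthState.DEAD] = mort_well
    m[:, HealthState.WELL, 1:4] = relapse[:, None] * mix

    residual = 1.0 - remission - mort_dep
    if np.any(residual < -_ROW_TOL):
        raise ValueError("remission + mortality exceed 1 in a symptomatic state")
    for s in _SYMPTOMATIC:
        m[:, s, HealthState.WELL] = remission
        m[:, s, HealthState.DEAD] = mort_dep
        if config.severity_mix == "relapse_proportions":
            m[:, s, 1:4] = residual[:, None] * mix
        else:  # tree: severities persist, no lateral moves
            m[:, s, s] = residual
    m[:, HealthState.DEAD, HealthState.DEAD] = 1.0
    return m


def _utility_vector(pa: Mapping[str, np.ndarray], config: ModelConfig) -> np.ndarray:
    u_well = (pa["utility_remission"] if config.well_utility_source == "remission"
              else pa["utility_age"])
    return np.stack([u_well, pa["utility_mild"], pa["utility_moderate"],
                     pa["utility_severe"], np.zeros_like(u_well)], axis=-1)


def build_transition_model(params: ParameterSet,
                           config: ModelConfig | None = None) -> TransitionModel:
    """Scalar transition matrix for one parameter set."""
    config = config or ModelConfig()
    return TransitionModel(_transition_matrices(_as_arrays(params), config)[0])


def _charged_states(config: ModelConfig) -> tuple[HealthState, ...]:
    if config.outpatient_states == "all_symptomatic":
        return _SYMPTOMATIC
    return (HealthState.MODERATE, HealthState.SEVERE)


def _stepup_states(config: ModelConfig) -> tuple[HealthState, ...]:
    if config.step_up_cbt_charge == "entries_all_symptomatic":
        return _SYMPTOMATIC
    return (HealthState.MODERATE, HealthState.SEVERE)


def _run_batch(init_occ: np.ndarray, matrices: np.ndarray,
               pa: Mapping[str, np.ndarray], config: ModelConfig,
               record_trace: bool = False):
    """Propagate the joint (state x in-school) occupancy and accrue outcomes.

    ``init_occ``: (n, 5) entry distribution (everyone starts enrolled).
    Returns total discounted cost (excluding program cost), QALYs, cumulative
    dropout probability — each (n,) — plus optional trace arrays.
    """
    n = init_occ.shape[0]
    horizon = int(round(float(pa["horizon_months"][0])))
    rate = float(pa["discount_annual"][0])
    u = _utility_vector(pa, config)                       # (n, 5)

    hazard = np.zeros((n, 5))
    hazard[:, HealthState.WELL] = pa["dropout_monthly_well"]
    for s in _SYMPTOMATIC:
        hazard[:, s] = pa["dropout_monthly_dep"]

    charged = list(_charged_states(config))
    stepup = list(_stepup_states(config))
    non_stepup = [s for s in HealthState if s not in stepup and s != HealthState.DEAD]
    hi_course = (pa["sessions_high"] * pa["minutes_high"] / 60.0
                 * pa["therapist_hourly"])

    occ_in = init_occ.copy()
    occ_out = np.zeros_like(occ_in)
    cost = np.zeros(n)
    qaly = np.zeros(n)

    if record_trace:
        occ_hist = np.empty((horizon + 1, 5));  occ_hist[0] = occ_in[0] + occ_out[0]
        in_hist = np.empty((horizon + 1, 5));   in_hist[0] = occ_in[0]
        drop_hist = np.empty(horizon + 1);      drop_hist[0] = 0.0
        cost_hist = np.empty(horizon);          qaly_hist = np.empty(horizon)

    def cycle_cost(occ: np.ndarray, entries: np.ndarray) -> np.ndarray:
        c = pa["outpatient_monthly"] * occ[:, charged].sum(axis=1)
        c = c + (pa["hosp_monthly_severe"] * pa["hosp_episode_cost"]
                 * occ[:, HealthState.SEVERE])
        if config.step_up_cbt_charge != "none":
            c = c + hi_course * entries
        return c

    for t in range(horizon):
        d0 = discount_factor(t, rate)
        d1 = discount_factor(t + 1, rate)
        leavers = occ_in * hazard
        stay_in = occ_in - leavers
        new_in = np.einsum("ns,nst->nt", stay_in, matrices)
        new_out = np.einsum("ns,nst->nt", occ_out + leavers, matrices)

        accrual_pop_start = occ_in if config.dropout_stops_accrual else occ_in + occ_out
        accrual_pop_end = new_in if config.dropout_stops_accrual else new_in + new_out
        # mass newly entering the stepped-up states during this cycle (initial
        # occupants of those states at t = 0 count as entries as well)
        pop_for_entries = stay_in if config.dropout_stops_accrual else stay_in + occ_out
        entries = np.einsum("ns,nst->nt", pop_for_entries[:, non_stepup],
                            matrices[:, non_stepup, :])[:, stepup].sum(axis=1)
        if t == 0 and config.step_up_cbt_charge != "none":
            entries = entries + accrual_pop_start[:, stepup].sum(axis=1)

        if config.accrual_timing == "cycle_start":
            c = cycle_cost(accrual_pop_start, entries) * d0
            q = (accrual_pop_start * u).sum(axis=1) / 12.0 * d0
        elif config.accrual_timing == "cycle_end":
            c = cycle_cost(accrual_pop_end, entries) * d1
            q = (accrual_pop_end * u).sum(axis=1) / 12.0 * d1
        else:  # half_cycle
            c = 0.5 * (cycle_cost(accrual_pop_start, entries) * d0
                       + cycle_cost(accrual_pop_end, entries) * d1)
            q = 0.5 * ((accrual_pop_start * u).sum(axis=1) / 12.0 * d0
                       + (accrual_pop_end * u).sum(axis=1) / 12.0 * d1)
        cost += c
        qaly += q
        occ_in, occ_out = new_in, new_out

        if record_trace:
            occ_hist[t + 1] = occ_in[0] + occ_out[0]
            in_hist[t + 1] = occ_in[0]
            drop_hist[t + 1] = occ_out[0].sum()
            cost_hist[t] = c[0]
            qaly_hist[t] = q[0]

        total = occ_in.sum(axis=1) + occ_out.sum(axis=1)
        if np.max(np.abs(total - 1.0)) > 1e-9:
            raise FloatingPointError("cohort occupancy drifted away from 1")

    dropout = occ_out.sum(axis=1)
    if record_trace:
        trace_arrays = (occ_hist, in_hist, drop_hist, cost_hist, qaly_hist)
        return cost, qaly, dropout, trace_arrays
    return cost, qaly, dropout, None


def run_cohort(init: InitialDistribution, tm: TransitionModel,
               params: ParameterSet, config: ModelConfig | None = None) -> CohortTrace:
    """Run the cohort model from an explicit entry distribution, with trace."""
    config = config or ModelConfig()
    pa = _as_arrays(params)
    cost, qaly, dropout, trace = _run_batch(
        init.occupancy()[None, :], tm.matrix[None, :, :], pa, config,
        record_trace=True)
    occ_hist, in_hist, drop_hist, cost_hist, qaly_hist = trace
    return CohortTrace(occupancy=occ_hist, in_school=in_hist,
                       cum_dropout=drop_hist, disc_cost=cost_hist,
                       disc_qaly=qaly_hist, program_cost=init.program_cost)


def run_strategy(strategy: Strategy, params: ParameterSet,
                 config: ModelConfig | None = None) -> StrategyOutcome:
    """Decision tree + cohort model for one strategy; deterministic totals."""
    config = config or ModelConfig()
    init = initial_distribution(strategy, params, config)
    tm = build_transition_model(params, config)
    trace = run_cohort(init, tm, params, config)
    return StrategyOutcome(strategy=Strategy(strategy).value,
                           total_cost=init.program_cost + float(trace.disc_cost.sum()),
                           total_qaly=float(trace.disc_qaly.sum()),
                           dropout_prob=float(trace.cum_dropout[-1]))


def run_strategy_batch(strategy: Strategy, pa: Mapping[str, np.ndarray],
                       config: ModelConfig | None = None
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized tree + cohort evaluation over ``n`` parameter draws.

    ``pa`` maps every parameter name to an (n,) array.  Returns
    (total_cost, total_qaly, dropout_prob) arrays.
    """
    config = config or ModelConfig()
    strategy = Strategy(strategy)
    if strategy is Strategy.INTERNET:
        acc, comp = pa["accept_internet"], pa["comply_internet"]
        rec = np.minimum(pa["recovery_low_cbt"] * pa["rel_effect_internet"], 1.0)
    else:
        acc, comp = pa["accept_inperson"], pa["comply_inperson"]
        rec = pa["recovery_low_cbt"]
    p_treat = acc * comp
    det = np.minimum(pa["deterioration_low_cbt"], 1.0 - rec)
    p_well = p_treat * rec + (1.0 - p_treat) * pa["recovery_none"]
    p_det = p_treat * det + (1.0 - p_treat) * pa["deterioration_none"]
    p_mod = p_det * pa["prop_moderate_among_modsev"]
    init = np.stack([p_well, 1.0 - p_well - p_det, p_mod, p_det - p_mod,
                     np.zeros_like(p_well)], axis=-1)

    low_course = pa["sessions_low"] * pa["minutes_low"] / 60.0 * pa["therapist_hourly"]
    per_participant = (low_course if strategy is Strategy.IN_PERSON else
                       low_course * pa["therapist_time_share_internet"]
                       + pa["platform_overhead"])
    payers = acc if config.program_cost_payers == "accepters" else p_treat
    program = payers * per_participant

    matrices = _transition_matrices(pa, config)
    cost, qaly, dropout, _ = _run_batch(init, matrices, pa, config)
    return program + cost, qaly, dropout
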