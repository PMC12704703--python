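"""Pairwise cost-effectiveness comparison: ICER, dominance, WTP rule, NMB."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import StrategyOutcome

__all__ = ["CEAComparison", "compare", "is_cost_effective",
           "net_monetary_benefit", "comparison_table"]


@dataclass(frozen=True)
class CEAComparison:
    """Intervention-vs-comparator increments.

    ``icer`` is Δcost/ΔQALY and is ``None`` when ΔQALY = 0 (never a division
    error).  ``dominant`` flags the strictly-better quadrant (cheaper and
    more effective).  A negative ICER is reported as-is, with the dominance
    flag carried alongside to disambiguate it.
    """

    d_cost: float
    d_qaly: float
    d_dropout: float
    icer: float | None
    dominant: bool


def compare(intervention: StrategyOutcome, comparator: StrategyOutcome) -> CEAComparison:
    """Incremental outcomes of ``intervention`` relative to ``comparator``."""
    d_cost = intervention.total_cost - comparator.total_cost
    d_qaly = intervention.total_qaly - comparator.total_qaly
    d_dropout = intervention.dropout_prob - comparator.dropout_prob
    icer = d_cost / d_qaly if d_qaly != 0.0 else None
    return CEAComparison(d_cost=d_cost, d_qaly=d_qaly, d_dropout=d_dropout,
                         icer=icer, dominant=(d_cost < 0.0 and d_qaly > 0.0))


def net_monetary_benefit(cmp: CEAComparison, wtp: float) -> float:
    """ΔQALY x WTP − Δcost; positive favours the intervention."""
    return cmp.d_qaly * wtp - cmp.d_cost


def is_cost_effective(cmp: CEAComparison, wtp: float) -> bool:
    """WTP acceptance rule for the intervention.

    Accepted if dominant, or if more costly *and* more effective with
    ICER < WTP; rejected if dominated (more costly, not more effective).
    The remaining quadrant — cheaper but less effective — is not covered by
    the two-branch rule, so the sign of the net monetary benefit decides it
    (this keeps the PSA acceptance fraction defined for every draw).
    """
    if wtp < 0:
        raise ValueError("willingness-to-pay threshold must be non-negative")
    if cmp.dominant:
        return True
    if cmp.d_cost > 0 and cmp.d_qaly > 0:
        return cmp.icer < wtp
    if cmp.d_cost >= 0:  # more costly, no QALY gain: dominated
        return False
    return net_monetary_benefit(cmp, wtp) > 0.0


def comparison_table(intervention: StrategyOutcome, comparator: StrategyOutcome
                     ) -> pd.DataFrame:
    """Base-case report with one row per strategy (costs, dropout, QALYs)."""
    cmp = compare(intervention, comparator)
    rows = [
        {"strategy": intervention.strategy,
         "cost_usd": intervention.total_cost, "incremental_cost_usd": cmp.d_cost,
         "dropout_pct": 100.0 * intervention.dropout_prob,
         "incremental_dropout_pct": 100.0 * cmp.d_dropout,
         "qalys": intervention.total_qaly, "incremental_qalys": cmp.d_qaly,
         "icer_usd_per_qaly": cmp.icer if cmp.icer is not None else np.nan,
         "dominant": cmp.dominant},
        {"strategy": comparator.strategy,
         "cost_usd": comparator.total_cost, "incremental_cost_usd": np.nan,
         "dropout_pct": 100.0 * comparator.dropout_prob,
         "incremental_dropout_pct": np.nan,
         "qalys": comparator.total_qaly, "incremental_qalys": np.nan,
         "icer_usd_per_qaly": np.nan, "dominant": np.nan},
    ]
    return pd.DataFrame(rows)
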