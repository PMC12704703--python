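"""Probabilistic sensitivity analysis: paired Monte Carlo model evaluations.

Each draw samples one joint parameter set from the per-parameter PSA
distributions and evaluates *both* strategies on it (common random
parameters), so the per-draw increments isolate the strategy effect from
parameter uncertainty.  A master seed spawns per-draw substreams, so the
first k draws are identical whatever the requested total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import run_strategy_batch
from .params import (ModelConfig, ParameterSet, parameter_values_from_quantiles,
                     quantile_blocks)
from .sensitivity import _vector_verdict
from .tree import Strategy

__all__ = ["PSAResult", "run_psa", "acceptance_fraction", "summarize", "ceac"]


@dataclass(frozen=True)
class PSAResult:
    """Per-draw paired outcomes for both strategies."""

    seed: int
    cost_internet: np.ndarray
    qaly_internet: np.ndarray
    cost_inperson: np.ndarray
    qaly_inperson: np.ndarray

    @property
    def n(self) -> int:
        return self.cost_internet.shape[0]

    @property
    def d_cost(self) -> np.ndarray:
        return self.cost_internet - self.cost_inperson

    @property
    def d_qaly(self) -> np.ndarray:
        return self.qaly_internet - self.qaly_inperson

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "draw": np.arange(self.n),
            "cost_internet": self.cost_internet,
            "qaly_internet": self.qaly_internet,
            "cost_inperson": self.cost_inperson,
            "qaly_inperson": self.qaly_inperson,
            "d_cost": self.d_cost, "d_qaly": self.d_qaly,
        })


def _draw_parameter_arrays(params: ParameterSet, n: int, seed: int,
                           config: ModelConfig) -> dict[str, np.ndarray]:
    """One (n,)-array per parameter, one independent substream per draw.

    Draw ``k`` takes its uniform quantiles from substream ``k`` of the
    master seed, so the first k draws are unchanged when n grows; the
    quantile-to-value maps (``ppf``) are then applied vectorized per
    parameter.
    """
    leaders, leader_of = quantile_blocks(params, config.psa_paired_quantiles)
    uniforms = np.empty((n, len(leaders)))
    for k, stream in enumerate(np.random.SeedSequence(seed).spawn(n)):
        uniforms[k] = np.random.default_rng(stream).random(len(leaders))
    quantiles = {leader: uniforms[:, j] for j, leader in enumerate(leaders)}
    return parameter_values_from_quantiles(params, quantiles, leader_of, n)


def run_psa(params: ParameterSet, n: int = 10_000, seed: int = 0,
            config: ModelConfig | None = None) -> PSAResult:
    """Evaluate ``n`` paired Monte Carlo draws; reproducible given ``seed``."""
    if n < 1:
        raise ValueError("n must be at least 1")
    config = config or ModelConfig()
    pa = _draw_parameter_arrays(params, n, seed, config)
    cost_net, qaly_net, _ = run_strategy_batch(Strategy.INTERNET, pa, config)
    cost_ip, qaly_ip, _ = run_strategy_batch(Strategy.IN_PERSON, pa, config)
    return PSAResult(seed=seed, cost_internet=cost_net, qaly_internet=qaly_net,
                     cost_inperson=cost_ip, qaly_inperson=qaly_ip)


def acceptance_fraction(psa: PSAResult, wtp: float) -> float:
    """Fraction of draws in which the internet strategy is cost-effective."""
    if psa.n == 0:
        raise ValueError("empty PSA result")
    return float(_vector_verdict(psa.d_cost, psa.d_qaly, wtp).mean())


def summarize(psa: PSAResult, interval: str = "percentile") -> dict[str, float]:
    """Means and 95% intervals of per-draw cost saving and QALY gain.

    ``interval`` is ``"percentile"`` (2.5/97.5 percentiles of the draws) or
    ``"normal"`` (mean ± 1.96 standard errors of the mean).
    """
    saving = -psa.d_cost
    gain = psa.d_qaly
    out = {
        "n": psa.n,
        "mean_cost_saving": float(saving.mean()),
        "mean_qaly_gain": float(gain.mean()),
        "se_cost_saving": float(saving.std(ddof=1) / np.sqrt(psa.n)) if psa.n > 1 else 0.0,
        "se_qaly_gain": float(gain.std(ddof=1) / np.sqrt(psa.n)) if psa.n > 1 else 0.0,
        "frac_cost_saving": float((psa.d_cost < 0).mean()),
        "frac_qaly_gaining": float((psa.d_qaly > 0).mean()),
    }
    if interval == "percentile":
        lo_c, hi_c = np.percentile(saving, [2.5, 97.5])
        lo_q, hi_q = np.percentile(gain, [2.5, 97.5])
    elif interval == "normal":
        lo_c = out["mean_cost_saving"] - 1.96 * out["se_cost_saving"]
        hi_c = out["mean_cost_saving"] + 1.96 * out["se_cost_saving"]
        lo_q = out["mean_qaly_gain"] - 1.96 * out["se_qaly_gain"]
        hi_q = out["mean_qaly_gain"] + 1.96 * out["se_qaly_gain"]
    else:
        raise ValueError(f"unknown interval method {interval!r}")
    out.update(cost_saving_ci=(float(lo_c), float(hi_c)),
               qaly_gain_ci=(float(lo_q), float(hi_q)))
    return out


def ceac(psa: PSAResult, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a WTP grid."""
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("empty WTP grid")
    if np.any(wtp_grid < 0):
        raise ValueError("WTP values must be non-negative")
    probs = [acceptance_fraction(psa, w) for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "prob_cost_effective": probs})
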