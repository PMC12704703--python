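"""Deterministic sensitivity analyses.

One-way analysis re-runs the full model at the endpoints of every
parameter's stated range (tornado ordering by ICER swing); the two-way
analysis maps the preferred strategy over a compliance grid for both
delivery modes; threshold search bisects a single parameter (possibly far
beyond its base range) for the point where the cost-effectiveness verdict
flips at the default willingness-to-pay threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import CEAComparison, compare, is_cost_effective
from .markov import run_strategy, run_strategy_batch
from .params import ModelConfig, ParameterError, ParameterSet
from .tree import Strategy

__all__ = ["OneWayResult", "TwoWayGrid", "ThresholdResult",
           "evaluate_comparison", "one_way", "tornado", "two_way",
           "threshold_search"]


def evaluate_comparison(params: ParameterSet,
                        config: ModelConfig | None = None) -> CEAComparison:
    """Internet-vs-in-person comparison at a single parameter set."""
    config = config or ModelConfig()
    return compare(run_strategy(Strategy.INTERNET, params, config),
                   run_strategy(Strategy.IN_PERSON, params, config))


@dataclass(frozen=True)
class OneWayResult:
    parameter: str
    low: float
    high: float
    icer_base: float | None
    icer_at_low: float | None
    icer_at_high: float | None
    dominant_at_low: bool
    dominant_at_high: bool

    @property
    def swing(self) -> float:
        """Width of the ICER interval spanned by the two endpoints."""
        ends = [x for x in (self.icer_at_low, self.icer_at_high) if x is not None]
        return abs(ends[0] - ends[1]) if len(ends) == 2 else np.inf


def one_way(param: str, params: ParameterSet,
            config: ModelConfig | None = None) -> OneWayResult:
    """Evaluate the comparison at a parameter's range endpoints."""
    spec = params.spec(param)
    if spec.is_fixed:
        raise ParameterError(f"{param}: no sensitivity range (fixed parameter)")
    base_cmp = evaluate_comparison(params, config)
    lo_cmp = evaluate_comparison(params.with_overrides({param: spec.low}), config)
    hi_cmp = evaluate_comparison(params.with_overrides({param: spec.high}), config)
    return OneWayResult(parameter=param, low=spec.low, high=spec.high,
                        icer_base=base_cmp.icer,
                        icer_at_low=lo_cmp.icer, icer_at_high=hi_cmp.icer,
                        dominant_at_low=lo_cmp.dominant,
                        dominant_at_high=hi_cmp.dominant)


def tornado(params: ParameterSet, config: ModelConfig | None = None) -> pd.DataFrame:
    """One-way results for every ranged parameter, sorted by ICER swing."""
    rows = []
    for name, spec in params.registry.items():
        if spec.is_fixed:
            continue
        r = one_way(name, params, config)
        rows.append({"parameter": name, "low": r.low, "high": r.high,
                     "icer_base": r.icer_base, "icer_at_low": r.icer_at_low,
                     "icer_at_high": r.icer_at_high,
                     "dominant_at_low": r.dominant_at_low,
                     "dominant_at_high": r.dominant_at_high,
                     "swing": r.swing})
    frame = pd.DataFrame(rows).sort_values("swing", ascending=False,
                                           kind="stable")
    return frame.reset_index(drop=True)


@dataclass(frozen=True)
class TwoWayGrid:
    """Preferred-strategy indicator over a compliance grid.

    ``internet_preferred[i, j]`` is the verdict at
    ``comply_internet = y[i]``, ``comply_inperson = x[j]``.
    """

    x_param: str
    y_param: str
    x: np.ndarray
    y: np.ndarray
    internet_preferred: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame({self.x_param: xx.ravel(), self.y_param: yy.ravel(),
                             "internet_preferred": self.internet_preferred.ravel()})


def _vector_verdict(d_cost: np.ndarray, d_qaly: np.ndarray, wtp: float) -> np.ndarray:
    """Vectorized form of the acceptance rule in :func:`cea.is_cost_effective`."""
    dominant = (d_cost < 0) & (d_qaly > 0)
    trade_off = (d_cost > 0) & (d_qaly > 0) & (d_cost < wtp * d_qaly)
    south_west = (d_cost < 0) & (d_qaly <= 0) & (d_qaly * wtp - d_cost > 0)
    return dominant | trade_off | south_west


def two_way(params: ParameterSet, config: ModelConfig | None = None,
            grid_step: float = 0.005, lo: float = 0.50, hi: float = 1.00,
            wtp: float | None = None) -> TwoWayGrid:
    """Preferred strategy over the (comply_inperson, comply_internet) grid.

    Grid ties (net monetary benefit exactly zero) go to the in-person
    comparator.  Runs as one vectorized batch.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    config = config or ModelConfig()
    wtp = params.wtp if wtp is None else wtp
    axis = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    axis = axis[axis <= hi + 1e-12]
    xx, yy = np.meshgrid(axis, axis)  # x: in-person, y: internet
    n = xx.size
    pa = {name: np.full(n, params[name]) for name in params}
    pa["comply_inperson"] = xx.ravel()
    pa["comply_internet"] = yy.ravel()
    cost_net, qaly_net, _ = run_strategy_batch(Strategy.INTERNET, pa, config)
    cost_ip, qaly_ip, _ = run_strategy_batch(Strategy.IN_PERSON, pa, config)
    verdict = _vector_verdict(cost_net - cost_ip, qaly_net - qaly_ip, wtp)
    return TwoWayGrid(x_param="comply_inperson", y_param="comply_internet",
                      x=axis, y=axis,
                      internet_preferred=verdict.reshape(xx.shape))


@dataclass(frozen=True)
class ThresholdResult:
    parameter: str
    bracket: tuple[float, float]
    threshold: float | None
    tolerance: float
    crossings: tuple[float, ...] = field(default_factory=tuple)


def threshold_search(param: str, bracket: tuple[float, float],
                     params: ParameterSet, config: ModelConfig | None = None,
                     wtp: float | None = None, tolerance: float | None = None,
                     scan_points: int = 33) -> ThresholdResult:
    """Bisect a parameter for the cost-effectiveness verdict flip.

    The bracket may extend beyond the parameter's base sensitivity envelope
    (extended analysis), so overrides are applied permissively.  A coarse
    scan first locates verdict changes; each is then bisected to
    ``tolerance`` (default 1 US $ for money scales, 0.001 otherwise).  If
    the verdict never changes, ``threshold`` is None.  All crossings are
    reported; ``threshold`` is the first.
    """
    config = config or ModelConfig()
    wtp = params.wtp if wtp is None else wtp
    spec = params.spec(param)
    if tolerance is None:
        tolerance = 1.0 if spec.scale == "money" else 1e-3

    def verdict(value: float) -> bool:
        cmp = evaluate_comparison(
            params.with_overrides({param: value}, strict=False), config)
        return is_cost_effective(cmp, wtp)

    grid = np.linspace(bracket[0], bracket[1], scan_points)
    verdicts = [verdict(v) for v in grid]
    crossings = []
    for k in range(len(grid) - 1):
        if verdicts[k] == verdicts[k + 1]:
            continue
        lo_v, hi_v = grid[k], grid[k + 1]
        v_lo = verdicts[k]
        while hi_v - lo_v > tolerance:
            mid = 0.5 * (lo_v + hi_v)
            if verdict(mid) == v_lo:
                lo_v = mid
            else:
                hi_v = mid
        crossings.append(0.5 * (lo_v + hi_v))
    return ThresholdResult(parameter=param, bracket=tuple(bracket),
                           threshold=crossings[0] if crossings else None,
                           tolerance=tolerance, crossings=tuple(crossings))
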