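"""Model parameter registry, validation, and PSA sampling distributions.

Every model input carries a base value, a deterministic sensitivity range,
and a sampling-distribution family for probabilistic sensitivity analysis.
The canonical values live in ``data/default_parameters.yaml`` (shipped with
the package); probabilities and proportions are stored as fractions.

Distribution construction follows the usual health-economics conventions:
triangular distributions use (low, mode=base, high); beta and gamma are fit
by method of moments with mean = base and sd = (high - low)/3.92, i.e. the
sensitivity range is read as an approximate 95% interval.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "ParameterSpec",
    "ParameterSet",
    "ModelConfig",
    "load_parameters",
    "load_registry",
    "make_sampler",
    "sample_parameter_set",
    "save_parameters",
    "DEFAULT_PARAMETER_FILE",
]

DIST_FAMILIES = ("beta", "gamma", "triangular", "fixed")
SCALES = ("probability", "proportion", "rate_percent_monthly", "utility",
          "money", "count", "multiplier")

#: parameter pairs whose uncertainty comes from a single source study and is
#: therefore sampled with a shared quantile in the PSA (see ModelConfig).
PAIRED_PARAMETERS = (
    ("accept_inperson", "accept_internet"),
    ("comply_inperson", "comply_internet"),
)

DEFAULT_PARAMETER_FILE = "default_parameters.yaml"

_UNIT_INTERVAL_SCALES = frozenset({"probability", "proportion", "utility"})


class ParameterError(ValueError):
    """Raised for unknown parameter names or invalid parameter values."""


@dataclass(frozen=True)
class ParameterSpec:
    """One named model input: base value, SA range, and PSA distribution."""

    name: str
    base: float
    low: float | None = None
    high: float | None = None
    dist: str = "fixed"
    scale: str = "count"
    units: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if self.dist not in DIST_FAMILIES:
            raise ParameterError(f"{self.name}: unknown distribution family {self.dist!r}")
        if self.scale not in SCALES:
            raise ParameterError(f"{self.name}: unknown scale {self.scale!r}")
        has_range = self.low is not None and self.high is not None
        if (self.dist == "fixed") == has_range:
            raise ParameterError(
                f"{self.name}: dist='fixed' must coincide with an absent SA range")
        if has_range and not (self.low <= self.base <= self.high):
            raise ParameterError(
                f"{self.name}: base {self.base} outside range [{self.low}, {self.high}]")
        self.validate(self.base)
        if has_range:
            self.validate(self.low)
            self.validate(self.high)

    @property
    def is_fixed(self) -> bool:
        return self.dist == "fixed"

    def validate(self, value: float) -> float:
        """Check a candidate value against this parameter's scale invariant."""
        if not np.isfinite(value):
            raise ParameterError(f"{self.name}: non-finite value {value!r}")
        if self.scale in _UNIT_INTERVAL_SCALES and not 0.0 <= value <= 1.0:
            raise ParameterError(
                f"{self.name}: {value} outside [0, 1] for scale {self.scale!r}")
        if self.scale in ("money", "count", "multiplier") and value < 0:
            raise ParameterError(f"{self.name}: negative value {value}")
        return float(value)


def _registry_from_mapping(raw: Mapping) -> dict[str, ParameterSpec]:
    registry: dict[str, ParameterSpec] = {}
    for name, block in raw["parameters"].items():
        registry[name] = ParameterSpec(
            name=name,
            base=float(block["base"]),
            low=None if block.get("low") is None else float(block["low"]),
            high=None if block.get("high") is None else float(block["high"]),
            dist=block.get("dist", "fixed"),
            scale=block.get("scale", "count"),
            units=block.get("units", ""),
            label=block.get("label", ""),
        )
    for name, value in raw.get("analysis", {}).items():
        registry[name] = ParameterSpec(
            name=name, base=float(value), dist="fixed",
            scale="proportion" if name == "discount_annual" else
            ("money" if name == "wtp" else "count"),
            units="", label=f"Analysis constant {name}")
    return registry


def load_registry(path: str | Path | None = None) -> dict[str, ParameterSpec]:
    """Load the full ParameterSpec registry from YAML (default: packaged file)."""
    if path is None:
        source = resources.files("icbt_cea.data").joinpath(DEFAULT_PARAMETER_FILE)
        raw = yaml.safe_load(source.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    return _registry_from_mapping(raw)


class ParameterSet(Mapping[str, float]):
    """A complete, validated assignment of values to every model input.

    Behaves as an immutable mapping; values are also available as attributes
    (``params.recovery_low_cbt``).  ``with_overrides`` returns a modified
    copy, re-validated against each parameter's scale invariant and — in
    strict mode — against its sensitivity envelope.
    """

    def __init__(self, values: Mapping[str, float],
                 registry: Mapping[str, ParameterSpec] | None = None) -> None:
        self._registry = dict(registry) if registry is not None else load_registry()
        unknown = set(values) - set(self._registry)
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        vals = {}
        for name, spec in self._registry.items():
            v = float(values.get(name, spec.base))
            spec.validate(v)
            vals[name] = v
        self._values = vals

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __getattr__(self, name: str) -> float:
        try:
            return self._values[name]
        except KeyError:
            raise AttributeError(name) from None

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ParameterSet) and self._values == other._values

    def __repr__(self) -> str:
        return f"ParameterSet({len(self._values)} parameters)"

    @property
    def registry(self) -> Mapping[str, ParameterSpec]:
        return self._registry

    def spec(self, name: str) -> ParameterSpec:
        try:
            return self._registry[name]
        except KeyError:
            raise ParameterError(f"unknown parameter {name!r}") from None

    def with_overrides(self, overrides: Mapping[str, float],
                       strict: bool = True) -> "ParameterSet":
        """Copy with ``overrides`` applied.

        In strict mode an override of a ranged parameter must stay inside its
        sensitivity envelope [low, high]; permissive mode only enforces the
        scale invariant (used by the extended sensitivity analyses, e.g.
        platform overhead up to 2000 US $ or therapist time share up to 50%).
        """
        for name, value in overrides.items():
            spec = self.spec(name)
            spec.validate(value)
            if strict and not spec.is_fixed and not (spec.low <= value <= spec.high):
                raise ParameterError(
                    f"{name}: override {value} outside SA envelope "
                    f"[{spec.low}, {spec.high}] (strict mode)")
        merged = dict(self._values)
        merged.update({k: float(v) for k, v in overrides.items()})
        return ParameterSet(merged, self._registry)

    def to_dict(self) -> dict[str, float]:
        return dict(self._values)


def load_parameters(config: str | Path | Mapping | None = None,
                    strict: bool = True) -> ParameterSet:
    """Build a ParameterSet from the canonical defaults plus optional overrides.

    ``config`` may be None (pure defaults), a mapping, or a path to a YAML/JSON
    file.  A file may either be a flat ``{name: value}`` mapping, or carry a
    full ``parameters:`` registry (same layout as the packaged default file),
    in which case it replaces the registry wholesale.
    """
    if config is None:
        return ParameterSet({})
    if isinstance(config, (str, Path)):
        raw = yaml.safe_load(Path(config).read_text())
        if raw is None:
            return ParameterSet({})
        if "parameters" in raw:
            registry = _registry_from_mapping(raw)
            return ParameterSet({}, registry)
        config = raw
    if not isinstance(config, Mapping):
        raise ParameterError(f"unsupported config object {type(config).__name__}")
    overrides = {k: v for k, v in config.items()}
    return ParameterSet({}).with_overrides(overrides, strict=strict)


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a ParameterSet back to YAML in the canonical registry layout."""
    out: dict = {"parameters": {}, "analysis": {}}
    for name, spec in params.registry.items():
        if spec.label.startswith("Analysis constant"):
            out["analysis"][name] = params[name]
            continue
        out["parameters"][name] = {
            "base": params[name], "low": spec.low, "high": spec.high,
            "dist": spec.dist, "scale": spec.scale, "units": spec.units,
            "label": spec.label,
        }
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


# ---------------------------------------------------------------------------
# Sampling distributions
# ---------------------------------------------------------------------------

class _Degenerate:
    """Point mass at ``value`` with the scipy frozen-distribution surface."""

    def __init__(self, value: float) -> None:
        self.value = float(value)

    def rvs(self, size=None, random_state=None):
        if size is None:
            return self.value
        return np.full(size, self.value)

    def ppf(self, q):
        return np.full_like(np.asarray(q, dtype=float), self.value)

    def mean(self) -> float:
        return self.value

    def std(self) -> float:
        return 0.0

    def support(self) -> tuple[float, float]:
        return (self.value, self.value)


def make_sampler(spec: ParameterSpec):
    """Map a ParameterSpec to a frozen sampling distribution.

    Returns a scipy frozen distribution (or a degenerate stand-in for fixed
    parameters) exposing ``rvs``, ``ppf``, ``mean``, ``std`` and ``support``.
    """
    if spec.is_fixed:
        return _Degenerate(spec.base)
    low, high, mean = float(spec.low), float(spec.high), float(spec.base)
    if spec.dist == "triangular":
        if high == low:
            return _Degenerate(mean)
        c = (mean - low) / (high - low)
        return stats.triang(c=c, loc=low, scale=high - low)
    sd = (high - low) / 3.92
    if not (np.isfinite(sd) and sd > 0):
        raise ParameterError(f"{spec.name}: degenerate moments for {spec.dist}")
    if spec.dist == "beta":
        nu = mean * (1.0 - mean) / sd**2 - 1.0
        a, b = mean * nu, (1.0 - mean) * nu
        if not (a > 0 and b > 0):
            raise ParameterError(
                f"{spec.name}: method-of-moments beta needs a,b > 0 "
                f"(got a={a:.4g}, b={b:.4g})")
        return stats.beta(a, b)
    if spec.dist == "gamma":
        shape = (mean / sd) ** 2
        scale = sd**2 / mean
        return stats.gamma(shape, scale=scale)
    raise ParameterError(f"{spec.name}: unsupported family {spec.dist!r}")


def quantile_blocks(params: ParameterSet, paired: bool = True
                    ) -> tuple[list[str], dict[str, str]]:
    """Uniform-quantile streams needed for one joint PSA draw.

    Returns the ordered list of stream leaders (one per non-fixed parameter,
    with each comonotone pair collapsed onto its first member when
    ``paired``) and the mapping from every non-fixed parameter to its
    leader.
    """
    pair_of: dict[str, str] = {}
    if paired:
        for a, b in PAIRED_PARAMETERS:
            pair_of[b] = a
    leaders: list[str] = []
    leader_of: dict[str, str] = {}
    for name, spec in params.registry.items():
        if spec.is_fixed:
            continue
        leader = pair_of.get(name, name)
        leader_of[name] = leader
        if leader not in leaders:
            leaders.append(leader)
    return leaders, leader_of


def parameter_values_from_quantiles(
        params: ParameterSet, quantiles: Mapping[str, np.ndarray],
        leader_of: Mapping[str, str], n: int) -> dict[str, np.ndarray]:
    """Map shared uniform quantiles through each parameter's marginal.

    Non-fixed parameters take ``ppf(u)`` of their (possibly shared) quantile
    stream — paired parameters mapped through the same ``u`` are comonotone.
    Fixed parameters come back as constant arrays.
    """
    values: dict[str, np.ndarray] = {}
    for name, spec in params.registry.items():
        if spec.is_fixed:
            values[name] = np.full(n, params[name])
            continue
        sampler = make_sampler(replace(spec, base=params[name]))
        u = quantiles[leader_of[name]]
        values[name] = np.asarray(sampler.ppf(u), dtype=float)
    return values


def sample_parameter_quantiles(
        params: ParameterSet, rng: np.random.Generator, n: int,
        paired: bool = True) -> dict[str, np.ndarray]:
    """Draw ``n`` PSA values per parameter, returned as (n,) arrays.

    Each parameter gets one independent uniform quantile stream, except the
    acceptance and compliance pairs, which (when ``paired``) share a single
    stream and are mapped through their own marginal distributions
    (comonotone coupling).  Fixed parameters are returned as constant arrays.
    """
    leaders, leader_of = quantile_blocks(params, paired)
    quantiles = {leader: rng.random(n) for leader in leaders}
    return parameter_values_from_quantiles(params, quantiles, leader_of, n)


def sample_parameter_set(params: ParameterSet, seed: int | np.random.Generator,
                         paired: bool = True, max_retries: int = 100) -> ParameterSet:
    """One joint PSA draw of every non-fixed parameter (reproducible by seed)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for attempt in range(max_retries + 1):
        draw = {k: float(v[0]) for k, v in
                sample_parameter_quantiles(params, rng, 1, paired=paired).items()}
        try:
            return ParameterSet(draw, params.registry)
        except ParameterError:
            if attempt == max_retries:
                raise
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Structural model configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Structural switches of the decision model.

    The defaults are the calibrated reference configuration; every switch is
    a documented modelling alternative, not a data input.

    severity_mix
        ``"relapse_proportions"``: the symptomatic mass is redistributed each
        cycle to the fixed mild/moderate/severe mix implied by
        ``prop_mild_relapse`` and ``prop_moderate_among_modsev`` (the
        symptomatic macro-state is differentiated by proportion).
        ``"tree"``: severities assigned by the decision tree persist; no
        lateral moves between severities.
    well_utility_source
        Utility of the well/remission state: ``"remission"`` (0.80) or
        ``"age"`` (age-specific population utility, 0.92).
    outpatient_states
        Which symptomatic severities accrue the monthly psychiatric
        outpatient cost: ``"all_symptomatic"`` or ``"moderate_severe"``.
    step_up_cbt_charge
        Optional one-off high-intensity CBT course charge per entry into the
        stepped-up set: ``"none"``, ``"entries_moderate_severe"``, or
        ``"entries_all_symptomatic"``.
    program_cost_payers
        Whether the low-intensity program cost is charged per accepter
        (resources committed at enrollment) or per complier.
    accrual_timing
        ``"cycle_end"``: each cycle accrues its end-of-cycle occupancy at the
        end-of-cycle discount factor; ``"cycle_start"``: start occupancy and
        discount; ``"half_cycle"``: average of the two.
    dropout_stops_accrual
        If True, students who permanently drop out of university stop
        accruing costs and QALYs (they still progress through health states
        for occupancy bookkeeping).
    psa_paired_quantiles
        Sample the acceptance pair and the compliance pair comonotonically in
        the PSA (shared quantile), reflecting their shared source studies.
    """

    severity_mix: str = "relapse_proportions"
    well_utility_source: str = "remission"
    outpatient_states: str = "all_symptomatic"
    step_up_cbt_charge: str = "none"
    program_cost_payers: str = "accepters"
    accrual_timing: str = "cycle_end"
    dropout_stops_accrual: bool = True
    psa_paired_quantiles: bool = True

    _choices = {
        "severity_mix": ("relapse_proportions", "tree"),
        "well_utility_source": ("remission", "age"),
        "outpatient_states": ("all_symptomatic", "moderate_severe"),
        "step_up_cbt_charge": ("none", "entries_moderate_severe",
                               "entries_all_symptomatic"),
        "program_cost_payers": ("accepters", "compliers"),
        "accrual_timing": ("cycle_end", "cycle_start", "half_cycle"),
    }

    def __post_init__(self) -> None:
        for name, choices in self._choices.items():
            if getattr(self, name) not in choices:
                raise ValueError(f"ModelConfig.{name}: {getattr(self, name)!r} "
                                 f"not one of {choices}")

    @classmethod
    def from_mapping(cls, raw: Mapping | None) -> "ModelConfig":
        return cls(**dict(raw or {}))
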