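"""Parameter registry, validation, and PSA distribution construction."""

import numpy as np
import pytest
import yaml

from icbt_cea import (ParameterError, load_parameters, make_sampler,
                      sample_parameter_set, save_parameters)
from icbt_cea.params import PAIRED_PARAMETERS


class TestRegistry:
    def test_defaults_match_published_inputs(self, params):
        assert params.recovery_low_cbt == 0.639
        assert params.deterioration_none == 0.091
        assert params.accept_internet == 0.753
        assert params.comply_inperson == 0.839
        assert params.mortality_monthly == pytest.approx(2.5e-5)
        assert params.rr_mortality_depressed == 1.81
        assert params.utility_severe == 0.33
        assert params.outpatient_monthly == 231
        assert params.horizon_months == 60
        assert params.cycle_months == 1
        assert params.discount_annual == 0.03
        assert params.wtp == 48119

    def test_probability_scales_live_in_unit_interval(self, params):
        for name, spec in params.registry.items():
            if spec.scale in ("probability", "proportion", "utility"):
                assert 0.0 <= params[name] <= 1.0, name

    def test_override_leaves_other_fields_untouched(self, params):
        changed = params.with_overrides({"wtp": 0.0}, strict=False)
        assert changed.wtp == 0.0
        assert {k: v for k, v in changed.items() if k != "wtp"} == \
            {k: v for k, v in params.items() if k != "wtp"}

    @pytest.mark.parametrize("override, strict", [
        ({"accept_internet": 1.2}, False),      # probability above 1
        ({"no_such_parameter": 0.5}, False),    # unknown name
        ({"platform_overhead": 500.0}, True),   # outside SA envelope, strict
        ({"outpatient_monthly": -1.0}, False),  # negative money
    ])
    def test_invalid_overrides_rejected(self, params, override, strict):
        with pytest.raises(ParameterError):
            params.with_overrides(override, strict=strict)

    def test_permissive_mode_allows_extended_ranges(self, params):
        extended = params.with_overrides(
            {"platform_overhead": 2000.0, "therapist_time_share_internet": 0.50},
            strict=False)
        assert extended.platform_overhead == 2000.0

    def test_load_from_flat_mapping(self):
        p = load_parameters({"recovery_low_cbt": 0.60})
        assert p.recovery_low_cbt == 0.60

    def test_yaml_round_trip(self, params, tmp_path):
        path = tmp_path / "params.yaml"
        save_parameters(params, path)
        assert load_parameters(path) == params


class TestSamplers:
    def test_triangular_support_and_mode(self, params):
        dist = make_sampler(params.spec("rel_effect_internet"))
        lo, hi = dist.support()
        assert (lo, hi) == (0.95, 1.05)
        draws = dist.rvs(size=100_000, random_state=np.random.default_rng(0))
        assert draws.min() >= 0.95 and draws.max() <= 1.05
        # mode at the base value: density peaks near 1.00
        hist, edges = np.histogram(draws, bins=25)
        peak = 0.5 * (edges[hist.argmax()] + edges[hist.argmax() + 1])
        assert abs(peak - 1.00) < 0.02

    def test_fixed_spec_is_degenerate(self, params):
        dist = make_sampler(params.spec("utility_age"))
        assert np.all(dist.rvs(size=100) == 0.92)
        assert dist.std() == 0.0

    @pytest.mark.parametrize("name", ["recovery_low_cbt", "comply_internet",
                                      "outpatient_monthly"])
    def test_method_of_moments_mean_recovered(self, params, name):
        spec = params.spec(name)
        dist = make_sampler(spec)
        draws = dist.rvs(size=100_000, random_state=np.random.default_rng(1))
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - spec.base) < 3 * se
        # sd targets (high - low)/3.92 for the moment-fitted families
        assert dist.std() == pytest.approx((spec.high - spec.low) / 3.92, rel=1e-6)

    def test_percentile_interval_covers_range_midpoint(self, params):
        for name, spec in params.registry.items():
            if spec.is_fixed:
                continue
            draws = make_sampler(spec).rvs(
                size=100_000, random_state=np.random.default_rng(2))
            lo, hi = np.percentile(draws, [2.5, 97.5])
            midpoint = 0.5 * (spec.low + spec.high)
            assert lo <= midpoint <= hi, name


class TestJointSampling:
    def test_same_seed_reproduces_draw(self, params):
        assert sample_parameter_set(params, 123) == sample_parameter_set(params, 123)

    def test_draws_respect_invariants(self, perturbed_sets):
        for ps in perturbed_sets:
            for name, spec in ps.registry.items():
                spec.validate(ps[name])
                if not spec.is_fixed and spec.dist != "gamma":
                    assert spec.low - 1e-9 <= ps[name] <= spec.high + 1e-9 or \
                        spec.dist == "beta"  # beta support is [0, 1], not the range

    def test_fixed_parameters_never_move(self, params, perturbed_sets):
        for ps in perturbed_sets:
            assert ps.utility_age == params.utility_age
            assert ps.minutes_low == params.minutes_low
            assert ps.wtp == params.wtp

    def test_monte_carlo_mean_matches_base(self, params):
        draws = np.array([sample_parameter_set(params, s)["comply_internet"]
                          for s in range(4000)])
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.808) < 3 * se

    def test_paired_quantiles_are_comonotone(self, params):
        rng = np.random.default_rng(7)
        from icbt_cea.params import sample_parameter_quantiles
        vals = sample_parameter_quantiles(params, rng, 2000, paired=True)
        for a, b in PAIRED_PARAMETERS:
            rho = np.corrcoef(vals[a], vals[b])[0, 1]
            assert rho > 0.99
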