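import numpy as np
import pytest

from uhccost.params import Parameter, ParameterRegistry, ValidationError
from uhccost.pipeline import build_outcome_model
from uhccost.sensitivity import (probabilistic_sensitivity,
                                 univariate_sensitivity)

# a self-contained toy registry satisfying the required-parameter contract
# is overkill here; sensitivity functions only need Parameter semantics, so
# build minimal registries without validate()


def toy_registry(params):
    return ParameterRegistry(params)


class TestTornado:
    def test_degenerate_range_no_swing(self):
        reg = toy_registry([Parameter("a", 2.0, 1.0, 3.0),
                            Parameter("b", 5.0, 5.0, 5.0)])
        model = lambda v: v["a"] * v["b"]
        results = univariate_sensitivity(model, reg, parameters=["b"])
        assert results[0].outcome_at_low == results[0].outcome_at_high == 10.0
        assert results[0].swing == 0.0

    def test_two_parameter_closed_form(self):
        # outcome = a*x + b with a in [1,3], b in [10,30]: swings 2x and 20
        reg = toy_registry([Parameter("a", 2.0, 1.0, 3.0),
                            Parameter("b", 20.0, 10.0, 30.0)])
        model = lambda v: v["a"] * 7.0 + v["b"]
        results = univariate_sensitivity(model, reg)
        by_name = {r.parameter: r for r in results}
        assert by_name["a"].outcome_at_low == pytest.approx(1 * 7 + 20)
        assert by_name["a"].outcome_at_high == pytest.approx(3 * 7 + 20)
        assert by_name["a"].swing == pytest.approx(14.0)
        assert by_name["b"].swing == pytest.approx(20.0)
        assert results[0].parameter == "b"  # sorted by swing

    def test_morbidity_monotone_on_real_model(self, registry, macro, profiles):
        model = build_outcome_model(registry, profiles, macro, "generic")
        base_outcome = model(registry.base_values())
        r = next(r for r in univariate_sensitivity(model, registry)
                 if r.parameter == "morbidity_rate")
        assert r.outcome_at_low < base_outcome < r.outcome_at_high

    def test_widening_range_weakly_widens_swing(self, registry, macro, profiles):
        model = build_outcome_model(registry, profiles, macro, "generic")
        narrow = univariate_sensitivity(model, registry,
                                        parameters=["morbidity_rate"])[0]
        wide_reg = ParameterRegistry([
            p if p.name != "morbidity_rate"
            else Parameter(p.name, p.base, 0.06, 0.14, p.units, p.kind)
            for p in registry.values()])
        wide = univariate_sensitivity(model, wide_reg,
                                      parameters=["morbidity_rate"])[0]
        assert wide.swing >= narrow.swing

    def test_model_failure_names_parameter(self):
        reg = toy_registry([Parameter("bad", 1.0, 0.5, 1.5)])
        def model(v):
            raise ZeroDivisionError
        with pytest.raises(RuntimeError, match="bad"):
            univariate_sensitivity(model, reg, parameters=["bad"])


class TestPSA:
    def test_degenerate_ranges_collapse_to_base(self):
        reg = toy_registry([Parameter("a", 3.0, 3.0, 3.0),
                            Parameter("b", 4.0, 4.0, 4.0)])
        model = lambda v: v["a"] + v["b"]
        r = probabilistic_sensitivity(model, reg, n_draws=50, seed=1)
        assert np.all(r.draws == 7.0)
        assert r.percentile_2_5 == r.mean == r.percentile_97_5 == 7.0

    def test_same_seed_identical_draws(self, registry, macro, profiles):
        model = build_outcome_model(registry, profiles, macro, "generic")
        r1 = probabilistic_sensitivity(model, registry, 200, seed=11)
        r2 = probabilistic_sensitivity(model, registry, 200, seed=11)
        assert np.array_equal(r1.draws, r2.draws)

    def test_uniform_quantiles_closed_form(self):
        # outcome = the parameter itself, uniform on [0,1]
        reg = toy_registry([Parameter("u", 0.5, 0.0, 1.0)])
        r = probabilistic_sensitivity(lambda v: v["u"], reg,
                                      n_draws=100_000, seed=3)
        assert r.percentile_2_5 == pytest.approx(0.025, abs=0.005)
        assert r.percentile_97_5 == pytest.approx(0.975, abs=0.005)
        assert r.mean == pytest.approx(0.5, abs=0.01)

    def test_interval_contains_base_premium(self, registry, macro, profiles):
        model = build_outcome_model(registry, profiles, macro, "generic")
        base_outcome = model(registry.base_values())
        r = probabilistic_sensitivity(model, registry, 1000, seed=20120127)
        assert r.percentile_2_5 <= base_outcome <= r.percentile_97_5
        assert r.percentile_2_5 <= r.mean <= r.percentile_97_5

    def test_interval_widens_with_more_parameters(self):
        # nested toy registries: adding an uncertain factor widens the CI
        base = [Parameter("a", 1.0, 0.8, 1.2)]
        nested = base + [Parameter("b", 1.0, 0.8, 1.2)]
        model = lambda v: v.get("a", 1.0) * v.get("b", 1.0)
        r1 = probabilistic_sensitivity(model, toy_registry(base), 4000, seed=5)
        r2 = probabilistic_sensitivity(model, toy_registry(nested), 4000, seed=5)
        assert (r2.percentile_97_5 - r2.percentile_2_5) >= \
            (r1.percentile_97_5 - r1.percentile_2_5)

    def test_invalid_range_rejected_before_sampling(self):
        reg = toy_registry([Parameter("a", 1.0, 2.0, 0.5, range_inconsistent=True)])
        # flagged-inconsistent parameters are excluded, so this runs
        r = probabilistic_sensitivity(lambda v: v["a"], reg, 10, seed=0)
        assert np.all(r.draws == 1.0)

    def test_too_few_draws_rejected(self):
        reg = toy_registry([Parameter("a", 1.0, 0.5, 1.5)])
        with pytest.raises(ValidationError):
            probabilistic_sensitivity(lambda v: v["a"], reg, n_draws=1, seed=0)

    def test_triangular_sampler_available(self):
        reg = toy_registry([Parameter("u", 0.5, 0.0, 1.0)])
        r = probabilistic_sensitivity(lambda v: v["u"], reg, 2000, seed=9,
                                      distribution="triangular")
        assert 0.0 < r.percentile_2_5 < r.percentile_97_5 < 1.0

    def test_unknown_distribution_rejected(self):
        reg = toy_registry([Parameter("u", 0.5, 0.0, 1.0)])
        with pytest.raises(ValidationError, match="distribution"):
            probabilistic_sensitivity(lambda v: v["u"], reg, 10, seed=0,
                                      distribution="normal")
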