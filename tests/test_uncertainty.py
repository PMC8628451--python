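"""Uncertainty toolkit: OWSA, scenarios, PSA, CEAC, thresholds, sweeps."""

from __future__ import annotations

import numpy as np
import pytest

from earlyhta.distributions import DistributionSpec, spec_from_range
from earlyhta.engine import ValidationError
from earlyhta.health_econ import ParameterSet, ParameterValue
from earlyhta.uncertainty import (
    PSASampleSet,
    ceac,
    owsa,
    parameter_sweep,
    psa,
    scenario,
    threshold_search,
)

from conftest import make_linear_builder


@pytest.fixture
def linear_builder():
    # delta_cost = price * 100 - savings; delta_qaly = effect
    return make_linear_builder(
        cost_coeffs={"price": 100.0, "savings": -1.0},
        qaly_coeffs={"effect": 1.0},
    )


class TestDistributions:
    def test_family_parameter_validation(self):
        with pytest.raises(ValueError):
            DistributionSpec("beta", (0.0, 1.0))
        with pytest.raises(ValueError):
            DistributionSpec("lognormal", (0.0, -1.0))
        with pytest.raises(ValueError):
            DistributionSpec("nope", (1.0, 2.0))

    @pytest.mark.parametrize(
        "kind,family", [("probability", "beta"), ("utility", "beta"),
                        ("cost", "gamma"), ("hazard-ratio", "lognormal")]
    )
    def test_kind_matched_families(self, kind, family):
        base = 0.3 if family == "beta" else 2.0
        lo, hi = 0.5 * base, 1.5 * base
        spec = spec_from_range(kind, base, lo, hi)
        assert spec.family == family

    def test_method_of_moments_beta_mean(self):
        spec = spec_from_range("probability", 0.3, 0.2, 0.4)
        assert spec.mean() == pytest.approx(0.3, abs=1e-12)
        draws = spec.sample(np.random.default_rng(0), size=10_000)
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.3) < 3 * se

    def test_gamma_mean_matches_base(self):
        spec = spec_from_range("cost", 1_000.0, 500.0, 2_000.0)
        assert spec.mean() == pytest.approx(1_000.0, rel=1e-12)


class TestOwsa:
    def test_inert_parameter_has_zero_width(self, linear_builder, toy_params):
        entries = owsa(linear_builder, toy_params, lambda r: r.delta_cost)
        by_name = {e.name: e for e in entries}
        assert by_name["n_patients"].width == 0.0  # degenerate range
        assert by_name["effect"].width == 0.0  # unused by delta_cost

    def test_closed_form_width_price(self, linear_builder, toy_params):
        entries = owsa(linear_builder, toy_params, lambda r: r.delta_cost)
        by_name = {e.name: e for e in entries}
        # delta_cost = 100 * price - savings; price in [10, 20] -> width 1000
        assert by_name["price"].width == pytest.approx(1_000.0)
        assert by_name["savings"].width == pytest.approx(1_000.0)

    def test_matches_two_point_reevaluation_oracle(self, linear_builder, toy_params):
        entries = owsa(linear_builder, toy_params, lambda r: r.delta_cost)
        base = toy_params.base_values()
        for e in entries:
            p = toy_params[e.name]
            for bound, got in ((p.low, e.outcome_low), (p.high, e.outcome_high)):
                values = dict(base)
                values[e.name] = bound
                assert got == pytest.approx(
                    linear_builder(values).delta_cost, abs=1e-12
                )

    def test_sorted_by_width_descending(self, linear_builder, toy_params):
        entries = owsa(linear_builder, toy_params, lambda r: r.delta_cost)
        widths = [e.width for e in entries]
        assert widths == sorted(widths, reverse=True)

    def test_affine_model_widths_equal_coefficient_times_range(self, toy_params):
        builder = make_linear_builder(
            cost_coeffs={"price": -7.0, "savings": 2.5}, qaly_coeffs={}
        )
        entries = {e.name: e for e in owsa(builder, toy_params, lambda r: r.delta_cost)}
        assert entries["price"].width == pytest.approx(7.0 * 10.0)
        assert entries["savings"].width == pytest.approx(2.5 * 1_000.0)

    def test_evaluation_failure_names_parameter_and_bound(self, toy_params):
        def exploding(values):
            if values["price"] == 10.0:
                raise RuntimeError("boom")
            return make_linear_builder({}, {})(values)

        with pytest.raises(ValidationError, match="price.*low"):
            owsa(exploding, toy_params, lambda r: r.delta_cost)


class TestScenario:
    def test_empty_override_map_is_base_case(self, linear_builder, toy_params):
        assert (
            scenario(linear_builder, toy_params, {}).delta_cost
            == linear_builder(toy_params.base_values()).delta_cost
        )

    def test_single_cost_override_shifts_linearly(self, linear_builder, toy_params):
        base = scenario(linear_builder, toy_params, {}).delta_cost
        res = scenario(linear_builder, toy_params, {"savings": 0.0}).delta_cost
        assert res - base == pytest.approx(500.0)  # removing savings of 500

    def test_simultaneous_overrides_equal_rebuilt_parameter_set(
        self, linear_builder, toy_params
    ):
        overrides = {"price": 12.0, "effect": 0.05}
        res = scenario(linear_builder, toy_params, overrides)
        rebuilt = toy_params.with_overrides(overrides)
        oracle = linear_builder(rebuilt.base_values())
        assert res.delta_cost == pytest.approx(oracle.delta_cost, abs=1e-12)
        assert res.delta_qaly == pytest.approx(oracle.delta_qaly, abs=1e-12)

    def test_unknown_override_rejected(self, linear_builder, toy_params):
        with pytest.raises(ValidationError, match="unknown"):
            scenario(linear_builder, toy_params, {"typo": 1.0})


def _params_with_dists():
    vals = []
    for name, kind, base, lo, hi in (
        ("price", "cost", 15.0, 10.0, 20.0),
        ("savings", "cost", 500.0, 300.0, 700.0),
        ("effect", "utility", 0.1, 0.05, 0.15),
    ):
        pv = ParameterValue(name, kind, base, lo, hi)
        vals.append(
            ParameterValue(
                name, kind, base, lo, hi, distribution=pv.default_distribution()
            )
        )
    vals.append(ParameterValue("inert", "count", 100.0, 100.0, 100.0))
    return ParameterSet(vals)


class TestPsa:
    def test_degenerate_distributions_reproduce_base(self, linear_builder, toy_params):
        # no parameter has a distribution -> all held at base
        samples = psa(linear_builder, toy_params, n=5, seed=0)
        base = linear_builder(toy_params.base_values())
        assert np.allclose(samples.delta_cost, base.delta_cost)
        assert np.allclose(samples.delta_qaly, base.delta_qaly)

    def test_same_seed_bit_identical(self, linear_builder):
        params = _params_with_dists()
        a = psa(linear_builder, params, n=64, seed=42)
        b = psa(linear_builder, params, n=64, seed=42)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert a.parameters.equals(b.parameters)
        c = psa(linear_builder, params, n=64, seed=43)
        assert not np.array_equal(a.delta_cost, c.delta_cost)

    def test_linear_model_mean_within_three_mc_standard_errors(self, linear_builder):
        params = _params_with_dists()
        samples = psa(linear_builder, params, n=10_000, seed=7)
        base = linear_builder(params.base_values())
        # distributions are mean-matched to base, model is linear
        se = samples.delta_cost.std(ddof=1) / np.sqrt(samples.n)
        assert abs(samples.delta_cost.mean() - base.delta_cost) < 3 * se
        se_q = samples.delta_qaly.std(ddof=1) / np.sqrt(samples.n)
        assert abs(samples.delta_qaly.mean() - base.delta_qaly) < 3 * se_q

    def test_missing_distribution_error_mode(self, linear_builder, toy_params):
        with pytest.raises(ValidationError, match="no distribution"):
            psa(linear_builder, toy_params, n=2, seed=0,
                on_missing_distribution="error")


class TestCeac:
    def _samples(self, pairs):
        pairs = np.asarray(pairs, dtype=float)
        n = len(pairs)
        import pandas as pd

        return PSASampleSet(
            delta_cost=pairs[:, 0],
            delta_qaly=pairs[:, 1],
            delta_ly=np.zeros(n),
            parameters=pd.DataFrame(index=range(n)),
            seed=0,
            n=n,
        )

    def test_dominant_draws_probability_one_everywhere(self):
        s = self._samples([(-10, 0.1), (-5, 0.2), (-1, 0.05)])
        curve = ceac(s, [0, 1_000, 100_000])
        assert np.all(curve.probabilities == 1.0)

    def test_hand_counted_nmb_signs(self):
        s = self._samples([(-10, 0.1), (10, 0.1), (10, -0.1)])
        assert ceac(s, [0.0]).probabilities[0] == pytest.approx(1 / 3)
        assert ceac(s, [200.0]).probabilities[0] == pytest.approx(2 / 3)

    def test_zero_nmb_tie_counts_as_not_cost_effective(self):
        s = self._samples([(10, 0.1)])
        assert ceac(s, [100.0]).probabilities[0] == 0.0  # NMB exactly 0

    def test_endpoints_match_cost_saving_and_qaly_gaining_fractions(self):
        rng = np.random.default_rng(0)
        pairs = np.column_stack(
            [rng.normal(0, 100, 200), rng.normal(0.01, 0.05, 200)]
        )
        s = self._samples(pairs)
        curve0 = ceac(s, [0.0])
        assert curve0.probabilities[0] == (s.delta_cost < 0).mean()
        lam_huge = 1e12
        curve_inf = ceac(s, [lam_huge])
        qaly_gaining = (s.delta_qaly > 0).mean()
        assert curve_inf.probabilities[0] == pytest.approx(qaly_gaining, abs=0.01)

    def test_empty_grid_rejected(self):
        s = self._samples([(0.0, 0.0)])
        with pytest.raises(ValidationError, match="grid"):
            ceac(s, [])


class TestThresholdSearch:
    def test_closed_form_root(self, linear_builder, toy_params):
        # delta_cost = 100*price - savings; cost-saving iff price < 5
        res = threshold_search(
            linear_builder, toy_params, "price",
            lambda r: r.delta_cost < 0, lo=0.0, hi=20.0, tol=1e-6,
        )
        assert res.found and res.value == pytest.approx(5.0, abs=1e-5)

    def test_no_flip_returns_no_threshold_not_exception(
        self, linear_builder, toy_params
    ):
        res = threshold_search(
            linear_builder, toy_params, "price",
            lambda r: r.delta_cost < 0, lo=10.0, hi=20.0,
        )
        assert not res.found and res.value is None
        assert "no threshold" in res.message

    def test_agrees_with_dense_grid_oracle(self, linear_builder, toy_params):
        tol = 0.01
        res = threshold_search(
            linear_builder, toy_params, "price",
            lambda r: r.delta_cost < 0, lo=0.0, hi=20.0, tol=tol,
        )
        grid = np.arange(0.0, 20.0, 0.001)
        base = toy_params.base_values()
        flags = [
            linear_builder({**base, "price": x}).delta_cost < 0 for x in grid
        ]
        flips = [x for x, a, b in zip(grid[1:], flags, flags[1:]) if a != b]
        assert len(flips) == 1
        assert abs(res.value - flips[0]) < tol + 0.001

    def test_substituting_threshold_back_sits_at_boundary(
        self, linear_builder, toy_params
    ):
        res = threshold_search(
            linear_builder, toy_params, "price",
            lambda r: r.delta_cost < 0, lo=0.0, hi=20.0, tol=1e-8,
        )
        at = scenario(linear_builder, toy_params, {"price": res.value})
        assert abs(at.delta_cost) < 1e-4  # 100 * tol margin on the outcome

    def test_non_monotone_criterion_detected_on_check_grid(self, toy_params):
        def vshaped(values):
            return make_linear_builder({}, {}, intercept_cost=abs(values["price"] - 15.0) - 2.0)(values)

        with pytest.raises(ValidationError, match="monotone"):
            threshold_search(
                vshaped, toy_params, "price",
                lambda r: r.delta_cost < 0, lo=10.0, hi=20.0, check_grid=20,
            )


class TestParameterSweep:
    def test_single_point_grid_equals_base_case(self, linear_builder, toy_params):
        frame = parameter_sweep(linear_builder, toy_params, "price", [15.0])
        base = linear_builder(toy_params.base_values())
        assert frame.loc[0, "delta_cost"] == pytest.approx(base.delta_cost)

    def test_linear_model_sweep_is_collinear(self, linear_builder, toy_params):
        grid = np.linspace(10.0, 20.0, 11)
        frame = parameter_sweep(linear_builder, toy_params, "price", grid)
        diffs = np.diff(frame["delta_cost"].to_numpy())
        assert np.all(np.abs(diffs - diffs[0]) < 1e-10)

    def test_grid_outside_support_rejected(self, linear_builder, toy_params):
        with pytest.raises(ValidationError, match="support"):
            parameter_sweep(linear_builder, toy_params, "effect", [-0.5])
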