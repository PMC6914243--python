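import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialcea import cea
from trialcea.cea import (
    CEPairSet,
    PopulationParams,
    build_cea_frame,
    ceac,
    ceac_stability,
    draw_ce_pairs,
    estimate_frame,
    icer,
    plane_distribution,
    sensitivity_suite,
    summarize,
)
from trialcea.errors import ConfigurationError


def make_pairs(dc, de, **kw):
    defaults = dict(
        perspective="societal", effect_kind="response", seed=0, method="parametric"
    )
    defaults.update(kw)
    return CEPairSet(np.asarray(dc, float), np.asarray(de, float), **defaults)


pair_arrays = st.lists(
    st.tuples(st.floats(-5000, 5000), st.floats(-1, 1)), min_size=1, max_size=200
)


class TestIcer:
    def test_societal_response(self):
        got = icer(1183, 0.03)
        assert got.value == pytest.approx(1183 / 0.03)
        assert round(got.value) == 39433
        assert got.quadrant == "NE"

    def test_provider_response_dominant(self):
        got = icer(-176, 0.03)
        assert got.value == pytest.approx(-176 / 0.03)
        assert round(got.value) == -5867
        assert got.quadrant == "SE"
        assert got.dominance == "dominant"

    def test_zero_cost(self):
        assert icer(0, 0.05).value == 0.0

    def test_zero_effect_is_undefined_not_infinite(self):
        got = icer(1000, 0.0)
        assert not got.defined
        assert np.isnan(got.value)

    def test_dominated_quadrant(self):
        assert icer(500, -0.1).dominance == "dominated"


class TestPlane:
    def test_point_mass_ne(self):
        pairs = make_pairs([1000.0] * 20, [0.1] * 20)
        got = plane_distribution(pairs)
        assert got.proportions == {"NE": 1.0, "NW": 0.0, "SE": 0.0, "SW": 0.0}

    def test_symmetric_cloud_quarters(self):
        rng = np.random.default_rng(3)
        pairs = make_pairs(rng.normal(0, 1000, 40_000), rng.normal(0, 0.1, 40_000))
        got = plane_distribution(pairs)
        for q in ("NE", "NW", "SE", "SW"):
            assert got.proportions[q] == pytest.approx(0.25, abs=0.01)

    @given(draws=pair_arrays)
    def test_partition_sums_to_one(self, draws):
        dc, de = zip(*draws)
        got = plane_distribution(make_pairs(dc, de))
        assert sum(got.proportions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_boundary_convention(self):
        # ΔE = 0 counts west, ΔC = 0 counts south
        got = plane_distribution(make_pairs([0.0, 5.0], [0.0, 0.0]))
        assert got.proportions["SW"] == 0.5
        assert got.proportions["NW"] == 0.5


class TestCeac:
    @given(draws=pair_arrays)
    @settings(max_examples=50)
    def test_brute_force_counting_equivalence(self, draws):
        dc, de = np.array([d for d, _ in draws]), np.array([e for _, e in draws])
        pairs = make_pairs(dc, de)
        grid = np.array([0.0, 1000.0, 5000.0, 20000.0, 80000.0])
        curve = ceac(pairs, grid)
        for lam, prob in zip(curve.wtp_grid, curve.probability):
            brute = sum(1 for c, e in zip(dc, de) if lam * e - c > 0) / len(dc)
            assert prob == brute  # exact

    def test_lambda_zero_is_prob_cost_saving(self):
        rng = np.random.default_rng(4)
        pairs = make_pairs(rng.normal(100, 500, 999), rng.normal(0, 0.1, 999))
        curve = ceac(pairs, [0.0, 1.0])
        assert curve.at(0.0) == np.mean(pairs.delta_cost < 0)

    def test_lambda_zero_equals_south_half(self):
        rng = np.random.default_rng(5)
        pairs = make_pairs(rng.normal(0, 500, 500), rng.normal(0, 0.1, 500))
        plane = plane_distribution(pairs)
        curve = ceac(pairs, [0.0, 1.0])
        assert curve.at(0.0) == pytest.approx(
            plane.proportions["SW"] + plane.proportions["SE"], abs=1e-12
        )

    def test_limit_probability_one(self):
        rng = np.random.default_rng(6)
        pairs = make_pairs(rng.normal(500, 200, 300), rng.uniform(0.01, 0.2, 300))
        curve = ceac(pairs, [1e9, 2e9])
        assert curve.probability[-1] == 1.0

    def test_monotone_when_all_effects_positive(self):
        rng = np.random.default_rng(7)
        pairs = make_pairs(rng.normal(0, 800, 400), rng.uniform(0.001, 0.3, 400))
        curve = ceac(pairs, np.arange(0, 50001, 500))
        assert (np.diff(curve.probability) >= 0).all()

    def test_tie_counts_as_not_cost_effective(self):
        pairs = make_pairs([100.0], [0.1])
        assert ceac(pairs, [1000.0, 2000.0]).at(1000.0) == 0.0

    def test_grid_must_increase(self):
        pairs = make_pairs([1.0], [1.0])
        with pytest.raises(ConfigurationError):
            ceac(pairs, [0.0, 0.0])


class TestDrawPairs:
    def test_determinism_bit_identical(self, small_panels):
        outcomes, costs = small_panels
        frame = build_cea_frame(outcomes, costs, "societal", "response")
        a = draw_ce_pairs(frame, n_draws=60, seed=42)
        b = draw_ce_pairs(frame, n_draws=60, seed=42)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert np.array_equal(a.delta_effect, b.delta_effect)

    def test_parametric_determinism(self, small_panels):
        outcomes, costs = small_panels
        frame = build_cea_frame(outcomes, costs, "provider", "qaly")
        a = draw_ce_pairs(frame, n_draws=200, seed=9, method="parametric")
        b = draw_ce_pairs(frame, n_draws=200, seed=9, method="parametric")
        assert np.array_equal(a.delta_cost, b.delta_cost)

    def test_bad_method(self, small_panels):
        outcomes, costs = small_panels
        frame = build_cea_frame(outcomes, costs, "societal", "response")
        with pytest.raises(ConfigurationError):
            draw_ce_pairs(frame, method="jackknife")

    def test_identical_arms_centered_on_origin(self):
        from helpers import symmetric_config
        from trialcea.costing import build_cost_panel
        from trialcea.outcomes import derive_outcomes
        from trialcea.synthetic import generate_trial

        cfg = symmetric_config(n_per_arm=(60, 60), seed=77)
        data = generate_trial(cfg)
        outcomes = derive_outcomes(data)
        costs = build_cost_panel(data, include_treatment=False)
        frame = build_cea_frame(outcomes, costs, "societal", "response")
        pairs = draw_ce_pairs(frame, n_draws=150, seed=1)
        assert abs(pairs.delta_cost.mean()) < 3 * pairs.delta_cost.std()
        assert abs(pairs.delta_effect.mean()) < 3 * pairs.delta_effect.std()

    def test_summary_fields(self, small_panels):
        outcomes, costs = small_panels
        frame = build_cea_frame(outcomes, costs, "societal", "episode")
        pairs = draw_ce_pairs(frame, n_draws=50, seed=3)
        row = summarize(pairs)
        assert row["perspective"] == "societal"
        total = row["pct_ne"] + row["pct_nw"] + row["pct_se"] + row["pct_sw"]
        assert total == pytest.approx(100.0, abs=1e-9)
        assert row["delta_cost_ci_low"] <= row["delta_cost"] <= row["delta_cost_ci_high"]


class TestSensitivity:
    def test_zero_inpatient_variant_is_noop(self):
        from helpers import symmetric_config
        from trialcea.costing import build_cost_panel
        from trialcea.outcomes import derive_outcomes
        from trialcea.synthetic import CostParams, generate_trial

        cfg = symmetric_config(
            n_per_arm=(25, 25),
            cost_params=CostParams(inpatient_prob=0.0),
            seed=19,
        )
        data = generate_trial(cfg)
        outcomes, costs = derive_outcomes(data), build_cost_panel(data)
        main_frame = build_cea_frame(outcomes, costs, "societal", "response")
        main = draw_ce_pairs(main_frame, n_draws=40, seed=2)
        variant = sensitivity_suite(
            outcomes, costs, ["exclude_inpatient"], n_draws=40, seed=2
        )["exclude_inpatient"]
        assert variant["delta_cost"] == pytest.approx(summarize(main)["delta_cost"])

    def test_unknown_variant_rejected(self, small_panels):
        outcomes, costs = small_panels
        with pytest.raises(ConfigurationError, match="unknown"):
            sensitivity_suite(outcomes, costs, ["winsorize"])

    def test_indirect_plus_direct_equals_societal_point_estimates(self, small_panels):
        outcomes, costs = small_panels
        societal = estimate_frame(
            build_cea_frame(outcomes, costs, "societal", "response")
        ).delta_cost
        indirect = estimate_frame(
            build_cea_frame(
                outcomes, costs, "societal", "response", indirect_only=True
            )
        ).delta_cost
        direct_costs = costs.copy()
        direct_costs["cum_indirect_only"] = (
            direct_costs["cum_societal"] - direct_costs["cum_indirect_nonmedical"]
        )
        direct = estimate_frame(
            build_cea_frame(
                outcomes, direct_costs, "societal", "response", indirect_only=True
            )
        ).delta_cost
        # additivity is exact only for a fixed GLS weighting; the refitted
        # variance ratios differ, so allow a small tolerance
        assert societal == pytest.approx(indirect + direct, rel=0.05, abs=50.0)

    def test_large_inpatient_outlier_moves_mean_cost(self):
        # single-time frame without baseline adjustment: adding X € to one
        # blended patient moves ΔC by exactly X / n_blended
        rows = []
        for treat in (1.0, 0.0):
            for i in range(20):
                rows.append(
                    {
                        "patient_id": len(rows),
                        "treat": treat,
                        "week": 30,
                        "cost": 1000.0 + 100.0 * (i % 3),
                        "effect": float(i % 2),
                    }
                )
        df = pd.DataFrame(rows)
        from trialcea.models import estimate_cea_effects

        base = estimate_cea_effects(df, "cost", "effect").delta_cost
        bumped = df.copy()
        bumped.loc[0, "cost"] += 5100.0
        moved = estimate_cea_effects(bumped, "cost", "effect").delta_cost
        assert moved - base == pytest.approx(5100.0 / 20, abs=1e-8)


class TestStability:
    def test_dispersion_decreases_with_n(self):
        res = ceac_stability(
            n_grid=(10, 75, 500),
            reps=40,
            wtp_grid=np.arange(0, 80001, 5000),
            seed=2,
        )
        by_n = res.dispersion_by_n()
        assert by_n[500] < by_n[10]

    def test_zero_variance_population_has_zero_dispersion(self):
        pop = PopulationParams(
            cost_mean=(5000, 4000), cost_sd=(0, 0),
            effect_mean=(0.5, 0.4), effect_sd=(0, 0), correlation=0.0,
        )
        res = ceac_stability(
            pop, n_grid=(10, 50), reps=10, wtp_grid=[0, 10000, 20000], seed=3
        )
        assert (res.table["dispersion"] == 0).all()

    def test_default_grid_includes_design_point(self):
        assert 75 in cea.DEFAULT_STABILITY_N_GRID

    def test_smallest_stable_n(self):
        res = ceac_stability(
            n_grid=(10, 75, 500), reps=30,
            wtp_grid=np.arange(0, 80001, 10000), seed=4,
        )
        n = res.smallest_stable_n(threshold=1.0)  # trivially satisfied
        assert n == 10

    def test_bad_grid(self):
        with pytest.raises(ConfigurationError):
            ceac_stability(n_grid=(50, 10), reps=5)


class TestPlots:
    def test_plane_and_ceac_plots_written(self, tmp_path, small_panels):
        outcomes, costs = small_panels
        frame = build_cea_frame(outcomes, costs, "societal", "response")
        pairs = draw_ce_pairs(frame, n_draws=30, seed=6, method="parametric")
        cea.plot_plane(pairs, tmp_path / "plane.png")
        cea.plot_ceac({"main": ceac(pairs)}, tmp_path / "ceac.svg")
        assert (tmp_path / "plane.png").stat().st_size > 0
        assert (tmp_path / "ceac.svg").stat().st_size > 0
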