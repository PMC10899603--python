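"""Techno-economic model: costing, sensitivity, Monte Carlo, breakeven, and
market-scale projection."""

import numpy as np
import pytest

from indikit import tea
from indikit.errors import (
    DistributionError,
    InputError,
    MissingPriceError,
    NoSolutionError,
    UnknownParameterError,
)


def one_item_recipe(price_table=None, amount_kg=1.0):
    """Batch making exactly 1 kg product from one mass-priced item."""
    recipe = tea.Recipe(
        name="toy", volume_L=1.0,
        items=[tea.RecipeItem("indoxyl", mass_kg=amount_kg)],
        product=tea.ProductSpec(molar_mass=1000.0, substrate_conc_M=1.0,
                                conversion=1.0))
    prices = price_table or tea.default_price_table()
    return recipe, prices


class TestCosting:
    def test_single_item_per_kg(self):
        recipe, prices = one_item_recipe()
        bd = tea.material_cost_per_kg(recipe, prices)
        assert bd.total == pytest.approx(5.0)
        assert bd.items == {"indoxyl": pytest.approx(5.0)}

    def test_three_item_recipe_matches_hand_sum(self):
        prices = tea.PriceTable()
        prices.set("a", 2.0)
        prices.set("b", 10.0)
        prices.set("power", 0.12, tea.ENERGY_UNIT)
        recipe = tea.Recipe(
            name="toy3", volume_L=2.0,
            items=[tea.RecipeItem("a", mass_kg=0.5),
                   tea.RecipeItem("b", conc_M=0.1, molar_mass=100.0),
                   tea.RecipeItem("power", energy_kWh=3.0)],
            product=tea.ProductSpec(molar_mass=250.0, substrate_conc_M=0.2,
                                    conversion=0.5))
        # product mass = 2 * 0.2 * 0.5 * 250/1000 = 0.05 kg
        # items: a 0.5*2=1.0; b 0.1*2*100/1000*10=0.2; power 3*0.12=0.36
        bd = tea.material_cost_per_kg(recipe, prices)
        assert bd.total == pytest.approx((1.0 + 0.2 + 0.36) / 0.05)
        assert bd.items["b"] == pytest.approx(0.2 / 0.05)

    def test_homogeneity_in_scale(self):
        recipe, prices = one_item_recipe()
        bd1 = tea.material_cost_per_kg(recipe, prices)
        doubled = tea.Recipe(
            name="x2", volume_L=2.0,
            items=[tea.RecipeItem("indoxyl", mass_kg=2.0)],
            product=recipe.product)
        assert tea.material_cost_per_kg(doubled, prices).total == \
            pytest.approx(bd1.total)

    def test_price_homogeneity_and_additivity(self):
        recipe, prices = one_item_recipe()
        scaled = prices.copy()
        for name, price in prices.entries.items():
            scaled.set(name, price.value * 3.0, price.unit)
        assert tea.material_cost_per_kg(recipe, scaled).total == \
            pytest.approx(3.0 * tea.material_cost_per_kg(recipe, prices).total)
        bd = tea.material_cost_per_kg(tea.default_recipes()["indican_batch"],
                                      prices)
        assert bd.total == pytest.approx(sum(bd.items.values()))

    def test_missing_price_names_item(self):
        recipe, _ = one_item_recipe()
        with pytest.raises(MissingPriceError, match="indoxyl"):
            tea.material_cost_per_kg(recipe, tea.PriceTable())

    def test_unit_mismatch_rejected(self):
        prices = tea.PriceTable()
        prices.set("indoxyl", 5.0, tea.ENERGY_UNIT)
        recipe, _ = one_item_recipe()
        with pytest.raises(InputError):
            tea.material_cost_per_kg(recipe, prices)


class TestCostTarget:
    def test_stated_formula(self):
        assert tea.cost_target(5.0, 3.0, 0.6) == pytest.approx(9.0)
        assert tea.cost_target(1.0, 1.0, 1.0) == 1.0

    def test_linear_in_each_argument(self):
        base = tea.cost_target(5.0, 3.0, 0.6)
        assert tea.cost_target(10.0, 3.0, 0.6) == pytest.approx(2 * base)
        assert tea.cost_target(5.0, 6.0, 0.6) == pytest.approx(2 * base)
        assert tea.cost_target(5.0, 3.0, 1.2) == pytest.approx(2 * base)


class TestSensitivity:
    def test_single_item_price_span(self):
        recipe, prices = one_item_recipe()
        df = tea.sensitivity_tornado(recipe, prices, ["prices.indoxyl"], 0.5)
        assert df.loc[0, "low_cost"] == pytest.approx(2.5)
        assert df.loc[0, "high_cost"] == pytest.approx(7.5)

    def test_zero_share_parameter_has_zero_range(self):
        prices = tea.default_price_table()
        recipe = tea.Recipe(
            name="toy", volume_L=1.0,
            items=[tea.RecipeItem("indoxyl", mass_kg=1.0),
                   tea.RecipeItem("water", mass_kg=0.0)],
            product=tea.ProductSpec(molar_mass=1000.0, substrate_conc_M=1.0,
                                    conversion=1.0))
        df = tea.sensitivity_tornado(recipe, prices, ["prices.water"], 0.5)
        assert df.loc[0, "range"] == pytest.approx(0.0)

    def test_ordering_matches_bruteforce(self):
        prices = tea.default_price_table()
        recipe = tea.default_recipes()["indican_batch"]
        params = ["prices.indoxyl", "prices.sucrose", "prices.enzymes",
                  "prices.citrate_phosphate_buffer",
                  "recipe.product.conversion"]
        df = tea.sensitivity_tornado(recipe, prices, params, 0.5)
        base_eval = tea.material_cost_per_kg

        def brute_range(path):
            v = tea._get_param(recipe, prices, path)
            lo = base_eval(*tea._with_param(recipe, prices, path, 0.5 * v)).total
            hi = base_eval(*tea._with_param(recipe, prices, path, 1.5 * v)).total
            return abs(hi - lo)

        expected = sorted(params, key=brute_range, reverse=True)
        assert list(df["parameter"]) == expected

    def test_unknown_path_rejected(self):
        recipe, prices = one_item_recipe()
        with pytest.raises(UnknownParameterError):
            tea.sensitivity_tornado(recipe, prices, ["prices.unobtainium"])


class TestMonteCarlo:
    def test_point_distributions_reproduce_deterministic_cost(self):
        recipe, prices = one_item_recipe()
        det = tea.material_cost_per_kg(recipe, prices).total
        dists = {"indoxyl": tea.PriceDistribution("indoxyl", "point",
                                                  {"value": 5.0})}
        s = tea.monte_carlo_cost(recipe, prices, dists, n=500, seed=1)
        assert s.mean == s.p5 == s.p50 == s.p95 == pytest.approx(det)

    def test_uniform_mean_converges(self):
        recipe, prices = one_item_recipe()
        dists = {"indoxyl": tea.PriceDistribution(
            "indoxyl", "uniform", {"low": 2.5, "high": 7.5})}
        n = 100_000
        s = tea.monte_carlo_cost(recipe, prices, dists, n=n, seed=3,
                                 keep_samples=True)
        se = s.samples.std(ddof=1) / np.sqrt(n)
        assert abs(s.mean - 5.0) < 3 * se

    def test_same_seed_identical(self):
        recipe, prices = one_item_recipe()
        dists = {"indoxyl": tea.triangular_from_point("indoxyl", 5.0)}
        a = tea.monte_carlo_cost(recipe, prices, dists, n=1000, seed=11)
        b = tea.monte_carlo_cost(recipe, prices, dists, n=1000, seed=11)
        assert (a.mean, a.p5, a.p50, a.p95) == (b.mean, b.p5, b.p50, b.p95)

    def test_invalid_distribution_rejected_before_sampling(self):
        with pytest.raises(DistributionError):
            tea.PriceDistribution("x", "uniform", {"low": 5.0, "high": 1.0})
        with pytest.raises(DistributionError):
            tea.PriceDistribution("x", "triangular",
                                  {"left": -1.0, "mode": 0.0, "right": 1.0})
        with pytest.raises(DistributionError):
            tea.PriceDistribution("x", "gaussian", {"mu": 0, "sigma": 1})

    def test_analytic_means(self):
        assert tea.PriceDistribution("x", "triangular",
                                     {"left": 1, "mode": 2, "right": 6}
                                     ).mean() == pytest.approx(3.0)
        assert tea.PriceDistribution("x", "lognormal",
                                     {"mu": 0.0, "sigma": 0.5}
                                     ).mean() == pytest.approx(np.exp(0.125))


class TestBreakeven:
    def test_matches_closed_form_for_linear_cost(self):
        # per-pair recipe: cost(V) = a + b*V with a = dye cost, b = water
        prices = tea.default_price_table()
        recipe = tea.Recipe(
            name="dye", volume_L=3.2,
            items=[tea.RecipeItem("indican", mass_kg=0.011),
                   tea.RecipeItem("water", conc_M=1000.0 / 18.015,
                                  molar_mass=18.015)],
            functional_unit="pair")
        a = 0.011 * prices["indican"].value
        b = prices["water"].value  # 1 kg water per liter
        target = a + b * 1.9
        found = tea.breakeven(recipe, prices, "recipe.volume_L", target,
                              bounds=(0.1, 10.0))
        assert found == pytest.approx(1.9, rel=1e-6)

    def test_non_bracketing_bounds_report_endpoints(self):
        recipe, prices = one_item_recipe()
        with pytest.raises(NoSolutionError, match="cost"):
            tea.breakeven(recipe, prices, "prices.indoxyl", 100.0,
                          bounds=(1.0, 10.0))

    def test_matches_dense_grid_scan(self):
        prices = tea.default_price_table()
        recipe = tea.default_recipes()["dyeing_enzymatic"]
        target = 0.30
        found = tea.breakeven(recipe, prices, "recipe.items.indican", target,
                              bounds=(1e-4, 0.1))
        grid = np.linspace(1e-4, 0.1, 20001)
        costs = [tea.dyeing_cost_per_jean(
            *tea._with_param(recipe, prices, "recipe.items.indican", g)).total
            for g in grid[::400]]
        # monotone increasing; grid bracketing around the solution
        assert np.all(np.diff(costs) > 0)
        got = tea.dyeing_cost_per_jean(
            *tea._with_param(recipe, prices, "recipe.items.indican",
                             found)).total
        assert got == pytest.approx(target, rel=1e-6)


class TestMarketScale:
    def test_reported_tank_count(self):
        res = tea.market_scale(tea.MarketScaleSpec())
        assert res.tanks_reported == 320
        assert res.tanks_exact == pytest.approx(321.4, abs=0.5)

    def test_doubling_titer_halves_exact_tanks(self):
        base = tea.market_scale(tea.MarketScaleSpec())
        double = tea.market_scale(tea.MarketScaleSpec(batch_titer_M=0.130))
        assert double.tanks_exact == pytest.approx(base.tanks_exact / 2)

    def test_annual_tonnage_matches_hand_arithmetic(self):
        spec = tea.MarketScaleSpec()
        mol = 50_000e6 / 262.3 * 2.0
        assert tea.market_scale(spec).annual_indican_tonnes == \
            pytest.approx(mol * 295.3 / 1e6)

    def test_capacity_covers_demand_at_reported_rounding(self):
        spec = tea.MarketScaleSpec()
        res = tea.market_scale(spec)
        per_tank = spec.batch_titer_M * spec.tank_volume_m3 * 1000 \
            * spec.days_per_year / spec.cycle_days
        demand_mol = 50_000e6 / 262.3 * 2.0
        assert res.tanks_reported * per_tank >= demand_mol * 0.99

    def test_invalid_spec(self):
        with pytest.raises(InputError):
            tea.MarketScaleSpec(tank_volume_m3=0.0)


class TestDyeingPerJean:
    def test_toy_recipe_arithmetic(self):
        prices = tea.PriceTable()
        prices.set("dye", 10.0)
        prices.set("electricity", 0.12, tea.ENERGY_UNIT)
        recipe = tea.Recipe(name="jean", volume_L=1.0,
                            items=[tea.RecipeItem("dye", mass_kg=0.001),
                                   tea.RecipeItem("electricity",
                                                  energy_kWh=0.4)],
                            functional_unit="pair")
        bd = tea.dyeing_cost_per_jean(recipe, prices)
        assert bd.total == pytest.approx(0.058)
        assert bd.total == pytest.approx(sum(bd.items.values()))

    def test_empty_recipe_costs_nothing(self):
        recipe = tea.Recipe(name="none", volume_L=1.0, items=[],
                            functional_unit="pair")
        assert tea.dyeing_cost_per_jean(recipe,
                                        tea.default_price_table()).total == 0.0


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg_text = """
prices:
  indoxyl: 6.0
  magic_dust: {value: 2.5, unit: USD/kg}
recipes:
  toy:
    volume_L: 1.0
    functional_unit: kg
    product: {molar_mass: 1000.0, substrate_conc_M: 1.0, conversion: 1.0}
    items:
      - {name: indoxyl, mass_kg: 1.0}
distributions:
  indoxyl: {family: uniform, low: 3.0, high: 9.0}
market_scale:
  batch_titer_M: 0.13
"""
        p = tmp_path / "tea.yaml"
        p.write_text(cfg_text)
        cfg = tea.load_config(p)
        assert cfg.prices["indoxyl"].value == 6.0
        assert cfg.prices["magic_dust"].value == 2.5
        assert cfg.prices["sucrose"].value == 0.5  # defaults preserved
        assert tea.material_cost_per_kg(cfg.recipes["toy"],
                                        cfg.prices).total == pytest.approx(6.0)
        assert cfg.distributions["indoxyl"].family == "uniform"
        assert cfg.market.batch_titer_M == 0.13
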