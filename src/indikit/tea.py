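"""Techno-economic costing of indican production and denim dyeing.

The model is deliberately simple: raw materials plus electricity, no capital
expenditure, labor, or depreciation.  A :class:`Recipe` lists what one batch
(or one pair of jeans) consumes; a :class:`PriceTable` prices each item in
USD/kg or USD/kWh; costs are additive over items and positively homogeneous
in prices.  On top of the point estimate sit:

* one-at-a-time sensitivity (tornado table),
* Monte-Carlo propagation of price uncertainty (point / uniform /
  triangular / lognormal families),
* a bisection breakeven solver (at which parameter value does the cost hit a
  target?), and
* a market-scale projection converting annual indigo demand into the number
  of batch tanks required for the replacement glycoside.

Aqueous buffer prices are interpreted as USD per kg of prepared solution with
1 L ~ 1 kg.  Utilities other than electricity are excluded; for the
photolytic process electricity is treated as a raw material.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DegenerateRecipeError,
    DistributionError,
    InputError,
    MissingPriceError,
    NoSolutionError,
    UnknownParameterError,
)

# ---------------------------------------------------------------------------
# Prices
# ---------------------------------------------------------------------------

MASS_UNIT = "USD/kg"
ENERGY_UNIT = "USD/kWh"


@dataclass(frozen=True)
class Price:
    value: float
    unit: str = MASS_UNIT

    def __post_init__(self) -> None:
        if self.value < 0:
            raise InputError(f"negative price {self.value}")
        if self.unit not in (MASS_UNIT, ENERGY_UNIT):
            raise InputError(f"unknown price unit {self.unit!r}")


@dataclass
class PriceTable:
    entries: dict[str, Price] = field(default_factory=dict)

    def __getitem__(self, item: str) -> Price:
        try:
            return self.entries[item]
        except KeyError:
            raise MissingPriceError(f"no price for item {item!r}") from None

    def __contains__(self, item: str) -> bool:
        return item in self.entries

    def set(self, item: str, value: float, unit: str = MASS_UNIT) -> None:
        self.entries[item] = Price(value, unit)

    def copy(self) -> "PriceTable":
        return PriceTable(dict(self.entries))


def default_price_table() -> PriceTable:
    """Bulk unit prices for the commodities of the indican process.

    Buffer prices are per kg of prepared solution; electricity is per kWh.
    """
    mass_priced = {
        "indoxyl": 5.0,
        "enzymes": 25.0,
        "udp": 50.0,
        "udp_glucose": 84_900.0,
        "sucrose": 0.5,
        "water": 0.0077,
        "hepes": 246.5,
        "citrate_phosphate_buffer": 0.1,
        "phosphate_buffer": 0.059,
        "hcl": 0.06,
        "caustic_soda": 4.5,
        "sodium_hydrosulphite": 1.15,
        "setamol": 0.04,
        "wetting_agent": 0.09,
        "indican": 15.0,
    }
    table = PriceTable({k: Price(v) for k, v in mass_priced.items()})
    table.set("electricity", 0.12, ENERGY_UNIT)
    return table


# ---------------------------------------------------------------------------
# Recipes
# ---------------------------------------------------------------------------

@dataclass
class RecipeItem:
    """One consumed input: a mass, a molar spec (needs the batch volume), or
    an energy amount."""

    name: str
    mass_kg: float | None = None
    conc_M: float | None = None
    molar_mass: float | None = None   # g/mol, with conc_M
    energy_kWh: float | None = None

    def __post_init__(self) -> None:
        modes = [self.mass_kg is not None,
                 self.conc_M is not None or self.molar_mass is not None,
                 self.energy_kWh is not None]
        if sum(modes) != 1:
            raise InputError(f"item {self.name!r} must specify exactly one of "
                             "mass, molar spec, or energy")
        if self.conc_M is not None and self.molar_mass is None:
            raise InputError(f"item {self.name!r}: molar spec needs molar_mass")

    def amount(self, volume_L: float) -> tuple[float, str]:
        """(amount, pricing unit) in kg or kWh for a batch of ``volume_L``."""
        if self.mass_kg is not None:
            return self.mass_kg, MASS_UNIT
        if self.energy_kWh is not None:
            return self.energy_kWh, ENERGY_UNIT
        return self.conc_M * volume_L * self.molar_mass / 1000.0, MASS_UNIT

    def scaled(self, factor: float) -> "RecipeItem":
        if self.mass_kg is not None:
            return replace(self, mass_kg=self.mass_kg * factor)
        if self.energy_kWh is not None:
            return replace(self, energy_kWh=self.energy_kWh * factor)
        return replace(self, conc_M=self.conc_M * factor)


@dataclass(frozen=True)
class ProductSpec:
    molar_mass: float          # g/mol
    substrate_conc_M: float
    conversion: float
    stoichiometry: float = 1.0  # product per substrate, mol/mol

    def __post_init__(self) -> None:
        if not 0 < self.conversion <= 1:
            raise InputError("conversion must be in (0, 1]")
        if min(self.molar_mass, self.substrate_conc_M, self.stoichiometry) <= 0:
            raise InputError("product spec values must be > 0")


@dataclass
class Recipe:
    name: str
    volume_L: float
    items: list[RecipeItem]
    reaction_time_h: float = 0.0
    product: ProductSpec | None = None
    functional_unit: str = "kg"   # "kg" | "pair"

    def __post_init__(self) -> None:
        if self.volume_L <= 0:
            raise InputError("batch volume must be > 0")
        for item in self.items:
            amt, _ = item.amount(self.volume_L)
            if amt < 0:
                raise InputError(f"negative amount for item {item.name!r}")

    def product_mass_kg(self) -> float:
        if self.product is None:
            raise DegenerateRecipeError(f"recipe {self.name!r} has no product")
        p = self.product
        return (self.volume_L * p.substrate_conc_M * p.conversion
                * p.stoichiometry * p.molar_mass / 1000.0)


@dataclass(frozen=True)
class CostBreakdown:
    items: dict[str, float]
    total: float
    functional_unit: str

    def as_series(self) -> pd.Series:
        return pd.Series(self.items, name=f"USD per {self.functional_unit}")


def _batch_cost(recipe: Recipe, prices: PriceTable) -> dict[str, float]:
    costs: dict[str, float] = {}
    for item in recipe.items:
        amount, unit = item.amount(recipe.volume_L)
        price = prices[item.name]
        if price.unit != unit:
            raise InputError(f"item {item.name!r} priced in {price.unit} but "
                             f"specified in {unit}")
        costs[item.name] = costs.get(item.name, 0.0) + amount * price.value
    return costs


def material_cost_per_kg(recipe: Recipe, prices: PriceTable) -> CostBreakdown:
    """Raw-material cost per kg of product, with per-item breakdown.

    Product mass per batch = volume x substrate concentration x conversion x
    stoichiometry x product molar mass.
    """
    mass = recipe.product_mass_kg()
    if mass <= 0:
        raise DegenerateRecipeError(f"recipe {recipe.name!r} makes no product")
    costs = {k: v / mass for k, v in _batch_cost(recipe, prices).items()}
    return CostBreakdown(items=costs, total=sum(costs.values()),
                         functional_unit="kg")


def dyeing_cost_per_jean(recipe: Recipe, prices: PriceTable) -> CostBreakdown:
    """Cost of dyeing one pair of jeans from a per-pair recipe."""
    if recipe.functional_unit != "pair":
        raise InputError("recipe functional unit must be 'pair'")
    costs = _batch_cost(recipe, prices)
    return CostBreakdown(items=costs, total=sum(costs.values()),
                         functional_unit="pair")


def evaluate_cost(recipe: Recipe, prices: PriceTable) -> CostBreakdown:
    if recipe.functional_unit == "pair":
        return dyeing_cost_per_jean(recipe, prices)
    return material_cost_per_kg(recipe, prices)


def cost_target(base_price: float = 5.0, price_multiplier: float = 3.0,
                material_fraction: float = 0.6) -> float:
    """Raw-material cost target: a fraction of a multiple of the incumbent
    dye's selling price (defaults: 60% of 3x of 5 USD/kg = 9 USD/kg)."""
    if min(base_price, price_multiplier, material_fraction) <= 0:
        raise InputError("cost-target factors must be > 0")
    return base_price * price_multiplier * material_fraction


# ---------------------------------------------------------------------------
# Parameter paths (sensitivity / breakeven)
# ---------------------------------------------------------------------------

def _get_param(recipe: Recipe, prices: PriceTable, path: str) -> float:
    parts = path.split(".")
    try:
        if parts[0] == "prices" and len(parts) == 2:
            return prices[parts[1]].value
        if parts[0] == "recipe":
            if parts[1] == "volume_L":
                return recipe.volume_L
            if parts[1] == "items" and len(parts) == 3:
                for item in recipe.items:
                    if item.name == parts[2]:
                        return item.amount(recipe.volume_L)[0]
                raise KeyError(parts[2])
            if parts[1] == "product" and len(parts) == 3:
                return float(getattr(recipe.product, parts[2]))
    except (KeyError, AttributeError, MissingPriceError):
        pass
    raise UnknownParameterError(f"cannot resolve parameter path {path!r}")


def _with_param(recipe: Recipe, prices: PriceTable, path: str,
                value: float):
    """A deep-copied (recipe, prices) with ``path`` set to ``value``."""
    recipe = copy.deepcopy(recipe)
    prices = prices.copy()
    parts = path.split(".")
    if parts[0] == "prices" and len(parts) == 2:
        prices.set(parts[1], value, prices[parts[1]].unit)
        return recipe, prices
    if parts[0] == "recipe":
        if parts[1] == "volume_L":
            recipe.volume_L = value
            return recipe, prices
        if parts[1] == "items" and len(parts) == 3:
            for i, item in enumerate(recipe.items):
                if item.name == parts[2]:
                    current = item.amount(recipe.volume_L)[0]
                    if current == 0:
                        raise UnknownParameterError(
                            f"item {parts[2]!r} has zero amount")
                    recipe.items[i] = item.scaled(value / current)
                    return recipe, prices
        if parts[1] == "product" and len(parts) == 3 and recipe.product:
            recipe.product = replace(recipe.product, **{parts[2]: value})
            return recipe, prices
    raise UnknownParameterError(f"cannot resolve parameter path {path!r}")


def sensitivity_tornado(recipe: Recipe, prices: PriceTable,
                        parameters: list[str], span: float = 0.5) -> pd.DataFrame:
    """One-at-a-time +/- ``span`` re-evaluation of total cost per parameter.

    Returns a table (parameter, low_cost, high_cost, range) sorted by range
    descending, ready for a tornado plot.
    """
    rows = []
    for path in parameters:
        base = _get_param(recipe, prices, path)
        lo = evaluate_cost(*_with_param(recipe, prices, path,
                                        base * (1 - span))).total
        hi = evaluate_cost(*_with_param(recipe, prices, path,
                                        base * (1 + span))).total
        rows.append((path, lo, hi, abs(hi - lo)))
    df = pd.DataFrame(rows, columns=["parameter", "low_cost", "high_cost",
                                     "range"])
    return df.sort_values("range", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# Price distributions and Monte Carlo
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriceDistribution:
    """Synthetic price uncertainty for one item.

    Families: ``point(value)``, ``uniform(low, high)``,
    ``triangular(left, mode, right)``, ``lognormal(mu, sigma)`` (parameters of
    the underlying normal).  Support must be non-negative.
    """

    item: str
    family: str
    params: dict[str, float]

    def __post_init__(self) -> None:
        p = self.params
        try:
            if self.family == "point":
                ok = p["value"] >= 0
            elif self.family == "uniform":
                ok = 0 <= p["low"] <= p["high"]
            elif self.family == "triangular":
                ok = 0 <= p["left"] <= p["mode"] <= p["right"] \
                    and p["left"] < p["right"]
            elif self.family == "lognormal":
                ok = p["sigma"] > 0
            else:
                raise DistributionError(f"unknown family {self.family!r}")
        except KeyError as exc:
            raise DistributionError(
                f"{self.family} distribution missing parameter {exc}") from None
        if not ok:
            raise DistributionError(
                f"invalid {self.family} parameters for {self.item!r}: {p}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = self.params
        if self.family == "point":
            return np.full(n, p["value"])
        if self.family == "uniform":
            return rng.uniform(p["low"], p["high"], n)
        if self.family == "triangular":
            return rng.triangular(p["left"], p["mode"], p["right"], n)
        return rng.lognormal(p["mu"], p["sigma"], n)

    def mean(self) -> float:
        p = self.params
        if self.family == "point":
            return p["value"]
        if self.family == "uniform":
            return (p["low"] + p["high"]) / 2
        if self.family == "triangular":
            return (p["left"] + p["mode"] + p["right"]) / 3
        return math.exp(p["mu"] + p["sigma"] ** 2 / 2)


def triangular_from_point(item: str, price: float,
                          span: float = 0.5) -> PriceDistribution:
    """Triangular distribution with mode at the printed price, +/- ``span``."""
    return PriceDistribution(item, "triangular",
                             {"left": price * (1 - span), "mode": price,
                              "right": price * (1 + span)})


@dataclass(frozen=True)
class MonteCarloSummary:
    mean: float
    p5: float
    p50: float
    p95: float
    n: int
    samples: np.ndarray | None = None


def monte_carlo_cost(recipe: Recipe, prices: PriceTable,
                     distributions: dict[str, PriceDistribution], n: int,
                     seed: int, keep_samples: bool = False) -> MonteCarloSummary:
    """Propagate price uncertainty through the (price-linear) cost model.

    Items without a distribution are held at their point price; sampling is
    seeded and reproducible.  Because cost is linear in prices, each item's
    amount is computed once and the draws reduce to a weighted sum.
    """
    if n < 100:
        raise InputError("Monte Carlo needs n >= 100 draws")
    for item, dist in distributions.items():
        if dist.item != item:
            raise DistributionError(f"distribution key {item!r} does not match "
                                    f"item {dist.item!r}")
    amounts: dict[str, float] = {}
    for item in recipe.items:
        amt, unit = item.amount(recipe.volume_L)
        if prices[item.name].unit != unit:
            raise InputError(f"item {item.name!r} priced in "
                             f"{prices[item.name].unit} but specified in {unit}")
        amounts[item.name] = amounts.get(item.name, 0.0) + amt
    denom = recipe.product_mass_kg() if recipe.functional_unit == "kg" else 1.0
    if denom <= 0:
        raise DegenerateRecipeError("zero product mass")
    rng = np.random.default_rng(seed)
    total = np.zeros(n)
    for name, amt in amounts.items():
        if name in distributions:
            total += amt * distributions[name].sample(rng, n)
        else:
            total += amt * prices[name].value
    total /= denom
    p5, p50, p95 = np.percentile(total, [5, 50, 95])
    return MonteCarloSummary(mean=float(total.mean()), p5=float(p5),
                             p50=float(p50), p95=float(p95), n=n,
                             samples=total if keep_samples else None)


# ---------------------------------------------------------------------------
# Breakeven
# ---------------------------------------------------------------------------

def breakeven(recipe: Recipe, prices: PriceTable, parameter: str,
              target_cost: float, bounds: tuple[float, float],
              rel_tol: float = 1e-6, max_iter: int = 200) -> float:
    """Parameter value at which total cost equals ``target_cost``.

    Bisection over ``bounds``; the cost must be monotone in the parameter and
    the target bracketed, otherwise ``NoSolutionError`` reports the endpoint
    costs.
    """
    lo, hi = float(bounds[0]), float(bounds[1])
    if not lo < hi:
        raise InputError("bounds must satisfy lo < hi")

    def f(x: float) -> float:
        return evaluate_cost(*_with_param(recipe, prices, parameter, x)).total \
            - target_cost

    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0:
        return lo
    if f_hi == 0:
        return hi
    if f_lo * f_hi > 0:
        raise NoSolutionError(
            f"target {target_cost} not bracketed: cost({lo}) = "
            f"{f_lo + target_cost:.6g}, cost({hi}) = {f_hi + target_cost:.6g}")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if f_mid == 0 or (hi - lo) <= rel_tol * max(abs(mid), 1e-30):
            return mid
        if f_lo * f_mid < 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Market scale
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarketScaleSpec:
    annual_dye_demand_tonnes: float = 50_000.0   # indigo per year
    indigo_molar_mass: float = 262.3             # g/mol
    indican_molar_mass: float = 295.3            # g/mol
    indican_per_indigo: float = 2.0              # mol/mol (2 indoxyl -> 1 indigo)
    batch_titer_M: float = 0.065                 # product, mol/L
    tank_volume_m3: float = 100.0
    cycle_days: float = 2.0
    days_per_year: float = 365.0

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if value <= 0:
                raise InputError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class MarketScaleResult:
    tanks_exact: float
    tanks_reported: int       # 2 significant figures
    annual_indican_tonnes: float


def round_sigfigs(x: float, sigfigs: int = 2) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sigfigs - 1))


def market_scale(spec: MarketScaleSpec = MarketScaleSpec()) -> MarketScaleResult:
    """Number of batch tanks needed to replace the annual indigo market.

    Annual indigo demand (mol) is converted to indican demand via the molar
    ratio; each tank produces titer x volume per batch at ``days_per_year /
    cycle_days`` batches per year.  The headline tank count is rounded to two
    significant figures.
    """
    indigo_mol = spec.annual_dye_demand_tonnes * 1e6 / spec.indigo_molar_mass
    indican_mol = indigo_mol * spec.indican_per_indigo
    per_tank_mol = (spec.batch_titer_M * spec.tank_volume_m3 * 1000.0
                    * spec.days_per_year / spec.cycle_days)
    tanks = indican_mol / per_tank_mol
    annual_tonnes = indican_mol * spec.indican_molar_mass / 1e6
    return MarketScaleResult(tanks_exact=tanks,
                             tanks_reported=int(round_sigfigs(tanks, 2)),
                             annual_indican_tonnes=annual_tonnes)


# ---------------------------------------------------------------------------
# Config file support
# ---------------------------------------------------------------------------

def _recipe_from_dict(name: str, d: dict) -> Recipe:
    items = [RecipeItem(name=i["name"], mass_kg=i.get("mass_kg"),
                        conc_M=i.get("conc_M"), molar_mass=i.get("molar_mass"),
                        energy_kWh=i.get("energy_kWh"))
             for i in d.get("items", [])]
    product = None
    if "product" in d:
        p = d["product"]
        product = ProductSpec(molar_mass=p["molar_mass"],
                              substrate_conc_M=p["substrate_conc_M"],
                              conversion=p["conversion"],
                              stoichiometry=p.get("stoichiometry", 1.0))
    return Recipe(name=name, volume_L=d["volume_L"], items=items,
                  reaction_time_h=d.get("reaction_time_h", 0.0),
                  product=product,
                  functional_unit=d.get("functional_unit", "kg"))


@dataclass
class TeaConfig:
    prices: PriceTable
    recipes: dict[str, Recipe]
    distributions: dict[str, PriceDistribution]
    market: MarketScaleSpec


def load_config(path) -> TeaConfig:
    """Read a YAML process configuration (prices, recipes, distributions,
    market-scale parameters); omitted sections fall back to defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    prices = default_price_table()
    for name, spec in (raw.get("prices") or {}).items():
        if isinstance(spec, dict):
            prices.set(name, float(spec["value"]), spec.get("unit", MASS_UNIT))
        else:
            prices.set(name, float(spec))
    recipes = {name: _recipe_from_dict(name, d)
               for name, d in (raw.get("recipes") or {}).items()}
    dists = {}
    for name, spec in (raw.get("distributions") or {}).items():
        family = spec.pop("family")
        dists[name] = PriceDistribution(name, family,
                                        {k: float(v) for k, v in spec.items()})
    market = MarketScaleSpec(**(raw.get("market_scale") or {}))
    return TeaConfig(prices=prices, recipes=recipes, distributions=dists,
                     market=market)


def default_recipes() -> dict[str, Recipe]:
    """Illustrative built-in process presets (synthetic compositions).

    ``indican_batch`` is a 1 L basis of the enzymatic glycosylation (100 mM
    indoxyl, 65% conversion, sucrose/UDP cofactor recycling, citrate-phosphate
    buffer); ``dyeing_enzymatic`` is a per-pair enzymatic dyeing bath.  Both
    are plausible stand-ins for exploring the cost model, not measured mass
    balances.
    """
    indican = Recipe(
        name="indican_batch", volume_L=1.0, reaction_time_h=24.0,
        items=[
            RecipeItem("indoxyl", conc_M=0.100, molar_mass=133.15),
            RecipeItem("sucrose", conc_M=0.200, molar_mass=342.30),
            RecipeItem("udp", conc_M=0.001, molar_mass=404.16),
            RecipeItem("citrate_phosphate_buffer", mass_kg=1.0),
            RecipeItem("water", mass_kg=1.0),
            RecipeItem("enzymes", mass_kg=0.0005),
        ],
        product=ProductSpec(molar_mass=295.29, substrate_conc_M=0.100,
                            conversion=0.65, stoichiometry=1.0),
        functional_unit="kg",
    )
    dyeing = Recipe(
        name="dyeing_enzymatic", volume_L=3.2, reaction_time_h=4.0,
        items=[
            RecipeItem("indican", mass_kg=0.011),
            RecipeItem("enzymes", mass_kg=0.00075),
            RecipeItem("phosphate_buffer", mass_kg=3.2),
            RecipeItem("water", mass_kg=3.2),
        ],
        functional_unit="pair",
    )
    return {r.name: r for r in (indican, dyeing)}
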