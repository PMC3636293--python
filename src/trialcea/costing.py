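"""Valuation of measured resource use in indexed euros (societal perspective).

Resource counts from 3-month-recall questionnaires are valued with
standardized Dutch unit prices, indexed from their price year to the
analysis index year with consumer price indices, annualized by weighting
each follow-up recall window by the gap since the previous wave, and
summed into a per-participant cost profile.  Medication is costed from
defined daily dosage including VAT, prescription charge and the
statutory pharmacist clawback.  Intervention delivery costs are fixed
per arm, with a sensitivity scenario in which participants' travel and
time costs (friction-cost valued) are folded into the program costs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Dutch consumer price index by year (2006 = 100).
CPI_DEFAULT = {2009: 105.38, 2011: 109.02}

#: Default medication costing constants (overridable per call).
VAT_RATE = 0.06
PRESCRIPTION_CHARGE = 6.00
CLAWBACK_RATE = 0.0682

#: Per-participant intervention delivery costs in euros by arm.  The
#: sensitivity scenario adds the monetary value of participants' travel
#: and time (friction cost approach) to the program costs.
INTERVENTION_COSTS = {
    "primary": {"MTC": 57.70, "MT": 7.70, "UC": 0.00},
    "sensitivity": {"MTC": 141.89, "MT": 82.24, "UC": 0.00},
}


class MissingPriceError(KeyError):
    """A used care category has no unit price."""

    def __init__(self, category: str):
        super().__init__(f"no unit price for category {category!r}")
        self.category = category


class SchemaError(ValueError):
    """Malformed recall-window layout or price table."""


def index_price(price: float, cpi_from: float, cpi_to: float) -> float:
    """Index a price between years by the ratio of consumer price indices."""
    if cpi_from <= 0:
        raise ValueError("cpi_from must be positive")
    if price < 0:
        raise ValueError("price must be non-negative")
    return price * cpi_to / cpi_from


def medication_cost(
    ddd_price: float,
    days: int,
    vat_rate: float = VAT_RATE,
    prescription_charge: float = PRESCRIPTION_CHARGE,
    clawback_rate: float = CLAWBACK_RATE,
) -> float:
    """Cost of a medication course from its defined-daily-dose price.

    ``ddd_price * days`` is discounted by the clawback (the statutory
    pharmacist discount), VAT is added, and a one-off prescription charge
    applies whenever any medication was dispensed.
    """
    if ddd_price < 0 or days < 0 or prescription_charge < 0:
        raise ValueError("medication cost inputs must be non-negative")
    if not (0 <= vat_rate < 1) or not (0 <= clawback_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    if days == 0:
        return 0.0
    return ddd_price * days * (1 - clawback_rate) * (1 + vat_rate) + prescription_charge


@dataclass(frozen=True)
class UnitPrice:
    category: str
    unit_price: float
    price_year: int
    source: str = "standard"  # {standard, real_cost, tariff, lowest}

    def __post_init__(self):
        if self.unit_price < 0:
            raise SchemaError(f"negative unit price for {self.category!r}")


@dataclass
class UnitPriceTable:
    """Care-category unit prices with price-year and indexing metadata."""

    prices: dict[str, UnitPrice]
    index_year: int = 2011
    cpi: dict[int, float] = field(default_factory=lambda: dict(CPI_DEFAULT))

    def __getitem__(self, category: str) -> UnitPrice:
        try:
            return self.prices[category]
        except KeyError:
            raise MissingPriceError(category) from None

    def __contains__(self, category: str) -> bool:
        return category in self.prices

    def indexed_price(self, category: str) -> float:
        """Unit price in index-year euros."""
        p = self[category]
        try:
            cpi_from = self.cpi[p.price_year]
            cpi_to = self.cpi[self.index_year]
        except KeyError as e:
            raise SchemaError(f"no CPI for year {e.args[0]}") from None
        return index_price(p.unit_price, cpi_from, cpi_to)

    @classmethod
    def from_csv(cls, path, index_year: int = 2011,
                 cpi: dict[int, float] | None = None) -> "UnitPriceTable":
        df = pd.read_csv(path)
        required = {"category", "unit_price", "price_year"}
        if not required.issubset(df.columns):
            raise SchemaError(
                f"price CSV must have columns {sorted(required)}; "
                f"got {list(df.columns)}"
            )
        prices = {}
        for _, row in df.iterrows():
            prices[str(row["category"])] = UnitPrice(
                category=str(row["category"]),
                unit_price=float(row["unit_price"]),
                price_year=int(row["price_year"]),
                source=str(row.get("source", "standard")),
            )
        return cls(prices=prices, index_year=index_year,
                   cpi=dict(cpi) if cpi else dict(CPI_DEFAULT))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [
                {
                    "category": p.category,
                    "unit_price": p.unit_price,
                    "price_year": p.price_year,
                    "source": p.source,
                }
                for p in self.prices.values()
            ]
        ).to_csv(path, index=False)

    @classmethod
    def default(cls) -> "UnitPriceTable":
        """The packaged 2009 standardized unit-price table."""
        ref = importlib.resources.files("trialcea.data") / "unit_prices_2009.csv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_csv(path)


@dataclass
class CostProfile:
    """Annual euro amounts for one participant."""

    participant_id: object
    by_category: dict[str, float]
    intervention: float = 0.0
    patient: float = 0.0

    @property
    def overall(self) -> float:
        """Overall health-care-related annual cost (sum of categories)."""
        return float(sum(self.by_category.values()))

    @property
    def total(self) -> float:
        return self.overall + self.intervention + self.patient


def recall_windows(wave_times, recall_years: float = 0.25):
    """(start, end) recall windows for the follow-up waves.

    Each follow-up wave at time t carries a retrospective window
    (t - recall, t]; the baseline questionnaire covers pre-randomization
    use and is excluded from annual totals.
    """
    times = list(wave_times)
    return [(t - recall_years, t) for t in times[1:]]


def annualize_costs(wave_costs, windows) -> float:
    """Scale recall-window costs to an annual total.

    ``wave_costs[i]`` is the euro amount reported in recall window
    ``windows[i] = (start, end)``.  Each window's cost is weighted by
    (gap since the previous window's end) / (recall length), so that
    windows jointly tiling the year pass through unscaled, sparse waves
    are scaled up to cover the uncovered gap, and a recall reaching back
    past the previous wave (or before randomization) is scaled down to
    avoid double counting.  The previous end of the first window is
    taken as time 0 (randomization).
    """
    wave_costs = list(wave_costs)
    windows = [(float(a), float(b)) for a, b in windows]
    if len(wave_costs) != len(windows):
        raise SchemaError("wave_costs and windows must have equal length")
    ends = [b for _a, b in windows]
    if any(b <= a for a, b in windows):
        raise SchemaError("each recall window must have end > start")
    if any(e2 <= e1 for e1, e2 in zip(ends, ends[1:])):
        raise SchemaError("recall windows must be ordered and non-overlapping")
    if any(start < prev_e for prev_e, (start, _end)
           in zip(ends, windows[1:])):
        raise SchemaError("recall windows must be ordered and non-overlapping")
    total = 0.0
    prev_end = 0.0
    for cost, (start, end) in zip(wave_costs, windows):
        gap = end - prev_end
        recall = end - start
        total += cost * gap / recall
        prev_end = end
    return total


def annualization_weights(wave_times, recall_years: float = 0.25) -> np.ndarray:
    """Per-follow-up-wave weights used by :func:`annualize_costs`."""
    windows = recall_windows(wave_times, recall_years)
    prev = [0.0] + [b for _a, b in windows[:-1]]
    return np.array([(b - p) / (b - a) for (a, b), p in zip(windows, prev)])


def intervention_cost(arm: str, scenario: str = "primary") -> float:
    """Per-participant program delivery cost for an arm under a scenario."""
    try:
        by_arm = INTERVENTION_COSTS[scenario]
    except KeyError:
        raise ValueError(f"unknown scenario {scenario!r}") from None
    try:
        return by_arm[arm]
    except KeyError:
        raise ValueError(f"unknown arm {arm!r}") from None


def value_resource_use(
    record: pd.DataFrame,
    prices: UnitPriceTable,
    categories=None,
    recall_years: float = 0.25,
) -> CostProfile:
    """Value one participant's per-wave resource counts into annual euros.

    ``record`` holds that participant's rows of the long-format table
    (one per wave, ordered by ``wave_time``).  Per category, counts are
    multiplied by the indexed unit price and annualized over the
    follow-up recall windows.
    """
    record = record.sort_values("wave_time")
    if categories is None:
        from trialcea.synthetic_trial import COST_CATEGORIES
        categories = [c for c in COST_CATEGORIES if c in record.columns]
    windows = recall_windows(record["wave_time"].tolist(), recall_years)
    by_cat = {}
    for cat in categories:
        counts = record[cat].to_numpy(dtype=float)
        if np.isnan(counts).any():
            raise ValueError(
                f"missing counts for category {cat!r}; impute before valuation"
            )
        price = prices.indexed_price(cat)  # raises MissingPriceError
        by_cat[cat] = annualize_costs(list(counts[1:] * price), windows)
    pid = record["id"].iloc[0] if "id" in record.columns else None
    return CostProfile(participant_id=pid, by_category=by_cat)


def value_costs_table(
    table: pd.DataFrame,
    prices: UnitPriceTable,
    categories=None,
    recall_years: float = 0.25,
) -> pd.DataFrame:
    """Vectorized valuation of every participant in a long-format table.

    Returns one row per participant: per-category annual euros, their sum
    ``health_cost``, plus ``arm``.  Equivalent to mapping
    :func:`value_resource_use` over participants.
    """
    if categories is None:
        from trialcea.synthetic_trial import COST_CATEGORIES
        categories = [c for c in COST_CATEGORIES if c in table.columns]
    for cat in categories:
        if cat not in prices:
            raise MissingPriceError(cat)
    wave_times = np.sort(table["wave_time"].unique())
    weights = annualization_weights(wave_times, recall_years)
    follow = table[table["wave"] > 0].copy()
    wmap = {w: weights[i] for i, w in
            enumerate(sorted(follow["wave"].unique()))}
    follow["_w"] = follow["wave"].map(wmap)
    out = {}
    for cat in categories:
        price = prices.indexed_price(cat)
        contrib = follow[cat] * price * follow["_w"]
        out[cat] = contrib.groupby(follow["id"]).sum(min_count=len(wmap))
    res = pd.DataFrame(out)
    res["health_cost"] = res[list(categories)].sum(axis=1)
    arms = table[table["wave"] == 0].set_index("id")["arm"]
    res.insert(0, "arm", arms)
    res.index.name = "id"
    return res.reset_index()
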