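"""Monetisation of carbon stocks: V = 44/12 · C · P.

Carbon stocks (tC) convert to CO₂-equivalent by the molar mass ratio 44/12;
P is a unit price in CNY per tCO₂e.  Two price schemes are built in:

``market_mean``
    Arithmetic mean of the 2019 transaction prices of China's eight
    regional carbon-trading pilots, 27.76 CNY/tCO₂e.
``optimal_low`` / ``optimal_high``
    A shadow ("optimal") price for forest carbon, quoted per tonne of
    carbon in USD (10.11–15.17 USD/tC), converted to CNY/tCO₂e through the
    12/44 mass ratio and the 2019 mean exchange rate 6.8985 CNY/USD.  The
    lower bound yields 19.02 CNY/tCO₂e.

Scheme prices are presented (and stored) rounded to 2 decimals, mirroring
how published prices are quoted; monetisation itself uses unrounded carbon.
Values are reported both in CNY and in 万 CNY (10⁴ CNY).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

#: tC → tCO₂e molar mass conversion factor.
C_TO_CO2 = 44.0 / 12.0

#: 2019 average transaction prices of the eight regional pilot carbon
#: markets, CNY per tCO₂e.
PILOT_PRICES_CNY_PER_TCO2E_2019: dict[str, float] = {
    "Beijing": 83.27,
    "Shanghai": 41.70,
    "Guangdong": 18.96,
    "Shenzhen": 10.84,
    "Hubei": 29.50,
    "Tianjin": 14.00,
    "Chongqing": 6.91,
    "Fujian": 16.89,
}

#: Shadow-price bounds for forest carbon sequestration, USD per tonne carbon.
OPTIMAL_PRICE_USD_PER_TC = (10.11, 15.17)

#: 2019 mean CNY/USD exchange rate (China Foreign Exchange Trade Center).
EXCHANGE_RATE_CNY_PER_USD_2019 = 6.8985


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, the convention of published money tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class ValuationError(ValueError):
    pass


@dataclass(frozen=True)
class PriceScheme:
    """A unit carbon price with the components it was derived from."""

    name: str
    price_cny_per_tco2e: float
    provenance: dict | None = None

    def __post_init__(self) -> None:
        if self.price_cny_per_tco2e <= 0:
            raise ValuationError("price must be positive")


def market_mean_price(
    pilot_prices: Mapping[str, float] | Sequence[float] | None = None,
) -> PriceScheme:
    """Arithmetic mean of pilot-market prices, rounded to 2 decimals."""
    if pilot_prices is None:
        pilot_prices = PILOT_PRICES_CNY_PER_TCO2E_2019
    values = list(
        pilot_prices.values() if isinstance(pilot_prices, Mapping) else pilot_prices
    )
    if not values:
        raise ValuationError("need at least one pilot price")
    if any(p <= 0 for p in values):
        raise ValuationError("pilot prices must be positive")
    price = round_half_up(sum(values) / len(values))
    return PriceScheme(
        "market_mean", price, provenance={"pilot_prices_cny_per_tco2e": list(values)}
    )


def optimal_price(
    usd_per_tc: float,
    exchange_cny_per_usd: float = EXCHANGE_RATE_CNY_PER_USD_2019,
    name: str = "optimal",
) -> PriceScheme:
    """Convert a USD-per-tonne-carbon shadow price to CNY per tCO₂e.

    price = usd_per_tc · (12/44) · exchange, rounded to 2 decimals.
    """
    if usd_per_tc <= 0 or exchange_cny_per_usd <= 0:
        raise ValuationError("price components must be positive")
    price = round_half_up(usd_per_tc / C_TO_CO2 * exchange_cny_per_usd)
    return PriceScheme(
        name,
        price,
        provenance={
            "usd_per_tC": usd_per_tc,
            "exchange_cny_per_usd": exchange_cny_per_usd,
        },
    )


def monetize(stock_groups: pd.DataFrame, scheme: PriceScheme) -> pd.DataFrame:
    """Value each group of an aggregated stock frame under one price scheme.

    ``stock_groups`` must have columns carbon_tC and area_hm2 (the output of
    ``StockTable.by``).  Adds value_cny = 44/12 · C · P, value_wan_cny
    (value/10⁴) and value_cny_per_hm2 (0 where area is 0).
    """
    out = stock_groups.copy()
    out["value_cny"] = C_TO_CO2 * out["carbon_tC"] * scheme.price_cny_per_tco2e
    out["value_wan_cny"] = out["value_cny"] / 1e4
    area = out["area_hm2"].to_numpy(float)
    value = out["value_cny"].to_numpy(float)
    out["value_cny_per_hm2"] = [v / a if a > 0 else 0.0 for v, a in zip(value, area)]
    out.attrs["scheme"] = scheme.name
    return out


def average_valuation(v1: pd.DataFrame, v2: pd.DataFrame) -> pd.DataFrame:
    """Row-wise mean of two valuations of the same stocks.

    Equivalent (exactly, by linearity) to valuing once at the mean of the
    two scheme prices.  Groups and carbon must match.
    """
    if not v1.index.equals(v2.index):
        raise ValuationError("valuations cover different groups")
    if not v1["carbon_tC"].equals(v2["carbon_tC"]):
        raise ValuationError("valuations price different carbon stocks")
    out = v1.copy()
    for col in ("value_cny", "value_wan_cny", "value_cny_per_hm2"):
        out[col] = (v1[col] + v2[col]) / 2.0
    out.attrs["scheme"] = f"mean({v1.attrs.get('scheme')}, {v2.attrs.get('scheme')})"
    return out
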