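"""Dependent variables of the three models, and the shared log convention.

For each zone and calendar month (pooled across years) the filtered
measurements yield the count, mean, sample SD, coefficient of variation
(SD/mean), and empirical percentiles.  Pairs with fewer than ``min_n``
measurements are excluded and logged.  All models fit on
``ln(x + delta)`` and report on the back-transformed pCi/L scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_QUANTILES",
    "zone_month_stats",
    "log_transform",
    "back_transform",
    "ZoneMonthResult",
]

DEFAULT_QUANTILES = (0.50, 0.75, 0.90)
DEFAULT_LOG_OFFSET = 0.1  # pCi/L; a measured value of exactly 0 is admissible


@dataclass
class ZoneMonthResult:
    table: pd.DataFrame  # zone_id, month, n, mean, sd, cov, p50, p75, p90, ...
    excluded: list[dict] = field(default_factory=list)  # {"zone_id","month","n","reason"}


def zone_month_stats(
    measurements: pd.DataFrame,
    min_n: int = 10,
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES,
) -> ZoneMonthResult:
    """Per zone x calendar-month statistics of filtered measurements.

    ``month`` is the calendar month of ``start_date`` pooled across years.
    ``sd`` is the sample standard deviation (ddof=1); percentiles use
    linear interpolation between closest order statistics.  Pairs with
    ``n < min_n`` are excluded and counted; a pair with mean 0 has an
    undefined CoV and is dropped with a distinct reason.
    """
    df = measurements.copy()
    df["month"] = pd.to_datetime(df["start_date"]).dt.month
    rows, excluded = [], []
    for (zone, month), grp in df.groupby(["zone_id", "month"], sort=True):
        n = len(grp)
        if n < min_n:
            excluded.append(
                {"zone_id": zone, "month": int(month), "n": n, "reason": f"n < {min_n}"}
            )
            continue
        v = grp["value"].to_numpy(dtype=float)
        mean = float(v.mean())
        if mean == 0.0:
            excluded.append(
                {"zone_id": zone, "month": int(month), "n": n, "reason": "mean == 0, CoV undefined"}
            )
            continue
        sd = float(v.std(ddof=1))
        row = {
            "zone_id": zone,
            "month": int(month),
            "n": n,
            "mean": mean,
            "sd": sd,
            "cov": sd / mean,
        }
        for q in quantiles:
            row[f"p{int(round(q * 100)):02d}"] = float(np.quantile(v, q))
        rows.append(row)
    table = pd.DataFrame(rows)
    return ZoneMonthResult(table=table, excluded=excluded)


def log_transform(values, offset: float = DEFAULT_LOG_OFFSET) -> np.ndarray:
    """z = ln(x + offset); raises if any x + offset <= 0."""
    x = np.asarray(values, dtype=float)
    if np.any(x + offset <= 0):
        raise ValueError(f"log_transform requires x + {offset} > 0 for all values")
    return np.log(x + offset)


def back_transform(values, offset: float = DEFAULT_LOG_OFFSET) -> np.ndarray:
    """Inverse of :func:`log_transform`: x = exp(z) - offset."""
    z = np.asarray(values, dtype=float)
    return np.exp(z) - offset
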