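"""Agro-climatic indices from daily weather, windowed by planting date.

Indices use conventional definitions: growing degree days from the simple
daily mean, dry days below 1 mm, heat days above a strict threshold. All
windows are half-open: [planting_date, planting_date + duration_days).
Outputs feed the covariate table unchanged.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

__all__ = [
    "DailyWeather",
    "WeatherError",
    "link_weather_window",
    "growing_degree_days",
    "max_dry_spell",
    "heat_days",
]


class WeatherError(ValueError):
    pass


@dataclass(frozen=True)
class DailyWeather:
    date: dt.date
    tmin: float
    tmax: float
    precip: float

    def __post_init__(self) -> None:
        if self.tmin > self.tmax:
            raise WeatherError(
                f"{self.date}: tmin {self.tmin} exceeds tmax {self.tmax}"
            )
        if self.precip < 0:
            raise WeatherError(f"{self.date}: negative precipitation {self.precip}")


def link_weather_window(
    series: list[DailyWeather], planting_date: dt.date, duration_days: int
) -> list[DailyWeather]:
    """Extract the gap-free window [planting_date, planting_date + duration)."""
    if duration_days < 0:
        raise WeatherError(f"negative duration {duration_days}")
    if duration_days == 0:
        return []
    by_date = {d.date: d for d in series}
    wanted = [planting_date + dt.timedelta(days=k) for k in range(duration_days)]
    missing = [d for d in wanted if d not in by_date]
    if missing:
        shown = ", ".join(str(d) for d in missing[:10])
        more = f" (+{len(missing) - 10} more)" if len(missing) > 10 else ""
        raise WeatherError(f"weather series missing dates: {shown}{more}")
    return [by_date[d] for d in wanted]


def _require_window(window: list[DailyWeather]) -> None:
    if not window:
        raise WeatherError("empty weather window")


def growing_degree_days(window: list[DailyWeather], t_base: float) -> float:
    """Sum over days of max(0, (tmax + tmin)/2 - t_base)."""
    _require_window(window)
    return float(
        sum(max(0.0, (d.tmax + d.tmin) / 2.0 - t_base) for d in window)
    )


def max_dry_spell(window: list[DailyWeather], threshold_mm: float = 1.0) -> int:
    """Longest run of consecutive days with precip < threshold_mm."""
    _require_window(window)
    longest = run = 0
    for d in window:
        if d.precip < threshold_mm:
            run += 1
            longest = max(longest, run)
        else:
            run = 0
    return longest


def heat_days(window: list[DailyWeather], t_crit: float) -> int:
    """Count of days with tmax strictly above t_crit."""
    _require_window(window)
    return sum(1 for d in window if d.tmax > t_crit)
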