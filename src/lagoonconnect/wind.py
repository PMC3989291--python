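"""Daily wind series: synthetic generation and CSV/NetCDF I/O.

The generator emulates a multi-year trade-wind climate as a seasonally
weighted *sticky* Markov mixture over a small set of wind regimes. Each
regime has a mean speed and meteorological direction (degrees the wind
comes *from*, clockwise from north) with normal scatter, and monthly
occurrence weights that shift the regime mixture through the year.
Persistence keeps the chain in one regime for a configurable number of
days on average, so that 30-day windows tend to be dominated by a single
regime — the structure the downstream regime classification presumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RegimeSpec",
    "WindSeries",
    "generate_wind_series",
    "read_wind_csv",
    "write_wind_csv",
    "direction_to_uv",
    "uv_to_speed_direction",
]


class WindFormatError(ValueError):
    """Malformed wind series file."""


def direction_to_uv(speed, direction_deg):
    """(u, v) from speed and meteorological direction (coming-from).

    u = -speed * sin(dir), v = -speed * cos(dir): an easterly wind
    (dir = 90 deg) blows toward the west (u < 0).
    """
    rad = np.deg2rad(direction_deg)
    return -speed * np.sin(rad), -speed * np.cos(rad)


def uv_to_speed_direction(u, v):
    """Speed and meteorological direction (deg) from components."""
    speed = np.hypot(u, v)
    direction = (np.degrees(np.arctan2(-u, -v))) % 360.0
    return speed, direction


@dataclass(frozen=True)
class RegimeSpec:
    """Statistical description of one wind regime for the generator.

    Monthly weights (length 12, Jan..Dec) set the regime's seasonal
    occurrence; they need not be normalized.
    """

    mean_speed: float
    mean_direction: float
    speed_sd: float = 1.0
    direction_sd: float = 15.0
    monthly_weights: tuple = (1.0,) * 12

    def __post_init__(self):
        if self.mean_speed < 0 or self.speed_sd < 0 or self.direction_sd < 0:
            raise ValueError("speed and SDs must be >= 0")
        if len(self.monthly_weights) != 12 or any(w < 0 for w in self.monthly_weights):
            raise ValueError("monthly_weights must be 12 non-negative numbers")


@dataclass
class WindSeries:
    """Gap-free daily wind series with zonal/meridian components (m/s)."""

    dates: pd.DatetimeIndex
    u: np.ndarray
    v: np.ndarray
    regime_labels: np.ndarray | None = None  # generator truth, if synthetic

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        n = len(self.dates)
        if self.u.shape != (n,) or self.v.shape != (n,):
            raise WindFormatError("u, v must match the date axis")
        if n > 1:
            deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
            if np.any(deltas != 1):
                raise WindFormatError("dates must be strictly daily with no gaps")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise WindFormatError("wind components must be finite")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    @property
    def direction(self) -> np.ndarray:
        return uv_to_speed_direction(self.u, self.v)[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "u": self.u, "v": self.v})


def generate_wind_series(
    start_date,
    end_date,
    regime_specs: list[RegimeSpec],
    persistence_days: float = 10.0,
    seed: int = 0,
) -> WindSeries:
    """Draw a daily (u, v) series from a seasonal sticky Markov mixture.

    Each day the chain either stays in its current regime (probability
    ``1 - 1/persistence_days``) or jumps to a regime drawn from the
    current month's weights. Within a regime, speed is normal (truncated
    at 0) and direction normal in degrees. Deterministic per seed.
    """
    if not regime_specs:
        raise ValueError("need at least one regime spec")
    dates = pd.date_range(start_date, end_date, freq="D")
    n = len(dates)
    if n == 0:
        return WindSeries(dates=dates, u=np.empty(0), v=np.empty(0),
                          regime_labels=np.empty(0, int))
    weights = np.array([spec.monthly_weights for spec in regime_specs], dtype=float)  # (k, 12)
    month_w = weights / weights.sum(axis=0, keepdims=True)
    if not np.all(np.isfinite(month_w)):
        raise ValueError("every month needs at least one positive regime weight")

    rng = np.random.default_rng(seed)
    stay = max(0.0, 1.0 - 1.0 / max(persistence_days, 1.0))
    months = dates.month.values - 1
    labels = np.empty(n, dtype=int)
    labels[0] = rng.choice(len(regime_specs), p=month_w[:, months[0]])
    for t in range(1, n):
        if rng.random() < stay:
            labels[t] = labels[t - 1]
        else:
            labels[t] = rng.choice(len(regime_specs), p=month_w[:, months[t]])

    speeds = np.empty(n)
    dirs = np.empty(n)
    for r, spec in enumerate(regime_specs):
        sel = labels == r
        m = int(sel.sum())
        if m == 0:
            continue
        speeds[sel] = np.maximum(rng.normal(spec.mean_speed, spec.speed_sd, m), 0.0)
        dirs[sel] = rng.normal(spec.mean_direction, spec.direction_sd, m)
    u, v = direction_to_uv(speeds, dirs)
    return WindSeries(dates=dates, u=u, v=v, regime_labels=labels)


def write_wind_csv(series: WindSeries, path) -> None:
    """Write a wind series as date,u,v CSV (ISO-8601 dates)."""
    df = series.to_frame()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def read_wind_csv(path) -> WindSeries:
    """Read a date,u,v CSV into a validated :class:`WindSeries`."""
    df = pd.read_csv(path)
    missing = {"date", "u", "v"} - set(df.columns)
    if missing:
        raise WindFormatError(f"missing columns: {sorted(missing)}")
    try:
        dates = pd.DatetimeIndex(pd.to_datetime(df["date"], format="ISO8601"))
        u = df["u"].astype(float).to_numpy()
        v = df["v"].astype(float).to_numpy()
    except (ValueError, TypeError) as exc:
        raise WindFormatError(f"unparseable wind series: {exc}") from exc
    if dates.has_duplicates:
        raise WindFormatError("duplicate dates in wind series")
    return WindSeries(dates=dates, u=u, v=v)
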