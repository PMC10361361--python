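"""Convert raw GPS fixes into per-animal-year daily step/turn series.

The processing chain mirrors standard daily-movement workflows for collared
ungulates: fixes are grouped into biological years (July 1 - June 30),
resampled to one location per day (the fix closest in time to 06:00), and
converted into step lengths (km) and turning angles (radians).  Days without
a usable fix yield explicitly MISSING steps/turns so that the downstream
hidden Markov model sees a complete daily grid.

Coordinates are planar meters (projected CRS) by default; a geodesic mode
(spherical great-circle distances and forward azimuths) is available for
lon/lat input.  Neither mode is asserted to be "the" original convention —
both occur in practice.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "DailyStepSeries",
    "assign_biological_day",
    "biological_day_to_date",
    "resample_daily",
    "build_step_series",
    "process_fixes",
    "read_fixes_csv",
    "write_series_csv",
    "read_series_csv",
    "wrap_angle",
]

#: Sentinel for an unobserved step or turn (NaN in arrays, empty field in CSV).
MISSING = np.nan

#: Steps shorter than this are floored so the gamma density stays finite.
MIN_STEP_KM = 1e-3

_EARTH_RADIUS_KM = 6371.0088

# Days from July 1 to Dec 31 inclusive (always 184, leap-independent).
_JUL_DEC_DAYS = 184


@dataclass
class DailyStepSeries:
    """One animal-year's daily observation sequence for the HMM.

    ``day`` is the day of the biological year (July 1 = 1, June 30 = 365) and
    forms a complete, consecutive grid from ``start_day`` to the last observed
    day.  ``step_km`` / ``turn_rad`` are NaN (:data:`MISSING`) on days where
    the quantity is undefined: the first grid day has no step, the first two
    have no turn, and any day adjacent to a fix gap loses the quantities that
    span the gap.
    """

    animal_year_id: str
    bio_year: int
    start_day: int
    day: np.ndarray
    step_km: np.ndarray
    turn_rad: np.ndarray

    def __post_init__(self) -> None:
        self.day = np.asarray(self.day, dtype=int)
        self.step_km = np.asarray(self.step_km, dtype=float)
        self.turn_rad = np.asarray(self.turn_rad, dtype=float)
        if len(self.day) == 0:
            raise ValueError("empty series")
        if not np.all(np.diff(self.day) == 1):
            raise ValueError("day grid must be consecutive")
        if self.day[0] != self.start_day:
            raise ValueError("start_day does not match day grid")
        obs = self.step_km[~np.isnan(self.step_km)]
        if np.any(obs <= 0):
            raise ValueError("observed steps must be positive")

    def __len__(self) -> int:
        return len(self.day)

    @property
    def n_observed_steps(self) -> int:
        return int(np.sum(~np.isnan(self.step_km)))

    @property
    def missing_step_fraction(self) -> float:
        """Fraction of grid days after the first whose step is MISSING."""
        if len(self) <= 1:
            return 0.0
        return float(np.mean(np.isnan(self.step_km[1:])))


def wrap_angle(theta):
    """Wrap angle(s) to the interval (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    out = -((-theta + np.pi) % (2.0 * np.pi) - np.pi)
    return out if out.ndim else float(out)


def assign_biological_day(timestamp) -> tuple[int, int]:
    """Map a timestamp to ``(bio_year, day)`` with July 1 = day 1.

    The biological year runs July 1 - June 30 and is labelled by the calendar
    year containing its July 1 start.  Feb 29 of a leap year shares Feb 28's
    index, so ``day`` is always in 1..365.
    """
    ts = pd.Timestamp(timestamp)
    d = ts.date()
    if d.month >= 7:
        bio_year = d.year
        day = (d - _dt.date(d.year, 7, 1)).days + 1
    else:
        bio_year = d.year - 1
        day_jan = (d - _dt.date(d.year, 1, 1)).days + 1  # 1..366
        leap = d.year % 4 == 0 and (d.year % 100 != 0 or d.year % 400 == 0)
        if leap and day_jan >= 60:  # Feb 29 onward collapse onto Feb 28
            day_jan -= 1
        day = _JUL_DEC_DAYS + day_jan
    return bio_year, day


def biological_day_to_date(bio_year: int, day: int) -> _dt.date:
    """Inverse of :func:`assign_biological_day` (Feb 29 is never produced)."""
    if not 1 <= day <= 365:
        raise ValueError(f"day must be in 1..365, got {day}")
    if day <= _JUL_DEC_DAYS:
        return _dt.date(bio_year, 7, 1) + _dt.timedelta(days=day - 1)
    year = bio_year + 1
    day_jan = day - _JUL_DEC_DAYS
    leap = year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)
    if leap and day_jan >= 60:
        day_jan += 1  # skip Feb 29
    return _dt.date(year, 1, 1) + _dt.timedelta(days=day_jan - 1)


def resample_daily(fixes: pd.DataFrame) -> pd.DataFrame:
    """Keep, per calendar day, the single fix closest in time to 06:00.

    Ties (fixes equidistant from 06:00) go to the earlier fix.  ``fixes``
    must belong to one animal and be sorted by timestamp.
    """
    if len(fixes) == 0:
        return fixes.copy()
    ts = pd.to_datetime(fixes["timestamp"])
    secs = (
        ts.dt.hour * 3600 + ts.dt.minute * 60 + ts.dt.second
    ).to_numpy(dtype=float)
    offset = np.abs(secs - 6 * 3600)
    tmp = fixes.copy()
    tmp["_date"] = ts.dt.date
    tmp["_offset"] = offset
    # stable sort: equidistant fixes keep input (time) order -> earlier wins
    tmp = tmp.sort_values(["_date", "_offset"], kind="stable")
    out = tmp.groupby("_date", sort=True).head(1)
    return out.drop(columns=["_date", "_offset"]).reset_index(drop=True)


def _planar_steps_bearings(x, y):
    dx, dy = np.diff(x), np.diff(y)
    dist_km = np.hypot(dx, dy) / 1000.0
    bearing = np.arctan2(dy, dx)  # CCW from +x
    return dist_km, bearing


def _geodesic_steps_bearings(lon, lat):
    lon, lat = np.radians(lon), np.radians(lat)
    lon1, lon2 = lon[:-1], lon[1:]
    lat1, lat2 = lat[:-1], lat[1:]
    dlon, dlat = lon2 - lon1, lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    dist_km = 2 * _EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    # forward azimuth, clockwise from north; converted to CCW-from-east so the
    # turning-angle sign convention matches the planar mode
    az = np.arctan2(
        np.sin(dlon) * np.cos(lat2),
        np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon),
    )
    return dist_km, np.pi / 2 - az


def build_step_series(
    daily_fixes: pd.DataFrame,
    bio_year: int,
    *,
    geodesic: bool = False,
    animal_year_id: str | None = None,
) -> DailyStepSeries:
    """Turn one animal-year's daily fixes into a :class:`DailyStepSeries`.

    The step on grid day ``t`` is the distance (km) between the day ``t-1``
    and day ``t`` locations; the turn on day ``t`` is the deviation of the
    ``t-1 -> t`` bearing from the ``t-2 -> t-1`` bearing (counterclockwise
    positive, wrapped to (-pi, pi]).  Either quantity is MISSING whenever any
    of the days it spans was not observed.
    """
    if len(daily_fixes) < 3:
        raise ValueError(
            f"animal-year rejected: need >=3 daily fixes, got {len(daily_fixes)}"
        )
    days = np.array(
        [assign_biological_day(t)[1] for t in daily_fixes["timestamp"]], dtype=int
    )
    years = np.array(
        [assign_biological_day(t)[0] for t in daily_fixes["timestamp"]], dtype=int
    )
    if not np.all(years == bio_year):
        raise ValueError("fixes span more than one biological year")
    if np.any(np.diff(days) < 1):
        raise ValueError("daily fixes must be strictly increasing in day")

    x = daily_fixes["x"].to_numpy(dtype=float)
    y = daily_fixes["y"].to_numpy(dtype=float)
    if geodesic:
        seg_km, bearing = _geodesic_steps_bearings(x, y)
    else:
        seg_km, bearing = _planar_steps_bearings(x, y)

    start_day, last_day = int(days[0]), int(days[-1])
    grid = np.arange(start_day, last_day + 1)
    t_len = len(grid)
    step = np.full(t_len, MISSING)
    turn = np.full(t_len, MISSING)

    pos = {int(d): i for i, d in enumerate(days)}  # day -> fix index
    for gi, d in enumerate(grid[1:], start=1):
        d = int(d)
        if d in pos and (d - 1) in pos and pos[d] == pos[d - 1] + 1:
            step[gi] = max(seg_km[pos[d] - 1], MIN_STEP_KM)
            if (d - 2) in pos and pos[d - 1] == pos[d - 2] + 1:
                turn[gi] = wrap_angle(bearing[pos[d] - 1] - bearing[pos[d] - 2])

    aid = animal_year_id
    if aid is None:
        base = str(daily_fixes["animal_id"].iloc[0]) if "animal_id" in daily_fixes else "animal"
        aid = f"{base}_{bio_year}"
    return DailyStepSeries(aid, bio_year, start_day, grid, step, turn)


def process_fixes(
    fixes: pd.DataFrame, *, geodesic: bool = False
) -> tuple[list[DailyStepSeries], list[str]]:
    """Full pipeline: raw fixes -> independent per-animal-year daily series.

    Returns the series list plus diagnostics for rejected animal-years
    (fewer than 3 daily fixes).
    """
    fixes = fixes.copy()
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"])
    if not np.isfinite(fixes[["x", "y"]].to_numpy(dtype=float)).all():
        raise ValueError("non-finite coordinates in input")
    fixes = fixes.sort_values(["animal_id", "timestamp"], kind="stable")
    fixes = fixes.drop_duplicates(subset=["animal_id", "timestamp"])

    by = np.array([assign_biological_day(t)[0] for t in fixes["timestamp"]])
    fixes["_bio_year"] = by

    series: list[DailyStepSeries] = []
    rejected: list[str] = []
    for (animal, year), grp in fixes.groupby(["animal_id", "_bio_year"], sort=True):
        daily = resample_daily(grp.drop(columns="_bio_year"))
        aid = f"{animal}_{year}"
        if len(daily) < 3:
            rejected.append(f"{aid}: only {len(daily)} daily fixes (<3)")
            continue
        series.append(
            build_step_series(daily, int(year), geodesic=geodesic, animal_year_id=aid)
        )
    return series, rejected


def read_fixes_csv(path) -> pd.DataFrame:
    """Read a fix table (animal_id, timestamp ISO-8601, x, y)."""
    df = pd.read_csv(path)
    required = {"animal_id", "timestamp", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fix CSV missing columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def write_series_csv(series_list: list[DailyStepSeries], path) -> None:
    """Write daily series as CSV; MISSING becomes an empty field."""
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "animal_year_id": s.animal_year_id,
                    "bio_year": s.bio_year,
                    "day": s.day,
                    "step_km": s.step_km,
                    "turn_rad": s.turn_rad,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, na_rep="")


def read_series_csv(path) -> list[DailyStepSeries]:
    df = pd.read_csv(path)
    out = []
    for aid, grp in df.groupby("animal_year_id", sort=True):
        grp = grp.sort_values("day")
        out.append(
            DailyStepSeries(
                str(aid),
                int(grp["bio_year"].iloc[0]),
                int(grp["day"].iloc[0]),
                grp["day"].to_numpy(),
                grp["step_km"].to_numpy(dtype=float),
                grp["turn_rad"].to_numpy(dtype=float),
            )
        )
    return out
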