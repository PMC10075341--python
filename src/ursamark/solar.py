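"""Solar events, diel periods, sun-relative time, RIC and actogram tables.

Sunrise/sunset use the NOAA solar-position equations at the official zenith
of 90.833 degrees (solar centre 50 arcminutes below the horizon, i.e.
refraction + solar radius), which agree with published almanac times to
about a minute at mid-latitudes.  No external ephemeris library is needed.

Diel periods follow the 2-h-window convention: *sunrise* is the hour before
to the hour after official sunrise, *sunset* likewise around official
sunset, *day* runs from 1 h after sunrise to 1 h before sunset, and *night*
covers the rest.  The four periods tile the 24-h day exactly.

Sun-relative time maps clock time onto [-1, +1] through a five-anchor
piecewise-linear transform (solar midnight -1, sunrise -0.5, solar noon 0,
sunset +0.5, next solar midnight +1), removing seasonal day-length
variation so that e.g. "just before sunset" is the same number in January
and June.
"""

from __future__ import annotations

import calendar
import math
from dataclasses import dataclass
from datetime import date as date_cls
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd

from .errors import DataConsistencyError, UnsupportedLatitudeError
from .ethogram import VISUAL_BEHAVIORS

PERIODS = ("sunrise", "day", "sunset", "night")

_OFFICIAL_ZENITH_DEG = 90.833


@dataclass(frozen=True)
class SolarDay:
    """Official sunrise/sunset (UTC) for one site and calendar date."""

    date: date_cls
    site_id: str
    sunrise: datetime
    sunset: datetime

    @property
    def noon(self) -> datetime:
        """Midpoint of sunrise and sunset (solar noon)."""
        return self.sunrise + (self.sunset - self.sunrise) / 2

    @property
    def day_length_hours(self) -> float:
        return (self.sunset - self.sunrise).total_seconds() / 3600


def _julian_day(dt: datetime) -> float:
    """Julian day number of a UTC datetime (astronomical convention)."""
    frac = (dt.hour + dt.minute / 60 + dt.second / 3600) / 24
    return dt.toordinal() + 1721424.5 + frac


def _solar_geometry(jd: float):
    """NOAA ephemeris terms: (declination deg, equation of time minutes)."""
    t = (jd - 2451545.0) / 36525.0
    l0 = (280.46646 + t * (36000.76983 + 0.0003032 * t)) % 360
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    e = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    mrad = math.radians(m)
    c = (
        math.sin(mrad) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + math.sin(2 * mrad) * (0.019993 - 0.000101 * t)
        + math.sin(3 * mrad) * 0.000289
    )
    true_long = l0 + c
    omega = math.radians(125.04 - 1934.136 * t)
    app_long = math.radians(true_long - 0.00569 - 0.00478 * math.sin(omega))
    eps0 = 23 + (26 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60) / 60
    eps = math.radians(eps0 + 0.00256 * math.cos(omega))
    decl = math.asin(math.sin(eps) * math.sin(app_long))

    y = math.tan(eps / 2) ** 2
    l0r = math.radians(l0)
    eot = 4 * math.degrees(
        y * math.sin(2 * l0r)
        - 2 * e * math.sin(mrad)
        + 4 * e * y * math.sin(mrad) * math.cos(2 * l0r)
        - 0.5 * y * y * math.sin(4 * l0r)
        - 1.25 * e * e * math.sin(2 * mrad)
    )
    return math.degrees(decl), eot


def solar_events(site, date) -> SolarDay:
    """Official sunrise and sunset (UTC) at a site on a calendar date.

    Raises :class:`UnsupportedLatitudeError` under polar day/night, when
    the sun never crosses the official zenith.
    """
    if isinstance(date, datetime):
        date = date.date()
    lat, lon = site.latitude, site.longitude
    # evaluate ephemeris terms at the site's approximate solar noon
    approx_noon = datetime(date.year, date.month, date.day, 12, tzinfo=timezone.utc)
    decl, eot = _solar_geometry(_julian_day(approx_noon) - lon / 360.0)

    latr, declr = math.radians(lat), math.radians(decl)
    cos_ha = (
        math.cos(math.radians(_OFFICIAL_ZENITH_DEG)) / (math.cos(latr) * math.cos(declr))
        - math.tan(latr) * math.tan(declr)
    )
    if not -1 <= cos_ha <= 1:
        raise UnsupportedLatitudeError(
            f"no official sunrise/sunset at latitude {lat} on {date} (polar day/night)"
        )
    ha_deg = math.degrees(math.acos(cos_ha))
    noon_min = 720 - 4 * lon - eot  # minutes UTC
    midnight = datetime(date.year, date.month, date.day, tzinfo=timezone.utc)
    sunrise = midnight + timedelta(minutes=noon_min - 4 * ha_deg)
    sunset = midnight + timedelta(minutes=noon_min + 4 * ha_deg)
    return SolarDay(date=date, site_id=site.site_id, sunrise=sunrise, sunset=sunset)


def classify_period(timestamp: datetime, solar_day: SolarDay) -> str:
    """Assign a timestamp to one of the four diel periods.

    Intervals are half-open [lo, hi): sunrise = [sunrise-1h, sunrise+1h),
    day = [sunrise+1h, sunset-1h), sunset = [sunset-1h, sunset+1h),
    night = everything else.
    """
    one_h = timedelta(hours=1)
    sr, ss = solar_day.sunrise, solar_day.sunset
    if sr - one_h <= timestamp < sr + one_h:
        return "sunrise"
    if sr + one_h <= timestamp < ss - one_h:
        return "day"
    if ss - one_h <= timestamp < ss + one_h:
        return "sunset"
    return "night"


def period_durations_hours(solar_day: SolarDay) -> dict[str, float]:
    """Hours each diel period occupies within one 24-h day (sums to 24)."""
    day_len = solar_day.day_length_hours
    day = max(0.0, day_len - 2.0)
    night = max(0.0, 24.0 - day_len - 2.0)
    return {"sunrise": 2.0, "day": day, "sunset": 2.0, "night": night}


def sun_relative_time(timestamp: datetime, solar_day: SolarDay) -> float:
    """Clock time re-expressed on [-1, +1], anchored to sunrise and sunset.

    Piecewise-linear anchors: solar midnight -> -1/+1, sunrise -> -0.5,
    solar noon (midpoint of sunrise and sunset) -> 0, sunset -> +0.5.
    Strictly increasing over the diel cycle, so seasonal day-length
    variation is absorbed by the transform.
    """
    noon = solar_day.noon
    x = (timestamp - noon).total_seconds() / 3600
    x = (x + 12) % 24 - 12  # wrap to [-12, 12)
    h_sr = (solar_day.sunrise - noon).total_seconds() / 3600  # negative
    h_ss = (solar_day.sunset - noon).total_seconds() / 3600  # positive
    if x < h_sr:
        return -1 + 0.5 * (x + 12) / (12 + h_sr)
    if x < 0:
        return -0.5 + 0.5 * (x - h_sr) / (-h_sr)
    if x < h_ss:
        return 0.5 * x / h_ss
    return 0.5 + 0.5 * (x - h_ss) / (12 - h_ss)


def sun_time_to_clock(sun_time: float, solar_day: SolarDay) -> datetime:
    """Inverse of :func:`sun_relative_time` (maps [-1, 1) to one diel cycle)."""
    noon = solar_day.noon
    h_sr = (solar_day.sunrise - noon).total_seconds() / 3600
    h_ss = (solar_day.sunset - noon).total_seconds() / 3600
    s = ((sun_time + 1) % 2) - 1  # wrap to [-1, 1)
    if s < -0.5:
        x = -12 + (s + 1) / 0.5 * (12 + h_sr)
    elif s < 0:
        x = h_sr + (s + 0.5) / 0.5 * (-h_sr)
    elif s < 0.5:
        x = s / 0.5 * h_ss
    else:
        x = h_ss + (s - 0.5) / 0.5 * (12 - h_ss)
    return noon + timedelta(hours=x)


def julian_date(timestamp) -> int:
    """Day-of-year (1 on 1 January), the ecological 'Julian date'."""
    if isinstance(timestamp, datetime):
        timestamp = timestamp.date()
    return timestamp.timetuple().tm_yday


# ---------------------------------------------------------------------------
# event annotation


def annotate_events(events, sites) -> pd.DataFrame:
    """Per-event temporal annotation: diel period, sun time, Julian date.

    Returns a DataFrame indexed by event_id with columns period, sun_time,
    julian_date, month, plus the event's sunrise/sunset for convenience.
    """
    site_map = {s.site_id: s for s in sites}
    rows = []
    for ev in events:
        site = site_map[ev.site_id]
        sd = solar_events(site, ev.start)
        rows.append(
            dict(
                event_id=ev.event_id,
                period=classify_period(ev.start, sd),
                sun_time=sun_relative_time(ev.start, sd),
                julian_date=julian_date(ev.start),
                month=ev.start.month,
                sunrise=sd.sunrise,
                sunset=sd.sunset,
            )
        )
    return pd.DataFrame(rows).set_index("event_id")


# ---------------------------------------------------------------------------
# survey effort and capture rate


def camera_trap_days(sites, year: int) -> pd.DataFrame:
    """Camera-trap days per month summed over sites.

    Any calendar day intersecting a deployment interval counts as a full
    trap day for that camera.
    """
    days = {m: 0 for m in range(1, 13)}
    for site in sites:
        for d0, d1 in site.deployments:
            start = max(d0.date() if isinstance(d0, datetime) else d0, date_cls(year, 1, 1))
            end = min(d1.date() if isinstance(d1, datetime) else d1, date_cls(year, 12, 31))
            d = start
            while d <= end:
                last = date_cls(d.year, d.month, calendar.monthrange(d.year, d.month)[1])
                stop = min(end, last)
                days[d.month] += (stop - d).days + 1
                d = stop + timedelta(days=1)
    return pd.DataFrame(
        {"month": list(days), "camera_trap_days": list(days.values())}
    ).set_index("month")


def compute_ric(events, sites, year: int) -> pd.DataFrame:
    """Monthly relative independent capture index.

    RIC = independent captures of the month / camera-trap days of the
    month x 1000.  A month with recorded events but zero trap days is a
    data inconsistency and raises.
    """
    effort = camera_trap_days(sites, year)
    captures = pd.Series(0, index=range(1, 13))
    for ev in events:
        if ev.start.year == year:
            captures[ev.start.month] += 1
    out = effort.copy()
    out["independent_captures"] = captures
    bad = out[(out.camera_trap_days == 0) & (out.independent_captures > 0)]
    if len(bad):
        raise DataConsistencyError(
            f"months with events but zero camera-trap days: {list(bad.index)}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ric"] = np.where(
            out.camera_trap_days > 0,
            1000.0 * out.independent_captures / out.camera_trap_days,
            0.0,
        )
    return out[["independent_captures", "camera_trap_days", "ric"]]


# ---------------------------------------------------------------------------
# actogram


def build_actogram(events, sites) -> pd.DataFrame:
    """One row per marking event: day of year, UTC hour, marking type.

    ``marking_type`` is "visual" when the event includes debarking
    behaviors and "chemical" otherwise; events that only investigate are
    excluded.  Per-day sunrise/sunset hours are included for overlay.
    """
    site_map = {s.site_id: s for s in sites}
    rows = []
    for ev in events:
        if not ev.is_marking:
            continue
        sd = solar_events(site_map[ev.site_id], ev.start)
        rows.append(
            dict(
                event_id=ev.event_id,
                day_of_year=julian_date(ev.start),
                utc_hour=ev.start.hour + ev.start.minute / 60 + ev.start.second / 3600,
                marking_type="visual" if ev.has(*VISUAL_BEHAVIORS) else "chemical",
                sunrise_hour=sd.sunrise.hour + sd.sunrise.minute / 60,
                sunset_hour=sd.sunset.hour + sd.sunset.minute / 60,
            )
        )
    cols = [
        "event_id",
        "day_of_year",
        "utc_hour",
        "marking_type",
        "sunrise_hour",
        "sunset_hour",
    ]
    return pd.DataFrame(rows, columns=cols)


__all__ = [
    "PERIODS",
    "SolarDay",
    "solar_events",
    "classify_period",
    "period_durations_hours",
    "sun_relative_time",
    "sun_time_to_clock",
    "julian_date",
    "annotate_events",
    "camera_trap_days",
    "compute_ric",
    "build_actogram",
]
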