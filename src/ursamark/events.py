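"""Event data model, CSV readers/writers, independence filtering, tabulations.

A *detection* is one camera trigger (one 60-s video); a *visit event* is a
cluster of detections at the same site closer together than an independence
window, treated as one bear visit.  Each detection carries an ordered list
of behavior *bouts* (code, start offset within the event, duration).

The native event log is a plain CSV with one row per bout; detections with
no coded behavior are written as a single row with an empty behavior field.
A BORIS-style aggregated-events export (observation id / subject /
behavior / start / stop) is also accepted, with a sidecar table mapping
observation ids onto sites, timestamps and classes.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .errors import EmptyDataError, RowParseError, SchemaError
from .ethogram import (
    BASE_BEHAVIORS,
    INVESTIGATION,
    MARKING_BEHAVIORS,
    VISUAL_BEHAVIORS,
    EthogramDefinition,
    coarse_class,
    COARSE_CLASSES,
    FINE_CLASSES,
    default_ethogram,
)
from .util import round_half_up

logger = logging.getLogger(__name__)

NATIVE_COLUMNS = [
    "site_id",
    "timestamp_iso8601_utc",
    "class",
    "behavior",
    "start_offset_s",
    "duration_s",
    "source",
    "mark_height",
]

BORIS_COLUMNS = ["Observation id", "Subject", "Behavior", "Start (s)", "Stop (s)"]

SOURCES = ("systematic", "opportunistic")
MARK_HEIGHTS = ("above_shoulder", "below_shoulder")


@dataclass(frozen=True)
class Bout:
    """One behavior bout: code, start offset (s) within the event, duration (s)."""

    behavior: str
    start_offset_s: float
    duration_s: float

    def __post_init__(self):
        if self.start_offset_s < 0:
            raise ValueError("bout start offset must be non-negative")
        if self.duration_s < 0:
            raise ValueError("bout duration must be non-negative")


@dataclass(frozen=True)
class CameraSite:
    """A camera-trap site with location and deployment intervals (closed dates)."""

    site_id: str
    latitude: float
    longitude: float
    utc_offset_hours: float = 0.0
    deployments: tuple[tuple[datetime, datetime], ...] = ()

    def __post_init__(self):
        if not -90 <= self.latitude <= 90:
            raise ValueError(f"latitude {self.latitude} out of range")
        if not -180 <= self.longitude <= 180:
            raise ValueError(f"longitude {self.longitude} out of range")
        spans = sorted(self.deployments)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 <= a1:
                raise ValueError(f"site {self.site_id}: overlapping deployments")


@dataclass(frozen=True)
class RawDetection:
    """One camera trigger with its ordered behavior bouts."""

    site_id: str
    timestamp: datetime
    bear_class: str
    bouts: tuple[Bout, ...] = ()
    source: str = "systematic"
    mark_height: str | None = None

    def __post_init__(self):
        offsets = [b.start_offset_s for b in self.bouts]
        if any(b > a for a, b in zip(offsets[1:], offsets)):
            raise ValueError("bout offsets must be non-decreasing")


@dataclass(frozen=True)
class VisitEvent:
    """One independent bear visit (clustered detections, bouts concatenated)."""

    event_id: str
    site_id: str
    start: datetime
    bear_class: str
    bouts: tuple[Bout, ...] = ()
    source: str = "systematic"
    mark_height: str | None = None
    behavior_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        flags = {}
        for b in self.bouts:
            flags[b.behavior] = True
        object.__setattr__(self, "behavior_flags", flags)

    def has(self, *codes: str) -> bool:
        return any(self.behavior_flags.get(c, False) for c in codes)

    @property
    def is_marking(self) -> bool:
        return self.has(*MARKING_BEHAVIORS)

    @property
    def is_visual_marking(self) -> bool:
        return self.has(*VISUAL_BEHAVIORS)


# ---------------------------------------------------------------------------
# I/O


def _parse_timestamp(value: str, line: int) -> datetime:
    try:
        ts = datetime.fromisoformat(value)
    except ValueError:
        raise RowParseError(f"unparseable timestamp {value!r}", line=line) from None
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def _check_code(code: str, allowed: frozenset[str], line: int) -> str:
    if code not in allowed:
        raise RowParseError(
            f"unknown behavior code {code!r}; allowed codes: {sorted(allowed)}",
            line=line,
        )
    return code


def parse_event_log(
    path,
    dialect: str = "native_csv",
    sidecar=None,
    ethogram: EthogramDefinition | None = None,
) -> list[RawDetection]:
    """Read an event log into detections.

    Parameters
    ----------
    path
        CSV file.  For the native dialect, one row per bout (empty
        ``behavior`` marks a trigger with no coded behavior); consecutive
        rows sharing (site_id, timestamp) form one detection.
    dialect
        ``"native_csv"`` or ``"boris_aggregated"``.
    sidecar
        Required for the BORIS dialect: CSV mapping
        ``observation_id -> site_id, timestamp_iso8601_utc, class[, source, mark_height]``.
    """
    ethogram = ethogram or default_ethogram()
    if dialect == "native_csv":
        return _parse_native(path, ethogram)
    if dialect == "boris_aggregated":
        if sidecar is None:
            raise ValueError("boris_aggregated dialect requires a sidecar table")
        return _parse_boris(path, sidecar, ethogram)
    raise ValueError(f"unknown dialect {dialect!r}")


def _require_columns(fieldnames, required, path):
    missing = [c for c in required if c not in (fieldnames or [])]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _parse_native(path, ethogram: EthogramDefinition) -> list[RawDetection]:
    detections: list[RawDetection] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames, NATIVE_COLUMNS, path)
        key = None
        bouts: list[Bout] = []
        meta: dict = {}

        def flush():
            if key is not None:
                detections.append(RawDetection(bouts=tuple(bouts), **meta))

        for i, row in enumerate(reader, start=2):
            ts = _parse_timestamp(row["timestamp_iso8601_utc"], i)
            k = (row["site_id"], ts)
            if k != key:
                flush()
                key = k
                bouts = []
                cls = row["class"] or "unknown"
                if cls not in FINE_CLASSES:
                    raise RowParseError(
                        f"unknown class {cls!r}; allowed: {list(FINE_CLASSES)}", line=i
                    )
                height = row.get("mark_height") or None
                if height is not None and height not in MARK_HEIGHTS:
                    raise RowParseError(
                        f"unknown mark_height {height!r}; allowed: {list(MARK_HEIGHTS)}",
                        line=i,
                    )
                meta = dict(
                    site_id=row["site_id"],
                    timestamp=ts,
                    bear_class=cls,
                    source=row.get("source") or "systematic",
                    mark_height=height,
                )
            if row["behavior"]:
                code = _check_code(row["behavior"], ethogram.behaviors, i)
                try:
                    start = float(row["start_offset_s"] or 0.0)
                    dur = float(row["duration_s"] or 0.0)
                except ValueError:
                    raise RowParseError("non-numeric bout offset/duration", line=i) from None
                bouts.append(Bout(code, start, dur))
        flush()
    return detections


def _parse_boris(path, sidecar, ethogram: EthogramDefinition) -> list[RawDetection]:
    side = pd.read_csv(sidecar, dtype=str)
    _require_columns(
        list(side.columns), ["observation_id", "site_id", "timestamp_iso8601_utc", "class"], sidecar
    )
    side = side.set_index("observation_id")

    groups: dict[str, list[Bout]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames, BORIS_COLUMNS, path)
        for i, row in enumerate(reader, start=2):
            obs = row["Observation id"]
            if obs not in groups:
                groups[obs] = []
                order.append(obs)
            code = _check_code(row["Behavior"], ethogram.behaviors, i)
            try:
                start = float(row["Start (s)"])
                stop = float(row["Stop (s)"])
            except ValueError:
                raise RowParseError("non-numeric Start/Stop", line=i) from None
            groups[obs].append(Bout(code, start, max(0.0, stop - start)))

    detections = []
    for obs in order:
        if obs not in side.index:
            raise SchemaError(f"observation {obs!r} missing from sidecar {sidecar}")
        rec = side.loc[obs]
        ts = _parse_timestamp(rec["timestamp_iso8601_utc"], 0)
        detections.append(
            RawDetection(
                site_id=rec["site_id"],
                timestamp=ts,
                bear_class=rec["class"],
                bouts=tuple(sorted(groups[obs], key=lambda b: b.start_offset_s)),
                source=rec.get("source", "systematic") or "systematic",
                mark_height=rec.get("mark_height", None) or None,
            )
        )
    return detections


def write_event_log(detections, path) -> None:
    """Write detections (or visit events) as a native event-log CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(NATIVE_COLUMNS)
        for det in detections:
            ts = getattr(det, "timestamp", None) or det.start
            base = [det.site_id, ts.strftime("%Y-%m-%dT%H:%M:%S+00:00"), det.bear_class]
            tail = [det.source, det.mark_height or ""]
            if det.bouts:
                for b in det.bouts:
                    writer.writerow(
                        base + [b.behavior, f"{b.start_offset_s:g}", f"{b.duration_s:g}"] + tail
                    )
            else:
                writer.writerow(base + ["", "", ""] + tail)


def parse_sites(path) -> list[CameraSite]:
    """Read site metadata CSV (repeatable rows: one per deployment)."""
    df = pd.read_csv(path, dtype={"site_id": str})
    _require_columns(
        list(df.columns),
        ["site_id", "latitude", "longitude", "utc_offset_hours", "deploy_start", "deploy_end"],
        path,
    )
    sites = []
    for site_id, grp in df.groupby("site_id", sort=True):
        spans = tuple(
            (
                datetime.fromisoformat(str(r.deploy_start)),
                datetime.fromisoformat(str(r.deploy_end)),
            )
            for r in grp.itertuples()
        )
        first = grp.iloc[0]
        sites.append(
            CameraSite(
                site_id=str(site_id),
                latitude=float(first.latitude),
                longitude=float(first.longitude),
                utc_offset_hours=float(first.utc_offset_hours),
                deployments=spans,
            )
        )
    return sites


def write_sites(sites, path) -> None:
    rows = []
    for s in sites:
        for d0, d1 in s.deployments:
            rows.append(
                dict(
                    site_id=s.site_id,
                    latitude=s.latitude,
                    longitude=s.longitude,
                    utc_offset_hours=s.utc_offset_hours,
                    deploy_start=d0.date().isoformat(),
                    deploy_end=d1.date().isoformat(),
                )
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# independence filtering


def filter_independent_events(detections, window_minutes: float = 30.0) -> list[VisitEvent]:
    """Cluster detections into independent visit events.

    Detections at the same site within ``window_minutes`` of the previous
    detection retained in the open event are merged into it (the gap rule
    chains, so a long visit that re-triggers the camera every few minutes
    stays one event).  Bouts are concatenated in time order with offsets
    re-expressed relative to the event start.
    """
    if window_minutes <= 0:
        raise ValueError("window_minutes must be positive")
    by_site: dict[str, list] = {}
    for d in detections:
        by_site.setdefault(d.site_id, []).append(_det_time(d))
    if any(ts != sorted(ts) for ts in by_site.values()):
        logger.warning("detections were out of time order; sorted before filtering")
    ordered = sorted(detections, key=lambda d: (d.site_id, _det_time(d)))

    events: list[VisitEvent] = []
    counters: dict[str, int] = {}
    current: list[RawDetection] = []

    def close(group):
        if not group:
            return
        site = group[0].site_id
        counters[site] = counters.get(site, 0) + 1
        start = _det_time(group[0])
        bouts = []
        height = None
        for det in group:
            shift = (_det_time(det) - start).total_seconds()
            for b in det.bouts:
                bouts.append(Bout(b.behavior, b.start_offset_s + shift, b.duration_s))
            if height is None:
                height = det.mark_height
        events.append(
            VisitEvent(
                event_id=f"{site}-{counters[site]:04d}",
                site_id=site,
                start=start,
                bear_class=group[0].bear_class,
                bouts=tuple(bouts),
                source=group[0].source,
                mark_height=height,
            )
        )

    for det in ordered:
        if (
            current
            and det.site_id == current[-1].site_id
            and (_det_time(det) - _det_time(current[-1])).total_seconds()
            <= window_minutes * 60
        ):
            current.append(det)
        else:
            close(current)
            current = [det]
    close(current)
    events.sort(key=lambda e: (e.start, e.site_id))
    return events


def _det_time(d) -> datetime:
    return getattr(d, "timestamp", None) or d.start


# ---------------------------------------------------------------------------
# view merging


def apply_merge(events, ethogram: EthogramDefinition, view: str):
    """Recode bout behaviors under a named merge view.

    Consecutive bouts that become the same supercode are kept distinct;
    collapsing runs is the sequence layer's concern.
    """
    mapping = ethogram.view(view)  # raises KeyError listing available views
    out = []
    for ev in events:
        bouts = tuple(
            Bout(mapping.get(b.behavior, b.behavior), b.start_offset_s, b.duration_s)
            for b in ev.bouts
        )
        out.append(replace(ev, bouts=bouts))
    return out


# ---------------------------------------------------------------------------
# tabulations


def tabulate_behavior_frequencies(events, behaviors=None) -> pd.DataFrame:
    """Per-behavior event counts and percent of all events.

    Behaviors can co-occur within an event, so the percents need not sum
    to 100.  Percentages are rounded half-up to one decimal.
    """
    events = list(events)
    if not events:
        raise EmptyDataError("empty event set")
    if behaviors is None:
        behaviors = sorted({b.behavior for ev in events for b in ev.bouts})
    rows = []
    n = len(events)
    for code in behaviors:
        k = sum(ev.has(code) for ev in events)
        rows.append(dict(behavior=code, n_events=k, percent=round_half_up(100 * k / n, 1)))
    return pd.DataFrame(rows).set_index("behavior")


#: Table-style behavior categories, each a predicate over one event.
BEHAVIOR_CATEGORIES = {
    "investigation": lambda ev: ev.has(INVESTIGATION) and not ev.is_marking,
    "investigation_and_marking": lambda ev: ev.has(INVESTIGATION) and ev.is_marking,
    "marking": lambda ev: ev.is_marking and not ev.has(INVESTIGATION),
    "visual_marking": lambda ev: ev.is_visual_marking,
    "pedal_marking": lambda ev: ev.has("pedal"),
}


def tabulate_class_behavior(events, grouping: str = "coarse") -> pd.DataFrame:
    """Class x behavior-category table of percentages.

    Each column holds the percent of that category's events attributable
    to each sex/age class, so each non-empty column sums to 100 (within
    rounding).
    """
    events = list(events)
    if grouping == "coarse":
        classes = list(COARSE_CLASSES)
        label = lambda ev: coarse_class(ev.bear_class)  # noqa: E731
    elif grouping == "fine":
        classes = list(FINE_CLASSES)
        label = lambda ev: ev.bear_class if ev.bear_class in FINE_CLASSES else "unknown"  # noqa: E731
    else:
        raise ValueError("grouping must be 'fine' or 'coarse'")

    table = pd.DataFrame(0.0, index=classes, columns=list(BEHAVIOR_CATEGORIES))
    for cat, pred in BEHAVIOR_CATEGORIES.items():
        members = [ev for ev in events if pred(ev)]
        if not members:
            continue
        counts = pd.Series([label(ev) for ev in members]).value_counts()
        for cls in classes:
            table.loc[cls, cat] = round_half_up(
                100 * counts.get(cls, 0) / len(members), 1
            )
    return table


def summarize_durations(events, behaviors=None) -> pd.DataFrame:
    """Per-behavior duration summary (mean/SD/min/max seconds) over events.

    A behavior absent from an event contributes 0 s to that event's total
    for the behavior, so minima are 0 whenever any event lacks the
    behavior.  SD is the sample standard deviation (0 for a single event).
    """
    events = list(events)
    if not events:
        raise EmptyDataError("empty event subset")
    if behaviors is None:
        behaviors = sorted(BASE_BEHAVIORS)
    rows = []
    for code in behaviors:
        totals = np.array(
            [sum(b.duration_s for b in ev.bouts if b.behavior == code) for ev in events]
        )
        sd = float(totals.std(ddof=1)) if len(totals) > 1 else 0.0
        rows.append(
            dict(
                behavior=code,
                mean_s=float(totals.mean()),
                sd_s=sd,
                min_s=float(totals.min()),
                max_s=float(totals.max()),
                n=len(totals),
            )
        )
    return pd.DataFrame(rows).set_index("behavior")


def tabulate_mark_heights(events) -> dict:
    """Share of visual marks above vs below the shoulder line, by month."""
    annotated = [ev for ev in events if ev.mark_height is not None]
    if not annotated:
        raise EmptyDataError("no events carry a mark-height annotation")
    n = len(annotated)
    above = sum(ev.mark_height == "above_shoulder" for ev in annotated)
    monthly: dict[int, dict[str, int]] = {}
    for ev in annotated:
        m = ev.start.month
        slot = monthly.setdefault(m, {"above_shoulder": 0, "below_shoulder": 0})
        slot[ev.mark_height] += 1
    return {
        "n_marks": n,
        "percent_above": round_half_up(100 * above / n, 1),
        "percent_below": round_half_up(100 * (n - above) / n, 1),
        "by_month": monthly,
    }


__all__ = [
    "Bout",
    "CameraSite",
    "RawDetection",
    "VisitEvent",
    "parse_event_log",
    "write_event_log",
    "parse_sites",
    "write_sites",
    "filter_independent_events",
    "apply_merge",
    "tabulate_behavior_frequencies",
    "tabulate_class_behavior",
    "summarize_durations",
    "tabulate_mark_heights",
    "BEHAVIOR_CATEGORIES",
]
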