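from datetime import datetime, timedelta, timezone

import numpy as np
import pytest
from hypothesis import settings

from ursamark.events import Bout, CameraSite, RawDetection, VisitEvent
from ursamark.sequences import END, START, TransitionModel
from ursamark.synthetic import SyntheticConfig, generate_events

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

UTC = timezone.utc


def ts(hour=12, minute=0, day=1, month=6, year=2021):
    return datetime(year, month, day, hour, minute, tzinfo=UTC)


def detection(site="S01", when=None, codes=(), cls="adult_male", **kw):
    """Build a RawDetection with one 5-s bout per code."""
    bouts = tuple(Bout(c, 6.0 * i, 5.0) for i, c in enumerate(codes))
    return RawDetection(
        site_id=site, timestamp=when or ts(), bear_class=cls, bouts=bouts, **kw
    )


def visit(event_id="E1", codes=(), cls="adult_male", when=None, site="S01", **kw):
    """Build a VisitEvent with one 5-s bout per code."""
    bouts = tuple(Bout(c, 6.0 * i, 5.0) for i, c in enumerate(codes))
    return VisitEvent(
        event_id=event_id,
        site_id=site,
        start=when or ts(),
        bear_class=cls,
        bouts=bouts,
        **kw,
    )


def make_site(site_id="S01", lat=43.1, lon=-6.3, year=2021):
    return CameraSite(
        site_id=site_id,
        latitude=lat,
        longitude=lon,
        utc_offset_hours=1.0,
        deployments=((datetime(year, 1, 1), datetime(year, 12, 31)),),
    )


def chain_from_rows(states, rows):
    """TransitionModel with known probabilities from a nested dict."""
    n = len(states)
    probs = np.zeros((n, n))
    idx = {s: i for i, s in enumerate(states)}
    for src, row in rows.items():
        for dst, p in row.items():
            probs[idx[src], idx[dst]] = p
    return TransitionModel(states=tuple(states), counts=probs.copy(), probs=probs)


def four_state_chain():
    """Small balanced chain; every row accumulates counts quickly."""
    return chain_from_rows(
        (START, "a", "b", END),
        {
            START: {"a": 0.6, "b": 0.4},
            "a": {"b": 0.5, END: 0.5},
            "b": {"a": 0.5, END: 0.5},
        },
    )


def marking_diagram_chain():
    """A 3-behavior chain shaped like the published sequence diagram:
    rubbing is the dominant entry, debarking returns to rubbing."""
    return chain_from_rows(
        (START, "debarking", "pedal", "rubbing", END),
        {
            START: {"rubbing": 0.89, "pedal": 0.11},
            "rubbing": {"debarking": 0.30, "pedal": 0.12, END: 0.58},
            "debarking": {"rubbing": 0.90, END: 0.10},
            "pedal": {"rubbing": 0.68, END: 0.32},
        },
    )


@pytest.fixture(scope="session")
def synthetic_dataset():
    """One default synthetic year (seed 7), shared across tests."""
    return generate_events(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def synthetic_paths(synthetic_dataset, tmp_path_factory):
    """The same dataset written out as CSV files."""
    out = tmp_path_factory.mktemp("sim")
    return synthetic_dataset.write(out)
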