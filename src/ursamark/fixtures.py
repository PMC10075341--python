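"""Hard-coded, seed-independent fixtures reconstructed from published counts.

``make_fixture_results_1`` rebuilds an event set whose per-behavior counts
match the year-long study's headline numbers (285 events; dorsal 222,
investigation 204, pedal 67, facial 62, visual 25).  The co-occurrence
pattern across events is arbitrary but fixed; only the marginal counts are
meaningful.  ``make_fixture_sequences`` rebuilds the 19-sequence visual
marking summary (all debarking preceded by chemical marking; 18 of 19
debarking bouts followed by another round of chemical marking).
"""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

from .events import Bout, VisitEvent
from .sequences import END, START, BehaviorSequence

N_EVENTS = 285
_COUNTS = {"dorsal": 222, "investigation": 204, "pedal": 67, "facial": 62}
# 25 visual-marking events: 11 clawing, 8 biting, 6 strip removals
_VISUAL_SPANS = {"clawing": (0, 11), "biting": (11, 19), "strip_removal": (19, 25)}
# index windows for the non-visual behaviors (arbitrary but fixed overlap)
_SPANS = {
    "dorsal": (0, 222),
    "investigation": (30, 234),
    "pedal": (0, 67),
    "facial": (60, 122),
}

_CLASS_CYCLE = (
    "adult_male",
    "adult_male",
    "adult_male",
    "adult_female",
    "subadult_male",
    "unknown",
    "female_with_cubs",
    "subadult_female",
    "cub",
)


def make_fixture_results_1() -> list[VisitEvent]:
    """285 visit events whose behavior-flag counts match the published totals."""
    base = datetime(2021, 1, 1, 12, 0, tzinfo=timezone.utc)
    events = []
    for i in range(N_EVENTS):
        codes = [c for c, (lo, hi) in _SPANS.items() if lo <= i < hi]
        for c, (lo, hi) in _VISUAL_SPANS.items():
            if lo <= i < hi:
                codes.append(c)
        bouts, offset = [], 0.0
        for c in codes:
            bouts.append(Bout(c, offset, 5.0))
            offset += 6.0
        if i < 25:  # visual markers: adult males during the mating season
            cls = "adult_male"
            start = datetime(2021, 5, 1, 18, 0, tzinfo=timezone.utc) + timedelta(
                days=i, minutes=7 * i
            )
        else:
            cls = _CLASS_CYCLE[i % len(_CLASS_CYCLE)]
            start = base + timedelta(days=i % 365, minutes=11 * i)
        events.append(
            VisitEvent(
                event_id=f"fx1-{i:03d}",
                site_id=f"S{i % 13 + 1:02d}",
                start=start,
                bear_class=cls,
                bouts=tuple(bouts),
                source="systematic" if i < 239 else "opportunistic",
            )
        )
    return events


def make_fixture_sequences() -> list[BehaviorSequence]:
    """19 visual-marking sequences: rubbing always precedes debarking, and
    18 of the 19 debarking bouts are followed by more rubbing."""
    seqs = [
        BehaviorSequence(f"fx2-{i:02d}", (START, "rubbing", "debarking", "rubbing", END))
        for i in range(18)
    ]
    seqs.append(BehaviorSequence("fx2-18", (START, "rubbing", "debarking", END)))
    return seqs
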