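"""Ethogram vocabulary: behavior codes, merge views, and bear sex/age classes.

The study ethogram codes five marking-related behaviors at rubbing trees.
Visual marking (debarking with claws or teeth, or removal of an experimental
bark strip) is stored as three distinct codes so that natural and
experimental marks can be separated when needed; merge *views* recode
bouts onto coarser vocabularies (e.g. dorsal + facial -> "rubbing" for
sequence analysis, the three debarking codes -> "debarking").
"""

from __future__ import annotations

from dataclasses import dataclass, field

# base behavior codes
DORSAL = "dorsal"
FACIAL = "facial"
PEDAL = "pedal"
INVESTIGATION = "investigation"
CLAWING = "clawing"
BITING = "biting"
STRIP_REMOVAL = "strip_removal"

BASE_BEHAVIORS = frozenset(
    {DORSAL, FACIAL, PEDAL, INVESTIGATION, CLAWING, BITING, STRIP_REMOVAL}
)

# supercodes produced by merge views
RUBBING = "rubbing"
DEBARKING = "debarking"

#: behaviors that deposit scent (chemical marking)
CHEMICAL_BEHAVIORS = frozenset({DORSAL, FACIAL, PEDAL, RUBBING})
#: behaviors that leave a visible mark (visual marking)
VISUAL_BEHAVIORS = frozenset({CLAWING, BITING, STRIP_REMOVAL, DEBARKING})
#: behaviors that count as "marking" (anything but sniffing around)
MARKING_BEHAVIORS = frozenset(
    {DORSAL, FACIAL, PEDAL, CLAWING, BITING, STRIP_REMOVAL, RUBBING, DEBARKING}
)


@dataclass(frozen=True)
class EthogramDefinition:
    """A closed behavior vocabulary plus named merge views.

    Parameters
    ----------
    behaviors
        The base behavior codes accepted in event logs.
    merge_maps
        Named maps ``code -> supercode``.  A view's supercodes must be
        disjoint from the base codes, and each map may only mention base
        codes.
    """

    behaviors: frozenset[str] = BASE_BEHAVIORS
    merge_maps: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        for view, mapping in self.merge_maps.items():
            unknown = set(mapping) - self.behaviors
            if unknown:
                raise ValueError(
                    f"merge view {view!r} maps codes not in the ethogram: {sorted(unknown)}"
                )
            clash = set(mapping.values()) & self.behaviors
            if clash:
                raise ValueError(
                    f"merge view {view!r} reuses base codes as supercodes: {sorted(clash)}"
                )

    def view(self, name: str) -> dict[str, str]:
        try:
            return self.merge_maps[name]
        except KeyError:
            raise KeyError(
                f"unknown view {name!r}; available views: {sorted(self.merge_maps)}"
            ) from None

    def recode(self, code: str, view: str) -> str:
        return self.view(view).get(code, code)


def default_ethogram() -> EthogramDefinition:
    """The study ethogram with its three standard merge views.

    * ``chemical_view`` couples dorsal and facial rubbing as ``rubbing``
      (the two deposit the same kind of scent signal).
    * ``visual_view`` couples clawing, biting and strip removal as
      ``debarking``.
    * ``sequence_view`` applies both couplings; with investigation
      dropped this is the 3-state vocabulary of the published sequence
      diagram (pedal / rubbing / debarking).
    """
    chemical = {DORSAL: RUBBING, FACIAL: RUBBING}
    visual = {CLAWING: DEBARKING, BITING: DEBARKING, STRIP_REMOVAL: DEBARKING}
    return EthogramDefinition(
        behaviors=BASE_BEHAVIORS,
        merge_maps={
            "chemical_view": dict(chemical),
            "visual_view": dict(visual),
            "sequence_view": {**chemical, **visual},
        },
    )


# ---------------------------------------------------------------------------
# sex/age classes

FINE_CLASSES = (
    "adult_male",
    "adult_female",
    "unknown_adult",
    "female_with_cubs",
    "subadult_male",
    "subadult_female",
    "unknown_subadult",
    "cub",
    "unknown",
)

COARSE_CLASSES = ("adult_male", "adult_female", "subadult", "cub", "unknown")

#: fixed fine -> coarse map.  Females with cubs report as adult females;
#: adults of unknown sex cannot be placed in a sexed row and fall into
#: "unknown", as do fully unknown individuals.
FINE_TO_COARSE: dict[str, str] = {
    "adult_male": "adult_male",
    "adult_female": "adult_female",
    "female_with_cubs": "adult_female",
    "unknown_adult": "unknown",
    "subadult_male": "subadult",
    "subadult_female": "subadult",
    "unknown_subadult": "subadult",
    "cub": "cub",
    "unknown": "unknown",
}

assert set(FINE_TO_COARSE) == set(FINE_CLASSES)
assert set(FINE_TO_COARSE.values()) <= set(COARSE_CLASSES)


def coarse_class(fine: str) -> str:
    """Map a fine sex/age label onto the five reporting classes."""
    try:
        return FINE_TO_COARSE[fine]
    except KeyError:
        return "unknown"
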