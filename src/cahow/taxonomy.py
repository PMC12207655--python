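"""Behaviour taxonomy: nine ethogram classes grouped into three activity modes.

The ethogram distinguishes three behaviours in the nesting burrow, three on
the water surface and three in flight.  The six non-burrow classes form the
"at-sea" set used by the diel activity analysis.
"""

from __future__ import annotations

from enum import Enum


class Mode(str, Enum):
    BURROW = "burrow"
    WATER = "water"
    FLYING = "flying"


class BehaviourClass(str, Enum):
    BURROW_STILL = "burrow-still"
    BURROW_STIRRING = "burrow-stirring"
    BURROW_ACTIVE = "burrow-active"
    WATER_INACTIVE = "water-inactive"
    WATER_ACTIVE = "water-active"
    WATER_INTENSIVE = "water-intensive"
    FLYING_DYNAMIC_SOARING = "flying-dynamic-soaring"
    FLYING_FLAP_GLIDE = "flying-flap-glide"
    FLYING_INTENSIVE = "flying-intensive"

    @property
    def mode(self) -> Mode:
        return CLASS_TO_MODE[self]


CLASS_TO_MODE: dict[BehaviourClass, Mode] = {
    BehaviourClass.BURROW_STILL: Mode.BURROW,
    BehaviourClass.BURROW_STIRRING: Mode.BURROW,
    BehaviourClass.BURROW_ACTIVE: Mode.BURROW,
    BehaviourClass.WATER_INACTIVE: Mode.WATER,
    BehaviourClass.WATER_ACTIVE: Mode.WATER,
    BehaviourClass.WATER_INTENSIVE: Mode.WATER,
    BehaviourClass.FLYING_DYNAMIC_SOARING: Mode.FLYING,
    BehaviourClass.FLYING_FLAP_GLIDE: Mode.FLYING,
    BehaviourClass.FLYING_INTENSIVE: Mode.FLYING,
}

ALL_CLASSES: tuple[BehaviourClass, ...] = tuple(BehaviourClass)

#: The six classes a bird can occupy while away from the colony.
AT_SEA_CLASSES: tuple[BehaviourClass, ...] = tuple(
    c for c in BehaviourClass if c.mode is not Mode.BURROW
)

FLYING_CLASSES: tuple[BehaviourClass, ...] = tuple(
    c for c in BehaviourClass if c.mode is Mode.FLYING
)


def collapse_modes(labels):
    """Map nine-class behaviour labels onto the three activity modes.

    Accepts a single label, or any iterable of labels / label strings, and
    returns mode value strings ("burrow" / "water" / "flying") with the same
    shape.  Within-mode confusions collapse to agreement, so mode-level
    accuracy is never below class-level accuracy.
    """
    if isinstance(labels, (str, BehaviourClass)):
        return BehaviourClass(labels).mode.value
    return [BehaviourClass(lab).mode.value for lab in labels]
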