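"""Pre-adapted dropper / collector / generalist foraging strategies.

All three roles share one ordered set of eight rules; role identity
comes solely from the initial values of two named memory variables,
STAY_UP and STAY_DOWN (aliases of the general memories M1/M2):

======================  ========  =========
role                    STAY_UP   STAY_DOWN
======================  ========  =========
dropper                 True      False
collector               False     True
generalist              False     False
======================  ========  =========

The memory gating makes each role exercise a different subset of the
shared rules — droppers R1, R4-R6; collectors R2-R3, R5, R7-R8;
generalists R1, R4-R5, R7-R8:

* R1  not carrying, outside the source, not STAY_DOWN -> phototaxis
  (travel toward the source, climbing the slope if needed)
* R2  not carrying, in the nest, STAY_DOWN -> phototaxis (a collector
  heads back toward the cache after delivering)
* R3  not carrying, on the slope, STAY_DOWN -> random walk (a collector
  straying onto the slope foot falls back to exploring; the asymmetric
  climb/descent speeds expel it downhill, so it never gets far up)
* R4  not carrying, in the source -> random walk + pickup (search the
  source and grab what comes within reach)
* R5  carrying -> anti-phototaxis (head home / downhill)
* R6  carrying, on the slope, STAY_UP -> drop (a dropper releases the
  item at the top of the slope and lets gravity do the transport)
* R7  carrying, in the nest -> drop (delivery)
* R8  not carrying, in the cache -> pickup (a collector's main grab; a
  generalist collects opportunistically on its way to the source)

The behavioral contracts this reproduces: a dropper climbs once and
shuttles between source and slope top, never descending again; a
collector never climbs, ferrying cache items to the nest and exploring
the cache by random walk when it is empty; a generalist does the whole
task end to end, only picking from the cache when an item happens to
lie on its path.
"""

from __future__ import annotations

from .rules import Rule, RuleSet, validate_ruleset

__all__ = ["ROLES", "make_strategy", "shared_rules"]

ROLES = ("dropper", "collector", "generalist")

_B_ALL = frozenset({"PHOTOTAXIS", "ANTI_PHOTOTAXIS", "RANDOM_WALK"})


def shared_rules() -> tuple[Rule, ...]:
    """The eight rules shared by all three hand-coded roles."""
    return (
        # R1: travel toward the source
        Rule(
            (("carrying", False), ("in_source", False), ("STAY_DOWN", False)),
            _B_ALL,
            (("set_behavior", "PHOTOTAXIS", 1.0),),
        ),
        # R2: collector leaves the nest toward the cache
        Rule(
            (("carrying", False), ("in_nest", True), ("STAY_DOWN", True)),
            _B_ALL,
            (("set_behavior", "PHOTOTAXIS", 1.0),),
        ),
        # R3: collector bounced off the slope foot resumes exploring
        Rule(
            (("carrying", False), ("in_slope", True), ("STAY_DOWN", True)),
            _B_ALL,
            (("set_behavior", "RANDOM_WALK", 1.0),),
        ),
        # R4: search the source area and pick up items in reach.  The
        # switch into random walk is probabilistic (p = 0.02 per 0.1 s
        # scan, ~5 s expected): phototaxis first carries the robot into
        # the interior of the source area, after which it explores; an
        # immediate switch would make it dither at the zone boundary.
        Rule(
            (("carrying", False), ("in_source", True)),
            _B_ALL,
            (("set_behavior", "RANDOM_WALK", 0.02), ("pickup", 1.0)),
        ),
        # R5: carry the load toward the nest (downhill)
        Rule(
            (("carrying", True),),
            _B_ALL,
            (("set_behavior", "ANTI_PHOTOTAXIS", 1.0),),
        ),
        # R6: dropper releases on the slope, gravity finishes the subtask
        Rule(
            (("carrying", True), ("in_slope", True), ("STAY_UP", True)),
            _B_ALL,
            (("drop", 1.0),),
        ),
        # R7: deliver in the nest
        Rule(
            (("carrying", True), ("in_nest", True)),
            _B_ALL,
            (("drop", 1.0),),
        ),
        # R8: grab from the cache
        Rule(
            (("carrying", False), ("in_cache", True)),
            _B_ALL,
            (("pickup", 1.0),),
        ),
    )


def make_strategy(role: str) -> RuleSet:
    """Build the validated RuleSet for one foraging role."""
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}: expected one of {ROLES}")
    init = {
        "dropper": {"STAY_UP": 1, "STAY_DOWN": 0},
        "collector": {"STAY_UP": 0, "STAY_DOWN": 1},
        "generalist": {"STAY_UP": 0, "STAY_DOWN": 0},
    }[role]
    rs = RuleSet(
        rules=shared_rules(),
        initial_behavior="RANDOM_WALK",
        initial_state=init,
        name=role,
    )
    errs = validate_ruleset(rs)
    if errs:  # pragma: no cover - construction bug guard
        raise AssertionError("; ".join(errs))
    return rs
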