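"""Probabilistic rule-based controllers and low-level behaviors.

A controller is an ordered rule set ``R = {R_i}``; each rule
``R_i = P_i x B_i x A_i`` combines

* preconditions ``P_i`` — required boolean values of state variables
  (zone indicators, carrying, ``want_pickup`` and two general-purpose
  memory variables ``M1``/``M2``, read as "non-zero"),
* a behavior subset ``B_i`` — the rule only fires while the robot is
  executing one of these low-level behaviors, and
* actions ``A_i`` — each executed independently with probability
  ``p_l`` when the rule fires: switch behavior, pick up, drop, or write
  a state variable.

Rules are scanned in order once per control step; behavior and state
writes are visible to later rules in the same scan, while pickup/drop
are handed to the simulator to attempt this step.

The three low-level behaviors are PHOTOTAXIS (steer toward the light
beacon, i.e. +x), ANTI_PHOTOTAXIS (away from it) and RANDOM_WALK
(piecewise-constant random heading with a uniform 2-10 s dwell).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .world import BEHAVIORS, ZONES

__all__ = [
    "Percepts",
    "ControlState",
    "Rule",
    "RuleSet",
    "behavior_command",
    "evaluate_rules",
    "validate_ruleset",
    "parse_ruleset",
    "RuleSyntaxError",
    "VARIABLES",
    "RW_DWELL_MIN",
    "RW_DWELL_MAX",
]

#: precondition / state variable names, in kernel order
VARIABLES = (
    "in_nest",
    "in_cache",
    "in_slope",
    "in_source",
    "carrying",
    "want_pickup",
    "M1",
    "M2",
)
#: named memories of the hand-coded strategies are aliases of M1/M2
VARIABLE_ALIASES = {"STAY_UP": "M1", "STAY_DOWN": "M2"}

STATE_VARS = ("want_pickup", "M1", "M2")
STATE_OPS = ("set_false", "set_true", "inc", "dec")
MEMORY_MAX = 3  # M1/M2 are bounded counters in {0..3}; want_pickup is boolean

RW_DWELL_MIN = 2.0
RW_DWELL_MAX = 10.0

BEHAVIOR_INDEX = {name: i for i, name in enumerate(BEHAVIORS)}
VARIABLE_INDEX = {name: i for i, name in enumerate(VARIABLES)}


class RuleSyntaxError(ValueError):
    """Raised when parsing a malformed rule-set text."""


@dataclass
class Percepts:
    """What one robot senses in one control step."""

    zone: str
    carrying: bool
    light_direction: tuple[float, float] = (1.0, 0.0)
    nearby_item: bool = False

    def __post_init__(self):
        if self.zone not in ZONES:
            raise ValueError(f"unknown zone {self.zone!r}")
        nx, ny = self.light_direction
        n = math.hypot(nx, ny)
        if not math.isclose(n, 1.0, rel_tol=1e-6):
            raise ValueError("light_direction must be a unit vector")


@dataclass
class ControlState:
    """Controller-visible internal state of one robot."""

    behavior: str = "RANDOM_WALK"
    want_pickup: int = 0
    M1: int = 0
    M2: int = 0

    def var(self, name: str, percepts: Percepts) -> bool:
        name = VARIABLE_ALIASES.get(name, name)
        if name.startswith("in_"):
            return percepts.zone == name[3:]
        if name == "carrying":
            return percepts.carrying
        return bool(getattr(self, name))


@dataclass(frozen=True)
class Rule:
    """One condition-behavior-action rule.

    ``preconditions`` maps variable name -> required boolean value;
    ``behaviors`` is the non-empty behavior subset; ``actions`` is an
    ordered tuple of ``(action, probability)`` where ``action`` is
    ``("set_behavior", name)``, ``("pickup",)``, ``("drop",)`` or
    ``("set_state", var, op)`` with op in set_true/set_false/inc/dec.
    """

    preconditions: tuple[tuple[str, bool], ...]
    behaviors: frozenset
    actions: tuple[tuple, ...]

    def violations(self) -> list[str]:
        errs = []
        if not self.behaviors:
            errs.append("behavior subset B_i must be non-empty")
        for b in self.behaviors:
            if b not in BEHAVIORS:
                errs.append(f"unknown behavior {b!r}")
        seen = set()
        for name, val in self.preconditions:
            canon = VARIABLE_ALIASES.get(name, name)
            if canon not in VARIABLES:
                errs.append(f"unknown precondition variable {name!r}")
            if canon in seen:
                errs.append(f"duplicate precondition on {name!r}")
            seen.add(canon)
            if not isinstance(val, (bool, np.bool_)):
                errs.append(f"precondition {name!r} value must be boolean")
        if not self.actions:
            errs.append("action list A_i must be non-empty")
        for act in self.actions:
            kind = act[0]
            p = act[-1] if len(act) >= 2 and isinstance(act[-1], (int, float)) else None
            if kind == "set_behavior":
                if act[1] not in BEHAVIORS:
                    errs.append(f"unknown behavior {act[1]!r} in set_behavior")
            elif kind in ("pickup", "drop"):
                pass
            elif kind == "set_state":
                var = VARIABLE_ALIASES.get(act[1], act[1])
                if var not in STATE_VARS:
                    errs.append(f"set_state targets unknown variable {act[1]!r}")
                if act[2] not in STATE_OPS:
                    errs.append(f"unknown state operation {act[2]!r}")
            else:
                errs.append(f"unknown action kind {kind!r}")
            if p is None or not 0.0 <= float(p) <= 1.0:
                errs.append(f"action probability {p!r} outside [0, 1]")
        return errs


@dataclass
class RuleSet:
    """Ordered list of rules plus the robot's initial internal state."""

    rules: tuple[Rule, ...] = ()
    initial_behavior: str = "RANDOM_WALK"
    initial_state: dict = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        self.rules = tuple(self.rules)
        canon = {}
        for k, v in dict(self.initial_state).items():
            if int(v):  # zero is the default; keep the mapping canonical
                canon[VARIABLE_ALIASES.get(k, k)] = int(v)
        self.initial_state = canon

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    @property
    def initial_behavior_index(self) -> int:
        return BEHAVIOR_INDEX[self.initial_behavior]

    def initial_control_state(self) -> ControlState:
        return ControlState(
            behavior=self.initial_behavior,
            want_pickup=int(self.initial_state.get("want_pickup", 0)),
            M1=int(self.initial_state.get("M1", 0)),
            M2=int(self.initial_state.get("M2", 0)),
        )

    # -- text format --------------------------------------------------------
    def to_text(self) -> str:
        lines = []
        if self.name:
            lines.append(f"# {self.name}")
        init = [f"behavior={self.initial_behavior}"]
        for k in STATE_VARS:
            v = self.initial_state.get(k, 0)
            if v:
                init.append(f"{k}={v}")
        lines.append("INIT " + " ".join(init))
        for rule in self.rules:
            conds = " & ".join(
                f"{name}={'True' if val else 'False'}" for name, val in rule.preconditions
            )
            conds = conds or "always=True"
            behs = ",".join(b for b in BEHAVIORS if b in rule.behaviors)
            acts = []
            for act in rule.actions:
                p = act[-1]
                if act[0] == "set_behavior":
                    s = f"behavior({act[1]})"
                elif act[0] == "pickup":
                    s = "pickup"
                elif act[0] == "drop":
                    s = "drop"
                else:  # set_state
                    var, op = act[1], act[2]
                    if op == "set_true":
                        s = f"set({var}=True)"
                    elif op == "set_false":
                        s = f"set({var}=False)"
                    else:
                        s = f"{op}({var})"
                acts.append(f"{s}@{p:g}")
            lines.append(f"IF {conds} WHILE {{{behs}}} THEN " + ", ".join(acts))
        return "\n".join(lines) + "\n"

    def __str__(self) -> str:
        return self.to_text()


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_RULE_RE = re.compile(r"^IF\s+(?P<conds>.+?)\s+WHILE\s*\{(?P<behs>[^}]*)\}\s*THEN\s+(?P<acts>.+)$")
_ACT_RE = re.compile(r"^(?P<body>.+?)@(?P<p>[0-9.eE+-]+)$")


def _parse_action(text: str) -> tuple:
    m = _ACT_RE.match(text.strip())
    if not m:
        raise RuleSyntaxError(f"malformed action {text!r} (expected action@p)")
    body, p = m.group("body").strip(), float(m.group("p"))
    if body == "pickup":
        return ("pickup", p)
    if body == "drop":
        return ("drop", p)
    bm = re.match(r"^behavior\((\w+)\)$", body)
    if bm:
        return ("set_behavior", bm.group(1), p)
    sm = re.match(r"^set\((\w+)\s*=\s*(\w+)\)$", body)
    if sm:
        var, val = sm.group(1), sm.group(2)
        op = "set_true" if val in ("True", "1") else "set_false"
        return ("set_state", var, op, p)
    im = re.match(r"^(inc|dec)\((\w+)\)$", body)
    if im:
        return ("set_state", im.group(2), im.group(1), p)
    raise RuleSyntaxError(f"unknown action {body!r}")


def parse_ruleset(text: str, name: str = "") -> RuleSet:
    """Parse the one-rule-per-line text format (inverse of ``to_text``)."""
    rules = []
    initial_behavior = "RANDOM_WALK"
    initial_state: dict = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("INIT"):
            for tok in line[4:].split():
                k, _, v = tok.partition("=")
                if k == "behavior":
                    if v not in BEHAVIORS:
                        raise RuleSyntaxError(f"line {lineno}: unknown behavior {v!r}")
                    initial_behavior = v
                else:
                    initial_state[k] = int(v) if v.isdigit() else int(v == "True")
            continue
        m = _RULE_RE.match(line)
        if not m:
            raise RuleSyntaxError(f"line {lineno}: malformed rule {line!r}")
        conds = []
        for c in m.group("conds").split("&"):
            c = c.strip()
            k, _, v = c.partition("=")
            k, v = k.strip(), v.strip()
            if k == "always":
                continue
            if v not in ("True", "False"):
                raise RuleSyntaxError(f"line {lineno}: condition value must be True/False")
            conds.append((k, v == "True"))
        behs = [b.strip() for b in m.group("behs").split(",") if b.strip()]
        if behs == ["*"]:
            behs = list(BEHAVIORS)
        acts = []
        for a in m.group("acts").split(","):
            if a.strip():
                acts.append(_parse_action(a))
        rules.append(Rule(tuple(conds), frozenset(behs), tuple(acts)))
    rs = RuleSet(tuple(rules), initial_behavior, initial_state, name=name)
    errs = validate_ruleset(rs)
    if errs:
        raise RuleSyntaxError("; ".join(errs))
    return rs


def validate_ruleset(ruleset: RuleSet) -> list[str]:
    """Check all rule invariants; returns a list of violations (empty = ok)."""
    errs = []
    for i, rule in enumerate(ruleset.rules, start=1):
        for e in rule.violations():
            errs.append(f"rule {i}: {e}")
    if ruleset.initial_behavior not in BEHAVIORS:
        errs.append(f"unknown initial behavior {ruleset.initial_behavior!r}")
    for k, v in ruleset.initial_state.items():
        if k not in STATE_VARS:
            errs.append(f"unknown initial state variable {k!r}")
        elif not 0 <= int(v) <= (1 if k == "want_pickup" else MEMORY_MAX):
            errs.append(f"initial {k}={v} out of range")
    return errs


# ---------------------------------------------------------------------------
# execution semantics (Python reference implementation)
# ---------------------------------------------------------------------------


def _draw(rng) -> float:
    if hasattr(rng, "next_float"):
        return rng.next_float()
    return float(rng.random())


def evaluate_rules(ruleset: RuleSet, percepts: Percepts, state: ControlState, rng):
    """Run one ordered rule scan.

    Returns ``(state, attempts)`` where ``attempts`` is the ordered list of
    ``"pickup"`` / ``"drop"`` actions for the simulator to try this step.
    ``state`` is updated in place: behavior switches and state-variable
    writes take effect immediately and are seen by later rules in the same
    scan.  The ``carrying`` percept is fixed for the whole scan (pickup and
    drop only happen after the scan).
    """
    attempts: list[str] = []
    for rule in ruleset.rules:
        if state.behavior not in rule.behaviors:
            continue
        if not all(state.var(name, percepts) == val for name, val in rule.preconditions):
            continue
        for act in rule.actions:
            p = act[-1]
            if p < 1.0 and _draw(rng) >= p:
                continue
            kind = act[0]
            if kind == "set_behavior":
                state.behavior = act[1]
            elif kind in ("pickup", "drop"):
                attempts.append(kind)
            else:  # set_state
                var = VARIABLE_ALIASES.get(act[1], act[1])
                op = act[2]
                cur = int(getattr(state, var))
                hi = 1 if var == "want_pickup" else MEMORY_MAX
                if op == "set_false":
                    nv = 0
                elif op == "set_true":
                    nv = 1
                elif op == "inc":
                    nv = min(cur + 1, hi)
                else:
                    nv = max(cur - 1, 0)
                setattr(state, var, nv)
    return state, attempts


def behavior_command(
    primitive: str,
    percepts: Percepts,
    rng,
    rw_state: dict | None = None,
    dt: float = 0.1,
) -> float:
    """Desired heading (radians) for one low-level behavior.

    PHOTOTAXIS steers along the light direction, ANTI_PHOTOTAXIS against
    it.  RANDOM_WALK keeps a piecewise-constant heading resampled
    uniformly on [0, 2pi) after a dwell drawn uniformly from
    [2 s, 10 s]; its state (heading, remaining dwell) lives in the
    caller-owned ``rw_state`` dict.
    """
    if primitive not in BEHAVIORS:
        raise ValueError(f"unknown behavior {primitive!r}")
    lx, ly = percepts.light_direction
    if primitive == "PHOTOTAXIS":
        return math.atan2(ly, lx)
    if primitive == "ANTI_PHOTOTAXIS":
        return math.atan2(-ly, -lx)
    if rw_state is None:
        rw_state = {}
    timer = rw_state.get("timer", 0.0) - dt
    if timer <= 0.0:
        rw_state["heading"] = 2.0 * math.pi * _draw(rng)
        timer = RW_DWELL_MIN + (RW_DWELL_MAX - RW_DWELL_MIN) * _draw(rng)
    rw_state["timer"] = timer
    return rw_state["heading"]


# ---------------------------------------------------------------------------
# compilation to the kernel's array encoding
# ---------------------------------------------------------------------------


@dataclass
class CompiledTeam:
    """Array encoding of one team's controllers for the numba kernel."""

    rule_lo: np.ndarray  # (n_robots,) first rule index per robot
    rule_hi: np.ndarray  # (n_robots,) one-past-last rule index
    pre: np.ndarray  # (n_rules_total, 8) int8: -1 don't care / 0 / 1
    bmask: np.ndarray  # (n_rules_total,) uint8 behavior bitmask
    act_off: np.ndarray  # (n_rules_total + 1,) int64 offsets
    act_type: np.ndarray  # int8: 0 set_behavior, 1 pickup, 2 drop, 3 set_state
    act_arg: np.ndarray  # int8 argument
    act_prob: np.ndarray  # float64 probability
    init_behavior: np.ndarray  # (n_robots,) int8
    init_state: np.ndarray  # (n_robots, 3) int8


def compile_team(controllers) -> CompiledTeam:
    """Flatten one RuleSet per robot into shared arrays.

    Controllers may repeat (homogeneous teams share one object); rule
    blocks are deduplicated per distinct object.
    """
    offsets: dict[int, tuple[int, int]] = {}
    pre_rows, bmasks, act_types, act_args, act_probs, act_off = [], [], [], [], [], [0]
    n_rules = 0

    def add(rs: RuleSet) -> tuple[int, int]:
        nonlocal n_rules
        key = id(rs)
        if key in offsets:
            return offsets[key]
        errs = validate_ruleset(rs)
        if errs:
            raise ValueError("invalid ruleset: " + "; ".join(errs))
        lo = n_rules
        for rule in rs.rules:
            row = np.full(8, -1, dtype=np.int8)
            for name, val in rule.preconditions:
                row[VARIABLE_INDEX[VARIABLE_ALIASES.get(name, name)]] = 1 if val else 0
            pre_rows.append(row)
            mask = 0
            for b in rule.behaviors:
                mask |= 1 << BEHAVIOR_INDEX[b]
            bmasks.append(mask)
            for act in rule.actions:
                p = float(act[-1])
                if act[0] == "set_behavior":
                    act_types.append(0)
                    act_args.append(BEHAVIOR_INDEX[act[1]])
                elif act[0] == "pickup":
                    act_types.append(1)
                    act_args.append(0)
                elif act[0] == "drop":
                    act_types.append(2)
                    act_args.append(0)
                else:
                    var = VARIABLE_ALIASES.get(act[1], act[1])
                    vi = STATE_VARS.index(var)
                    oi = STATE_OPS.index(act[2])
                    act_types.append(3)
                    act_args.append(vi * 4 + oi)
                act_probs.append(p)
            act_off.append(len(act_types))
            n_rules += 1
        offsets[key] = (lo, n_rules)
        return offsets[key]

    n = len(controllers)
    rule_lo = np.zeros(n, dtype=np.int64)
    rule_hi = np.zeros(n, dtype=np.int64)
    init_behavior = np.zeros(n, dtype=np.int8)
    init_state = np.zeros((n, 3), dtype=np.int8)
    for i, rs in enumerate(controllers):
        lo, hi = add(rs)
        rule_lo[i], rule_hi[i] = lo, hi
        init_behavior[i] = rs.initial_behavior_index
        init_state[i, 0] = int(rs.initial_state.get("want_pickup", 0))
        init_state[i, 1] = int(rs.initial_state.get("M1", 0))
        init_state[i, 2] = int(rs.initial_state.get("M2", 0))

    return CompiledTeam(
        rule_lo=rule_lo,
        rule_hi=rule_hi,
        pre=np.array(pre_rows, dtype=np.int8).reshape(n_rules, 8),
        bmask=np.array(bmasks, dtype=np.uint8),
        act_off=np.array(act_off, dtype=np.int64),
        act_type=np.array(act_types, dtype=np.int8),
        act_arg=np.array(act_args, dtype=np.int8),
        act_prob=np.array(act_probs, dtype=np.float64),
        init_behavior=init_behavior,
        init_state=init_state,
    )
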