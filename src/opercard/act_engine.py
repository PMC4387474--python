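"""Auckland Card Task simulator.

The ACT is a two-deck concurrent-schedule task.  Rewards and penalties are
arranged on the decks by two *independent* variable-interval (VI) streams:
a single exponential timer per stream arranges an event after a variable
interval, assigns it to a deck (probabilistically, without replacement from
the scheduled per-deck counts — dependent scheduling in the Stubbs–Pliskoff
sense), and then halts until a key press on the assigned deck collects the
event.  Dependent scheduling guarantees the obtained per-deck event ratio
equals the arranged ratio whenever a component runs to completion.

Each session condition varies exactly one dimension (reward frequency,
reward magnitude, penalty frequency, penalty magnitude) across its four
components while holding the other three constant and equal across decks;
the scheduled net reward per component is identical ($700 total) in every
condition.  A component ends when every scheduled event has been collected
or after 8 minutes, whichever comes first — an exclusive preference for one
deck stalls the other deck's armed events and forces a timeout, which is
the task's missing-data mechanism.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

MAX_COMPONENT_DURATION = 480.0  # seconds (8 min)
EVENTS_PER_VARIED_STREAM = 20
MAGNITUDE_OFFSETS = (-20.0, -10.0, 0.0, 10.0, 20.0)


class ConditionConfigError(ValueError):
    """Raised for malformed condition configuration."""


@dataclass(frozen=True)
class ComponentSpec:
    """One ACT component: scheduled event counts and magnitudes per deck.

    Deck indexing is (deck1, deck2) throughout.  ``*_variable`` marks the
    magnitude cells that vary from event to event around their mean.
    """

    condition: int
    component: int
    reward_count: tuple[int, int]
    reward_mean: tuple[float, float]
    reward_variable: bool
    penalty_count: tuple[int, int]
    penalty_mean: tuple[float, float]
    penalty_variable: bool
    max_duration: float = MAX_COMPONENT_DURATION

    @property
    def varied_stream(self) -> str:
        """The stream carrying the manipulated dimension."""
        return "reward" if self.condition in (1, 2) else "penalty"

    def counts(self, stream: str) -> tuple[int, int]:
        return self.reward_count if stream == "reward" else self.penalty_count

    def means(self, stream: str) -> tuple[float, float]:
        return self.reward_mean if stream == "reward" else self.penalty_mean

    def is_variable(self, stream: str) -> bool:
        return self.reward_variable if stream == "reward" else self.penalty_variable

    def net_reward(self, deck: int) -> float:
        """Scheduled net reward for a deck (1 or 2), assuming full delivery."""
        i = deck - 1
        return (
            self.reward_count[i] * self.reward_mean[i]
            - self.penalty_count[i] * self.penalty_mean[i]
        )


def _load_table() -> dict:
    ref = importlib.resources.files("opercard.data") / "act_table4.json"
    return json.loads(ref.read_text())


def _cell_counts(p: Sequence[float], variable: bool) -> tuple[int, int]:
    """Derive per-deck scheduled event counts from a condition-table cell.

    A varied-frequency dimension (unequal probabilities) splits 20 events by
    the printed probabilities; a varied-magnitude dimension schedules 10
    events per deck; a constant dimension schedules 5 per deck.
    """
    if abs(p[0] + p[1] - 1.0) > 1e-9:
        raise ConditionConfigError(f"cell probabilities {p} do not sum to 1")
    if p[0] != p[1]:
        c1 = round(EVENTS_PER_VARIED_STREAM * p[0])
        return (c1, EVENTS_PER_VARIED_STREAM - c1)
    return (10, 10) if variable else (5, 5)


def build_condition(condition_id: int, config: dict | None = None) -> list[ComponentSpec]:
    """Build the four ComponentSpecs of one session condition (1-4)."""
    table = config if config is not None else _load_table()
    key = str(condition_id)
    if key not in table:
        raise ValueError(f"condition_id must be 1-4, got {condition_id}")
    specs = []
    for i, comp in enumerate(table[key]["components"], start=1):
        r, p = comp["reward"], comp["penalty"]
        specs.append(
            ComponentSpec(
                condition=condition_id,
                component=i,
                reward_count=_cell_counts(r["p"], r["variable"]),
                reward_mean=(float(r["amount"][0]), float(r["amount"][1])),
                reward_variable=bool(r["variable"]),
                penalty_count=_cell_counts(p["p"], p["variable"]),
                penalty_mean=(float(p["amount"][0]), float(p["amount"][1])),
                penalty_variable=bool(p["variable"]),
            )
        )
    return specs


def sample_magnitude(
    mean: float,
    variable: bool,
    rng: np.random.Generator,
    offsets: Sequence[float] = MAGNITUDE_OFFSETS,
) -> float:
    """One event magnitude: the mean exactly, or a uniform draw around it."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if not variable:
        return mean
    values = [mean + o for o in offsets]
    if min(values) <= 0:
        raise ConditionConfigError(f"magnitude set {values} contains nonpositive values")
    return float(values[rng.integers(len(values))])


def _balanced_magnitudes(
    mean: float, count: int, rng: np.random.Generator,
    offsets: Sequence[float] = MAGNITUDE_OFFSETS,
) -> list[float]:
    """Shuffled multiset of ``count`` magnitudes summing to ``count * mean``.

    Offsets are cycled so per-deck totals hit the scheduled amount exactly
    (counts here are always multiples of the offset-set size).
    """
    values = [mean + offsets[i % len(offsets)] for i in range(count)]
    if min(values) <= 0:
        raise ConditionConfigError(f"magnitude set around {mean} contains nonpositive values")
    rng.shuffle(values)
    return values


@dataclass(frozen=True)
class ArrangedEvent:
    interval: float  # VI timer interval preceding this event (s)
    deck: int  # 1 or 2
    amount: float


def arrange_schedule(
    spec: ComponentSpec,
    stream: str,
    seed: int | np.random.Generator | None = None,
    vi_mean: float | None = None,
) -> list[ArrangedEvent]:
    """Arrange one stream's events: VI intervals, deck assignment, magnitudes.

    A single VI timer serves both decks: intervals are exponential with mean
    ``vi_mean`` (default: 60% of the component duration divided by the
    stream's total event count, leaving timeout headroom for an attentive
    responder).  Deck assignment draws without replacement from the scheduled
    per-deck counts, so exactly those counts are arranged.  Variable
    magnitudes come from a balanced multiset per deck (totals exact).
    """
    if stream not in ("reward", "penalty"):
        raise ValueError(f"stream must be 'reward' or 'penalty', got {stream!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = spec.counts(stream)
    means = spec.means(stream)
    total = counts[0] + counts[1]
    if vi_mean is None:
        vi_mean = spec.max_duration * 0.6 / total
    deck_labels = np.array([1] * counts[0] + [2] * counts[1])
    rng.shuffle(deck_labels)
    if spec.is_variable(stream):
        mags = {
            1: _balanced_magnitudes(means[0], counts[0], rng),
            2: _balanced_magnitudes(means[1], counts[1], rng),
        }
    else:
        mags = {1: [means[0]] * counts[0], 2: [means[1]] * counts[1]}
    used = {1: 0, 2: 0}
    plan = []
    for deck in deck_labels:
        deck = int(deck)
        plan.append(
            ArrangedEvent(
                interval=float(rng.exponential(vi_mean)),
                deck=deck,
                amount=mags[deck][used[deck]],
            )
        )
        used[deck] += 1
    return plan


@dataclass(frozen=True)
class ACTEvent:
    time: float
    kind: str  # press | reward | penalty | component_end
    deck: int | None
    amount: float | None


@dataclass
class ObtainedState:
    """Running per-component tallies handed to the agent at each press."""

    presses: list[int] = field(default_factory=lambda: [0, 0])
    rewards: list[tuple[int, float]] = field(default_factory=list)  # (deck, amount)
    penalties: list[tuple[int, float]] = field(default_factory=list)


@dataclass
class ACTEventLog:
    """Timestamped event stream of one component run."""

    condition: int
    component: int
    spec: ComponentSpec
    events: list[ACTEvent]
    termination_reason: str  # all_delivered | timeout
    session: str = "sim"

    def events_of(self, kind: str, deck: int | None = None) -> list[ACTEvent]:
        return [
            e
            for e in self.events
            if e.kind == kind and (deck is None or e.deck == deck)
        ]

    def delivered_count(self, stream: str, deck: int) -> int:
        return len(self.events_of(stream, deck))

    def delivered_amount(self, stream: str, deck: int) -> float:
        return sum(e.amount for e in self.events_of(stream, deck))

    def net_delivered(self, deck: int) -> float:
        return self.delivered_amount("reward", deck) - self.delivered_amount(
            "penalty", deck
        )

    @property
    def end_time(self) -> float:
        return self.events[-1].time if self.events else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "session": self.session,
                "condition": self.condition,
                "component": self.component,
                "time_s": [e.time for e in self.events],
                "kind": [e.kind for e in self.events],
                "deck": [e.deck for e in self.events],
                "amount": [e.amount for e in self.events],
            }
        )


# An ACT policy maps (time, obtained state, RNG) -> (delay to next press, deck).
ACTPolicy = Callable[[float, ObtainedState, np.random.Generator], tuple[float, int]]


class _StreamState:
    """Dependent-scheduling runtime state for one stream."""

    def __init__(self, plan: list[ArrangedEvent]):
        self.plan = plan
        self.idx = 0
        # time at which the current event becomes available for collection;
        # the timer for event i+1 starts only when event i is collected
        self.arm_time = plan[0].interval if plan else np.inf

    @property
    def done(self) -> bool:
        return self.idx >= len(self.plan)

    def try_collect(self, t: float, deck: int) -> ArrangedEvent | None:
        if self.done or t < self.arm_time:
            return None
        ev = self.plan[self.idx]
        if ev.deck != deck:
            return None
        self.idx += 1
        self.arm_time = (
            t + self.plan[self.idx].interval if not self.done else np.inf
        )
        return ev


def run_component(
    agent: ACTPolicy,
    spec: ComponentSpec,
    seed: int | None = None,
    session: str = "sim",
    vi_mean: float | None = None,
) -> ACTEventLog:
    """Run one component against a continuous-time press policy.

    Reward and penalty streams run independently; each press can collect at
    most one armed event per stream.  The component ends when both streams
    are exhausted (``all_delivered``) or at ``spec.max_duration`` seconds
    (``timeout``).
    """
    root = np.random.default_rng(seed)
    rng_reward, rng_penalty, rng_agent = root.spawn(3)
    streams = {
        "reward": _StreamState(arrange_schedule(spec, "reward", rng_reward, vi_mean)),
        "penalty": _StreamState(arrange_schedule(spec, "penalty", rng_penalty, vi_mean)),
    }
    events: list[ACTEvent] = []
    state = ObtainedState()
    t = 0.0
    reason = "timeout"
    while True:
        dt, deck = agent(t, state, rng_agent)
        if dt <= 0:
            raise ValueError("agent returned nonpositive inter-press interval")
        if deck not in (1, 2):
            raise ValueError(f"agent returned invalid deck {deck!r}")
        t += dt
        if t > spec.max_duration:
            t = spec.max_duration
            break
        events.append(ACTEvent(time=t, kind="press", deck=deck, amount=None))
        state.presses[deck - 1] += 1
        for name, stream in streams.items():
            ev = stream.try_collect(t, deck)
            if ev is not None:
                events.append(ACTEvent(time=t, kind=name, deck=deck, amount=ev.amount))
                (state.rewards if name == "reward" else state.penalties).append(
                    (deck, ev.amount)
                )
        if streams["reward"].done and streams["penalty"].done:
            reason = "all_delivered"
            break
    events.append(ACTEvent(time=t, kind="component_end", deck=None, amount=None))
    return ACTEventLog(
        condition=spec.condition,
        component=spec.component,
        spec=spec,
        events=events,
        termination_reason=reason,
        session=session,
    )


def run_session(
    agent: ACTPolicy,
    condition_id: int,
    seed: int | None = None,
    session: str = "sim",
    config: dict | None = None,
    vi_mean: float | None = None,
) -> list[ACTEventLog]:
    """Run the four components of a condition in seeded random order.

    Returns the component logs in presentation order; each log carries its
    Table-position component id, so analyses are order-agnostic.
    """
    specs = build_condition(condition_id, config)
    root = np.random.default_rng(seed)
    order = root.permutation(4)
    comp_seeds = root.integers(0, 2**31 - 1, size=4)
    return [
        run_component(agent, specs[i], int(comp_seeds[k]), session, vi_mean)
        for k, i in enumerate(order)
    ]


def write_event_logs(logs: Sequence[ACTEventLog], path) -> None:
    """Write component logs to a single CSV (act event-log format)."""
    pd.concat([l.to_frame() for l in logs], ignore_index=True).to_csv(path, index=False)


def read_event_logs(path, config: dict | None = None) -> list[ACTEventLog]:
    """Read component logs from CSV, rebuilding specs from the condition table."""
    df = pd.read_csv(path)
    required = {"session", "condition", "component", "time_s", "kind", "deck", "amount"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"event log missing columns {sorted(missing)}")
    logs = []
    for (sess, cond, comp), grp in df.groupby(["session", "condition", "component"]):
        spec = build_condition(int(cond), config)[int(comp) - 1]
        grp = grp.sort_values("time_s")
        events = [
            ACTEvent(
                time=float(r.time_s),
                kind=str(r.kind),
                deck=None if pd.isna(r.deck) else int(r.deck),
                amount=None if pd.isna(r.amount) else float(r.amount),
            )
            for r in grp.itertuples(index=False)
        ]
        delivered = sum(1 for e in events if e.kind in ("reward", "penalty"))
        scheduled = sum(spec.reward_count) + sum(spec.penalty_count)
        logs.append(
            ACTEventLog(
                condition=int(cond),
                component=int(comp),
                spec=spec,
                events=events,
                termination_reason="all_delivered" if delivered == scheduled else "timeout",
                session=str(sess),
            )
        )
    return logs
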