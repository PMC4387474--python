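"""Synthetic agents for the IGT and ACT.

Neither task's human data are deposited, so these generators provide the
statistical structure the analyses assume.  The IGT agent is a delta-rule
expectancy learner with softmax choice: on each trial the chosen deck's
expectancy is nudged toward the trial's net outcome (with a separate weight
on losses), and choices are softmax in the expectancies with a uniform
exploration floor.  Heterogeneous learning rates reproduce the documented
phenomenology — fast and slow learners, non-learners that never stabilize,
and varied final deck preferences.  Named archetypes are fixed parameter
sets (plus two deterministic special cases) stored as data.

The ACT agent is a generalized-matching responder in continuous time:
presses arrive at a fixed rate and each press goes to deck 1 with
probability p satisfying logit10(p) = a * (log10 obtained-reward-ratio -
log10 obtained-penalty-ratio) + log bias, estimated over a window of recent
obtained events.  Before any events are obtained allocation is 50/50, so
blockwise sensitivity starts near zero and rises as the estimate sharpens.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import math

import numpy as np

from .act_engine import ACTPolicy, ObtainedState
from .igt_engine import DECKS, GOOD_DECKS, IGTPolicy, Trial

OUTCOME_SCALE = 100.0  # currency units per unit expectancy


@dataclass(frozen=True)
class IGTAgentParams:
    learning_rate: float = 0.15
    inverse_temperature: float = 3.0
    loss_weight: float = 1.0
    exploration_floor: float = 0.05
    archetype: str | None = None
    allowed_decks: tuple[str, ...] = DECKS

    def __post_init__(self) -> None:
        if not 0.0 <= self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in [0, 1]")
        if self.inverse_temperature < 0 or self.loss_weight < 0:
            raise ValueError("inverse_temperature and loss_weight must be >= 0")
        if not 0.0 <= self.exploration_floor <= 1.0:
            raise ValueError("exploration_floor must lie in [0, 1]")
        if not set(self.allowed_decks) <= set(DECKS) or not self.allowed_decks:
            raise ValueError(f"invalid allowed_decks {self.allowed_decks}")


# Archetype parameter sets; "ideal" and "perseverative" are deterministic
# special cases handled in igt_agent.
IGT_ARCHETYPES: dict[str, dict] = {
    "ideal": {},
    "random": {"learning_rate": 0.5, "inverse_temperature": 0.0, "exploration_floor": 1.0},
    "perseverative": {},
    "late-learner": {"learning_rate": 0.04, "inverse_temperature": 3.0,
                     "exploration_floor": 0.05},
    "non-learner": {"learning_rate": 0.005, "inverse_temperature": 1.0,
                    "exploration_floor": 0.4},
}


def _ideal_policy(allowed: Sequence[str]) -> IGTPolicy:
    """Sweep each allowed deck once, then alternate over the allowed good decks."""
    targets = [d for d in allowed if d in GOOD_DECKS] or list(allowed)

    def policy(history: Sequence[Trial], rng: np.random.Generator) -> str:
        t = len(history)
        if t < len(allowed):
            return allowed[t]
        return targets[t % len(targets)]

    return policy


def _perseverative_policy(allowed: Sequence[str]) -> IGTPolicy:
    def policy(history: Sequence[Trial], rng: np.random.Generator) -> str:
        if not history:
            return allowed[rng.integers(len(allowed))]
        return history[0].deck

    return policy


def igt_agent(params: IGTAgentParams, seed: int | None = None) -> IGTPolicy:
    """Build an IGT policy from parameters (or a named archetype).

    The returned policy is a deterministic function of (history, rng): the
    expectancy state is reconstructed from the history, so replaying the
    same history with the same engine seed reproduces the same choices.
    ``seed`` is unused by the parametric agent (the engine supplies the RNG)
    and accepted for interface symmetry with the ACT agent.
    """
    if params.archetype is not None:
        if params.archetype not in IGT_ARCHETYPES:
            raise ValueError(f"unknown archetype {params.archetype!r}")
        if params.archetype == "ideal":
            return _ideal_policy(params.allowed_decks)
        if params.archetype == "perseverative":
            return _perseverative_policy(params.allowed_decks)
        params = replace(
            params, archetype=None, **IGT_ARCHETYPES[params.archetype]
        )
    allowed = list(params.allowed_decks)
    # incremental expectancy cache keyed by history length
    state = {"values": {d: 0.0 for d in DECKS}, "n_seen": 0}

    def _update(trial: Trial) -> None:
        outcome = (trial.win - params.loss_weight * trial.loss) / OUTCOME_SCALE
        v = state["values"][trial.deck]
        state["values"][trial.deck] = v + params.learning_rate * (outcome - v)

    def policy(history: Sequence[Trial], rng: np.random.Generator) -> str:
        if len(history) < state["n_seen"]:
            state["values"] = {d: 0.0 for d in DECKS}
            state["n_seen"] = 0
        for trial in history[state["n_seen"] :]:
            _update(trial)
        state["n_seen"] = len(history)
        v = np.array([state["values"][d] for d in allowed])
        z = params.inverse_temperature * v
        z -= z.max()
        soft = np.exp(z)
        soft /= soft.sum()
        probs = (
            params.exploration_floor / len(allowed)
            + (1.0 - params.exploration_floor) * soft
        )
        return allowed[rng.choice(len(allowed), p=probs)]

    return policy


@dataclass(frozen=True)
class ACTAgentParams:
    sensitivity: float = 0.8
    log_bias: float = 0.0
    press_rate: float = 1.5  # presses per second
    estimate_window: int = 40  # obtained events per stream; 40 covers a component

    def __post_init__(self) -> None:
        if self.press_rate <= 0:
            raise ValueError("press_rate must be positive")
        if self.estimate_window < 1:
            raise ValueError("estimate_window must be >= 1")


def _window_log_ratio(events: list[tuple[int, float]], window: int) -> float:
    """log10 of deck1/deck2 obtained amounts over the last ``window`` events.

    Zero on either deck (including no events yet) contributes no term: the
    agent stays indifferent on that stream until both decks have paid out.
    """
    recent = events[-window:]
    a1 = sum(amt for deck, amt in recent if deck == 1)
    a2 = sum(amt for deck, amt in recent if deck == 2)
    if a1 <= 0 or a2 <= 0:
        return 0.0
    return math.log10(a1 / a2)


def act_agent(params: ACTAgentParams, seed: int | None = None) -> ACTPolicy:
    """Build a continuous-time matching policy for :func:`run_component`.

    Presses arrive at ``press_rate`` (exponential inter-press intervals from
    the engine-supplied RNG).  Allocation follows the generalized matching
    law on the agent's own obtained-amount estimates, with penalties
    entering repulsively; ``seed`` is accepted for interface symmetry but
    the engine RNG carries all stochasticity.
    """

    def policy(
        t: float, state: ObtainedState, rng: np.random.Generator
    ) -> tuple[float, int]:
        dt = float(rng.exponential(1.0 / params.press_rate))
        term = _window_log_ratio(state.rewards, params.estimate_window) - _window_log_ratio(
            state.penalties, params.estimate_window
        )
        logit = params.sensitivity * term + params.log_bias
        p1 = 1.0 / (1.0 + 10.0 ** (-logit))
        deck = 1 if rng.random() < p1 else 2
        return max(dt, 1e-9), deck

    return policy


@dataclass(frozen=True)
class CohortMember:
    agent_id: str
    kind: str  # igt | act
    params: IGTAgentParams | ACTAgentParams
    seed: int


def _draw_param(spec, rng: np.random.Generator):
    if isinstance(spec, (int, float, str, bool)):
        return spec
    if isinstance(spec, (tuple, list)):
        tag = spec[0]
        if tag == "uniform":
            return float(rng.uniform(spec[1], spec[2]))
        if tag == "loguniform":
            return float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
        if tag == "choice":
            options = spec[1]
            probs = spec[2] if len(spec) > 2 else None
            return options[rng.choice(len(options), p=probs)]
    raise ValueError(f"invalid parameter distribution spec {spec!r}")


def build_cohort(
    n: int,
    kind: str,
    param_distributions: dict,
    seed: int | None = None,
) -> tuple[list[CohortMember], list[dict]]:
    """Draw a reproducible cohort of agent parameter sets.

    ``param_distributions`` maps parameter names to either a fixed value or
    a distribution spec: ``("uniform", lo, hi)``, ``("loguniform", lo, hi)``
    or ``("choice", options[, probs])``.  Returns the members (each with its
    own session seed) and a manifest recording every drawn value — the
    ground truth for parameter-recovery checks.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if kind not in ("igt", "act"):
        raise ValueError(f"kind must be 'igt' or 'act', got {kind!r}")
    cls = IGTAgentParams if kind == "igt" else ACTAgentParams
    rng = np.random.default_rng(seed)
    members, manifest = [], []
    for i in range(n):
        drawn = {name: _draw_param(spec, rng) for name, spec in param_distributions.items()}
        member_seed = int(rng.integers(0, 2**31 - 1))
        try:
            params = cls(**drawn)
        except TypeError as exc:
            raise ValueError(f"invalid parameter name for {kind} agent: {exc}") from None
        agent_id = f"{kind}{i + 1:03d}"
        members.append(CohortMember(agent_id, kind, params, member_seed))
        manifest.append({"agent_id": agent_id, "seed": member_seed, **drawn})
    return members, manifest
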