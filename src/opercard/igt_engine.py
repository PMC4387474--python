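"""Iowa Gambling Task session machinery.

The IGT presents four decks (A-D) of cards; each draw yields a win and,
sometimes, a simultaneous loss.  Decks A and B pay $100 per card but lose
$250 net per 10 cards; decks C and D pay $50 per card and gain $250 net per
10 cards.  A and C impose frequent small losses, B and D a single large loss
per 10 cards.  Outcomes are defined for 40 cards per deck and the schedule
repeats cyclically for longer sessions.  Sessions start on a $2000 loan and
further $2000 loans are granted whenever the balance would go negative.

This module is purely turn-based: no inter-trial timing is modelled.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

DECKS = ("A", "B", "C", "D")
GOOD_DECKS = frozenset({"C", "D"})
BAD_DECKS = frozenset({"A", "B"})
LOAN_AMOUNT = 2000.0


class ScheduleFormatError(ValueError):
    """Raised when a payoff-schedule file is malformed."""


class TrialLogFormatError(ValueError):
    """Raised when a trial-log file is malformed."""


@dataclass(frozen=True)
class PayoffSchedule:
    """Per-deck ordered card outcomes, cyclic after ``cycle_length`` draws.

    ``decks`` maps each deck label to a tuple of ``(win, loss)`` pairs, both
    non-negative currency amounts; a loss of 0 means a reward-only card.
    """

    decks: dict[str, tuple[tuple[float, float], ...]]
    cycle_length: int = 40

    def __post_init__(self) -> None:
        if set(self.decks) != set(DECKS):
            raise ScheduleFormatError(
                f"schedule must define decks {DECKS}, got {sorted(self.decks)}"
            )
        for deck, cards in self.decks.items():
            if len(cards) != self.cycle_length:
                raise ScheduleFormatError(
                    f"deck {deck} has {len(cards)} cards, expected {self.cycle_length}"
                )
            for pos, (win, loss) in enumerate(cards, start=1):
                if win < 0 or loss < 0:
                    raise ScheduleFormatError(
                        f"deck {deck} position {pos}: negative amount"
                    )

    def net_per_cycle(self, deck: str) -> float:
        """Net outcome (wins minus losses) over one full 40-card cycle."""
        return float(sum(w - l for w, l in self.decks[deck]))


def load_payoff_schedule(source: str | Path) -> PayoffSchedule:
    """Load a payoff schedule from a CSV file or a packaged fixture name.

    The CSV format has columns ``deck,position,win,loss`` with positions
    1..40 per deck.  The packaged fixture ``"bechara_standard"`` follows the
    standard task structure described in the module docstring.
    """
    source = str(source)
    if "/" not in source and not source.endswith(".csv"):
        ref = importlib.resources.files("opercard.data") / f"{source}.csv"
        if not ref.is_file():
            raise ScheduleFormatError(f"unknown packaged schedule {source!r}")
        with importlib.resources.as_file(ref) as path:
            df = pd.read_csv(path)
    else:
        df = pd.read_csv(source)
    required = {"deck", "position", "win", "loss"}
    if not required.issubset(df.columns):
        raise ScheduleFormatError(
            f"schedule file missing columns {sorted(required - set(df.columns))}"
        )
    decks: dict[str, tuple[tuple[float, float], ...]] = {}
    for deck, grp in df.groupby("deck"):
        grp = grp.sort_values("position")
        positions = grp["position"].to_numpy()
        if not np.array_equal(positions, np.arange(1, len(grp) + 1)):
            bad = int(positions[positions != np.arange(1, len(grp) + 1)][0])
            raise ScheduleFormatError(f"deck {deck}: bad position sequence near row {bad}")
        decks[str(deck)] = tuple(
            (float(w), float(l)) for w, l in zip(grp["win"], grp["loss"])
        )
    return PayoffSchedule(decks=decks)


def draw_outcome(
    schedule: PayoffSchedule, deck: str, draw_count: int
) -> tuple[float, float]:
    """Outcome ``(win, loss)`` of the ``draw_count``-th draw from ``deck``.

    ``draw_count`` is 1-based and counts draws from that deck only; the
    40-card schedule repeats, so draw 41 equals draw 1.
    """
    if deck not in schedule.decks:
        raise KeyError(f"unknown deck label {deck!r}")
    if draw_count < 1:
        raise ValueError(f"draw_count must be >= 1, got {draw_count}")
    pos = (draw_count - 1) % schedule.cycle_length
    return schedule.decks[deck][pos]


@dataclass(frozen=True)
class Trial:
    trial: int  # 1-based
    deck: str
    win: float
    loss: float
    balance: float  # after win/loss and any loan top-up


@dataclass
class IGTTrialLog:
    """One participant's ordered IGT session record."""

    participant_id: str
    trials: list[Trial] = field(default_factory=list)
    loans: int = 1  # session starts on one loan

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def deck_sequence(self) -> list[str]:
        return [t.deck for t in self.trials]

    @property
    def balance_trace(self) -> np.ndarray:
        return np.array([t.balance for t in self.trials])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "trial": [t.trial for t in self.trials],
                "deck": [t.deck for t in self.trials],
                "win": [t.win for t in self.trials],
                "loss": [t.loss for t in self.trials],
                "balance": [t.balance for t in self.trials],
            }
        )


# An IGT policy maps (history so far, RNG) -> deck label.
IGTPolicy = Callable[[Sequence[Trial], np.random.Generator], str]


def run_igt_session(
    policy: IGTPolicy,
    schedule: PayoffSchedule,
    n_trials: int = 200,
    seed: int | None = None,
    participant_id: str = "sim",
    loan_mode: str = "add",
) -> IGTTrialLog:
    """Run a turn-based IGT session against an agent policy.

    The session starts with a balance of one $2000 loan.  After each trial's
    win and loss are applied, a further $2000 loan is granted whenever the
    balance is negative: ``loan_mode="add"`` adds $2000 to the balance (the
    default), ``loan_mode="reset"`` resets the balance to zero.  Identical
    ``(policy, seed)`` pairs produce identical logs.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if loan_mode not in ("add", "reset"):
        raise ValueError(f"loan_mode must be 'add' or 'reset', got {loan_mode!r}")
    rng = np.random.default_rng(seed)
    log = IGTTrialLog(participant_id=participant_id)
    balance = LOAN_AMOUNT
    draw_counts = {d: 0 for d in DECKS}
    for t in range(1, n_trials + 1):
        deck = policy(log.trials, rng)
        if deck not in DECKS:
            raise ValueError(f"policy returned invalid deck {deck!r} at trial {t}")
        draw_counts[deck] += 1
        win, loss = draw_outcome(schedule, deck, draw_counts[deck])
        balance += win - loss
        while balance < 0:
            log.loans += 1
            balance = balance + LOAN_AMOUNT if loan_mode == "add" else 0.0
        log.trials.append(Trial(trial=t, deck=deck, win=win, loss=loss, balance=balance))
    return log


def write_trial_log(log: IGTTrialLog, path: str | Path) -> None:
    """Write a trial log to CSV (columns participant_id,trial,deck,win,loss,balance)."""
    log.to_frame().to_csv(path, index=False)


def read_trial_log(path: str | Path) -> IGTTrialLog:
    """Read a trial log written by :func:`write_trial_log`."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TrialLogFormatError(f"empty trial-log file: {path}") from None
    required = {"participant_id", "trial", "deck", "win", "loss", "balance"}
    missing = required - set(df.columns)
    if missing:
        raise TrialLogFormatError(f"trial log missing columns {sorted(missing)}")
    if len(df) == 0:
        raise TrialLogFormatError(f"trial log has no rows: {path}")
    df = df.sort_values("trial")
    trials_idx = df["trial"].to_numpy()
    if not np.array_equal(trials_idx, np.arange(1, len(df) + 1)):
        raise TrialLogFormatError("trial indices are not contiguous 1..N")
    log = IGTTrialLog(participant_id=str(df["participant_id"].iloc[0]))
    for row in df.itertuples(index=False):
        log.trials.append(
            Trial(
                trial=int(row.trial),
                deck=str(row.deck),
                win=float(row.win),
                loss=float(row.loss),
                balance=float(row.balance),
            )
        )
    return log
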