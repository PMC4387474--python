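"""Operant-style analytics for Iowa Gambling Task trial logs.

Implements proportional net scores, 20-trial block aggregation, deck and
switch proportions, impairment classification under two conventional
thresholds, and a block-based stability criterion: a block shows a strong
single-deck preference when that deck's choice proportion is at least 0.50
and exceeds every other deck's by at least 0.25; failing that, a strong
pair preference when two decks jointly account for at least 0.75 of choices
and differ by less than 0.25.  Behaviour is stable when the same preference
label holds for three consecutive blocks (60 trials).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .igt_engine import BAD_DECKS, DECKS, GOOD_DECKS, IGTTrialLog

IMPAIRMENT_CRITERIA = {
    "bechara_0.10": 0.10,  # net score < 0.10, the original patient-normed cutoff
    "steingroever_0.00": 0.00,  # stricter net score < 0.00
}


def _deck_sequence(log: IGTTrialLog | Sequence[str]) -> list[str]:
    if isinstance(log, IGTTrialLog):
        return log.deck_sequence
    return list(log)


def net_score(
    log: IGTTrialLog | Sequence[str], trial_range: tuple[int, int] | None = None
) -> float:
    """Proportional net score over an inclusive 1-based trial range.

    ``(n_C + n_D - n_A - n_B) / n`` — the classic good-minus-bad deck count,
    divided by the number of trials so values lie in [-1, 1] and are
    comparable across task lengths.
    """
    decks = _deck_sequence(log)
    if trial_range is None:
        trial_range = (1, len(decks))
    lo, hi = trial_range
    if lo < 1 or hi > len(decks) or lo > hi:
        raise ValueError(f"trial range {trial_range} invalid for log of length {len(decks)}")
    window = decks[lo - 1 : hi]
    good = sum(d in GOOD_DECKS for d in window)
    bad = sum(d in BAD_DECKS for d in window)
    return (good - bad) / len(window)


def stable_window_net_score(
    log: IGTTrialLog | Sequence[str], window: tuple[int, int]
) -> float:
    """Net score restricted to a stable window (e.g. the final 40 trials)."""
    return net_score(log, window)


def classify_impairment(net: float, criterion: str = "bechara_0.10") -> bool:
    """True iff ``net`` falls strictly below the named impairment threshold."""
    if not -1.0 <= net <= 1.0:
        raise ValueError(f"net score {net} outside [-1, 1]")
    try:
        threshold = IMPAIRMENT_CRITERIA[criterion]
    except KeyError:
        raise ValueError(
            f"unknown criterion {criterion!r}; choose from {sorted(IMPAIRMENT_CRITERIA)}"
        ) from None
    return net < threshold


@dataclass(frozen=True)
class BlockPreferenceProfile:
    """Per-deck choice proportions within one block of trials."""

    block_index: int  # 1-based
    block_size: int
    proportions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"block {self.block_index}: proportions sum to {total}")


def block_profiles(
    log: IGTTrialLog | Sequence[str], block_size: int = 20
) -> list[BlockPreferenceProfile]:
    """Split a log into consecutive blocks and compute deck proportions.

    The log length must divide evenly into blocks; a partial final block is
    rejected rather than silently dropped.
    """
    if block_size <= 0:
        raise ValueError("block_size must be positive")
    decks = _deck_sequence(log)
    if len(decks) % block_size != 0:
        raise ValueError(
            f"log length {len(decks)} is not a multiple of block_size {block_size}"
        )
    profiles = []
    for b in range(len(decks) // block_size):
        chunk = decks[b * block_size : (b + 1) * block_size]
        counts = Counter(chunk)
        profiles.append(
            BlockPreferenceProfile(
                block_index=b + 1,
                block_size=block_size,
                proportions={d: counts.get(d, 0) / block_size for d in DECKS},
            )
        )
    return profiles


def switch_proportion(
    log: IGTTrialLog | Sequence[str], block_size: int = 20
) -> np.ndarray:
    """Per-block fraction of trials whose deck differs from the previous trial.

    Trial t is an eligible comparison when t >= 2; the comparison crossing a
    block boundary is attributed to the later block, so block 1 has
    ``block_size - 1`` eligible comparisons and later blocks ``block_size``.
    """
    if block_size <= 0:
        raise ValueError("block_size must be positive")
    decks = _deck_sequence(log)
    if len(decks) % block_size != 0:
        raise ValueError(
            f"log length {len(decks)} is not a multiple of block_size {block_size}"
        )
    switches = np.array(
        [decks[i] != decks[i - 1] for i in range(1, len(decks))], dtype=float
    )
    out = []
    for b in range(len(decks) // block_size):
        # comparison at trial t (1-based, t>=2) lives at switches[t-2]
        lo = max(b * block_size + 1, 2) - 2
        hi = (b + 1) * block_size - 1
        chunk = switches[lo:hi]
        out.append(chunk.mean() if len(chunk) else 0.0)
    return np.array(out)


@dataclass(frozen=True)
class PreferenceLabel:
    """A block's preference: a single deck, an (unordered) pair, or none."""

    decks: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.decks) > 2 or not self.decks <= set(DECKS):
            raise ValueError(f"invalid preference decks {set(self.decks)}")

    @property
    def kind(self) -> str:
        return {0: "none", 1: "single", 2: "pair"}[len(self.decks)]

    def __str__(self) -> str:
        return "+".join(sorted(self.decks)) if self.decks else "none"


NO_PREFERENCE = PreferenceLabel(frozenset())


def block_preference(profile: BlockPreferenceProfile) -> PreferenceLabel:
    """Apply the strong-preference rules to one block.

    Single-deck rule first (p >= 0.50 and a >= 0.25 margin over every other
    deck); the pair rule (joint p >= 0.75, difference < 0.25) only applies
    when no single deck qualifies.
    """
    p = profile.proportions
    for d in DECKS:
        if p[d] >= 0.50 and all(p[d] - p[e] >= 0.25 for e in DECKS if e != d):
            return PreferenceLabel(frozenset({d}))
    for i, d in enumerate(DECKS):
        for e in DECKS[i + 1 :]:
            if p[d] + p[e] >= 0.75 and abs(p[d] - p[e]) < 0.25:
                return PreferenceLabel(frozenset({d, e}))
    return NO_PREFERENCE


@dataclass
class StabilityResult:
    """Outcome of the stability criterion over a sequence of block labels."""

    labels: list[PreferenceLabel]
    first_stable_block: int | None  # final block of the earliest qualifying run
    stable_preference: PreferenceLabel | None
    decision_class: str  # good | poor | bad-deck
    later_changes: int = 0  # label changes after the criterion locked

    @property
    def is_stable(self) -> bool:
        return self.first_stable_block is not None


def detect_stability(
    labels: Sequence[PreferenceLabel], run_length: int = 3
) -> StabilityResult:
    """Find the earliest run of ``run_length`` identical non-none labels.

    ``first_stable_block`` is the (1-based) index of the *last* block of that
    run, so with 20-trial blocks "stable by 100 trials" means
    ``first_stable_block <= 5``.  The criterion locks at first satisfaction;
    later label changes are counted but do not re-classify.

    ``decision_class`` is "good" when the stable preference involves only
    decks C/D, "bad-deck" when it includes A or B, and "poor" when the
    criterion is never met.
    """
    if not labels:
        raise ValueError("labels must be nonempty")
    labels = list(labels)
    first_stable = None
    stable_pref = None
    for i in range(run_length - 1, len(labels)):
        run = labels[i - run_length + 1 : i + 1]
        if run[0].kind != "none" and all(l == run[0] for l in run):
            first_stable = i + 1
            stable_pref = run[0]
            break
    if first_stable is None:
        return StabilityResult(labels, None, None, "poor")
    decision = "good" if stable_pref.decks <= GOOD_DECKS else "bad-deck"
    later = sum(
        1
        for j in range(first_stable, len(labels))
        if labels[j] != labels[j - 1]
    )
    return StabilityResult(labels, first_stable, stable_pref, decision, later)


def stability_result(
    log: IGTTrialLog | Sequence[str], block_size: int = 20, run_length: int = 3
) -> StabilityResult:
    """Convenience: profile a log into blocks, label each, detect stability."""
    return detect_stability(
        [block_preference(p) for p in block_profiles(log, block_size)], run_length
    )


def cohort_summary(
    logs: Iterable[IGTTrialLog], block_size: int = 20, run_length: int = 3
) -> dict:
    """Cohort-level summary across equal-length logs.

    Returns per-epoch (first half, second half, full task) net-score
    statistics with impairment proportions under both thresholds, the
    cumulative proportion of participants stable by each block, and a
    histogram of stable preferences.
    """
    logs = list(logs)
    if not logs:
        raise ValueError("need at least one log")
    n_trials = len(logs[0])
    offenders = [l.participant_id for l in logs if len(l) != n_trials]
    if offenders:
        raise ValueError(f"logs of unequal length: {offenders}")
    half = n_trials // 2
    epochs = {
        f"1-{half}": (1, half),
        f"{half + 1}-{n_trials}": (half + 1, n_trials),
        f"1-{n_trials}": (1, n_trials),
    }
    rows = []
    for name, rng in epochs.items():
        nets = np.array([net_score(l, rng) for l in logs])
        rows.append(
            {
                "trials": name,
                "mean": nets.mean(),
                "sd": nets.std(ddof=1) if len(nets) > 1 else 0.0,
                "min": nets.min(),
                "max": nets.max(),
                "range": nets.max() - nets.min(),
                "prop_impaired_bechara": np.mean(
                    [classify_impairment(v, "bechara_0.10") for v in nets]
                ),
                "prop_impaired_steingroever": np.mean(
                    [classify_impairment(v, "steingroever_0.00") for v in nets]
                ),
            }
        )
    net_table = pd.DataFrame(rows).set_index("trials")

    results = [stability_result(l, block_size, run_length) for l in logs]
    n_blocks = n_trials // block_size
    stable_by_block = np.array(
        [
            np.mean([r.is_stable and r.first_stable_block <= b for r in results])
            for b in range(1, n_blocks + 1)
        ]
    )
    pref_hist = Counter(
        str(r.stable_preference) if r.is_stable else "none" for r in results
    )
    return {
        "net_scores": net_table,
        "stable_by_block": stable_by_block,
        "preference_histogram": dict(pref_hist),
        "stability_results": results,
    }
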