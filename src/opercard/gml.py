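"""Generalized-matching-law sensitivity estimation from ACT event logs.

The generalized matching law states log(B1/B2) = a * log(R1/R2) + log c,
where B are responses, R reinforcers, a the sensitivity and log c the bias
(base-10 logs by operant convention).  Within each condition only one
dimension varies across components, so each condition is fitted on its own
varied stream: rewards for conditions 1-2, penalties for 3-4.

Blocks are delimited by every 4th event of the varied stream.  A block's
response ratio uses the presses made during the block; its reinforcer ratio
uses everything obtained on the varied stream from the start of the
component to the end of the block.  Obtained amounts (not raw counts) form
the reinforcer ratio; with constant magnitudes the two are identical, while
in magnitude conditions the amount ratio carries the manipulation that
equal counts cannot.  For the penalty conditions the ratio is inverted
(deck2/deck1) so that responding *away* from the punished deck yields a
positive sensitivity, the convention in which punishment sensitivities are
reported.

Ratios with a zero numerator or denominator are flagged invalid, never
silently dropped or continuity-corrected by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .act_engine import ACTEventLog

STABLE_BLOCKS = {1: 2, 2: 3, 3: 3, 4: 3}  # final blocks averaged per condition


class GMLDegenerateError(ValueError):
    """Raised when all regression x-values coincide."""


@dataclass(frozen=True)
class RatioPoint:
    """One (log response ratio, log reinforcer ratio) point for the GML fit."""

    condition: int
    component: int
    block: int  # 1-based
    log_response_ratio: float  # log10(deck1 presses / deck2 presses) in block
    log_reinforcer_ratio: float  # oriented varied-stream amount ratio, cumulative
    valid: bool


def block_ratio_points(
    logs: Sequence[ACTEventLog],
    block_size: int = 4,
    continuity_correction: bool = False,
) -> list[RatioPoint]:
    """Blockwise ratio points for the four component logs of one condition.

    Every component contributes ``scheduled_events / block_size`` points;
    blocks whose events were never delivered (timeouts) or whose ratios are
    undefined are returned with ``valid=False`` and NaN ratios.  With
    ``continuity_correction`` 0.5 is added to each press count and unit
    weight to each amount, defining otherwise-invalid ratios.
    """
    if block_size <= 0:
        raise ValueError("block_size must be positive")
    conditions = {l.condition for l in logs}
    if len(conditions) != 1:
        raise ValueError(f"logs from mixed conditions: {sorted(conditions)}")
    points = []
    for log in logs:
        stream = log.spec.varied_stream
        invert = stream == "penalty"
        scheduled = sum(log.spec.counts(stream))
        n_blocks = scheduled // block_size
        varied = sorted(
            (e for e in log.events if e.kind == stream), key=lambda e: e.time
        )
        presses = sorted(
            (e for e in log.events if e.kind == "press"), key=lambda e: e.time
        )
        prev_end = 0.0
        cum_amount = [0.0, 0.0]
        k = 0  # varied events consumed
        for b in range(1, n_blocks + 1):
            if len(varied) < b * block_size:
                points.append(
                    RatioPoint(log.condition, log.component, b, math.nan, math.nan, False)
                )
                continue
            t_end = varied[b * block_size - 1].time
            while k < b * block_size:
                ev = varied[k]
                cum_amount[ev.deck - 1] += ev.amount
                k += 1
            n_press = [0, 0]
            for p in presses:
                if prev_end < p.time <= t_end or (b == 1 and p.time == 0.0):
                    n_press[p.deck - 1] += 1
            prev_end = t_end
            b1, b2 = n_press
            r1, r2 = cum_amount
            if continuity_correction:
                b1, b2 = b1 + 0.5, b2 + 0.5
                r1, r2 = r1 + 1.0, r2 + 1.0
            if min(b1, b2, r1, r2) <= 0:
                points.append(
                    RatioPoint(log.condition, log.component, b, math.nan, math.nan, False)
                )
                continue
            log_r = math.log10(r2 / r1) if invert else math.log10(r1 / r2)
            points.append(
                RatioPoint(
                    log.condition,
                    log.component,
                    b,
                    math.log10(b1 / b2),
                    log_r,
                    True,
                )
            )
    return points


@dataclass(frozen=True)
class SensitivityEstimate:
    """OLS fit of the generalized matching law over a set of ratio points."""

    sensitivity: float  # slope a (NaN when undefined)
    log_bias: float  # intercept log c
    r_squared: float
    n_points: int
    missing_points: int
    block: int | str | None = None  # block index, "stable", or None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.sensitivity)


_UNDEFINED = dict(sensitivity=math.nan, log_bias=math.nan, r_squared=math.nan)


def fit_gml(
    points: Sequence[RatioPoint], block: int | str | None = None
) -> SensitivityEstimate:
    """Ordinary least squares of log response ratio on log reinforcer ratio.

    Fewer than two valid points yields an undefined (flagged) estimate, not
    an exception; identical x-values across all valid points are a
    degenerate design and raise :class:`GMLDegenerateError`.
    """
    valid = [p for p in points if p.valid]
    missing = len(points) - len(valid)
    if len(valid) < 2:
        return SensitivityEstimate(
            **_UNDEFINED, n_points=len(valid), missing_points=missing, block=block
        )
    x = np.array([p.log_reinforcer_ratio for p in valid])
    y = np.array([p.log_response_ratio for p in valid])
    if np.ptp(x) == 0:
        raise GMLDegenerateError("all reinforcer ratios identical; slope undefined")
    res = stats.linregress(x, y)
    return SensitivityEstimate(
        sensitivity=float(res.slope),
        log_bias=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(valid),
        missing_points=missing,
        block=block,
    )


def participant_block_estimates(
    logs: Sequence[ACTEventLog], block_size: int = 4
) -> list[SensitivityEstimate]:
    """Per-block GML fits for one participant's four component logs.

    Block k's fit pools the four components' block-k points (one point per
    component), giving the blockwise learning curve for that participant.
    """
    points = block_ratio_points(logs, block_size)
    n_blocks = max(p.block for p in points)
    out = []
    for b in range(1, n_blocks + 1):
        blk = [p for p in points if p.block == b]
        try:
            out.append(fit_gml(blk, block=b))
        except GMLDegenerateError:
            # coincident cumulative ratios (common in the first blocks, where
            # few events are in) leave the slope unidentified for this block
            out.append(
                SensitivityEstimate(
                    **_UNDEFINED,
                    n_points=0,
                    missing_points=len(blk),
                    block=b,
                )
            )
    return out


@dataclass(frozen=True)
class CohortBlockSensitivity:
    block: int
    mean: float
    sem: float
    n: int  # participants with a defined estimate
    missing: int  # participants without one


def blockwise_sensitivity(
    cohort_logs: Mapping[str, Sequence[ACTEventLog]],
    block: int,
    block_size: int = 4,
) -> CohortBlockSensitivity:
    """Cohort mean/SEM of block-``block`` sensitivity across participants."""
    values = []
    missing = 0
    for logs in cohort_logs.values():
        est = participant_block_estimates(logs, block_size)[block - 1]
        if est.defined:
            values.append(est.sensitivity)
        else:
            missing += 1
    arr = np.array(values)
    return CohortBlockSensitivity(
        block=block,
        mean=float(arr.mean()) if len(arr) else math.nan,
        sem=float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else math.nan,
        n=len(arr),
        missing=missing,
    )


def sensitivity_curve(
    cohort_logs: Mapping[str, Sequence[ACTEventLog]], block_size: int = 4
) -> list[CohortBlockSensitivity]:
    """The full cohort learning curve (one entry per block)."""
    any_logs = next(iter(cohort_logs.values()))
    stream = any_logs[0].spec.varied_stream
    n_blocks = sum(any_logs[0].spec.counts(stream)) // block_size
    return [
        blockwise_sensitivity(cohort_logs, b, block_size) for b in range(1, n_blocks + 1)
    ]


def stable_sensitivity(
    block_estimates: Sequence[SensitivityEstimate], condition_id: int
) -> SensitivityEstimate:
    """Stable sensitivity: mean over the condition's designated final blocks.

    The last two blocks are averaged in condition 1 and the last three in
    conditions 2-4; undefined blocks are skipped and the count of
    contributing blocks reported via ``n_points``.  All designated blocks
    undefined yields a flagged undefined estimate.
    """
    if condition_id not in STABLE_BLOCKS:
        raise ValueError(f"condition_id must be 1-4, got {condition_id}")
    k = STABLE_BLOCKS[condition_id]
    tail = block_estimates[-k:]
    defined = [e for e in tail if e.defined]
    if not defined:
        return SensitivityEstimate(
            **_UNDEFINED, n_points=0, missing_points=len(tail), block="stable"
        )
    return SensitivityEstimate(
        sensitivity=float(np.mean([e.sensitivity for e in defined])),
        log_bias=float(np.mean([e.log_bias for e in defined])),
        r_squared=math.nan,
        n_points=len(defined),
        missing_points=len(tail) - len(defined),
        block="stable",
    )
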