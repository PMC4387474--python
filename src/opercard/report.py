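"""Cross-task analysis and report assembly.

Classifies participants by their IGT stability outcome (good decision
makers with stable good-deck preferences, persistent poor performers who
never stabilized, and stable bad-deck performers, who are excluded from the
cross-task comparison), compares group ACT sensitivities with two-tailed
Mann-Whitney U tests, and assembles deterministic table/figure bundles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .igt_analysis import cohort_summary
from .igt_engine import IGTTrialLog

CONDITION_LABELS = {
    1: "reward_frequency",
    2: "reward_magnitude",
    3: "penalty_frequency",
    4: "penalty_magnitude",
}


@dataclass(frozen=True)
class CrossTaskRecord:
    """One participant's IGT class plus their four stable ACT sensitivities."""

    participant_id: str
    decision_class: str  # good | poor | bad-deck
    sensitivities: dict[int, float]  # condition -> stable sensitivity (NaN if undefined)


def classify_groups(
    records: Sequence[CrossTaskRecord],
) -> tuple[list[CrossTaskRecord], list[CrossTaskRecord], list[CrossTaskRecord]]:
    """Partition records into (good, poor, excluded) by IGT decision class."""
    good = [r for r in records if r.decision_class == "good"]
    poor = [r for r in records if r.decision_class == "poor"]
    excluded = [r for r in records if r.decision_class == "bad-deck"]
    return good, poor, excluded


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float  # the smaller of the two U statistics
    p_two_tailed: float
    r: float  # Z / sqrt(N); negative when group A tends larger
    n_a: int
    n_b: int
    n_excluded: int  # undefined values dropped
    defined: bool = True


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float]
) -> MannWhitneyResult:
    """Two-tailed Mann-Whitney U test with rank-biserial-style effect size.

    Undefined (NaN) values are excluded with counts reported.  U is computed
    by midrank rank-sums; p is exact for small samples without ties and a
    tie-corrected normal approximation otherwise.  The effect size is
    r = Z / sqrt(N), reported negative when group A tends to exceed group B
    (so with A = good decision makers, higher sensitivity in the good group
    gives negative r).
    """
    a = np.asarray([v for v in group_a if not math.isnan(v)], dtype=float)
    b = np.asarray([v for v in group_b if not math.isnan(v)], dtype=float)
    n_excluded = (len(group_a) - len(a)) + (len(group_b) - len(b))
    if len(a) == 0 or len(b) == 0:
        return MannWhitneyResult(
            math.nan, math.nan, math.nan, len(a), len(b), n_excluded, defined=False
        )
    n1, n2 = len(a), len(b)
    has_ties = len(np.unique(np.concatenate([a, b]))) < n1 + n2
    method = "exact" if (not has_ties and max(n1, n2) <= 20) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_a = float(res.statistic)  # pairs where a > b (ties count half)
    u = min(u_a, n1 * n2 - u_a)
    # tie-corrected normal deviate for the effect size (no continuity shift)
    combined = np.concatenate([a, b])
    _, tie_counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    sigma = math.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    z = (u_a - n1 * n2 / 2.0) / sigma if sigma > 0 else 0.0
    r = -z / math.sqrt(n)
    return MannWhitneyResult(u, float(res.pvalue), r, n1, n2, n_excluded)


def cross_task_comparison(
    records: Sequence[CrossTaskRecord],
) -> pd.DataFrame:
    """Good-vs-poor Mann-Whitney comparison for each ACT condition."""
    good, poor, _ = classify_groups(records)
    rows = []
    for cond, label in CONDITION_LABELS.items():
        res = mann_whitney(
            [r.sensitivities.get(cond, math.nan) for r in good],
            [r.sensitivities.get(cond, math.nan) for r in poor],
        )
        rows.append(
            {
                "condition": cond,
                "dimension": label,
                "U": res.U,
                "p_two_tailed": res.p_two_tailed,
                "r": res.r,
                "n_good": res.n_a,
                "n_poor": res.n_b,
                "n_excluded": res.n_excluded,
            }
        )
    return pd.DataFrame(rows).set_index("condition")


def build_report(
    igt_logs: Sequence[IGTTrialLog],
    sensitivity_curves: Mapping[int, Sequence] | None = None,
    records: Sequence[CrossTaskRecord] | None = None,
    out_dir: str | Path | None = None,
    make_figures: bool = False,
) -> dict:
    """Assemble the deterministic report bundle.

    Always contains the IGT cohort tables; adds the condition x block
    sensitivity table when curves are supplied and the cross-task comparison
    when records are supplied.  With ``out_dir`` the tables are written as
    CSV, the summary as JSON, and (optionally) simple matplotlib renderings
    of the learning-curve figures.  Reruns on identical inputs are
    byte-identical.
    """
    summary = cohort_summary(igt_logs)
    bundle: dict = {
        "igt_net_scores": summary["net_scores"],
        "igt_stable_by_block": pd.DataFrame(
            {
                "block": np.arange(1, len(summary["stable_by_block"]) + 1),
                "prop_stable": summary["stable_by_block"],
            }
        ),
        "igt_preference_histogram": summary["preference_histogram"],
    }
    if sensitivity_curves is not None:
        rows = []
        for cond, curve in sensitivity_curves.items():
            for est in curve:
                rows.append(
                    {
                        "condition": cond,
                        "block": est.block,
                        "mean_sensitivity": est.mean,
                        "sem": est.sem,
                        "n": est.n,
                        "missing": est.missing,
                    }
                )
        bundle["act_sensitivity_by_block"] = pd.DataFrame(rows)
    if records is not None:
        bundle["cross_task"] = cross_task_comparison(records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, obj in bundle.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(out_dir / f"{name}.csv")
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(
                {
                    "n_participants": len(igt_logs),
                    "preference_histogram": bundle["igt_preference_histogram"],
                    "mean_net_full_task": float(
                        bundle["igt_net_scores"]["mean"].iloc[-1]
                    ),
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        if make_figures:
            _write_figures(bundle, out_dir)
    return bundle


def _write_figures(bundle: dict, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(bundle["igt_stable_by_block"]["block"], bundle["igt_stable_by_block"]["prop_stable"], "o-")
    ax.set_xlabel("20-trial block")
    ax.set_ylabel("Proportion stable")
    fig.tight_layout()
    fig.savefig(out_dir / "igt_stability.png", dpi=100)
    plt.close(fig)
    if "act_sensitivity_by_block" in bundle:
        df = bundle["act_sensitivity_by_block"]
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for cond, grp in df.groupby("condition"):
            ax.errorbar(grp["block"], grp["mean_sensitivity"], yerr=grp["sem"],
                        label=CONDITION_LABELS[int(cond)], marker="o")
        ax.set_xlabel("Block of varied-stream events")
        ax.set_ylabel("Mean sensitivity")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out_dir / "act_sensitivity.png", dpi=100)
        plt.close(fig)
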