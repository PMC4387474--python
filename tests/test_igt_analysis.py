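"""IGT analytics: net scores, blocks, switches, preference and stability rules."""

import itertools

import numpy as np
import pytest

import opercard as oc
from opercard.igt_analysis import (
    BlockPreferenceProfile,
    NO_PREFERENCE,
    block_preference,
    detect_stability,
)
from opercard.igt_engine import DECKS


def profile(pa, pb, pc, pd, block=1, size=20):
    return BlockPreferenceProfile(
        block_index=block, block_size=size,
        proportions={"A": pa, "B": pb, "C": pc, "D": pd},
    )


def label(*decks):
    return oc.PreferenceLabel(frozenset(decks))


class TestNetScore:
    def test_all_good_is_one(self):
        assert oc.net_score(["C"] * 100) == 1.0

    def test_balanced_is_zero(self):
        assert oc.net_score(["A", "C"] * 50) == 0.0

    def test_62_38_split_gives_024(self):
        seq = ["C"] * 62 + ["A"] * 38
        assert oc.net_score(seq) == pytest.approx(0.24)

    def test_epoch_additivity(self, learner_logs):
        """Net over the full task is the mean of the two equal epochs, exactly."""
        for log in learner_logs:
            full = oc.net_score(log, (1, 200))
            first = oc.net_score(log, (1, 100))
            second = oc.net_score(log, (101, 200))
            assert full == pytest.approx((first + second) / 2, abs=1e-12)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            oc.net_score(["C"] * 10, (5, 4))

    def test_window_exceeding_log_rejected(self):
        with pytest.raises(ValueError):
            oc.stable_window_net_score(["C"] * 100, (61, 120))

    def test_stable_window_counts_directly(self):
        # 27 good / 13 bad choices in a 40-trial window -> (27-13)/40 = 0.35
        seq = ["A"] * 160 + ["C"] * 27 + ["B"] * 13
        assert oc.stable_window_net_score(seq, (161, 200)) == pytest.approx(0.35)


class TestBlocksAndSwitches:
    def test_single_deck_block(self):
        (p,) = oc.block_profiles(["D"] * 20)
        assert p.proportions == {"A": 0.0, "B": 0.0, "C": 0.0, "D": 1.0}

    def test_half_half_block(self):
        (p,) = oc.block_profiles(["A"] * 10 + ["B"] * 10)
        assert p.proportions["A"] == 0.5 and p.proportions["B"] == 0.5

    def test_200_trials_make_10_blocks(self, ideal_log):
        assert len(oc.block_profiles(ideal_log)) == 10

    def test_partial_block_rejected(self):
        with pytest.raises(ValueError):
            oc.block_profiles(["C"] * 30, block_size=20)

    def test_bad_block_size(self):
        with pytest.raises(ValueError):
            oc.block_profiles(["C"] * 20, block_size=0)

    def test_constant_log_never_switches(self):
        assert np.all(oc.switch_proportion(["C"] * 200) == 0.0)

    def test_alternation_always_switches(self):
        assert np.all(oc.switch_proportion(["A", "B"] * 100) == 1.0)

    def test_switch_counts_match_brute_force(self):
        rng = np.random.default_rng(3)
        seq = [DECKS[i] for i in rng.integers(0, 4, size=200)]
        props = oc.switch_proportion(seq)
        # brute force: comparison at trial t belongs to block ceil(t/20), t>=2
        for b in range(10):
            trials = [t for t in range(2, 201) if (t - 1) // 20 == b]
            expected = np.mean([seq[t - 1] != seq[t - 2] for t in trials])
            assert props[b] == pytest.approx(expected)

    def test_block_one_denominator_is_19(self):
        # exactly one switch among the 19 eligible comparisons of block 1
        seq = ["A"] * 10 + ["B"] * 10
        assert oc.switch_proportion(seq, block_size=20)[0] == pytest.approx(1 / 19)


class TestImpairment:
    @pytest.mark.parametrize(
        "net,criterion,expected",
        [
            (0.09, "bechara_0.10", True),
            (0.10, "bechara_0.10", False),
            (-0.01, "steingroever_0.00", True),
            (0.00, "steingroever_0.00", False),
        ],
    )
    def test_thresholds_strict(self, net, criterion, expected):
        assert oc.classify_impairment(net, criterion) is expected

    def test_unknown_criterion(self):
        with pytest.raises(ValueError):
            oc.classify_impairment(0.5, "other")


class TestBlockPreference:
    def test_single_deck_rule(self):
        assert block_preference(profile(0.10, 0.10, 0.60, 0.20)) == label("C")

    def test_pair_rule(self):
        assert block_preference(profile(0.05, 0.05, 0.45, 0.45)) == label("C", "D")

    def test_no_preference(self):
        assert block_preference(profile(0.25, 0.05, 0.40, 0.30)) == NO_PREFERENCE

    def test_single_rule_takes_precedence(self):
        # C qualifies singly (0.60 >= 0.5, margins >= 0.25) even though C+D >= 0.75
        p = profile(0.05, 0.00, 0.60, 0.35)
        assert block_preference(p) == label("C")

    def test_equal_split_falls_to_pair_rule(self):
        assert block_preference(profile(0.5, 0.5, 0.0, 0.0)) == label("A", "B")

    def test_matches_exhaustive_rule_scan(self):
        """The implementation agrees with a direct transcription of both rules
        over a grid of valid profiles."""
        grid = np.arange(0, 21) / 20
        rng = np.random.default_rng(0)
        checked = 0
        for pa, pb, pc in itertools.product(grid, grid, grid):
            pd_ = 1.0 - pa - pb - pc
            if pd_ < -1e-9 or pd_ > 1:
                continue
            if rng.random() > 0.15:  # subsample the simplex for speed
                continue
            p = {"A": pa, "B": pb, "C": pc, "D": max(pd_, 0.0)}
            singles = [
                d for d in DECKS
                if p[d] >= 0.50 and all(p[d] - p[e] >= 0.25 for e in DECKS if e != d)
            ]
            if singles:
                expected = label(singles[0])
            else:
                pairs = [
                    (d, e)
                    for d, e in itertools.combinations(DECKS, 2)
                    if p[d] + p[e] >= 0.75 and abs(p[d] - p[e]) < 0.25
                ]
                expected = label(*pairs[0]) if pairs else NO_PREFERENCE
            prof = BlockPreferenceProfile(1, 20, p)
            assert block_preference(prof) == expected
            checked += 1
        assert checked > 100


class TestDetectStability:
    def test_immediate_stability(self):
        res = detect_stability([label("C")] * 10)
        assert res.first_stable_block == 3
        assert res.stable_preference == label("C")
        assert res.decision_class == "good"

    def test_never_stable(self):
        res = detect_stability([NO_PREFERENCE] * 10)
        assert not res.is_stable
        assert res.decision_class == "poor"

    def test_bad_deck_pair(self):
        res = detect_stability([label("B", "D")] * 5)
        assert res.first_stable_block == 3
        assert res.decision_class == "bad-deck"

    def test_matches_exhaustive_window_scan(self):
        """Oracle: earliest length-3 window of identical non-none labels, over
        1,000 random label sequences."""
        atoms = [NO_PREFERENCE] + [label(d) for d in DECKS] + [
            label(*p) for p in itertools.combinations(DECKS, 2)
        ]
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            n = int(rng.integers(3, 12))
            seq = [atoms[i] for i in rng.integers(0, len(atoms), size=n)]
            expected = None
            for i in range(n - 2):
                w = seq[i : i + 3]
                if w[0].kind != "none" and w[0] == w[1] == w[2]:
                    expected = i + 3
                    break
            res = detect_stability(seq)
            assert res.first_stable_block == expected
            if expected is not None:
                assert res.stable_preference == seq[expected - 1]

    def test_later_changes_counted(self):
        seq = [label("C")] * 3 + [label("D")] * 2
        res = detect_stability(seq)
        assert res.first_stable_block == 3
        assert res.later_changes == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            detect_stability([])


class TestLabelPermutationSymmetry:
    def test_swapping_decks_permutes_labels(self, learner_logs):
        """Permuting deck labels in a log permutes preference labels identically
        and flips the decision class when good/bad roles swap."""
        swap = {"A": "C", "C": "A", "B": "D", "D": "B"}
        for log in learner_logs[:4]:
            seq = log.deck_sequence
            res = oc.stability_result(seq)
            res_swapped = oc.stability_result([swap[d] for d in seq])
            assert res_swapped.first_stable_block == res.first_stable_block
            if res.is_stable:
                assert res_swapped.stable_preference == oc.PreferenceLabel(
                    frozenset(swap[d] for d in res.stable_preference.decks)
                )
                flipped = {"good": "bad-deck", "bad-deck": "good"}
                mixed = res.stable_preference.decks & {"A", "B"} and \
                    res.stable_preference.decks & {"C", "D"}
                if not mixed:
                    assert res_swapped.decision_class == flipped[res.decision_class]


class TestCohortSummary:
    def test_single_perfect_participant(self):
        log = oc.IGTTrialLog("p1")
        pol = oc.igt_agent(oc.IGTAgentParams(archetype="ideal", allowed_decks=("C", "D")))
        sched = oc.load_payoff_schedule("bechara_standard")
        log = oc.run_igt_session(pol, sched, 200, seed=1, participant_id="p1")
        summary = oc.cohort_summary([log])
        assert summary["net_scores"].loc["1-200", "mean"] == 1.0
        assert summary["net_scores"].loc["1-200", "sd"] == 0.0
        assert summary["net_scores"].loc["1-200", "prop_impaired_bechara"] == 0.0

    def test_matches_brute_force_recount(self, learner_logs):
        summary = oc.cohort_summary(learner_logs)
        nets = [oc.net_score(l, (1, 100)) for l in learner_logs]
        row = summary["net_scores"].iloc[0]
        assert row["mean"] == pytest.approx(np.mean(nets))
        assert row["sd"] == pytest.approx(np.std(nets, ddof=1))
        assert row["range"] == pytest.approx(np.ptp(nets))
        assert row["prop_impaired_bechara"] == pytest.approx(
            np.mean([n < 0.10 for n in nets])
        )
        # preference histogram covers everyone
        assert sum(summary["preference_histogram"].values()) == len(learner_logs)
        # stable_by_block is a nondecreasing cumulative proportion
        sb = summary["stable_by_block"]
        assert np.all(np.diff(sb) >= 0)

    def test_unequal_lengths_rejected(self, learner_logs, schedule):
        short = oc.run_igt_session(
            lambda h, r: "C", schedule, 100, seed=0, participant_id="short"
        )
        with pytest.raises(ValueError, match="short"):
            oc.cohort_summary([*learner_logs, short])
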