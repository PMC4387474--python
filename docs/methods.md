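# Methods

This note documents the models behind `opercard`, the parameters that
matter, the design decisions taken where the design was genuinely open, and
what the synthetic-agent validation does and does not establish.

## IGT engine

**Payoff schedule.** Four decks, 40 cards each, repeating cyclically (draw
41 from a deck equals draw 1). The packaged `bechara_standard` fixture
follows the standard task structure: decks A/B pay $100 per card and lose
$1250 per 10 cards (net −$250); decks C/D pay $50 and lose $250 per 10
(net +$250); A and C impose five losses per 10 cards, B and D a single
large loss. The exact card order within each 10-card sub-block is
configuration, not behaviourally load-bearing for any analysis here, and
alternative schedules are drop-in CSV files (`deck,position,win,loss`).

**Sessions.** Turn-based; inter-trial timing, card colours, and sounds are
not modelled because nothing downstream consumes them. The balance starts
at one $2000 loan; whenever the balance goes negative another $2000 loan is
granted. Two loan semantics exist: `add` (default; $2000 is added to the
balance, preserving the shortfall) and `reset` (balance snaps to zero). The
accounting identity `final balance = loans * 2000 + wins − losses` holds
exactly under `add` and is enforced by test. Sessions are a pure function
of (policy, seed).

## IGT analysis

**Net score** is proportional: `(nC + nD − nA − nB) / n`, range [−1, 1],
so 100-trial and 200-trial epochs are directly comparable. Net over the
full task is exactly the mean of the two 100-trial epoch nets.

**Strong preference rules** (per 20-trial block): a *single deck* qualifies
when its proportion is ≥ 0.50 **and** exceeds every other deck's by
≥ 0.25; if no single deck qualifies, a *pair* qualifies when the two decks
jointly reach ≥ 0.75 and differ by < 0.25. The single rule is evaluated
first; inequality directions (≥ for the single margins, strict < for the
pair difference) follow the criterion's wording. A 0.50/0.50 split fails
the single rule's margin and falls to the pair rule.

**Stability** requires the same non-none label for 3 consecutive blocks.
`first_stable_block` is the final block of the earliest qualifying run
("stable by trial 100" ⇔ `first_stable_block ≤ 5` at block size 20). The
criterion locks at first satisfaction; later label changes are counted
(`later_changes`) but do not reclassify — a deliberate mirror of how such
criteria are used in practice, and a known limitation for agents that
drift late. Decision classes: `good` (stable on C, D, or C+D), `bad-deck`
(stable preference involving A or B), `poor` (never stable).

**Switch proportions**: trial *t* is an eligible comparison when t ≥ 2 and
the comparison crossing a block boundary belongs to the later block, so
block 1 has 19 eligible comparisons and subsequent blocks 20. Values stay
in [0, 1] by construction.

Partial final blocks are rejected, never silently dropped.

## ACT engine

**Conditions.** Four conditions × four components. One dimension varies
across components (reward frequency, reward magnitude, penalty frequency,
penalty magnitude — conditions 1–4); the other three are constant and
equal across decks. Scheduled event counts derive from the condition
table: a varied-frequency dimension splits 20 events by the printed
probabilities (0.25/0.75 → 5/15, 0.35/0.65 → 7/13); a varied-magnitude
dimension schedules 10 events per deck; constant dimensions schedule 5 per
deck ($30 penalties in the reward conditions, $170 rewards in the penalty
conditions). Every component's scheduled net reward is $100/$600,
$200/$500, $500/$200 or $600/$100 per deck — $700 total in all 16
components, so a fully delivered session pays identically in every
condition.

**Variable magnitudes** ("v" cells) draw from the symmetric set
{mean−20, mean−10, mean, mean+10, mean+20}. Within an arranged component
the per-deck draws form a balanced multiset (each offset appears equally
often), so per-deck totals equal `count × mean` exactly and the scheduled
net rewards are preserved; `sample_magnitude` also exposes plain uniform
draws from the set.

**Scheduling.** Reward and penalty streams run independently. Within a
stream, a single VI timer arranges events at exponential intervals; each
arranged event is assigned to deck 1 or 2 by drawing without replacement
from the scheduled per-deck counts (so exactly those counts are arranged),
and the timer halts until a press on the assigned deck collects the event —
dependent scheduling, which guarantees obtained ratios equal arranged
ratios on completed components. The default VI mean is
`0.6 × 480 s / total stream events`, leaving timeout headroom for an
attentive responder; with exponential intervals the total arrangement time
of a 10-event stream still exceeds the 8-minute cap occasionally (~10% of
components for a balanced 1–2 press/s responder), so exact-delivery
guarantees are stated conditional on `all_delivered`. A component ends when
both streams are exhausted or at 480 s. An exclusive single-deck responder
stalls the other deck's armed events and always times out — this is the
missing-data mechanism that makes late-block sensitivity estimates
undefined for extreme responders.

No changeover delay is imposed and display/deception elements (card flip
animations, the random offset added to displayed winnings) are not
modelled: no analysis consumes them.

## GML estimation

Blocks are delimited by every 4th event of the condition's *varied* stream
(rewards for conditions 1–2, penalties for 3–4), the dimension that carries
the information. A block's **response ratio** uses presses within the
block; its **reinforcer ratio** uses everything obtained on the varied
stream from component start to block end. Ratios are ratios of obtained
**amounts**: with constant magnitudes this is identical to the event-count
ratio, and in the magnitude conditions (where counts are 10/10 by design
and a count ratio would be degenerate) it carries the magnitude
manipulation. For penalty conditions the ratio is inverted (deck2/deck1) so
that responding away from the more/larger-punished deck yields a positive
sensitivity — the convention under which punishment sensitivities are
reported and compared with reward sensitivities.

Fits are base-10 ordinary least squares (slope = sensitivity, intercept =
log bias). Undefined ratios (zero press counts or amounts on either deck)
are flagged invalid, never dropped silently; an optional continuity
correction (+0.5 presses, +1 amount) exists but is off by default, matching
the practice of reporting missing estimates rather than manufacturing
them. Fewer than two valid points yields a flagged undefined estimate;
coincident x-values (routine in the first block or two) likewise.

**Stable sensitivity** averages each participant's final block estimates —
the last 2 blocks in condition 1 and the last 3 in conditions 2–4, where
group learning curves have levelled out — skipping undefined blocks and
reporting how many contributed.

## Synthetic agents

No generative model of participants is prescribed by the tasks themselves;
the agents are the simplest mechanisms producing the phenomenology the
analyses assume.

**IGT learner** (delta rule + softmax): the chosen deck's expectancy moves
toward the trial's net outcome, `V_d ← V_d + α (win − λ·loss − V_d) / 100`,
and choice is softmax(β·V) mixed with a uniform exploration floor ε.
Defaults α = 0.15, β = 3, λ = 1, ε = 0.05. β = 3 was calibrated so that
strong learners (α = 0.2) usually satisfy the stability criterion
(~80% within 200 trials, most by trial 160) while still flickering
occasionally between the C, D, and C+D labels, as humans do; higher β
paradoxically destabilizes labels by locking onto single decks early.
Archetypes are stored parameter sets — `random` (β = 0), `late-learner`
(α = 0.04), `non-learner` (α = 0.005, ε = 0.4) — plus two deterministic
special cases: `ideal` (sweeps each deck once, then alternates C/D;
restrictable to a deck subset) and `perseverative` (sticks with its first
choice).

**ACT matching responder**: presses arrive at `press_rate` (default 1.5/s,
a comfortable human keying rate); each press goes to deck 1 with
probability p where `logit10(p) = a·(log10 R̂1/R̂2 − log10 P̂1/P̂2) + log c`,
with R̂/P̂ the obtained reward/penalty amounts over the last
`estimate_window` events per stream (default 40, i.e. cumulative within a
component — each stream schedules at most 20 events). Streams on which
either deck has paid nothing contribute no term, so allocation starts at
50/50 and sharpens as contingency knowledge accrues — which is exactly why
estimated blockwise sensitivity rises across blocks, reproducing the
characteristic learning curves.

**Cohorts** are drawn from explicit parameter distributions with per-agent
seeds; the manifest records every drawn value as ground truth for recovery
tests.

## Cross-task comparison

Good decision makers (stable good-deck preference within 200 trials) are
compared with persistent poor performers (never stable) on each ACT
sensitivity dimension; stable bad-deck performers are excluded.
`mann_whitney` reports the smaller-U convention, an exact two-tailed p for
small untied samples (tie-corrected normal approximation otherwise), and
effect size `r = Z/√N`, signed negative when the first group tends larger.
Undefined sensitivities are excluded pairwise with per-test n reported.

## Validation with synthetic agents — what it shows and what it does not

The acceptance suite verifies: the schedule arithmetic exactly; the
stability criterion against an exhaustive window scan; the OLS estimator
against closed-form regression; the Mann–Whitney U against exhaustive pair
enumeration; that matching agents with a ∈ {0.3, 0.8, 1.3} are recovered
with **median** stable sensitivity within ±0.15 per condition over 50
seeded sessions each; that cohort sensitivity curves rise across blocks in
≥95% of seeded cohorts; and that exclusive responders produce timeouts
with flagged-undefined late blocks.

Per-session estimates are substantially noisier than the median: the
stable-sensitivity sd across seeds is ≈0.10 at a = 0.3 and ≈0.25–0.30 at
a = 1.3, dominated by the volatility of cumulative obtained-amount ratios
in 4-event blocks (raising the press rate barely changes it). This is a
property of 4-point GML fits on this schedule geometry, not of the agents,
and is consistent with the very wide individual sensitivity ranges such
tasks produce in humans. Single-participant stable sensitivities should
therefore be read as noisy measurements.

The agents reproduce the *structure* real data are assumed to have
(gradual learning, heterogeneous stabilization, non-learners, matching
allocation); passing tests validate the analysis machinery on that
structure. They do not show that human cohorts match any particular group
mean, and no human-derived values are targets of the simulation.

## Problem sizes

Defaults used by the test suite and acceptance script: 200-trial IGT
sessions, 20-trial blocks; full 4-component ACT sessions (40 scheduled
events per component); recovery at 50 seeds per sensitivity level per
condition and learning-curve checks on 20 cohorts of 8 agents.
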