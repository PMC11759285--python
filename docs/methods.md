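# Methods

## The task

A serial fixed-interval (sFI) session is a sequence of blocks. Each
block fixes an FI duration drawn without replacement from an ordered
list (default 12, 24, 36, 48, 60 s) and lasts a number of trials drawn
without replacement from a second list (13, 15, 17, 19, 21). When a
list is exhausted it is reshuffled in full, so every aligned window of
five consecutive draws is a permutation; the two lists refresh
independently, and both start fresh each session. Within a trial the
lever is always live: the first press at or after the FI delivers the
reward and starts the next trial, and nothing else cues trial or block
boundaries. A session ends at 100 rewards or at the 90-min mark
(whichever first); the trial in progress at timeout is completed and
then the session stops — the simplest well-defined contract, since
nothing in the task description forces aborting a trial mid-press.

Variants: the *novel* protocol substitutes the printed list
13, 15, 31, 45, 57 s (each within 60–140 % of the trained value it
replaces — the pipeline checks this with exact arithmetic); the
*de novo* protocol rescales each trained duration by an independent
factor `0.8 + 0.4·X`, `X ~ U(0,1)`, once per session, so the animal
faces a distinct duration set every day within 80–120 % of the
originals.

## The behaving agent

The simulator's agent is a deliberately reduced surrogate for
accumulator models of timing. It is **not** a full drift-diffusion
simulation; it keeps exactly the three properties the downstream
analyses are sensitive to:

1. **Threshold fraction** `k` (default 0.5): the mean onset of timed,
   high-rate pressing is `k × FÎ`, where `FÎ` is the agent's current
   duration estimate. This mirrors accumulator accounts in which
   responding starts when the accumulated quantity passes ~50 % of its
   maximum.
2. **Scalar (Weber) noise** `w` (default 0.2): the start time is drawn
   from Normal(k·FÎ, (w·k·FÎ)²) truncated below at the consumption
   delay, so its SD is proportional to its mean (constant CV), the
   signature property of interval timing.
3. **Delta-rule updating** `α`: after every reward,
   `FÎ ← FÎ + α·(experienced − FÎ)`. `α = 1` is one-shot updating;
   `α = 0.05` is slow, iterative learning. The experienced interval is
   the trial's **reward time** — the only duration feedback the task
   delivers, since only the pellet marks the trial boundary. A
   consequence worth knowing: after a large FI decrease the agent's
   first presses come *after* the new deadline, so it experiences its
   own (late) reward time rather than the new FI and converges
   geometrically over a few trials even at `α = 1`. Decreases are
   therefore learned more slowly than increases, for purely structural
   reasons.

Pressing is the superposition of two homogeneous Poisson processes:
baseline "lever sampling" (default 0.1/s) from the end of the
consumption pause onward, and timed pressing (default 2.0/s) from the
sampled start time onward. The defaults are the packaged study
conditions: one sampling press per ~10 s keeps the first-press
estimator realistically shallow, while 2 presses/s of timed responding
keeps the burst delay (the wait for two consecutive fast IPIs) short
relative to even the 12-s trials, which is what lets the rate-based
estimators recover `k` without truncation bias. The mouse-like preset
(8-s consumption pause, 3/s timed rate) reproduces the near-absence of
usable 12-s-trial data seen when the pellet takes most of a short
interval to eat. The hard no-press consumption window is a
simplification; real consumption pauses are soft and variable.

Randomness: one seeded `numpy` generator per session, the seed recorded
on the `Session`; cohorts spawn independent child seeds from a master
seed. Sessions are therefore byte-reproducible.

What the generator does *not* emulate: satiety drift across a session,
post-reward pressing tails that cross trial boundaries (trials end at
the rewarded press by construction), pre-training history, and
between-subject parameter heterogeneity. Tests passing on this
synthetic data therefore certify the *pipeline* — estimator
definitions, exclusion rules, statistics — not any claim about real
rodent behavior beyond the structural ones encoded in the agent.

## Start-time estimators

All four are computed independently per trial, and **no estimate below
5 s is ever reported** (pressing routinely continues past reward into
the next trial's food retrieval, so early presses are uninformative).
Analysis is restricted to each session's first five blocks. Missing
values stay missing; nothing is imputed.

- **First press**: earliest press ≥ 5 s.
- **First burst**: first press of the earliest run of three presses
  whose two IPIs both fall at or below the experiment-wide 40 %
  quantile of pooled within-trial IPIs. The quantile is nearest-rank
  (type 1) with inclusive comparison — reproducible without
  interpolation ambiguity — and is fixed once per experiment before
  any per-trial analysis (a per-subject pooling option exists, off by
  default). The burst is stamped at its first press. IPIs never span a
  reward, because trials end at the rewarded press.
- **Rate crossing**: presses are counted in 1-s bins, smoothed by a
  centered 3-bin moving average truncated at the edges (no phase lag),
  and the estimate is the left edge of the first bin whose smoothed
  rate strictly exceeds 2× the session-average press rate (total
  presses / total trial time). The bin left edge is a fixed convention
  chosen for bit-exact testability.
- **Change point (CPRL)**: see below.

## The change-point detector

Within-trial IPIs (presses ≥ 5 s only) are modeled as exponential
waiting times. For a window of n IPIs, a change at split c puts IPIs
1..c under one rate and c+1..n under another; rates are integrated out
against a Gamma(a, b) prior, giving the closed-form marginal
`Γ(a+n)/Γ(a) · bᵃ/(b+Σx)^(a+n)`. The evidence for a change is the
Bayes factor of the *best* split (ties to the earliest), and detection
is sequential: IPIs are added one at a time and the first growing
window whose best-split BF reaches 10 fires. The reported change time
is the press ending the pre-change segment — the press that begins the
new-rate regime. A generalized (max-over-splits) Bayes factor rather
than a model average keeps the "first point with a likelihood factor of
10" decision rule deterministic.

**Prior calibration.** The scale `b` is anchored to the median pooled
IPI of the experiment (fixed before per-trial analysis), which makes
the detector scale-free: multiplying all IPIs by c and the prior scale
by c leaves every BF unchanged. The shape is `a = 0.05`. This is
deliberately diffuse: the sequential scan maximizes over prefixes *and*
splits, which inflates false alarms badly under an informative prior
(an a = 1 prior at the same scale fires on ~27 % of exchangeable
30-IPI sequences). A diffuse rate prior penalizes the extra parameter
of the change model (the Bartlett effect) and restores error control:
at the packaged defaults, exchangeable 30-IPI sequences fire in ~3 % of
runs, while an 8-fold rate step with ten IPIs per segment is detected
in ~98 % with ~0 s median timing error. These operating characteristics
are recomputed by `scripts/acceptance.py` and asserted in the test
suite; the prior is a repository setting, not an empirical claim.

Known behavior: raising the BF threshold never turns a missing result
into a detection and never fires on less data, but the reported change
*press* can occasionally refine to a slightly earlier one, because with
more data the best split can move backward toward the true change
(~0.7 % of random step sequences). The detector reports only the first
change point; multiple change points per trial are out of scope.

## Transition analysis

Each block boundary yields, per estimator, a record holding the
previous block's mean start time, the change direction, a magnitude
class, and the values of the first T = 10 trials under the new FI
(T is configurable; 10 covers the span over which adaptation resolves
at every learning rate we simulate). Records whose previous-block mean
is undefined are dropped. For the burst, rate-crossing and change-point
estimators, boundaries touching the *shortest* duration of the
session's list are excluded (sparse pressing on the shortest FI makes
those estimates unreliable); the rule keys on rank, not on the literal
value 12, so it carries over to novel and rescaled lists. First press
keeps all boundaries.

Magnitude classes key on the rank gap in the ordered duration list:
adjacent = *small*, at least two intervening durations = *large*, and
a gap of exactly two forms an explicit *intermediate* class rather than
being silently folded into either group.

Post-transition values are normalized to the previous-block mean
(100 % = no change) and aggregated across records by trial index with
pairwise deletion. Adaptation latency is the smallest post-transition
trial whose record-level normalized values differ from 100 % by a
two-sided one-sample t test, Holm-corrected across the T trials — a
documented, exportable replacement for repeated-measures ANOVA with
post-hoc tests, which is out of scope (the tidy record table is
exported for external stats tools). Cohort-level claims are made from
trial 2 onward (`TransitionResults.earliest_adaptation`): trial 1
carries no information about the new FI, and its normalized values
show small structural biases that have nothing to do with learning —
the previous block's own first trial inflates that block's mean, and a
boundary changes the trial duration and hence what a truncated
estimator can report. With gradual agents a related artifact appears
at *every* trial: the estimate trends within each block, so the
previous-block mean systematically differs from block-end behavior.
The per-trial tables expose all of this rather than hiding it.

The correlation view pools (FI, start time) pairs at a fixed
post-transition trial index across blocks 2–5 (block 1 has no preceding
transition) and reports Pearson r, R², the two-sided p from the t
transform, and n; fewer than three pairs or constant FI gives a
missing result.

## Numerical conventions

- Times serialize to CSV at 1 ms fixed precision, the resolution floor
  for all comparisons; two presses within the same millisecond merge
  into one event on write. Block and trial indices are 1-based.
- Quantiles are nearest-rank; rate crossings use strict `>` and return
  bin left edges; burst IPIs use inclusive `≤`; change-point split ties
  break to the earliest split. All chosen once, for exact testability.
- Degenerate inputs: empty sessions, empty IPI pools, non-positive
  IPIs, unknown FIs and malformed event logs raise errors naming the
  problem (and the row, for logs); trials that merely lack data yield
  missing values, never errors.

## Study sizes in the validation suite

The packaged validation runs (`sfi_timing.validation`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) use cohorts of
20 subjects × 1 session for slope recovery, adaptation latency and
correlation build-up; 10 subjects for the gradual (α = 0.05) contrast,
matching its small-transition analysis; 500 replicates per
change-point calibration scenario; 10,000 sequences for the burst
oracle and de-novo ratio sweeps; and 1,000 sessions for the protocol
audit. These sizes give stable statistics (slopes vary by ~±0.01
across master seeds) while keeping a full validation run around ten
seconds.

## Known limitations

- The agent's start-time distribution is truncated Gaussian by choice
  (parameter recovery is exact and testable), not derived from a
  first-passage process; real start-time distributions are skewed.
- First press is baseline-dominated by design, so its FI scaling is
  shallow; the package asserts only a significantly positive trend for
  it, not the k-slope the other estimators recover.
- Change-point detection needs at least one pre-change IPI after the
  5-s censor; short FIs with sparse baseline pressing therefore yield
  many missing change points (as they do in real data on 12-s trials).
- The cited change-point-by-relative-likelihood family of algorithms
  is realized here as an exponential-rate/conjugate-Gamma sequential
  Bayes-factor test with the prior exposed in configuration; other
  members of that family may weight splits or priors differently.
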