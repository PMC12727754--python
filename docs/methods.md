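# Methods

This note documents the models, parameters, numerical choices and known
limitations of fitkit, in the order the pipeline runs.

## Screening

FIT solutions pass two screens. Step 1 asks a binary judge, once per vote,
whether both question elements "play a role" in the solution; the solution
advances only on a unanimous run of yes votes (default 3, configurable).
Verdicts are parsed from the leading token of the response,
case-insensitively, ignoring punctuation; an unparseable response is retried
once and then raised as a judge error, which leaves the solution *unscreened*
rather than failed — screening failures and judge outages are distinct
states. Step 2 removes every solution of any trial whose participant
reported not understanding the elements or the goal. The third feedback item
(whether the final solution was completed before the timer) does **not**
remove anything by default: the documented screen names only elements and
goal. Because the feedback questionnaire also collected the completion item,
a `drop_incomplete_last` switch is provided that removes the trial's
highest-`order_index` solution; it is off by default. Feedback flags are
trial-level; if rows of one trial disagree, flags are AND-ed across rows so
the result is independent of row order.

AUT answers use a three-step completeness screen: a terminal Japanese period
(。) marks completeness, a bare repetition of the question item marks
incompleteness, everything else goes to the judge with a cut-off probe where
a leading "No" (not cut off) marks the answer complete.

## Elo ground truth

Ratings follow the standard logistic Elo update with K = 16, initial rating
1600 and logistic scale 400 points. Both sides of a match update with the
same K, so each match conserves the rating sum and the total mass is always
n·1600 — this is asserted as a property test. Matches are replayed in strict
timestamp order with a stable tie-break on record index; permuting
timestamps can change final ratings (inherent to sequential Elo), so the
replay is defined to be deterministic given an order rather than
order-invariant. Sanity matches and matches from QC-failed blocks never
update ratings, but the solutions they reference (other than the designed
sanity solutions) still appear in the table at the initial rating with count
0, so downstream joins see the full roster. Ratings from fewer than 9
matches are flagged provisional.

## Scheduling and quality control

A rater plan is 3 dimensions (random order per rater) × 6 questions × 21
match slots, slot 11 being the block's sanity pair. Real pairs are sampled
with weight exp(−|ΔR|/τ), τ = 100 rating points by default: the published
procedure states only "higher priority for closer ratings", and the
exponential kernel is smooth, tunable, and degrades to uniform sampling as
τ → ∞. When several pairs tie on weight, the tie breaks toward the lowest
total match count (uniformly among remaining ties), which spreads matches
evenly early on. A pair is never repeated within a block; if a tiny
question exhausts all pairs before 20 real slots, the exclusion set resets
for a second pass. The six questions per dimension are the ones with the
lowest cumulative match counts (balance maximizes rating reliability; the
source procedure does not specify the subset rule).

QC is block-level: the 20 real judgments of a (rater, dimension, question)
block count iff the block's sanity judgment picked the designed winner. The
discard unit is deliberately the 21-match block — the finest unit containing
the failed check; invalidating the whole 6-question dimension set would be
the conservative alternative and can be emulated by discarding all blocks of
a rater × dimension.

The scheduler reads an epochal ratings snapshot refreshed after each
completed rater. This stands in for periodic batch updates in a live
deployment and keeps scheduling decoupled from wall-clock time; the final
ratings are always recomputed from the full QC-filtered log, so snapshot
cadence affects only pair selection, never the result.

## Automated rating

Prompts concatenate four building blocks (introduction, dimension
definition, FIT question, numbered solutions) with exactly one dimension per
prompt, at most 20 solutions per batch, a 1–100 scale, and an
explain-first-rate-later structure whose third line per solution is a JSON
fragment (`{"novelty":x}`, `{"feasibility":x}`, `{"goal attainment
level":x}`). Parsing extracts the dimension's fragments in order, tolerating
curly quotes; values outside [1, 100] are treated as missing. Each dimension
is rated three times with an independent shuffle per repeat (the repeat
protocol does not state whether shuffles were reused; independent shuffles
decorrelate position effects). A batch leaving solutions unscored is
re-queried up to twice; afterwards the mean uses whichever repeats produced
a score, and solutions unscored in all repeats are reported rather than
imputed. The judge is a plain text-in/text-out callable: tests and
simulations use deterministic mocks, and a live adapter for OpenAI-style
APIs is provided as an optional import.

## Validation statistics

The weighted rank correlation is defined as the weighted Pearson correlation
of the average-tie rank vectors, with Elo match counts as weights, so
solutions with better-estimated ratings count more. The defining anchor,
asserted to 1e−12, is that equal weights recover Spearman's coefficient
exactly. (The literature offers several weighted rank coefficients; this is
the simplest one satisfying the stated role, and it is isolated behind
`weighted_rank_correlation` should a different definition be preferred.)
Per-question coefficients are summarized by mean and (n−1) standard
deviation across questions; questions with fewer than 3 overlapping,
positively weighted solutions are excluded and reported.

Skewness is the biased third standardized moment (no small-sample
correction), matching the default of the numerical environments commonly
used for such reports. The language/protocol comparison is realized as a
paired two-sided t-test across questions with paired Cohen's d
(mean(diff)/sd(diff)) and the default JZS paired Bayes factor (Cauchy scale
√2/2, via pingouin); the underlying publication reports p/d/BF without
naming the test, and the paired t matches both effect-size definitions.

Sample-size planning uses the **exact** sampling distribution of the sample
correlation under bivariate normality (the hypergeometric-function density),
not the Fisher-z approximation — the two disagree on the minimal n for
typical planning queries. The critical value comes from the exact null via
the t transform; power integrates the alternative density by adaptive
quadrature; the minimal n is found by doubling + bisection (power is
monotone in n) and verified by the minimality contract
power(n) ≥ target > power(n−1). For ρ = 0.3, α = 0.05, power 0.9 this gives
n = 112, cross-checked against Monte Carlo to within 3 standard errors at
3×10⁴ replicates in the test suite.

## Individual scoring

Fluency is the mean number of solutions per question; it counts all
submitted solutions by default because fluency is defined over *proposed*
solutions, with a `valid_only` switch for post-screening counts. Dimension
scores are best-of-question: the mean over questions of the maximum solution
score within each question; questions with no scored solutions are excluded
from that mean (a maximum over an empty set is undefined) but still
contribute zero to fluency. CAQ science = culinary arts + inventions +
scientific inquiry; CAQ art = visual arts + music + dance + creative writing
+ humor + theater and film; architectural design is excluded per the
instrument's factor analysis. K-DOCS science = self/everyday + scholarly +
mechanics/scientific; K-DOCS art = performance + artistic.

## Simulator

Latent solution quality on the three dimensions is drawn from a Gaussian
copula with correlation targets (+0.23 GAL–CN, +0.28 GAL–CF, −0.49 CN–CF)
carrying the empirically observed sign structure, with left-skewed
skew-normal marginals (shape −4 for feasibility, −3 for goal attainment) and
a symmetric normal for novelty; columns are standardized to a common scale.
Raters follow a Thurstone choice model — A beats B with probability
Φ((q_A − q_B)/(√2·σ)) — with a lapse rate (pure guessing) and a sanity
failure rate applied as a plain Bernoulli on sanity slots, which makes the
QC edge cases (rates 0 and 1) exact. Automated scores are a noisy affine map
of the latents onto 1–100 (center 55, slope 18 per latent SD, noise SD 12 by
default), clipped to the scale.

Defaults mirror the study conditions: 50 questions × 42 solutions, 144
participants, 122 raters, moderate rater noise (σ = 0.5, ≈ 76% accuracy at a
1-SD latent gap), 2% lapses, 5% sanity failures. Recovery checks use the
`low_noise_config` preset — 6 questions × 20 solutions, σ = 0.1, no lapses or
sanity failures, 6 raters (each block contributes 2 matches per solution, so
6 raters ≈ 12 matches per solution) — chosen as desk-scale problem sizes
that keep the full end-to-end run under a few seconds. An independent
Bradley–Terry MLE (minorization–maximization) on the same match log serves
as a cross-check oracle for the Elo ranking on small instances.

What the simulator does **not** emulate: real solution text (texts are
templated placeholders, so screening judges must be mocked), semantic
duplicates, rater drift or fatigue within a session, position effects in
LLM batches, and per-question heterogeneity in rater reliability. Passing
recovery tests therefore show that the *pipeline machinery* recovers known
latent structure under its own assumptions — they do not validate any
particular LLM judge on real data.

## Known limitations

- Elo replay is order-sensitive by construction; only determinism given a
  log is guaranteed.
- The weighted rank correlation definition is one of several in use; the
  equal-weights reduction is its contract.
- ja/zh question banks are not bundled (only the English table is published
  in full); user-supplied files are assumed to correspond to the English
  bank row by row.
- The live LLM adapter is untested against a real endpoint in this
  repository; all tests run against deterministic mocks.
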