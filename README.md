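# fitkit

Evaluation machinery for the **Fusion Innovation Test (FIT)**, a creative
problem-solving task in which participants must combine two everyday elements
(e.g. *digital camera* + *coloring book*) into solutions that achieve a stated
real-world goal (*foster personal creativity and expression*). Goals are
either Self Improvement Goals (SIG) or Sustainable Development Goals (SDG).
The package is for behavioral researchers who run the FIT (or similar
divergent/convergent creativity tasks) and need the full scoring pipeline:

1. **Screening** (`fitkit.screening`) — a two-step validity screen: a binary
   LLM judge checks that both elements play a role in a solution (unanimity
   over 3 votes), then participant feedback removes trials whose elements or
   goal were not understood. A three-step completeness screen for
   Alternative Uses Test (AUT) answers is included.
2. **Human ground truth via Elo rating** (`fitkit.elo`, `fitkit.scheduler`) —
   solutions meet in two-alternative forced-choice matches on three
   dimensions (Combination Novelty, Combination Feasibility, Goal Attainment
   Level). After each match the ratings update as

   ```
   E_A = 1 / (1 + 10^((R_B - R_A)/400)),      R'_A = R_A + K (S_A - E_A)
   ```

   with K = 16 and all ratings starting at 1600. The scheduler builds rater
   plans of 3 dimensions × 6 questions × 21 matches, prioritizes pairs with
   close ratings, hides a sanity-check pair (designed obvious winner) in slot
   11 of every block, and discards a block's judgments when its sanity check
   is answered wrongly. Ratings from fewer than 9 matches are flagged
   provisional.
3. **Automated LLM rating** (`fitkit.llm_judge`) — batched (≤ 20 solutions),
   shuffled, thrice-repeated 1–100 rating prompts per dimension, with strict
   JSON-fragment parsing (`{"novelty":x}` etc.) behind a pluggable
   text-in/text-out judge (deterministic mocks included; any LLM API can be
   adapted).
4. **Validation and planning statistics** (`fitkit.stats`) — per-question
   *weighted rank correlation* between automated scores and Elo ratings
   (weighted Pearson on average ranks, weights = Elo match counts), skewness,
   Spearman tests, paired t / Cohen's d / JZS Bayes factor comparisons, and
   exact-distribution power analysis for correlation tests.
5. **Individual scoring** (`fitkit.scoring`) — fluency and best-of-question
   dimension scores per participant, plus CAQ and K-DOCS science/art domain
   aggregation.
6. **Simulation** (`fitkit.synth`) — a synthetic-data generator (correlated
   latent qualities via a Gaussian copula, Thurstone-model raters with lapses
   and sanity failures, noisy affine LLM scores) that exercises the entire
   pipeline end-to-end and measures how well the recovered ratings match the
   known latent ground truth.

The bundled English question bank (50 questions, 25 SIG / 25 SDG, five sets
of 5 + 5) ships as versioned CSV; `fitkit.core` loads it and handles set
partitioning, balanced session assignment and solution I/O.

## Worked example

Run the simulated experiment at the desk-scale low-noise preset (6 questions
× 20 solutions, near-noiseless raters, 6 raters ⇒ 12 matches per solution):

```python
from fitkit.synth import low_noise_config, run_experiment

res = run_experiment(low_noise_config(seed=7))
for d, s in res.validation.items():
    print(d.value, f"mean r = {s.mean:.2f} +/- {s.sd:.2f} over {s.n_questions} questions")
print("mean recovery:", round(res.mean_recovery, 3))
```

prints

```
combination_novelty mean r = 0.94 +/- 0.02 over 6 questions
combination_feasibility mean r = 0.94 +/- 0.03 over 6 questions
goal_attainment mean r = 0.95 +/- 0.02 over 6 questions
mean recovery: 0.946
```

`mean r` is the average per-question weighted rank correlation between the
simulated automated scores and the Elo ground truth — the validation
statistic you would compute on real data. `mean recovery` is the average
per-question Spearman correlation between the *known* latent qualities and
the recovered Elo ratings: at 12 matches per solution the rating procedure
reconstructs the latent ranking almost perfectly, so a lower `mean r` on real
data reflects genuine judge–human disagreement, not Elo noise.

Power planning for a correlation study:

```python
from fitkit.stats import required_sample_size
required_sample_size(rho=0.3, alpha=0.05, power=0.9)   # -> 112 participants
```

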