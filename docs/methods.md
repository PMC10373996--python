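# Methods

## The problem and the model

A full-length health-literacy instrument scores a participant 0–100 from 67
binary items: 50 reading-comprehension cloze items (R1–R50, 1 point each) and
17 interviewer-administered numeracy items (N1–N17, prorated to 50 points,
i.e. number-correct × 50/17), with the total rounded half-up. The total is
classified as inadequate (0–59), marginal (60–74) or adequate (75–100);
inadequate + marginal together are "low" functional health literacy.

A short form is an integer-weighted linear predictor of the full-length
total,

    Y = b0 + Σ_j b_j C_j,    C_j ∈ {0,1},  b_j ∈ ℤ,

estimated by ordinary least squares and trimmed to integers so it can be
scored by hand. Candidate item subsets are unions of *sentence-sets*:
maximal runs of consecutive reading items that form one sentence. Selecting
whole sets preserves sentence meaning; the sets are the atomic units of the
search. Set membership is data carried in the bank file, not inferred from
text.

## The search

For every model size m = 1, 2, … (total items), every combination of sets
whose sizes sum to m is evaluated by leave-one-out cross-validation: for each
participant i the model is fitted by least squares on the other n−1 rows, its
coefficients (intercept included) are rounded half away from zero, and the
trimmed model predicts row i. The pooled predictions give the RMSE and the
Pearson correlation with the observed full-length scores. The winner at a
size has the highest pooled r; ties break by lower RMSE, then fewer sets,
then lexicographic set ids (the tie order is a package convention). The
search stops at the smallest size whose winner meets the quality goal
(default r ≥ 0.9, reading items only); if no reading-only model ever meets it
and the goal permits, a second pass adds numeracy items as singleton sets and
the pass used is recorded. The final model's published coefficients are the
per-fold float coefficient means trimmed once at the end — trimming each fold
and then averaging would generally produce non-integers, defeating the
purpose of an integer rule.

Reported alongside r is a Fisher-z 95% confidence interval
(tanh(atanh(r) ± 1.96/√(n−3))) and a two-sided t-test p-value.

### Two-stage evaluation

Exact integer LOOCV refits each combination n times. The per-fold float
solutions are obtained in closed form via the rank-one downdate
β₍ᵢ₎ = β − (AᵀA)⁻¹ aᵢ eᵢ/(1−hᵢ), which is algebraically identical to
refitting and falls back to explicit per-fold solves (pseudo-inverse where
rank-deficient) whenever the design is deficient or a leverage reaches 1.
Even so, the number of combinations per size grows quickly, so by default all
combinations at a size are first *screened* with the closed-form leave-one-out
residuals of the float fit (the PRESS identity, using hat-matrix leverages),
and exact integer-trimmed LOOCV runs only on the best `screen_top` (default
50) screened candidates. `exact=True` disables screening. The two modes agree
on every packaged test instance; screening can in principle drop a candidate
whose integer trimming helps more than its float fit suggests, which is why
the exact mode exists.

### Numerical conventions

- **Integer trimming** rounds half away from zero (2.5 → 3, −2.5 → −3). A
  truncation alternative was considered and rejected: round-half-away keeps
  |trimmed − float| ≤ 0.5 per coefficient, which the tests assert.
- **Degenerate predictor columns** (all 0 or all 1 inside a training fold)
  are retained and the fold solved with the pseudo-inverse, so coefficient
  vectors keep a fixed length across folds; such solves are flagged.
- **Fit preconditions:** n > p + 1 for a fit or a LOOCV evaluation of a
  p-item combination; combinations too large for the cohort are skipped.
- **Short-form scores are clipped** to [0, 100] before level classification.
  For the packaged 20-item rule this never binds (its analytic range is
  [23, 95]: the intercept alone, and the intercept plus the positive-weight
  sum).
- **Score rounding:** full-length totals round half-up to an integer before
  level assignment. Whether the original study rounded before classifying is
  not stated; half-up is this package's convention.
- **Administration time** is prorated per part and rounded up to whole
  minutes per part: ceil(12·n_read/50) + ceil(10·n_num/17). The ceiling form
  is the one rule that reproduces all four published times (22, 12, 9, 5
  minutes) simultaneously.
- **Numeracy prorating in `score_full`** generalises to 50/n_numeracy (and a
  single-part bank scales that part to 100) so reduced banks used in testing
  remain scorable; on the canonical 67-item bank it is exactly the 50/17
  convention above.
- **One-vs-rest accuracies** are reported as whole percents, rounded half-up
  (on the packaged level pairs this yields 92/80/88).
- **Point-biserial strength bands** on |r|: weak [0, 0.2), medium [0.2, 0.5),
  high [0.5, 1] — lower bound inclusive, since the conventional band edges
  overlap at 0.2 and 0.5.

## The packaged fixtures

- `ds_tofhla_bank.json` — the 67-item bank with a 19-set partition of the
  reading items. Only six set boundaries (R2–3, R13–14, R18–21, R23–25,
  R37–41, R42–45) are publicly documented; the other 13 are **reconstructed**
  to be contiguous and to match the documented size histogram
  {1:5, 2:7, 3:1, 4:3, 5:2, 6:1}. Analyses that depend on the exact
  boundaries of those 13 sets inherit this assumption.
- `ds_tofhla_short.json` — the published 20-item integer rule
  (intercept 23; weights 2,5,1,7,4,4,2,5,4,5,8,3,3,0,4,2,0,6,5,2 on
  R2,R3,R13,R14,R18–R21,R23–R25,R37–R45). Items R39 and R42 carry weight 0:
  administered for sentence integrity, contributing no points.
- `level_pairs.csv` — 158 true/predicted level pairs realizing the
  published confusion matrix (the matrix determines the pairs up to row
  order).

## The synthetic cohort generator

Responses follow a two-parameter logistic (2PL) item-response model: ability
θᵢ ~ Normal(0, 1), P(correct) = logistic(a_j(θᵢ − b_j)). This is the simplest
standard mechanism producing unidimensional, difficulty-ordered binary data;
reading difficulties are constrained non-decreasing in administration order,
matching the instrument's easy-to-hard passage design.

The default configuration uses a common discrimination a = 1.42 with reading
difficulties linear from −2.59 to 0.60 and numeracy from −2.65 to 0.22.
These values were calibrated once, numerically, so that simulated full-length
scores reproduce the published cohort's marginals — across seeded replicates
the mean of cohort means falls within 71.6 ± 3, SDs within 18.7 ± 3, and
level proportions within 8 percentage points of 25/21/54 — and are frozen.
Only those marginals are reproduced: the real cohort's item-level difficulty
and discrimination values are unpublished, so item-level statistics of
simulated cohorts (e.g. which sets win a search) carry no information about
the real instrument. Passing tests demonstrate that the machinery recovers
structure the generator planted, not that any particular item subset is
optimal in real data.

The **planted-signal regime** (`planted_sets=...`) gives items inside the
named sets discrimination 5.0 and all others 1.0. This concentrates the
usable ability information in the planted sets while keeping the background
informative enough that the full-length score remains predictable at r ≥ 0.9
— with a much weaker background no subset of items can predict the noisy
full score that well, so recovery and goal attainment could not be tested
together. A subtlety the test suite documents: because candidate items are
part of the full score they predict, a high-variance *uninformative* item has
self-prediction value, so "this subset carries all the discrimination"
experiments must make background items near-constant (extremely easy) rather
than coin-flips.

Numeracy items share the single latent trait; no guessing parameter (3PL),
multidimensionality, or differential item functioning is modelled.

## Test scale

Oracle-equivalence and recovery properties run on reduced instances (banks of
5–8 sets, cohorts of 40–60; 10–20 seeded replicates), sizes chosen so the
brute-force power-set oracles stay cheap while leaving the properties sharp;
the full 19-set bank is exercised end-to-end via the screened search in the
CLI and recovery tests. The packaged search itself handles the full bank in
seconds per size with screening.

## Known limitations

- The exhaustive search is exponential in the number of sets; it is intended
  for instruments with tens of sets, not hundreds.
- LOOCV-selected models are still selected on the same cohort; external
  validation on an independent sample is outside the package's scope.
- The generator's calibration reproduces marginal score structure only, and
  the reconstructed 13 set boundaries in the packaged bank are a documented
  assumption, not data.
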