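# Methods

`wat2barthel` estimates the Barthel Index (BI) — a 0–100 score of
independence in activities of daily living, recorded in steps of 5 — from
step-count streams collected by a wrist-worn activity tracker, and converts
the estimate into a dependence class: A (total dependence, BI ≤ 20),
B (severe dependence, 20 < BI ≤ 60), C (moderate/mild dependence or
independent, BI > 60). The intended users are groups modelling functional
status in patients with complex chronic diseases, where activity is sparse,
bursty and systematically under-counted whenever the patient walks with an
aid.

## Preprocessing: from raw stream to a mean 24-hour profile

Raw samples are `(patient_id, timestamp, steps, heart_rate)` at minute-level
resolution. The stages, in order:

1. **Quality rule.** A missing heart rate means the device was not worn
   properly, so the simultaneous step count cannot be trusted. At hourly
   granularity (the default), an hour whose median heart rate is missing has
   its step sum invalidated; a sample-level variant (`nullify_missing_hr`)
   is provided for streams where per-sample nulling is preferred.
2. **Hourly aggregation.** Steps are summed and heart rate medianed per
   (patient, calendar day, hour).
3. **Smoothing.** The chronological hourly series is smoothed with a
   centred rolling mean of width 3 *before* any grouping by hour-of-day.
   Missing hours are skipped in the window (a missing-aware mean), never
   imputed as zero — zero would conflate "device off" with "no movement".
   At the series edges the mean uses the available one or two neighbours, so
   a constant series is a fixed point of the smoother.
4. **Mean profile.** Within the 30-day half-open window ending the day
   before the clinical encounter, the smoothed values are averaged by
   hour-of-day, giving a 24-value profile. A patient counts a day toward
   sufficiency if that day has at least one non-null hourly record; patients
   with fewer than 14 such days are *excluded* (an explicit
   `InsufficientDataError`, surfaced in the pipeline manifest), not
   zero-filled. An hour-of-day with no usable data anywhere in the window
   (possible only if the device was never worn at that hour) is reported as
   0 so the profile stays finite; this case does not arise in practice
   because smoothing spreads evidence into neighbouring hours.

Defaults: `window_days=30`, `min_days=14`, smoothing width 3. Timestamps
are interpreted in a single civil time zone; hour-of-day is the local clock
hour.

## Features

The profile is reduced to one statistic per day segment — morning
(07–13 h), afternoon (14–19 h), evening (20–23 h), overnight (00–06 h);
inclusive hour bins that partition the day exactly. The default statistic
is the **maximum** smoothed hourly step count in the segment: these
patients' movements are short-lived bursts (rarely longer than an hour), so
a segment's peak hour is a more stable summary of its representative
activity than the sum or mean, both of which are diluted by empty hours.
`sum` and `mean` reducers are available behind the same interface for
comparison. Features are left unscaled — trees are invariant to monotone
feature scaling, and raw step units keep thresholds interpretable.

The walking-aid group is one-hot encoded as `no_walking_aid`,
`cane_or_walker`, `wheelchair`. Wrist devices under-count steps during
assisted ambulation, so the aid group is a confounder the model must see.
Caregiver-assisted walking is grouped with canes/walkers because the
support, and the under-counting, are comparable; crutch users likewise fall
in `cane_or_walker` under the three-group scheme.

## The model

A CART regression tree, authored in this package:

- Greedy binary recursive partitioning minimising within-node sum of
  squared errors (SSE); leaf prediction is the mean training target, so
  predictions are always inside the training target range.
- Candidate thresholds are midpoints between consecutive distinct sorted
  values of each feature.
- A split is accepted only if the *weighted* impurity decrease
  `(SSE_node − SSE_left − SSE_right) / n_total` reaches
  `min_impurity_decrease`, both children have ≥ `min_samples_leaf` rows and
  the node has ≥ `min_samples_split` rows.
- Ties in split quality (within a relative tolerance of 1e-9 of the node
  SSE, so floating-point accumulation order cannot flip a decision) break
  to the lowest feature index, then the lowest threshold. Fits are fully
  deterministic.
- `min_samples_split = 1` is accepted for grid compatibility but clamped to
  2 with a warning — a binary split needs two children.
- `max_depth` is exposed as an optional cap but is deliberately *not* part
  of the tuning grid; shallow trees emerge from the other constraints.

**Train/validation split.** 70/30, stratified by walking-aid group: within
each group rows are shuffled (seeded) and allocated by largest-remainder
apportionment so the global train count is exactly `round(0.7·N)` while
each group stays as close to 70% as integers allow. Groups with fewer than
two rows go wholly to training with a warning. Rows tagged
`role == "test"` (a production-like hold-out) are refused by both the
fitter and the tuner.

**Hyperparameter tuning.** 7-fold cross-validation over the dense grid
`min_impurity_decrease ∈ {0.00, 0.01, …, 1.00}` ×
`min_samples_leaf ∈ {1..10}` × `min_samples_split ∈ {1..10}` — 10,100
candidates. The default selection score is negative mean squared error;
negative median absolute error is available (`scoring=
"neg_median_absolute_error"`) for users who prefer the robust criterion.
The winner is the argmax of the mean held-out score, ties broken to the
lexicographically smallest hyperparameter tuple.

A structural fact makes the full grid cheap: the greedy split *choice* at a
node never depends on `min_impurity_decrease` (the parameter only gates
split acceptance), so the tree at any threshold is a pruning of the tree
fitted at threshold zero. The tuner fits one full tree per
(fold, `min_samples_leaf`, `min_samples_split`) combination — 700 fits —
and scores all 101 impurity thresholds by reading, for each validation row,
the value of the first node on its root-to-leaf path whose running-minimum
weighted decrease falls below the threshold. A test verifies this scoring
is exactly equal to naive refitting per candidate.

**Permutation importance.** For each feature, the drop in R² when that
column alone is shuffled, repeated `n_repeats` (default 50) times with a
seeded generator; the full per-repeat distribution is returned for
violin-style summaries alongside descending means.

## Evaluation

MAE, MAD (median absolute error), RMSE and R² on the continuous
predictions, then class metrics (precision/recall/F1 per class, accuracy,
3×3 confusion matrix) after mapping both true and predicted BI through the
class cut-points. The regress-then-classify order is intentional: BI is
continuous, and small regression errors near a cut-point should cost one
adjacent class, not destabilise a direct classifier. Undefined
precision/recall ratios (a class never predicted, or absent from the truth)
are reported as 0.00 with a warning, so low-support classes remain visible
in reports. Rendered tables round errors and class metrics to 2 decimals
and print accuracy as an integer percent; exact fractions are kept in the
JSON serialisation.

## The synthetic cohort generator

No clinical data ship with this package; the generator produces cohorts
with the statistical structure the pipeline assumes, so every stage is
testable end to end.

Per patient: a dependence class is drawn from `class_mix` (default
1/9 A, 4/9 B, 4/9 C — a 90-patient pilot-style cohort), the true BI
uniformly from the class's grid of multiples of 5 (A: 0–20, B: 25–60,
C: 65–100), and a walking-aid group from class-conditional proportions
chosen so that aid need decreases with independence while the implied
marginals land near ~17% wheelchair / ~26% cane-walker-caregiver / ~58%
none. Activity is generated at 1-minute resolution as bursts:

- per-day burst count ~ Poisson with a class-dependent rate
  (A: 2, B: 5, C: 8 bursts/day);
- burst start hour ~ round(Normal(anchor, 1.2 h)) with the anchor drawn
  from the meal hours (9, 14, 21 — breakfast, lunch, dinner of the
  customary Spanish timetable), clipped to 0–23;
- burst duration is 1 clock hour, extended to 2 with probability 0.25, and
  the burst's active minutes are confined to those one or two consecutive
  clock hours — bursts never span more than two hours by construction;
- burst step total ~ Poisson(amplitude × duration), with per-patient
  amplitude = class base (A: 40, B: 150, C: 350 steps/burst-hour) ×
  (0.5 + BI/100), so expected activity is strictly increasing in BI within
  and across classes.

Recorded steps are then thinned binomially by the aid-group attenuation
factor (wheelchair 0.15, cane/walker 0.6, none 1.0), emulating wrist-device
under-counting during assisted ambulation. Heart rate is a per-patient
baseline ~ Normal(72, 5) bpm plus a small activity offset;
`inject_missingness` blanks heart-rate samples independently with
probability `missing_hr_prob` (default 0.05), feeding the preprocessing
quality rule. With probability `dropout_prob` (default 0.10) a patient
stops recording at a uniformly chosen day, producing records that exercise
the 14-day exclusion path.

What the generator does **not** emulate: sleep records, wear-time
periodicity (e.g. charging routines producing structured daily gaps),
autocorrelated multi-day illness episodes, device clock drift, or any
clinical covariates. Passing tests therefore demonstrate that the pipeline
machinery is correct under the stated generative assumptions, not that the
model attains any particular accuracy on real cohorts.

## Numerical and design choices

- Sampling interval 1 minute (configurable divisor of 60); hourly
  aggregation downstream makes the raw resolution immaterial.
- Split units are rows of whatever table is supplied; the pipeline applies
  the 70/30 split to the post-exclusion feature table.
- The hourly quality rule defaults to hourly granularity (median heart rate
  of the hour missing ⇒ hour invalid); sample-level nulling is available
  and composes with it.
- Seeds: a single pipeline seed expands into independent per-stage seeds
  via `numpy.random.SeedSequence.spawn`, so stages are reproducible in
  isolation and reruns are byte-identical.
- Problem sizes in the test-suite and acceptance computations (cohorts of
  60–300 patients, 10–30 recorded days) were chosen as the smallest sizes
  at which the tested statistical properties are stable; the tuning grid is
  always exercised in full (10,100 candidates, 7 folds).

## Known limitations

- The pruning shortcut in the tuner relies on the split choice being
  independent of `min_impurity_decrease`; if a different impurity gate were
  added (e.g. one that alters the search itself), the shortcut would need
  revisiting (the equivalence test would catch it).
- Largest-remainder allocation makes per-group train counts depend weakly
  on the other groups' sizes (a known property of apportionment methods).
- Profiles assume one encounter per patient-window; longitudinal modelling
  of repeated encounters is out of scope.
- The class-A corner (few patients, near-zero activity, heavy attenuation)
  is intrinsically hard; like any mean-leaf tree, predictions cannot leave
  the training target range, which is a feature for BI but means class A
  is never predicted if no class-A patient survives preprocessing.
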