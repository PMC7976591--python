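# Methods

## The decision problem

At every hemodialysis occasion (weekly or biweekly) the physician issues a
dosing direction per medication: UP / STAY / DOWN for the
erythropoiesis-stimulating agent (ESA), UP / STAY for the iron supplement
(IS, which stops automatically after six weeks).  Doses move by one
discrete syringe/ampoule unit, so the *direction*, not a continuous dose,
is the learning target.  The package learns these directions from recorded
physician decisions and evaluates agreement with them — it deliberately
contains no physiological prediction model, because the system imitates
expert behaviour rather than forecasting hemoglobin.

## Synthetic cohort generator

Real records of this kind are not publicly available, so the generator
produces cohorts with the statistical structure the analysis depends on.
Per patient, hemoglobin follows a first-order dose-responsive recursion

    hb[t+1] = hb[t] − hb_decay · (hb[t] − floor[t]) + esa_effect · u[t]^0.7 + ε[t]

with `u[t]` the ESA dose in units, `ε ~ N(0, lab_noise_sd²)` and `floor[t]`
a slowly drifting anemic baseline (random walk, slight upward mean).  The
concave exponent 0.7 encodes diminishing ESA response at higher doses.
Ferritin drains with erythropoietic activity, refills while iron is dosed,
and is *observed* (with TSAT) only every `iron_panel_period` = 4 occasions;
Hb and MCV are observed every occasion.

A deterministic latent policy stands in for the physician: ESA UP when Hb
is below 10.0 g/dl (or near-low and falling fast), DOWN when above
12.0 g/dl (or near-high and rising fast), otherwise STAY, with a
two-occasion cooldown after any change so its effect can be observed and
with dose bounds respected; IS UP when the latest ferritin < 100 ng/ml or
TSAT < 20 %, then a six-week course.  The cooldown is clinically natural
and has a second purpose: it guarantees non-STAY decisions are isolated,
which makes the delay corruption (below) well-defined and invertible.

Recording corruption is applied to the *records only* — doses always
follow the latent policy:

* label noise: a latent non-STAY is recorded STAY with probability
  `p_label_noise` (a missed change; the conservative direction only, so
  appropriateness against the latent label stays interpretable);
* delay: a recorded non-STAY moves one occasion later with probability
  `p_delay`; the carrying occasion has no blood panel (the unavailable
  result being the real-world cause of such delays) and its decision date
  is the late recording date.

Default calibration (chosen once): `lab_noise_sd` = 0.45 g/dl,
`floor_drift_sd` = 0.13, `floor_drift_mean` = 0.012, `esa_effect` = 0.40,
`hb_decay` = 0.20.  These put ≈83 % of hemoglobin values inside the target
range and make the recorded ESA direction mix ≈7 % UP / 85 % STAY / 8 %
DOWN — the STAY-dominated imbalance regime of maintenance cohorts.

What the generator does **not** emulate: real pharmacokinetics, ESA
hyporesponders, inflammation and comorbidity, mortality/censoring,
physician disagreement, and the modest DOWN-over-UP excess real cohorts
show (the simulated controller's corrections are nearly symmetric).
Passing tests therefore demonstrate that the pipeline recovers a
recoverable policy under realistic observation artifacts — not clinical
performance on real patients.

## Rectification

A non-STAY record counts as delayed when its occasion lacks a blood panel
or its decision date differs from its exam date.  It is moved to the
nearest earlier occasion with a panel, at most `max_lag_occasions` (default
1, configurable to 2 for biweekly records) back; the vacated occasion
becomes STAY.  STAY records never move; a move onto an occasion already
holding a *different* non-STAY direction is logged as a conflict and left
alone rather than resolved.  The operation is idempotent and conserves
non-STAY counts.  By default rectification is applied to training data
only — validation records are evaluated as recorded.

## Features

Per occasion *t* and analyte (Hb, MCV, ferritin, TSAT): level at *t*,
level at *t−1*, and their difference.  Iron panel values are carried
forward (last observation) because they are drawn monthly while decisions
happen weekly.  Dose histories cover the `history_len` = 4 occasions
ending at *t−1* — the current occasion's dose realizes the decision being
predicted and is excluded.  A weeks-on-iron counter tracks the automatic
stop rule.  Rows exist for occasions ≥ `warmup` = 4.  The rows for *t−1*
and *t* are stacked as a length-two sequence: the ESA net consumes them
flattened, the IS net stepwise.  Normalization (center/scale per feature)
is fitted on training rows only.  Trends are one-step differences; the
window is configurable.

The schema stores the four analytes named above; adding further analytes
is an extension point of `features._ANALYTES` plus the cohort CSV schema.

## Decision models

ESA: feed-forward ReLU stack, 10 hidden layers × 16 units over the
flattened two-timing input, softmax over (UP, STAY, DOWN).  IS: an Elman
recurrent cell over the two timings followed by a dense stack (same total
depth), softmax over (UP, STAY).  Both train with Adam (lr 3·10⁻³, batch
512, 40 epochs by default) on class-weighted cross-entropy with L1 (10⁻⁵)
on weight matrices (never biases) and dropout 0.1 on hidden activations.
Widths, optimizer, epochs and dropout are artifact choices — small enough
that a 100-fold cross-validation trains in minutes on one CPU; they are
all in `ModelConfig`.  Small datasets (≲1000 rows) need more epochs /
smaller batches than the defaults, which the examples and tests set
explicitly.  Everything is NumPy and bit-deterministic given the seed.

Class weights start at the inverse ratios `w_c = W/(K·n_c)`.  Because that
alone leaves per-class recalls unequal, `equalize_recalls` retrains with
the multiplicative update `w_c ← w_c · (mean_recall/recall_c)^γ`
(γ = 0.5, weights renormalized to mean 1) until the training recall spread
is ≤ `tol` = 0.1 or `max_rounds` is exhausted, returning the best-spread
round.  Recalls here are measured with argmax classification: the
operating threshold is selected only after the weights are fixed, so using
it inside the loop would be circular.

## Two-step classification

STAY iff P_STAY > T (strict: T = 1 forbids STAY, T = 0 with any STAY mass
forces it), otherwise the larger of P_UP / P_DOWN; an exact tie goes to
UP, under-treated anemia being the flagged clinical risk (the event has
measure zero and is logged when it occurs).  T is chosen on the training
data as the point of the STAY-vs-NON-STAY ROC nearest (0, 1), searched on
a 201-point grid over [0, 1]; ties break toward larger T (more dose
changes, favouring timing sensitivity).  When a training fold contains a
single class (no ROC), the shipped reference operating points (0.475 ESA,
0.470 IS) are used.  `roc_curve` with `grid=None` steps through every
distinct P_STAY value, which makes the trapezoidal AUC equal the
Mann–Whitney pairwise-concordance estimator exactly (ties half-credited).

## Evaluation

LOPO re-derives *everything* per fold — normalizer, class weights,
equalization, threshold — from the fold's training patients, then predicts
the held-out patient; rates are pooled per occasion (a per-patient mean is
also reported, since pooling conventions differ).  RDV trains once and
evaluates on a disjoint cohort; shared patient ids are a hard error.

R_TOTAL is exact same-date agreement; R_UP/R_STAY/R_DOWN are per-class
recalls (precisions are reported alongside but not used for any bound).
Disagreements are categorized in priority order:

1. **correct** — prediction equals the record;
2. **before_physician** — the system called the same UP/DOWN the physician
   recorded within the next 3 occasions (configurable); each recorded
   change credits at most one earlier prediction, the nearest one;
3. **latent_appropriate** — synthetic cohorts only: the prediction matches
   the generator's uncorrupted policy label.  This is the automatable
   stand-in for appropriate-on-clinical-review; on real cohorts the
   residual category is instead **unreviewed**, for export to human
   review, because appropriateness there is a judgment this package must
   not pretend to automate;
4. **incorrect**.

The gross clinically-appropriate rate is (1+2+3)/total and always bounds
R_TOTAL from above.

## Problem sizes

The reference benchmark is 100 patients × 60 occasions (5600 evaluated
rows after warm-up), 100 LOPO folds, each with up to two equalization
trainings; it completes in a few minutes on one CPU.  Unit and property
tests use 8–40 patients.  The development-ladder ablation is checked at
constrained training budgets, where the shallow unweighted baseline
visibly collapses to all-STAY; the ladder's rungs are not mutually
monotone in min(R_UP, R_DOWN) — class weighting overshoots the minority
classes and the ROC threshold then rebalances toward STAY — so the test
asserts each developed configuration against the baseline rather than
rung-to-rung monotonicity.

## Known limitations

* The generator's latent policy is a single deterministic rule; real
  records mix physicians and unmodelled covariates, so replication rates
  here are upper-end estimates of what the method achieves on real data.
* The latent-appropriate category exists only where latent labels exist;
  real-data runs report unreviewed occasions instead of resolving them.
* Drug-specific pharmacology is out of scope: two ESA agents with
  different potency can be simulated but are pooled in training.
* Dose equivalence across iron preparations, cost analysis and prospective
  validation are out of scope.
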