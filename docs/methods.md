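# Methods

## Problem and data model

The package predicts the Global Clinical Dementia Rating score (CDRGLOB,
five stages: 0, 0.5, 1, 2, 3) of a patient's next clinic visit from the
patient's past visits. A visit row carries 77 clinical features across six
categories — demographics, health history, physical information (including
MMSE), the CDR scale elements, the Geriatric Depression Scale (GDS) and
the Functional Activities Questionnaire (FAQ) — plus a derived *time
interval* feature: the whole months to the following visit, with the final
step holding the user-chosen prediction horizon. The packaged feature
dictionary (`adprog.default_schema`) allocates types and level counts so
that one-hot encoding of all categoricals expands the 78 predictors to
exactly 234 input columns; the real study's variable list is not public,
so the dictionary is a stand-in that satisfies the published counts with
clinically plausible variables.

Patients with at least 3 visits are accepted. The source material is
ambiguous between "more than three" and a minimum of 3; the explicit
minimum is honoured.

## Synthetic cohort simulator

Real cohorts of this kind are access-restricted, so the package generates
synthetic ones that reproduce the published summary structure:

* **Stage paths.** First-visit stages are drawn from
  (0.074, 0.477, 0.349, 0.070, 0.030) — the 0.477 and 0.349 entries are
  the published first-visit fractions at CDR 0.5 and CDR 1; the remainder
  is a fixture choice summing to 1. Subsequent stages follow the published
  5×5 per-visit transition matrix (row-stochastic to 4 decimals; its
  structural zeros, e.g. severe patients never reverting to CDR 0, are
  preserved exactly). The matrix is treated as per-visit, not per-month,
  matching its definition over consecutive visits.
* **Visit counts.** Categorical on {3..12} with geometric-decay weights
  tilted (by solving for the decay rate) so the mean is exactly 4.98; only
  the min, max and mean are published.
* **Intervals.** Probability 0.46 at 12 months; the remaining mass spread
  over {5..60}\{12} with geometric decay (rate 0.9) away from 12 — a
  qualitative match to the published histogram shape.
* **Interval modulation (optional, default off).** For experiments where
  interval information must genuinely matter, worsening transition
  probabilities are multiplied by
  `strength ** (2*sigmoid(sharpness*(dt-12)/12) - 1)` and the row is
  renormalised (defaults: strength 4, sharpness 3). The factor is 1 at the
  modal 12-month gap, grows toward `strength` for long gaps and shrinks
  toward `1/strength` for short ones. The defaults were chosen by an
  analytic power calculation: the oracle accuracy gain from knowing the
  interval is ≈0.036 under these settings, large enough for the
  with/without-interval comparison to be identifiable at desk scale,
  whereas a factor capped at 2 can almost never flip the optimal
  prediction (gain ≈0.001).
* **Feature emission.** CDR elements equal the true stage value with
  probability `p_fid` (default 0.7), else an adjacent scale value; CDRSUM
  is the sum of the six standard elements. FAQ items are Binomial(4, p)
  with p increasing linearly in stage. GDS items are stage-independent
  Bernoulli noise (mirroring the published finding that GDS carries little
  predictive signal). MMSE declines with stage; other physical and static
  demographic/history variables are stage-independent. `signal_categories`
  restricts which categories carry stage signal, used by the ablation
  experiments. With `p_fid = 1` the current stage is fully observed, which
  makes the best achievable next-stage accuracy computable in closed form
  (`bayes_accuracy`): Σ_s π_s · max_s' P[s, s'].
* **Missingness.** Each feature has an assigned missing rate from the
  published band profile (bands ≤5% up to 25–30%; band representatives
  0.03/0.08/0.13/0.18/0.23/0.28). The published band counts total 79
  against 77 assignable features; two slots were dropped from the largest
  (≤5%) band. Bands are assigned clinically: CDR and demographics lowest,
  GDS highest (consistent with GDS "did not answer" behaviour). The label
  and the time interval are never missing.
* **Determinism.** All randomness flows from one seed through independent
  `SeedSequence` child streams per pipeline stage (structure, paths,
  emission, missingness); emission is vectorised column-wise over all
  visit rows. Identical seeds give byte-identical CSV output.

What the simulator does **not** emulate: real marginal distributions of
the clinical variables, correlations beyond the stage link, informative
(non-random) missingness, measurement drift, or death/dropout. Passing
tests therefore demonstrate correctness of the pipeline and learnability
of Markov stage dynamics — not clinical performance on real data.

## Preprocessing

Imputation follows a statistic-by-pool grid: the statistic is chosen by
data type (continuous → mean, ordinal → median, nominal → mode) and the
pool by temporal behaviour (static features → first visits of all
patients; dynamic → all visits of all patients; patient-specific dynamic →
the same patient's other visits). Ordinal medians use the lower middle
value so fills stay on the admissible grid; modes break ties toward the
smallest value. A patient with no observed value for a patient-specific
feature falls back to the all-visits statistic. Continuous features are
z-scored with training-fold mean and *population* variance; categoricals
(ordinal and nominal alike) are one-hot encoded. The time-interval column
is passed raw, in months, so that the "without time intervals" model
variant is a clean zeroing of one column (a flag enables z-scoring it
instead). All statistics are fitted on training folds only.

Sequences are padded to the batch maximum plus one trailing zero row (the
shifted many-to-one layout); padded steps are masked and the hidden state
carries through them unchanged, so the prediction is read exactly at the
last real step and pad rows provably cannot change it (tested).

## Network, loss and training

Two LSTM layers of 100 units (gate weights act on the concatenation
[h_prev, x]; layer 1 input width 234, layer 2 input width 100) and a
5-way softmax head. The default loss is the binary-style cross-entropy
summed over all five softmax components, −Σ(y log ŷ + (1−y) log(1−ŷ)),
plus λ·Σw² over gate and head weight matrices (not biases); standard
categorical cross-entropy is available as `loss_variant="categorical_ce"`.
The binary-style form is unusual with a softmax head but is kept as the
default for fidelity; both variants are gradient-checked. Probabilities
are clamped to [1e−12, 1−1e−12] inside logs.

Backpropagation through time and the optimizer (adaptive moments,
β₁=0.9, β₂=0.999) are hand-implemented in numpy. Defaults, chosen as
fixture values because the original hyperparameters are not public:
λ = 1e−4, base learning rate 1e−3 with ×0.95 exponential decay per epoch,
batch size 64, 50 epochs, weight init uniform in ±1/√fan-in, and an
exponential moving average of parameters (decay 0.99) used at evaluation
time. Training is deterministic given the seed. Ties in the predicted
distribution resolve toward the lower stage.

## Baselines

Three fixed-width constructions feed injected scikit-learn classifiers
(multinomial LR, RBF SVM, CART, 100-tree RF): per-feature aggregation
over all visits (mean/median/mode by type), concatenation of the most
recent r visits (r = 2 by default; r must stay below the dataset's
minimum visit count), and the last visit alone — which equals the r = 1
merge exactly, by construction. Aggregation operates on raw values and the
result is imputed/normalized/encoded with the same pipeline as the
network. Each merged visit keeps its own interval (the last being the
prediction horizon); the aggregate construction appends the horizon as an
extra column since its averaged interval blends it away.

## Evaluation

Accuracy, PPIA and SPIA. PPIA is exact-stage accuracy restricted to
patients whose true next stage exceeds their current stage; SPIA is
exact-stage accuracy restricted to patients whose true next stage is CDR 2
or 3. Both are reported as absent on an empty denominator. (An alternative
reading — binary group-membership accuracy — exists; the subgroup
exact-stage reading is adopted.) Cross-validation is 10-fold by default,
patient-level (a patient's visits never straddle folds), with per-fold
refitting of imputation and normalization; fold summaries use the sample
standard deviation (n−1). The ablation harness removes subsets of
{CDR, GDS, FAQ} — demographics, health history, physical information and
the time interval are always retained as basic information — and the
single-feature harness adds one CDR/FAQ feature back to the basic model
using identical folds.

## Problem sizes in the shipped checks

The test suite exercises the published calibration targets at sizes chosen
as the package's own desk-scale defaults: transition calibration on
~300,000 simulated transitions; visit-count and first-visit summaries on
100,000 draws; the closed-form learning check on 5,000 training / 1,000
held-out patients with `p_fid = 1` at 8 epochs (accuracy within 0.05 of
the analytic optimum); the interval-information ordering on a 2,400-patient
modulated cohort with 3-fold cross-validation at 10 epochs; and the CDR
ablation ordering on a 900-patient cohort whose emission signal is
confined to CDR. Epoch counts reflect where training visibly plateaus on
these cohorts.

## Known limitations

* The feature dictionary is synthetic; real NACC variable semantics,
  codes and sentinel values are out of scope.
* The loss default follows the printed binary-style form; published
  headline accuracies are not reproducible without the restricted data,
  and the package makes no attempt to match them.
* Single-threaded numpy training is adequate for desk-scale cohorts
  (seconds per epoch at 5,000 patients) but not for large-scale use.
* The simulator's Markov assumption means history beyond the current
  stage carries no extra signal; a recurrent model can at best match the
  closed-form optimum on such data.
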