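# Methods

This note records what the package actually computes, the parameters that
matter, and the design decisions taken where more than one reasonable choice
existed. Nothing here states an empirical number that the test suite or
`scripts/acceptance.py` does not itself recompute.

## Simulated cohort

The simulator (`ehrsynth.sim`) emulates the layout of a colorectal-cancer
registry extract rather than any real dataset:

* **Static table** — patient id, first diagnosis date (uniform over the
  2008-01-01 … 2021-07-31 study window), age (normal, mean 59, SD 11, clipped
  to 18–94), sex (Bernoulli, default 57.4% male), tumour-site diagnosis code
  (57.9 / 32.6 / 9.5% across three codes), ordinal stage (I–IV), death date
  or null.
* **Survival mechanism** — proportional hazards with an exponential baseline:
  the linear predictor uses centred covariates with configurable log-hazard
  coefficients (default `age` 0.03/year, `stage` 0.45/level). The baseline
  rate is calibrated by bisection so that the expected in-window death
  fraction equals `frac_dead` (default 17.8%). Survivors are administratively
  censored at the window end. Because covariates are drawn before times, a
  Cox fit on the uncensored truth recovers the coefficients (tested).
* **Event tables** — surgery (≈85% of patients, one record), chemotherapy
  (≈70%, cycle count from a zero-truncated negative binomial), laboratory
  results (everyone). Inter-event gaps are exponential with gamma-distributed
  patient-level mean gaps, which produces the irregular, overdispersed visit
  spacing the pipeline must handle. Laboratory values are log-normal with
  configurable sigma (`heavy_tail_shape`, default 1.0), giving the long-tailed
  positive values that motivate Hellinger over KL-type divergences.
* **Planted inconsistencies** — `inject_inconsistencies` moves the first
  treatment of a configured fraction of patients before diagnosis or past the
  selection cutoff, and deletes all treatment rows for another fraction. A
  hidden `_flag` column records the ground truth so tests can assert that
  cohort selection removes exactly the planted records.

What the simulator does **not** emulate: clinically coherent care pathways,
correlations between treatment choice and outcome beyond the hazard model,
missing-not-at-random laboratory panels, or the real registry's 33-variable
dictionary. Passing tests therefore demonstrate that the pipeline's machinery
is correct and well calibrated on data with the right *statistical shape*,
not that the generator would reach any particular fidelity on real hospital
records.

## Cohort selection and consolidation

`Diff = min(first surgery date, first chemotherapy date) − first diagnosis
date`, in days. Patients are retained when `0 ≤ Diff < cutoff`; exclusions are
partitioned into `≥ cutoff`, `< 0` and `null` (no treatment date), and the
partition always sums to the input size. "Three months" is implemented as 91
days and is configurable; `Diff = 0` (treatment on the diagnosis day) is
retained.

Consolidation joins all event tables on patient id, converts event dates to
integer day offsets from first diagnosis, merges same-day events from
different tables into one sequence row, and drops (with a logged count)
events dated before diagnosis and same-day collisions within a single column.
Survival time is death date minus diagnosis date, or censoring date minus
diagnosis date for survivors; the censoring date defaults to the latest date
observed in the cohort and is set to the study-window end by the pipeline.
The schema (variable order, category levels, numeric ranges) is inferred at
consolidation time and travels with the dataset; all downstream modules use
it rather than re-inferring anything.

## Feature encoding

Categoricals are one-hot over schema levels. Numerics are min–max scaled to
[0, 1] with stored bounds; variables whose sample skewness exceeds 2 are
scaled on a `log1p(x − vmin)` axis instead (long-tailed laboratory values
would otherwise squash into the first few histogram bins), and variables that
are integral in the data are rounded on decode. The threshold of 2 was chosen
because mildly skewed variables with large offsets are *hurt* by the log axis
(decoder noise becomes multiplicative), while strongly skewed ones are helped.

Sequences are padded to `max_seq_len` with an explicit row-validity mask.
Each dynamic categorical carries an extra "missing" level; each dynamic
numeric carries a presence flag. The TIMESTAMP axis is stored as non-negative
inter-event gaps on a `log1p` axis (typical gaps are days to weeks while the
horizon is years); decoding takes a cumulative sum, so any decoded sequence
is sorted and non-negative by construction. The inverse transform is exact on
categoricals and exact up to float round-off (then integer rounding) on
numerics — tested to 1e-6.

## Generator

With no GPU framework in the dependency set, the training core
(`ehrsynth.nn`) is plain numpy: dense layers with manual reverse-mode
gradients, Adam, and a one-hidden-layer tanh critic for which the gradient
penalty's *parameter* gradient — a second-derivative quantity — has a closed
form, verified against finite differences in the test suite.

The encoder and decoder are MLPs over the flattened masked padded
representation (static block ‖ sequence block ‖ mask), with a softmax head
per categorical group per position, linear heads for numeric channels
(clipped to [0, 1] at sampling time), and a softmax length head over
0 … `max_seq_len`. Squared-error terms are upweighted ×5 relative to
cross-entropy so the decoder does not neglect the numerically small numeric
loss. A recurrent encoder would be the natural alternative; the flattened MLP
was chosen because it keeps the hand-written backward pass simple and
auditable, at the cost of not sharing parameters across time steps — a
reasonable trade at desk scale where `max_seq_len` is a few dozen.

The adversarial stage trains on **whitened** latent codes (ZCA, computed on
the training codes) and parameterizes the generator as `z + MLP(z)` with a
small-initialized residual, so training starts at the exact first-two-moment
equilibrium and only has to learn higher-order structure. Two further choices
stabilize the shallow-critic game, both adopted after observing
characteristic failures at this scale:

* the critic's hidden layer is a frozen random-feature bank (random
  projections with mixed scales, uniform offsets) and only the head is
  trained — the head problem is then nearly convex and tracks the moving
  generator quickly;
* the head is re-initialized every `critic_reset_every` generator steps
  (default 50) followed by a burst of `critic_reset_burst` critic updates
  (default 80). The penalty term `(‖∇f‖ − 1)²` is a double well in the
  critic weights: a critic caught in a wrong-orientation basin feeds the
  generator a persistently wrong signal (runaway or collapse); restarting
  from small weights lets the Wasserstein difference term pick the correct
  orientation before the wells harden.

The WGAN-GP objective itself is standard: penalty weight λ = 10 on uniform
interpolates, 5 critic steps per generator step, both configurable.

Defaults (`GenConfig`): latent 32, hidden 256, 250 autoencoder epochs, 60
adversarial epochs, batch 128, Adam 1e-3 (autoencoder), 5e-5 (generator),
3e-3 (critic head). These train a 2,000-patient model in roughly two minutes
on one CPU. Sampling is deterministic given the model state and a seed, and
sampled records are schema-valid by construction (argmax levels, clipped
numerics, lengths clipped to [1, max_seq_len]).

## Fidelity metrics

* **Hellinger** — `sqrt(1 − Σ√(p_k q_k))`, computed through the
  algebraically identical `sqrt(½ Σ(√p_k − √q_k)²)` form, which returns an
  exact 0 for identical inputs. Categoricals use the union of observed
  levels; numerics use 50 equal-width bins (configurable) over the pooled
  min–max range, so both sides share one support and zero-mass bins
  contribute nothing. Dynamic variables pool all event rows; a variable
  constant on both sides scores 0 with a note.
* **TSTR / TRTS / TRTR** — logistic regression (default) on identical
  summary features in all three directions; the label is the death
  indicator; `survival_days` is excluded from the features (it encodes the
  label almost perfectly). Summary features are static encodings plus
  per-variable sequence aggregates (count, mean, last value; level fractions
  for categoricals; length and mean gap for the time axis) — padded tensors
  would be wasteful for shallow classifiers.
* **Propensity MSE** — records labelled real = 0 / synthetic = 1, truncated
  to a 1:1 mix; p_i are out-of-fold probabilities under stratified 5-fold
  cross-fitting (an in-sample discriminator could memorize); the classifier
  default is histogram gradient boosting; both the raw value (range 0–0.25)
  and the /0.25-scaled value are returned. Both datasets are featurized on
  the real side's schema so scaling differences cannot masquerade as signal.
* **t-SNE dispersion** — a joint 2-D embedding of pooled real and synthetic
  latent codes (fixed seed); "dispersion" is implemented as the per-axis
  sample variance of each group's embedding coordinates, a plain spread
  summary on the embedding axes.
* **Histograms** — shared bin edges per variable, counts and normalized
  frequencies for both sides, exported as CSV for external plotting.

## Survival utility

A random survival forest (scikit-survival; 50 trees, minimum leaf 15, fixed
seed) is trained once on real and once on synthetic data and both are
evaluated on the same real holdout, on an event-time-quantile grid up to
1,825 days (five years, default 50 points; quantile spacing keeps cost flat):

* **C-index** — Harrell's estimator, 0.5 credit for risk ties; pairs are
  comparable when the earlier subject has an observed event. Matches an
  exhaustive pair-enumeration oracle and scikit-survival's implementation on
  censored instances (tested).
* **Brier score** — Graf's IPCW form with Kaplan–Meier censoring weights:
  deaths by t weight 1/G(t_i⁻), subjects under observation weight 1/G(t),
  censored-before-t subjects weight 0. With no censoring before t this is the
  plain mean squared error (tested). S(0|x) is pinned to 1.
* **IBS** — trapezoidal integral of the Brier curve, normalized by the grid
  span; exact for piecewise-linear curves.
* **Time-resolved AUC** — status dichotomized at each grid time among
  subjects whose status at t is known; NaN where only one class remains.

## Privacy

* **DCR** — exact (brute-force) nearest-neighbour Euclidean distance on the
  same flattened encoding used everywhere (one-hot categoricals, min–max
  numerics, mask-zeroed padded sequences, normalized length), unscaled. The
  comparison pairs the holdout-vs-training distances (what *unseen real*
  records look like) against synthetic-vs-training; risk is flagged when the
  synthetic minimum undercuts the holdout minimum. Note that when the
  synthetic set is statistically independent of the training set and the
  same size as the holdout, the two minima are exchangeable and the ordering
  is a fair coin; a *generated* sample sits farther out because the decoder
  smooths — that is the behaviour worth asserting, and the one the
  acceptance suite asserts.
* **Membership inference** — target model: support-vector classifier with
  probability outputs trained on T to predict the death label; 4 shadow
  models (default) trained on disjoint "in" halves of S with matched "out"
  halves; the attack model (also an SVC) learns in/out from (probability
  vector, predicted label, true label) records; evaluation on an exactly 1:1
  balanced mix of T members and H non-members, truncated seed-deterministically.
  Accuracy near 50% means the synthetic data does not reveal membership.

## Orchestration and reproducibility

`run_pipeline` executes simulate → select → consolidate → split → train →
sample → evaluate, persisting every stage's inputs and outputs under the
output directory and assembling one JSON report with provenance (config
hash — invariant to the output path — global seed, per-stage substream seeds
derived by hashing `seed:stage`, library versions). All randomness flows
from the single global seed; rerunning the same config and seed reproduces
every metric exactly (tested). `render_report` turns the report into a
Markdown summary with the static/dynamic Hellinger tables, the classifier
AUCs, the survival metric table, and the privacy verdict; missing sections
render as "skipped".

## Problem sizes and known limitations

The test suite and acceptance script run at deliberately reduced scale —
cohorts of a few hundred to 4,500 simulated patients, latent dimension
16–32, minutes of CPU — chosen as the smallest sizes at which the stochastic
bands (binomial null bands, Hellinger sampling floors) are informative.
Known limitations: the flattened-MLP decoder reproduces smooth continuous
marginals with some variance shrinkage (visible as Hellinger distances of
0.1–0.25 on wide continuous variables at small n, against a finite-sample
floor of roughly `sqrt(bins / 8n)` even for identical laws); the latent GAN
matches first and second moments well but learns higher moments only
partially at these step counts; and a gradient-boosted propensity
discriminator can still separate real from synthetic records at reduced
training scale even when per-variable marginals are close — users should
read the scaled pMSE together with the Hellinger table, not in isolation.
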