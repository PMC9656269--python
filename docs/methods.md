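# Methods

This note documents the models and procedures `harfuse` implements,
the parameters that matter, the design choices made where the design
was genuinely open, and what the synthetic benchmark does and does
not demonstrate.

## Problem setting

Multi-sensor human activity recognition at the decision level: each
body-worn sensor unit (e.g. a triaxial accelerometer at one position)
trains its own classifier, and only the classifiers' decisions are
combined.  Decision-level fusion tolerates heterogeneous sensors and
saves bandwidth, but its quality hinges on three things the package
addresses in turn: the accuracy and diversity of the base
classifiers, the selection of a sub-ensemble worth fusing, and the
fusion rule itself.

## Preprocessing

- **Missing values** are forward-filled (each gap repeats the last
  observed value); a gap at the head of a channel is back-filled from
  the first observation, since dropping stream prefixes would shorten
  every channel differently.  A channel with no observations at all
  is an error.  Fill precedes outlier removal — the Hampel filter
  needs a gap-free series; the reverse order is equally defensible
  but must pick a missing-sample convention for the rolling window.
- **Spikes** are removed with a centered Hampel filter: a sample
  deviating from its rolling-window median by more than
  `n_sigmas · 1.4826 · MAD` (defaults: window = one second of
  samples, i.e. half-width = rate/2; n_sigmas = 3) is replaced by
  that median.  A zero MAD (locally constant signal) would let any
  spike through, so the scale falls back to 1.4826·1e−9 there —
  a spike on a flat channel is still caught, a genuinely constant
  window is untouched.
- **Segmentation**: `window_len = max(2, floor(0.5 s · rate))`,
  `step = floor(window_len · (1 − overlap))` (floor keeps odd window
  lengths deterministic across sampling rates, e.g. 30 Hz → 15-sample
  windows, step 7).  Windows whose samples carry more than one label
  are discarded rather than majority-labeled: recordings are
  per-activity blocks, so straddling windows are segmentation
  artifacts, not transition examples.

## Features

Eight per-channel window statistics: max, min, mean, RMS, standard
deviation with the population (1/N) divisor, skewness, kurtosis as
the fourth standardized moment *without* excess subtraction (a
Gaussian window scores 3), and energy Σa². A zero-variance window
takes skewness = kurtosis = 0 (the defining ratios are 0/0 and zero
keeps tables finite).  Min-max normalization to [0, 1] is fitted on
the training split only and test values are clipped — fitting on all
data would leak test statistics into training.

## ELM experts

Single-hidden-layer networks with uniform [−1, 1] random input
weights and biases, sigmoid activation, and output weights from ridge
least squares against one-hot targets (`hidden` default 100, `ridge`
default 1e−6; ridge stabilizes the solve when hidden activations are
nearly collinear, and `ridge = 0` switches to the pseudoinverse).
The random hidden layer doubles as a diversity source across experts;
each expert gets its own derived seed.  Raw scores are kept
unnormalized — decision vectors are formed downstream.

## Pruning

Both criteria consume a binary correctness matrix computed on a
held-out validation split (selection on training correctness would be
optimistic).

**Mixed diversity.** For each ordered pair, the correlation
coefficient ρ, Yule's Q and the disagreement rate Dis are computed
from the joint correctness counts N11/N10/N01/N00.  Zero-denominator
conventions: ρ = 0 when any marginal factor vanishes, Q = 0 when
N11·N00 + N10·N01 = 0 — both neutral in the score sum.  The
per-classifier score η_i averages ρ + Q + Dis over *all* j including
j = i; the self pair contributes the constant 2 whenever the
classifier has both correct and wrong samples, so including it shifts
every η equally and never changes which classifiers clear the pool
mean AV (property-tested; the argument genuinely needs the mixed-row
condition, since a perfect or null classifier's self pair hits the
zero-denominator guards).  Classifiers with η_i > AV are kept,
ordered by descending η; an all-equal pool falls back to the full
pool.  Note the literal ρ + Q + Dis score is *similarity*-signed
(identical classifiers score high); a `normalized` transform
(((1−ρ)/2 + (1−Q)/2 + Dis)/3, larger = more diverse on [0, 1]) is
available as a config switch, and both modes are tested — the
selection rule is the same either way.

**Complementarity.** Greedy forward selection: seed with the most
accurate classifier, then repeatedly add the candidate correct on the
most validation samples the current sub-ensemble decides wrongly.
The sub-ensemble's decision is scored from correctness alone: a
strict majority of correct members counts as correct, an exact split
defers to the most accurate member (plurality over decided labels is
not recoverable from a correctness matrix; this rule agrees with it
whenever a majority is correct).  Ties break toward higher individual
accuracy, then lower id.

**Ensemble size** is the argmax of the validation
accuracy-versus-size curve over ranking prefixes (majority-vote
fusion during the sweep, the only fuser available before weights are
fitted), overridable by config.

## GDM fusion

Experts emit decision vectors U_k on the class simplex — one-hot of
the decided label in `crisp` mode (default; it makes the reduction to
majority voting exact and testable) or a softmax of the scores in
`soft` mode.  The group decision is G = Σ λ_k U_k with
λ_k = φ·α_k + (1−φ)·β_k; all argmax ties everywhere resolve to the
lowest class index so the fusers stay comparable.

**Subjective weights α (genetic algorithm).**  Chromosomes are m
genes of 8 bits; decoding normalizes the gene integers to the
simplex, and an all-zero chromosome is repaired by setting one random
bit.  Fitness is 1/(Y − ΣSt + ε) with ε = 1e−6 — the reciprocal of
the error count, guarded so a perfectly fused batch stays finite;
any strictly monotone guard ranks chromosomes identically.
Operators: roulette-wheel selection, single-point crossover at a
uniform cut of the flattened bit string (probability 0.8), double
mutation (probability 0.1: flip one whole random gene or one random
bit, chosen uniformly), elitism of one for seeded-run stability.
Population 30, 50 generations by default; the best-ever chromosome is
returned.  These sizes are ordinary GA practice for a ≤ 100-bit
search space.

**Objective weights β (deviation adjustment).**  β is initialized at
α: the objective weight is a deviation-driven *correction of* the
subjective weight, not an independent prior — initializing β uniform
makes the combined λ an average of the optimized weights with
near-uniform ones, which empirically destroys the coalition structure
the GA found (the fused accuracy falls below the GA-only baseline and
at times below plain majority voting).  Each adjustment pass computes
the batch-mean deviation r_k = mean over samples of Σ_j (u_kj − g_j)²
(summed over classes), then moves β by +Δλ/c for experts below the
mean deviation and −Δλ/d for those above (Δλ = 0.05; c, d the counts
on each side, so the transfer conserves the simplex before the
non-negativity clip and renormalization).  If every expert sits on
one side, nothing moves.  **One pass is the default.**  Iterating the
±Δλ transfer many times runs it to its absorbing state: all objective
mass lands on the most consensual expert(s), and with crisp vectors a
λ_k > 1/2 expert dictates every fused decision — the ensemble
collapses to a single classifier, defeating the purpose of fusion.
The epoch count and stopping tolerance remain configurable
(`gdm_epochs`, `gdm_tol`) for studying that regime.

**φ** (preference between the two weight families) defaults to 0.5;
φ = 1 reproduces the GA-only fuser exactly, φ = 0 trusts only the
deviation-adjusted weights.  Weights are frozen at test time.

**Baselines.** MV: plurality over decided labels; WA: λ proportional
to each expert's training accuracy; GA: α with no adjustment.

## Evaluation

Confusion matrix over a fixed class order (absent classes keep zero
rows/columns), one-vs-rest TP/TN/FP/FN per class, precision, recall
and F1 with the 0/0 → 0 convention, overall accuracy, and
unweighted macro averages — the standard multiclass extension of the
binary definitions, matching per-activity recall readings off the
confusion matrix diagonal.

## Synthetic data and the benchmark

The generator emulates per-position, per-activity inertial signals:
for a position with separability s, class k gets mean offset
s·Δ·k and sinusoid frequency f0·(1 + 0.2·s·k), with per-axis phase
offsets, a slow linear trend, Gaussian noise, and optional missing
samples (NaN) and spikes (≥ 10 channel-sd from the channel mean).
Activities are generated as contiguous blocks per subject, so windows
never straddle activities in normal operation.  The trend uses
*block-local* time: with a global clock, each activity block would
sit at a different drift offset and elapsed time itself would
separate the classes — leakage that has nothing to do with the
signals being emulated.

The *complementary-experts benchmark* (4 positions, 3 activities,
32 Hz, 0.5 s windows, 50% overlap, 600 train / 300 test windows)
renders, at each position, one activity with another activity's
parameters, making that position blind to exactly one class pair;
the three distinct pairs are covered and the weakest position
duplicates one of them.  Separability decays across positions
(2.0, 1.5, 1.0, 0.6) because real body positions are not equally
informative — this asymmetry is also precisely what weighted fusion
can exploit and plain voting cannot.  Noise sd is 0.6 against unit
signal amplitude.  Under these conditions single experts sit near
55–71% while the fused classifiers reach 84–93%.

What the benchmark does **not** show: real inertial signals are not
stationary sinusoids; there is no sensor drift across sessions, no
inter-subject variability, no class imbalance, and no label noise.
Passing results demonstrate that the selection and fusion machinery
behaves as designed under controlled complementarity, not that any
particular accuracy transfers to field recordings.

## Problem sizes and reproducibility

Default test-suite and acceptance problem sizes — 300–600 windows,
pools of ≤ 12 experts, GA populations of 30 over 50 generations,
5–10 seeds per claim — were chosen so every statistical check has
enough samples for its tolerance (binomial CIs are quoted in the
tests where chance-level behavior is asserted) while a full run
completes in well under a minute.  A single `seed` fans out through
`numpy.random.SeedSequence` to the data generator, splits, every
expert's hidden layer and the GA, so identical configurations
reproduce bit-identically.

## Known limitations

- The literal mixed diversity score prefers *correlated* accurate
  classifiers (its claimed "larger = more diverse" reading only holds
  for the normalized transform); both modes are provided and the
  choice is config-exposed.
- The deviation adjustment rewards consensus, not correctness; labels
  enter only through α.  With φ → 0 and many adjustment passes it can
  suppress a minority expert that is right where the majority is
  wrong.
- ELM experts use a single shared hidden-layer size; per-position
  capacity tuning is out of scope.
- Raw-dialect loaders for public HAR corpora are out of scope; users
  pre-convert recordings to the stream-CSV contract
  (`timestamp,label,POS/Sensor/axis,...`, missing values as empty
  fields).
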