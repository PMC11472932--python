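# Methods

## Generative model

Each participant-condition block is a first-order state-space recursion over
trials.  The state is the 2-D movement aim (initialized at the target
centre) and the previous trial's binary outcome.  Per trial, the endpoint
is the aim plus motor noise (SD σ_M per axis, every trial) plus exploratory
noise (SD σ_E per axis) gated on the previous trial having missed.  Reward
is the deterministic, boundary-inclusive rectangle test against the target
(major extent 12 cm on the task-redundant y axis; minor width on the
task-relevant x axis).  The aim then updates by three processes per axis:
a reinforcement update (gain α, active only when a success follows a miss,
absorbing a fraction of the successful exploratory deviation), a correction
toward the previous aim (gain β^aim), and a correction toward the target
centre (gain β^target), the latter two acting only when positional error
feedback is available.

Feedback conditions force whole processes off rather than refit them:
reinforcement-only sets all β = 0, error-only sets all α = 0, combined
feedback leaves all gains active.  The outcome is computed from the
simulated endpoint in every condition — the gating of exploratory noise on
success applies even without explicit reward feedback, since a miss is
visible through the cursor.  The nine-model family shares the execution
equations; reduced variants fix specific β gains to zero (e.g. the variant
with no target-centre correction along the redundant axis removes
β^{target,y}).

Conventions the equations leave open, fixed here:

- **r₀ = 1**: the trial before the first is treated as a success, so trial 1
  carries no exploratory noise, consistent with the aim starting at the
  target centre.  Configurable per session.
- **Deviate order**: four standard normals per trial are always drawn in the
  order (motor-x, motor-y, explore-x, explore-y), whether or not the
  exploratory draws are used.  Gating therefore changes which values enter
  the recursion, never the stream itself, and the same seed yields aligned
  noise across conditions — condition contrasts are paired at the level of
  the random stream.
- **No carry-over**: each condition block starts from a fresh state
  (re-centred aim), standing in for the washout blocks between conditions.
- **Target width**: the minor width is 0.65 × the participant's baseline
  lateral SD.  Baseline blocks contain no exploration by construction, so
  the default applies the rule to the motor-noise SD directly
  (0.65 σ_{M,x}); an option instead estimates the SD from a simulated
  10-trial no-feedback baseline block, which adds realistic width
  variation across simulees.

The batched simulator is a numba kernel looping trials-outer /
individuals-inner; a test suite asserts exact (1e-12) agreement with a
naive pure-Python transcription of the update equations over 100 seeds.

## Reference parameters

The a priori cohort predictions use σ_M = (0.37, 0.49) cm,
σ_E = (0.38, 0.88) cm, α = (0.99, 0.99), β^aim = (0.15, 0.25),
β^target = (0.13, 0.01), with the Parkinson's-like group at α = (0.5, 0.5)
and everything else shared.  The recovery suites generate data from the
reduced best-fit variant (β^{target,y} = 0) with α_y = 0.79 (control)
vs 0.52 (reduced-gain group).

## Exploration metrics

Lag-1 autocorrelation of endpoints along one axis is the Pearson
correlation of the N−1 consecutive-trial pairs, each lagged copy
standardized by its own mean and SD — 199 pairs from a 200-trial block, 99
from a 100-trial block.  The classical one-mean autocovariance estimator is
available behind a flag for sensitivity checks; the two agree closely for
long series.  A constant series has no defined ACF and propagates as nan;
cohort cells average per-participant ACFs (unweighted), excluding undefined
ones.  Outcome-conditioned variability is the sample SD (n−1 denominator)
of consecutive-trial endpoint changes, classified by the outcome of the
earlier trial, never crossing block boundaries; classes with fewer than two
changes are reported absent, not zero.

## Fitting and model selection

Models are fit to cohort-mean ACF cells (axis × condition × group), not to
raw trials.  The objective regenerates a synthetic cohort per evaluation
from a fixed set of deviates (common random numbers derived from the
config seed), making the loss a deterministic function of the parameters;
the loss is the squared difference summed over cells, per experiment, and
experiments present sum into the total.  Optimization is bound-constrained
Powell (gains in [0, 1]; noise SDs bounded by the observed range of
participant variability) from random warm starts, the best polished and
then used to seed a participant-level bootstrap: participants are resampled
with replacement within experiment × group, cell means recomputed, and the
optimization restarted; reported parameters are per-parameter bootstrap
medians with 2.5/25/50/75/97.5 percentile intervals.

The two-group fit shares the four noise SDs between groups and gives each
group its own gain set in one joint optimization; each group receives its
own loss and information criteria, counting its free gains plus an equal
(half) share of the shared SDs.  Model selection fits the first two
experiment designs jointly (one combined score, n = 10 cells) and the
third design's groups separately (n = 6 cells each), sums each model's
AIC (2k + n ln L) and BIC (k ln n + n ln L) across scores, and ranks
ascending with ties going to fewer parameters.  Both n-accounting choices
are configurable; the criteria formulas require L > 0 and are refused, not
clamped, otherwise.

Numerical choices: the parameter count k and datapoint count n enter the
criteria exactly as above; Powell occasionally probes a hair outside the
box constraints and candidate vectors are clipped back before simulation;
the final parameter set is re-scored on a larger simulated cohort than the
one used during optimization (the protocol's 500-simulee "stable estimate"
size) when the two differ, which stabilizes the reported loss without
changing the optimization path.

Budgets: the full-scale profile uses 10,000 warm starts, 10,000 bootstrap
iterations, 500 simulated individuals per evaluation and 1,000,000 test
iterations.  The desk-scale profile (50/200/100, 10,000 test iterations) is
the default for interactive use.  The recovery test suites run smaller
still — a handful of warm starts with capped Powell evaluation budgets, 80
individuals per evaluation and 500 for final scoring — sizes chosen so the
replicated experiments (20 parameter-recovery fits, 10 nine-model
selections) run on a single desktop core in minutes.

## Statistical layer

Mean comparisons use a shift-null percentile bootstrap: both samples are
recentred to the pooled mean, rescaled by √(n/(n−1)) so resampled means
carry the correct sampling variance, resampled with replacement, and the
observed mean difference is compared against the resampled null
distribution (two-sided on |Δ|, one-sided on signed Δ for theory-driven
predictions).  Paired comparisons resample centred within-participant
difference scores.  P-values use the add-one rule (c+1)/(B+1).  A pooled
label-permutation test is available behind a flag.  Note the percentile
mean test is asymptotically a z-test: at very small per-group n its size
exceeds the nominal level slightly (the z-vs-t gap), which is why the
calibration suite evaluates size at the experiments' actual group size
(36 per group), where the measured type-I error is ≈0.056 at α = 0.05.
Common-language effect size is the percentage of cross-pairs favouring the
first sample, ties counting half; it is exact, symmetric and invariant to
joint monotone transforms.

## Synthetic cohorts

The generator emulates the three experiment designs: two conditions × 200
trials × 36 participants; three conditions × 200 trials × 36; and three
conditions × 100 trials with 12 controls plus 10 reduced-gain
(Parkinson's-like) participants.  Group structure, per-participant widths,
sub-seeds and counterbalanced condition order are recorded in a manifest;
datasets are pure functions of (design, config, seed).  Between-participant
parameter jitter (truncated to the parameter bounds) is available but
defaults to zero, matching the modelling assumption of constant parameters
across simulees.  Baseline and washout blocks are represented only by
their consequences (target width, state reset); raw baseline trials are
not emitted by default.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: reaction/movement times, kinematic
trajectories, fatigue or learning drift across blocks, aiming strategies,
medication state, and any between-participant heterogeneity beyond
optional parameter jitter.  Recovery results show the pipeline identifies
its own generating process at realistic sample sizes; they do not certify
the model against violations of its assumptions.

## Known limitations

- ACF-cell fitting discards within-participant detail; parameters weakly
  identified by cell means (notably the separate noise SDs) recover poorly
  even when gains recover well.
- Adjacent model variants can be near-degenerate at some parameter values
  (a small aim-correction gain on the minor axis is hard to distinguish
  from none), so model recovery is probabilistic, not certain — hence the
  replicated-majority criteria.
- The bootstrap test size is slightly above nominal for per-group n below
  ~10; use the permutation variant if exact size matters at such sizes.
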