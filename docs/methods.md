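# Methods

This note documents the models and procedures implemented in catglm,
the assumptions behind them, the defaults and why they were chosen,
and what the synthetic-data experiments do and do not establish.

## Category spaces and grid geometry

Stimuli live at integer grid coordinates (orientation index on x,
spatial-frequency index on y). All boundary geometry — angle, offset,
signed distance — is computed in these index units rather than in
degrees / cycles-per-degree, because orientations are spaced linearly
but spatial frequencies roughly logarithmically, and the behavioral
analyses bin choices by *steps* from the boundary. The angle
convention sets 0° to a boundary parallel to the spatial-frequency
axis (a pure-orientation rule), measured counter-clockwise; 45° weighs
both dimensions equally. Stimuli within 10⁻⁹ grid units of the
boundary line are excluded from the task; a 7×7 grid with a 45°
boundary through its center therefore yields 21 + 21 labeled stimuli
with 7 excluded. The reduced chronic-imaging space keeps, per side,
the n (default 5) labeled stimuli nearest the boundary, with
deterministic tie-breaking by grid position.

## Behavioral simulation

The agent picks "right" with probability
`lapse/2 + (1 − lapse)·σ(steepness·(d + side_bias))`, where d is the
signed grid distance to the agent's own planted boundary, σ the
logistic function, and `steepness = inf` a perfect step categorizer.
Misses occur with an independent per-trial probability (real mice miss
trials, but no rate model is implied; default 0.1 in demo configs, 0
in the agent default). Trial phases follow the head-fixed task: ITI
5 s, no-lick/no-run period 0.7 s, stimulus 1.5 s, delay 0.2 s,
response window 10 s. Stated jitters (e.g. "1.5 ± 0.1 s") are sampled
uniformly over ± the jitter; the jitter distribution is a modeling
choice exposed in `TimingConfig`. Response-lick latency is
0.3 s + Exp(0.5 s), truncated at 3 s, which keeps every trial's
response events inside the GLM's per-trial window (see below). Reward
coincides with the decisive lick on correct trials; a 2-s time-out
follows incorrect licks.

## Neural simulation

Each neuron owns nonnegative planted kernels — weight sequences over
the 0.5-s-spaced time offsets of each regressor set — and its clean
rate is exactly `design_matrix @ weights` in spikes/s, using the very
design construction the encoding model fits. This identity (verified
to < 10⁻⁹ in tests) anchors all recovery experiments: whatever the GLM
fails to recover is attributable to noise, penalty, or analysis
choices, never to a generator/model mismatch. On top of the clean
rate, trial-to-trial variability is a per-trial, per-neuron gamma-
distributed multiplicative gain (CV 0.2 by default — "Poisson-like"
reliability variation), plus rectified Gaussian frame noise
(sd 0.5 spikes/s) since inferred-spike traces are nonnegative and
roughly continuous; the result is clipped at zero. Default amplitudes
(planted kernel peaks ~2–5 spikes/s over a ~0.2 spikes/s baseline)
match the scale of deconvolved calcium signals at ~15 Hz.

Covariates are generated consistently with the trial events: running
speed as sinusoidal bouts after each trial's run onset plus AR(1)
noise, rectified; per-spout lick rates as bouts spanning each trial's
choice-lick to post-reward period on the chosen side, smoothed, plus
AR(1) noise. This makes the movement regressors genuinely (and
realistically) correlated with choice and reward — a deliberate
property, since disentangling exactly such correlated influences is
the encoding model's job.

Raw fluorescence rendering convolves spikes with an exponential
calcium kernel (τ = 0.7 s), adds `contamination ×` a slowly varying
neuropil trace, pairs the result with a constant structural channel,
and applies a shared multiplicative sinusoidal drift to all traces.

## Signal conditioning

Neuropil correction subtracts 0.7 × the neuropil trace and adds back
the median of the scaled neuropil so baselines stay positive. The
add-back is a constant: the correction is exactly linear only up to
that offset, and drift cancellation is therefore a property of the
*channel ratio*, not of the corrected trace. ΔR/R divides the
activity channel by the structural channel, then references each
frame's ratio R to R₀, the mean of the lowest 25% of R values in a
60-s window centered on the frame (windows truncated at the trace
edges, no padding). "Mean of the lower quartile" rather than a single
percentile is a deliberate robustness choice and is configurable.

## Exact tests and bootstrap

With group sizes routinely below ten, both rank tests use exact nulls:
the Wilcoxon signed-rank test enumerates all 2ⁿ sign assignments
(n ≤ 25; zero differences dropped, mid-ranks for ties, half-unit rank
lattice handled exactly), and the Mann–Whitney U test uses the classic
counting recursion over all C(n_a+n_b, n_a) arrangements
(n_a + n_b ≤ 20, no ties). Beyond those sizes, tie-corrected normal
approximations with continuity correction take over. Both match
brute-force enumeration for all n ≤ 10 in the test suite. The
bootstrap for means is the percentile method, default 1000 resamples;
its ~95% coverage is verified at n = 100 per dataset (percentile
intervals undercover for very small samples — a known property, not a
defect of the implementation).

## Responsiveness

A neuron is responsive to a stimulus when (1) the Mann–Whitney U test
comparing per-trial mean rates in the 1 s before vs. after stimulus
onset is significant at P < 0.05, and (2) the trial-averaged
post-onset trace peaks at least 0.01 above the mean pre-onset rate.
The 0.01 threshold is applied in spikes/s by default (configurable to
per-frame; the native units of the criterion are a genuinely open
choice). Because detection power grows with trial count, in-task
sessions draw 8 trials per stimulus without replacement, apply the
criteria, and repeat 100 times; the per-neuron probability of ≥ 1
significant stimulus is directly comparable to out-of-task sessions
with their fixed 8 repeats, and the session's responsive fraction is
the mean of these probabilities (an identity asserted in tests).

Chronic time courses (rows = recordings, columns = labeled time
points TC1, TC2, task_bs, [task_bs2,] task_learned, TC_final) are
min–max normalized per row (constant rows carry no shape and are set
flat), clustered by k-means (Euclidean, best of 20 restarts) for
k = 2…8, and the selected k maximizes Δinertia = mean inertia of 100
per-row-shuffled datasets − real inertia. The four-component model
regresses a time course on base ≡ 1, decay = 2^−index (indexed over
imaging time points, not calendar days), an in-task indicator and a
post-learning indicator, by NNLS; per-component ΔR² refits 100 times
with that component's values permuted across time points (base, the
intercept, cannot be shuffled). Zero-variance targets report R² = 1
with a flag; label sets that collapse the design (e.g. all-in-task)
warn and flag the weights as a pseudo-solution.

## Encoding model

**Design.** Discrete events (stimulus onset, choice-lick sequences,
response-window lick, reward, time-out, run onset) become unit-area
Gaussian kernels (σ = 0.5 s, truncated at ±3σ) evaluated at the exact
event times, one column per (level, offset) with offsets spaced 0.5 s
over each set's range: stimulus-aligned sets (orientation level,
spatial-frequency level, category side, task/response-made) 0…+3 s;
choice and reward/time-out sets −0.5…+2.5 s; run onset −0.5…+2 s.
Continuous channels (running speed, per-spout lick rates) are smoothed
with the same kernel (unit-sum, amplitude preserving) and shifted over
−1…+1 s. A constant column completes the matrix. These ranges are
configurable defaults. Derived levels with no events (e.g. a "miss"
choice level) are dropped. The response is smoothed with the same
centered Gaussian; on synthetic sessions, whose rates already carry
the Gaussian-basis profile, this widens recovered kernels slightly
(median planted-vs-fitted correlation 0.87 at defaults vs. 0.99 with
smoothing off) — both settings are exposed.

**Frame inclusion.** Fitting uses equal-length, non-overlapping
windows of −1.5…+5.5 s around each stimulus onset. Equal lengths make
trial-level cross-validation, trial-identity shuffles and per-trial
Gram caching exactly defined; the window covers every discrete kernel
range at typical response latencies, and late tails of very slow
trials fall outside the fit rather than being modeled.

**Fit.** λ = 0.01 × Σy_train. The penalty is proportional to the
response's total mass, making the estimator equivariant to the
arbitrary amplitude units of deconvolved spikes; the scale 0.01 sits
at the optimum of the train-vs-cross-validated R² calibration curve on
default synthetic sessions (the same calibration procedure the task
pipeline prescribes for choosing the penalty), and a per-sample mode
(λ ∝ N) is available. The nonnegative QP is solved exactly:
G = XᵀX + εI (ε = 10⁻¹⁰ · trace-scale) is Cholesky-factored and the
problem handed to Lawson–Hanson NNLS; the solution matches exhaustive
active-set enumeration to 10⁻⁶ on small designs (oracle test).

**Significance.** The real and a shuffled model are each fitted over
100 cross-validation repeats; the shuffle permutes the assignment of
per-trial response windows to per-trial design windows — preserving
within-trial temporal structure — with a fresh permutation per repeat,
so the shuffled R² distribution carries permutation variance. A
neuron is significant iff the mean shuffled R² lies below the 2.5th
percentile of the real R² values *and* the mean real R² lies above the
97.5th percentile of the shuffled values. The percentile-of-values
interval is deliberate: cross-validation repeats of the same data are
strongly dependent, and a bootstrap CI of their mean ignores the
data-realization variance — measured on 100 pure-noise neurons it
flags ~20% false positives, while the value-interval rule flags 0 of
100 with full power on planted neurons. The mean-CI variant is kept
as an option for comparison.

**Unique contributions.** ΔR²(subgroup) = mean cross-validated R² of
the full model − mean with that subgroup's columns permuted across
trials (fresh permutation per repeat). The shuffled Gram is assembled
from cached blocks (unshuffled block, permuted-trial block) plus a
fresh cross block — algebraically identical to shuffling the design,
verified against the brute-force product. Null calibration: across
subgroups with zero planted weight, the 95th percentile of |ΔR²| is
~0.01 at the default session scale.

**Collinearity (VIF).** Sets within one trial epoch are redundant *by
construction*: every trial carries exactly one orientation, one
spatial frequency and one category, so complete one-hot sets obey
exact sum constraints; a staircase boundary additionally makes the
category indicator additively separable into orientation + SF
indicators; and the decisive lick *is* the reward/time-out moment, so
choice₂ = reward + timeout exactly. The textbook
regress-on-all-other-columns VIF is therefore infinite on this design
family regardless of the data. The default diagnostic instead
regresses each kernel column of the named subgroups on all columns of
sets from *other trial epochs* (stimulus-locked vs. response-locked
vs. locomotion) — the scientifically relevant confounding question —
and yields maxima of ~3 on default sessions, comfortably below the
conventional threshold of 5. The literal pools (within_set,
across_sets, all) remain available and expose the structural
infinities explicitly.

**Classification.** With matched neurons at an in-task baseline and a
post-learning time point, significance at (both / learned only /
baseline only / neither) maps to stable / gained / lost / never, and
the changed:stable ratio is (gained + lost) / stable.

## Category tuning indices

Semantic CTI contrasts the mean left- vs. right-category kernel
weights; feature CTI aggregates, over the active task stimuli, each
stimulus' orientation-level and SF-level mean weights by category
membership; ΔCTI = semantic − feature. Weights are averaged across
cross-validation repeats first, then across offsets within a set.
Nonnegativity bounds all indices in [−1, 1]. Choice selectivity is
|w̄_choiceL − w̄_choiceR| / (w̄_choiceL + w̄_choiceR), averaged over both
choice-set definitions (lick-sequence and decisive-lick aligned); the
signed variant is exposed. Because these are scale-free ratios, a
leak of < 1% of a neuron's weight mass into an otherwise-unused kernel
family can swing the ratio to ±1; in the bundled `cti_result`, an
index whose denominator is below 5% of the neuron's combined
category + feature weight mass is taken at its no-tuning limit of 0,
while the individual index functions keep the strict
zero-denominator → invalid contract. The indices are side-signed
(relabeling left↔right negates semantic and feature CTI alike), so
ΔCTI of a right-preferring feature-tuned neuron whose semantic
denominator is negligible should be interpreted with care — the
sign convention is only unambiguous when semantic and feature
contrasts share a side or when pooling |ΔCTI|.

## What the generator does and does not emulate

It emulates: the task's trial structure and timing jitter; boundary-
governed choices with lapse, bias and misses; kernel-based neural
coupling to stimulus, category, choice, reward and movement with
realistic cross-correlations between covariates and events;
nonnegative, noisy, trial-variable inferred-spike traces;
contaminated, drifting two-channel fluorescence. It does not emulate:
pixel-level movies or ROI segmentation; spike-inference artifacts
beyond kernel convolution (the FOOPSI step is upstream of this
package's inputs); adaptation or learning *within* a session;
correlated noise across neurons; eye or pupil dynamics. Passing
recovery tests on this generator therefore demonstrates the analysis
chain is correct and calibrated under its stated assumptions — not
that those assumptions exhaust real cortical data.

## Problem sizes and determinism

Synthetic validation uses sessions of 60–300 trials with the
10-stimulus reduced space at 15 Hz — enough that every stimulus
collects tens of trials, matching the design logic of the reduced
space — with 100 pure-noise neurons for calibration and 20 mixed
archetypes for recovery; behavioral boundary recovery uses 10⁴-trial
simulations of the full 7×7 space. Every random step flows through an
explicit seed (NumPy `SeedSequence` spawning per stage), and identical
seeds reproduce sessions byte-for-byte; the pipeline manifest records
config, seeds, package version and per-stage timings so any number in
a results bundle can be regenerated.
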