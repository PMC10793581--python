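# Methods

## The task and the coordinate system

All times are milliseconds from fixation onset on a single trial clock:
fixation 0–500, sample 500–1000, delay 1000–2500, test onset at 2500 with the
stimulus visible until the response or for at most 500 ms.  Reaction time
(RT) is measured from test onset; response-aligned analyses place 0 at
`2500 + rt`.  Recording of a trial extends to
`2500 + max(test_max, rt + 200)` ms, so analyses up to 3000 ms (stimulus
clock) and short post-response windows are always covered.

## Generative model of a session

Each of the 32 channels is an inhomogeneous Poisson process with rate

```
r_c(t) = baseline
       + stim_gain[c, shown(t)] · 1{stimulus on screen, shifted by visual latency}
       + sign(choice) · decision_gain · d_c · ramp(t)
```

clipped at zero.  `shown(t)` is the sample or test stimulus; tuning follows
stimulus onset and offset with a common visual latency.  The choice signal is
additive along a fixed unit population vector `d`, switches on
`decision_latency` after test onset with a linear rise of `decision_ramp`,
and off at the response; its sign follows the *choice* (forward = +), so on
error trials it is inverted relative to the match/nonmatch trial type.  A
config switch (`signal_follows="trial_type"`) instead ties the sign to the
physical trial type — the control condition in which a correct-trained
decoder *generalizes* to error trials.

Spike times are drawn by thinning: per-channel homogeneous candidates at the
rate ceiling, accepted with probability `r_c(t)/ceiling`.  Configs whose
worst-case clipped time mass exceeds 1% of channel-time are rejected with a
diagnostic rather than silently distorting rates.

**Trial labels are counterbalanced, not i.i.d.**  Match/nonmatch counts
follow `p_match` deterministically and stimulus pairs are balanced within
each trial type, as in the behavioral protocol (trial counts
pseudo-randomized to be equal).  Errors are likewise spread uniformly over
stimulus-pair cells.  This matters at desk scale: with i.i.d. labels the
correct-trial subset acquires chance correlations between trial type and
test-stimulus identity, and the strong stimulus signal then leaks into the
choice decoder — precisely the "stimulus-type cue" confound the
correct→error analysis exists to rule out.  The generator removes it by
design; real sessions approximate this by their much larger trial counts.

**Default study conditions** (chosen once, on task statistics and V1 MUA
plausibility): baseline 10 sp/s; one preferred stimulus per channel with
amplitude ~U(6, 10) sp/s, giving near-ceiling (>90%) 3-class stimulus
decoding at n ≈ 600 correct trials; visual latency 50 ms; decision gain
5 sp/s (choice decodability ~0.65–0.70, i.e. present but far from ceiling,
as expected for an early sensory area); decision latency 150 ms, ramp
100 ms; decision direction at 90° to the stimulus-contrast span (separate
subspaces); error rate 0.2; RT truncated-normal(600, 150) ms, matching
session-mean RTs of 500–650 ms.  `p_match = 0.5`.

What the generator does **not** emulate: spike-sorting artifacts,
inter-channel noise correlations, firing-rate adaptation, slow drifts,
eye-movement variability, stimulus-difficulty-dependent errors.  Passing
tests therefore demonstrate correctness of the *estimators* under a
known-truth Poisson world, not robustness to every property of real
recordings — in particular, correlated noise would lower effective decoding
performance and widen all recovery error bars.

## Binning

Causal windows `(t − w, t]`, labeled by the right edge, half-open so a spike
at exactly the label time counts once and disjoint windows (step = window)
conserve counts exactly.  Bin labels run from `t_start + w` to `t_stop` on
the session clock.  Rates are counts / w in spikes/s.  Spikes from trials
not present in the supplied trial table (e.g. excluded error trials) are
dropped.  Spike detection for raw traces thresholds |signal| at 4× the SD of
the whole (bandpassed) trace with a refractory dead time; a MAD-based
`robust` option exists but is off by default, matching the plain
standard-deviation convention.

## Decoding

LDA with pooled within-class covariance shrunk toward its diagonal,
`Σ λ = (1−λ)S + λ·diag(S)`, λ = 0.1 by default — 32 channels against
~20–30 training trials per class per fold makes some regularization
necessary; λ = 0 is available and used in tests against closed forms.
Priors are empirical class frequencies.  Exact score ties break toward the
lowest class label.  Cross-validation is one stratified 20-fold partition
(reduced with a warning when the smallest class is smaller); "20 repeated
stratified sampling (20 folds)" is read as one 20-fold CV, with an
`n_repeats` knob for the alternative reading.  Only correct trials enter
decoding by default.

Interpolation uses natural cubic splines per session *before* averaging
(2-ms default grid).  The chance-crossing latency estimator returns the
first post-test-onset time at which the session-mean interpolated curve
exceeds chance and stays above it for a persistence window.  The default
persistence is 50 ms; **for few-session curves 150 ms (the window length) is
the better choice and is what the recovery analyses use**, because
cross-validated accuracies at neighboring bins share ~14/15 of their window
and trials, so pure-noise excursions above chance persist for up to a window
length, while true signal persists indefinitely.  When quantifying recovery
of an injected latency, the natural ground truth is the half-amplitude point
of the 100-ms linear rise (injected latency + 50 ms): a ramped signal has no
single "onset" visible to a crossing detector, and the half-rise point is
the standard latency convention for such signals.  Under the default
conditions (3 sessions × 900 trials per estimate, 10-ms steps) recovered
latencies match that target with median absolute error well under 60 ms
across injected latencies of 100–400 ms.

The cross-condition test takes the rate vector of the causal window ending
at 2900 ms, excludes trials with RT < 400 ms (their response precedes that
window, so the choice signal is already off), trains on correct trials
within each CV step and evaluates the same decoder on all retained error
trials.  Below-0.5 transfer accuracy, mirroring the held-out correct
accuracy about 0.5, is the choice-coding signature.

## Subspaces

`fit_discriminant_subspace` returns the leading generalized eigenvectors of
(between-class scatter, within-class scatter), unit-normed, eigenvalue
ordered, sign fixed by the largest-magnitude entry.  `build_subspace_model`
fits the 2-D stimulus projection (test-stimulus labels) and the 1-D decision
axis (match/nonmatch labels) from the same correct-trial rate vectors at the
reference time (default 2700 ms), warning when the requested time is off the
bin grid or when match/nonmatch separability there is statistically at
chance.  Projections of trajectories (trials × bins × 3) and
condition-averaged traces (3 stimuli × 2 lever directions) support the
state-space view; silhouette scores (Euclidean, singleton classes scored 0
with a warning) quantify "clear clustering" vs "complete overlap".

**Raw LDA axes systematically exaggerate subspace orthogonality.**  The
within-class scatter of the match/nonmatch fit contains the (large)
between-stimulus variance, so the generalized eigenproblem down-weights
exactly the directions inside the stimulus span: with the default tuning
strength, a decision direction injected at 30° is "recovered" at ~80° by the
raw fit.  Sampling noise adds a second bias: the estimated axis carries a
noise component in all 32 dimensions, dragging the measured angle toward
that of a random vector (~80° against a 2-D span).  `estimate_decision_angle`
corrects both: (i) within-class scatter is pooled within
(stimulus × trial type) cells for the span fit, so neither signal
contaminates it; (ii) the decision axis is the cell-balanced match−nonmatch
mean difference; (iii) the sampling covariance of that mean difference is
subtracted from both the in-span and the total energy of the axis (a
classical attenuation correction), with rate vectors averaged over the
2750–2900 ms bins to raise the integration time.  Energies can be pooled
across sessions before taking the ratio, which stabilizes angles near 90°
where the corrected in-span energy fluctuates around zero.  With 5 sessions
of 600 trials, injected angles of 30/60/90° are recovered within a few
degrees.  The raw-fit bias is worth remembering when interpreting claimed
orthogonality of coding subspaces in real data.

## Numerical and interface choices

* Degenerate LDA inputs: singular pooled covariance at λ = 0 raises with
  advice to use shrinkage; constant features under λ > 0 fall back to a
  vanishing ridge so the classifier reduces to its priors.
* A constant (zero-variance) trace is rejected by spike detection rather
  than returning an empty event list — with SD = 0 every sample "crosses"
  a zero threshold, so no sensible event set exists.
* Interpolated curves may overshoot [0, 1] slightly (cubic splines);
  overshoot is reported as-is rather than clipped.
* On-disk formats: CSV directory (events, trials, meta.json) and single-file
  HDF5, round-tripping bit-identically at 1-µs time resolution; simulation
  configs as JSON (TOML accepted on read — the standard library reads but
  does not write TOML).
* Full-pipeline runs are deterministic given (config, seed); every summary
  is stamped with the config hash, seed and package version.
* Scale choices in tests: recovery experiments use 3–5 sessions of 600–900
  trials — enough that estimator error, not generator noise, dominates the
  comparison — and the permutation null uses 100 relabelings of a balanced
  trial subset (balancing makes the nominal 1/k chance level exact; with
  unequal class counts an empirical-prior decoder converges to the majority
  proportion instead).

## Known limitations

* Poisson spiking with independent channels; no noise correlations, so
  absolute decoding accuracies are optimistic relative to real populations
  of this size.
* The latency estimator is a crossing detector: it inherits a positive
  detection delay that shrinks with sessions/trials but never fully
  disappears; compare latencies across conditions measured at the same
  noise level.
* The additive choice-signal model is one of several plausible forms
  (multiplicative/gain-like alternatives are not implemented).
* Subspace fits at a single 150-ms window are noisy; the noise-corrected
  angle estimator addresses the measurement, not the fit — the
  `SubspaceModel` used for visualization still carries the raw-LDA biases
  described above.
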