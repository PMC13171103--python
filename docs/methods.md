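# Methods

`setshift` re-implements, as a tested pipeline, a population analysis of
medial-prefrontal-cortex (mPFC) calcium imaging during attentional set
shifting: single-neuron ROC tuning, PCA state-trajectory geometry, hidden
Markov model (HMM) decoding of behavioral states, and logistic decoding of
trial outcomes. Because the recordings the analysis was designed for are
not public, the package ships a synthetic-session generator that emulates
their statistical structure; every stage runs end-to-end on generated
cohorts. This note documents the models, the generator, the numerical
choices, and what passing tests do and do not establish.

## Task and behavioral model

A session is one extra-dimensional-shift (EDS) stage of the attentional
set-shifting task. The animal digs in one of two bowls on each trial
(outcome correct/incorrect) and finishes when it digs correctly six times
consecutively, having also withheld digging in the unrewarded bowl
("correct rejection") at least twice. The session splits into an **early**
(trial-and-error) state and a **late** (rule-following) state defined as
the maximal terminal run of consecutive correct trials; the **switch
point** is the first late trial. `trials_to_criterion` counts all trials
through the first trial at which both criterion conditions hold, so it is
at least 6 whenever it is defined.

The generator draws the early-block length as `min_early_trials` plus a
geometric excess (means chosen so control sessions average ~18 trials and
test sessions ~26, matching the published trials-to-criterion scale), fills
it with Bernoulli(`p_correct_early` = 0.5) outcomes, and appends six
correct trials. Early blocks are resampled until (i) they contain no
correct run of six (such a session would already have ended) and (ii) the
final early trial is an error (otherwise the terminal run would absorb the
end of the early block and the planted switch would not be recoverable
from behavior). The Monte-Carlo calibration test therefore compares
against an oracle that replicates both rejection rules, not against the
unconditional binomial. Choice times are spaced `inter_choice_interval`
(14 s) ± 1 s of uniform jitter, which keeps the ±5 s analysis windows of
consecutive trials disjoint.

## Fluorescence model

Traces are simulated at 20 Hz in z-scorable units. Each neuron is the sum
of:

1. **Baseline noise** — i.i.d. Gaussian, `noise_sd` = 2 per sample. The
   analyses use 5 s window means (100 samples), so the private noise of a
   window mean is `noise_sd`/10.
2. **Tuned drives** — boxcar drives over the 5 s before each choice on
   which the neuron's variable takes its preferred condition, with random
   preferred sign per neuron and variable. Choice neurons follow the
   upcoming outcome, history neurons the previous trial's outcome (the
   first trial carries no history drive), and switch neurons the neural
   state (below). Amplitudes are `effect_size` for choice/history and
   `effect_size * separation_scale` for switch.
3. **A shared peri-choice response** — three smooth temporal motifs over
   the ±5 s around every choice with Gaussian per-neuron loadings
   (`event_gain` = 1.4). Real event-locked population activity is
   low-rank; without this component a six-component PCA of trial-averaged
   trajectories could not reach the ~80%+ explained variance the analysis
   presumes. Because the response repeats identically on (almost) every
   trial, it is information-free for every trial-wise contrast.
4. **State-dependent remapping** — switch-tuned neurons use different
   motif loadings in the neural-early and neural-late states, correlated
   at `state_motif_corr`. Control populations remap fully (corr 0.0), so
   their early/late trajectories decorrelate; test populations barely
   remap (corr 0.9), leaving the two state vectors similar. This carries
   the group effect on trajectory distance and vector similarity.
5. **Shared gain fluctuations** — each phasic drive (choice, history) is
   multiplied per trial by `1 + ξ`, with ξ drawn once per trial per
   variable and shared across neurons (`shared_gain_sd`: control 0.15,
   test 0.85). Being common across neurons, this noise lies along the
   population coding axes and caps population decodability at roughly
   `√2 / shared_gain_sd` regardless of population size, while single-neuron
   discriminability degrades far less. This is the mechanism by which the
   test group has *more* responsive neurons yet *worse* population
   decoding; with independent noise only, larger tuned fractions would
   make the test group decode better. The two variables get independent
   streams: with a single shared stream a linear readout can estimate the
   gain from history-tuned neurons and cancel it.

All drives and motifs are convolved with a difference-of-exponentials
calcium kernel, `exp(-t/τ_d) − exp(-t/τ_r)` (τ_r = 0.1 s, τ_d = 0.5 s,
GCaMP6f-like). For drive convolution the kernel is normalized to unit
discrete sum so a sustained drive keeps its plateau amplitude in z-units;
the unit-peak form is available as the impulse response (used when
injecting synthetic transients).

**Neural lead.** The neural state transition precedes the behavioral
switch point by `neural_lead_trials` (control 3, test 7): rule acquisition
shows in population activity before performance reaches criterion, and the
longer lag under LC inhibition is what makes the decoded switch point more
negative in the test group. Lead trials carry `lead_drive_fraction` = 0.75
of the full switch drive — rule acquisition is gradual — so lead trials
still cluster with the late state in the HMM while remaining separable
from late trials in the ROC contrast (at fraction 1.0 they tie with late
trials and put a hard ceiling on the early-vs-late AUC).

**Tuning assignment.** Each neuron draws each variable independently at the
configured `tuning_fractions` (control ≈ 10/6/17%, test ≈ 17/13/25% for
choice/history/switch, following the published responsive fractions);
singly tuned neurons gain one extra variable with probability
`mixed_tuning_rate` (control 0.10, test 0.22) so mixed selectivity is more
common in the test group. Ground truth is stored per session.

**Group presets.** `GeneratorConfig.preset("control"/"test")` fixes the
study conditions: 100 neurons per session (scaled down from the reported
128 ± 31), four sessions per group in a default cohort, and the group
differences above. The test preset also has a higher `effect_size`
(0.55 vs 0.45): LC inhibition enhances engagement — responses are
amplified but noisier — and a weaker-amplitude variant makes the planted
tuned fractions undetectable, inverting the intended group effect on
responsive fractions. `min_early_trials` is 12 for the test group
(LC-inhibited mice never switch quickly), which also guarantees the neural
lead fits inside the early block.

## Single-neuron tuning

Traces are z-scored per neuron over the whole session (sample SD, n−1).
For each neuron the per-trial mean over the (−5, 0] s pre-choice window in
50 ms bins feeds three two-class contrasts: switch (behavioral early vs
late), history (previous trial correct vs incorrect; trial 1 dropped), and
choice (upcoming outcome). Discriminability is the rank-based AUC (ties
count ½). Significance is a two-sided label-permutation test on
|AUC − 0.5| with add-one correction, p = (1 + #{|AUC* − ½| ≥ |AUC − ½|}) /
(n_perm + 1), n_perm = 1000 by default; the same uniform permutation is
applied to all neurons of a session. A contrast whose smaller class has
fewer than two trials is unclassifiable (NaN, not responsive). Neurons
with p < 0.05 are responsive; responsive to ≥ 2 variables is mixed. No
multiple-testing correction is applied across neurons or contrasts — the
tabulated quantities are raw-alpha responsive fractions, so ~5% of truly
untuned neurons are expected to flag per contrast, and because state and
outcome are correlated by task design (the late state is all-correct),
neurons tuned to one variable can flag another. Pooled group fractions are
therefore biased upward relative to the planted probabilities; the
package's tests treat the *direction* of group differences as the reliable
readout, not the absolute fractions. Group comparisons use Pearson
chi-squared on 2×2 tables, df = 1, no continuity correction.

## Population geometry

Early and late state trajectories are trial-averaged z-scored activity in
50 ms bins over (−5, +5) s around the choice (200 bins), computed per
session and stacked neuron-wise across a group's sessions on the common
choice-relative grid. Per bootstrap iteration (20 by default) a random 80%
of neurons is drawn (shared by both states), each neuron's trajectory is
smoothed with a Gaussian kernel (σ = 150 ms, truncated at 3σ), and PCA is
fitted jointly on the row-concatenation of both state matrices (centered
per neuron) so both trajectories live in one space; the leading six
components are kept (fewer if the subset is smaller, with a warning).
Metrics: the per-bin Euclidean distance across retained components, its
mean and maximum over bins with centers in (−5, 0) ("pre-choice mean" and
"peak"), and the vector similarity — the unweighted mean over retained
components of the Pearson correlation between the two states' per-PC time
series (zero-variance series are excluded). Bootstrap iterations are
treated as samples when groups are compared, which is pseudo-replication;
the report labels the dispersion accordingly.

## HMM state decoding

Per trial the feature is the 5 s pre-choice window mean per neuron
(segmenting into 50 ms bins and averaging collapses to this), for a random
40% of neurons, reduced to 3 principal components (matching the outcome
decoder's predictor count; exposed in config). Sessions are balanced to 31
trials by drawing the missing count of source-trial indices with
replacement and sorting, which keeps duplicates adjacent to their source
and preserves the single early→late transition. K-means (10 Lloyd
restarts, best within-cluster SS, empty-cluster re-seeding) initializes a
2-state diagonal-covariance Gaussian HMM: emission means/variances from
the hard assignment, transitions from Laplace-smoothed consecutive-label
counts. Baum-Welch runs on a random 90% of trials (chronological order
preserved), entirely in log space (no underflow for any practical length),
with a 1e-6 variance floor, max 100 iterations, and stops when the
log-likelihood gain falls below 1e-4; the likelihood trace is recorded and
is non-decreasing. Viterbi decodes the full sequence in log space (ties
break to the lower state index) so held-out trials keep temporal context.

Hidden states map to early/late by **relative** overlap with the
behavioral labels on training trials: the state with the greater
late-trial fraction becomes late. An absolute majority rule would map both
states to early whenever the neural lead exceeds the six-trial terminal
run — exactly the regime of interest. Ties go to the state occupying later
sequence positions; a state absent from training takes the complement of
the present one's majority. Scores: state accuracy against behavioral
labels over all balanced positions and over the held-out 10%, and
Δ switch = (source trial of the first position of the terminal
predicted-late run) − (behavioral switch point). Iterations whose decoded
sequence ends in the early state have no terminal late run: accuracy is
still recorded, Δ switch is undefined, and the iteration counts toward the
reported failure rate; k-means/EM failures invalidate the iteration
entirely. The protocol repeats over bootstrap iterations (1000 in the full
protocol; the desk default is 200).

Because the generator ties the neural transition to the behavioral switch
minus the planted lead, the decoded Δ switch centers near −3 (control) and
−7 (test), and state accuracy is limited mainly by the lead itself —
mirroring the phenomenology the analysis was designed to quantify.

## Outcome (choice) decoding

Same subsampling, balancing, and PCA-to-3 protocol; the PCA is refit per
neuron subsample. A logistic model predicts the trial outcome from the
three components: penalized Bernoulli log-likelihood, L2 = 1e-3 on the
non-intercept weights (guarantees existence/uniqueness on separable
bootstrap samples), Newton/IRLS with backtracking so the penalized
log-likelihood is non-decreasing, gradient tolerance 1e-8. The 90/10 split
is stratified by outcome; iterations where a side of the split would be
single-class are invalid and reported in the failure rate. Probabilities
strictly above 0.5 predict "correct"; exactly 0.5 maps to "incorrect"
(zero-measure, fixed for determinism). Note that outcome and state are not
orthogonal readouts: late trials are all correct by definition, and the
test suite asserts that correlation rather than treating the two decoders
as independent.

## Group statistics and pipeline

`compare_groups` follows one decision rule: two-tailed Wilcoxon rank-sum
(normal approximation with tie correction, no continuity correction,
reporting the first sample's rank sum) when both samples have n > 7,
otherwise a two-tailed pooled-variance t-test (the rule is keyed to
min(n1, n2); the boundary case is ambiguous in common usage and this
choice is documented here). No continuity correction is applied so that
identical samples give p = 1 exactly.

`run_pipeline` simulates a cohort (default 4 + 4 sessions), then runs
labeling, tuning (with pooled fraction tables and chi-squared
comparisons), geometry, and both decoders, and assembles a versioned
`report.json`. All randomness derives from the master seed through
`numpy.random.SeedSequence` spawning, so a rerun with the same seed is
byte-identical; stage wall-times go to the logger, not the report. Desk
problem sizes — 100 neurons/session, 4 sessions/group, 200 decoder
iterations, 1000 permutations — are the package defaults chosen to keep a
full cohort analysis under a minute while leaving every effect detectable;
the full-protocol values (1000 iterations) are plain config changes.

## What the synthetic tests do and do not show

Passing tests establish that each algorithm implements its contract
(exact oracles for Viterbi, AUC, chi-squared, distances), that the
estimators are calibrated under the null, and that the pipeline recovers
planted effects in the direction and ordering the generator encodes. They
do not validate the biological claims: the generator's drives are boxcars,
its noise is Gaussian (i.i.d. privately plus low-rank shared terms), its
transients are kernel-shaped, and real mPFC data have richer temporal
statistics, non-Gaussian noise, and unknown tuning geometry. Absolute
values of distances, similarities, and accuracies are properties of the
generator configuration, not of cortex. The planted group differences
(fractions, amplitudes, gain noise, remapping, lead) were chosen so the
qualitative orderings match the phenomenon under study; only those
orderings, never the printed values of the original recordings, are
asserted.

## Known limitations

- Transient detection (threshold 2.0 z on / 0.5 z off, FWHM duration) is a
  package choice; whether duration should be supra-threshold time instead
  of FWHM is a sensitivity the API exposes via thresholds.
- The responsive-fraction tables inherit the raw-alpha inflation and
  cross-contrast contamination discussed above; planted-vs-measured
  agreement is approximate by construction.
- With 50 ms bins at 20 Hz each bin holds exactly one sample; the binning
  code supports coarser bins but not super-resolution.
- The 2-state HMM is fixed; no model selection over the state count.
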