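# Methods

`seqdisc` implements the behavioral and neural-population analyses of a
head-fixed GO/NOGO tactile sequence-discrimination experiment, together with a
synthetic-data generator that provides ground truth for every stage.  This
note documents the models, the parameters that matter, the numerical choices,
and what the synthetic validation does and does not establish.

## Task model

A trial presents a four-segment vibration "word" for 550 ms, followed by a
1.5 s response window.  The GO and NOGO sequences share their first and last
segments and swap the two central ones, so the earliest time at which they can
be distinguished is the end of the first segment — 100 ms after onset by
default.  Outcomes follow signal-detection conventions: a lick in the response
window is a HIT on GO and a false alarm (FA) on NOGO; withholding is a MISS on
GO and a correct rejection (CR) on NOGO.  Licks during the stimulus period are
neither rewarded nor punished and never set the outcome; `parse_outcomes`
recomputes outcomes from licks so that synthetic and recorded logs share one
code path.

## Behavioral statistics

**Percent correct.**  The sliding 50-trial performance measure is balanced
accuracy, `100 × ½ (hit rate + CR rate)`.  This is the natural reading of a
percent-correct metric "corrected for the proportions of GO and NOGO trials":
it puts chance at 50% for any GO fraction, which is the property the
70%-criterion usage requires.  Windows lacking either trial type yield NaN.

**d′** is `z(HR) − z(FAR)` with rates clipped to `[1/2n, 1 − 1/2n]` (n = the
relevant trial count) so perfect sessions remain finite.

**Lick PSTHs** use 100 ms bins from stimulus onset to the end of the response
window, averaged separately over HIT and FA trials.  With
`include_acausal=False`, licks earlier than the divergence time — necessarily
blind to trial identity — are dropped first.

**Discriminative lick latency (DLL).**  The DLL is the first 100 ms bin at
which the HIT-minus-FA lick-rate difference curve rises above a resampled 95%
confidence limit; it upper-bounds the session's mean decision time.  The
threshold is calibrated *family-wise over the whole trial*: for each of 50
resampled sets the HIT/FA trial labels are permuted at fixed group sizes, the
difference curve recomputed, and its maximum over bins retained; the threshold
is the 95th percentile (upper order statistic) of these maxima, and the
crossing must persist for two consecutive bins.  Under identical GO and NOGO
lick processes a crossing anywhere in the trial is therefore a well-below-5%
event per session, which is what makes "UNDEFINED" the correct null answer.
We considered the alternative of pooling subsampled half-split difference
values across bins and thresholding at their 95th percentile (kept as
`dll_threshold_mode="pooled"`); with a genuine rate step, that pooled quantile
sits *above* the plateau of the full-data curve (the pooled mass is dominated
by post-divergence bins), so strong effects paradoxically return UNDEFINED,
and under the null it behaves like a pointwise 5% limit tested at ~20 bins.
The permutation-maximum construction avoids both failure modes.  Sessions
need at least 10 HIT and 10 FA trials; with ~20 FA trials the family-wise
threshold is conservative and short sessions often return UNDEFINED — the
estimator is designed to favour "no call" over a false latency.

**DLL variance partition** is a plain sum-of-squares decomposition across
mice: `between = Σ n_g (ȳ_g − ȳ)² / Σ (y − ȳ)²`, `within = 1 − between`.

## Fluorescence processing

Neuropil contamination is removed as `F = F_raw − α·F_neuropil` with α = 0.7
by default.  The baseline F₀ is a centred 3-minute sliding-window statistic,
truncated at the trace edges: the 5th percentile for cells whose fluorescence
distribution is highly skewed (sample skewness > 1 — cells dominated by
sparse positive transients, where a median would track the transients), and
the median for symmetric cells.  ΔF/F₀ = (F − F₀)/F₀ is invariant to
multiplicative rescaling of F by construction.

**Trial alignment.**  Mean ΔF/F₀ traces are built per outcome (HIT, MISS, FA,
CR, aligned to stimulus onset) and per first lick (HIT and FA), each 41
frames at 10.8 Hz (≈3.8 s).  Lick-aligned traces place the first lick at
frame index 11, leaving ≈1 s of pre-lick context so that action-predictive
activity (which rises *before* the lick, i.e. at negative latency) is visible.
Alignment is nearest-frame, not interpolated: all task epochs are several
frames long at this rate.  The six traces concatenated in the fixed order
[HIT, MISS, FA, CR, HIT-lick, FA-lick] form the 246-sample response vector.
Neurons missing a condition are excluded by default (`policy="error"`); a
zero-fill policy exists for exploratory use.  Baseline statistics (mean, SD)
come from the 0.5 s preceding each trial's stimulus onset, pooled over
trials.  Pre-lick windows are deliberately *not* used for the baseline: they
overlap stimulus- and action-driven transients and would inflate the SD,
which the 3-SD responsiveness and latency rules divide by.

**Response latency** is the time of the first frame at which a trace departs
more than 3 SD from its baseline mean, relative to the trace's alignment
event; it is negative for pre-lick buildup.

## Heuristic functional classification

The visual scoring of functional classes is emulated by a deterministic rule
cascade so it can be validated against generator ground truth.  In order:
unresponsive (no condition beyond 3 SD) → UNCLASSIFIED; pre-lick response on
both HIT and FA with weak MISS/CR → ACTION (subdivided into stimulus-period
vs response-period variants by whether the session's median first lick
precedes stimulus offset); post-lick response on HIT only → REWARD, on FA
only → ERROR (the opposite lick condition must be *unresponsive*, not merely
weaker, because a pure licking neuron responds on both, more strongly where
licks summate); inter-trial lick response at a substantial fraction of the
task-lick response → LICKING; responsive on all four outcomes → SENSORY_CUE
if the mean GO and NOGO traces share their time course, SENSORY_FEATURE if
they are time-shifted copies (normalised trace distance, threshold 0.35 —
at 10.8 Hz a 150 ms preferred-segment offset quantises to 1–2 frames, so a
pure latency comparison is fragile while shifted calcium transients separate
cleanly in shape); GO-only or NOGO-only responses independent of licking →
SENSORY_CATEGORY; otherwise UNCLASSIFIED.  "Weak" means a peak below half the
neuron's largest condition peak.  These rules are an operationalisation for
synthetic validation; no claim is made that they reproduce human scoring of
real recordings.

## PAIRS

Response vectors are projected onto a common 8-component PCA basis (fitted on
the pooled population; cumulative explained variance is reported and a
warning logged below 90%) and unit-normalised, so the dot product of two
feature vectors is the cosine of their similarity angle.  Each neuron's
statistic is the mean angle to its k = 3 nearest neighbours; the population
statistic is the median over neurons.  Clustered response profiles make it
small.  Significance is one-sided against surrogate populations that preserve
each coordinate's empirical marginal while destroying between-coordinate
dependence; surrogate vectors are re-unit-normalised and the statistic
recomputed identically.  The p-value is the add-one estimator
`(1 + #{surrogate ≤ observed}) / (1 + n_surrogates)`, so beating all 10,000
surrogates reports exactly 1/10001 < 10⁻⁴.

Coordinate marginals are preserved by *permutation* by default.  Sampling
with replacement (available as `pairs_surrogate_mode="resample"`) makes the
test severely conservative: bootstrap duplicates make surrogate populations
systematically more clustered than an exchangeable null, and on isotropic
populations the measured type-I fraction drops to zero (mean p ≈ 0.8).
Permutation calibrates correctly (measured type-I fraction 0.035 at the 5%
level over 200 isotropic populations).

Per-session analyses share one PCA basis per training category, use
session-level marginals for the surrogates, and skip sessions with 25 or
fewer neurons.

## Per-neuron decoding

Each neuron's trial-by-frame ΔF/F₀ matrix (trial start to end of the response
window, 22 frames) is decoded for GO-vs-NOGO and lick-vs-no-lick labels with
a linear SVM.  If the majority class exceeds 75% of trials it is randomly
thinned to exactly the 75/25 ceiling; neurons are excluded unless more than
100 trials remain (the same rule is applied to both tasks).  Accuracy is
stratified 5-fold cross-validation, maximised over C ∈ {0.001, 0.01, 0.1, 1};
features are standardised per fold with training-fold statistics only; grid
ties resolve to the smallest C.  Significance repeats the full pipeline
(including C selection) on label-shuffled surrogates; a neuron is significant
iff its accuracy strictly exceeds at least 95% of surrogate accuracies, ties
counting against.  With 100 surrogates this is the "better than 95 of 100"
criterion and yields a ~5% type-I rate by construction (measured 7.5% on 200
label-independent neurons at 50 surrogates, inside sampling error of the
expected 3/51 ≈ 5.9%).

Population summaries report significant fractions per group with a Pearson
χ² independence test (no continuity correction) and per-task median accuracy
of significant neurons.  2×2 comparisons use Fisher's exact test; the
reported odds ratio is the unconditional sample estimate `ad/bc`, which is
the convention that reproduces the published worked-example value of 5.19.

## Synthetic-data generator

The generator defines the validation conditions; its defaults are held fixed.

**Behavior.**  Sessions have 400 trials (p_GO = 0.5) separated by a 3 s
inter-trial interval.  Each trial draws a latent lick decision (probability
0.95 on GO, 0.25 on NOGO).  Decided trials produce Poisson licks whose rate
steps from the 0.5 Hz base rate to 8 Hz (GO) or 3 Hz (NOGO) at the
ground-truth discriminative latency `true_dll` (default 300 ms); undecided
trials lick only impulsively, during the stimulus period and inter-trial
interval, never in the response window.  This makes outcomes map exactly onto
the latent decisions and places the HIT−FA lick-rate divergence at
`true_dll`.  The observer is memoryless across trials.

**Calcium.**  Neurons place class-specific events on the session timeline
(stimulus onset; preferred-segment onset, hence 150 ms later on one trial
type; divergence time on GO trials only; a −300 ms lead before the first lick
on HIT/FA; every lick; a +300 ms lag after the first lick on HIT or on FA),
convolve them with a GCaMP6f-like double-exponential kernel (τ_rise 50 ms,
τ_decay 400 ms, peak-normalised), and add i.i.d. Gaussian noise (default SD
0.05 of unit amplitude).  The model is linear in events with no spiking
nonlinearity, matching the analyses' decision to work on ΔF/F₀ directly
rather than deconvolved activity.

**What passing does and does not show.**  The generator produces i.i.d.
Gaussian noise, perfectly stationary baselines, stereotyped kernels, and an
observer whose decisions are independent across trials.  Real recordings have
correlated noise, slow drift, diverse indicator kinetics, satiety and
engagement trends, and behavioral serial dependence.  Green validation
therefore establishes *internal correctness and calibration* of the
estimators under their stated assumptions — not that the heuristic class
labels or decoder counts would reproduce published values on real data, which
are not packaged here.

## Validation battery sizes

The acceptance battery (also exposed as `seqdisc.benchmarks`) uses: 67
sessions per latency level on the grid {0.2, 0.3, 0.5 s} plus 100 null
sessions (400 trials each); 200 isotropic populations of 40 neurons with
1,000 PAIRS surrogates, a 120-neuron clustered population, and one
10,000-surrogate run for the p-floor identity; 200 label-independent neurons
(120 trials × 22 frames) and 20 action-predictive neurons at 50 decoding
surrogates.  These sizes keep the whole battery to a few minutes on one core
while leaving each check's sampling error well inside its acceptance band.

## Known limitations

* The DLL estimator is deliberately conservative in short sessions (few FA
  trials widen the permutation threshold); it prefers UNDEFINED to a false
  latency.
* `compute_dff` evaluates a percentile per frame (O(frames × window)); fine
  at session scale, slow for hour-long recordings.
* The heuristic classifier's thresholds (weak fraction 0.5, shape distance
  0.35, inter-trial lick fraction 0.25) are tuned to the generator's event
  geometry and are exposed as function arguments, not config entries.
* Mixed-effects session-performance models and optogenetic ANOVA analyses are
  out of scope; the per-session summary table exported by `behavior` carries
  the columns needed to fit them elsewhere.
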