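# Methods

`hemidyn` implements a complete analysis stack for studying how lateralized
visual object information is represented in the two cerebral hemispheres over
time, together with a synthetic data generator that makes every stage
testable against known ground truth.  This note documents the models, the
numerical choices, and what the synthetic validation does and does not show.

## The experimental model

The emulated experiment presents 36 stimuli — 24 object images (6 concepts ×
4 exemplars: bird, fish, tree, boat, face, tool) and 12 word labels (6
concepts × 2 case variants) — in rapid serial streams lateralized to the left
or right visual hemifield, at 5 Hz (100 ms on, 100 ms off), while 1000-Hz
EEG-like activity is recorded.  Single-hemifield sequences present one
stimulus per trial (each image twice per hemifield per 192-trial sequence,
each word four times — a doubling that the analysis later subsamples away);
dual-hemifield sequences present one stimulus to each hemifield
simultaneously.  The study-scale defaults are 20 participants, 24 single and
12 dual sequences, giving 48 analyzed repeats per stimulus per hemifield per
condition.

## The synthetic EEG generator

Because visual input projects first to the hemisphere contralateral to the
stimulated hemifield, the generator gives each stimulus a latent activation
pattern (default 8 components per participant) and renders it as:

* **contralateral response** — the pattern, projected through a fixed random
  orthonormal participant-specific map onto the 6 cluster channels, under a
  raised-cosine bump (default width 100 ms) starting at `contra_onset`
  (default 80 ms);
* **ipsilateral response** — the same latent pattern truncated to its first
  `ceil(retention · pattern_dim)` components (default retention 0.6, making
  ipsilateral information a strict subset of contralateral information),
  scaled by `ipsi_gain` (default 0.6 — the empirical ipsilateral amplitude
  ratio is not constrained by lateralized-ERP reports, so this is a free,
  documented choice) and delayed by `transfer_delay` (default 20 ms,
  mid-range of occipital interhemispheric transfer estimates of roughly
  15–30 ms);
* **dual-stimulus interference** — in dual trials both stimuli contribute and
  all pattern signal after `interference_onset` (150 ms, matching the
  observation that early processing proceeds unimpeded) is multiplied by
  `interference_attenuation` (default 0.8);
* **noise** — additive AR(1) Gaussian noise per channel (coefficient 0.9 at
  1 kHz), scaled so that RMS(signal)/RMS(noise) over the cluster channels
  within 0–500 ms equals `snr`; `snr=0` produces pure noise.

Latent patterns can optionally mix a shared image/word factor and a shared
concept factor (`w_image`, `w_concept`) with stimulus-unique structure
(`w_unique`, default 1/0/0 mix weights of 0/0/1), so that the neural RDM
geometry carries a controllable amount of model-related structure.  The
triplet-response generator draws three distinct stimuli per trial and applies
a Luce (softmax) choice rule over each stimulus's summed latent dissimilarity
to the other two; the temperature is the only noise source, and temperature→0
recovers the deterministic odd-one-out.

**What the generator does not emulate:** volume conduction and realistic
forward-model topographies, eye movements and artifacts, trial-order
adaptation, overlapping responses from the 5-Hz stream (epochs are rendered
independently), or participant heterogeneity beyond independent pattern and
noise draws.  Passing tests therefore demonstrate the *analysis machinery* —
estimator correctness, calibration, and parameter recovery under the stated
noise model — not performance claims about real EEG.

## Decoding

Pairwise decoding uses a regularized linear discriminant per stimulus pair
per 1-ms time point on the 6-channel cluster patterns: pooled within-class
covariance with closed-form Ledoit–Wolf shrinkage toward the scaled identity,
computed independently at every time point (vectorized batched linear
algebra; scikit-learn's LDA is the cross-check oracle in the tests).
Shrinkage is needed because 6-channel covariances estimated from small
per-fold samples are ill-conditioned; the intensity can be fixed or disabled.
Folds contain whole sequences (fold = sequence rank mod n_folds; 12 folds at
study scale, 6 within an odd/even half), so training and test data never
share a sequence.  Decision-boundary ties classify to the smaller stimulus
id.  No pseudo-trial averaging and no temporal windowing are applied.  Words
are subsampled (without replacement, stratified over sequences) to the image
repeat count per hemifield and condition before decoding.

## RSA, transfer delay, and consistency

Neural RDMs (36×36, 630 unique cells) hold pairwise accuracies per time
point.  All between-hemisphere correlations are split-half: RDMs from odd
sequences of one hemisphere are Spearman-correlated with RDMs from even
sequences of the other, for every pair of time points, and the two cross
pairings are averaged (symmetric in the split assignment, lower variance —
the single-direction alternative is also valid, but noisier).  Spearman is
computed as Pearson on average-fractional ranks; zero-variance time points
yield undefined cells that are excluded (zero-filling would bias delay
profiles toward 0).  The delay profile averages the time×time surface along
off-center diagonals (delays −100..100 ms, window 0–500 ms, both
configurable); positive delay means the contralateral hemisphere leads.  The
asymmetry test applies the directional interval-null Bayes factor to the
paired per-participant difference profile(+d) − profile(−d).  Contra/ipsi
collapsing averages left-hemisphere/RVF with right-hemisphere/LVF (and the
complement) at the output level — after correlation, not before.

## Behavior and commonality

Triplet responses code the chosen odd-one-out as dissimilar (1) from the
other two and the remaining pair as similar (0); RDM cells are means over all
trials of all participants containing the pair (pooling tolerates
per-participant coverage gaps; never co-observed pairs stay missing).  Two
binary stimulus models — same-modality (image/word) and same-concept — and
Spearman correlations over pairwise-complete cells relate behavior, models
and neural RDM series.  Comparison of two dependent correlations sharing one
variable uses the Fisher-transform z with the shared-variable covariance
correction and the 630 RDM cells as n; RDM cells are not independent
observations, so this follows convention rather than strict sampling theory,
and permutation p-values (stimulus-label permutations) are offered instead of
parametric ones.

Commonality analysis regresses neural RDM cells on both behavioral models
(OLS with intercept, computed via QR projections) and on each model alone;
differences of R² give the unique and common components, which satisfy
`unique_image + unique_concept + common = R²_full` to numerical precision
(asserted at 1e-10).  Negative common variance (suppressor structure) is
reported as-is.  The permutation null jointly permutes the stimulus labels
(rows and columns) of the neural RDM — cell-wise shuffling would break RDM
geometry and inflate false positives — recomputing the partition at every
time point, with one permutation per repetition shared across time so the
null preserves temporal dependence (per-time permutations are available as an
option).  p-values use the add-one convention: observed values exceeding all
1000 permutations map to p = 1/1001 < 0.001.

## Bayes factors and onsets

The one-sample JZS test places a Cauchy prior (scale 0.707) on the
standardized effect size δ and compares the marginal likelihood over the
alternative region with that over the interval null (|δ| ≤ 0.5), each with
the prior renormalized on its region; the data enter through the one-sample
t statistic whose likelihood at δ is noncentral-t with noncentrality δ√n.
Above-chance decoding (μ₀ = 0.5) and positive-correlation tests are
directional (δ > 0.5); condition differences are two-sided.  Whether a
directional test should use a half-Cauchy prior or a two-sided prior with
directional mass is a genuine convention choice; the renormalized-region
construction implemented here is the half-Cauchy-style variant, and the
`direction` switch exposes all three regions.

Numerically, the marginal is integrated in the prior-CDF domain (finite
region, exact prior weighting) by panel Gauss–Legendre refined around the
likelihood peak, with the node order doubled until two estimates agree to
1e-6 relative.  The noncentral-t likelihood itself is evaluated through the
exact scale-mixture representation E_s[s φ(st − μ)] with s = √(χ²_ν/ν),
integrated by 64-node Gauss–Legendre around the analytic saddle point; this
is vectorized over noncentralities and agrees with scipy's noncentral-t pdf
to ~1e-6 relative in all regimes with non-negligible density (tests compare
the full Bayes factor against a 1e5-node trapezoid oracle at 1e-4).
Zero-variance samples have no defined effect size and raise by default; time
course wrappers can substitute the limiting (infinite) Bayes factor, which
arises when a high-SNR simulation saturates accuracy at 1.0.

Onsets are the first time point (t ≥ 0) opening a run of ≥ 10 consecutive
1-ms samples with BF > 10; series with no qualifying run report no onset
rather than a coerced value.  Confidence intervals for onset and peak
statistics come from leave-two-participants-out jackknifing (all C(n,2)
subsamples — 190 at n = 20), recomputing the statistic through the full group
pipeline per subsample and taking 2.5th/97.5th percentiles; subsamples with
undefined statistics are excluded and counted.

## Problem sizes used in the validation suite

The test suite and the acceptance script run at desk scale, chosen as the
package's own validation conditions: a 12-stimulus inventory (3 concepts),
5–12 participants, 12–24 single sequences, and epochs of −100..300/500 ms
where the full −100..800 ms window adds only signal-free time.  Chance
calibration uses snr=0 with 10 independent seeds; delay recovery injects
transfer delays of 10/20/40 ms at snr=3 with full pattern retention (snr
chosen below accuracy saturation so RDM time courses retain variance);
commonality calibration uses 200 permutations across 20 seeds with the flag
rate compared to its nominal 1/201 under temporal correlation of the null
series.  Study-scale runs (20 participants, 36 stimuli, full windows) use the
same code paths through `run_pipeline` and the CLI.

## Known limitations

* The behavioral z-test convention (n = 630 RDM cells) inherits the
  non-independence caveat above.
* `import_epochs` supports BrainVision/EEGLAB through MNE when installed;
  only the native container round-trip is exercised by the test suite, since
  no writers for those formats are available here.
* The decoder assumes a balanced two-class problem per pair; class imbalance
  handling is limited to the design-level word subsampling.
* Jackknife onset CIs recompute Bayes-factor time courses per subsample;
  at study scale (190 subsamples × 901 time points) this is minutes of CPU,
  not seconds.
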