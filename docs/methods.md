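# Methods

This note documents the models, conventions and design choices behind each
stage, what the synthetic generators do and do not emulate, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic data

All generators are pure functions of their parameter spec (including its
seed): repeated calls are byte-identical. In the pipeline, every stage
draws its seeds from a named substream of one root seed
(`SeedSequence([root, crc32(stage_name)])`), so adding or toggling a stage
never perturbs the draws of any other.

**Wave epochs.** Channel c of an epoch carries
`A·cos(2πft − s·c·Δφ) + N(0, σ²)` with s = +1 (forward), −1 (backward) or 0
(standing). With row 0 the most posterior electrode, s = +1 means the
oscillation peaks progressively later toward anterior sites — a
posterior→anterior wave. Defaults: 1000 Hz sampling, the 7-electrode
midline montage (Oz, POz, Pz, CPz, Cz, FCz, Fz), Δφ = 0.8 rad/channel
(close to one spatial cycle across 7 electrodes, so the planted wave loads
near a spatial DFT bin). Noise is i.i.d. Gaussian — no 1/f background, no
spatial correlation — so passing tests show the *measure* works, not that
real EEG satisfies its assumptions.

**Trial patterns.** The two condition means sit at ±(d/2)·σ along a random
unit direction u, where d is the condition separation in noise-SD units. A
second unit direction v (orthogonalized against u) carries the latent
feature axis: trial i receives `sqrt(c)·σ·z_i·v` plus residual noise
`sqrt(1−c)·σ` per feature, with z_i the standardized rating of its
stimulus. The coupling c ∈ [0, 1] is therefore the fraction of
(non-condition) variance along the latent axis, which makes feature-RSA
recovery monotone in c by construction. Because the signal lives on a
single axis, its contribution to pattern correlations dilutes roughly as
1/n_features — compact regions (≈10–30 features) are the regime where a
given coupling is recoverable from a few dozen stimuli, and the tests and
demo use such sizes. An optional `structure_seed` fixes (u, v) separately
from the noise stream; two datasets sharing it emulate two modalities with
a common representational geometry, the regime cross-modal transfer
exploits. Default sizes mirror a typical design: 25 trials/condition over
5 runs, so leave-one-run-out trains on 40 trials (20 per condition) and
tests on 10.

**Behavior.** Each subject gets a Gaussian random intercept on the logit
scale shared across conditions (mirroring a random-intercept mixed model
without fitting one); trials are Bernoulli draws. An optional per-subject
logit shift on the IH condition only lets the pipeline plant a subject-level
association between the neural index and the behavioral IH−NP difference.

**Mediation triples.** X is the balanced {0, −1} stimulation coding
(0 = pre, −1 = post); M = aX + ε, Y = c′X + bM + ε with Gaussian noise.

**Phase betas.** `gen_phase_betas` draws the four per-subject regional
betas (pre/post × IH/NP) as a common baseline plus the planted contrasts
plus independent Gaussian subject noise; the planted deactivation index is
`post_contrast − pre_contrast`.

## Traveling waves

The 2D FFT of an electrode-by-time map separates propagation direction.
Conventions, fixed once and used consistently:

- power = |FFT|²; the 2D power is normalized by `n_electrodes²·n_samples`
  and the 1D baseline by `n_samples`, so a perfectly coherent plane wave
  scores comparably to a single electrode's 1D power at the same frequency;
- dB = `10·log10(power/baseline)` (a power-ratio convention; condition
  contrasts are invariant to this choice);
- the baseline is the across-electrode mean of the 1D temporal power
  spectra — the wording "mean of the 1D-FFT results" does not pin down the
  averaging dimension or amplitude-vs-power units, so this per-frequency
  power mean is a documented decision;
- the spatial zero line (standing energy), the temporal DC bin, and — for
  even electrode counts — the direction-ambiguous spatial Nyquist row are
  excluded from the quadrant maxima;
- no windowing/tapering; the frequency grid is the native DFT grid of the
  epoch, and band membership is by bin center in [lo, hi), gamma closed at
  40 Hz;
- which spatial half-plane is "forward" is not taken from any library's
  sign convention but calibrated once: a planted posterior→anterior wave
  `cos(ωt − cΔφ)` has its energy at spatial frequency k = −CΔφ/2π under
  the DFT kernel `exp(−2πi(kc/C + mt/T))`, so the forward quadrant is
  k < 0 at positive temporal frequency. A calibration unit test pins this.

Per-trial spectra are computed and then aggregated within condition (rather
than transforming a trial-averaged map), preserving trial-level variance
for the paired contrast. Quadrant powers below 1e−15 of the map's total
spectral power are floored to exact zero: a zero-phase-gradient (standing)
oscillation has analytically zero off-axis spatial energy, and without the
floor its quadrant "powers" would be rounding residue whose dB ratio is
meaningless. Floored powers convert to −inf dB (flagged with a warning);
two floored powers are symmetric by definition.

Note the dB measure saturates when the coherent oscillation dominates its
own baseline bin: a pure amplitude difference between conditions then
cancels. A planted condition effect must be an SNR difference against a
broadband noise floor — which is also the physiologically relevant regime
for single-trial EEG.

## Changepoint detection

`dp_segment` is an exact dynamic program over all admissible breakpoint
placements under the L1 cost (sum of absolute deviations from the segment
median; lower median for even lengths — any value in the median interval
gives the same cost, the choice only fixes a convention). min_size defaults
to 2 samples to exclude degenerate one-point segments. Ties are broken
toward the earliest breakpoint using a relative cost tolerance of 1e−9:
L1 segmentations tie *exactly* whenever a boundary sample lies between the
two segment medians, and without the tolerance floating-point rounding —
which shifting or scaling the signal perturbs — would decide such ties.
`locate_boundary` restricts the curve to a time window, segments with
n_bkps = 1, and flags a breakpoint pinned against a window edge as
unreliable (the window, not the data, put it there).

## Decoding

The classifier is a linear maximum-margin SVM with fixed unit
regularization (C = 1), preceded by PCA fitted on the training fold only;
`n_components` defaults to min(n_train − 1, n_features) and is clamped to
the training rank with a warning. Multiclass uses one-vs-one majority vote.
AUC is the Mann–Whitney probability that a random positive outscores a
random negative, ties counted ½ (computed from midranks; a brute-force
pair-count oracle verifies it in the tests). Accuracy is reported alongside
where relevant; four-class feature decoding uses accuracy against chance
0.25.

Bootstrap iterations resample trials with replacement, stratified by class
— and additionally by run under leave-one-run-out, preserving every run's
class composition so the scheme stays feasible for any seed — then balance
classes by undersampling, then run the full CV. Whether resampling precedes
or follows undersampling is a documented choice (resample first). With
n_boot = 1, resampling is skipped and per-fold scores are returned
(length k·n_repeats, or the number of runs). Median-split ties go to "low".
A training fold containing a single class is skipped with a log message;
if all folds are skipped the call is rejected.

Cross-modal decoding balances the training modality, subsamples the test
modality to match the training sample size, and fits reduction + classifier
on the training modality only; passing the same object as train and test is
allowed as an explicit leakage-diagnostic mode (flagged with a warning).

## Representational similarity

Vectorization takes the lower triangle excluding the diagonal (including
the diagonal would inflate correlations mechanically). The conceptual-model
comparison uses Spearman correlation and builds its null by jointly
permuting item labels (rows and columns together) of one matrix —
preserving symmetry and exchangeability; permuting cells independently
would break both. `p = (1 + #{|ρ_perm| ≥ |ρ_obs|}) / (n_perm + 1)`,
two-sided by default; which matrix is permuted and one- vs two-sidedness
are exposed as options. Note the p-value floor 1/(n_perm+1) is not
attainable for block-structured data: label permutations that preserve (or
swap) the condition blocks reproduce the observed correlation exactly.

The decoupling test is Steiger's z for two dependent correlations sharing
one variable (the feature RSM), with Fisher-transformed correlations and
the pooled-r covariance term. The effective n is the number of vectorized
cells, as is conventional in RSA; those cells are not independent
observations, and the result object carries that caveat explicitly.

## Inference

The deactivation index `(β_post,IH − β_post,NP) − (β_pre,IH − β_pre,NP)` is
invariant to common additive offsets and equivariant under scaling. The
phase boundary defaults to 3.0 s and is configurable — the pipeline treats
it as an input the changepoint stage can supply. Brain–behavior cells with
a constant input are flagged undefined and excluded from the FDR family;
the family is all (measure × window) cells of one call, configurable
because family boundaries are per-table decisions.

Mediation paths come from nested least squares (a: M on X; b, c′: Y on X
and M; c: Y on X), which guarantees c = c′ + a·b as an algebraic identity.
The bootstrap CI is bias-corrected (BC, not BCa — no acceleration term):
`z₀ = Φ⁻¹(#{a·b* < a·b}/n_boot)` with a continuity guard at 0 and 1, and
percentile endpoints at `Φ(2z₀ ± z_{α/2})`. Degenerate resamples with
constant X are redrawn (capped). X stays coded {0, −1} end to end — the
signs of a and c′ depend on it. Known property: in configurations with one
strong path and one null path, the BC interval's type-I error runs above
nominal (the tests bound it at 0.11 rather than 0.05); the plain percentile
interval does not show this, and the BC machinery itself is verified
against an independently coded oracle. The full/partial mediation label is
deliberately not applied; paths and CIs are reported as-is.

## Pipeline and problem sizes

The demo pipeline runs five stages (waves → changepoint → decoding → RSA →
inference) at sizes chosen to exercise every code path at desk scale: 30
trials/condition of 1 s epochs at 250 Hz for waves; a 6 s decoding curve at
100 Hz with the step planted at 3.0 s; 25 trials/condition × 5 runs × 100
features with 100 bootstrap iterations for decoding; 30 stimuli × 20
features with 5000 permutations for RSA; 36 subjects and a 5000-sample
bootstrap for inference. The full run takes well under a minute on one
core. Outputs are deterministic JSON/CSV (sorted keys, no timestamps) plus
a manifest of SHA-256 content hashes; reruns are byte-identical.

## Limitations

- Gaussian i.i.d. noise everywhere: no 1/f spectra, autocorrelation,
  hemodynamics, or spatially structured noise. Green tests certify the
  estimators against their own assumptions, not real-data robustness.
- The single-axis latent feature model dilutes with dimensionality; in
  wide feature spaces the same coupling value produces weaker feature-RSA
  signal.
- The Steiger test's effective n over RSM cells is statistically
  contestable (cells share items); treat its p-values as conventional, not
  exact.
- The quadrant method quantifies plane-wave energy along a fixed axis; it
  does not localize sources, handle curved wavefronts, or replace
  phase-gradient methods.
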