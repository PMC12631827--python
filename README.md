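# deactdyn

Analysis toolkit for the **temporal deactivation dynamics of inhibitory
control** — the hypothesis that actively inhibiting a stimulus is implemented
not by extra processing but by a progressive *deactivation* of sensory
cortex that deepens across a temporal boundary (~3 s post-stimulus), visible
simultaneously in EEG traveling waves, multivariate decodability, and
representational geometry.

The package implements the bespoke computations of that analysis program as
a tested pipeline, exercised end-to-end on synthetic data with planted,
recoverable structure:

- **Traveling waves** (`deactdyn.travelwave`) — signals from an ordered
  electrode axis (e.g. the midline Oz → Fz) are stacked into a 2D
  electrode-by-time map; the 2D-FFT separates forward (posterior→anterior)
  from backward wave energy by spatial-frequency quadrant. For each temporal
  frequency f in 4–40 Hz, FW(f) and BW(f) are the quadrant maxima over
  nonzero spatial frequencies, expressed as `10·log10(power/baseline)` dB
  against the across-electrode mean 1D spectrum, and averaged within the
  theta (4–8), alpha (8–14), beta (14–30) and gamma (30–40 Hz) bands.
- **Changepoint detection** (`deactdyn.changepoint`) — exact dynamic
  programming segmentation of a decoding time course under the L1 cost
  `Σᵢ |xᵢ − median(segment)|`, with a single breakpoint (n_bkps = 1) marking
  the temporal boundary of the neural shift.
- **Decoding** (`deactdyn.decoding`) — condition decoding from single-trial
  activation patterns: undersampling for class balance, PCA fitted on
  training folds only, linear SVM, leave-one-run-out or repeated k-fold CV
  with bootstrap resampling, ROC-AUC (Mann–Whitney, ties ½) and accuracy;
  four-class feature decoding from median-split ratings (chance 0.25); and
  cross-modal transfer where reduction and classifier fitted on one
  modality score another.
- **Representational similarity** (`deactdyn.rsa`) — neural RDMs
  (1 − Pearson r between trial patterns), feature RDMs (|Δrating|),
  RSM = 1 − RDM, Spearman comparison against a binary conceptual model with
  a 5000-iteration label-permutation test, and Steiger's z for the
  condition-wise *decoupling* of feature–neural alignment (two dependent
  correlations sharing the feature RSM).
- **Inference** (`deactdyn.inferstats`) — the temporal deactivation index
  `(post-boundary β_IH − β_NP) − (pre-boundary β_IH − β_NP)`, behavioral
  difference scores (IH − NP), Pearson brain–behavior correlation with
  Benjamini–Hochberg FDR control, and simple mediation
  (X → M → Y, X coded {0, −1}) with a 5000-sample bias-corrected bootstrap
  CI on the indirect effect a·b.
- **Synthetic data** (`deactdyn.synthgen`) — first-class generators for every
  input: plane-wave EEG epochs with a planted direction, trial-pattern
  matrices with planted condition separation and a latent feature axis,
  piecewise-constant decoding curves, mediation triples with planted paths,
  and binary behavioral responses with subject heterogeneity. All are pure
  functions of (spec, seed).

## Worked example

Run the end-to-end demo (simulate → analyze → report) from one seed:

```bash
deactdyn pipeline run --seed 1 --out report/
```

or, in Python:

```python
from deactdyn.config import RunConfig
from deactdyn.pipeline import run_pipeline

report = run_pipeline(RunConfig(seed=1), "report")
```

With seed 1 the report contains (abridged):

```
waves:       alpha FW−BW (IH)        +2.20 dB   # planted forward alpha wave
             alpha FW contrast IH−NP +0.60 dB   # stronger coherent wave under IH
changepoint: boundary_time_s          3.00      # planted step at 3.0 s recovered
decoding:    loro_auc                 0.724     # separable conditions (chance 0.5)
             crossmodal_auc           0.742     # shared structure transfers
             feature4_accuracy        0.334     # 4-class features (chance 0.25)
rsa:         decoupling Δr            0.363     # NP tracks features, IH decoupled
             decoupling z             5.83
inference:   deactivation_index_mean −0.366     # planted −0.40 (IH deepens post-3s)
             brain_behavior_r         0.875     # planted neural-behavior link
             mediation indirect       0.059  CI [−0.014, 0.160]
```

Reading it: the forward alpha wave dominates its backward counterpart by
2.2 dB and is stronger under inhibition; the decoding time course breaks at
exactly the planted 3.0 s boundary; conditions are decodable above chance
within and across modalities; feature–neural alignment collapses under
inhibition (Δr = 0.36, Steiger z = 5.8); and the per-subject deactivation
index recovers the planted −0.4 contrast and correlates with behavior. The
mediation paths are estimated from one n = 200 draw, so the indirect effect
carries visible sampling error — its bootstrap CI is the honest summary.

Every stage's JSON/CSV lands in `report/` with a `manifest.json` of content
hashes; rerunning with the same config is byte-identical.

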