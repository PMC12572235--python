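# Methods

## Problem and model

In subthalamic deep brain stimulation (DBS) for Parkinson's disease, the
contact used for chronic stimulation is found by a monopolar review: each
contact is stimulated at increasing amplitude until sustained benefit
appears (therapeutic-effect threshold, TET, mA) or side effects force a
stop (side-effect threshold, SET, mA). The therapeutic window TW = SET −
TET, normalized by the range of amplitudes tested so that it lies in
[−1, 1], is the clinical utility of a contact. `dbswin` predicts this
normalized window from resting-state electrophysiology:

* **STN power features** — one Welch power spectrum per contact channel
  (2 s epochs, 50 % overlap, Hann taper, integer frequencies 1–300 Hz),
  line-noise removal by linear interpolation around the 50 Hz harmonics,
  aperiodic (1/f) removal, and band averaging over seven bands: theta 3–7,
  alpha 8–12, low-beta 13–20, high-beta 21–35, low-gamma 36–60, high-gamma
  60–90, HFO 200–300 Hz (limits inclusive; 60 Hz intentionally belongs to
  both gamma bands).
* **STN–cortex coherence features** — magnitude-squared multitaper
  coherence between each contact and 30 cortical parcel channels, averaged
  per band, spatially z-scored across parcels per band (ddof = 1), and
  hemisphere-aligned by mirroring left-electrode maps across the
  mid-sagittal plane so that `_R` parcels are ipsilateral to every
  electrode.

The full table is 7 + 30×7 = 217 features per contact. Ring-mode composite
contacts (segments driven together) receive the element-wise mean of their
segments' feature rows, computed after z-scoring. An optional anatomical
feature is the Euclidean distance to the published STN sweet spot
(x = ±12.58, y = −13.41, z = −5.87 mm; x sign matching the electrode side).

A gradient-boosted tree ensemble (XGBoost) maps features to the normalized
window. Evaluation is leave-one-electrode-out (LOEO): all contacts of one
electrode are held out while every other electrode trains the model.
Feature selection and hyperparameter tuning are nested, i.e. run inside
every training fold only.

## Nested selection and tuning

**Boruta.** Each round appends a column-shuffled shadow copy of every
surviving feature, fits a 100-tree random forest (impurity importance,
`max_features="sqrt"`), and scores a hit for real features beating the best
shadow. Hits are tested two-sided against Binomial(rounds, ½) at α = 0.05:
significantly above chance → confirmed, below → rejected and dropped.
Features still undecided when the round budget (100) is exhausted are
rejected — the conservative reading. **Consensus:** Boruta runs on 10
bootstrap resamples of training *electrodes* (contacts of an electrode
always travel together) and features confirmed in ≥ 7 of 10 runs are kept.
An empty consensus falls back to the full feature set with a loud warning
rather than producing an unfittable model.

**Tuning.** Stage 1 picks the tree count by grouped (per-electrode) K-fold
cross-validation with early stopping on held-out squared error. Stage 2 is
a seeded derivative-free random search (25 draws by default) over max depth
2–8, learning rate 0.01–0.3 (log-uniform), row subsample 0.5–1, column
subsample 0.3–1, minimum child weight 1–10, and L1/L2 regularization 0–5,
scored by grouped-CV mean squared error. The library defaults are always
included as a candidate, so tuning cannot do worse than not tuning on its
own objective. Grouped folds mirror the leakage structure of LOEO.

## Evaluation statistics

Pearson's r between predicted and actual windows (two-sided t test,
n − 2 df), and a linear mixed-effects model of actual on predicted windows
with a random intercept per electrode (REML; Wald CI and p) to respect the
repeated measures. For the ranking view, contacts are ordered per electrode
by predicted window (ties → ascending contact id) and the cumulative hit
ratio counts the fraction of electrodes whose clinician-chosen contact sits
within the top *i* ranks. Only electrodes with ≥ 4 tested contacts enter.
The null distribution draws an independent uniform random ordering per
electrode 10,000 times; observed ratios above the per-rank 95th percentile
are flagged significant (per-rank rule, no multiplicity correction). When
electrodes differ in contact count, ranks beyond an electrode's depth count
as hits — the chosen contact is certainly within the electrode's own list;
this convention is asserted in tests. Feature importance is the selection
frequency across LOEO folds, normalized per (region group, band) by the
number of areas in the lobe; the STN is its own single-area group.

## Synthetic cohorts

The generator is the testbed: every stage of the analysis runs on cohorts
whose ground truth is known. Each patient has a bilateral electrode (8
contacts per side) and 30 parcel channels in 15 homologous left/right pairs
labeled by lobe (frontal, parietal, temporal, occipital, sensorimotor,
cerebellum) — placeholders with the correct count and lobe structure, not
an anatomical atlas. A latent per-contact quality q ~ N(0, 1), independent
across contacts, drives everything:

* contact signals = 1/f background (log-power slope −1.5) + band-limited
  Gaussian oscillations (alpha fixed at 0.25 a.u.; low-beta 0.20, high-gamma
  0.15 and HFO 0.10 a.u. scaled by 1 + `quality_effect`·q) + a 50 Hz
  sinusoid (0.5 a.u.). Oscillations are band-passed noise, not sinusoids,
  so multitaper coherence behaves as on real data;
* per hemisphere a high-beta (21–35 Hz) common source enters three
  electrode-relative parcels (ipsilateral superior frontal, ipsilateral
  superior temporal, contralateral posterior cerebellum; weight 0.8) and
  every contact of that side with weight 0.6·(1 + `quality_effect`·q);
* review thresholds: TET = 2.0 − 1.2·`quality_effect`·q + ε,
  SET = 3.5 + 1.2·`quality_effect`·q + ε with ε ~ N(0, 0.3 mA), rounded up
  to the 0.5 mA amplitude step and censored to "absent" above the 5 mA
  maximum (absent means no effect up to the maximum and is imputed with
  it); an extra 10 % of thresholds are missing at random. The slope of
  1.2 mA per quality SD was fixed once so that the true normalized window
  tracks q with Spearman ρ ≳ 0.85 at the default noise level — strong
  but imperfect coupling, as a usable biomarker would show. The chosen
  contact is the widest-true-window contact (ties → lowest contact id),
  standing in for the clinician's choice.

Coherence between a contact and a coupled parcel follows the two-SNR closed
form c = 1/((1 + 1/s₁)(1 + 1/s₂)), which the tests verify against long-run
simulation. What the generator does **not** emulate: volume conduction and
shared references, beamformer leakage between parcels, artifacts beyond
line noise, non-stationarity, inter-patient spectral variability, or any
true anatomical layout. Passing recovery tests therefore shows the pipeline
is correct and leakage-free, not that the clinical effect sizes transfer.

## Numerical choices

* Coherence uses DPSS tapers with ±2 Hz half-bandwidth on 2 s epochs
  (NW = 4, 7 tapers) and **non-overlapping** epochs, so the averaged
  cross-spectral estimates are independent and the small-sample coherence
  bias is exactly 1/(epochs × tapers), which the tests assert. The PSD
  chain keeps 50 % overlap.
* Line-noise interpolation replaces bins strictly within ±7 Hz of each
  50 Hz harmonic; the anchors are the bins at exactly ±7 Hz (43 and 57 Hz
  for the fundamental). The 300 Hz harmonic has no right anchor and is
  filled flat from 293 Hz. Overlapping notches merge. Bins outside notches
  are bit-identical.
* The aperiodic fit (1–90 Hz) is a knee-free power law in log-log space,
  refitted iteratively after masking upward outliers (oscillatory peaks);
  above 90 Hz a straight line of log10 power vs linear frequency is fitted,
  excluding interpolated bins, and subtracted. Band values are signed
  log10 residuals — not floored at zero.
* Non-positive spectral power before the log, zero-variance channels, zero
  parcel variance before z-scoring, and constant regression targets raise
  errors rather than propagate NaNs. Stage order (raw → denoised →
  periodic) is enforced; re-applying a stage raises.
* All randomness flows from integer seeds through `numpy` SeedSequence
  spawning (per patient, per fold, per resample), making cohorts and LOEO
  runs bit-for-bit reproducible.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the full LOEO pipeline on a
demonstration-scale cohort of 8 bilateral patients (16 electrodes, 128
contacts, 20 s of signal per patient) at a reduced selection/tuning budget
(15 Boruta rounds, 50-tree forests, 8 search draws, 4 CV folds), one seeded
effect cohort and one quality-decoupled null cohort; the selector's error
rates use 100 simulated datasets of 200 rows × 50 features; permutation
nulls use 10,000 permutations. These sizes are the package's chosen
demonstration scale; the defaults (`SimConfig()`, `ModelConfig()`) encode
the full study-like settings (20 patients, 60 s, 100 Boruta rounds, 10-fold
grouped CV, 25 search draws).

## Known limitations

* The parcel scheme is a stand-in; real analyses would substitute an atlas
  parcellation and a source-reconstruction step in front of the coherence
  module.
* The threshold model is a plausible stand-in, not a claim about the
  clinical distribution of monopolar-review thresholds.
* Boruta's undecided-at-termination features are rejected; with small round
  budgets this is conservative and can shrink the consensus set.
* The mixed-effects Wald inference is asymptotic; with few electrodes the
  CI is approximate.
* `amp_range` is carried as data on each review (maximum minus minimum
  amplitude tested) rather than recomputed from amplitude lists.
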