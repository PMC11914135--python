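# Methods

## The question the package addresses

RSVP P300 spellers calibrate their classifiers offline, and most
pipelines filter the *whole* calibration recording before cutting trial
epochs (conventional filtering, CF). During closed-loop use, however,
data arrive one inquiry at a time, and each chunk must be filtered
independently. Online-parity filtering (OF) reproduces that constraint
during calibration: the raw record is first cut into per-inquiry epochs
with a transient-absorbing buffer on each end, each epoch is filtered on
its own with zero initial filter state, and only then are trials
extracted. The package compares classifier performance between the two
orders on synthetic EEG whose structure makes the difference
consequential (filter transients, line noise, blink artifacts).

## Synthetic EEG generator

No public recording accompanies the original task, so every analysis
runs on generated sessions. The generator is intentionally minimal —
just enough structure that filtering order matters:

- **Background**: independent per-channel AR(1) noise, coefficient 0.95,
  innovation standard deviation `background_sd_uV` (default 10 µV;
  per-subject draws in the study replica are uniform on [5, 15] µV).
  The AR(1) concentrates power at low frequencies, as EEG does.
- **Alpha rhythm**: a 10 Hz sinusoid, 4 µV, random phase per channel.
- **Line noise**: a 60 Hz sinusoid, 5 µV, one phase shared across
  channels.
- **Blinks**: Poisson events at 0.1/s; each is a 400 ms half-sine of
  100 µV on Fp1/Fp2, scaled 0.3 on F3/Fz/F4, zero elsewhere.
- **ERP**: every target stimulus adds an N200 (−2 µV Gaussian, latency
  0.20 s, width 0.025 s, weighted to O1/O2 at 1.0 and P3/P4 at 0.6) and
  a P300 (+5 µV Gaussian, latency 0.35 s, width 0.06 s, weighted to Pz
  1.0, Cz 0.8, P3/P4 0.6). A per-trial latency jitter (sd 0.02 s) is
  shared by both components. Bumps are truncated at ±4 widths so their
  support is finite.

The channel montage is the deduplicated 19-label 10-20 set of the
original dry-electrode headset; sampling rate 300 Hz. The calibration
schedule is 110 inquiries of 10 symbols at 5 Hz (1 s prompt, 0.5 s
fixation, 2 s inquiry; 10% of inquiries are target-free; target position
uniform over the ten slots). The gap between inquiries defaults to 2 s;
published descriptions of this task give both 2 s and 4 s, so the value
is configurable and neither is asserted.

Draw order inside the generator is fixed and independent of amplitude
values, so scaling one amplitude rescales exactly that component:
two sessions differing only in `p300_amp_uV` share noise sample by
sample. All randomness flows from one seed; the study replica derives
per-subject and per-component sub-seeds from the master seed by fixed
integer offsets.

**What the generator does not emulate**: real ERP shape variability and
habituation, non-stationary noise, electrode pops, eye movements locked
to the stimulus stream, volume-conduction correlation structure between
channels (channels are independent except for the deterministic
components). Passing tests therefore demonstrate correctness of the
pipeline mechanics and sane statistical behavior, not expected
performance on human data.

## Filter chain

In order: a 2nd-order IIR notch at 60 Hz with quality factor 30
(bandwidth 2 Hz), applied forward-backward so its net phase is zero and
its effective magnitude is the squared single-pass response; a causal
5th-order Butterworth bandpass (order parameter 5, i.e. 10 poles after
the band transform), default 1–20 Hz, run forward only with zero initial
conditions; decimation by keeping every 2nd sample starting at index 0.
The bandpass already attenuates far above 20 Hz, so no extra anti-alias
stage precedes the decimation; broadband-noise tests confirm < 1% of
output power above twice the band edge.

CF applies this chain once to the whole record. OF cuts each inquiry
from the *raw* record spanning (first onset − buffer) to (last onset +
trial window + buffer), buffer 1.0 s by default, and filters each epoch
independently; overlapping epochs are cut independently, mirroring
chunked online delivery. Epoch starts are snapped down to the decimation
grid so CF and OF share the same post-downsample sample phase. On
stationary in-band input the two agree to < 2% of trial RMS with the 1 s
buffer (the 1 Hz high-pass transient decays like e^(−2π·t)), and the
discrepancy shrinks monotonically with buffer length.

**Trial window.** Trials are cut at each stimulus onset with a default
window of 0.7 s. The causal bandpass matters here: its response to a
0.35 s-latency P300 is an oscillation whose largest deflection lands
near 0.47 s and whose rebound peaks near 0.69 s after the stimulus, so a
0.5 s window (a common choice at a 5 Hz presentation rate) discards most
of the usable energy. Windows of successive trials overlap at 5 Hz;
overlap is allowed and each trial is cut independently. The window
remains a parameter, and 0.5 s works everywhere it is requested.
Post-decimation onset mapping uses integer floor division (sub-sample
onset error at most one decimated sample, far below the ERP width).

## Classifiers

All three consume the trial tensor and emit a **positive likelihood
ratio** per trial, so the online decision threshold of 1.0 is the
natural (class-balanced) boundary. For the two probabilistic
discriminants this is the posterior odds divided by the training-set
prior odds — the class-conditional likelihood ratio implied by the
model. Under this task's ~10:1 non-target:target imbalance, thresholding
raw posterior odds at 1.0 would almost never call a positive.

- **PRK**: per-channel PCA (components kept until 0.6 cumulative
  explained variance, fit on all trials), concatenated across channels;
  a regularized discriminant with class covariances shrunk toward the
  pooled covariance (λ = 0.9) and then toward a scaled identity
  (γ = 0.5); the 1-D score is the difference of class Gaussian
  log-densities; Gaussian KDEs (Silverman bandwidth) fit per class to
  the scores, and the likelihood is their ratio. Two calibration details
  matter. First, the KDEs are fit on *out-of-fold* scores from an
  internal stratified 10-fold split — in-sample scores are
  optimistically separated and would mis-calibrate the ratio at 1.0.
  Second, the ratio is evaluated in log space (log-sum-exp); naive
  density evaluation underflows in far tails at high SNR and would pin
  every ratio to a floor. The retention/shrinkage defaults are heavier
  than textbook values because with ~100 target trials and hundreds of
  PCA features the per-class covariance estimates otherwise invert the
  held-out ranking; a (λ, γ) grid search is available in
  `cross_validate(grid=...)`.
- **LR**: logistic regression with an L2 penalty at fixed inverse
  regularization C = 0.0183 (quasi-Newton solver, tolerance 1e-6, max
  1000 iterations) on per-feature-standardized flattened trials.
  Standardization parameters come from the training split only;
  zero-variance features are centered and left unscaled.
- **RLDA**: per-class xDAWN spatial filters (2 per class) from the
  generalized eigenproblem of evoked-energy vs average trial covariance;
  super-trials stack the filtered class prototypes on the filtered
  trial; their covariances (plus a 1e-10-scale jitter to stay strictly
  SPD) are mapped to the tangent space at their affine-invariant
  Riemannian mean (damped fixed-point iteration from a log-Euclidean
  start, tolerance 1e-8, max 150 iterations, with stall detection at
  the eigendecomposition precision floor for ill-conditioned stacks;
  d×d matrices give d(d+1)/2 tangent features with √2 off-diagonal
  weighting); a shrinkage LDA (Ledoit-Wolf, eigen solver) classifies
  the tangent vectors.

**Cross-validation** is stratified 10-fold (seeded shuffle); each fold
classifies held-out likelihood ratios at 1.0 and accumulates balanced
accuracy and MCC; fold means and sample standard deviations are
reported. When a hyperparameter grid is supplied, the grid point
maximizing the mean selection metric (MCC by default) is reported.

## Metrics and statistics

BA = (TPR + TNR)/2, undefined (an error) when a class is empty.
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)); any zero factor
in the denominator returns 0, matching the "no better than random"
semantics of the degenerate cases.

Per-subject OF and CF metric vectors are compared with a paired
sign-flip permutation t-test: t = mean(d)/(sd(d)/√n) with sample sd,
null built from 50,000 independent random sign flips, two-tailed p with
the add-one correction (1 + #extreme)/(1 + N) so Monte-Carlo p-values
stay in (0, 1]. For scalar per-subject metrics a "cluster" permutation
test degenerates to a single-point cluster, so this is the operationally
identical form; the two-tailed t quantile at α = 0.05 (df = subjects −
1, i.e. 29 at the study's cohort size) is reported alongside as the
cluster-forming threshold. Identically zero differences return p = 1.0.

## Online simulation

Copy-phrase sessions (four five-letter words by default, 10-symbol
inquiries that always contain the current target letter, No-Preview
style) are replayed through the OF pipeline only — never CF, enforced by
the dataset's provenance tag — and scored with the saved calibration
model. The confusion rule is strict: targets with likelihood > 1.0 are
TP, ≤ 1.0 FN; non-targets > 1.0 FP, ≤ 1.0 TN; a likelihood of exactly
1.0 is a negative call. BA and MCC derive from the summed confusion
matrix; per-trial likelihood records are retained so other decision
rules can be layered without re-simulation. No letter-selection or
backspace dynamics are modeled — scoring is per trial.

## Study replica

`ExperimentConfig` defaults to the study's conditions: 30 subjects, 110
inquiries each, per-subject P300 amplitude uniform on [2, 8] µV and
noise sd uniform on [5, 15] µV, band 1–20 Hz, all three models, 10-fold
CV, 50,000 permutations, band sweep over {1–10, 0.2–20, 1–20, 0.1–50}
Hz (PRK, MCC), and a simulated cohort of the 25 subjects with the
highest mean calibration MCC (a stand-in for the original
low-calibration-accuracy exclusions, which used an AUC criterion; the
mapping is approximate and not claimed equivalent). Reports are tidy
CSVs plus a JSON manifest and a plain-text summary; repeated writes of
the same report are byte-identical.

At the default noise range many synthetic subjects classify near
chance: the 1 Hz high-pass removes a large share of the monophasic
P300's energy, and the AR(1) background at 5–15 µV innovation sd is
loud relative to what survives. This is an honest property of the
generator's conditions, not of the pipelines; the SNR-recovery tests
(below) use a fixed 2 µV noise floor where the amplitude gradient is
clearly resolvable.

## Problem sizes in the shipped tests and acceptance script

Test and script sizes are chosen as desk-scale replicas: the SNR
parameter-recovery check uses 5 synthetic subjects at the full 110
inquiries with noise sd fixed at 2 µV and P300 amplitudes {0, 2, 5, 8}
µV, the same per-subject seed across the amplitude grid (noise held
fixed, so monotonicity is tested on paired data). The type-I calibration
of the permutation test uses 200 null replicates at n = 30 with 2,000
permutations each. `scripts/acceptance.py` runs an 8-subject,
60-inquiry study replica with all three models, the full 4-band sweep,
and a 5-subject, 2-phrase simulation.

## Known limitations

- The generator's channels are conditionally independent given the
  deterministic components; spatial covariance learned by the models is
  therefore weaker than in real EEG.
- LR and RLDA likelihoods are prior-corrected posterior odds, not
  calibrated class-conditional densities; their absolute scale is only
  as good as the underlying probabilistic model.
- The degenerate-denominator MCC convention (return 0) and the add-one
  permutation p-value are documented conventions, not claims about the
  original analysis.
- The simulated cohort selection by calibration MCC approximates, but
  is not identical to, an AUC-based exclusion.
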