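# Methods

This note documents the models, parameter defaults and numerical choices
behind `fatiguenet`, and what the synthetic studies do and do not show
about real recordings.

## Signal model and preprocessing

Recordings are time × channel matrices of hemoglobin concentration change
at 16 Hz (default), 24 channels grouped into 8 regions of interest (ROIs)
over prefrontal cortex (L-PFC, M-PFC, R-PFC), frontal eye fields (L-FEF,
R-FEF), supplementary motor area (SMA) and premotor cortex (L-PMC,
R-PMC). Channel ids are 1-based; array columns are 0-based; the montage
layer owns the translation. Missing values are rejected rather than
imputed.

**Band-pass filter.** Chebyshev type I, order 4, 0.5 dB passband ripple,
applied forward–backward (`sosfiltfilt`) for zero phase; second-order
sections keep the narrow low-frequency designs numerically stable. The
type, order and ripple are engineering defaults (config-exposed), chosen
as the common compromise between rolloff steepness and passband
distortion. A band whose upper edge reaches the Nyquist frequency is
rejected, not clipped. Because the filter is applied twice, passband gain
lies in [0.89, 1.0] (ripple squared) — a unit passband sinusoid emerges
with amplitude ≥ 0.89.

**Entropy-weight fusion.** For each ROI and band, channel weights are
computed on the *filtered* channel submatrix (band-wise aggregation): a
channel can be informative in one band and flat in another. Each channel
is min-max scaled to [0, 1] — raw amplitude ratios are meaningless for
signed hemoglobin changes — then treated as a distribution over time
points; its normalised Shannon entropy e ∈ [0, 1] yields weight
ω ∝ 1 − e. Constant channels get the uniform-distribution convention
(e = 1, weight 0); if every channel in an ROI is constant the weights
fall back to uniform. Weights always form a probability vector, so the
ROI series is a convex combination of its channels.

## Connectivity and graph metrics

Pearson correlation between ROI series gives r (8×8); graph weights are
w = |r| with zero diagonal. Signed r is preserved separately and feeds
the classifier features; absolute weights were chosen for the graph
metrics because path lengths and geometric triangle means require
nonnegative weights (config allows |r| features instead of signed ones).

* **Clustering** (per node): geometric mean of triangle weights around
  the node, weights normalised by the network maximum, averaged over
  ordered neighbour pairs; nodes with degree < 2 contribute 0. Network
  clustering is the mean over nodes. Implementation is a cubed-matrix
  identity; tests verify it against a brute-force triple loop at 1e−12.
* **Path length**: Dijkstra shortest paths with edge length 1/w, averaged
  over ordered pairs. Disconnected graphs return the mean over reachable
  pairs plus a flag rather than an error or an infinite value —
  at the default sparsity disconnection is rare and a hard failure would
  be brittle.
* **Sparsity thresholding**: keep the k = round(s·n(n−1)/2) strongest
  edges (round half up; ties broken by lexicographic node order so
  repeated runs agree). At the default s = 0.45 on 8 nodes, k = 13, so
  every thresholded network in a study has exactly the same edge count.
* **Small-worldness**: σ = (C/C_rand)/(L/L_rand) against matched random
  networks: degree-preserving double-edge-swap rewiring (10·E attempted
  swaps) of the thresholded support, plus permutation of the weight
  multiset in weighted mode. "Matched" is operationalised as same node
  count, edge count, degree sequence and (weighted) weight multiset.
  The support threshold is applied in *both* modes: on a complete
  correlation graph, degree-preserving rewiring is a no-op and a pure
  weight-permutation null leaves γ ≈ 1 with λ > 1, making σ < 1 a
  structural artifact; thresholding first (weights kept in weighted mode,
  replaced by 1 in unweighted mode) is the standard brain-network
  practice and restores an informative null. `sparsity=1.0` recovers the
  full-matrix variant. Defaults: 100 replicates, seeded.

Hemisphere asymmetry is summarised as the mean weight over the 3
left–left and 3 right–right ROI pairs; medial ROIs are excluded.

## Fatigue labeling

MFI-20 sessions are scored as the mean of the 20 items (1–5, items
pre-oriented so higher = more fatigued; reverse-scoring is data
preparation, not pipeline work). Behavioral score = mean correct-trial
reaction time / accuracy (higher = worse). Non-fatigue is split off by
1-D k-means (k = 2, 20 restarts); the threshold is the smallest score in
the upper cluster, so "score below threshold" is non-fatigue. The
moderate/severe boundary scans candidates over [2.57, 5.00] step 0.01
and maximises the absolute Welch t between the groups' behavior scores
(Welch because group sizes and variances differ by construction; the
smallest candidate wins ties; groups below 3 members are skipped). The
exact thresholds found on any cohort are properties of that cohort.

## Group statistics

Fixed-effects two-way ANOVA (fatigue level × task) with interaction,
Type III sums of squares under sum-to-zero coding — the convention of
standard statistics packages, safe for unbalanced cells; effect size is
partial η² = SS/(SS + SS_err). Tukey–Kramer post-hocs (studentized-range
test with the unequal-n correction) run only where the level main effect
is significant (α = 0.05) without a significant interaction. No
multiple-testing correction is applied across connectivity pairs by
default (a Benjamini–Hochberg flag exists for users who want it).
Sessions are treated as independent observations.

## Classification

Binary tasks: non-fatigue vs fatigue, and moderate vs severe. Features
per session: 28 signed correlations + weighted C and L per
(species, band), plus 15 time-domain descriptors per (species, band,
ROI) — 2,250 in total, in a fixed documented name order. The "Hjorth
parameter" slot is Hjorth mobility (activity duplicates variance, and
adding complexity would make 16 descriptors); the kurtosis/waveform/
pulse/margin factors follow condition-monitoring conventions; histogram
entropy uses 64 bins over [min, max]; descriptors whose denominator
vanishes on degenerate signals return 0, never NaN, so tree models see
no missing values.

Within each of 5 stratified outer folds: Gini-importance ranking on the
training split (random forest, 200 trees), top-k selection
(default k = 100), then a genetic algorithm (tournament selection,
uniform crossover, per-gene mutation, elitism; default population 8,
5 generations) maximising inner 3-fold CV accuracy over a small forest
hyperparameter grid. Selection and tuning never see outer test rows —
the non-nested alternative leaks labels, and a dedicated test constructs
a dataset where leakage would be visible in the selected features.
Metrics are pooled over outer folds; the positive class for recall/F1 is
fatigue (respectively severe).

## Synthetic data generator

The generator emulates the *structure the analysis assumes*, not fNIRS
biophysics:

* **Per-band ROI latents** with a prescribed correlation matrix: 8
  independent white-noise series are band-pass filtered (same filter as
  the pipeline), standardised, mixed with the symmetric PSD square root
  of the target and re-standardised. Mixing filtered noise rather than
  sinusoids keeps in-band spectra flat and correlation estimates full
  rank. Narrow bands carry few effective samples per second
  (≈ 2·bandwidth·duration), so single-session correlation estimates in
  bands I–II are intrinsically noisy; this is physics, not a bug.
* **Default coupling** (all bands): three modules — prefrontal
  {L-PFC, M-PFC, R-PFC}, eye fields {L-FEF, R-FEF}, sensorimotor
  {SMA, L-PMC, R-PMC} — with within-module correlation 0.60, three
  long-range links (L-PFC–L-FEF, R-PFC–R-FEF, M-PFC–SMA) at 0.45 and
  background 0.15. Clusters plus shortcuts is the canonical small-world
  construction and yields weighted σ > 1 in all five bands downstream.
  Band amplitudes decline with frequency (1.0, 0.9, 0.8, 0.6, 0.5) as
  hemodynamic power does.
* **Channels** copy their ROI latent plus independent Gaussian sensor
  noise (σ = 0.25). HbR = −κ·(HbO latent) + noise with κ = 0.6 (deoxy
  changes mirror oxy changes, imperfectly); HbT = HbO + HbR exactly, the
  only choice consistent with total hemoglobin's definition.
* **Fatigue-level effects** are multiplicative modifiers on the per-band
  coupling, mirroring the qualitative directions reported for task-induced
  fatigue: moderate fatigue (L2) scales right-hemisphere band-II coupling
  ×1.40 and band-III coupling ×0.30; severe fatigue (L3) scales band III
  ×0.15 and band IV ×0.70. After scaling, targets are projected back to
  the nearest valid correlation matrix (eigenvalue clipping). The
  *magnitudes* are the package's own desk-scale choices: max-normalised
  weighted clustering is nearly invariant to uniform coupling rescaling,
  so detecting a clustering effect in a 72-session study requires
  substantially stronger contrast than a 100+-session cohort would; a
  design-phase power analysis set these values once so the encoded
  band-III effect is reliably detectable at the default study size.
* **Scores**: MFI items ~ round(N(center, 1.0)) clipped to 1..5 with
  centers 1.8 / 3.0 / 4.0 for L1/L2/L3 (generative moderate/severe
  boundary at the midpoint 3.5); n-back trials (30 per session) with
  reaction time N(0.45, 0.05)/N(0.55, 0.06)/N(0.70, 0.08) s truncated at
  0.15 s and accuracy 0.95/0.88/0.78. The item spread 1.0 makes adjacent
  level distributions overlap, which is both realistic and what makes
  the threshold-scan argmax concentrate at the generative boundary
  instead of at the edge of an empty gap.
* **Study design**: full factorial, 8 sessions per (task × level) cell
  (72 sessions), 1200 s at 16 Hz per session. Per-session seeds are
  derived by hashing (master seed, participant, task, level), so growing
  the study never reshuffles existing participants.

**What passing tests show — and don't.** The synthetic studies have
stationary Gaussian signals, exact within-ROI homogeneity, no motion
artifacts, no hemodynamic response shape, no physiological nuisance
rhythms and no inter-individual variability beyond sampling noise.
Passing tests demonstrate that the pipeline recovers structure it is
pointed at and is internally consistent — not that real recordings
contain that structure.

## Problem sizes in tests and the acceptance script

The acceptance script simulates 10 sessions (default coupling, no level
effects) and reports the per-band mean weighted σ over 100 null
replicates. Recovery tests use 10 simulated studies for the band-III
effect, 20 score-only cohorts for the threshold scan, and 3 studies with
900 s sessions and a reduced hyperparameter search for the
classification benchmark — sizes chosen to make the checks sharp while
keeping a full test run in minutes.

## Known limitations

* The weighted small-world convention (threshold, then rewire) is one of
  several in the literature; `sparsity=1.0` exposes the full-matrix
  variant, whose σ is systematically ≤ 1 under a permutation null.
* k-means on 1-D scores with k = 2 assumes a bimodal-ish score
  distribution; degenerate cohorts (all scores equal) are rejected.
* The GA explores a small discrete grid; it is a tuning convenience, not
  a global optimiser.
* Band edges at 16 Hz leave bands I–III spectrally narrow; session
  lengths below ~10 minutes make band-I connectivity estimates mostly
  noise.
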