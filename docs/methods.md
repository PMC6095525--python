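# Methods

This note records the models, estimators and numerical choices behind
`eegfc`, the defaults they take, and what the synthetic test bed does and
does not establish about real EEG.

## Synthetic cohort model

Each channel carries one noisy phase oscillator per frequency band,
discretised at the sampling rate `fs`:

    θ_i[t+1] = θ_i[t] + 2π f_b / fs + Σ_j K_ij sin(θ_j[t] − θ_i[t]) / fs + σ ξ[t]

with `ξ ~ N(0,1)` i.i.d. The observed signal is the sum of the band
oscillators' cosines (equal amplitude weights) plus white measurement
noise, optionally multiplied by an instantaneous mixing matrix
`(1−m)·I + m·M`. Parameters and defaults:

| parameter | default | units | rationale |
|---|---|---|---|
| `fs` | 256 | Hz | standard clinical EEG rate for this montage |
| `n_channels` | 8 | — | Fp1, Fp2, C3, C4, T3, T4, O1, O2 |
| `duration_s` | 160 | s | 8 candidate 20 s windows, 5 analysed |
| `f_b` | geometric mean of band edges | Hz | single defensible scalar per band |
| `phase_noise_sd` (σ) | 0.4 | rad/√sample | yields mid-range PLV (~0.3–0.7) where both indices are informative |
| `measurement_noise_sd` | 0.2 | a.u. | small relative to unit-amplitude oscillators |
| coupling `K` (`k0`, `dk`) | user-set | rad/s | the relative-phase concentration scales as κ ≈ 2K/(fs σ²), so K ≈ 20 gives PLV ≈ 0.45 and K ≈ 50 gives PLV ≈ 0.8; `dk` is the planted group difference and is exposed as a free parameter because no literature value exists for the real effect sizes |
| `mixing_strength` (m) | 0 | — | `M` decays exponentially with electrode index distance and is Sinkhorn-scaled to be symmetric and doubly stochastic; a crude but monotone volume-conduction analogue |

Per-subject seeds are derived from `(cohort seed, subject index, condition)`
through `numpy.random.SeedSequence`, so cohorts are reproducible and
parallel-safe. Coupled channels are integrated with an explicit Euler loop;
uncoupled channels reduce to a vectorised cumulative sum.

The generator emulates band-specific pairwise phase coupling, group
differences, zero-lag mixing and planted non-stationary windows. It does
**not** emulate 1/f background spectra, eye-blink or muscle artifacts,
realistic head geometry, or amplitude–phase coupling. Passing tests
therefore establish that the pipeline recovers what it is designed to
measure under its own model assumptions — not that the clinical effect
sizes or accuracies would be reproduced on real recordings.

### Planted non-stationarity and the detrending null space

`inject_nonstationarity(kind="trend")` adds an exactly linear ramp
(magnitude in units of the window's detrended SD, so repeated applications
compose additively). Because the preprocessing stage removes the per-segment
best-fit line before KPSS scoring, such a ramp lies in the null space of the
detrend projection: detrend-then-KPSS scores are provably unchanged. Real
EEG drifts are not exactly linear, which is why the pipeline's
detrend-then-rank design still works in practice; tests that verify the
ranking displacement therefore score the windows as injected (z-scored
without detrending), which is the regime the KPSS statistic addresses
directly.

## Preprocessing

- Segments: `floor(T/20 s)` non-overlapping windows, linearly detrended and
  z-normalised per channel (mean and variance tolerances 1e-10); a channel
  with SD < 1e-12 raises a degenerate-channel error naming the electrode.
- KPSS: level (constant-mean) variant by default, `trend` available;
  Newey–West lag truncation `l = floor(4·(L/100)^0.25)` (= 10 at L = 5120).
  Statistics come from `statsmodels`; the table-interpolation warning for
  off-table p-values is suppressed (only the statistic is used).
- Selection: the k = 5 smallest channel-averaged statistics, ascending; ties
  broken by segment index for determinism. `random` mode (the baseline
  regime) draws k indices without replacement under a seed.
- Band-pass: order-256 Hamming-window FIR per band, applied
  forward–backward (`filtfilt`), i.e. net order 512 and exactly zero phase.
  The phrasing "zero-phase FIR of order 256" admits either forward–backward
  application or delay compensation; forward–backward was chosen because the
  zero-phase property is exact by construction. Pad length is clamped to
  `L−1` so short test segments remain filterable.

## Phase synchronisation

- Phases from the analytic signal (`scipy.signal.hilbert`), wrapped to
  (−π, π]. The first and last 0.5 s of every segment are excluded before
  averaging, suppressing filter/Hilbert boundary transients (the window
  length was chosen as a few cycles of the slowest band).
- Relative phase for PLV is wrapped to [0, 2π); for PLI the signed
  difference wrapped to (−π, π] is used, since an absolute value would
  collapse the lead/lag sign that PLI is built on. `sign(0) = −1`.
- Subject-level matrices are the arithmetic mean of per-segment index
  values over the 5 analysis segments (pooling phases across segments
  before estimating a single index is the main alternative; averaging was
  chosen so each segment contributes one independent estimate).

## Twin surrogates

- Embedding: delay `τ` = first strict local minimum of the lagged mutual
  information (16 equal-width bins, lags 1..64; fallback τ = fs/10 with a
  warning when no interior minimum exists); dimension `m` = smallest value
  in 1..10 whose Kennel false-nearest-neighbour fraction (tolerance ratio
  10) drops below 1%, else the argmin fraction with a warning. White noise
  has no finite embedding dimension, and its FNN fraction decays slowly —
  the estimator then settles around m ≈ 5–6, which is recorded rather than
  hidden.
- Recurrence threshold δ: the 10% quantile of off-diagonal max-norm
  distances between delay vectors (mid-range recurrence rate standard in
  this literature); a Theiler window of `m·τ` samples is blanked so
  temporal neighbours are not declared twins.
- Twins are points with byte-identical recurrence columns. Continuous noisy
  signals often have none; the surrogates then degenerate to randomly
  restarted runs of the original trajectory (warned once), which is a
  weaker but still valid null. Empirically the rank of the original PLV
  among 99 surrogates under independence is near-uniform (mean rank ≈ 47 of
  99), so the p < 0.01 one-sided test is slightly conservative — its
  rejection rate over 200 independent pairs sits in the binomial band
  [0, 5] used by the calibration test.
- Per pair, the lower-index channel is surrogated and the partner left
  untouched (the test criterion compares the original index against all 99
  surrogate pairings). A subject-level entry survives thresholding iff it
  is significant in a strict majority of the 5 segments; majority
  aggregation was chosen for robustness, the alternative (all-segments)
  being much more conservative.

## SCA estimator

The single-cluster model `A_il ≈ ρ_i ρ_l (i ≠ l)` is fitted by an iterated
diagonal-corrected leading-eigenpair factorisation: the uninformative unit
diagonal is replaced by off-diagonal row means, then repeatedly by `ρ_i²`,
with `ρ = √λ₁·v₁` (sign-fixed nonnegative, clipped to [0, 1]) until
`max|Δρ| < 1e-10` or 100 iterations. On an exact outer-product matrix the
fixed point recovers the generating ρ (construct-and-recover tests assert
1e-6). The cluster strength is `r = λ₁/N`, so `r ∈ [0, 1]` with `r = 1` iff
all `ρ_i = 1`. A fully thresholded (all-zero off-diagonal) matrix raises an
explicit `sca-inapplicable` error, which the experiment grid converts into
skip markers for the SCA variants of the thresholded dataset.

## Feature selection

- Discretization: supervised Fayyad–Irani MDLP (recursive entropy cuts,
  each accepted only if the information gain passes the MDL test). Features
  with no accepted cut collapse to one bin and thus have SU = 0 — on small
  cohorts this is most of them, which is what makes FCBF on 280 features
  tractable. Equal-frequency binning is available as a config alternative.
- FCBF with relevance threshold δ = 0 (no rule exists for tuning it);
  ordering ties broken lexicographically for determinism. The
  implementation is checked against a direct transcription of the
  approximate-Markov-blanket definitions on random tables.
- Scatter Search: population 50, reference set 10 (5 by quality, 5 by
  max-min Hamming diversity), all 2-subset combinations, child =
  intersection plus coin-flip symmetric difference (repaired non-empty),
  improvement = first-improvement bit-flip hill climb on the CFS merit,
  static reference-set update, stop when the set is unchanged or after 50
  rounds; deterministic given the seed. The candidate pool is restricted to
  features with nonzero class-SU: adding a zero-SU feature leaves the CFS
  numerator unchanged and strictly grows the denominator, so the optimum
  provably excludes them.

## Bayesian-network classifier

- Score: BDeu (Bayesian Dirichlet with uniform structure prior, equivalent
  sample size 1), decomposable per node; verified against a closed-form
  Dirichlet-multinomial counting oracle.
- Class edges Y → X_i are fixed; searches move only feature-feature edges,
  with at most 2 feature parents per node by default (configurable to 4).
- K2 ordering: class first, then features by descending SU with the class,
  ties lexicographic. HC starts from naive Bayes and applies the best
  strictly-improving add/delete/reverse; tie-break is the canonical
  enumeration add < delete < reverse, lexicographic pairs. LHC expands the
  5 best moves 2 plies and applies the first move of the best cumulative
  sequence; visited structures are tracked so a look-ahead cannot cycle,
  and the best-seen structure is returned. Single-bin (uninformative)
  features are excluded from edge moves — their local scores are invariant
  to any parent change, so this is an exact pruning.
- CPTs: add-one (Laplace) smoothed conditional frequencies; unseen parent
  configurations give uniform rows. Posterior ties at prediction resolve to
  the negative (control) class.

## Evaluation

- LOOCV holds out one subject per fold; discretization, structure search
  and CPT fitting always happen on the training fold only. The selector
  runs once on the full table before cross-validation in the default
  *faithful* mode (reproducing the original protocol — a known selection
  leakage that inflates estimates), or inside every fold in *nested* mode
  for honest estimates.
- Sensitivity = TP/(TP+FN) with the patient group positive; specificity =
  TN/(TN+FP); accuracy = (TP+TN)/n. Undefined ratios are reported as NaN,
  never as 0. Grid rows with accuracy ≥ 0.70 are flagged.
- Failures inside a grid cell (e.g. a search that cannot run) are recorded
  as `na` rows with the exception attached, not raised.

## Problem sizes used by the test suite

The suite exercises every stage at sizes chosen to keep the complete run in
a few minutes on one core while leaving each statistical check adequately
powered: end-to-end planted-effect recovery uses a 20+20 cohort at full
segment length (160 s per condition, five 20 s segments); the grid test
uses a 2+2 cohort with 4 s segments, two bands and 19 surrogates (the rank
test then operates at p < 0.05 instead of p < 0.01 — the mechanism under
test is identical); surrogate calibration uses 200 independent 512-sample
pairs with 99 surrogates each.

## Known limitations

- Twin surrogates of continuous noisy data usually degenerate to restarted
  trajectory runs (no exact twins); the test stays valid but is mildly
  conservative.
- The exactly-linear planted trend is invisible to detrend-then-KPSS
  ranking (see above); it remains useful for testing the scoring path
  itself.
- SCA assumes a single synchronisation cluster; multi-cluster structure is
  projected onto the leading eigenpair.
- The faithful selector mode leaks selection information across folds by
  design; use nested mode when an unbiased estimate matters.
- With cohorts of tens of subjects, MDLP accepts few cuts and many grid
  cells degenerate to majority-class prediction (sensitivity 1, specificity
  0); this is a property of the method at this sample size, not a defect of
  the implementation.
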