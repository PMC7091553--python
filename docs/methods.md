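# Methods

This note documents the models and procedures implemented in `alelm`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data experiments do and do not demonstrate.

## Regularized ELM

The classifier is a single-hidden-layer feedforward network whose hidden
parameters are never trained.  For inputs `x ∈ ℝᵖ` and `M` hidden neurons,
the hidden output matrix is `H[j,i] = g(aᵢ·xⱼ + bᵢ)`; only the linear
output map `β ∈ ℝ^{M×q}` is fit, by minimizing
`½‖β‖² + (c/2)‖Hβ − Y‖²` with one-vs-rest targets `Y`.

Choices and rationale:

- **Hidden-parameter distributions.**  Weights i.i.d. uniform on [−1, 1],
  biases uniform on [0, 1] — the common ELM convention.  The layer is a
  pure function of its integer seed and is stored with the model, so a
  serialized model reproduces its predictions exactly.
- **Target encoding.**  One-vs-rest ±1 by default.  The sigmoid posterior
  map places probability 0.5 at decision value 0, which is the class
  boundary only under a symmetric encoding; a 0/1 encoding is available
  (`target_encoding="zero-one"`) for users who prefer regression-style
  targets, but it shifts the posterior calibration point and is not the
  default.
- **Activation.**  Sigmoid by default; a Gaussian `g(z) = e^{−z²}` is
  available behind the same config switch.
- **Standardization.**  Features are z-scored with training-set (i.e.
  labeled-set) statistics before the random projection, and the same
  statistics standardize candidate features before any cosine computation.
  Without this, the random projection saturates on badly scaled features
  and cosine angles are dominated by whichever feature has the largest
  units.  Constant features receive unit scale.
- **Linear algebra.**  Both closed-form branches (`N > M` primal, `N ≤ M`
  dual) are symmetric positive-definite solves (`scipy.linalg.solve`,
  `assume_a="pos"`); no matrix is ever explicitly inverted.  The two
  branches agree to ~1e-14 at `N = M` (verified against an independent
  eigendecomposition solver in the tests).
- **Posterior guard.**  If a row's sigmoid outputs all underflow to zero,
  the row falls back to the uniform distribution `1/q`.  This cannot change
  any ordering derived from finite decision values.
- **Tie-breaks.**  Argmax prediction ties resolve to the lowest class
  index; every selection tie in the query strategies resolves to the lowest
  candidate index.  Nothing in the pipeline depends on dict ordering or
  unstable sorts, so the whole train → query → predict path is a pure
  function of (data, M, c, seed).

## Query strategies

- **BvSB uncertainty** (`bvsb_scores`): difference of the two largest
  posterior entries; in [0, 1], smaller = more uncertain.  For many-class
  problems this is a better-behaved uncertainty measure than entropy
  because it ignores the probability mass spread over irrelevant classes.
- **Diversity**: the similarity of a candidate to a set is its *maximum*
  cosine to any member (a worst-case, not average, notion — one
  near-duplicate is enough to mark a candidate redundant).  The combined
  criterion adds the similarity to the already-picked batch and to the
  labeled set, so it penalizes both intra-batch redundancy and re-querying
  regions already labeled.  Zero vectors get similarity 0 (orthogonal-like)
  rather than NaN, and are logged.
- **Batch selection** is sequential greedy: screen the pool to the `h`
  most uncertain candidates, then `m` times pick the argmin of
  `λ·BvSB + (1−λ)·(div to picked + div to labeled)`.  The first pick's
  batch-diversity term is 0 (empty set).  Greedy is the standard reading
  for this family of batch-mode criteria; each step is verified against an
  exhaustive per-step scan in the tests.
- **Baselines**: margin sampling operates on *raw* decision values (a
  config switch moves it to mapped posteriors); entropy uses natural log
  (base only rescales the ranking); random selection is the
  passive-learning control and is the only strategy that consumes the run's
  random generator.

`h` defaults to the rule `5m`; near pool exhaustion it is clamped to the
remaining pool size.

## The active-learning loop

Each round: train the ELM on the labeled set `L`, record test accuracy,
stop-check, query `m` pool samples, reveal their labels, move them to `L`.
Conventions:

- **Curve convention.**  `y₀` is the accuracy of the model trained on the
  initial labeled set, before any query; a run with `N_iter` query rounds
  records `N_iter + 1` accuracies, matching the `N_iter` trapezoids of the
  ALC formula.
- **Batch size.**  A fractional `m` resolves against the *original* pool
  size (rounded to nearest, at least 1) and stays fixed; if fewer than `m`
  samples remain, the remainder is queried and the loop stops.
- **Stop rule.**  Stop when strictly more than `max_fraction` (default
  0.8) of the original pool has been queried, or when the last
  `stabilize_window = 3` recorded accuracies all lie within
  `stabilize_tol = 1e-3` of each other.  "Accuracy stabilized" admits many
  operationalizations; a short window with a tight tolerance was chosen so
  the budget cap — which is always active — remains the binding rule except
  on genuinely flat curves.  Both knobs are configurable; setting
  `stabilize_tol=0` disables the stability clause.
- **Regularizer.**  `c` is a fixed positive number by default (1.0).  With
  `c="auto"` it is re-selected every round by minimum PRESS on the current
  labeled set over the grid `e⁻⁵, e⁻⁴·⁵, …, e⁵` — coarser than the tuning
  grid in `model_selection` because it runs once per round.
- **Determinism.**  A run is bit-reproducible from `config.seed`: the
  hidden layer uses the seed directly, the random baseline draws from a
  generator created at run start, and all other selection is tie-broken by
  index.  `run_experiment` uses seeds `seed+0 … seed+n_runs−1`.

## Model selection

- **PRESS.**  For ridge with fixed penalty, the leave-one-out residual of
  sample j is exactly `rⱼ/(1 − hatⱼⱼ)` with
  `HAT = H(HᵀH + I/c)⁻¹Hᵀ` — the Sherman–Morrison argument for ordinary
  least squares carries over unchanged because removing a sample leaves the
  penalty term intact.  The dual form `HHᵀ(HHᵀ + I/c)⁻¹` is used when
  `N ≤ M`; by the push-through identity both give the same hat matrix.
  The implementation is validated against brute-force N-refit LOO to 1e-6,
  which is what makes the shortcut safe to rely on.  Leverages within
  1e-12 of 1 are clamped with a warning.
- **Selecting M** uses stratified k-fold CV with `c` re-selected per fold
  by PRESS, so M's score is not hostage to a single global `c`.  Folds are
  reduced (with a warning) if the smallest class has fewer members than
  `folds`.
- **Selecting λ.**  No single obvious objective exists for a tradeoff
  parameter that only matters *during* learning; the package scores each λ
  by the ALC of a short seeded active-learning simulation (labeled data
  split 20/80 into initial set and internal pool, curve scored on the
  user's validation split) and returns the argmax.  Users who skip tuning
  can pass λ directly (default 0.5).  All selectors break ties toward the
  smallest grid value.

## EEG pipeline

- **Windowing**: epochs are cropped to cue-relative seconds (default
  0.5–2.5 s; cue at t = 0, indices 0-based, windows half-open).  The stored
  window is the one actually achieved on the sample grid, so repeated crops
  compose exactly.
- **Filtering**: fifth-order Butterworth band-pass 8–30 Hz, applied
  forward-backward (`sosfiltfilt`) by default.  Zero-phase filtering
  doubles the effective order but leaves the phase of the short 2-s window
  untouched, which matters because CSP consumes second-order statistics of
  the windowed signal; a single causal pass is available via
  `zero_phase=False`.
- **OVR-CSP**: per-trial spatial covariances are normalized by their trace
  (making features invariant to global gain), averaged per class, and each
  class's filters solve the generalized eigenproblem of
  `(C_k, C_k + C_rest)`.  Eigenvectors come out `(C_k + C_rest)`-orthonormal
  — the whitening property the tests assert to 1e-6.  Three filters from
  each end of the spectrum (6 per class, 24 features for 4 classes) is the
  conventional split; only the total feature dimension is externally
  constrained, the 3+3 split is this package's default.  Features are
  log-variances of the filtered signals, normalized within each class's
  filter block; a variance floor of 1e-12 guards degenerate (e.g. all-zero)
  trials, and near-singular composite covariances are ridge-regularized by
  `1e-8·trace/channels` with a warning.
- **GDF input** is delegated to an optional adapter built on MNE
  (`read_gdf_epochs`); the core consumes only the documented HDF5/ndarray
  epoch container and never parses GDF itself.

## Synthetic data

- **Gaussian-mixture pools** emulate the benchmark setup for pool-based AL:
  a small labeled set (10 %), a large pool (40 %) and a test half,
  stratified by class.  The default spec is 3 equiprobable unit-covariance
  classes in 6 dimensions with means at `2·e_k` — pairwise mean distance
  2√2 standard deviations, i.e. moderate overlap: a small labeled set
  trains a clearly sub-asymptotic classifier, leaving measurable room for
  querying to help, while `n = 600` keeps a full multi-strategy,
  multi-seed experiment in the low seconds on one CPU.  The
  redundant-pool variant replicates pool points with isotropic jitter of
  1e-3 × the per-feature std, keeping within-replicate cosine above 0.999 —
  a direct probe of the diversity term.
- **Oscillatory EEG** epochs are white noise plus a band-limited
  oscillation (variance 6, i.e. ~8 dB above the unit-variance background)
  on a class-specific channel pair, each class in its own sub-band of
  8–30 Hz; 80 trials/class, 8 channels, 250 Hz, 3-s epochs.  This
  reproduces exactly the structure CSP assumes — class-dependent
  *stationary band power with a fixed spatial pattern* — and nothing else:
  no volume conduction, no artifacts, no non-stationarity, no
  between-session drift.  Passing pipeline tests therefore demonstrate
  correctness of the windowing/filtering/CSP/ELM chain, not expected
  accuracy on real recordings, where class-conditional band-power
  differences are far subtler (real four-class motor-imagery accuracies
  typically fall in the 50–85 % range rather than near 100 %).

The same caveat applies to the active-learning simulations: on the default
mixture the learning curves rise only a few points from `y₀` to the
full-pool plateau, so ALC differences between strategies are small; the
simulations verify the machinery (bookkeeping, determinism, the ordering of
double-criteria vs. random selection under the stated conditions), not the
magnitude of gains on harder real datasets.

## Problem sizes

Default test and acceptance workloads are deliberately desk-scale: mixtures
of ≤ 600 points in 6 dimensions, 10-seed experiments, EEG fixtures of
320 trials × 8 channels × 750 samples.  The full test suite runs in well
under a minute on a single CPU; `scripts/acceptance.py` in a few seconds.

## Known limitations

- No online/sequential ELM updates; each round refits from scratch (cheap
  at these sizes, quadratic-ish in `M` and `|L|`).
- The margin baseline's historical definition (raw outputs vs posteriors)
  is ambiguous in the literature; both are implemented, raw is the default.
- `select_lambda`'s objective is a design choice (validation ALC of an
  internal simulation); other objectives (final accuracy, CV accuracy) are
  defensible and may pick different λ on flat score tables.
- OVR-CSP assumes stationary, epoch-aligned band power; no filter-bank or
  Riemannian variants, no artifact handling, no channel selection.
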