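# Methods

`oddballiem` re-implements, as a tested and fully synthetic-data-driven
pipeline, the forward (inverted) encoding analysis used to ask whether
surprising visual stimuli evoke mismatch-coded neural responses and whether
attention boosts them. This note documents the models, the choices that were
genuinely open, and what the synthetic experiments do and do not show.

## Stimulus design

The roving-oddball design presents a periodic stream of oriented gratings
(100 ms on, 500 ms inter-stimulus interval, 415 gratings per block; nine
orientations, 0–160° in 20° steps). In *roving* blocks an orientation
repeats 4–11 times (*standards*; the 5th–7th repetitions are the labelled
standards) before jumping to a new orientation (*deviant*). In
*equiprobable* blocks the orientation changes on every presentation
(*controls*) — unpredictable, but never establishing an expectation.

Orientation order is counterbalanced with modified de Bruijn sequences:
Eulerian circuits (Hierholzer, with seeded random edge ordering so different
sessions get different valid sequences) on

- the complete digraph over 9 symbols (each ordered distinct pair once as a
  cyclic 2-window, length 72), and
- the digraph whose nodes are ordered distinct pairs and whose edges are
  ordered all-pairwise-distinct triples (each such triple once, length
  9·8·7 = 504).

The all-distinct reading of "no successive repetitions" is forced by the
printed length (504; the weaker no-immediate-repeat reading gives 576). The
master sequence concatenates two triple copies and three pair copies
(1,224 symbols). Concatenating cyclic sequences can create an immediate
repeat at the triple→pair seam; the pair sequence is rotated until its first
symbol differs from the preceding symbol — rotation leaves the cyclic window
census invariant. Pair-transition counts in the master sequence are
near-uniform (seams allow an imbalance of a few counts), so decoding of any
orientation is not biased by the preceding one.

Train lengths are sampled from the relative weights (31, 31, 31, 23, 5, 5,
5, 5) over 4..11. The printed counts do not reconcile exactly with 18 blocks
of 415 gratings under per-orientation balancing, so the weights are treated
as a sampling distribution, not a per-block quota; the last train of each
block is truncated at the block boundary. Targets (18 per block, 2 per
orientation, pairwise onsets ≥ 1.5 s) are placed by bounded rejection over
orientations in random order; fixation-dot events (18 per block, same gap
rule) are drawn uniformly under the gap constraint with the exact spacing
construction (shrink the interval by the total gap, draw order statistics,
re-inflate), which is uniform over the constrained set and never needs
retries.

The signed mismatch angle (current − previous orientation in 180° space) is
mapped to the half-open interval (−90°, 90°], giving the orthogonal
deviation the unique representative +90° (unreachable on the 20° grid but
well defined). The first stimulus of a block has no predecessor; its
mismatch angle is missing and such trials are excluded from mismatch
decoding.

## Generative model of the epochs

The simulator is the exact inverse of the decoder's linear model
B = WC + N. Per trial, the 64-electrode (configurable) signal is

- an orientation component: a fixed electrodes × 9 spatial-pattern matrix
  (random unit-norm columns, pairwise correlations kept below 0.9) times the
  rectified-cosine basis response to the presented orientation, scaled by a
  condition × attention gain and a gamma-shaped post-stimulus envelope
  peaking at 130 ms;
- for deviants only, a mismatch component on a second, independent pattern
  matrix, coded on the same 9-channel basis at the wrapped mismatch angle
  (optionally at a fixed 90° in "orthogonal mismatch" mode), with gain
  `base(attention) · (1 + 0.12·(preceding standards − 4)) ·
  (1 + 0.25·(|deviation|/20° − 1))` and an envelope peaking at 400 ms;
- spatially correlated noise (a fixed random electrodes × sources mixing of
  white sources, SD 1.0) plus independent sensor noise (SD 0.5).

Epochs span −150 to +650 ms at 256 Hz (205 samples) and are baseline
corrected over −100 to 0 ms, matching the analysis contract.

Default gains (orientation 0.08 attended / 0.05 ignored; mismatch 0.08
deviant-attended / 0.04 deviant-ignored / 0 for controls) encode the
hypothesis structure under study — attention boosts orientation coding
everywhere and gates a deviant-only mismatch code that strengthens with
prediction strength and deviation magnitude. Their magnitudes are calibrated
so the decoded profile amplitudes land in the 0.1–0.7 a.u. range of real
recordings: the estimator's per-channel scalar regression spills correlated
channel signal into every weight vector, so fitted amplitudes run roughly
five times the injected gain at these noise levels. The noise model has no
1/f structure, no artefacts, and no biophysical source geometry: passing
recovery tests shows the estimator chain is correct and well calibrated
under its own assumptions, not that it is robust to real EEG confounds.

## Inverted encoding

Channels are nine half-wave rectified cosines raised to the 8th power,
centred on the orientation grid. Angle differences are wrapped explicitly
into [−90°, 90°] on the 180° circle; within that range the cosine is
non-negative, so this is equivalent to the angle-doubling formulation. A
useful analytic invariant used by the tests: the nine channels sum to
9·C(8,4)/2⁸ = 2.4609375 at every angle (all harmonics of cos⁸ cancel over
nine equispaced centres).

Per time point (after a 27.3 ms moving average — the widest odd window under
30 ms at 256 Hz, 7 samples) and channel *i*:

- weights  w_i = B c_iᵀ (c_i c_iᵀ)⁻¹ on per-electrode de-meaned training
  data (per-channel scalar least squares, not multivariate OLS — this is the
  estimator's defining choice);
- residual covariance Σ̃_i = ε_i ε_iᵀ/(n−1), shrunk toward ν·I (ν = mean
  eigenvalue) with the analytic Ledoit–Wolf intensity, computed in-package
  and vectorized over channels via the identity
  Σ_t ‖x_t x_tᵀ − S‖²_F = Σ_t ‖x_t‖⁴ − n‖S‖²_F (the test suite checks it
  against scikit-learn's `ledoit_wolf_shrinkage` and a textbook loop);
- filter  v_i = Σ̃_i⁻¹ w_i / (w_iᵀ Σ̃_i⁻¹ w_i), which satisfies the
  unit-gain constraint v_iᵀ w_i = 1 exactly.

Held-out data are decoded as C_test = Vᵀ B_test after de-meaning with the
*training* electrode means — the original description states de-meaning only
for training; reusing train means keeps the affine contract consistent and
avoids test-set leakage. Single-trial channel responses are circularly
shifted so the coded channel sits at offset 0 (−80…+80°) and averaged per
condition.

Cross-validation uses 3 folds at block granularity, iterated (100 by
default; reduced-scale runs use 10). Blocks are dealt round-robin to folds
*stratified by each block's label composition* (with a random starting
fold per stratum), so every condition reaches every fold whenever it spans
at least as many blocks as folds; a condition that cannot be placed raises a
configuration error naming it. Within each fold, per-condition trial counts
are balanced to the smallest count by selecting the least-used trials
(seeded random tie-breaks), accumulating usage across iterations. Mismatch
decoding re-codes the design matrix at the wrapped mismatch angle (−40° maps
to the 140° channel). Temporal generalization trains at each strided time
point and tests at all of them under the same cross-validation contract; at
full scale (205 samples, 7-sample window, stride 3) the valid strided axis
has 67 points with symmetric margins — one more than the 66 a
trim-both-margins-after-striding convention yields; the diagonal equals the
on-axis time course exactly at matched seeds.

## Tuning quantification

Centered profiles are summarised by y(x) = A·exp(κ(cos(2π(x−μ)/180) − 1)) + b
— the cosine taken on the doubled angle so the function has a 180° period
and its trough 90° from the centre (the cos² reading halves the period and
cannot represent the observed profiles). Bounded trust-region-reflective
least squares with the conventional constraints A ∈ (−0.5, 2),
κ ∈ (1.5, 200), b ∈ (−1, 0.5) and initial values (0.5, 2, 0); μ is pinned at
0 for centered profiles and free in [−90°, 90°] for individual mismatch
channels, initialised at the strongest channel to avoid inverted fits. The
asymmetric A/b lower bounds are honoured verbatim and configurable. Fits are
unweighted over the nine channel values; per-cell failures in time-course
sweeps are recorded (`converged=False`), never raised.

## Inference

- **Cluster permutation**: dependent-samples t (two conditions) or one-way
  repeated-measures F (three; one-tailed by construction) per sample;
  samples above the α = 0.05 parametric threshold form clusters by run
  contiguity (1-D) or 4-connectivity (2-D train × test grids — the
  connectivity of the original toolbox is not documented, 4-connectivity is
  the conservative choice); clusters are scored by summed statistic
  (maxsum). The null permutes condition labels independently within each
  participant; cluster p = (r+1)/(n_perm+1), never zero. Interaction tests
  operate on attended-minus-ignored difference maps per prediction
  condition.
- **Univariate sensitivity**: each electrode/time signal is regressed on
  [sin 2θ, cos 2θ, 1]; angles are doubled so 180° circularity maps onto the
  full circle (not stated in the original description but required for
  orientation data). S = √(β_sin² + β_cos²) is rank-normalised against a
  design-shuffling null (1,000 permutations) and z-scored through the
  inverse normal CDF with the mid-rank convention (r + 0.5)/(n + 1), keeping
  z finite.
- **Bayes factors**: uniform-prior marginal likelihood over the point-null
  likelihood, BF₁₀ = [(Φ((u−m)/se) − Φ((l−m)/se))/(u−l)] / φ(m; 0, se),
  verified against numerical quadrature to 1e−6.

## Reduced-scale defaults and runtime

The full design (18 roving + 3 equiprobable blocks × 2 sessions, 64
electrodes, 100 iterations, 5,000 permutations) is supported but the
package's canned experiments run at a reduced scale chosen as the smallest
configuration that preserves every structural property of the design: 3
roving + 3 equiprobable full-size blocks per attention condition (≈ 5,000
trials), 32 electrodes, 10 cross-validation iterations, ~40 decoded time
points (stride 5), 500 permutations. At this scale the single-participant
recovery study takes ~35 s and the statistical-calibration suite ~15 s on
one CPU.

## Known limitations

- The generator shares the decoder's basis; recovery results do not probe
  basis mismatch (off-grid orientations are rejected by design).
- No 1/f noise, artefacts, or volume-conduction geometry; calibration of the
  cluster tests is demonstrated under exchangeable synthetic nulls only.
- Fitted amplitude is not an unbiased estimate of injected gain (see the
  ~5× spillover factor above); all scientific comparisons are within-scale
  contrasts, which the recovery tests mirror.
- Reproduction of the original human-data effect windows and amplitudes
  requires the deposited dataset and is out of scope.
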