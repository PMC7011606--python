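# Methods

This note documents the models, the synthetic data they are exercised on,
and the numerical choices, in enough detail to judge what the tests do and
do not establish.

## Video representation

A clip is reduced to a fixed-length vector in three stages.

**Dense trajectories.** Points are seeded at the centers of a regular grid
(stride 5 px) in every frame whose cell holds no active track, advected by
dense optical flow (iterative Lucas–Kanade, radius 5, each component
median-filtered 3×3 before sampling), and tracked for exactly L = 15
frames — about one second at the 15 fps of the camera network this
pipeline targets. Tracks that leave the image are dropped; finished tracks
with total displacement below 1 px are discarded as static. Camera-motion
compensation is deliberately omitted: the cameras are fixed, so the
background is static and produces no trajectories. Points seeded just
ahead of a moving object are picked up mid-window and yield
partial-displacement tracks; analyses that need pure object tracks raise
`min_displacement` accordingly.

**Descriptors.** Each trajectory contributes 220 dimensions: the 28-dim
shape block (the 14 displacement vectors, L1-normalized by the total
displacement magnitude, hence invariant to uniform speed scaling), and
8-bin orientation histograms of optical flow (motion, 96 dims) and of
image gradients (appearance, 96 dims) over a 16×16 px tube split into
2×2 spatial × 3 temporal cells, each histogram magnitude-weighted and the
motion/appearance blocks L2-normalized. Gradient-based appearance is
invariant to affine intensity changes; tubes at the image border are
clamped. Blocks with no signal (e.g. zero-contrast tubes) stay exactly
zero rather than being normalized.

**Fisher encoding.** Descriptors are PCA-projected to half their dimension
(default) and modeled by a K = 64 diagonal Gaussian mixture fitted on
training descriptors only. A video's embedding concatenates per-component
first- and second-order deviation blocks (2·K·D′ dims), then applies the
signed square root and L2 normalization. The encoding is an average over
descriptors, so duplicating a descriptor set changes nothing, and a video
with no usable trajectories encodes to a flagged zero vector so that
downstream multi-view learning can treat the view as uninformative — a
fully occluded camera must not crash the pipeline.

The mixture fit floors per-dimension variances at `reg_covar = 1e-3`. This
matters at the descriptor-sample sizes used here (10²–10⁴): without the
floor the mixture collapses onto near-degenerate clusters whose inverse
standard deviations dominate the encoding and erase class structure. At
realistic sample sizes (millions of descriptors) the floor is inactive.

## Multi-view classification

Both classifiers are one-vs-rest linear SVMs (squared hinge, C = 1,
liblinear primal solver, tol 1e-7) over the four classes in the fixed
order crawling, sitting, standing, walking. Class-balanced weighting is
not applied; the protocol's stratified splits keep training proportions
equal to the data's.

*SVM-MV* trains on the label-transfer expansion (every view inherits its
bag's label) and fuses per-view predictions by majority vote. Vote ties —
possible with 5 votes over 4 classes — break toward the larger sum of
per-view decision scores among the tied classes, then toward the earlier
class in the fixed order.

*MI-SVM* starts each class from the label-transfer training set
(iteration 0: all views of positive bags are candidate positives), then
alternates witness selection (the view with the highest current decision
score in each positive bag) with refitting on witnesses versus all views
of negative bags, stopping when the witness assignment repeats or after
20 alternations (a non-converged model is returned with its flag set).
The regularized squared-hinge objective on the witness training set is
non-increasing across rounds up to solver tolerance; the per-class
objective history is kept on the model for inspection. Bags missing some
views simply contribute fewer votes / fewer score candidates; nothing is
imputed.

**Split protocol.** Per class the training count is
⌈train_frac · n⌉ — with the benchmark's class sizes (166, 228, 406, 248)
and train_frac = 0.8 this ceiling rounding is the one convention that
yields exactly 840 training and 208 test instances per split (4200 and
1040 per-view videos). Split *i* of a plan is shuffled with seed
`seed + i`. Accuracy is the percentage of correctly classified test
instances, averaged over splits; confusion matrices are row-normalized to
percent with ground truth on rows.

## The CRI Markov decision process

States (NL, L, T/A, M) and actions (f, s, b) are fixed; T/A is a single
merged touching-or-aroused state. Utilities default to u = (0, 0, 1, 2)
and are collected on *entering* a state. The sufficient statistic is the
integer count tensor N[s, a, s′], updated online one observed transition
at a time.

Two estimators share the counts. Maximum likelihood divides each row by
its total and deliberately returns *undefined* (NaN) rows for unobserved
(state, action) pairs — distinct from a uniform default, so that planning
on unestimated rows fails loudly and forces an explicit smoothing choice.
Additive smoothing with λ > 0 (default λ = 1, configurable to study the
sparse-data regime) makes every row strictly positive and row-stochastic
and converges to ML as λ → 0. The smoothing family is additive because it
has a transparent closed form; nothing downstream depends on that
particular choice.

Value iteration (γ default 0.95, sup-norm tolerance 1e-8) maximizes
expected discounted utility; greedy ties break toward the earlier action
in (f, s, b). Correctness is checked against exhaustive enumeration: all
3⁴ = 81 deterministic stationary policies evaluated exactly by solving
(I − γP_π)V = R_π. The *regular* policy — the human-operator baseline —
is encoded as NL→f, L→f, T/A→s, M→b; this mapping is an interpretation of
the operators' narrative strategy (approach a disengaged child, hold
while touched, retreat when chased) and is flagged as such in the code.

Sessions are scored by the sum of utilities of the states entered,
divided by session duration (so sessions of different lengths compare),
and between-session change is the absolute difference of those rates.

## Synthetic data

**Scene renderer.** 48×64 px grayscale frames, five views with small
horizontal viewpoint shifts, a static noise-textured background, and a
single child agent drawn as a soft elliptical blob whose kinematics
follow the scripted archetype: crawling (low, wide, slow horizontal
oscillation), sitting (small, low, subtle sway), standing (tall, narrow,
subtle bob), walking (tall, fast horizontal gait). Sitting and standing
are deliberately near-static so that, as with trajectory features on real
footage, the static pair is the hard one. Occlusion hides the child
behind a static mask per (view, segment) with the scripted probability
and flips the per-frame visibility flag; distractor agents re-use
archetype motions elsewhere in the scene. Rendering is 2-D orthographic;
no 3-D camera model is attempted — the goal is to exercise the pipeline,
not photorealism.

**Feature-space bags.** For classifier benchmarks at scale, per-view
features are drawn directly: class means of norm 3 (unit isotropic
noise), and with probability 0.4 a view is replaced by a draw from the
shared zero-mean background distribution and recorded as uninformative.
This reproduces the mechanism that separates the two classifiers — label
transfer trains SVM-MV on background views carrying class labels, and
majority voting loses when most views are occluded, while MI-SVM's
witness selection and max-over-views scoring sidestep both. Default class
counts are the benchmark proportions 166/228/406/248.

**Child profiles.** Two synthetic fixtures, not calibrated to any
subject: a *responsive* child (retreating sustains and converts
engagement; e.g. the M-row under b keeps 0.85 mass on M) and a
*distractible* child (fast decay to NL under every action).
Inter-transition times are exponential with mean dwell 2 s — no timing
structure beyond a rate is needed, since only time-normalized utilities
are consumed downstream. Recovery experiments explore with uniform random
actions to guarantee row coverage.

What passing tests show — and do not. The simulators demonstrate that the
estimators, planner, and classifiers behave correctly under their own
modeling assumptions (Markov child, stationary tensors, Gaussian view
features, blob kinematics). They cannot certify accuracy levels on real
multi-child footage: real descriptor distributions, annotation noise, and
non-stationary child behavior are outside the generators' scope, which is
why the benchmark assertions are directional (e.g. MI-SVM ≥ SVM-MV under
occlusion) rather than absolute.

## Problem sizes and numerics

Tests and the acceptance script use: 20 random MDPs for the
planner-enumeration check; 10,000 transitions for ML consistency
(total-variation < 0.05) and 30 transitions × 100 seeds for the sparse
regime; 100 paired 180-s sessions for the policy contrast; the full
1048-bag benchmark with five splits for the classifier comparison; and
rendered end-to-end runs at 6 instances/class × 3 views × 20-frame
segments, enough for the >85% end-to-end sanity bound while keeping the
optical-flow cost modest. Numerical tolerances: row-stochasticity 1e-9;
value-iteration tolerance 1e-8 with exact linear-solve policy evaluation
as oracle; MI-SVM objective monotonicity asserted to 1e-4 relative (the
solver's duality gap); closed-form shape agreement to 0.02 absolute per
component (flow estimation error on clean translation is well below
this).

## Known limitations

- The trajectory extractor is a simplified scheme: no warped-flow camera
  compensation, no multi-scale pyramid, nearest-neighbor flow sampling.
- Optical flow in perfectly textureless moving regions is ambiguous and
  the iterative LK filler can propagate motion into flat areas; the
  renderer's textured background avoids this, but untextured real footage
  would not.
- Temporal action detection is out of scope: instance boundaries come
  from per-frame annotations (run-length segmentation with half-open,
  0-based frame intervals), not from the classifier.
- The MDP assumes a stationary, fully observed child state; partially
  observable variants are not implemented.
- Episode logs record state *entries*; utility accumulation counts each
  logged entry once, so a different logging convention (e.g. per-time-step
  sampling) would rescale rates.
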