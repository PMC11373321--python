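# Methods

`morphembed` learns fixed-length vector representations of single-neuron
morphology without labels.  A neuron reconstruction (SWC) is treated as a
rooted tree of typed 3-D points; a graph transformer summarizes it into one
CLS vector; the encoder is pre-trained by teacher–student self-distillation
over connectivity-preserving augmentations.  This note records the model,
the defaults and why, the numerical choices, and what the synthetic test
bench does and does not show.

## Input representation

An SWC file is parsed in two passes (nodes, then parent links), so
child-before-parent line order is legal.  Type codes outside 1–4 are
preserved; files with several parent=−1 fragments keep the largest
component in lenient mode and are rejected in strict mode.  Preprocessing:

1. **Centering** — all coordinates are shifted so the root (usually the
   soma) sits at the origin.
2. **Axon pruning** (optional, default on) — axon nodes (type 2) with
   undirected degree ≤ 2 are removed in a single pass over the input
   degrees; axon branch points are kept.  Survivors re-link to their
   nearest surviving ancestor, which preserves the branching skeleton and
   connectivity.  The pass is deliberately *one-shot*: a second application
   can remove more nodes (a branch point whose terminal branches were all
   pruned drops to degree ≤ 2), so pruning is a preprocessing step, not a
   fixpoint operator.
3. **Downsampling** (optional) — reduce to exactly `n_target` nodes,
   keeping the root and all branch points first (non-branching nodes carry
   little topology), filling the quota by seeded uniform sampling, and
   contracting removed chain nodes by ancestor re-linking.

The model-ready `FeatureGraph` has per-node features
(x, y, z, radius, one-hot type over {soma, axon, basal, apical, other}),
a symmetric binary adjacency, and row 0 = root.

## Augmentations

Two shape augmentations — Gaussian coordinate noise (`shift_sigma`, default
1 µm/axis) and a rigid rotation about a uniformly random axis with angle
U[0, 2π) — and two topology augmentations — independent deletion of each
terminal branch with probability `branch_delete_prob` (default 0.2) and
subgraph sampling retaining `subgraph_fraction` of nodes (default 0.8) with
ancestor re-linking.  "Branch" means a terminal (leaf-ending) segment:
deleting internal branches would orphan subtrees and break the guarantee
that every augmented output is a single connected acyclic tree.  Order is
topology-then-shape so the geometric noise applies to the final node set.
Magnitude defaults are mild, deliberately overridable, and are the
generator-facing study conditions for all tests.

## Encoder

Features are embedded by a two-layer GELU MLP; positional information is
the first `k` eigenvectors (ascending eigenvalue, default k = 16) of the
normalized graph Laplacian L = I − D^(−1/2) A D^(−1/2), linearly projected
to `d_model` and added.  A learnable CLS token (feature + position vector)
is prepended; its adjacency row is 1 to itself and 0 elsewhere.  Each
pre-norm layer applies gated graph attention then a feed-forward MLP, both
with residuals:

    Attention(Q, K, V, A) = softmax(λ QKᵀ/√d_k + γ A) V,   [λ, γ] = exp(W₂ x)

λ and γ are positive per-token scalars computed from each query token and
shared across heads; W₂ is zero-initialized so training starts at the
balanced point λ = γ = 1.  σ is row-wise softmax — the interpolation
between dot-product attention and adjacency message passing, and the CLS
self-loop weight, only make sense under row normalization.  The final-layer
CLS row is the neuron embedding.

Numerical choices:

- **Coordinate scale.** x, y, z are divided by a fixed 100 µm at the
  encoder input.  Raw coordinates are O(10²) µm while radius and type are
  O(1); without the rescaling, coordinate magnitude dominates every token
  direction and the radius/type channels are effectively invisible to
  attention.  A fixed (not per-neuron) scale keeps absolute size
  information, which is biologically discriminative.
- **Eigenvector sign.** Each PE column's sign is fixed by the sign of
  Σᵢ vᵢ³ when that functional is decisively nonzero (it is permutation-
  invariant), else by making the largest-magnitude entry positive.  This
  makes encoding deterministic and, for graphs whose leading spectrum is
  simple and signs decisive, invariant to node relabelling.  Eigenvectors
  that are antisymmetric under a graph automorphism (twin terminal leaves)
  have no order-invariant sign under any rule; repeated eigenvalues leave
  the basis defined only up to rotation.  The invariance tests restrict
  themselves to this domain of validity.
- If k exceeds the node count the PE table is zero-padded; a single-node
  graph is legal.
- λ, γ are recomputed per layer from that layer's (normalized) input.

Adapters (optional, `adapter_dim` > 0) are bottleneck MLPs
(down-projection → GELU → zero-initialized up-projection) added beside the
attention and feed-forward sublayers; inserting them into a trained
checkpoint is exactly the identity.

All of this runs on a small reverse-mode automatic-differentiation engine
over numpy (`morphembed._autodiff`, float64), whose gradients are verified
against central finite differences in the test suite — including one check
through the entire encoder.

## Pre-training

Per step, for each neuron in the batch: one augmented view goes to the
teacher; the same view, either masked (features of ⌈`mask_fraction`·n⌉
non-root nodes replaced by a learned 9-D mask vector; default 0.3) or
cropped (subgraph at `crop_fraction`, default 0.6), each with probability
½ per sample, goes to the student.  The total loss is

    w_c · consistency + w_r · reconstruction + w_k · koleo,   defaults (1, 1, 0.1)

- **Consistency**: cross-entropy between the teacher's centered,
  temperature-sharpened projection distribution (τ_t = 0.04,
  gradient-detached) and the student's log-softmax (τ_s = 0.1), averaged
  over the batch.  The center is an EMA (momentum 0.9) of teacher
  projection batch means, the standard collapse guard.
- **Reconstruction**: MSE of a node-level head predicting the *per-view
  standardized* features at masked positions (zero for cropped views).
  Standardization keeps the MSE O(1) whatever the neuron's physical size;
  on raw µm² the term is 10³–10⁴ at initialization and drowns the other
  losses.
- **KoLeo**: −mean log nearest-neighbor distance of the L2-normalized
  student CLS batch (Kozachenko–Leonenko differential-entropy estimator up
  to constants), weight 0.1, ε = 10⁻¹² for degenerate pairs.

Only the student receives gradients (Adam, lr 10⁻³).  The teacher is an
exponential moving average of the student (momentum 0.996) — the test
suite replays this recursion bit-for-bit against recorded student
snapshots, which simultaneously proves no gradient reaches the teacher.
Embeddings are taken from the teacher after training, the usual
self-distillation convention (averaged weights are slightly more stable).
These loss-head and hyperparameter choices follow standard
self-distillation practice and are all configurable.

## Evaluation protocols

- **Frozen kNN probe**: Euclidean 5-NN, majority vote, ties resolved by
  the nearest neighbor among tied classes; per seed a stratified 7:3 split
  with SMOTE-style rebalancing of the training portion (minorities
  oversampled by x + u(x_nn − x), u ~ U[0,1], between same-class nearest
  neighbors; majorities undersampled; target = rounded mean class count);
  mean ± sd over 5 seeds.  Stratification (rather than fully random
  splits) prevents empty-class test folds on small condition datasets and
  is recorded in the report.
- **Fine-tuning**: linear classifier on CLS embeddings, cross-entropy,
  Adam lr 10⁻² (adapters + a linear head tolerate a fast rate), 7:3
  held-out split.  `adapter` mode updates only adapters and the head — the
  backbone is asserted bit-identical; `full` mode updates everything.
- **Morphometrics**: total cable length; width/height/depth = x/y/z extents
  of centered coordinates (axis convention documented, not inferred);
  stem/tip counts; branch points and branch order exclude the soma (a
  multi-stem root is not a bifurcation); max Euclidean and along-tree path
  distance from the root; spherical soma surface 4πr²; mean diameter.
  `log_transform` is log1p so zero counts stay zero.

## Synthetic test bench

The generator grows neurons by stochastic elongation/bifurcation: stems
leave the soma in random directions; a uniformly chosen active tip either
bifurcates (probability `branch_prob`, capped at `max_depth` branch
orders) or elongates with Gaussian direction jitter; segment lengths are
Gaussian; radii taper multiplicatively; stems are axon-typed with
probability `axon_fraction`.  The target node count is hit exactly and
everything is seeded.  Three presets span densely branching ("tufted",
branch_prob 0.40, short segments), sparsely branching ("sparse", 0.06,
long segments) and long-projection ("projecting", few long straight
neurites) phenotypes; a kNN on log-morphometrics recovers the classes with
accuracy ≥ 0.9, so embedding-quality tests against them are not vacuous.

The scaled study used by the tests and by `scripts/acceptance.py`:
200 neurons (100 per class, 150–250 nodes), a 2-layer, d_model = 64
encoder, 300 pre-training steps with batch 8 — sizes chosen so the entire
study runs in a couple of minutes on one CPU core while still exhibiting
the qualitative behaviour of interest (self-distilled embeddings separate
the classes; a random encoder probed with shuffled labels sits at chance;
accuracy is stable between 200- and 800-node downsampling of 850–1000-node
neurons).

What the synthetic bench does **not** show: real reconstructions have
imaging noise, dialect quirks, soma contours, and far subtler class
differences than the presets; passing these tests demonstrates the
machinery is correct and the training dynamics behave, not that the
defaults reach state-of-the-art accuracy on curated corpora.

## Known limitations

- The one-shot axon pruning is not a fixpoint: re-pruning a pruned tree
  can remove former branch points whose branches were deleted.  This is
  intentional (see above) but means the operation should be applied once,
  at preprocessing time.
- Node-order invariance of the embedding is exact only where the Laplacian
  sign convention is decisive (see Encoder).
- The autodiff engine is float64 and single-threaded; it is sized for
  desk-scale studies, not for corpus-scale pre-training runs.
- `rebalance` interpolates in embedding space, so synthetic minority
  points are meaningful only if the embedding space is locally linear —
  the usual SMOTE caveat.
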