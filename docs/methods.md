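# Methods

## Problem and model

Inter-helical residue contact prediction for α-helical transmembrane (TM)
chains is treated as binary classification of candidate residue pairs. A
candidate pair (i, j) must lie on two *different* annotated TM helices with
sequence separation j − i ≥ 5; it is labelled a contact when the minimum
heavy-atom cross distance is strictly below 5.5 Å. Both constants are
exposed (`min_separation`, `threshold`); the strict inequality means a pair
at exactly 5.5 Å is a non-contact. Distances are computed over whatever
heavy atoms a residue record contains — missing side-chain atoms are simply
absent, never imputed.

The classifier never sees the pair's own distance. Its input is the 3×3
sequence-window neighbourhood around (i, j) with the centre excluded: eight
position pairs in fixed row-major order, each contributing one feature
block. Two representations are implemented:

- **SDF** (40 = 8 × 5): per neighbour `[D1 mean, D1 SD, Dα, δ, θ]`.
  D1 statistics run over all M×N heavy-atom cross pairs (population SD,
  divide by MN); Dα is Cα–Cα; δ is the angle between residue-plane normals
  `cross(N − Cα, C − Cα)`; θ is the angle between the two helix axes.
- **CF** (192 = 8 × 24): raw x, y, z of N, Cα, O, Cβ of both residues
  (lower position first). Glycine or any residue without Cβ repeats the Cα
  coordinates in the Cβ slot.

A helix axis is the renormalised mean of the *unit* O(i)→N(i+4) vectors
(the α-helical hydrogen-bond partner, i ranging over the segment); per-turn
normalisation weights every turn equally regardless of local bond-length
variation. Segments shorter than 5 residues have no axis and raise an
error. Angles (δ, θ) are reported in [0°, 180°] — parallel and antiparallel
packing are biologically distinct, so the angle is *not* folded to
[0°, 90°] (a `fold` option would be a one-line wrapper; it is deliberately
not the default). Arccos arguments are clamped to [−1, 1] against rounding.

### Numerical reproducibility of SDFs

Every SDF entry is quantised to 10⁻⁶ (Å or degrees). The quantities are
mathematically invariant under rigid motion, but floating-point evaluation
of the same quantity in two frames differs in the last few ulps; rounding
at 10⁻⁶ — far below any structural signal and far above the ~10⁻¹⁰
evaluation jitter — makes the feature matrix of a chain bit-identical in
every laboratory frame. Unit tests compare the *unquantised* geometry
functions against brute-force oracles at 10⁻⁹.

### Window boundary rule

Neighbour positions outside the chain, or lacking required atoms,
contribute a zero block plus a per-neighbour validity flag; the candidate
pair itself is always kept, so feature-row counts equal candidate counts.
θ for a neighbour uses the helix containing that neighbour; a neighbour
that falls off its annotated helix inherits the central residue's helix
axis, so boundary windows still have a defined angle.

## Classifier and training recipe

A fully connected network with six leaky-ReLU (slope 0.01) hidden layers —
default widths 64, 48, 32, 24, 16, 8 from a 192-dim input down to one
sigmoid output — is trained with Adam (lr 10⁻⁴, β = 0.9/0.999) on binary
cross-entropy in mini-batches of 256 for a fixed epoch count (default 400),
with every gradient clipped element-wise to [−1, 1] before the update and
all weights initialised Xavier-uniform from the run seed (biases zero).
SDF input first passes through a **static** 40→192 linear projection:
Xavier-initialised from the same seed and excluded from optimisation, so
the identical network body serves both feature sets ("static" is read as
frozen; a trainable variant is a config switch). No early stopping, weight
decay, dropout, re-weighting or resampling: the ~2% class imbalance is
handled by the ranking metrics, not by the optimiser.

The default widths deserve a note: the hidden-layer capacity is sized to
the data. On the shipped study scale (~5 × 10³ candidate pairs per training
split) a much wider taper (512 → 16, ~3 × 10⁵ parameters) fits the training
set perfectly but transfers visibly worse to noisy test structures — the
classic overfitting signature — while the ~2 × 10⁴-parameter default keeps
held-out ranking quality markedly higher at the same training recipe.
Widths are plain configuration for users with larger corpora.

The network is implemented directly in numpy (forward, backward, Adam).
At these sizes a CPU trains it in seconds per 100 epochs, and owning the
loop makes the recipe's specifics — per-batch element-wise clipping, the
frozen projection, per-epoch reshuffling reseeded from the run seed —
exact and auditable. Mini-batch order is drawn from `(seed, epoch)` so
runs are bitwise reproducible.

Scaling is min–max to [−1, 1], fitted on training rows only and reused
unchanged on validation/test rows (which may therefore leave [−1, 1]);
constant columns map to −1. Fitting on the training side only avoids
leaking test statistics into the model.

## Evaluation protocol

All metrics are computed per sequence, then averaged across sequences
(mean ± population SD). Average precision is the threshold-sweep sum
Σₙ (Rₙ − Rₙ₋₁) Pₙ with tied scores grouped at one threshold; for a binary
annotation — the contact map read directly off a structure — it collapses
to P × R, with precision defined as 0 when nothing is predicted positive.
AUC-ROC uses the trapezoidal rule. Top-k precision/recall uses
k = max(1, ⌊L·f⌋) for f ∈ {1, ½, ⅕, ⅒}, L the combined TM-helix length,
k clamped to the number of pairs, score ties broken lexicographically by
(i, j). Chains where a metric is undefined (no contacts; single-class
labels) are excluded from that metric's average with a logged warning —
NaN in the per-sequence table, never silently zero.

Cross-validation splits by sequence, never by pair: per fold, scaler and
model see only training chains. Validation chains may be swapped for
perturbed twins — features from the noisy structure, labels from the clean
one — mirroring train-on-experimental / test-on-predicted transfer. Fold
assignment derives from `(base_seed, repeat)`; per-fold model seeds are
`base_seed·10⁴ + repeat·10² + fold` and are recorded in the report.

## Synthetic data: what it emulates, and what it does not

The generator builds ideal α-helices (rise 1.5 Å/residue, twist
100°/residue) with N, Cα, C, O, Cβ placed on per-atom-type cylinders
(radius, phase, z-offset) chosen so bond geometry is near-canonical
(Cα–Cα ≈ 3.83 Å, O(i)···N(i+4) ≈ 2.9 Å roughly parallel to the axis).
Helices are packed at a controllable inter-axis distance and angle
(odd-indexed helices tilted; 180° default = antiparallel), each with a
random azimuthal spin, and the whole chain is expressed in a random rigid
laboratory frame — as deposited structures are. Placement transforms give
exact ground-truth axes and inter-axis angles; contact labels come from
applying the contact rule to the emitted coordinates. Bundles whose
helices interpenetrate (inter-helix Cα–Cα < 1 Å) are rejected.

The default 10-chain study set cycles through 2-, 3- and 4-helix bundles,
lengths 12–16, inter-axis distances 9.4–10.6 Å and near-antiparallel tilts
(155–180°), yielding ≈ 6,500 candidate pairs at an aggregate contact ratio
of ≈ 2% — the imbalance regime of real TM datasets. The packing-distance
band is the one generator constant calibrated to land in that regime.

Predicted-structure error is emulated by i.i.d. Gaussian noise per
coordinate (default σ = 1 Å for test twins); labels are *never*
regenerated from noisy coordinates. `predicted_twin` additionally
re-expresses the twin in its own random laboratory frame, as an
independently produced prediction would be — rigid-invariant quantities
are untouched by this, but raw-coordinate features see the frame change,
which is precisely the distribution shift that separates the two feature
families across structure sources. This is deliberately pessimistic:
real predicted-structure error is spatially correlated (whole helices
shift or tilt together), which preserves local geometry far better than
independent atomic jitter. Consequently absolute noisy-test AP here is
well below what transfer from predicted structures of real proteins
achieves, and the synthetic experiments support *relative* statements —
SDF ranking transfers better than both the read-off binary map and the
CF baseline under identical noise — not absolute performance claims.
Synthetic chains also have no side chains beyond Cβ, no loops, no kinked
or curved helices, and no membrane context.

## Sizes and defaults used in shipped computations

Tests and the acceptance script run the protocol at desk scale chosen so
the whole suite completes comfortably on one CPU: 10 chains, 5-fold CV,
one repeat, 100 training epochs (the package default remains 400; at
~6.5k pairs the training loss is already < 10⁻² by epoch 100). The
acceptance script derives every stream of randomness (dataset, noise,
fold assignment, weights) from its single `--seed`.

## Known limitations

- Axis estimation assumes straight helices; kinked helices get a single
  averaged axis (piecewise axes are out of scope).
- Insertion-coded PDB numbering is rejected rather than renumbered; the
  window and separation logic requires plain integers. Offsets handle the
  common predicted-vs-experimental numbering shifts.
- The binary-annotation AP (P × R) is a single-operating-point summary and
  is not comparable to sweep AP on an absolute scale; the package reports
  it only as the read-off baseline, as the protocol prescribes.
- Feature-distribution statistics (pooled mean/SD of scaled matrices) are
  descriptive; no divergence test is attached to them.
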