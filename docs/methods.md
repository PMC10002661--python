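# Methods

## The problem

Deterministic streamline tractography estimates white-matter (WM) pathways
by following fiber orientation distribution (FOD) peaks through a voxel
grid: from point x_i, sample the FOD grid by trilinear interpolation
(SAMP), choose the peak direction d_i best aligned with the incoming
direction, and step x_{i+1} = x_i + γ d_i (γ = 1 mm by default).  This
package implements that reference tracker and two learned propagators that
replace the peak-following rule with a recurrent network:

- a **teacher** g(FOD(x_i), h_{i-1}) that maps the 45 even eighth-order
  spherical-harmonic FOD coefficients at the current point, plus a hidden
  state h carrying streamline memory, to the next step direction expressed
  as spherical angles (θ, φ);
- a **student** that replaces the FOD grid with I = CONV(features), a
  single 7×7×7 3D convolution over a structural-intensity-plus-context
  feature stack (1.4 cm receptive field per axis at 2 mm voxels), and
  reuses the teacher's recurrent (GRU) and output (LIN) layers as frozen
  transfers while its embedding MLP is distilled toward the teacher's.

Both networks share the trunk: a four-block MLP (linear 512 → batch norm →
leaky ReLU 0.1), two stacked GRUs of hidden width 512, and a linear head
from the 1024-vector (MLP out ‖ top GRU out) to (θ, φ).  Training minimizes
the cosine loss L(z1, z2) = 1 − ⟨z1, z2⟩/(‖z1‖‖z2‖) between predicted and
reference step directions, averaged over the valid steps of a chunk of
streamlines, with Adam at a constant learning rate of 0.001 and batch size
of one chunk.  The student adds the same cosine penalty between its MLP
output and the teacher's MLP output at the same points (distillation
weight 1.0 by default — the two terms are summed unweighted; the weight is
exposed in `TrainConfig`).

Because SAMP is differentiable in both the sample location and the grid
values, gradients flow from the loss through the trunk, through the
trilinear weights, into the convolution — this is what makes the student
end-to-end trainable.  The networks are implemented directly in NumPy
(float32) with hand-derived backward passes (BPTT for the GRUs); every
backward path is checked against central finite differences in the test
suite.  Single-row and narrow-output matrix products during tracking are
computed through fixed-shape code paths so that a tractogram is a pure
function of (checkpoint, seed list, configuration) and is identical for
any batch size.

## Synthetic subjects

No external data are used.  A phantom subject consists of analytic fiber
bundles — tubes of radius 6 mm around straight, arc, or crossing-pair
centerlines — voxelized on an isotropic grid (default 40³ voxels at 2 mm).
Per voxel the FOD is the partial-volume-weighted sum of even-order-8
projections of Watson densities W(u) ∝ exp(κ(t·u)²) about the local
centerline tangents t (κ = 15 by default), computed by Gauss–Legendre ×
azimuth spherical quadrature.  Partial-volume weights are fractions of 27
sub-voxel samples inside the tube.  Cortical-GM caps (2 voxels thick)
close each bundle end and double as endpoint parcels; a CSF rim lines the
volume boundary; the deep-GM channel exists but is empty, keeping the
4-channel tissue contract and the 1 + 4 + regions + bundles feature
arithmetic (46 regions and 72 bundle channels give the full 123-channel
stack).

Two deliberate departures from an idealized tube, both needed for the
learning task to be well posed:

- **Along-tract structure.** A homogeneous tube is symmetric under
  traversal reversal, so step labels would be fundamentally ambiguous to
  any propagator that infers its direction of travel from image content.
  Real anatomy is not translation-symmetric: tracts show systematic
  along-tract microstructure gradients (the basis of tractometry), and
  anatomy is broadly consistent across individuals.  Each bundle therefore
  carries a monotone ±25 % amplitude profile along its arclength (shared
  across subjects, since geometry is shared), and each subject carries a
  smooth multiplicative modulation field: a fixed "anatomical" component
  shared by all subjects (Gaussian random field, σ = 2 voxels, 30 %
  amplitude, fixed seed) plus a smaller per-subject component (8 %).  Both
  apply to the FOD amplitudes and the WM intensity.  The shared structure
  is what lets a propagator trained on some subjects resolve its direction
  of travel on an unseen one; the along-tract profile in particular makes
  the travel direction readable from any two consecutive samples.
- **Orientation randomization.** Each reference streamline's point order
  is flipped with probability 1/2 when tracked, as in real bidirectionally
  tracked corpora, so the learner sees both traversals.

The pseudo-structural image uses tissue contrasts WM > GM > CSF, Gaussian
smoothing (σ = 1 voxel), additive noise, and normalization to the median
within the brain mask (median ≡ 1).

What the phantoms do *not* emulate: realistic MR contrast and artifacts,
partial-volume mixtures of more than a few tissue classes, anatomical
variability of bundle geometry across subjects (geometry is fixed; only
texture and noise vary), and the segmentation errors of real context
channels.  Passing tests therefore demonstrate that the implementation
learns and reproduces propagation under known geometry — not performance
on clinical data.

## Reference tracker and stopping rules

Seeds are drawn uniformly over WM voxel volumes (`wm_random`) or over WM
voxels 6-adjacent to GM (`gmwm_interface`, the default for generating
training data).  The initial direction is the largest FOD peak at the
seed; a second pass tracks its antipode, and the halves are concatenated.
Tissue membership is a nearest-voxel lookup of the one-hot masks.  The
anatomically constrained rules are a reconstruction of published
anatomically-constrained tractography logic (the source's exact appendix
rules are not public): continue in WM; entering cortical or deep GM stops
the streamline and keeps the entering point; entering CSF or leaving the
brain truncates at the last valid point; no FOD peak above the amplitude
cutoff (0.1) within the per-step curvature limit (45°) stops; and a
finished streamline is accepted iff its length lies in [10, 200] mm.
Peak extraction seeds candidates on a subdivided icosahedron (2562
vertices) and refines each by iterated tangent-plane quadratic fits
(sub-0.1° accuracy on band-limited kernels); peak deduplication uses a 25°
minimum separation.

Learned tracking seeds in WM, starts from a zero hidden state, and is
bidirectional: after the first pass stops, the point sequence is reversed
and replayed through the network from a zero state to rebuild the memory,
then tracking continues from the seed-side end.  The same stopping rules
apply; streamline min/max length applies to the combined streamline.

## Desk-scale problem sizes

Full-scale tracking (10⁶ streamlines, patience 200) is supported through
the `paper_scale` configuration profile but is far outside a desktop
budget; the shipped defaults are desk-scale choices made once:

- subjects: 40³ voxels at 2 mm, three bundles (90° crossing pair + arc);
  the training corpus in the acceptance run uses a compact 32³ variant of
  the same layout so that sequences are ~35 steps long;
- corpora: ~1–2 × 10³ streamlines per subject, chunks of 32–256
  streamlines (the `TrainConfig` default remains 1000);
- training: patience 10–20 epochs, ≤ 100 epochs, where an epoch is one
  shuffled pass over all training chunks;
- tracking: ~10³ accepted streamlines per tractogram.

Numerical notes: spherical quadrature uses 48×96 Gauss–Legendre × uniform
azimuth nodes (verified against a refined grid at build time); the Watson
normalizer uses 128-node Gauss–Legendre; (θ, φ) follow the physics
convention (θ from +z, φ from +x in (−π, π], φ ≡ 0 at the poles); the LIN
output is used as raw angles without squashing, since the cosine loss is
periodic in both angles; batch-norm uses batch statistics during training
and running averages (momentum 0.1) elsewhere; GRU recurrent weights are
initialized orthogonally with a +1 update-gate bias so that memory
persists from the start of training; out-of-bounds SAMP clamps to the grid
edge and raises a flag consumed by the stopping logic.

## Evaluation battery

Bundle assignment on phantoms uses ground-truth membership masks (a
streamline joins the bundle covering the largest fraction ≥ 0.5 of its
points).  Bundle measures: streamline count, mean length (sum of segment
lengths), mean span (endpoint distance), volume (traversed-voxel count ×
voxel volume), and surface area (exposed voxel faces × face area).
Overlap: Dice on binarized traversal masks; bundle adjacency as the
symmetrized mean nearest-neighbour MDF over streamlines resampled to 20
equidistant points.  Connectomes accumulate streamline counts and mean
lengths over unordered endpoint-parcel pairs (zero diagonal; unlabeled
endpoints dropped).  Graph summaries on the count-weighted graph: maximum
modularity over greedy agglomeration plus 10 seeded Louvain restarts,
average weighted betweenness centrality, and characteristic path length,
with edge distance 1/weight; all are validated against exhaustive
small-graph oracles in the tests.  Connectome Pearson correlations are
computed over the dense strict upper triangle, zeros included.

## Known limitations

- The stopping rules and measure definitions are reconstructions of the
  cited conventions, each isolated behind a single operation so a
  corrected definition is a one-site change.
- The real spherical-harmonic convention is internally consistent
  (orthonormal, Descoteaux-style ordering) but no external FOD files are
  ingested, so no cross-tool convention checks exist.
- Phantom geometry is shared across subjects; generalization is tested
  across texture/noise realizations only.
- Training at the shipped desk scale trades accuracy for wall time; the
  learned trackers are demonstrations of the mechanism, not competitive
  models.
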