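# Methods

## The segmentation model

voxwalk interpolates a sparse slice annotation through a 3D intensity
volume. Every labeled voxel `x0` of the annotation is a *seed* that
launches `norw` Monte-Carlo random walks of `sorw` steps each on the
six-connected voxel grid. A walk carries its seed's label and a frozen
pair of reference values — the seed intensity `I(x0)` and a local
intensity spread `σ` — and steps from its current voxel `x` to a
face-neighbor `y(j)` with probability

    P(y(j) | x) = w(y(j)) / Σ_i w(y(i)),
    w(y)        = exp( −(I(x0) − I(y))² / (2 σ²) ),

where neighbors outside the volume receive weight 0. The weights depend
only on the *start* position, never on the path: a walk is a sampler of
"territory that looks like my seed's neighborhood". Small `σ` (a seed in
a clean, homogeneous region) confines walks to closely matching
intensities; large `σ` (a noisy or heterogeneous neighborhood) lets them
roam, degrading gracefully toward an unbiased walk.

Every visited position — the start, and the position after each of the
`sorw` steps — increments the per-label hit counter `Φ_label` at that
voxel. Counting every visit (rather than first visits only) makes the
hit budget exact: a run deposits precisely `Σ_seeds walks(seed) ×
(sorw + 1)` hits, which the test suite asserts as an identity. The final
segmentation assigns each voxel to `argmax_i Φ_i`, voxels with no hits
to background, and ties to the smallest label id (deterministic and
order-independent).

### Background competition

A pre-segmented plane is *fully* segmented: what the annotator left
unlabeled on that plane is background, not "unknown". The pipeline
therefore gives the background of every annotated plane an explicit
temporary label (`augment_background`, enabled by default) whose walks
compete with the object labels; the label is mapped back to 0 after
assignment. Without this the empty space around an object would be
claimed unopposed by whatever walks escape it — on the recovery phantom
this single choice is the difference between Dice ≈ 0.28 and ≈ 0.999.
The library-level engine (`extract_seeds`/`run_walks`) stays agnostic:
it seeds nonzero labels only and rejects label 0, so callers who want
object-only walks can have them.

### Adaptive walk counts

Walks from deep inside an object rarely influence contested boundaries.
A seed is classified *interior* when the `101 × 101` in-plane window
around it contains no other label (background does not break
interiority: the rule exists to spot competition between labels).
Interior seeds launch `interior_norw` walks (default 1) instead of
`norw`. On small phantoms whose planes fit inside the window the rule
rarely fires once background competition is active; on large volumes it
is a pure speed-up with unchanged boundaries.

### Determinism and block decomposition

The RNG is counter-based: each walk's xorshift64* stream is keyed by
SplitMix64 mixing of `(base_seed, global seed index, walk index)`.
Results are bit-identical across runs and independent of seed ordering,
scheduling, or partitioning, and hit accumulation is a commutative sum —
the per-seed computations could run concurrently without changing the
output. `run_blocks` partitions the volume into near-equal z-slabs, each
extended by `ghost` slices (default 100) on both sides; a block walks
only its own seeds, confined to its extended slab (slab edges clip like
volume borders), and overlapping hits are summed. With full overlap the
decomposition is exactly identical to the single-block run (asserted
bitwise); with the default ghost of 100 slices the assignments agree to
Dice ≥ 0.99 on phantoms whose seed planes are not adjacent to the cuts.

## Post-processing

**Smoothing.** Each label's hit field evolves under mean-curvature flow
`∂Φ/∂t = μ |∇Φ| div(∇Φ/|∇Φ|)`, discretized with central differences and
an explicit Euler step (`dt = 0.1`, gradient regularized by
`ε = 1e−6`, default 100 iterations, negative values clamped to 0).
Because the flow acts on hit counts rather than on a binary mask, thin
structures backed by many hits resist erosion. `dt = 0.1` is within the
stability bound of the explicit 3D scheme for moderate `μ`; divergence
raises an error naming the iteration. The smoothed assignment is offered
alongside the raw one, never in place of it.

**Uncertainty.** `U(x) = 1 − Π_{i≠argmax} (1 − Φ_i(x)/Φ_max(x))`,
invariant under uniform rescaling of the hits at a voxel; `U = 0` for an
unchallenged label, `U = 1` when two labels tie. Where `Φ_max = 0` (no
walk ever arrived) U is defined as 1 — a voxel the evidence never
reached is maximally uncertain.

**Cleanup.** `remove_outliers` deletes, per label, 26-connected
components smaller than `threshold` (default 0.9) times that label's
largest component. `fill_holes` fills 6-connected background cavities
that do not touch the volume hull and are smaller than `threshold`
times the label's total size. The 26/6 pairing is the standard
complementary choice that avoids foreground/background topological
paradoxes. Both operations are idempotent; outlier removal never grows
and hole filling never shrinks a label.

**Active contours.** Optional refinement runs a morphological Chan–Vese
evolution (scikit-image) per label against the intensity image,
sequentially in ascending label order with previously claimed voxels
masked out, so labels never overlap; a label that would vanish entirely
is kept at its input extent.

## Evaluation metrics

Dice aggregates all nonzero labels in one quotient,
`2 Σ_i |X_i ∩ X'_i| / (|X| + |X'|)`, with `|X|` counting labeled voxels
only, so background never inflates the score. ASD averages, over every
in-plane boundary point of the reference annotation (2D four-neighbor
boundary on its annotated planes), the Euclidean distance to the nearest
3D surface voxel (six-neighbor surface) of the same label in the result;
voxels at a plane or volume edge count as boundary/surface. Distances
are in voxel units (unit spacing). A reference label with no surface in
the result is *lost*; any lost label makes ASD undefined and the lost
count is reported instead. The twofold cross-validation splits the
annotated planes alternately into sets A and B, interpolates from one
and scores on the other, both ways, and averages.

## Synthetic phantoms

`make_phantom` builds multi-object volumes (stacked spheres, nested
shells, or interlocking wavy slabs) with per-object mean intensities on
a common background, additive Gaussian noise, and dense integer ground
truth; `sparsify_labels` keeps every k-th plane; `perturb_labels`
emulates annotator inconsistency by random per-plane dilation/erosion of
each label region (dilation claims background only, labels stay
disjoint). All generators are pure functions of spec and seed.

The default recovery phantom is 96×64×64 voxels (z, y, x) with two
spheres stacked along z, object means at 120 ± 50 on a 120 background,
and noise σ = 10 — a contrast-to-noise ratio typical of stained microCT
material, and a size that keeps a full default-configuration run
(norw = 10, sorw = 4000) around half a minute on one core. The phantom
emulates the features the walk weights actually see — per-object
contrast, noise, sparse planes, annotation error — and deliberately not
tomographic physics (beam hardening, ring artifacts, partial-volume
blur) or anisotropic voxels. Passing recovery tests on it shows the
mechanics are right under controlled contrast; it does not bound
performance on real specimens with faint or interlocked boundaries.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `norw` | 10 | walks per (edge) seed; more walks, denser evidence |
| `sorw` | 4000 | steps per walk; must scale with slice spacing |
| `adaptive` / `interior_norw` | on / 1 | reduced walks for interior seeds |
| `interior_window` | 101 | in-plane window of the interiority rule (px) |
| `sigma_window` | 3 | in-plane window of the per-seed σ estimate (px) |
| `sigma_min` | 1.0 | σ clamp (intensity units on the 0–255 scale) |
| `n_blocks` / `ghost` | 1 / 100 | z-slab decomposition and overlap (slices) |
| smoothing `μ`, `n_iter`, `dt` | 1.0, 100, 0.1 | curvature-flow magnitude and scheme |
| cleanup thresholds | 0.9 | outlier / hole size cutoffs (relative) |

σ is estimated in a 3×3 in-plane window as the RMS deviation from the
seed's own intensity (the window is in-plane because seeds live on
annotated planes) and clamped at `sigma_min` so a perfectly constant
neighborhood behaves as the uniform-walk limit rather than freezing.
Intensity normalization maps the global min/max of non-8-bit data to
[0, 255]; a constant volume maps to zeros (any constant is equally
uninformative); 8-bit data pass through untouched.

## Problem sizes used by the test suite and acceptance script

Unit tests run on volumes of ≤ 48×32×32 with reduced walk budgets
(norw ≤ 6, sorw ≤ 800). The acceptance checks run the default
configuration on the 96×64×64 phantom across annotation spacings of
every 5th/10th/20th/40th plane, verify the walk statistics on a uniform
9³ volume against an independent simple-random-walk simulator at 10⁵
walks, and repeat the interpolation from two independently perturbed
annotations. These sizes were chosen so the whole battery completes in
minutes on a single core while every stage still runs at its default
parameters.

## Known limitations

- Step weighting is isotropic; voxel spacing is carried as metadata but
  ignored by walks and distances.
- The mean-uncertainty summary is driven by finite-sampling overlap at
  boundaries. On high-contrast phantoms whose segmentation barely
  degrades, thinning the annotation can *narrow* the uncertain band
  (minority-label hit counts at distant boundaries drop to exactly
  zero) even though genuine ambiguity grows; the monotone increase of
  mean uncertainty with slice spacing seen on difficult real material
  does not reproduce on such phantoms. Per-voxel U remains informative;
  the volume-mean summary is the fragile quantity.
- Supported formats are multipage TIFF, NRRD and NIfTI-1; mesh formats,
  DICOM series and PNG stacks are out of scope.
- Active-contour refinement is a generic region-based evolution, not a
  tuned replacement for the walk result; it is off by default.
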