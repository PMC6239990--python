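# Methods

## The mapping problem

A volumetric template (a group-average anatomical grid) and a surface
template (a spherical mesh with vertex-wise correspondence across
subjects) are distinct coordinate systems with no exact transformation
between them: each was built by averaging a different cohort under a
different registration model. Any direct template-to-template
registration inherits the blurriness of both averages.

Registration fusion avoids the direct route. For each subject `s` in a
cohort, two registrations are assumed given (this package estimates
neither): a volume-side transform `phi_s` carrying template-volume
points into the subject's anatomy, and a spherical registration
assigning every vertex of the subject's cortical mesh a position on the
common sphere. Composing them links the two templates *through* the
subject, and averaging over subjects cancels independent per-subject
registration errors.

### Volume → surface

For template-surface vertex `v`:

1. locate `v`'s sphere position inside the subject's spherical mesh
   (barycentric weights on the containing spherical triangle);
2. apply those weights to the subject's anatomical vertex positions,
   giving a point `p_s(v)` on the subject's cortical surface;
3. carry `p_s(v)` into the volumetric template: `q_s(v) = phi_s^{-1}(p_s(v))`;
4. the fused mapping is the arithmetic mean of `q_s(v)` over subjects
   (world-mm coordinates; no renormalization is needed on this side).

A vertex that leaves a subject's displacement-field hull drops that
subject from its average (with a warning); a vertex with no
contributors is an error.

### Surface → volume, coverage masks and dilation

Not every template voxel is cortex in every subject, so this direction
carries a per-voxel **coverage fraction**. Per subject, each
template-grid voxel center is mapped into subject space; voxels landing
inside the subject's cortical-ribbon mask are assigned the common-sphere
position of the subject's nearest mid-surface vertex. Sphere positions
are averaged arithmetically over contributing subjects and renormalized
to unit length (the sphere is the only representation shared across
subjects; a zero-norm mean — antipodal cancellation — is flagged and
excluded, never guessed). Coverage thresholds use `>=`: the **tight
mask** keeps voxels that are cortex in at least 50% of subjects, the
**loose mask** at least 15%. Every loose-but-not-tight voxel then copies
the assignment of its Euclidean-nearest tight voxel (distances between
voxel centers in world mm, so anisotropic grids behave; ties go to the
lowest linear index, x fastest). Finalization snaps each loose voxel's
averaged sphere coordinate to the nearest template-sphere vertex.

### Baselines

Two single-registration baselines run on the identical mask/dilation
machinery: an **affine baseline** (one affine between the volumetric
template and the surface template's volume, applied to a supplied
vertex-to-volume coordinate table) and a **single-registration
baseline** (the fusion pipeline with N = 1, the "template processed
once as a subject" construction).

## Transform algebra

Dense transforms are displacement fields: `x -> x + u(x)`, `u` in world
mm on the field's own grid, interpolated trilinearly. Chains apply
steps sequentially; composition is lazy, with optional baking to a
single field on a stated grid. Image resampling is pull-back: to put an
image from space A onto a grid in B, the chain must map B-points to
A-points. Inversion uses the fixed-point iteration
`v_{k+1}(x) = -u(x + v_k(x))` from `v_0 = -u`, stopping when the max
update drops below `tol` (default 0.01 mm; 0.005 mm inside the phantom
generator) or failing with the achieved residual after `max_iter`
(default 50). The iteration contracts for the smooth, sub-voxel-gradient
fields used here. Out-of-hull policy: point mapping errors by default
(`zero`, `nan` and `clamp` policies are selectable); image resampling
fills with 0.

Numerical conventions: world coordinates are RAS mm everywhere, voxel
indices 0-based, conversions happen at file boundaries only; label id 0
is background; every tie (nearest vertex, nearest tight voxel,
winner-takes-all) resolves to the lowest index or id; barycentric
weights are clipped at `-1e-9`, renormalized to sum to one, and
reproduce the query point within 1e-6 on the unit sphere.

## Metrics and statistics

**NAD** (normalized absolute difference) between a projected and a
reference nonnegative map: `Σ|projected − truth| / Σ truth`; lower is
better; undefined (an error) when the reference sums to zero. **Dice**
between two label supports: `2|A∩B| / (|A|+|B|)`; a label absent from
both sides is a flagged error, never silently 1. **Paired t**:
`t = mean(d) / (sd(d)/√n)`, df `n−1`, two-sided p from the t
distribution; zero-variance differences are a flagged degenerate case.
**FDR**: Benjamini–Hochberg step-up (largest k with
`p_(k) ≤ k·q/m`) at q = 0.05 across the set of pairwise approach
comparisons per metric. Structure-wise metrics carry the two
hemisphere half-shells as replicates, nan-averaged per structure before
testing.

## The phantom world

Real inputs (FreeSurfer/ANTs registrations, anatomical parcellations)
are replaced by a fully specified phantom in which every quantity has a
closed form or a brute-force oracle; realism is a non-goal.

- **Template**: a 48³ grid of 1 mm voxels, world origin at the grid
  center; the "cortical ribbon" is the shell `14 ≤ r ≤ 18` mm; the
  surface is a subdivision-3 icosphere (642 vertices) at the mid-shell
  radius 16 mm, its radial projection the common unit sphere.
- **Parcellation**: 16 sectors from greedy farthest-point seeds on the
  sphere, half drawn in each half-shell so every parcel belongs to one
  "hemisphere" (anatomical parcellations are hemisphere-wise; a parcel
  is only ever scored in its own hemisphere). Vertices take their
  nearest same-hemisphere seed; ribbon voxels take their nearest
  mid-surface vertex's label — the same surface-to-volume construction
  used for real cortical label volumes, which keeps the volumetric and
  surface label supports consistent.
- **Subjects**: a per-subject displacement field from Gaussian noise on
  a 6³ control grid, smoothed (Gaussian, σ = 2 control spacings —
  smooth enough that the fixed-point inversion converges well below
  tolerance), upsampled, and rescaled so the maximum displacement
  equals `amplitude` (default 1 mm — a realistic residual for
  template-space misregistration). The spherical registration is
  jittered by a smooth tangential field `d_i = (I − v_i v_iᵀ) B v_i`
  with one Gaussian 3×3 draw `B` per subject (its antisymmetric part is
  an infinitesimal rotation), rescaled to a maximum angle `jitter_deg`
  (default 2°, ≈ 0.56 mm at the mid-shell radius). Exact inverses of
  the generating warps are recorded (tolerance 0.005 mm).
- **Recentering** (default on): the cohort-mean control-grid noise and
  the cohort-mean jitter draw are subtracted before per-subject
  scaling, making the template the cohort's true center on both
  channels. The per-subject max-norm rescaling afterwards leaves a
  small `O(std(scale)/√N)` residual mean. Draws are keyed by
  (master seed, draw name, subject index), so cohort prefixes are
  stable when the cohort grows (recentering, which depends on N, is the
  one deliberate exception).
- **Ground truth**: the exact volume→surface mapping is the template's
  own mid-surface coordinates; the exact surface→volume mapping sends
  each ribbon voxel to its nearest mid-surface vertex.

What the phantom does *not* emulate: MRI intensities and noise,
segmentation errors (each subject's ribbon is exactly the warped
template ribbon, so phantom coverage is ≈ 1 throughout the ribbon and
the tight/loose distinction is exercised by the baselines and the
geometry tests rather than by cohort variation), folding-pattern
variability, and truly independent volume- and surface-side
registration errors. Passing tests therefore demonstrate the
correctness of the fusion/projection/evaluation machinery and its
convergence behavior under controlled error, not performance on real
anatomy.

## Evaluation design on the phantom

The two simulated workflows mirror the intended applications:

- **Volume → surface (NAD)**: subject parcellations are carried to the
  template grid and averaged into per-parcel probabilistic maps; a
  tested mapping projects each map to the surface (trilinear), and the
  reference is the *same map projected through the exact ground-truth
  mapping* with the same interpolation. The phantom's per-subject
  transforms are exact, so a reference built by resampling through them
  (the literal surface route) reproduces the template labels
  identically and would carry no signal; projecting through the exact
  mapping instead makes NAD a continuous, sub-voxel-sensitive measure
  of mapping error alone.
- **Surface → volume (Dice)**: the winner-takes-all surface
  parcellation is projected into the volume through a tested
  surface→volume mapping (nearest) and compared parcel-wise, within
  each parcel's hemisphere, against the winner-takes-all volumetric
  parcellation from the subjects' volume route.
- **Convergence**: for each seed one 32-subject cohort is built; the
  fused mapping is averaged over the leading 4/8/16/32 subjects
  (prefix-stable) and scored against the fixed evaluation maps. The
  perturbation is zero-mean on both channels, with the jitter angle set
  to `amplitude / r_mid` radians so 1 mm bounds the per-subject
  composed-mapping error; the mean error then falls with cohort size
  (the phantom analogue, at reduced scale, of fusion-quality
  convergence over hundreds of subjects).
- **Ordering**: registration fusion versus the affine baseline (a fixed
  2° rotation, 2% scale, ~1 mm translation misalignment — the kind of
  residual an affine cannot remove) and the single-registration
  baseline (one extra jittered subject outside the fused cohort), with
  paired t + FDR over parcels.

Problem sizes throughout (48³ grid, 642 vertices, cohorts ≤ 32, 10
seeds) are the package's reduced-scale study conditions; they keep every
experiment a desk-scale computation while preserving the qualitative
behavior of interest.

## Known limitations

- The spherical-jitter model is a single linear field per subject:
  smooth and zero-mean-able, but without the spatially localized
  folding errors of real spherical registration.
- Coverage masks are nearly degenerate on the phantom cohort (see
  above); their thresholds, subset invariant and dilation are verified
  against brute-force oracles and the offset affine baseline instead.
- The inverse of a dense field is represented on the same grid as the
  forward field; between nodes it is accurate only where the forward
  field's gradient is well below one (all generated phantoms satisfy
  this; strongly folding fields fail inversion loudly, with the
  residual reported).
- GIFTI pointsets are stored at float32 precision (format convention);
  the plain-text mesh dialect round-trips float64 exactly. NIfTI affines
  live in float32 header fields, exact for the integer-valued affines
  used here.
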