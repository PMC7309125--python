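# Methods

## The problem

Sparse anatomical landmarks on 3D facial surface scans are the entry
point of most geometric-morphometric analyses of craniofacial shape, and
manual placement is the bottleneck: slow, and subject to inter- and
intra-observer bias.  `facemark` implements a fully automatic,
image-based landmarking algorithm for colored facial surface meshes,
together with the evaluation machinery (Procrustes statistics, landmark
error tables) needed to score any landmarking method, and a non-rigid
ICP surface registration used as a comparison method.

Twelve landmarks are produced: endocanthion and exocanthion left/right
(`en_*`, `ex_*`), nasion (`n`), pronasale (`prn`), subnasale (`sn`),
gnathion (`gn`), cheilion left/right (`ch_*`), and labiale superius /
inferius (`ls`, `li`).  Suffixes `_r`/`_l` are the subject's anatomical
right/left.  All coordinates are millimetres.

## The image-based landmarking algorithm

The algorithm reduces 3D landmarking to 2D landmarking plus ray
casting:

1. **Coarse localization.**  Five wide-angle (50°) virtual pinhole
   cameras are placed around the scan, all focused on the vertex
   centroid: one 60 cm along +z (the expected facial direction in the
   scanner frame, which looks along −z with +y up) and four offset
   60 cm along ±x and ±y.  Each view is rendered and passed to a 2D
   face detector until one fires; the highest-confidence box wins.
2. **2D landmarking and back-projection.**  A 68-point 2D landmarker is
   run on the selected view; twelve of the 68 points are mapped to the
   anatomical landmarks (see below) and each landmark pixel's viewing
   ray is cast onto the mesh.  The first intersection is the 3D
   landmark, so landmarks always lie on the scanned surface.
3. **Frontal-camera refinement.**  From seven of the recovered
   landmarks a frontal camera is computed: positioned 80 cm from the
   pronasale along the outward facial direction
   `(ch_r − ex_l) × (ch_l − ex_r)` (the cross product of the diagonals
   spanning the eye and mouth corners), focused on the pronasale with a
   narrow 20° view angle, and rolled so the image vertical aligns with
   `n − ls` (only the component perpendicular to the view direction is
   used).  The scan is re-rendered, re-detected, and re-landmarked from
   this view.  The refinement runs twice by default
   (`PipelineConfig.n_refinements = 2`): the second frontal rendering
   supplies the final landmarks.

### Rendering and ray casting

Rendering is a deliberately minimal software rasterizer: unlit,
perspective-correct interpolation of per-vertex colors, visibility by a
depth buffer of Euclidean hit distances.  There is no lighting model
because both the fixture detector and typical 2D landmark models consume
appearance, and unlit vertex colors make the render → detect → ray-cast
chain exactly reproducible.  Depth at each covered pixel is computed by
intersecting that pixel's ray with the triangle's supporting plane, so
rendered depths agree with the ray caster to floating-point accuracy
(tested at 1e-6 relative).  The ray caster is vectorized
Möller–Trumbore over all triangles with no approximate acceleration
structure; tests compare it against a scalar exhaustive implementation.

Image conventions: origin top-left, x right, y down, pixel centers at
`(i + 0.5, j + 0.5)`; the view angle is the full vertical field of view
and pixels are square.  Default render size is 512 × 512, giving a
frontal-view pixel footprint of `2·800·tan(10°)/512 ≈ 0.55 mm`.

Triangles with any vertex behind the camera are skipped rather than
clipped; every camera in this pipeline is placed 60–80 cm from a scan a
few tens of centimetres across, so partial clipping does not arise in
intended use.

### 2D models and the 68 → 12 mapping

The face detector and 68-point landmarker are interfaces.  Production
use wraps pretrained models through `ExternalModelAdapter` (plain
callables in, boxes / 68-point arrays out); nothing is bundled or
downloaded, and the package is fully functional and tested without any
model file via `FixtureMarkerDetector` (below).

The 68 → 12 index table (0-based, iBUG-68 semantics) is: eye corners
36/39/42/45, nose bridge top 27 (nasion proxy), nose tip 30, subnasale
33, mouth corners 48/54, lip midpoints 51/57, chin 8 (gnathion proxy).
iBUG's image-left eye is the subject's anatomical right.  The table is
an explicit, overridable parameter (`map_68_to_12(..., mapping=...)`)
because nasion and gnathion are type-2 landmarks whose 68-point proxies
are genuinely ambiguous.

### Failure handling

If no array view yields a detection the pipeline raises "face not
found".  A detected view can still fail landmark extraction — at oblique
poses a medial landmark can be occluded by the nose — so the pipeline
falls through to the remaining array cameras in order before giving up.  If a frontal refinement fails (no detection, ray misses beyond
the cap, degenerate landmark geometry) the last successful landmark set
is returned with a warning — a refinement should never make output
unavailable.  A 2D landmark that falls a sub-pixel outside the
silhouette (e.g. gnathion on a tilted chin) would make its ray miss; the
default `nearest_point` policy snaps to the closest surface point to the
ray, capped at 5 mm to prevent gross snapping (`error` raises instead).

## Evaluation machinery

`centroid_size` is the root summed squared distance of a configuration
from its centroid.  `rigid_align` is the SVD orthogonal-Procrustes
solution with `det(R) = +1` enforced — anatomical configurations are
chiral, so reflections are never acceptable.  `gpa` scales each
configuration to unit centroid size *once*, then iterates
rigid-alignment to the evolving mean until the mean moves less than
`tol = 1e-8` (Frobenius); there is no rescaling inside the loop.  The
Procrustes distance from the mean is the root summed squared distance
between an aligned configuration and the mean shape.  Mean-shape
initialization is the first sample; order-invariance of the result is
tested rather than assumed.

`landmark_errors` tabulates per-subject, per-landmark Euclidean
distances with per-landmark mean/SD, per-subject means, and an overall
row; SDs use the sample (n−1) convention.  `average_over_observers`
averages each subject/landmark distance over two observers' ground
truths before aggregating — the convention for scoring a method against
two manual landmarkings.

## NICP registration (comparison method)

The alternative landmarking route registers an atlas mesh onto the scan
and reads landmarks off known atlas vertices.  Per stiffness α the
energy is

    E(X) = Σ_i w_i ‖X_i v̂_i − u_i‖² + α Σ_{(i,j)∈edges} ‖(X_i − X_j) G‖²_F

with one 3×4 affine `X_i` per atlas vertex, `u_i` the closest compatible
point on the target surface (point-to-triangle, not nearest-vertex, for
resolution independence), and `G = diag(1, 1, 1, γ)`.  Correspondence
assignment alternates with one exact sparse least-squares solve for all
`X_i` (normal equations, sparse LU), so the energy is non-increasing
within an inner loop at fixed weights — asserted per-iteration in tests.
Correspondences are rejected beyond 20 mm, beyond 60° normal
disagreement, or on the target border.  The stiffness schedule (8
geometric steps, 50 → 1), γ = 1, and the rejection thresholds are
conventional values exposed in `NICPConfig`; the package's correctness
claims (fixpoint, rigid recovery, bias inequality) are robust to them.

Landmarks enter only through the affine initialization — the 3×4
least-squares fit of atlas landmarks to subject landmarks — never the
energy, so read-off landmarks are a genuine test of the registration.  A
guide-point term (`landmark_weight > 0`) exists for atlas-building
workflows and is off by default.  `average_atlas` builds an atlas from
meshes in dense correspondence by rigid-only (no scaling) Procrustes
alignment of the vertex sets followed by per-vertex averaging.

The locally-affine regularization has a known consequence: it resists
deformation away from the atlas, so NICP-derived shapes crowd toward the
mean.  On synthetic populations the mean Procrustes distance from the
mean of NICP-read-off landmarks is reliably *smaller* than that of the
ground-truth landmarks; the package asserts this as an inequality, a
caution against using regularized registration for dysmorphology
phenotyping where extreme shapes are the signal.

## Synthetic fixtures

`make_face_fixture` builds an ellipsoidal head (default half-extents
80 × 110 × 70 mm — adult-head scale) with a radial Gaussian nose bump
(25 mm high, 20 mm wide) and 5 mm eye-socket depressions, at ~20k
triangles (icosphere subdivision 5, ≈3 mm vertex spacing, comparable to
a consumer surface scanner).  Twelve landmark positions are fixed by
canonical outward directions; a 4 mm-radius patch of vertices around
each is painted a reserved saturated marker color (pairwise RGB distance
≥ 0.5; matching threshold 0.15).  The returned ground truth is the
painted patch's vertex centroid projected back to the surface, so the
truth coincides with the visual center of the rendered blob and is an
exact surface point.

`make_population` adds band-limited radial displacement fields (10
random low-frequency cosine modes, RMS amplitude = `deformation_scale`)
to the canonical fixture; all members share topology and the ground
truth rides along on its supporting triangle.  `perturb_landmarks`
models observer noise as iid per-axis Gaussians.

What the fixtures do *not* emulate: texture and shading variation,
scanner noise and holes, hair/eyelash occlusion, closed eyes, and real
anatomical variation.  Passing fixture tests therefore demonstrates the
geometric correctness of the rendering/detection/back-projection/
registration chain, not the 2D models' robustness on real faces — that
depends on the pretrained models supplied through the adapter.

At coarse resolutions (icosphere subdivision ≤ 2) the 4 mm marker
patches cannot be kept disjoint and fixture generation raises; use
subdivision ≥ 3 (registration tests) or 5 (rendering tests).

## Problem sizes and numerical choices

Tests and the acceptance script use the ~20k-triangle fixture for
pipeline runs (≈9 s per scan with the pure-Python rasterizer), the
~5k-triangle (subdivision 4) fixture for NICP recovery, and the
~1.3k-triangle (subdivision 3) fixture for NICP population studies —
sizes chosen so the full study re-runs in a few minutes while leaving
every measured property far from its threshold.  Degenerate inputs
(collinear eye/mouth corners, `n − ls` parallel to the view direction,
coplanar landmark configurations, rank-deficient alignments,
disconnected atlases, zero centroid size) raise informative errors
rather than propagating NaNs.  Ray-cast ties at identical distance
resolve to the lowest triangle index; detection-confidence ties resolve
to the first box.

## Known limitations

* Color is required: the pipeline has no geometry-only fallback, so
  anonymized (color-stripped) scans cannot be landmarked.
* Texture atlases are not read; bake textures to vertex colors first.
* The rasterizer skips triangles straddling the camera plane instead of
  clipping them.
* NICP hyperparameters are conventional defaults, not values tuned on
  real scan populations.
* The 68 → 12 table is one defensible choice; nasion and gnathion
  inherit the ambiguity of their 2D proxies.
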