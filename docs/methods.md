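# Methods

`simplexssm` builds a PCA statistical shape model (SSM) from a set of binary
segmentations of the same anatomical structure.  The hard part of SSM
construction is point correspondence: every training shape must be described
by the same landmarks in the same order.  The package establishes
correspondence by mesh-to-volume registration — a single landmarked template
is fitted to every sample, so the converged template vertices *are* the
corresponding landmarks.

## The deformable 2-simplex mesh

A 2-simplex mesh is a closed polygonal surface in which every vertex has
exactly three neighbors; it is the topological dual of a triangle mesh (one
simplex vertex per triangle, neighbors across shared edges).  We place dual
vertices at triangle centroids, which is robust to obtuse triangles.

The local shape at a vertex `P` with neighbor triangle `(N1, N2, N3)` is
encoded by

- metric parameters `(eps1, eps2, eps3)`, the barycentric coordinates of the
  orthogonal projection `F` of `P` onto the neighbor plane (sum to 1);
- the simplex angle `phi ∈ [-pi, pi]`, a signed angle defined through the
  circumscribed circle (center `C`, radius `r`) of the neighbor triangle and
  the circumscribed sphere (radius `R`) of the tetrahedron; the local mean
  curvature is `H = sin(phi)/r`;
- the height `L(r, d, phi)` of `P` above the neighbor plane, with
  `d = ||F - C||`.

These quantities reconstruct the vertex exactly:
`P = eps1·N1 + eps2·N2 + eps3·N3 + L(r, d, phi)·n`.

Two numerical choices matter here.  First, the height is evaluated in a
sine/cosine form,

    A = r² cos²(phi) + (r² - d²) sin²(phi)
    L = (r² - d²) sin(phi) / (sqrt(A) + r cos(phi))      for cos(phi) ≥ 0
    L = (sqrt(A) - r cos(phi)) / sin(phi)                for cos(phi) < 0

which is algebraically identical to the tan-based form but finite at
`|phi| = pi/2` and cancellation-free on the obtuse side.  Second, the
simplex angle is computed as `phi = atan2(2 r L, r² - ||P - C||²)`, which on
the positive-normal side agrees with the circumsphere definition
(`cos phi = (||C-O||/R)·sign((C-O)·n)`) and extends it mirror-symmetrically
to the negative side; with any other sign convention the reconstruction
identity fails for vertices below the neighbor plane.  The round-trip
identity is enforced by tests to 1e-6 mm on all fixture meshes (observed
error ~1e-14 relative).  The `(r, d, phi)` parameterization is one-to-one
only while `F` projects inside the circumcircle (`d < r`); outside that
regime the height is reported as undefined and energy evaluation treats the
configuration as infinitely penalized.

## From volumes to meshes

Each binary volume is zero-padded by one voxel, triangulated by marching
cubes at iso-level 0.5 in world millimetres (voxel `(i,j,k)` maps to
`origin + index·spacing`), smoothed with low-pass Taubin smoothing (default
20 iterations, passband 0.1 — chosen over plain Laplacian smoothing to keep
volume shrinkage under 2%), and decimated by quadric edge collapse to a
configurable face budget (default 2 500).  Decimation fixes the landmark
count `N`, since the dual simplex mesh has one vertex per triangle.

## Template selection and affine initialization

The training sample most similar to the average shape is used as the
template: each sample is registered to every other and the sample with the
smallest summed post-registration dissimilarity wins (lowest index on ties).

Registration represents both point sets as Gaussian mixtures — one isotropic
component per vertex, uniform weights, shared standard deviation (default:
the mesh mean edge length, which acts as a smoothing bandwidth; noisy inputs
warrant a few edge lengths) — and minimizes the L2 distance between the
transformed template mixture and the target mixture over an affine map
`x → A x + t`.  Dropping the transformation-independent target self-term,
the objective is `∫f² − 2∫fg`, both terms closed-form sums of Gaussian
product integrals `phi(0 | mu_i − nu_j, (s_f² + s_g²) I)`.  Isotropic
covariances make the rotated covariance exact (`Q s²I Qᵀ = s²I`), so the
objective depends on `A` only; we therefore optimize the 12 raw parameters
`(A, t)` unconstrained with analytic gradients (L-BFGS), over a
coarse-to-fine scale schedule (4×, then 1×) to widen the basin of attraction
from an identity start, and polar-factorize `A = QS` afterwards.  The closed
form is verified against 3-D trapezoid quadrature (spectrally accurate for
Gaussians) to 1e-6 relative; noiseless affine perturbations with condition
number < 3 are recovered with < 1% parameter error.  Mixtures are capped at
1 000 components by deterministic stride subsampling (250 during template
selection, where only the ranking matters).

## VFC external energy

The external energy is the magnitude of the vector field convolution (VFC)
field: the edge map (gradient magnitude of the Gaussian-blurred volume,
sigma = 1 voxel for binary inputs, min-max normalized to [0, 1]) convolved
with a kernel whose vectors point toward the kernel origin with magnitude
`m1(r) = (r + 1e-8)^-1.7` (the Gaussian variant `m2` is available).
Convolution is zero-padded linear convolution via FFT, cropped to the grid,
and verified against direct spatial convolution to 1e-10.

A point worth stating explicitly because it determines the sign of the
energy: the VFC *vectors cancel on the boundary*.  Edge contributions
surround a boundary point symmetrically, so the field magnitude has a sharp
local minimum at the object surface (the force equilibrium of the underlying
field) and a peak a voxel or two outside.  The greedy evolution therefore
minimizes the sampled magnitude directly — measured profiles across a
digitized sphere show the on-boundary magnitude at ~5% of its off-boundary
peak.  Consistently, sampling outside the volume returns the *maximum*
energy, which walls the mesh in.  The kernel radius matters at desk scale:
long-range kernels (radius beyond roughly half the object diameter) let the
far side of a closed boundary dominate and wash the equilibrium minimum out;
the desk-scale runs use radius 10 voxels on 64³ volumes, while the
full-scale default (256, capped at the largest volume dimension) suits
CT-sized data.  Energy volumes are precomputed once per target and can be
persisted as scalar images.

## Greedy evolution

Per iteration each vertex scores `w³ + 1` candidates — the voxel centers of
a `w×w×w` window (default `w = 11`) around the voxel containing it, plus its
current continuous position so "no move" is always available.  The score is
`alpha·Ē_int + beta·Ē_ext` (defaults `alpha = 0.4`, `beta = 1.0`) where each
energy is independently min-max normalized over the window (constant sets
normalize to zeros), making the weights scale-free.  The internal energy at
a candidate, with neighbors frozen at their current positions, is the
tangential term `||(N1+N2+N3)/3 − F||²` plus the normal term
`(L(r, d, phĩ) − L)²`, where `phĩ` is the mean simplex angle of the three
neighbors on the current mesh — a C² smoothness prior.  The winning
candidate `Q` moves the vertex only along its normal,
`P ← P + ((Q − P)·n)n`, and all updates in an iteration are computed from
the pre-step mesh (synchronous), so the result is independent of vertex
order.  Argmin ties break by smallest distance to the current position, then
candidate index.  Iteration stops when the largest displacement falls below
`move_tol` (default 0.1 voxel) or after 200 iterations; ten consecutive
iterations of growing displacement abort with a divergence error.

Two properties of this scheme are worth knowing.  The per-iteration
displacement is bounded by half the window diagonal, and the selection is
verified vertex-for-vertex against a brute-force exhaustive search.
Conversely, the internal term alone is *not* independently convergent: the
update is a synchronous, voxel-quantized angle-averaging iteration that is
only marginally stable without the external anchor, which is why `beta > 0`
is enforced.  Accuracy is voxel-limited: candidates are voxel centers, so
the converged surface sits within about half a voxel of the energy minimum
(measured: 0.84 voxel mean on the 64³ ellipsoid benchmark).

## Model building and evaluation

The corresponded landmark vectors (3N-dimensional, mm) are aligned by
generalized Procrustes analysis — translation and rotation only by default,
so the model keeps metric units; scaling is a flag.  The model is the
eigendecomposition of the sample covariance `S = 1/(K−1) Σ (x_i − x̄)(x_i −
x̄)ᵀ`, solved through the K×K Gram (dual) eigenproblem when `3N > K` (both
paths tested identical to 1e-9).  Eigenvector signs are fixed by making the
largest-magnitude component positive.  The retained-mode count is the
smallest `t` whose cumulative variance ratio strictly exceeds 0.98.  New
shapes are `x̄ + Σ b_m φ_m` with `b_m` clamped to `±3√λ_m`; coefficients for
a given shape are orthonormal projections `b_m = φ_mᵀ(x − x̄)` (the natural
least-squares choice).

Quality metrics:

- **Compactness** `C(M) = Σ_{m≤M} λ_m` (mm²).
- **Generalization**: leave-one-out — rebuild the model without shape `i`,
  re-center the held-out shape on the leave-one-out mean centroid, project
  onto the first `M` modes, reconstruct, measure.  The held-out shape is
  *not* re-rotated by default: the inputs are already jointly GPA-aligned,
  and an extra Procrustes rotation moves an in-span shape out of the mode
  span, destroying the exact-reconstruction property that anchors the tests
  (`with_rotation=True` enables it for shapes arriving in arbitrary pose).
- **Specificity**: draw `n` shapes (default 10 000) with coefficients
  uniform on `±3√λ_m`, record each one's distance to the nearest training
  shape (exact linear scan), deterministic given the seed.

Both error metrics default to the root-mean point-to-point distance per
shape pair, `||x − x'||/√N` in mm — the defining sums are squared norms, but
mm-scale numbers are what the field reports; the raw squared norm is
available via `units='sq'`.  Note that specificity need not fall with `M`
for small training sets: each additional uniformly-sampled mode contributes
about `4λ_m` of expected squared distance to the nearest of a few training
points (uniform `±3√λ` has variance `3λ`), so the curve can rise even for a
perfect model.

## Synthetic study conditions

All tests and the acceptance script run on generated data; the generators
are first-class, seeded, bitwise-reproducible code.  The family generator
emulates a set of segmented scans: a base ellipsoid (default semi-axes
20/15/12 mm on a 64³, 1 mm grid — large enough for a few thousand surface
voxels, small enough for minutes-scale runs; the acceptance pipeline uses
18/14/12 to leave deformation headroom inside the grid) deformed by smooth radial
displacement modes driven by low-order spherical-harmonic patterns, with
coefficients `b_k ~ N(0, λ_k)` (default relative amplitudes 0.05 and 0.025,
i.e. ±15%/±7.5% radius changes at 3σ — comparable inter-subject variation to
published femur models).  Surfaces are radial graphs, so ground-truth
landmark meshes with exact correspondence and analytic surface distances
come for free.  What this does *not* emulate: marked concavities or
high-curvature ridges (femoral neck), topological noise, anisotropic
spacing, or segmentation errors — so passing tests demonstrate correctness
of the machinery and recovery under smooth, genus-0, isotropic conditions,
not clinical-grade robustness.

Problem sizes used by the acceptance script: a K=6 family at 1 280 landmarks
for the full pipeline, the 64³ ellipsoid benchmark for the template fit, and
a K=30 family at 162 landmarks for eigenstructure recovery.

## Known limitations

- The VFC kernel is built in voxel units; with anisotropic spacing the
  kernel is anisotropic in mm (fixtures use isotropic spacing).
- Voxel-center candidates bound the fit accuracy at about half a voxel;
  there is no sub-voxel refinement stage.
- Template topology is fixed: no topology changes, open surfaces, or k ≠ 2
  simplex meshes.
- GMM registration is affine only; strongly non-affine shape differences
  must be absorbed by the greedy evolution.
- The equilibrium-well argument assumes closed boundaries in binary images;
  for gray-level data with weak edges the kernel radius / gamma trade-off
  needs care.
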