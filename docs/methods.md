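# Methods

`protshape` scores the global shape similarity of three-dimensional protein
surface models.  A model is a closed (or near-closed) triangle mesh of the
molecular surface; the method never looks at atoms, sequence or chemistry —
only at the geometry of the surface.  The pipeline is:

    mesh  →  discrete curvature  →  shape index (SI) and salient geometric
    feature (SGF) per vertex  →  K-means condensation to two K-vectors
    →  K×K feature matrix  →  matrix grey relation degree η ∈ (0, 1]

## Discrete curvature

Per-vertex Gaussian curvature is the angle deficit divided by a vertex area,

    kG(i) = (2π − Σ_j θ_ij) / A_i ,

with `π −` instead of `2π −` at boundary vertices; mean curvature comes from
edge lengths and signed dihedral angles,

    kM(i) = −(1 / 4 A_i) Σ_{e ∋ i} len(e) · β(e) ,

where β(e) > 0 at edges that are convex with respect to outward normals.
Boundary edges contribute nothing, and boundary vertices are flagged (their
estimates are biased; the descriptor excludes them by default).  Principal
curvatures follow algebraically:

    k1, k2 = kM ± sqrt(kM² − kG) ,

with negative discriminants clamped to zero (an umbilic) and counted as a
mesh-quality signal.

**Sign convention.**  The leading minus sign in kM makes a closed convex
surface with outward winding *negative* (unit sphere → kM = −1 in the
refinement limit).  This "convex-negative" calibration is what makes the
shape-index formula below assign +1 to convex caps; it is pinned by an
explicit unit-sphere test.  `orient_outward` establishes the winding
convention the calibration relies on (breadth-first propagation of
consistency, then a global flip of any closed component whose signed volume
is negative).

**Vertex areas.**  The curvature denominators use Meyer-style mixed
(Voronoi-with-obtuse-correction) areas.  We first tried the simpler
one-third-of-incident-faces (barycentric) weighting; on a subdivision-4 unit
icosphere it leaves up to ~15 % pointwise error in kG concentrated at the
twelve valence-5 vertices, and makes kM² − kG negative at over half the
vertices.  Mixed areas bring the worst-case error to 0.14 % (kG) / 0.09 %
(kM) with no clamping, so the pointwise accuracy the rest of the pipeline
needs is only available with them.  The *SGF* area fractions (below) still
use barycentric areas — there only ratios within a small patch matter.

## Shape index

    SI = −(2/π) · arctan( (k1 + k2) / (k1 − k2) )  ∈ [−1, 1]

+1 is a convex cap, 0 a perfect saddle (k1 = −k2), −1 a concave cup.  The
formula is singular at umbilics (k1 = k2).  Wherever the spread
|k1 − k2| ≤ `umbilic_tol` · max(|k1|, |k2|, 1) the limit value is used
instead: +1 if kM < 0, −1 if kM > 0, 0 if |kM| ≤ `umbilic_tol`.

`umbilic_tol` defaults to **0.1**.  The value is calibrated to discretization
noise at true umbilics: on unit icospheres the spurious principal-curvature
spread measures ≈ 0.17 / 0.086 / 0.043 at subdivisions 2 / 3 / 4, so 0.1
absorbs the noise from subdivision 3 up while leaving genuinely anisotropic
vertices (spread of order 1) untouched.  A sphere therefore reports SI = +1
exactly at every vertex, which is also what makes the descriptor's
constant-field corollary (below) exact.

## Salient geometric feature

For each vertex i, let F(i) be the topological neighbourhood within
`ring_depth` (default 2) edge hops.  Then

    SGF(i) = w1 · Σ_{j∈F} AreaFrac(j) · SI(j)³  +  w2 · N · Var ,

with w1 = w2 = 0.5; AreaFrac normalises barycentric vertex areas within F;
N counts cluster members whose SI is a *strict* extremum over their own
full-mesh 1-ring; Var is the population variance of SI over F.  Design
choices worth stating:

- the saliency term `w2·N·Var` is added once per cluster, not once per
  member — otherwise SGF would grow with cluster size even on constant
  fields, and a constant field SI ≡ c must give SGF ≡ w1·c³ (a sphere gives
  SGF ≡ 0.5 exactly);
- strict extrema mean plateaus contribute N = 0, so constant fields are not
  all-extremal;
- population (divide-by-|F|) variance keeps |F| = 1 well-defined.

SI and SGF both depend only on curvature *ratios* and topology, so both are
invariant under rigid motion and uniform scaling — and so is everything
downstream.

## Descriptor

Each per-vertex channel is condensed by 1-D K-means (K = 48 by default) into
its K cluster means: T for SI, P for SGF, each sorted ascending.  K-means
labels carry no meaning across runs, so sorting makes the descriptor
canonical and entry-wise comparable; it is also what makes the descriptor
invariant under vertex re-indexing.  The descriptor is

    M = T Tᵀ + P Pᵀ        (K × K, symmetric, PSD, rank ≤ 2),

i.e. QᵀQ for Q the 2×K stack of the two vectors.

**1-D K-means solver.**  Lloyd iterations from randomly drawn data-point
centers — ties to the lower-indexed center, empty clusters re-seeded with the
farthest point — are run from several seeded starts (uniform and
D²-weighted draws).  Plain Lloyd routinely stalls 10–50 % above the optimal
within-cluster sum of squares once K grows past a handful, because repairing
a misallocation of centers between modes needs many boundaries to move at
once.  Every start is therefore polished in the sorted-interval
representation with exact merge–split moves (delete the cheapest boundary,
re-insert the most profitable one), followed by a short iterated-local-search
phase with kick moves.  Against an exact dynamic-programming 1-D K-means
oracle the solver's WCSS stays within 3.5 % of optimal on every instance
tried (two families × 50 instances, n ≤ 2000, K ≤ 48); the test suite gates
at 1.05×.  All randomness flows through one seed; results are deterministic.

In batch runs each model's seed is the global seed offset by a CRC-32 hash of
the model name, so adding a model to a library never changes the other
models' descriptors.

## Similarity: matrix grey relation degree

For two equal-shaped matrices X, Y, each line (row, then column) is reduced
to the sum of its zero-start image (the line minus its first element):
s(k) for X, t(k) for Y, and

    ε(k) = (1 + |s| + |t|) / (1 + |s| + |t| + |s − t|) ∈ (0, 1],
    η = ½ (mean_k ε_rows + mean_k ε_cols).

η = 1 exactly for X = Y (self-similarity is always 1.000), η is symmetric,
and adding a scalar constant to either matrix changes nothing (the zero-start
images cancel it).  Two caveats are inherent to the printed formula and left
as-is: the fixed "1 +" offsets make η sensitive to the absolute numeric scale
of the matrices, and shift-blindness means matrices differing by a constant
are indistinguishable.

Clustering uses the dissimilarity d = 1 − η with average linkage (UPGMA, via
scipy); merge heights are monotone and serialise to Newick.

## Synthetic test surfaces

The generators provide every downstream stage with analytic ground truth:
icospheres (kG = 1/r², kM = −1/r), tori (closed-form kG, kM in the tube
angle), saddle patches z = x² − y² (kM = 0, kG = −4 at the center — the
SI = 0 case), plus two seeded deformers: Gaussian displacement along vertex
normals (topology-preserving noise) and smooth low-order radial "blobby"
deformations (distinct lumpy shapes for retrieval tests).

What they emulate — and what they don't: these surfaces exercise convex,
saddle, concave and mixed-curvature regimes at controlled resolution, but
real molecular surfaces have pockets, tunnels, deep invaginations and
meshing artefacts from whatever surface generator produced them.  Passing
tests demonstrate the correctness and the invariances of the machinery, not
retrieval accuracy on protein families; that depends on mesh provenance and
resolution, which the similarity score is *not* normalised for.

**Noise amplitude in robustness tests.**  Vertex noise of std σ propagates
into discrete curvature roughly as σ/h² for edge length h, so "small" must
be judged against the curvature scale, not the geometry: on a subdivision-3
unit icosphere (h ≈ 0.16), σ = 5·10⁻⁴ perturbs curvature by ~2 % — a
genuinely noisy copy — while σ = 5·10⁻³ already perturbs it by ~20 % and at
finer meshes scrambles the shape-index field beyond recognition.  The
retrieval tests use the curvature-calibrated value.

## Problem sizes and numerical choices

The test suite runs on icospheres up to subdivision 5 (10 242 vertices,
curvature only) and subdivision 4 (2 562 vertices, full pipeline), a 48×24
torus and 41×41 saddle; batch tests use K = 24 over five models.  Mesh
cleaning merges vertices within 10⁻⁸ of the bounding-box diagonal
(scale-free), drops degenerate/duplicate faces, and fan-triangulates
polygonal input faces from their first vertex.  K-means convergence uses a
center-shift tolerance of 10⁻⁸ with at most 100 Lloyd iterations per start.
CSV output rounds η to 4 decimals; JSON keeps full precision.

## Known limitations

- η is not normalised for mesh resolution or descriptor scale; comparing
  meshes of wildly different resolution conflates discretization with shape.
- Surface generation from atomic coordinates is out of scope; results on
  protein data inherit whatever the external mesher did.
- Non-orientable input is rejected; open meshes are accepted with warnings,
  but outwardness (hence the SI sign) is undefined for them.
- The SGF neighbourhood is topological (edge hops), so strongly anisotropic
  triangulations change the effective patch size.
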