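# protshape

Global shape similarity for three-dimensional protein surface models.

Structural biologists often need to ask "which models in this library have
the same overall surface shape as this one?" without relying on sequence or
atomic superposition — e.g. when comparing surfaces generated from different
PDB entries, or clustering a benchmark set (Skolnick, Chew–Kedem) by shape
family.  `protshape` answers that question from surface geometry alone: the
input is a triangle mesh of the molecular surface (OFF, PLY or OBJ; mesh
generation from atomic coordinates is up to your favourite surface mesher),
the output is a similarity score η ∈ (0, 1] with η = 1 for identical shapes.

## Method

For each vertex of a clean, outward-oriented mesh the package estimates the
discrete Gaussian and mean curvatures (angle deficit and edge-dihedral
formulas over mixed vertex areas), recovers the principal curvatures
k₁ ≥ k₂ = k_M ± √(k_M² − k_G), and computes two scale-free fields:

- **shape index**  SI = −(2/π)·arctan((k₁+k₂)/(k₁−k₂)) ∈ [−1, 1], which maps
  local surface type (convex cap +1, saddle 0, concave cup −1);
- **salient geometric feature**  SGF = w₁·Σ AreaFrac·SI³ + w₂·N·Var over a
  2-ring neighbourhood, which highlights regions whose curvature varies
  strongly (N = local SI extrema count, Var = SI variance).

Each field is condensed by seeded 1-D K-means (K = 48) into a sorted vector
of cluster means — T for SI, P for SGF — and the model's descriptor is the
K×K rank-≤2 matrix M = TTᵀ + PPᵀ.  Two descriptors are compared with a
matrix-extended grey relation degree: each row/column is reduced to its
zero-start sum s, and

  ε(k) = (1+|s|+|t|) / (1+|s|+|t|+|s−t|),   η = ½(mean ε_rows + mean ε_cols).

Batch tools build all-vs-all similarity matrices, rank a library against a
query, and cluster models by average linkage (UPGMA) on d = 1 − η.
See `docs/methods.md` for conventions, parameter defaults and limitations.

## Worked example

No protein meshes at hand?  The built-in generators create test surfaces
with known curvature:

```
$ protshape synth icosphere --radius 1 --subdiv 3 -o sphere.off
wrote 642 vertices, 1280 faces to sphere.off
$ protshape synth icosphere --radius 1 --subdiv 3 --noise 0.0005 --seed 1 -o lib/noisy.off
$ protshape synth torus --major 2 --minor 0.5 -o lib/torus.off
$ protshape synth icosphere --subdiv 3 --blob 0.35 --seed 2 -o lib/blob.off

$ protshape rank sphere.off lib --seed 0
noisy   0.6071
torus   0.5370
blob    0.5248
```

The noisy copy of the sphere ranks first (η = 0.6071), ahead of the torus
and a lumpy "blobby" deformation — the ordering a shape measure must get
right.  A model against itself always scores exactly 1:

```
$ protshape describe sphere.off -o sphere.desc.json --seed 0
descriptor of sphere (K=48) -> sphere.desc.json
$ protshape grey sphere.desc.json sphere.desc.json
1.0000
```

`protshape matrix DIR -o sim.csv` writes the all-vs-all similarity table and
`protshape cluster DIR -o tree.nwk` the average-linkage dendrogram in Newick.
The same operations are available as library functions (`compare`,
`all_vs_all`, `rank_query`, `average_linkage` in `protshape`).

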