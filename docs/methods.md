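# Methods

`headmesher` converts multi-label or probabilistic tissue segmentations of
head MRI into a nested multi-layer surface model and a labeled, quality- and
size-bounded tetrahedral mesh.  This note documents the models, the numerical
choices, and what the synthetic phantoms do and do not establish.

## The layered tissue model and gap insertion

The head is modeled as nested tissue layers — scalp ⊃ skull ⊃ CSF ⊃ GM ⊃ WM —
each either strictly enclosing the next or sharing a boundary with it.  The
pipeline works with *cumulative* probability maps `C_i = clamp(Σ_{j≤i} P_j)`
(innermost tissue first), whose 0.5-level sets are the layer boundaries.  For
probabilistic inputs built from nested interfaces the cumulative maps cross
0.5 exactly on the interfaces, which is why all thresholding in the package
is cumulative.

Where two adjacent boundaries merge, their iso-surfaces would coincide or
intersect.  Before extraction the pipeline therefore inserts a gap of
`epsilon` voxels between every adjacent cumulative pair, by one of two dual
voxel operators:

* thickening `T+`: the outer map becomes `max(P_in + P_out, D_eps(P_in))`,
  where `D_eps` is the cubic max-filter of half-edge `epsilon` voxels
  (Chebyshev neighborhood; a shrinking window at the grid border);
* thinning `T-`: the inner map becomes `min(P_in, E_eps(P_in + P_out))` with
  the dual min-filter `E_eps`.

Both operators are local: where the pair is separated by at least `epsilon`
voxels the dilation/erosion never exceeds the other map, so nothing changes
(exactly, not approximately — the suite asserts this).  The voxels whose
0.5-membership flips are recorded; sub-threshold value changes move the
extracted interface by well under a voxel and are deliberately *not*
recorded, because the record delimits the later relabeling zone.

Defaults: `epsilon = 1` voxel (the smallest value that separates level
sets); thinning for the innermost (WM inside GM) pair, thickening for all
outer pairs; both overridable per pair.  Air cavities are carved from their
host layer's cumulative map only and extracted as their own closed surfaces;
outer cumulative maps are built with the cavity re-added so nesting is not
punctured.

## Surface extraction

Each layer boundary is the 0.5-level iso-surface of its cumulative map,
extracted by marching cubes at a stride matched to the layer's density
target.  The per-layer density parameter `Rmax` bounds the circumradius of
every surface triangle (the radius of its bounding Delaunay sphere), with
defaults 1.7 mm for WM and GM, 2.0 mm for CSF, 2.5 mm for skull and 3.5 mm
for scalp; the extraction threshold is 0.5.

The raw surface is smoothed (Taubin low-pass by default, `λ=0.5, µ=−0.53`;
Laplacian `α=0.5` and Laplacian+HC `α=0.1, β=0.6` are also provided),
simplified by quadric-error-metric edge collapse toward the target edge
length, and isotropically remeshed (long-edge splits, short-edge collapses
with a circumradius guard, shape-improving flips, tangential relaxation).
Two further steps matter for downstream quality:

* triangles whose circumradius exceeds ~1.3× their shortest edge are
  relaxed/flipped/collapsed away, because that ratio caps the radius-edge
  quality of any volume element built on the triangle;
* after all connectivity editing, vertices are re-projected onto the
  trilinear 0.5-level of the map along their normals (bisection), undoing
  the sub-voxel drift of smoothing and simplification.  This projection is
  what keeps thin-shell volumes (CSF) accurate to better than 1%.

Surface simplification for its own sake (`decimate`) uses the same QEM
collapse with an edge budget: `keep_ratio` is the fraction of edges
preserved.  The nearest-node surface-error statistic used to characterize it
is the distance from each decimated node to the closest original node.

The volumetric Boolean union rasterizes both solids on a shared fine grid
and re-extracts the union mask; its accuracy is set by the grid pitch and is
well within 1% for smooth shapes.  Point-in-surface queries use generalized
winding numbers (solid-angle sums), which resolve points near the surface
deterministically; large point sets go through a two-tier classifier (voxel
flood fill plus ray-parity for the shell voxels).

## Volume meshing

No embeddable tetrahedralization engine is bundled; the mesher is written
here and specializes in star-shaped domains, which covers closed head-like
geometries.  It combines three constructions:

1. **Prism bands.**  The outer surface is extruded inward band by band: the
   boundary polyhedron is scaled toward its volume centroid and the shell
   between the copies is tiled with three tetrahedra per triangle column
   (minimum-vertex-id quad diagonals make bands watertight by construction).
   The first band's outer boundary *is* the input surface, so the summed
   element volume equals the enclosed surface volume to floating point —
   the pipeline's conservation guarantee.  Band heights are ~0.8 of the
   local edge length (the prism-split quality optimum) and, critically,
   band interfaces are *snapped to the median radii of the interior tissue
   surfaces* whenever that keeps the cell aspect healthy.  Aligned
   interfaces are what make per-tissue mesh volumes accurate: cells never
   straddle a label boundary by half their height.

2. **A protected Delaunay core.**  Inside the last front the domain is
   filled with the Delaunay tetrahedralization of the front vertices plus
   interior points arranged as jittered concentric shells, anchored to any
   remaining interior tissue radii.  Interior points keep a protection
   distance from the front so that the front's faces appear as Delaunay
   facets; faces that still fail (locally reflex, near-cocircular spots of
   the front) are recovered exactly by flip-tetrahedron surgery and, for
   whole skipped vertices, by excising and re-fanning the vertex star.  The
   construction is accepted only when the total cell volume reproduces the
   front's enclosed volume (to half the pipeline's 1e-6 conservation
   budget).  Oversized cells are refined by centroid insertion with a
   divergence guard.

3. **Quality polish.**  2-3 and 3-2 bistellar flips plus optimization
   smoothing of interior nodes (boundary nodes never move) drive every
   element under the radius-edge bound.

The quality parameter `q` bounds the radius-edge ratio `R/L` (circumsphere
radius over shortest edge) of every element; default `q = 1.414`.  Note the
regular tetrahedron *minimizes* this ratio at √6/4, so a meaningful bound
must be an upper bound on all elements, and that is what is enforced;
`tetrahedralize` verifies it (and `Vmax = 30 mm³` by default) on every
element and raises otherwise.  A sizing field, when given, acts as a local
`Vmax` at element centroids, honored by band heights and interior point
spacing; a constant field reduces to the global bound.

Interior tissue boundaries are not constrained facets: they are recovered by
classifying each element against the nested surfaces (innermost containing
surface wins; air surfaces take precedence), using a majority vote over five
interior sample points per element.  The bare-centroid rule carries a
curvature bias of order `(h/R)²` that systematically shrinks convex regions;
voting removes most of it, and the interface alignment above removes the
rest.  On the phantom suite the per-tissue mesh volumes agree with the
segmentation to about 1%.

## Boundary recovery (relabeling)

When gaps were inserted between merged boundaries, the mesh initially
assigns the gap shell to the outer tissue.  Relabeling retags it: elements
whose centroids fall in recorded altered voxels are grouped into
face-connected components, and each component is relabeled by majority vote
of its centroids against the original, pre-gap segmentation at threshold
0.5 (ties resolve to the innermost candidate, since gaps are carved from the
inner tissue).  Elements outside the record never change, so the step is
exactly the identity when no boundary was merged.  On the merged-boundary
phantom this restores the GM volume ratio from ~0.92 to within 1% of unity.

## Quality and conservation metrics

* Joe-Liu quality: `12 (3V)^{2/3} / Σ l_ij²` — 1 for the regular
  tetrahedron, 0 when degenerate, scale- and rigid-motion-invariant.
* Radius-edge ratio: circumsphere radius over shortest edge, ≥ √6/4.
* `Vrel`: enclosed volume of a tissue's boundary over the segmentation
  volume of the tissue.  The numerator is surface-based (cumulative
  enclosed volumes differenced per shell) or, for a labeled mesh, the
  summed element volume per label.  The denominator uses the
  cumulative-threshold partition for probabilistic stacks (a thin blurred
  layer's own map can peak below 0.5 even where the layer clearly exists;
  the cumulative maps cross 0.5 exactly on the interfaces) and the literal
  per-label count for label/binary stacks.

## The phantom generator

Phantoms are concentric spherical (or ellipsoidal) interfaces with radii
40/36/33/31/27 mm on a 96³ grid at 1 mm spacing by default, giving layer
thicknesses of 4/3/2/4 mm — bracketing adult scalp (~7 mm), skull (~4 mm),
CSF (~2.7 mm) and cortical GM (~3.3 mm) at a desk-scale grid.  Probability
maps are Gaussian CDFs of the radial signed distance (blur 1 mm by default),
so every cumulative 0.5-level set lies exactly on its analytic interface and
every shell volume has a closed form (1-D quadrature when a merged cap
deforms an interface).  Controlled pathologies: a merged boundary (an inner
interface pushed onto the next outer one over a 60° polar cap with a smooth
12° transition), an air cavity inside a host layer, and seeded misclassified
noise islands.

What the phantoms do not emulate: cortical folding, anisotropic voxels,
intensity noise, topological defects of real segmentations, and non-star-
shaped anatomy.  Passing the suite therefore establishes the correctness of
the operators and the conservation/quality machinery, not robustness to
arbitrary clinical segmentations; in particular the volume mesher requires
the outer boundary to be star-shaped about its volume centroid and rejects
other inputs explicitly.

## Numerical choices and limitations

* Grid border handling for the morphological filters is the shrinking
  window; all neighborhoods are full cubes (Chebyshev balls).
* Clamping `P_in + P_out` to [0, 1] preserves probability semantics and
  provably does not move any 0.5-level set.
* The problem sizes of the test suite (96³ phantoms, ~40 k elements) were
  chosen so a full pipeline run takes on the order of two minutes on one
  CPU; the same code paths scale to finer settings via `Rmax`/`Vmax`.
* Exactly cospherical inputs (e.g. perfect icospheres at high density) can
  defeat the core's facet recovery; a tiny radius-preserving tangential
  jitter applied during banding makes generic inputs safe, but highly
  symmetric dense surfaces may still leave a few elements above the quality
  bound, which `tetrahedralize` reports.
* Mesh-based per-tissue volumes are accurate to ~1% at the default density;
  resolving much better than that requires elements substantially smaller
  than the thinnest layer.
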