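# headmesher

Surface-based tetrahedral meshing of segmented head and brain MRI.

Model-based neuroimaging — functional near-infrared spectroscopy forward
models, EEG/MEG source analysis, photobiomodulation dosimetry — needs
anatomically faithful tetrahedral meshes of the head: scalp, skull, CSF,
gray and white matter as nested, labeled regions.  Building such meshes
directly from voxel segmentations tends to produce ragged boundaries,
broken thin layers (CSF) and noise islands.  `headmesher` instead goes
through a *surface* model: it turns per-tissue probability (or multi-label)
volumes into smooth, closed, non-intersecting boundary surfaces, then fills
them with a quality- and size-bounded tetrahedral mesh whose element labels
follow the anatomy.

The pipeline:

1. **Layered model.**  Cumulative tissue maps are formed innermost→outermost
   and a small gap (`ε` voxels) is inserted wherever adjacent boundaries
   merge, using dual thickening/thinning operators built on cubic max/min
   filters: `T+ : P_out ← max(P_in + P_out, D_ε(P_in))` and
   `T− : P_in ← min(P_in, E_ε(P_in + P_out))`.  The operators only act where
   boundaries touch; the altered voxels are recorded.  Air cavities are
   carried as separate regions.
2. **Surfaces.**  Each boundary is extracted at threshold 0.5 with a
   per-layer triangle-size bound `Rmax` (circumradius of every triangle),
   smoothed (Taubin / Laplacian / Laplacian+HC), simplified by quadric edge
   collapse, and snapped back onto the level set.
3. **Tetrahedra.**  The nested surfaces are filled by a radially layered,
   boundary-conforming mesher with a protected Delaunay core.  Every element
   satisfies the radius-edge bound `q` (`R_i/L_i ≤ q`, default 1.414) and
   the volume bound `Vmax` (default 30 mm³); the summed element volume
   equals the outer surface's enclosed volume to floating-point precision.
4. **Labels and recovery.**  Elements are labeled by the innermost
   containing surface; the gap regions inserted in step 1 are retagged
   against the original segmentation, restoring shared boundaries.
5. **QC.**  Joe–Liu quality (`12(3V)^{2/3}/Σl²`, 1 = regular tetrahedron),
   radius-edge ratios, element volumes and per-tissue volume-conservation
   ratios `Vrel` (boundary-enclosed volume over segmentation volume) are
   reported as JSON/markdown.

A synthetic phantom family (nested spheres with analytic volumes, optional
merged boundaries, air cavities and noise islands) provides offline oracles
for every stage; see `docs/methods.md` for the models and numerical choices.

## Worked example

```python
from headmesher import (PipelineConfig, run_pipeline, make_layered_phantom)
from headmesher.phantoms import PRESETS

stack, analytic = make_layered_phantom(PRESETS["five-layer"])
result = run_pipeline(PipelineConfig(), stack)

print(result.mesh.n_nodes, result.mesh.n_elements)
print(f"mean Joe-Liu {result.report.joe_liu_mean:.3f}")
for name, vr in result.report.v_rel.items():
    print(f"{name:6s} Vrel {vr:.4f}")
```

On the default five-layer phantom (interface radii 40/36/33/31/27 mm, 96³
voxels at 1 mm) this prints a mesh of about 7 400 nodes and 41 000 elements
with

```
7401 41167
mean Joe-Liu 0.750
wm     Vrel 0.9937
gm     Vrel 1.0049
csf    Vrel 0.9815
skull  Vrel 1.0049
scalp  Vrel 0.9891
```

— every element under the radius-edge bound 1.414 and the volume bound
30 mm³, and every tissue's volume conserved to within 2% of its
segmentation (the thin 2 mm CSF shell is the hardest).  A full run takes
roughly two minutes on one CPU.

The same pipeline is available from the shell:

```sh
headmesher phantom --preset five-layer -o phantom/
headmesher run -s wm=phantom/wm.nii.gz -s gm=phantom/gm.nii.gz \
    -s csf=phantom/csf.nii.gz -s skull=phantom/skull.nii.gz \
    -s scalp=phantom/scalp.nii.gz -o head.vtk
headmesher qc head.vtk
headmesher surfaces-only --phantom-preset five-layer -o surfaces/
```

`run` accepts a JSON config (tissue order, per-layer `Rmax`, gap strategy,
`q`, `Vmax`, relabeling on/off) and writes the mesh (VTK legacy, Gmsh MSH
2.2 or TetGen .node/.ele), a QC report and a reproducibility manifest.

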