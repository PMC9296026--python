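# jointmorph

Quantify larval zebrafish jaw-joint growth from tracked cell centroids and
predict joint shape change with an anisotropic finite-element growth model.

Between 3.5 and 5.5 days post fertilisation the zebrafish jaw joint — the
posterior end of Meckel's cartilage (MC) opposing the anterior end of the
palatoquadrate (PQ), separated by the interzone — acquires its interlocking
shape mainly through oriented chondrocyte volume expansion rather than
proliferation or matrix deposition. `jointmorph` implements the full
analysis chain for studying this process, starting from cell-centroid
tables with track correspondences (not images):

1. **cell links** (`jointmorph.links`) — adjacency between neighbouring
   chondrocytes (3D Delaunay edges pruned at 1.5× the median edge length),
   links conserved across a 12-h window, and the cell-dynamics metrics
   (division % per window, tracked-cell volume expansion %).
2. **growth maps** (`jointmorph.growth`) — on a 15 μm cubic grid of regions
   of interest (ROIs), the *statistical velocity gradient*
   `V = sym(M⁻¹C)` with texture tensor `M = ⟨ℓ⊗ℓ⟩` and link-change tensor
   `C = ⟨ℓ⊗Δℓ⟩/Δt`, where ℓ are centroid-to-centroid link vectors. `V`'s
   eigenvalues, ordered by magnitude (main / second / third direction), are
   the local strain rates (h⁻¹) and its eigenvectors the growth directions
   — a growth ellipsoid per ROI. Maps from several specimens are averaged
   per ROI after interquartile-range outlier removal.
3. **shape averaging** (`jointmorph.shapes`) — transversal slice outlines of
   aligned specimen surfaces, arc-length point correspondence, point-wise
   averaging, and lofting of the averaged outline stacks into a labelled
   tetrahedral simulation domain (MC, PQ, interzone, hypertrophic bands).
4. **FE growth** (`jointmorph.fe`) — incremental small-strain linear
   elasticity with element-wise growth eigenstrains
   `ε_g = R·diag(g₁,g₂,g₃)·Rᵀ·Δt/n` along per-ROI material frames
   (cartilage E = 54.8 kPa, interzone 0.25 % of that, ν = 0.3), mapped
   fields between ROI centres, hypertrophic extension from the adjacent
   30 μm of proliferative cartilage, physiological boundary conditions, and
   the two ablations: per-rudiment **homogenised** fields and **isotropised**
   (sphere) fields.
5. **scoring** (`jointmorph.scoring`) — five shape features (MC length /
   depth / width, PQ length / depth) as labelled sub-mesh extents, and the
   percentage match of change `100·(pred−init)/(target−init)` binned as
   <10 % no growth, 10–70 % undergrowth, 70–130 % accurate, >130 %
   overgrowth.
6. **synthetic data** (`jointmorph.synthetic`) — cell clouds, track maps and
   toy joint meshes with known imposed velocity-gradient fields, so every
   stage can be validated against exact ground truth.
7. **pipeline** (`jointmorph.pipeline`, CLI `jointmorph`) — orchestration of
   the full study across 12-h windows with config, provenance and reports.

## Worked example

```python
import numpy as np
from jointmorph import build_adjacency, compute_growth_map, match_links, summarize_rates
from jointmorph.synthetic import SyntheticSpec, apply_growth_field, generate_rudiment_cells

spec = SyntheticSpec(n_cells=50, imposed_field=np.diag([0.001, 0.004, 0.02]),
                     centroid_noise_sd=0.2, seed=1)
cells_t0 = generate_rudiment_cells(spec)
cells_t1, track, truth = apply_growth_field(cells_t0, spec)
conserved = match_links(build_adjacency(cells_t0), cells_t0, cells_t1, track, dt=12.0)
gmap = compute_growth_map(conserved, side=15.0, window=spec.window)
print(summarize_rates(gmap))
```

prints

```
region direction  mean_rate_per_h  sd_rate_per_h  n_rois
   all      main         0.019794       0.000545      12
   all    second         0.004623       0.000660      12
   all     third         0.001279       0.000761      12
```

i.e. from nothing but noisy centroid positions and track labels the
per-ROI ellipsoids recover the imposed anisotropic rates (0.02, 0.004,
0.001 h⁻¹) with sub-millistrain accuracy. The `examples/` directory holds
one short script per capability (growth quantification, shape averaging,
FE growth, scoring, and the full multi-window study with ablations); the
same stages are available as CLI subcommands
(`jointmorph simulate-data | links | growth-maps | average-shape | grow |
score | run-all`).

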