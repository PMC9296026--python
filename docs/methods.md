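# Methods

## The model

`jointmorph` treats joint morphogenesis as a two-stage problem: *measure*
the local tissue deformation-rate field from tracked cell centroids, then
*predict* shape change by driving an elastic model of the joint with that
field as growth.

### Statistical velocity gradient

Within each cubic region of interest (ROI, side 15 μm, matching roughly two
cell diameters), the cell pattern is summarised by link vectors ℓ between
the centroids of adjoining cells. Adjoining is operationalised as edges of
the 3D Delaunay tessellation pruned at a maximum link length (default 1.5×
the median edge length; k-nearest-neighbour and fixed-radius adjacency are
selectable). For links whose endpoints are both tracked across a window Δt,
with texture tensor `M = ⟨ℓ₀ ⊗ ℓ₀⟩` and `C = ⟨ℓ₀ ⊗ (ℓ₁−ℓ₀)⟩/Δt`, the
statistical velocity gradient is

    V = sym(M⁻¹ C)   (h⁻¹).

The estimator is pinned by an exactness contract: if every link moves by a
uniform affine velocity gradient L, then `C = M Lᵀ` and `V = sym(L)` with
no discretisation error. The antisymmetric part of `M⁻¹C` carries the local
rigid rotation rate and is discarded. `V` is reported as a growth
ellipsoid: eigenvalues sorted by **descending magnitude** (main, second,
third direction; a strong contraction outranks a mild expansion, which is
the only ordering consistent with observed anterior-element windows whose
largest-magnitude rate is negative) and eigenvectors with a deterministic
sign (largest component positive).

Per-ROI validity requires `min_links = 4` (the minimum for a full-rank 3D
texture tensor) and a condition number of M below 10⁸; invalid ROIs are
flagged, never zero-filled. Maps from several specimens are averaged per
ROI: samples whose main radius falls outside Tukey fences
(Q1 − 1.5·IQR, Q3 + 1.5·IQR; quartiles by linear interpolation) are
dropped, the surviving tensors averaged component-wise and re-decomposed. A
strict `[Q1, Q3]` mode is available; with ≤ 2 samples no rule can identify
an outlier and nothing is removed. Averaging full tensors (rather than
radii and axes separately) keeps the result a valid symmetric rate tensor.

### Growth simulation

Growth over a window is simulated on a region-labelled 4-node tetrahedral
mesh by incremental small-strain linear elasticity with geometry update:
per increment an element eigenstrain `ε_g = R·diag(g₁,g₂,g₃)·Rᵀ·(Δt/n)` is
applied as initial strain, the displacement solved (sparse direct solve),
and node coordinates updated. A spatially uniform field on a free body is
stress-free and compounds to the analytic per-axis stretch `(1+gΔt/n)ⁿ`;
incompatible fields develop residual stresses. The default `n = 12`
increments per 12-h window keeps `|g|Δt/n ≲ 0.02` per step. Growth frames
are held fixed in global coordinates across increments; under
constraint-induced rigid rotation this introduces a first-order error
(≈ 1 % on the deformation tensor in the worst synthetic test), negligible
at the small rotations of the jaw model.

Materials: cartilage E = 54.8 kPa (nanoindentation of 5-dpf jaw joints),
interzone 0.25 % of that, ν = 0.3 throughout; all overridable. Boundary
conditions: the anterior end of the ceratohyal fixed in all directions, the
anterior MC end fixed mediolaterally (mirror symmetry with the missing
half-jaw), the posterior PQ end free only anteroposteriorly.

Field mapping: the three ellipsoid radii are interpolated linearly between
ROI centres (barycentric on the Delaunay triangulation of the centres;
nearest valid ROI outside the hull), while growth *directions* are
piecewise constant — each element takes the axes of its containing (or
nearest valid) ROI. Hypertrophic regions, invisible to cell tracking, get
the mean eigenstrain-rate tensor of the adjacent 30 μm band of
proliferative cartilage; the mean tensor's ellipsoid supplies both rates
and the single orientation used throughout the region. Averaging the
tensor, not per-element frames, prevents eigenvector noise from leaking the
dominant rate into spurious bending of the long hypertrophic shaft. In the
MC hypertrophic region the orientation is additionally rotated by a linear
regression of cell orientation against distance from the joint line
(coefficients are measured inputs; default slope 0). The ceratohyal
carries no measured field; it inherits the growth of the nearest posterior
cartilage elements, because a rigidly non-growing anchor would bend the
growing jaw against its fixed end.

Ablations: *homogenised* fields replace every ROI tensor of a rudiment by
the rudiment mean (conserving the mean exactly; orientations then vary only
between rudiments), and *isotropised* fields replace each ellipsoid by a
sphere of radius (λ₁+λ₂+λ₃)/3 (conserving the trace, i.e. the volumetric
rate, exactly per ROI).

### Scoring

Five features — MC length, depth, width and PQ length, depth — are measured
as axis-aligned extents of the labelled rudiment sub-meshes, matching
outline measurements in lateral (length, depth) and ventral (length, width)
views. Predictions are scored per feature by the percentage match of
change, `100·(m_pred − m_init)/(m_target − m_init)`, binned at 10/70/130 %
into no-growth / undergrowth / accurate / overgrowth. Boundary values go to
the higher-quality bin; a feature whose target equals its initial value is
reported unscoreable rather than divided by zero.

## Synthetic data: what it emulates and what it does not

The generator produces what live imaging and manual tracking would yield,
with exact ground truth. Per joint element (the 30 μm of each rudiment
facing the interzone): tens of cells (default 40) placed uniformly with a
6 μm hard-core spacing, advected by the linearised flow
`p → p + L(p−c)Δt` about the element centre, plus i.i.d. Gaussian centroid
noise (default 0.2 μm, sub-voxel localisation error). The linearised update
makes the recoverable ground truth exactly `sym(L)` in the small-rate
regime of larval cartilage (|L|Δt ≲ 0.3); a matrix-exponential update is
available. Divisions occur at the observed rarity (defaults 2.42 %/12 h in
the MC element, 0.50 % in the PQ): one daughter keeps the parent id, one
gets a fresh id at a small offset, and division pairs are excluded from
conserved links. Cell volumes expand by the observed means (18.49 % and
23.68 % per 12 h). No intercalation is simulated, matching observation.

The default imposed per-window rates are the measured window means of the
larval jaw joint (main rate ranging from −2.06×10⁻² h⁻¹, a transient
anterior-element contraction, to +2.45×10⁻² h⁻¹, with transverse rates
near zero), so a default run reproduces the magnitude, anisotropy, sign
pattern and temporal trend of the real tissue.

The toy simulation domain is a parametric half-jaw: box-section rods for MC
(20×20×70 μm) and PQ (30×20×80 μm) separated by a 10 μm interzone gap,
hypertrophic bands beyond 30 μm from the joint line, and a ventral
ceratohyal bar carrying the boundary conditions. Box sections were chosen
over elliptic ones so that the lattice-voxelised mesh reproduces the
parametric region volumes exactly at every refinement level; curved,
realistic cross-sections enter through the shape-averaging loft instead.

What passing synthetic tests does **not** show about real data: the
generator's flow is affine per rudiment, so it cannot probe sub-ROI strain
gradients; its noise is isotropic Gaussian, unlike segmentation artefacts;
cell shape, columnar stacking in the MC hypertrophic region (the cause of a
known medio-lateral contraction failure mode), and anterior-tip cell
rearrangements are not represented; and the target shapes are generated by
the same growth operator, so end-to-end "accurate" scores certify
self-consistency of estimation → mapping → simulation → measurement, not
fidelity to biological shape data.

## Meshing

Two generators, both producing conforming, positively oriented,
region-partitioned tet meshes. (1) Lattice voxelisation (toy joint):
region-indicator sampling at voxel centres, six tets per cube (Freudenthal
split, conforming across faces). (2) Outline lofting (average shapes and
any rod-like stack): every transversal plane carries the same disc topology
(centre node, `n_rings` rings, outer ring exactly on the outline), planes
joined by wedges split into tets with global-index-consistent diagonals;
the interzone cross-section blends linearly between the facing rudiment
outlines, so it fills the gap conformally. Cross-section areas — hence
region volumes — are exact up to the polygonal outline (inscribed-polygon
deficit ≈ 0.6 % at 32 boundary points, ≈ 0.04 % at 128).

## Numerical choices and degenerate inputs

- Quartiles: linear interpolation (numpy default), documented because the
  outlier fences depend on it.
- Eigen ties: `argsort` on −|λ| is stable, so exactly equal magnitudes keep
  eigh's ascending order; axis signs fixed by the largest component.
- Degenerate clouds (coplanar/collinear) fall back from Delaunay to
  k-nearest-neighbour adjacency with a warning; coincident centroids are
  rejected.
- ROIs with < 4 links or an ill-conditioned texture tensor are invalid and
  are filled by interpolation/nearest assignment at the mapping stage, not
  zeroed.
- The FE solver reports failure (with stage diagnostics) on element
  inversion, non-finite solutions, or boundary conditions that leave
  rigid-body modes; it never silently continues.
- Reports are JSON with sorted keys and no timestamps: a rerun with the
  same config and seed is byte-identical. Every report carries a
  provenance block (config hash, seed, package version).

## Problem sizes

Default study runs use 40 cells per joint element, 3 synthetic specimens
per window (8 in the end-to-end validation experiments, where averaging
across specimens is what suppresses interface-ROI noise), a 5 μm mesh
pitch (≈ 4.5 k tets, ≈ 3 k DOF) and 12 FE increments per window; a full
four-window study completes in well under a minute on one core. Monte-Carlo
estimator validation uses 100 seeds.

## Known limitations

- Small-strain incremental elasticity with fixed global growth frames; no
  hyperelasticity, contact, or mechanobiological feedback (muscle loading
  is out of scope).
- Growth directions are piecewise constant per ROI; only rates are
  interpolated, so frame fields can jump at ROI boundaries.
- Features are axis-aligned extents: rigid-rotation-sensitive, and extent
  measures rectify noise (any spurious bowing increases them). Transverse
  features with near-zero target change amplify estimation noise through
  the percentage-match denominator — the same instability the real study
  reports for MC width.
- The interzone's outer boundary is parametric (gap-filling blend), not
  inferred from imaging.
- Two-timepoint windows only; no continuous-time tissue flow.
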