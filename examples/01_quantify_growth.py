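"""Quantify local tissue growth from tracked cell centroids.

Generates one synthetic joint element over a 12-h window with a known
velocity-gradient tensor, builds centroid adjacency links, matches them
across the window, and recovers the per-ROI statistical velocity gradient.
The recovered ellipsoid radii are the local strain rates (h⁻¹) along the
main/second/third growth directions; with zero noise they equal the imposed
sym(L) exactly.
"""

import numpy as np

from jointmorph import build_adjacency, compute_growth_map, match_links, summarize_rates
from jointmorph.synthetic import SyntheticSpec, apply_growth_field, generate_rudiment_cells

# anisotropic growth: 2 %/h along the rudiment axis (z), much less transversely
spec = SyntheticSpec(
    n_cells=50,
    imposed_field=np.diag([0.001, 0.004, 0.02]),
    centroid_noise_sd=0.2,
    seed=1,
)
cells_t0 = generate_rudiment_cells(spec)
cells_t1, track, truth = apply_growth_field(cells_t0, spec)

links = build_adjacency(cells_t0)  # Delaunay edges, pruned at 1.5x median length
conserved = match_links(links, cells_t0, cells_t1, track, dt=12.0)
gmap = compute_growth_map(conserved, side=15.0, window=spec.window)

print(f"{len(cells_t0)} cells, {len(links)} links, "
      f"{len(conserved)} conserved across the window")
print(f"{len(gmap.entries)} valid 15-um ROIs\n")
print(summarize_rates(gmap).to_string(index=False))
print("\nimposed rates (main, second, third):",
      np.sort(np.linalg.eigvalsh(truth.rate_tensor))[::-1])
# The mean main rate approaches 0.02/h: the ROI tensors recover the imposed
# anisotropic growth from nothing but centroid positions and track labels.
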