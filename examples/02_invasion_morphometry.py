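"""Quantify invasion distance and cell shape on a synthetic invasion field.

Generates elliptical cells biased toward the endothelial channel whose
elongation grows with invasion depth, then measures per-cell aspect ratio,
circularity and signed invasion distance from the rendered label mask alone.
"""
import numpy as np

from vesselflux import SimulationConfig, invasion_distances, shape_descriptors
from vesselflux.synthetic import simulate_invasion_field

cfg = SimulationConfig(seed=2)
mask, truth = simulate_invasion_field(cfg, n_cells=80, bias=60.0, edge_x=0.0)
records = shape_descriptors(mask)

# mask columns start half a field-width behind the channel edge
x_um = records["centroid_x_um"] - mask.labels.shape[1] * mask.pixel_size / 2.0
inv = invasion_distances(x_um.to_numpy(), channel_edge_x=0.0)

print(f"cells measured: {len(records)}")
print(f"mean signed invasion distance: {inv.mean:.1f} +/- {inv.sem:.1f} um (SEM)"
      f"  [generator bias: 60 um]")
invaded = records[inv.distances > 100.0]
near = records[inv.distances <= 0.0]
print(f"aspect ratio  > 100 um deep: {invaded['aspect_ratio'].mean():.2f}"
      f"   behind the edge: {near['aspect_ratio'].mean():.2f}")
print(f"circularity   > 100 um deep: {invaded['circularity'].mean():.2f}"
      f"   behind the edge: {near['circularity'].mean():.2f}")
print()
print("Invaded cells are more elongated (higher AR, lower circularity),")
print("reproducing the shape-vs-depth gradient the generator encodes.")
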