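"""Estimate how many myocytes one sympathetic neuron can innervate.

Random 50-μm transects are cast across a synthetic cardiomyocyte
boundary mosaic (mean cell diameter 24 μm); the crossing counts give the
mean boundary spacing, and dividing a neuron's total dendritic process
length by that spacing bounds the number of cells its processes cross.
The worked example with the published transect statistics (N = 4.21 ±
2.05 over 50 μm, ~1,000 μm of process) is reproduced at the end.
"""

from neurocard import (innervated_cell_range, random_transects,
                       spacing_from_counts, synthesize_boundary_mask,
                       weighted_neurite_length)

mask = synthesize_boundary_mask(mean_cell_diameter=24.0,
                                image_shape=(512, 512), pixel_size=1.0,
                                seed=5)
res = random_transects(mask, length_um=50.0, n_transects=100, seed=6)
print(f"crossings per 50 um transect: {res.mean_N:.2f} +/- {res.sd_N:.2f}")
print(f"boundary spacing:             {res.spacing_mean:.2f} "
      f"+/- {res.spacing_sd:.2f} um")

lengths = weighted_neurite_length([[400.0, 380.0, 250.0],
                                   [900.0, 300.0],
                                   [650.0, 420.0, 150.0]])
print(f"mean process length/neuron:   {lengths.mean_by_neuron:.0f} um")

est = innervated_cell_range(lengths.mean_by_neuron, res.spacing_mean,
                            res.spacing_sd, rounding="none")
print(f"cells innervated per neuron:  {est.cells_min}-{est.cells_max} "
      f"(mean {est.cells_mean})")

# Worked example with the published statistics:
mean, sd = spacing_from_counts(50.0, 4.21, 2.05)
est = innervated_cell_range(1000.0, mean, sd, rounding="spacing_first")
print(f"published statistics:         spacing {mean:.2f} +/- {sd:.2f} um "
      f"-> {est.cells_min}-{est.cells_max} cells (mean {est.cells_mean})")
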