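"""Simulate a landscape and a virtual species, then sample occurrences.

Builds a 4-layer autocorrelated climate field, defines a specialist
species with Gaussian responses on two driving variables (flat responses
on two nuisance layers), and draws presence points proportional to
suitability. Printed numbers: the suitability range, the fraction of the
landscape with suitability >= 0.5 (the species' prevalence), and the mean
suitability at the sampled points (should far exceed the landscape mean).
"""

import numpy as np

import nichekit as nk

species = nk.default_species()
names = list(species.response_params)
stack = nk.generate_landscape(4, (60, 60), autocorr_range=2, seed=1, layer_names=names)
surface = nk.suitability_surface(species, stack)
occ = nk.sample_occurrences(surface, stack, 500, seed=2)

row, col = stack.point_to_rowcol(occ.lon, occ.lat)
print(f"suitability range: [{surface.min():.4f}, {surface.max():.4f}]")
print(f"prevalence (suitability >= 0.5): {(surface >= 0.5).mean():.3f}")
print(f"mean suitability at occurrences: {surface[row, col].mean():.3f}")
print(f"mean suitability over landscape: {surface.mean():.3f}")
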