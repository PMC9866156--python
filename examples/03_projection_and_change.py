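"""Project an ensemble onto current and future climate and account for
the change.

Projects the fitted ensemble onto the training stack and onto a warmed
copy (+0.5 sd on the first driving layer), classifies suitability into
the four classes, sums spherical areas per class in km^2, and reports the
gain/loss balance and the centroid shift. gain - loss always equals the
suitable-area difference exactly.
"""

import nichekit as nk

species = nk.default_species()
names = list(species.response_params)
stack = nk.generate_landscape(4, (60, 60), autocorr_range=2, seed=1, layer_names=names)
surface = nk.suitability_surface(species, stack)
occ = nk.sample_occurrences(surface, stack, 500, seed=2)
pabs = nk.sample_pseudo_absence(stack, occ, n=1000, seed=3)
data = nk.build_sample_matrix(stack, occ, pabs)
models, evals = nk.run_replicates(["RF", "GLM", "GBM"], data, reps=3, seed=4)
em = nk.build_ensemble(models, evals, data, k=3, seed=4)

now = nk.project(em, stack)
future = nk.project(em, nk.perturb_stack(stack, {"env1": (0.5, 1.0)}, "2050s"))

labels = em.scheme.labels
for smap in (now, future):
    areas = nk.area_by_class(smap.classes(em.scheme), smap.stack)
    pretty = {labels[c]: f"{a:,.0f}" for c, a in areas.items()}
    print(f"{smap.scenario:>12}: areas km^2 {pretty}")

ch = nk.change(now.binary(em.cutoff), future.binary(em.cutoff), stack)
print(f"gain {ch.gain_km2:,.0f} km^2, loss {ch.loss_km2:,.0f} km^2")
c_now = nk.centroid(now.binary(em.cutoff), stack)
c_fut = nk.centroid(future.binary(em.cutoff), stack)
move = nk.shift(c_now, c_fut)
print(f"centroid ({c_now.lon:.2f}, {c_now.lat:.2f}) -> ({c_fut.lon:.2f}, {c_fut.lat:.2f}); "
      f"{move['distance_km']:.1f} km at bearing {move['bearing_deg']:.0f} deg")
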