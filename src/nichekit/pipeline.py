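"""End-to-end pipeline driver.

Runs the full workflow in protocol order — occurrence preparation,
replicate model fitting, evaluation, ensemble construction, scenario
projection with area/centroid accounting, and the COUE niche comparison —
writing every table, map and manifest into one run directory. When no real
inputs are configured, a synthetic bundle (virtual species, two ranges,
perturbed future stacks) is generated first, so the whole chain can run
self-contained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import ensemble as ens
from . import models as mdl
from . import niche, prep, project, synth
from .config import RunConfig, stage_seed
from .evaluate import summarize
from .occurrences import read_occurrences
from .raster import read_stack

logger = logging.getLogger(__name__)

__all__ = ["simulate_bundle", "run_pipeline"]


def simulate_bundle(config: RunConfig, seed: int | None = None):
    """Generate the synthetic study inputs: native/invaded range pair plus
    perturbed future stacks for the native (analysis) region."""
    seed = config.seed if seed is None else seed
    occ_nat, occ_inv, stack_nat, stack_inv = synth.make_range_pair(
        niche_offset=config.synth_offset,
        n_native=config.synth_n_native,
        n_invasive=config.synth_n_invasive,
        seed=stage_seed(seed, "simulate"),
        shape=config.synth_shape,
        autocorr_range=config.synth_autocorr,
    )
    driving = stack_nat.names[0]
    scenarios = {"near-current": stack_nat}
    for tag, mult in (("2030s_ssp1-2.6", 0.5), ("2030s_ssp5-8.5", 1.0), ("2050s_ssp5-8.5", 2.0)):
        scenarios[tag] = synth.perturb_stack(
            stack_nat, {driving: (config.synth_future_shift * mult, 1.0)}, tag
        )
    return occ_nat, occ_inv, synth.ScenarioSet(stacks=scenarios), stack_inv


def run_pipeline(config: RunConfig, out_dir: str | Path, seed: int | None = None) -> Path:
    """Execute every stage in order; returns the run directory."""
    seed = config.seed if seed is None else seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "seed": seed, "config_hash": config.config_hash()}

    # -- inputs -------------------------------------------------------------
    if config.occurrences and config.stacks:
        occ = read_occurrences(config.occurrences)
        scenarios = {tag: read_stack(d) for tag, d in config.stacks.items()}
        base = scenarios["near-current"]
        occ_nat = occ.subset(occ.records["range_label"] == "native")
        occ_inv = occ.subset(occ.records["range_label"] == "invasive")
        stack_inv = None
    else:
        occ_nat, occ_inv, scen, stack_inv = simulate_bundle(config, seed)
        scenarios = scen.stacks
        base = scenarios["near-current"]
    manifest["scenarios"] = list(scenarios)

    # -- prep ---------------------------------------------------------------
    occ_clean = prep.clean(occ_nat)
    cell = config.thinning_cell_size or base.cell_size
    occ_thin = prep.thin_to_grid(occ_clean, cell, x_origin=base.x_origin, y_origin=base.y_origin)
    pabs = prep.sample_pseudo_absence(
        base, occ_thin, n=config.n_pseudo_absence, seed=stage_seed(seed, "pseudo_absence")
    )
    full = prep.build_sample_matrix(base, occ_thin, pabs)
    retained = prep.filter_collinear(
        full, threshold=config.collinearity_threshold, priority=config.priority
    )
    data = full.select(retained)
    manifest["n_presences"] = int(data.y.sum())
    manifest["n_pseudo_absence"] = int((data.y == 0).sum())
    manifest["retained_variables"] = retained
    (out / "retained_variables.json").write_text(json.dumps(retained, indent=2))

    # -- models + evaluation ------------------------------------------------
    fit_seed = stage_seed(seed, "fit")
    models, evals = mdl.run_replicates(
        config.families, data, split=config.split, reps=config.reps, seed=fit_seed
    )
    eval_df = pd.DataFrame(
        [
            {
                "family": e.family, "replicate": e.replicate, "auc": e.auc,
                "tss": e.tss_max, "cutoff": e.cutoff, "sensitivity": e.sensitivity,
                "specificity": e.specificity, "failed": e.failed,
            }
            for e in evals
        ]
    )
    eval_df.to_csv(out / "evals.csv", index=False)
    summary = summarize(evals)
    summary.to_csv(out / "summary.csv")
    manifest["n_fitted_models"] = sum(m is not None for m in models)

    # -- ensemble -----------------------------------------------------------
    em = ens.build_ensemble(
        models, evals, data, k=config.k, split=config.split, seed=fit_seed,
        rule=config.combination_rule, bounds=config.class_bounds,
    )
    manifest["ensemble"] = {
        "families": em.families, "cutoff": em.cutoff, "auc": em.auc, "tss": em.tss,
    }
    importance = ens.variable_importance(
        em, data, n_perm=3, seed=stage_seed(seed, "importance")
    )
    importance.rename("importance").to_csv(out / "importance.csv")

    # -- projection ---------------------------------------------------------
    areas_rows, centroid_rows, change_rows = [], [], []
    maps: dict[str, project.SuitabilityMap] = {}
    for tag, stack in scenarios.items():
        smap = project.project(em, stack)
        maps[tag] = smap
        classes = smap.classes(em.scheme)
        areas = project.area_by_class(classes, stack)
        labels = em.scheme.labels
        row = {"scenario": tag}
        row.update({labels[c]: areas.get(c, 0.0) for c in range(4)})
        row["total_suitable"] = sum(areas.get(c, 0.0) for c in (1, 2, 3))
        areas_rows.append(row)
        c = project.centroid(smap.binary(em.cutoff), stack)
        centroid_rows.append({"scenario": tag, "lon": c.lon, "lat": c.lat})
        np.savetxt(out / f"suitability_{tag}.csv", smap.p, delimiter=",", fmt="%.1f")
    base_binary = maps["near-current"].binary(em.cutoff)
    for tag, smap in maps.items():
        if tag == "near-current":
            continue
        ch = project.change(base_binary, smap.binary(em.cutoff), smap.stack)
        change_rows.append({"scenario": tag, "gain_km2": ch.gain_km2, "loss_km2": ch.loss_km2})
    pd.DataFrame(areas_rows).to_csv(out / "areas_km2.csv", index=False)
    pd.DataFrame(centroid_rows).to_csv(out / "centroids.csv", index=False)
    pd.DataFrame(change_rows).to_csv(out / "changes_km2.csv", index=False)

    # -- niche comparison ---------------------------------------------------
    if stack_inv is not None and len(occ_inv) >= 5:
        nat_bg = pd.DataFrame(base.to_matrix()[0], columns=base.names)
        inv_bg = pd.DataFrame(stack_inv.to_matrix()[0], columns=stack_inv.names)
        nat_env = prep.extract(base, occ_thin)
        inv_env = prep.extract(stack_inv, prep.clean(occ_inv))
        result = niche.compare_niches(
            nat_bg, inv_bg, nat_env, inv_env,
            reps=config.niche_reps, seed=stage_seed(seed, "niche"),
            resolution=config.niche_resolution,
        )
        manifest["niche"] = {
            "schoener_d": result.d, "expansion": result.expansion,
            "stability": result.stability, "unfilling": result.unfilling,
            "p_equivalency": result.p_equivalency,
            "p_similarity_nat_inv": result.p_similarity_nat_inv,
            "p_similarity_inv_nat": result.p_similarity_inv_nat,
            "n_reps": result.n_reps,
        }
        (out / "niche.json").write_text(json.dumps(manifest["niche"], indent=2))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
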