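"""End-to-end driver: simulate -> classify -> match -> overlap -> grid/GLM
-> impute -> trait space.

Runs the whole analysis on one synthetic dataset and returns a nested report
dictionary. Problem sizes (replicates, trees, Monte-Carlo samples) are
configurable; the study-scale defaults live on the individual modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import hyperspace, iucn, matching, prey, spatial, synthetic, traits
from .hyperspace import HypervolumeConfig
from .traits import ImputationConfig


@dataclass
class PipelineConfig:
    sim: synthetic.SimConfig = field(default_factory=synthetic.SimConfig)
    n_predators: int = 8
    misspell_rate: float = 0.1
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    hypervolume: HypervolumeConfig = field(default_factory=HypervolumeConfig)
    n_rand: int = 333
    hv_dim: int = 5


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage on synthetic inputs; returns the report dict."""
    sim = cfg.sim
    seed = sim.seed
    report: dict = {"seed": seed, "n_species": sim.n_species}

    # 1. simulate
    records = synthetic.generate_species_table(sim)
    tree = synthetic.generate_phylogeny(
        sim.n_species, seed, tip_names=[r.binomial for r in records]
    )
    class_by_species = {r.binomial: r.class_name for r in records}
    truth, masked = synthetic.generate_trait_table(tree, sim, class_by_species)
    ranges = synthetic.generate_ranges(records, sim)
    diets = synthetic.generate_predator_diets(
        records, ranges, cfg.n_predators, cfg.misspell_rate, seed + 3,
        grid_dims=sim.grid_dims,
    )

    # 2. classify uses and threats
    retained = iucn.filter_assessed(records)
    counts = iucn.summarize_groups(retained)
    overlaps = iucn.category_overlaps(retained)
    report["classification"] = {
        "n_total": counts.n_total,
        "n_used": counts.n_used,
        "pct_used": counts.pct_used,
        "n_use_threat": counts.n_use_threat,
        "n_risk_use_threat": counts.n_risk_use_threat,
        "pct_risk_of_used": counts.pct_risk_of_used,
        "multiple_use_fraction": overlaps.multiple_use_fraction,
    }

    # 3. reconcile prey names and compare prey diversity
    reference = [r.binomial for r in retained]
    comparisons = []
    n_perturbed = n_resolved_true = n_candidate_true = 0
    for diet in diets:
        reports = matching.reconcile_binomials(diet.prey_names, reference)
        for rep, true_name in zip(reports, diet.true_identities):
            if rep.query != true_name:  # a perturbed name
                n_perturbed += 1
                if rep.best_match == true_name:
                    n_candidate_true += 1
                    if rep.disposition in {"exact", "resolved_spelling"}:
                        n_resolved_true += 1
        resolved = set(matching.resolved_names(reports))
        if not resolved:
            continue
        comparisons.append(
            prey.prey_diversity_ratio(
                diet.predator, resolved, retained, ranges, diet.range_cells
            )
        )
    report["prey_comparisons"] = {
        "n_predators": len(comparisons),
        "median_overlap_percent": float(
            np.median([c.overlap_percent for c in comparisons])
        ),
        "max_ratio_all": float(max(c.ratio_all for c in comparisons)),
        "min_ratio_all": float(min(c.ratio_all for c in comparisons)),
        # fraction of perturbed names auto-resolved to their true source,
        # and the fraction whose true source was at least flagged for review
        "misspelling_recovery_rate": (
            n_resolved_true / n_perturbed if n_perturbed else 1.0
        ),
        "misspelling_candidate_rate": (
            n_candidate_true / n_perturbed if n_perturbed else 1.0
        ),
    }

    # 4. grid tabulation + NB GLM standardization
    n_cells = sim.grid_dims[0] * sim.grid_dims[1]
    grid = spatial.tabulate_grid(
        {r.binomial: ranges[r.binomial] for r in retained}, retained, n_cells
    )
    fit = spatial.fit_use_availability_glm(grid)
    resid = spatial.pearson_residuals(fit)
    report["spatial"] = {
        "n_cells_fit": int(len(fit.cell_ids)),
        "slope": fit.slope,
        "intercept": fit.intercept,
        "theta": fit.theta,
        "mean_pearson_residual": float(resid["pearson_residual"].mean()),
        "n_outlier_cells": int(resid["outlier"].sum()),
    }

    # 5. trait pipeline on the terrestrial bird+mammal subset
    tm = [
        r.binomial
        for r in retained
        if r.class_name in {"Aves", "Mammalia"} and "terrestrial" in r.realms
    ]
    sub = masked.loc[[b for b in masked.index if b in set(tm)]]
    diet_cols = [f"diet_{c}" for c in synthetic.DIET_CATEGORIES]
    diet_obs = sub[diet_cols].dropna()
    axis = traits.diet_axis(diet_obs)
    five = sub[list(synthetic.TRAIT_NAMES)].copy()
    five["diet"] = axis.scores.reindex(five.index)
    standardized, transform = traits.transform_traits(five)
    eig = traits.phylo_eigenvectors(tree, k=cfg.imputation.n_eigenvectors)
    imputed = traits.rf_impute(standardized, eig, cfg.imputation)
    report["traits"] = {
        "n_trait_species": len(five),
        "diet_variance_explained_pct": 100.0 * axis.variance_explained,
        "oob_nrmse_mean": {k: float(v) for k, v in imputed.oob_nrmse_mean.items()},
    }

    # 6. trait space + hypervolume nulls
    space = hyperspace.pca_space(imputed.sets)
    by_name = {r.binomial: r for r in retained}
    groups = {b: iucn.classify_use(by_name[b]) for b in space.scores.index}
    used_idx = [b for b, g in groups.items() if g != iucn.UseGroup.NOT_USED]
    not_used_idx = [b for b, g in groups.items() if g == iucn.UseGroup.NOT_USED]
    risk_idx = [
        b for b, g in groups.items()
        if g == iucn.UseGroup.EXTINCTION_RISK_USE_THREAT
    ]
    dims = list(range(cfg.hv_dim))
    pool = space.scores.iloc[:, dims].to_numpy()
    used_pts = space.scores.loc[used_idx].iloc[:, dims].to_numpy()
    null = hyperspace.null_distribution(
        used_pts, pool, n_rand=cfg.n_rand, cfg=cfg.hypervolume, seed=seed + 11
    )
    contour = hyperspace.density_contour(
        space.scores.loc[used_idx, ["PC1", "PC2"]].to_numpy(), prob=0.5
    )
    per_trait = hyperspace.per_trait_comparisons(
        imputed.sets, used_idx, not_used_idx
    )
    report["trait_space"] = {
        "variance_explained": [float(v) for v in space.variance_explained],
        "n_used": len(used_idx),
        "n_not_used": len(not_used_idx),
        "n_risk": len(risk_idx),
        "observed_volume": null.observed_volume,
        "null_volume_median": float(np.median(null.random_volumes)),
        "p_volume": null.p_volume,
        "observed_unique_percent": null.observed_unique_percent,
        "p_unique": null.p_unique,
        "contour_inside_fraction": float(np.mean(contour.inside)),
        "per_trait": per_trait.to_dict(orient="records"),
    }
    return report
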