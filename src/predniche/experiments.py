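"""Reusable simulation experiments: parameter-recovery and calibration rigs.

These wire the synthetic generators to the estimators so that recovery
studies (imputation of masked traits, null-model calibration) can be run
identically from the test suite, the acceptance script and the analysis
drivers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import hyperspace, synthetic, traits
from .hyperspace import HypervolumeConfig
from .synthetic import DIET_CATEGORIES, SimConfig, TRAIT_NAMES
from .traits import ImputationConfig

DIET_COLS = [f"diet_{c}" for c in DIET_CATEGORIES]


def imputation_recovery_setup(
    n: int = 300,
    phylo_signal: float = 0.95,
    missingness: float = 0.2,
    seed: int = 1,
):
    """Tree, standardized complete truth, masked copy, and eigenvectors.

    The masked table is standardized with the truth's transform parameters so
    held-out entries are directly comparable after imputation.
    """
    cfg = SimConfig(
        n_species=n, seed=seed, phylo_signal=phylo_signal,
        missingness=missingness,
        class_weights={"Aves": 0.5, "Mammalia": 0.5},
    )
    tree = synthetic.generate_phylogeny(n, seed)
    truth, masked = synthetic.generate_trait_table(tree, cfg)
    ax = traits.diet_axis(truth[DIET_COLS])

    def five(df: pd.DataFrame) -> pd.DataFrame:
        out = df[list(TRAIT_NAMES)].copy()
        out["diet"] = ax.scores.where(df[DIET_COLS].notna().all(axis=1))
        return out

    z_truth, tf = traits.transform_traits(five(truth))
    z_masked = five(masked)
    for col in ("body_mass", "generation_length"):
        z_masked[col] = np.log10(z_masked[col])
    for col in ("litter_clutch", "habitat_breadth"):
        z_masked[col] = np.sqrt(z_masked[col])
    z_masked = (z_masked - tf.means) / tf.sds
    eig = traits.phylo_eigenvectors(tree, k=10)
    return tree, z_truth, z_masked, eig


def heldout_recovery_correlations(
    z_truth: pd.DataFrame,
    z_masked: pd.DataFrame,
    filled: pd.DataFrame,
    min_heldout: int = 10,
) -> dict[str, float]:
    """Correlation between imputed values and the masked-out truth, per trait."""
    out: dict[str, float] = {}
    for col in z_masked.columns:
        held_out = z_masked[col].isna() & z_truth[col].notna()
        if held_out.sum() >= min_heldout:
            out[col] = float(
                np.corrcoef(filled.loc[held_out, col],
                            z_truth.loc[held_out, col])[0, 1]
            )
    return out


def imputation_recovery_experiment(
    seeds=range(1, 6),
    n: int = 300,
    phylo_signal: float = 0.95,
    missingness: float = 0.2,
    cfg: ImputationConfig | None = None,
) -> pd.DataFrame:
    """Held-out recovery per trait across seeds (one row per seed)."""
    cfg = cfg or ImputationConfig(n_sets=1, n_trees=100, seed=0)
    rows = []
    for seed in seeds:
        _, z_truth, z_masked, eig = imputation_recovery_setup(
            n=n, phylo_signal=phylo_signal, missingness=missingness, seed=seed
        )
        filled = traits.rf_impute(z_masked, eig, cfg).sets[0]
        rows.append(
            {"seed": seed,
             **heldout_recovery_correlations(z_truth, z_masked, filled)}
        )
    return pd.DataFrame(rows).set_index("seed")


def null_model_type_one_error(
    n_repeats: int = 50,
    pool_size: int = 300,
    group_size: int = 40,
    dim: int = 3,
    n_rand: int = 99,
    mc_samples: int = 4000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the rarefied-null volume test when the group really
    is a random sample of the pool (should sit near ``alpha``)."""
    cfg = HypervolumeConfig(mc_samples=mc_samples)
    rejections = 0
    for rep in range(n_repeats):
        rng = np.random.default_rng((seed * 1000 + 100 + rep) % 2**31)
        pool = rng.standard_normal((pool_size, dim))
        group = pool[rng.choice(pool_size, group_size, replace=False)]
        null = hyperspace.null_distribution(
            group, pool, n_rand=n_rand, cfg=cfg, seed=rep, compute_unique=False
        )
        rejections += null.p_volume <= alpha
    return rejections / n_repeats
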