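"""Synthetic IUCN-like data with the statistical structure the analysis assumes.

Every generator is deterministic for a fixed seed and emulates one input of
the pipeline: a species table with multi-category use assignment and 5.1.x /
5.4.x threat-code structure, a pure-birth phylogeny, phylogenetically
autocorrelated traits with missing-at-random gaps, contiguous grid-cell
ranges, and predator diet lists containing misspelled binomials (with the
true identity logged so the matcher can be validated).

Nothing here attempts real biogeography; the generators reproduce only the
distributional features downstream code relies on.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .iucn import (
    REALMS,
    RED_LIST_STATUSES,
    SpeciesRecord,
    USE_CATEGORIES,
    USE_THREAT_CODES,
    VERTEBRATE_CLASSES,
)

TRAIT_NAMES = ("body_mass", "litter_clutch", "habitat_breadth", "generation_length")
DIET_CATEGORIES = (
    "invertebrates",
    "vertebrates",
    "fruit",
    "nectar",
    "seed",
    "plant_other",
    "scavenger",
)

_DEFAULT_CLASS_WEIGHTS = {
    "Actinopterygii": 0.40,
    "Aves": 0.24,
    "Reptilia": 0.14,
    "Amphibia": 0.12,
    "Mammalia": 0.08,
    "Chondrichthyes": 0.02,
}
# Use prevalence loosely shaped like the observed category frequencies:
# food and pets dominate, the remainder are rare.
_DEFAULT_USE_PREVALENCE = {
    "food": 0.17,
    "pets": 0.12,
    "sport_hunting": 0.03,
    "medicine": 0.02,
    "wearing_apparel": 0.02,
    "handicrafts": 0.01,
    "animal_feed": 0.01,
    "research": 0.005,
    "other": 0.005,
}
_DEFAULT_STATUS_MIXTURE = {
    "LC": 0.62,
    "NT": 0.06,
    "VU": 0.09,
    "EN": 0.07,
    "CR": 0.04,
    "DD": 0.12,
}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic inputs.

    ``phylo_signal`` acts like Pagel's lambda: traits are a blend of a
    Brownian-motion component on the tree and an i.i.d. component, with
    covariance ``lambda * C_tree + (1 - lambda) * I`` on the standardized
    scale.
    """

    n_species: int = 2000
    class_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_WEIGHTS)
    )
    use_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_USE_PREVALENCE)
    )
    threat_given_use: float = 0.5
    status_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_STATUS_MIXTURE)
    )
    missingness: float = 0.17
    phylo_signal: float = 0.8
    grid_dims: tuple[int, int] = (40, 80)
    bycatch_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ConfigurationError("n_species must be >= 2")
        for name, mapping in (
            ("class_weights", self.class_weights),
            ("status_mixture", self.status_mixture),
        ):
            total = sum(mapping.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1, got {total}")
            if any(not 0.0 <= p <= 1.0 for p in mapping.values()):
                raise ConfigurationError(f"{name} has probabilities outside [0,1]")
        bad = [
            (k, p) for k, p in self.use_prevalence.items() if not 0.0 <= p <= 1.0
        ]
        if bad:
            raise ConfigurationError(f"use_prevalence outside [0,1]: {bad}")
        if not 0.0 <= self.threat_given_use <= 1.0:
            raise ConfigurationError("threat_given_use must be in [0,1]")
        if not 0.0 <= self.missingness < 1.0:
            raise ConfigurationError("missingness must be in [0,1)")
        if not 0.0 <= self.phylo_signal <= 1.0:
            raise ConfigurationError("phylo_signal must be in [0,1]")
        if self.grid_dims[0] < 1 or self.grid_dims[1] < 1:
            raise ConfigurationError("grid_dims must be positive")
        unknown = set(self.use_prevalence) - set(USE_CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown use categories: {sorted(unknown)}")


_VOWELS = "aeiou"
_CONSONANTS = "".join(c for c in string.ascii_lowercase if c not in _VOWELS)


def _make_word(rng: np.random.Generator, n_syllables: int) -> str:
    return "".join(
        rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS))
        for _ in range(n_syllables)
    )


def make_binomials(n: int, rng: np.random.Generator) -> list[str]:
    """Unique, well-formed pronounceable binomials ("Genus species")."""
    names: list[str] = []
    seen: set[str] = set()
    while len(names) < n:
        genus = _make_word(rng, int(rng.integers(3, 5))).capitalize()
        epithet = _make_word(rng, int(rng.integers(3, 6)))
        binomial = f"{genus} {epithet}"
        if binomial not in seen:
            seen.add(binomial)
            names.append(binomial)
    return names


def generate_species_table(cfg: SimConfig) -> list[SpeciesRecord]:
    """Sample a species table matching the configured marginals.

    Use categories are assigned independently with probabilities
    ``use_prevalence``; a used species carries a biological-resource-use
    threat code (a random member of the 5.1/5.4 branch) with probability
    ``threat_given_use``. A small fraction of unused species carry the
    ``bycatch`` marker together with a 5.x code, mirroring species threatened
    only by unintentional take.
    """
    rng = np.random.default_rng(cfg.seed)
    binomials = make_binomials(cfg.n_species, rng)

    class_names = list(cfg.class_weights)
    class_p = np.array([cfg.class_weights[c] for c in class_names])
    classes = rng.choice(class_names, size=cfg.n_species, p=class_p)

    status_names = list(cfg.status_mixture)
    status_p = np.array([cfg.status_mixture[s] for s in status_names])
    statuses = rng.choice(status_names, size=cfg.n_species, p=status_p)

    threat_pool = sorted(USE_THREAT_CODES)
    other_threats = ["1.1", "2.1.2", "8.1.2", "11.1"]

    records: list[SpeciesRecord] = []
    for i in range(cfg.n_species):
        uses = frozenset(
            cat for cat, p in cfg.use_prevalence.items() if rng.random() < p
        )
        # realms: at least one, loosely tied to class
        realm_probs = {
            "Actinopterygii": (0.02, 0.45, 0.65),
            "Chondrichthyes": (0.0, 0.05, 0.98),
            "Amphibia": (0.85, 0.75, 0.0),
        }.get(classes[i], (0.92, 0.18, 0.06))
        realms = frozenset(
            realm for realm, p in zip(REALMS, realm_probs) if rng.random() < p
        )
        if not realms:
            realms = frozenset({REALMS[int(rng.integers(0, 3))]})

        threats: set[str] = set()
        bycatch = False
        if uses:
            if rng.random() < cfg.threat_given_use:
                threats.add(threat_pool[int(rng.integers(0, len(threat_pool)))])
        else:
            if rng.random() < cfg.bycatch_rate:
                bycatch = True
                threats.add(threat_pool[int(rng.integers(0, len(threat_pool)))])
        # unrelated background threats
        for code in other_threats:
            if rng.random() < 0.1:
                threats.add(code)

        records.append(
            SpeciesRecord(
                taxon_id=f"T{i:06d}",
                binomial=binomials[i],
                class_name=str(classes[i]),
                status=str(statuses[i]),
                realms=realms,
                use_categories=uses,
                threat_codes=frozenset(threats),
                bycatch=bycatch,
            )
        )
    return records


def generate_phylogeny(n_species: int, seed: int,
                       tip_names: Sequence[str] | None = None) -> dendropy.Tree:
    """Ultrametric pure-birth tree with tips named by binomial.

    Uses a birth-death simulation with zero death rate; branch lengths are in
    units of expected speciation events.
    """
    if n_species < 2:
        raise ConfigurationError("n_species must be >= 2")
    import random as _random

    rng = _random.Random(seed)
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rng,
    )
    # The simulation stops at the instant of the n-th speciation, leaving the
    # newest sister pair at zero distance; sample the tree a waiting time
    # later (Exp(n * birth_rate), during which no further event occurs).
    dt = rng.expovariate(n_species)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + dt
    if tip_names is None:
        rng_np = np.random.default_rng(seed)
        tip_names = make_binomials(n_species, rng_np)
    taxa = tree.taxon_namespace
    for taxon, name in zip(sorted(taxa, key=lambda t: t.label), tip_names):
        taxon.label = name
    return tree


def tree_vcv(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Shared-path-length (Brownian covariance) matrix and tip labels.

    C[i, j] = depth of the MRCA of tips i and j; C[i, i] = tip depth.
    Computed by a single post-order traversal (O(n^2) assignments).
    """
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    index = {label: k for k, label in enumerate(tips)}
    n = len(tips)
    C = np.zeros((n, n))

    # node depths from root
    for node in tree.preorder_node_iter():
        parent_depth = 0.0 if node.parent_node is None else node.parent_node._depth
        node._depth = parent_depth + (node.edge.length or 0.0)

    for node in tree.postorder_node_iter():
        if node.is_leaf():
            k = index[node.taxon.label]
            node._tipset = [k]
            C[k, k] = node._depth
        else:
            groups = [child._tipset for child in node.child_nodes()]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    ia, ib = np.array(groups[a]), np.array(groups[b])
                    C[np.ix_(ia, ib)] = node._depth
                    C[np.ix_(ib, ia)] = node._depth
            node._tipset = [k for g in groups for k in g]
    return C, tips


def patristic_distances(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Pairwise path-length (patristic) distance matrix and tip labels."""
    C, tips = tree_vcv(tree)
    depths = np.diag(C)
    D = depths[:, None] + depths[None, :] - 2.0 * C
    np.fill_diagonal(D, 0.0)
    return D, tips


def _phylo_normal(
    C: np.ndarray, lam: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draws with covariance lam * C_std + (1 - lam) * I (columns independent)."""
    n = C.shape[0]
    scale = np.sqrt(np.outer(np.diag(C), np.diag(C)))
    C_std = C / np.where(scale > 0, scale, 1.0)
    cov = lam * C_std + (1.0 - lam) * np.eye(n)
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
    return L @ rng.standard_normal((n, size))


def generate_trait_table(
    tree: dendropy.Tree,
    cfg: SimConfig,
    class_by_species: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(ground truth, masked) trait tables indexed by binomial.

    Continuous traits (body mass, litter/clutch size, habitat breadth,
    generation length) are monotone transforms of phylogenetically
    autocorrelated normals; the 7 diet proportions are a softmax of latent
    autocorrelated normals, so every row sums to one. Masking is
    missing-completely-at-random per trait at rate ``missingness``; when
    ``class_by_species`` is given, generation length is left complete for the
    bird class (its coverage is complete in the compiled data the pipeline
    mirrors).
    """
    if cfg.missingness >= 1.0:
        raise ConfigurationError("missingness must be < 1")
    rng = np.random.default_rng(cfg.seed + 1)
    C, tips = tree_vcv(tree)
    n = len(tips)
    lam = cfg.phylo_signal

    latent = _phylo_normal(C, lam, 5 + len(DIET_CATEGORIES), rng)
    # allometric integration: a shared phylogenetic "size" factor couples the
    # life-history traits (larger species live longer, have smaller litters),
    # as in real bird/mammal trait compilations; column variances stay 1
    size = latent[:, 0]

    def blend(load: float, noise: np.ndarray) -> np.ndarray:
        return load * size + np.sqrt(1.0 - load**2) * noise

    truth = pd.DataFrame(index=pd.Index(tips, name="binomial"))
    truth["body_mass"] = 10.0 ** (2.0 + 1.2 * blend(0.85, latent[:, 1]))  # grams
    truth["litter_clutch"] = np.round(
        np.maximum(1.0, np.exp(1.0 + 0.6 * blend(-0.7, latent[:, 2])))
    )
    truth["habitat_breadth"] = np.clip(
        np.round(np.exp(0.9 + 0.7 * blend(0.7, latent[:, 3]))), 1, 30
    )
    truth["generation_length"] = np.maximum(
        0.2, np.exp(1.2 + 0.8 * blend(0.8, latent[:, 4]))
    )
    diet_latent = 1.5 * latent[:, 5:]
    diet = np.exp(diet_latent)
    diet /= diet.sum(axis=1, keepdims=True)
    for j, cat in enumerate(DIET_CATEGORIES):
        truth[f"diet_{cat}"] = diet[:, j]

    masked = truth.copy()
    maskable = list(TRAIT_NAMES)
    for col in maskable:
        if (
            col == "generation_length"
            and class_by_species is not None
        ):
            is_bird = np.array(
                [class_by_species.get(t) == "Aves" for t in tips]
            )
            miss = (rng.random(n) < cfg.missingness) & ~is_bird
        else:
            miss = rng.random(n) < cfg.missingness
        masked.loc[miss, col] = np.nan
    # diet proportions go missing jointly (a species' diet is recorded or not)
    diet_missing = rng.random(n) < cfg.missingness
    for cat in DIET_CATEGORIES:
        masked.loc[diet_missing, f"diet_{cat}"] = np.nan
    return truth, masked


def _grow_blob(
    start: tuple[int, int], size: int, dims: tuple[int, int], rng: np.random.Generator
) -> set[int]:
    """4-connected blob of ``size`` cells grown by seeded random accretion."""
    rows, cols = dims
    blob = {start}
    frontier = [start]
    while len(blob) < size and frontier:
        r, c = frontier[int(rng.integers(0, len(frontier)))]
        neighbors = [
            (r + dr, c + dc)
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
            if 0 <= r + dr < rows and 0 <= c + dc < cols and (r + dr, c + dc) not in blob
        ]
        if not neighbors:
            frontier.remove((r, c))
            continue
        cell = neighbors[int(rng.integers(0, len(neighbors)))]
        blob.add(cell)
        frontier.append(cell)
    return {r * cols + c for r, c in blob}


def generate_ranges(
    species: Sequence[SpeciesRecord], cfg: SimConfig
) -> dict[str, set[int]]:
    """Contiguous grid-cell range (set of cell ids) per binomial.

    Cell id = row * n_cols + col. Range sizes are log-normal, so a few
    species are widespread and most are narrow — every species keeps >= 1
    cell.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    rows, cols = cfg.grid_dims
    n_cells = rows * cols
    ranges: dict[str, set[int]] = {}
    for rec in species:
        size = int(np.clip(np.round(rng.lognormal(2.0, 1.2)), 1, max(1, n_cells // 4)))
        start = (int(rng.integers(0, rows)), int(rng.integers(0, cols)))
        ranges[rec.binomial] = _grow_blob(start, size, cfg.grid_dims, rng)
    return ranges


def perturb_name(name: str, rng: np.random.Generator, n_edits: int) -> str:
    """Random character edits with OSA distance in [1, n_edits] guaranteed.

    Edits are substitute/insert/delete/transpose; because interacting edits
    can inflate the optimal-alignment distance beyond the edit count, the
    result is checked and re-drawn until the distance constraint holds.
    """
    from .matching import osa_distance

    for _ in range(50):
        chars = list(name)
        for _ in range(n_edits):
            op = rng.integers(0, 4)
            # avoid editing the space separating genus and epithet
            positions = [i for i, ch in enumerate(chars) if ch != " "]
            i = positions[int(rng.integers(0, len(positions)))]
            if op == 0:  # substitute
                chars[i] = str(rng.choice(list(string.ascii_lowercase)))
            elif op == 1:  # insert
                chars.insert(i + 1, str(rng.choice(list(string.ascii_lowercase))))
            elif op == 2 and len(chars) > 3:  # delete
                del chars[i]
            else:  # adjacent transposition
                if i + 1 < len(chars) and chars[i + 1] != " ":
                    chars[i], chars[i + 1] = chars[i + 1], chars[i]
        out = "".join(chars)
        if out != name and 1 <= osa_distance(out, name) <= n_edits:
            return out
    return name + "x"  # single insertion: distance 1


@dataclass
class PredatorDiet:
    predator: str
    range_cells: set[int]
    prey_names: list[str]          # as recorded, possibly misspelled
    true_identities: list[str]     # ground truth for matcher validation


def generate_predator_diets(
    species: Sequence[SpeciesRecord],
    ranges: Mapping[str, set[int]],
    n_predators: int,
    misspell_rate: float,
    seed: int,
    grid_dims: tuple[int, int] = (40, 80),
    edits: tuple[int, int] = (1, 2),
) -> list[PredatorDiet]:
    """Predator diet lists sampled from species co-occurring in range.

    A recorded fraction ``misspell_rate`` of prey names is perturbed by 1-2
    character edits; ``true_identities`` logs the unperturbed binomials.
    """
    if not 0.0 <= misspell_rate < 1.0:
        raise ConfigurationError("misspell_rate must be in [0,1)")
    rng = np.random.default_rng(seed)
    rows, cols = grid_dims
    diets: list[PredatorDiet] = []
    for p in range(n_predators):
        size = int(np.clip(np.round(rng.lognormal(4.0, 0.8)), 20, rows * cols // 2))
        start = (int(rng.integers(0, rows)), int(rng.integers(0, cols)))
        cells = _grow_blob(start, size, grid_dims, rng)
        in_range = [
            rec.binomial
            for rec in species
            if ranges.get(rec.binomial, set()) & cells
        ]
        if not in_range:
            in_range = [species[int(rng.integers(0, len(species)))].binomial]
        k = min(len(in_range), int(rng.integers(5, 40)))
        prey = list(rng.choice(in_range, size=k, replace=False))
        recorded = []
        for name in prey:
            if rng.random() < misspell_rate:
                n_edits = int(rng.integers(edits[0], edits[1] + 1))
                recorded.append(perturb_name(name, rng, n_edits))
            else:
                recorded.append(name)
        diets.append(
            PredatorDiet(
                predator=f"Predator_{p:02d}",
                range_cells=cells,
                prey_names=recorded,
                true_identities=prey,
            )
        )
    return diets


# ---------------------------------------------------------------- I/O helpers

def write_ranges(ranges: Mapping[str, set[int]], path: str | Path) -> None:
    rows = [
        {"binomial": name, "cells": ",".join(str(c) for c in sorted(cells))}
        for name, cells in sorted(ranges.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_ranges(path: str | Path) -> dict[str, set[int]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return {
        row["binomial"]: {int(c) for c in row["cells"].split(",") if c}
        for _, row in df.iterrows()
    }


def write_predator_diets(diets: Sequence[PredatorDiet], path: str | Path) -> None:
    rows = [
        {
            "predator": d.predator,
            "cells": ",".join(str(c) for c in sorted(d.range_cells)),
            "prey": "|".join(d.prey_names),
            "true_identities": "|".join(d.true_identities),
        }
        for d in diets
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_predator_diets(path: str | Path) -> list[PredatorDiet]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        PredatorDiet(
            predator=row["predator"],
            range_cells={int(c) for c in row["cells"].split(",") if c},
            prey_names=[p for p in row["prey"].split("|") if p],
            true_identities=[p for p in row["true_identities"].split("|") if p],
        )
        for _, row in df.iterrows()
    ]
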