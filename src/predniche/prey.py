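"""Prey-diversity and dietary-overlap comparisons between humans and
individual non-human predators, assessed over the predator's range.

For each comparator predator the human "diet" is the set of species with a
documented use whose range intersects the predator's range; the diversity
ratio divides that count by the predator's resolved prey-species count, and
dietary overlap is the percent of the predator's prey that humans also use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .iucn import SpeciesRecord


@dataclass
class PredatorComparison:
    predator: str
    n_predator_prey: int
    n_human_prey_all_uses: int
    n_human_prey_food: int
    ratio_all: float
    ratio_food: float
    overlap_percent: float


class EmptyRangeError(ValueError):
    pass


class UndefinedRatioError(ValueError):
    pass


def human_prey_in_range(
    predator_range: set[int],
    species: Sequence[SpeciesRecord],
    ranges: Mapping[str, set[int]],
    use_filter: str = "all",
) -> set[str]:
    """Species used by humans whose range intersects the predator's range.

    ``use_filter``: ``"all"`` — any documented use; ``"food"`` — used as
    human food. Any grid-cell intersection counts as co-occurrence (no
    fractional-area threshold). Only species with spatial data participate.
    """
    if not predator_range:
        raise EmptyRangeError("predator range is empty")
    if use_filter not in {"all", "food"}:
        raise ValueError("use_filter must be 'all' or 'food'")
    out: set[str] = set()
    for rec in species:
        if not rec.used:
            continue
        if use_filter == "food" and "food" not in rec.use_categories:
            continue
        cells = ranges.get(rec.binomial)
        if cells and cells & predator_range:
            out.add(rec.binomial)
    return out


def diversity_ratio(n_human_prey: int, n_predator_prey: int) -> float:
    """How many times more species humans exploit than the predator preys on
    (e.g. 2707 human prey over 9 jaguar prey is ~300x)."""
    if n_predator_prey < 1:
        raise UndefinedRatioError("predator must have >= 1 resolved prey species")
    return n_human_prey / n_predator_prey


def dietary_overlap(predator_prey: set[str], human_prey: set[str]) -> float:
    """Percent of the predator's prey species also used by humans."""
    if not predator_prey:
        raise ValueError("predator prey set is empty")
    return 100.0 * len(predator_prey & human_prey) / len(predator_prey)


def prey_diversity_ratio(
    predator: str,
    predator_prey: set[str],
    species: Sequence[SpeciesRecord],
    ranges: Mapping[str, set[int]],
    predator_range: set[int],
) -> PredatorComparison:
    """Full comparison for one predator: counts, ratios and overlap.

    ``predator_prey`` must contain resolved, reference-matched species names
    only (names resolvable just to genus/family are excluded upstream).
    """
    if not predator_prey:
        raise UndefinedRatioError(f"{predator}: zero resolved prey species")
    human_all = human_prey_in_range(predator_range, species, ranges, "all")
    human_food = human_prey_in_range(predator_range, species, ranges, "food")
    n_prey = len(predator_prey)
    return PredatorComparison(
        predator=predator,
        n_predator_prey=n_prey,
        n_human_prey_all_uses=len(human_all),
        n_human_prey_food=len(human_food),
        ratio_all=len(human_all) / n_prey,
        ratio_food=len(human_food) / n_prey,
        overlap_percent=dietary_overlap(predator_prey, human_all),
    )
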