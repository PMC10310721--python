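"""Use-and-trade / threat classification of Red List species records.

The central objects are :class:`SpeciesRecord` (one assessed species) and the
four-way use grouping used throughout the analysis:

* ``NOT_USED`` — no documented use-and-trade category;
* ``USE_NOT_THREAT`` — used, but biological resource use (IUCN threat branch
  5.1 hunting/collecting, 5.4 fishing/harvesting) is not listed as a threat;
* ``USE_THREAT`` — used, use listed as a threat, but the species is not
  assessed as facing extinction (not VU/EN/CR);
* ``EXTINCTION_RISK_USE_THREAT`` — used, use listed as a threat, and the
  species is Vulnerable, Endangered or Critically Endangered.

The groups partition the retained species; the last three partition the used
species.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: The six vertebrate classes retained after dropping classes with <100 species.
VERTEBRATE_CLASSES = (
    "Actinopterygii",
    "Aves",
    "Reptilia",
    "Amphibia",
    "Mammalia",
    "Chondrichthyes",
)

#: Red List categories. VU/EN/CR together constitute "facing extinction".
RED_LIST_STATUSES = ("LC", "NT", "VU", "EN", "CR", "EX", "EW", "DD")
THREATENED_STATUSES = frozenset({"VU", "EN", "CR"})

REALMS = ("terrestrial", "freshwater", "marine")

#: 18 use-and-trade categories (abbreviated labels; e.g. "pets" abbreviates
#: "Pets/display animals, horticulture"). Label mapping is configuration.
USE_CATEGORIES = (
    "food",
    "animal_feed",
    "medicine",
    "poisons",
    "manufacturing_chemicals",
    "other_chemicals",
    "fuels",
    "fibre",
    "construction",
    "wearing_apparel",
    "household_goods",
    "handicrafts",
    "pets",
    "research",
    "sport_hunting",
    "ex_situ_production",
    "other",
    "unknown_use",
)

#: Threat codes marking biological resource use: direct hunting/collecting of
#: terrestrial animals (5.1 and descendants) and fishing/harvesting of aquatic
#: resources (5.4 and descendants). A "$"-suffixed code in scheme dumps marks
#: the bare top-level category and is normalized to it.
USE_THREAT_CODES = frozenset(
    {"5.1", "5.1.1", "5.1.2", "5.1.3", "5.1.4",
     "5.4", "5.4.1", "5.4.2", "5.4.3", "5.4.4", "5.4.5", "5.4.6"}
)

MIN_CLASS_SIZE = 100

_LIST_SEP = "|"

REQUIRED_COLUMNS = (
    "taxon_id",
    "binomial",
    "class_name",
    "status",
    "realms",
    "use_categories",
    "threat_codes",
    "bycatch",
)


class UseGroup(str, Enum):
    NOT_USED = "NOT_USED"
    USE_NOT_THREAT = "USE_NOT_THREAT"
    USE_THREAT = "USE_THREAT"
    EXTINCTION_RISK_USE_THREAT = "EXTINCTION_RISK_USE_THREAT"


@dataclass
class SpeciesRecord:
    """One assessed species.

    ``bycatch`` marks species whose only interaction with exploitation is
    unintentional take; such species carry no use-and-trade category and are
    classified ``NOT_USED`` even when a 5.x threat code is present.
    """

    taxon_id: str
    binomial: str
    class_name: str
    status: str
    realms: frozenset[str]
    use_categories: frozenset[str]
    threat_codes: frozenset[str]
    bycatch: bool = False

    def __post_init__(self) -> None:
        if len(self.binomial.split()) != 2:
            raise ValueError(
                f"binomial must have exactly two tokens: {self.binomial!r}"
            )

    @property
    def used(self) -> bool:
        return len(self.use_categories) > 0


class SchemaError(ValueError):
    """Input table lacks required structure."""


class IntegrityError(ValueError):
    """Input table violates uniqueness or referential constraints."""


def _split_cell(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    text = str(cell).strip()
    if not text:
        return frozenset()
    return frozenset(tok.strip() for tok in text.split(_LIST_SEP) if tok.strip())


def _join_cell(items: Iterable[str]) -> str:
    return _LIST_SEP.join(sorted(items))


def load_species_table(path: str | Path) -> list[SpeciesRecord]:
    """Read a species table (TSV) into records.

    Malformed rows (e.g. a binomial without exactly two tokens) are reported
    with their line number and dropped. Raises :class:`SchemaError` when a
    required column is missing and :class:`IntegrityError` on duplicate
    taxon ids.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    if df.empty:
        logger.warning("species table %s has no data rows", path)
        return []
    dup = df["taxon_id"][df["taxon_id"].duplicated()]
    if not dup.empty:
        raise IntegrityError(f"duplicate taxon_id(s): {sorted(set(dup))}")

    records: list[SpeciesRecord] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            records.append(
                SpeciesRecord(
                    taxon_id=row["taxon_id"],
                    binomial=" ".join(str(row["binomial"]).split()),
                    class_name=row["class_name"],
                    status=row["status"],
                    realms=_split_cell(row["realms"]),
                    use_categories=_split_cell(row["use_categories"]),
                    threat_codes=_split_cell(row["threat_codes"]),
                    bycatch=str(row["bycatch"]).strip().lower()
                    in {"1", "true", "yes"},
                )
            )
        except ValueError as exc:
            logger.warning("line %d rejected: %s", line_no, exc)
    return records


def write_species_table(records: Sequence[SpeciesRecord], path: str | Path) -> None:
    """Write records to TSV (inverse of :func:`load_species_table`)."""
    rows = [
        {
            "taxon_id": r.taxon_id,
            "binomial": r.binomial,
            "class_name": r.class_name,
            "status": r.status,
            "realms": _join_cell(r.realms),
            "use_categories": _join_cell(r.use_categories),
            "threat_codes": _join_cell(r.threat_codes),
            "bycatch": str(r.bycatch).lower(),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def filter_assessed(records: Sequence[SpeciesRecord]) -> list[SpeciesRecord]:
    """Restrict to extant species in sufficiently sampled classes.

    Drops Extinct (EX) and Extinct in the Wild (EW) species, then drops any
    class with fewer than 100 remaining species.
    """
    extant = [r for r in records if r.status not in {"EX", "EW"}]
    class_sizes = Counter(r.class_name for r in extant)
    kept = [r for r in extant if class_sizes[r.class_name] >= MIN_CLASS_SIZE]
    logger.info(
        "filter_assessed: %d -> %d records (%d classes retained)",
        len(records),
        len(kept),
        len({r.class_name for r in kept}),
    )
    return kept


def normalize_threat_code(code: str) -> str:
    """Strip the '$' marker used for top-level categories in scheme dumps."""
    return code.rstrip("$").strip()


def use_is_threat(record: SpeciesRecord) -> bool:
    """True iff any threat code falls in the biological-resource-use branch
    (5.1 hunting/collecting or 5.4 fishing/harvesting, or their descendants)."""
    for raw in record.threat_codes:
        code = normalize_threat_code(raw)
        if code in USE_THREAT_CODES:
            return True
        if code and not all(part.isdigit() for part in code.split(".")):
            logger.warning("unrecognized threat code %r treated as non-matching", raw)
    return False


def classify_use(record: SpeciesRecord) -> UseGroup:
    """Assign a record to its use group (pure function of the record).

    DD species are retained but can never fall in the extinction-risk group,
    which is defined strictly by VU/EN/CR status.
    """
    if not record.used:
        return UseGroup.NOT_USED
    if use_is_threat(record):
        if record.status in THREATENED_STATUSES:
            return UseGroup.EXTINCTION_RISK_USE_THREAT
        return UseGroup.USE_THREAT
    return UseGroup.USE_NOT_THREAT


@dataclass
class GroupCounts:
    """Group tallies with per-class and per-realm breakdowns.

    Invariants: ``n_not_used + n_used == n_total`` and
    ``n_use_not_threat + n_use_threat + n_risk_use_threat == n_used``.
    A species occupying several realms is counted once per realm.
    """

    n_total: int
    n_not_used: int
    n_used: int
    n_use_not_threat: int
    n_use_threat: int
    n_risk_use_threat: int
    per_class: dict = field(default_factory=dict)
    per_realm: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_not_used + self.n_used != self.n_total:
            raise IntegrityError("not_used + used != total")
        if (
            self.n_use_not_threat + self.n_use_threat + self.n_risk_use_threat
            != self.n_used
        ):
            raise IntegrityError("used subgroups do not sum to used")

    @property
    def pct_used(self) -> float:
        return 100.0 * self.n_used / self.n_total if self.n_total else 0.0

    @property
    def pct_use_threat_of_total(self) -> float:
        """Percent of all species with use listed as a threat but not at risk."""
        return 100.0 * self.n_use_threat / self.n_total if self.n_total else 0.0

    @property
    def pct_use_threat_of_used(self) -> float:
        return 100.0 * self.n_use_threat / self.n_used if self.n_used else 0.0

    @property
    def pct_risk_of_used(self) -> float:
        return 100.0 * self.n_risk_use_threat / self.n_used if self.n_used else 0.0

def percent(part: int, total: int) -> float:
    """Percentage with a zero-safe denominator, as reported in summaries."""
    return 100.0 * part / total if total else 0.0


def _tally(records: Sequence[SpeciesRecord]) -> dict[str, int]:
    groups = Counter(classify_use(r).value for r in records)
    n_used = (
        groups[UseGroup.USE_NOT_THREAT.value]
        + groups[UseGroup.USE_THREAT.value]
        + groups[UseGroup.EXTINCTION_RISK_USE_THREAT.value]
    )
    return {
        "n_total": len(records),
        "n_not_used": groups[UseGroup.NOT_USED.value],
        "n_used": n_used,
        "n_use_not_threat": groups[UseGroup.USE_NOT_THREAT.value],
        "n_use_threat": groups[UseGroup.USE_THREAT.value],
        "n_risk_use_threat": groups[UseGroup.EXTINCTION_RISK_USE_THREAT.value],
    }


def summarize_groups(records: Sequence[SpeciesRecord]) -> GroupCounts:
    """Tally the four use groups overall, per class, and per realm."""
    overall = _tally(records)
    per_class = {
        cls: _tally([r for r in records if r.class_name == cls])
        for cls in sorted({r.class_name for r in records})
    }
    per_realm = {
        realm: _tally([r for r in records if realm in r.realms])
        for realm in REALMS
    }
    return GroupCounts(**overall, per_class=per_class, per_realm=per_realm)


@dataclass
class OverlapTable:
    """Species counts per exact use-category combination plus marginals."""

    combination_counts: dict[frozenset, int]
    marginal_counts: dict[str, int]
    n_used: int
    multiple_use_fraction: float

    def pairwise_overlap(self, a: str, b: str) -> int:
        """Species having both categories (possibly among others)."""
        return sum(
            n for combo, n in self.combination_counts.items()
            if a in combo and b in combo
        )


def category_overlaps(
    records: Sequence[SpeciesRecord],
    grouping: str | None = None,
    group_value: str | None = None,
) -> OverlapTable:
    """Count species in every non-empty use-category combination.

    ``grouping`` restricts the tally to one realm (``"realm"``) or one class
    (``"class"``), with ``group_value`` naming it. Combination cells are
    disjoint (each used species contributes to exactly one cell — its exact
    category set) so they sum to the used-species count; marginals count every
    species carrying the category.
    """
    if grouping == "realm":
        records = [r for r in records if group_value in r.realms]
    elif grouping == "class":
        records = [r for r in records if r.class_name == group_value]
    elif grouping is not None:
        raise ValueError("grouping must be 'realm', 'class' or None")

    used = [r for r in records if r.used]
    combo_counts: Counter = Counter(r.use_categories for r in used)
    marginals: Counter = Counter()
    for r in used:
        marginals.update(r.use_categories)
    n_multi = sum(1 for r in used if len(r.use_categories) > 1)
    return OverlapTable(
        combination_counts=dict(combo_counts),
        marginal_counts=dict(marginals),
        n_used=len(used),
        multiple_use_fraction=(n_multi / len(used)) if used else 0.0,
    )


def overlap_table_to_frame(table: OverlapTable) -> pd.DataFrame:
    """One row per category combination, for TSV export."""
    rows = [
        {"categories": _join_cell(combo), "n_species": n}
        for combo, n in sorted(
            table.combination_counts.items(), key=lambda kv: (-kv[1], _join_cell(kv[0]))
        )
    ]
    return pd.DataFrame(rows, columns=["categories", "n_species"])
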