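"""Classify species into use/threat groups and tabulate category overlaps.

Reads results/data/species.tsv; writes per-species groups, the group summary
(overall, per class, per realm), and the use-category overlap table.
"""

import json
from pathlib import Path

import pandas as pd

from predniche import iucn

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = iucn.filter_assessed(iucn.load_species_table(ROOT / "data" / "species.tsv"))
    groups = pd.DataFrame(
        {"binomial": [r.binomial for r in records],
         "group": [iucn.classify_use(r).value for r in records]}
    )
    groups.to_csv(ROOT / "use_groups.tsv", sep="\t", index=False)

    counts = iucn.summarize_groups(records)
    overlap = iucn.category_overlaps(records)
    (ROOT / "classification_summary.json").write_text(json.dumps({
        "n_total": counts.n_total,
        "n_not_used": counts.n_not_used,
        "n_used": counts.n_used,
        "n_use_not_threat": counts.n_use_not_threat,
        "n_use_threat": counts.n_use_threat,
        "n_risk_use_threat": counts.n_risk_use_threat,
        "pct_used": counts.pct_used,
        "pct_use_threat_of_used": counts.pct_use_threat_of_used,
        "pct_risk_of_used": counts.pct_risk_of_used,
        "multiple_use_fraction": overlap.multiple_use_fraction,
        "per_class": counts.per_class,
        "per_realm": counts.per_realm,
    }, indent=2))
    iucn.overlap_table_to_frame(overlap).to_csv(
        ROOT / "use_category_overlaps.tsv", sep="\t", index=False
    )

    print(f"{counts.n_used} of {counts.n_total} species used "
          f"({counts.pct_used:.1f}%); use a threat for "
          f"{counts.pct_use_threat_of_used:.1f}% of used species; "
          f"{100 * overlap.multiple_use_fraction:.1f}% of used species have "
          f"multiple uses")


if __name__ == "__main__":
    main()
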