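"""Generate the synthetic study inputs.

Writes a 2,000-species Red-List-like table, an ultrametric phylogeny,
trait tables (complete truth + masked), grid-cell ranges, and predator diet
lists (10% of prey names misspelled, truth logged) under results/data/.
"""

from pathlib import Path

from predniche import iucn, synthetic

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = synthetic.SimConfig(n_species=2000, seed=SEED)
    records = synthetic.generate_species_table(cfg)
    iucn.write_species_table(records, OUT / "species.tsv")

    tree = synthetic.generate_phylogeny(
        cfg.n_species, SEED, tip_names=[r.binomial for r in records]
    )
    tree.write(path=str(OUT / "tree.nwk"), schema="newick")

    classes = {r.binomial: r.class_name for r in records}
    truth, masked = synthetic.generate_trait_table(tree, cfg, classes)
    truth.to_csv(OUT / "traits_truth.tsv", sep="\t")
    masked.to_csv(OUT / "traits.tsv", sep="\t")

    ranges = synthetic.generate_ranges(records, cfg)
    synthetic.write_ranges(ranges, OUT / "ranges.tsv")

    diets = synthetic.generate_predator_diets(
        records, ranges, n_predators=6, misspell_rate=0.1, seed=SEED + 3,
        grid_dims=cfg.grid_dims,
    )
    synthetic.write_predator_diets(diets, OUT / "predator_diets.tsv")

    n_missing = int(masked.isna().sum().sum())
    print(f"wrote {len(records)} species, {len(tree.leaf_nodes())}-tip tree, "
          f"{n_missing} masked trait entries, {len(diets)} predator diets "
          f"to {OUT}")


if __name__ == "__main__":
    main()
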