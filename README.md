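# predniche

Tools for quantifying humanity's predatory niche: how many vertebrate
species people kill or collect, how that exploitation compares with the
diets of wide-ranging non-human predators, where exploitation outruns
species availability, and how much ecological trait space the exploited
species occupy.

The package is organized as an analysis pipeline over Red-List-style
inputs (a species table with use-and-trade categories and threat codes, a
phylogeny, a trait table, gridded ranges, predator diet lists). Because the
compiled assessment data cannot be redistributed, a first-class synthetic
generator produces inputs with the same statistical structure, so the whole
pipeline runs, and is tested, end to end out of the box. It is written for
conservation ecologists and macroecologists who want to reuse or scrutinize
the individual stages.

## What it computes

1. **Use/threat classification** (`predniche.iucn`). Species are classified
   into four groups: *not used*; *used, not threatened by use*; *use
   considered a threat* (a threat code in the biological-resource-use branch
   — hunting/collecting 5.1.x or fishing/harvesting 5.4.x) but not at
   extinction risk; and *extinction risk & use considered threat*
   (additionally VU/EN/CR). The groups partition the assessed species, and
   the last three partition the used species. Extinct (EX/EW) species and
   classes with <100 species are excluded; species whose only interaction
   with exploitation is bycatch count as not used.
2. **Name reconciliation** (`predniche.matching`). Prey binomials from diet
   studies are matched to the reference list with optimal string alignment
   (restricted Damerau-Levenshtein) similarity `1 - d/max(len)`, with a
   two-threshold triage: > 0.9 auto-resolves, 0.5–0.9 is flagged for review
   (excluded unless an arbiter resolves it), <= 0.5 is unknown.
3. **Prey-diversity comparisons** (`predniche.prey`). For each predator,
   the number of species humans use within the predator's range, the
   diversity ratio (human prey / predator prey, all uses and food only),
   and dietary overlap (% of predator prey also used by humans).
4. **Spatial standardization** (`predniche.spatial`). Per grid cell:
   species present, used, used for food, used as pets; then a
   negative-binomial GLM `used ~ log(present)` (log link, ML dispersion)
   whose Pearson residuals `r_i = (y_i - mu_i)/sqrt(mu_i + mu_i^2/theta)`
   map where exploitation exceeds availability.
5. **Trait pipeline** (`predniche.traits`). A five-trait space — body mass
   (log10), litter/clutch size (sqrt), habitat breadth (sqrt), generation
   length (log10), and a diet axis (first principal coordinate of Gower
   distances among 7 diet proportions) — z-scored, then missing values
   imputed by iterative random forests (500 trees, mtry 4, 15 sets) with
   the first 10 phylogenetic eigenvectors as predictors, reporting
   out-of-bag NRMSE per trait.
6. **Trait-space hypervolumes** (`predniche.hyperspace`). PCA scores
   averaged across imputed sets; one-class SVM hypervolumes (volume in
   SD^5 by Monte-Carlo integration); 50% kernel-density contours; rarefied
   null models (333 same-size random samples from the species pool) with
   one-sided permutation p-values `(#{random > observed} + 1)/(n + 1)`;
   Hedges' g and Mann-Whitney U per trait.

## Worked example

Run the numbered drivers in order (each prints what it found and writes
tables under `results/`):

```bash
python analysis/01_simulate_inputs.py
python analysis/02_classify_uses.py
python analysis/03_match_prey_names.py
python analysis/04_prey_overlap.py
python analysis/05_spatial_glm.py
python analysis/06_impute_traits.py
python analysis/07_trait_space.py
```

Output of a full run (seed 1, 2,000 synthetic species):

```
wrote 2000 species, 2000-tip tree, 3560 masked trait entries, 6 predator diets to results/data
672 of 1960 species used (34.3%); use a threat for 39.7% of used species; 14.6% of used species have multiple uses
matched 185 prey records {'exact': 164, 'resolved_spelling': 12, 'needs_review': 6, 'unknown': 3}; 12/17 misspelled names recovered (70.6%)
6 predators compared; humans use 0.6-1.9x as many species over shared ranges; median dietary overlap 29.6%
NB GLM over 3200 occupied cells: used ~ exp(-1.10 + 0.99 log(present)), theta=351249090.2; 31 residual outliers
imputed 406 missing entries for 588 terrestrial birds/mammals across 5 sets; diet axis explains 24% of diet variation; OOB NRMSE: body_mass=0.52, litter_clutch=0.59, habitat_breadth=0.65, generation_length=0.57, diet=0.77
used group (232 spp): volume 87.029 SD^5 vs null median 83.805 (p=0.400); unique volume 28.5% (p=0.490)
```

Reading the numbers: 34.3% of the synthetic species carry a use category
(the generator's configured prevalence), and 39.7% of those have use listed
as a threat. Of 17 deliberately misspelled prey names, 12 auto-resolve above
the 0.9 similarity threshold (the rest land in the review band — 2-edit
corruptions of short names). The NB-GLM slope near 1 with an enormous theta
says used richness tracks availability essentially proportionally and
without overdispersion — as it must, since the generator assigns uses
independently of geography; for the same reason the used group's trait-space
volume is statistically indistinguishable from rarefied random samples
(p = 0.40), i.e. the null model correctly declines to find non-random trait
selection where none was simulated. A CLI (`predniche simulate|classify|
match|overlap|grid|glm|impute|hyperspace`) exposes the same stages on
user-supplied files.

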