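# srpkit

Do rare species or common species drive species richness patterns (SRPs)?

Most regional assemblages contain many species with tiny ranges and a few
wide-ranging ones, yet in several taxa the *common* species turn out to
carry the spatial richness pattern. `srpkit` implements the standard
analytical toolkit for asking that question of grid-mapped point-occurrence
data — originally motivated by subterranean faunas (cave amphipods and
beetles), where single-site endemics can make up a third of all species.
It is aimed at macroecologists and conservation analysts working with
point records on a projected plane.

## What it computes

**Range size and rarity.** Each species' range is its *maximum linear
extent* (MLE): the largest pairwise Euclidean distance among its
occurrence points, in km (0 for a single-site endemic). Species are split
into four MLE quartiles with tie-block cohesion (species tied on MLE always
share a quartile); quartile 1 is "rare", quartile 4 "common".

**Gridded richness.** A square grid (default 20 × 20 km) is overlain on
the study plane; richness is the number of species per occupied cell.
Cells are classified relative to the richest cell *r*max:
class 1 (> 85 % of *r*max) are *hotspots*, classes 1–2 (≥ 60 %) are
*species-rich cells* (SRCs). Two taxa's surfaces are compared with
Kendall's τ_b, the rank correlation with tie correction,

    τ_b = (C − D) / √((n₀ − n₁)(n₀ − n₂)),

suited to integer richness vectors full of ties.

**Stepwise reconstruction.** Species are added one by one, rarest-first
(ascending MLE) or commonest-first (descending), and after every addition
the subset's per-cell richness is correlated (τ_b) with the overall
richness. Species tied on MLE are ordered at random within their block;
curves are per-step medians over many tie randomizations. A null model of
fully random addition orders yields per-step 95 % envelopes and two-sided
empirical p-values, p = (1 + #{|τᵣ − med| ≥ |τ_obs − med|}) / (R + 1).
Curves can also be read against the subset's *cumulative information
content*, CI = Σᵢ pᵢ(1 − pᵢ), where pᵢ is the proportion of analysis
cells occupied by species *i* — the expected binomial variance each
species contributes to the pattern.

**Richness regression.** Per-cell overall richness is regressed on rare-
or common-species richness with log-link GLMs (Poisson, or negative
binomial with profile-ML dispersion), summarized by explained deviance
("pseudo R²") and AICc. Residual spatial autocorrelation is diagnosed
with a Moran's I correlogram over equal-pair-count distance classes
(permutation-tested) and removed with forward-selected spatial eigenvector
filters (PCNM / Moran's eigenvector maps; 59 km truncation by default).

**Synthetic assemblages.** A seedable generator produces occurrence
datasets with the right-skewed range structure of real subterranean data
(lognormal MLE body plus a single-site block) in three scenarios —
`common_driven`, `rare_driven`, `neutral` — so the whole pipeline is
testable end to end without any data download.

## Worked example

```python
import numpy as np
import srpkit

cfg = srpkit.ScenarioConfig(n_species=150, scenario="common_driven", seed=11)
records = srpkit.generate_assemblage(cfg)

profiles = srpkit.assign_quartiles(srpkit.species_profiles(records))
summary = srpkit.rsfd_summary(profiles)
print(f"{summary['n_species']} species, skewness {summary['skewness']:.2f}, "
      f"{summary['n_single_site']} single-site endemics ({summary['single_site_pct']}%)")

surface = srpkit.richness_surface(records, srpkit.GridSpec.covering(records))
cls = srpkit.classify_richness(surface)
print(f"{len(surface.cells)} occupied cells, richest cell holds {surface.r_max} species")
print(f"{len(srpkit.hotspots(cls))} hotspots, {len(srpkit.srcs(cls))} species-rich cells")

_, overall, species_cells = surface.species_cell_indices()
in_grid = profiles[profiles.species_id.isin(species_cells)].reset_index(drop=True)
desc = srpkit.median_curve(in_grid, species_cells, overall, "descending",
                           n_randomizations=100, rng=np.random.default_rng(1))
asc = srpkit.median_curve(in_grid, species_cells, overall, "ascending",
                          n_randomizations=100, rng=np.random.default_rng(2))
for curve in (desc, asc):
    x = srpkit.crossing_point(curve, 0.5)
    print(f"{curve.direction}: tau_b exceeds 0.5 after {x['pct_species']:.1f}% of species "
          f"({x['pct_ci']:.1f}% of information content)")
```

prints

```
150 species, skewness 3.21, 47 single-site endemics (31%)
161 occupied cells, richest cell holds 12 species
2 hotspots, 11 species-rich cells
descending: tau_b exceeds 0.5 after 10.7% of species (33.8% of information content)
ascending: tau_b exceeds 0.5 after 80.0% of species (50.9% of information content)
```

Read: this assemblage has the typical strongly right-skewed range-size
distribution (skewness 3.2, 31 % single-site endemics). Adding the
commonest species first reconstructs the overall richness pattern after
only ~11 % of species, while rarest-first needs 80 % — the signature of a
pattern driven by common species. On the information-content axis the gap
narrows (34 % vs 51 %), because each wide-ranging species carries far more
pattern information than a single-site endemic.

## Command line

The same stages are exposed as subcommands:

```bash
srpkit simulate --scenario common_driven --n-species 150 --seed 11 --out occ.csv
srpkit profile-ranges occ.csv --out profiles.csv
srpkit grid occ.csv --out classes.csv
srpkit reconstruct occ.csv --reps 500 --seed 1 --out curves.csv
srpkit glm occ.csv --reps 500 --seed 1 --out glms.csv
srpkit compose occ.csv --out src_composition.csv
srpkit run-all occ.csv --reps 500 --seed 1 --out results/
```

Occurrence files are delimited text with header
`species_id, locality_id, x_km, y_km, accuracy_km, in_study_area` on
projected planar km coordinates; records with positional accuracy worse
than 6 km (configurable) are dropped on read. `run-all` writes all result
tables plus a `manifest.json` with the config hash and seeds; identical
input and config reproduce identical outputs byte for byte.

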