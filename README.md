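# polypnet

Analysis toolkit for two-group coral polyp feeding experiments: after
heat-induced bailout, reattached polyps of a scleractinian coral are reared
for 60 days with or without daily brine-shrimp (*Artemia*) feeding, and the
question is how feeding changes growth, energy budget, immunity and the
transcriptome. `polypnet` implements the downstream analysis for that
design end to end, driven by a truth-labelled synthetic-data generator so
every stage is testable without raw specimen data.

## What it computes

**Physiology.** Symbiont density (cells cm⁻²), chlorophyll *a*+*c₂* per
cell from the two-wavelength dinoflagellate equations
(chl *a* = 11.43·OD₆₆₃ − 0.64·OD₆₃₀; chl *c₂* = 27.09·OD₆₃₀ − 3.63·OD₆₆₃),
and the caspase-3 activation level (ratio of group-mean A₄₀₅).

**Energetics.** Standard-curve quantification of carbohydrate/lipid,
energy available Ea = 17.5·carb + 39.5·lipid + 24·protein (kJ g⁻¹),
ETS-based energy consumption Ec via Beer–Lambert and the oxyenthalpic
equivalent (484 kJ mol⁻¹ O₂, 2 formazan : 1 O₂), and the cellular energy
allocation index CEA = Ea/Ec, normalised per cm² or per polyp.

**Group statistics.** Each trait is routed by Shapiro–Wilk (per group) and
Levene (across groups) at α = 0.05: both pass → pooled-variance Student's
*t*; otherwise Mann–Whitney U. Plus Benjamini–Hochberg FDR and PCA with a
reproducible loading-sign convention.

**Differential expression.** log₂(CPM+1) normalisation, per-gene
log₂FC(Feeding/Control) with a Welch *t* statistic, BH q-values, and the
strict screening rule |log₂FC| > 1 AND q < 0.05.

**Co-expression network.** Pearson correlation → unsigned distance
1 − |r| → Ward.D2 hierarchical clustering (Lance–Williams recurrence on
squared distances) → a simplified dynamic tree cut with a minimum module
size → module eigengenes (first principal component) → merging of modules
whose eigengenes correlate at r > 0.75 → kME, module–trait Pearson tests
with BH adjustment (significant at q < 0.05), and Cytoscape-ready
node/edge/SIF export with size-ranked colour names (turquoise, blue,
brown, yellow, …; grey = unassigned).

**Enrichment.** Hypergeometric over-representation of gene sets with BH
q-values alongside.

**Synthetic data.** A single-factor-per-module model
x_g = a_g·e_m + √(1−a_g²)·ε_g with a 13-module size profile
(1255/1226/1130/…/48 of a 5000-gene network), one module driven by the
feeding indicator, physiological tables drawn from the experiment's
reported group means/SDs, and simulated assay plates with known lines.

## Worked example

```sh
polypnet run --seed 1 --out runs/demo
```

simulates the full study design (19,397 genes by default; the example
below used a reduced 900-gene dataset with a 400-gene network) and writes
per-stage tables plus `summary.txt`:

```
Physiology (control vs feeding):
  diameter_day30_um: 2495±58.4 vs 2645±102 [student_t, p=0.02077]*
  polyp_count_day60: 6.463±0.524 vs 10.51±2.09 [mann_whitney, p=0.01587]*
  symbiont_density_1e5_cells_cm2: 2.175±0.0928 vs 2.584±0.084 [student_t, p=8.351e-05]***
  caspase_a405: 0.9421±0.113 vs 0.6144±0.0448 [mann_whitney, p=0.007937]**
  ...
Energetics (group means):
  control: Ea 27.999 J cm^-2, CEA 5.06e+04
  feeding: Ea 32.839 J cm^-2, CEA 6.14e+04
Caspase-3 activation level (feeding/control A405): 0.652
Co-expression modules: 31
  turquoise: 79 genes (19.75%)
  ...
```

Reading this: feeding polyps grew faster (larger diameters, more new
polyps), hold more symbionts and energy reserve (higher Ea), and show
suppressed apoptosis (caspase ratio 0.652 < 1). Each line names the test
the routing rule actually selected. Library use mirrors the CLI:
`polypnet.coexpression` exposes every network step, `polypnet.diffexpr`
the DEG screen, `polypnet.synthetic_data` the generators.

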