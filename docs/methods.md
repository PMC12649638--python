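# Methods

## Scope and data model

`polypnet` analyses a two-group (control vs feeding) coral polyp
experiment with five biological replicates per group. The in-memory
substrate is a genes × samples `pandas.DataFrame` plus a sample → group
mapping; physiological data are wide per-colony tables. All interchange
formats are plain text (TSV/CSV/JSON/SIF).

## Synthetic data

Expression follows a single-factor-per-module model. For gene *g* in
module *m* and sample *s*:

    x_g(s) = a_g · e_m(s) + sqrt(1 − a_g²) · ε_g(s)

with latent eigengene trajectories e_m ~ N(0, 1) i.i.d. per sample,
loadings a_g uniform on a configurable range (default [0.6, 0.95]), and
residuals ε_g ~ N(0, noise_sd²) (default 1, so genes have unit variance).
One *driven* module — by default the 4th largest, the position the
size-ranked palette names "yellow" — has its latent shifted by
`trait_effect` (default 2) standard deviations in the feeding group.
Background genes are pure noise. Closed-form consequences used as test
oracles: cor(x_g, x_h) → a_g·a_h within a module, cor(x_g, e_m) → a_g
(the population kME), and the module eigengene's variance-explained
fraction → the mean squared loading.

The default module-size profile is 13 modules over a 5000-gene network:
1255, 1226, 1130, 380, 250, 180, 140, 110, 90, 75, 60, 56, 48. The three
largest and the smallest are the study's reported sizes (25.1 %, 24.52 %,
22.6 %, 0.96 % of the network); the intermediate nine are package
defaults chosen to decrease monotonically and complete the 5000 total.
`scaled_module_sizes(total)` maps the profile onto smaller networks by
proportional rounding, preserving the sum.

Physiological tables draw each trait per group from a normal with the
study's reported mean/SD (polyp diameter at day 30/60, polyp counts,
skeleton weight, symbiont density, chlorophyll per cell, host and
symbiont Ea). Reported "±" values are treated as SDs. Caspase A405,
T-AOC and MDA scales are not reported numerically; their defaults are
synthetic, chosen so caspase activation is clearly suppressed by feeding
(ratio ≈ 0.62) while T-AOC and MDA overlap between groups, matching the
qualitative pattern. Assay plates are simulated as
absorbance = slope·concentration + intercept + noise with the glucose
standard series 0, 0.08, 0.16, 0.24, 0.32 mg mL⁻¹.

What the generator does *not* emulate: count overdispersion (counts are
an opt-in Poisson(exp(x)) transform), batch effects, parent-genotype
structure, library-size variation, or symbiont-transcriptome admixture.
Passing tests therefore demonstrate correctness of the computations under
a clean factor model, not robustness to those real-data features.

## Physiology and energetics

Symbiont density is cells / surface area; the caller owns aliquot
scaling of counts to the whole homogenate. Chlorophyll uses the standard
dinoflagellate chl a+c₂ two-wavelength equations with coefficients
11.43/−0.64 and 27.09/−3.63 (µg mL⁻¹ per AU), exposed as constants
because the appropriate calibration depends on the acetone fraction;
near-blank readings that drive an equation negative are clamped to zero
with a warning. Caspase-3 activation is the ratio of group means of
A₄₀₅, not the mean of per-pair ratios.

Standard curves are ordinary least squares with an intercept (the blank
well is part of the standard series). Energy available uses combustion
enthalpies 17.5 / 39.5 / 24 kJ g⁻¹ (carbohydrate / lipid / protein);
energy consumption converts the INT-formazan kinetic slope (AU min⁻¹)
through Beer–Lambert (ε = 15,900 L mol⁻¹ cm⁻¹ by default), the fixed
2 : 1 formazan : O₂ stoichiometry, and 484 kJ mol⁻¹ O₂, giving J h⁻¹.
All four constants are configurable (`EnergyConstants`). CEA = Ea/Ec is
invariant to any normalisation applied to both terms; per-area and
per-polyp normalisation are explicit unit-tagged operations.

## Group statistics

The routing rule applies Shapiro–Wilk per group and Levene (mean-centred;
median-centring available) across groups at α_assumptions = 0.05 — the
same level as the inference α, since only one significance level is part
of the design. If every assumption p ≥ α the comparison is a two-sided
pooled-variance Student's *t* (not Welch: failing homogeneity re-routes
to Mann–Whitney rather than adjusting the t-test). Mann–Whitney uses
exact enumeration for tie-free groups of ≤ 8 and the tie-corrected normal
approximation otherwise. Degenerate inputs are given conventions rather
than errors: a constant group passes the normality gate and a zero-
variance comparison returns p = 1 when means agree, p = 0 otherwise.

BH adjustment is the step-up q_(i) = min_{j≥i} p_(j)·m/j, clipped at 1.
PCA centres (and optionally scales) columns, takes the SVD, and fixes
each loading column's sign so its largest-magnitude entry is positive,
making biplots reproducible across linear-algebra backends.

## Differential expression

The DE statistic is a deliberately simple stand-in: Welch *t* on
log₂(CPM+1) values with BH adjustment. A negative-binomial shrinkage
model is out of scope; what is preserved exactly is the screening rule,
with strict inequalities: selected ⇔ |log₂FC| > 1 AND q < 0.05.
Orientation is Feeding/Control — positive log₂FC means up in feeding.
Note the pseudocount: a planted k-fold change on the count scale gives a
log₂FC of log₂ k only up to the +1, so exactness claims are at large
counts. At the study's n = 5 + 5 with unit-variance log-scale noise,
only genes with shifts ≳ 1.5 SD survive BH — the screen is conservative
by construction on simulated data.

## Co-expression network

Genes are filtered (optional mean floor, then top-N by variance,
default N = 5000, stable original order). The network is unsigned:
D = 1 − |r|. Ward.D2 is implemented directly — Lance–Williams recurrence
on squared distances,

    d(k, i∪j)² = ((n_i+n_k)d_ik² + (n_j+n_k)d_jk² − n_k d_ij²) / (n_i+n_j+n_k),

heights reported unsquared, minimum-distance pair merged at each step
with ties broken by the lowest index pair (leaves keep their positions;
a merged cluster takes its smaller constituent's position). The
implementation is validated against both a naive loop-based reference
and scipy's independent `linkage(..., "ward")` to 1e-9. Ward heights are
monotone; an inversion is logged as an error.

The tree cut is a documented simplification of branch-aware dynamic
cutting: a static cut height (default the 0.99 quantile of merge
heights), a minimum module size (default 30; scaled proportionally when
the network is scaled down, e.g. 12 at 2000 genes), branches below the
minimum left grey, and a recursive refinement that splits a kept cluster
at its top merge whenever both children meet the minimum size. The
refinement deliberately over-fragments; the eigengene-merge step
(iteratively joining the most-correlated module pair while r > 0.75,
greedy, lowest-pair tie-break) re-assembles fragments whose latent
signals agree. The stopping rule makes "no eigengene pair above r = 0.75"
a hard post-condition.

Eigengenes are the first right singular vector of the module's z-scored
(ddof = 1) expression, scaled to unit variance and signed to correlate
non-negatively with the module's mean profile. kME is the plain Pearson
correlation between a gene and an eigengene. Module–trait inference uses
Pearson r with the t-transform p-value, BH over all module × trait
pairs, significance at q < 0.05; Shapiro–Wilk checks on eigengenes and
traits are recorded as warning flags, not gates (a binary group
indicator always flags). Module colours follow the conventional
size-ranked palette; ties in size rank break by smallest member index.

### What module recovery can achieve at n = 5 + 5

With 10 samples, loadings down to 0.6 and 13 modules, per-gene
assignment is noise-limited: a loading-0.6 gene carries 36 % signal
variance and its sample correlation with its own latent is routinely
beaten by one of the 12 competing latents. A supervised upper bound that
assigns every gene to the true latent of maximal |correlation| reaches
an adjusted Rand index of only ~0.6–0.85 across seeds (mean ≈ 0.7); the
unsupervised pipeline lands near that ceiling (mean ARI ≈ 0.65). High-
fidelity recovery (ARI ≥ 0.8) at this sample size is therefore not an
attainable benchmark under these loadings, and the recovery test
documents this honestly. Module-level inference is far more robust: the
driven module carries the smallest module–trait q in the large majority
of seeds, and the merge post-condition holds always.

## Enrichment

Over-representation uses the hypergeometric upper tail
P(X ≥ k | N, K, n), validated against exhaustive enumeration of draws on
small universes. Term significance is conventionally read from raw p at
0.05; BH q-values are reported alongside. No ontology-graph propagation
is performed.

## Pipeline, determinism and problem sizes

`run_pipeline` executes inputs → physiology → energetics → group stats →
DE → network → enrichment → summary, writing every stage table with unit
header comments and a JSON manifest (seed, parameters, SHA-256 of every
output; the output directory itself is excluded so identical runs are
byte-identical wherever written). Every tie in every stage is broken
deterministically, so a seed fixes the entire run bit for bit.

Default scales mirror the study (19,397 genes, 5000-gene network,
13 modules, 5 + 5 samples). The test suite and the acceptance script
exercise the same structure at reduced sizes chosen once — a 2000-gene
network (minimum module size 12) for recovery properties and a 400-gene
network for end-to-end determinism — with Monte-Carlo identity checks at
up to 500 samples where a closed-form target exists.

## Known limitations

- The DE stand-in has no dispersion shrinkage or independent filtering;
  its null calibration is verified, its power at n = 5 is modest.
- The tree cut is a simplified variant; the original branch-aware
  algorithm's deep-split behaviour is not reproduced, so the number of
  detected modules is parameter-dependent and is not a validation target.
- Chlorophyll coefficients assume the standard dinoflagellate
  calibration; extracts in a different acetone fraction need different
  constants.
- Module recovery fidelity at n = 5 + 5 is information-limited (see
  above); conclusions should rest on module-level statistics, not
  per-gene membership.
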