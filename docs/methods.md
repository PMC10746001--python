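# Methods

`enterosig` re-implements, as a tested library, the statistical analysis of
a three-arm diet-intervention study in which a control diet (ND), a high-fat
diet (HFD) and the high-fat diet plus a treatment (HFD-T070) are compared on
cecal-microbiota composition and lipid physiology. This note records the
models, the defaults and their rationale, the numerical choices, and what
the synthetic data do and do not establish.

## Community profiling

**Aggregation.** Counts are summed to phylum or genus from greengenes-style
lineage strings. A taxon whose name at the requested rank is missing or a
placeholder (`?`, `uncl...`) is pooled under `uncl. <nearest resolvable
ancestor>`; rows with no resolvable ancestor go to `unassigned` with a
warning. Column totals are preserved exactly.

**Alpha diversity.** Shannon H = −Σ pᵢ ln pᵢ in nats; Pielou evenness
J = H / ln S (undefined, reported as NaN, when only one taxon is present).
Richness is the rarefied bias-corrected Chao1,
S_obs + F₁(F₁−1)/(2(F₂+1)), averaged over seeded subsamples drawn without
replacement (multivariate hypergeometric). Defaults: depth = the minimum
sample total, 100 repetitions. The F₂+1 denominator keeps the estimator
defined when no doubletons are observed.

**Beta diversity.** Bray–Curtis on per-sample proportions, binary Jaccard on
presence/absence of raw counts. Proportions (not rarefied counts) are the
normalization because the count table is the only assumed input; the choice
is recorded in output provenance headers.

**PCoA.** Classical metric scaling: Gower double-centering of −½D²,
symmetric eigendecomposition, coordinates from positive eigenvalues only.
Negative eigenvalues (non-Euclidean dissimilarities) are reported but
excluded from the proportion-explained denominator; a Lingoes correction
(+2·|λ_min| on squared off-diagonal dissimilarities) is available behind a
flag and off by default.

**PERMANOVA.** Anderson's partition on squared dissimilarities:
SS_total = Σ_{i<j} d²ᵢⱼ / N, SS_within summed per group, pseudo-F with
(k−1, N−k) degrees of freedom, R² = SS_among / SS_total. The p-value is
(1 + #{F_perm ≥ F_obs}) / (1 + B) under seeded whole-sample-label
permutation (default B = 9999). Pairwise mode re-runs the test on each
group pair's sub-matrix; pairwise p-values are reported unadjusted.
Perfect separation (SS_within = 0) yields pseudo-F = ∞ with R² = 1.

**F/B ratio.** Firmicutes/Bacteroidetes per-sample relative-abundance
ratio; samples without Bacteroidetes are reported missing with a warning,
never as infinities. Group summaries are mean ± SEM with pairwise percent
changes of group means.

## Indicator-taxa effect patterns

Per taxon (relative abundance): a Kruskal–Wallis test across the three
groups, Benjamini–Hochberg correction across taxa, then six simple linear
regressions of abundance on coded group units:

| model | units (ND, HFD, HFD-T070) | reading |
|---|---|---|
| 1 | 25, 75, 10  | return beyond normal |
| 2 | 25, 75, 25  | return to normal |
| 3 | 25, 75, 50  | partial return |
| 4 | 25, 75, 75  | no rescue |
| 5 | 25, 75, 100 | accentuates disease effect |
| 6 | 100, 100, 10 | treatment-only change |

A taxon is an **indicator** iff its FDR-adjusted KW q < α and at least one
model's slope is significant (two-sided t, unadjusted by default; a flag
enables BH across the six models). Among significant models the one with
the highest R² is selected — R² (= r² of the simple regression) is the
natural scale-free effect size comparable across codings. Exact R² ties
break to the lowest model id. α = 0.05 throughout. Abundances enter the
regressions untransformed (a `transform` hook exists); the KW gate is
rank-based and unaffected by monotone transforms. Pearson correlations with
the phenotype (e.g. total cholesterol) are computed for the indicator set
only and BH-corrected within that set; samples with missing phenotype are
dropped pairwise. Group order (control, disease, treated) is taken from the
declared metadata order, never inferred from label strings.

## Physiology metrics

- **Net AUC**: trapezoidal integral of c(t) − c(0) over the full sampling
  window (0–720 min grid for the oral fat tolerance test). Negative
  excursions are kept — it is a net, not positive-incremental, AUC; a
  `positive_only` flag clamps at zero for the incremental variant.
- **TG secretion rate**: OLS slope of serum TG (mg/mL) on time over the
  0/45/90/120-min post-Poloxamer grid, multiplied by the intravascular
  distribution volume, 3.8 mL per 100 g body weight. Concentrations are
  expected in mg/mL (divide mg/dL values by 100). A negative fitted slope
  is returned with a warning — it signals incomplete lipase blockade.
- **Cholesterol absorption**: dual-isotope plasma ratio,
  100 × (serum oral-tracer counts / oral dose) / (serum IV-tracer counts /
  IV dose), both serum counts over the same aliquot. Not clipped at 100%;
  values above 150% warn.
- **LPL activity** = total − hepatic lipase; negative differences are
  reported with a warning, never clamped.
- **Fecal sterols**: concentration (µg/mg dry feces) × dry mass / collection
  days per cage, divided by animals per cage for the per-animal rate.
- **Relative expression**: Livak 2^−ΔΔCt with ΔCt = Ct(target) − Ct(reference
  housekeeping gene) and the control ΔCt summarized by the arithmetic mean;
  by construction the geometric mean of Rq over the control group is 1.

## Group-comparison decision tree

Shapiro–Wilk per group at α = 0.05; if every group passes, one-way ANOVA
with Tukey's HSD (jointly adjusted); otherwise Kruskal–Wallis with Dunn's
post-hoc test. Dunn z uses pooled average ranks with the tie correction
Σ(t³−t)/(12(N−1)); pairwise p-values are Bonferroni-adjusted over all pairs
by default (BH and none available). Groups with n < 3 or identical values
(degenerate for Shapiro–Wilk) force the nonparametric path with a warning.
Normality is tested per group, not on residuals (a residual mode could be
added; per-group is the simplest faithful reading of the routing rule).
Repeated-measures designs are out of scope: time courses are reduced to
scalar summaries (net AUC, slope) before comparison.

## Synthetic study generator

The generator emulates the study's design — 3 groups × 16 animals, genus- or
OTU-level overdispersed compositional counts — so every stage is testable
without animal data. Per sample, taxon weights are baseline lognormal sizes
(between-taxon log-sd 1.5) times per-sample lognormal noise (log-sd
`dispersion`, default 0.3 ≈ 31% CV), closed to proportions and drawn
multinomially at Poisson-varying depth (mean 20 000 reads).

A planted taxon's expected group profile is
r_g = (u_g / u_control)^(ln e / ln 3) for coded units u and effect
multiplier e: since every model in the bank codes a 3-fold control→disease
contrast (25 → 75), e is calibrated as the realized fold change of that
contrast — at e = 3 the expected group relative abundances are exactly
proportional to the coded units, larger e amplifies the pattern, e → 1
flattens it. The power map preserves the ordering and relative shape of the
units, so the planted model remains identifiable at every e > 1. The
remaining probability mass is renormalized across unplanted taxa only,
keeping planted profiles free of closure distortion. Consequence worth
knowing: unplanted taxa share the complement of the planted mass, so when a
community-dominant taxon is planted, many unplanted taxa acquire genuine
group differences in relative abundance (compositional spillover) — these
are correct detections in relative-abundance space, not false positives.

Phenotype values are base level (2 g/L total cholesterol) plus weighted
standardized relative abundances of designated taxa plus Gaussian noise.
OFTT curves are gamma-shaped, baseline + A·(t/t_peak)·exp(1 − t/t_peak),
so they start exactly at baseline, peak at t_peak with height A, and
return; Poloxamer curves are linear with non-negative slope. Isotope
records draw a lognormal IV plasma fraction and set the oral fraction so
the ratio estimator recovers the planted absorption exactly (noise-free)
or in expectation (mean-one multiplicative noise). Ct tables shift the
target Ct by −log₂(fold) per group. All randomness flows from one integer
seed per spec through a local `numpy` generator; writers emit a provenance
header with a spec hash and the seed.

What the synthetic data do **not** emulate: phylogenetic correlation among
taxa, cage effects on composition, zero-inflation beyond what the
multinomial induces, read-level artifacts (chimeras, OTU picking),
between-animal kinetic parameter variation, and any mechanistic link
between the microbiota and the physiology endpoints. Passing tests
demonstrate the statistical machinery is correct under the stated model,
not that the pipeline's power claims transfer to real 16S data.

## Problem sizes and numerical choices

The reference synthetic study is 3 × 16 samples × 200 genera with twelve
planted taxa (two per model, effect 3); the replicated recovery analysis
uses 20 studies of 100 taxa; PERMANOVA defaults to 9999 permutations (999
in the end-to-end runs, 99 in large calibration loops, which keeps the
α = 0.05 rejection probability unbiased at a p-resolution of 1/100).
Distance symmetry is required within 1e−8; PCoA eigenvalues below 1e−12
(relative) are treated as null axes; PERMANOVA's R² partition is exact to
1e−10 against a brute-force sum-of-squares oracle. Kruskal–Wallis on a
zero-range vector returns H = 0, p = 1 rather than an error. BH q-values
are step-up with enforced monotonicity and always ≥ the raw p.

## Known limitations

- Pairwise PERMANOVA p-values are unadjusted (matching how the pairwise
  results are typically quoted); adjust downstream if many pairs are tested.
- The indicator procedure treats relative abundances as independent
  responses; no compositional (CLR/ALR) or phylogenetic modeling.
- Dunn's test uses the normal approximation; very small groups with heavy
  ties are better served by exact permutation, which is not implemented.
- UniFrac and tree-aware diversity are out of scope (no phylogeny input).
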