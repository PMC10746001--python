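# enterosig

Statistical analysis of three-arm diet-intervention studies: gut-microbiota
profiling, indicator-taxa effect-pattern classification, and derived
lipid-physiology endpoints. Written for biostatisticians and microbiome
analysts who need the full chain — count table to report — as a tested,
scriptable Python library rather than a collection of one-off notebook cells.

The study design it targets is a control diet (ND), a high-fat diet (HFD)
and the high-fat diet plus a candidate treatment (HFD-T070), with n ≈ 16
animals per arm, a cecal 16S count table at phylum/genus level, a
per-animal phenotype such as total cholesterol, and classic lipid-handling
assays (oral fat tolerance, Poloxamer-blocked TG secretion, dual-isotope
cholesterol absorption, lipase activities, fecal sterols, RT-qPCR).

## What it computes

**Community profiles** — Shannon H and Pielou evenness, rarefied
bias-corrected Chao1 richness, Bray–Curtis and binary-Jaccard
dissimilarities, principal-coordinate analysis, PERMANOVA (omnibus and
pairwise) with seeded permutation p-values and R² = SS_among/SS_total, and
the Firmicutes/Bacteroidetes ratio.

**Indicator taxa** — a taxon is an indicator when its abundance differs
among groups (Kruskal–Wallis, BH-FDR across taxa) *and* at least one of six
coded linear models fits it: units are assigned per group — (25, 75, 10),
(25, 75, 25), (25, 75, 50), (25, 75, 75), (25, 75, 100), (100, 100, 10) for
(ND, HFD, HFD-T070) — encoding overshooting rescue, full rescue, partial
rescue, no rescue, aggravation, and treatment-only change. Abundance is
regressed on the units; among significant models the highest R² names the
taxon's pattern. Indicator taxa are then Pearson-correlated with the
phenotype (BH-FDR within the indicator set).

**Physiology** — net (baseline-corrected, trapezoidal) AUC; hepatic TG
secretion rate = OLS slope × intravascular volume (3.8 mL/100 g body
weight); fractional cholesterol absorption = 100 × (oral-tracer per-dose
serum fraction)/(IV-tracer per-dose serum fraction); LPL = total − hepatic
lipase; fecal sterol µg/day per cage and per animal; Livak
Rq = 2^−ΔΔCt relative expression.

**Group statistics** — the per-endpoint decision tree: Shapiro–Wilk per
group, then one-way ANOVA + Tukey HSD or Kruskal–Wallis + Dunn (Bonferroni).

**Synthetic studies** — a seeded generator producing every input above with
planted effect patterns, for testing and power exploration. See
`docs/methods.md` for the model and its limits.

## Worked example

```python
import numpy as np
import enterosig as es

study = es.default_study(seed=1)          # 3 groups x 16 animals x 200 genera
genus = es.aggregate(study["table"], "genus")
groups = study["design"].group_series()

dm = es.distance_matrix(genus, "bray")
res = es.permanova(dm, groups, n_permutations=999, seed=1, pairwise=True)
print(f"PERMANOVA (Bray-Curtis, genus): R2={res.r_squared:.3f}, p={res.p_value:.3f}")

ind = es.select_indicators(genus, groups, study["phenotype"], bank=study["design"].bank)
hits = [r for r in ind if r.is_indicator]
print(f"indicator taxa: {len(hits)} of {len(ind)}")
r = next(r for r in hits if r.taxon == "Genus002")
print(f"  {r.taxon}: model {r.selected_model} ({r.pattern_label}), "
      f"q_kw={r.q_kw:.2e}, r={r.phenotype_r:.2f}, q_r={r.phenotype_q:.3f}")

aucs = {}
for s in study["oftt"]:
    aucs.setdefault(s.group, []).append(es.net_auc(s))
nd, hfd, trt = (np.mean(aucs[g]) for g in ("ND", "HFD", "HFD-T070"))
print(f"net AUC (mg*min/mL): ND={nd:.0f}, HFD={hfd:.0f}, HFD-T070={trt:.0f} "
      f"({100*(trt-hfd)/hfd:+.0f}% vs HFD)")
```

prints

```
PERMANOVA (Bray-Curtis, genus): R2=0.165, p=0.001
indicator taxa: 13 of 200
  Genus002: model 2 (return to normal), q_kw=5.06e-06, r=0.58, q_r=0.000
net AUC (mg*min/mL): ND=538, HFD=1685, HFD-T070=955 (-43% vs HFD)
```

All twelve planted taxa come back as indicators, eleven with their exact
planted pattern and one with the adjacent coding (no rescue vs.
aggravation); the thirteenth hit is compositional spillover — see
`docs/methods.md`. Microbial composition separates the three arms
(p = 0.001 at 999 permutations); the treated arm's post-gavage triglyceride
excursion is cut by 43% relative to the high-fat arm.

The same chain is available from the shell:

```sh
enterosig simulate --seed 1 --out study/
enterosig profiles --table study/abundance.tsv --meta study/metadata.tsv \
    --level genus --metric bray --permutations 9999 --seed 1 --out profiles/
enterosig indicators --table study/abundance.tsv --meta study/metadata.tsv \
    --phenotype total_cholesterol --out indicators.tsv
enterosig physio auc --data study/oftt.csv --out auc.tsv
enterosig compare --data auc.tsv --endpoint net_auc --out auc_stats.tsv
```

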