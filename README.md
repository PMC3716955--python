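# phyloarray

Phylogenetic-microarray microbiota profiling and statistics for small
mucosal case–control studies.

The package targets the analysis style of HITChip-type 16S microarrays
applied to duodenal biopsies of children with celiac disease (CD)
versus healthy controls (HC): probe-level signals are QC'd, normalized
and aggregated into genus-like (L2) and phylum-like (L1) taxon
profiles; community structure is summarized by alpha diversity
(Simpson's 1/D, Shannon), PCA and redundancy analysis (RDA) with a
label-permutation test; the microbiota's innate-immune ligand load
(MAMP content — Gram+/Gram− fractions for TLR2/TLR4, flagellated
fraction for TLR5, genomic-GC statistics for TLR9) is scored from taxon
annotations; a cross-validated feature-selection + random-forest
procedure searches for a small bacterial sub-profile that discriminates
the cohorts, with permutation-based significance of its prediction
error; and qPCR expression is analyzed by the comparative-Ct (ΔΔCt)
method with a normality-gated ANOVA/Kruskal–Wallis cascade and
Benjamini–Hochberg FDR control.

Because raw probe-level data of this kind are rarely public, the
package includes a first-class synthetic-cohort generator anchored on a
packaged reference table of 65 duodenal genus-like groups (cohort
mean ± SD abundances plus Gram/flagella/GC% annotations), so the whole
pipeline is reproducible and testable offline.

## Core quantities

- L2 abundance: sum of probe intensities per genus-like group; L1
  divides each probe by its number of target phylotypes first.
- Diversity: 1/D = 1/Σpᵢ², H = −Σpᵢ ln pᵢ on probe-level proportions.
- RDA: pseudo-F = (SS_constrained/df_g)/(SS_residual/df_r);
  p = (1 + #{F* ≥ F})/(1 + n_perm).
- MAMP: abundance-weighted sums/means over annotation classes;
  high-GC fraction uses GC% > 58.
- Discovery: stratified 9-fold CV over six selectors (t-test top
  2/4/6/8/10, above-mean Gini importance); error pooled over folds;
  the winner's CV predictions are tested by label permutation.
- Expression: RQ = 2^(−ΔΔCt) with 18S normalization and a cohort
  calibrator.

## Worked example

```python
import phyloarray as pa
from phyloarray import discovery, mamp

template = pa.load_reference_community()

# reference-table ligand loads (HC cohort means as a pseudo-sample)
ann = template.annotations
hc = template.means("HC")
print(round(mamp.gram_fraction(hc, ann, "positive"), 1))   # 46.1
print(round(mamp.flagellated_fraction(hc, ann), 1))        # 20.5  (Y-only)
print(round(mamp.mean_gc(hc, ann), 1))                     # 48.8
print(round(mamp.high_gc_fraction(hc, ann), 1))            # 32.7  (GC% > 58)

# synthetic 9 vs 10 cohort with the 8-group sub-profile planted 4-fold
cfg = pa.SimulationConfig(seed=7, effect_multiplier=4.0)
abund, meta = pa.simulate_abundances(template, cfg)
errors, best, selected = discovery.nested_cv_select_method(
    abund, meta, seed=7, rf_params=discovery.RFParams(n_estimators=100)
)
result = discovery.permutation_test_error(
    abund, meta, best, n_perm=10_000, seed=7,
    rf_params=discovery.RFParams(n_estimators=100),
)
print(best.label)                        # ttest_top_8
print(round(result.cv_error, 3))         # 0.053  (1 of 19 misclassified)
print(round(result.null_median, 3))      # 0.474  (chance-level null)
print(round(result.permutation_p, 5))    # 0.0004
```

The first block reproduces the reference community's summary rows: the
healthy duodenal community is ~46% Gram-positive (TLR2 ligand load),
~20.5% unambiguously flagellated (TLR5), with a mean genomic GC of ~49%
and a third of the signal from high-GC taxa (TLR9 proxy). The second
block shows the discovery machinery recovering a planted eight-group
signal: the t-test-top-8 selector wins the nested CV, misclassifies one
of 19 samples, and its error is far below the permutation null
(median ≈ 0.47–0.53 depending on the prediction composition), giving
the smallest attainable p at 10,000 permutations.

A command-line interface mirrors the library
(`phyloarray simulate|profiles|diversity|mamp|discover|expression|validate|run-all`).

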