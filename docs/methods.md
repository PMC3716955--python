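# Methods

`phyloarray` re-implements, as a tested library, a complete analysis
workflow for phylogenetic-microarray (HITChip-style) profiling of the
duodenal mucosal microbiota in a small case–control design: 9 healthy
control (HC) children versus 10 newly diagnosed celiac (CD) children,
with 6 treated celiac adults (T-CD) appearing in the gene-expression
arm. Because probe-level data of this kind are not publicly deposited,
the package ships a synthetic-data generator whose defaults encode that
study design, so every stage can be exercised and validated end to end.

## Synthetic cohort generator

**Community model.** The generator is anchored on a curated reference
table of 65 duodenal genus-like (L2) groups carrying, per group: HC and
CD cohort means and standard deviations of relative abundance (%), Gram
status, flagellation (Y / N / strain-variable Y/N), and the genomic GC%
of a representative species. Per sample, each group's abundance is drawn
from a log-normal distribution moment-matched to the cohort mean m and
SD s (σ² = ln(1 + s²/m²), μ = ln m − σ²/2) and the sample is
renormalized to 100%. The log-normal is chosen because mucosal profiles
are strictly positive and strongly individual-specific, with SDs often
exceeding means; no correlation structure between groups is modeled
beyond the negative correlation induced by compositional closure.
Groups with cohort mean < 0.01% are zeroed in a sample when the draw
falls below a floor of 1e-6% (below-detection dropout); the floor is
configurable.

**Null vs planted structure.** By default both cohorts are drawn from
the HC column (`shared_template_cohort="HC"`), so the two groups differ
only through the optional planted effect: a configurable multiplier
applied, before renormalization, to a chosen set of groups in one
cohort. The default planted set is the eight-group sub-profile the
workflow is designed to detect (three groups enriched in CD —
*Prevotella melaninogenica et rel.*, *Haemophilus*, *Serratia* — and
five in HC). Setting `shared_template_cohort=None` instead draws each
cohort from its own column, reproducing the reference table's mild,
individually non-significant cohort differences. `effect_multiplier`
defaults to 1.0 (pure null); recovery experiments use 4-fold.

**Probe decomposition.** Each group's signal is split across 5 probes
(1 synthetic phylotype per probe — a miniature stand-in for a
several-thousand-probe array) with fixed Dirichlet weights, scaled to
arbitrary fluorescence units (1e5 per 100%), plus a log-normal
background of level 50. Two technical replicates are emitted with
multiplicative log-normal noise of scale 0.10 (natural-log SD), which
keeps replicate Pearson correlations comfortably above the 0.94 QC
threshold while remaining visible. The default signal-intensity
threshold is 2× the background level.

**qPCR tables.** Triplicate Ct values per sample × gene with an 18S
endogenous control at Ct ≈ 15, per-gene baseline ΔCt of 10 cycles,
per-sample input offsets (SD 0.3 cycles, cancelling in ΔCt), replicate
noise SD 0.15 cycles, and user-specified (cohort, gene) Ct shifts
(−1 cycle ⇒ 2-fold expression).

**What the generator does not emulate:** cross-hybridization between
probes, probe-specific affinity bias, inter-group abundance
correlations, compositional zeros structured by phylogeny, and
amplification-efficiency differences in qPCR. Passing tests therefore
demonstrate correctness of the statistical machinery under a plausible
null/planted model, not performance guarantees on real mucosal data.

## Profile construction

Technical replicates are QC'd by Pearson correlation (> 0.94 keeps the
pair, which is then averaged; with more than two replicates the
best-correlating pair is kept; single replicates pass with a warning).
Between-sample normalization is min–max: each sample is affinely mapped
onto the envelope [median of per-sample minima, median of per-sample
maxima]. This is one of several published variants of the min–max idea;
the function is a pluggable step so a quantile-matching variant can be
substituted. Intensities at or below the threshold (strict inequality)
are zeroed; for log-scale analyses surviving values are
log10-transformed. Genus-like (L2) signal is the plain sum of probe
intensities per group; phylum-like (L1) signal divides each probe's
intensity by its number of known target phylotypes before summation so
promiscuous probes are not over-counted. Relative abundances are
percent-of-total per sample; cohort tables report arithmetic mean ± SD
of per-sample percentages.

## Diversity and ordination

Simpson's reciprocal index 1/D = 1/Σp² and the Shannon index
H = −Σp ln p (natural log, the ecology convention) are computed on
thresholded, non-log probe-level signal normalized to proportions. PCA
operates on column-centered log10 profiles, unscaled. Redundancy
analysis (RDA) constrains the centered profile matrix by the
group-indicator design; the constrained (between-group) sum of squares
over the total gives the constrained-variance fraction, and the test
statistic is the pseudo-F = (SS_c/df_groups)/(SS_res/df_residual), the
convention of vegan-style implementations. Significance comes from a
seeded label permutation with the +1 convention,
p = (1 + #{F* ≥ F}) / (1 + n_perm), so p is never zero. With a single
binary constraint the constrained fraction equals the classical
between/total sum-of-squares ratio, which the tests verify to 1e-10.

## MAMP (TLR ligand-load) scoring

From relative abundances and the annotation table the package computes,
per sample: the Gram-positive fraction (lipoteichoic acid / TLR2 ligand
proxy), Gram-negative fraction (LPS / TLR4), flagellated fraction
(flagellin / TLR5), abundance-weighted mean genomic GC%, and the
fraction of groups with GC% strictly above 58 (unmethylated CpG / TLR9
proxy). Strain-variably flagellated groups ("Y/N") are excluded from
the flagellated fraction: with the reference table's cohort means the
Y-only convention yields 20.4% (HC), whereas counting Y/N groups gives
≈ 21.5% — only the former matches the table's own summary row. GC
weights are renormalized over annotated, detected groups so the mean is
a true weighted mean.

## Sub-profile discovery

Stratified 9-fold cross-validation (every fold contains both classes;
with 9 HC / 10 CD each fold holds 1 HC and 1–2 CD) evaluates six
feature-selection candidates: the 2, 4, 6, 8 or 10 groups with smallest
two-sided Student t-test p-values on log10 abundances (ties broken
lexicographically; zero-variance features get p = 1), or the groups
whose mean-decrease-in-Gini importance from a random forest on all
groups exceeds the mean importance. Per fold, selection sees only the
training samples; a random forest (default 1000 trees, √p features per
split, seeded; 25–100 trees in the fast test configurations) is fit on
the selected groups and scored on the held-out fold. Per-method error
pools misclassifications over folds and divides by n, because fold
sizes are unequal. The lowest-error candidate (ties to the fewer
features) is then applied to the full data to name the sub-profile.

**Permutation significance.** The default null permutes the labels
freely and recounts the misclassification of the *fixed* held-out CV
prediction vector against each permuted labeling — the classical
exchangeability test of an observed prediction. Its null is
hypergeometric given the prediction composition: with 9 predicted
controls among 9 HC / 10 CD the error is (18 − 2K)/19 with
K ~ HG(19, 9, 9), giving a median of 10/19 ≈ 53% and a central 95%
interval of [6/19, 14/19] ≈ [32%, 74%]. Because the null is conditional
on the prediction vector, calibration checks condition replicate
cohorts on that composition. A conservative alternative
(`scheme="refit"`) re-runs the entire CV — selection included — per
permutation; it folds selection's ability to chase spurious structure
into the null and is noticeably wider on synthetic data (95% interval
roughly [21%, 79%]). Both use p = (1 + #{err* ≤ err}) / (1 + n_perm).

## Expression statistics

Comparative-Ct: replicate Cts are averaged (replicate SD > 0.5 cycles
is flagged), ΔCt = Ct_target − Ct_18S, ΔΔCt subtracts the calibrator
cohort's mean ΔCt per gene (default calibrator: HC; configurable), and
RQ = 2^(−ΔΔCt). Cross-cohort comparisons are gated by Shapiro–Wilk on
the group-mean-model residuals at α = 0.05: the parametric branch runs
one-way ANOVA with Tukey HSD pairwise comparisons, the nonparametric
branch Kruskal–Wallis with pairwise two-sided rank-sum tests (the
post-hoc is not pinned down by convention; Wilcoxon rank-sum is the
package's choice). Pairwise p-values are Benjamini–Hochberg adjusted
within each family and flagged at adjusted p < 0.05. Genus-wise
case/control differences use two-sided Student t-tests on log10
abundances, BH-adjusted across the 65 groups. Abundance–expression
associations use Spearman rank correlation with average ranks,
BH-adjusted across all pairs; constant columns are reported missing.

## Numerical and design choices

- All randomness descends from a single seed through SHA-256-derived
  31-bit per-stage substreams, so any stage can be re-run in isolation.
- Threshold boundary is strict ("above threshold"); log-feature
  pseudocount for classification is 1e-6% (results are insensitive to
  this between 1e-6 and 0.1).
- Permutation p-values use the +1 convention throughout.
- Random-forest hyperparameters and the Gini-selection cutoff
  (above-mean importance) are exposed in `RFParams` /
  `FeatureSelectionMethod`.
- Problem sizes used by the shipped checks: 1000–10,000 permutations
  for the CV-error null, 199 permutations × 200 replicate cohorts for
  ordination calibration, 20 replicate cohorts for planted-signal
  recovery — sizes at which every Monte-Carlo summary in the test suite
  is stable to well under its asserted tolerance.

## Known limitations

Subject-level results of the motivating design (a specific observed CV
error, ordination p-value on a given sub-profile, or per-subject
correlation coefficients) depend on per-sample profiles that are not
public and are out of scope; the package instead validates the
machinery by calibration and parameter-recovery experiments. The
min–max normalization reference is one defensible reading of a loosely
specified step. The discovery stage assumes exactly two classes.
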