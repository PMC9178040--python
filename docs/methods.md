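# Methods

## The synthetic MAGIC population

The generator emulates the structure of an eight-founder MAGIC RIL
population. Defaults mirror a wheat panel: 21 chromosomes totalling
5405 cM (54.05 Morgans), ~350 markers per chromosome (~7.3k SNPs), 210
funnels carrying 231 lines with unequal counts, 38 traits measured in two
years, trait heritabilities spanning 0.05–0.95.

**Crossing and meiosis.** Each funnel combines the eight founders through
four two-way, two four-way and one eight-way cross in a random founder
order, followed by selfing (default 4 generations) and a final gamete that
becomes the line's single founder mosaic. Crossover counts per chromosome
are Poisson with mean equal to the chromosome length in Morgans, positions
uniform, no interference — the Haldane model implied by a cM map. Tested
consequences: the recombination fraction between loci d cM apart matches
(1 − e^(−2d/100))/2 (0.4323 at 1 Morgan), and founder ancestry is
symmetric at 1/8 per founder. Residual heterozygosity after selfing
(~6% per locus at 4 generations) is deliberately ignored: lines are
represented by one mosaic, which is what downstream founder-probability
regression assumes anyway.

**Founder alleles.** Each marker's count of founders carrying the minor
allele is drawn uniformly from the feasible range implied by `maf_min`
(default 1/8, i.e. any segregating split), then carriers are chosen at
random. This gives a flat founder-frequency spectrum — adequate for
exercising the scans, unlike a real array's ascertained spectrum.

**Founder probabilities.** The grid emits the true mosaic founder with
probability 1 − u and spreads u (default 0.05) uniformly over the other
seven founders. This emulates the softness of HMM-inferred probabilities
without re-implementing the inference; it does not emulate locally
ambiguous regions where two founders share a haplotype.

**Phenotypes.** A planted QTL contributes `score × effect × year
multiplier`, where the score is the founder's biallelic allele at the
nearest marker (biallelic mode) or an arbitrary founder pattern (founder
mode). Residuals are multivariate normal across traits with a configurable
correlation matrix; an optional funnel random effect models shared recent
ancestry. The per-trait residual variance is solved from the *empirical*
genetic variance of the simulated lines so that the broad-sense
heritability of replicate-averaged line means equals the target:
`Vr = replicates × Vg_hat × (1 − h²)/h²`. Calibrating on the realized
rather than theoretical genetic variance guarantees realized ≈ target
(verified to ±0.05). Targets of exactly 0 (with genetic signal present) or
1 (without) are rejected as infeasible.

What the generator does *not* emulate: genotyping ascertainment, missing
founder probabilities, spatial field trends (line means are emitted
directly, standing in for BLUPs), selection during population development,
epistasis, and crossover interference. Passing tests therefore demonstrate
correctness of the inference machinery under the stated generative model,
not robustness to those real-data complications.

## Trait preparation

Pairwise-complete Pearson correlations (pairs with < 3 complete
observations flagged missing) feed the sign-blind dissimilarity
`d = 2(1 − |r|)`, clustered by Ward agglomeration in the "on-distances"
(ward.D2) convention via scipy's linkage and cut to k = 8 groups by
default. Group PCA standardizes each trait, eigendecomposes the group
correlation matrix, and emits scores as pseudo-traits `G<g>_PC<k>`. All
PCs of a group are carried into QTL scanning. Two conventions are fixed
for determinism: lines missing any group trait are dropped when estimating
weightings (scores emitted for all complete lines), and each component is
sign-flipped so its largest-magnitude weighting is positive.

Heritability is estimated by one-way method-of-moments variance components
on replicated values (Vg from the between/within mean-square difference,
truncated at zero; H² = Vg/(Vg + Vr/r̄) with r̄ the mean replication).
This is a deliberate simplification of spatially adjusted REML-based
estimators used on real trials; the pipeline consumes adjusted means
regardless, so the estimator only affects reporting.

## QTL detection

**Weights.** "Adjusting for" unequal funnel sizes is read as inverse
weighting: w = 1/(funnel size), normalised to mean one so each funnel
contributes equal total weight. Weighting proportional to funnel size
would amplify rather than correct the imbalance; the proportional variant
remains available behind `weighting: proportional` for comparison.

**Scans.** Both modes are weighted least squares conditional on the
intercept plus previously selected terms, implemented by residualising
against the QR basis of the sqrt-weighted base design. SNP mode tests each
marker with a 1-df partial F test (identical to the coefficient t-test;
verified against direct normal-equations solves to |Δp| < 1e-10).
Haplotype mode regresses on all eight founder-probability columns at a
grid position; the sum-to-one collinearity leaves 7 estimable contrasts,
tested jointly (7-df F). Coefficients come from a minimum-norm least
squares solve and are re-expressed as a centered 8-vector — invariant to
the dropped-column/reference choice, and comparable across QTL. A locally
absent founder reduces the rank and df, and the position is flagged.
Markers monomorphic in-sample are kept in the profile with p = 1 so
profile indices stay aligned to the map. Missing genotype calls are
mean-imputed for scanning.

**Thresholds.** The effective test count is reconstructed as
`n_blocks = n_chromosomes + recomb_per_chromosome × map_length_Morgans`
(237.2 at the 21/4/54.05 defaults); the value may also be set directly.
Addition requires p < alpha_add/n_blocks (0.00042 default); backward
elimination uses criterion `n·log(RSS/n) + k × parameters` with k = 13.73
per parameter in SNP mode — equivalent, through the χ²(1) quantile, to a
drop threshold of p ≈ 0.00021 = 0.05/237.19 — and k = 5 per parameter in
haplotype mode. The per-parameter reading of k (rather than per term) is
adopted because it is what makes the k = 13.73 ↔ p = 0.00021 equivalence
hold on 1 df. Ties in forward selection break by lowest p, then
chromosome order, then position; collinear candidates eliminate the
later-added member first.

**FDR confidence.** Benjamini–Hochberg is applied to the full vector of
per-position p-values of the scan in which a QTL was added ("at this
stage" is read as addition time, using all information from that
iteration's genome scan); adjusted p < 0.05 marks high confidence, and the
label is not revised by backward elimination.

**Intervals and PVE.** The support set contains positions within 20 cM of
the peak whose −log₁₀ p is within 2 of the peak's; the reported flanks are
the nearest positions outside that set on each side (one-sided at
chromosome ends). The rule is applied literally to the (possibly
non-monotone) profile; an independent brute-force implementation backs the
tests. Per-QTL PVE is the sequential (addition-order) sum of squares over
the total weighted sum of squares; the model-level PVE is the adjusted R².
Type-I vs Type-III attribution is a genuine choice; sequential SS is used
because it matches the stepwise construction of the model.

**SNP-mode founder vectors.** For co-localization, SNP QTL need an
8-founder vector: each founder's biallelic allele at the peak marker times
the fitted effect, centered. This places SNP and haplotype detections in a
common vector space at the cost of forcing SNP vectors to a two-valued
pattern.

## Consensus QTL

Pairs co-localize when on the same chromosome, peaks ≤ 20 cM apart
(inclusive), and Pearson r of the centered founder vectors > 0.6 (strict);
a zero-variance vector makes the correlation undefined and the pair
distinct. Single-linkage clustering of the 0/1 distances cut at 0.5 equals
connected components of the co-localization graph (tested exhaustively
against a union-find oracle), so distant QTL on one chromosome merge only
through chaining — documented single-linkage behaviour, not a defect.
With only 8 points the founder-vector correlation is noisy; the threshold
is a config key but the default follows the rule as stated. Group position
is summarised by the median member peak.

## Numerical and scale choices

Simulation-backed tests run at desk scale: genomes of 2–3 chromosomes of
100–120 cM with ~1 marker/cM (the marker density of the emulated study),
populations of 120–500 lines, 100–200 replicates for power/calibration
claims, chosen to keep the full suite within a few minutes while leaving
binomial noise well inside the asserted margins. Null calibration of the
genome-wide addition rate uses 237 independent markers so that the
realized number of independent tests matches the default block count. The
study-scale defaults (21 chromosomes, 231 lines, 38 traits) remain the CLI
defaults.

## Known limitations

- Founder probabilities come from truth plus symmetric noise, not from an
  identity-by-descent HMM; scan behaviour under realistic, locally
  correlated probability errors is untested.
- The Gaussian likelihood in backward elimination assumes weighted
  homoscedastic residuals; robust/mixed-model variants are out of scope.
- Greedy Ward agglomeration is verified against exhaustive optima on
  separated cluster structures; on pathological dissimilarities the greedy
  cut can differ from the global Ward optimum, as with any agglomerative
  method.
- The consensus rule inherits the coarseness of 8-point correlations:
  antagonistic founder patterns can fail to merge even when truly
  co-localized.
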