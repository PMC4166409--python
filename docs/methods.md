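# Methods

## Statistical model

The phenotype is a visual IDC score on a bounded 1–5 scale, treated as
continuous. Raw scores are adjusted by population least-squares means
(`adjusted = raw − population mean + grand mean`), which removes the
year/population offset while preserving within-population deviations and
ranks. The combined-population analysis is the default so that alleles rare
in one subpopulation retain power.

Single-marker association is tested under six models: ordinary least squares
with no covariates (naive), with the principal components explaining 25% or
50% of cumulative genotypic variance (PC₂₅, PC₅₀), and the same three
covariate sets with an additional polygenic random effect (kinship). The
mixed model is

    y = Wα + xβ + u + ε,   u ~ N(0, σ²_g K),   ε ~ N(0, σ²_e I)

with K the centered relatedness matrix `XcXcᵀ/m` over m markers. The test is
*exact* in the sense that the variance ratio λ = σ²_g/σ²_e is re-optimized by
restricted maximum likelihood under every marker's alternative model, rather
than fixed at its null value; β is then assessed by a Wald F(1, n−c−1) test.
A single eigendecomposition of K rotates the problem so each REML evaluation
is O(n).

**Numerical strategy for λ.** The batch scanner evaluates the restricted
likelihood on a log₁₀ grid over λ ∈ [10⁻⁶, 10⁶] with step 0.1, refines the
per-marker optimum by quadratic interpolation of the three bracketing grid
values, and recomputes exact Wald statistics at the refined λ (falling back
to the grid optimum if refinement does not improve the restricted
likelihood). The likelihood is unimodal-in-practice and flat near its
optimum, so this matches bounded scalar optimization (used by the
single-marker API, tolerance 1e-7 in log₁₀λ) to well below the Wald test's
sensitivity; when K = I the two reduce to OLS p-values exactly. λ at a grid
boundary is flagged, not fatal. p-values are floored at 1e-300 before
−log₁₀ transforms.

**Model selection** uses the rank-based mean squared difference
MSD = (1/m) Σ (p₍ᵢ₎ − i/(m+1))², with i/(m+1) the mean uniform order
statistic (i/m is noted as an alternative but not used). Smallest MSD wins;
ties (which occur when REML drives λ → 0 and a kinship model collapses onto
its fixed-effect counterpart) resolve to the first model in the canonical
order.

**Significance thresholds** are empirical: the 0.0001 and 0.001 quantiles
(the "0.01-percentile" and "0.1-percentile" tails) of the observed p-value
distribution, each computed per bootstrap resample of the m p-values
(type-7 linear interpolation) and aggregated as the mean over B = 10,000
resamples (median available). Resampling p-values — rather than re-running
the association on resampled genotypes — is the only desk-feasible reading of
bootstrapping over ~35,000 markers; the aggregator choice moves the cutoff by
far less than seed-to-seed variation.

**Per-marker summaries** report allele-class means over homozygous carriers
only (dosage 0 vs 2; heterozygotes are excluded from means but kept in the
simple regression that yields R²), the absolute mean difference, the additive
effect of the variant allele = (variant mean − reference mean)/2 — an exact
identity enforced in tests — and MAF in percent.

## Linkage disequilibrium

Pairwise LD is the squared Pearson correlation of dosage residuals after
regression on structure covariates (PC₂₅ by default); with no covariates it
is the plain allele-count r². Decay with physical distance is fitted by
least squares on the drift–recombination expectation

    E(r²) = [(10+C)/((2+C)(11+C))] · [1 + ((3+C)(12+12C+C²))/(n(2+C)(11+C))]

with C = ρ·d and ρ free. The fit is a multi-start search over a log-spaced ρ
grid (10⁻¹² … 10⁻³ per bp) refined by bounded minimization (xatol 1e-10).
Two properties of this expectation matter for interpretation: it saturates
below 0.5 as C → 0 and asymptotes to the sampling floor 1/n as C → ∞, so
crossing distances are only defined for query levels inside that range
(a query at r² = 0.7 reports no crossing; observed binned decay is emitted
alongside the fit). All-pairs computation is O(m²), so intra-chromosomal
pairs within a distance window are subsampled uniformly under a seed.

## QTL delineation and downstream analyses

Stepwise selection over the 0.1-percentile-significant markers is forward
entry (smallest partial p ≤ 0.05, overall model F p ≤ 0.05) with backward
elimination of any retained marker whose partial p rises above 0.05;
candidates collinear with the current model are skipped, so duplicated
markers enter once. Covariates are markers only by default (PCs can be
added). Note that with k independent null candidates the minimum null
partial p falls below 0.05 with probability ≈ 1 − 0.95ᵏ per step, so a small
number of false inclusions is expected behavior of the 0.05 gate, not a
defect.

A QTL region grows outward from a stepwise lead while the partial r² between
the current block **edge** and the next adjacent marker exceeds 0.6
(lead-anchored chaining is available as an option); boundaries are the
outermost member-marker positions, so an isolated lead yields a point
region. Adjacent blocks merge when the gap is < 10 kb AND at most 4
intervening markers are not in LD (r² ≤ 0.6 with every member of both
blocks); the AND/OR reading of that rule is configurable because the
original phrasing is ambiguous, and merging repeats to a fixpoint.
Gene overlap is any-intersection of 1-based closed intervals ("within" is
read inclusively; for genes fully inside a region both readings agree).

Epistasis fits y ~ covariates + m₁ + m₂ + m₁·m₂ for every unordered pair of
significant markers (PC₂₅ covariates), flagging interaction p ≤ 1E-03;
collinear pairs are degenerate with p = 1. Allelic combinations string the
carried allele letter per stepwise marker in fixed order; samples
heterozygous or missing at any selected marker are excluded and counted.
Classification is **inclusive** — mean ≤ 2.5 tolerant, ≥ 3.5 susceptible —
because the inclusive rule is the one consistent with a boundary mean of
exactly 2.50 being called tolerant and with the published 14/6 split of the
twenty printed combination means.

## Variant annotation

Sites are classified with precedence coding > UTR > intron > intergenic
across all overlapping transcripts; among coding calls, non-synonymous
outranks synonymous, with remaining ties broken by lexicographic transcript
id. Codons are assembled from the spliced CDS in transcript orientation
(reverse-complemented on the minus strand, validated as strand-symmetric by
mirrored fixtures), the variant base substituted, and both codons translated;
start/stop gains and losses fold into non-synonymous. A transcript whose
spliced CDS length is not divisible by 3 is skipped with a warning. A VCF
REF allele that contradicts the FASTA is an error, not a warning.
Transitions are purine↔purine or pyrimidine↔pyrimidine substitutions; the
Ts/Tv ratio is reported as infinite if no transversion is present.

## Synthetic data generator

The generator emulates the analysis' assumed structure, not soybean
demography. Two subpopulations (defaults 132 and 138 lines) draw from
disjoint founder pools of 8 haplotypes each. Founder haplotypes are
piecewise-constant over haplotype blocks whose boundaries arrive at half the
per-bp switch rate, with block frequencies drawn Uniform(maf_floor,
1−maf_floor) and differentiated between subpopulations by a Balding–Nichols
Beta spread (F_ST = 0.10); a per-marker flip noise of 0.015 sets the
within-block LD ceiling. Each inbred line is a founder mosaic (switches at
the other half of the rate), doubled into dosages 0/2; heterozygotes are
never emitted, though the pipeline accepts dosage 1 from real VCFs. With the
default switch rate of 2.5e-7/bp this produces pairwise partial r² ≈ 0.7 at
~500 kb, monotone decay, PC1 separation of the subpopulations, and Gower
similarity concentrated in a band of interquartile range < 0.15 around
~0.63.

Phenotypes are baseline 2.76 + subpopulation shift (default 0.10 IDC units,
a modest year/population offset) + Σᵢ aᵢ·(dosageᵢ − 1) + N(0, 0.30²),
**clipped** (not truncated-resampled) to [1, 5] to match the bounded visual
score. The eight-QTL study profile plants additive effects of magnitude
0.13–0.19 at variant-allele frequencies 0.20–0.50, one per listed
chromosome; planted markers get exact-count founder alleles at the target
frequency in both pools so effects are estimable within each. Missing calls
(default 10%) are masked after phenotypes are computed.

What the generator does **not** emulate: recombination maps or crossover
interference, genotyping error and allelic dropout typical of GBS,
LD-preserving imputation (the pipeline's mode imputation attenuates
post-imputation LD relative to a haplotype-aware imputer, shortening
delineated regions), clustered significant markers from dense local signal,
and any real candidate-gene biology (the annotation genome is random
sequence with constructed gene models). Passing tests therefore demonstrate
correctness of the statistical machinery under the assumed structure, not
end-to-end fidelity to a particular field dataset.

## Problem sizes and test design

The test suite exercises statistical properties at the sizes where they are
stated: model-calibration and MSD-ranking simulations use n = 270 and
m = 2,000 over 20 seeds; planted-QTL recovery uses m = 5,000 over 20 seeds
with B = 2,000 bootstrap resamples (the threshold is a mean of B quantiles,
so its Monte Carlo error at B = 2,000 is far below the assertion bands);
type-I-error pooling uses ten m = 10,000 null panels. The acceptance script
runs the full study scale (m = 34,000, B = 10,000). Genomic-control lambda
on a single 2,000-marker panel has a seed-to-seed SD near 0.1, so
calibration assertions pool p-values across panels before computing lambda.

## Known limitations

- Mode imputation is a declared stand-in for haplotype-cluster imputation;
  marker counts and LD after imputation differ from an LD-aware imputer, and
  filtering on observed calls approximates the impute-then-filter order.
- The percentile-tail threshold flags ≈ m×level markers regardless of signal
  strength; on sparse-signal panels most flagged markers are unlinked false
  positives, which inflates the stepwise marker count relative to panels
  where significant markers cluster in LD blocks.
- The LMM grid step bounds the reported λ's resolution to ~26% relative;
  Wald p-values are insensitive to this but downstream consumers of λ itself
  should use the single-marker API.
- Only single-transcript, two-exon gene models are generated; the annotator
  handles arbitrary GFF3 transcripts but splice-site and frameshift effects
  are out of scope.
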