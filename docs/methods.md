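# Methods

This note documents the statistical models implemented in `loopgene`, the
design of the synthetic data that validates them, the numerical choices, and
what the validation suite does and does not demonstrate.

## Fine-mapping

Each locus is fine-mapped from marginal summary statistics (β, se) under the
single-causal-variant assumption. Variant evidence is the approximate Bayes
factor with a normal prior N(0, W) on the effect,

    ABF = sqrt(V/(V+W)) · exp(z²W / (2(V+W))),  V = se², z = β/se,

computed in log space so arbitrarily large z stays finite. Posterior
probabilities are the softmax of log ABF over the locus; the level-L
credible set accumulates variants in decreasing posterior order until the
cumulative probability first reaches L (inclusive stop). Ties in posterior
probability break deterministically by (chromosome, position, variant id).
Variants with missing β or se are dropped with a logged warning rather than
imputed. Defaults: W = 0.04 (prior SD 0.2 per allele, the field-standard
default for quantitative traits; exposed in `FinemapConfig`), L = 0.99.

Because the greedy prefix takes the largest posteriors first, it is also the
smallest-cardinality set achieving the level when posteriors are distinct;
the suite checks this against exhaustive subset enumeration.

*Assumptions and limits.* One causal variant per locus and no functional
priors. Multi-causal architectures (conditional analysis, SuSiE-style sum of
single effects) are out of scope; with more than one causal signal per locus
the reported sets cover only the strongest signal.

## Loop calling

Valid read pairs are classified before binning: a *duplicate* repeats the
full coordinate/strand tuple of an earlier record; unique pairs split into
*trans* (different chromosomes), *cis-long* (separation > 20 kb) and
*cis-short*. Percentages are reported against all valid pairs, so the three
unique categories sum exactly to the unique percentage.

Unique cis pairs are aggregated into 5 kb bin pairs
(bin = floor((pos−1)/resolution)) and tested within anchor separations of
20 kb–2 Mb. The background has two components:

* **Distance decay** p(d): candidate pairs (including observed-zero pairs)
  are split into up to 200 distance bins of approximately equal pair count;
  the raw per-pair probability per bin, (Σ counts)/(total counts · pairs in
  bin), is made monotone non-increasing by pool-adjacent-violators weighted
  by pair count. Queries interpolate in log-log space with end-segment
  extrapolation — exact for power-law decay and, importantly, not flattened
  at the steep short-distance end, where linear edge-clipping was found to
  understate expected counts by ~10% and break error control.
* **Visibility bias** b_i: marginal bin coverage normalized by the bin's
  expected coverage under the decay model, E_i = Σ_j p(d_ij)·b_j over
  candidate partners, iterated (5 rounds) to the Poisson marginal fixed
  point and scaled to mean 1 over covered bins. The naive coverage/mean
  ratio is available when no decay model is passed, but it understates the
  visibility of bins near chromosome ends — which have fewer candidate
  partners — by up to 2× on megabase-scale test chromosomes, producing
  spurious edge loops. Zero-coverage bins get b = 0 and are excluded from
  testing.

Each candidate pair is scored with the upper-tail binomial probability
P(X ≥ k | N, π_ij), N the total cis contact count and
π_ij ∝ p(d_ij)·b_i·b_j rescaled to preserve the total candidate probability
mass. Benjamini–Hochberg adjustment runs over all candidates with nonzero
expected probability (proper multiplicity accounting, including zeros);
loops are candidates with q ≤ 0.01 (the loop-calling tool's customary
default; exposed) and k > 0. This is a deliberately simplified,
binomial-background reimplementation of the peak-to-all loop-calling model;
spline-based negative-binomial regression, ICE balancing, restriction-site
filters and trans loops are out of scope.

Merging across cell lines unions loop tables; bin-identical loops collapse
into one record with the union of source labels and the minimum q.

## Anchor annotation and variant-to-gene mapping

Promoters are strand-aware windows around the TSS, ±2,500 bp by default —
half a 5 kb bin on each side, so a promoter marks at most its own bin and
neighbors; the window is configurable. Anchor categories follow fixed
precedence: promoter > 5'UTR > 3'UTR > exon > intron > downstream (≤3 kb
past the 3' end) > distal intergenic. A loop's category comes from its
non-promoter anchor (both promoters → promoter–promoter; UTR, exon and
downstream collapse into promoter–other).

A credible variant is a 1 bp point (SNPs only; indels out of scope). A
variant inside one anchor links to every gene whose promoter window (or
body, per the mode flag — the two readings of "genes at an anchor" are both
kept) overlaps the other anchor; link distance is |variant position − TSS|,
with the anchor-midpoint separation carried as an alternative column. Links
deduplicate on (variant, gene, loop). The open-chromatin filter keeps
variants lying in a peak of every supplied peak set (or any, per flag); its
output is always a subset of its input and grows monotonically with added
peaks. Note that with an upstream promoter extension, promoter-mode gene
lookup is *not* a subset of body-mode lookup (an anchor can touch only the
upstream flank); the suite demonstrates both the inclusion that holds for
zero upstream extension and a counterexample otherwise.

Proximal (baseline) targets assign each variant its containing gene body,
else the nearest TSS, ties to the smaller coordinate then gene id. Target
sets are compared after uppercasing symbols; fold ratios are reported to
one decimal and undefined against empty sets.

## Heritability enrichment (stratified LD-score regression)

LD scores are ℓ_j(C) = Σ_k r²_adj(j,k)·a_C(k) over a 1 Mb window (bp window
rather than cM, since synthetic panels have no genetic map), with the
finite-sample adjustment r²_adj = r² − (1−r²)/(n−2) and the self term
included. The regression

    E[χ²_j] = intercept + Σ_c coef_c · N·ℓ_j(c)/M

is fitted by weighted least squares with the standard weights
1/(ℓ_base · (1 + N·h²_agg·ℓ_base/M)²), where h²_agg is the aggregate
heritability estimate from mean χ². Per-SNP contributions τ_c = coef_c/M
accumulate into per-category heritability h²_c, and enrichment is
(h²_c/h²)/(M_c/M) with a 20-block delete-one jackknife SE. A base-only
model has enrichment identically 1; all-χ²=1 input returns τ = 0 and
intercept 1 exactly. A rank-deficient design raises an error naming the
collinear categories. The intercept can be constrained to 1
(`constrain_intercept=True`) — appropriate when confounding is known absent,
as in simulation, where it greatly stabilizes the enrichment ratio's
denominator at small SNP counts. This is a minimal core: the published
53-annotation baseline model is represented only by whatever extra
annotation columns the caller supplies.

## ssGSEA and differential expression

For one sample, genes are ranked by expression descending (ties broken by
gene name for determinism). With hit weights rank^α (rank m for the top
gene, α = 0.25 by default — the GSVA convention) and miss increments
1/(m − |S|), the enrichment score is the sum over positions of (cumulative
hit-weight fraction − cumulative miss fraction). The score depends on the
ranking only, hence is invariant under any strictly increasing transform of
a sample's values; across samples, scores are normalized by their range.
The differential-expression stage is a per-gene Welch t-test with BH
adjustment (significant: q < 0.05); the test choice is deliberately minimal
and isolated behind one function. Genes with zero variance in both groups
are flagged undefined and excluded from adjustment.

## Synthetic data: what it emulates, and what it does not

One chromosome per GWAS locus (no trans bookkeeping). Generators are pure
functions of (config, seed); a truth record lists every planted object
exactly once. When seeding several generators from one base seed, spawn
distinct child seeds — reusing one integer seed across generators replays
the same underlying bit stream and can correlate supposedly independent
draws.

* **Genotypes.** Founder haplotypes arise by first-order Markov copying of
  a uniform quantile along sorted allele frequencies (MAF uniform in
  (0.05, 0.5]); individuals draw two founders with replacement. The copying
  rate targets the adjacent-dosage correlation (default 0.6); an optional
  block mode varies the rate in haplotype-like blocks, producing the
  heterogeneous LD-score landscape real panels show (homogeneous chains
  make the base LD score nearly constant and collinear with the regression
  intercept). This is a caricature of LD: no recombination hotspots, allele
  ages or selection.
* **GWAS.** Quantitative trait y = effect·g + noise with unit total
  variance; marginal OLS slope and SE per SNP. The default effect is sized
  for an expected causal |z| of 6 at n = 5,000. For the heritability
  experiment, summary statistics are instead drawn from the multivariate
  normal model z ~ N(√n·Rβ, R) with R from a 20,000-haplotype founder pool
  (sampled through the haplotype matrix as a square root of R). The
  summary-statistic route has regression intercept exactly 1 by
  construction; individual-level simulation at m ≈ n carries finite-sample
  tagging inflation of order h²·m/n that the intercept must absorb.
* **Contacts.** Expected count depth·p(d)·b_i·b_j with p(d) ∝ d^(−1),
  log-normal bias (σ = 0.2), Poisson counts (gamma-Poisson behind an
  overdispersion knob, default off, keeping the caller's null exact).
  Planted loops multiply the pair mean by 5 at separations drawn
  log-uniformly from 20–300 kb (median ≈ 77 kb, the order of observed loop
  distance medians). The defaults — depth 10⁶ cis contacts on a 2 Mb
  chromosome, fold 5, bias σ 0.2 — were fixed by a design-time power
  calculation: at the farthest planted separation and a 1st-percentile bias
  product, the binomial tail of a fold-5 signal (~10⁻⁹) clears the BH
  threshold (~10⁻⁶) with orders-of-magnitude margin. Not emulated:
  restriction fragments, read-level structure, trans contacts, TADs,
  condition-dependent looping.
* **Annotation & expression.** Non-overlapping gene bodies with 1–4 exons
  and small UTR stubs; log2-scale expression normal per gene (log-normal
  intensities), with planted genes shifted by 2 log2 units in the tumor
  group. Microarray-style; no count noise or library-size structure.
* **End-to-end studies.** Per locus, the causal variant's bin is looped to
  a gene-promoter bin (the intended link), plus background loops; two cell
  lines share planted loops but draw independent counts; ATAC-like peaks
  cover every causal variant in both cell lines; linked target genes are
  planted as differentially expressed.

Passing tests on these data show the pipeline's logic and calibration are
correct under its own model assumptions. They do not show robustness to
real-data pathologies: reference bias, structural variation, copy-number
driven coverage, batch effects, population stratification, or loop calls at
read depths far below the reference conditions.

## Problem sizes used in validation

Credible-set coverage: 1,000 loci × 100 SNPs at n = 5,000. Loop error
control: 50 null maps and 20 planted maps of a 2 Mb chromosome at depth
10⁶ (~78,600 candidate pairs each). End-to-end recovery: 20 studies × 5
loci. Heritability recovery: one 2,000-SNP / 2,000-sample panel, 50
replicate GWAS draws. Oracle equivalence: ≥100 random fixtures per
statistic at tolerance 1e−10. These sizes make the full suite complete in
a few minutes on one CPU while keeping every stochastic criterion
comfortably away from its threshold.

## Known limitations

* The loop caller's binomial background underestimates variance if real
  counts are overdispersed; the generator's overdispersion knob exists
  precisely to probe this, and FDR control is only claimed for the Poisson
  null.
* Credible sets inherit every limitation of the ABF (normal approximation
  to the likelihood, single causal variant, shared prior across variants).
* The S-LDSC core omits the multi-annotation baseline model; enrichment
  estimates on real data conditioned only on the base category are
  confounded by any annotation correlated with the target category.
* ssGSEA scores are comparable only within the sample set they were
  normalized in.
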