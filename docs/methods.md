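# Methods

## Scope and data model

All analyses operate on a `GenotypePanel`: a samples × markers matrix of
counted-allele doses (0/1/2, NaN missing) over biallelic autosomal SNPs with
a physical marker map, read from and written to PLINK bed/bim/fam (v1,
SNP-major). Doses count the bim A1 allele as stored; the rare-allele scores
are orientation-sensitive, so the scoring entry points re-orient the panel
to count the minor allele (`orient_minor`) before computing anything.
Positions are 1-based inclusive throughout, including peak and ROH
coordinates.

## Quality control

Markers are removed when missingness exceeds 2 % or a Hardy–Weinberg exact
test rejects at p < 10⁻⁶; samples with more than 2 % missing genotypes
(after marker filtering) are removed. The HWE test is the plain conditional
exact test — the full distribution of the heterozygote count given the
allele counts, summing probabilities ≤ the observed configuration — with no
mid-p correction. LD pruning is greedy and windowed (50-SNP windows, step
5, r² > 0.5 removes the lower-MAF member), with pairwise-complete r² and
monomorphic markers retained (their correlation is undefined).

## Relationship matrices

The off-diagonal estimator weights allele sharing by 1/(2p(1−p)); the
diagonal uses the standard companion form
1 + [x² − (1+2p)x + 2p²]/(2p(1−p)). Both are invariant to orientation
flips. Missing data are handled pairwise-complete: each pair's denominator
counts jointly non-missing markers, and `RelationshipMatrix.n_matrix`
stores those counts so that matrices computed on disjoint marker sets pool
exactly (`combine_grms`), which is also how the per-chromosome matrices
reproduce the all-marker matrix. MAF windows are half-open intervals
(low, high] on the minor-allele frequency; monomorphic markers are always
excluded (the weight is undefined). Relatedness pruning drops, at each
step, the sample with the most above-cutoff partners (ties: first in
sample order) until no pair exceeds 0.025.

## Rarity scores and peak calling

Per-marker terms 1/(x·p) are summed over carried minor alleles; markers
with x = 0 contribute exactly 0, and windows average over all their
markers (zero-dose markers included in the denominator). Windows are
non-overlapping 50-SNP blocks per chromosome; the trailing partial window
is averaged over its actual marker count and flagged. Peak seeding uses a
strict threshold on the window mean; two seeds on one chromosome separated
by at most 9 sub-threshold windows merge into one peak including the
in-between windows; peak coverage runs from the first SNP of the first
member window to the last SNP of the last, inclusive. Two guards keep
partial windows from generating artefacts: a partial window is compared on
its rarity *mass* relative to the nominal window size (otherwise one rare
allele in a 20-marker trailing window is inflated by the small
denominator), and partial windows under 10 markers never seed.

### Threshold calibration and cohort size

With panel-derived frequencies the smallest attainable frequency is one
copy in 2n chromosomes, so the score scale grows linearly with cohort
size: a cohort singleton scores 2n. Absolute thresholds therefore do not
transfer between cohort sizes. Two copy-number-anchored quantities do,
and `copy_number_cutoffs(n)` provides them:

* marker-selection cutoff 2n/8 — the score of an allele observed 8 times
  or fewer (2,472 ≈ 2,500, i.e. p ≤ 0.0004, at 2n = 19,778);
* window threshold 2·(2n)/50 — two cohort singletons' worth of mass per
  window. In a very large cohort one 8-copy allele towers over the
  common-allele background (mean per-marker term ≈ 1.7) and the published
  window threshold of 50 is far below the singleton mass of 2n/50 ≈ 400;
  in a small cohort the background does not shrink while the singleton
  mass does, and a *single* singleton (an isolated private variant or a
  genotyping error) is statistically indistinguishable from background, so
  a window must carry at least two singletons' excess mass to count as
  part of a rare haplotype.

Default arguments stay at the published large-cohort values (2,500 and
50); the synthetic studies at n = 300 use `copy_number_cutoffs(300)` →
(75, 24).

Outlier classification is relative and needs no calibration: individuals
whose total peak coverage exceeds the cohort mean + 3 SD are flagged.
Origin assignment looks up every marker whose term exceeds the selection
cutoff in any sample and reports the reference population with the highest
frequency of the (minor-oriented) rare allele; markers absent from the
reference table are "unknown".

## Runs of homozygosity

Implemented as a direct maximal-run search under the stated constraints
(span ≥ 5 Mb, ≥ 50 SNPs, ≤ 1 heterozygote, ≤ 5 missing, gaps ≤ 100 kb)
rather than a sliding window-vote heuristic: the parameters define the run
properties and the search is checked against an exhaustive oracle in the
tests. Heterozygote/missing budgets apply per final segment. Runs are
trimmed to start and end on homozygous calls; where maximal candidate runs
overlap (e.g. two heterozygotes within one long homozygous stretch), the
longest span wins, then earliest start. Segment length is
end − start + 1. UPD flagging requires ROH coverage of ≥ 99 % of a
chromosome's genotyped span for one sample.

## Geography and mixed models

PCs are raw eigenvector coordinates of the GRM (no √λ rescaling), sorted
by descending eigenvalue with the largest-magnitude entry of each vector
made positive so results are deterministic. PC–coordinate regressions fit
each PC on latitude and longitude jointly by OLS; the coordinate predictor
fits latitude and longitude as two separate OLS models on the first 20
PCs. The GEO kernel is 1 − d/d_max on Euclidean distance in degree space
(translation- and scale-invariant, unit diagonal; all-ones when every
sample shares one location); a Gaussian kernel is available behind a flag.
Degrees are treated as a flat plane — at the few-hundred-km scale of the
emulated study region the great-circle distortion is immaterial.

Variance components are estimated by average-information REML with an
active-set treatment of the zero boundary (components pinned at zero with
negative gradient sit out an iteration), step-halving on the AI direction,
an EM fallback step, and a positive floor on the residual variance.
Convergence is declared at relative log-likelihood change < 10⁻⁸ (at most
200 iterations) or at a constrained stationary point where neither step
improves. Kernels are bent to positive semi-definite by eigenvalue
clipping when needed (logged). Standard errors come from the inverse AI
matrix; fixed effects are GLS at the final variance estimates, with
dummy-coded factors and sequential-rank dropping of aliased columns.
`fit_fixed_effects(..., fix_genetic_zero=True)` pins σ²_g at zero and
reproduces OLS, which the tests verify against statsmodels.

## The synthetic cohorts

`simulate_cohort` draws ancestral frequencies uniform on (0.05, 0.95) and
population frequencies from the Balding–Nichols law
Beta(p(1−F)/F, (1−p)(1−F)/F) with per-population F; genotypes are
Binomial(2, p_pop). The marker map spreads markers uniformly over 22
autosomes with human chromosome-length proportions, scaled by a
configurable factor so desk-scale marker counts keep chip-like densities
(the default studies use scale 0.05 → a 145-Mb genome, ~7 kb spacing at
20,000 markers). Pedigree offspring are produced by gene dropping with
Haldane-model crossovers at 1.2 cM/Mb on the *unscaled* physical length,
free recombination between chromosomes and random phase in founders.
Geographic structure assigns samples to regions (default: six
Scottish-range locations) and re-draws a clinal marker subset with
frequencies shifted per degree of latitude/longitude. Homozygosity
injection rewrites heterozygotes within requested spans (or a whole
chromosome, for isodisomy) by duplicating one random allele.

### The introgression study scenario

`introgression_study` is the canonical detection scenario: 300 host
samples, 20,000 markers, 5 % carriers receiving non-overlapping donor
tracts until 4 % of the genome is covered. Tract lengths are
shifted-exponential with mean 3 Mb, floored at 1.5 Mb and capped at 7 Mb —
sub-megabase segments would reflect old admixture rather than the
few-generations-back foreign ancestor being modelled. Within a tract one
implicit haplotype is redrawn: the new dose is one allele retained from
the host genotype plus one Bernoulli(p_donor) draw (phase is never
modelled globally; the analyses consume doses only).

The donor's frequency architecture matters more than its aggregate
divergence. Detection rests on markers where the host is (nearly)
monomorphic for the common allele while the donor still carries the
alternative — the situation of a population that has kept ancestral
diversity a bottlenecked host has lost. A single symmetric divergence
parameter cannot produce such markers at usable density: host-rare implies
ancestrally rare implies donor-rare. The scenario therefore combines a
symmetric Balding–Nichols background (F = 0.026) with a 15 % marker class
that is bottleneck-lost in the host (frequency exponential, mean 3×10⁻⁴)
and common in the donor (uniform on 0.35–0.80). The class fractions were
chosen so the realised pairwise Hudson F_ST between host and donor is
≈ 0.15 — the divergence of the emulated host/donor contrast — which the
tests assert. At these conditions the rarity-outlier classifier reaches
sensitivity ≥ 0.9 at false-positive rate ≤ 0.01, the Spearman correlation
between true introgressed fraction and called peak coverage exceeds 0.9,
and > 80 % of selected in-tract rare alleles are assigned to the donor by
reference-frequency argmax.

### What the generator does and does not emulate

It reproduces the statistical structure the analyses assume: drift-scaled
frequency divergence, dose-level introgressed haplotypes dense in
host-rare alleles, Mendelian transmission with crossovers, smooth
frequency clines, and homozygous segments. It does not model LD beyond
the injected blocks (`inject_ld_block` writes near-perfect LD regions for
the inversion/MHC analyses), chip ascertainment, genotyping error,
mutation, or phased haplotypes. Passing tests therefore demonstrate that
the estimators and callers recover the structure they target under their
own model assumptions at desk scale — not that real-cohort effect sizes
or error rates are reproduced; real-data thresholds (particularly the
rarity thresholds, see above) must be calibrated to cohort size.

## Problem sizes

The default test and acceptance runs use cohorts of 250–400 samples and
5,000–20,000 markers, 30 REML replicates at n = 400, 1,000 random window
tracks for the peak-caller oracle, and exhaustive ROH oracles on panels of
up to a few thousand markers — sizes chosen so the whole suite runs on a
single CPU in a few minutes while every estimator is still exercised
against an independent oracle.
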