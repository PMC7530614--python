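# Methods

This note documents the models and procedures implemented in `haplosweep`,
the assumptions behind them, the defaults that matter, and what the
synthetic cohorts do and do not establish about real data.

## Data model

All statistics operate on a `HaplotypeDataset`: a variants × haplotypes
matrix of phased biallelic alleles (0 reference, 1 alternate), 1-based
variant positions strictly increasing per chromosome, and per-sample
population / species / karyotype labels inherited by both haplotype
columns of a sample. Genotype dosages (for Rogers–Huff r and PCA) are
obtained by summing the two columns of each sample. Missing or unphased
genotypes are never imputed: VCF records containing them are dropped at
read time and counted in a per-reason tally, because the intended inputs
are fully phased call sets. Multiallelic records are likewise excluded.
Analyses are single-chromosome; multi-chromosome inputs must be subset
with a region first.

Variant filters follow two rules used throughout: *segregating* keeps a
variant iff its alternate-allele frequency strictly exceeds 5% in at least
one population, and *nonsingleton* keeps a variant iff its minor allele is
carried by ≥ 3 haplotypes. Both thresholds are parameters; both filters
are per-variant predicates and therefore commute.

## Sweep statistics

EHH at a flank x is the probability that two haplotypes drawn without
replacement from the group are identical over the closed variant interval
from the core to x; it equals 1 at the core by definition (empty
extension) and is computed independently per direction, which matches the
one-profile-per-side way decay is usually displayed. The *core span* is
the bp distance between the outermost flanks on each side at which EHH
still exceeds 0.95 (threshold configurable); the 0.05 decay points are
reported separately.

Garud's H statistics and haplotype diversity are computed from exact
haplotype-class frequencies in a window. Haplotype diversity uses the
unbiased n/(n−1) estimator so a group of all-distinct haplotypes scores
exactly 1. Moving scans use blocks of 500 variants advancing by 20% of
the block (100 variants) by default; where a source describes the same
scheme as "20% overlap", we read it as 20% *step*, and both numbers are
configurable through `WindowSpec`. The trailing partial window is
dropped. Point estimates over an explicit region carry
leave-one-haplotype-out jackknife means and SEs,
SE = sqrt((n−1)/n · Σ(θᵢ − θ̄)²).

## Diversity and divergence

π is Σ 2p(1−p)·n/(n−1) over variants per accessible base; Dxy is
Σ [p_A(1−p_B) + p_B(1−p_A)] per accessible base. π_N and π_S restrict the
variant sum to effect classes but share one accessible-base denominator,
so π_N/π_S is a pure variant-sum ratio: this sidesteps the per-class site
counts that effect predictors do not supply, changes both absolute values
by the same factor, and leaves every between-group comparison intact.
When no accessibility mask is given, bp windows use the window length as
the denominator.

The Dxy-ratio scan computes dxy(focal, refA)/dxy(focal, refB) in bp
windows (default 20,000 bp advancing 18,000 bp, i.e. 10% overlap).
Ratio < 1 flags windows where the focal group is closer to refA. With
refA = the donor background and refB = the recipients' native background,
the set of ratio<1 windows estimates the introgressed tract; zero-
denominator windows are reported undefined rather than dropped.

## Patterson's D and direction of introgression

Per site, with outgroup-polarised frequencies (sites with p_O > 0.5 are
flipped in all populations),

    num = [p_A(1−p_B) − (1−p_A)p_B] · p_C · (1−p_O)
    den = [p_A(1−p_B) + (1−p_A)p_B] · p_C · (1−p_O)
    D   = Σ num / Σ den.

The sign convention is that D > 0 indicates excess derived-allele sharing
between A and C, D < 0 between B and C. Inference uses a delete-one-block
jackknife over contiguous 100-variant blocks (≥ 3 blocks required; the
trailing partial block merges into the last full one), Z = D/SE and a
two-sided normal p-value floored at machine precision. If every
delete-one estimate coincides the SE is exactly 0; the result carries a
`degenerate_se` flag and a nonzero D is then treated as maximally
significant rather than undefined.

The direction test runs two complementary analyses for a focal allele
shared by species i and j, each restricted to specimens *homozygous* for
the focal allele state (and optionally for a karyotype class), which
avoids mixing resistant and wild-type haplotypes within a sample:
test 1 sets A = resistant-i, B = wild-type-i, C = wild-type-j; test 2
swaps the species. A significantly positive test 1 with a flat test 2
means the resistant haplotypes of species i carry the background of
species j — the allele originated in j. Both significant, both flat, or
any other pattern is inconclusive. No multiple-testing correction is
applied across population pairs; the significance threshold is a
parameter (default α = 0.05).

## Haplotype networks

Exact-duplicate haplotypes are collapsed into classes (multiplicities kept
as node annotations) before computing Hamming distances. The minimum
spanning tree is built by Kruskal's algorithm with deterministic
lexicographic tie-breaking on (weight, node, node); every non-tree edge
whose weight ties the heaviest MST edge on the path it would close is
retained as a *tie edge*, giving a network rather than a strict tree.
Clusters are the connected components of the MST after removing edges with
weight > 3 (strict; configurable); tie edges annotate the display but do
not join components, which keeps the clustering well-defined regardless of
which co-optimal tree Kruskal happened to return. Clusters below 1%
cohort frequency are flagged for display filtering.

## Inversion karyotyping

10,000 random SNPs (seeded, uniform without replacement) are drawn from
the inversion interval after the nonsingleton and segregating filters;
if fewer qualify, all are used with a warning. Dosages are
Patterson-scaled — centred by mean dosage, divided by sqrt(p(1−p)) with
p = mean/2, monomorphic variants dropped — and decomposed by SVD.
Component signs are fixed by forcing the first retained variant's loading
non-negative, so scores are reproducible across runs and sample
orderings. A linear-kernel SVC with C = 1 is trained on the top 10
components of the labelled samples; on linearly separable classes (which
diverged inversion backgrounds produce, with heterozygotes intermediate on
PC1) its training accuracy, precision and recall are all 1.0, and that
behavioural contract — not the particular margin solver — is what the
tests pin down.

## NG86 dN/dS

The Nei–Gojobori (1986) estimator with equal pathway weighting and no
transition/transversion weighting. Fractional site counts assign each of
the nine single-nucleotide changes of a codon 1/3 of a site to its effect
class; changes *to* stop codons count as nonsynonymous, so N + S always
equals 3 × codons (some implementations instead exclude stop-directed
changes from the site denominators, which yields slightly smaller S;
the method name is recorded in all outputs to prevent silent cross-method
comparison). Observed differences are averaged over the minimal
mutational pathways between codons, excluding pathways that traverse a
stop codon unless all do. pN = Nd/N and pS = Sd/S receive the
Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 or pS = 0 yield
NaN with a warning. Gapped or ambiguous codons are masked; internal stops
are rejected. Peptide identity is matches over comparable columns,
excluding only double-gap columns (a single gap is a mismatch).

## Synthetic cohorts

The generator is forward-free: it composes founder haplotypes and copies
them with crossover, realising directly the structures the statistics are
meant to detect, with trivial runtime and exact ground truth. It is not a
coalescent or forward simulator and makes no demographic claims.

Background variation has three components, all seeded and configurable:

- *shared ancestral polymorphism* — a fraction of sites (default 0.3)
  with per-site frequencies drawn Uniform(0.05, 0.95), sampled
  independently per haplotype; the outgroup carries these at ≤ 5% leakage
  so site patterns are polarisable;
- *fixed divergences* — karyotype-diagnostic sites (fixed between the INV
  and STD backgrounds, confined to the inversion interval) and
  species-diagnostic sites (fixed derived in exactly one species).
  Species-level fixed differences are what make interspecific
  allele-frequency contrasts, and hence ABBA–BABA tests, informative;
- *private mutations* — Poisson(10 by default) per haplotype, uniform
  over the remaining sites.

The hard sweep replaces a stated fraction of haplotypes per population
with copies of one founder that carries the core resistance allele and
all linked markers; each copy crosses over with the haplotype it replaced
at an exponential distance (rate = recomb rate per bp) on each side of
the core, so carrier homozygosity decays with distance. Carriers are
allocated sample-major (both copies of a sample before the next), so a
high-frequency sweep produces homozygous specimens — required by the
homozygote-restricted direction test. The founder can be shared across
populations (one origin) or drawn per population (independent origins,
the null for the direction test). Tracts are symmetric around the core;
one-sided decay is produced, where wanted, by the introgression tract,
which is how asymmetric decay arises in the motivating biology.

Introgression events copy the donor founder into n target haplotypes
(chosen in a named population or karyotype background) over
[core − L, core + L), always including the core variant, leaving the
recipients' own background outside. Recovery tests compare recipients'
columns site-by-site against the recorded truth.

The quartet frequency simulator is separate and lighter: under the null,
A and B are independent Binomial(40)/40 perturbations of one shared
ancestral frequency per site, C an independent draw, O a perturbation of
0.02; gene-flow scenarios mix C's frequency into A or B with a stated
weight at every site.

What passing tests show — and do not. The cohorts establish that each
statistic recovers the structure it targets under clean conditions:
correct formulas, correct window/jackknife mechanics, correct direction
logic, calibrated null. They do not establish robustness to LD structure
from real demography, mutation-rate or recombination-rate heterogeneity,
phasing or genotyping error, or unsampled gene flow; absolute values such
as variance-explained fractions in PCA depend on real LD and are not
asserted.

## Problem sizes and numerical choices

Validation runs use desk-scale cohorts chosen to keep the full suite
fast while leaving each effect far from threshold: 50–90 samples,
600–4,000 variants over 60–250 kb, 50-block-plus jackknives for null
calibration (5,000–10,000 quartet sites), 20-seed recovery batches and
100-seed direction-of-effect batches. Degenerate inputs are handled
explicitly rather than silently: monomorphic loci give NaN (with a
warning) in LD, zero denominators give NaN in D and undefined windows in
the Dxy scan, groups below the minimum size raise errors naming the
group, and every tie-break (MST edges, PCA signs) is deterministic.

## Known limitations

- The generator's inversion is a label plus fixed differences: it does not
  suppress recombination mechanistically, so karyotype-aware analyses rely
  on the truth labels rather than emergent LD.
- Patterson's D uses the normal approximation to the jackknife Z; with few
  blocks (< ~20) the test runs slightly liberal, and the block count is
  reported so users can judge.
- π_N/π_S is a variant-sum ratio, not a per-site-class rate ratio;
  compare only within the same convention.
- NG86 pathway counting is exact but assumes equal pathway weights; no
  codon-model ML alternative is provided.
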