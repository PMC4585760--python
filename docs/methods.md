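# Methods

This note documents the models, algorithms, parameters and design
choices behind `rohscan`, in the spirit of a statistical methods
appendix. Everything quantitative stated here is computed by the test
suite or the example scripts; nothing is asserted about real cohorts.

## Data model

A panel is a samples × SNPs matrix of genotype codes (`hom_a1`, `het`,
`hom_a2`, `missing`) with per-sample phenotype labels (case / control /
missing) and a sorted autosomal SNP map (chromosomes 1–22, 1-based
inclusive base-pair coordinates). PLINK text (.ped/.map) and binary
(.bed/.bim/.fam, SNP-major, two bits per call) filesets are read and
written bit-exactly; writing then reading is the identity on genotype
codes and both axis orders. In text input the A1 allele of a SNP is the
lexicographically smaller **observed** allele — a deterministic
convention that matters only for labelling, since every downstream
stage consumes hom/het/missing states, never allele identities.
Non-autosomal records are dropped at read time with a logged count.

## Quality control

The cascade runs in a fixed order: call rates → relatedness → MAF/HWE.

1. **Call rates.** Samples with < 95% called genotypes are removed
   first; SNP call rates are then recomputed on the retained samples
   and SNPs below 95% are removed. The two-pass order means a SNP whose
   only missing calls sat in a removed sample survives.
2. **Relatedness.** Identity by state (IBS) between two samples is the
   fraction of jointly called SNPs with identical genotype codes. Pairs
   with IBS strictly above 0.80 are processed in descending IBS order,
   skipping samples already removed; the lower-call-rate member is
   dropped (ties drop the later index). The greedy order and
   tie-breaks are fixed for determinism; only the pair rule itself is
   prescribed by the underlying analysis.
3. **MAF / HWE.** SNPs with minor allele frequency below 0.05 (over all
   samples, non-missing calls) are removed, as are SNPs whose exact
   Hardy-Weinberg test falls below P = 10⁻⁵ in *either* the cases or
   the controls. The HWE test enumerates every heterozygote count
   compatible with the observed allele counts and sums the
   probabilities of configurations no more probable than the observed
   one; the conditional distribution is computed in log space and
   normalised, and the enumeration is verified against exact rational
   arithmetic in the tests. The exact test is used rather than the
   asymptotic chi-square because it is the field standard, behaves at
   small counts, and is testable by enumeration; for balanced counts in
   the hundreds per class the two agree within ~10% relative.

A PCA ancestry screen is provided as a separate stage: genotypes are
mean-imputed, centred and scaled by √(2p(1−p)) per SNP (monomorphic
SNPs skipped), the top components are taken from an SVD, and a sample
is flagged when any component coordinate exceeds a configurable number
of per-component standard deviations (default 6). Without external
reference panels this is a gross-outlier screen, not an ancestry
assignment, which is why the default is permissive.

Re-running the cascade on its own output is the identity under the
simulated study conditions; this is a property test, not a theorem —
adversarial inputs near a threshold could flip on the second pass
because call rates and MAF shift as rows/columns are removed.

## Chance-run calibration

Under a null of independent SNP calls that are heterozygous with
probability *h*, the expected number of all-homozygous length-*L*
windows across *S* SNPs and *N* individuals is approximated by

    E[chance runs] = (1 − h)^L · S · N

(a window-count approximation; no run-boundary correction). The
minimum informative run length is the smallest integer *L* with
E < α (default α = 0.05). At the scale of a large GWAS panel
(S = 484,072, N = 5,788, h = 0.34) this gives L = 60 with
E[60] ≈ 0.0417. SNP-array markers are correlated, so 60 *independent*
calls correspond to more SNPs: with T tag groups after LD pruning the
package computes ⌈L · S / T⌉, which is 80 for T = 363,152 (a 25%
information reduction). The pipeline's default minimum segment size is
pinned at 84 SNPs — the conventional, slightly more conservative
choice at this scale — while the ceiling-based value remains available
from `ld_adjusted_length`.

The null model itself is exercised by simulation: on iid panels the
observed count of fully homozygous L-windows is compared with
(S − L + 1)(1 − h)^L · N. Because overlapping windows cluster into
runs, the count is over-dispersed relative to Poisson (a run of length
L + G contributes G + 1 windows), so a 3-Poisson-SD band is a
reasonably tight but not exact calibration check; the fixed-seed tests
sit comfortably inside it.

## ROH calling

Per sample and chromosome, every window of W = 50 consecutive SNPs is
scored; a window passes when it has at most H = 1 heterozygous (2% of
W) and at most M = 5 missing calls. Each SNP's score is the fraction
of windows containing it that pass, and the SNP is flagged when the
score reaches the flag threshold (default 0.05). Maximal runs of
flagged SNPs are split where adjacent SNPs lie more than 1000 kb
apart, then emitted as segments when they have ≥ 84 SNPs, span
≥ 1000 kb and average ≤ 50 kb per SNP (each criterion can be disabled).
Gap splitting precedes the size criteria; the order is fixed for
determinism. The heterozygote allowance exists to absorb genotyping
error and other artificial heterozygosity inside truly homozygous
tracts, so an isolated het inside a passing region is included in the
segment and counted in its `NHET`.

Two consequences of the window-score rule are worth knowing. First,
with threshold 0.05 and W = 50 an interior SNP needs ≥ 3 passing
windows, so a called segment starts and ends 2 SNPs inside the
underlying homozygous run (runs abutting a chromosome end are covered
by fewer windows and not trimmed there). Second, a called run extends
outward to the first flanking heterozygote — a geometric overshoot of
mean ≈ (1−h)/h SNPs — and can continue across isolated hets. Recovery
of planted tracts is therefore tested as: ≥ 95% of planted segments
are recovered, each recovered call covers the planted interval up to
the 2-SNP trim, and unplanted samples yield no calls; an exact ≤ 2-SNP
boundary-error guarantee is not attainable under this model and is not
claimed. With H = M = 0 and the gap/length/density criteria disabled,
the caller reduces exactly to a maximal-homozygous-run scanner for
runs ≥ W when the flag threshold is ≤ 1/W, and agrees with that
scanner on iid null panels at the default threshold; both equivalences
are tested against explicit-loop oracles.

## Consensus ROH

Individual segments are recoded into a binary indicator (1 = SNP
inside an ROH for that sample). The prune/trim procedure is then:

1. zero every SNP column with fewer than `min_carriers` (default 10)
   ones;
2. per sample, delete indicator runs now shorter than `min_snps`
   (default 75; runs never span chromosomes);
3. recompute column counts; candidate regions are the maximal
   per-chromosome intervals with count ≥ `min_carriers` and length
   ≥ `min_snps`;
4. trim each candidate to the sub-interval of ≥ `min_snps` SNPs that is
   covered end-to-end by the **largest** number of samples (ties:
   longer, then leftmost). Those samples are the region's carriers.

Step 4 is this package's resolution of a genuinely open corner: when
individual runs only partially overlap a high-count interval
(boundaries are staggered, as they always are in practice because run
ends drift to each sample's nearest heterozygote), the untrimmed
interval is typically covered end-to-end by almost nobody, which would
make carrier counts meaningless. The max-carrier core restores the
defining property of a common ROH — at least `min_snps` consecutive
calls shared by at least `min_carriers` samples with identical start
and end — while agreeing with the naive procedure whenever runs are
aligned. If no sub-interval reaches `min_carriers` full-coverage
carriers, the untrimmed interval is reported with a `low_coverage`
flag. Regions are numbered `ROH1`, `ROH2`, … in genome order. An
any-overlap carrier definition is deliberately *not* the default: it
would break the identical-boundary property; the carrier table is
always full-coverage with respect to the reported (trimmed) interval.

The implementation is verified against an exhaustive explicit-loop
reference (all sub-intervals enumerated) on random indicator matrices
and a hand-traced staggered fixture, and is idempotent on its own
output. One caution: the number of consensus regions is **not**
monotone in `min_carriers` — raising the threshold can zero bridge
columns and split one interval into two — so no such monotonicity is
claimed or tested.

## Association and burden statistics

Each consensus ROH yields a 2×2 table of carrier status by phenotype.
The test is the Pearson chi-square with 1 df and no continuity
correction — chi² = n(ad − bc)² / ((a+b)(c+d)(a+c)(b+d)) — which
reproduces printed statistics from published carrier tables far more
closely than corrected variants; a Yates-corrected version is
available behind a flag. The odds ratio is ad/bc (infinite when
bc = 0); a zero column margin returns an explicit degenerate marker.
Results carry a Bonferroni flag (p < 0.05 / number of regions) and the
subset below p = 0.01 is reported separately, matching the
conventional reporting threshold for this analysis.

The genome-wide burden comparison is a pooled-variance two-sample
Student t-test on per-individual consensus-ROH counts (df =
n₁ + n₂ − 2; Welch available behind a flag). Cumulative distributions
are survival curves of per-individual total called-ROH length — at
each observed x, the fraction of the group with total ≥ x — with the
supremum distance between the case and control curves reported; a
count-based curve can be built the same way since the underlying
counts are exposed. Autosome coverage is the union of consensus
intervals (1-based inclusive, overlaps merged) divided by the summed
chromosome lengths; the pipeline uses the last SNP position per
chromosome as the observed chromosome length.

Under the null (equal carrier frequencies) the chi-square's type-I
error at nominal 0.05 stays within the exact binomial 99% interval
across 500 replicate tables at realistic carrier frequencies; this is
checked by simulation.

## Synthetic panels

The generator emulates the statistical structure the analysis assumes,
not any particular cohort:

* **Allele frequencies** per SNP from U(0.05, 0.48).
* **LD** from finite haplotype pools: SNPs are grouped into blocks of
  20, a pool of 20 haplotypes is drawn per block from the SNP
  frequencies, and each individual draws two pool haplotypes per
  block. Expected heterozygosity is E[2p(1−p)]·(1 − 1/K) ≈ 0.34 with
  these defaults — the MAF range is the heterozygosity dial, chosen
  once to match the ~0.34 of a typical outbred control series. This
  produces correlated adjacent SNPs (what the tag-group correction
  exists for) but no recombination-map realism.
* **Marker spacing** uniform 10–30 kb (mean 20 kb), so that an 84-SNP
  segment spans ~1.7 Mb and clears the 1000 kb length criterion; real
  arrays are denser but the analysis depends on SNP counts, not
  physical density.
* **Background autozygosity**: with probability 0.10 an individual
  receives one autozygous tract of 90–140 SNPs at a uniform position —
  a single pool haplotype copied over both chromosomes.
* **Risk ROH**: carriers are drawn Bernoulli per group (defaults 15%
  of 500 cases, 8% of 500 controls) and receive an autozygous tract
  spanning exactly the configured region. Case/control status is
  assigned through these carrier frequencies directly rather than via
  a liability model, matching the 2×2 analysis.
* **Noise**: each genotype flips to one of the other two codes with
  probability 0.002 (the symmetric error model that creates the
  artificial heterozygosity the window allowance absorbs) and is set
  missing with probability 0.01.

Everything is reproducible from the seed, including byte-identical
PLINK exports. What passing tests on these panels do **not** show:
behaviour under real LD decay, allele-frequency spectra, batch effects
between differently genotyped case and control series, or population
structure beyond the two-subpopulation PCA fixtures.

## Problem sizes and numerical choices

The test suite uses deliberately modest sizes chosen to preserve each
property being tested: null-calibration panels of 200 × 50,000 (where
the expected window count ≈ 38.6 is large enough for a meaningful
band), oracle-equivalence panels of 50 × 1,000, consensus oracles on
20 × 200 indicators, and 200 replicates of the 500/500 × 2,000
planted-risk design (where the planted region's expected chi-square
≈ 10–14 dominates null competitors). Scoring uses integer cumulative
sums; the flag comparison `n_pass ≥ threshold · n_cover` is evaluated
with a 10⁻⁹ slack so exact-threshold windows flag deterministically
across platforms. The HWE p-value is floored at the smallest positive
float and capped at 1. Ceiling division in `ld_adjusted_length` uses
integer arithmetic to avoid floating-point edge cases.

## Known limitations

* The chance-run formula is a window-count approximation; it slightly
  overcounts expected runs relative to a boundary-corrected formula.
* The caller is the window heuristic, not an HMM; no phasing, no
  X chromosome, no CNV awareness.
* IBS pruning is a plain genotype-identity measure, not a kinship
  estimator; it flags duplicates and near-duplicates, not subtle
  relatedness.
* The PCA screen cannot assign ancestry without reference panels.
* Consensus carrier status requires full coverage of the trimmed core;
  individuals whose runs cover most but not all of a region are not
  counted as carriers, which is conservative for association.
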