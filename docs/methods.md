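# Methods

This note documents the statistical models implemented in `fundusnp`, the
defaults and why they were chosen, the design decisions taken where more
than one reading was defensible, what the synthetic-data generators do and
do not emulate, and the problem sizes at which the test suite and the
calibration script exercise the pipeline.

## Read-level filters

Reads carry a fixed-length 5′ barcode identifying the individual.
Demultiplexing is an exact prefix match by default (`max_barcode_mismatch
= 0`); a read is assigned only when exactly one barcode matches within the
allowed mismatch count, so ties are left unassigned rather than guessed.
Only the barcode is trimmed; any primer tail downstream of it is left on
the read, since trimming it is an assembly-stage concern.

Two sequence filters follow, in this order: (1) any read containing an
ambiguous base (N) is removed — a single N is a strong indicator of a
low-quality read; (2) reads shorter than `min_read_length` (default 100 bp)
are removed, "shorter than" being strict so a 100-bp read is kept. A short
read containing an N is counted in the ambiguity category. The counts
partition the input exactly, which the suite checks as a property.

## Individual-level genotype model

At one pileup position within one individual, observed bases Y₁…Y_N carry
error probabilities e_j = 10^(−Q_j/10). Q = 0 gives a raw "error
probability" of 1, which is not meaningful for a four-letter alphabet, so
e_j is capped at 0.75 — the value at which a base becomes uninformative
(uniform over the four nucleotides) rather than anti-informative.

The major allele A is the modal observed base (ties broken alphabetically
for reproducibility) and the minor allele a the second most frequent.
Likelihoods are

* homozygous for A: each copy reads A with probability 1 − e_j, otherwise
  one of the three remaining bases with probability e_j/3 each;
* heterozygous A/a: each copy first draws a true allele (½ each), so bases
  in {A, a} are emitted with probability ½(1 − e_j) + ½·e_j/3 and the
  remaining two bases with e_j/3.

The posterior uses a prior probability of heterozygosity of 10⁻⁴ (the
per-site mutation-rate scale appropriate for a vertebrate genome screen);
the locus is classified heterozygous when the posterior exceeds ½. All
products are accumulated in log space, so the computation is underflow-free
to depths far beyond anything a pileup will present (~10⁵ copies).

### Allele-balance LRT

Heterozygote classifications are confirmed by a likelihood-ratio test on
the informative copies (those reading A or a). The probability of reading
the major allele is π_j(p) = p(1 − e_j) + (1 − p)e_j, where p is the major
allele's frequency among the true copies; the test is H₀: p = 0.5 versus
H_a: p > 0.5, with p̂ found by bounded scalar maximisation on [0.5, 1]
(the log-likelihood is concave, and the closed form is available only when
all e_j are equal). −2·LRT is referred to χ²(1). Because the MLE sits on
the boundary under H₀, the true null is the mixture ½χ²(0) + ½χ²(1) and the
χ²(1) reference is conservative — its realised size at nominal 0.05 is
about 0.025, which the suite verifies by simulation. The mixture reference
is available as `lrt_null = "mixture"` for users who want nominal size.

A rejection means the site is skewed toward one allele, the signature of a
sequencing-error pile on a homozygote, so the default policy
(`lrt_rejection_to_hom = True`) reverts the call to homozygous. The
opposite policy — keeping the Bayesian heterozygote — is a configuration
flag, since either direction is defensible; the default is the one that
suppresses false heterozygotes, consistent with the pipeline's overall
conservatism about duplicated loci.

## Population-level detection

All copies at a position, pooled across individuals, are screened against a
simulated error-only null: assuming the site homozygous for its major
allele, each copy misreads with its own e_j (replicate r reuses the data's
positional e₁…e_N — no averaging) and a misread lands uniformly on the
three other bases. The test statistic is the copy count of the most
frequent non-major base ("second-allele count"); an alternative statistic,
the total of all non-major copies, is available as `second_mode =
"all_nonmajor"`. The null uses 10,000 replicates and the critical value c
is the smallest count whose empirical right tail is ≤ 0.001; a site is
flagged when its observed count is ≥ c. With an error-free null the
distribution is degenerate at zero and c = 1, so any observed second allele
is significant. Because the statistic is discrete, the realised tail at c
is typically well below the nominal 0.001 (at N = 50 copies and Q = 20 it
is ≈ 10⁻⁴), so the detector's measured false-positive rate on error-only
loci sits comfortably under the nominal level — the calibration the
acceptance script measures.

Each locus draws its replicates from an RNG stream keyed by (seed, contig,
position), so results are independent of processing order and the whole
stage is bit-reproducible.

### Homolog filters

Candidates passing the null are filtered against artifacts caused by
co-assembled duplicated loci. The implemented rules: at least
`min_indiv_2x` = 3 individuals covered at 2× at the site; no other
null-passing candidate within `proximity_bp` = 5 bases (inclusive, same
contig only); and an individual-level heterozygote fraction not above
`max_het_fraction` = 0.90. The sentence combining these rules admits two
grammatical readings, so both are implemented: the default "conservative"
mode requires all three conditions (matching the stated goal of minimising
homolog false positives), while "literal" mode waives the coverage
requirement when the proximity or heterozygosity clause holds. The default
is a package decision, not a claim about the original authors' intent.

## Genotype-matrix QC

Loci are removed when: the call rate is not strictly greater than 0.90;
more than half of the individuals' genotypes carry a low-probability flag
from the typing software; the missing fraction exceeds the per-analysis
group cap (0.05 for the focal species whose markers were ascertained
in-sample, 0.10 for cross-species panels — a parameter, not a hard-coded
species name); or the locus shows excess heterozygosity. "Excessive
heterozygosity" is not a quantified published threshold, so the screen
requires both pooled H_O > 0.60 and H_O > H_E within every population where
the locus has data; the 0.60 default is chosen to be well above anything a
biallelic locus can sustain at equilibrium (max 0.5 at p = 0.5) while not
firing on ordinary sampling noise, and is exposed in the configuration.

## Population-genetic estimators

* **H_E** uses the small-sample correction 2p̂q̂ · 2n/(2n − 1), unbiased
  under Hardy-Weinberg sampling; the suite verifies unbiasedness by
  simulation at p ∈ {0.1, 0.3, 0.5}.
* **F (= F_IS)** is 1 − H̄_O/H̄_E over polymorphic loci (ratio of means);
  the per-locus-average alternative is a configuration option. Its
  significance comes from permuting the 2n called allele copies among
  individuals within the population, independently per locus — which
  preserves allele counts (H_E is invariant) and destroys only the
  within-individual pairing — with a two-sided p-value and the standard
  +1/(n_perm + 1) correction, default 10,000 permutations.
* **HWE** uses the exact conditional test: given n and the minor-allele
  copy count, the p-value sums the probabilities of all heterozygote counts
  no more probable than the observed one. The reported "% departing HWE"
  counts polymorphic loci with p < 0.05, uncorrected (the denominator is
  polymorphic loci, since the test is degenerate for monomorphic ones).
* **AMOVA** decomposes allele-copy variance (0/1 mismatch distances, the
  frequency-based form appropriate for biallelic SNPs) into among-region,
  among-population-within-region and within-population components using the
  classical unbalanced nested mean-square equations, per locus, with
  components summed over loci and Φ_CT, Φ_SC, Φ_ST derived from the sums.
  Negative component estimates are reported as-is with a flag, never
  silently truncated. Permutation p-values move individuals among all
  populations (Φ_ST), individuals among populations within regions (Φ_SC),
  and whole populations among regions (Φ_CT). With a single region the
  analysis collapses to the two-level design.
* **F_ST** is the Weir–Cockerham θ estimator, multi-locus as a ratio of
  summed components, symmetric in the pair and allowed to be slightly
  negative by sampling error. The distance matrix used for Mantel clips
  negatives to zero.
* **Mantel** correlates upper-triangle entries (Pearson) and permutes rows
  and columns of the genetic matrix jointly; one-sided "greater" by
  default, since isolation by distance predicts a positive correlation.
  The implementation is cross-checked against scikit-bio's Mantel test in
  the suite.

## Synthetic data

The pileup generator emits allele copies with exactly the emission model
the caller assumes (hom: 1 − e correct, e/3 per alternative; het: equal
allele mixture) over short contigs (default 240 bp, the scale of
reduced-representation pyrosequencing contigs), with per-copy qualities
Normal(20, 3) rounded into [5, 45] — the Phred-20 scale of the target
platform — per-individual site depth Poisson, and Hardy-Weinberg genotypes
at SNP sites. It does **not** emulate platform-specific artifacts:
homopolymer indel errors, flowgram noise, chimeric reads, mapping or
assembly error, or quality-score miscalibration. Passing round-trip tests
therefore demonstrates correctness of the inference given the assumed error
model, not robustness to 454-specific artifact classes.

The genotype-matrix generator controls differentiation with the
Balding–Nichols beta model (population frequency ~ Beta around its anchor
with variance F·p(1 − p)), chosen over coalescent simulation because it
gives direct design-F_ST control with analytic expectations and no
additional dependency. Region-level divergence uses the same model at
F_CT, under which the expected among-region AMOVA fraction equals F_CT.
Isolation by distance is a Gaussian copula across populations arranged on a
linear transect: correlated standard normals with corr = exp(−d/ℓ)
(d = population index distance, ℓ = `ibd_decay`) are pushed through each
population's Balding–Nichols quantile function, so every marginal keeps its
design differentiation while nearby populations stay similar. Missingness
is uniform at random (not platform-structured), and ascertainment bias is
emulated by forcing a chosen fraction of loci monomorphic for the
ancestral-major allele in designated regions, leaving truth labels
elsewhere untouched.

## Problem sizes and numerical choices

The suite and calibration script run at desk scale, with sizes chosen so
Monte-Carlo bounds are meaningful: error-null calibration at 200,000
error-only loci (N = 50 copies, Q = 20) against the 10,000-replicate null;
caller recovery on 1,000 homozygous + 1,000 heterozygous simulated loci at
20× and Q = 20 (observed: ≥99 % / ≥95 % correct); LRT size from 10,000
balanced-heterozygote simulations at depth 30; θ recovery at design F_ST ∈
{0.05, 0.2, 0.44} with 2 × 20 individuals and 300 loci (tolerance ±0.05);
AMOVA region-fraction recovery at F_CT = 0.3 with 2 regions × 2 populations
× 30 individuals and 600 loci (±5 percentage points); Mantel calibration
over 200 independent replicates and power at the documented settings — 8
linear populations, 20 individuals each, 200 loci, F_ST = 0.15, ℓ = 2.0,
999 permutations — where p < 0.01 in ≥90 % of replicates.

Numerical details worth knowing: posterior and LRT arithmetic is in log
space; the LRT maximiser uses bounded Brent with xatol 10⁻⁸–10⁻¹⁰ and the
statistic is floored at 0; modal-allele ties break alphabetically;
permutation p-values always use the +1 correction so they are never 0;
exact-test probabilities are computed via log-gamma and renormalised; the
HWE comparison uses a 1 + 10⁻¹² relative tolerance when summing "as or less
probable" configurations to absorb floating-point ties. Degenerate inputs
are defined rather than accidental: empty pileups yield NOCALL, monomorphic
populations make F undefined (an error, not a NaN), loci with no called
copies drop out of AMOVA sums, and an error-free null flags any observed
second allele.

## Known limitations

Contig assembly and quality rescaling are out of scope — the pipeline
starts from pileups. The individual caller is strictly biallelic within an
individual (third alleles at a site are treated as errors), and there is no
indel model. AMOVA significance for Φ_CT is limited by the number of
distinct population-to-region assignments when regions are few. The
estimators are standard published forms; numerical identity with any
particular legacy software package (e.g. Arlequin's internal variants) is
not claimed.
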