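# fundusnp

SNP discovery and population genetics for reduced-representation sequencing
panels in non-model fish.

`fundusnp` reimplements, as a tested library and command-line pipeline, the
two-level variant-detection design used for barcoded 454-style pyrosequencing
of *Fundulus* killifish, together with the downstream population-genetic
analysis of the resulting biallelic SNP genotype matrices. It is aimed at
population geneticists who have (a) demultiplexable reads or per-contig
pileups with per-base Phred qualities and (b) individuals × loci genotype
matrices with population and region labels, and who want the whole chain —
from raw base calls to F-statistics and isolation by distance — reproducible
from a single seed.

## What it computes

**Read QC.** Barcode demultiplexing (exact or mismatch-tolerant prefix
match, ties unassigned), removal of reads containing any ambiguous base, and
removal of reads shorter than 100 bp (ambiguity checked first).

**Individual-level genotype calling.** At each pileup position within an
individual, with observed bases Y₁…Y_N and Phred-derived error probabilities
e_j = 10^(−Q/10) (capped at 0.75), the locus is called homozygous or
heterozygous from the posterior

    L_hom = ∏_j [ (1−e_j)           if Y_j = A, else e_j/3 ]
    L_het = ∏_j [ ½(1−e_j) + ½e_j/3 if Y_j ∈ {A, a}, else e_j/3 ]
    P(het | data) = π L_het / (π L_het + (1−π) L_hom),   π = 10⁻⁴

where A and a are the two most frequent observed bases. Heterozygote calls
are confirmed by a likelihood-ratio test of allele balance: with
π_j(p) = p(1−e_j) + (1−p)e_j the probability of reading the major allele,
the test is H₀: p = 0.5 against H_a: p > 0.5, −2·LRT referred to χ²(1).
Rejection (a site skewed toward one allele) reverts the call to homozygous
by default.

**Population-level SNP detection.** All copies at a position are pooled; a
Monte-Carlo null (default 10,000 replicates) simulates pure sequencing error
(each copy misreads with its own e_j, uniformly over the three other bases)
and the count of the most frequent non-major base ("second allele") is
compared with the null's 0.001 right-tail critical value. Candidates then
pass homolog-artifact filters: ≥3 individuals covered at 2×, no other
candidate within 5 bp on the same contig, and not >90 % of individuals
called heterozygous (a "literal" alternative reading, where the latter two
clauses waive the coverage rule, is selectable).

**Population genetics.** Marker QC (call rate >90 %, low-probability
genotype fraction, per-group missingness caps, excess-heterozygosity
screen); per-population percent polymorphic loci P_O, observed and unbiased
expected heterozygosity H_O and H_E = 2p̂q̂·2n/(2n−1), fixation index
F = 1 − H_O/H_E with a 10,000-permutation test; the exact conditional
Hardy-Weinberg test; fixed-difference classification across species;
hierarchical AMOVA (regions / populations / within) with Φ-statistics and
permutation p-values; multi-locus Weir–Cockerham θ (F_ST); and a Mantel
test of isolation by distance.

**Synthetic data.** Generators for pileups with known genotypes and
Phred-scale errors, and for structured genotype matrices (Balding–Nichols
differentiation, region-level divergence, stepping-stone isolation by
distance via a Gaussian copula, missingness, ascertainment-bias
monomorphism) — each with a truth table, so every stage of the pipeline is
testable without external data.

## Worked example

```sh
fundusnp simulate genotypes --out demo --seed 3 --n-loci 30 --inds-per-pop 8
fundusnp popgen summary --genotypes demo/genotypes.csv \
    --out demo/summary.csv --perms 1000 --seed 1
fundusnp popgen mantel --genotypes demo/genotypes.csv \
    --geo demo/geo_dist.csv --perms 999 --seed 1
```

The summary CSV contains one row per population. For the simulated demo
(two regions × three populations, design F_ST = 0.1), the first rows are:

```
population,n_individuals,n_loci,P_O,H_O,H_E,F,F_pvalue,pct_hwe_departure
pop1,8,26,88.4615,0.298077,0.315385,0.054878,0.537463,4.34783
pop2,8,25,84,0.355,0.349,-0.017192,0.859141,0
```

`P_O` is the percentage of loci segregating in that population; `H_O` and
`H_E` the mean observed and expected heterozygosity; `F` the
within-population fixation index (positive = heterozygote deficit), with its
allele-permutation p-value; and the last column the percentage of
polymorphic loci rejecting the exact Hardy-Weinberg test at 0.05. The
Mantel command prints the matrix correlation between pairwise θ and
geographic distance and its one-sided permutation p-value
(`r = 0.2473  p = 0.198` for this small demo — 30 loci is far below the
power settings documented in `docs/methods.md`).

The full pipeline (`fundusnp run --pileup ... --genotypes ... --out run/`)
writes per-stage tables, a minimal VCF, and a manifest with input checksums;
re-running with the same config and seed reproduces every output
byte-for-byte.

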