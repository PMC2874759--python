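"""Synthetic inputs with the statistical structure the pipeline assumes.

Two generators are provided, each with a truth table so downstream tests are
self-grading:

* :func:`simulate_pileups` emits multi-individual pileups over short contigs
  (default 240 bp, the scale of reduced-representation pyrosequencing
  contigs) with Phred-20-scale base errors and a mixture of homozygous and
  heterozygous genotypes at SNP sites.  Base emission uses exactly the model
  the caller assumes: a homozygote emits its allele with probability 1 - e
  and each other base with e/3; a heterozygote draws one of its two alleles
  with probability 1/2 first.

* :func:`simulate_genotype_matrix` emits multi-population biallelic genotype
  matrices with Balding-Nichols differentiated allele frequencies
  (design-F_ST controlled), optional region-level divergence (F_CT),
  optional stepping-stone isolation-by-distance correlation between
  population frequencies (a Gaussian copula with exponentially decaying
  correlation preserves the Balding-Nichols marginals), uniform missingness,
  and ascertainment-bias-style forced monomorphism in designated groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .popgen import MISSING, GenotypeMatrix

__all__ = [
    "PileupSimConfig",
    "PopSimConfig",
    "simulate_site_copies",
    "simulate_pileups",
    "simulate_genotype_matrix",
    "geographic_distances",
]

BASES = np.array(["A", "C", "G", "T"])


@dataclass
class PileupSimConfig:
    """Configuration for the pileup generator.

    ``mean_coverage`` is the Poisson mean of per-individual depth at each
    site.  ``snp_density`` is the per-bp probability that a site is a true
    SNP; at SNP sites each individual's genotype is drawn at Hardy-Weinberg
    from a minor-allele frequency uniform on ``maf_range``.  Qualities are
    Normal(``q_mean``, ``q_sd``), rounded and clipped to [5, 45].
    """

    n_contigs: int = 5
    contig_length: int = 240
    n_individuals: int = 8
    mean_coverage: float = 3.0
    snp_density: float = 0.01
    maf_range: tuple[float, float] = (0.2, 0.5)
    q_mean: float = 20.0
    q_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_contigs, self.contig_length, self.n_individuals) < 1:
            raise ValueError("counts must be positive")
        if not 5.0 <= self.q_mean <= 45.0:
            raise ValueError("q_mean must lie in [5, 45]")
        if not 0.0 <= self.snp_density <= 1.0:
            raise ValueError("snp_density must lie in [0, 1]")


def _draw_qualities(n: int, q_mean: float, q_sd: float, rng: np.random.Generator) -> np.ndarray:
    q = np.rint(rng.normal(q_mean, q_sd, size=n))
    return np.clip(q, 5, 45).astype(int)


def simulate_site_copies(
    genotype: tuple[str, str],
    n_copies: int,
    qualities: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Emit observed bases for ``n_copies`` reads of one site in one individual.

    ``genotype`` is the pair of true alleles (equal for a homozygote).  Each
    copy first picks a true allele (1/2 each), then misreads with
    probability e = 10**(-Q/10), landing uniformly on the three other bases.
    """
    alleles = np.asarray(genotype)
    true_idx = rng.integers(0, 2, size=n_copies)
    true_bases = alleles[true_idx]
    e = 10.0 ** (-np.asarray(qualities, dtype=float) / 10.0)
    err = rng.random(n_copies) < e
    out = true_bases.copy()
    if err.any():
        for i in np.nonzero(err)[0]:
            others = BASES[BASES != true_bases[i]]
            out[i] = others[rng.integers(0, 3)]
    return out


def simulate_pileups(cfg: PileupSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a pileup table and its truth table.

    Returns ``(pileup, truth)``: the pileup has columns contig, pos,
    individual, base, phred (one row per observed allele copy); the truth
    table has one row per individual per SNP site with columns contig, pos,
    individual, allele1, allele2, zygosity, maf.  Non-SNP sites are
    monomorphic for the contig's reference base.  Deterministic given
    ``cfg.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x51A7]))
    pileup_rows: dict[str, list] = {
        "contig": [], "pos": [], "individual": [], "base": [], "phred": []
    }
    truth_rows: dict[str, list] = {
        "contig": [], "pos": [], "individual": [], "allele1": [], "allele2": [],
        "zygosity": [], "maf": [],
    }
    individuals = [f"ind{i + 1}" for i in range(cfg.n_individuals)]
    for c in range(cfg.n_contigs):
        contig = f"contig{c + 1}"
        ref = rng.choice(BASES, size=cfg.contig_length)
        is_snp = rng.random(cfg.contig_length) < cfg.snp_density
        for pos in range(cfg.contig_length):
            major = ref[pos]
            if is_snp[pos]:
                minor = rng.choice(BASES[BASES != major])
                maf = rng.uniform(*cfg.maf_range)
            depths = rng.poisson(cfg.mean_coverage, size=cfg.n_individuals)
            for i, ind in enumerate(individuals):
                if is_snp[pos]:
                    n_minor = rng.binomial(2, maf)
                    genotype = (major, minor) if n_minor == 1 else (
                        (minor, minor) if n_minor == 2 else (major, major)
                    )
                    truth_rows["contig"].append(contig)
                    truth_rows["pos"].append(pos)
                    truth_rows["individual"].append(ind)
                    truth_rows["allele1"].append(genotype[0])
                    truth_rows["allele2"].append(genotype[1])
                    truth_rows["zygosity"].append(
                        "HET" if genotype[0] != genotype[1] else "HOM"
                    )
                    truth_rows["maf"].append(maf)
                else:
                    genotype = (major, major)
                depth = int(depths[i])
                if depth == 0:
                    continue
                quals = _draw_qualities(depth, cfg.q_mean, cfg.q_sd, rng)
                bases = simulate_site_copies(genotype, depth, quals, rng)
                pileup_rows["contig"].extend([contig] * depth)
                pileup_rows["pos"].extend([pos] * depth)
                pileup_rows["individual"].extend([ind] * depth)
                pileup_rows["base"].extend(bases.tolist())
                pileup_rows["phred"].extend(quals.tolist())
    return pd.DataFrame(pileup_rows), pd.DataFrame(truth_rows)


@dataclass
class PopSimConfig:
    """Configuration for the structured genotype-matrix generator.

    ``fst`` is the Balding-Nichols design differentiation of population
    frequencies around their region frequency; ``fct`` the region-level
    divergence around the ancestral frequency.  ``ibd_decay`` (in units of
    population index distance along the sampling transect) switches on
    stepping-stone correlation: population frequency draws share a Gaussian
    copula with correlation exp(-d/ibd_decay), so nearby populations are
    more similar while every marginal stays Balding-Nichols at ``fst``.
    ``monomorphic_fraction`` forces that fraction of loci monomorphic (for
    the ancestral-major allele) in populations of ``monomorphic_regions``,
    emulating ascertainment bias.
    """

    n_regions: int = 2
    pops_per_region: int = 3
    inds_per_pop: int = 20
    n_loci: int = 300
    maf_range: tuple[float, float] = (0.05, 0.5)
    fst: float = 0.1
    fct: float = 0.0
    ibd_decay: float | None = None
    missing_rate: float = 0.02
    monomorphic_fraction: float = 0.0
    monomorphic_regions: tuple[str, ...] = ()
    pop_spacing_km: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst < 1.0 and 0.0 <= self.fct < 1.0):
            raise ValueError("fst and fct must lie in [0, 1)")
        if not 0.0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5]")
        if min(self.n_regions, self.pops_per_region, self.inds_per_pop, self.n_loci) < 1:
            raise ValueError("counts must be positive")


def _balding_nichols(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """Draw descendant frequencies around p with differentiation f."""
    if f == 0.0:
        return p.copy()
    shape = (1.0 - f) / f
    return rng.beta(np.maximum(p * shape, 1e-9), np.maximum((1.0 - p) * shape, 1e-9))


def _bn_copula(
    p_anc: np.ndarray, f: float, corr: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Correlated Balding-Nichols draws: Gaussian copula with Beta marginals.

    Returns an array (n_pops, n_loci).  With ``f == 0`` every population
    gets the ancestral frequency.
    """
    n_pops = corr.shape[0]
    if f == 0.0:
        return np.tile(p_anc, (n_pops, 1))
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(n_pops))
    z = chol @ rng.standard_normal((n_pops, p_anc.size))
    u = norm.cdf(z)
    shape = (1.0 - f) / f
    a = np.maximum(p_anc * shape, 1e-9)
    b = np.maximum((1.0 - p_anc) * shape, 1e-9)
    return beta_dist.ppf(u, a[None, :], b[None, :])


def geographic_distances(pop_names: list[str], spacing_km: float = 50.0) -> pd.DataFrame:
    """Distance matrix for populations spaced evenly along a linear transect."""
    n = len(pop_names)
    idx = np.arange(n, dtype=float)
    d = np.abs(idx[:, None] - idx[None, :]) * spacing_km
    return pd.DataFrame(d, index=pop_names, columns=pop_names)


def simulate_genotype_matrix(
    cfg: PopSimConfig,
) -> tuple[GenotypeMatrix, dict]:
    """Generate a structured genotype matrix and its truth parameters.

    Populations are laid out on a linear transect (regions in order, pops
    within regions in order).  Per locus: ancestral frequency ~ Uniform on
    ``maf_range``; region frequencies by Balding-Nichols at ``fct``;
    population frequencies by Balding-Nichols at ``fst`` around the region
    frequency, with stepping-stone correlation when ``ibd_decay`` is set;
    genotypes at Hardy-Weinberg within each population; missingness uniform
    at random.  The truth dict carries the ancestral and population
    frequencies, forced-monomorphic flags and the geographic distance
    matrix.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x9E1D]))
    n_pops = cfg.n_regions * cfg.pops_per_region
    region_names = [f"region{r + 1}" for r in range(cfg.n_regions)]
    pop_names = [
        f"pop{r * cfg.pops_per_region + s + 1}"
        for r in range(cfg.n_regions)
        for s in range(cfg.pops_per_region)
    ]
    region_of_pop = np.repeat(np.arange(cfg.n_regions), cfg.pops_per_region)

    p_anc = rng.uniform(*cfg.maf_range, size=cfg.n_loci)
    p_region = np.stack(
        [_balding_nichols(p_anc, cfg.fct, rng) for _ in range(cfg.n_regions)]
    )  # (regions, loci)
    anchor = p_region[region_of_pop]  # (pops, loci)
    if cfg.ibd_decay is not None and cfg.ibd_decay > 0:
        idx = np.arange(n_pops, dtype=float)
        corr = np.exp(-np.abs(idx[:, None] - idx[None, :]) / cfg.ibd_decay)
        # copula draws keep each marginal BN around its regional anchor
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(n_pops))
        z = chol @ rng.standard_normal((n_pops, cfg.n_loci))
        u = norm.cdf(z)
        if cfg.fst == 0.0:
            p_pop = anchor
        else:
            shape = (1.0 - cfg.fst) / cfg.fst
            a = np.maximum(anchor * shape, 1e-9)
            b = np.maximum((1.0 - anchor) * shape, 1e-9)
            p_pop = beta_dist.ppf(u, a, b)
    else:
        p_pop = np.stack(
            [_balding_nichols(anchor[k], cfg.fst, rng) for k in range(n_pops)]
        )

    # genotypes at HWE within populations
    genotypes = np.empty((n_pops * cfg.inds_per_pop, cfg.n_loci), dtype=np.int8)
    populations = []
    regions = []
    individuals = []
    for k, pop in enumerate(pop_names):
        sl = slice(k * cfg.inds_per_pop, (k + 1) * cfg.inds_per_pop)
        genotypes[sl] = rng.binomial(2, p_pop[k], size=(cfg.inds_per_pop, cfg.n_loci)).astype(
            np.int8
        )
        populations += [pop] * cfg.inds_per_pop
        regions += [region_names[region_of_pop[k]]] * cfg.inds_per_pop
        individuals += [f"{pop}_ind{i + 1}" for i in range(cfg.inds_per_pop)]

    # ascertainment-bias emulation: force loci monomorphic in designated regions
    forced = np.zeros(cfg.n_loci, dtype=bool)
    if cfg.monomorphic_fraction > 0 and cfg.monomorphic_regions:
        n_forced = int(round(cfg.monomorphic_fraction * cfg.n_loci))
        forced_idx = rng.choice(cfg.n_loci, size=n_forced, replace=False)
        forced[forced_idx] = True
        target = np.isin(np.asarray(regions, dtype=object), list(cfg.monomorphic_regions))
        for j in forced_idx:
            genotypes[target, j] = 0

    if cfg.missing_rate > 0:
        miss = rng.random(genotypes.shape) < cfg.missing_rate
        genotypes[miss] = MISSING

    gm = GenotypeMatrix(
        genotypes,
        individuals=individuals,
        loci=[f"snp{j + 1}" for j in range(cfg.n_loci)],
        populations=populations,
        regions=regions,
    )
    truth = {
        "p_ancestral": p_anc,
        "p_region": pd.DataFrame(p_region, index=region_names),
        "p_pop": pd.DataFrame(p_pop, index=pop_names),
        "forced_monomorphic": forced,
        "geo_dist": geographic_distances(pop_names, cfg.pop_spacing_km),
        "config": cfg,
    }
    return gm, truth
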