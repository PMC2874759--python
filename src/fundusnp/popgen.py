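"""Population-genetic statistics for biallelic SNP genotype matrices.

Genotypes are coded per individual x locus as the number of copies of the
alternative allele (0 = AA, 1 = Aa, 2 = aa, -1 = missing), with population
and optional region labels per individual.  The module provides:

* locus/marker QC (call rate, low-probability genotype fraction,
  missingness, excess-heterozygosity homolog screen);
* per-population summaries: percent polymorphic loci P_O, mean observed and
  unbiased expected heterozygosity H_O / H_E, the within-population fixation
  index F = 1 - H_O/H_E with an allele-permutation significance test, and
  the percentage of loci departing Hardy-Weinberg equilibrium;
* the exact conditional HWE test;
* cross-species locus classification (fixed differences etc.);
* hierarchical AMOVA on allele copies (regions / populations / within) with
  permutation p-values for the Phi-statistics;
* the multi-locus Weir-Cockerham theta estimator of F_ST;
* a Mantel test of isolation by distance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "GenotypeMatrix",
    "PopGenSummary",
    "AMOVAResult",
    "MantelResult",
    "qc_filter",
    "locus_stats",
    "summarize_population",
    "fis_permutation_test",
    "hwe_exact_test",
    "classify_cross_species",
    "amova",
    "pairwise_fst",
    "fst_matrix",
    "mantel_test",
    "read_distance_csv",
    "write_distance_csv",
]

MISSING = -1
_STR2CODE = {"AA": 0, "Aa": 1, "aA": 1, "aa": 2, "NA": MISSING, "": MISSING, ".": MISSING}
_CODE2STR = {0: "AA", 1: "Aa", 2: "aa", MISSING: "NA"}


class GenotypeMatrix:
    """Individuals x biallelic loci with population/region labels.

    ``genotypes`` is an int array (individuals x loci) over {-1, 0, 1, 2}.
    ``low_prob`` optionally flags genotypes the typing software called with
    low probability (same shape, boolean).
    """

    def __init__(
        self,
        genotypes: np.ndarray | pd.DataFrame,
        individuals: Sequence[str] | None = None,
        loci: Sequence[str] | None = None,
        populations: Sequence[str] | None = None,
        regions: Sequence[str] | None = None,
        low_prob: np.ndarray | None = None,
    ):
        if isinstance(genotypes, pd.DataFrame):
            individuals = list(genotypes.index) if individuals is None else list(individuals)
            loci = list(genotypes.columns) if loci is None else list(loci)
            genotypes = genotypes.to_numpy()
        g = np.asarray(genotypes, dtype=np.int8)
        if g.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x loci)")
        if not np.isin(g, [MISSING, 0, 1, 2]).all():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        n_ind, n_loci = g.shape
        self.genotypes = g
        self.individuals = list(individuals) if individuals is not None else [
            f"ind{i}" for i in range(n_ind)
        ]
        self.loci = list(loci) if loci is not None else [f"locus{j}" for j in range(n_loci)]
        if populations is None:
            raise ValueError("population labels are required")
        self.populations = np.asarray(populations, dtype=object)
        if self.populations.size != n_ind:
            raise ValueError("one population label per individual required")
        self.regions = None if regions is None else np.asarray(regions, dtype=object)
        if self.regions is not None:
            if self.regions.size != n_ind:
                raise ValueError("one region label per individual required")
            # region labels must partition populations
            for pop in np.unique(self.populations):
                if len(set(self.regions[self.populations == pop])) != 1:
                    raise ValueError(f"population {pop} spans multiple regions")
        self.low_prob = None
        if low_prob is not None:
            lp = np.asarray(low_prob, dtype=bool)
            if lp.shape != g.shape:
                raise ValueError("low_prob must match genotype shape")
            self.low_prob = lp

    # -- basic accessors -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def population_mask(self, population: str) -> np.ndarray:
        mask = self.populations == population
        if not mask.any():
            raise KeyError(f"unknown population {population!r}")
        return mask

    def subset_loci(self, keep: Sequence[str] | np.ndarray) -> "GenotypeMatrix":
        if np.asarray(keep).dtype == bool:
            idx = np.nonzero(np.asarray(keep))[0]
        else:
            pos = {l: j for j, l in enumerate(self.loci)}
            idx = np.array([pos[l] for l in keep], dtype=int)
        return GenotypeMatrix(
            self.genotypes[:, idx],
            individuals=self.individuals,
            loci=[self.loci[j] for j in idx],
            populations=self.populations,
            regions=self.regions,
            low_prob=None if self.low_prob is None else self.low_prob[:, idx],
        )

    # -- I/O --------------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path, quality_path: str | Path | None = None) -> "GenotypeMatrix":
        """Load from CSV with columns id, population[, region], then loci
        with genotype strings AA/Aa/aa/NA.  ``quality_path`` optionally
        points to a same-shape CSV of OK/LOW_PROBABILITY flags."""
        df = pd.read_csv(path, dtype=str).fillna("NA")
        meta_cols = ["id", "population"] + (["region"] if "region" in df.columns else [])
        loci = [c for c in df.columns if c not in meta_cols]
        try:
            g = df[loci].apply(lambda col: col.map(_STR2CODE)).to_numpy()
        except Exception as exc:  # unknown genotype string
            raise ValueError(f"{path}: unparseable genotype value ({exc})") from exc
        if np.isnan(np.asarray(g, dtype=float)).any():
            raise ValueError(f"{path}: unknown genotype strings present")
        low_prob = None
        if quality_path is not None:
            q = pd.read_csv(quality_path, dtype=str).fillna("OK")
            low_prob = (q[loci] == "LOW_PROBABILITY").to_numpy()
        return cls(
            np.asarray(g, dtype=np.int8),
            individuals=df["id"].tolist(),
            loci=loci,
            populations=df["population"].tolist(),
            regions=df["region"].tolist() if "region" in df.columns else None,
            low_prob=low_prob,
        )

    def to_csv(self, path: str | Path) -> None:
        data = {"id": self.individuals, "population": self.populations}
        if self.regions is not None:
            data["region"] = self.regions
        for j, locus in enumerate(self.loci):
            data[locus] = [_CODE2STR[int(v)] for v in self.genotypes[:, j]]
        pd.DataFrame(data).to_csv(path, index=False)


@dataclass
class PopGenSummary:
    population: str
    n_individuals: int
    n_loci: int
    P_O: float  # percent polymorphic loci
    H_O: float
    H_E: float
    F: float
    F_pvalue: float | None
    pct_hwe_departure: float


@dataclass
class AMOVAResult:
    sigma2: dict[str, float]  # variance components by stratum name
    percentages: dict[str, float]
    phi: dict[str, float]  # Phi_CT, Phi_SC, Phi_ST (3-level) or Phi_ST (2-level)
    p_values: dict[str, float]
    n_permutations: int
    negative_components: bool = False


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int


# ---------------------------------------------------------------------------
# per-locus statistics
# ---------------------------------------------------------------------------

def _counts(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_called, het count, alt-allele copy count) per locus for int matrix g."""
    called = g != MISSING
    n = called.sum(axis=0)
    het = (g == 1).sum(axis=0)
    alt = np.where(called, g, 0).sum(axis=0)
    return n, het, alt


def locus_stats(g: np.ndarray) -> pd.DataFrame:
    """Per-locus n, allele frequency, observed and unbiased expected het.

    H_E uses the small-sample correction 2*p*q * 2n/(2n-1).  Loci with no
    called genotypes get NaN statistics.
    """
    n, het, alt = _counts(np.asarray(g))
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(n > 0, alt / (2.0 * n), np.nan)  # alt-allele frequency
        p = 1.0 - q
        h_obs = np.where(n > 0, het / n, np.nan)
        corr = np.where(n > 0, 2.0 * n / np.maximum(2.0 * n - 1.0, 1.0), np.nan)
        h_exp = 2.0 * p * q * corr
    polymorphic = (n > 0) & (alt > 0) & (alt < 2 * n)
    return pd.DataFrame(
        {"n": n, "p": p, "h_obs": h_obs, "h_exp": h_exp, "polymorphic": polymorphic}
    )


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(
    gm: GenotypeMatrix,
    min_call_rate: float = 0.90,
    max_low_prob_fraction: float = 0.50,
    max_missing_per_locus: float | None = None,
    het_excess_threshold: float = 0.60,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove loci failing marker QC; return the filtered matrix and report.

    Rules (a locus is removed if any fires):

    * call rate: fraction of individuals with a genotype must be strictly
      greater than ``min_call_rate``;
    * low probability: fraction of individuals whose genotype was flagged
      LOW_PROBABILITY must not exceed ``max_low_prob_fraction`` (strictly
      greater removes);
    * missingness: missing fraction above ``max_missing_per_locus`` (the
      per-analysis-group parameter, e.g. 0.05 or 0.10) removes, if set;
    * heterozygosity excess (homolog screen): pooled observed heterozygosity
      above ``het_excess_threshold`` AND H_O > H_E within every population
      where the locus has data.

    The report lists one row per removed locus with boolean rule columns.
    """
    for thr in (min_call_rate, max_low_prob_fraction, het_excess_threshold):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    if gm.n_individuals == 0 or gm.n_loci == 0:
        raise ValueError("empty genotype matrix")
    g = gm.genotypes
    called = g != MISSING
    call_rate = called.mean(axis=0)
    fail_call = call_rate <= min_call_rate

    if gm.low_prob is not None:
        fail_lowp = gm.low_prob.mean(axis=0) > max_low_prob_fraction
    else:
        fail_lowp = np.zeros(gm.n_loci, dtype=bool)

    if max_missing_per_locus is not None:
        fail_miss = (1.0 - call_rate) > max_missing_per_locus
    else:
        fail_miss = np.zeros(gm.n_loci, dtype=bool)

    pooled = locus_stats(g)
    per_pop_excess = np.ones(gm.n_loci, dtype=bool)
    for pop in np.unique(gm.populations):
        sub = locus_stats(g[gm.populations == pop])
        has_data = sub["n"].to_numpy() > 0
        excess = sub["h_obs"].to_numpy() > sub["h_exp"].to_numpy()
        per_pop_excess &= np.where(has_data, excess, True)
    fail_het = (
        (pooled["h_obs"].to_numpy() > het_excess_threshold)
        & pooled["polymorphic"].to_numpy()
        & per_pop_excess
    )

    removed = fail_call | fail_lowp | fail_miss | fail_het
    report = pd.DataFrame(
        {
            "locus": gm.loci,
            "call_rate": call_rate,
            "fail_call_rate": fail_call,
            "fail_low_probability": fail_lowp,
            "fail_missingness": fail_miss,
            "fail_het_excess": fail_het,
        }
    )
    report = report[removed].reset_index(drop=True)
    return gm.subset_loci(~removed), report


# ---------------------------------------------------------------------------
# per-population summaries
# ---------------------------------------------------------------------------

def summarize_population(
    gm: GenotypeMatrix,
    population: str,
    max_missing: float | None = None,
    hwe_alpha: float = 0.05,
    f_mode: str = "multilocus",
    n_perm: int = 0,
    seed: int = 0,
) -> PopGenSummary:
    """Diversity summary for one population.

    Loci with a within-population missing fraction above ``max_missing`` are
    excluded from the means.  ``f_mode='multilocus'`` computes
    F = 1 - mean(H_O)/mean(H_E) over polymorphic loci (ratio of means);
    ``'per_locus'`` averages per-locus 1 - h_o/h_e instead.  When
    ``n_perm`` > 0 an allele-permutation p-value for F is attached.  The
    HWE-departure percentage counts polymorphic loci whose exact test gives
    p < ``hwe_alpha``.
    """
    mask = gm.population_mask(population)
    if mask.sum() < 2:
        raise ValueError(f"population {population!r} has fewer than 2 individuals")
    g = gm.genotypes[mask]
    stats = locus_stats(g)
    usable = stats["n"].to_numpy() > 0
    if max_missing is not None:
        usable &= (1.0 - stats["n"].to_numpy() / mask.sum()) <= max_missing
    if not usable.any():
        raise ValueError("no loci pass the missingness threshold")
    sub = stats[usable]
    poly = sub["polymorphic"].to_numpy()
    p_o = 100.0 * poly.mean()
    h_o = float(sub["h_obs"].mean())
    h_e = float(sub["h_exp"].mean())
    f = _fixation_index(sub, f_mode)

    # HWE departures among polymorphic loci
    n_dep = 0
    n_poly = int(poly.sum())
    for j in np.nonzero(usable)[0]:
        if not stats["polymorphic"].iloc[j]:
            continue
        col = g[:, j]
        n_aa = int((col == 0).sum())
        n_ab = int((col == 1).sum())
        n_bb = int((col == 2).sum())
        if hwe_exact_test(n_aa, n_ab, n_bb) < hwe_alpha:
            n_dep += 1
    pct_hwe = 100.0 * n_dep / n_poly if n_poly else 0.0

    f_p = None
    if n_perm > 0:
        _, f_p = fis_permutation_test(
            gm, population, n_perm=n_perm, seed=seed, max_missing=max_missing, f_mode=f_mode
        )
    return PopGenSummary(
        population=population,
        n_individuals=int(mask.sum()),
        n_loci=int(usable.sum()),
        P_O=p_o,
        H_O=h_o,
        H_E=h_e,
        F=f,
        F_pvalue=f_p,
        pct_hwe_departure=pct_hwe,
    )


def _fixation_index(stats: pd.DataFrame, f_mode: str) -> float:
    poly = stats[stats["polymorphic"]]
    if len(poly) == 0:
        raise ValueError("fixation index undefined: no polymorphic loci")
    if f_mode == "multilocus":
        return float(1.0 - poly["h_obs"].mean() / poly["h_exp"].mean())
    if f_mode == "per_locus":
        return float((1.0 - poly["h_obs"] / poly["h_exp"]).mean())
    raise ValueError(f"unknown f_mode {f_mode!r}")


def fis_permutation_test(
    gm: GenotypeMatrix,
    population: str,
    n_perm: int = 10_000,
    seed: int = 0,
    max_missing: float | None = None,
    f_mode: str = "multilocus",
) -> tuple[float, float]:
    """Test F = F_IS against zero by permuting allele copies among individuals.

    For each permutation the 2n called allele copies at every locus are
    shuffled independently and re-paired into genotypes, destroying any
    within-individual allele correlation while preserving allele counts
    (so H_E is invariant and only H_O resamples).  Two-sided p-value with
    the +1/(n_perm+1) correction.  Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    mask = gm.population_mask(population)
    g = gm.genotypes[mask]
    stats = locus_stats(g)
    usable = stats["n"].to_numpy() > 0
    if max_missing is not None:
        usable &= (1.0 - stats["n"].to_numpy() / mask.sum()) <= max_missing
    stats = stats[usable]
    poly_idx = np.nonzero(usable)[0][stats["polymorphic"].to_numpy()]
    if poly_idx.size == 0:
        raise ValueError("fixation index undefined: population is monomorphic")
    f_obs = _fixation_index(stats, f_mode)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x46495]))
    h_exp = stats[stats["polymorphic"]]["h_exp"].to_numpy()
    n_called = stats[stats["polymorphic"]]["n"].to_numpy().astype(int)
    # permuted observed het per locus per replicate
    h_obs_perm = np.empty((n_perm, poly_idx.size))
    for k, j in enumerate(poly_idx):
        col = g[:, j]
        col = col[col != MISSING]
        copies = np.repeat([0, 1], [2 * len(col) - col.sum(), col.sum()])
        # vectorised shuffles: one random permutation per replicate
        keys = rng.random((n_perm, copies.size))
        order = np.argsort(keys, axis=1)
        shuffled = copies[order]
        pairs = shuffled.reshape(n_perm, -1, 2)
        h_obs_perm[:, k] = (pairs[:, :, 0] != pairs[:, :, 1]).mean(axis=1)
    if f_mode == "multilocus":
        f_perm = 1.0 - h_obs_perm.mean(axis=1) / h_exp.mean()
    else:
        f_perm = (1.0 - h_obs_perm / h_exp).mean(axis=1)
    p = (1.0 + np.sum(np.abs(f_perm) >= abs(f_obs) - 1e-12)) / (n_perm + 1.0)
    return f_obs, float(p)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional test of Hardy-Weinberg proportions.

    Conditions on the sample size n and the minor-allele copy count; sums
    the probabilities of all heterozygote counts whose conditional
    probability does not exceed that of the observed configuration.
    Monomorphic samples return p = 1.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotype required")
    n_a = n_Aa + 2 * n_aa  # copies of allele a
    n_rare = min(n_a, 2 * n - n_a)
    if n_rare == 0:
        return 1.0
    obs_het = n_Aa

    # heterozygote counts with the parity of n_rare, 0..n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(h | n, n_a) up to a constant: conditional distribution of the
    # heterozygote count under random union of gametes
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(rare_hom + 1)
        - gammaln(common_hom + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == obs_het]
    if p_obs.size == 0:
        raise ValueError("observed heterozygote count inconsistent with allele count parity")
    return float(min(1.0, probs[probs <= p_obs[0] * (1.0 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# cross-species classification
# ---------------------------------------------------------------------------

def classify_cross_species(gm_a: GenotypeMatrix, gm_b: GenotypeMatrix) -> pd.Series:
    """Classify shared loci across two genotype sets.

    Labels: POLY_BOTH, POLY_A_ONLY, POLY_B_ONLY, MONO_SHARED (monomorphic in
    both for the same allele), FIXED_DIFFERENCE (monomorphic in both for
    opposite alleles), UNAMPLIFIED (all genotypes missing in at least one
    set).
    """
    shared = [l for l in gm_a.loci if l in set(gm_b.loci)]
    if not shared:
        raise ValueError("genotype sets share no loci")
    sub_a = gm_a.subset_loci(shared)
    sub_b = gm_b.subset_loci(shared)

    def _state(g: np.ndarray) -> tuple[str, float]:
        n, het, alt = _counts(g)
        n, alt = int(n[0]), int(alt[0])
        if n == 0:
            return "UNAMPLIFIED", np.nan
        if 0 < alt < 2 * n:
            return "POLY", np.nan
        return "MONO", alt / (2.0 * n)  # fixed-allele dose: 0.0 or 1.0

    labels = {}
    for j, locus in enumerate(shared):
        state_a, dose_a = _state(sub_a.genotypes[:, j : j + 1])
        state_b, dose_b = _state(sub_b.genotypes[:, j : j + 1])
        if "UNAMPLIFIED" in (state_a, state_b):
            labels[locus] = "UNAMPLIFIED"
        elif state_a == "POLY" and state_b == "POLY":
            labels[locus] = "POLY_BOTH"
        elif state_a == "POLY":
            labels[locus] = "POLY_A_ONLY"
        elif state_b == "POLY":
            labels[locus] = "POLY_B_ONLY"
        elif dose_a != dose_b:
            labels[locus] = "FIXED_DIFFERENCE"
        else:
            labels[locus] = "MONO_SHARED"
    return pd.Series(labels, name="class")


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _amova_components(
    alt: np.ndarray, cop: np.ndarray, pop_of: np.ndarray, region_of: np.ndarray | None
) -> tuple[np.ndarray, ...]:
    """Per-locus nested variance components on allele copies.

    ``alt``: individuals x loci alternative-allele doses (0/1/2, 0 where
    missing); ``cop``: copies per individual per locus (2 or 0);
    ``pop_of``: population index per individual; ``region_of``: region
    index per population (or None for the 2-level design).

    Returns per-locus arrays: 3-level (sig_a, sig_b, sig_c) or 2-level
    (sig_b, sig_c).  Uses the classical unbalanced nested ANOVA
    mean-square equations; components may be negative.
    """
    n_pops = pop_of.max() + 1
    memb = np.zeros((n_pops, alt.shape[0]))
    memb[pop_of, np.arange(alt.shape[0])] = 1.0
    s_p = memb @ alt  # alt-copy sums per pop per locus
    n_p = memb @ cop  # allele copies per pop per locus
    n_tot = n_p.sum(axis=0)
    s_tot = s_p.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ybar_p = np.where(n_p > 0, s_p / n_p, 0.0)
        ybar = s_tot / n_tot
        ss_within = (s_p - n_p * ybar_p**2).sum(axis=0)

    p_eff = (n_p > 0).sum(axis=0)
    if region_of is None:
        ss_pops = (n_p * (ybar_p - ybar) ** 2).sum(axis=0)
        df_b = np.maximum(p_eff - 1, 0)
        df_c = np.maximum(n_tot - p_eff, 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ms_w = np.where(df_c > 0, ss_within / df_c, 0.0)
            ms_b = np.where(df_b > 0, ss_pops / df_b, 0.0)
            n_prime = np.where(
                df_b > 0, (n_tot - (n_p**2).sum(axis=0) / n_tot) / np.maximum(df_b, 1), np.nan
            )
            sig_c = ms_w
            sig_b = np.where(df_b > 0, (ms_b - ms_w) / n_prime, 0.0)
        return sig_b, sig_c

    n_regions = region_of.max() + 1
    rmemb = np.zeros((n_regions, n_pops))
    rmemb[region_of, np.arange(n_pops)] = 1.0
    s_g = rmemb @ s_p
    n_g = rmemb @ n_p
    g_eff = (n_g > 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ybar_g = np.where(n_g > 0, s_g / n_g, 0.0)
        ss_regions = (n_g * (ybar_g - ybar) ** 2).sum(axis=0)
        ss_pops = (n_p * (ybar_p - ybar_g[region_of]) ** 2).sum(axis=0)
        df_a = np.maximum(g_eff - 1, 0)
        df_b = np.maximum(p_eff - g_eff, 0)
        df_c = np.maximum(n_tot - p_eff, 0)
        ms_w = np.where(df_c > 0, ss_within / df_c, 0.0)
        ms_b = np.where(df_b > 0, ss_pops / df_b, 0.0)
        ms_a = np.where(df_a > 0, ss_regions / df_a, 0.0)
        # coefficients of the expected mean squares (unbalanced design)
        sum_np2_over_ng = ((rmemb @ (n_p**2)) / np.where(n_g > 0, n_g, 1.0)).sum(axis=0)
        n1 = np.where(df_b > 0, (n_tot - sum_np2_over_ng) / np.maximum(df_b, 1), np.nan)
        n2 = np.where(
            df_a > 0,
            (sum_np2_over_ng - (n_p**2).sum(axis=0) / n_tot) / np.maximum(df_a, 1),
            np.nan,
        )
        n3 = np.where(
            df_a > 0, (n_tot - (n_g**2).sum(axis=0) / n_tot) / np.maximum(df_a, 1), np.nan
        )
        sig_c = ms_w
        sig_b = np.where((df_b > 0) & (n1 > 0), (ms_b - ms_w) / np.where(n1 > 0, n1, 1.0), 0.0)
        sig_a = np.where(
            (df_a > 0) & (n3 > 0),
            (ms_a - ms_w - n2 * sig_b) / np.where(n3 > 0, n3, 1.0),
            0.0,
        )
    return sig_a, sig_b, sig_c


def _amova_stats(gm_alt, gm_cop, pop_of, region_of):
    comps = _amova_components(gm_alt, gm_cop, pop_of, region_of)
    sums = [float(np.nansum(c)) for c in comps]
    return sums


def amova(
    gm: GenotypeMatrix,
    n_perm: int = 1000,
    seed: int = 0,
) -> AMOVAResult:
    """Hierarchical AMOVA on allele copies.

    With region labels: three strata (among regions, among populations
    within regions, within populations) and Phi_CT / Phi_SC / Phi_ST.
    Without regions (or a single region): two strata and Phi_ST only.
    Distances between allele copies are 0/1 mismatches, so the analysis is
    the frequency-based (F_ST-style) AMOVA, with variance components summed
    over loci.  Negative component estimates are reported as-is with a
    flag.  Significance by permutation: individuals among all populations
    (Phi_ST), individuals among populations within regions (Phi_SC), whole
    populations among regions (Phi_CT).
    """
    g = gm.genotypes.astype(float)
    called = g != MISSING
    alt = np.where(called, g, 0.0)
    cop = 2.0 * called

    pops = list(np.unique(gm.populations))
    pop_of = np.array([pops.index(p) for p in gm.populations])
    three_level = gm.regions is not None and len(set(gm.regions)) > 1
    if three_level:
        regions = list(np.unique(gm.regions))
        region_of_pop = np.array(
            [regions.index(gm.regions[np.nonzero(gm.populations == p)[0][0]]) for p in pops]
        )
    else:
        region_of_pop = None

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA40A]))

    if three_level:
        sa, sb, sc = _amova_stats(alt, cop, pop_of, region_of_pop)
        total = sa + sb + sc
        phi_ct = sa / total if total else 0.0
        phi_sc = sb / (sb + sc) if (sb + sc) else 0.0
        phi_st = (sa + sb) / total if total else 0.0
        exceed = {"Phi_ST": 0, "Phi_SC": 0, "Phi_CT": 0}
        for _ in range(n_perm):
            perm_all = rng.permutation(len(pop_of))
            a1, b1, c1 = _amova_stats(alt[perm_all], cop[perm_all], pop_of, region_of_pop)
            t1 = a1 + b1 + c1
            if t1 and (a1 + b1) / t1 >= phi_st - 1e-12:
                exceed["Phi_ST"] += 1
            # permute individuals among populations within each region
            perm_within = np.arange(len(pop_of))
            ind_region = region_of_pop[pop_of]
            for r in range(region_of_pop.max() + 1):
                idx = np.nonzero(ind_region == r)[0]
                perm_within[idx] = idx[rng.permutation(idx.size)]
            a2, b2, c2 = _amova_stats(alt[perm_within], cop[perm_within], pop_of, region_of_pop)
            if (b2 + c2) and b2 / (b2 + c2) >= phi_sc - 1e-12:
                exceed["Phi_SC"] += 1
            # permute whole populations among regions
            perm_pops = rng.permutation(region_of_pop)
            a3, b3, c3 = _amova_stats(alt, cop, pop_of, perm_pops)
            t3 = a3 + b3 + c3
            if t3 and a3 / t3 >= phi_ct - 1e-12:
                exceed["Phi_CT"] += 1
        sigma2 = {"among_regions": sa, "among_pops_within_regions": sb, "within_pops": sc}
        phi = {"Phi_CT": phi_ct, "Phi_SC": phi_sc, "Phi_ST": phi_st}
    else:
        sb, sc = _amova_stats(alt, cop, pop_of, None)
        total = sb + sc
        phi_st = sb / total if total else 0.0
        exceed = {"Phi_ST": 0}
        for _ in range(n_perm):
            perm_all = rng.permutation(len(pop_of))
            b1, c1 = _amova_stats(alt[perm_all], cop[perm_all], pop_of, None)
            t1 = b1 + c1
            if t1 and b1 / t1 >= phi_st - 1e-12:
                exceed["Phi_ST"] += 1
        sigma2 = {"among_pops": sb, "within_pops": sc}
        phi = {"Phi_ST": phi_st}

    total = sum(sigma2.values())
    percentages = {k: (100.0 * v / total if total else 0.0) for k, v in sigma2.items()}
    p_values = {k: (v + 1.0) / (n_perm + 1.0) for k, v in exceed.items()}
    return AMOVAResult(
        sigma2=sigma2,
        percentages=percentages,
        phi=phi,
        p_values=p_values,
        n_permutations=n_perm,
        negative_components=any(v < 0 for v in sigma2.values()),
    )


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def _wc_components(gm: GenotypeMatrix, pop_list: list[str]) -> tuple[float, float]:
    """Summed Weir-Cockerham (a, a+b+c) over loci for the given populations."""
    r = len(pop_list)
    masks = [gm.population_mask(p) for p in pop_list]
    n_i = np.stack([( gm.genotypes[m] != MISSING).sum(axis=0) for m in masks])  # inds called
    het_i = np.stack([(gm.genotypes[m] == 1).sum(axis=0) for m in masks])
    alt_i = np.stack(
        [np.where(gm.genotypes[m] != MISSING, gm.genotypes[m], 0).sum(axis=0) for m in masks]
    )
    usable = (n_i > 0).all(axis=0)
    n_i = n_i[:, usable].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_i = alt_i[:, usable] / (2.0 * n_i)
        h_i = het_i[:, usable] / n_i
        nbar = n_i.mean(axis=0)
        total = n_i.sum(axis=0)
        nc = (total - (n_i**2).sum(axis=0) / total) / (r - 1.0)
        pbar = (n_i * p_i).sum(axis=0) / total
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / total
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    # drop loci with undefined components (e.g. a population of size 1)
    finite = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return float(a[finite].sum()), float((a + b + c)[finite].sum())


def pairwise_fst(gm: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Multi-locus Weir-Cockerham theta between two populations.

    Ratio of summed variance components over loci; symmetric in the pair;
    can be slightly negative by sampling error.  Raises if the pair shares
    no polymorphic locus.
    """
    sub = gm.subset_loci(_shared_poly_mask(gm, [pop_a, pop_b]))
    if sub.n_loci == 0:
        raise ValueError(f"no shared polymorphic loci between {pop_a} and {pop_b}")
    num, den = _wc_components(sub, [pop_a, pop_b])
    if den == 0.0:
        raise ValueError("Weir-Cockerham denominator is zero")
    return num / den


def _shared_poly_mask(gm: GenotypeMatrix, pop_list: list[str]) -> np.ndarray:
    """Loci called in every listed population and polymorphic in the pool."""
    masks = [gm.population_mask(p) for p in pop_list]
    called_everywhere = np.ones(gm.n_loci, dtype=bool)
    for m in masks:
        called_everywhere &= (gm.genotypes[m] != MISSING).any(axis=0)
    pool = np.concatenate([gm.genotypes[m] for m in masks])
    return called_everywhere & locus_stats(pool)["polymorphic"].to_numpy()


def fst_matrix(gm: GenotypeMatrix) -> pd.DataFrame:
    """Symmetric pairwise Weir-Cockerham theta matrix over all populations.

    Negative estimates are clipped to 0 so the matrix is usable as a
    genetic distance (the diagonal is 0).
    """
    pops = list(dict.fromkeys(gm.populations))
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for a, b in itertools.combinations(pops, 2):
        theta = max(0.0, pairwise_fst(gm, a, b))
        mat.loc[a, b] = mat.loc[b, a] = theta
    return mat


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def _as_square(d, name: str) -> tuple[np.ndarray, list[str] | None]:
    labels = None
    if isinstance(d, pd.DataFrame):
        labels = list(d.index)
        if list(d.columns) != labels:
            raise ValueError(f"{name}: row and column labels differ")
        d = d.to_numpy(dtype=float)
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-9):
        raise ValueError(f"{name} must have a zero diagonal")
    return d, labels


def mantel_test(
    genetic_dist,
    geographic_dist,
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test of matrix correlation (isolation by distance).

    r is the Pearson correlation over upper-triangle entries; the null is
    generated by jointly permuting rows and columns of the genetic matrix.
    One-sided 'greater' by default (isolation by distance predicts a
    positive correlation), with the +1 permutation correction.  Labelled
    DataFrames are aligned on the geographic matrix's ordering.
    """
    d1, lab1 = _as_square(genetic_dist, "genetic_dist")
    d2, lab2 = _as_square(geographic_dist, "geographic_dist")
    if lab1 is not None and lab2 is not None:
        if set(lab1) != set(lab2):
            raise ValueError("distance matrices have mismatched labels")
        order = [lab1.index(l) for l in lab2]
        d1 = d1[np.ix_(order, order)]
    if d1.shape != d2.shape:
        raise ValueError("distance matrices must have equal shape")
    n = d1.shape[0]
    if n < 4:
        raise ValueError("Mantel test requires at least 4 objects")
    iu = np.triu_indices(n, k=1)

    def corr(mat: np.ndarray) -> float:
        x, y = mat[iu], d2[iu]
        sx, sy = x.std(), y.std()
        if sx == 0.0 or sy == 0.0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(d1)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x3A27E1]))
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = corr(d1[np.ix_(perm, perm)])
        if alternative == "greater":
            exceed += r_perm >= r_obs - 1e-12
        elif alternative == "two-sided":
            exceed += abs(r_perm) >= abs(r_obs) - 1e-12
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    p = (exceed + 1.0) / (n_perm + 1.0)
    return MantelResult(r=r_obs, p_value=float(p), n_permutations=n_perm)


def read_distance_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_distance_csv(d: pd.DataFrame, path: str | Path) -> None:
    d.to_csv(path)
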