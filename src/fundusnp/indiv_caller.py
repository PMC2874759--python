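"""Individual-level genotype calling: Bayesian posterior plus LRT confirmation.

At each pileup position within one individual, the observed allele copies
``Y_1..Y_N`` each carry a Phred-derived error probability ``e_j``.  The locus
is classified homozygous (for the major allele ``A``) or heterozygous
(``A``/``a``, the two most frequent observed bases) by comparing

    L_hom = prod_j [ (1 - e_j)       if Y_j == A else e_j / 3 ]
    L_het = prod_j [ (1-e_j)/2 + e_j/6  if Y_j in {A, a} else e_j / 3 ]

under a small prior probability of heterozygosity (the per-site mutation
rate, default 1e-4).  An error turns the true base into each of the three
other bases with equal probability e_j/3; under heterozygosity each copy is
drawn from either allele with probability 1/2.

Loci classified heterozygous are then confirmed with a likelihood-ratio test
on allele balance.  Among informative copies (those reading A or a), the
probability of reading the major allele is modelled as

    pi_j(p) = p (1 - e_j) + (1 - p) e_j

where p is the frequency of the major allele among the true copies.  The
test is H0: p = 0.5 (balanced heterozygote) against Ha: p > 0.5, with
-2 * log-likelihood-ratio referred to chi-square(1).  Because the MLE is
constrained to [0.5, 1], the chi-square(1) reference is conservative (the
boundary null is a 1/2 chi2(0) + 1/2 chi2(1) mixture, available via
``null_dist='mixture'``).  A rejection is evidence the site is skewed toward
one allele (e.g. a sequencing-error pile on a homozygote), so by default a
rejected heterozygote call reverts to homozygous.

All likelihoods are accumulated in log space.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

__all__ = [
    "PHRED_ERROR_CAP",
    "phred_to_error",
    "IndividualLocus",
    "GenotypeCall",
    "genotype_posterior",
    "het_lrt",
    "call_individual",
    "call_pileup",
]

#: Error probabilities are capped here: at e >= 0.75 a base carries no
#: information about which of the four nucleotides was present.
PHRED_ERROR_CAP = 0.75


def phred_to_error(q):
    """Convert Phred quality Q to an error probability, 10**(-Q/10).

    Accepts scalars or arrays.  Values are capped at ``PHRED_ERROR_CAP`` so a
    Q=0 base (raw e=1.0) degrades to an uninformative, not impossible,
    observation.  Negative Q raises ValueError.
    """
    q_arr = np.asarray(q, dtype=float)
    if np.any(q_arr < 0):
        raise ValueError("Phred quality must be non-negative")
    e = np.minimum(10.0 ** (-q_arr / 10.0), PHRED_ERROR_CAP)
    if np.isscalar(q) or q_arr.ndim == 0:
        return float(e)
    return e


def _ranked_alleles(bases: Sequence[str]) -> list[str]:
    """Bases ordered by descending count, ties broken lexicographically."""
    counts = Counter(bases)
    return sorted(counts, key=lambda b: (-counts[b], b))


@dataclass
class IndividualLocus:
    """All allele copies observed at one contig position in one individual."""

    contig_id: str
    position: int  # 0-based
    bases: np.ndarray  # dtype '<U1', the observed base per copy
    errors: np.ndarray  # per-copy error probabilities e_j

    def __post_init__(self) -> None:
        self.bases = np.asarray(self.bases, dtype="<U1")
        self.errors = np.asarray(self.errors, dtype=float)
        if self.bases.shape != self.errors.shape:
            raise ValueError("bases and errors must have equal length")

    @classmethod
    def from_observations(
        cls, contig_id: str, position: int, bases: Sequence[str], qualities: Sequence[int]
    ) -> "IndividualLocus":
        quals = np.asarray(list(qualities), dtype=float)
        return cls(contig_id, position, np.asarray(list(bases)), phred_to_error(quals))

    @property
    def n_obs(self) -> int:
        return int(self.bases.size)

    @property
    def major_allele(self) -> str | None:
        if self.n_obs == 0:
            return None
        return _ranked_alleles(self.bases)[0]

    @property
    def minor_allele(self) -> str | None:
        ranked = _ranked_alleles(self.bases)
        return ranked[1] if len(ranked) > 1 else None


@dataclass
class GenotypeCall:
    p_hom: float | None
    p_het: float | None
    bayes_class: str | None  # HOM / HET
    lrt_stat: float | None = None
    lrt_p: float | None = None
    final_class: str = "NOCALL"  # HOM / HET / NOCALL


def _log_likelihoods(locus: IndividualLocus) -> tuple[float, float]:
    """(log L_hom, log L_het) under the emission model described above."""
    major = locus.major_allele
    minor = locus.minor_allele
    e = locus.errors
    is_major = locus.bases == major
    is_allele = is_major if minor is None else (is_major | (locus.bases == minor))
    log_lhom = float(
        np.sum(np.log1p(-e[is_major])) + np.sum(np.log(e[~is_major] / 3.0))
    )
    het_emit = 0.5 * (1.0 - e) + 0.5 * (e / 3.0)
    log_lhet = float(
        np.sum(np.log(het_emit[is_allele])) + np.sum(np.log(e[~is_allele] / 3.0))
    )
    return log_lhom, log_lhet


def genotype_posterior(locus: IndividualLocus, prior: float = 1e-4) -> GenotypeCall:
    """Posterior probability that the locus is heterozygous.

    ``prior`` is the prior probability of heterozygosity (mutation rate);
    must lie in (0, 1).  A locus with no observations yields NOCALL with
    posteriors unset.
    """
    if not 0.0 < prior < 1.0:
        raise ValueError("prior must lie in (0, 1)")
    if locus.n_obs == 0:
        return GenotypeCall(p_hom=None, p_het=None, bayes_class=None, final_class="NOCALL")
    log_lhom, log_lhet = _log_likelihoods(locus)
    # p_het = prior*L_het / (prior*L_het + (1-prior)*L_hom), in log space
    log_odds_hom = np.log1p(-prior) - np.log(prior) + log_lhom - log_lhet
    p_het = float(1.0 / (1.0 + np.exp(log_odds_hom)))
    bayes_class = "HET" if p_het > 1.0 - p_het else "HOM"
    return GenotypeCall(
        p_hom=1.0 - p_het, p_het=p_het, bayes_class=bayes_class, final_class=bayes_class
    )


def _lrt_loglik(p: float, is_major: np.ndarray, e: np.ndarray) -> float:
    pi = p * (1.0 - e) + (1.0 - p) * e
    return float(np.sum(np.log(pi[is_major])) + np.sum(np.log1p(-pi[~is_major])))


def het_lrt(locus: IndividualLocus, null_dist: str = "chi2") -> tuple[float, float]:
    """Allele-balance LRT for a putative heterozygote.

    Only copies reading the major or minor allele are informative.  Returns
    ``(lrt_stat, p_value)`` where ``lrt_stat = -2 [l(0.5) - l(p_hat)]`` with
    p_hat the MLE of the major-allele frequency constrained to [0.5, 1], and
    the p-value is the chi-square(1) upper tail (or the boundary mixture
    1/2 chi2(0) + 1/2 chi2(1) when ``null_dist='mixture'``).
    """
    minor = locus.minor_allele
    if minor is None:
        raise ValueError("LRT requires a locus with a defined minor allele")
    major = locus.major_allele
    informative = (locus.bases == major) | (locus.bases == minor)
    is_major = (locus.bases == major)[informative]
    e = locus.errors[informative]

    res = minimize_scalar(
        lambda p: -_lrt_loglik(p, is_major, e),
        bounds=(0.5, 1.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    ll_hat = max(-res.fun, _lrt_loglik(0.5, is_major, e))
    stat = max(0.0, 2.0 * (ll_hat - _lrt_loglik(0.5, is_major, e)))
    if null_dist == "chi2":
        p_value = float(chi2.sf(stat, df=1))
    elif null_dist == "mixture":
        p_value = 1.0 if stat == 0.0 else float(0.5 * chi2.sf(stat, df=1))
    else:
        raise ValueError(f"unknown null_dist {null_dist!r}")
    return stat, p_value


def call_individual(
    locus: IndividualLocus,
    prior: float = 1e-4,
    lrt_alpha: float = 0.05,
    lrt_rejection_to_hom: bool = True,
    null_dist: str = "chi2",
) -> GenotypeCall:
    """Full two-stage call: Bayesian classification, LRT confirmation of HETs.

    When the LRT rejects allele balance at ``lrt_alpha``, the default policy
    reverts the call to HOM (the skew suggests errors on a homozygote);
    ``lrt_rejection_to_hom=False`` retains the Bayesian HET class instead.
    """
    call = genotype_posterior(locus, prior=prior)
    if call.final_class == "HET" and locus.minor_allele is not None:
        call.lrt_stat, call.lrt_p = het_lrt(locus, null_dist=null_dist)
        if call.lrt_p < lrt_alpha and lrt_rejection_to_hom:
            call.final_class = "HOM"
    return call


def call_pileup(
    pileup: pd.DataFrame,
    prior: float = 1e-4,
    lrt_alpha: float = 0.05,
    lrt_rejection_to_hom: bool = True,
    null_dist: str = "chi2",
) -> pd.DataFrame:
    """Call every (contig, position, individual) group of a pileup table.

    ``pileup`` columns: contig, pos, individual, base, phred.  Returns one
    row per group with columns contig, pos, individual, n_obs, major, minor,
    p_het, lrt_stat, lrt_p, final_class.
    """
    required = {"contig", "pos", "individual", "base", "phred"}
    missing = required - set(pileup.columns)
    if missing:
        raise ValueError(f"pileup is missing columns: {sorted(missing)}")
    rows = []
    for (contig, pos, individual), grp in pileup.groupby(
        ["contig", "pos", "individual"], sort=True
    ):
        locus = IndividualLocus.from_observations(
            contig, int(pos), grp["base"].to_numpy(), grp["phred"].to_numpy()
        )
        call = call_individual(
            locus,
            prior=prior,
            lrt_alpha=lrt_alpha,
            lrt_rejection_to_hom=lrt_rejection_to_hom,
            null_dist=null_dist,
        )
        rows.append(
            {
                "contig": contig,
                "pos": int(pos),
                "individual": individual,
                "n_obs": locus.n_obs,
                "major": locus.major_allele,
                "minor": locus.minor_allele if locus.minor_allele else ".",
                "p_het": call.p_het,
                "lrt_stat": call.lrt_stat,
                "lrt_p": call.lrt_p,
                "final_class": call.final_class,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "pos", "individual", "n_obs", "major", "minor",
            "p_het", "lrt_stat", "lrt_p", "final_class",
        ],
    )
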