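"""Population-level SNP detection against a simulated sequencing-error null.

For each multi-allelic pileup position, all allele copies across individuals
are pooled.  Under the null hypothesis that the site is homozygous for the
major allele, each copy reads the major allele with probability 1 - e_j and
one of the three other bases with probability e_j/3 each.  Simulating this
model yields the null distribution of the "second-allele count" (the copy
count of the most frequent non-major base); a site is flagged as a potential
SNP when its observed count reaches the critical value, the smallest count
whose right-tail null probability is at most alpha (default 0.001, null
built from 10,000 replicates).

Flagged sites then pass through homolog-artifact filters: a minimum number
of individuals covered at 2x, suppression of clustered candidates (within
5 bp on the same contig), and suppression of sites where almost all
individuals were called heterozygous — the signature of co-assembled
duplicated loci.  Two readings of the published filter sentence are
implemented: a "conservative" all-exclusions mode (default) and a "literal"
mode in which proximity or pervasive heterozygosity waives the coverage
requirement.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indiv_caller import call_pileup, phred_to_error

__all__ = [
    "ErrorNull",
    "locus_rng",
    "simulate_second_counts",
    "simulate_error_null",
    "critical_value",
    "detect_potential_snps",
    "apply_population_filters",
    "write_vcf",
]


def locus_rng(seed: int, contig_id: str, position: int) -> np.random.Generator:
    """Per-locus RNG stream derived from (seed, contig, position).

    Results are therefore independent of the order in which loci are
    processed.
    """
    key = zlib.crc32(f"{contig_id}:{position}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key, int(position)]))


def simulate_second_counts(
    errors: np.ndarray, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Second-allele counts for ``reps`` error-only replicates of one locus.

    ``errors`` holds the per-copy error probabilities e_1..e_N (replicate r
    reuses the same positional e_j values as the data).  Each copy misreads
    with probability e_j; a misread lands on each of the three non-major
    bases with probability 1/3.  Returns the per-replicate maximum count
    over the three alternative bases.
    """
    errors = np.asarray(errors, dtype=float)
    n_err = (rng.random((reps, errors.size)) < errors).sum(axis=1)
    alt_counts = rng.multinomial(n_err, [1.0 / 3.0] * 3)
    return alt_counts.max(axis=1)


@dataclass
class ErrorNull:
    """Monte-Carlo null distribution of the second-allele count at one locus."""

    contig_id: str
    position: int
    reps: int
    histogram: np.ndarray = field(repr=False)  # histogram[c] = #replicates with count c
    alpha: float
    seed: int

    @property
    def critical_value(self) -> int:
        return critical_value(self, self.alpha)

    def tail_probability(self, count: int) -> float:
        """Empirical P(second-allele count >= count) under the null."""
        if count <= 0:
            return 1.0
        if count >= self.histogram.size:
            return 0.0
        return float(self.histogram[count:].sum() / self.reps)


def simulate_error_null(
    errors: np.ndarray,
    contig_id: str = ".",
    position: int = 0,
    reps: int = 10_000,
    alpha: float = 0.001,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> ErrorNull:
    """Build the error-model null for a locus with copy error probs ``errors``.

    Deterministic given ``seed`` (a per-locus stream is derived from seed,
    contig and position unless an explicit ``rng`` is passed).  Fewer than
    1,000 replicates triggers a warning: the 0.001 tail is then unstable.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size < 1:
        raise ValueError("locus must have at least one allele copy")
    if reps < 1000:
        warnings.warn(
            f"reps={reps} < 1000: critical value unstable at alpha={alpha}",
            stacklevel=2,
        )
    if rng is None:
        rng = locus_rng(seed, contig_id, position)
    counts = simulate_second_counts(errors, reps, rng)
    histogram = np.bincount(counts, minlength=errors.size + 1)
    return ErrorNull(
        contig_id=contig_id,
        position=position,
        reps=reps,
        histogram=histogram,
        alpha=alpha,
        seed=seed,
    )


def critical_value(null: ErrorNull, alpha: float | None = None) -> int:
    """Smallest count c with empirical right tail P(count >= c) <= alpha.

    A locus is flagged when its observed second-allele count is >= c.  With
    alpha = 1 this returns 0 (everything flagged); with an error-free null
    (all mass at 0) it returns 1.
    """
    if alpha is None:
        alpha = null.alpha
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    # right tail at c, for c = 0 .. len(histogram)
    tail = np.concatenate([np.cumsum(null.histogram[::-1])[::-1], [0]]) / null.reps
    passing = np.nonzero(tail <= alpha)[0]
    return int(passing[0])


def _pooled_locus_stats(group: pd.DataFrame) -> tuple[str, str | None, int]:
    """(major, second allele, second count) for one pooled pileup position."""
    counts = group["base"].value_counts()
    order = sorted(counts.index, key=lambda b: (-counts[b], b))
    major = order[0]
    if len(order) < 2:
        return major, None, 0
    second = order[1]
    return major, second, int(counts[second])


def detect_potential_snps(
    pileup: pd.DataFrame,
    indiv_calls: pd.DataFrame | None = None,
    reps: int = 10_000,
    alpha: float = 0.001,
    seed: int = 0,
    second_mode: str = "second_allele",
    prior: float = 1e-4,
    lrt_alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen every multi-allelic pooled position against its error null.

    ``pileup`` columns: contig, pos, individual, base, phred.  ``indiv_calls``
    is the output of :func:`fundusnp.indiv_caller.call_pileup`; when omitted
    it is computed from the pileup.  ``second_mode`` selects the tested
    statistic: ``'second_allele'`` (copy count of the most frequent non-major
    base, the default) or ``'all_nonmajor'`` (total non-major copies).

    Returns one record per multi-allelic position with columns contig, pos,
    major, second, second_count, critical_value, passed_null, n_indiv_2x,
    het_fraction.
    """
    required = {"contig", "pos", "individual", "base", "phred"}
    missing = required - set(pileup.columns)
    if missing:
        raise ValueError(f"pileup is missing columns: {sorted(missing)}")
    if pileup["individual"].isna().any():
        raise ValueError("pileup rows must carry individual labels")
    if second_mode not in ("second_allele", "all_nonmajor"):
        raise ValueError(f"unknown second_mode {second_mode!r}")
    if indiv_calls is None:
        indiv_calls = call_pileup(pileup, prior=prior, lrt_alpha=lrt_alpha)

    het_lookup: dict[tuple[str, int], float] = {}
    for (contig, pos), grp in indiv_calls.groupby(["contig", "pos"], sort=False):
        callable_ = grp[grp["final_class"] != "NOCALL"]
        het_lookup[(contig, int(pos))] = (
            float((callable_["final_class"] == "HET").mean()) if len(callable_) else 0.0
        )

    records = []
    for (contig, pos), grp in pileup.groupby(["contig", "pos"], sort=True):
        pos = int(pos)
        major, second, second_count = _pooled_locus_stats(grp)
        if second is None:
            continue  # monoallelic position: not a candidate
        if second_mode == "all_nonmajor":
            second_count = int((grp["base"] != major).sum())
        errors = phred_to_error(grp["phred"].to_numpy(dtype=float))
        null = simulate_error_null(
            errors, contig_id=contig, position=pos, reps=reps, alpha=alpha, seed=seed
        )
        crit = critical_value(null, alpha)
        depth_per_ind = grp.groupby("individual").size()
        records.append(
            {
                "contig": contig,
                "pos": pos,
                "major": major,
                "second": second,
                "second_count": second_count,
                "critical_value": crit,
                "passed_null": bool(second_count >= crit),
                "n_indiv_2x": int((depth_per_ind >= 2).sum()),
                "het_fraction": het_lookup.get((contig, pos), 0.0),
            }
        )
    return pd.DataFrame(
        records,
        columns=[
            "contig", "pos", "major", "second", "second_count",
            "critical_value", "passed_null", "n_indiv_2x", "het_fraction",
        ],
    )


def apply_population_filters(
    records: pd.DataFrame,
    min_indiv_2x: int = 3,
    proximity_bp: int = 5,
    max_het_fraction: float = 0.90,
    mode: str = "conservative",
) -> pd.DataFrame:
    """Apply the homolog-artifact filters and set ``final_pass``.

    Conservative mode (default) requires every condition: the null is
    exceeded, at least ``min_indiv_2x`` individuals have 2x coverage, no
    other null-passing candidate lies within ``proximity_bp`` bases on the
    same contig, and the individual-level heterozygote fraction is not above
    ``max_het_fraction``.  Literal mode instead waives the coverage
    requirement when the proximity or heterozygosity clause holds.  The
    operation is idempotent: it only reads ``passed_null`` and writes
    ``near_snp_within_5bp`` and ``final_pass``.
    """
    if mode not in ("conservative", "literal"):
        raise ValueError(f"unknown filter mode {mode!r}")
    out = records.copy()
    near = np.zeros(len(out), dtype=bool)
    passed = out["passed_null"].to_numpy(dtype=bool)
    contigs = out["contig"].to_numpy()
    positions = out["pos"].to_numpy()
    for i in range(len(out)):
        if not passed[i]:
            continue
        same = (contigs == contigs[i]) & passed
        dist = np.abs(positions - positions[i])
        near[i] = bool(np.any(same & (dist <= proximity_bp) & (dist > 0)))
    out["near_snp_within_5bp"] = near
    cov_ok = out["n_indiv_2x"].to_numpy() >= min_indiv_2x
    het_bad = out["het_fraction"].to_numpy() > max_het_fraction
    if mode == "conservative":
        out["final_pass"] = passed & cov_ok & ~near & ~het_bad
    else:
        out["final_pass"] = passed & (cov_ok | near | het_bad)
    return out


def write_vcf(records: pd.DataFrame, path) -> None:
    """Write candidate records as a minimal VCF 4.2 (1-based positions).

    FILTER encodes which rule failed (PASS, null, coverage, proximity,
    het_excess); INFO carries the second-allele count, the null critical
    value, the 2x-individual count and the heterozygote fraction.
    """
    lines = [
        "##fileformat=VCFv4.2",
        "##source=fundusnp",
        '##INFO=<ID=SC,Number=1,Type=Integer,Description="Second-allele copy count">',
        '##INFO=<ID=CV,Number=1,Type=Integer,Description="Error-null critical value">',
        '##INFO=<ID=NI2X,Number=1,Type=Integer,Description="Individuals covered at 2x">',
        '##INFO=<ID=HF,Number=1,Type=Float,Description="Individual-level heterozygote fraction">',
        '##FILTER=<ID=null,Description="Second-allele count below error-null critical value">',
        '##FILTER=<ID=coverage,Description="Fewer individuals at 2x than required">',
        '##FILTER=<ID=proximity,Description="Another candidate within the proximity window">',
        '##FILTER=<ID=het_excess,Description="Heterozygote fraction above threshold">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    has_final = "final_pass" in records.columns
    for _, rec in records.iterrows():
        fails = []
        if not rec["passed_null"]:
            fails.append("null")
        if has_final and not rec["final_pass"]:
            if rec.get("n_indiv_2x", 0) < 3:
                fails.append("coverage")
            if rec.get("near_snp_within_5bp", False):
                fails.append("proximity")
            if rec.get("het_fraction", 0.0) > 0.90:
                fails.append("het_excess")
        filt = "PASS" if not fails else ";".join(dict.fromkeys(fails))
        info = (
            f"SC={int(rec['second_count'])};CV={int(rec['critical_value'])};"
            f"NI2X={int(rec['n_indiv_2x'])};HF={rec['het_fraction']:.4f}"
        )
        lines.append(
            f"{rec['contig']}\t{int(rec['pos']) + 1}\t.\t{rec['major']}\t"
            f"{rec['second']}\t.\t{filt}\t{info}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
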