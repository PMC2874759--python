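"""End-to-end orchestration: demux -> filter -> individual calls -> population
SNP detection -> population genetics, with a reproducible run manifest.

All stage outputs, a machine-readable manifest (configuration, input
checksums, package version) and a log are written into the run directory.
Given the same manifest and seed, outputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .indiv_caller import call_pileup
from .pop_caller import apply_population_filters, detect_potential_snps, write_vcf
from .popgen import (
    GenotypeMatrix,
    amova,
    fst_matrix,
    mantel_test,
    qc_filter,
    read_distance_csv,
    summarize_population,
)
from .read_qc import BarcodeTable, demultiplex, demux_report, filter_reads, read_fastq, write_fastq

__all__ = ["run_pipeline", "load_pileup", "PipelineError"]

PILEUP_COLUMNS = ["contig", "pos", "individual", "base", "phred"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_pileup(path: str | Path) -> pd.DataFrame:
    """Read a pileup TSV (contig, pos, individual, base, phred), validating
    each row; a corrupt row raises with the file and line number."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise PipelineError(f"{path}: pileup is missing columns {sorted(missing)}")
    for col, caster in (("pos", int), ("phred", int)):
        try:
            df[col] = df[col].astype(caster)
        except (TypeError, ValueError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise PipelineError(
                f"{path}: line {bad + 2}: non-integer value in column {col!r}"
            ) from None
    bad_base = ~df["base"].isin(list("ACGTN"))
    if bad_base.any():
        raise PipelineError(
            f"{path}: line {int(df.index[bad_base][0]) + 2}: invalid base "
            f"{df.loc[df.index[bad_base][0], 'base']!r}"
        )
    return df


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    fastq: str | Path | None = None,
    barcodes: str | Path | None = None,
    pileup: str | Path | None = None,
    genotypes: str | Path | None = None,
    quality_flags: str | Path | None = None,
    geo_dist: str | Path | None = None,
) -> Path:
    """Execute the configured stages; return the run directory.

    Read stages run when ``fastq``+``barcodes`` are given; variant stages
    when a ``pileup`` is given; population-genetic stages when a
    ``genotypes`` CSV is given (with Mantel when ``geo_dist`` is also
    given).  On failure a FAILED marker naming the stage is left in the run
    directory and :class:`PipelineError` is raised; partial outputs are
    retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("fundusnp")
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    inputs = {
        name: str(p)
        for name, p in (
            ("fastq", fastq), ("barcodes", barcodes), ("pileup", pileup),
            ("genotypes", genotypes), ("quality_flags", quality_flags),
            ("geo_dist", geo_dist),
        )
        if p is not None
    }
    manifest = {
        "fundusnp_version": __version__,
        "config": config.to_dict(),
        "inputs": {k: {"path": v, "sha256": _sha256(Path(v))} for k, v in inputs.items()},
    }
    log.info("run configuration: %s", json.dumps(config.to_dict(), sort_keys=True))

    stage = "setup"
    try:
        if fastq is not None and barcodes is not None:
            stage = "demux"
            reads = read_fastq(fastq, quality_offset=config.quality_offset)
            table = BarcodeTable.from_tsv(barcodes)
            assigned, unassigned = demultiplex(reads, table, config.max_barcode_mismatch)
            stage = "filter"
            kept, n_amb, n_short = filter_reads(assigned, config.min_read_length)
            report = demux_report(assigned, unassigned, kept, n_amb, n_short)
            report.to_csv(out / "read_qc_report.tsv", sep="\t", index=False)
            by_ind: dict[str, list] = {}
            for r in kept:
                by_ind.setdefault(r.individual_id, []).append(r)
            for ind, rlist in sorted(by_ind.items()):
                write_fastq(rlist, out / f"reads_{ind}.fastq")
            log.info(
                "demux/filter: %d assigned, %d unassigned, %d kept "
                "(%d ambiguous, %d short)",
                len(assigned), len(unassigned), len(kept), n_amb, n_short,
            )

        if pileup is not None:
            stage = "call-indiv"
            pile = load_pileup(pileup)
            indiv = call_pileup(
                pile,
                prior=config.prior,
                lrt_alpha=config.lrt_alpha,
                lrt_rejection_to_hom=config.lrt_rejection_to_hom,
                null_dist=config.lrt_null,
            )
            indiv.to_csv(out / "indiv_calls.tsv", sep="\t", index=False, float_format="%.6g")
            stage = "call-pop"
            records = detect_potential_snps(
                pile,
                indiv_calls=indiv,
                reps=config.reps,
                alpha=config.alpha,
                seed=config.seed,
                second_mode=config.second_mode,
            )
            records = apply_population_filters(
                records,
                min_indiv_2x=config.min_indiv_2x,
                proximity_bp=config.proximity_bp,
                max_het_fraction=config.max_het_fraction,
                mode=config.filter_mode,
            )
            records.to_csv(out / "snp_report.tsv", sep="\t", index=False, float_format="%.6g")
            write_vcf(records, out / "snps.vcf")
            log.info(
                "call-pop: %d candidates, %d passed all filters",
                len(records), int(records["final_pass"].sum()),
            )

        if genotypes is not None:
            stage = "popgen"
            gm = GenotypeMatrix.from_csv(genotypes, quality_path=quality_flags)
            gm, qc_report = qc_filter(
                gm,
                min_call_rate=config.min_call_rate,
                max_low_prob_fraction=config.max_low_prob_fraction,
                max_missing_per_locus=config.max_missing,
                het_excess_threshold=config.het_excess_threshold,
            )
            qc_report.to_csv(out / "genotype_qc_report.tsv", sep="\t", index=False)
            rows = []
            for pop in dict.fromkeys(gm.populations):
                s = summarize_population(
                    gm, pop,
                    max_missing=config.max_missing,
                    hwe_alpha=config.hwe_alpha,
                    f_mode=config.f_mode,
                    n_perm=config.n_perm,
                    seed=config.seed,
                )
                rows.append(asdict(s))
            pd.DataFrame(rows).to_csv(
                out / "popgen_summary.csv", index=False, float_format="%.6g"
            )
            res = amova(gm, n_perm=min(config.n_perm, 1000), seed=config.seed)
            amova_rows = [
                {
                    "stratum": k,
                    "sigma2": res.sigma2[k],
                    "percent": res.percentages[k],
                }
                for k in res.sigma2
            ]
            amova_df = pd.DataFrame(amova_rows)
            for k, v in res.phi.items():
                amova_df[k] = v
            for k, v in res.p_values.items():
                amova_df[f"p_{k}"] = v
            amova_df.to_csv(out / "amova.csv", index=False, float_format="%.6g")
            if geo_dist is not None:
                stage = "mantel"
                d_geo = read_distance_csv(geo_dist)
                d_gen = fst_matrix(gm)
                m = mantel_test(
                    d_gen, d_geo, n_perm=config.mantel_perm, seed=config.seed
                )
                (out / "mantel.txt").write_text(
                    f"r\t{m.r:.6g}\np_value\t{m.p_value:.6g}\n"
                    f"n_permutations\t{m.n_permutations}\n"
                )
            log.info("popgen: %d loci after QC", gm.n_loci)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        log.error("stage %s failed: %s", stage, exc)
        log.removeHandler(handler)
        handler.close()
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.removeHandler(handler)
    handler.close()
    return out
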