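"""VCF and table input/output.

Reading goes through :mod:`cyvcf2`; writing emits minimal, valid VCF v4.2
text (one biallelic SNP per record, GT-only FORMAT) so that a written
cohort round-trips exactly through the reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotypes import (
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    make_variant_table,
)

logger = logging.getLogger(__name__)

_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def _calls_from_record(rec) -> np.ndarray:
    # allele-level decoding so half-missing genotypes (./1) become MISSING
    alleles = rec.genotype.array()[:, :2]
    calls = alleles.sum(axis=1).astype(np.int8)
    calls[(alleles < 0).any(axis=1)] = MISSING
    return calls


@dataclass
class ReadReport:
    n_records: int = 0
    n_kept: int = 0
    n_skipped_multiallelic: int = 0
    n_skipped_non_snp: int = 0


def read_population_map(path) -> dict[str, str]:
    """Two-column TSV (sample, population) -> dict."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                sample, pop = line.split()[:2]
                mapping[sample] = pop
    return mapping


def write_population_map(matrix: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        for sample, pop in zip(matrix.samples, matrix.populations):
            fh.write(f"{sample}\t{pop}\n")


def read_genotypes(
    vcf_path, population_map: dict[str, str] | str
) -> tuple[GenotypeMatrix, pd.DataFrame, ReadReport]:
    """Read a VCF into a genotype matrix.

    Multiallelic records and non-SNP alleles are skipped (counted in the
    returned report); half-missing genotypes become MISSING.  Every sample
    must appear in ``population_map``.
    """
    if isinstance(population_map, (str, bytes)) or hasattr(population_map, "__fspath__"):
        population_map = read_population_map(population_map)
    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    for s in samples:
        if s not in population_map:
            raise ValueError(f"sample {s!r} absent from population map")

    report = ReadReport()
    rows, chroms, poss, ids, refs, alts = [], [], [], [], [], []
    for rec in vcf:
        report.n_records += 1
        if len(rec.ALT) != 1:
            report.n_skipped_multiallelic += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            report.n_skipped_non_snp += 1
            continue
        rows.append(_calls_from_record(rec))
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        ids.append(rec.ID or ".")
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
    report.n_kept = len(rows)
    if report.n_skipped_multiallelic or report.n_skipped_non_snp:
        logger.info(
            "skipped %d multiallelic and %d non-SNP records",
            report.n_skipped_multiallelic, report.n_skipped_non_snp,
        )
    calls = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    variants = make_variant_table(chroms, poss, ref=refs, alt=alts, ids=ids)
    matrix = GenotypeMatrix(calls, samples, [population_map[s] for s in samples])
    return matrix, variants, report


def write_vcf(matrix: GenotypeMatrix, variants: pd.DataFrame, path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal VCF v4.2 with GT-only genotypes."""
    if matrix.n_variants != len(variants):
        raise ValueError("matrix and variant table have inconsistent dimensions")
    chrom = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy()
    vid = variants["id"].to_numpy()
    ref = variants["ref"].to_numpy()
    alt = variants["alt"].to_numpy()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        seen = dict.fromkeys(chrom)
        for c in seen:
            if contig_lengths and c in contig_lengths:
                fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples) + "\n"
        )
        calls = matrix.calls
        for j in range(len(variants)):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in calls[:, j])
            fh.write(
                f"{chrom[j]}\t{pos[j]}\t{vid[j]}\t{ref[j]}\t{alt[j]}\t.\t.\t.\tGT\t{gts}\n"
            )


def write_cohort(matrix: GenotypeMatrix, variants: pd.DataFrame, out_dir,
                 contig_lengths: dict[str, int] | None = None) -> dict[str, str]:
    """Write VCF + population map (+ chromosome-length table if known)."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "population_map": os.path.join(out_dir, "populations.tsv"),
    }
    write_vcf(matrix, variants, paths["vcf"], contig_lengths)
    write_population_map(matrix, paths["population_map"])
    if contig_lengths:
        paths["chromosome_lengths"] = os.path.join(out_dir, "chromosome_lengths.tsv")
        with open(paths["chromosome_lengths"], "w") as fh:
            for c, length in contig_lengths.items():
                fh.write(f"{c}\t{length}\n")
    return paths
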