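"""End-to-end orchestration: simulate/load -> QC -> diversity -> ROH ->
summaries -> islands -> overlaps, driven by a single YAML config.

Every number written to the report bundle is produced by the module
operations; the pipeline only composes and serializes them.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import diversity, islands as isl, qc, report, simulate, stats
from .detection import ROHSet, ScanParams, scan_cohort, write_segments_bed, write_segments_tsv
from .genotypes import GenotypeMatrix
from .io import read_genotypes, write_cohort
from .simulate import GenomeLayout, PopulationProfile

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for malformed pipeline configuration."""


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "rohscan_out"
    # exactly one of (simulation) or (vcf + population_map) must be set
    simulation: dict | None = None
    vcf: str | None = None
    population_map: str | None = None
    chromosome_lengths: str | None = None
    annotations: str | None = None
    min_callrate: float = 0.1
    hwe_alpha: float = 1e-6
    scan: ScanParams = field(default_factory=ScanParams)
    genome_bp: int = stats.DEFAULT_GENOME_BP
    island_top_fraction: float = 0.01
    island_max_gap_kb: float = 1000.0
    island_min_snps: int = 2

    def validate(self) -> None:
        has_sim = self.simulation is not None
        has_files = self.vcf is not None
        if has_sim == has_files:
            raise ConfigError(
                "config must provide exactly one of a simulation block or "
                "input file paths"
            )
        if has_files:
            if self.population_map is None:
                raise ConfigError("input mode requires a population map")
            for p in (self.vcf, self.population_map, self.chromosome_lengths,
                      self.annotations):
                if p is not None and not os.path.exists(p):
                    raise ConfigError(f"input file not found: {p}")
        elif self.annotations is not None and not os.path.exists(self.annotations):
            raise ConfigError(f"input file not found: {self.annotations}")


def _layout_from_config(block: dict) -> GenomeLayout:
    chroms = tuple((str(n), int(l)) for n, l in block["chromosomes"])
    return GenomeLayout(chromosomes=chroms,
                        snp_density=float(block.get("snp_density", 1 / 5000)))


def _profiles_from_config(block: list[dict]) -> tuple[PopulationProfile, ...]:
    bins = {f"{lo:g}-{hi:g}" if hi is not None else f">{lo:g}": (lo, hi)
            for lo, hi in simulate.LENGTH_CLASS_BINS_MB}
    profiles = []
    for p in block:
        tracts = tuple(
            (bins[str(k)], float(v)) for k, v in (p.get("tracts") or {}).items()
        )
        profiles.append(
            PopulationProfile(
                name=str(p["name"]),
                n_individuals=int(p["n_individuals"]),
                target_het=float(p["target_het"]),
                missing_rate=float(p.get("missing_rate", 0.0)),
                within_tract_het_rate=float(p.get("within_tract_het_rate", 0.0)),
                tract_length_distribution=tracts,
            )
        )
    return tuple(profiles)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    scan = ScanParams(**(raw.pop("scan", None) or {}))
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(scan=scan, **raw)
    cfg.validate()
    return cfg


def default_simulation_config(seed: int = 0, out_dir: str = "rohscan_out") -> PipelineConfig:
    """Desk-scale five-population simulation with all default profiles."""
    layout = simulate.default_layout()
    profiles = simulate.default_profiles()
    sim = {
        "layout": {
            "chromosomes": [[n, l] for n, l in layout.chromosomes],
            "snp_density": layout.snp_density,
        },
        "populations": [
            {
                "name": p.name,
                "n_individuals": p.n_individuals,
                "target_het": p.target_het,
                "missing_rate": p.missing_rate,
                "within_tract_het_rate": p.within_tract_het_rate,
                "tracts": {
                    (f"{lo:g}-{hi:g}" if hi is not None else f">{lo:g}"): c
                    for (lo, hi), c in p.tract_length_distribution
                },
            }
            for p in profiles
        ],
    }
    return PipelineConfig(seed=seed, out_dir=out_dir, simulation=sim,
                          genome_bp=layout.total_length)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle under ``config.out_dir``.

    Returns the in-memory results keyed by stage.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    log_lines: list[str] = [f"seed\t{config.seed}"]

    def _stage(name):
        logger.info("stage: %s", name)
        log_lines.append(f"stage\t{name}")

    results: dict = {}
    try:
        _stage("input")
        if config.simulation is not None:
            layout = _layout_from_config(config.simulation["layout"])
            profiles = _profiles_from_config(config.simulation["populations"])
            matrix, variants, truth = simulate.simulate_cohort(
                layout, profiles, config.seed
            )
            contigs = dict(layout.chromosomes)
            write_cohort(matrix, variants, config.out_dir, contigs)
            simulate.write_truth_bed(
                truth, os.path.join(config.out_dir, "truth_tracts.bed")
            )
            results["truth"] = truth
        else:
            matrix, variants, read_report = read_genotypes(
                config.vcf, config.population_map
            )
            log_lines.append(f"vcf_records_kept\t{read_report.n_kept}")
            if config.chromosome_lengths:
                layout = simulate.read_chromosome_lengths(config.chromosome_lengths)
            else:
                # fall back to last observed position per chromosome
                last = variants.groupby("chrom", sort=False)["pos"].max()
                layout = GenomeLayout(
                    chromosomes=tuple((c, int(p)) for c, p in last.items()),
                    snp_density=1 / 5000,
                )
        results["matrix"], results["variants"] = matrix, variants
        results["layout"] = layout
        log_lines.append(f"n_individuals\t{matrix.n_individuals}")
        log_lines.append(f"n_variants_input\t{matrix.n_variants}")

        _stage("qc")
        matrix, variants, qc_report = qc.filter_variants(
            matrix, variants, config.min_callrate, config.hwe_alpha
        )
        results["qc_report"] = qc_report
        qc_report.to_frame().to_csv(
            os.path.join(config.out_dir, "qc_report.tsv"), sep="\t", index=False
        )
        log_lines.append(f"n_variants_retained\t{qc_report.n_retained}")

        _stage("diversity")
        div = diversity.diversity_summary(matrix, variants)
        results["diversity"] = div
        report.write_diversity_table(
            div, os.path.join(config.out_dir, "diversity_summary.tsv")
        )

        _stage("roh")
        rohset = scan_cohort(matrix, variants, config.scan)
        results["rohset"] = rohset
        write_segments_tsv(rohset, os.path.join(config.out_dir, "roh_segments.tsv"))
        write_segments_bed(rohset, os.path.join(config.out_dir, "roh_segments.bed"))
        log_lines.append(f"n_roh_segments\t{len(rohset.segments)}")
        for name, value in dataclasses.asdict(config.scan).items():
            log_lines.append(f"scan.{name}\t{value}")

        _stage("stats")
        length_classes = stats.classify_lengths(rohset)
        froh = stats.f_roh(rohset, stats.GenomeSize(config.genome_bp))
        per_ind = stats.per_individual_summary(rohset)
        coverage = stats.chromosome_coverage(rohset, layout)
        results.update(
            length_classes=length_classes, froh=froh, per_individual=per_ind,
            coverage=coverage,
        )
        report.write_length_class_table(
            length_classes, os.path.join(config.out_dir, "roh_length_classes.tsv")
        )
        report.write_froh_table(
            stats.froh_population_summary(froh),
            os.path.join(config.out_dir, "froh_by_class.tsv"),
        )
        report.write_per_individual_table(
            per_ind, froh, diversity_fis={
                pop: diversity.wright_fis(matrix, pop) for pop in matrix.population_names()
            },
            path=os.path.join(config.out_dir, "roh_per_individual.tsv"),
        )
        coverage.to_csv(
            os.path.join(config.out_dir, "chromosome_coverage.tsv"),
            sep="\t", index=False, float_format="%.4f",
        )

        _stage("islands")
        all_islands: list = []
        thresholds: dict[str, float] = {}
        for pop in matrix.population_names():
            track = isl.snp_incidence(rohset, variants, pop)
            thr = isl.island_threshold(track, config.island_top_fraction)
            thresholds[pop] = thr
            all_islands.extend(
                isl.call_islands(
                    track, thr, population=pop,
                    max_gap_kb=config.island_max_gap_kb,
                    min_snps=config.island_min_snps,
                )
            )
            log_lines.append(f"island_threshold.{pop}\t{thr:.4f}")
        results["islands"] = all_islands
        results["island_thresholds"] = thresholds
        isl.islands_to_frame(all_islands).to_csv(
            os.path.join(config.out_dir, "roh_islands.tsv"),
            sep="\t", index=False, float_format="%.4f",
        )
        isl.write_islands_bed(
            all_islands, os.path.join(config.out_dir, "roh_islands.bed")
        )

        _stage("overlap")
        overlap_frames = []
        pops = matrix.population_names()
        by_pop = {
            p: [i.to_interval() for i in all_islands if i.population == p]
            for p in pops
        }
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                pairs = isl.intersect_intervals(by_pop[pops[i]], by_pop[pops[j]])
                overlap_frames.append(
                    isl.overlap_report(pairs, group_a=pops[i], group_b=pops[j])
                )
        if config.annotations:
            ann = isl.read_bed_intervals(config.annotations)
            for p in pops:
                pairs = isl.intersect_intervals(by_pop[p], ann)
                overlap_frames.append(
                    isl.overlap_report(pairs, group_a=p, group_b="annotation")
                )
        overlaps = (
            pd.concat(overlap_frames, ignore_index=True)
            if overlap_frames else isl.overlap_report([])
        )
        results["overlaps"] = overlaps
        overlaps.to_csv(
            os.path.join(config.out_dir, "island_overlaps.tsv"),
            sep="\t", index=False,
        )
    except ConfigError:
        raise
    except Exception as exc:  # annotate with the failing stage
        stage = log_lines[-1].split("\t")[-1]
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(os.path.join(config.out_dir, "run_log.tsv"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return results
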