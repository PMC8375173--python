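"""End-to-end survey orchestration: scan -> classify -> motifs -> summaries,
with optional Ka/Ks and expression stages, and a machine-readable report."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from zfsurvey._version import __version__ as _version
from zfsurvey.accessory_motifs import find_boxes, hits_to_table, read_library
from zfsurvey.errors import ConfigError
from zfsurvey.evolution import DEFAULT_LAMBDA, kaks_table, read_codon_pairs
from zfsurvey.expression import (
    categorize_levels,
    cluster_groups,
    expressed_filter,
    log_transform,
    read_tpm,
)
from zfsurvey.sequence_io import read_gene_models, read_protein_fasta, try_parse_gene_id
from zfsurvey.subset_classify import (
    assign_subset,
    assignments_to_table,
    build_architecture,
    dedupe_variants,
    summarize_family,
)
from zfsurvey.zf_scan import ScanParams, domains_to_table, scan_domains

logger = logging.getLogger(__name__)

ALL_STAGES = ("scan", "classify", "motifs", "kaks", "expression")


@dataclass
class RunConfig:
    """Inputs, thresholds and stage selection of one survey run."""

    protein_fasta: Optional[str] = None
    gff3: Optional[str] = None
    tpm: Optional[str] = None
    cds_pairs: Optional[str] = None
    motif_library: Optional[str] = None
    outdir: str = "zfsurvey_out"
    stages: tuple[str, ...] = ALL_STAGES
    scan_params: ScanParams = field(default_factory=ScanParams)
    min_tpm: float = 0.5
    min_samples: int = 1
    n_expression_groups: int = 5
    low_max: float = 1.0
    high_min: float = 5.0
    neutral_band: float = 0.05
    lam: float = DEFAULT_LAMBDA
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")
        needs_fasta = {"scan", "classify", "motifs"} & set(self.stages)
        if needs_fasta and not self.protein_fasta:
            raise ConfigError(f"stages {sorted(needs_fasta)} need protein_fasta")
        if "kaks" in self.stages and not self.cds_pairs:
            raise ConfigError("stage kaks needs cds_pairs")
        if "expression" in self.stages and not self.tpm:
            raise ConfigError("stage expression needs tpm")
        for path_attr in ("protein_fasta", "gff3", "tpm", "cds_pairs", "motif_library"):
            path = getattr(self, path_attr)
            if path and not Path(path).exists():
                raise ConfigError(f"{path_attr} path does not exist: {path}")
        if not (0 <= self.neutral_band < 1):
            raise ConfigError("neutral_band must be in [0, 1)")
        if self.min_tpm < 0 or self.min_samples < 1:
            raise ConfigError("expressed-filter thresholds out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a flat key-value mapping")
        scan_keys = {f.name for f in __import__("dataclasses").fields(ScanParams)}
        scan_kwargs = {k: raw.pop(k) for k in list(raw) if k in scan_keys}
        if "stages" in raw and isinstance(raw["stages"], str):
            raw["stages"] = tuple(s.strip() for s in raw["stages"].split(","))
        known = {f.name for f in __import__("dataclasses").fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys {sorted(bad)}")
        cfg = cls(**raw)
        if scan_kwargs:
            cfg.scan_params = ScanParams(**scan_kwargs)
        return cfg


@dataclass
class SurveyReport:
    outdir: Path
    completed_stages: list[str]
    counts: dict[str, int]
    summary: Optional[object] = None   # FamilySummary when classify ran


def run_survey(config: RunConfig) -> SurveyReport:
    """Run the requested stages, writing TSV tables and a MANIFEST to outdir.

    A failing stage leaves the completed stages' outputs in place; the
    MANIFEST records which stages finished.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    counts: dict[str, int] = {}
    summary = None
    log_lines = [f"zfsurvey {_version}", f"config: {config}"]

    def manifest() -> None:
        (outdir / "MANIFEST.json").write_text(json.dumps({
            "version": _version,
            "completed_stages": completed,
            "counts": counts,
        }, indent=2))
        (outdir / "run.log").write_text(
            "\n".join(log_lines + [f"finished: {time.strftime('%Y-%m-%dT%H:%M:%S')}"])
            + "\n"
        )

    try:
        records = None
        domains_by_protein = {}
        if {"scan", "classify", "motifs"} & set(config.stages):
            records = read_protein_fasta(config.protein_fasta)
            counts["proteins"] = len(records)
            log_lines.append(f"read {len(records)} proteins from {config.protein_fasta}")

        if "scan" in config.stages:
            all_domains = []
            for rec in records:
                doms = scan_domains(rec, config.scan_params)
                domains_by_protein[rec.id] = doms
                all_domains.extend(doms)
            domains_to_table(all_domains).to_csv(
                outdir / "domains.tsv", sep="\t", index=False)
            counts["domains"] = len(all_domains)
            log_lines.append(f"scan: {len(all_domains)} fingers")
            completed.append("scan")

        if "classify" in config.stages:
            if "scan" not in config.stages:
                raise ConfigError("classify requires the scan stage")
            assignments = []
            for rec in records:
                doms = domains_by_protein.get(rec.id, [])
                if doms:
                    assignments.append(assign_subset(build_architecture(doms)))
            gene_of = {}
            loci = {}
            for rec in records:
                locus, _ = try_parse_gene_id(rec.id)
                gene_of[rec.id] = (rec.gene_id, rec.variant)
                if any(d.protein_id == rec.id for d in domains_by_protein.get(rec.id, [])):
                    loci.setdefault(rec.gene_id, locus)
            assignments_to_table(assignments, gene_of).to_csv(
                outdir / "proteins.tsv", sep="\t", index=False)
            _, variant_report = dedupe_variants(assignments, gene_of)
            variant_report.to_csv(outdir / "variants.tsv", sep="\t", index=False)
            models = read_gene_models(config.gff3) if config.gff3 else None
            summary = summarize_family(assignments, loci, models)
            _write_summary(summary, outdir / "summary.tsv")
            counts["classified_proteins"] = len(assignments)
            counts["tandem"] = summary.tandem_count
            counts["isolated"] = summary.isolated_count
            log_lines.append(
                f"classify: {summary.tandem_count} tandem / "
                f"{summary.isolated_count} isolated"
            )
            completed.append("classify")

        if "motifs" in config.stages:
            if "scan" not in config.stages:
                raise ConfigError("motifs requires the scan stage")
            library = (read_library(config.motif_library)
                       if config.motif_library else None)
            hits = []
            for rec in records:
                hits.extend(find_boxes(rec, domains_by_protein.get(rec.id, []), library))
            hits_to_table(hits).to_csv(outdir / "motifs.tsv", sep="\t", index=False)
            counts["motif_hits"] = len(hits)
            log_lines.append(f"motifs: {len(hits)} hits")
            completed.append("motifs")

        if "kaks" in config.stages:
            pairs = read_codon_pairs(config.cds_pairs)
            table = kaks_table(pairs, neutral_band=config.neutral_band, lam=config.lam)
            table.to_csv(outdir / "kaks.tsv", sep="\t", index=False)
            counts["codon_pairs"] = len(pairs)
            log_lines.append(f"kaks: {len(pairs)} pairs")
            completed.append("kaks")

        if "expression" in config.stages:
            tpm = read_tpm(config.tpm)
            expressed = expressed_filter(tpm, config.min_tpm, config.min_samples)
            assignment = cluster_groups(expressed, k=config.n_expression_groups)
            out = assignment.groups.to_frame()
            out.to_csv(outdir / "expression_groups.tsv", sep="\t",
                       index_label="gene_id")
            logm = log_transform(expressed)
            try:
                categorize_levels(logm, config.low_max, config.high_min).to_csv(
                    outdir / "expression_levels.tsv", sep="\t", index_label="gene_id")
            except Exception:
                log_lines.append("expression: organ-level calls skipped "
                                 "(non-standard sample codes)")
            logm.reset_index(names="gene_id").melt(
                id_vars="gene_id", var_name="sample", value_name="log2_tpm"
            ).to_csv(outdir / "expression_long.tsv", sep="\t", index=False)
            counts["genes_total"] = len(tpm)
            counts["genes_expressed"] = len(expressed)
            log_lines.append(f"expression: {len(expressed)}/{len(tpm)} expressed")
            completed.append("expression")
    except Exception:
        manifest()
        raise
    manifest()
    return SurveyReport(outdir=outdir, completed_stages=completed,
                        counts=counts, summary=summary)


def _write_summary(summary, path: Path) -> None:
    """Summary TSV blocks: subsets, arrangement, chromosome x subgenome, arms, introns."""
    lines = ["block\tkey\tcount\tpercent"]
    for subset, n in summary.subset_counts.items():
        lines.append(f"subset\t{subset}\t{n}\t")
    lines.append(f"arrangement\ttandem\t{summary.tandem_count}\t{summary.tandem_pct}")
    lines.append(
        f"arrangement\tisolated\t{summary.isolated_count}\t{summary.isolated_pct}")
    for chrom in sorted(summary.chromosome_counts):
        lines.append(f"chromosome\t{chrom}\t{summary.chromosome_counts[chrom]}"
                     f"\t{summary.chromosome_pct[chrom]}")
    for (chrom, sub), n in sorted(summary.chrom_subgenome.items()):
        lines.append(f"chrom_subgenome\t{chrom}{sub}\t{n}\t")
    for sub in ("A", "B", "D"):
        lines.append(f"subgenome\t{sub}\t{summary.subgenome_counts.get(sub, 0)}"
                     f"\t{summary.subgenome_pct.get(sub, '')}")
    for arm in ("S", "L"):
        lines.append(f"arm\t{arm}\t{summary.arm_counts.get(arm, 0)}"
                     f"\t{summary.arm_pct.get(arm, '')}")
    for k in sorted(summary.intron_histogram):
        lines.append(f"introns\t{k}\t{summary.intron_histogram[k]}\t")
    lines.append(f"introns\tintronless\t{summary.intronless_genes}\t")
    path.write_text("\n".join(lines) + "\n")
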