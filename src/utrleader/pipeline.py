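"""End-to-end pipeline runner: preprocess -> filter -> infer -> consolidate
-> haplotype validation -> linkage disequilibrium.

Each stage writes its output to the run directory in the same text formats
the stage-level CLI commands use, so any intermediate can be re-loaded and
re-run independently.  All thresholds live in :class:`PipelineConfig`; the
defaults are the pipeline's standard operating point (30% base extraction,
50% coverage, 80% consolidation quorum, 75-CDR3/20-read allele filter, 0.95
segregation purity).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import consensus as cns
from . import filtering, linkage, preprocess, validation
from .io import (
    read_fastq_pairs,
    read_rearrangement_table,
    write_fasta,
    write_fastq,
)

logger = logging.getLogger("utrleader")


@dataclass
class PipelineConfig:
    window: int = preprocess.DEFAULT_WINDOW
    motif: str = preprocess.DEFAULT_MOTIF
    min_overlap: int = preprocess.DEFAULT_MIN_OVERLAP
    max_mismatch_frac: float = preprocess.DEFAULT_MAX_MISMATCH_FRAC
    min_unique_cdr3: int = filtering.MIN_UNIQUE_CDR3
    min_reads: int = filtering.MIN_READS
    base_threshold: float = cns.BASE_THRESHOLD
    coverage_threshold: float = cns.COVERAGE_THRESHOLD
    length_quorum: float = cns.LENGTH_QUORUM
    min_purity: float = validation.MIN_PURITY
    min_reads_segregation: int = validation.MIN_READS_SEGREGATION
    match_min_overlap: int = validation.MIN_MATCH_OVERLAP
    min_minor_fraction: float = 0.1
    j_gene: str = validation.DEFAULT_J_GENE
    maf_threshold: float = validation.MAF_THRESHOLD
    ld_min_observed: int = linkage.MIN_OBSERVED
    field_map: dict = field(default_factory=dict)
    leader_lengths: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("base_threshold", "coverage_threshold", "length_quorum",
                     "min_purity"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name}: {value} outside (0, 1]")
        for name in ("min_unique_cdr3", "min_reads", "min_reads_segregation",
                     "ld_min_observed"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, subject: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for subject {subject!r}: {cause}")
        self.stage = stage
        self.subject = subject


def run_pipeline(
    config: PipelineConfig,
    manifest: Mapping[str, Mapping[str, str]],
    outdir: str | Path,
) -> dict:
    """Run all stages over a per-subject file manifest.

    ``manifest`` maps subject id -> {"fwd": R1 fastq, "rev": R2 fastq,
    "table": annotated rearrangement TSV}; "fwd"/"rev" may be omitted to
    skip pre-processing (annotation is always consumed from the table).
    Returns the machine-readable summary, also written to ``summary.json``.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for subject, files in manifest.items():
        for key, path in files.items():
            if not Path(path).exists():
                raise FileNotFoundError(
                    f"manifest entry {subject!r}/{key!r}: missing file {path}"
                )

    summary: dict = {"subjects": {}, "alleles": {}, "linkage": []}
    filtered_by_subject: dict[str, list] = {}
    groups_by_subject: dict[str, list] = {}
    per_allele_records: dict[str, list] = defaultdict(list)

    for subject, files in manifest.items():
        ssum: dict = {}
        # --- preprocess ------------------------------------------------
        if "fwd" in files and "rev" in files:
            try:
                joined, rejects, report = preprocess.preprocess_pairs(
                    read_fastq_pairs(files["fwd"], files["rev"]),
                    window=config.window,
                    core_motif=config.motif,
                    min_overlap=config.min_overlap,
                    max_mismatch_frac=config.max_mismatch_frac,
                )
            except Exception as exc:  # noqa: BLE001 - abort names the stage
                raise StageError("preprocess", subject, exc) from exc
            write_fastq(joined, outdir / f"{subject}_joined.fastq")
            ssum["preprocess"] = report.to_dict()
        # --- filter ----------------------------------------------------
        try:
            rows = list(
                read_rearrangement_table(files["table"], config.field_map)
            )
            groups, n_ambiguous = filtering.group_alleles(rows, subject)
            kept = filtering.filter_alleles(
                groups, config.min_unique_cdr3, config.min_reads
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("filter", subject, exc) from exc
        filtered_rows = [r for g in kept for r in g.reads]
        filtered_by_subject[subject] = rows
        groups_by_subject[subject] = kept
        ssum["filter"] = {
            "n_rows": len(rows),
            "n_ambiguous_v_call": n_ambiguous,
            "n_allele_groups": len(groups),
            "n_allele_groups_kept": len(kept),
            "n_filtered_reads": len(filtered_rows),
        }
        # --- infer -----------------------------------------------------
        inferred = 0
        for group in kept:
            try:
                records = cns.build_consensus(
                    [r.upstream_seq for r in group.reads],
                    base_threshold=config.base_threshold,
                    coverage_threshold=config.coverage_threshold,
                    subject_id=subject,
                    allele=group.allele,
                )
            except Exception as exc:  # noqa: BLE001
                raise StageError("infer", subject, exc) from exc
            per_allele_records[group.allele].extend(records)
            inferred += len(records)
        ssum["infer"] = {"n_consensus_records": inferred}
        summary["subjects"][subject] = ssum

    # --- consolidate ---------------------------------------------------
    variants_by_allele: dict[str, list[cns.ConsolidatedVariant]] = {}
    fasta_records, descriptions = [], {}
    for allele, records in sorted(per_allele_records.items()):
        variants = cns.consolidate(records, config.length_quorum)
        variants_by_allele[allele] = variants
        flags = cns.flag_artifacts(variants, core_motif=config.motif)
        summary["alleles"][allele] = {
            "n_subject_records": len(records),
            "variants": {
                v.label: {
                    "length": len(v.sequence),
                    "subject_count": v.subject_count,
                }
                for v in variants
            },
            "artifact_flags": [
                {"variant": f.variant, "reason": f.reason} for f in flags
            ],
        }
        for v in variants:
            fasta_records.append((v.name, v.sequence))
            descriptions[v.name] = f"subjects={v.subject_count}"
    if fasta_records:
        write_fasta(fasta_records, outdir / "variants.fasta", descriptions)

    # --- validate (haplotype segregation) -------------------------------
    haplotype_records: list[linkage.HaplotypeRecord] = []
    genes = sorted({a.split("*")[0] for a in variants_by_allele})
    for subject, rows in filtered_by_subject.items():
        zero_err = [r for r in rows if r.v_errors == 0]
        pair = validation.detect_j_heterozygosity(
            zero_err, config.min_minor_fraction, config.j_gene
        )
        vsum = summary["subjects"][subject]
        if pair is None:
            vsum["haplotype"] = {"heterozygous": False}
            continue
        table = validation.haplotype_counts(
            zero_err, variants_by_allele, pair, subject,
            config.match_min_overlap,
        )
        calls = validation.call_segregation(
            table, config.min_purity, config.min_reads_segregation
        )
        vsum["haplotype"] = {
            "heterozygous": True,
            "j_allele_pair": list(pair),
            "counts": {
                f"{a}-{l}": list(c) for (a, l), c in table.rows.items()
            },
            "calls": [
                {
                    "variant": f"{c.variant[0]}-{c.variant[1]}",
                    "assigned_j_allele": c.assigned_j_allele,
                    "purity": c.purity,
                    "total_reads": c.total_reads,
                    "validated": c.validated,
                }
                for c in calls
            ],
        }
        # haplotype records for the LD panel
        for j_allele in pair:
            assignment = {}
            for gene in genes:
                token = linkage.ABSENT
                for call in calls:
                    if (
                        call.validated
                        and call.assigned_j_allele == j_allele
                        and call.variant[0].split("*")[0] == gene
                    ):
                        token = f"{call.variant[0]}-{call.variant[1]}"
                        break
                assignment[gene] = token
            haplotype_records.append(
                linkage.HaplotypeRecord(f"{subject}|{j_allele}", assignment)
            )

    # --- linkage disequilibrium -----------------------------------------
    if haplotype_records and genes:
        stats = linkage.combo_stats(
            haplotype_records, genes, config.ld_min_observed
        )
        summary["linkage"] = [
            {
                "combo": list(s.combo),
                "observed": s.observed,
                "expected": s.expected,
                "ratio": s.ratio,
            }
            for s in stats
        ]
        summary["linkage_genes"] = genes
        summary["n_haplotypes"] = len(haplotype_records)

    with open(outdir / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
    return summary
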