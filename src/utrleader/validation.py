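"""Validation of inferred upstream variants.

Four independent lines of evidence support an inferred upstream variant:

* haplotype segregation — in a subject heterozygous at the anchor J gene
  (IGHJ6 in practice), transcripts carrying a genuine germline upstream
  variant derive from one chromosome and should associate almost exclusively
  with one J allele;
* CDR3-length diversity — a genuine variant is expressed by many independent
  rearrangements, visible as a broad CDR3 amino-acid length distribution;
* raw-read base ratios at the 5' fringe (base -93 of the 92-base upstream
  regions typical of the IGHV4 subgroup) per haplotype;
* population genomics — diversified upstream positions should correspond to
  SNPs segregating at non-negligible minor allele frequency.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .consensus import ConsolidatedVariant
from .io import Rearrangement

logger = logging.getLogger("utrleader")

DEFAULT_J_GENE = "IGHJ6"
MIN_PURITY = 0.95
MIN_READS_SEGREGATION = 5
MIN_MATCH_OVERLAP = 30
MAF_THRESHOLD = 0.01


@dataclass
class HaplotypeCountTable:
    """Per-variant read counts split by the two J alleles of a het subject."""

    subject_id: str
    j_allele_pair: tuple[str, str]
    rows: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)


@dataclass(frozen=True)
class SegregationCall:
    variant: tuple[str, str]  # (allele, label)
    assigned_j_allele: str
    purity: float
    total_reads: int
    validated: bool


@dataclass(frozen=True)
class PopulationVariant:
    contig: str
    position: int  # 1-based, VCF convention
    ref: str
    alt: str
    maf: float


def detect_j_heterozygosity(
    rows: Iterable[Rearrangement],
    min_minor_fraction: float = 0.1,
    j_gene: str = DEFAULT_J_GENE,
) -> tuple[str, str] | None:
    """Return the subject's two anchor-J alleles, or None if homozygous.

    Both alleles must each account for at least ``min_minor_fraction`` of the
    reads assigned to the anchor gene.  The pair is returned in lexicographic
    order.
    """
    counts = Counter(
        row.j_call for row in rows if row.j_call.split("*")[0] == j_gene
    )
    total = sum(counts.values())
    if total == 0 or len(counts) < 2:
        return None
    (a1, c1), (a2, c2) = counts.most_common(2)
    if c2 / total < min_minor_fraction:
        return None
    return tuple(sorted((a1, a2)))  # type: ignore[return-value]


def match_upstream_to_variant(
    upstream_seq: str,
    variants: Sequence[ConsolidatedVariant],
    min_overlap: int = MIN_MATCH_OVERLAP,
) -> ConsolidatedVariant | None:
    """Assign a read's upstream segment to exactly one variant, or None.

    A read matches a variant when it is identical to it over the read's full
    3'-anchored overlap and that overlap spans at least ``min_overlap``
    bases.  Reads compatible with more than one variant are ambiguous and
    dropped.
    """
    hits = []
    for v in variants:
        ov = min(len(upstream_seq), len(v.sequence))
        if ov >= min_overlap and upstream_seq[-ov:] == v.sequence[-ov:]:
            hits.append(v)
    return hits[0] if len(hits) == 1 else None


def haplotype_counts(
    rows: Iterable[Rearrangement],
    variants_by_allele: Mapping[str, Sequence[ConsolidatedVariant]],
    j_allele_pair: tuple[str, str],
    subject_id: str = "",
    min_overlap: int = MIN_MATCH_OVERLAP,
) -> HaplotypeCountTable:
    """Count, per upstream variant, reads associated with each J allele."""
    counts: dict[tuple[str, str], list[int]] = defaultdict(lambda: [0, 0])
    for allele, variants in variants_by_allele.items():
        for v in variants:
            counts[(allele, v.label)]  # materialise (0,0) rows
    for row in rows:
        if row.j_call not in j_allele_pair:
            continue
        variants = variants_by_allele.get(row.v_call)
        if not variants:
            continue
        match = match_upstream_to_variant(row.upstream_seq, variants, min_overlap)
        if match is None:
            continue
        counts[(row.v_call, match.label)][j_allele_pair.index(row.j_call)] += 1
    return HaplotypeCountTable(
        subject_id=subject_id,
        j_allele_pair=j_allele_pair,
        rows={k: (v[0], v[1]) for k, v in sorted(counts.items())},
    )


def call_segregation(
    table: HaplotypeCountTable,
    min_purity: float = MIN_PURITY,
    min_reads: int = MIN_READS_SEGREGATION,
) -> list[SegregationCall]:
    """Call haplotype segregation for each variant row with enough reads.

    Purity is max(count)/sum(counts); a variant is validated when its purity
    reaches ``min_purity`` (default 0.95 — near-perfect segregation is
    expected, but single stray reads from J mis-assignment do occur).
    """
    calls = []
    for (allele, label), (c0, c1) in table.rows.items():
        total = c0 + c1
        if total < min_reads:
            continue
        purity = max(c0, c1) / total
        assigned = table.j_allele_pair[0 if c0 >= c1 else 1]
        calls.append(
            SegregationCall(
                variant=(allele, label),
                assigned_j_allele=assigned,
                purity=purity,
                total_reads=total,
                validated=purity >= min_purity,
            )
        )
    return calls


def cdr3_length_distribution(
    rows: Iterable[Rearrangement],
) -> tuple[dict[int, int], int]:
    """Histogram of CDR3 amino-acid lengths and the unique-CDR3 count."""
    hist: Counter[int] = Counter()
    unique: set[str] = set()
    for row in rows:
        hist[len(row.cdr3_aa)] += 1
        unique.add(row.cdr3_aa)
    return dict(sorted(hist.items())), len(unique)


def plot_cdr3_distributions(
    per_subject: Mapping[str, Mapping[int, int]], out_path: str, title: str = ""
) -> None:
    """Render per-subject CDR3-length histograms as overlaid lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for subject, hist in per_subject.items():
        lengths = sorted(hist)
        ax.plot(lengths, [hist[l] for l in lengths], label=subject)
    ax.set_xlabel("CDR3 length (aa)")
    ax.set_ylabel("reads")
    if title:
        ax.set_title(title)
    ax.legend(fontsize="small")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


@dataclass
class BaseMinus93Result:
    """Per-haplotype T/G occurrence at base -93 of a 92-base upstream."""

    counts: dict[str, dict[str, int]]  # j allele -> {"T": n, "G": n, "other": n}

    def ratio(self, j_allele: str) -> float | None:
        c = self.counts.get(j_allele, {})
        if not c.get("G"):
            return None
        return c.get("T", 0) / c["G"]


def base_minus93_ratio(
    reads: Iterable[tuple[str, str]],
    reference_92: str,
) -> BaseMinus93Result:
    """Count T and G at -93 among reads perfectly matching bases -1..-92.

    ``reads`` yields (upstream segment, J allele) pairs for transcripts
    unambiguously assigned to one V allele.  Only reads whose 3'-anchored
    92 bases equal ``reference_92`` and that extend to -93 contribute.
    Both counts are always reported; the ratio is T over G.
    """
    if len(reference_92) != 92:
        raise ValueError(
            f"reference_92 must be exactly 92 bases, got {len(reference_92)}"
        )
    counts: dict[str, dict[str, int]] = {}
    for upstream, j_allele in reads:
        if len(upstream) < 93 or upstream[-92:] != reference_92:
            continue
        base = upstream[-93]
        slot = counts.setdefault(j_allele, {"T": 0, "G": 0, "other": 0})
        slot[base if base in ("T", "G") else "other"] += 1
    return BaseMinus93Result(counts=counts)


def variant_expression_frequency(
    rows: Sequence[Rearrangement],
    allele: str,
    variant: ConsolidatedVariant,
    min_overlap: int = MIN_MATCH_OVERLAP,
    sibling_variants: Sequence[ConsolidatedVariant] | None = None,
) -> float:
    """Fraction of a subject's filtered reads expressing one variant.

    The denominator is all filtered reads of the subject; the numerator is
    reads of ``allele`` whose upstream segment matches ``variant``
    unambiguously (against ``sibling_variants`` when provided).
    """
    if not rows:
        raise ValueError("no filtered reads for subject")
    pool = list(sibling_variants) if sibling_variants else [variant]
    if variant not in pool:
        pool.append(variant)
    matched = sum(
        1
        for row in rows
        if row.v_call == allele
        and match_upstream_to_variant(row.upstream_seq, pool, min_overlap)
        is variant
    )
    return matched / len(rows)


def cohort_summary(fractions: Sequence[float]) -> tuple[float, float, int]:
    """Mean, standard deviation (population, ddof=0) and n of a cohort."""
    n = len(fractions)
    mean = sum(fractions) / n
    sd = math.sqrt(sum((f - mean) ** 2 for f in fractions) / n)
    return mean, sd, n


def extract_population_variants(
    vcf_path: str,
    contig: str,
    start: int,
    end: int,
    maf_threshold: float = MAF_THRESHOLD,
) -> list[PopulationVariant]:
    """Extract SNPs with folded minor allele frequency above a threshold.

    ``start``/``end`` delimit a 1-based inclusive interval on ``contig``.
    Allele frequency comes from the INFO AF field when present, otherwise
    from genotypes.  Multi-allelic sites are decomposed into biallelic
    records (each alt versus the rest) before MAF folding, and kept when
    maf > maf_threshold (strictly above, matching a ">1%" rule).
    """
    from cyvcf2 import VCF

    out: list[PopulationVariant] = []
    vcf = VCF(vcf_path)
    for record in vcf:
        if record.CHROM != contig or not (start <= record.POS <= end):
            continue
        afs = record.INFO.get("AF")
        if afs is not None:
            if isinstance(afs, (int, float)):
                afs = [float(afs)]
            else:
                afs = [float(a) for a in afs]
        else:
            # fall back to genotype counting, decomposing multi-allelics
            alleles = [
                a for gt in record.genotypes for a in gt[:-1] if a >= 0
            ]
            if not alleles:
                continue
            afs = [
                sum(1 for a in alleles if a == i + 1) / len(alleles)
                for i in range(len(record.ALT))
            ]
        for alt, af in zip(record.ALT, afs):
            maf = min(float(af), 1.0 - float(af))
            if maf > maf_threshold:
                out.append(
                    PopulationVariant(
                        contig=record.CHROM,
                        position=record.POS,
                        ref=record.REF,
                        alt=alt,
                        maf=maf,
                    )
                )
    vcf.close()
    return out
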