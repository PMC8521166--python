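"""Upstream consensus inference, cross-subject consolidation and labelling.

The inference walks 3'->5' from the V-region boundary, one upstream position
at a time.  At each position it considers the reads of the current group that
cover the position (long enough, and not N there):

* if fewer than ``coverage_threshold`` (default 50%) of the group's reads
  cover the position, extension stops — the consensus ends at the previous
  position;
* otherwise every base carried by at least ``base_threshold`` (default 30%)
  of the covering reads is extractable.  A single extractable base extends
  the consensus; two or more signal co-expressed variants, so the covering
  reads are partitioned by their base at that position and each partition
  carrying an extractable base is re-processed independently, starting over
  from the 3' end.  Partitions below the threshold (at most one can be, at
  30%) are discarded as unsupported.

A consensus therefore records the (sub)group that supports it, and its
length is the longest 3'-anchored prefix at which group coverage stays at or
above the coverage threshold with at least one extractable base.

Per-subject consensus sequences of one allele are then consolidated across
subjects: sequences identical over their shared 3'-anchored extent are
clustered, and the reported length is the largest L such that at least
``length_quorum`` (default 80%) of the cluster's members reach L.  Variants
get per-allele letter labels (A, B, C, ...) by descending subject support,
ties broken by sequence order — the labelling is deterministic but arbitrary,
matching no external naming.
"""

from __future__ import annotations

import itertools
import logging
import string
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import DEFAULT_LEADER_LENGTH

logger = logging.getLogger("utrleader")

BASE_THRESHOLD = 0.30
COVERAGE_THRESHOLD = 0.50
LENGTH_QUORUM = 0.80


@dataclass(frozen=True)
class UpstreamConsensusRecord:
    """One inferred upstream sequence for one subject/allele (sub)group."""

    subject_id: str
    allele: str
    sequence: str  # 5'->3'; the 3' end abuts the V region
    n_reads: int
    coverage_at_5prime: float
    read_indices: tuple[int, ...] = field(default=(), compare=False)


@dataclass
class ConsolidatedVariant:
    """A cross-subject upstream variant with a per-allele letter label."""

    allele: str
    label: str
    sequence: str
    subject_count: int
    member_lengths: list[int]
    members: list[UpstreamConsensusRecord] = field(default_factory=list)

    @property
    def name(self) -> str:
        return f"{self.allele}-{self.label}"


@dataclass(frozen=True)
class ArtifactFlag:
    variant: str  # "<allele>-<label>"
    reason: str  # homopolymer_indel_vs_sibling | adaptor_remnant | low_cdr3_diversity
    detail: str = ""


def _covering(reads: Sequence[str], group: Sequence[int], pos: int) -> list[int]:
    """Indices of group reads covering 3'-anchored position `pos` (1-based)."""
    return [
        i for i in group if len(reads[i]) >= pos and reads[i][-pos] != "N"
    ]


def build_consensus(
    upstream_reads: Sequence[str],
    base_threshold: float = BASE_THRESHOLD,
    coverage_threshold: float = COVERAGE_THRESHOLD,
    subject_id: str = "",
    allele: str = "",
) -> list[UpstreamConsensusRecord]:
    """Infer upstream consensus sequence(s) from 3'-anchored upstream reads.

    Returns one record per read subgroup that supports a distinct variant.
    Subgroups whose consensus is empty (no extractable base even at -1) are
    dropped.  The result is independent of input read order.
    """
    if not upstream_reads:
        raise ValueError("build_consensus requires at least one read")
    reads = [r.upper() for r in upstream_reads]
    records: list[UpstreamConsensusRecord] = []

    def process(group: list[int]) -> None:
        n = len(group)
        pieces: list[str] = []
        cov_at_tip = 0.0
        pos = 1
        while True:
            covering = _covering(reads, group, pos)
            frac = len(covering) / n
            if frac < coverage_threshold:
                break
            counts = Counter(reads[i][-pos] for i in covering)
            winners = sorted(
                b for b, c in counts.items()
                if c / len(covering) >= base_threshold
            )
            if not winners:
                break
            if len(winners) >= 2:
                # Partition covering reads by base; sizes sum to len(covering).
                for base in winners:
                    process([i for i in covering if reads[i][-pos] == base])
                for base in sorted(set(counts) - set(winners)):
                    logger.debug(
                        "dropping %d reads with unsupported base %s at -%d",
                        counts[base], base, pos,
                    )
                return
            pieces.append(winners[0])
            cov_at_tip = frac
            pos += 1
        if pieces:
            records.append(
                UpstreamConsensusRecord(
                    subject_id=subject_id,
                    allele=allele,
                    sequence="".join(reversed(pieces)),
                    n_reads=n,
                    coverage_at_5prime=cov_at_tip,
                    read_indices=tuple(sorted(group)),
                )
            )

    process(list(range(len(reads))))
    records.sort(key=lambda r: (-r.n_reads, r.sequence))
    return records


def _tail_compatible(a: str, b: str) -> bool:
    """True when two 5'->3' sequences agree over their shared 3' extent."""
    ov = min(len(a), len(b))
    return a[-ov:] == b[-ov:]


def _variant_labels() -> Iterable[str]:
    letters = string.ascii_uppercase
    yield from letters
    for pair in itertools.product(letters, repeat=2):
        yield "".join(pair)


def quorum_length(lengths: Sequence[int], length_quorum: float = LENGTH_QUORUM) -> int:
    """Largest L such that at least `length_quorum` of lengths are >= L."""
    n = len(lengths)
    return max(
        l for l in lengths if sum(x >= l for x in lengths) / n >= length_quorum
    )


def consolidate(
    per_subject: Sequence[UpstreamConsensusRecord],
    length_quorum: float = LENGTH_QUORUM,
) -> list[ConsolidatedVariant]:
    """Consolidate one allele's per-subject consensus records into variants.

    Records are clustered so that any two members of a cluster are identical
    over their overlapping 3'-anchored extent (records differing only in how
    far 5' they stretch are the same variant).  Clustering is deterministic:
    records are considered longest-first and join the first cluster they are
    compatible with in full.
    """
    if not per_subject:
        return []
    alleles = {r.allele for r in per_subject}
    if len(alleles) > 1:
        raise ValueError(f"consolidate expects one allele, got {alleles}")
    ordered = sorted(
        per_subject, key=lambda r: (-len(r.sequence), r.sequence, r.subject_id)
    )
    clusters: list[list[UpstreamConsensusRecord]] = []
    for rec in ordered:
        for cluster in clusters:
            if all(_tail_compatible(rec.sequence, m.sequence) for m in cluster):
                cluster.append(rec)
                break
        else:
            clusters.append([rec])

    variants: list[ConsolidatedVariant] = []
    for cluster in clusters:
        lengths = [len(m.sequence) for m in cluster]
        L = quorum_length(lengths, length_quorum)
        longest = max(cluster, key=lambda m: len(m.sequence))
        variants.append(
            ConsolidatedVariant(
                allele=cluster[0].allele,
                label="",
                sequence=longest.sequence[-L:],
                subject_count=len(cluster),
                member_lengths=sorted(lengths, reverse=True),
                members=cluster,
            )
        )
    variants.sort(key=lambda v: (-v.subject_count, v.sequence))
    for label, variant in zip(_variant_labels(), variants):
        variant.label = label
    return variants


def _single_deletion_neighbours(seq: str) -> Iterable[str]:
    """Sequences reachable by deleting one base inside a homopolymer run >=2."""
    seen = set()
    for i in range(len(seq)):
        in_run = (i > 0 and seq[i - 1] == seq[i]) or (
            i + 1 < len(seq) and seq[i + 1] == seq[i]
        )
        if in_run:
            cand = seq[:i] + seq[i + 1 :]
            if cand not in seen:
                seen.add(cand)
                yield cand


def flag_artifacts(
    variants: Sequence[ConsolidatedVariant],
    core_motif: str = "TACGGG",
    unique_cdr3_counts: Mapping[str, int] | None = None,
    min_unique_cdr3: int | None = None,
) -> list[ArtifactFlag]:
    """Flag variants that look like library or sequencing artifacts.

    ``variants`` must all belong to one allele (siblings).  Three reasons:
    a one-base homopolymer insertion relative to a sibling variant, adaptor
    remnants at the 5' terminus (the core motif or a >=3-base G-run), and low
    supporting unique-CDR3 diversity (only when counts are supplied).
    Flags are advisory; nothing is auto-removed.
    """
    flags: list[ArtifactFlag] = []
    for v in variants:
        for cand in _single_deletion_neighbours(v.sequence):
            hit = next(
                (
                    s for s in variants
                    if s is not v and _tail_compatible(cand, s.sequence)
                ),
                None,
            )
            if hit is not None:
                flags.append(
                    ArtifactFlag(
                        v.name, "homopolymer_indel_vs_sibling",
                        f"one deletion matches sibling {hit.name}",
                    )
                )
                break
        if v.sequence.startswith(core_motif) or v.sequence.startswith("GGG"):
            flags.append(ArtifactFlag(v.name, "adaptor_remnant"))
        if (
            min_unique_cdr3 is not None
            and unique_cdr3_counts is not None
            and unique_cdr3_counts.get(v.name, 0) < min_unique_cdr3
        ):
            flags.append(
                ArtifactFlag(
                    v.name, "low_cdr3_diversity",
                    f"{unique_cdr3_counts.get(v.name, 0)} < {min_unique_cdr3}",
                )
            )
    return flags


@dataclass
class PositionAnnotation:
    """Leader/5'UTR boundary annotation of a consolidated variant."""

    variant: str
    leader_length: int
    has_full_leader: bool
    leader_seq: str = ""
    utr_seq: str = ""
    initiation_codon: str = ""
    atg_ok: bool = False
    atg_positions: tuple[int, int] | None = None  # (-L, -(L-2))
    warning: str = ""


def annotate_positions(
    variant: ConsolidatedVariant, leader_length: int = DEFAULT_LEADER_LENGTH
) -> PositionAnnotation:
    """Split a variant into leader exon and 5'UTR, checking the ATG.

    Bases -1..-leader_length are the leader exon; anything further 5' is
    inferable 5'UTR.  For the default 19-aa signal peptide the initiation
    codon occupies -57..-55.  A variant shorter than the leader cannot be
    segmented and is annotated with a warning instead.
    """
    seq = variant.sequence
    if len(seq) < leader_length:
        return PositionAnnotation(
            variant=variant.name,
            leader_length=leader_length,
            has_full_leader=False,
            warning=(
                f"sequence length {len(seq)} is shorter than the "
                f"{leader_length}-base leader; no 5'UTR boundary emitted"
            ),
        )
    leader = seq[-leader_length:]
    codon = leader[:3]
    return PositionAnnotation(
        variant=variant.name,
        leader_length=leader_length,
        has_full_leader=True,
        leader_seq=leader,
        utr_seq=seq[:-leader_length],
        initiation_codon=codon,
        atg_ok=codon == "ATG",
        atg_positions=(-leader_length, -(leader_length - 2)),
    )
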