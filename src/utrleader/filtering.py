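"""Read- and allele-level repertoire filters, applied per subject.

Two layers of filtering precede upstream-consensus inference:

* read level — only transcripts whose V region matches the assigned germline
  allele exactly (zero V-errors) are used, excluding sequencing errors,
  somatic hypermutation, and misassigned reads;
* allele level — an allele is only analysed when it shows enough independent
  rearrangements (unique CDR3s, counted over ALL entries regardless of
  V-errors) and enough clean reads (zero-V-error entries).

Both thresholds are strict in the "fewer than" sense: the defaults keep an
allele with exactly 75 unique CDR3s and exactly 20 clean reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .io import Rearrangement

logger = logging.getLogger("utrleader")

MIN_UNIQUE_CDR3 = 75
MIN_READS = 20


@dataclass
class AlleleGroup:
    """All usable evidence for one IGHV allele in one subject."""

    subject_id: str
    allele: str
    reads: list[Rearrangement] = field(default_factory=list)
    n_unique_cdr3_all: int = 0

    @property
    def n_reads_zero_error(self) -> int:
        return len(self.reads)


def filter_reads(rows: Iterable[Rearrangement]) -> Iterator[Rearrangement]:
    """Keep only rows whose V region matches the germline exactly."""
    for row in rows:
        if row.v_errors == 0:
            yield row


def group_alleles(
    rows: Iterable[Rearrangement], subject_id: str
) -> tuple[list[AlleleGroup], int]:
    """Group a subject's rows per IGHV allele.

    Unique-CDR3 counting spans all entries of the allele (any V-error count);
    member reads are restricted to zero V-errors.  Rows with ambiguous
    multi-allele V calls (comma-separated) cannot be attributed to a single
    allele and are excluded; their count is returned alongside the groups.
    Rows with empty CDR3 contribute no CDR3 but do count as reads.
    """
    groups: dict[str, AlleleGroup] = {}
    cdr3s: dict[str, set[str]] = {}
    n_ambiguous = 0
    for row in rows:
        if "," in row.v_call:
            n_ambiguous += 1
            continue
        group = groups.setdefault(
            row.v_call, AlleleGroup(subject_id, row.v_call)
        )
        if row.cdr3_aa:
            cdr3s.setdefault(row.v_call, set()).add(row.cdr3_aa)
        if row.v_errors == 0:
            group.reads.append(row)
    for allele, group in groups.items():
        group.n_unique_cdr3_all = len(cdr3s.get(allele, ()))
    if n_ambiguous:
        logger.info(
            "%s: %d rows with ambiguous v_call excluded from grouping",
            subject_id, n_ambiguous,
        )
    return list(groups.values()), n_ambiguous


def filter_alleles(
    groups: Iterable[AlleleGroup],
    min_unique_cdr3: int = MIN_UNIQUE_CDR3,
    min_reads: int = MIN_READS,
) -> list[AlleleGroup]:
    """Keep allele groups with enough clonal diversity and clean reads."""
    return [
        g
        for g in groups
        if g.n_unique_cdr3_all >= min_unique_cdr3
        and g.n_reads_zero_error >= min_reads
    ]
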