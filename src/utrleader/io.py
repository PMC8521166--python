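"""Readers and writers for the file formats used across the pipeline.

Covers 4-line FASTQ (Phred+33), FASTA, and AIRR-style tab-separated
rearrangement tables, plus the shared upstream coordinate convention.

Upstream coordinates are 3'-anchored negative integers: base -1 is the base
immediately 5' of the V-region start (the last base of the leader exon), and
positions grow more negative moving 5'-ward.  Sequences are stored 5'->3' and
indexed from the right, so ``base_at(seq, -k) == seq[-k]`` whenever the
sequence reaches that far.  Every length/threshold rule in the pipeline (the
30% extraction rule, the 50% coverage rule, the -93 analyses) is anchored at
the V-region boundary, which makes this the natural frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("utrleader")

#: Default logical-name -> column-name mapping for rearrangement tables.
#: Column names follow the AIRR Rearrangement schema where one exists;
#: ``V_errors`` is the germline-annotator extension column counting V-region
#: mismatches against the assigned germline allele, and ``v_sequence_start``
#: is 1-based per AIRR convention.
DEFAULT_FIELD_MAP: dict[str, str] = {
    "sequence_id": "sequence_id",
    "sequence": "sequence",
    "v_call": "v_call",
    "j_call": "j_call",
    "v_errors": "V_errors",
    "cdr3_aa": "cdr3_aa",
    "v_sequence_start": "v_sequence_start",
}

#: Leader (signal-peptide exon) length in nucleotides.  Most IGHV leaders
#: encode a 19-aa signal peptide, i.e. 57 nt with the initiation ATG at
#: -57..-55.  Known exceptions carry a 20-aa leader with the ATG at -60..-58.
DEFAULT_LEADER_LENGTH = 57
LEADER_LENGTH_OVERRIDES: dict[str, int] = {
    "IGHV3-64": 60,
    "IGHV6-1": 60,
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse-complement a DNA string (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def position_label(offset_from_3prime: int) -> int:
    """Map a 1-based offset from the V-region boundary to its upstream label.

    Offset 1 (the 3'-most upstream base, the last base of the leader) maps to
    -1; offset 57 maps to -57 (the A of a default-length leader's ATG).
    """
    if offset_from_3prime < 1:
        raise ValueError(
            f"offset_from_3prime must be >= 1, got {offset_from_3prime}"
        )
    return -offset_from_3prime


def base_at(seq: str, position: int) -> str | None:
    """Base of a 5'->3' upstream sequence at a negative upstream position.

    Returns ``None`` when the sequence does not extend that far 5'.
    """
    if position > -1:
        raise ValueError(f"upstream positions are <= -1, got {position}")
    k = -position
    if len(seq) < k:
        return None
    return seq[-k]


def leader_length_for(
    allele: str, overrides: Mapping[str, int] | None = None
) -> int:
    """Leader exon length for an allele, honouring per-gene overrides.

    Overrides are keyed by gene (``IGHV3-64``) or full allele name
    (``IGHV3-64*01``); the full name wins.
    """
    table = dict(LEADER_LENGTH_OVERRIDES)
    if overrides:
        table.update(overrides)
    if allele in table:
        return table[allele]
    gene = allele.split("*")[0]
    return table.get(gene, DEFAULT_LEADER_LENGTH)


@dataclass
class RawReadPair:
    """A forward/reverse mate pair as read from paired FASTQ files."""

    read_id: str
    fwd_seq: str
    fwd_qual: str
    rev_seq: str
    rev_qual: str

    def validate(self) -> None:
        if len(self.fwd_qual) != len(self.fwd_seq):
            raise ValueError(f"{self.read_id}: forward qual/seq length mismatch")
        if len(self.rev_qual) != len(self.rev_seq):
            raise ValueError(f"{self.read_id}: reverse qual/seq length mismatch")


@dataclass(frozen=True)
class Rearrangement:
    """One annotated transcript row from a rearrangement table."""

    sequence_id: str
    sequence: str
    v_call: str
    j_call: str
    v_errors: int
    cdr3_aa: str
    v_start: int  # 0-based index into `sequence` of the first V-region base

    @property
    def upstream_seq(self) -> str:
        """The 5'UTR-leader segment: everything 5' of the V region."""
        return self.sequence[: self.v_start]


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) from a 4-line Phred+33 FASTQ file."""
    with open(path) as handle:
        yield from FastqGeneralIterator(handle)


def write_fastq(
    records: Iterable[tuple[str, str, str]], path: str | Path
) -> None:
    with open(path, "w") as handle:
        for rid, seq, qual in records:
            handle.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def _strip_mate_suffix(read_id: str) -> str:
    rid = read_id.split()[0]
    if len(rid) > 2 and rid[-2] == "/" and rid[-1] in "12":
        rid = rid[:-2]
    return rid


def read_fastq_pairs(
    fwd_path: str | Path, rev_path: str | Path
) -> Iterator[RawReadPair]:
    """Pair up mates from two parallel FASTQ files by shared identifier."""
    fwd = read_fastq(fwd_path)
    rev = read_fastq(rev_path)
    for (fid, fseq, fqual), (rid, rseq, rqual) in zip(fwd, rev, strict=True):
        fid, rid = _strip_mate_suffix(fid), _strip_mate_suffix(rid)
        if fid != rid:
            raise ValueError(
                f"mate identifiers out of sync: {fid!r} vs {rid!r}"
            )
        yield RawReadPair(fid, fseq, fqual, rseq, rqual)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping (order preserved)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(
    records: Iterable[tuple[str, str]] | Mapping[str, str],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    seq_records = [
        SeqRecord(
            Seq(seq),
            id=rid,
            description=(descriptions or {}).get(rid, ""),
        )
        for rid, seq in items
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Rearrangement tables
# ---------------------------------------------------------------------------

def read_rearrangement_table(
    path: str | Path,
    field_map: Mapping[str, str] | None = None,
) -> Iterator[Rearrangement]:
    """Stream annotated rearrangements from a tab-separated table.

    The table must carry a header row containing every mapped column.  Rows
    whose V-error count cannot be parsed as an integer are reported and
    skipped; a missing required column is a fatal configuration error naming
    the column.
    """
    fmap = dict(DEFAULT_FIELD_MAP)
    if field_map:
        fmap.update(field_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for logical, column in fmap.items():
        if column not in df.columns:
            raise ValueError(
                f"rearrangement table {path} is missing required column "
                f"{column!r} (mapped from field {logical!r})"
            )
    for row in df.itertuples(index=False):
        record = row._asdict() if hasattr(row, "_asdict") else dict(row)
        raw_errors = record[fmap["v_errors"]]
        try:
            v_errors = int(raw_errors)
        except (TypeError, ValueError):
            logger.warning(
                "skipping row %s: unparsable v_errors %r",
                record[fmap["sequence_id"]],
                raw_errors,
            )
            continue
        yield Rearrangement(
            sequence_id=record[fmap["sequence_id"]],
            sequence=record[fmap["sequence"]].upper(),
            v_call=record[fmap["v_call"]],
            j_call=record[fmap["j_call"]],
            v_errors=v_errors,
            cdr3_aa=record[fmap["cdr3_aa"]],
            v_start=int(record[fmap["v_sequence_start"]]) - 1,
        )


def write_rearrangement_table(
    records: Iterable[Rearrangement],
    path: str | Path,
    field_map: Mapping[str, str] | None = None,
) -> None:
    """Write rearrangements as a tab-separated table (inverse of the reader)."""
    fmap = dict(DEFAULT_FIELD_MAP)
    if field_map:
        fmap.update(field_map)
    rows = [
        {
            fmap["sequence_id"]: r.sequence_id,
            fmap["sequence"]: r.sequence,
            fmap["v_call"]: r.v_call,
            fmap["j_call"]: r.j_call,
            fmap["v_errors"]: r.v_errors,
            fmap["cdr3_aa"]: r.cdr3_aa,
            fmap["v_sequence_start"]: r.v_start + 1,
        }
        for r in records
    ]
    columns = [fmap[k] for k in DEFAULT_FIELD_MAP]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
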