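"""5'-RACE read pre-processing.

5'-RACE library generation appends a homopolymeric G-tail (via TdT) to the
transcript 5' end, preceded here by a random barcode and a ``TAC`` linker, so
every forward read starts ``<barcode>TACGGG...G<transcript 5' end>``.  This
module removes that decoration: it locates the adaptor core motif within a
fixed search window, trims everything up to and including the maximal G-run
that follows it, discards forward reads without a recognisable adaptor, and
joins surviving mates into full-length sequences by overlap.

Trimming is deliberately strict: the adaptor motif is matched exactly, the
whole G-run is removed (library Gs are indistinguishable from biological
5'-terminal Gs), and adaptor-less reads are dropped rather than rescued.
This eliminates artefactual 5'-terminal Gs at the cost of occasionally
shortening genuinely G-starting transcripts by their leading G-run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .io import RawReadPair, revcomp

logger = logging.getLogger("utrleader")

DEFAULT_WINDOW = 40
DEFAULT_MOTIF = "TACGGG"
DEFAULT_MIN_OVERLAP = 10
DEFAULT_MAX_MISMATCH_FRAC = 0.1


@dataclass
class TrimmedRead:
    read_id: str
    seq: str
    qual: str


@dataclass
class TrimReport:
    """Accounting for one pre-processing run.

    ``n_input = n_kept + n_discarded_no_adaptor + n_discarded_empty``;
    ``n_unjoined`` counts kept pairs whose mates failed to overlap (they are
    emitted to the reject stream, not silently dropped).
    """

    n_input: int = 0
    n_kept: int = 0
    n_discarded_no_adaptor: int = 0
    n_discarded_empty: int = 0
    n_joined: int = 0
    n_unjoined: int = 0
    trim_offsets: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_discarded_no_adaptor": self.n_discarded_no_adaptor,
            "n_discarded_empty": self.n_discarded_empty,
            "n_joined": self.n_joined,
            "n_unjoined": self.n_unjoined,
        }


def find_adaptor(
    fwd_seq: str,
    search_window: int = DEFAULT_WINDOW,
    core_motif: str = DEFAULT_MOTIF,
) -> int | None:
    """0-based start of the first adaptor-motif occurrence starting within
    the first ``search_window`` bases, or ``None``.

    First-occurrence matching is intentional: the true adaptor precedes the
    insert, so a spurious internal motif must not cause over-trimming.
    """
    if search_window < len(core_motif):
        raise ValueError("search window shorter than the adaptor motif")
    idx = fwd_seq.find(core_motif, 0, search_window - 1 + len(core_motif))
    return None if idx < 0 else idx


def trim_forward(
    seq: str, qual: str, adaptor_offset: int
) -> tuple[str, str, int]:
    """Remove the prefix through the last G of the maximal G-run that starts
    after the ``TAC`` linker at ``adaptor_offset``.

    Returns (trimmed seq, trimmed qual, number of bases removed).  The
    remainder may be empty; callers discard and count empty results.
    """
    if seq[adaptor_offset : adaptor_offset + 3] != "TAC":
        raise ValueError(
            f"no TAC linker at offset {adaptor_offset}: the adaptor must be "
            "located with find_adaptor first"
        )
    run_start = adaptor_offset + 3
    j = run_start
    while j < len(seq) and seq[j] == "G":
        j += 1
    if j - run_start < 3:
        raise ValueError(
            f"G-run after TAC at offset {adaptor_offset} is shorter than 3"
        )
    return seq[j:], qual[j:], j


def merge_overlap(
    fwd_seq: str,
    fwd_qual: str,
    rev_seq: str,
    rev_qual: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> tuple[str, str] | None:
    """Join a trimmed forward read with its reverse-complemented mate.

    ``rev_seq``/``rev_qual`` are given in sequencer orientation and are
    reverse-complemented here.  Alignments are scanned from the largest
    possible overlap downwards (the reverse read may contain the forward read
    entirely); the first alignment with at least ``min_overlap`` aligned
    bases and a mismatch fraction at most ``max_mismatch_frac`` wins.
    Returns the merged (seq, qual) or ``None`` when the mates do not overlap.
    """
    rc = revcomp(rev_seq)
    rc_qual = rev_qual[::-1]
    f = fwd_seq
    for o in range(0, len(f) - min_overlap + 1):
        ov = min(len(f) - o, len(rc))
        if ov < min_overlap:
            break
        window_f = f[o : o + ov]
        window_r = rc[:ov]
        mism = sum(a != b for a, b in zip(window_f, window_r))
        if mism <= max_mismatch_frac * ov:
            if len(rc) >= len(f) - o:
                return f[:o] + rc, fwd_qual[:o] + rc_qual
            # reverse read contained within the forward read
            return f, fwd_qual
    return None


def preprocess_pairs(
    pairs: Iterable[RawReadPair],
    window: int = DEFAULT_WINDOW,
    core_motif: str = DEFAULT_MOTIF,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> tuple[list[tuple[str, str, str]], list[str], TrimReport]:
    """Run the full pre-processing stage over a stream of read pairs.

    Returns (joined records as (id, seq, qual), reject read ids, report).
    Forward reads lacking the adaptor are dropped together with their mates;
    pairs whose mates fail to overlap go to the reject list.
    """
    report = TrimReport()
    joined: list[tuple[str, str, str]] = []
    rejects: list[str] = []
    seen: set[str] = set()
    for pair in pairs:
        if pair.read_id in seen:
            raise ValueError(f"duplicate read id {pair.read_id!r}")
        seen.add(pair.read_id)
        report.n_input += 1
        offset = find_adaptor(pair.fwd_seq, window, core_motif)
        if offset is None:
            report.n_discarded_no_adaptor += 1
            continue
        seq, qual, removed = trim_forward(pair.fwd_seq, pair.fwd_qual, offset)
        if not seq:
            report.n_discarded_empty += 1
            logger.debug("read %s empty after trimming", pair.read_id)
            continue
        report.n_kept += 1
        report.trim_offsets[pair.read_id] = removed
        merged = merge_overlap(
            seq, qual, pair.rev_seq, pair.rev_qual,
            min_overlap, max_mismatch_frac,
        )
        if merged is None:
            report.n_unjoined += 1
            rejects.append(pair.read_id)
            continue
        report.n_joined += 1
        joined.append((pair.read_id, merged[0], merged[1]))
    return joined, rejects, report
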