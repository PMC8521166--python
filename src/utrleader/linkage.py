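"""Linkage disequilibrium of upstream-labelled alleles across a gene panel.

Each J-anchored haplotype contributes one token per panel gene — the
expressed allele plus its upstream-variant letter (e.g. ``IGHV4-4*02-D``),
or the explicit token ``absent`` when no expressed allele of the gene could
be placed on that haplotype (poorly expressed alleles are real haplotype
members even when invisible to inference).  Under random association the
expected count of a combination is N times the product of the tokens'
marginal frequencies; enrichment is reported as the observed/expected ratio,
with no significance testing attached.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from math import prod
from typing import Mapping, Sequence

ABSENT = "absent"
MIN_OBSERVED = 2


@dataclass(frozen=True)
class HaplotypeRecord:
    """One resolved haplotype: subject + J allele, token per panel gene."""

    haplotype_id: str
    assignment: Mapping[str, str]


@dataclass(frozen=True)
class ComboStat:
    combo: tuple[str, ...]
    observed: int
    expected: float
    ratio: float | None  # None when expected == 0


def _check_panel(
    haplotypes: Sequence[HaplotypeRecord], genes: Sequence[str]
) -> None:
    for hap in haplotypes:
        missing = [g for g in genes if g not in hap.assignment]
        if missing:
            raise ValueError(
                f"haplotype {hap.haplotype_id!r} lacks a token for "
                f"gene(s) {missing}; use {ABSENT!r} explicitly"
            )


def marginal_frequencies(
    haplotypes: Sequence[HaplotypeRecord],
    genes: Sequence[str],
) -> dict[str, dict[str, float]]:
    """Per-gene token frequencies over the haplotype collection."""
    if not haplotypes:
        raise ValueError("marginal_frequencies requires at least one haplotype")
    _check_panel(haplotypes, genes)
    n = len(haplotypes)
    freqs: dict[str, dict[str, float]] = {}
    for gene in genes:
        counts = Counter(h.assignment[gene] for h in haplotypes)
        freqs[gene] = {tok: c / n for tok, c in sorted(counts.items())}
    return freqs


def combo_stats(
    haplotypes: Sequence[HaplotypeRecord],
    genes: Sequence[str],
    min_observed: int = MIN_OBSERVED,
) -> list[ComboStat]:
    """Observed vs expected frequency of each gene-panel combination.

    Expected counts use plug-in marginal frequencies assuming random
    association; only combinations observed at least ``min_observed`` times
    are reported.  Results are sorted by descending observed count, then
    combination order.
    """
    freqs = marginal_frequencies(haplotypes, genes)
    n = len(haplotypes)
    observed = Counter(
        tuple(h.assignment[g] for g in genes) for h in haplotypes
    )
    stats = []
    for combo, obs in observed.items():
        if obs < min_observed:
            continue
        expected = n * prod(freqs[g][t] for g, t in zip(genes, combo))
        ratio = obs / expected if expected > 0 else None
        stats.append(ComboStat(combo, obs, expected, ratio))
    stats.sort(key=lambda s: (-s.observed, s.combo))
    return stats
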