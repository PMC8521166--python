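"""Independent brute-force oracles used to cross-check the pipeline.

These are deliberately written against the rules as stated, with different
data structures and control flow than the library implementation, and share
no code with it.
"""

from __future__ import annotations


def brute_force_consensus(
    reads: list[str],
    base_threshold: float = 0.30,
    coverage_threshold: float = 0.50,
) -> list[tuple[str, int]]:
    """Exhaustive position-wise partitioner over 3'-anchored reads.

    Returns a sorted list of (consensus sequence, supporting read count).
    """
    results: list[tuple[str, int]] = []

    def walk(group: frozenset[int]) -> None:
        n = len(group)
        tail_first: list[str] = []
        p = 0
        while True:
            p += 1
            cov = frozenset(
                i
                for i in group
                if len(reads[i]) >= p and reads[i][len(reads[i]) - p] != "N"
            )
            if len(cov) / n < coverage_threshold:
                break
            tally: dict[str, set[int]] = {}
            for i in cov:
                tally.setdefault(reads[i][len(reads[i]) - p], set()).add(i)
            winners = {
                b: members
                for b, members in tally.items()
                if len(members) / len(cov) >= base_threshold
            }
            if not winners:
                break
            if len(winners) > 1:
                for b in sorted(winners):
                    walk(frozenset(winners[b]))
                return
            ((b, _),) = winners.items()
            tail_first.append(b)
        if tail_first:
            results.append(("".join(reversed(tail_first)), n))

    walk(frozenset(range(len(reads))))
    return sorted(results)


def brute_force_quorum_length(lengths: list[int], quorum: float = 0.80) -> int:
    """Scan every candidate length for the cross-subject consolidation rule."""
    n = len(lengths)
    best = 0
    for candidate in range(1, max(lengths) + 1):
        reaching = sum(1 for x in lengths if x >= candidate)
        if reaching / n >= quorum:
            best = candidate
    return best


def brute_force_coverage_length(read_lengths: list[int], coverage: float = 0.50) -> int:
    """Scan every candidate length for the 50%-coverage truncation rule
    (reads assumed unanimous in content)."""
    n = len(read_lengths)
    best = 0
    for candidate in range(1, max(read_lengths) + 1):
        if sum(1 for x in read_lengths if x >= candidate) / n >= coverage:
            best = candidate
    return best
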