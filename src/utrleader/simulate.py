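"""Ground-truthed synthetic 5'-RACE repertoire generator.

Emulates the structure of a naive IgM 5'-RACE library on a multi-subject
cohort: per IGHV allele a set of planted upstream (5'UTR-leader) variants at
known mixture fractions and chromosome placements, transcripts with random
CDR3 junctions, molecule-level substitution error, adaptor decoration of the
forward reads (random barcode + TAC + G-tail), IGHJ6 het/hom genotypes with
a configurable J mis-assignment rate, and full per-read ground truth.

V regions are short synthetic stand-ins (~60 bases): no pipeline stage
depends on biological V content beyond identity matching.  Every emitted
read has exactly one truth record, and the whole generator is deterministic
given the seed.

Two constraints keep trim-level ground truth exact rather than ambiguous:
barcodes are resampled so the adaptor motif's first occurrence in the
decorated prefix is the true adaptor start, and a read's transcript fragment
never begins with G (leading Gs would be absorbed into the G-tail by any
trimmer, so the recoverable fragment starts at the first non-G base).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .io import Rearrangement, revcomp, write_fastq, write_rearrangement_table

BASES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# one fixed codon per amino acid (reverse translation for junctions)
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

J_ALLELES = ("IGHJ6*02", "IGHJ6*03")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    seed: int = 1
    n_subjects: int = 3
    n_alleles: int = 3
    mixture: tuple[float, ...] = (0.6, 0.4)  # per-allele variant fractions
    variant_chromosomes: tuple[int, ...] | None = None  # default: i % 2
    reads_per_allele: int = 200
    error_rate: float = 0.001  # per-base substitution, molecule level
    upstream_len: int = 100
    v_len: int = 60
    j_len: int = 30
    read_len: int = 250
    full_extent_prob: float = 0.7  # truncated-geometric 5'-extent parameter
    min_extent: int = 40
    barcode_len: tuple[int, int] = (8, 16)
    g_tail_len: tuple[int, int] = (3, 15)
    j_heterozygous: bool | Sequence[bool] = True  # per subject, or global
    j_mis_rate: float = 0.005
    cdr3_len_range: tuple[int, int] = (8, 22)
    n_variant_diffs: int = 1  # substitutions distinguishing sibling variants
    diff_position_range: tuple[int, int] = (40, 90)  # 3'-anchored offsets

    def validate(self) -> None:
        if abs(sum(self.mixture) - 1.0) > 1e-9:
            raise ValueError("mixture: fractions must sum to 1")
        for name in ("error_rate", "j_mis_rate", "full_extent_prob"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}: rate {value} outside [0, 1]")
        if self.variant_chromosomes is not None and len(
            self.variant_chromosomes
        ) != len(self.mixture):
            raise ValueError(
                "variant_chromosomes: must give one chromosome per variant"
            )
        if self.min_extent > self.upstream_len:
            raise ValueError("min_extent: exceeds upstream_len")
        if self.diff_position_range[1] > self.upstream_len:
            raise ValueError("diff_position_range: exceeds upstream_len")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        for key in (
            "mixture", "variant_chromosomes", "barcode_len", "g_tail_len",
            "cdr3_len_range", "diff_position_range",
        ):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class UpstreamVariantTruth:
    allele: str
    variant_id: str  # "<allele>/v<i>"
    sequence: str  # full upstream, 5'->3'
    chromosome: int
    fraction: float


@dataclass
class Reference:
    v_seqs: dict[str, str]
    j_seqs: dict[str, str]
    variants: dict[str, list[UpstreamVariantTruth]]  # allele -> variants


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    subject_id: str
    transcript: str  # post-error, pre-decoration
    fragment: str  # forward-read biological fragment after the adaptor
    chromosome: int
    variant_id: str
    cdr3_aa: str
    j_true: str


@dataclass
class SubjectData:
    subject_id: str
    j_genotype: tuple[str, str]  # per chromosome 0/1
    pairs: list  # RawReadPair-compatible tuples written to FASTQ
    rearrangements: list[Rearrangement]
    truth: list[ReadTruth]


@dataclass
class SimulatedRepertoire:
    config: SimulationConfig
    reference: Reference
    subjects: list[SubjectData]

    def truth_variants(self, allele: str) -> list[UpstreamVariantTruth]:
        return self.reference.variants[allele]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _mutate(rng: np.random.Generator, seq: str, positions: np.ndarray) -> str:
    out = list(seq)
    for pos in positions:
        choices = [b for b in BASES if b != out[pos]]
        out[pos] = choices[rng.integers(0, 3)]
    return "".join(out)


def make_reference(config: SimulationConfig, rng: np.random.Generator) -> Reference:
    """Germline V/J stand-ins plus planted upstream variants per allele."""
    v_seqs, variants = {}, {}
    j_base = _random_seq(rng, config.j_len)
    j_seqs = {
        J_ALLELES[0]: j_base,
        J_ALLELES[1]: _mutate(rng, j_base, np.array([2, config.j_len // 2])),
    }
    chroms = config.variant_chromosomes or tuple(
        i % 2 for i in range(len(config.mixture))
    )
    for k in range(config.n_alleles):
        allele = f"IGHVS-{k + 1}*01"
        v_seqs[allele] = _random_seq(rng, config.v_len)
        base = "A" + _random_seq(rng, config.upstream_len - 1)  # non-G 5' end
        lo, hi = config.diff_position_range
        allele_variants = []
        used_offsets: set[int] = set()
        for i, fraction in enumerate(config.mixture):
            if i == 0:
                seq = base
            else:
                offsets = []
                while len(offsets) < config.n_variant_diffs:
                    off = int(rng.integers(lo, hi + 1))  # 3'-anchored offset
                    if off not in used_offsets:
                        used_offsets.add(off)
                        offsets.append(config.upstream_len - off)
                seq = _mutate(rng, base, np.array(offsets))
            allele_variants.append(
                UpstreamVariantTruth(
                    allele=allele,
                    variant_id=f"{allele}/v{i}",
                    sequence=seq,
                    chromosome=chroms[i],
                    fraction=fraction,
                )
            )
        variants[allele] = allele_variants
    return Reference(v_seqs=v_seqs, j_seqs=j_seqs, variants=variants)


def _draw_extent(config: SimulationConfig, rng: np.random.Generator) -> int:
    """Truncated-geometric 5' extent over the upstream region."""
    shortfall = int(rng.geometric(config.full_extent_prob)) - 1
    shortfall = min(shortfall, config.upstream_len - config.min_extent)
    return config.upstream_len - shortfall


def _draw_barcode(config: SimulationConfig, rng: np.random.Generator,
                  tail: int) -> str:
    """Barcode such that TACGGG first occurs at the true adaptor start."""
    lo, hi = config.barcode_len
    while True:
        barcode = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        decorated = barcode + "TAC" + "G" * tail
        if decorated.find("TACGGG") == len(barcode):
            return barcode


def _subject_het(config: SimulationConfig, s: int) -> bool:
    if isinstance(config.j_heterozygous, bool):
        return config.j_heterozygous
    return bool(config.j_heterozygous[s])


def simulate_repertoire(config: SimulationConfig) -> SimulatedRepertoire:
    """Generate the full cohort: read pairs, annotated tables, ground truth."""
    from .io import RawReadPair

    config.validate()
    rng = np.random.default_rng(config.seed)
    reference = make_reference(config, rng)
    mixture = np.asarray(config.mixture, dtype=float)
    subjects: list[SubjectData] = []
    counter = 0
    for s in range(config.n_subjects):
        subject_id = f"S{s + 1}"
        genotype = (
            (J_ALLELES[0], J_ALLELES[1])
            if _subject_het(config, s)
            else (J_ALLELES[0], J_ALLELES[0])
        )
        pairs, rearrangements, truths = [], [], []
        for allele, allele_variants in reference.variants.items():
            v_seq = reference.v_seqs[allele]
            for _ in range(config.reads_per_allele):
                counter += 1
                read_id = f"{subject_id}:R{counter:07d}"
                variant = allele_variants[
                    int(rng.choice(len(mixture), p=mixture))
                ]
                chrom = variant.chromosome
                j_true = genotype[chrom]
                j_call = j_true
                if rng.random() < config.j_mis_rate:
                    j_call = (
                        J_ALLELES[1] if j_true == J_ALLELES[0] else J_ALLELES[0]
                    )
                extent = _draw_extent(config, rng)
                offset = config.upstream_len - extent
                while (
                    offset < config.upstream_len - 1
                    and variant.sequence[offset] == "G"
                ):
                    offset += 1  # leading Gs are unrecoverable post-trim
                upstream_frag = variant.sequence[offset:]
                lo, hi = config.cdr3_len_range
                cdr3_aa = "".join(
                    AMINO_ACIDS[i]
                    for i in rng.integers(
                        0, len(AMINO_ACIDS), size=int(rng.integers(lo, hi + 1))
                    )
                )
                cdr3_nt = "".join(_CODON[a] for a in cdr3_aa)
                clean = (
                    upstream_frag + v_seq + cdr3_nt + reference.j_seqs[j_true]
                )
                err_pos = np.flatnonzero(
                    rng.random(len(clean)) < config.error_rate
                )
                transcript = (
                    _mutate(rng, clean, err_pos) if err_pos.size else clean
                )
                v_lo = len(upstream_frag)
                v_errors = int(
                    sum(1 for p in err_pos if v_lo <= p < v_lo + config.v_len)
                )
                tail = int(
                    rng.integers(config.g_tail_len[0], config.g_tail_len[1] + 1)
                )
                barcode = _draw_barcode(config, rng, tail)
                decoration = barcode + "TAC" + "G" * tail
                frag_cap = max(0, config.read_len - len(decoration))
                fragment = transcript[:frag_cap]
                fwd_seq = decoration + fragment
                rev_seq = revcomp(transcript[-config.read_len :])
                pairs.append(
                    RawReadPair(
                        read_id=read_id,
                        fwd_seq=fwd_seq,
                        fwd_qual="I" * len(fwd_seq),
                        rev_seq=rev_seq,
                        rev_qual="I" * len(rev_seq),
                    )
                )
                rearrangements.append(
                    Rearrangement(
                        sequence_id=read_id,
                        sequence=transcript,
                        v_call=allele,
                        j_call=j_call,
                        v_errors=v_errors,
                        cdr3_aa=cdr3_aa,
                        v_start=v_lo,
                    )
                )
                truths.append(
                    ReadTruth(
                        read_id=read_id,
                        subject_id=subject_id,
                        transcript=transcript,
                        fragment=fragment,
                        chromosome=chrom,
                        variant_id=variant.variant_id,
                        cdr3_aa=cdr3_aa,
                        j_true=j_true,
                    )
                )
        subjects.append(
            SubjectData(
                subject_id=subject_id,
                j_genotype=genotype,
                pairs=pairs,
                rearrangements=rearrangements,
                truth=truths,
            )
        )
    return SimulatedRepertoire(
        config=config, reference=reference, subjects=subjects
    )


@dataclass
class RecoveryReport:
    """Outcome of comparing inferred variants against planted truth."""

    n_truth: int
    n_inferred: int
    recovered: list[str]  # truth variant_ids recovered verbatim
    missed: list[str]
    spurious: list[str]  # inferred sequences matching no truth variant

    @property
    def all_recovered(self) -> bool:
        return not self.missed and not self.spurious


def truth_compare(
    inferred_sequences: Sequence[str],
    truth_variants: Sequence[UpstreamVariantTruth],
) -> RecoveryReport:
    """Compare inferred upstream sequences with planted variants verbatim."""
    truth_by_seq = {t.sequence: t.variant_id for t in truth_variants}
    recovered, spurious = [], []
    seen: set[str] = set()
    for seq in inferred_sequences:
        vid = truth_by_seq.get(seq)
        if vid is not None and vid not in seen:
            seen.add(vid)
            recovered.append(vid)
        elif vid is None:
            spurious.append(seq)
    missed = [t.variant_id for t in truth_variants if t.variant_id not in seen]
    return RecoveryReport(
        n_truth=len(truth_variants),
        n_inferred=len(inferred_sequences),
        recovered=recovered,
        missed=missed,
        spurious=spurious,
    )


def write_outputs(sim: SimulatedRepertoire, outdir: str | Path) -> None:
    """Write R1/R2 FASTQ, annotated TSV, truth TSV and a config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for subject in sim.subjects:
        prefix = outdir / subject.subject_id
        write_fastq(
            ((p.read_id, p.fwd_seq, p.fwd_qual) for p in subject.pairs),
            f"{prefix}_R1.fastq",
        )
        write_fastq(
            ((p.read_id, p.rev_seq, p.rev_qual) for p in subject.pairs),
            f"{prefix}_R2.fastq",
        )
        write_rearrangement_table(
            subject.rearrangements, f"{prefix}_annotated.tsv"
        )
        with open(f"{prefix}_truth.tsv", "w") as handle:
            handle.write(
                "read_id\tsubject_id\tchromosome\tvariant_id\tcdr3_aa\t"
                "j_true\tfragment\ttranscript\n"
            )
            for t in subject.truth:
                handle.write(
                    f"{t.read_id}\t{t.subject_id}\t{t.chromosome}\t"
                    f"{t.variant_id}\t{t.cdr3_aa}\t{t.j_true}\t"
                    f"{t.fragment}\t{t.transcript}\n"
                )
    with open(outdir / "config.json", "w") as handle:
        json.dump(sim.config.to_dict(), handle, indent=2)
    with open(outdir / "truth_variants.tsv", "w") as handle:
        handle.write("allele\tvariant_id\tchromosome\tfraction\tsequence\n")
        for allele, variants in sim.reference.variants.items():
            for v in variants:
                handle.write(
                    f"{allele}\t{v.variant_id}\t{v.chromosome}\t"
                    f"{v.fraction}\t{v.sequence}\n"
                )
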