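"""Small-RNA read processing and 5'-anchored window quantification.

The processing contract: 3' adapters are removed by exact prefix search,
inserts outside 18-28 nt are discarded, surviving sequences are collapsed to
unique tallies and mapped to the genome allowing zero mismatches, and each
mature miRNA is quantified from the distinct sequences whose mapped 5' end
falls within ±3 nt of its annotated 5' end.  Within that window the
sequence with the maximal count is the *reference sequence*, and the
miRNA's abundance is the summed count of window sequences sharing the
reference's 5' position.

Offsets are expressed in mature-RNA orientation: on the plus strand
``offset = read_5p - locus_5p``; on the minus strand the sign is flipped,
so negative offsets are always upstream of the mature 5' end.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .synthetic import MiRNALocus, ToyGenome, revcomp

_ACGT = set("ACGT")


@dataclass(frozen=True)
class TrimmedSequence:
    sequence: str
    count: int

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("collapsed counts must be >= 1")


@dataclass(frozen=True)
class SequenceAlignment:
    """A zero-mismatch genomic placement of one distinct read sequence."""

    sequence: str
    chrom: str
    strand: str
    start: int
    end: int
    five_prime_pos: int

    def __post_init__(self):
        expected = self.start if self.strand == "+" else self.end
        if self.five_prime_pos != expected:
            raise ValueError("five_prime_pos inconsistent with strand")


@dataclass
class MiRNAQuantRecord:
    """Quantification of one mature miRNA from its 5' window.

    ``window_sequences`` lists (sequence, count, offset) for every distinct
    sequence captured by the window; ``reference_sequence`` is the
    max-count member (None when the window is empty) and ``abundance`` sums
    the counts of members sharing the reference's observed 5' position —
    which may differ from the annotated one.
    """

    mirna_id: str
    reference_sequence: str | None
    reference_five_prime_pos: int | None
    abundance: int
    window_sequences: list[tuple[str, int, int]] = field(default_factory=list)


def trim_adapter(read: str, adapter: str, min_prefix: int = 8, min_fallback: int = 5) -> str | None:
    """Remove the 3' adapter from one read; None when no adapter is found.

    The leftmost exact occurrence of the adapter's first ``min_prefix``
    nucleotides marks the insert end.  When that prefix is absent the
    adapter may be truncated at the read's 3' terminus, so progressively
    shorter prefixes (down to ``min_fallback`` nt) are tried anchored at the
    read end.
    """
    if not read:
        raise ValueError("empty read")
    if set(adapter) - _ACGT:
        raise ValueError("adapter must be A/C/G/T only")
    if len(adapter) < min_prefix:
        raise ValueError("adapter shorter than min_prefix")
    pos = read.find(adapter[:min_prefix])
    if pos != -1:
        return read[:pos]
    for k in range(min_prefix - 1, min_fallback - 1, -1):
        if read.endswith(adapter[:k]):
            return read[: len(read) - k]
    return None


def trim_and_tally(
    reads: list[tuple[str, str]], adapter: str, min_prefix: int = 8
) -> tuple[list[TrimmedSequence], int]:
    """Trim all reads and collapse identical inserts; rejected reads counted."""
    tally: Counter[str] = Counter()
    n_rejected = 0
    for _, seq in reads:
        insert = trim_adapter(seq, adapter, min_prefix=min_prefix)
        if insert is None:
            n_rejected += 1
        elif insert:  # empty inserts carry no sequence; the length filter would drop them anyway
            tally[insert] += 1
    return [TrimmedSequence(s, c) for s, c in sorted(tally.items())], n_rejected


def length_filter(
    tally: list[TrimmedSequence], min_len: int = 18, max_len: int = 28
) -> list[TrimmedSequence]:
    """Keep sequences of 18-28 nt inclusive (the retained size range)."""
    return [t for t in tally if min_len <= len(t.sequence) <= max_len]


def map_exact(tally: list[TrimmedSequence], genome: ToyGenome) -> list[SequenceAlignment]:
    """Report every zero-mismatch occurrence of each sequence on both strands.

    Sequences with no perfect match are dropped; a sequence with several
    genomic occurrences yields one alignment per occurrence.
    """
    alignments: list[SequenceAlignment] = []
    for t in tally:
        seq = t.sequence
        rc = revcomp(seq)
        for chrom in genome.chrom_names:
            chrom_seq = genome.sequences[chrom]
            L = len(seq)
            pos = chrom_seq.find(seq)
            while pos != -1:
                start = pos + 1
                alignments.append(
                    SequenceAlignment(seq, chrom, "+", start, start + L - 1, start)
                )
                pos = chrom_seq.find(seq, pos + 1)
            if rc != seq:
                pos = chrom_seq.find(rc)
                while pos != -1:
                    start = pos + 1
                    end = start + L - 1
                    alignments.append(SequenceAlignment(seq, chrom, "-", start, end, end))
                    pos = chrom_seq.find(rc, pos + 1)
            else:
                # palindromic sequence: the same occurrence also reads on '-'
                pos = chrom_seq.find(seq)
                while pos != -1:
                    start = pos + 1
                    end = start + L - 1
                    alignments.append(SequenceAlignment(seq, chrom, "-", start, end, end))
                    pos = chrom_seq.find(seq, pos + 1)
    return alignments


def _rna_offset(read_5p: int, locus: MiRNALocus) -> int:
    off = read_5p - locus.five_prime_pos
    return off if locus.strand == "+" else -off


def quantify_mirna(
    alignments: list[SequenceAlignment],
    counts: dict[str, int],
    loci: list[MiRNALocus],
    window: int = 3,
) -> list[MiRNAQuantRecord]:
    """5'-anchored window quantification of each mature miRNA.

    A distinct sequence belongs to a locus's window when at least one of its
    alignments sits on the locus's chromosome and strand with
    ``|read_5p - locus_5p| <= window``.  A multi-mapping sequence
    contributes its full count to every miRNA whose window captures one of
    its alignments, but only once per miRNA however many in-window
    alignments it has; its representative offset is the in-window alignment
    closest to the annotated 5' end (ties to the upstream one).  Reference
    ties break by smaller |offset|, then longer sequence, then lexicographic
    order.
    """
    seen = set()
    for loc in loci:
        if loc.mirna_id in seen:
            raise ValueError(f"duplicate mirna_id {loc.mirna_id}")
        seen.add(loc.mirna_id)

    by_key: dict[tuple[str, str], list[tuple[int, str]]] = defaultdict(list)
    for aln in alignments:
        by_key[(aln.chrom, aln.strand)].append((aln.five_prime_pos, aln.sequence))

    records = []
    for loc in loci:
        # representative (offset, 5' position) per distinct in-window sequence
        members: dict[str, tuple[int, int]] = {}
        for pos5, seq in by_key.get((loc.chrom, loc.strand), ()):
            off = _rna_offset(pos5, loc)
            if abs(off) > window:
                continue
            prev = members.get(seq)
            if prev is None or (abs(off), off) < (abs(prev[0]), prev[0]):
                members[seq] = (off, pos5)
        if not members:
            records.append(MiRNAQuantRecord(loc.mirna_id, None, None, 0, []))
            continue
        window_sequences = sorted(
            ((seq, counts[seq], off) for seq, (off, _) in members.items()),
            key=lambda t: (-t[1], abs(t[2]), -len(t[0]), t[0]),
        )
        ref_seq, ref_count, ref_off = window_sequences[0]
        ref_pos = members[ref_seq][1]
        abundance = sum(
            counts[seq] for seq, (off, pos) in members.items() if pos == ref_pos
        )
        records.append(
            MiRNAQuantRecord(loc.mirna_id, ref_seq, ref_pos, abundance, window_sequences)
        )
    return records


def quant_records_to_frame(records: list[MiRNAQuantRecord], loci: list[MiRNALocus]) -> pd.DataFrame:
    """Per-miRNA quantification table (reference offset in RNA orientation)."""
    by_id = {loc.mirna_id: loc for loc in loci}
    rows = []
    for rec in records:
        loc = by_id[rec.mirna_id]
        rows.append(
            {
                "mirna_id": rec.mirna_id,
                "reference_sequence": rec.reference_sequence or "",
                "reference_offset": (
                    _rna_offset(rec.reference_five_prime_pos, loc)
                    if rec.reference_five_prime_pos is not None
                    else ""
                ),
                "abundance": rec.abundance,
            }
        )
    return pd.DataFrame(rows, columns=["mirna_id", "reference_sequence", "reference_offset", "abundance"])


def window_detail_frame(records: list[MiRNAQuantRecord]) -> pd.DataFrame:
    rows = [
        {"mirna_id": rec.mirna_id, "sequence": seq, "count": count, "offset": off}
        for rec in records
        for seq, count, off in rec.window_sequences
    ]
    return pd.DataFrame(rows, columns=["mirna_id", "sequence", "count", "offset"])


def quantify_sample(
    reads: list[tuple[str, str]],
    genome: ToyGenome,
    loci: list[MiRNALocus],
    adapter: str,
    window: int = 3,
    min_len: int = 18,
    max_len: int = 28,
) -> list[MiRNAQuantRecord]:
    """Full per-sample path: trim → length filter → map → quantify."""
    tally, _ = trim_and_tally(reads, adapter)
    tally = length_filter(tally, min_len, max_len)
    alignments = map_exact(tally, genome)
    counts = {t.sequence: t.count for t in tally}
    return quantify_mirna(alignments, counts, loci, window=window)
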