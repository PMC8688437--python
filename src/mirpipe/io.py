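"""Readers and writers for the plain-text formats used across the pipeline.

FASTA/FASTQ go through Biopython, SAM through pysam.  miRNA loci use a
miRBase-dialect GFF3 (type ``miRNA``, attributes ``ID``/``Name``, 1-based
inclusive coordinates); the dialect is narrow enough that a strict
line-oriented reader/writer is used.  Tabular data are tab-separated UTF-8
with a header row, via pandas.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_GFF_COLS = 9


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]], quality_char: str = "I") -> None:
    """Write 4-line FASTQ records with a constant Phred+33 quality string."""
    with open(path, "w", encoding="utf-8") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_mirna_gff3(path: str | Path, loci) -> None:
    """Write miRNA loci in the miRBase GFF3 dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            attrs = f"ID={loc.mirna_id};Name={loc.mirna_id}"
            fh.write(
                "\t".join(
                    [
                        loc.chrom,
                        "mirpipe",
                        "miRNA",
                        str(loc.start),
                        str(loc.end),
                        ".",
                        loc.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_mirna_gff3(path: str | Path, genome: dict[str, str] | None = None) -> list:
    """Parse miRNA loci from a miRBase-dialect GFF3.

    When ``genome`` is given, mature sequences are re-extracted from it
    (reverse-complemented on the minus strand); otherwise ``mature_seq`` is
    left empty.
    """
    from .synthetic import MiRNALocus, revcomp

    loci = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _GFF_COLS:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype != "miRNA":
                continue
            m = re.search(r"ID=([^;]+)", attrs)
            if m is None:
                raise ValueError(f"GFF3 miRNA record without ID attribute: {line!r}")
            start_i, end_i = int(start), int(end)
            mature = ""
            if genome is not None:
                mature = genome[chrom][start_i - 1 : end_i]
                if strand == "-":
                    mature = revcomp(mature)
            loci.append(
                MiRNALocus(
                    mirna_id=m.group(1),
                    chrom=chrom,
                    strand=strand,
                    start=start_i,
                    end=end_i,
                    five_prime_pos=start_i if strand == "+" else end_i,
                    mature_seq=mature,
                )
            )
    return loci


def write_tsv(path: str | Path, frame: pd.DataFrame, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def read_sam_tally(path: str | Path) -> tuple[list, dict[str, int]]:
    """SAM ingestion for quantification: unique alignments plus per-sequence counts.

    Counts are per distinct read name (a multi-mapped read contributes one
    count however many records it has); alignments are deduplicated per
    (sequence, chrom, strand, start).
    """
    alignments = read_sam_alignments(path, keep_names=True)
    names_per_seq: dict[str, set[str]] = {}
    unique = {}
    for name, aln in alignments:
        names_per_seq.setdefault(aln.sequence, set()).add(name)
        unique[(aln.sequence, aln.chrom, aln.strand, aln.start)] = aln
    counts = {s: len(names) for s, names in names_per_seq.items()}
    return list(unique.values()), counts


def read_sam_alignments(path: str | Path, keep_names: bool = False) -> list:
    """Ingest externally produced alignments, keeping perfect matches only.

    A record is kept when its NM tag is 0, or, failing that, when its MD tag
    describes an all-match run.  Records with neither tag, or with any
    mismatch or indel, are discarded — mirroring the requirement that only
    sequences perfectly matching the genome are quantified.
    """
    import pysam

    from .quant import SequenceAlignment

    alignments = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for rec in sam:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            if any(op != 0 for op, _ in (rec.cigartuples or [])):
                continue  # indels/clips break the perfect-match contract
            if rec.has_tag("NM"):
                if rec.get_tag("NM") != 0:
                    continue
            elif rec.has_tag("MD"):
                if not re.fullmatch(r"\d+", str(rec.get_tag("MD"))):
                    continue
            else:
                continue
            start = rec.reference_start + 1  # SAM is 0-based half-open here
            end = rec.reference_end  # pysam reference_end is exclusive 0-based == inclusive 1-based
            strand = "-" if rec.is_reverse else "+"
            seq = rec.query_sequence.upper()
            if rec.is_reverse:
                from .synthetic import revcomp

                seq = revcomp(seq)  # restore the read's original orientation
            aln = SequenceAlignment(
                sequence=seq,
                chrom=rec.reference_name,
                strand=strand,
                start=start,
                end=end,
                five_prime_pos=start if strand == "+" else end,
            )
            alignments.append((rec.query_name, aln) if keep_names else aln)
    return alignments
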