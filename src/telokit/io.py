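"""FASTA/FASTQ/GFF3/TSV input and output.

Readers accept any line wrapping (Biopython parsers underneath); the FASTA
writer wraps at 60 columns and the FASTQ writer emits fixed quality so that
identical inputs give byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO

FASTA_WRAP = 60
FASTQ_QUALITY_CHAR = "I"


@dataclass(frozen=True)
class TranscriptRecord:
    """One assembled transcript, namespaced by the dataset it came from."""

    id: str
    sequence: str
    dataset: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        allowed = set("ACGTN")
        seq = self.sequence.upper()
        if not allowed.issuperset(seq):
            bad = sorted(set(seq) - allowed)
            raise ValueError(f"transcript {self.id}: bad characters {bad!r}")
        object.__setattr__(self, "sequence", seq)


def read_fasta(path: str | Path, dataset: str | None = None) -> list[TranscriptRecord]:
    """Read a (possibly wrapped) multi-FASTA into TranscriptRecords.

    Sequences are upper-cased; duplicate ids within one file are an error.
    The dataset label defaults to the file stem.
    """
    path = Path(path)
    label = dataset if dataset is not None else path.stem
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate transcript id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(TranscriptRecord(rec.id, str(rec.seq), label))
    return records


def write_fasta(
    records: Iterable[TranscriptRecord | tuple[str, str]],
    handle_or_path: TextIO | str | Path,
) -> None:
    """Write records as 60-column-wrapped FASTA."""
    close = False
    if isinstance(handle_or_path, (str, Path)):
        handle = open(handle_or_path, "w")
        close = True
    else:
        handle = handle_or_path
    try:
        for rec in records:
            if isinstance(rec, tuple):
                name, seq = rec
            else:
                name, seq = rec.id, rec.sequence
            handle.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WRAP):
                handle.write(seq[i : i + FASTA_WRAP] + "\n")
    finally:
        if close:
            handle.close()


def read_reads(path: str | Path) -> list[str]:
    """Read sequences from FASTA or FASTQ (sniffed from the first character)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)]


def write_fastq(
    reads: Iterable[tuple[str, str]], handle_or_path: TextIO | str | Path
) -> None:
    """Write (name, sequence) reads as FASTQ with fixed quality."""
    close = False
    if isinstance(handle_or_path, (str, Path)):
        handle = open(handle_or_path, "w")
        close = True
    else:
        handle = handle_or_path
    try:
        for name, seq in reads:
            handle.write(f"@{name}\n{seq}\n+\n{FASTQ_QUALITY_CHAR * len(seq)}\n")
    finally:
        if close:
            handle.close()


def write_gff3(
    features: Iterable[tuple[str, str, int, int, float | None, str]],
    handle_or_path: TextIO | str | Path,
    source: str = "telokit",
) -> None:
    """Write features as GFF3.

    Each feature is (seqid, type, start, end, score, strand) with 0-based
    half-open coordinates; the writer converts to GFF3's 1-based inclusive.
    """
    close = False
    if isinstance(handle_or_path, (str, Path)):
        handle = open(handle_or_path, "w")
        close = True
    else:
        handle = handle_or_path
    try:
        handle.write("##gff-version 3\n")
        for seqid, ftype, start, end, score, strand in features:
            score_str = "." if score is None else f"{score:.4g}"
            handle.write(
                f"{seqid}\t{source}\t{ftype}\t{start + 1}\t{end}\t"
                f"{score_str}\t{strand}\t.\t.\n"
            )
    finally:
        if close:
            handle.close()


def read_trf_table(path: str | Path) -> list[tuple[float, float]]:
    """Read a two-column (size_bp, intensity) TSV/CSV, header optional."""
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split("\t")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                continue  # header line
    return rows


def iter_fasta_stream(path: str | Path, dataset: str | None = None) -> Iterator[TranscriptRecord]:
    """Streaming variant of read_fasta for large assemblies."""
    path = Path(path)
    label = dataset if dataset is not None else path.stem
    for rec in SeqIO.parse(str(path), "fasta"):
        yield TranscriptRecord(rec.id, str(rec.seq), label)
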