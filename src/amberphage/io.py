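"""File I/O shared by the pipeline: FASTQ, FASTA, peptide lists, TSV/JSON.

FASTQ is read with a small 4-line-record reader so that malformed records can
be reported with exact line numbers; FASTA goes through Biopython.  Both plain
and gzip-compressed inputs are accepted, sniffed by magic bytes.
"""

from __future__ import annotations

import gzip
import json
import logging
from collections.abc import Iterable, Iterator
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("amberphage")


class FastqParseError(ValueError):
    """Malformed FASTQ input; the message names the offending line."""


def open_text_auto(path: str | Path):
    """Open a possibly-gzipped file for text reading (sniffs magic bytes)."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path: str | Path, phred_offset: int = 33) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (id, sequence, quality-int-list) from a 4-line-record FASTQ file.

    Raises :class:`FastqParseError` naming the first bad line for truncated
    records, header/separator glitches, and sequence/quality length mismatch.
    """
    with open_text_auto(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqParseError(
                    f"{path}: line {lineno}: expected '@' header, got {header[:30]!r}"
                )
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise FastqParseError(
                    f"{path}: line {lineno}: truncated record {header[:30]!r}"
                )
            lineno += 3
            if not plus.startswith("+"):
                raise FastqParseError(
                    f"{path}: line {lineno - 1}: expected '+' separator"
                )
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"{path}: line {lineno}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            phred = [ord(c) - phred_offset for c in qual]
            if phred and min(phred) < 0:
                raise FastqParseError(
                    f"{path}: line {lineno}: quality below Phred+{phred_offset} range"
                )
            yield header[1:].split()[0], seq.upper(), phred


def write_fastq(
    path: str | Path,
    records: Iterable[tuple[str, str, list[int]]],
    phred_offset: int = 33,
) -> int:
    """Write (id, seq, qual) records as FASTQ; gzip if the path ends in .gz."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            qstr = "".join(chr(q + phred_offset) for q in qual)
            fh.write(f"@{rid}\n{seq}\n+\n{qstr}\n")
            n += 1
    return n


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> int:
    seqrecs = (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records)
    return SeqIO.write(seqrecs, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def read_sequence_list(path: str | Path) -> list[str]:
    """Read sequences from FASTA or a plain one-per-line text/TSV file.

    For TSV lines the first column is taken; '#'-prefixed lines are skipped.
    """
    path = Path(path)
    with open_text_auto(path) as fh:
        first = fh.read(1)
    if first == ">":
        return [seq for _, seq in read_fasta(path)]
    seqs: list[str] = []
    with open_text_auto(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            seqs.append(line.split("\t")[0].upper())
    return seqs


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
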