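"""Format helpers: FASTA/FASTQ round-trips and browser-track writers.

All genomic intervals written here are 0-based half-open (BED/bedGraph
convention). Gzip is handled transparently by file extension.
"""

from __future__ import annotations

import gzip
import hashlib
import os
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

FastqRead = tuple[str, str, str]  # (name, sequence, quality string)


def open_text(path: str | os.PathLike, mode: str = "rt"):
    """Open plain or gzipped text depending on the ``.gz`` suffix."""
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a (possibly wrapped, possibly gzipped) multi-FASTA into a dict."""
    with open_text(path) as handle:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return seqs


def write_fasta(path: str | os.PathLike, seqs: Mapping[str, str], width: int = 60) -> None:
    with open_text(path, "wt") as out:
        for name, seq in seqs.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def read_fastq(path: str | os.PathLike) -> Iterator[FastqRead]:
    """Yield (name, sequence, quality) tuples from a FASTQ(.gz) file."""
    with open_text(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield title.split()[0], seq, qual


def write_fastq(path: str | os.PathLike, reads: Iterable[FastqRead]) -> int:
    n = 0
    with open_text(path, "wt") as out:
        for name, seq, qual in reads:
            out.write(f"@{name}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def write_bedgraph(
    path: str | os.PathLike,
    intervals: Iterable[tuple[str, int, int, float]],
    track_name: str | None = None,
) -> None:
    with open_text(path, "wt") as out:
        if track_name:
            out.write(f'track type=bedGraph name="{track_name}"\n')
        for chrom, start, end, value in intervals:
            out.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def write_bed(path: str | os.PathLike, rows: Iterable[tuple]) -> None:
    with open_text(path, "wt") as out:
        for row in rows:
            out.write("\t".join(str(x) for x in row) + "\n")


def file_md5(path: str | os.PathLike) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
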