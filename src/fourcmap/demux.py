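"""Read sorting by viewpoint barcode+primer prefix, trimming, subsampling.

Multiplexed 4C libraries tag every inverse-PCR primer with a 4-nt barcode;
a sequenced read therefore starts with ``barcode + primer`` followed by the
captured fragment end. Demultiplexing is exact-prefix: a 4-nt barcode
leaves no mismatch budget, so a read is assigned to a viewpoint iff its
sequence begins with that viewpoint's barcode+primer with zero mismatches,
and the prefix (plus qualities, in register) is trimmed off. Everything
else lands in an ``unassigned`` bucket.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from . import io as fio
from .io import FastqRead

UNASSIGNED = "unassigned"

_DNA = set("ACGT")


@dataclass(frozen=True)
class Viewpoint:
    """One 4C viewpoint: its demultiplexing prefix and (optional) locus.

    ``chrom``/``position`` are the known genomic coordinates for endogenous
    viewpoints (or a validated transgene locus); a transgene-internal
    viewpoint has no reference position and leaves them unset.
    """

    name: str
    barcode: str
    primer: str
    chrom: str | None = None
    position: int | None = None
    source: str = "genomic"  # "genomic" or "transgene"

    def __post_init__(self):
        if len(self.barcode) != 4:
            raise ValueError(f"viewpoint {self.name}: barcode must be 4 nt, got {self.barcode!r}")
        if len(self.primer) < 15:
            raise ValueError(f"viewpoint {self.name}: primer must be >= 15 nt")
        if set(self.barcode.upper()) - _DNA or set(self.primer.upper()) - _DNA:
            raise ValueError(f"viewpoint {self.name}: barcode/primer must be A/C/G/T only")
        if self.source not in ("genomic", "transgene"):
            raise ValueError(f"viewpoint {self.name}: unknown source {self.source!r}")

    @property
    def prefix(self) -> str:
        return (self.barcode + self.primer).upper()


def validate_viewpoints(viewpoints: Iterable[Viewpoint]) -> list[Viewpoint]:
    """Reject duplicate barcode+primer prefixes (ambiguous demultiplexing)."""
    vps = list(viewpoints)
    seen: dict[str, str] = {}
    for vp in vps:
        if vp.prefix in seen:
            raise ValueError(
                f"duplicate barcode+primer prefix shared by viewpoints "
                f"{seen[vp.prefix]!r} and {vp.name!r}"
            )
        seen[vp.prefix] = vp.name
    return vps


def load_viewpoints(path: str | os.PathLike) -> list[Viewpoint]:
    """Load viewpoint definitions from a YAML list or a TSV table.

    TSV columns: name, barcode, primer, chrom, position, source; '.' or an
    empty field means unset. YAML: a list of mappings with the same keys.
    """
    path = Path(path)
    vps: list[Viewpoint] = []
    if path.suffix in (".yaml", ".yml"):
        with open(path) as fh:
            entries = yaml.safe_load(fh)
        for e in entries:
            vps.append(
                Viewpoint(
                    name=e["name"],
                    barcode=e["barcode"],
                    primer=e["primer"],
                    chrom=e.get("chrom"),
                    position=e.get("position"),
                    source=e.get("source", "genomic"),
                )
            )
    else:
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                fields += ["."] * (6 - len(fields))
                name, barcode, primer, chrom, pos, source = fields[:6]
                vps.append(
                    Viewpoint(
                        name=name,
                        barcode=barcode,
                        primer=primer,
                        chrom=None if chrom in (".", "") else chrom,
                        position=None if pos in (".", "") else int(pos),
                        source="genomic" if source in (".", "") else source,
                    )
                )
    return validate_viewpoints(vps)


@dataclass
class DemuxResult:
    """Per-viewpoint trimmed reads plus bookkeeping counts."""

    reads: dict[str, list[FastqRead]] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def demultiplex(reads: Iterable[FastqRead], viewpoints: Iterable[Viewpoint]) -> DemuxResult:
    """Assign reads to viewpoints by exact barcode+primer prefix and trim.

    Reads shorter than a viewpoint prefix can never match it; reads matching
    no viewpoint go to the ``unassigned`` bucket untrimmed. Assigned +
    unassigned counts always equal the input count.
    """
    vps = validate_viewpoints(viewpoints)
    result = DemuxResult(
        reads={vp.name: [] for vp in vps} | {UNASSIGNED: []},
        counts={vp.name: 0 for vp in vps} | {UNASSIGNED: 0},
    )
    prefixes = [(vp.name, vp.prefix, len(vp.prefix)) for vp in vps]
    for name, seq, qual in reads:
        up = seq.upper()
        for vp_name, prefix, plen in prefixes:
            if up.startswith(prefix):
                result.reads[vp_name].append((name, seq[plen:], qual[plen:]))
                result.counts[vp_name] += 1
                break
        else:
            result.reads[UNASSIGNED].append((name, seq, qual))
            result.counts[UNASSIGNED] += 1
    return result


def demultiplex_fastq(
    fastq_path: str | os.PathLike,
    viewpoints: Iterable[Viewpoint],
    out_dir: str | os.PathLike,
    gzip_out: bool = False,
) -> dict[str, int]:
    """File-level wrapper: one trimmed FASTQ per viewpoint plus unassigned."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = demultiplex(fio.read_fastq(fastq_path), viewpoints)
    suffix = ".fastq.gz" if gzip_out else ".fastq"
    for bucket, bucket_reads in result.reads.items():
        fio.write_fastq(out_dir / f"{bucket}{suffix}", bucket_reads)
    return result.counts


def subsample_viewpoint_reads(
    reads: Iterable[FastqRead], n: int, seed: int
) -> list[FastqRead]:
    """Uniform sample of min(n, total) reads without replacement.

    Deterministic given ``seed``; the kept reads preserve their input order.
    Matches the protocol of thinning viewpoint-containing reads to a fixed
    depth (50,000 in the reference workflow) before enrichment analysis.
    """
    if n < 0:
        raise ValueError("subsample size must be >= 0")
    pool = list(reads)
    if n >= len(pool):
        return pool
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(pool), size=n, replace=False)
    keep.sort()
    return [pool[i] for i in keep]
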