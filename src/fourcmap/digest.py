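"""In-silico restriction digestion and fragment-end sequence indexing.

4C statistics live on the grid of restriction sites of the primary cutter
(Csp6I, recognition GTAC, in the reference protocol; DpnII, GATC, is the
circularizing second cutter). A :class:`SiteMap` holds, per chromosome, the
sorted 0-based coordinates of every exact occurrence of the recognition
sequence on the forward strand — both supported enzymes are palindromic, so
forward-strand scanning finds every cut site. ``N`` bases never match, which
keeps assembly gaps free of phantom sites.

A :class:`FragmentEndIndex` stores, for each site, the two sequences a 4C
read can begin with after primer trimming: the downstream strand starting at
the site, and the reverse-complement of the strand ending at the site. This
is the reduced search space an exact mapper needs — 4C reads always start
flush at a restriction-site boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from . import io as fio

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DOWNSTREAM = "down"
UPSTREAM = "up"


def revcomp(seq: str) -> str:
    """Reverse complement (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SiteMap:
    """Per-chromosome sorted restriction-site coordinates for one enzyme.

    ``sites[chrom]`` is a sorted int64 array of 0-based positions of the
    first base of the recognition sequence.
    """

    enzyme_name: str
    recognition_seq: str
    sites: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]

    @property
    def site_length(self) -> int:
        return len(self.recognition_seq)

    def n_sites(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(len(self.sites[chrom]))
        return int(sum(len(v) for v in self.sites.values()))

    def chroms(self) -> list[str]:
        return list(self.sites)

    def to_bed(self, path) -> None:
        L = self.site_length
        fio.write_bed(
            path,
            (
                (chrom, int(p), int(p) + L)
                for chrom, pos in self.sites.items()
                for p in pos
            ),
        )

    def to_json(self, path, genome_md5: str | None = None) -> None:
        payload = {
            "enzyme_name": self.enzyme_name,
            "recognition_seq": self.recognition_seq,
            "genome_md5": genome_md5,
            "chrom_lengths": self.chrom_lengths,
            "sites": {c: [int(x) for x in v] for c, v in self.sites.items()},
        }
        with open(path, "w") as out:
            json.dump(payload, out)

    @classmethod
    def from_json(cls, path) -> "SiteMap":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            enzyme_name=payload["enzyme_name"],
            recognition_seq=payload["recognition_seq"],
            sites={c: np.asarray(v, dtype=np.int64) for c, v in payload["sites"].items()},
            chrom_lengths=payload["chrom_lengths"],
        )

    def validate(self, genome: Mapping[str, str]) -> None:
        """Check every recorded site against the genome sequence."""
        recog = self.recognition_seq.upper()
        L = len(recog)
        for chrom, positions in self.sites.items():
            seq = genome[chrom].upper()
            for p in positions:
                if seq[p : p + L] != recog:
                    raise AssertionError(f"site {chrom}:{p} does not read {recog}")


def digest(sequences: Mapping[str, str], recognition_seq: str, enzyme_name: str = "") -> SiteMap:
    """Scan every chromosome for exact occurrences of ``recognition_seq``.

    Only palindromic recognition sequences are accepted (the forward-strand
    scan then covers both strands). Overlapping occurrences are all
    reported; ``N`` never matches.
    """
    recog = recognition_seq.upper()
    if not recog:
        raise ValueError("recognition sequence must be non-empty")
    if set(recog) - set("ACGT"):
        raise ValueError(f"recognition sequence {recognition_seq!r} contains non-DNA characters")
    if revcomp(recog) != recog:
        raise ValueError(
            f"recognition sequence {recog} is not palindromic; only palindromic "
            "enzymes are supported (forward-strand scanning would miss sites)"
        )
    if not sequences or all(len(s) == 0 for s in sequences.values()):
        raise ValueError("empty genome")

    sites: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for chrom, seq in sequences.items():
        up = seq.upper()
        positions = []
        p = up.find(recog)
        while p != -1:
            positions.append(p)
            p = up.find(recog, p + 1)  # +1, not +len: overlaps are reported
        sites[chrom] = np.asarray(positions, dtype=np.int64)
        lengths[chrom] = len(seq)
    return SiteMap(enzyme_name or recog, recog, sites, lengths)


@dataclass(frozen=True)
class FragEnd:
    """One fragment-end entry: the expected read sequence at a site boundary."""

    chrom: str
    site: int  # site position (0-based, first base of recognition seq)
    side: str  # DOWNSTREAM or UPSTREAM
    site_index: int  # index into SiteMap.sites[chrom]
    seq: str


@dataclass
class FragmentEndIndex:
    """Fragment-end sequences for every restriction site, keyed for lookup.

    The downstream entry at site ``p`` is ``genome[p : p+read_length]``; the
    upstream entry is ``revcomp(genome[p+L-read_length : p+L])`` with ``L``
    the recognition length, so both read as sequenced strands and both begin
    with the (palindromic) recognition sequence. Entries are truncated, not
    padded, at chromosome ends.
    """

    read_length: int
    site_map: SiteMap
    ends: list[FragEnd] = field(default_factory=list)

    def __iter__(self) -> Iterator[FragEnd]:
        return iter(self.ends)

    def __len__(self) -> int:
        return len(self.ends)

    def prefix_lookup(self, min_prefix: int) -> dict[str, list[FragEnd]]:
        """Bucket entries by their first ``min_prefix`` bases."""
        table: dict[str, list[FragEnd]] = {}
        for end in self.ends:
            table.setdefault(end.seq[:min_prefix], []).append(end)
        return table

    def end_sequence(self, chrom: str, site: int, side: str) -> str:
        for end in self.ends:
            if end.chrom == chrom and end.site == site and end.side == side:
                return end.seq
        raise KeyError((chrom, site, side))


def build_fragend_index(
    site_map: SiteMap, genome: Mapping[str, str], read_length: int
) -> FragmentEndIndex:
    """Extract both fragment-end sequences for every site in ``site_map``."""
    L = site_map.site_length
    if read_length < L:
        raise ValueError(f"read_length {read_length} is shorter than the recognition sequence ({L})")
    ends: list[FragEnd] = []
    for chrom, positions in site_map.sites.items():
        seq = genome[chrom].upper()
        for idx, p in enumerate(positions):
            p = int(p)
            down = seq[p : p + read_length]
            up = revcomp(seq[max(0, p + L - read_length) : p + L])
            ends.append(FragEnd(chrom, p, DOWNSTREAM, idx, down))
            ends.append(FragEnd(chrom, p, UPSTREAM, idx, up))
    return FragmentEndIndex(read_length=read_length, site_map=site_map, ends=ends)
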