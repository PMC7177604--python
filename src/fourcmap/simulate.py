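"""Synthetic genomes, transgenic events, 4C reads, and paired-end fragments
with exact ground truth.

The generator emulates the data-generating process of a 4C experiment on a
transgenic plant well enough to exercise every pipeline stage:

* i.i.d. random chromosomes at a configurable GC content (0.36 by default,
  the Arabidopsis genome-wide value);
* structural events — transgene (T-DNA) insertion, inversion, reciprocal
  translocation — applied to the reference to produce the *sample* genome,
  with every induced junction recorded;
* single-end 4C reads drawn from restriction-fragment ends of the SAMPLE
  genome around a viewpoint, with cis contact probability decaying as a
  power law of linear distance, max(d, d0)^(-alpha), plus a uniform trans
  background. Reads carry the barcode+primer prefix and are later analyzed
  against the REFERENCE — that asymmetry is what turns a transgene
  viewpoint into a peak at the insertion point and a rearrangement into a
  one-sided signal drop, mirroring the real experimental design;
* uniformly sampled paired-end fragments (accessibility-library-like)
  whose mates are lifted back to reference/plasmid coordinates, flagging
  fragments that span a junction.

Every output is a pure function of (parameters, seed). No sequencing
errors are introduced by default: the built-in mapper is exact-prefix, and
error modeling is a robustness knob, not a correctness requirement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import pysam
import yaml

from .digest import DOWNSTREAM, UPSTREAM, digest, revcomp
from .io import FastqRead

DEFAULT_GC = 0.36
DEFAULT_READ_LENGTH = 75
DEFAULT_ALPHA = 1.0
DEFAULT_MIN_DISTANCE = 1_000
DEFAULT_TRANS_FRACTION = 0.05


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_dna(length: int, gc: float, rng: int | np.random.Generator) -> str:
    """i.i.d. DNA at the given GC fraction (A/T and G/C split evenly)."""
    if not (0 <= gc <= 1):
        raise ValueError("gc must be in [0, 1]")
    rng = _as_rng(rng)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return rng.choice(alphabet, size=length, p=probs).tobytes().decode()


def simulate_genome(
    chromosomes: Sequence[tuple[str, int]],
    gc: float = DEFAULT_GC,
    seed: int | np.random.Generator = 0,
) -> dict[str, str]:
    """Random multi-chromosome reference; deterministic given the seed."""
    rng = _as_rng(seed)
    return {name: random_dna(length, gc, rng) for name, length in chromosomes}


# ---------------------------------------------------------------------------
# structural events


@dataclass(frozen=True)
class Insertion:
    """Splice a foreign (plasmid/T-DNA) sequence into a chromosome."""

    chrom: str
    pos: int
    seq: str
    name: str = "tdna"


@dataclass(frozen=True)
class Inversion:
    """Reverse-complement the reference interval [start, end)."""

    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class Translocation:
    """Reciprocally exchange the terminal segments beyond two breakpoints."""

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int


Event = Union[Insertion, Inversion, Translocation]


@dataclass(frozen=True)
class SampleBlock:
    """One source interval placed on a sample chromosome."""

    sample_start: int
    sample_end: int
    contig: str
    start: int
    end: int
    strand: str  # "+" or "-"


@dataclass(frozen=True)
class Junction:
    """A breakpoint in the sample genome, with reference context."""

    sample_chrom: str
    sample_pos: int
    left_contig: str
    left_ref: int  # reference coordinate of the base immediately left
    left_strand: str
    right_contig: str
    right_ref: int  # reference coordinate of the base immediately right
    right_strand: str


@dataclass(frozen=True)
class MateMap:
    """Reference placement of one mate (majority block)."""

    contig: str
    pos: int
    is_reverse: bool


@dataclass
class SampleGenome:
    """The edited genome: sequences, block structure, junction truth."""

    seqs: dict[str, str]
    blocks: dict[str, list[SampleBlock]]
    junctions: list[Junction]
    events: list[Event] = field(default_factory=list)
    extra_seqs: dict[str, str] = field(default_factory=dict)

    def chrom_length(self, chrom: str) -> int:
        return len(self.seqs[chrom])

    def to_ref(self, chrom: str, pos: int) -> tuple[str, int, str]:
        """Map one sample coordinate to (contig, reference position, strand)."""
        for blk in self.blocks[chrom]:
            if blk.sample_start <= pos < blk.sample_end:
                off = pos - blk.sample_start
                if blk.strand == "+":
                    return blk.contig, blk.start + off, "+"
                return blk.contig, blk.end - 1 - off, "-"
        raise ValueError(f"position {chrom}:{pos} outside the sample genome")

    def map_interval(self, chrom: str, a: int, b: int) -> tuple[MateMap | None, bool]:
        """Majority-block placement of sample interval [a, b).

        Returns (placement of the clipped majority part, crosses_junction).
        Mirrors what a local aligner does with a junction-spanning read:
        the larger portion aligns, the rest is clipped.
        """
        overlaps = []
        for blk in self.blocks[chrom]:
            lo, hi = max(a, blk.sample_start), min(b, blk.sample_end)
            if lo < hi:
                overlaps.append((hi - lo, lo, hi, blk))
        if not overlaps:
            return None, False
        crosses = len(overlaps) > 1
        _, lo, hi, blk = max(overlaps, key=lambda t: t[0])
        if blk.strand == "+":
            ref_pos = blk.start + (lo - blk.sample_start)
            is_rev = False
        else:
            ref_pos = blk.end - (hi - blk.sample_start)
            is_rev = True
        return MateMap(blk.contig, ref_pos, is_rev), crosses

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(j) for j in self.junctions])


def _locate_block(
    lists: dict[str, list[list]], ref_chrom: str, pos: int
) -> tuple[str, int]:
    """Find (sample chrom, block index) whose forward block contains ``pos``,
    splitting the block so a boundary falls exactly at ``pos``."""
    for sample_chrom, blocks in lists.items():
        for i, blk in enumerate(blocks):
            contig, start, end, strand = blk
            if contig != ref_chrom or strand != "+":
                continue
            if pos == start:
                return sample_chrom, i
            if start < pos < end:
                blocks[i : i + 1] = [[contig, start, pos, "+"], [contig, pos, end, "+"]]
                return sample_chrom, i + 1
            if pos == end and i == len(blocks) - 1:
                return sample_chrom, i + 1
    raise ValueError(
        f"event position {ref_chrom}:{pos} does not fall in a pristine region; "
        "events must not overlap"
    )


def apply_events(
    reference: Mapping[str, str], events: Iterable[Event]
) -> SampleGenome:
    """Edit the reference by an ordered list of non-overlapping events.

    Insertions splice the foreign sequence at their position; inversions
    reverse-complement their interval; translocations exchange terminal
    segments between two chromosomes. Every induced junction is recorded
    with reference context on both sides.
    """
    lists: dict[str, list[list]] = {
        chrom: [[chrom, 0, len(seq), "+"]] for chrom, seq in reference.items()
    }
    extra: dict[str, str] = {}
    events = list(events)
    for ev in events:
        if isinstance(ev, Insertion):
            if not (0 <= ev.pos <= len(reference[ev.chrom])):
                raise ValueError(f"insertion position out of bounds: {ev.chrom}:{ev.pos}")
            if ev.name in extra and extra[ev.name] != ev.seq:
                raise ValueError(f"conflicting sequences for inserted contig {ev.name!r}")
            extra[ev.name] = ev.seq
            sc, i = _locate_block(lists, ev.chrom, ev.pos)
            lists[sc].insert(i, [ev.name, 0, len(ev.seq), "+"])
        elif isinstance(ev, Inversion):
            if not (0 <= ev.start < ev.end <= len(reference[ev.chrom])):
                raise ValueError(f"inversion interval out of bounds: {ev}")
            sc1, i = _locate_block(lists, ev.chrom, ev.start)
            sc2, j = _locate_block(lists, ev.chrom, ev.end)
            if sc1 != sc2 or j < i:
                raise ValueError("inversion interval spans rearranged regions")
            middle = lists[sc1][i:j]
            if any(b[3] != "+" or b[0] != ev.chrom for b in middle):
                raise ValueError("inversion overlaps a previous event")
            lists[sc1][i:j] = [[b[0], b[1], b[2], "-"] for b in reversed(middle)]
        elif isinstance(ev, Translocation):
            sca, i = _locate_block(lists, ev.chrom_a, ev.pos_a)
            scb, j = _locate_block(lists, ev.chrom_b, ev.pos_b)
            if sca == scb:
                raise ValueError("translocation breakpoints resolve to the same chromosome")
            tail_a, tail_b = lists[sca][i:], lists[scb][j:]
            lists[sca][i:], lists[scb][j:] = tail_b, tail_a
        else:
            raise TypeError(f"unknown event type {type(ev).__name__}")

    seqs: dict[str, str] = {}
    blocks: dict[str, list[SampleBlock]] = {}
    junctions: list[Junction] = []
    sources = dict(reference) | extra
    for chrom, blist in lists.items():
        parts: list[str] = []
        sample_blocks: list[SampleBlock] = []
        offset = 0
        for contig, start, end, strand in blist:
            piece = sources[contig][start:end]
            if strand == "-":
                piece = revcomp(piece)
            sample_blocks.append(
                SampleBlock(offset, offset + len(piece), contig, start, end, strand)
            )
            parts.append(piece)
            offset += len(piece)
        seqs[chrom] = "".join(parts)
        blocks[chrom] = sample_blocks
        for left, right in zip(sample_blocks, sample_blocks[1:]):
            junctions.append(
                Junction(
                    sample_chrom=chrom,
                    sample_pos=right.sample_start,
                    left_contig=left.contig,
                    left_ref=left.end - 1 if left.strand == "+" else left.start,
                    left_strand=left.strand,
                    right_contig=right.contig,
                    right_ref=right.start if right.strand == "+" else right.end - 1,
                    right_strand=right.strand,
                )
            )
    return SampleGenome(
        seqs=seqs, blocks=blocks, junctions=junctions, events=events, extra_seqs=extra
    )


# ---------------------------------------------------------------------------
# 4C read simulation


def simulate_4c_reads(
    sample_genome: Mapping[str, str],
    viewpoint_chrom: str,
    viewpoint_pos: int,
    barcode: str,
    primer: str,
    n_reads: int,
    read_length: int = DEFAULT_READ_LENGTH,
    alpha: float = DEFAULT_ALPHA,
    min_distance: int = DEFAULT_MIN_DISTANCE,
    trans_fraction: float = DEFAULT_TRANS_FRACTION,
    recognition_seq: str = "GTAC",
    seed: int | np.random.Generator = 0,
) -> tuple[list[FastqRead], pd.DataFrame]:
    """Draw 4C reads from restriction-fragment ends of the sample genome.

    Each read picks, with probability ``trans_fraction``, a uniformly
    random fragment end genome-wide; otherwise a fragment end on the
    viewpoint chromosome with probability proportional to
    ``max(d, min_distance) ** -alpha`` where d is the linear distance from
    the viewpoint to the fragment-end boundary. The read sequence is
    ``barcode + primer + fragment-end sequence`` truncated to
    ``read_length`` (fragment ends are taken from the sample genome, so
    reads from edited regions carry the edited sequence).

    Returns the reads plus a per-read truth table (sample chromosome, site,
    side, end boundary, distance to viewpoint, trans flag).
    """
    if not (0 <= trans_fraction <= 1):
        raise ValueError("trans_fraction must be in [0, 1]")
    rng = _as_rng(seed)
    prefix = (barcode + primer).upper()
    frag_len = read_length - len(prefix)
    if frag_len < 12:
        raise ValueError("read_length leaves fewer than 12 bp after barcode+primer")

    site_map = digest(sample_genome, recognition_seq)
    L = site_map.site_length
    if site_map.n_sites(viewpoint_chrom) < 2:
        raise ValueError(f"viewpoint chromosome {viewpoint_chrom} has < 2 restriction sites")

    chroms = site_map.chroms()
    chrom_arr, site_arr, side_arr, boundary_arr = [], [], [], []
    for ci, chrom in enumerate(chroms):
        pos = site_map.sites[chrom]
        m = len(pos)
        chrom_arr.append(np.full(2 * m, ci))
        site_arr.append(np.repeat(pos, 2))
        side_arr.append(np.tile([0, 1], m))  # 0 = downstream, 1 = upstream
        boundary_arr.append(np.repeat(pos, 2) + np.tile([0, L], m))
    chrom_idx = np.concatenate(chrom_arr)
    sites = np.concatenate(site_arr)
    sides = np.concatenate(side_arr)
    boundaries = np.concatenate(boundary_arr)
    n_ends = len(sites)

    vp_ci = chroms.index(viewpoint_chrom)
    cis_idx = np.flatnonzero(chrom_idx == vp_ci)
    d_cis = np.abs(boundaries[cis_idx] - viewpoint_pos).astype(float)
    weights = np.maximum(d_cis, min_distance) ** (-alpha)
    weights /= weights.sum()

    is_trans = rng.random(n_reads) < trans_fraction
    picks = np.empty(n_reads, dtype=np.int64)
    n_cis = int((~is_trans).sum())
    picks[~is_trans] = rng.choice(cis_idx, size=n_cis, p=weights)
    picks[is_trans] = rng.integers(0, n_ends, size=n_reads - n_cis)

    cache: dict[int, str] = {}

    def end_seq(e: int) -> str:
        seq = cache.get(e)
        if seq is None:
            chrom = chroms[chrom_idx[e]]
            p = int(sites[e])
            genome_seq = sample_genome[chrom]
            if sides[e] == 0:
                seq = genome_seq[p : p + frag_len]
            else:
                seq = revcomp(genome_seq[max(0, p + L - frag_len) : p + L])
            cache[e] = seq
        return seq

    reads: list[FastqRead] = []
    for i, e in enumerate(picks):
        seq = prefix + end_seq(int(e))
        reads.append((f"read{i}", seq, "I" * len(seq)))

    same_chrom = chrom_idx[picks] == vp_ci
    distance = np.where(
        same_chrom, np.abs(boundaries[picks] - viewpoint_pos), -1
    ).astype(np.int64)
    truth = pd.DataFrame(
        {
            "read": [r[0] for r in reads],
            "chrom": [chroms[c] for c in chrom_idx[picks]],
            "site": sites[picks],
            "side": np.where(sides[picks] == 0, DOWNSTREAM, UPSTREAM),
            "boundary": boundaries[picks],
            "distance": distance,
            "is_trans": is_trans,
        }
    )
    return reads, truth


def perfect_4c_sam(
    trimmed_reads: Sequence[FastqRead],
    truth: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    path,
    site_length: int = 4,
) -> None:
    """Write the alignments an ideal aligner would report for 4C reads.

    Assumes the reads were simulated on an unedited genome (truth
    coordinates are then valid reference coordinates): downstream-side
    reads align forward starting at the site; upstream-side reads align
    reverse ending at the site boundary.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": int(n)} for c, n in chrom_lengths.items()],
    }
    by_name = {row.read: row for row in truth.itertuples()}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for name, seq, _ in trimmed_reads:
            row = by_name[name]
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = name
            rec.query_sequence = seq
            rec.mapping_quality = 60
            rec.cigartuples = [(0, len(seq))]
            rec.reference_id = out.header.references.index(row.chrom)
            if row.side == DOWNSTREAM:
                rec.flag = 0
                rec.reference_start = int(row.site)
            else:
                rec.flag = 16
                rec.reference_start = int(row.site) + site_length - len(seq)
            out.write(rec)


# ---------------------------------------------------------------------------
# paired-end fragment simulation


@dataclass(frozen=True)
class PairTruth:
    name: str
    chrom: str  # sample chromosome
    frag_start: int
    frag_end: int
    mate1: MateMap | None
    mate2: MateMap | None
    crosses_junction: bool


def simulate_paired_reads(
    sample: SampleGenome,
    n_pairs: int,
    read_length: int = DEFAULT_READ_LENGTH,
    fragment_mean: float = 400.0,
    fragment_sd: float = 50.0,
    seed: int | np.random.Generator = 0,
) -> tuple[list[tuple[str, str, str, str, str]], list[PairTruth]]:
    """Uniformly sample paired-end fragments across the sample genome.

    Mates are the two fragment ends (the inner mate reverse-complemented,
    standard FR orientation). The truth lifts each mate back to
    reference/plasmid coordinates through the sample's block structure and
    flags fragments spanning a junction.

    Returns ([(name, seq1, qual1, seq2, qual2), ...], [PairTruth, ...]).
    """
    if fragment_mean <= 2 * read_length:
        raise ValueError("fragment_mean must exceed twice the read length")
    rng = _as_rng(seed)
    chroms = list(sample.seqs)
    lengths = np.array([len(sample.seqs[c]) for c in chroms], dtype=float)
    chrom_probs = lengths / lengths.sum()
    chrom_picks = rng.choice(len(chroms), size=n_pairs, p=chrom_probs)
    frag_lens = np.clip(
        rng.normal(fragment_mean, fragment_sd, size=n_pairs),
        2 * read_length,
        None,
    ).astype(np.int64)
    starts = (
        rng.random(n_pairs) * np.maximum(lengths[chrom_picks] - frag_lens, 1)
    ).astype(np.int64)

    pairs = []
    truths = []
    for i in range(n_pairs):
        chrom = chroms[chrom_picks[i]]
        a = int(starts[i])
        b = min(a + int(frag_lens[i]), len(sample.seqs[chrom]))
        frag = sample.seqs[chrom][a:b]
        seq1 = frag[:read_length]
        seq2 = revcomp(frag[-read_length:])
        name = f"pair{i}"
        map1, c1 = sample.map_interval(chrom, a, a + read_length)
        map2, c2 = sample.map_interval(chrom, b - read_length, b)
        if map2 is not None:
            map2 = MateMap(map2.contig, map2.pos, not map2.is_reverse)
        pairs.append((name, seq1, "I" * len(seq1), seq2, "I" * len(seq2)))
        truths.append(
            PairTruth(
                name=name,
                chrom=chrom,
                frag_start=a,
                frag_end=b,
                mate1=map1,
                mate2=map2,
                crosses_junction=c1 or c2 or (b - a > 0 and _spans(sample, chrom, a, b)),
            )
        )
    return pairs, truths


def _spans(sample: SampleGenome, chrom: str, a: int, b: int) -> bool:
    return any(a < j.sample_pos < b for j in sample.junctions if j.sample_chrom == chrom)


def perfect_paired_sam(
    truths: Sequence[PairTruth],
    contig_lengths: Mapping[str, int],
    path,
    read_length: int = DEFAULT_READ_LENGTH,
    with_sequences: bool = False,
    pairs: Sequence[tuple[str, str, str, str, str]] | None = None,
) -> None:
    """Write ideal paired alignments for simulated fragments.

    Pairs whose mates both have a reference placement get two primary
    records with full mate information; placements come from the
    generator's truth, so the SAM reflects what a perfect aligner against
    reference+plasmid would report (junction-spanning mates are placed at
    their majority block, as a soft-clipping aligner would).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": int(n)} for c, n in contig_lengths.items()],
    }
    seqs = {}
    if with_sequences and pairs is not None:
        seqs = {p[0]: (p[1], p[3]) for p in pairs}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        refs = out.header.references
        for t in truths:
            if t.mate1 is None or t.mate2 is None:
                continue
            for which, mate, other in ((1, t.mate1, t.mate2), (2, t.mate2, t.mate1)):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = t.name
                rec.mapping_quality = 60
                flag = 0x1  # paired
                flag |= 0x40 if which == 1 else 0x80
                if mate.is_reverse:
                    flag |= 0x10
                if other.is_reverse:
                    flag |= 0x20
                rec.flag = flag
                rec.reference_id = refs.index(mate.contig)
                rec.reference_start = mate.pos
                rec.next_reference_id = refs.index(other.contig)
                rec.next_reference_start = other.pos
                if with_sequences and t.name in seqs:
                    rec.query_sequence = seqs[t.name][which - 1]
                    rec.cigartuples = [(0, len(rec.query_sequence))]
                else:
                    rec.cigartuples = [(0, read_length)]
                out.write(rec)


# ---------------------------------------------------------------------------
# YAML-configurable simulation (CLI entry)


@dataclass
class SimConfig:
    """Declarative simulation scenario (YAML-loadable)."""

    seed: int = 0
    chromosomes: list[tuple[str, int]] = field(default_factory=lambda: [("chr1", 1_000_000)])
    gc: float = DEFAULT_GC
    events: list[Event] = field(default_factory=list)
    viewpoint: dict = field(default_factory=dict)  # chrom/pos on the sample, or tdna midpoint
    n_reads: int = 50_000
    read_length: int = DEFAULT_READ_LENGTH
    decay_exponent: float = DEFAULT_ALPHA
    min_distance: int = DEFAULT_MIN_DISTANCE
    trans_fraction: float = DEFAULT_TRANS_FRACTION
    barcode: str = "ACGT"
    primer: str = "GAGTCCTGAGTACGAT"
    n_pairs: int = 0
    fragment_mean: float = 400.0
    fragment_sd: float = 50.0
    tdna_length: int = 8_000
    tdna_gc: float = 0.45

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        events = []
        for e in raw.pop("events", []):
            kind = e.pop("kind")
            if kind == "insertion":
                events.append(Insertion(**e))
            elif kind == "inversion":
                events.append(Inversion(**e))
            elif kind == "translocation":
                events.append(Translocation(**e))
            else:
                raise ValueError(f"unknown event kind {kind!r}")
        chroms = [(c["name"], int(c["length"])) for c in raw.pop("chromosomes", [])]
        cfg = cls(**raw)
        if chroms:
            cfg.chromosomes = chroms
        cfg.events = events
        return cfg
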