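"""Preset simulation scenarios and end-to-end analysis runners.

These are the study conditions the package's validation battery runs
under; tests and the reproduction script share them so every number is
recomputed the same way.

* ``insertion_scenario`` — the standard localization benchmark: a 10 Mb
  three-chromosome genome, one 8 kb transgene insertion, a viewpoint at
  the transgene midpoint, 50,000 viewpoint reads with power-law contact
  decay (alpha = 1) and 5% trans background. The question it answers: how
  far is the called peak center from the true insertion point (DPC)?

* ``inversion_scenario`` / ``translocation_scenario`` — rearrangement
  signatures. These use 10,000 / 12 Mb-scale conditions so that the
  contact signal decays to background well within a segment length, the
  regime in which one-sided signal drops are observable (in the reference
  organism, chromosomes are ~20-30 Mb and rearranged segments hundreds of
  kb, so real data sits in this regime too; see the methods note).

* ``paired_scenario`` — split-mate insertion detection from a uniform
  paired-end library at ~20x fragment coverage.

Every scenario is a pure function of its seed.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demux import Viewpoint, demultiplex
from .digest import build_fragend_index, digest
from .mapping import CoverageTrack, map_fragends, unique_coverage
from .peaks import BreakpointCall, Peak, call_peaks, detect_discontinuity, dpc
from .pscore import PScoreTrack, pscore_track
from .rearrange import (
    ContinuityResult,
    InsertionCall,
    SegmentEnd,
    build_fusion,
    junction_continuity,
    liftover_track,
    scan_split_mates,
)
from .simulate import (
    Insertion,
    Inversion,
    SampleGenome,
    Translocation,
    apply_events,
    perfect_paired_sam,
    random_dna,
    simulate_4c_reads,
    simulate_genome,
    simulate_paired_reads,
)

BARCODE = "ACGT"
PRIMER = "GAGTCCTGAGTACGAT"  # 16 nt reading primer adjacent to the first cutter
RECOGNITION = "GTAC"

# Peak-calling threshold for the rearrangement scenarios. Their viewpoint
# chromosomes carry a substantial covered-site background (the power-law
# contact tail), where score-5 windows occur by fluctuation far from any
# breakpoint; the rearrangement-associated peaks score > 80 in these
# conditions, so a threshold of 25 separates them from tail noise by more
# than 2.5x in both directions while changing nothing about the statistic.
# Runs are merged within one scoring window (50 kb): the windowed score
# smears a coverage cliff over half a window, so supra-threshold spillover
# within a window of a run is part of the same blurred feature.
REARRANGEMENT_MIN_SCORE = 25.0
REARRANGEMENT_MERGE_GAP = 50_000


def _seeds(seed: int, n: int) -> list[int]:
    """Derive n independent child seeds below 2**31 from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


@dataclass
class ViewpointAnalysis:
    """Everything the core pipeline produces for one simulated viewpoint."""

    reference: dict[str, str]
    sample: SampleGenome
    coverage: CoverageTrack
    pscores: PScoreTrack
    peaks: list[Peak]
    viewpoint_ref_chrom: str | None
    viewpoint_ref_pos: int | None
    reads_mapped: int = 0
    dpc_by_cutoff: dict[float, int] = field(default_factory=dict)

    @property
    def top_peak(self) -> Peak | None:
        return self.peaks[0] if self.peaks else None


def analyze_viewpoint_reads(
    reference: dict[str, str],
    reads,
    viewpoint: Viewpoint,
    read_length: int = 75,
    min_prefix: int = 15,
    window_size: int = 50_000,
    min_score: float = 5.0,
    merge_gap: int = 20_000,
) -> tuple[CoverageTrack, PScoreTrack, list[Peak], int]:
    """Demultiplex, map, score, and call peaks against the reference."""
    site_map = digest(reference, RECOGNITION, "Csp6I")
    index = build_fragend_index(site_map, reference, read_length)
    demux_result = demultiplex(reads, [viewpoint])
    raw = map_fragends(demux_result.reads[viewpoint.name], index, min_prefix=min_prefix)
    coverage = unique_coverage(raw)
    pscores = pscore_track(coverage, window_size=window_size)
    peaks = call_peaks(pscores, min_score=min_score, merge_gap=merge_gap)
    return coverage, pscores, peaks, raw.stats["assigned"]


# ---------------------------------------------------------------------------
# standard transgene-insertion localization scenario

INSERTION_CHROMS = [("chr1", 4_000_000), ("chr2", 3_500_000), ("chr3", 2_500_000)]
INSERTION_CHROM = "chr2"
INSERTION_POS = 1_750_000
TDNA_LENGTH = 8_000


def insertion_scenario(
    seed: int,
    n_reads: int = 50_000,
    trans_fraction: float = 0.05,
    alpha: float = 1.0,
    reads_only: bool = False,
):
    """One 8 kb transgene insertion on a 10 Mb genome, transgene-midpoint
    viewpoint, analyzed against the unedited reference."""
    s_genome, s_tdna, s_reads = _seeds(seed, 3)
    reference = simulate_genome(INSERTION_CHROMS, seed=s_genome)
    tdna = random_dna(TDNA_LENGTH, gc=0.45, rng=np.random.default_rng(s_tdna))
    sample = apply_events(reference, [Insertion(INSERTION_CHROM, INSERTION_POS, tdna)])
    vp_sample_pos = INSERTION_POS + TDNA_LENGTH // 2  # transgene midpoint
    reads, truth = simulate_4c_reads(
        sample.seqs,
        INSERTION_CHROM,
        vp_sample_pos,
        BARCODE,
        PRIMER,
        n_reads=n_reads,
        alpha=alpha,
        trans_fraction=trans_fraction,
        seed=s_reads,
    )
    if reads_only:
        return reference, sample, reads, truth

    viewpoint = Viewpoint("tdna_vp", BARCODE, PRIMER, source="transgene")
    coverage, pscores, peaks, n_mapped = analyze_viewpoint_reads(reference, reads, viewpoint)
    result = ViewpointAnalysis(
        reference=reference,
        sample=sample,
        coverage=coverage,
        pscores=pscores,
        peaks=peaks,
        viewpoint_ref_chrom=INSERTION_CHROM,
        viewpoint_ref_pos=INSERTION_POS,
        reads_mapped=n_mapped,
    )
    if peaks and peaks[0].chrom == INSERTION_CHROM:
        for c in (0.5, 0.8, 0.9):
            result.dpc_by_cutoff[c] = dpc(peaks[0], c, INSERTION_POS).dpc
    return result


def insertion_battery(seeds: list[int]) -> pd.DataFrame:
    """Run the standard scenario across seeds; one row of metrics per seed."""
    rows = []
    for seed in seeds:
        r = insertion_scenario(seed)
        top = r.top_peak
        rows.append(
            {
                "seed": seed,
                "n_peaks": len(r.peaks),
                "top_chrom": top.chrom if top else None,
                "on_true_chrom": bool(top and top.chrom == INSERTION_CHROM),
                "dpc50": r.dpc_by_cutoff.get(0.5, np.nan),
                "dpc80": r.dpc_by_cutoff.get(0.8, np.nan),
                "dpc90": r.dpc_by_cutoff.get(0.9, np.nan),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# inversion scenario

INVERSION_CHROMS = [("chr1", 8_000_000), ("chr2", 2_000_000)]
INVERSION_START = 4_000_000
INVERSION_END = 5_500_000
INVERSION_VP_OFFSET = 20_000  # viewpoint 20 kb inside the sample-left segment end


@dataclass
class InversionOutcome:
    peaks: list[Peak]
    calls_by_peak: list[list[BreakpointCall]]
    true_ends: tuple[int, int]

    def recovered(self, tol: int = 25_000) -> bool:
        """Exactly two peaks, each carrying a drop call at one true end."""
        if len(self.peaks) != 2:
            return False
        hit_ends = set()
        for calls in self.calls_by_peak:
            if len(calls) != 1:
                return False
            for end in self.true_ends:
                if abs(calls[0].position - end) <= tol:
                    hit_ends.add(end)
        return hit_ends == set(self.true_ends)


def inversion_scenario(seed: int, n_reads: int = 10_000) -> InversionOutcome:
    """A 1.5 Mb inversion with a genomic viewpoint just inside one end.

    Reads decay around the viewpoint on the *sample* chromosome; mapped to
    the reference they form two peaks — one at each inversion breakpoint —
    each falling off a cliff where sample-adjacent sequence becomes
    reference-distant.
    """
    s_genome, s_reads = _seeds(seed, 2)
    reference = simulate_genome(INVERSION_CHROMS, seed=s_genome)
    sample = apply_events(
        reference, [Inversion("chr1", INVERSION_START, INVERSION_END)]
    )
    vp_sample_pos = INVERSION_START + INVERSION_VP_OFFSET
    reads, _ = simulate_4c_reads(
        sample.seqs, "chr1", vp_sample_pos, BARCODE, PRIMER,
        n_reads=n_reads, seed=s_reads,
    )
    viewpoint = Viewpoint("inv_vp", BARCODE, PRIMER)
    coverage, pscores, peaks, _ = analyze_viewpoint_reads(
        reference, reads, viewpoint,
        min_score=REARRANGEMENT_MIN_SCORE, merge_gap=REARRANGEMENT_MERGE_GAP,
    )
    calls = [detect_discontinuity(p, coverage, pscores) for p in peaks]
    return InversionOutcome(
        peaks=peaks,
        calls_by_peak=calls,
        true_ends=(INVERSION_START, INVERSION_END),
    )


def rearrangement_free_scenario(seed: int, n_reads: int = 10_000) -> list[BreakpointCall]:
    """Genomic viewpoint on an unedited genome: the discontinuity detector's
    false-positive control, run at the same depth/genome conditions as the
    rearrangement scenarios. Returns all discontinuity calls (expected none:
    the contact profile is symmetric)."""
    s_genome, s_reads = _seeds(seed, 2)
    reference = simulate_genome(INVERSION_CHROMS, seed=s_genome)
    vp_pos = INVERSION_START + INVERSION_VP_OFFSET
    reads, _ = simulate_4c_reads(
        reference, "chr1", vp_pos, BARCODE, PRIMER, n_reads=n_reads, seed=s_reads
    )
    viewpoint = Viewpoint("ctrl_vp", BARCODE, PRIMER, chrom="chr1", position=vp_pos)
    coverage, pscores, peaks, _ = analyze_viewpoint_reads(
        reference, reads, viewpoint,
        min_score=REARRANGEMENT_MIN_SCORE, merge_gap=REARRANGEMENT_MERGE_GAP,
    )
    calls: list[BreakpointCall] = []
    for p in peaks:
        calls.extend(detect_discontinuity(p, coverage, pscores))
    return calls


# ---------------------------------------------------------------------------
# reciprocal-translocation scenario

TRANSLOC_CHROMS = [("chr1", 6_000_000), ("chr2", 6_000_000)]
TRANSLOC_BP1 = 3_500_000  # chr1 breakpoint
TRANSLOC_BP2 = 2_000_000  # chr2 breakpoint
TRANSLOC_VP_OFFSET = 60_000  # genomic viewpoint 60 kb left of the chr1 breakpoint


@dataclass
class TranslocationOutcome:
    peaks: list[Peak]
    coverage: CoverageTrack
    pscores: PScoreTrack
    reference: dict[str, str]
    true_continuity: ContinuityResult
    offset_continuity: ContinuityResult
    calls: list[BreakpointCall]


def translocation_scenario(
    seed: int, n_reads: int = 10_000, offset: int = 200_000
) -> TranslocationOutcome:
    """Reciprocal terminal exchange between two chromosomes.

    The viewpoint sits 60 kb upstream of the chr1 breakpoint on the fused
    sample chromosome, so its 4C signal runs off chr1 at the breakpoint
    and reappears as a cis-like block on chr2. The true fusion model
    restores a continuous profile across the junction; a fusion offset by
    ``offset`` bp does not.
    """
    s_genome, s_reads = _seeds(seed, 2)
    reference = simulate_genome(TRANSLOC_CHROMS, seed=s_genome)
    sample = apply_events(
        reference,
        [Translocation("chr1", TRANSLOC_BP1, "chr2", TRANSLOC_BP2)],
    )
    vp_pos = TRANSLOC_BP1 - TRANSLOC_VP_OFFSET  # identical in sample and reference
    reads, _ = simulate_4c_reads(
        sample.seqs, "chr1", vp_pos, BARCODE, PRIMER, n_reads=n_reads, seed=s_reads
    )
    viewpoint = Viewpoint("tr_vp", BARCODE, PRIMER, chrom="chr1", position=vp_pos)
    coverage, pscores, peaks, _ = analyze_viewpoint_reads(
        reference, reads, viewpoint,
        min_score=REARRANGEMENT_MIN_SCORE, merge_gap=REARRANGEMENT_MERGE_GAP,
    )

    def continuity(bp1: int, bp2: int) -> ContinuityResult:
        fusion, _ = build_fusion(
            reference,
            SegmentEnd("chr1", bp1, "left"),
            SegmentEnd("chr2", bp2, "right"),
        )
        hybrid_cov = liftover_track(coverage, fusion)
        return junction_continuity(hybrid_cov, fusion.junction)

    calls = []
    for p in peaks[:2]:
        calls.extend(detect_discontinuity(p, coverage, pscores))
    return TranslocationOutcome(
        peaks=peaks,
        coverage=coverage,
        pscores=pscores,
        reference=reference,
        true_continuity=continuity(TRANSLOC_BP1, TRANSLOC_BP2),
        offset_continuity=continuity(TRANSLOC_BP1 - offset, TRANSLOC_BP2 - offset),
        calls=calls,
    )


# ---------------------------------------------------------------------------
# paired-end split-mate scenario

PAIRED_CHROM_LEN = 1_000_000
PAIRED_INSERTION_POS = 500_000
PLASMID_NAME = "plasmid"
PLASMID_LENGTH = 8_000


def paired_scenario(
    seed: int,
    with_insertion: bool = True,
    chrom_len: int = PAIRED_CHROM_LEN,
    insertion_pos: int | None = None,
    coverage: float = 20.0,
    fragment_mean: float = 400.0,
    tmp_dir: str | None = None,
) -> tuple[list[InsertionCall], SampleGenome]:
    """Uniform paired-end library over a genome with (or without) one
    plasmid insertion; split mates are scanned from the ideal alignments."""
    s_genome, s_plasmid, s_pairs = _seeds(seed, 3)
    reference = simulate_genome([("chr1", chrom_len)], seed=s_genome)
    plasmid = random_dna(PLASMID_LENGTH, gc=0.45, rng=np.random.default_rng(s_plasmid))
    events = []
    if with_insertion:
        pos = PAIRED_INSERTION_POS if insertion_pos is None else insertion_pos
        events.append(Insertion("chr1", pos, plasmid, name=PLASMID_NAME))
    sample = apply_events(reference, events)
    n_pairs = int(coverage * sum(len(s) for s in sample.seqs.values()) / fragment_mean)
    _, truths = simulate_paired_reads(
        sample, n_pairs=n_pairs, fragment_mean=fragment_mean, seed=s_pairs
    )
    contig_lengths = {c: len(s) for c, s in reference.items()}
    contig_lengths[PLASMID_NAME] = PLASMID_LENGTH
    with tempfile.TemporaryDirectory(dir=tmp_dir) as td:
        sam_path = os.path.join(td, "pairs.sam")
        perfect_paired_sam(truths, contig_lengths, sam_path)
        calls = scan_split_mates(sam_path, PLASMID_NAME)
    return calls, sample
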