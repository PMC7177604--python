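"""Peak calling on the enrichment track, peak-base geometry, and
one-sided discontinuity (rearrangement-signature) detection.

A peak is a maximal run of sites scoring above threshold (nearby runs are
merged); its summit is the top-scoring site. For a cutoff c in (0, 1], the
peak *base* is the contiguous run of sites scoring at least c times the
summit score around the summit, and its midpoint is the peak *center*. The
distance from peak center to the (known or true) viewpoint position — the
DPC — is the localization-error metric of the whole method; the base at
50% of peak height centers closest to the viewpoint because local
asymmetry of the signal is worst near the top of the peak.

A peak flanked on exactly one side by background-level coverage marks a
point where the linear DNA template is interrupted (inversion or
translocation junction). ``detect_discontinuity`` formalizes the visual
"sharp transition from dense to sparse" read pattern as a flank contrast:
a side is called when its covered-site fraction falls to (or below) the
chromosome background while the opposite flank stays above it, and a
Fisher exact test on the two flanks' covered/uncovered counts is
significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .mapping import CoverageTrack
from .pscore import PScoreTrack

DEFAULT_MIN_SCORE = 5.0
DEFAULT_MERGE_GAP = 20_000
DEFAULT_CUTOFFS = (0.5, 0.8, 0.9)
DEFAULT_FLANK = 50_000
DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class PeakBase:
    """Base interval of a peak at one cutoff: outermost qualifying sites."""

    left: int
    right: int

    @property
    def center(self) -> int:
        return (self.left + self.right) // 2

    def contains(self, pos: int) -> bool:
        return self.left <= pos <= self.right

    def __contains__(self, other: "PeakBase") -> bool:
        return self.left <= other.left and other.right <= self.right


@dataclass
class Peak:
    chrom: str
    summit_pos: int
    summit_score: float
    summit_index: int  # index of the summit site in the site/score arrays
    start_index: int  # first supra-threshold site of the region
    end_index: int  # last supra-threshold site of the region (inclusive)
    bases: dict[float, PeakBase] = field(default_factory=dict)
    rank: int = 0

    def base(self, cutoff: float) -> PeakBase:
        return self.bases[cutoff]


@dataclass(frozen=True)
class DPCResult:
    """Distance from a peak-base center to the viewpoint position."""

    viewpoint: str
    chrom: str
    cutoff: float
    center: int
    viewpoint_pos: int
    dpc: int


@dataclass(frozen=True)
class BreakpointCall:
    """A one-sided density drop at a peak-base boundary."""

    chrom: str
    position: int  # the 50%-cutoff base boundary on the drop side
    drop_side: str  # "left" or "right"
    drop_fraction: float  # covered-site fraction in the drop-side flank
    opp_fraction: float  # covered-site fraction in the opposite flank
    p_value: float  # Fisher exact two-sided p of the flank contrast
    edge: bool = False  # flank truncated by a chromosome end
    method: str = "flank_fisher"


def peak_base(
    ptrack: PScoreTrack, chrom: str, summit_index: int, cutoff: float
) -> PeakBase:
    """Walk outward from the summit while p_score >= cutoff * summit score."""
    if not (0 < cutoff <= 1):
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    scores = ptrack.p_score[chrom]
    pos = ptrack.site_map.sites[chrom]
    threshold = cutoff * scores[summit_index]
    lo = summit_index
    while lo - 1 >= 0 and scores[lo - 1] >= threshold:
        lo -= 1
    hi = summit_index
    while hi + 1 < len(scores) and scores[hi + 1] >= threshold:
        hi += 1
    return PeakBase(left=int(pos[lo]), right=int(pos[hi]))


def _tied_summit_run(scores: np.ndarray, lo: int, hi: int) -> tuple[int, int, float]:
    """First contiguous run of top-scoring sites in scores[lo:hi+1].

    Returns (first_index, last_index, top_score); ties beyond the first
    contiguous run are ignored (symmetric and deterministic within a run).
    """
    window = scores[lo : hi + 1]
    top = float(window.max())
    tied = np.flatnonzero(window == top) + lo
    run_end = 0
    while run_end + 1 < len(tied) and tied[run_end + 1] == tied[run_end] + 1:
        run_end += 1
    return int(tied[0]), int(tied[run_end]), top


def call_peaks(
    ptrack: PScoreTrack,
    min_score: float = DEFAULT_MIN_SCORE,
    merge_gap: int = DEFAULT_MERGE_GAP,
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
) -> list[Peak]:
    """Find supra-threshold regions genome-wide and rank them by summit.

    Candidate regions are maximal runs of sites with p_score >= min_score;
    runs whose gap is smaller than ``merge_gap`` are merged (the merge gap
    sits below the statistic's window so genuinely separate insertions a
    window-width apart are never fused). Each region yields one peak whose
    summit is its top-scoring site; summit ties resolve to the midpoint of
    the tied run, rounded down. Peaks are ranked genome-wide by summit
    score, descending.
    """
    if min_score <= 0:
        raise ValueError("min_score must be > 0")
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    peaks: list[Peak] = []
    for chrom in ptrack.chroms():
        scores = ptrack.p_score[chrom]
        pos = ptrack.site_map.sites[chrom]
        above = scores >= min_score
        if not above.any():
            continue
        # maximal runs of supra-threshold sites
        runs: list[list[int]] = []
        for i in np.flatnonzero(above):
            i = int(i)
            if runs and i == runs[-1][1] + 1:
                runs[-1][1] = i
            else:
                runs.append([i, i])
        # merge runs separated by less than merge_gap (genomic distance)
        merged: list[list[int]] = []
        for run in runs:
            if merged and pos[run[0]] - pos[merged[-1][1]] < merge_gap:
                merged[-1][1] = run[1]
            else:
                merged.append(run)
        for lo, hi in merged:
            first, last, top = _tied_summit_run(scores, lo, hi)
            summit_pos = (int(pos[first]) + int(pos[last])) // 2
            summit_index = (first + last) // 2
            peak = Peak(
                chrom=chrom,
                summit_pos=summit_pos,
                summit_score=top,
                summit_index=summit_index,
                start_index=lo,
                end_index=hi,
            )
            for c in cutoffs:
                peak.bases[c] = peak_base(ptrack, chrom, summit_index, c)
            peaks.append(peak)
    peaks.sort(key=lambda p: (-p.summit_score, p.chrom, p.summit_pos))
    for rank, p in enumerate(peaks, start=1):
        p.rank = rank
    return peaks


def dpc(
    peak: Peak,
    cutoff: float,
    viewpoint_pos: int,
    viewpoint_chrom: str | None = None,
    viewpoint_name: str = "",
) -> DPCResult:
    """Distance from the peak-base center at ``cutoff`` to the viewpoint."""
    if viewpoint_chrom is not None and viewpoint_chrom != peak.chrom:
        raise ValueError(
            f"viewpoint on {viewpoint_chrom} but peak on {peak.chrom}; "
            "DPC is defined within one chromosome"
        )
    center = peak.base(cutoff).center
    return DPCResult(
        viewpoint=viewpoint_name,
        chrom=peak.chrom,
        cutoff=cutoff,
        center=center,
        viewpoint_pos=viewpoint_pos,
        dpc=abs(center - viewpoint_pos),
    )


def _flank_stats(
    positions: np.ndarray, indicators: np.ndarray, lo: float, hi: float
) -> tuple[int, int]:
    """(covered, total) sites with position in [lo, hi)."""
    i = np.searchsorted(positions, lo, side="left")
    j = np.searchsorted(positions, hi, side="left")
    sub = indicators[i:j]
    return int(sub.sum()), int(len(sub))


def detect_discontinuity(
    peak: Peak,
    coverage: CoverageTrack,
    pscores: PScoreTrack,
    flank: int = DEFAULT_FLANK,
    alpha: float = DEFAULT_ALPHA,
    skip: int | None = None,
) -> list[BreakpointCall]:
    """Test both flanks of the 50%-cutoff peak base for a one-sided drop.

    A side is called when its covered-site fraction is at or below the
    chromosome background p0, the opposite side's fraction exceeds p0, and
    the two flanks' covered/uncovered counts differ by a two-sided Fisher
    exact test at ``alpha``. The call position is the base boundary on the
    dropped side. Flanks truncated by a chromosome end are still evaluated
    but flagged ``edge=True``.

    Because the windowed score blurs a coverage cliff over half a window,
    the 50%-base boundary falls short of the cliff and the adjacent
    half-window mixes dense and sparse signal; the flanks therefore start
    ``skip`` bp beyond the base boundary (default: half the scoring
    window). Pass ``skip=0`` to measure flush against the boundary.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    if coverage.indicators is None:
        raise ValueError("indicators not populated; run unique_coverage first")
    if skip is None:
        skip = pscores.window_size // 2
    chrom = peak.chrom
    base = peak.bases.get(0.5) or peak_base(pscores, chrom, peak.summit_index, 0.5)
    positions = coverage.site_map.sites[chrom]
    indicators = coverage.indicators[chrom]
    chrom_len = coverage.site_map.chrom_lengths[chrom]
    p0 = pscores.p0[chrom]

    k_left, n_left = _flank_stats(
        positions, indicators, base.left - skip - flank, base.left - skip
    )
    k_right, n_right = _flank_stats(
        positions, indicators, base.right + 1 + skip, base.right + 1 + skip + flank
    )
    f_left = k_left / n_left if n_left else 0.0
    f_right = k_right / n_right if n_right else 0.0
    if n_left == 0 and n_right == 0:
        return []
    _, p_value = fisher_exact(
        [[k_left, n_left - k_left], [k_right, n_right - k_right]],
        alternative="two-sided",
    )
    edge = (base.left - skip - flank < 0) or (base.right + 1 + skip + flank > chrom_len)

    calls: list[BreakpointCall] = []
    for side, f_side, f_opp, boundary in (
        ("left", f_left, f_right, base.left),
        ("right", f_right, f_left, base.right),
    ):
        if f_side <= p0 < f_opp and p_value < alpha:
            calls.append(
                BreakpointCall(
                    chrom=chrom,
                    position=boundary,
                    drop_side=side,
                    drop_fraction=f_side,
                    opp_fraction=f_opp,
                    p_value=float(p_value),
                    edge=edge,
                )
            )
    return calls


def peaks_table(
    peaks: list[Peak],
    viewpoint_name: str = "",
    viewpoint_chrom: str | None = None,
    viewpoint_pos: int | None = None,
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
) -> pd.DataFrame:
    """Tabulate called peaks (one row per peak) with per-cutoff bases/DPC."""
    rows = []
    for p in peaks:
        row = {
            "viewpoint": viewpoint_name,
            "rank": p.rank,
            "chrom": p.chrom,
            "summit_pos": p.summit_pos,
            "summit_score": p.summit_score,
        }
        for c in cutoffs:
            base = p.bases[c]
            tag = f"{int(round(c * 100))}"
            row[f"base{tag}_left"] = base.left
            row[f"base{tag}_right"] = base.right
            row[f"center{tag}"] = base.center
            if viewpoint_pos is not None and viewpoint_chrom == p.chrom:
                row[f"dpc{tag}"] = abs(base.center - viewpoint_pos)
        rows.append(row)
    return pd.DataFrame(rows)
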