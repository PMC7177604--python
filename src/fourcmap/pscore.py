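"""The windowed binomial enrichment statistic (p-score).

For every restriction site, consider the window of all sites within a
50 kb span centered on it (inclusive at both edges, truncated — never
re-centered — at chromosome ends). With n sites in the window, k of them
covered, and p0 the chromosome-wide covered-site fraction, the one-tailed
upper binomial tail P(X >= k), X ~ Binomial(n, p0), measures local
enrichment of covered sites over the chromosome background. The track
stores p_score = -log10(p-value), capped for numerical safety.

The statistic consumes only the binary coverage indicator, so it inherits
immunity to PCR duplication, and it is a signal, not a formal test: no
multiple-testing correction is applied here — thresholds belong to peak
calling downstream.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from . import io as fio
from .mapping import CoverageTrack
from .digest import SiteMap

DEFAULT_WINDOW = 50_000
DEFAULT_CAP = 300.0
_P_FLOOR = 1e-300  # p-value underflow floor matching the default cap


def chromosome_background(track: CoverageTrack) -> dict[str, float]:
    """Fraction of covered sites per chromosome (the background rate p0).

    Chromosomes without any restriction site are excluded with a warning.
    """
    if track.indicators is None:
        raise ValueError("indicators not populated; run unique_coverage first")
    p0: dict[str, float] = {}
    for chrom, ind in track.indicators.items():
        if len(ind) == 0:
            warnings.warn(f"chromosome {chrom} has no restriction sites; excluded")
            continue
        p0[chrom] = float(ind.mean())
    return p0


@dataclass
class PScoreTrack:
    """Per-site enrichment scores on the restriction-site grid."""

    site_map: SiteMap
    window_size: int
    cap: float
    p0: dict[str, float]
    k: dict[str, np.ndarray] = field(default_factory=dict)
    n: dict[str, np.ndarray] = field(default_factory=dict)
    p_value: dict[str, np.ndarray] = field(default_factory=dict)
    p_score: dict[str, np.ndarray] = field(default_factory=dict)

    def chroms(self) -> list[str]:
        return list(self.p_score)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chroms():
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": self.site_map.sites[chrom],
                        "k": self.k[chrom],
                        "n": self.n[chrom],
                        "p0": self.p0[chrom],
                        "p_value": self.p_value[chrom],
                        "p_score": self.p_score[chrom],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_bedgraph(self, path: str | os.PathLike) -> None:
        L = self.site_map.site_length
        fio.write_bedgraph(
            path,
            (
                (chrom, int(p), int(p) + L, float(s))
                for chrom in self.chroms()
                for p, s in zip(self.site_map.sites[chrom], self.p_score[chrom])
            ),
        )


def pscore_track(
    track: CoverageTrack,
    window_size: int = DEFAULT_WINDOW,
    cap: float = DEFAULT_CAP,
) -> PScoreTrack:
    """Compute the windowed binomial enrichment score at every site.

    Window membership is by genomic position — all sites within
    ``window_size/2`` bp of the focal site, the focal site included — not
    by a fixed site count, so n varies with local site density and shrinks
    at chromosome ends.
    """
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    if track.indicators is None:
        raise ValueError("indicators not populated; run unique_coverage first")

    p0 = chromosome_background(track)
    out = PScoreTrack(site_map=track.site_map, window_size=window_size, cap=cap, p0=p0)
    half = window_size / 2.0
    for chrom, rate in p0.items():
        pos = track.site_map.sites[chrom]
        ind = track.indicators[chrom].astype(np.int64)
        left = np.searchsorted(pos, pos - half, side="left")
        right = np.searchsorted(pos, pos + half, side="right")
        n = right - left
        csum = np.concatenate([[0], np.cumsum(ind)])
        k = csum[right] - csum[left]
        # upper tail P(X >= k) = sf(k-1); sf handles k=0 (=> 1) and p0 in {0,1}
        p_value = binom.sf(k - 1, n, rate)
        p_value = np.clip(p_value, _P_FLOOR, 1.0)
        p_value[k == 0] = 1.0
        score = np.minimum(-np.log10(p_value), cap)
        score[k == 0] = 0.0
        out.k[chrom] = k.astype(np.int64)
        out.n[chrom] = n.astype(np.int64)
        out.p_value[chrom] = p_value
        out.p_score[chrom] = score
    return out
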