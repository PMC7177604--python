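"""Shared fixtures: small deterministic inputs and the session-scoped
standard simulation battery (expensive, computed once, summarized to
scalars so memory stays flat)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fourcmap.peaks import dpc
from fourcmap.scenarios import INSERTION_CHROM, insertion_scenario

BATTERY_SEEDS = list(range(1, 21))


@pytest.fixture(scope="session")
def insertion_battery_summary() -> pd.DataFrame:
    """Standard transgene-localization scenario over 20 seeds.

    One row per seed with the top-peak metrics plus a per-seed check of
    the cutoff-nesting invariant across *all* called peaks.
    """
    rows = []
    for seed in BATTERY_SEEDS:
        r = insertion_scenario(seed)
        nested = True
        for p in r.peaks:
            b50, b80, b90 = p.bases[0.5], p.bases[0.8], p.bases[0.9]
            nested &= (b90 in b80) and (b80 in b50)
            nested &= b50.contains(p.summit_pos) and b50.contains(b50.center)
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
                "nested": nested,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
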