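"""Peak calling, peak-base geometry, DPC, and discontinuity detection."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from fourcmap.peaks import (
    call_peaks,
    detect_discontinuity,
    dpc,
    peak_base,
)
from fourcmap.scenarios import rearrangement_free_scenario
from tests.test_pscore import make_track
from fourcmap.pscore import pscore_track, PScoreTrack
from fourcmap.digest import SiteMap


def make_pscore(positions, scores, chrom="c", chrom_len=10_000_000, window=50_000):
    """Hand-built score track (bypasses the binomial machinery)."""
    sm = SiteMap(
        "Csp6I", "GTAC",
        {chrom: np.asarray(positions, dtype=np.int64)},
        {chrom: chrom_len},
    )
    scores = np.asarray(scores, dtype=float)
    return PScoreTrack(
        site_map=sm, window_size=window, cap=300.0, p0={chrom: 0.05},
        k={chrom: (scores > 0).astype(np.int64)},
        n={chrom: np.ones_like(scores, dtype=np.int64)},
        p_value={chrom: 10.0 ** (-scores)},
        p_score={chrom: scores},
    )


class TestPeakBase:
    TRACK = make_pscore(np.arange(7) * 100, [1, 2, 5, 10, 5, 4, 1])

    def test_hand_built_half_height_base(self):
        base = peak_base(self.TRACK, "c", 3, 0.5)
        assert (base.left, base.right) == (200, 400)  # the sites scoring 5,10,5
        assert base.center == 300

    def test_cutoff_one_is_summit_alone(self):
        base = peak_base(self.TRACK, "c", 3, 1.0)
        assert (base.left, base.right) == (300, 300)

    def test_symmetric_track_centers_on_summit(self):
        track = make_pscore(np.arange(9) * 50, [1, 2, 4, 8, 16, 8, 4, 2, 1])
        for cutoff in (0.5, 0.8, 0.9, 1.0):
            assert peak_base(track, "c", 4, cutoff).center == 200

    def test_cutoff_out_of_range_rejected(self):
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                peak_base(self.TRACK, "c", 3, bad)


class TestCallPeaks:
    def test_single_supra_threshold_run_is_one_peak(self):
        track = make_pscore(np.arange(10) * 500, [0, 0, 6, 9, 7, 0, 0, 0, 0, 0])
        peaks = call_peaks(track, min_score=5.0)
        assert len(peaks) == 1
        assert peaks[0].summit_pos == 1500
        assert peaks[0].summit_score == 9

    def test_merge_gap_rule(self):
        # two runs 5 kb apart merge at 20 kb; 50 kb apart stay separate
        pos = [0, 1000, 3500, 6000, 7000]
        track = make_pscore(pos, [8, 8, 1, 9, 9])
        assert len(call_peaks(track, min_score=5.0, merge_gap=20_000)) == 1
        pos = [0, 1000, 25_000, 51_000, 52_000]
        track = make_pscore(pos, [8, 8, 1, 9, 9])
        assert len(call_peaks(track, min_score=5.0, merge_gap=20_000)) == 2

    def test_ranking_is_by_summit_score(self):
        track = make_pscore([0, 100_000, 200_000], [6, 0, 12])
        peaks = call_peaks(track, min_score=5.0, merge_gap=10_000)
        assert [p.rank for p in peaks] == [1, 2]
        assert peaks[0].summit_score == 12

    def test_summit_tie_resolves_to_run_midpoint(self):
        track = make_pscore(np.arange(5) * 100, [1, 7, 7, 7, 1])
        peaks = call_peaks(track, min_score=5.0)
        assert peaks[0].summit_pos == (100 + 300) // 2

    def test_cutoff_nesting_on_called_peaks(self):
        track = make_pscore(
            np.arange(11) * 200, [0, 1, 3, 6, 9, 10, 9, 6, 3, 1, 0]
        )
        (peak,) = call_peaks(track, min_score=5.0)
        assert peak.bases[0.9] in peak.bases[0.8]
        assert peak.bases[0.8] in peak.bases[0.5]
        assert peak.bases[0.5].contains(peak.summit_pos)


class TestDPC:
    def test_zero_when_center_equals_viewpoint(self):
        track = make_pscore(np.arange(9) * 50, [1, 2, 4, 8, 16, 8, 4, 2, 1])
        (peak,) = call_peaks(track, min_score=3.0)
        assert dpc(peak, 0.5, 200).dpc == 0

    def test_printed_distance_arithmetic(self):
        track = make_pscore([9_000, 10_000, 11_000], [2, 8, 2])
        (peak,) = call_peaks(track, min_score=5.0)
        assert peak.bases[0.5].center == 10_000
        assert dpc(peak, 0.5, 12_407).dpc == 2_407

    def test_chromosome_mismatch_rejected(self):
        track = make_pscore([0, 100], [1, 8])
        (peak,) = call_peaks(track, min_score=5.0)
        with pytest.raises(ValueError, match="chromosome"):
            dpc(peak, 0.5, 100, viewpoint_chrom="other")


def fisher_two_sided_oracle(k1, n1, k2, n2):
    """Exact two-sided Fisher p by hypergeometric enumeration."""
    total_pos, total = k1 + k2, n1 + n2
    rv = hypergeom(total, total_pos, n1)
    p_obs = rv.pmf(k1)
    return sum(rv.pmf(x) for x in range(total_pos + 1) if rv.pmf(x) <= p_obs * (1 + 1e-9))


class TestDiscontinuity:
    @staticmethod
    def _scene(left_covered=40, right_covered=2):
        """A dense site plateau flanked by moderately and sparsely covered
        50-site flanks, on a mostly empty chromosome (low background)."""
        rng = np.random.default_rng(5)
        left_pos = np.arange(50) * 1_000  # 0 .. 49k
        plateau_pos = 50_000 + np.arange(50) * 200  # 50k .. 59.8k: dense grid
        right_pos = 61_000 + np.arange(50) * 1_000  # 61k .. 110k
        tail_pos = 130_000 + np.arange(300) * 1_000  # empty background tail
        pos = np.concatenate([left_pos, plateau_pos, right_pos, tail_pos])
        ind = np.zeros(len(pos), dtype=np.uint8)
        ind[50:100] = 1  # plateau fully covered
        ind[rng.choice(np.arange(0, 50), size=left_covered, replace=False)] = 1
        ind[100 + rng.choice(np.arange(0, 50), size=right_covered, replace=False)] = 1
        track = make_track({"c": pos}, {"c": ind}, chrom_len=450_000)
        ps = pscore_track(track, window_size=10_000)
        peaks = call_peaks(ps, min_score=5.0, merge_gap=3_000)
        return track, ps, peaks

    def test_one_sided_drop_called_with_exact_fisher_p(self):
        track, ps, peaks = self._scene()
        top = peaks[0]
        calls = detect_discontinuity(top, track, ps, flank=50_000, skip=0)
        assert len(calls) == 1
        call = calls[0]
        assert call.drop_side == "right"
        assert call.drop_fraction <= ps.p0["c"] < call.opp_fraction
        assert call.position == top.bases[0.5].right
        # independent recomputation of the flank table and its exact Fisher p
        pos = track.site_map.sites["c"]
        ind = track.indicators["c"]
        base = top.bases[0.5]
        in_left = (pos >= base.left - 50_000) & (pos < base.left)
        in_right = (pos > base.right) & (pos <= base.right + 50_000)
        k_l, n_l = int(ind[in_left].sum()), int(in_left.sum())
        k_r, n_r = int(ind[in_right].sum()), int(in_right.sum())
        assert call.drop_fraction == pytest.approx(k_r / n_r)
        assert call.opp_fraction == pytest.approx(k_l / n_l)
        expected = fisher_two_sided_oracle(k_l, n_l, k_r, n_r)
        assert call.p_value == pytest.approx(expected, rel=1e-6)

    def test_symmetric_flanks_yield_no_calls(self):
        track, ps, peaks = self._scene(left_covered=40, right_covered=40)
        assert detect_discontinuity(peaks[0], track, ps, flank=50_000, skip=0) == []

    def test_fisher_oracle_against_scipy(self):
        from scipy.stats import fisher_exact

        _, p = fisher_exact([[40, 10], [2, 48]], alternative="two-sided")
        assert p == pytest.approx(fisher_two_sided_oracle(40, 50, 2, 50), rel=1e-9)

    def test_invalid_flank_rejected(self):
        track, ps, peaks = self._scene()
        with pytest.raises(ValueError):
            detect_discontinuity(peaks[0], track, ps, flank=0)


def test_no_false_discontinuities_on_rearrangement_free_simulations():
    """The detector stays silent on symmetric (unrearranged) profiles in
    at least 95% of seeded replicates."""
    n_reps = 30
    with_calls = sum(bool(rearrangement_free_scenario(seed)) for seed in range(1, n_reps + 1))
    assert with_calls <= int(np.ceil(0.05 * n_reps))
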