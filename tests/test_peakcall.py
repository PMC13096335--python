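"""Summit detection, replicate consistency, merging and peak emission."""

import numpy as np
import pytest

from cutmap.genome import GenomeIndex
from cutmap.profiles import ConditionProfile, FoldChangeTrack, log2fc
from cutmap.peakcall import (
    Thresholds,
    SummitCandidate,
    local_maxima,
    find_summits,
    replicate_support,
    merge_summits,
    emit_peaks,
    call_peaks,
    call_peaks_from_tracks,
)
from cutmap.readends import EndCountTrack
from cutmap import simulate as sim


def _profile_pair(treated_smoothed, mock_smoothed, pc=0.1):
    t = ConditionProfile(
        "treated", {"chr": np.asarray(treated_smoothed, float)},
        {"chr": np.asarray(treated_smoothed, float)}, 5,
    )
    m = ConditionProfile(
        "mock", {"chr": np.asarray(mock_smoothed, float)},
        {"chr": np.asarray(mock_smoothed, float)}, 5,
    )
    fc = log2fc(t, m, pc)
    return t, m, fc


class TestLocalMaxima:
    def test_matches_brute_force_on_random_profiles(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            x = rng.normal(size=1000)
            # tie-free data: a maximum strictly exceeds its existing neighbors
            expected = [
                i
                for i in range(1000)
                if (i == 0 or x[i] > x[i - 1]) and (i == 999 or x[i] > x[i + 1])
            ]
            assert local_maxima(x) == expected

    def test_plateau_reports_center(self):
        assert local_maxima(np.array([0.0, 2, 2, 2, 0])) == [2]
        assert local_maxima(np.array([0.0, 2, 2, 0])) == [1]  # left-of-center

    def test_constant_array_has_no_maxima(self):
        assert local_maxima(np.full(10, 3.0)) == []

    def test_edge_maximum(self):
        assert local_maxima(np.array([5.0, 1, 0, 1, 2])) == [0, 4]

    def test_floating_point_jitter_on_plateau_is_ignored(self):
        x = np.array([0.0, 4.0, 4.0 * (1 + 1e-13), 4.0, 0.0])
        assert local_maxima(x) == [2]


class TestFindSummits:
    def test_flat_equal_profiles_yield_nothing(self):
        t, m, fc = _profile_pair(np.full(50, 2.0), np.full(50, 2.0))
        assert find_summits(t, m, fc, Thresholds()) == []

    def test_single_enriched_position(self):
        treated = np.zeros(21)
        treated[10] = 2.0
        t, m, fc = _profile_pair(treated, np.zeros(21))
        cands = find_summits(t, m, fc, Thresholds())
        assert [c.position for c in cands] == [10]
        # log2((2.0+0.1)/0.1) = 4.39; ratio 21
        assert np.isclose(cands[0].log2fc, np.log2(21))
        assert np.isclose(cands[0].ratio, 21)

    def test_insufficient_log2fc_excluded(self):
        treated = np.zeros(21)
        treated[10] = 2.0
        mock = np.zeros(21)
        mock[10] = 0.65  # log2(2.1/0.75) ~ 1.49 < 2, ratio 2.8 >= 1.2, signal ok
        t, m, fc = _profile_pair(treated, mock)
        assert fc.values["chr"][10] < 2.0
        assert find_summits(t, m, fc, Thresholds()) == []

    def test_insufficient_signal_excluded(self):
        treated = np.zeros(21)
        treated[10] = 0.9  # below 1.0 CPM
        t, m, fc = _profile_pair(treated, np.zeros(21))
        assert find_summits(t, m, fc, Thresholds()) == []


class TestReplicateSupport:
    def _tracks(self, maxima):
        tracks = []
        for i, v in enumerate(maxima):
            counts = np.zeros(100, dtype=np.int64)
            counts[50] = v
            tracks.append(EndCountTrack(f"t{i}", "treated", {"chr": counts}))
        return tracks

    def _cand(self, pos=50):
        return SummitCandidate("chr", pos, 10.0, 0.0, 5.0, 10.0)

    def test_counts_replicates_reaching_threshold(self):
        th = Thresholds()
        assert replicate_support(self._cand(), self._tracks([6, 4, 0]), th) == 1
        assert replicate_support(self._cand(), self._tracks([5, 5, 0]), th) == 2

    def test_count_at_window_edge_counts(self):
        counts = np.zeros(100, dtype=np.int64)
        counts[51] = 5  # summit + 1 only
        track = EndCountTrack("t0", "treated", {"chr": counts})
        assert replicate_support(self._cand(50), [track], Thresholds()) == 1

    def test_window_clipped_at_contig_edge(self):
        counts = np.zeros(100, dtype=np.int64)
        counts[0] = 7
        track = EndCountTrack("t0", "treated", {"chr": counts})
        assert replicate_support(self._cand(0), [track], Thresholds()) == 1


class TestMergeSummits:
    def _cand(self, pos, signal):
        return SummitCandidate("chr", pos, signal, 0.0, 5.0, 10.0)

    def test_nearby_summits_merge_to_strongest(self):
        merged = merge_summits([self._cand(100, 3.0), self._cand(102, 5.0)], Thresholds())
        assert [c.position for c in merged] == [102]

    def test_gap_beyond_merge_distance_keeps_both(self):
        merged = merge_summits([self._cand(100, 3.0), self._cand(104, 5.0)], Thresholds())
        assert [c.position for c in merged] == [100, 104]

    def test_equal_signal_tie_breaks_leftmost(self):
        merged = merge_summits([self._cand(100, 3.0), self._cand(103, 3.0)], Thresholds())
        assert [c.position for c in merged] == [100]

    def test_transitive_chain_collapses(self):
        chain = [self._cand(p, s) for p, s in [(10, 1.0), (13, 2.0), (16, 9.0), (30, 1.0)]]
        merged = merge_summits(chain, Thresholds())
        assert [c.position for c in merged] == [16, 30]

    def test_merged_gaps_exceed_merge_distance(self):
        rng = np.random.default_rng(3)
        cands = [self._cand(int(p), float(s)) for p, s in
                 zip(np.sort(rng.choice(500, 80, replace=False)), rng.random(80))]
        merged = merge_summits(cands, Thresholds())
        gaps = np.diff([c.position for c in merged])
        assert (gaps > Thresholds().merge_distance).all()


class TestEmitPeaks:
    def test_three_bp_interval_centered_on_summit(self):
        genome = GenomeIndex({"chr": 1000})
        peaks = emit_peaks(
            [SummitCandidate("chr", 100, 5.0, 0.0, 4.0, 10.0, support=3)],
            genome, Thresholds(),
        )
        p = peaks[0]
        assert (p.start, p.end) == (99, 102)
        assert p.midpoint == 100.5

    def test_summit_at_contig_start_clipped(self):
        genome = GenomeIndex({"chr": 1000})
        peaks = emit_peaks(
            [SummitCandidate("chr", 0, 5.0, 0.0, 4.0, 10.0)], genome, Thresholds()
        )
        assert (peaks[0].start, peaks[0].end) == (0, 2)


class TestCallPeaks:
    def test_self_comparison_yields_no_peaks(self, bam_factory):
        reads = [{"contig": "chr", "start": s, "length": 60} for s in range(0, 900, 23)]
        bam = bam_factory({"chr": 1000}, reads)
        genome = GenomeIndex({"chr": 1000})
        peaks = call_peaks([bam], [bam], genome)
        assert len(peaks) == 0

    def test_planted_sites_recovered(self, tmp_path):
        genome = GenomeIndex({"sim": 20000})
        truth = sim.default_site_truth(
            genome_length=20000, n_sites=4, seed=11, min_separation=2000
        )
        res = sim.simulate_site_seq(genome, truth, tmp_path / "sim")
        peaks = call_peaks(res.treated_paths, res.mock_paths, genome)
        planted = [p for _, p, _ in truth.planted_sites]
        assert len(peaks) == 4
        assert all(any(abs(p.summit - s) <= 1 for s in planted) for p in peaks)

    def test_every_emitted_peak_satisfies_thresholds(self, tmp_path):
        th = Thresholds()
        genome = GenomeIndex({"sim": 20000})
        truth = sim.default_site_truth(genome_length=20000, n_sites=4, seed=5,
                                       min_separation=2000)
        res = sim.simulate_site_seq(genome, truth, tmp_path / "sim")
        peaks = call_peaks(res.treated_paths, res.mock_paths, genome, th=th)
        for p in peaks:
            assert p.treated_smoothed >= th.min_signal
            assert p.log2fc >= th.min_log2fc
            assert p.ratio >= th.min_ratio
            assert p.support >= th.min_supporting_replicates

    def test_raising_thresholds_never_adds_peaks(self, tmp_path):
        genome = GenomeIndex({"sim": 20000})
        truth = sim.default_site_truth(genome_length=20000, n_sites=4, seed=9,
                                       min_separation=2000)
        res = sim.simulate_site_seq(genome, truth, tmp_path / "sim")
        from cutmap.readends import extract_r1_ends

        rt = [extract_r1_ends(f, genome) for f in res.treated_paths]
        rm = [extract_r1_ends(f, genome, condition="mock") for f in res.mock_paths]
        base = len(call_peaks_from_tracks(rt, rm, genome, Thresholds()))
        for stricter in [
            Thresholds(min_signal=10.0),
            Thresholds(min_log2fc=5.0),
            Thresholds(min_ratio=10.0),
            Thresholds(min_raw_count=15),
            Thresholds(min_supporting_replicates=3),
        ]:
            assert len(call_peaks_from_tracks(rt, rm, genome, stricter)) <= base

    def test_requires_input_files(self):
        with pytest.raises(ValueError):
            call_peaks([], ["x.bam"], GenomeIndex({"chr": 10}))


def test_thresholds_validation():
    with pytest.raises(ValueError):
        Thresholds(peak_width=4)
    with pytest.raises(ValueError):
        Thresholds(min_signal=-1)
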