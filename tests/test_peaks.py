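"""Peak-operation tests with brute-force oracles for merge, overlap and FRiP,
plus null/spike behavior of the minimal Poisson caller."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bivalos import (
    GenomeModel,
    bin_coverage,
    call_peaks_simple,
    frip,
    merge_within,
    overlap_peaks,
    read_peaks,
    top_n_by_score,
    write_narrowpeak,
)
from bivalos.coverage import CoverageTrack
from bivalos.peaks import PeakSet

from conftest import fragments_frame, peak_frame


def _ps(rows):
    return PeakSet(peaks=peak_frame(rows))


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def brute_merge(intervals, max_gap):
    """Transitive closure of the gap<=max_gap relation via union-find."""
    iv = sorted(intervals)
    parent = list(range(len(iv)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(iv)), 2):
        (c1, s1, e1), (c2, s2, e2) = iv[i], iv[j]
        if c1 == c2 and max(s1, s2) - min(e1, e2) <= max_gap:
            parent[find(i)] = find(j)
    groups = {}
    for i in range(len(iv)):
        groups.setdefault(find(i), []).append(iv[i])
    return sorted(
        (g[0][0], min(s for _, s, _ in g), max(e for _, _, e in g)) for g in groups.values()
    )


def brute_overlap_counts(a, b, min_overlap=1):
    def hits(qs, ts):
        n = 0
        for qc, qs_, qe in qs:
            if any(tc == qc and min(qe, te) - max(qs_, ts_) >= min_overlap for tc, ts_, te in ts):
                n += 1
        return n

    return hits(a, b), hits(b, a)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


class TestReadPeaks:
    def test_narrowpeak_round_trip_sorted(self, tmp_path):
        p = tmp_path / "x.narrowPeak"
        rows = [("chr1", 5000, 5400, "b", 90, ".", 3.2, 4.0, 2.5, 200),
                ("chr1", 100, 400, "a", 50, ".", 2.0, 3.0, 1.5, 150)]
        with open(p, "w") as fh:
            for r in rows:
                fh.write("\t".join(map(str, r)) + "\n")
        ps = read_peaks(p)
        assert len(ps) == 3 - 1
        assert ps.peaks["start"].tolist() == [100, 5000]  # sorted on read

    def test_bed3_scores_default_zero_with_warning(self, tmp_path, caplog):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t100\t200\nchr1\t300\t400\n")
        with caplog.at_level("WARNING"):
            ps = read_peaks(p)
        assert (ps.peaks["score"] == 0.0).all()
        assert any("score" in r.message for r in caplog.records)

    def test_malformed_line_raises_with_line_number(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t100\t200\nchr1\tnotanint\t400\n")
        with pytest.raises(ValueError, match=":2"):
            read_peaks(p)


class TestMergeWithin:
    def test_gap_within_threshold_merges(self):
        m = merge_within(_ps([("chr1", 0, 100), ("chr1", 4000, 4100)]), 5000)
        assert len(m) == 1
        assert m.peaks.loc[0, ["start", "end"]].tolist() == [0, 4100]

    def test_gap_beyond_threshold_kept_apart(self):
        m = merge_within(_ps([("chr1", 0, 100), ("chr1", 6100, 6200)]), 5000)
        assert len(m) == 2

    def test_transitive_chain_collapses(self):
        rows = [("chr1", 0, 100), ("chr1", 4100, 4200), ("chr1", 8200, 8300)]
        m = merge_within(_ps(rows), 5000)
        assert len(m) == 1
        assert m.peaks.loc[0, "end"] == 8300

    def test_merged_score_is_max(self):
        m = merge_within(_ps([("chr1", 0, 100, 5.0), ("chr1", 50, 200, 9.0)]), 0)
        assert m.peaks.loc[0, "score"] == 9.0

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(42)
        rows = [("chr1", int(s), int(s) + int(l), float(sc))
                for s, l, sc in zip(rng.integers(0, 100_000, 60),
                                    rng.integers(50, 3000, 60),
                                    rng.random(60))]
        shuffled = [rows[i] for i in rng.permutation(60)]
        m1 = merge_within(_ps(rows), 1000)
        m2 = merge_within(_ps(shuffled), 1000)
        m3 = merge_within(m1, 1000)
        cols = ["chrom", "start", "end"]
        assert m1.peaks[cols].equals(m2.peaks[cols])
        assert m1.peaks[cols].equals(m3.peaks[cols])

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            rows = [("chr1", int(s), int(s) + int(l))
                    for s, l in zip(rng.integers(0, 50_000, 40), rng.integers(10, 2000, 40))]
            got = merge_within(_ps(rows), 500).peaks
            expected = brute_merge(rows, 500)
            assert list(zip(got["chrom"], got["start"], got["end"])) == expected


class TestTopN:
    def test_selects_highest_scores(self):
        rows = [("chr1", i * 1000, i * 1000 + 100, s) for i, s in enumerate([5, 9, 1, 7, 3])]
        t = top_n_by_score(_ps(rows), 3)
        assert sorted(t.peaks["score"]) == [5, 7, 9]

    def test_n_larger_than_count_is_identity(self):
        rows = [("chr1", 0, 100, 1.0), ("chr1", 500, 600, 2.0)]
        assert len(top_n_by_score(_ps(rows), 100)) == 2

    def test_tie_at_cutoff_prefers_earlier_coordinate(self):
        rows = [("chr1", 5000, 5100, 1.0), ("chr1", 100, 200, 1.0), ("chr1", 9000, 9100, 8.0)]
        t = top_n_by_score(_ps(rows), 2)
        assert t.peaks["start"].tolist() == [100, 9000]


class TestOverlap:
    def test_identical_sets_full_overlap(self):
        a = _ps([("chr1", 0, 100), ("chr1", 500, 700)])
        r = overlap_peaks(a, a)
        assert r["frac_a_overlapping"] == 1.0 and r["frac_b_overlapping"] == 1.0
        assert r["jaccard"] == 1.0

    def test_disjoint_sets(self):
        a = _ps([("chr1", 0, 100)])
        b = _ps([("chr1", 200, 300)])
        r = overlap_peaks(a, b)
        assert r["count_a_overlapping"] == 0 and r["jaccard"] == 0.0

    def test_nested_peak_counts_both_directions(self):
        a = _ps([("chr1", 0, 1000)])
        b = _ps([("chr1", 400, 500)])
        r = overlap_peaks(a, b)
        assert r["count_a_overlapping"] == 1 and r["count_b_overlapping"] == 1
        assert r["jaccard"] == pytest.approx(100 / 1000)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(11)
        for trial in range(5):
            rows_a = [("chr1", int(s), int(s) + int(l))
                      for s, l in zip(rng.integers(0, 30_000, 30), rng.integers(20, 900, 30))]
            rows_b = [("chr1", int(s), int(s) + int(l))
                      for s, l in zip(rng.integers(0, 30_000, 25), rng.integers(20, 900, 25))]
            r = overlap_peaks(_ps(rows_a), _ps(rows_b))
            ea, eb = brute_overlap_counts(rows_a, rows_b)
            assert (r["count_a_overlapping"], r["count_b_overlapping"]) == (ea, eb)


class TestFrip:
    def test_simple_fraction(self):
        frags = fragments_frame(
            [("chr1", i * 10, i * 10 + 5, 60) for i in range(80)]
            + [("chr1", 50_000 + i * 10, 50_000 + i * 10 + 5, 60) for i in range(20)]
        )
        peaks = _ps([("chr1", 0, 1000)])
        assert frip(frags, peaks) == pytest.approx(0.80)

    def test_empty_peaks_give_zero(self):
        frags = fragments_frame([("chr1", 0, 100, 60)])
        assert frip(frags, _ps([])) == 0.0

    def test_empty_fragments_rejected(self):
        with pytest.raises(ValueError, match="no fragments"):
            frip(fragments_frame([]), _ps([("chr1", 0, 100)]))

    def test_uniform_fragments_match_peak_coverage_fraction(self):
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 999_000, size=20_000)
        frags = fragments_frame([("chr1", int(s), int(s) + 1, 60) for s in starts])
        # peaks covering 10% of the 1 Mb genome
        peaks = _ps([("chr1", i * 100_000, i * 100_000 + 10_000) for i in range(10)])
        assert frip(frags, peaks) == pytest.approx(0.10, abs=0.01)

    def test_invariant_under_peak_merging(self):
        rng = np.random.default_rng(5)
        starts = rng.integers(0, 90_000, size=2_000)
        frags = fragments_frame([("chr1", int(s), int(s) + 150, 60) for s in starts])
        rows = [("chr1", int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 80_000, 30), rng.integers(100, 3000, 30))]
        ps = _ps(rows)
        assert frip(frags, ps) == frip(frags, merge_within(ps, 0))

    def test_matches_brute_force_membership(self):
        rng = np.random.default_rng(13)
        frows = [("chr1", int(s), int(s) + int(l))
                 for s, l in zip(rng.integers(0, 20_000, 100), rng.integers(50, 400, 100))]
        prows = [("chr1", int(s), int(s) + int(l))
                 for s, l in zip(rng.integers(0, 20_000, 15), rng.integers(100, 1500, 15))]
        frags = fragments_frame([r + (60,) for r in frows])
        got = frip(frags, _ps(prows))
        expected = sum(
            any(min(fe, pe) - max(fs, ps_) >= 1 for _, ps_, pe in prows)
            for _, fs, fe in frows
        ) / len(frows)
        assert got == pytest.approx(expected)


class TestSimpleCaller:
    def _track(self, counts, bin_size=500):
        v = np.asarray(counts, dtype=float)
        return CoverageTrack(bin_size=bin_size, values={"chr1": v},
                             chrom_sizes={"chr1": len(v) * bin_size},
                             n_fragments=int(v.sum()))

    def test_uniform_poisson_track_rarely_yields_peaks(self):
        rng = np.random.default_rng(17)
        n_with_peaks = 0
        for _ in range(20):
            t = self._track(rng.poisson(5.0, size=2000))
            n_with_peaks += len(call_peaks_simple(t)) > 0
        assert n_with_peaks <= 1  # >= 95% of seeds peak-free

    def test_spiked_promoter_detected_within_one_bin(self):
        rng = np.random.default_rng(19)
        counts = rng.poisson(2.0, size=2000).astype(float)
        counts[1000:1006] += 40.0  # 20x spike over 6 bins
        ps = call_peaks_simple(self._track(counts))
        assert len(ps) == 1
        assert abs(ps.peaks.loc[0, "start"] - 1000 * 500) <= 500
        assert abs(ps.peaks.loc[0, "end"] - 1006 * 500) <= 500

    def test_all_zero_track_rejected(self):
        with pytest.raises(ValueError, match="no signal"):
            call_peaks_simple(self._track(np.zeros(100)))

    def test_runs_shorter_than_min_bins_dropped(self):
        counts = np.ones(2000)
        counts[500] = 500.0  # single-bin spike
        ps = call_peaks_simple(self._track(counts), min_bins=2)
        assert len(ps) == 0


def test_narrowpeak_write_read_round_trip(tmp_path):
    ps = _ps([("chr1", 0, 100, 5.0), ("chr1", 500, 900, 7.5)])
    path = tmp_path / "out.narrowPeak"
    write_narrowpeak(ps, path)
    back = read_peaks(path)
    cols = ["chrom", "start", "end", "score"]
    assert back.peaks[cols].equals(ps.peaks[cols])
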