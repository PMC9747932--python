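"""Coverage binning, CPM, correlation, constant-gene selection and
quantile-anchoring tests, including the scale-recovery and idempotency
properties of the anchoring map."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from bivalos import (
    GenomeModel,
    bin_coverage,
    correlation_matrix,
    cpm_normalize,
    promoter_signal,
    quantile_anchor,
    select_constant_genes,
    simulate_fragments,
)
from bivalos.coverage import ConstantGeneSet, CoverageTrack

from conftest import fragments_frame


def _flat_genome(n_bp=1_000_000):
    return GenomeModel(chrom_sizes={"chr1": n_bp}, genes=[])


class TestBinCoverage:
    def test_single_fragment_counts_in_midpoint_bin(self):
        g = _flat_genome()
        t = bin_coverage(fragments_frame([("chr1", 100, 300, 60)]), g, bin_size=1000)
        assert t.values["chr1"][0] == 1.0
        assert t.values["chr1"][1:].sum() == 0.0

    def test_empty_input_gives_zero_track(self):
        t = bin_coverage(fragments_frame([]), _flat_genome(), 1000)
        assert t.total == 0.0
        assert t.n_fragments == 0

    def test_unknown_chromosome_skipped(self, caplog):
        frags = fragments_frame([("chrUn", 0, 200, 60), ("chr1", 0, 200, 60)])
        with caplog.at_level("WARNING"):
            t = bin_coverage(frags, _flat_genome(), 1000)
        assert t.total == 1.0
        assert t.n_fragments == 2  # CPM denominator still counts all input

    def test_totals_conserved_and_poisson_spread(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 999_800, size=10_000)
        frags = fragments_frame([("chr1", int(s), int(s) + 200, 60) for s in starts])
        t = bin_coverage(frags, _flat_genome(), 1000)
        v = t.values["chr1"]
        assert v.sum() == 10_000
        # uniform 10/bin: all counts inside generous Poisson bounds
        assert v.mean() == pytest.approx(10.0, rel=0.01)
        assert v.max() < 30 and (v > 0).mean() > 0.99


class TestCPM:
    def test_cpm_value(self):
        g = _flat_genome(10_000)
        frags = fragments_frame([("chr1", 0, 200, 60), ("chr1", 0, 210, 60)])
        t = cpm_normalize(bin_coverage(frags, g, 1000))
        assert t.values["chr1"][0] == pytest.approx(2.0 * 1e6 / 2)

    def test_cpm_sum_rule(self, small_genome, small_truth):
        frags, _ = simulate_fragments(small_truth, small_genome, "H3K4me3", "A2a",
                                      depth=5_000, seed=1)
        raw = bin_coverage(frags, small_genome, 1000)
        cpm = cpm_normalize(raw)
        assigned = raw.total
        assert cpm.total == pytest.approx(1e6 * assigned / raw.n_fragments)

    def test_cpm_requires_raw_state(self):
        g = _flat_genome(10_000)
        t = cpm_normalize(bin_coverage(fragments_frame([("chr1", 0, 200, 60)]), g, 1000))
        with pytest.raises(ValueError, match="raw"):
            cpm_normalize(t)

    def test_zero_total_rejected(self):
        t = bin_coverage(fragments_frame([]), _flat_genome(), 1000)
        with pytest.raises(ZeroDivisionError):
            cpm_normalize(t)

    def test_depth_invariance_of_cpm_distribution(self, small_genome, small_truth):
        """Doubling depth leaves the CPM distribution essentially unchanged."""
        kw = dict(duplicate_rate=0.0, low_mapq_fraction=0.0)
        f1, _ = simulate_fragments(small_truth, small_genome, "H3K4me3", "A2a",
                                   depth=20_000, seed=2, **kw)
        f2, _ = simulate_fragments(small_truth, small_genome, "H3K4me3", "A2a",
                                   depth=40_000, seed=3, **kw)
        t1 = cpm_normalize(bin_coverage(f1, small_genome, 1000))
        t2 = cpm_normalize(bin_coverage(f2, small_genome, 1000))
        q1 = np.quantile(t1.values["chr1"], [0.5, 0.9, 0.99])
        q2 = np.quantile(t2.values["chr1"], [0.5, 0.9, 0.99])
        assert np.allclose(q1, q2, rtol=0.25, atol=t1.total / 1e4)


class TestCorrelation:
    def _track(self, vals):
        v = np.asarray(vals, dtype=float)
        return CoverageTrack(bin_size=1000, values={"chr1": v},
                             chrom_sizes={"chr1": len(v) * 1000}, n_fragments=1)

    def test_self_correlation_is_one(self):
        t = self._track([1, 2, 3, 4, 5])
        r = correlation_matrix([t, t], skip_zeros=False)
        assert r.iloc[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_tracks(self):
        a = np.array([1.0, 2, 3, 4, 5])
        r = correlation_matrix([self._track(a), self._track(a.max() - a)], skip_zeros=False)
        assert r.iloc[0, 1] == pytest.approx(-1.0)

    def test_requires_two_tracks(self):
        with pytest.raises(ValueError, match="at least 2"):
            correlation_matrix([self._track([1, 2])])

    def test_skip_zeros_drops_all_zero_bins(self):
        a = self._track([0, 1, 2, 0, 3])
        b = self._track([0, 2, 4, 0, 6])
        r_all = correlation_matrix([a, b], skip_zeros=False)
        r_skip = correlation_matrix([a, b], skip_zeros=True)
        assert r_skip.iloc[0, 1] == pytest.approx(1.0)
        assert r_all.iloc[0, 1] == pytest.approx(1.0)  # proportional anyway
        # a bin zero in only one track is kept
        c = self._track([0, 1, 2, 5, 3])
        r = correlation_matrix([a, c], skip_zeros=True)
        assert r.iloc[0, 1] < 1.0


class TestConstantGenes:
    def _expr(self, pairs):
        idx = [f"g{i}" for i in range(len(pairs))]
        a = pd.Series([p[0] for p in pairs], index=idx, dtype=float)
        b = pd.Series([p[1] for p in pairs], index=idx, dtype=float)
        return a, b

    def test_selection_rules(self):
        a, b = self._expr([(8, 8), (8, 20), (0.5, 0.5), (2, 2.2)])
        cs = select_constant_genes(a, b)
        assert set(cs.gene_ids) == {"g0", "g3"}  # (8,20): |lfc|~1.32; (0.5,0.5): below min

    def test_empty_result_is_actionable_error(self):
        a, b = self._expr([(8, 80), (0.1, 0.1)])
        with pytest.raises(ValueError, match="loosen|lower"):
            select_constant_genes(a, b)


def _promoter_spike_tracks(genome, scale=2.0, seed=0):
    """Two CPM-state tracks where B = scale x A, with smooth random signal."""
    rng = np.random.default_rng(seed)
    n = genome.chrom_sizes["chr1"] // 1000
    base = rng.gamma(2.0, 2.0, size=n) + 0.5
    a = CoverageTrack(1000, {"chr1": base}, dict(genome.chrom_sizes), state="CPM",
                      sample=("m", "A"), n_fragments=1)
    b = CoverageTrack(1000, {"chr1": base * scale}, dict(genome.chrom_sizes), state="CPM",
                      sample=("m", "B"), n_fragments=1)
    return a, b


class TestQuantileAnchor:
    def test_identical_tracks_unchanged(self, small_genome):
        a, _ = _promoter_spike_tracks(small_genome)
        const = ConstantGeneSet(small_genome.gene_ids[:30], 0.25, 1.0)
        out = quantile_anchor([a, a], small_genome, const)
        assert np.allclose(out[0].values["chr1"], a.values["chr1"], atol=1e-9)
        assert out[0].state == "quantile-anchored"

    def test_scaled_track_anchored_onto_common_quantiles(self, small_genome):
        a, b = _promoter_spike_tracks(small_genome, scale=2.0)
        const = ConstantGeneSet(small_genome.gene_ids[:30], 0.25, 1.0)
        oa, ob = quantile_anchor([a, b], small_genome, const)
        sig_a = promoter_signal(oa, small_genome, const.gene_ids)
        sig_b = promoter_signal(ob, small_genome, const.gene_ids)
        assert np.allclose(np.sort(sig_a), np.sort(sig_b), rtol=1e-6)

    def test_anchoring_preserves_ranks(self, small_genome):
        a, b = _promoter_spike_tracks(small_genome, scale=1.7, seed=3)
        const = ConstantGeneSet(small_genome.gene_ids[:40], 0.25, 1.0)
        _, ob = quantile_anchor([a, b], small_genome, const)
        orig = b.values["chr1"]
        mapped = ob.values["chr1"]
        order = np.argsort(orig, kind="stable")
        assert (np.diff(mapped[order]) >= -1e-12).all()

    def test_anchoring_idempotent(self, small_genome):
        a, b = _promoter_spike_tracks(small_genome, scale=1.5, seed=5)
        const = ConstantGeneSet(small_genome.gene_ids[:40], 0.25, 1.0)
        once = quantile_anchor([a, b], small_genome, const)
        twice = quantile_anchor(
            [replace(t, state="CPM") for t in once], small_genome, const
        )
        for t1, t2 in zip(once, twice):
            assert np.allclose(t1.values["chr1"], t2.values["chr1"], atol=1e-9)

    def test_requires_cpm_state(self, small_genome):
        a, _ = _promoter_spike_tracks(small_genome)
        raw = replace(a, state="raw")
        const = ConstantGeneSet(small_genome.gene_ids[:30], 0.25, 1.0)
        with pytest.raises(ValueError, match="CPM"):
            quantile_anchor([raw, a], small_genome, const)

    def test_degenerate_signal_names_sample(self, small_genome):
        a, _ = _promoter_spike_tracks(small_genome)
        flat = replace(a, values={"chr1": np.ones_like(a.values["chr1"])},
                       sample=("m", "FLAT"))
        const = ConstantGeneSet(small_genome.gene_ids[:30], 0.25, 1.0)
        with pytest.raises(ValueError, match="FLAT"):
            quantile_anchor([a, flat], small_genome, const)

    def test_too_few_constant_genes_rejected(self, small_genome):
        a, b = _promoter_spike_tracks(small_genome)
        const = ConstantGeneSet(small_genome.gene_ids[:3], 0.25, 1.0)
        with pytest.raises(ValueError, match="constant genes"):
            quantile_anchor([a, b], small_genome, const, min_genes=10)

    def test_global_scale_factor_removed_at_constant_genes(self, small_genome, small_truth):
        """A 1.5x efficiency distortion between samples disappears after
        anchoring (median constant-gene promoter ratio returns to ~1)."""
        kw = dict(duplicate_rate=0.0, low_mapq_fraction=0.0)
        f1, _ = simulate_fragments(small_truth, small_genome, "H3K4me3", "A2a",
                                   depth=40_000, seed=7, efficiency=1.5, **kw)
        f2, _ = simulate_fragments(small_truth, small_genome, "H3K4me3", "D1",
                                   depth=40_000, seed=8, efficiency=1.0, **kw)
        t1 = cpm_normalize(bin_coverage(f1, small_genome, 1000, sample=("K4", "A2a")))
        t2 = cpm_normalize(bin_coverage(f2, small_genome, 1000, sample=("K4", "D1")))
        # constant genes: marked identically in both cell types
        same = small_truth.states.index[
            (small_truth.states["A2a"] == small_truth.states["D1"])
            & small_truth.states["A2a"].isin(["K4only", "bivalent"])
        ]
        const = ConstantGeneSet(list(same[:40]), 0.25, 1.0)
        o1, o2 = quantile_anchor([t1, t2], small_genome, const)
        s1 = promoter_signal(o1, small_genome, const.gene_ids)
        s2 = promoter_signal(o2, small_genome, const.gene_ids)
        ratio = (s1 / s2).median()
        assert 0.9 < ratio < 1.1
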