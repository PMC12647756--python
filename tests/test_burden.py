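import numpy as np
import pytest

import raresv as rv
from raresv.burden import (
    BurdenConfig,
    compare_callsets,
    filter_rare_large,
    fold_enrichment,
    tabulate,
    tile_genome,
    window_counts,
    window_enrichment,
)
from raresv.caller import SVCall, SVCallSet
from raresv.stats import holm_sidak, two_proportion_test


def call(svlen, support=1, sv_type="DEL", chrom="LGI", start=10_000):
    reads = frozenset(f"r{start}_{i}" for i in range(support))
    end = start if sv_type == "INS" else start + svlen
    return SVCall(sv_type, chrom, start, end, svlen, support, reads)


class TestBurdenConfig:
    def test_defaults_mirror_study_design(self):
        cfg = BurdenConfig()
        assert cfg.min_len == 1000
        assert cfg.support_set == {1, 2}
        assert cfg.size_bins == ((1000, 10_000), (10_000, 50_000), (50_000, 100_000))
        assert cfg.window_size == 300_000

    def test_invalid_bins_rejected(self):
        with pytest.raises(ValueError):
            BurdenConfig(size_bins=((1000, 500),))
        with pytest.raises(ValueError):
            BurdenConfig(size_bins=((1000, 10_000), (5000, 20_000)))
        with pytest.raises(ValueError):
            BurdenConfig(min_len=2000)


class TestFilterRareLarge:
    def test_rule_application(self):
        cs = SVCallSet([call(500, 1), call(1500, 1, start=20_000),
                        call(20_000, 3, start=40_000)])
        out = filter_rare_large(cs, BurdenConfig())
        assert [(c.svlen, c.support) for c in out.calls] == [(1500, 1)]
        assert out.provenance["removed_by_length"] == 1
        assert out.provenance["removed_by_support"] == 1

    def test_strictly_greater_than_threshold(self):
        cs = SVCallSet([call(1000), call(1001, start=20_000)])
        out = filter_rare_large(cs, BurdenConfig())
        assert [c.svlen for c in out.calls] == [1001]

    def test_empty_callset(self):
        out = filter_rare_large(SVCallSet([]), BurdenConfig())
        assert len(out) == 0
        assert out.provenance["removed_by_length"] == 0

    def test_bnd_bypasses_length(self):
        bnd = SVCall("BND", "LGI", 100, 100, 0, 1, frozenset({"r"}),
                     mate_chrom="LGII", mate_pos=5)
        out = filter_rare_large(SVCallSet([bnd]), BurdenConfig())
        assert len(out) == 1

    def test_filter_monotone_in_min_len(self):
        rng = np.random.default_rng(0)
        cs = SVCallSet(
            [call(int(l), start=3000 * i)
             for i, l in enumerate(rng.integers(100, 60_000, 200))]
        )
        strict = filter_rare_large(cs, BurdenConfig(min_len=5000,
                                                    size_bins=((5000, 10_000),)))
        loose = filter_rare_large(cs, BurdenConfig(min_len=1000))
        assert len(strict) <= len(loose) <= len(cs)


class TestTabulate:
    def test_half_open_edges(self):
        cs = SVCallSet([call(1500), call(9999, start=20_000),
                        call(10_000, start=40_000)])
        t = tabulate(cs, BurdenConfig())
        assert t.count("DEL", "1000-10000") == 2
        assert t.count("DEL", "10000-50000") == 1

    def test_out_of_range_remainder(self):
        t = tabulate(SVCallSet([call(100_000)]), BurdenConfig())
        assert int(t.overflow["DEL"]) == 1
        assert int(t.totals["DEL"]) == 1
        assert t.bins.loc["DEL"].sum() == 0

    def test_log_uniform_bin_proportions_match_analytic(self):
        model = rv.LogUniformSizeModel(1000, 100_000)
        lens = model.sample(np.random.default_rng(1), 4000)
        cs = SVCallSet(
            [call(int(l), start=250 * i) for i, l in enumerate(lens)]
        )
        cfg = BurdenConfig()
        t = tabulate(cs, cfg)
        for (lo, hi), lab in zip(cfg.size_bins, cfg.bin_labels()):
            p = model.bin_log_measure(lo, hi)
            observed = t.count("DEL", lab)
            sd = np.sqrt(4000 * p * (1 - p))
            assert abs(observed - 4000 * p) < 4 * sd


class TestFoldEnrichment:
    def _table(self, n, sv_type="DEL"):
        return tabulate(
            SVCallSet([call(1500, sv_type=sv_type, start=2000 * i)
                       for i in range(n)]),
            BurdenConfig(),
        )

    def test_plain_ratio_without_pseudocount(self):
        df = fold_enrichment(self._table(30), self._table(15), BurdenConfig())
        row = df.query("sv_type == 'DEL' and size_bin == 'overall'").iloc[0]
        assert row.fold == pytest.approx(2.0)
        assert not row.pseudocount_used

    def test_zero_denominator_uses_pseudocount_and_marks(self):
        df = fold_enrichment(self._table(5), self._table(0), BurdenConfig())
        row = df.query("sv_type == 'DEL' and size_bin == 'overall'").iloc[0]
        assert row.fold == pytest.approx(6.0)
        assert row.pseudocount_used

    def test_swapped_arguments_reciprocal(self):
        a, b = self._table(30), self._table(15)
        cfg = BurdenConfig()
        f1 = fold_enrichment(a, b, cfg).query(
            "sv_type=='DEL' and size_bin=='overall'").iloc[0].fold
        f2 = fold_enrichment(b, a, cfg).query(
            "sv_type=='DEL' and size_bin=='overall'").iloc[0].fold
        assert f1 == pytest.approx(1 / f2)


class TestWindowCounts:
    def test_tiling_ceiling_division(self):
        win = tile_genome({"LGI": 1_000_000}, 300_000)
        assert len(win) == 4
        assert win.iloc[-1].end - win.iloc[-1].start == 100_000

    def test_half_open_boundary(self):
        cs = SVCallSet([call(1500, start=300_000)])
        track = window_counts(cs, {"LGI": 1_000_000}, BurdenConfig())
        assert track.windows.iloc[1]["DEL"] == 1
        assert track.windows.iloc[0]["DEL"] == 0

    def test_counts_conserved(self):
        rng = np.random.default_rng(2)
        cs = SVCallSet(
            [call(1500, start=int(s)) for s in rng.integers(0, 900_000, 57)]
        )
        track = window_counts(cs, {"LGI": 1_000_000}, BurdenConfig())
        assert track.windows["DEL"].sum() == 57

    def test_unknown_chromosome_raises(self):
        cs = SVCallSet([call(1500, chrom="chrX")])
        with pytest.raises(ValueError, match="unknown chromosome"):
            window_counts(cs, {"LGI": 1_000_000}, BurdenConfig())


class TestWindowEnrichment:
    def test_identical_tracks_nothing_significant(self):
        cs = SVCallSet(
            [call(1500, start=10_000 * i) for i in range(40)]
        )
        cfg = BurdenConfig(window_size=100_000)
        track = window_counts(cs, {"LGI": 500_000}, cfg)
        df = window_enrichment(track, track, cfg)
        assert (df.raw_p == 1.0).all()
        assert not df.significant.any()

    def test_concentrated_window_detected_and_matches_oracle(self):
        """One window holding 20 vs 0 calls out of 100-call libraries is
        flagged; adjusted p agrees with the closed-form computation."""
        cfg = BurdenConfig(window_size=100_000)
        genome = {"LGI": 1_000_000}
        rng = np.random.default_rng(3)
        base = [call(1500, start=int(s))
                for s in rng.integers(100_000, 999_000, 80)]
        hot = [call(1500, start=int(s)) for s in rng.integers(0, 99_000, 20)]
        treat = window_counts(SVCallSet(base + hot), genome, cfg)
        rng2 = np.random.default_rng(4)
        ctrl = window_counts(
            SVCallSet([call(1500, start=int(s))
                       for s in rng2.integers(100_000, 999_000, 100)]),
            genome, cfg,
        )
        df = window_enrichment(treat, ctrl, cfg)
        row = df[(df.start == 0) & (df.sv_type == "DEL")].iloc[0]
        assert row.significant
        # closed-form oracle for that window
        raw = np.array([
            two_proportion_test(int(a), 100, int(b), 100)
            for a, b in zip(treat.windows["DEL"], ctrl.windows["DEL"])
        ])
        adj, _ = holm_sidak(raw, cfg.alpha)
        assert row.adj_p == pytest.approx(adj[0])

    def test_mismatched_tilings_rejected(self):
        cfg = BurdenConfig(window_size=100_000)
        cs = SVCallSet([call(1500)])
        a = window_counts(cs, {"LGI": 500_000}, cfg)
        b = window_counts(cs, {"LGI": 600_000}, cfg)
        with pytest.raises(ValueError, match="tilings"):
            window_enrichment(a, b, cfg)


class TestCompareCallsets:
    def test_report_plumbs_counts_and_summary(self):
        treat = SVCallSet([call(1500, start=5000 * i) for i in range(20)])
        ctrl = SVCallSet([call(1500, start=5000 * i) for i in range(10)])
        rep = compare_callsets(treat, ctrl, {"LGI": 1_000_000})
        assert rep.overall_fold("DEL") == pytest.approx(2.0)
        text = rep.summary()
        assert "DEL" in text and "fold = 2.00" in text
        js = rep.to_json_summary()
        assert '"fold": 2.0' in js
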