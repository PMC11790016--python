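"""Sliding-window statistics: membership, log2FC, empirical null test,
FDR adjustment, and domain calling."""
import numpy as np
import pandas as pd
import pytest

import crisprtile as ct
from crisprtile.errors import ValidationError
from crisprtile.windows import ComparisonResult, Window

from conftest import simulate_screen


def _make_table(norm_cols):
    df = pd.DataFrame(norm_cols)
    table = ct.CountTable(raw=df.astype(np.int64))
    table.normalized = df.astype(float)
    return table


class TestAssignWindows:
    def test_window_grid_arithmetic(self, tiny_library):
        wins = ct.assign_windows(tiny_library, (0, 4000), window=2000, step=1000,
                                 min_guides=1)
        assert [(w.start, w.end) for w in wins] == [(0, 2000), (1000, 3000), (2000, 4000)]

    def test_guide_belongs_to_every_window_containing_midpoint(self):
        lib = [ct.GuideRecord("t1", "A" * 20, "chr3", 1490, 1510, "+", "tiling")]
        wins = ct.assign_windows(lib, (0, 4000), window=2000, step=1000, min_guides=1)
        members = [(w.start, w.end) for w in wins if "t1" in w.guide_ids]
        assert members == [(0, 2000), (1000, 3000)]

    def test_min_guides_filter_drops_sparse_windows(self, tiny_library):
        # tiny_library has 8 tiling guides across 6 kb: ~2-3 per 2 kb window
        wins = ct.assign_windows(tiny_library, (0, 6000), min_guides=5)
        assert wins == []

    def test_controls_never_members(self, tiny_library):
        wins = ct.assign_windows(tiny_library, (0, 6000), min_guides=1)
        member_ids = {g for w in wins for g in w.guide_ids}
        assert all(gid.startswith("TILE_") for gid in member_ids)

    def test_empty_region_rejected(self, tiny_library):
        with pytest.raises(ValidationError):
            ct.assign_windows(tiny_library, (100, 100))
        with pytest.raises(ValidationError):
            ct.assign_windows(tiny_library, (0, 4000), window=100, step=200)


class TestGuideLog2FC:
    def test_doubling_gives_one(self):
        table = _make_table({"a": [200.0], "b": [100.0]})
        table.raw.index = ["g"]
        table.normalized.index = ["g"]
        assert ct.guide_log2fc(table, "a", "b")["g"] == 1.0

    def test_equal_abundance_gives_zero(self):
        table = _make_table({"a": [150.0, 7.0], "b": [150.0, 7.0]})
        assert (ct.guide_log2fc(table, "a", "b") == 0).all()

    def test_double_dropout_with_pseudocount_is_zero(self):
        raw = pd.DataFrame({"a": [0, 10], "b": [0, 10]})
        table = ct.normalize_counts(ct.CountTable(raw=raw), pseudocount=0.5)
        assert ct.guide_log2fc(table, "a", "b").iloc[0] == 0.0

    def test_unknown_sample_raises_key_error(self):
        table = _make_table({"a": [1.0], "b": [1.0]})
        with pytest.raises(KeyError):
            ct.guide_log2fc(table, "a", "zz")


class TestWindowTest:
    def _uniform_fc(self, value, n_members=6, n_null=30):
        members = [f"TILE_{i:06d}" for i in range(n_members)]
        nulls = [f"NT_{i:05d}" for i in range(n_null)]
        fc = pd.Series(value, index=members + nulls, dtype=float)
        w = Window("chr3", 0, 2000, tuple(members))
        return w, fc, nulls

    def test_degenerate_null_gives_p_one(self):
        w, fc, nulls = self._uniform_fc(0.7)
        ct.window_test([w], fc, nulls, B=500, seed=0)
        res = w.stats["low_vs_high"]
        assert res.T == pytest.approx(0.7)
        assert res.p == 1.0

    def test_empirical_p_floor_is_one_over_b_plus_one(self):
        members = [f"TILE_{i:06d}" for i in range(6)]
        nulls = [f"NT_{i:05d}" for i in range(30)]
        fc = pd.Series(0.0, index=members + nulls, dtype=float)
        fc[members] = 100.0  # far outside any resampled null
        w = Window("chr3", 0, 2000, tuple(members))
        ct.window_test([w], fc, nulls, B=999, seed=0)
        assert w.stats["low_vs_high"].p == pytest.approx(1 / 1000)

    def test_two_sidedness_is_symmetric(self):
        rng = np.random.default_rng(3)
        members = [f"TILE_{i:06d}" for i in range(8)]
        nulls = [f"NT_{i:05d}" for i in range(40)]
        null_vals = rng.normal(size=40)
        fc_pos = pd.Series(np.r_[np.full(8, 1.3), null_vals], index=members + nulls)
        fc_neg = pd.Series(np.r_[np.full(8, -1.3), null_vals], index=members + nulls)
        w1 = Window("chr3", 0, 2000, tuple(members))
        w2 = Window("chr3", 0, 2000, tuple(members))
        ct.window_test([w1], fc_pos, nulls, B=2000, seed=5)
        ct.window_test([w2], fc_neg, nulls, B=2000, seed=5)
        assert w1.stats["low_vs_high"].p == w2.stats["low_vs_high"].p

    def test_planted_repressive_element_detected_across_seeds(self):
        hits = 0
        for s in range(20):
            lib, table, els = simulate_screen(
                [(24_000, 25_000, 0.6)], [77, s],
                n_cells=50_000, depth_per_bin=500_000,
            )
            wins = ct.assign_windows(lib, (0, 50_000))
            nulls = [g.guide_id for g in lib if g.category == "nontargeting"]
            fc = ct.guide_log2fc(table, "g_low", "g_high")
            ct.window_test(wins, fc, nulls, B=2000, seed=[78, s])
            truth = [w for w in wins if w.start < 25_000 and 24_000 < w.end]
            best = min(truth, key=lambda w: w.stats["low_vs_high"].p)
            res = best.stats["low_vs_high"]
            hits += res.p < 0.05 and res.T > 0
        assert hits >= 18  # >= 90% of seeds

    def test_permuting_library_order_leaves_results_bit_identical(self):
        lib, table, _ = simulate_screen(
            [(24_000, 25_000, 0.6)], [88], n_cells=20_000, depth_per_bin=100_000,
        )
        nulls = [g.guide_id for g in lib if g.category == "nontargeting"]
        fc = ct.guide_log2fc(table, "g_low", "g_high")
        rng = np.random.default_rng(1)
        shuffled = [lib[i] for i in rng.permutation(len(lib))]
        out = {}
        for tag, library in [("orig", lib), ("perm", shuffled)]:
            wins = ct.assign_windows(library, (0, 50_000))
            ct.window_test(wins, fc.sample(frac=1, random_state=2) if tag == "perm" else fc,
                           nulls, B=300, seed=9)
            out[tag] = [(w.start, w.stats["low_vs_high"].T, w.stats["low_vs_high"].p)
                        for w in wins]
        assert out["orig"] == out["perm"]

    def test_empty_null_pool_rejected(self):
        w, fc, _ = self._uniform_fc(0.5)
        with pytest.raises(ValidationError):
            ct.window_test([w], fc, [], seed=0)

    def test_rank_sum_alternative_flags_same_planted_element(self):
        lib, table, _ = simulate_screen(
            [(24_000, 25_000, 0.8)], [99], n_cells=50_000, depth_per_bin=500_000,
        )
        wins = ct.assign_windows(lib, (0, 50_000), step=2000)
        nulls = [g.guide_id for g in lib if g.category == "nontargeting"]
        fc = ct.guide_log2fc(table, "g_low", "g_high")
        ct.window_test(wins, fc, nulls, B=500, seed=1, statistic="rank_sum")
        best = min(wins, key=lambda w: w.stats["low_vs_high"].p)
        assert best.start < 25_000 and 24_000 < best.end
        assert best.stats["low_vs_high"].T > 0


class TestDirectionSemantics:
    @pytest.mark.parametrize("effect,sign", [(0.6, 1), (-0.6, -1)])
    def test_repression_positive_activation_negative(self, effect, sign):
        lib, table, els = simulate_screen(
            [(24_000, 25_000, effect)], [55, 1 if effect > 0 else 2],
            n_cells=50_000, depth_per_bin=500_000,
        )
        wins = ct.assign_windows(lib, (0, 50_000))
        nulls = [g.guide_id for g in lib if g.category == "nontargeting"]
        fc = ct.guide_log2fc(table, "g_low", "g_high")
        ct.window_test(wins, fc, nulls, B=500, seed=3)
        truth = [w for w in wins if w.start < 25_000 and 24_000 < w.end]
        best = min(truth, key=lambda w: w.stats["low_vs_high"].p)
        assert np.sign(best.stats["low_vs_high"].T) == sign


class TestAdjustFDR:
    def _wins(self, pvals):
        out = []
        for i, p in enumerate(pvals):
            w = Window("chr3", i * 2000, (i + 1) * 2000, ("TILE_000000",))
            w.stats["low_vs_high"] = ComparisonResult(T=1.0, p=p)
            out.append(w)
        return out

    def test_single_window_q_equals_p(self):
        wins = ct.adjust_fdr(self._wins([0.04]))
        assert wins[0].stats["low_vs_high"].q == pytest.approx(0.04)

    def test_hand_computed_bh(self):
        wins = ct.adjust_fdr(self._wins([0.01, 0.02, 0.03]))
        qs = [w.stats["low_vs_high"].q for w in wins]
        assert qs == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones_stay_ones_and_q_dominates_p(self):
        wins = ct.adjust_fdr(self._wins([1.0, 1.0, 1.0]))
        assert all(w.stats["low_vs_high"].q == 1.0 for w in wins)
        rng = np.random.default_rng(0)
        wins = ct.adjust_fdr(self._wins(list(rng.uniform(size=20))))
        assert all(
            w.stats["low_vs_high"].q >= w.stats["low_vs_high"].p - 1e-15 for w in wins
        )


class TestCallDomains:
    def _win(self, start, end, p, T):
        w = Window("chr3", start, end, ("TILE_000000",) * 1)
        w.stats["low_vs_high"] = ComparisonResult(T=T, p=p)
        return w

    def test_overlapping_significant_windows_merge(self):
        wins = [self._win(0, 2000, 0.01, 1.0), self._win(1000, 3000, 0.02, 1.0),
                self._win(5000, 7000, 0.5, 1.0)]
        calls = ct.call_domains(wins)
        assert [(c.start, c.end) for c in calls] == [(0, 3000)]
        assert calls[0].min_p == 0.01 and calls[0].n_windows == 2

    def test_no_significant_windows_gives_empty_list(self):
        calls = ct.call_domains([self._win(0, 2000, 0.9, 1.0)])
        assert calls == []

    def test_wrong_direction_keeps_nominal_only(self):
        calls = ct.call_domains([self._win(0, 2000, 0.01, -2.0)], require_direction=1)
        assert calls[0].flags["nominal"] is True
        assert calls[0].flags["on_target_direction"] is False

    def test_atac_flag_from_peak_intersection(self):
        peaks = ct.FeatureSet.from_records([("chr3", 1500, 1600)], "atac_peak")
        calls = ct.call_domains([self._win(0, 2000, 0.01, 1.0)], peaks=peaks)
        assert calls[0].flags["atac_overlap"] is True
        far = ct.FeatureSet.from_records([("chr3", 9000, 9100)], "atac_peak")
        calls = ct.call_domains([self._win(0, 2000, 0.01, 1.0)], peaks=far)
        assert calls[0].flags["atac_overlap"] is False

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValidationError):
            ct.call_domains([], alpha=0.0)

    def test_filter_calls_by_tier(self):
        calls = ct.call_domains(
            [self._win(0, 2000, 0.01, 1.0), self._win(5000, 7000, 0.01, -1.0)],
            require_direction=1,
        )
        assert len(ct.filter_calls(calls, "nominal")) == 2
        kept = ct.filter_calls(calls, "on_target_direction")
        assert [(c.start, c.end) for c in kept] == [(0, 2000)]
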