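"""Analysis-pair assembly, paired-scale contrasts, class summaries."""

import numpy as np
import pandas as pd
import pytest

from painrescale import (
    PAIR_CLASSES,
    SCALE_0_100,
    ConversionSource,
    PairResult,
    ScaleDefinition,
    build_pairs,
    classify_scale_pair,
    compare_pair,
    sensitivity_filter,
    summarize_all,
    summarize_pairs,
)
from conftest import make_arm

S100 = SCALE_0_100
S10 = ScaleDefinition("NRS-10", 0, 10)
S10B = ScaleDefinition("mBPI-10", 0, 10)
S4 = ScaleDefinition("VRS-4", 0, 3)
S5 = ScaleDefinition("VRS-5", 0, 4)


class TestClassify:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (S10, S100, "ten_vs_hundred"),
            (S100, S10, "ten_vs_hundred"),
            (S4, S10, "ten_vs_small"),
            (S5, S10, "ten_vs_small"),
            (S4, S100, "hundred_vs_small_4pt"),
            (S5, S100, "hundred_vs_small_5pt"),
        ],
    )
    def test_classes(self, a, b, expected):
        assert classify_scale_pair(a, b) == expected

    def test_equal_ranges_rejected(self):
        with pytest.raises(ValueError, match="equal ranges"):
            classify_scale_pair(S10, S10B)


def two_scale_group(scales, arms=("A", "B"), timepoint="tp1", **arm_kw):
    rows = []
    for scale in scales:
        ratio = scale.range / 100.0
        for i, arm in enumerate(arms):
            rows.append(
                make_arm(
                    arm,
                    scale=scale,
                    mean=(40.0 + 10.0 * i) * ratio,
                    sd=20.0 * ratio,
                    timepoint=timepoint,
                    **arm_kw,
                )
            )
    return rows


class TestBuildPairs:
    def test_three_arm_trial_yields_all_arm_combinations(self):
        rows = two_scale_group((S100, S4), arms=("A", "B", "C"))
        specs = build_pairs(rows)
        assert len(specs) == 3
        assert {(s.arm_a, s.arm_b) for s in specs} == {
            ("A", "B"),
            ("A", "C"),
            ("B", "C"),
        }

    def test_two_0_10_scales_and_one_0_100_give_two_pairs(self):
        rows = two_scale_group((S100, S10, S10B))
        specs = build_pairs(rows)
        assert len(specs) == 2
        assert all(s.pair_class == "ten_vs_hundred" for s in specs)
        assert {s.scale_small.name for s in specs} == {"NRS-10", "mBPI-10"}

    def test_four_timepoints_give_four_pairs(self):
        rows = []
        for tp in ("tp1", "tp2", "tp3", "tp4"):
            rows.extend(two_scale_group((S100, S10), timepoint=tp))
        assert len(build_pairs(rows)) == 4

    def test_arm_on_one_scale_only_is_skipped(self, caplog):
        rows = two_scale_group((S100, S10))
        rows.append(make_arm("C", scale=S100, mean=45.0))
        with caplog.at_level("WARNING", logger="painrescale.pairs"):
            specs = build_pairs(rows)
        assert len(specs) == 1
        assert any("one scale only" in rec.message for rec in caplog.records)

    def test_small_scale_ordered_first(self):
        specs = build_pairs(two_scale_group((S100, S4)))
        assert specs[0].scale_small is not None
        assert specs[0].scale_small.range < specs[0].scale_large.range


class TestComparePair:
    def test_identical_rescaled_summaries_split_weight_evenly(self):
        spec = build_pairs(two_scale_group((S100, S10)))[0]
        res = compare_pair(spec)
        assert res.delta_md == pytest.approx(0.0)
        assert res.weight_small_pct == pytest.approx(50.0)
        assert not res.excluded

    def test_noisier_small_scale_gets_under_half_weight(self):
        rows = two_scale_group((S100,))
        # 0-10 scale with double the rescaled SD
        rows.append(make_arm("A", scale=S10, mean=4.0, sd=4.0))
        rows.append(make_arm("B", scale=S10, mean=5.0, sd=4.0))
        res = compare_pair(build_pairs(rows)[0])
        assert res.weight_small_pct < 50.0

    def test_delta_is_small_scale_md_minus_large_scale_md(self):
        rows = two_scale_group((S100,))
        rows.append(make_arm("A", scale=S10, mean=3.8, sd=2.0))
        rows.append(make_arm("B", scale=S10, mean=5.0, sd=2.0))
        res = compare_pair(build_pairs(rows)[0])
        assert res.delta_md == pytest.approx(res.md_small.md - res.md_large.md)
        assert res.md_small.md == pytest.approx(-12.0)
        assert res.md_large.md == pytest.approx(-10.0)
        assert res.delta_md == pytest.approx(-2.0)

    def test_degenerate_converted_sd_marks_pair_excluded(self, caplog):
        rows = two_scale_group((S100,))
        rows.append(
            make_arm(
                "A",
                scale=S4,
                mean=1.0,
                sd=0.0,
                converted_from=ConversionSource.MEDIAN_RANGE,
            )
        )
        rows.append(make_arm("B", scale=S4, mean=1.5, sd=0.7))
        with caplog.at_level("WARNING", logger="painrescale.pairs"):
            res = compare_pair(build_pairs(rows)[0])
        assert res.excluded
        assert "SD of 0" in res.exclusion_reason
        assert "median_range" in res.exclusion_reason
        assert res.delta_md is None
        assert any("excluded" in rec.message for rec in caplog.records)

    def test_fixed_effect_weights_ignore_tau2(self):
        rows = two_scale_group((S100,))
        rows.append(make_arm("A", scale=S10, mean=3.0, sd=2.0))
        rows.append(make_arm("B", scale=S10, mean=5.0, sd=2.0))
        spec = build_pairs(rows)[0]
        res = compare_pair(spec, weight_model="fixed_effect")
        v_small = res.md_small.variance
        v_large = res.md_large.variance
        expected = 100.0 * (1 / v_small) / (1 / v_small + 1 / v_large)
        assert res.weight_small_pct == pytest.approx(expected)


def fake_result(delta, weight=50.0, pair_class="ten_vs_hundred", trial="t1",
                converted=False, excluded=False):
    return PairResult(
        trial_id=trial,
        comparison_id="c1",
        timepoint="tp1",
        arm_a="A",
        arm_b="B",
        scale_small=S10,
        scale_large=S100,
        pair_class=pair_class,
        md_small=None,
        md_large=None,
        delta_md=None if excluded else delta,
        weight_small_pct=None if excluded else weight,
        converted=converted,
        excluded=excluded,
        exclusion_reason="SD of 0" if excluded else None,
    )


class TestSummarizePairs:
    def test_symmetric_deltas(self):
        s = summarize_pairs([fake_result(1.0), fake_result(-1.0)], "ten_vs_hundred")
        assert s.mean_delta_md == pytest.approx(0.0)
        assert (s.min_delta_md, s.max_delta_md) == (-1.0, 1.0)
        assert (s.n_higher, s.n_lower) == (1, 1)

    def test_single_pair_collapses_mean_and_range(self):
        s = summarize_pairs([fake_result(2.5, weight=40.0)], "ten_vs_hundred")
        assert s.mean_delta_md == s.min_delta_md == s.max_delta_md == 2.5
        assert s.mean_weight_diff_pct == pytest.approx(-20.0)

    def test_ties_count_in_neither_direction(self):
        s = summarize_pairs([fake_result(0.0), fake_result(1.0)], "ten_vs_hundred")
        assert (s.n_higher, s.n_lower) == (1, 0)
        assert s.n_higher + s.n_lower <= s.n_pairs

    def test_matches_spreadsheet_style_recomputation(self):
        rng = np.random.default_rng(11)
        deltas = rng.normal(0, 3, 10).round(3)
        weights = rng.uniform(30, 70, 10).round(2)
        results = [
            fake_result(d, w, trial=f"t{i % 4}")
            for i, (d, w) in enumerate(zip(deltas, weights))
        ]
        s = summarize_pairs(results, "ten_vs_hundred")
        df = pd.DataFrame({"delta": deltas, "w": weights})
        assert s.n_pairs == 10
        assert s.n_trials == 4
        assert s.mean_delta_md == pytest.approx(df["delta"].mean())
        assert s.min_delta_md == pytest.approx(df["delta"].min())
        assert s.max_delta_md == pytest.approx(df["delta"].max())
        assert s.mean_abs_delta_md == pytest.approx(df["delta"].abs().mean())
        assert s.n_higher == int((df["delta"] > 0).sum())
        assert s.n_lower == int((df["delta"] < 0).sum())
        assert s.mean_weight_diff_pct == pytest.approx(
            ((df["w"] - 50) * 2).mean()
        )
        assert s.min_weight_diff_pct == pytest.approx(((df["w"] - 50) * 2).min())

    def test_empty_class_yields_empty_marker(self):
        s = summarize_pairs([fake_result(1.0)], "hundred_vs_small_4pt")
        assert s.empty
        assert s.n_pairs == 0
        assert s.mean_delta_md is None

    def test_excluded_pairs_never_contribute(self):
        results = [
            fake_result(1.0),
            fake_result(99.0, excluded=True),
        ]
        s = summarize_pairs(results, "ten_vs_hundred")
        assert s.n_pairs == 1
        assert s.n_excluded == 1
        assert s.mean_delta_md == pytest.approx(1.0)

    def test_order_invariance(self):
        results = [fake_result(d, 45.0 + d) for d in (-2.0, 0.5, 3.0, -1.0)]
        forward = summarize_pairs(results, "ten_vs_hundred")
        backward = summarize_pairs(list(reversed(results)), "ten_vs_hundred")
        assert forward == backward

    def test_every_pair_lands_in_exactly_one_class(self):
        results = [
            fake_result(1.0, pair_class="ten_vs_hundred"),
            fake_result(2.0, pair_class="ten_vs_small"),
            fake_result(3.0, pair_class="hundred_vs_small_4pt"),
            fake_result(4.0, pair_class="hundred_vs_small_5pt"),
            fake_result(5.0, pair_class="ten_vs_hundred"),
        ]
        summaries = summarize_all(results)
        assert [s.pair_class for s in summaries] == list(PAIR_CLASSES)
        assert sum(s.n_pairs for s in summaries) == len(results)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown pair class"):
            summarize_pairs([], "nope")


class TestSensitivityFilter:
    def test_no_converted_pairs_is_identity(self):
        results = [fake_result(1.0), fake_result(2.0)]
        assert sensitivity_filter(results) == results

    def test_all_converted_gives_empty_list(self):
        results = [fake_result(1.0, converted=True)]
        assert sensitivity_filter(results) == []

    def test_mixed_set_keeps_only_unconverted(self):
        results = [
            fake_result(1.0),
            fake_result(2.0, converted=True),
            fake_result(3.0),
            fake_result(4.0, converted=True),
        ]
        kept = sensitivity_filter(results)
        assert len(kept) == len(results) - 2
        assert all(not r.converted for r in kept)
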