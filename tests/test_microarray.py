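"""Normalization chain and Tukey-HSD differential expression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mirpipe import microarray as ma
from mirpipe.microarray import DEConfig, NormalizedMatrix, ProbesetMatrix

from _oracles import bh_stepup, hsd_q_direct, studentized_range_sf
from conftest import make_normalized, make_samples


def build_matrix(mirna_rows, anti_rows, dabg_rows=None, samples=None):
    samples = samples if samples is not None else make_samples(("A",), 2)
    cols = samples["sample_id"].tolist()
    ids = [f"m{i}" for i in range(len(mirna_rows))] + [
        f"bg{i}" for i in range(len(anti_rows))
    ]
    inten = pd.DataFrame(list(mirna_rows) + list(anti_rows), index=ids, columns=cols)
    if dabg_rows is None:
        dabg = pd.DataFrame(0.01, index=ids, columns=cols)
    else:
        dabg = pd.DataFrame(
            list(dabg_rows) + [[0.5] * len(cols)] * len(anti_rows),
            index=ids, columns=cols,
        )
    probe_class = pd.Series(
        [ma.HUMAN_MATURE] * len(mirna_rows) + [ma.ANTIGENOMIC] * len(anti_rows),
        index=ids,
    )
    return ProbesetMatrix(
        intensities=inten.astype(float), dabg_p=dabg.astype(float),
        probe_class=probe_class, samples=samples,
    )


class TestNormalize:
    def test_intensity_at_background_mean_maps_to_zero(self):
        # intensity == per-sample antigenomic mean -> 0 -> log2(1+0) = 0
        matrix = build_matrix([[10.0] * 4], [[10.0] * 4, [10.0] * 4])
        out = ma.normalize(matrix)
        assert np.allclose(out.values.values, 0.0)

    def test_background_plus_seven_gives_log2_eight(self):
        matrix = build_matrix([[17.0] * 4], [[10.0] * 4, [10.0] * 4])
        out = ma.normalize(matrix)
        assert np.allclose(out.values.values, 3.0)

    def test_dabg_mask_dominates_intensity(self):
        # 100 above background but detection p = 0.2 -> masked to 0
        dabg = [[0.2, 0.01, 0.01, 0.01]]
        matrix = build_matrix([[110.0] * 4], [[10.0] * 4], dabg_rows=dabg)
        out = ma.normalize(matrix)
        row = out.values.iloc[0].values
        assert row[0] == 0.0 and np.allclose(row[1:], np.log2(101.0))

    def test_negative_after_subtraction_floors_to_zero(self):
        matrix = build_matrix([[5.0] * 4], [[10.0] * 4])
        out = ma.normalize(matrix)
        assert (out.values.values == 0.0).all()

    def test_zero_background_is_identity_up_to_log_transform(self):
        vals = [[3.0, 7.0, 15.0, 31.0]]
        matrix = build_matrix(vals, [[0.0] * 4])
        out = ma.normalize(matrix)
        assert np.allclose(out.values.values, np.log2(1 + np.array(vals)))

    def test_no_antigenomic_probesets_is_an_error(self):
        samples = make_samples(("A",), 2)
        cols = samples["sample_id"].tolist()
        inten = pd.DataFrame([[10.0] * 4], index=["m0"], columns=cols)
        dabg = pd.DataFrame(0.01, index=["m0"], columns=cols)
        matrix = ProbesetMatrix(
            intensities=inten, dabg_p=dabg,
            probe_class=pd.Series([ma.HUMAN_MATURE], index=["m0"]),
            samples=samples,
        )
        with pytest.raises(ma.NormalizationError, match="antigenomic"):
            ma.normalize(matrix)

    def test_negative_intensity_rejected_at_construction(self):
        with pytest.raises(ValueError, match="negative intensity"):
            build_matrix([[-1.0, 2.0, 2.0, 2.0]], [[1.0] * 4])

    def test_expressed_requires_both_cell_lines(self):
        # nonzero only in line A -> not expressed
        norm_vals = {
            "both": [1, 1, 1, 1, 1, 1, 1, 1],
            "line_a_only": [1, 1, 1, 1, 0, 0, 0, 0],
        }
        samples = make_samples(("A", "B"), 2)
        anti = [[0.0] * 8, [0.0] * 8]
        linear = {k: list(np.exp2(v) - 1 + 0.0) for k, v in norm_vals.items()}
        matrix = build_matrix(list(linear.values()), anti, samples=samples)
        out = ma.normalize(matrix)
        assert bool(out.expressed.iloc[0]) is True
        assert bool(out.expressed.iloc[1]) is False


class TestTukeyHSD:
    def test_matches_hand_computed_example(self):
        # CON = {0,1,0,1}, IK1 = {2,3,2,3} after sheet ordering
        norm8 = make_normalized(
            {"m1": [0, 1, 2, 3, 0, 1, 2, 3]}, cell_lines=("A", "B"), reps=2
        )
        stats = ma.tukey_hsd(norm8, DEConfig(grouping="two_group"))
        assert stats.loc["m1", "difference"] == pytest.approx(2.0)
        assert stats.loc["m1", "q_stat"] == pytest.approx(6.928, abs=1e-3)

    def test_identical_groups_give_zero_difference_p_one(self):
        norm = make_normalized({"m1": [2, 3, 2, 3, 2, 3, 2, 3]})
        stats = ma.tukey_hsd(norm, DEConfig(grouping="two_group"))
        assert stats.loc["m1", "difference"] == pytest.approx(0.0)
        assert stats.loc["m1", "p_value"] == pytest.approx(1.0, abs=1e-9)

    def test_label_swap_negates_difference_keeps_q_and_p(self):
        vals = [0.3, 1.1, 2.4, 3.2, 0.7, 1.5, 2.2, 3.3]
        norm = make_normalized({"m1": vals})
        swapped_samples = norm.samples.copy()
        swapped_samples["condition"] = swapped_samples["condition"].map(
            {"CON": "IK1", "IK1": "CON"}
        )
        swapped = NormalizedMatrix(norm.values, norm.expressed, swapped_samples)
        a = ma.tukey_hsd(norm, DEConfig(grouping="two_group"))
        b = ma.tukey_hsd(swapped, DEConfig(grouping="two_group"))
        assert a.loc["m1", "difference"] == pytest.approx(-b.loc["m1", "difference"])
        assert a.loc["m1", "q_stat"] == pytest.approx(b.loc["m1", "q_stat"])
        assert a.loc["m1", "p_value"] == pytest.approx(b.loc["m1", "p_value"])

    def test_zero_variance_with_different_means_flags_p_zero(self):
        norm = make_normalized({"m1": [1, 1, 3, 3, 1, 1, 3, 3]})
        with pytest.warns(RuntimeWarning, match="zero within-group variance"):
            stats = ma.tukey_hsd(norm, DEConfig(grouping="two_group"))
        assert stats.loc["m1", "p_value"] == 0.0
        assert stats.loc["m1", "zero_variance"]

    def test_single_replicate_group_is_an_error(self):
        samples = pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "cell_line": ["A"] * 3,
                "condition": ["CON", "CON", "IK1"],
                "replicate": ["1", "2", "1"],
            }
        )
        norm = NormalizedMatrix(
            values=pd.DataFrame([[1.0, 2.0, 3.0]], index=["m1"],
                                columns=["s1", "s2", "s3"]),
            expressed=pd.Series([True], index=["m1"]),
            samples=samples,
        )
        with pytest.raises(ma.StatisticsError, match="fewer than 2 replicates"):
            ma.tukey_hsd(norm, DEConfig(grouping="two_group"))

    def test_unexpressed_mirnas_are_excluded_from_testing(self):
        norm = make_normalized({"m1": [0, 1, 2, 3, 0, 1, 2, 3],
                                "m2": [1, 2, 3, 4, 1, 2, 3, 4]})
        norm.expressed["m2"] = False
        stats = ma.tukey_hsd(norm, DEConfig(grouping="two_group"))
        assert list(stats.index) == ["m1"]

    @pytest.mark.parametrize("grouping,k_expected", [("two_group", 2), ("four_group", 4)])
    def test_q_and_p_match_independent_oracle(self, rng, grouping, k_expected):
        """On random small instances, q and the studentized-range p agree
        with direct formula evaluation + numerically integrated CDF."""
        for _ in range(5):
            vals = rng.normal(5, 1, 8)
            norm = make_normalized({"m1": list(vals)})
            stats = ma.tukey_hsd(norm, DEConfig(grouping=grouping))
            labels = norm.samples["condition"].values
            con, ik1 = vals[labels == "CON"], vals[labels == "IK1"]
            if grouping == "two_group":
                _, q_ref, k, df = hsd_q_direct(con, ik1)
            else:
                groups = [vals[i : i + 2] for i in range(0, 8, 2)]
                ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
                df, k = 4, 4
                se = np.sqrt(ssw / df / 2 * (1 / 4 + 1 / 4))
                q_ref = abs(ik1.mean() - con.mean()) / se
            assert k == k_expected
            assert stats.loc["m1", "q_stat"] == pytest.approx(q_ref, rel=1e-12)
            p_ref = studentized_range_sf(q_ref, k, df)
            assert stats.loc["m1", "p_value"] == pytest.approx(p_ref, rel=1e-8)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert ma.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_enumerated_example(self):
        assert ma.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_empty_list(self):
        assert len(ma.bh_adjust([])) == 0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_literal_stepup_and_is_monotone(self, ps):
        adj = ma.bh_adjust(ps)
        assert adj == pytest.approx(bh_stepup(ps))
        order = np.argsort(ps)
        assert (np.diff(np.asarray(adj)[order]) >= -1e-12).all()


class TestCallDE:
    @pytest.mark.parametrize(
        "difference,fdr,expected",
        [(1.5, 0.01, "up"), (1.5, 0.20, "ns"), (0.9, 0.001, "ns"),
         (-1.5, 0.01, "down"), (1.0, 0.001, "ns")],  # threshold is strict >
    )
    def test_direction_rules(self, difference, fdr, expected):
        # craft p-values whose BH adjustment reproduces the target fdr
        stats = pd.DataFrame(
            {"mean_con": [0.0], "mean_ik1": [difference],
             "difference": [difference], "q_stat": [1.0],
             "p_value": [fdr], "zero_variance": [False]},
            index=pd.Index(["m1"], name="mirna_id"),
        )
        out = ma.call_de(stats)
        assert out.loc["m1", "direction"] == expected

    def test_sorted_by_fdr_then_effect(self):
        stats = pd.DataFrame(
            {"mean_con": [0, 0, 0], "mean_ik1": [2, 3, 1],
             "difference": [2.0, 3.0, 1.5], "q_stat": [9, 9, 9],
             "p_value": [0.01, 0.01, 0.2], "zero_variance": [False] * 3},
            index=pd.Index(["a", "b", "c"], name="mirna_id"),
        )
        out = ma.call_de(stats)
        assert list(out.index) == ["b", "a", "c"]


class TestDEConfig:
    @pytest.mark.parametrize(
        "kwargs", [{"dabg_alpha": 0.0}, {"fdr_alpha": 1.5},
                   {"diff_threshold": -1}, {"grouping": "six_group"}]
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DEConfig(**kwargs)
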