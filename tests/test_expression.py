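"""Probe filtering, normalization, fold changes and ddCt."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirtraffic import expression as ex
from mirtraffic.reference import TABLE1, table1_records
from mirtraffic.synthgen import ExpressionSpec, make_expression_dataset, make_qpcr


class TestMADFilter:
    def test_gross_outlier_removed(self):
        # median 3, MAD 1: 100 scores (100-3)/1 = 97
        out = ex.filter_outlier_probes([1, 2, 3, 4, 100])
        assert sorted(out) == [1, 2, 3, 4]

    def test_all_equal_none_removed(self):
        assert len(ex.filter_outlier_probes([5.0] * 6)) == 6

    def test_zero_mad_epsilon_fallback(self, caplog):
        with caplog.at_level("INFO", logger="mirtraffic.expression"):
            out = ex.filter_outlier_probes([10, 10, 10, 11])
        assert sorted(out) == [10, 10, 10]
        assert any("zero-MAD" in rec.message for rec in caplog.records)

    def test_small_groups_returned_unchanged(self):
        assert len(ex.filter_outlier_probes([1, 100])) == 2

    def test_symmetric_data_survives(self):
        rng = np.random.default_rng(0)
        x = rng.normal(100, 5, 50)
        out = ex.filter_outlier_probes(x)
        assert len(out) >= 45  # only genuine tails trimmed


class TestSummarize:
    def test_mean_of_retained(self):
        probes = pd.DataFrame(
            {"probe_id": ["p1", "p2"], "transcript_id": ["t", "t"], "a1": [2.0, 4.0]}
        )
        out = ex.summarize_probes(probes)
        assert out.loc["t", "a1"] == 3.0

    def test_single_probe_passthrough(self):
        probes = pd.DataFrame({"probe_id": ["p1"], "transcript_id": ["t"], "a1": [7.0]})
        assert ex.summarize_probes(probes).loc["t", "a1"] == 7.0

    def test_outlier_removed_before_mean(self):
        probes = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(5)],
                "transcript_id": ["t"] * 5,
                "a1": [1.0, 2.0, 3.0, 4.0, 100.0],
            }
        )
        assert ex.summarize_probes(probes).loc["t", "a1"] == 2.5


class TestQuantileNormalize:
    def test_two_by_two_hand_example(self):
        mat = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 4.0]})
        out = ex.quantile_normalize(mat)
        assert out["a"].tolist() == [1.5, 3.5]
        assert out["b"].tolist() == [1.5, 3.5]

    def test_identical_columns_unchanged(self):
        mat = pd.DataFrame({"a": [5.0, 1.0, 3.0], "b": [5.0, 1.0, 3.0]})
        out = ex.quantile_normalize(mat)
        pd.testing.assert_frame_equal(out, mat)

    def test_columns_share_distribution_and_preserve_order(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.lognormal(5, 1, size=(50, 4)), columns=list("abcd"))
        out = ex.quantile_normalize(mat)
        ref = np.sort(out["a"].to_numpy())
        for col in "bcd":
            assert np.allclose(np.sort(out[col].to_numpy()), ref)
            assert (
                stats.spearmanr(mat[col], out[col]).statistic == pytest.approx(1.0)
            )

    def test_needs_two_columns(self):
        with pytest.raises(ValueError):
            ex.quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "test,control,expected",
        [(50, 100, -2.0), (100, 100, 1.0), (180, 100, 1.8), (100, 180, -1.8)],
    )
    def test_values(self, test, control, expected):
        assert ex.signed_fold_change(test, control) == pytest.approx(expected)

    def test_antisymmetry_and_magnitude(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b = rng.uniform(1, 1000, 2)
            fc = ex.signed_fold_change(a, b)
            assert abs(fc) >= 1
            if not np.isclose(a, b):
                assert fc == pytest.approx(-ex.signed_fold_change(b, a))

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            ex.signed_fold_change(0, 10)


class TestArraySdStat:
    def test_direct_formula(self):
        assert ex.array_sd_stat(2, 1, 0.25, 0.25) == pytest.approx(2.0)

    def test_null_is_zero(self):
        assert ex.array_sd_stat(5, 5, 1, 1) == 0

    def test_degenerate_flagged(self):
        assert ex.array_sd_stat(2, 1, 0, 0) is None


class TestSelectRegulated:
    def test_table1_threshold_counts(self):
        """Re-applying the 1.8-fold filter to the published hit table
        reproduces its per-timepoint row counts."""
        hits = ex.select_regulated(table1_records(), threshold=1.8)
        per_tp = hits["per_timepoint"]
        assert len(per_tp[12]["up"]) + len(per_tp[12]["down"]) == 4
        assert len(per_tp[24]["up"]) + len(per_tp[24]["down"]) == 9
        assert len(per_tp[48]["up"]) + len(per_tp[48]["down"]) == 18
        assert per_tp[12]["down"] == ["TGFBR2", "DAZAP2", "MICA", "TBC1D2"]
        assert per_tp[12]["up"] == []

    def test_union_deduplicates(self):
        hits = ex.select_regulated(table1_records(), threshold=1.8)
        union = hits["union"]
        assert len(union) == len(set(union))
        assert len(union) == TABLE1["gene"].nunique()

    def test_empty_records(self):
        assert ex.select_regulated([], 1.5) == {"per_timepoint": {}, "union": []}

    def test_transcript_in_two_timepoints_counted_once(self):
        recs = [
            ex.FoldChangeRecord("t", 12, -2.0, None),
            ex.FoldChangeRecord("t", 24, -1.9, None),
        ]
        assert ex.select_regulated(recs, 1.5)["union"] == ["t"]


class TestDdct:
    def _table(self, test_target, test_ref, ctrl_target, ctrl_ref):
        rows = []
        for cond, (tgt, ref) in {
            "test": (test_target, test_ref),
            "control": (ctrl_target, ctrl_ref),
        }.items():
            rows.append({"gene": "target", "condition": cond, "ct": tgt})
            rows.append({"gene": "reference", "condition": cond, "ct": ref})
        return pd.DataFrame(rows)

    @pytest.mark.parametrize(
        "tt,tr,ct,cr,expected",
        [
            (24, 20, 24, 20, 1.0),  # ddCt 0
            (25, 20, 24, 20, 0.5),  # ddCt 1
            (23, 20, 24, 20, 2.0),  # ddCt -1
            (22, 20, 24, 20, 4.0),  # ddCt -2
        ],
    )
    def test_closed_forms(self, tt, tr, ct, cr, expected):
        out = ex.relative_expression_ddct(self._table(tt, tr, ct, cr))
        assert out["relative_expression"] == pytest.approx(expected)

    def test_technical_replicates_averaged(self):
        df = pd.DataFrame(
            [
                {"gene": "target", "condition": "test", "ct": 25.2, "replicate": 1},
                {"gene": "target", "condition": "test", "ct": 24.8, "replicate": 2},
                {"gene": "reference", "condition": "test", "ct": 20.0, "replicate": 1},
                {"gene": "target", "condition": "control", "ct": 24.0, "replicate": 1},
                {"gene": "reference", "condition": "control", "ct": 20.0, "replicate": 1},
            ]
        )
        out = ex.relative_expression_ddct(df)
        assert out["delta_delta_ct"] == pytest.approx(1.0)

    def test_missing_reference_rejected(self):
        df = pd.DataFrame(
            [
                {"gene": "target", "condition": "test", "ct": 25},
                {"gene": "target", "condition": "control", "ct": 24},
            ]
        )
        with pytest.raises(ValueError):
            ex.relative_expression_ddct(df)


class TestPipelineRecovery:
    def test_planted_halving_recovered(self):
        planted = {("TX0001", 24): 0.5, ("TX0002", 24): 0.5}
        spec = ExpressionSpec(
            n_transcripts=60, planted_fold_changes=planted, rng_seed=8
        )
        probes, design, _ = make_expression_dataset(spec)
        recs = ex.fold_changes(ex.summarize_probes(probes), design)
        by_key = {(r.transcript_id, r.timepoint): r.fold_change for r in recs}
        assert by_key[("TX0001", 24)] == pytest.approx(-2.0, abs=0.35)
        assert by_key[("TX0002", 24)] == pytest.approx(-2.0, abs=0.35)
        # the same transcripts are null at the other time points
        assert abs(by_key[("TX0001", 12)]) < 1.3

    def test_null_dataset_yields_no_calls(self):
        spec = ExpressionSpec(n_transcripts=60, rng_seed=9)
        probes, design, _ = make_expression_dataset(spec)
        recs = ex.fold_changes(ex.summarize_probes(probes), design)
        assert ex.select_regulated(recs, 1.5)["union"] == []

    def test_qpcr_round_trip_zero_noise(self):
        ct, truth = make_qpcr({"s": 1.7}, noise_sd=0.0, rng_seed=0)
        out = ex.relative_expression_ddct(ct)
        assert out["relative_expression"] == pytest.approx(2.0**-1.7)
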