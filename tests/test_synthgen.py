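"""Generator contracts: determinism, ground-truth agreement, planted effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from mirtraffic import expression as ex
from mirtraffic.seedscan import count_by_region, scan_sequence
from mirtraffic.synthgen import (
    Condition,
    ExpressionSpec,
    NucleiFieldSpec,
    PlantedSites,
    ScreenSpec,
    TranscriptomeSpec,
    make_expression_dataset,
    make_nuclei_field,
    make_qpcr,
    make_transcriptome,
    make_uptake_screen,
)
from mirtraffic.synthgen.screen import default_conditions, well_measurements


class TestNucleiField:
    def test_requested_count_of_connected_components(self):
        _, truth = make_nuclei_field(
            NucleiFieldSpec(n_cells=10, image_shape=(256, 256), rng_seed=1)
        )
        assert truth.n_nuclei == 10
        _, n = ndimage.label(truth.label_mask > 0)
        assert n == 10  # interphase nuclei are single blobs

    def test_seeded_determinism_bit_identical(self):
        spec = NucleiFieldSpec(n_cells=12, image_shape=(256, 256), rng_seed=9)
        f1, g1 = make_nuclei_field(spec)
        f2, g2 = make_nuclei_field(spec)
        assert np.array_equal(f1.channels["nuclei"], f2.channels["nuclei"])
        assert np.array_equal(g1.label_mask, g2.label_mask)
        assert g1.classes == g2.classes

    def test_class_mix_follows_binomial_sampling(self):
        _, truth = make_nuclei_field(
            NucleiFieldSpec(
                n_cells=200,
                image_shape=(1500, 1500),
                class_mix=(0.5, 0.5, 0.0, 0.0),
                rng_seed=3,
            )
        )
        n_inter = truth.classes.count("interphase")
        # within 4 binomial SDs of 100
        assert abs(n_inter - 100) < 4 * np.sqrt(200 * 0.25)
        assert truth.classes.count("apoptosis") == 0

    def test_nuclei_do_not_overlap(self):
        _, truth = make_nuclei_field(
            NucleiFieldSpec(
                n_cells=40, image_shape=(512, 512), class_mix=(0.25, 0.25, 0.25, 0.25), rng_seed=4
            )
        )
        # every labeled pixel belongs to exactly one label by construction;
        # check labels are spatially coherent: no label pixel adjacent to a
        # different nonzero label
        mask = truth.label_mask
        for shift in ((0, 1), (1, 0)):
            a = mask[: mask.shape[0] - shift[0], : mask.shape[1] - shift[1]]
            b = mask[shift[0] :, shift[1] :]
            touching = (a > 0) & (b > 0) & (a != b)
            assert not touching.any()

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError):
            NucleiFieldSpec(class_mix=(0.5, 0.5, 0.5, 0.0))
        with pytest.raises(ValueError):
            NucleiFieldSpec(image_shape=(32, 32))


class TestUptakeScreen:
    def test_negative_control_wells_near_control_median(self):
        spec = ScreenSpec(default_conditions(), rng_seed=0)
        cells, platemap, truth = make_uptake_screen(spec)
        nc = truth[truth.condition == "neg_ctrl"]["true_median"]
        assert nc.mean() == pytest.approx(1000.0, rel=0.05)

    def test_replicate_structure_and_determinism(self):
        spec = ScreenSpec(default_conditions({"m": -2.0}), rng_seed=7)
        c1, p1, t1 = make_uptake_screen(spec)
        c2, p2, t2 = make_uptake_screen(spec)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(p1, p2)
        assert set(p1.replicate) == {1, 2, 3}

    def test_well_count_matches_layout(self):
        conds = [
            Condition("nc", "negative_control", 0.0, n_wells=4),
            Condition("t", "test", -1.0, n_wells=2),
        ]
        spec = ScreenSpec(conds, replicates=2, rng_seed=1)
        _, platemap, _ = make_uptake_screen(spec)
        assert len(platemap) == spec.n_wells == 12

    def test_requires_negative_controls(self):
        with pytest.raises(ValueError):
            ScreenSpec([Condition("t", "test", -1.0)], rng_seed=0)

    def test_negative_controls_must_be_null(self):
        with pytest.raises(ValueError):
            Condition("nc", "negative_control", -1.0)


class TestTranscriptome:
    def test_planted_counts_found_by_scan(self):
        spec = TranscriptomeSpec(
            n_transcripts=4,
            planted_sites=[PlantedSites("TX0001", "utr3", 5)],
            rng_seed=1,
        )
        models, regions, truth = make_transcriptome(spec)
        rc = count_by_region(models[0], "GCACUUU")
        assert rc.counts["utr3"] == 5
        assert rc.total() == 5

    def test_truth_coordinates_equal_scan_offsets(self):
        spec = TranscriptomeSpec(
            n_transcripts=5,
            planted_sites=[
                PlantedSites("TX0001", "utr3", 3),
                PlantedSites("TX0002", "cds", 2),
                PlantedSites("TX0003", "utr5", 1),
            ],
            rng_seed=6,
        )
        models, _, truth = make_transcriptome(spec)
        for m in models:
            found = sorted(s for s, _, _ in scan_sequence(m.sequence, "GCACUUU"))
            planted = sorted(truth[truth.transcript_id == m.transcript_id]["start"])
            assert found == planted

    def test_pos1_mismatch_site_has_non_g_first_base(self):
        spec = TranscriptomeSpec(
            n_transcripts=1,
            planted_sites=[PlantedSites("TX0001", "utr3", 1, allow_pos1_mismatch=True)],
            rng_seed=2,
        )
        _, _, truth = make_transcriptome(spec)
        site = truth.iloc[0]["site"]
        assert site[1:] == "CACUUU" and site[0] != "G"
        assert truth.iloc[0]["pos1_mismatch"]

    def test_background_free_of_core_when_nothing_planted(self):
        spec = TranscriptomeSpec(n_transcripts=6, rng_seed=3)
        models, _, truth = make_transcriptome(spec)
        assert truth.empty
        for m in models:
            assert scan_sequence(m.sequence, "GCACUUU") == []

    def test_determinism(self):
        spec = TranscriptomeSpec(n_transcripts=3, rng_seed=5)
        m1, r1, t1 = make_transcriptome(spec)
        m2, r2, t2 = make_transcriptome(spec)
        assert [a.sequence for a in m1] == [b.sequence for b in m2]
        pd.testing.assert_frame_equal(r1, r2)

    def test_overfull_region_rejected(self):
        with pytest.raises(ValueError):
            TranscriptomeSpec(
                region_length_ranges={"utr3": (30, 40)},
                planted_sites=[PlantedSites("TX0001", "utr3", 6)],
            )

    def test_cds_length_multiple_of_three(self):
        models, regions, _ = make_transcriptome(TranscriptomeSpec(n_transcripts=5, rng_seed=8))
        cds = regions[regions.region == "cds"]
        assert ((cds.end - cds.start) % 3 == 0).all()


class TestExpressionDataset:
    def test_zero_outlier_rate_no_gross_removals(self):
        # a bare 2.5x(unscaled MAD) cut trims ~9% of well-behaved lognormal
        # values (ordinary tails), but none of the removals are gross
        # outliers and the retained mean stays unbiased
        spec = ExpressionSpec(n_transcripts=30, outlier_probe_rate=0.0, rng_seed=4)
        probes, design, _ = make_expression_dataset(spec)
        col = design["array"].iloc[0]
        total = removed = gross = 0
        for _, grp in probes.groupby("transcript_id"):
            vals = grp[col].to_numpy()
            kept = ex.filter_outlier_probes(vals)
            dropped = len(vals) - len(kept)
            total += len(vals)
            removed += dropped
            med = np.median(vals)
            gross += int(np.sum(np.abs(vals / med) > 3) - np.sum(np.abs(kept / med) > 3))
            assert kept.mean() == pytest.approx(vals.mean(), rel=0.1)
        assert removed / total < 0.15
        assert gross == 0  # nothing beyond 3x the median existed or survived

    def test_duplicate_arrays_per_condition(self):
        spec = ExpressionSpec(n_transcripts=5, rng_seed=0)
        _, design, _ = make_expression_dataset(spec)
        counts = design.groupby(["condition", "timepoint"]).size()
        assert (counts == 2).all()

    def test_planted_truth_recorded(self):
        spec = ExpressionSpec(
            n_transcripts=5, planted_fold_changes={("TX0001", 12): 0.5}, rng_seed=0
        )
        _, _, truth = make_expression_dataset(spec)
        row = truth[(truth.transcript_id == "TX0001") & (truth.timepoint == 12)]
        assert row["planted_fold"].iloc[0] == 0.5
        assert (truth[truth.transcript_id == "TX0002"]["planted_fold"] == 1.0).all()

    def test_determinism(self):
        spec = ExpressionSpec(n_transcripts=10, rng_seed=2)
        p1, d1, t1 = make_expression_dataset(spec)
        p2, d2, t2 = make_expression_dataset(spec)
        pd.testing.assert_frame_equal(p1, p2)

    def test_minimum_probes_enforced(self):
        with pytest.raises(ValueError):
            ExpressionSpec(probes_per_transcript=0)
        with pytest.raises(ValueError):
            ExpressionSpec(replicates=1)


class TestQpcr:
    @pytest.mark.parametrize("ddct,expected", [(0.0, 1.0), (1.0, 0.5), (-1.0, 2.0)])
    def test_zero_noise_closed_form(self, ddct, expected):
        ct, truth = make_qpcr({"s": ddct}, noise_sd=0.0)
        out = ex.relative_expression_ddct(ct)
        assert out["relative_expression"] == pytest.approx(expected)
        assert truth["relative_expression"].iloc[0] == pytest.approx(expected)

    def test_noise_perturbs_but_centers_on_truth(self):
        vals = []
        for seed in range(40):
            ct, _ = make_qpcr({"s": 1.0}, noise_sd=0.2, rng_seed=seed)
            vals.append(ex.relative_expression_ddct(ct)["delta_delta_ct"])
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)
        assert np.std(vals) > 0

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            make_qpcr({"s": 0.0}, noise_sd=-1.0)


class TestScreenScoreCalibration:
    def test_mean_score_over_many_wells_converges_to_planted_effect(self):
        from mirtraffic import screenstats as ss

        for effect in (-3.0, 0.0, 1.5):
            means = []
            for seed in range(3):
                conds = [
                    Condition("nc", "negative_control", 0.0, n_wells=60),
                    Condition("t", "test", effect, n_wells=100),
                ]
                spec = ScreenSpec(conds, replicates=1, rng_seed=200 + seed)
                cells, _, _ = make_uptake_screen(spec)
                scores = ss.normalize_experiments(well_measurements(cells))
                means.append(np.mean([s.score for s in scores if s.condition == "t"]))
            assert np.mean(means) == pytest.approx(effect, abs=0.3)
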