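"""Focus-to-cell assignment, positivity calls, applicability rule, cell table."""

import numpy as np
import pandas as pd
import pytest

from conftest import as_image, easy_scene, half_amp_tolerance
from fociquant import (
    ChannelSpec,
    DetectionParams,
    FocusSet,
    NucleusLabelMap,
    applicability_check,
    assign_foci,
    build_cell_table,
    call_positive,
    detect_foci,
    dilate_labels,
    segment_nuclei,
)
from fociquant.quantify import REASON_LOW_EXPRESSION, REASON_NOT_SEPARABLE
from fociquant.simulate import match_cells


def toy_cells():
    lab = np.zeros((20, 40), dtype=np.int32)
    lab[4:12, 4:12] = 1
    lab[4:12, 24:32] = 2
    return dilate_labels(NucleusLabelMap(lab), 0)


class TestAssignFoci:
    def test_three_foci_in_one_territory(self):
        cells = toy_cells()
        fs = FocusSet("p", [(5, 5, 1.0), (6, 8, 1.0), (10, 10, 1.0)], image_shape=(20, 40))
        counts, strays = assign_foci(fs, cells)
        assert counts.tolist() == [3, 0] and strays == 0

    def test_background_focus_is_stray(self):
        cells = toy_cells()
        fs = FocusSet("p", [(1, 1, 1.0)], image_shape=(20, 40))
        counts, strays = assign_foci(fs, cells)
        assert counts.tolist() == [0, 0] and strays == 1

    def test_shape_mismatch_rejected(self):
        fs = FocusSet("p", [(0, 0, 1.0)], image_shape=(8, 8))
        with pytest.raises(ValueError):
            assign_foci(fs, toy_cells())

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_conservation_on_simulated_scenes(self, seed):
        """Per channel: sum of per-cell counts plus strays equals total foci."""
        spec = ChannelSpec("p", zero_inflation=0.3, mean_count=4.0, stray_rate=3.0)
        scene = easy_scene(seed=seed, n_nuclei=8, size=180, channels=(spec,))
        nuclei = segment_nuclei(as_image(scene.stack[0]))
        cells = dilate_labels(nuclei, 3)
        fs = detect_foci(as_image(scene.stack[1]), DetectionParams(tolerance=10.0))
        counts, strays = assign_foci(fs, cells)
        assert counts.sum() + strays == len(fs)

    def test_per_cell_counts_recover_ground_truth(self):
        scene = easy_scene(seed=31)
        nuclei = segment_nuclei(as_image(scene.stack[0]))
        cells = dilate_labels(nuclei, 3)
        spec = scene.config.channels[0]
        fs = detect_foci(
            as_image(scene.stack[1]), DetectionParams(tolerance=half_amp_tolerance(spec))
        )
        counts, _ = assign_foci(fs, cells)
        mapping = match_cells(scene.ground_truth, nuclei.labels)
        truth = scene.ground_truth.counts_map()
        exact = [
            counts[lab - 1] == truth[(cid, "probeA")] for lab, cid in mapping.items()
        ]
        assert np.mean(exact) >= 0.98


class TestCallPositive:
    def test_three_or_more_is_positive(self):
        assert call_positive([2])[0] == False  # noqa: E712
        assert call_positive([3])[0] == True  # noqa: E712
        assert call_positive([0])[0] == False  # noqa: E712

    def test_exhaustive_against_rule(self):
        ks = np.arange(0, 51)
        np.testing.assert_array_equal(call_positive(ks), ks >= 3)

    def test_threshold_below_one_rejected(self):
        with pytest.raises(ValueError):
            call_positive([1], threshold=0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            call_positive(np.array([-1]))

    def test_threshold_monotonicity(self, rng):
        counts = rng.poisson(4, size=500)
        n_pos = [call_positive(counts, t).sum() for t in range(1, 10)]
        assert n_pos == sorted(n_pos, reverse=True)

    def test_population_positive_fraction_matches_zip_tail(self):
        """call_positive over planted counts reproduces the closed-form
        P(K >= 3) of the zero-inflated law within 3 standard errors."""
        from fociquant import zip_tail_ge

        pi, lam = 0.2, 5.0
        flags = []
        for seed in range(25):
            scene = easy_scene(
                seed=200 + seed,
                channels=(ChannelSpec("p", zero_inflation=pi, mean_count=lam),),
            )
            counts = scene.ground_truth.true_counts["count"].to_numpy()
            flags.extend(call_positive(counts))
        flags = np.asarray(flags, dtype=float)
        p = zip_tail_ge(3, pi, lam)
        se = np.sqrt(p * (1 - p) / flags.size)
        assert abs(flags.mean() - p) <= 3 * se


def make_table(counts, region="r1", channel="p"):
    counts = np.asarray(counts)
    return pd.DataFrame(
        {
            "cell_id": np.arange(1, counts.size + 1),
            "region": region,
            f"count_{channel}": counts,
            f"positive_{channel}": counts >= 3,
        }
    )


class TestApplicability:
    def test_high_expression_quantifiable(self):
        verdict = applicability_check(make_table([5] * 10), "p", "r1")
        assert verdict.quantifiable and verdict.reasons == ()

    def test_mean_just_below_four_not_quantifiable(self):
        verdict = applicability_check(make_table([4] * 9 + [3]), "p", "r1")
        assert verdict.mean_dots_per_cell == pytest.approx(3.9)
        assert not verdict.quantifiable
        assert verdict.reasons == (REASON_LOW_EXPRESSION,)

    def test_separability_failure_overrides_high_expression(self):
        verdict = applicability_check(
            make_table([10] * 10), "p", "r1", separability=False
        )
        assert not verdict.quantifiable
        assert verdict.reasons == (REASON_NOT_SEPARABLE,)

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError):
            applicability_check(make_table([5] * 10), "nope", "r1")

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            applicability_check(make_table([5] * 10), "p", "elsewhere")


class TestBuildCellTable:
    def test_counts_and_flags(self):
        cells = toy_cells()
        fs = FocusSet(
            "p", [(5, 5, 1.0), (6, 8, 1.0), (10, 10, 1.0)], image_shape=(20, 40)
        )
        table = build_cell_table(cells, [fs])
        assert table["count_p"].tolist() == [3, 0]
        assert table["positive_p"].tolist() == [True, False]
        assert table["cell_id"].tolist() == [1, 2]

    def test_centroid_outside_every_region_gives_none(self):
        cells = toy_cells()
        region = {"left": np.zeros((20, 40), dtype=bool)}
        region["left"][:, :16] = True
        table = build_cell_table(cells, [], regions=region)
        assert table["region"].tolist() == ["left", None]

    def test_overlapping_region_masks_rejected_by_name(self):
        cells = toy_cells()
        a = np.zeros((20, 40), dtype=bool)
        b = np.zeros((20, 40), dtype=bool)
        a[:, :20] = True
        b[:, 15:] = True
        with pytest.raises(ValueError, match="alpha.*beta"):
            build_cell_table(cells, [], regions={"alpha": a, "beta": b})

    def test_rebuild_is_bit_identical(self):
        scene = easy_scene(seed=41, n_nuclei=10, size=200)
        nuclei = segment_nuclei(as_image(scene.stack[0]))
        cells = dilate_labels(nuclei, 3)
        fs = detect_foci(as_image(scene.stack[1]), DetectionParams(tolerance=10.0))
        t1 = build_cell_table(cells, [fs])
        t2 = build_cell_table(cells, [fs])
        pd.testing.assert_frame_equal(t1, t2)
        assert t1.to_csv() == t2.to_csv()

    def test_full_scene_positivity_matches_ground_truth(self):
        """Three channels, easy regime: flags agree with planted truth for
        >= 98% of (cell, channel) pairs."""
        specs = (
            ChannelSpec("ch1", zero_inflation=0.2, mean_count=5.0),
            ChannelSpec("ch2", zero_inflation=0.5, mean_count=4.0),
            ChannelSpec("ch3", zero_inflation=0.8, mean_count=6.0),
        )
        scene = easy_scene(seed=51, n_nuclei=50, channels=specs)
        nuclei = segment_nuclei(as_image(scene.stack[0]))
        cells = dilate_labels(nuclei, 3)
        focus_sets = [
            detect_foci(
                as_image(scene.stack[i + 1], spec.name),
                DetectionParams(tolerance=half_amp_tolerance(spec)),
            )
            for i, spec in enumerate(specs)
        ]
        table = build_cell_table(cells, focus_sets)
        mapping = match_cells(scene.ground_truth, nuclei.labels)
        truth = scene.ground_truth.positive_map()
        agree = [
            bool(row[f"positive_{spec.name}"]) == truth[(mapping[row.cell_id], spec.name)]
            for _, row in table.iterrows()
            if row.cell_id in mapping
            for spec in specs
        ]
        assert len(agree) >= 0.9 * 3 * 50
        assert np.mean(agree) >= 0.98
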