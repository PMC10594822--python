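import numpy as np
import pandas as pd
import pytest

from neuromorph import Manifest, ValidationError, aggregate_timecourse, summarize_image
from neuromorph.attachment import AttachmentPointSet
from neuromorph.morphometry import MotifRecord
from neuromorph.pipeline import process_image
from neuromorph.summarize import summaries_to_table


def _motif(cls, length=10.0, area=100.0, circ=0.9, ar=1.2):
    return MotifRecord(
        label=1, area=area, perimeter=30.0, circularity=circ, major_axis=10.0,
        minor_axis=10.0 / ar, aspect_ratio=ar, length=length, centroid=(0.0, 0.0),
        motif_class=cls,
    )


def _summary(image_id, n_cb=1, lengths=(40.0, 60.0), n_att=2):
    cbs = [_motif("cell_body") for _ in range(n_cb)]
    nrs = [_motif("neurite", length=l) for l in lengths]
    att = AttachmentPointSet(np.zeros((2, 2), bool), [], n_att)
    return summarize_image(image_id, cbs, nrs, att)


def _manifest(entries):
    return Manifest(pd.DataFrame(
        [{"path": f"{i}.tif", "well_id": w, "area_id": a, "time_h": t, "condition": c}
         for i, (w, a, t, c) in entries.items()]
    ))


class TestSummarizeImage:
    def test_zero_neurites_mean_absent_not_zero(self):
        s = summarize_image("img", [_motif("cell_body")], [], None)
        assert s.n_neurites == 0
        assert s.mean_neurite_length is None
        # absent means serialize to empty CSV cells
        table = summaries_to_table([s])
        assert np.isnan(table.loc[0, "mean_neurite_length"])

    def test_mean_of_two_lengths(self):
        s = _summary("img", lengths=(40.0, 60.0))
        assert s.mean_neurite_length == 50.0

    def test_rejected_records_excluded(self):
        s = summarize_image("img", [_motif("rejected")], [_motif("rejected")], None)
        assert s.n_cell_bodies == 0 and s.n_neurites == 0

    def test_full_scene_matches_ground_truth_aggregates(self, junction_scene, criteria):
        image, truth = junction_scene
        res = process_image(image, criteria, image_id="scene")
        s = res.summary
        assert s.n_cell_bodies == truth.n_somata
        assert s.n_neurites == len(truth.neurites)
        assert s.n_attachment_points == truth.n_junctions
        true_mean_len = truth.neurites["length"].mean()
        assert s.mean_neurite_length == pytest.approx(true_mean_len, rel=0.10)


class TestAggregateTimecourse:
    def test_three_replicates_mean_two_sd_one(self):
        summaries = [_summary(str(i), n_att=v) for i, v in enumerate((1, 2, 3))]
        manifest = _manifest({0: ("W1", "A1", 0.0, "ctrl"), 1: ("W2", "A1", 0.0, "ctrl"),
                              2: ("W3", "A1", 0.0, "ctrl")})
        out = aggregate_timecourse(summaries, manifest)
        row = out[out.metric == "n_attachment_points"].iloc[0]
        assert row["mean"] == 2.0 and row["sd"] == 1.0 and row["n"] == 3

    def test_single_well_sd_absent(self):
        out = aggregate_timecourse([_summary("0")], _manifest({0: ("W1", "A1", 0.0, "c")}))
        assert out["n"].eq(1).all()
        assert out["sd"].isna().all()

    def test_identical_replicates_sd_zero(self):
        summaries = [_summary(str(i)) for i in range(3)]
        manifest = _manifest({i: (f"W{i}", "A1", 0.0, "c") for i in range(3)})
        out = aggregate_timecourse(summaries, manifest)
        assert out["sd"].eq(0).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        summaries = [_summary(str(i), n_att=int(v)) for i, v in
                     enumerate(rng.integers(0, 9, size=6))]
        manifest = _manifest({i: (f"W{i % 3}", f"A{i // 3}", 12.0, "ctrl") for i in range(6)})
        ref = aggregate_timecourse(summaries, manifest)
        for _ in range(10):
            order = rng.permutation(len(summaries))
            shuffled = [summaries[i] for i in order]
            pd.testing.assert_frame_equal(aggregate_timecourse(shuffled, manifest), ref)

    def test_two_stage_matches_hand_computation(self):
        # 3 wells × 8 areas with a seeded metric draw: average areas within
        # each well first, then mean/sd (n−1) across the three well means.
        rng = np.random.default_rng(55)
        values = rng.integers(0, 20, size=(3, 8))
        summaries, rows = [], {}
        k = 0
        for w in range(3):
            for a in range(8):
                summaries.append(_summary(str(k), n_att=int(values[w, a])))
                rows[k] = (f"W{w}", f"A{a}", 24.0, "ctrl")
                k += 1
        out = aggregate_timecourse(summaries, _manifest(rows))
        row = out[out.metric == "n_attachment_points"].iloc[0]
        well_means = values.mean(axis=1)
        assert row["mean"] == pytest.approx(well_means.mean())
        assert row["sd"] == pytest.approx(well_means.std(ddof=1))
        assert row["n"] == 3
        # pooling all 24 areas instead is the group_by="area" alternative
        out_area = aggregate_timecourse(summaries, _manifest(rows), group_by="area")
        row_a = out_area[out_area.metric == "n_attachment_points"].iloc[0]
        assert row_a["n"] == 24
        assert row_a["mean"] == pytest.approx(values.mean())

    def test_orphan_summary_rejected_with_listing(self):
        with pytest.raises(ValidationError, match="orphan|not present"):
            aggregate_timecourse([_summary("ghost")], _manifest({0: ("W1", "A1", 0.0, "c")}))
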