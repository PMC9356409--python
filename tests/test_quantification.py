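import logging
import math

import numpy as np
import pandas as pd
import pytest
from skimage import draw

from _oracles import cylinder_volume, sphere_volume
from budtrack.data_model import AnnotationTable, LabelFrame
from budtrack.quantification import (
    align_at_bud_emergence,
    combine_mother_bud,
    estimate_volume,
    fluor_metrics,
    metrics_table,
    volumes_frame,
)
from conftest import disk_mask


def _row(frame_i, cell, stage="G1", gen=2, rel=-1, relationship="mother",
         emerg=-1, division=-1, history=True):
    return dict(
        frame_i=frame_i, Cell_ID=cell, cell_cycle_stage=stage, generation_num=gen,
        relative_ID=rel, relationship=relationship, emerg_frame_i=emerg,
        division_frame_i=division, is_history_known=history,
    )


class TestEstimateVolume:
    def test_disk_matches_sphere(self):
        mask = disk_mask((64, 64), (32, 32), 20)
        v = estimate_volume(mask).volume_vox
        assert v == pytest.approx(sphere_volume(20), rel=0.02)

    def test_rectangle_matches_cylinder(self):
        mask = np.zeros((50, 50), bool)
        mask[10:40, 10:21] = True  # 30 tall x 11 wide
        v = estimate_volume(mask).volume_vox
        assert v == pytest.approx(cylinder_volume(5.5, 30), rel=0.03)

    def test_single_pixel(self):
        v = estimate_volume(np.ones((1, 1), bool)).volume_vox
        assert v == pytest.approx(math.pi * 0.25)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            estimate_volume(np.zeros((5, 5), bool))

    @pytest.mark.parametrize("k", [2, 3])
    def test_cubic_scaling(self, k):
        base = disk_mask((64, 64), (32, 32), 10)
        scaled = disk_mask((64 * k, 64 * k), (32 * k, 32 * k), 10 * k)
        v1 = estimate_volume(base).volume_vox
        vk = estimate_volume(scaled).volume_vox
        assert vk / v1 == pytest.approx(k**3, rel=0.05)

    @pytest.mark.parametrize("angle", [15, 37, 60, 80])
    def test_rotation_invariance_of_ellipse(self, angle):
        def ellipse(rot):
            img = np.zeros((201, 201), bool)
            rr, cc = draw.ellipse(100, 100, 40, 25, rotation=math.radians(rot))
            img[rr, cc] = True
            return img

        v0 = estimate_volume(ellipse(0)).volume_vox
        v = estimate_volume(ellipse(angle)).volume_vox
        assert abs(v - v0) / v0 < 0.03

    def test_femtolitre_conversion_is_cubic_in_pixel_size(self):
        mask = disk_mask((64, 64), (32, 32), 10)
        v = estimate_volume(mask, pixel_size_um=0.1095)
        assert v.volume_fl == pytest.approx(v.volume_vox * 0.1095**3)


class TestFluorMetrics:
    def _frame_and_intensity(self):
        img = np.zeros((20, 20), np.int32)
        img[5:10, 5:10] = 1  # 25 px cell
        intensity = np.full((20, 20), 100.0)
        intensity[img == 1] = 300.0
        return LabelFrame(img), intensity

    def test_constant_cell_on_constant_background(self):
        labels, intensity = self._frame_and_intensity()
        m = fluor_metrics(labels, intensity)[1]
        assert m.bg_median == 100.0
        assert m.corrected_mean == 200.0
        assert m.amount == 5000.0
        assert m.amount == m.corrected_mean * m.area

    def test_cell_equal_to_background_has_zero_amount(self):
        labels, _ = self._frame_and_intensity()
        m = fluor_metrics(labels, np.full((20, 20), 7.0))[1]
        assert m.amount == 0.0

    def test_concentration_is_amount_over_voxel_volume(self):
        labels, intensity = self._frame_and_intensity()
        vols = volumes_frame(labels)
        m = fluor_metrics(labels, intensity, vols)[1]
        assert m.concentration == pytest.approx(5000.0 / vols[1].volume_vox)

    def test_offset_invariance_is_exact(self):
        labels, intensity = self._frame_and_intensity()
        base = fluor_metrics(labels, intensity)[1]
        shifted = fluor_metrics(labels, intensity + 123.456)[1]
        # the offset cancels up to float64 rounding of the shifted values
        assert shifted.corrected_mean == pytest.approx(base.corrected_mean, rel=1e-12)
        assert shifted.amount == pytest.approx(base.amount, rel=1e-12)

    def test_fully_covered_frame_rejected(self):
        labels = LabelFrame(np.ones((8, 8), np.int32))
        with pytest.raises(ValueError):
            fluor_metrics(labels, np.ones((8, 8)))


class TestCombineMotherBud:
    def _table(self):
        return AnnotationTable.from_rows([
            _row(0, 1),
            _row(1, 1, stage="S/G2/M", rel=2),
            _row(1, 2, stage="S/G2/M", gen=0, rel=1, relationship="bud", emerg=1),
        ])

    def _metrics(self):
        return pd.DataFrame([
            {"frame_i": 0, "Cell_ID": 1, "amount": 4000.0, "volume_vox": 900.0},
            {"frame_i": 1, "Cell_ID": 1, "amount": 5000.0, "volume_vox": 1000.0},
            {"frame_i": 1, "Cell_ID": 2, "amount": 1000.0, "volume_vox": 200.0},
        ])

    def test_pair_amounts_are_summed(self):
        out = combine_mother_bud(self._table(), self._metrics())
        at1 = out[(out.frame_i == 1) & (out.Cell_ID == 1)].iloc[0]
        assert at1["combined_amount"] == 6000.0
        assert at1["combined_volume_vox"] == 1200.0

    def test_g1_frames_pass_through(self):
        out = combine_mother_bud(self._table(), self._metrics())
        at0 = out[(out.frame_i == 0) & (out.Cell_ID == 1)].iloc[0]
        assert at0["combined_amount"] == 4000.0

    def test_total_amount_is_conserved(self):
        metrics = self._metrics()
        out = combine_mother_bud(self._table(), metrics)
        assert out["combined_amount"].sum() == pytest.approx(metrics["amount"].sum())

    def test_colony_conservation(self, colony):
        rng = np.random.default_rng(0)
        rows = []
        for t in range(len(colony.movie)):
            for lab in colony.movie[t].labels:
                rows.append({"frame_i": t, "Cell_ID": int(lab),
                             "amount": float(rng.uniform(10, 100))})
        metrics = pd.DataFrame(rows)
        out = combine_mother_bud(colony.truth_table, metrics)
        # bud amounts folded into mothers: totals match frame by frame
        for t in range(len(colony.movie)):
            assert out[out.frame_i == t]["combined_amount"].sum() == pytest.approx(
                metrics[metrics.frame_i == t]["amount"].sum()
            )


class TestAlignAtBudEmergence:
    def _table(self):
        rows = [_row(f, 1) for f in range(0, 12)]
        rows += [_row(f, 3) for f in range(0, 12)]  # never buds
        for f in range(12, 14):
            rows.append(_row(f, 1, stage="S/G2/M", rel=2))
            rows.append(_row(f, 3))
            rows.append(_row(f, 2, stage="S/G2/M", gen=0, rel=1, relationship="bud", emerg=12))
        return AnnotationTable.from_rows(rows)

    def test_emergence_frame_maps_to_zero(self):
        series = pd.DataFrame(
            [{"frame_i": f, "Cell_ID": 1, "value": f} for f in range(14)]
        )
        out = align_at_bud_emergence(self._table(), series)
        assert int(out.loc[out.frame_i == 12, "t"].iloc[0]) == 0
        assert int(out.loc[out.frame_i == 0, "t"].iloc[0]) == -12

    def test_cells_that_never_bud_are_excluded_and_logged(self, caplog):
        series = pd.DataFrame([
            {"frame_i": 0, "Cell_ID": 1, "value": 1.0},
            {"frame_i": 0, "Cell_ID": 3, "value": 1.0},
        ])
        with caplog.at_level(logging.INFO, logger="budtrack.quantification"):
            out = align_at_bud_emergence(self._table(), series)
        assert set(out["Cell_ID"]) == {1}
        assert any("never buds" in r.message for r in caplog.records)

    def test_two_mothers_align_on_common_axis(self):
        rows = []
        for f in range(0, 10):
            rows.append(_row(f, 1, stage="S/G2/M" if f >= 5 else "G1",
                             rel=10 if f >= 5 else -1))
            rows.append(_row(f, 2, stage="S/G2/M" if f >= 9 else "G1",
                             rel=11 if f >= 9 else -1))
            if f >= 5:
                rows.append(_row(f, 10, stage="S/G2/M", gen=0, rel=1, relationship="bud", emerg=5))
            if f >= 9:
                rows.append(_row(f, 11, stage="S/G2/M", gen=0, rel=2, relationship="bud", emerg=9))
        table = AnnotationTable.from_rows(rows)
        series = pd.DataFrame(
            [{"frame_i": f, "Cell_ID": c, "value": 1.0}
             for f in range(10) for c in (1, 2)]
        )
        out = align_at_bud_emergence(table, series)
        assert int(out.loc[(out.Cell_ID == 1) & (out.frame_i == 5), "t"].iloc[0]) == 0
        assert int(out.loc[(out.Cell_ID == 2) & (out.frame_i == 9), "t"].iloc[0]) == 0


def test_metrics_table_has_volume_columns(colony):
    frame = colony.movie[0]
    intensity = np.full(frame.pixels.shape, 50.0)
    intensity[frame.pixels > 0] = 120.0
    vols = volumes_frame(frame)
    df = metrics_table({0: fluor_metrics(frame, intensity, vols)}, {0: vols})
    assert {"amount", "concentration", "volume_vox", "volume_fl"} <= set(df.columns)
    assert len(df) == len(frame.labels)
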