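"""Per-cell aggregation, QC exclusion rules, and stain gating."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from omiflim import (
    aggregate_cell,
    apply_qc,
    gate_cd56,
    gate_cd69,
    load_masks,
    qc_passed,
    qc_summary,
)
from omiflim.features import FEATURE_COLUMNS, QC_RULES
from omiflim.fitting import DecayCube, PixelFitMap
from omiflim.model import BIN_WIDTH_PS


def _flat_fitmap(shape, tau1=400.0, tau2=2500.0, a1=0.7, a2=0.3, chi2=1.0):
    h, w = shape
    ones = np.ones((h, w))
    tau_m = (a1 * tau1 + a2 * tau2) / (a1 + a2)
    return PixelFitMap(
        tau1=tau1 * ones,
        tau2=tau2 * ones,
        alpha1_raw=a1 * ones,
        alpha2_raw=a2 * ones,
        c_background=0 * ones,
        tau_m=tau_m * ones,
        chi2_reduced=chi2 * ones,
        n_photons=np.full((h, w), 5000, dtype=np.int64),
        converged=np.ones((h, w), dtype=bool),
        valid_mask=np.ones((h, w), dtype=bool),
    )


def _cube(shape, per_pixel_total, n_bins=10):
    h, w = shape
    per_bin = per_pixel_total // n_bins
    return DecayCube(
        np.full((h, w, n_bins), per_bin, dtype=np.int64), BIN_WIDTH_PS
    )


class TestLoadMasks:
    def test_relabels_contiguously(self):
        lab = np.zeros((4, 4), dtype=int)
        lab[0, 0] = 3
        lab[2, 2] = 7
        out, n = load_masks(lab)
        assert n == 2
        assert set(np.unique(out)) == {0, 1, 2}

    def test_empty_image(self):
        out, n = load_masks(np.zeros((4, 4), dtype=int))
        assert n == 0 and out.sum() == 0

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            load_masks(np.full((4, 4), 0.5))


class TestAggregateCell:
    def _setup(self, shape=(6, 6)):
        labels = np.zeros(shape, dtype=int)
        labels[1:4, 1:4] = 1  # 9-pixel cell
        fitmaps = {"nadph": _flat_fitmap(shape), "fad": _flat_fitmap(shape, 350, 2300)}
        return labels, fitmaps

    def test_orr_from_summed_intensities(self):
        labels, fitmaps = self._setup()
        cubes = {"nadph": _cube((6, 6), 80), "fad": _cube((6, 6), 20)}
        rec = aggregate_cell(fitmaps, cubes, labels, 1)
        assert rec.orr == pytest.approx(0.8)

    def test_orr_bounds_when_one_channel_dark(self):
        labels, fitmaps = self._setup()
        rec = aggregate_cell(
            fitmaps, {"nadph": _cube((6, 6), 80), "fad": _cube((6, 6), 0)}, labels, 1
        )
        assert rec.orr == 1.0
        rec = aggregate_cell(
            fitmaps, {"nadph": _cube((6, 6), 0), "fad": _cube((6, 6), 20)}, labels, 1
        )
        assert rec.orr == 0.0

    def test_homogeneous_cell_mean_equals_pixel_value(self):
        labels, fitmaps = self._setup()
        cubes = {"nadph": _cube((6, 6), 80), "fad": _cube((6, 6), 20)}
        rec = aggregate_cell(fitmaps, cubes, labels, 1)
        assert rec.nadph_tau_m == pytest.approx(1030.0)
        assert rec.area_px == 9
        assert rec.mean_nadph_intensity == pytest.approx(80.0)

    def test_no_valid_pixels_flagged(self):
        labels, fitmaps = self._setup()
        for fm in fitmaps.values():
            fm.valid_mask[:] = False
        cubes = {"nadph": _cube((6, 6), 80), "fad": _cube((6, 6), 20)}
        rec = aggregate_cell(fitmaps, cubes, labels, 1)
        assert not rec.qc_pass and rec.qc_reasons == "no-valid-pixels"

    def test_missing_label_rejected(self):
        labels, fitmaps = self._setup()
        cubes = {"nadph": _cube((6, 6), 80), "fad": _cube((6, 6), 20)}
        with pytest.raises(ValueError):
            aggregate_cell(fitmaps, cubes, labels, 99)

    def test_cell_orr_is_intensity_weighted_pixel_orr(self, small_pipeline):
        # sum-then-ratio equals the intensity-weighted mean of pixel ratios
        scene = small_pipeline["scene"]
        n_int = small_pipeline["cubes"]["nadph"].counts.sum(axis=2).astype(float)
        f_int = small_pipeline["cubes"]["fad"].counts.sum(axis=2).astype(float)
        table = small_pipeline["table"]
        for row in table.itertuples():
            mask = scene.label_image == row.cell_id
            tot = n_int[mask] + f_int[mask]
            pix = np.divide(n_int[mask], tot, out=np.zeros_like(tot), where=tot > 0)
            weighted = (pix * tot).sum() / tot.sum()
            assert row.orr == pytest.approx(weighted, abs=1e-12)


def _qc_table(**overrides):
    base = {
        "cell_id": 1,
        "donor": "a",
        "condition": "quiescent",
        "cell_type": "t",
        "area_px": 100,
        "nadph_tau_m": 1000.0,
        "nadph_tau1": 400.0,
        "nadph_tau2": 2500.0,
        "nadph_alpha1": 70.0,
        "fad_tau_m": 900.0,
        "fad_tau1": 350.0,
        "fad_tau2": 2300.0,
        "fad_alpha1": 70.0,
        "orr": 0.5,
        "mean_nadph_intensity": 100.0,
        "chi2_mean": 1.0,
        "chi2_max": 1.0,
        "valid_pixel_frac": 1.0,
        "qc_pass": True,
        "qc_reasons": "",
    }
    base.update(overrides)
    return base


class TestApplyQc:
    @pytest.mark.parametrize(
        "overrides,excluded,reason",
        [
            ({"area_px": 69}, True, "small-mask"),
            ({"area_px": 70}, False, None),
            ({"chi2_mean": 1.31}, True, "poor-fit"),
            ({"chi2_mean": 1.30}, False, None),
            ({"nadph_tau1": 349.0}, True, "short-tau1"),
            ({"nadph_tau1": 350.0}, False, None),
            ({"mean_nadph_intensity": 9.99}, True, "low-intensity"),
            ({"mean_nadph_intensity": 10.0}, False, None),
        ],
    )
    def test_strict_inequality_boundaries(self, overrides, excluded, reason):
        df = apply_qc(pd.DataFrame([_qc_table(**overrides)]))
        assert bool(df.qc_pass[0]) == (not excluded)
        if excluded:
            assert reason in df.qc_reasons[0]

    def test_multiple_reasons_accumulate(self):
        df = apply_qc(pd.DataFrame([_qc_table(area_px=50, chi2_mean=2.0)]))
        assert df.qc_reasons[0] == "small-mask,poor-fit"

    def test_idempotence(self):
        df = pd.DataFrame([_qc_table(), _qc_table(area_px=10, cell_id=2)])
        once = apply_qc(df)
        twice = apply_qc(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_exact_exclusion_counts(self):
        rows = []
        cid = 0
        for k, over in [
            (7, {"area_px": 30}),
            (5, {"chi2_mean": 1.5}),
            (4, {"nadph_tau1": 300.0}),
            (3, {"mean_nadph_intensity": 5.0}),
        ]:
            for _ in range(k):
                cid += 1
                rows.append(_qc_table(cell_id=cid, **over))
        for _ in range(10):
            cid += 1
            rows.append(_qc_table(cell_id=cid))
        df = apply_qc(pd.DataFrame(rows))
        summary = qc_summary(df)
        assert summary["excluded_by_reason"] == {
            "small-mask": 7,
            "poor-fit": 5,
            "short-tau1": 4,
            "low-intensity": 3,
        }
        assert summary["n_pass"] == 10
        assert len(qc_passed(df)) == 10


class TestStainGates:
    def test_cd56_threshold_strictly_above(self):
        df = pd.DataFrame({"cd56_intensity": [99.0, 100.0, 101.0]})
        out = gate_cd56(df, threshold=100.0)
        assert list(out.cd56_bright) == [False, False, True]

    def test_cd56_constructed_ten_percent(self):
        intens = np.concatenate([np.full(90, 50.0), np.full(10, 150.0)])
        out = gate_cd56(pd.DataFrame({"cd56_intensity": intens}), threshold=100.0)
        assert out.attrs["cd56_bright_fraction"] == pytest.approx(0.10)

    def test_cd69_hand_threshold(self):
        q = np.array([8.0, 10.0, 12.0])  # mean 10, sample SD 2
        pos, frac, thr = gate_cd69(np.array([12.9, 13.1, 14.0]), q)
        assert thr == pytest.approx(13.0)
        assert list(pos) == [False, True, True]

    def test_cd69_self_gating_matches_normal_tail(self):
        rng = np.random.default_rng(0)
        q = rng.normal(10, 2, size=100_000)
        _, frac, _ = gate_cd69(q, q)
        assert frac == pytest.approx(sps.norm.sf(1.5), abs=0.01)

    def test_cd69_far_shifted_population_fully_positive(self):
        rng = np.random.default_rng(1)
        q = rng.normal(10, 2, size=1000)
        _, frac, _ = gate_cd69(q + 100, q)
        assert frac == 1.0

    def test_cd69_requires_two_quiescent_cells(self):
        with pytest.raises(ValueError):
            gate_cd69(np.array([1.0]), np.array([1.0]))


def test_pipeline_table_has_documented_columns(small_pipeline):
    assert list(small_pipeline["table"].columns) == FEATURE_COLUMNS
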