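"""Asymmetry classification, frame averaging and non-resected set algebra."""

import numpy as np
import pytest

from perifocal.abnormality import (
    average_frames,
    classify_abnormal,
    contralateral_mean,
    nonresected_abnormality,
    subject_abnormality_profile,
)
from perifocal.phantom import DeficitSpec, make_pet
from perifocal.voi import VOIDefinition, build_voi
from perifocal.volumes import BinaryMask, PETVolume


@pytest.fixture(scope="module")
def voi_masks(phantom_labels):
    return {
        (kind, side): build_voi(phantom_labels, VOIDefinition(kind, side))
        for kind in ("A_H_PH", "TL") for side in ("left", "right")
    }


class TestAverageFrames:
    def test_constant_dynamic_collapses_to_constant(self, small_grid):
        data = np.full((4,) + small_grid.shape, 3.0)
        pet = PETVolume(small_grid, data, tracer="FMZ",
                        frame_times_s=[(0, 10), (10, 20), (20, 30), (30, 40)])
        out = average_frames(pet, 0, 40)
        assert not out.is_dynamic
        np.testing.assert_allclose(out.data, 3.0)

    def test_two_equal_frames_average(self, small_grid):
        data = np.stack([np.full(small_grid.shape, 10.0),
                         np.full(small_grid.shape, 20.0)])
        pet = PETVolume(small_grid, data, tracer="FMZ",
                        frame_times_s=[(0, 60), (60, 120)])
        np.testing.assert_allclose(average_frames(pet, 0, 120).data, 15.0)

    def test_window_weighted_mean_matches_brute_force(self, small_grid, rng):
        n = 16
        data = rng.random((n,) + small_grid.shape) * 100
        times = [(150.0 * i, 150.0 * (i + 1)) for i in range(n)]  # 40-min scan
        pet = PETVolume(small_grid, data, tracer="FMZ", frame_times_s=times)
        out = average_frames(pet, 600.0, 1200.0)
        # independent oracle: explicit overlap-weighted sum per frame
        w = np.array([max(0.0, min(e, 1200.0) - max(s, 600.0)) for s, e in times])
        brute = np.einsum("f,fxyz->xyz", w / w.sum(), data)
        np.testing.assert_allclose(out.data, brute, rtol=1e-12)
        # only frames 4..7 overlap the 10-20 min window
        assert (w > 0).sum() == 4

    def test_empty_window_rejected(self, small_grid):
        data = np.stack([np.zeros(small_grid.shape)] * 2)
        pet = PETVolume(small_grid, data, tracer="FMZ",
                        frame_times_s=[(0, 10), (10, 20)])
        with pytest.raises(ValueError):
            average_frames(pet, 100, 200)
        with pytest.raises(ValueError):
            average_frames(pet, 20, 10)


class TestContralateralMean:
    def test_uniform_and_two_voxel_mean(self, small_grid):
        pet = PETVolume(small_grid, np.full(small_grid.shape, 100.0))
        m = np.zeros(small_grid.shape, bool)
        m[1, 1, 1] = True
        assert contralateral_mean(pet, BinaryMask(small_grid, m)) == 100.0
        vals = np.zeros(small_grid.shape)
        vals[0, 0, 0], vals[0, 0, 1] = 80.0, 120.0
        m2 = np.zeros(small_grid.shape, bool)
        m2[0, 0, 0] = m2[0, 0, 1] = True
        assert contralateral_mean(PETVolume(small_grid, vals),
                                  BinaryMask(small_grid, m2)) == 100.0

    def test_noisy_phantom_mean_close_to_baseline(self, phantom_labels, voi_masks):
        region = BinaryMask(phantom_labels.grid,
                            np.zeros(phantom_labels.grid.shape, bool))
        pet = make_pet(phantom_labels, DeficitSpec("FDG", region, noise_sd=5.0, seed=4))
        contra = voi_masks[("TL", "right")]
        u = contralateral_mean(pet, contra)
        se = 5.0 / np.sqrt(contra.count)
        assert abs(u - 100.0) < 4 * se

    def test_empty_voi_rejected(self, small_grid):
        pet = PETVolume(small_grid, np.ones(small_grid.shape))
        with pytest.raises(ValueError):
            contralateral_mean(pet, BinaryMask(small_grid, np.zeros(small_grid.shape, bool)))


class TestClassifyAbnormal:
    def test_threshold_is_strict(self, small_grid):
        vals = np.full(small_grid.shape, 100.0)
        vals[0, 0, 0], vals[0, 0, 1], vals[0, 0, 2] = 89.0, 91.0, 90.0
        voi = BinaryMask(small_grid, np.ones(small_grid.shape, bool))
        abn = classify_abnormal(PETVolume(small_grid, vals), voi, u_bar=100.0)
        assert abn.data[0, 0, 0]
        assert not abn.data[0, 0, 1]
        assert not abn.data[0, 0, 2]  # exactly 10 % below: normal

    def test_symmetric_noiseless_phantom_empty(self, phantom_labels, voi_masks):
        region = BinaryMask(phantom_labels.grid,
                            np.zeros(phantom_labels.grid.shape, bool))
        pet = make_pet(phantom_labels, DeficitSpec("FDG", region))
        u = contralateral_mean(pet, voi_masks[("TL", "right")])
        abn = classify_abnormal(pet, voi_masks[("TL", "left")], u)
        assert abn.count == 0

    def test_planted_deficit_recovered_exactly(self, phantom_labels, voi_masks):
        region = phantom_labels.structure_mask({"hippocampus", "amygdala"}, "left")
        pet = make_pet(phantom_labels,
                       DeficitSpec("FDG", region, depth_fraction=0.2, noise_sd=0.0))
        u = contralateral_mean(pet, voi_masks[("A_H_PH", "right")])
        abn = classify_abnormal(pet, voi_masks[("A_H_PH", "left")], u)
        expected = region & voi_masks[("A_H_PH", "left")]
        np.testing.assert_array_equal(abn.data, expected.data)

    def test_threshold_monotonicity(self, phantom_labels, voi_masks):
        region = phantom_labels.structure_mask({"hippocampus"}, "left")
        pet = make_pet(phantom_labels,
                       DeficitSpec("FDG", region, depth_fraction=0.3, noise_sd=8.0, seed=2))
        u = contralateral_mean(pet, voi_masks[("TL", "right")])
        prev = None
        for f in (0.05, 0.10, 0.20, 0.40):
            abn = classify_abnormal(pet, voi_masks[("TL", "left")], u, f)
            if prev is not None:
                assert abn.issubset(prev)
            prev = abn

    def test_bad_inputs_rejected(self, small_grid):
        pet = PETVolume(small_grid, np.ones(small_grid.shape))
        voi = BinaryMask(small_grid, np.ones(small_grid.shape, bool))
        with pytest.raises(ValueError):
            classify_abnormal(pet, voi, u_bar=0.0)
        with pytest.raises(ValueError):
            classify_abnormal(pet, voi, u_bar=1.0, threshold_fraction=1.5)


class TestNonresected:
    def test_fully_resected_and_fully_spared(self, small_grid):
        abn = np.zeros(small_grid.shape, bool)
        abn[2:6, 2:6, 2:6] = True
        abn_m = BinaryMask(small_grid, abn)
        res_all = BinaryMask(small_grid, np.ones(small_grid.shape, bool))
        mask, mm3, pct = nonresected_abnormality(abn_m, res_all)
        assert (mask.count, mm3, pct) == (0, 0.0, 0.0)
        res_none = BinaryMask(small_grid, np.zeros(small_grid.shape, bool))
        _, _, pct = nonresected_abnormality(abn_m, res_none)
        assert pct == 100.0

    def test_percentage_arithmetic(self, small_grid, rng):
        abn = np.zeros(small_grid.shape, bool)
        abn.ravel()[rng.choice(abn.size, 1000, replace=False)] = True
        res = np.zeros(small_grid.shape, bool)
        idx = np.flatnonzero(abn.ravel())[:190]
        res.ravel()[idx] = True
        _, mm3, pct = nonresected_abnormality(
            BinaryMask(small_grid, abn), BinaryMask(small_grid, res)
        )
        assert mm3 == 810.0
        assert pct == pytest.approx(81.0)

    def test_empty_abnormality_rejected(self, small_grid):
        empty = BinaryMask(small_grid, np.zeros(small_grid.shape, bool))
        with pytest.raises(ValueError):
            nonresected_abnormality(empty, empty)


class TestSubjectProfile:
    def test_four_records_with_conservation_and_nesting(
        self, phantom_labels, left_resection, voi_masks
    ):
        _, truth = left_resection
        region = phantom_labels.structure_mask(
            {"hippocampus", "amygdala", "parahippocampal"}, "left"
        )
        fdg = make_pet(phantom_labels,
                       DeficitSpec("FDG", region, depth_fraction=0.2, noise_sd=3.0, seed=6))
        fmz = make_pet(phantom_labels,
                       DeficitSpec("FMZ", region, depth_fraction=0.2, noise_sd=3.0, seed=7),
                       n_frames=8)
        profile = subject_abnormality_profile(phantom_labels, truth, fdg, fmz, "left")
        assert set(profile) == {("FDG", "A_H_PH"), ("FDG", "TL"),
                                ("FMZ", "A_H_PH"), ("FMZ", "TL")}
        for res in profile.values():
            assert res.resected_abn_mm3 + res.nonres_abn_mm3 == pytest.approx(res.pre_abn_mm3)
            if res.pre_abn_mm3 > 0:
                assert res.resected_pct + res.nonres_pct == pytest.approx(100.0)
        # abnormal voxels found in the mesial VOI lie inside the TL VOI
        for tracer in ("FDG", "FMZ"):
            inner = profile[(tracer, "A_H_PH")].abn_mask
            assert inner.issubset(voi_masks[("TL", "left")])

    def test_symmetric_phantom_all_records_empty(self, phantom_labels, left_resection):
        _, truth = left_resection
        region = BinaryMask(phantom_labels.grid,
                            np.zeros(phantom_labels.grid.shape, bool))
        fdg = make_pet(phantom_labels, DeficitSpec("FDG", region))
        fmz = make_pet(phantom_labels, DeficitSpec("FMZ", region), n_frames=4)
        profile = subject_abnormality_profile(phantom_labels, truth, fdg, fmz, "left")
        assert all(res.pre_abn_mm3 == 0.0 for res in profile.values())
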