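"""Feature extraction, activation/size indices, densitometry, ΔΔCt."""

import math

import numpy as np
import pandas as pd
import pytest

from gliamorph import (
    BinaryMask,
    GrayImage,
    StainedSection,
    ValidationError,
    activation_index,
    analyze_section,
    ddct_fold_change,
    normalize_to_control,
    optical_density,
    size_index,
    skeleton_length_um,
    stained_area_fraction,
)
from gliamorph.morphometry import _object_perimeter_um


class TestSkeletonLength:
    def test_horizontal_bar_step_rule(self):
        sk = np.zeros((10, 120), bool)
        sk[5, 10:110] = True  # 100 px, 99 orthogonal steps
        assert skeleton_length_um(sk, 0.5) == pytest.approx(99 * 0.5)

    def test_diagonal_bar_step_rule(self):
        sk = np.zeros((120, 120), bool)
        idx = np.arange(100)
        sk[idx + 5, idx + 5] = True  # 99 diagonal steps
        assert skeleton_length_um(sk, 0.5) == pytest.approx(99 * math.sqrt(2) * 0.5)

    def test_empty_skeleton(self):
        assert skeleton_length_um(np.zeros((5, 5), bool), 1.0) == 0.0


class TestFormFactor:
    @pytest.mark.parametrize("radius,lo,hi", [(20, 0.90, 1.05), (40, 0.92, 1.05), (80, 0.95, 1.05)])
    def test_disk_form_factor_windows(self, radius, lo, hi):
        n = 2 * radius + 9
        rr, cc = np.mgrid[:n, :n]
        disk = (rr - n // 2) ** 2 + (cc - n // 2) ** 2 <= radius**2
        area = disk.sum()
        perim = _object_perimeter_um(disk, 1.0)
        ff = 4 * math.pi * area / perim**2
        assert lo <= ff <= hi

    def test_form_factor_approaches_one_with_radius(self):
        ffs = []
        for radius in (20, 40, 80):
            n = 2 * radius + 9
            rr, cc = np.mgrid[:n, :n]
            disk = (rr - n // 2) ** 2 + (cc - n // 2) ** 2 <= radius**2
            perim = _object_perimeter_um(disk, 1.0)
            ffs.append(4 * math.pi * disk.sum() / perim**2)
        assert abs(1 - ffs[2]) <= abs(1 - ffs[0])


class TestOpticalDensity:
    def test_tenfold_contrast_gives_unit_od(self):
        gray = GrayImage(np.full((10, 10), 250.0), 1.0)
        obj = np.zeros((10, 10), bool)
        obj[2:4, 2:4] = True
        gray.pixels[obj] = 25.0
        od = optical_density(gray, obj, obj, np.ones((10, 10), bool))
        assert od == pytest.approx(1.0, abs=1e-12)

    def test_equal_means_give_zero(self):
        gray = GrayImage(np.full((6, 6), 100.0), 1.0)
        obj = np.zeros((6, 6), bool)
        obj[0, 0] = True
        assert optical_density(gray, obj, obj, np.ones((6, 6), bool)) == 0.0

    def test_random_masks_match_arithmetic(self, rng):
        gray = GrayImage(rng.uniform(10, 250, (20, 20)), 1.0)
        obj = rng.random((20, 20)) < 0.2
        excl = obj | (rng.random((20, 20)) < 0.1)
        tissue = np.ones((20, 20), bool)
        if not obj.any() or not (~excl).any():
            pytest.skip("degenerate draw")
        expected = math.log10(gray.pixels[~excl].mean() / gray.pixels[obj].mean())
        assert optical_density(gray, obj, excl, tissue) == pytest.approx(expected, abs=1e-12)

    def test_empty_background_rejected(self):
        gray = GrayImage(np.full((4, 4), 100.0), 1.0)
        obj = np.ones((4, 4), bool)
        with pytest.raises(ValidationError):
            optical_density(gray, obj, obj, np.ones((4, 4), bool))


def _cells(rows):
    return pd.DataFrame(rows, columns=["soma_area_um2", "proximal_area_um2", "distal_area_um2"])


class TestIndices:
    def test_activation_arithmetic(self):
        cells = _cells([[100.0, 50.0, 75.0]])
        assert activation_index(cells) == pytest.approx(2.0)

    def test_activation_undefined_without_distal(self):
        assert math.isnan(activation_index(_cells([[100.0, 50.0, 0.0]])))
        assert math.isnan(activation_index(_cells([])))

    def test_size_index_arithmetic(self):
        cells = _cells([[100.0, 50.0, 0.0], [100.0, 50.0, 0.0]])
        assert size_index(cells) == pytest.approx(150.0)
        assert math.isnan(size_index(_cells([])))

    def test_indices_invariant_to_translation_and_rotation(self, small_analysis):
        section, _, analysis = small_analysis
        base = (activation_index(analysis.cells), size_index(analysis.cells))
        shifted = np.full_like(section.pixels, 255)
        shifted[8:, 8:] = section.pixels[:-8, :-8]
        a_t = analyze_section(StainedSection(shifted, section.calibration))
        assert activation_index(a_t.cells) == pytest.approx(base[0], rel=1e-9)
        assert size_index(a_t.cells) == pytest.approx(base[1], rel=1e-9)
        rotated = np.ascontiguousarray(np.rot90(section.pixels))
        a_r = analyze_section(StainedSection(rotated, section.calibration))
        # thinning is not exactly rotation-equivariant; indices agree closely
        assert activation_index(a_r.cells) == pytest.approx(base[0], rel=0.05)
        assert size_index(a_r.cells) == pytest.approx(base[1], rel=0.05)


class TestStainedArea:
    def test_unstained_roi(self):
        gray = GrayImage(np.full((20, 20), 250.0), 0.5)
        tissue = BinaryMask(np.ones((20, 20), bool), 0.5)
        frac, intden = stained_area_fraction(gray, tissue, np.ones((20, 20), bool), 100.0)
        assert frac == 0.0 and intden == 0.0

    def test_half_stained_roi(self):
        arr = np.full((20, 20), 250.0)
        arr[:10] = 50.0
        gray = GrayImage(arr, 0.5)
        tissue = BinaryMask(np.ones((20, 20), bool), 0.5)
        frac, intden = stained_area_fraction(gray, tissue, np.ones((20, 20), bool), 100.0)
        assert frac == pytest.approx(0.5)
        assert intden == pytest.approx(200 * (255 - 50) * 0.25)

    def test_matches_pixel_loop_oracle(self, rng):
        arr = rng.uniform(0, 255, (15, 15))
        tissue = rng.random((15, 15)) < 0.8
        roi = rng.random((15, 15)) < 0.7
        if not (tissue & roi).any():
            pytest.skip("degenerate draw")
        frac, intden = stained_area_fraction(
            GrayImage(arr, 0.5), BinaryMask(tissue, 0.5), roi, 128.0
        )
        n_roi = n_stained = 0
        total = 0.0
        for r in range(15):
            for c in range(15):
                if tissue[r, c] and roi[r, c]:
                    n_roi += 1
                    if arr[r, c] <= 128.0:
                        n_stained += 1
                        total += (255.0 - arr[r, c]) * 0.25
        assert frac == pytest.approx(n_stained / n_roi)
        assert intden == pytest.approx(total)


class TestNormalization:
    def test_control_mean_maps_to_one(self):
        vals = [2.0, 4.0, 6.0]
        groups = ["ctrl", "ctrl", "treated"]
        out = normalize_to_control(vals, groups, "ctrl")
        assert out.tolist() == [2 / 3, 4 / 3, 2.0]
        assert out[np.array(groups) == "ctrl"].mean() == pytest.approx(1.0)

    def test_order_invariance(self):
        vals = np.array([5.0, 1.0, 3.0])
        groups = np.array(["a", "ctrl", "ctrl"])
        out1 = normalize_to_control(vals, groups, "ctrl")
        perm = [2, 0, 1]
        out2 = normalize_to_control(vals[perm], groups[perm], "ctrl")
        assert out1.iloc[0] == out2.iloc[1]

    def test_empty_or_zero_control_rejected(self):
        with pytest.raises(ValidationError):
            normalize_to_control([1.0], ["a"], "ctrl")
        with pytest.raises(ValidationError):
            normalize_to_control([0.0, 1.0], ["ctrl", "a"], "ctrl")


class TestDdct:
    def test_fold_change_closed_forms(self):
        table = pd.DataFrame(
            {
                "sample": ["s1", "s2", "s3", "s4"],
                "group": ["cal", "cal", "t", "t"],
                "target_ct": [20.0, 20.0, 21.0, 18.0],
                "reference_ct": [15.0, 15.0, 15.0, 15.0],
            }
        )
        out = ddct_fold_change(table, "cal")
        # calibrator ΔCt mean = 5 → ΔΔCt = {0, 0, 1, −2} → folds {1, 1, 0.5, 4}
        assert out["fold_change"].tolist() == pytest.approx([1.0, 1.0, 0.5, 4.0])

    def test_missing_calibrator_rejected(self):
        table = pd.DataFrame(
            {"sample": ["s"], "group": ["t"], "target_ct": [20.0], "reference_ct": [15.0]}
        )
        with pytest.raises(ValidationError):
            ddct_fold_change(table, "cal")

    def test_nonfinite_ct_rejected(self):
        table = pd.DataFrame(
            {"sample": ["s"], "group": ["cal"], "target_ct": [np.nan], "reference_ct": [15.0]}
        )
        with pytest.raises(ValidationError):
            ddct_fold_change(table, "cal")
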