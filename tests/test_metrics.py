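"""Evaluation metrics against enumeration and brute-force oracles."""

import numpy as np
import pytest
from scipy import ndimage, stats

from gpseg.metrics import (EmptyMaskError, com_distance, dice, evaluate_case,
                           hausdorff_distance, mean_surface_distance,
                           precision_recall, significance_matrix,
                           surface_voxels, volume_cm3)
from gpseg.volume_io import LabelVolume


def brute_force_surface(mask):
    """Enumerate border voxels by checking all six neighbours explicitly."""
    pts = []
    shape = mask.shape
    for idx in np.argwhere(mask):
        i, j, k = idx
        border = False
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                  (0, 0, 1), (0, 0, -1)):
            n = (i + d[0], j + d[1], k + d[2])
            if any(c < 0 or c >= s for c, s in zip(n, shape)) or not mask[n]:
                border = True
                break
        if border:
            pts.append(idx)
    return np.asarray(pts)


def brute_force_msd_hd(a, b, spacing):
    """All-pairs surface distances (the oracle for MSD and HD)."""
    pa = (brute_force_surface(a) + 0.5) * np.asarray(spacing)
    pb = (brute_force_surface(b) + 0.5) * np.asarray(spacing)
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    d_ab = d.min(axis=1)
    d_ba = d.min(axis=0)
    msd = 0.5 * (d_ab.mean() + d_ba.mean())
    hd = max(d_ab.max(), d_ba.max())
    return msd, hd


def random_mask(rng, shape, p=0.3):
    m = rng.random(shape) < p
    if not m.any():
        m[tuple(rng.integers(0, s) for s in shape)] = True
    return m


class TestDice:
    def test_identity_and_disjoint(self):
        a = np.zeros((4, 4, 4), bool)
        a[:2] = True
        assert dice(a, a) == 1.0
        assert dice(a, ~a) == 0.0

    def test_hand_value(self):
        a = np.zeros(16, bool)
        b = np.zeros(16, bool)
        a[:4] = True
        b[2:6] = True
        assert dice(a.reshape(4, 2, 2), b.reshape(4, 2, 2)) == 0.5

    def test_both_empty(self):
        z = np.zeros((3, 3, 3), bool)
        assert dice(z, z) == 1.0


class TestCoM:
    def test_pythagorean(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[0, 0, 0] = True
        b[3, 4, 0] = True
        assert com_distance(a, b, (1, 1, 1)) == pytest.approx(5.0)
        assert com_distance(a, b, (0.39, 0.39, 0.39)) == pytest.approx(1.95)

    def test_identity_and_empty(self):
        a = np.zeros((4, 4, 4), bool)
        a[1:3] = True
        assert com_distance(a, a, (1, 1, 1)) == 0.0
        with pytest.raises(EmptyMaskError):
            com_distance(a, np.zeros_like(a), (1, 1, 1))


class TestSurface:
    def test_single_voxel(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        assert surface_voxels(m, (1, 1, 1)).shape == (1, 3)

    @pytest.mark.parametrize("n,expected", [(3, 26), (5, 98)])
    def test_solid_cube_counts(self, n, expected):
        m = np.zeros((n + 2, n + 2, n + 2), bool)
        m[1:n + 1, 1:n + 1, 1:n + 1] = True
        assert len(surface_voxels(m, (1, 1, 1))) == expected

    def test_grid_boundary_counts_as_outside(self):
        # a full grid: every voxel except the centre touches the grid edge
        m = np.ones((3, 3, 3), bool)
        assert len(surface_voxels(m, (1, 1, 1))) == 26

    def test_matches_brute_force(self, rng):
        m = random_mask(rng, (7, 6, 5))
        mine = surface_voxels(m, (1, 1, 1))
        oracle = (brute_force_surface(m) + 0.5) * 1.0
        assert np.array_equal(np.sort(mine, axis=0), np.sort(oracle, axis=0))


class TestSurfaceDistances:
    def test_identity(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:4, 1:4, 1:4] = True
        assert mean_surface_distance(m, m, (1, 1, 1)) == 0.0
        assert hausdorff_distance(m, m, (1, 1, 1)) == 0.0

    def test_parallel_plates(self):
        a = np.zeros((10, 5, 5), bool)
        b = np.zeros((10, 5, 5), bool)
        a[2] = True
        b[6] = True  # 4 mm apart at unit spacing
        assert mean_surface_distance(a, b, (1, 1, 1)) == pytest.approx(4.0)
        assert hausdorff_distance(a, b, (1, 1, 1)) == pytest.approx(4.0)

    def test_two_point_hausdorff(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[0, 0, 0] = True
        b[3, 4, 0] = True
        assert hausdorff_distance(a, b, (1, 1, 1)) == pytest.approx(5.0)

    def test_brute_force_oracle_and_hd_vs_msd(self, rng):
        for _ in range(25):
            shape = tuple(rng.integers(4, 9, 3))
            spacing = tuple(rng.uniform(0.3, 1.5, 3))
            a = random_mask(rng, shape)
            b = random_mask(rng, shape)
            msd_o, hd_o = brute_force_msd_hd(a, b, spacing)
            msd = mean_surface_distance(a, b, spacing)
            hd = hausdorff_distance(a, b, spacing)
            assert msd == pytest.approx(msd_o, abs=1e-9)
            assert hd == pytest.approx(hd_o, abs=1e-9)
            assert hd >= msd - 1e-12

    def test_directed_option(self):
        a = np.zeros((6, 6, 6), bool)
        b = np.zeros((6, 6, 6), bool)
        a[2:4, 2:4, 2:4] = True
        b[1:5, 1:5, 1:5] = True
        directed = mean_surface_distance(a, b, (1, 1, 1), symmetric=False)
        pa = surface_voxels(a, (1, 1, 1))
        pb = surface_voxels(b, (1, 1, 1))
        d = np.linalg.norm(pa[:, None] - pb[None], axis=-1).min(axis=1)
        assert directed == pytest.approx(d.mean(), abs=1e-12)


class TestVolumePrecisionRecall:
    def test_volume_values(self):
        assert volume_cm3(np.zeros((4, 4, 4), bool), (1, 1, 1)) == 0.0
        m = np.ones((10, 10, 10), bool)
        assert volume_cm3(m, (1, 1, 1)) == pytest.approx(1.0)
        # the published manual GPe scale: ~21k voxels at 0.39 mm iso
        m2 = np.ones(21074, bool)
        assert 21074 * 0.39 ** 3 / 1000 == pytest.approx(1.2503, abs=1e-3)

    def test_precision_recall_values(self):
        pred = np.zeros(32, bool)
        truth = np.zeros(32, bool)
        pred[:10] = True            # 8 tp + 2 fp
        truth[:8] = True
        truth[10:18] = True         # 8 fn
        p, r = precision_recall(pred.reshape(4, 4, 2), truth.reshape(4, 4, 2))
        assert (p, r) == (pytest.approx(0.8), pytest.approx(0.5))

    def test_subset_case(self):
        truth = np.zeros((4, 4, 4), bool)
        truth[1:3, 1:3, 1:3] = True
        pred = truth.copy()
        pred[1, 1, 1] = pred[1, 1, 1]
        pred[2, 2, 2] = False
        p, r = precision_recall(pred, truth)
        assert p == 1.0 and r < 1.0


class TestEvaluateCase:
    def test_identity_report(self, small_phantom):
        _, lab, _ = small_phantom
        report = evaluate_case(lab, lab)
        for entry in report.entries:
            assert entry.dice == 1.0
            assert entry.com_distance_mm == 0.0
            assert entry.msd_mm == 0.0
            assert entry.volume_pred_cm3 == entry.volume_truth_cm3

    def test_dilated_prediction(self, small_phantom):
        _, lab, _ = small_phantom
        grown = lab.data.copy()
        for cls in (1, 2):
            mask = ndimage.binary_dilation(lab.data == cls)
            grown[mask & (lab.data == 0)] = cls
        # one-voxel dilation of GPi can eat the GPe-facing lamina only
        report = evaluate_case(LabelVolume(grown, lab.spacing), lab)
        gpe = report.get("GPe", "left")
        assert gpe.recall == pytest.approx(1.0)
        assert gpe.precision < 1.0
        assert gpe.msd_mm <= np.linalg.norm(lab.spacing)

    def test_truth_volume_close_to_analytic(self, small_phantom):
        _, lab, truth = small_phantom
        report = evaluate_case(lab, lab)
        for side in ("left", "right"):
            for structure in ("GPe", "GPi"):
                analytic = truth.get(side, structure).volume_cm3
                measured = report.get(structure, side).volume_truth_cm3
                assert measured == pytest.approx(analytic, rel=0.03)

    def test_geometry_mismatch(self, small_phantom):
        _, lab, _ = small_phantom
        other = LabelVolume(lab.data[:-2], lab.spacing)
        with pytest.raises(ValueError):
            evaluate_case(other, lab)


class TestSignificance:
    def test_symmetry_and_categories(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(5, 1, 40)        # 5 SDs apart
        c = rng.normal(0.1, 1, 40)
        mat = significance_matrix({"m1": a, "m2": b, "m3": c})
        assert np.allclose(mat.p_values, mat.p_values.T, equal_nan=True)
        assert mat.category(0, 1) == "p<0.001"
        assert np.isnan(mat.p_values[0, 0])

    def test_identical_distributions_not_significant(self, rng):
        ns = 0
        for _ in range(40):
            a = rng.normal(0, 1, 50)
            b = rng.normal(0, 1, 50)
            if significance_matrix({"a": a, "b": b}).category(0, 1) == "ns":
                ns += 1
        assert ns >= 36  # ~alpha = 0.05

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            significance_matrix({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        with pytest.raises(ValueError):
            significance_matrix({"a": [1.0, 2.0]})

    def test_matches_scipy_anova(self, rng):
        groups = {k: rng.normal(i, 1, 30) for i, k in enumerate("abc")}
        mat = significance_matrix(groups)
        f, p = stats.f_oneway(*groups.values())
        assert mat.anova_f == pytest.approx(f)
        assert mat.anova_p == pytest.approx(p)
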