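"""Phantom rendering, contour perturbation, DSC calibration, dataset."""

import numpy as np
import pytest
from scipy.optimize import brentq

from segqa import phantom, qa
from segqa.phantom import PerturbationConfig, PhantomParams


def disk_mask(size: int, cy: float, cx: float, r: float) -> np.ndarray:
    rr, cc = np.ogrid[:size, :size]
    return (((rr - cy) ** 2 + (cc - cx) ** 2) <= r * r).astype(np.uint8)


class TestMakePhantom:
    def test_zero_target_gives_empty_mask(self):
        p = PhantomParams(target_semiaxes=(0.0, 0.0))
        _, gt = phantom.make_phantom(p, 10)
        assert gt.sum() == 0

    def test_deterministic_for_fixed_seed(self):
        p = PhantomParams(seed=123)
        ct1, gt1 = phantom.make_phantom(p, 7)
        ct2, gt2 = phantom.make_phantom(p, 7)
        np.testing.assert_array_equal(ct1, ct2)
        np.testing.assert_array_equal(gt1, gt2)

    def test_mid_stack_area_within_published_range(self):
        _, gt = phantom.make_phantom(PhantomParams(), 10)
        assert 440 <= gt.sum() <= 12440

    def test_stack_ends_empty_interior_connected(self):
        from scipy import ndimage

        p = PhantomParams()
        for s in (0, p.n_slices - 1):
            _, gt = phantom.make_phantom(p, s)
            assert gt.sum() == 0
        _, gt = phantom.make_phantom(p, 10)
        _, n_components = ndimage.label(gt)
        assert n_components == 1

    def test_ct_carries_target_signal(self):
        ct, gt = phantom.make_phantom(PhantomParams(), 10)
        assert ct[gt == 1].mean() > ct[gt == 0].mean() + 50

    def test_invalid_geometry_rejected(self):
        p = PhantomParams(target_center=(256.0, 470.0))
        with pytest.raises(ValueError, match="outside the body"):
            phantom.make_phantom(p, 10)

    def test_slice_index_out_of_range(self):
        with pytest.raises(IndexError):
            phantom.make_phantom(PhantomParams(), 99)


class TestPerturbSegmentation:
    def test_identity_with_zero_perturbation(self):
        _, gt = phantom.make_phantom(PhantomParams(), 10)
        prob = phantom.perturb_segmentation(gt, PerturbationConfig(boundary_softness_tau=1e-4))
        np.testing.assert_array_equal(qa.threshold_probability(prob), gt)

    def test_probabilities_in_unit_interval(self):
        _, gt = phantom.make_phantom(PhantomParams(), 10)
        cfg = PerturbationConfig(shift=5.0, dilation=2.0, deform_amplitude=3.0)
        prob = phantom.perturb_segmentation(gt, cfg)
        assert prob.min() >= 0.0 and prob.max() <= 1.0

    def test_dropout_yields_all_zero_and_dsc_zero(self):
        _, gt = phantom.make_phantom(PhantomParams(), 10)
        prob = phantom.perturb_segmentation(gt, PerturbationConfig(dropout_prob=1.0))
        assert prob.sum() == 0.0
        assert qa.slice_dsc(gt, qa.threshold_probability(prob)) == 0.0

    def test_spurious_blob_disjoint_from_target(self):
        _, gt = phantom.make_phantom(PhantomParams(), 10)
        cfg = PerturbationConfig(spurious_prob=1.0, seed=5)
        pred = qa.threshold_probability(phantom.perturb_segmentation(gt, cfg))
        extra = pred & ~gt.astype(bool)
        assert extra.sum() > 50  # a real blob appeared
        # the blob does not touch the true target
        from scipy import ndimage

        dil = ndimage.binary_dilation(gt, iterations=3)
        assert not (extra & dil).any()

    def test_dilation_dsc_matches_rasterized_disk_oracle(self):
        # dilating a 40 px disk by +3 px: compare against explicit pixel
        # counting of the 40 px and 43 px rasterized disks
        gt = disk_mask(128, 64, 64, 40)
        prob = phantom.perturb_segmentation(gt, PerturbationConfig(dilation=3.0))
        got = qa.slice_dsc(gt, qa.threshold_probability(prob))
        bigger = disk_mask(128, 64, 64, 43)
        n_a = int(gt.sum())
        n_b = int(bigger.sum())
        n_i = int((gt & bigger).sum())
        expected = 2 * n_i / (n_a + n_b)
        assert got == pytest.approx(expected, abs=0.015)

    def test_tau_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            PerturbationConfig(boundary_softness_tau=0.0)

    def test_monotone_in_dilation_magnitude(self):
        _, gt = phantom.make_phantom(PhantomParams(), 10)
        dscs = []
        for d in (0.0, 2.0, 5.0, 9.0, 14.0):
            prob = phantom.perturb_segmentation(gt, PerturbationConfig(dilation=d))
            dscs.append(qa.slice_dsc(gt, qa.threshold_probability(prob)))
        assert all(a >= b for a, b in zip(dscs, dscs[1:]))
        dscs = []
        for d in (0.0, -2.0, -5.0, -9.0, -14.0):
            prob = phantom.perturb_segmentation(gt, PerturbationConfig(dilation=d))
            dscs.append(qa.slice_dsc(gt, qa.threshold_probability(prob)))
        assert all(a >= b for a, b in zip(dscs, dscs[1:]))


class TestCalibrateToDsc:
    def test_perfect_target_keeps_zero_dilation(self):
        _, gt = phantom.make_phantom(PhantomParams(), 10)
        cfg = phantom.calibrate_to_dsc(gt, 1.0, "dilation")
        assert cfg.dilation == pytest.approx(0.0, abs=1e-9)
        prob = phantom.perturb_segmentation(gt, cfg)
        assert qa.slice_dsc(gt, qa.threshold_probability(prob)) == 1.0

    @pytest.mark.parametrize("free", ["shift", "dilation", "deform_amplitude"])
    def test_achieves_mid_target_verified_by_pixel_counting(self, free):
        _, gt = phantom.make_phantom(PhantomParams(), 10)
        cfg = phantom.calibrate_to_dsc(gt, 0.85, free)
        pred = qa.threshold_probability(phantom.perturb_segmentation(gt, cfg))
        n_a, n_b = int(gt.sum()), int(pred.sum())
        n_i = int((gt.astype(bool) & pred.astype(bool)).sum())
        achieved = 2 * n_i / (n_a + n_b)
        assert 0.83 <= achieved <= 0.87

    def test_shift_consistent_with_circle_overlap_formula(self):
        r = 40.0
        gt = disk_mask(160, 80, 80, r)
        cfg = phantom.calibrate_to_dsc(gt, 0.5, "shift")

        def analytic_dsc(s):
            inter = 2 * r * r * np.arccos(s / (2 * r)) - (s / 2) * np.sqrt(4 * r * r - s * s)
            return inter / (np.pi * r * r)

        s_expected = brentq(lambda s: analytic_dsc(s) - 0.5, 1.0, 2 * r - 1e-6)
        assert abs(cfg.shift) == pytest.approx(s_expected, abs=1.5)

    def test_unreachable_target_reported(self):
        # a mandatory large shift makes DSC 0.99 impossible
        _, gt = phantom.make_phantom(PhantomParams(), 10)
        base = PerturbationConfig(shift=60.0)
        with pytest.raises(phantom.CalibrationError):
            phantom.calibrate_to_dsc(gt, 0.99, "dilation", base)

    def test_empty_mask_rejected(self):
        with pytest.raises(phantom.CalibrationError, match="empty"):
            phantom.calibrate_to_dsc(np.zeros((32, 32), dtype=np.uint8), 0.8, "shift")

    def test_invalid_arguments(self):
        gt = disk_mask(64, 32, 32, 10)
        with pytest.raises(ValueError, match="free_parameter"):
            phantom.calibrate_to_dsc(gt, 0.8, "tau")
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            phantom.calibrate_to_dsc(gt, 1.2, "shift")


@pytest.fixture(scope="module")
def small():
    return phantom.generate_dataset(n_patients=6, slices_per_patient=10, seed=21)


class TestGenerateDataset:
    def test_degenerate_mix_all_good(self):
        ds = phantom.generate_dataset(n_patients=2, slices_per_patient=6,
                                      quality_mix=(1.0, 0.0, 0.0), seed=3)
        assert (ds.manifest["quality_level"] == qa.GOOD).all()

    def test_reproducible_from_seed(self, small):
        again = phantom.generate_dataset(n_patients=6, slices_per_patient=10, seed=21)
        assert small.manifest.equals(again.manifest)
        for pid in small.patients:
            for chan in ("ct", "gt", "prob"):
                np.testing.assert_array_equal(small.volumes[pid][chan],
                                              again.volumes[pid][chan])

    def test_manifest_dsc_matches_recomputation(self, small):
        for _, row in small.manifest.iterrows():
            v = small.volumes[row["patient_id"]]
            s = int(row["slice_index"])
            dsc = qa.slice_dsc(v["gt"][:, :, s],
                               qa.threshold_probability(np.clip(v["prob"][:, :, s], 0, 1)))
            assert abs(dsc - row["dsc"]) <= 1e-9

    def test_splits_disjoint_by_patient(self, small):
        per_patient = small.manifest.groupby("patient_id")["split"].nunique()
        assert (per_patient == 1).all()
        assert set(small.split.values()) == {"train", "val", "test"}

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError, match="quality_mix"):
            phantom.generate_dataset(2, 4, quality_mix=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="counts"):
            phantom.generate_dataset(0, 4)

    def test_save_load_round_trip(self, small, tmp_path):
        small.save(tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "generator_config.yaml").exists()
        back = phantom.SyntheticDataset.load(tmp_path)
        assert back.manifest["dsc"].tolist() == pytest.approx(small.manifest["dsc"].tolist())
        pid = small.patients[0]
        np.testing.assert_array_equal(back.volumes[pid]["gt"], small.volumes[pid]["gt"])
        np.testing.assert_allclose(back.volumes[pid]["prob"], small.volumes[pid]["prob"],
                                   atol=1e-6)
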