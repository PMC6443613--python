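"""Triplanar patch extraction, segmenter training contract, and QC."""

import numpy as np
import pytest

from myotriage import (
    PatchSpec,
    TriplanarSegmenter,
    extract_triplanar_patches,
    qc_segmentation,
    segment_volume,
)
from myotriage.segmentation import extract_triplanar_batch
from tests_oracles import brute_force_triplanar


class TestPatchExtraction:
    def test_constant_volume_gives_constant_patches(self):
        vol = np.full((12, 12, 12), 100.0)
        patches = extract_triplanar_patches(vol, (6, 6, 6), PatchSpec(5, (1, 3)))
        assert patches.shape == (6, 5, 5)
        assert np.all(patches == 100.0)

    def test_fine_scale_center_pixel_equals_voxel_intensity(self, rng):
        vol = rng.normal(size=(16, 20, 18))
        spec = PatchSpec(7, (1, 2))
        for voxel in rng.integers(0, (16, 20, 18), size=(20, 3)):
            patches = extract_triplanar_patches(vol, voxel, spec)
            for ch in range(3):  # fine-scale channels
                assert patches[ch, 3, 3] == vol[tuple(voxel)]

    def test_matches_brute_force_slicing_oracle(self, rng):
        vol = rng.normal(size=(32, 32, 32))
        spec = PatchSpec(9, (1, 3))
        voxels = rng.integers(0, 32, size=(50, 3))
        batch = extract_triplanar_batch(vol, voxels, spec)
        for k, voxel in enumerate(voxels):
            oracle = brute_force_triplanar(vol, voxel, spec)
            assert np.array_equal(batch[k], oracle)

    def test_voxel_outside_grid_raises(self):
        vol = np.zeros((8, 8, 8))
        with pytest.raises(IndexError):
            extract_triplanar_patches(vol, (8, 0, 0), PatchSpec(5))

    def test_patch_spec_validation(self):
        with pytest.raises(ValueError):
            PatchSpec(patch_edge=8)
        with pytest.raises(ValueError):
            PatchSpec(scales=(3, 1))
        with pytest.raises(ValueError):
            PatchSpec(scales=(1, 2, 3))


class TestSegmenterTraining:
    def test_training_reduces_loss(self, trained_segmenter):
        trace = trained_segmenter.loss_trace_
        assert trace[-1] < trace[0]
        assert np.all(np.isfinite(trace))

    def test_same_seed_reproduces_loss_trace(self, phantom_set):
        vols, masks, _ = phantom_set
        cfg = dict(patch_edge=9, epochs=1, samples_per_volume=300, random_state=5)
        a = TriplanarSegmenter(**cfg).fit(vols[:2], masks[:2])
        b = TriplanarSegmenter(**cfg).fit(vols[:2], masks[:2])
        assert a.loss_trace_ == b.loss_trace_

    def test_all_empty_masks_rejected(self, phantom_set):
        vols, _, _ = phantom_set
        empty = [np.zeros_like(v, dtype=np.uint8) for v in vols[:2]]
        with pytest.raises(ValueError, match="nothing to learn"):
            TriplanarSegmenter(patch_edge=9).fit(vols[:2], empty)

    def test_checkpoint_roundtrip(self, trained_segmenter, phantom_set, tmp_path):
        vols, _, _ = phantom_set
        path = tmp_path / "seg.npz"
        trained_segmenter.save(path)
        loaded = TriplanarSegmenter.load(path)
        a = trained_segmenter.decision_volume(vols[4])
        b = loaded.decision_volume(vols[4])
        assert np.array_equal(a, b)


class TestSegmentation:
    def test_mask_on_identical_grid_and_binary(self, trained_segmenter, phantom_set):
        vols, _, _ = phantom_set
        mask = segment_volume(trained_segmenter, vols[4])
        assert mask.shape == vols[4].shape
        assert set(np.unique(mask)) <= {0, 1}

    def test_dice_on_held_out_phantoms(self, trained_segmenter, phantom_set):
        vols, masks, _ = phantom_set
        for i in (4, 5):  # not used in training
            pred = trained_segmenter.predict_mask(vols[i])
            dice = 2 * np.sum((pred > 0) & (masks[i] > 0)) / (
                pred.sum() + masks[i].sum()
            )
            assert dice >= 0.85

    def test_pure_background_volume_yields_sparse_mask(
        self, trained_segmenter, rng
    ):
        vol = rng.normal(-50.0, 20.0, size=(32, 48, 48))
        mask = trained_segmenter.predict_mask(vol)
        assert mask.mean() < 0.05

    def test_deterministic_masks(self, trained_segmenter, phantom_set):
        vols, _, _ = phantom_set
        m1 = trained_segmenter.predict_mask(vols[5])
        m2 = trained_segmenter.predict_mask(vols[5])
        assert np.array_equal(m1, m2)


class TestQC:
    def test_empty_mask_fails_with_volume_reason(self):
        passed, reasons = qc_segmentation(np.zeros((8, 8, 8)), (1, 1, 1))
        assert not passed
        assert any("below minimum" in r for r in reasons)

    def test_true_phantom_mask_passes(self, phantom_set, cohort_spec):
        _, masks, _ = phantom_set
        passed, reasons = qc_segmentation(masks[0], cohort_spec.voxel_spacing)
        assert passed, reasons

    def test_distant_spurious_blob_fails_connectivity(
        self, phantom_set, cohort_spec
    ):
        _, masks, _ = phantom_set
        mask = masks[0].copy()
        blob = int(0.4 * mask.sum())
        free = np.argwhere(mask == 0)
        corner = free[np.lexsort(free.T[::-1])][:blob]
        mask[tuple(corner.T)] = 1
        passed, reasons = qc_segmentation(mask, cohort_spec.voxel_spacing)
        assert not passed
        assert any("connected component" in r for r in reasons)

    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            qc_segmentation(np.full((4, 4, 4), 2), (1, 1, 1))
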