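"""Threshold / island-removal / density-selection behavior."""

import numpy as np
import pytest
from scipy import ndimage

from tavi4d import (
    BinaryMask,
    ScalarVolume,
    SegmentationParams,
    component_density,
    dice,
    remove_small_islands,
    segment_frame,
    threshold_volume,
)

PHANTOM_PARAMS = SegmentationParams(th1=800, th2=1000)


def _vol(arr, spacing=1.0):
    return ScalarVolume(np.asarray(arr, np.float32), spacing=(spacing,) * 3)


class TestThreshold:
    def test_all_below_threshold_is_an_error(self):
        with pytest.raises(ValueError, match="no candidate"):
            threshold_volume(_vol(np.full((8, 8, 8), 40.0)), 800)

    def test_strictly_greater_semantics(self):
        mask = threshold_volume(_vol(np.full((4, 4, 4), 801.0)), 800)
        assert mask.voxels.all()
        with pytest.raises(ValueError):
            threshold_volume(_vol(np.full((4, 4, 4), 800.0)), 800)

    def test_phantom_frame_within_foreground(self, cyl_phantom):
        study, truth = cyl_phantom
        mask = threshold_volume(study[0], 800)
        covered = (mask.voxels & truth.frame_mask[0].voxels).sum()
        assert covered / truth.frame_mask[0].count > 0.999

    def test_monotone_in_th1(self, cyl_phantom):
        study, _ = cyl_phantom
        counts = [threshold_volume(study[0], th).count for th in (500, 800, 1500, 2500)]
        assert counts == sorted(counts, reverse=True)


class TestIslandRemoval:
    def _two_blob_mask(self):
        vox = np.zeros((40, 40, 60), bool)
        vox[2:4, 2:4, 2:4] = True  # 8 voxels
        vox[10:35, 10:35, 10:45] = True  # 21875 voxels
        return BinaryMask(vox, spacing=(1, 1, 1))

    def test_small_component_removed(self):
        out = remove_small_islands(self._two_blob_mask(), th2=11000)
        assert out.count == 25 * 25 * 35
        _, n = ndimage.label(out.voxels)
        assert n == 1

    def test_exact_size_is_retained(self):
        vox = np.zeros((12, 12, 12), bool)
        vox[2:7, 2:7, 2:6] = True  # exactly 100 voxels
        out = remove_small_islands(BinaryMask(vox, spacing=(1, 1, 1)), th2=100)
        assert out.count == 100

    def test_everything_removed_is_an_error(self):
        with pytest.raises(ValueError, match="th2"):
            remove_small_islands(self._two_blob_mask(), th2=10**6)

    def test_phantom_artifacts_leave_two_components(self, artifact_phantom):
        study, _ = artifact_phantom
        out = remove_small_islands(threshold_volume(study[0], 800), th2=1000)
        _, n = ndimage.label(out.voxels, np.ones((3, 3, 3)))
        assert n == 2  # frame + calcification; all 10 speckles gone

    def test_labeling_agrees_with_flood_fill_oracle(self, cyl_phantom):
        study, _ = cyl_phantom
        mask = threshold_volume(study[0], 800)
        lab, n = ndimage.label(mask.voxels, np.ones((3, 3, 3)))
        # brute-force BFS flood fill over a downsampled copy
        vox = mask.voxels[::2, ::2, ::2]
        seen = np.zeros_like(vox, bool)
        n_oracle = 0
        offsets = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
                   if (a, b, c) != (0, 0, 0)]
        for start in zip(*np.nonzero(vox)):
            if seen[start]:
                continue
            n_oracle += 1
            stack = [start]
            seen[start] = True
            while stack:
                p = stack.pop()
                for off in offsets:
                    q = tuple(np.add(p, off))
                    if all(0 <= q[i] < vox.shape[i] for i in range(3)) and vox[q] and not seen[q]:
                        seen[q] = True
                        stack.append(q)
        lab_ds, n_ds = ndimage.label(vox, np.ones((3, 3, 3)))
        assert n_ds == n_oracle


class TestDensity:
    def test_solid_ball_is_dense(self):
        x, y, z = np.meshgrid(*(np.arange(32),) * 3, indexing="ij")
        ball = (x - 16) ** 2 + (y - 16) ** 2 + (z - 16) ** 2 <= 10**2
        d = component_density(BinaryMask(ball, spacing=(1, 1, 1)))
        assert d > 0.9

    def test_hollow_shell_density_matches_brute_force(self):
        x, y, z = np.meshgrid(*(np.arange(32),) * 3, indexing="ij")
        r2 = (x - 16) ** 2 + (y - 16) ** 2 + (z - 16) ** 2
        shell = (r2 <= 10**2) & (r2 > 9**2)
        ball = r2 <= 10**2
        expected = shell.sum() / ball.sum()  # ~0.27
        d = component_density(BinaryMask(shell, spacing=(1, 1, 1)))
        assert d == pytest.approx(expected, abs=0.05)

    def test_frame_less_dense_than_calcification(self, artifact_phantom):
        study, truth = artifact_phantom
        out = remove_small_islands(threshold_volume(study[0], 800), th2=1000)
        lab, n = ndimage.label(out.voxels, np.ones((3, 3, 3)))
        dens = {}
        for i in range(1, n + 1):
            comp = out.with_voxels(lab == i)
            is_frame = dice(comp, truth.frame_mask[0]) > 0.5
            dens["frame" if is_frame else "calc"] = component_density(comp)
        assert dens["frame"] < dens["calc"]
        assert dens["frame"] < 0.5 < dens["calc"]


class TestSegmentFrame:
    def test_artifact_phantom_recovers_frame(self, artifact_phantom):
        study, truth = artifact_phantom
        out = segment_frame(study[0], PHANTOM_PARAMS)
        _, n = ndimage.label(out.voxels, np.ones((3, 3, 3)))
        assert n == 1
        assert dice(out, truth.frame_mask[0]) >= 0.90

    def test_clean_phantom_equals_island_removal(self, cyl_phantom):
        study, _ = cyl_phantom
        direct = remove_small_islands(threshold_volume(study[0], 800), 1000)
        out = segment_frame(study[0], PHANTOM_PARAMS)
        np.testing.assert_array_equal(out.voxels, direct.voxels)

    def test_solid_blob_only_is_an_error(self):
        vox = np.full((32, 32, 32), 40.0, np.float32)
        x, y, z = np.meshgrid(*(np.arange(32),) * 3, indexing="ij")
        vox[(x - 16) ** 2 + (y - 16) ** 2 + (z - 16) ** 2 <= 12**2] = 1200.0
        with pytest.raises(ValueError, match="thread-like"):
            segment_frame(_vol(vox), SegmentationParams(th1=800, th2=100))

    def test_idempotent_on_isolated_frame(self, cyl_phantom):
        study, _ = cyl_phantom
        out = segment_frame(study[0], PHANTOM_PARAMS)
        isolated = study[0].voxels * out.voxels  # zero all non-frame voxels
        again = segment_frame(_vol_like(study[0], isolated), PHANTOM_PARAMS)
        np.testing.assert_array_equal(again.voxels, out.voxels)


def _vol_like(ref, arr):
    return ScalarVolume(arr, ref.spacing, ref.origin, ref.orientation)
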