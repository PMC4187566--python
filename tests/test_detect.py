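"""Acinar-entrance detection: thresholding, wall thickness, counting."""

import warnings

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from acinostat.detect import (
    DetectParams,
    count_acini,
    detect_entrances,
    resolution_limit,
    resolve_threshold,
    tissue_mask,
    wall_thickness_map,
)
from acinostat.imaging import ImageStack, split_substacks
from acinostat.phantom import AIR_GRAY, TISSUE_GRAY


def match_table(entrances, truth, voxel_size, radius_um=25.0):
    """(n_matched, n_false_positive) matching detections to ground truth."""
    gt = np.array([e.position for e in truth])
    det = np.array([e.position for e in entrances])
    if len(det) == 0:
        return 0, 0
    dm = cdist(det, gt) * voxel_size
    return int((dm.min(axis=0) < radius_um).sum()), int(
        (dm.min(axis=1) >= radius_um).sum()
    )


def straight_tube_stack(
    shape=(120, 64, 64), r_lumen=5, wall=4, voxel=2.35, axis_yx=(32, 32)
):
    """A thick-walled straight airway along z, open at both z faces."""
    z, y, x = np.indices(shape)
    rad = np.sqrt((y - axis_yx[0]) ** 2 + (x - axis_yx[1]) ** 2)
    vox = np.full(shape, AIR_GRAY, np.uint8)
    vox[(rad > r_lumen) & (rad <= r_lumen + wall)] = TISSUE_GRAY
    return ImageStack(vox, voxel)


class TestTissueMask:
    def test_noiseless_phantom_recovered_exactly(self):
        from tests.conftest import make_phantom

        ph = make_phantom(5, seed=8, gen_range=(4, 6), noise_sd=0.0)
        mask = tissue_mask(ph.stack, threshold=115)
        assert np.array_equal(mask, ph.tissue_mask)

    def test_otsu_on_noisy_phantom_below_one_percent_error(self, phantom13):
        mask = tissue_mask(phantom13.stack, threshold="otsu")
        disagree = (mask != phantom13.tissue_mask).mean()
        assert disagree < 0.01

    def test_single_class_stacks_rejected(self):
        with pytest.raises(ValueError, match="air|tissue"):
            tissue_mask(np.zeros((8, 8, 8), np.uint8), threshold=10)
        with pytest.raises(ValueError, match="air|tissue"):
            tissue_mask(np.full((8, 8, 8), 200, np.uint8), threshold=10)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            resolve_threshold(np.zeros((4, 4, 4), np.uint8), "median")


def brute_force_local_thickness(tissue, voxel_size):
    """Largest inscribed sphere through each voxel, by exhaustive search.

    Independent oracle for wall_thickness_map; usable only on tiny masks.
    """
    from scipy import ndimage as ndi

    edt = ndi.distance_transform_edt(tissue)
    coords = np.argwhere(tissue)
    out = np.zeros(tissue.shape)
    centers = np.argwhere(edt >= 1)
    radii = edt[tuple(centers.T)]
    for v in coords:
        d = np.linalg.norm(centers - v, axis=1)
        ok = d <= radii - 1 + 1e-3
        ok |= (d == 0)
        if ok.any():
            out[tuple(v)] = 2 * int(np.floor(radii[ok].max()))
    return out * voxel_size


class TestWallThickness:
    def test_solid_slab_interior(self):
        tissue = np.zeros((24, 24, 24), bool)
        tissue[7:17] = True  # 10 voxels thick
        lt = wall_thickness_map(tissue, voxel_size=3.0)
        center = lt[12, 12, 12]
        assert abs(center - 10 * 3.0) <= 3.0  # within one voxel

    def test_hollow_cylinder_wall_matches_brute_force(self):
        z, y, x = np.indices((16, 30, 30))
        rad = np.sqrt((y - 15) ** 2 + (x - 15) ** 2)
        tissue = (rad > 6) & (rad <= 10)  # 4-voxel wall
        lt = wall_thickness_map(tissue, voxel_size=2.0)
        mid = tissue[8]
        med = np.median(lt[8][mid])
        assert abs(med - 4 * 2.0) <= 2.0
        oracle = brute_force_local_thickness(tissue[6:10], 2.0)
        sample = tissue[6:10]
        assert np.median(lt[6:10][sample]) == pytest.approx(
            np.median(oracle[sample]), abs=2.0
        )

    def test_phantom_wall_contrast_reaches_detection_ratio(self, phantom13):
        """Conducting vs acinar wall thickness in the rendered stack exceeds
        the drop ratio used for detection."""
        ph = phantom13
        crop = tuple(slice(0, min(s, 160)) for s in ph.tissue_mask.shape)
        lt = wall_thickness_map(ph.tissue_mask[crop], ph.stack.voxel_size)
        from scipy import ndimage as ndi

        st = ndi.generate_binary_structure(3, 1)
        cond = ndi.binary_dilation(ph.conducting_mask[crop], st) & ph.tissue_mask[crop]
        acin = (
            ndi.binary_dilation(ph.acinar_mask[crop], st)
            & ph.tissue_mask[crop]
            & ~cond
        )
        ratio = np.median(lt[cond]) / np.median(lt[acin])
        assert ratio >= 2.0


class TestDetectEntrances:
    def test_recovers_thirteen_with_positions(self, phantom13):
        ents = detect_entrances(phantom13.stack)
        assert len(ents) == phantom13.n_acini == 13
        matched, fp = match_table(ents, phantom13.truth, 2.35)
        assert matched == 13 and fp == 0
        # localization: along the airway axis the transition is pinned to a
        # couple of voxels
        gt = {e.acinus_id: e for e in phantom13.tree.entrances}
        det = np.array([e.position for e in ents], float)
        for e in phantom13.truth:
            b = phantom13.tree.branch(e.branch_id)
            axis = b.direction
            pos_vox = (e.position_um - phantom13.origin_um) / 2.35
            d_axial = np.abs((det - pos_vox) @ axis).min()
            assert d_axial <= 4.0  # voxels

    def test_thick_tube_without_alveoli_yields_nothing(self):
        ents = detect_entrances(straight_tube_stack())
        assert ents == []

    def test_dual_entrances_counted_as_two_and_paired(self, phantom13_dual):
        ents = detect_entrances(phantom13_dual.stack)
        assert len(ents) == phantom13_dual.n_acini
        n_gt_pairs = sum(1 for e in phantom13_dual.truth if e.dual_of is not None) // 2
        n_det_pairs = sum(1 for e in ents if e.dual_of is not None) // 2
        assert n_det_pairs == n_gt_pairs
        # paired labels are mutual
        by_label = {e.label: e for e in ents}
        for e in ents:
            if e.dual_of:
                assert by_label[e.dual_of].dual_of == e.label

    def test_entrance_wall_thicknesses_reported(self, phantom13):
        ents = detect_entrances(phantom13.stack)
        for e in ents:
            assert e.wall_thickness_proximal > e.wall_thickness_distal
            assert e.wall_thickness_proximal >= 2 * 0.9 * e.wall_thickness_distal

    def test_coarse_voxel_size_warns(self):
        s = straight_tube_stack(voxel=4.0)
        with pytest.warns(UserWarning, match="reliability"):
            detect_entrances(s)


class TestCountAcini:
    def test_split_invariance(self, phantom13):
        whole = count_acini(phantom13.stack)
        for depth in (64, 100):
            subs = split_substacks(
                phantom13.stack, depth=depth, enforce_depth_range=False
            )
            split = count_acini(subs, parent=phantom13.stack)
            assert split.n_acini == whole.n_acini == 13
            assert sum(split.per_substack_counts) == split.n_acini
            assert len({e.label for e in split.entrances}) == split.n_acini

    def test_substack_attribution_is_unique(self, phantom13):
        subs = split_substacks(phantom13.stack, depth=80, enforce_depth_range=False)
        res = count_acini(subs, parent=phantom13.stack)
        for e in res.entrances:
            lo, hi = subs.ranges[e.substack_index]
            assert lo <= e.position[0] < hi

    def test_empty_stack_counts_zero(self):
        empty = ImageStack(np.full((60, 40, 40), AIR_GRAY, np.uint8), 2.35)
        # some tissue so thresholding is well defined, but no airways
        empty.voxels[0:2] = TISSUE_GRAY
        res = count_acini(empty)
        assert res.n_acini == 0

    def test_inconsistent_voxel_sizes_rejected(self, phantom13):
        subs = split_substacks(phantom13.stack, depth=80, enforce_depth_range=False)
        subs.substacks[0].stack.voxel_size = 3.0
        with pytest.raises(ValueError, match="voxel sizes"):
            count_acini(subs, parent=phantom13.stack)
        subs.substacks[0].stack.voxel_size = 2.35


class TestResolutionLimit:
    def test_published_count_pattern(self):
        # the regions of interest kept their counts down to 3.6 µm and lost
        # acini from 4 µm on
        sizes = [2.35, 3, 3.5, 3.6, 4, 5, 10]
        counts = [13, 13, 13, 13, 11, 9, 4]
        assert resolution_limit(sizes, counts) == 3.6

    def test_all_equal_returns_largest(self):
        assert resolution_limit([2, 3, 4], [9, 9, 9]) == 4

    def test_immediate_decrease_returns_native(self):
        assert resolution_limit([2, 3, 4], [9, 8, 7]) == 2

    def test_unsorted_sizes_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            resolution_limit([3, 2], [5, 5])
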