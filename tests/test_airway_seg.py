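"""Stopper placement, region growing, and generation numbering."""

import numpy as np
import pytest
from scipy import ndimage as ndi

import acinostat.airway_seg as aseg
from acinostat import detect as adet
from acinostat._skeleton import SkeletonGraph, bfs_tree, junction_generations
from acinostat.imaging import ImageStack
from acinostat.phantom import AIR_GRAY, TISSUE_GRAY
from tests.test_detect import straight_tube_stack


@pytest.fixture(scope="module")
def segmented13(phantom13):
    """Stoppers at the true entrances + region growing on the 13-acinus
    phantom (shared across the module's tests)."""
    ph = phantom13
    thr = adet.resolve_threshold(ph.stack, "otsu")
    rmap = aseg.lumen_radius_map(ph.stack, thr)
    stoppers = aseg.place_stoppers([e.position for e in ph.truth], rmap, 1.5)
    b0 = ph.tree.branches[0]
    seed = tuple(
        np.round((b0.p0 + b0.direction * 8 - ph.origin_um) / 2.35).astype(int)
    )
    seg = aseg.region_grow(ph.stack, [seed], thr, stoppers, downsample_factor=2)
    return ph, thr, stoppers, seed, seg


class TestPlaceStoppers:
    def test_one_sphere_per_entrance(self, segmented13):
        ph, thr, stoppers, _, _ = segmented13
        assert len(stoppers) == 13
        rmap = aseg.lumen_radius_map(ph.stack, thr)
        for (pos, r), label in zip(stoppers.spheres, stoppers.source_labels):
            assert r >= rmap[pos]  # radius at least the local lumen radius

    def test_small_radius_factor_rejected(self, phantom13):
        thr = adet.resolve_threshold(phantom13.stack, "otsu")
        rmap = aseg.lumen_radius_map(phantom13.stack, thr)
        with pytest.raises(ValueError, match="radius_factor"):
            aseg.place_stoppers([(5, 5, 5)], rmap, radius_factor=0.8)

    def test_entrance_in_tissue_rejected_by_label(self, phantom13):
        thr = adet.resolve_threshold(phantom13.stack, "otsu")
        rmap = aseg.lumen_radius_map(phantom13.stack, thr)
        tissue_voxel = tuple(np.argwhere(phantom13.tissue_mask)[0])
        with pytest.raises(ValueError, match="E0001"):
            aseg.place_stoppers([tissue_voxel], rmap, 1.5)


class TestRegionGrow:
    def test_open_tube_fully_segmented(self):
        s = straight_tube_stack()
        seg = aseg.region_grow(s, [(60, 32, 32)], 115.0, None, downsample_factor=1)
        z, y, x = np.indices(s.shape)
        lumen = np.sqrt((y - 32) ** 2 + (x - 32) ** 2) <= 5
        assert (seg.conducting_mask & lumen).sum() / lumen.sum() > 0.99

    def test_mid_tube_stopper_blocks_distal_lumen(self):
        s = straight_tube_stack()
        stoppers = aseg.StopperSet(
            spheres=[((60, 32, 32), 1.5 * 5 * 2.35)], source_labels=["E0001"]
        )
        seg = aseg.region_grow(s, [(5, 32, 32)], 115.0, stoppers, downsample_factor=1)
        assert seg.conducting_mask[20, 32, 32]
        assert not seg.conducting_mask[100, 32, 32]  # distal of the sphere

    def test_stopper_impermeability_exact(self, segmented13):
        """The grown set never contains a voxel inside a stopper sphere."""
        ph, _, stoppers, _, seg = segmented13
        f = seg.downsample_factor
        for (c, r_um) in stoppers.spheres:
            c_ds = np.array(c) / f
            r_vox = r_um / (2.35 * f)
            lo = np.maximum(np.floor(c_ds - r_vox).astype(int), 0)
            hi = np.minimum(
                np.ceil(c_ds + r_vox).astype(int) + 1, seg.conducting_mask.shape
            )
            zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            inside = (zz - c_ds[0]) ** 2 + (yy - c_ds[1]) ** 2 + (
                xx - c_ds[2]
            ) ** 2 <= r_vox**2
            assert not (seg.conducting_mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] & inside).any()

    def test_no_leak_and_high_coverage(self, segmented13):
        ph, _, _, _, seg = segmented13
        up = aseg.upsample_mask(seg, ph.stack.shape)
        assert int((up & ph.acinar_mask).sum()) == 0
        coverage = (up & ph.conducting_mask).sum() / ph.conducting_mask.sum()
        assert coverage >= 0.95

    def test_seed_invariance_within_lumen(self, segmented13):
        ph, thr, stoppers, seed, seg = segmented13
        other = (seed[0] + 20, seed[1], seed[2])
        assert ph.stack.voxels[other] < thr
        seg2 = aseg.region_grow(ph.stack, [other], thr, stoppers, 2)
        assert np.array_equal(seg.conducting_mask, seg2.conducting_mask)

    def test_seed_validation(self, phantom13):
        thr = adet.resolve_threshold(phantom13.stack, "otsu")
        tissue_voxel = tuple(np.argwhere(phantom13.tissue_mask)[100])
        with pytest.raises(ValueError, match="air voxel"):
            aseg.region_grow(phantom13.stack, [tissue_voxel], thr, None, 2)

    def test_seed_inside_stopper_rejected(self):
        s = straight_tube_stack()
        stoppers = aseg.StopperSet(
            spheres=[((60, 32, 32), 40.0)], source_labels=["E0001"]
        )
        with pytest.raises(ValueError, match="stopper"):
            aseg.region_grow(s, [(60, 32, 32)], 115.0, stoppers, 1)

    def test_downsampled_mask_loses_few_lumen_voxels(self, segmented13):
        """Factor-2 growing, upsampled back, misses <5% of the conducting
        lumen it can reach (air-preserving block-minimum downsampling)."""
        ph, _, _, _, seg = segmented13
        up = aseg.upsample_mask(seg, ph.stack.shape)
        missed = (ph.conducting_mask & ~up).sum() / ph.conducting_mask.sum()
        assert missed < 0.05


class TestGenerations:
    def test_unbranched_tube_is_generation_zero(self):
        s = straight_tube_stack()
        seg = aseg.region_grow(s, [(60, 32, 32)], 115.0, None, downsample_factor=1)
        seg = aseg.assign_generations(seg)
        assert set(seg.node_generation.tolist()) == {0}

    def test_perfect_binary_tree_depth_four(self):
        """On an ideal binary-tree skeleton, leaves sit at generation 4.

        Branch levels alternate their divergence axis (y, x, y, x) with
        shrinking magnitudes so no two chains ever become 26-adjacent
        except at their shared junction.
        """
        voxels: set[tuple[int, int, int]] = set()

        def chain(start, depth):
            """Diagonal 8-step chains to the two children; returns ends."""
            z0, y0, x0 = start
            axis = depth % 2  # 0: diverge in y, 1: diverge in x
            step_every = 1 if depth < 2 else 2  # magnitudes 8, 8, 4, 4
            ends = []
            for sign in (-1, 1):
                z, y, x = z0, y0, x0
                for k in range(1, 9):
                    z = z0 + k
                    if k % step_every == 0:
                        if axis == 0:
                            y += sign
                        else:
                            x += sign
                    voxels.add((z, y, x))
                ends.append((z, y, x))
            return ends

        root_pos = (0, 32, 32)
        voxels.add(root_pos)
        frontier = [root_pos]
        for depth in range(4):
            nxt = []
            for node in frontier:
                nxt.extend(chain(node, depth))
            frontier = nxt
        grid = np.zeros((40, 64, 64), bool)
        for v in voxels:
            grid[v] = True
        g = SkeletonGraph(np.argwhere(grid), grid.shape)
        root = int(np.argmin(g.coords[:, 0]))
        parent, dist, order = bfs_tree(g, root)
        gen = junction_generations(g, parent, order)
        deg = g.degrees
        leaves = (deg == 1) & (np.arange(len(g)) != root)
        assert leaves.sum() == 16
        assert set(gen[leaves].tolist()) == {4}

    def test_phantom_entrance_generations_annotated(self, phantom25):
        """Generations annotated from the segmented tree agree with the
        generator's bookkeeping for most entrances and bracket the
        configured range."""
        ph = phantom25
        thr = adet.resolve_threshold(ph.stack, "otsu")
        rmap = aseg.lumen_radius_map(ph.stack, thr)
        stoppers = aseg.place_stoppers([e.position for e in ph.truth], rmap, 1.5)
        b0 = ph.tree.branches[0]
        seed = tuple(
            np.round((b0.p0 + b0.direction * 8 - ph.origin_um) / 2.35).astype(int)
        )
        seg = aseg.region_grow(ph.stack, [seed], thr, stoppers, 2)
        seg = aseg.assign_generations(seg)
        gens = aseg.entrance_generations(seg, [e.position for e in ph.truth])
        gt = [e.generation for e in ph.truth]
        exact = sum(int(a == b) for a, b in zip(gens, gt)) / len(gt)
        assert exact >= 0.6
        assert all(abs(a - b) <= 1 for a, b in zip(gens, gt))
        gmin, gmax = ph.params.generation_range_entrances
        assert abs(min(gens) - gmin) <= 1 and abs(max(gens) - gmax) <= 1

    def test_disconnected_mask_rejected(self):
        vox = np.full((40, 40, 40), AIR_GRAY, np.uint8)
        vox[5:10, 5:10, 5:10] = AIR_GRAY
        mask = np.zeros((20, 20, 20), bool)
        mask[2:5, 2:5, 2:5] = True
        mask[12:15, 12:15, 12:15] = True
        seg = aseg.AirwaySegmentation(
            conducting_mask=mask, downsample_factor=1, voxel_size=2.35, seeds=[]
        )
        with pytest.raises(ValueError, match="components"):
            aseg.assign_generations(seg)
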