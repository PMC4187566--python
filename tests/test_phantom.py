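"""Synthetic airway-tree generation and voxelization."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from acinostat.detect import wall_thickness_map
from acinostat.phantom import (
    GeometryError,
    TreeParams,
    generate_airway_tree,
    voxelize_tree,
)
from tests.conftest import make_phantom


class TestTreeParams:
    def test_wall_contrast_invariant(self):
        with pytest.raises(ValueError, match="2x"):
            TreeParams(n_acini_target=5, wall_thickness_conducting=8.0,
                       wall_thickness_acinar=5.0)

    def test_generation_range_bounds(self):
        with pytest.raises(ValueError, match="4, 25"):
            TreeParams(n_acini_target=5, generation_range_entrances=(2, 8))
        with pytest.raises(ValueError, match="4, 25"):
            TreeParams(n_acini_target=5, generation_range_entrances=(4, 30))

    def test_fractions_validated(self):
        with pytest.raises(ValueError):
            TreeParams(n_acini_target=5, dual_entrance_fraction=1.2)
        with pytest.raises(ValueError):
            TreeParams(n_acini_target=5, monopodial_bias=-0.1)


class TestTreeStructure:
    def test_thirteen_acini_realized_exactly(self):
        tree = generate_airway_tree(
            TreeParams(n_acini_target=13, seed=1,
                       generation_range_entrances=(4, 8))
        )
        assert len({e.acinus_id for e in tree.entrances}) == 13
        assert tree.n_realized == 13

    def test_one_transitional_bronchiole_per_path(self):
        """Walking from any entrance to the root crosses exactly one
        transitional bronchiole."""
        tree = generate_airway_tree(
            TreeParams(n_acini_target=25, seed=7,
                       generation_range_entrances=(4, 9),
                       dual_entrance_fraction=0.3)
        )
        for e in tree.entrances:
            count = 0
            b = tree.branch(e.branch_id)
            while b is not None:
                if b.btype == "transitional_bronchiole":
                    count += 1
                b = tree.branch(b.parent_id) if b.parent_id is not None else None
            assert count == 1

    def test_terminal_bronchioles_have_transitional_children(self):
        tree = generate_airway_tree(
            TreeParams(n_acini_target=25, seed=7,
                       generation_range_entrances=(4, 9),
                       dual_entrance_fraction=0.3)
        )
        children = {}
        for b in tree.branches:
            if b.parent_id is not None:
                children.setdefault(b.parent_id, []).append(b)
        for b in tree.branches:
            if b.btype == "terminal_bronchiole":
                kinds = [c.btype for c in children.get(b.id, [])]
                assert kinds.count("transitional_bronchiole") >= 1

    def test_transitional_bronchioles_own_one_or_two_entrances(self):
        tree = generate_airway_tree(
            TreeParams(n_acini_target=24, seed=4,
                       generation_range_entrances=(4, 9),
                       dual_entrance_fraction=0.5)
        )
        per_trb = {}
        for e in tree.entrances:
            per_trb.setdefault(e.branch_id, []).append(e)
        for bid, ents in per_trb.items():
            assert tree.branch(bid).btype == "transitional_bronchiole"
            assert len(ents) in (1, 2)
        # every acinus id appears exactly once
        ids = [e.acinus_id for e in tree.entrances]
        assert len(ids) == len(set(ids))

    def test_dual_fraction_zero_means_single_entrances(self):
        tree = generate_airway_tree(
            TreeParams(n_acini_target=12, seed=2,
                       generation_range_entrances=(4, 8),
                       dual_entrance_fraction=0.0)
        )
        per_trb = {}
        for e in tree.entrances:
            per_trb.setdefault(e.branch_id, []).append(e)
        assert all(len(v) == 1 for v in per_trb.values())
        assert all(e.dual_of is None for e in tree.entrances)

    def test_dual_fraction_one_doubles_transitional_bronchioles(self):
        tree = generate_airway_tree(
            TreeParams(n_acini_target=12, seed=2,
                       generation_range_entrances=(4, 8),
                       dual_entrance_fraction=1.0)
        )
        trbs_with_entrances = {e.branch_id for e in tree.entrances}
        assert len(tree.entrances) == 2 * len(trbs_with_entrances)
        assert all(e.dual_of is not None for e in tree.entrances)

    def test_dual_fraction_approximated_at_scale(self):
        """For a large target the realized fraction of branched transitional
        bronchioles tracks the requested fraction within 0.1."""
        tree = generate_airway_tree(
            TreeParams(n_acini_target=100, seed=3,
                       generation_range_entrances=(4, 15),
                       dual_entrance_fraction=0.3)
        )
        per_trb = {}
        for e in tree.entrances:
            per_trb.setdefault(e.branch_id, []).append(e)
        frac = sum(1 for v in per_trb.values() if len(v) == 2) / len(per_trb)
        assert abs(frac - 0.3) <= 0.1

    def test_entrance_generations_inside_requested_range(self):
        tree = generate_airway_tree(
            TreeParams(n_acini_target=25, seed=9,
                       generation_range_entrances=(5, 9))
        )
        gens = [e.generation for e in tree.entrances]
        assert min(gens) >= 5 and max(gens) <= 9

    def test_unsatisfiable_geometry_raises(self):
        # far too many acini for the narrowest generation band
        with pytest.raises(GeometryError):
            generate_airway_tree(
                TreeParams(n_acini_target=400, seed=0,
                           generation_range_entrances=(4, 5))
            )


class TestVoxelization:
    def test_deterministic_rendering(self):
        a = make_phantom(6, seed=42, gen_range=(4, 6))
        b = make_phantom(6, seed=42, gen_range=(4, 6))
        assert np.array_equal(a.stack.voxels, b.stack.voxels)
        assert [e.position for e in a.truth] == [e.position for e in b.truth]

    def test_masks_disjoint_and_lumen_connected(self, phantom13):
        ph = phantom13
        assert not (ph.conducting_mask & ph.acinar_mask).any()
        assert not (ph.tissue_mask & (ph.conducting_mask | ph.acinar_mask)).any()
        lum = ph.conducting_mask | ph.acinar_mask
        lab, _ = ndi.label(~ph.tissue_mask, ndi.generate_binary_structure(3, 1))
        ids = set(np.unique(lab[lum])) - {0}
        assert len(ids) == 1
        # the lumen never merges with the background surrounding the lobe
        edge = set(np.unique(np.concatenate([
            lab[:, 0].ravel(), lab[:, -1].ravel(),
            lab[:, :, 0].ravel(), lab[:, :, -1].ravel(),
        ]))) - {0}
        assert not (ids & edge)

    def test_entrances_inside_lumen(self, phantom13):
        lum = phantom13.conducting_mask | phantom13.acinar_mask
        for e in phantom13.truth:
            assert lum[e.position]

    def test_wall_thickness_contrast_in_rendered_stack(self, phantom13):
        """Local thickness at conducting walls is at least twice that of
        acinar walls (the detectability guarantee), measured by the
        inscribed-sphere transform on ground-truth tissue."""
        ph = phantom13
        v = ph.stack.voxel_size
        crop = tuple(slice(0, min(s, 180)) for s in ph.tissue_mask.shape)
        tis = ph.tissue_mask[crop]
        lt = wall_thickness_map(tis, v)
        dil = ndi.binary_dilation(ph.conducting_mask[crop],
                                  ndi.generate_binary_structure(3, 1))
        cond_wall = dil & tis
        dil_a = ndi.binary_dilation(ph.acinar_mask[crop],
                                    ndi.generate_binary_structure(3, 1))
        acin_wall = dil_a & tis & ~cond_wall
        t_cond = np.median(lt[cond_wall])
        t_acin = np.median(lt[acin_wall])
        assert t_cond / t_acin >= 2.0

    def test_voxel_budget_enforced(self):
        params = TreeParams(n_acini_target=5, seed=0,
                            generation_range_entrances=(4, 6))
        tree = generate_airway_tree(params)
        with pytest.raises(ValueError, match="budget"):
            voxelize_tree(tree, 2.35, voxel_budget=1000)

    def test_voxel_size_must_resolve_conducting_wall(self):
        params = TreeParams(n_acini_target=5, seed=0,
                            generation_range_entrances=(4, 6))
        tree = generate_airway_tree(params)
        with pytest.raises(ValueError, match="wall"):
            voxelize_tree(tree, 9.0)

    def test_two_class_grayscale_with_noise(self, phantom13):
        vox = phantom13.stack.voxels
        tis = phantom13.tissue_mask
        assert abs(float(vox[tis].mean()) - 200) < 3
        assert abs(float(vox[~tis].mean()) - 30) < 3
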