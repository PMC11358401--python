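import numpy as np
import pytest

from hemilabel import (
    MirrorConfig,
    PhantomSpec,
    RigidTransform,
    compose_full_brain,
    make_phantom_hemisphere,
    mask_background,
    mirror_cost,
    optimize_mirror_transform,
    reflect_across_midplane,
)
from hemilabel.mirroring import adaptive_alpha
from hemilabel.core import LabelMap

from conftest import ras_affine
from oracles import mirror_shift_gridsearch


def single_voxel_mask(world_x):
    a = ras_affine(1.0, (world_x, 0.0, 0.0))
    return LabelMap(np.ones((1, 1, 1), dtype=np.int32), a)


class TestRigidTransform:
    def test_rotation_determinant_is_one(self):
        t = RigidTransform([10, -20, 30], [1, 2, 3])
        assert np.linalg.det(t.matrix[:3, :3]) == pytest.approx(1.0)

    def test_inverse_roundtrip(self):
        rng = np.random.default_rng(0)
        t = RigidTransform(rng.uniform(-30, 30, 3), rng.uniform(-5, 5, 3))
        pts = rng.uniform(-10, 10, (20, 3))
        back = t.inverse().apply(t.apply(pts))
        np.testing.assert_allclose(back, pts, atol=1e-10)

    def test_compose_matches_sequential_application(self):
        rng = np.random.default_rng(1)
        t1 = RigidTransform(rng.uniform(-20, 20, 3), rng.uniform(-3, 3, 3))
        t2 = RigidTransform(rng.uniform(-20, 20, 3), rng.uniform(-3, 3, 3))
        pts = rng.uniform(-5, 5, (10, 3))
        np.testing.assert_allclose(
            t1.compose(t2).apply(pts), t1.apply(t2.apply(pts)), atol=1e-10
        )

    def test_dict_roundtrip(self):
        t = RigidTransform([1.5, -2.0, 0.25], [4.0, 0.0, -1.0])
        back = RigidTransform.from_dict(t.to_dict())
        np.testing.assert_allclose(back.rotation, t.rotation)
        np.testing.assert_allclose(back.translation, t.translation)


class TestMirrorCost:
    def test_positive_crossing_voxel(self):
        # one voxel at x = +2 mm, alpha 0.5: cost = 2 - 0.5*2
        assert mirror_cost(single_voxel_mask(2.0), RigidTransform(), 0.5) == pytest.approx(1.0)

    def test_negative_voxel(self):
        # one voxel at x = -3 mm, alpha 0.5: cost = 0 - 0.5*(-3)
        assert mirror_cost(single_voxel_mask(-3.0), RigidTransform(), 0.5) == pytest.approx(1.5)

    def test_alpha_limit_for_noncrossing_mask(self, brain_mask):
        # all voxels at x < 0: crossing term vanishes, cost -> 0 as alpha -> 0
        for alpha in (1e-2, 1e-4, 1e-6):
            c = mirror_cost(brain_mask, RigidTransform(), alpha)
            assert c >= 0.0
        assert mirror_cost(brain_mask, RigidTransform(), 1e-6) < mirror_cost(
            brain_mask, RigidTransform(), 1e-2
        )

    def test_crossing_always_net_penalized(self):
        # moving a voxel from the plane to +d increases cost by (1-alpha)d > 0
        for alpha in (0.1, 0.5, 0.9):
            at_plane = mirror_cost(single_voxel_mask(0.0), RigidTransform(), alpha)
            crossed = mirror_cost(single_voxel_mask(1.0), RigidTransform(), alpha)
            assert crossed - at_plane == pytest.approx(1.0 - alpha)
            assert crossed > at_plane

    def test_empty_mask_rejected(self):
        lm = LabelMap(np.zeros((2, 2, 2), dtype=np.int32), ras_affine())
        with pytest.raises(ValueError, match="empty"):
            mirror_cost(lm, RigidTransform(), 0.1)


class TestOptimize:
    def test_flush_hemisphere_gives_identity(self):
        # voxels already flush: medial face on the plane
        data = np.zeros((10, 6, 6), dtype=np.int32)
        data[:, 1:5, 1:5] = 1
        a = ras_affine(1.0, (-9.0, 0.0, 0.0))  # x centres -9..0
        mask = LabelMap(data, a)
        t = optimize_mirror_transform(mask, MirrorConfig(dof="rigid"))
        assert np.linalg.norm(t.translation) < 0.1
        assert np.all(np.abs(t.rotation) < 0.1)

    def test_translation_matches_grid_search_oracle(self, brain_mask):
        cfg = MirrorConfig(dof="tx")
        t = optimize_mirror_transform(brain_mask, cfg)
        xs = brain_mask.world_coordinates(np.argwhere(brain_mask.data > 0))[:, 0]
        alpha = adaptive_alpha(xs, float(np.max(brain_mask.spacing)))
        t_star, _ = mirror_shift_gridsearch(xs, alpha, -2.0, 6.0, step=0.01)
        assert abs(t.translation[0] - t_star) <= 0.05

    def test_gap_hemisphere_shifted_flush(self):
        # mask occupying x in [-10, -4]: optimal shift ~ +4 mm
        data = np.zeros((16, 8, 8), dtype=np.int32)
        data[2:9, 2:6, 2:6] = 1
        a = ras_affine(1.0, (-12.0, 0.0, 0.0))  # occupied centres -10..-4
        mask = LabelMap(data, a)
        t = optimize_mirror_transform(mask, MirrorConfig(dof="tx"))
        assert t.translation[0] == pytest.approx(4.0, abs=0.05)

    def test_crossing_hemisphere_pulled_back(self):
        data = np.zeros((16, 8, 8), dtype=np.int32)
        data[2:16, 2:6, 2:6] = 1
        a = ras_affine(1.0, (-12.0, 0.0, 0.0))  # occupied centres -10..+3
        mask = LabelMap(data, a)
        cfg = MirrorConfig(dof="tx", crossing_tolerance=0.5)
        t = optimize_mirror_transform(mask, cfg)
        x_after = t.apply(mask.world_coordinates(np.argwhere(mask.data > 0)))[:, 0]
        assert (x_after > cfg.crossing_tolerance).sum() == 0
        assert x_after.max() >= -2.0

    def test_cost_history_monotone_in_best_so_far(self, brain_mask):
        _, history = optimize_mirror_transform(
            brain_mask, MirrorConfig(), return_history=True
        )
        best = np.minimum.accumulate(history)
        assert np.all(np.diff(best) <= 0)

    def test_deterministic(self, brain_mask):
        t1 = optimize_mirror_transform(brain_mask, MirrorConfig())
        t2 = optimize_mirror_transform(brain_mask, MirrorConfig())
        np.testing.assert_array_equal(t1.translation, t2.translation)
        np.testing.assert_array_equal(t1.rotation, t2.rotation)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MirrorConfig(alpha=1.5)
        with pytest.raises(ValueError):
            MirrorConfig(crossing_tolerance=-1.0)
        with pytest.raises(ValueError):
            MirrorConfig(dof="scaling")


class TestReflect:
    def test_involution(self, clean_phantom):
        _, lm = clean_phantom
        back = reflect_across_midplane(reflect_across_midplane(lm))
        np.testing.assert_array_equal(back.data, lm.data)
        np.testing.assert_allclose(back.affine, lm.affine, atol=1e-12)

    def test_world_x_negated(self):
        data = np.zeros((10, 4, 4), dtype=np.int32)
        data[1:7, 1, 1] = 1  # centres x in [-6, -1]
        lm = LabelMap(data, ras_affine(1.0, (-7.0, 0.0, 0.0)))
        out = reflect_across_midplane(lm)
        xs = out.world_coordinates(np.argwhere(out.data > 0))[:, 0]
        assert xs.min() == pytest.approx(1.0)
        assert xs.max() == pytest.approx(6.0)

    def test_label_counts_preserved(self, merged_map):
        out = reflect_across_midplane(merged_map)
        for lid in merged_map.ids():
            assert (out.data == lid).sum() == (merged_map.data == lid).sum()


@pytest.fixture(scope="module")
def full_brain(merged_map, brain_mask):
    cfg = MirrorConfig()
    t = optimize_mirror_transform(brain_mask, cfg)
    return compose_full_brain(merged_map, t, cfg), merged_map


class TestCompose:
    def test_ten_distinct_subregions(self, full_brain):
        full, _ = full_brain
        sub = [i for i in full.ids() if 1 <= i <= 10]
        assert sub == list(range(1, 11))

    def test_hemisphere_masks_disjoint(self, full_brain):
        full, _ = full_brain
        left = full.data[: full.shape[0] // 2]
        right = full.data[full.shape[0] // 2:]
        # mirrored copy occupies the reflected voxels of the other half:
        # overlap would have collapsed labels; check by reflective symmetry
        swapped = full.data[::-1].copy()
        for a, b in zip(range(1, 6), range(6, 11)):
            tmp = swapped.copy()
            swapped[tmp == a] = b
            swapped[tmp == b] = a
        np.testing.assert_array_equal(swapped, full.data)
        assert (left > 0).sum() == (right > 0).sum()

    def test_subregion_count_doubles(self, full_brain):
        full, merged = full_brain
        single = int(np.isin(merged.data, range(1, 6)).sum())
        double = int(np.isin(full.data, range(1, 11)).sum())
        assert abs(double - 2 * single) <= 0.02 * 2 * single

    def test_context_ids_kept_on_both_sides(self, full_brain):
        full, merged = full_brain
        ctx_ids = [i for i in merged.ids() if i > 100]
        half = full.shape[0] // 2
        for cid in ctx_ids:
            assert (full.data[:half] == cid).sum() > 0
            assert (full.data[half:] == cid).sum() > 0

    def test_grid_symmetric_about_midplane(self, full_brain):
        full, _ = full_brain
        xs = full.affine[0, 0] * np.arange(full.shape[0]) + full.affine[0, 3]
        np.testing.assert_allclose(xs + xs[::-1], 0.0, atol=1e-9)

    def test_requires_subregions(self, brain_mask):
        ctx_only = LabelMap(
            (brain_mask.data * 101).astype(np.int32), brain_mask.affine.copy()
        )
        with pytest.raises(ValueError, match="subregion"):
            compose_full_brain(ctx_only, RigidTransform())
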