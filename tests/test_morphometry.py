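"""Strahler orders, terminal-segment stats, boundary/span volumes."""

import numpy as np
import pytest

import arbordyn as ad
from arbordyn.errors import DegenerateGeometryError, UndefinedStatisticError
from arbordyn.morphometry import _AlphaComplex
from arbordyn.simulate import GrowthSimConfig, random_arbor, simulate_series


def node_strahler_oracle(arbor):
    """Independent recursive node-based Strahler order (leaves 1; an
    internal node takes max of child orders, +1 on a tie at the max)."""
    import sys

    sys.setrecursionlimit(10000)

    def rec(k):
        ch = arbor._children[k]
        if not ch:
            return 1
        orders = [rec(c) for c in ch]
        top = max(orders)
        return top + 1 if orders.count(top) >= 2 else top

    return {int(arbor.ids[k]): rec(k) for k in range(arbor.n_nodes)}


class TestStrahler:
    def test_unbranched_path_single_order_one(self):
        a = ad.Arbor([1, 2, 3], [-1, 1, 2], np.c_[np.arange(3), np.zeros((3, 2))])
        assert list(ad.strahler_orders(a).values()) == [1]

    def test_y_shape(self, y_arbor):
        orders = ad.strahler_orders(y_arbor)
        assert sorted(orders.values()) == [1, 1, 2]
        stem = next(s for s in orders if s.kind == "internal")
        assert orders[stem] == 2

    def test_perfect_binary_tree_depth(self, binary_arbor):
        assert max(ad.strahler_orders(binary_arbor).values()) == 4

    def test_matches_recursive_oracle_on_random_trees(self):
        for seed in range(200):
            a = random_arbor(seed, n_branches=int(2 + seed % 14))
            oracle = node_strahler_oracle(a)
            for seg, order in ad.strahler_orders(a).items():
                assert order == oracle[seg.distal_id], f"seed {seed}"


class TestTerminalSegments:
    def test_y_lengths(self, y_arbor):
        assert ad.terminal_segment_lengths(y_arbor) == pytest.approx([5.0, 5.0])

    def test_unbranched_axon(self):
        a = ad.Arbor([1, 2], [-1, 1], np.array([[0, 0, 0], [10.0, 0, 0]]))
        assert ad.terminal_segment_lengths(a) == pytest.approx([10.0])
        assert ad.skeleton_length(a) == 0.0

    def test_skeleton_is_stem_for_y(self, y_arbor):
        assert ad.skeleton_length(y_arbor) == pytest.approx(10.0)

    def test_conservation_on_random_trees(self, random_arbors):
        for a in random_arbors:
            total = sum(ad.terminal_segment_lengths(a)) + ad.skeleton_length(a)
            assert total == pytest.approx(a.total_length, abs=1e-6)

    def test_terminal_point_counts(self, y_arbor, random_arbors):
        assert ad.count_terminal_points(y_arbor) == 2
        for a in random_arbors:
            n_order1 = sum(
                1 for o in ad.strahler_orders(a).values() if o == 1
            )
            assert ad.count_terminal_points(a) == n_order1


class TestBinning:
    def test_arithmetic_example(self):
        pct = ad.bin_terminal_segments([2.0, 3.0, 7.0])
        assert pct["<5 um"] == pytest.approx(200 / 3)
        assert pct["5-10 um"] == pytest.approx(100 / 3)
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)

    def test_single_bin_all(self):
        pct = ad.bin_terminal_segments([2.0, 2.5, 4.9])
        assert pct["<5 um"] == pytest.approx(100.0)

    def test_below_threshold_excluded(self):
        pct = ad.bin_terminal_segments([1.0, 2.0])  # 1.0 below the 1.5 floor
        assert sum(pct.values()) == pytest.approx(100.0)
        assert pct["<5 um"] == pytest.approx(100.0)

    def test_empty_distribution_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            ad.bin_terminal_segments([1.0])

    def test_permutation_invariance(self, rng):
        lengths = rng.uniform(1.5, 20, 30)
        a = ad.bin_terminal_segments(list(lengths))
        b = ad.bin_terminal_segments(list(rng.permutation(lengths)))
        for k in a:
            assert a[k] == pytest.approx(b[k])


CUBE = np.array(
    [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
)


class TestBoundaryVolume:
    def test_unit_cube_hull(self):
        assert ad.boundary_volume(CUBE, shrink=0.0) == pytest.approx(1.0)

    def test_monotone_in_shrink(self):
        series, _ = simulate_series(GrowthSimConfig(seed=31))
        for pts in (CUBE, series.arbors[0].xyz):
            ac = _AlphaComplex(pts)
            vols = [ac.volume_at_shrink(s) for s in np.linspace(0, 1, 5)]
            assert all(a >= b - 1e-9 for a, b in zip(vols, vols[1:]))
            assert vols[-1] <= vols[0] + 1e-9

    def test_degenerate_coplanar_rejected(self):
        flat = np.c_[np.random.default_rng(0).uniform(size=(20, 2)), np.zeros(20)]
        with pytest.raises(DegenerateGeometryError):
            ad.boundary_volume(flat, 0.0)

    def test_l_slab_tight_volume_matches_voxel_oracle(self):
        # L-shaped slab: two 0.5 μm-thick arms; dense surface+interior points
        g = 0.25
        xs = np.arange(0, 4 + g / 2, g)
        ys = np.arange(0, 4 + g / 2, g)
        zs = np.arange(0, 0.5 + g / 2, g)
        pts = np.array(
            [
                [x, y, z]
                for x in xs
                for y in ys
                for z in zs
                if x <= 1.0 or y <= 1.0
            ]
        )
        ac = _AlphaComplex(pts)
        tight = ac.volume_at_shrink(1.0)
        # voxel integration of the kept complex at 0.05 μm
        keep = ac.radii <= ac.r_tight + 1e-12
        vg = 0.05
        centers = np.array(
            [
                [x + vg / 2, y + vg / 2, z + vg / 2]
                for x in np.arange(0, 4, vg)
                for y in np.arange(0, 4, vg)
                for z in np.arange(0, 0.5, vg)
            ]
        )
        simp = ac.tri.find_simplex(centers)
        inside = (simp >= 0) & keep[simp]
        voxel_volume = inside.sum() * vg**3
        assert tight == pytest.approx(voxel_volume, rel=0.05)


class TestSpanVolume:
    def test_solid_cube_cloud_is_convex(self, rng):
        g = np.linspace(0, 1, 9)
        pts = np.array([[x, y, z] for x in g for y in g for z in g])
        pts += rng.normal(0, 0.005, pts.shape)
        res = ad.span_volume(pts)
        assert res.convexity > 0.9
        assert res.span_volume == pytest.approx(res.hull_volume, rel=0.05)

    def test_thin_v_is_nonconvex(self):
        t = np.linspace(0, 1, 60)
        arm1 = np.c_[t * 10, t * 10, np.zeros_like(t)]
        arm2 = np.c_[t * 10, -t * 10, np.zeros_like(t)]
        pts = np.vstack([arm1, arm2]) + np.random.default_rng(2).normal(
            0, 0.3, (120, 3)
        )
        res = ad.span_volume(pts)
        assert res.convexity < 1.0
        assert res.span_volume < res.hull_volume

    def test_span_between_tight_and_hull_on_simulations(self):
        for seed in (41, 42, 43):
            series, _ = simulate_series(GrowthSimConfig(seed=seed))
            res = ad.span_volume(series.arbors[-1])
            assert res.tight_volume <= res.span_volume + 1e-9
            assert res.span_volume <= res.hull_volume + 1e-9
            assert res.convexity == pytest.approx(
                res.tight_volume / res.hull_volume
            )


class TestExpansionIndex:
    def test_identity_and_threefold(self):
        assert ad.expansion_index(5.0, 5.0) == 0.0
        assert ad.expansion_index(1.0, 3.0) == pytest.approx(0.5)

    def test_antisymmetry(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.1, 10, 2)
            assert ad.expansion_index(a, b) == pytest.approx(
                -ad.expansion_index(b, a)
            )

    def test_zero_volumes_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            ad.expansion_index(0.0, 0.0)
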