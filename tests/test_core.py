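"""Tree model, SWC round trips, segments, resampling, rigid alignment."""

import numpy as np
import pytest

import arbordyn as ad
from arbordyn.errors import DegenerateFitError, SWCFormatError
from arbordyn.simulate import GrowthSimConfig, random_arbor, simulate_series


def _write(tmp_path, text):
    p = tmp_path / "a.swc"
    p.write_text(text)
    return p


class TestReadSWC:
    def test_three_node_line(self, tmp_path):
        p = _write(tmp_path, "1 2 0 0 0 1 -1\n2 2 0 0 1 1 1\n3 2 0 0 2 1 2\n")
        a = ad.read_swc(p)
        assert a.n_nodes == 3
        assert a.total_length == pytest.approx(2.0)

    def test_comments_and_blank_lines_ignored(self, tmp_path):
        p = _write(tmp_path, "# header\n\n1 2 0 0 0 1 -1\n")
        assert ad.read_swc(p).n_nodes == 1

    def test_dangling_parent_rejected(self, tmp_path):
        p = _write(tmp_path, "1 2 0 0 0 1 -1\n5 2 0 0 1 1 99\n")
        with pytest.raises(SWCFormatError, match="dangling parent"):
            ad.read_swc(p)

    def test_multiple_roots_rejected(self, tmp_path):
        p = _write(tmp_path, "1 2 0 0 0 1 -1\n2 2 1 0 0 1 -1\n")
        with pytest.raises(SWCFormatError, match="root"):
            ad.read_swc(p)

    def test_non_numeric_field_reports_line(self, tmp_path):
        p = _write(tmp_path, "1 2 0 0 0 1 -1\n2 2 x 0 1 1 1\n")
        with pytest.raises(SWCFormatError, match=":2"):
            ad.read_swc(p)


class TestWriteSWC:
    def test_single_node(self, tmp_path):
        a = ad.Arbor([1], [-1], np.zeros((1, 3)))
        p = tmp_path / "one.swc"
        ad.write_swc(a, p)
        data = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        assert len(data) == 1
        assert data[0].split()[-1] == "-1"

    def test_round_trip_random_arbors(self, tmp_path, random_arbors):
        for i, a in enumerate(random_arbors):
            p = tmp_path / f"{i}.swc"
            ad.write_swc(a, p)
            assert ad.read_swc(p).approx_equal(a, tol=1e-4)

    def test_round_trip_simulated_snapshot(self, tmp_path):
        series, _ = simulate_series(GrowthSimConfig(seed=21))
        p = tmp_path / "snap.swc"
        ad.write_swc(series.arbors[-1], p)
        assert ad.read_swc(p).approx_equal(series.arbors[-1], tol=1e-4)

    def test_shuffled_input_reemitted_parent_first(self, tmp_path, rng):
        a = random_arbor(5, n_branches=8)
        perm = rng.permutation(a.n_nodes)
        shuffled = ad.Arbor(
            a.ids[perm], a.parents[perm], a.xyz[perm], a.radius[perm],
            a.type_code[perm],
        )
        p = tmp_path / "s.swc"
        ad.write_swc(shuffled, p)
        seen = set()
        for line in p.read_text().splitlines():
            if line.startswith("#"):
                continue
            nid, parent = int(line.split()[0]), int(line.split()[-1])
            assert parent == -1 or parent in seen
            seen.add(nid)
        assert ad.read_swc(p).approx_equal(a, tol=1e-4)


class TestSegments:
    def test_unbranched_path_is_one_terminal_segment(self):
        n = 10
        a = ad.Arbor(
            range(1, n + 1), [-1] + list(range(1, n)),
            np.c_[np.arange(n), np.zeros(n), np.zeros(n)],
        )
        segs = ad.decompose_segments(a)
        assert len(segs) == 1
        assert segs[0].kind == "terminal"
        assert segs[0].length == pytest.approx(n - 1)

    def test_y_shape_three_segments(self, y_arbor):
        segs = ad.decompose_segments(y_arbor)
        kinds = sorted(s.kind for s in segs)
        assert kinds == ["internal", "terminal", "terminal"]
        assert sum(s.length for s in segs) == pytest.approx(y_arbor.total_length)

    def test_single_node_has_no_segments(self):
        a = ad.Arbor([1], [-1], np.zeros((1, 3)))
        assert ad.decompose_segments(a) == []

    def test_counts_partition_and_length_on_random_trees(self, random_arbors):
        for a in random_arbors:
            segs = ad.decompose_segments(a)
            # brute-force node classification
            n_terminal = sum(1 for k in range(a.n_nodes) if not a._children[k])
            n_branch = sum(
                1
                for k in range(a.n_nodes)
                if len(a._children[k]) >= 2 and k != a.root_index
            )
            # a segment ends at every non-root branch point and every terminal
            assert len(segs) == n_terminal + n_branch
            # each non-root node owned by exactly one segment
            owned = [i for s in segs for i in s.owned_ids]
            assert sorted(owned) == sorted(
                int(i) for i in a.ids if int(i) != a.root_id
            )
            assert sum(s.length for s in segs) == pytest.approx(
                a.total_length, abs=1e-6
            )


class TestResample:
    def test_straight_segment_even_steps(self):
        a = ad.Arbor([1, 2], [-1, 1], np.array([[0, 0, 0], [1.5, 0, 0.0]]))
        r = ad.resample_arbor(a, spacing=0.15)
        assert r.n_nodes == 11
        assert np.allclose(r.edge_lengths[1:], 0.15)

    def test_terminal_and_branch_points_preserved(self, y_arbor):
        r = ad.resample_arbor(y_arbor, 0.3)
        orig_terms = {tuple(np.round(y_arbor.position_of(i), 6))
                      for i in y_arbor.terminal_ids}
        new_terms = {tuple(np.round(r.position_of(i), 6)) for i in r.terminal_ids}
        assert orig_terms == new_terms
        assert len(r.branch_point_ids) == len(y_arbor.branch_point_ids)

    def test_spacing_tolerance_within_segments(self):
        a = random_arbor(9, n_branches=6, jitter=0.15)
        r = ad.resample_arbor(a, 0.15)
        for seg in ad.decompose_segments(r):
            steps = [
                np.linalg.norm(r.position_of(b) - r.position_of(a_))
                for a_, b in zip(seg.node_ids, seg.node_ids[1:])
            ]
            for s in steps[:-1]:  # final step of a segment may be shorter
                assert s == pytest.approx(0.15, rel=0.10)

    def test_cable_length_conserved(self, random_arbors):
        for a in random_arbors:
            if a.total_length < 0.15:
                continue
            r = ad.resample_arbor(a, 0.15)
            assert r.total_length == pytest.approx(a.total_length, rel=0.01)

    def test_oversize_spacing_rejected(self, y_arbor):
        with pytest.raises(ValueError, match="cable length"):
            ad.resample_arbor(y_arbor, spacing=1000.0)


class TestRigidAlign:
    def test_coincident_landmarks_identity(self, y_arbor):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        lm = ad.Landmarks(pts, pts)
        out = ad.rigid_align(y_arbor, lm)
        assert out.approx_equal(y_arbor, tol=1e-9)

    def test_recovers_known_rotation_translation(self, y_arbor):
        theta = np.pi / 2
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1.0]]
        )
        t = np.array([5.0, 0.0, 0.0])
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 1.0]])
        moved = y_arbor.transformed(R, t)
        lm = ad.Landmarks(src=pts @ R.T + t, dst=pts)
        back = ad.rigid_align(moved, lm)
        assert back.approx_equal(y_arbor, tol=1e-6)

    def test_isometry(self, rng):
        a = random_arbor(3, n_branches=6)
        pts = rng.normal(size=(5, 3))
        Rth = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(Rth) < 0:
            Rth[:, 0] *= -1
        lm = ad.Landmarks(pts, pts @ Rth.T + 2.0)
        out = ad.rigid_align(a, lm)
        d0 = np.linalg.norm(a.xyz[:, None] - a.xyz[None], axis=2)
        d1 = np.linalg.norm(out.xyz[:, None] - out.xyz[None], axis=2)
        assert np.max(np.abs(d0 - d1)) < 1e-6

    def test_too_few_or_collinear_pairs_rejected(self):
        with pytest.raises(DegenerateFitError):
            ad.fit_rigid(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.c_[np.arange(4), np.zeros(4), np.zeros(4)]
        with pytest.raises(DegenerateFitError, match="collinear"):
            ad.fit_rigid(line, line + 1.0)

    def test_noisy_fit_beats_coarse_rotation_grid(self, rng):
        """Kabsch RMSD ≤ best 1°-grid rotation about the true axis."""
        from arbordyn.core import landmark_rmsd

        theta = 0.4
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1.0]]
        )
        t = np.array([1.0, -2.0, 0.5])
        src = rng.normal(size=(8, 3)) * 10
        dst = src @ R.T + t + rng.normal(0, 0.1, (8, 3))
        lm = ad.Landmarks(src, dst)
        Rf, tf = ad.fit_rigid(src, dst)
        best = np.inf
        for ang in np.deg2rad(np.arange(0, 360, 1.0)):
            Rg = np.array(
                [[np.cos(ang), -np.sin(ang), 0],
                 [np.sin(ang), np.cos(ang), 0],
                 [0, 0, 1.0]]
            )
            tg = dst.mean(axis=0) - Rg @ src.mean(axis=0)
            best = min(best, landmark_rmsd(lm, Rg, tg))
        assert landmark_rmsd(lm, Rf, tf) <= best + 1e-12
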