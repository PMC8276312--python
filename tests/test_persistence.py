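"""Vietoris-Rips persistence against the brute-force oracle; cycles."""

from itertools import combinations

import numpy as np
import pytest

import wormtda as w
from wormtda.persistence import (
    PersistenceDiagram,
    order_cycle,
    representative_cycle,
    significant_features,
    vr_diagram,
)
from conftest import brute_force_vr


def finite_bars(diagram):
    pts = diagram.points
    return sorted(map(tuple, pts[np.isfinite(pts[:, 1])]))


class TestDiagramsAgainstOracle:
    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("dim", [2, 3, 5])
    def test_random_small_clouds_match_brute_force(self, seed, dim):
        rng = np.random.default_rng(1000 * dim + seed)
        n = int(rng.integers(4, 9))
        pts = rng.normal(size=(n, dim))
        expected = brute_force_vr(pts, max_degree=1)
        got = vr_diagram(pts, max_degree=1)
        for degree in (0, 1):
            exp = [(b, d) for b, d in expected[degree] if np.isfinite(d)]
            assert np.allclose(
                np.array(finite_bars(got[degree])).reshape(-1, 2),
                np.array(exp).reshape(-1, 2),
                atol=1e-12,
            ), f"degree {degree} mismatch at seed {seed}"

    def test_unit_square_loop(self, unit_square):
        dgm = vr_diagram(unit_square, 1)[1]
        assert len(dgm) == 1
        assert np.allclose(dgm.points[0], [1.0, np.sqrt(2)], atol=1e-12)

    def test_collinear_points_have_no_loops(self):
        pts = np.c_[np.arange(10.0), np.zeros(10)]
        assert len(vr_diagram(pts, 1)[1]) == 0

    def test_two_circles_multiplicity_two(self):
        cloud = w.generate_two_circles(30, 1.0)
        dgm = vr_diagram(cloud, 1)[1]
        top = dgm.max_persistence_point()
        assert dgm.multiplicity(top, tol=1e-9) == 2

    def test_degree0_circle_bars(self):
        th = 2 * np.pi * np.arange(8) / 8
        pts = np.c_[np.cos(th), np.sin(th)]
        dgm0 = vr_diagram(pts, 0)[0]
        deaths = np.sort(dgm0.points[:, 1])
        gap = 2 * np.sin(np.pi / 8)
        assert np.allclose(deaths[:-1], gap, atol=1e-12)
        assert np.isinf(deaths[-1])

    def test_empty_cloud_raises(self):
        with pytest.raises(ValueError):
            vr_diagram(np.empty((0, 2)))

    def test_scale_equivariance(self, rng):
        pts = rng.normal(size=(10, 3))
        c = 3.7
        a = np.array(finite_bars(vr_diagram(pts, 1)[1]))
        b = np.array(finite_bars(vr_diagram(c * pts, 1)[1]))
        assert np.allclose(c * a, b, atol=1e-9)

    def test_bottleneck_stability_smoke(self, rng):
        th = 2 * np.pi * np.arange(14) / 14
        pts = np.c_[np.cos(th), np.sin(th)]
        delta = 0.01
        noise = rng.uniform(-delta, delta, size=pts.shape)
        a = np.array(finite_bars(vr_diagram(pts, 1)[1]))
        b = np.array(finite_bars(vr_diagram(pts + noise, 1)[1]))
        # single dominant bar each; perturbation <= delta*sqrt(2) in 2-norm
        move = np.abs(a[-1] - b[-1]).max()
        assert move <= 2 * delta * np.sqrt(2) + 1e-12


class TestSignificantFeatures:
    def test_empty_and_singleton(self):
        assert significant_features(PersistenceDiagram(1, np.empty((0, 2)))) == []
        dgm = PersistenceDiagram(1, [[0.5, 2.0]])
        assert significant_features(dgm) == [(0.5, 2.0)]

    def test_ratio_rule_on_three_bars(self):
        dgm = PersistenceDiagram(1, [[0, 10], [0, 9], [0, 1]])
        feats = significant_features(dgm, ratio=0.3)
        assert len(feats) == 2
        assert feats[0] == (0.0, 10.0)


class TestRepresentativeCycles:
    def test_unit_square_boundary(self, unit_square):
        dgm = vr_diagram(unit_square, 1)[1]
        cyc = representative_cycle(unit_square, tuple(dgm.points[0]))
        assert len(cyc.edges) == 4
        assert {frozenset(e) for e in cyc.edges} == {
            frozenset(p) for p in [(0, 1), (0, 3), (1, 2), (2, 3)]
        }

    def test_circle_cycle_winds_once(self):
        th = 2 * np.pi * np.arange(24) / 24
        pts = np.c_[np.cos(th), np.sin(th)]
        dgm = vr_diagram(pts, 1)[1]
        cyc = order_cycle(
            representative_cycle(pts, tuple(dgm.max_persistence_point()))
        )
        loop = pts[cyc.vertex_sequence] - pts[cyc.vertex_sequence].mean(axis=0)
        ang = np.unwrap(np.arctan2(loop[:, 1], loop[:, 0]))
        winding = (ang[-1] - ang[0] + (ang[1] - ang[0])) / (2 * np.pi)
        assert round(abs(winding)) == 1

    def test_edges_no_longer_than_birth(self, rng):
        pts = rng.normal(size=(20, 2))
        dgm = vr_diagram(pts, 1)[1]
        if len(dgm) == 0:
            pytest.skip("no loop in this draw")
        target = tuple(dgm.max_persistence_point())
        cyc = representative_cycle(pts, target)
        for i, j in cyc.edges:
            assert np.linalg.norm(pts[i] - pts[j]) <= target[0] + 1e-12

    def test_cycle_becomes_boundary_at_death_scale(self):
        """Homological validity: at the death scale the cycle's GF(2) chain
        lies in the image of the triangle boundary map; just below it does
        not (the class genuinely persists until its death)."""
        th = 2 * np.pi * np.arange(10) / 10
        pts = np.c_[np.cos(th), np.sin(th)]
        dgm = vr_diagram(pts, 1)[1]
        birth, death = dgm.max_persistence_point()
        cyc = representative_cycle(pts, (birth, death))

        edges = list(combinations(range(len(pts)), 2))
        eidx = {e: i for i, e in enumerate(edges)}
        z = np.zeros(len(edges), dtype=np.uint8)
        for i, j in cyc.edges:
            z[eidx[tuple(sorted((i, j)))]] ^= 1

        def in_boundary_image(scale):
            cols = []
            for tri in combinations(range(len(pts)), 3):
                diam = max(
                    np.linalg.norm(pts[a] - pts[b])
                    for a, b in combinations(tri, 2)
                )
                if diam <= scale:
                    col = np.zeros(len(edges), dtype=np.uint8)
                    for face in combinations(tri, 2):
                        col[eidx[face]] = 1
                    cols.append(col)
            if not cols:
                return not z.any()
            M = np.array(cols, dtype=np.uint8).T  # edges x triangles
            v = z.copy()
            # GF(2) elimination of [M | v]
            A = np.concatenate([M, v[:, None]], axis=1)
            row = 0
            for col in range(M.shape[1]):
                piv = np.nonzero(A[row:, col])[0]
                if piv.size == 0:
                    continue
                A[[row, row + piv[0]]] = A[[row + piv[0], row]]
                mask = A[:, col].astype(bool)
                mask[row] = False
                A[mask] ^= A[row]
                row += 1
                if row == A.shape[0]:
                    break
            return not A[row:, -1].any()

        assert in_boundary_image(death + 1e-9)
        assert not in_boundary_image(death - 1e-6)


class TestOrderCycle:
    def make_loop_cycle(self, vertices):
        edges = [
            (vertices[i], vertices[(i + 1) % len(vertices)])
            for i in range(len(vertices))
        ]
        return w.RepresentativeCycle(diagram_point=(0.0, 1.0), edges=edges)

    def test_contiguous_increasing_is_forward(self):
        cyc = order_cycle(self.make_loop_cycle(list(range(5, 21))))
        assert cyc.direction == "forward"
        assert len(cyc.vertex_sequence) == 16

    def test_orientation_invariant_to_edge_listing(self):
        a = order_cycle(self.make_loop_cycle(list(range(5, 21))))
        rev_edges = [(j, i) for i, j in reversed(a.edges)]
        b = order_cycle(
            w.RepresentativeCycle(diagram_point=(0.0, 1.0), edges=rev_edges)
        )
        assert a.direction == b.direction == "forward"

    def test_majority_rule(self):
        # 7 increasing steps out of 10 -> forward
        verts = [0, 1, 2, 3, 4, 5, 6, 9, 8, 7]
        cyc = order_cycle(self.make_loop_cycle(verts))
        assert cyc.direction == "forward"

    def test_descending_loop_reorients_to_increasing_time(self):
        # an undirected loop listed in descending time is canonically
        # re-oriented so consecutive steps majority-increase
        cyc = order_cycle(self.make_loop_cycle(list(range(20, 4, -1))))
        assert cyc.direction == "forward"
        steps = np.diff(cyc.time_indices)
        assert (steps > 0).sum() > (steps < 0).sum()

    def test_non_loop_raises(self):
        bad = w.RepresentativeCycle(
            diagram_point=(0.0, 1.0), edges=[(0, 1), (1, 2), (2, 0), (2, 3)]
        )
        with pytest.raises(ValueError):
            order_cycle(bad)


class TestMaxminSubsample:
    def test_deterministic_and_sorted(self, rng):
        pts = rng.normal(size=(50, 3))
        a, ia = w.maxmin_subsample(pts, 10, seed=1)
        b, ib = w.maxmin_subsample(pts, 10, seed=1)
        assert np.array_equal(ia, ib)
        assert np.all(np.diff(ia) > 0)
        assert len(a) == 10

    def test_k_at_least_n_returns_all(self, rng):
        pts = rng.normal(size=(5, 2))
        a, idx = w.maxmin_subsample(pts, 10, seed=0)
        assert np.array_equal(a, pts)
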