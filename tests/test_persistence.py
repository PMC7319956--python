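import math
from itertools import combinations

import numpy as np
import pytest

from molpi import Molecule, compute_pd, fixture, pairwise_distances, rips_h0, rips_h1
from molpi.persistence import read_pd_csv, write_pd_csv

from conftest import random_cloud


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def prim_mst_weights(dists: np.ndarray) -> list[float]:
    """Brute-force O(N^3) Prim MST, independent of scipy."""
    n = dists.shape[0]
    in_tree = [0]
    weights = []
    while len(in_tree) < n:
        best = (math.inf, None)
        for i in in_tree:
            for j in range(n):
                if j not in in_tree and dists[i, j] < best[0]:
                    best = (dists[i, j], j)
        weights.append(best[0])
        in_tree.append(best[1])
    return sorted(weights)


def gf2_rank(rows: list[int]) -> int:
    """Rank over GF(2) of a matrix given as bitmask rows."""
    rank = 0
    pivots: list[int] = []
    for row in rows:
        for p in pivots:
            row = min(row, row ^ p)
        if row:
            pivots.append(row)
            pivots.sort(reverse=True)
            rank += 1
    return rank


def betti1_at(dists: np.ndarray, t: float) -> int:
    """First Betti number of the Rips complex at parameter t.

    beta1 = (E - rank d1) - rank d2, with boundary matrices assembled from
    scratch — independent of the paired column-reduction implementation.
    """
    n = dists.shape[0]
    edges = [(i, j) for i, j in combinations(range(n), 2) if dists[i, j] <= t]
    eidx = {e: k for k, e in enumerate(edges)}
    d1 = [(1 << i) | (1 << j) for i, j in edges]
    d2 = []
    for i, j, k in combinations(range(n), 3):
        if max(dists[i, j], dists[i, k], dists[j, k]) <= t:
            d2.append((1 << eidx[(i, j)]) | (1 << eidx[(i, k)]) | (1 << eidx[(j, k)]))
    return (len(edges) - gf2_rank(d1)) - gf2_rank(d2)


# ---------------------------------------------------------------------------
# H0
# ---------------------------------------------------------------------------

class TestH0:
    def test_deaths_equal_mst_edges_on_random_clouds(self):
        """Sorted H0 deaths == brute-force MST edge weights (single linkage)."""
        rng = np.random.default_rng(202)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            pts = random_cloud(rng, n)
            dists = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            points = rips_h0(dists)
            assert len(points) == n - 1
            assert all(p.birth == 0.0 for p in points)
            got = sorted(p.death for p in points)
            np.testing.assert_allclose(got, prim_mst_weights(dists), atol=1e-9)

    def test_h0_pairs_are_the_merge_edges(self):
        rng = np.random.default_rng(7)
        pts = random_cloud(rng, 8)
        dists = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        for p in rips_h0(dists):
            a, b = p.pair
            assert dists[a, b] == pytest.approx(p.death, abs=1e-12)

    def test_diatomic_single_bar(self, diatomics):
        hbr, _ = diatomics
        (p,) = rips_h0(pairwise_distances(hbr))
        assert (p.birth, p.death) == (0.0, pytest.approx(1.41))
        assert p.pair == (0, 1)

    def test_collinear_points(self):
        mol = Molecule("line", ["C"] * 3, np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]]))
        deaths = sorted(p.death for p in rips_h0(pairwise_distances(mol)))
        assert deaths == pytest.approx([1.0, 1.0])

    def test_single_atom_empty(self):
        assert rips_h0(np.zeros((1, 1))) == []

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            rips_h0(np.zeros((0, 0)))

    def test_coincident_atoms_warn_and_drop(self):
        pts = np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0]], dtype=float)
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        with pytest.warns(UserWarning, match="coincident"):
            points = rips_h0(d)
        assert [p.death for p in points] == pytest.approx([1.0])


# ---------------------------------------------------------------------------
# H1
# ---------------------------------------------------------------------------

class TestH1:
    def test_unit_square_hand_enumeration(self):
        """4-cycle born when the last side arrives (1), filled by the
        diagonal triangles (sqrt 2) — enumerated by hand."""
        sq = fixture("square4")
        (bar,) = rips_h1(pairwise_distances(sq))
        assert bar.birth == pytest.approx(1.0, abs=1e-12)
        assert bar.death == pytest.approx(math.sqrt(2), abs=1e-12)

    def test_equilateral_triangle_has_no_h1(self):
        tri = fixture("triangle3")
        assert rips_h1(pairwise_distances(tri)) == []

    def test_regular_hexagon_bar(self):
        # side s ring: born at s, killed by short diagonals at s*sqrt(3)
        s = 1.39
        pts = np.array(
            [[s * math.cos(math.radians(60 * k)), s * math.sin(math.radians(60 * k)), 0]
             for k in range(6)]
        )
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        (bar,) = rips_h1(d)
        assert bar.birth == pytest.approx(s, abs=1e-9)
        assert bar.death == pytest.approx(s * math.sqrt(3), abs=1e-9)

    def test_bars_match_betti_curve_on_random_clouds(self):
        """Interval counts agree with rank-computed Betti numbers at every
        midpoint between critical values (independent GF(2) elimination)."""
        rng = np.random.default_rng(31)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            pts = random_cloud(rng, n, scale=1.5)
            dists = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            bars = rips_h1(dists)
            crit = sorted(set(dists[np.triu_indices(n, k=1)]))
            probes = [(a + b) / 2 for a, b in zip(crit, crit[1:])]
            for t in probes:
                expected = betti1_at(dists, t)
                got = sum(1 for b in bars if b.birth <= t < b.death)
                assert got == expected

    def test_fewer_than_three_points(self):
        assert rips_h1(np.array([[0.0, 1.0], [1.0, 0.0]])) == []


# ---------------------------------------------------------------------------
# Full diagrams and their invariances
# ---------------------------------------------------------------------------

def rigid_transform(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=(3, 3))
    rot, _ = np.linalg.qr(q)
    if np.linalg.det(rot) < 0:
        rot[:, 0] *= -1
    return coords @ rot.T + rng.normal(size=3)


class TestComputePD:
    def test_anisole_worked_example(self, anisole):
        pd_ = compute_pd(anisole)
        assert pd_.n_atoms == 16
        h0 = pd_.in_dim(0)
        assert len(h0) == 15
        deaths = sorted(p.death for p in h0)
        assert deaths[0] == pytest.approx(1.09)   # C-H bonds appear first
        assert deaths[-1] == pytest.approx(1.43)  # O-CH3 is the longest merge
        holes = [p for p in pd_.in_dim(1) if p.persistence > 0.1]
        assert len(holes) == 2  # phenyl ring + methoxy/ring void

    def test_identical_diagrams_for_equal_geometry(self, diatomics):
        hbr, f2 = diatomics
        a = [(p.dim, p.birth, p.death) for p in compute_pd(hbr).points]
        b = [(p.dim, p.birth, p.death) for p in compute_pd(f2).points]
        assert a == b

    def test_single_atom_diagram_empty(self):
        mol = Molecule("atom", ["C"], np.zeros((1, 3)))
        pd_ = compute_pd(mol)
        assert pd_.points == [] and pd_.n_atoms == 1

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            pts = random_cloud(rng, 9)
            mol = Molecule("m", ["C"] * 9, pts)
            moved = Molecule("m", ["C"] * 9, rigid_transform(pts, rng))
            a = sorted((p.dim, p.birth, p.death) for p in compute_pd(mol).points)
            b = sorted((p.dim, p.birth, p.death) for p in compute_pd(moved).points)
            for (da, ba, xa), (db, bb, xb) in zip(a, b):
                assert da == db
                assert abs(ba - bb) <= 1e-8 and abs(xa - xb) <= 1e-8

    def test_stability_under_perturbation(self):
        """Moving every atom by at most eps moves matched PD entries by at
        most 2 eps (Rips stability on the diameter scale)."""
        rng = np.random.default_rng(3)
        pts = random_cloud(rng, 10)
        mol = Molecule("m", ["C"] * 10, pts)
        eps = 0.01
        delta = rng.uniform(-1, 1, size=pts.shape)
        delta *= eps / np.linalg.norm(delta, axis=1, keepdims=True)
        pert = Molecule("m", ["C"] * 10, pts + delta)
        for dim in (0, 1):
            a = sorted((p.birth, p.death) for p in compute_pd(mol).in_dim(dim))
            b = sorted((p.birth, p.death) for p in compute_pd(pert).in_dim(dim))
            assert len(a) == len(b)
            for (b1, d1), (b2, d2) in zip(a, b):
                assert max(abs(b1 - b2), abs(d1 - d2)) <= 2 * eps + 1e-12

    def test_scaling_covariance(self):
        rng = np.random.default_rng(9)
        pts = random_cloud(rng, 8)
        s = 2.7
        a = compute_pd(Molecule("m", ["C"] * 8, pts))
        b = compute_pd(Molecule("m", ["C"] * 8, s * pts))
        for pa, pb in zip(sorted(a.points, key=lambda p: (p.dim, p.birth, p.death)),
                          sorted(b.points, key=lambda p: (p.dim, p.birth, p.death))):
            assert pb.birth == pytest.approx(s * pa.birth, abs=1e-9)
            assert pb.death == pytest.approx(s * pa.death, abs=1e-9)


def test_pd_csv_round_trip(tmp_path, anisole):
    pd_ = compute_pd(anisole)
    path = tmp_path / "pd.csv"
    write_pd_csv(pd_, path)
    back = read_pd_csv(path, "anisole")
    assert back.n_atoms == pd_.n_atoms
    a = [(p.dim, p.birth, p.death, p.pair) for p in pd_.points]
    b = [(p.dim, p.birth, p.death, p.pair) for p in back.points]
    for (d1, b1, x1, pr1), (d2, b2, x2, pr2) in zip(a, b):
        assert d1 == d2 and pr1 == pr2
        assert b2 == pytest.approx(b1, abs=1e-7) and x2 == pytest.approx(x1, abs=1e-7)
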