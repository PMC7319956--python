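"""Vietoris-Rips persistent homology (H0, H1) of molecular point clouds.

The filtration parameter is interatomic *distance* (Rips/diameter scale): an
edge enters the complex at the distance between its endpoints, a triangle at
its longest edge. Under this convention a bond of length d produces an H0
death at exactly d, so connected-component deaths land at bond lengths
(C-H near 1.09 Å, C-C/C-O near 1.4 Å) and H1 bars record ring-like voids.

H0 is computed through the single-linkage / minimum-spanning-tree
equivalence: the multiset of H0 deaths of a Rips filtration equals the MST
edge weights, and each death is attributed to the atom pair whose merge
killed the component. H1 uses the standard boundary-matrix column reduction
over GF(2) on simplices up to dimension 2. The never-dying H0 component is
excluded from the diagram, and zero-persistence pairs are dropped.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist

from .io import Molecule

__all__ = [
    "PDPoint",
    "PersistenceDiagram",
    "pairwise_distances",
    "rips_h0",
    "rips_h1",
    "compute_pd",
    "write_pd_csv",
    "read_pd_csv",
]


@dataclass(frozen=True)
class PDPoint:
    """One persistence pair: (birth, death) in Å, with the homology dimension.

    Dimension-0 points are born at 0 and carry the index pair of the two
    atoms whose merge distance killed the component (the MST edge endpoints).
    """

    dim: int
    birth: float
    death: float
    pair: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.dim not in (0, 1):
            raise ValueError(f"dim must be 0 or 1, got {self.dim}")
        if not (self.death > self.birth):
            raise ValueError(f"death {self.death} must exceed birth {self.birth}")
        if (self.pair is not None) != (self.dim == 0):
            raise ValueError("atom pair must be present iff dim == 0")

    @property
    def persistence(self) -> float:
        return self.death - self.birth


@dataclass
class PersistenceDiagram:
    """Finite H0/H1 features of one molecule.

    Contains exactly ``n_atoms - 1`` dimension-0 points: the component that
    never dies is excluded by convention.
    """

    molecule_id: str
    points: list[PDPoint] = field(default_factory=list)
    n_atoms: int = 0

    def in_dim(self, dim: int) -> list[PDPoint]:
        return [p for p in self.points if p.dim == dim]


def pairwise_distances(mol: Molecule) -> np.ndarray:
    """Symmetric N x N Euclidean distance matrix in Å (zero diagonal)."""
    if mol.n_atoms == 1:
        return np.zeros((1, 1))
    return squareform(pdist(mol.coords))


def rips_h0(dists: np.ndarray) -> list[PDPoint]:
    """Dimension-0 persistence pairs from a distance matrix.

    Returns N-1 points (one per finite bar), each born at 0 and dying at a
    Euclidean-MST edge weight, attributed to that edge's endpoints. Pairs are
    sorted by (death, atom indices) for reproducibility. Coincident atoms
    (distance 0) would give zero-persistence bars; these are discarded with
    a warning.
    """
    dists = np.asarray(dists, dtype=float)
    n = dists.shape[0]
    if n == 0:
        raise ValueError("empty distance matrix")
    if n == 1:
        return []
    # coincident atoms merge at distance 0: those bars are zero-persistence
    # and dropped; the MST then runs on one representative per location
    # (scipy's dense MST treats 0 as "no edge", so we must dedup ourselves)
    keep = np.ones(n, dtype=bool)
    iu, ju = np.nonzero(np.triu(dists == 0.0, k=1))
    if iu.size:
        warnings.warn(
            "coincident atoms detected: zero-persistence H0 bars discarded",
            stacklevel=2,
        )
        for i, j in zip(iu, ju):
            if keep[i]:
                keep[j] = False
    idx = np.nonzero(keep)[0]
    sub = dists[np.ix_(idx, idx)]
    if len(idx) == 1:
        return []
    mst = minimum_spanning_tree(sub).tocoo()
    edges = sorted(
        (float(w), min(int(idx[i]), int(idx[j])), max(int(idx[i]), int(idx[j])))
        for i, j, w in zip(mst.row, mst.col, mst.data)
    )
    return [PDPoint(0, 0.0, w, (a, b)) for w, a, b in edges]


def _rips_simplices(dists: np.ndarray) -> list[tuple[float, int, tuple[int, ...]]]:
    """All edges and triangles with filtration values, in reduction order.

    Order: (filtration value, dimension, lexicographic vertices) — a simplex
    never precedes its faces, and ties are broken reproducibly.
    """
    n = dists.shape[0]
    out: list[tuple[float, int, tuple[int, ...]]] = []
    for i, j in combinations(range(n), 2):
        out.append((float(dists[i, j]), 1, (i, j)))
    for i, j, k in combinations(range(n), 3):
        f = float(max(dists[i, j], dists[i, k], dists[j, k]))
        out.append((f, 2, (i, j, k)))
    out.sort(key=lambda t: (t[0], t[1], t[2]))
    return out


def rips_h1(dists: np.ndarray) -> list[PDPoint]:
    """Dimension-1 persistence pairs of the Rips filtration (simplices <= dim 2).

    Standard persistence algorithm: process simplices in filtration order,
    reduce each triangle's boundary column over GF(2) against earlier pivots;
    an edge that becomes a pivot of a reduced triangle column dies there, and
    the (edge value, triangle value) interval is an H1 bar when positive.
    Zero-persistence pairs are discarded.
    """
    dists = np.asarray(dists, dtype=float)
    n = dists.shape[0]
    if n < 3:
        return []
    simplices = _rips_simplices(dists)
    # column index in filtration order; edges that are "positive" (create a
    # cycle) are the potential H1 births
    index: dict[tuple[int, ...], int] = {}
    values: list[float] = []
    for idx, (f, _, verts) in enumerate(simplices):
        index[verts] = idx
        values.append(f)

    # H0 union-find to mark negative edges (they kill components, not cycles)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    negative_edge: set[int] = set()
    for idx, (f, dim, verts) in enumerate(simplices):
        if dim != 1:
            continue
        ra, rb = find(verts[0]), find(verts[1])
        if ra != rb:
            parent[ra] = rb
            negative_edge.add(idx)

    pivot_of: dict[int, int] = {}  # pivot edge index -> reduced column (as set)
    columns: dict[int, frozenset[int]] = {}
    bars: list[tuple[float, float, tuple[int, ...]]] = []
    for idx, (f, dim, verts) in enumerate(simplices):
        if dim != 2:
            continue
        i, j, k = verts
        col = {index[(i, j)], index[(i, k)], index[(j, k)]}
        while col:
            piv = max(col)
            if piv in pivot_of:
                col ^= columns[pivot_of[piv]]
            else:
                break
        if col:
            piv = max(col)
            pivot_of[piv] = idx
            columns[idx] = frozenset(col)
            if piv not in negative_edge:
                birth, death = values[piv], f
                if death > birth:
                    bars.append((birth, death, simplices[piv][2]))
        # a fully-reduced (zero) triangle column creates a 2-cycle: irrelevant here
    bars.sort(key=lambda t: (t[0], t[1], t[2]))
    return [PDPoint(1, b, d) for b, d, _ in bars]


def compute_pd(mol: Molecule) -> PersistenceDiagram:
    """Full H0 + H1 persistence diagram of a molecule (deterministic)."""
    dists = pairwise_distances(mol)
    points = rips_h0(dists)
    if mol.n_atoms >= 3:
        points = points + rips_h1(dists)
    return PersistenceDiagram(mol.id, points, mol.n_atoms)


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def write_pd_csv(pd_: PersistenceDiagram, path: str | Path) -> None:
    """Export a diagram as CSV with columns dim,birth,death,atom_a,atom_b."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["dim", "birth", "death", "atom_a", "atom_b"])
        for p in pd_.points:
            a, b = (p.pair if p.pair is not None else ("", ""))
            w.writerow([p.dim, f"{p.birth:.9g}", f"{p.death:.9g}", a, b])


def read_pd_csv(path: str | Path, molecule_id: str = "", n_atoms: int = 0) -> PersistenceDiagram:
    points: list[PDPoint] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            dim = int(row["dim"])
            pair = (int(row["atom_a"]), int(row["atom_b"])) if dim == 0 else None
            points.append(PDPoint(dim, float(row["birth"]), float(row["death"]), pair))
    if not n_atoms:
        n_atoms = len([p for p in points if p.dim == 0]) + 1
    return PersistenceDiagram(molecule_id, points, n_atoms)
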