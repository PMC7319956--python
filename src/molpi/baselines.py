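"""Coulomb-matrix and Bag-of-Bonds baseline representations.

Both are built from atomic numbers and inverse interatomic distances (Å) and
are the classic points of comparison for any new molecular fingerprint.
Unlike persistence images their vector length is set by the largest molecule
in the featurized set: smaller molecules are zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import ElementTable, Molecule, PAULING_TABLE
from .persistence import pairwise_distances

__all__ = [
    "coulomb_matrix",
    "featurize_cm",
    "BoBSchema",
    "bob_schema",
    "bag_of_bonds",
    "featurize_bob",
]


def coulomb_matrix(mol: Molecule, table: ElementTable = PAULING_TABLE) -> np.ndarray:
    """N x N Coulomb matrix: 0.5 * Z**2.4 on the diagonal, Zi*Zj/dij off it.

    Rows/columns are sorted by descending row norm so the matrix is invariant
    to the input atom ordering.
    """
    z = np.array([table.z(s) for s in mol.elements], dtype=float)
    d = pairwise_distances(mol)
    if mol.n_atoms > 1 and np.any(d[np.triu_indices(mol.n_atoms, k=1)] == 0.0):
        raise ValueError("coincident atoms: Coulomb matrix is undefined at d = 0")
    with np.errstate(divide="ignore"):
        m = np.outer(z, z) / np.where(d == 0.0, np.inf, d)
    np.fill_diagonal(m, 0.5 * z**2.4)
    order = np.argsort(-np.linalg.norm(m, axis=1), kind="stable")
    return m[np.ix_(order, order)]


def featurize_cm(mols: list[Molecule], table: ElementTable = PAULING_TABLE) -> pd.DataFrame:
    """Flattened Coulomb matrices zero-padded to the largest molecule in the set."""
    nmax = max(m.n_atoms for m in mols)
    rows = np.zeros((len(mols), nmax * nmax))
    ids = []
    for k, mol in enumerate(mols):
        cm = coulomb_matrix(mol, table)
        padded = np.zeros((nmax, nmax))
        padded[: mol.n_atoms, : mol.n_atoms] = cm
        rows[k] = padded.reshape(-1)
        ids.append(mol.id)
    return pd.DataFrame(rows, index=pd.Index(ids, name="id"))


@dataclass(frozen=True)
class BoBSchema:
    """Bag labels and per-bag lengths fixed by a molecule set."""

    sizes: tuple[tuple[str, int], ...]  # (label, max count) sorted by label

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lbl for lbl, _ in self.sizes)

    @property
    def length(self) -> int:
        return sum(n for _, n in self.sizes)


def _pair_label(a: str, b: str) -> str:
    return "-".join(sorted((a, b)))


def bob_schema(mols: list[Molecule]) -> BoBSchema:
    """Derive the shared bag schema (labels and max lengths) from a set."""
    counts: dict[str, int] = {}
    for mol in mols:
        local: dict[str, int] = {}
        for a, b in combinations(mol.elements, 2):
            lbl = _pair_label(a, b)
            local[lbl] = local.get(lbl, 0) + 1
        for lbl, n in local.items():
            counts[lbl] = max(counts.get(lbl, 0), n)
    return BoBSchema(tuple(sorted(counts.items())))


def bag_of_bonds(
    mol: Molecule,
    table: ElementTable = PAULING_TABLE,
    schema: BoBSchema | None = None,
) -> dict[str, list[float]]:
    """Bags of Zi*Zj/dij pair terms keyed by unordered element pair.

    Each bag is sorted descending and zero-padded to the schema length; a
    pair absent from the schema raises.
    """
    if schema is None:
        schema = bob_schema([mol])
    d = pairwise_distances(mol)
    z = [table.z(s) for s in mol.elements]
    bags: dict[str, list[float]] = {lbl: [] for lbl in schema.labels}
    for i, j in combinations(range(mol.n_atoms), 2):
        lbl = _pair_label(mol.elements[i], mol.elements[j])
        if lbl not in bags:
            raise ValueError(f"pair {lbl!r} missing from the set schema")
        if d[i, j] == 0.0:
            raise ValueError("coincident atoms: pair term undefined at d = 0")
        bags[lbl].append(z[i] * z[j] / d[i, j])
    sizes = dict(schema.sizes)
    for lbl, vals in bags.items():
        vals.sort(reverse=True)
        if len(vals) > sizes[lbl]:
            raise ValueError(f"bag {lbl!r} overflows the schema ({len(vals)} > {sizes[lbl]})")
        vals.extend([0.0] * (sizes[lbl] - len(vals)))
    return bags


def featurize_bob(mols: list[Molecule], table: ElementTable = PAULING_TABLE) -> pd.DataFrame:
    """Concatenated, schema-aligned Bag-of-Bonds vectors for a molecule set."""
    schema = bob_schema(mols)
    rows = np.zeros((len(mols), schema.length))
    ids = []
    for k, mol in enumerate(mols):
        bags = bag_of_bonds(mol, table, schema)
        rows[k] = np.concatenate([bags[lbl] for lbl in schema.labels])
        ids.append(mol.id)
    return pd.DataFrame(rows, index=pd.Index(ids, name="id"))
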