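"""Molecular geometry I/O: XYZ and SDF parsing, element properties, fixtures.

A :class:`Molecule` is an element-labeled 3-D point cloud. Bonds are never
inferred or stored: the downstream topological representation consumes
coordinates only. All coordinates are in angstroms (Å).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Molecule",
    "ElementTable",
    "PAULING_TABLE",
    "read_xyz",
    "write_xyz",
    "read_sdf",
    "read_property_csv",
    "attach_properties",
    "fixture",
    "FIXTURE_NAMES",
]


class MoleculeParseError(ValueError):
    """Raised when a geometry file cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class ElementTable:
    """Per-element properties: Pauling electronegativity chi and atomic number Z."""

    data: dict[str, tuple[float, int]]

    def chi(self, symbol: str) -> float:
        return self._get(symbol)[0]

    def z(self, symbol: str) -> int:
        return self._get(symbol)[1]

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.data

    def _get(self, symbol: str) -> tuple[float, int]:
        try:
            return self.data[symbol]
        except KeyError:
            raise KeyError(
                f"element {symbol!r} not in the element table "
                f"(known: {sorted(self.data)})"
            ) from None


#: Pauling electronegativities and atomic numbers for the elements a small
#: organic / halide screening set needs.
PAULING_TABLE = ElementTable(
    {
        "H": (2.20, 1),
        "B": (2.04, 5),
        "C": (2.55, 6),
        "N": (3.04, 7),
        "O": (3.44, 8),
        "F": (3.98, 9),
        "Si": (1.90, 14),
        "P": (2.19, 15),
        "S": (2.58, 16),
        "Cl": (3.16, 17),
        "Br": (2.96, 35),
        "I": (2.66, 53),
    }
)


@dataclass
class Molecule:
    """An identified 3-D atomic point cloud with optional scalar properties.

    Parameters
    ----------
    id : str
        Molecule identifier (XYZ comment line, SDF title, or assigned).
    elements : list of str
        One element symbol per atom.
    coords : (N, 3) float array
        Cartesian coordinates in Å.
    properties : dict, optional
        Property name -> value (energies in kcal/mol).
    """

    id: str
    elements: list[str]
    coords: np.ndarray
    properties: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {self.coords.shape}")
        if len(self.elements) != self.coords.shape[0]:
            raise ValueError(
                f"{len(self.elements)} element labels for "
                f"{self.coords.shape[0]} coordinate rows"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("molecule must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path, table: ElementTable = PAULING_TABLE) -> list[Molecule]:
    """Read a (possibly multi-record) XYZ file.

    Each record is a count line, a comment line (used as the molecule id when
    non-empty), and N atom lines ``symbol x y z``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    mols: list[Molecule] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():  # tolerate blank separator lines
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise MoleculeParseError(
                f"{path}:{i + 1}: expected an atom count, got {lines[i]!r}"
            ) from None
        if natoms < 1:
            raise MoleculeParseError(f"{path}:{i + 1}: atom count must be >= 1")
        if i + 1 + natoms >= len(lines) + 1 and i + 1 + natoms > len(lines):
            raise MoleculeParseError(
                f"{path}:{i + 1}: record declares {natoms} atoms but file ends early"
            )
        comment = lines[i + 1].strip() if i + 1 < len(lines) else ""
        mol_id = comment if comment else str(len(mols))
        elements: list[str] = []
        coords = np.empty((natoms, 3))
        for k in range(natoms):
            ln = i + 2 + k
            if ln >= len(lines):
                raise MoleculeParseError(
                    f"{path}:{ln + 1}: record truncated ({natoms} atoms declared)"
                )
            parts = lines[ln].split()
            if len(parts) < 4:
                raise MoleculeParseError(
                    f"{path}:{ln + 1}: expected 'symbol x y z', got {lines[ln]!r}"
                )
            sym = parts[0]
            if sym not in table:
                raise MoleculeParseError(
                    f"{path}:{ln + 1}: unknown element symbol {sym!r}"
                )
            try:
                coords[k] = [float(v) for v in parts[1:4]]
            except ValueError:
                raise MoleculeParseError(
                    f"{path}:{ln + 1}: non-numeric coordinate in {lines[ln]!r}"
                ) from None
            elements.append(sym)
        mols.append(Molecule(mol_id, elements, coords))
        i += 2 + natoms
    return mols


def write_xyz(mols: Iterable[Molecule] | Molecule, path: str | Path) -> None:
    """Write molecules as a multi-record XYZ file (coordinates to 6 decimals)."""
    if isinstance(mols, Molecule):
        mols = [mols]
    out = []
    for mol in mols:
        out.append(str(mol.n_atoms))
        out.append(mol.id)
        for sym, (x, y, z) in zip(mol.elements, mol.coords):
            out.append(f"{sym} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# SDF (V2000)
# ---------------------------------------------------------------------------

def read_sdf(path: str | Path, table: ElementTable = PAULING_TABLE) -> list[Molecule]:
    """Read a V2000 SDF file; atom block only (bonds ignored), with data items.

    Numeric ``> <name>`` data items become molecule properties.
    """
    path = Path(path)
    text = path.read_text()
    mols: list[Molecule] = []
    offset = 0
    for record in text.split("$$$$"):
        lines = record.splitlines()
        # strip leading blank lines left over from the $$$$ split
        while lines and not lines[0].strip():
            lines.pop(0)
            offset += 1
        if not lines:
            continue
        if len(lines) < 4:
            raise MoleculeParseError(f"{path}: truncated SDF record near line {offset + 1}")
        title = lines[0].strip()
        counts = lines[3]
        try:
            natoms = int(counts[0:3])
        except (ValueError, IndexError):
            raise MoleculeParseError(
                f"{path}:{offset + 4}: malformed counts line {counts!r}"
            ) from None
        if natoms < 1:
            raise MoleculeParseError(
                f"{path}:{offset + 4}: SDF record declares {natoms} atoms"
            )
        if len(lines) < 4 + natoms:
            raise MoleculeParseError(
                f"{path}:{offset + 4}: atom block truncated ({natoms} atoms declared)"
            )
        elements: list[str] = []
        coords = np.empty((natoms, 3))
        for k in range(natoms):
            ln = lines[4 + k]
            try:
                coords[k] = [float(ln[0:10]), float(ln[10:20]), float(ln[20:30])]
                sym = ln[31:34].strip() or ln.split()[3]
            except (ValueError, IndexError):
                raise MoleculeParseError(
                    f"{path}:{offset + 5 + k}: malformed atom line {ln!r}"
                ) from None
            if sym not in table:
                raise MoleculeParseError(
                    f"{path}:{offset + 5 + k}: unknown element symbol {sym!r}"
                )
            elements.append(sym)
        props: dict[str, float] = {}
        key = None
        for ln in lines[4 + natoms:]:
            s = ln.strip()
            if s.startswith(">"):
                l, r = s.find("<"), s.rfind(">")
                key = s[l + 1: r] if 0 <= l < r else None
            elif key is not None and s:
                try:
                    props[key] = float(s)
                except ValueError:
                    pass  # non-numeric data items are ignored
                key = None
        mol_id = title if title else str(len(mols))
        mols.append(Molecule(mol_id, elements, coords, props))
        offset += record.count("\n") + 1
    return mols


# ---------------------------------------------------------------------------
# Property tables
# ---------------------------------------------------------------------------

def read_property_csv(path: str | Path) -> pd.DataFrame:
    """Read a labels CSV with header ``id,<property>[,...]``; id as string index."""
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError(f"{path}: labels CSV must have an 'id' column")
    return df.set_index("id")


def attach_properties(mols: list[Molecule], labels: pd.DataFrame) -> list[Molecule]:
    """Copy label columns into ``mol.properties`` for molecules present in *labels*."""
    for mol in mols:
        if mol.id in labels.index:
            for col in labels.columns:
                mol.properties[col] = float(labels.loc[mol.id, col])
    return mols


# ---------------------------------------------------------------------------
# Fixture geometries (deterministic, idealized)
# ---------------------------------------------------------------------------

def _anisole() -> Molecule:
    """Idealized anisole (C6H5-O-CH3, 16 atoms).

    Planar ring: aromatic C-C 1.39 Å, C-H 1.09 Å, C(ar)-O 1.36 Å,
    O-CH3 1.43 Å, 120° at O, tetrahedral staggered methyl. The real molecule's
    conformer differs slightly; bond distances (which set the H0 deaths) match
    standard values.
    """
    cc, ch, co, ocm = 1.39, 1.09, 1.36, 1.43
    elements: list[str] = []
    coords: list[list[float]] = []
    # ring carbons on a circle of radius = side length (regular hexagon)
    for k in range(6):
        a = math.radians(60 * k)
        elements.append("C")
        coords.append([cc * math.cos(a), cc * math.sin(a), 0.0])
    # ring hydrogens on C2..C6 (C1 at angle 0 carries the methoxy group)
    for k in range(1, 6):
        a = math.radians(60 * k)
        elements.append("H")
        coords.append([(cc + ch) * math.cos(a), (cc + ch) * math.sin(a), 0.0])
    # ether oxygen, radially out from C1
    o = np.array([cc + co, 0.0, 0.0])
    elements.append("O")
    coords.append(o.tolist())
    # methyl carbon: C1-O-C angle 120 deg, in plane
    a = math.radians(60)
    cm = o + ocm * np.array([math.cos(a), math.sin(a), 0.0])
    elements.append("C")
    coords.append(cm.tolist())
    # methyl hydrogens: tetrahedral (109.47 deg to the O-C bond), staggered
    u = (cm - o) / np.linalg.norm(cm - o)
    v = np.array([-u[1], u[0], 0.0])  # in-plane normal to the O-C bond
    w = np.array([0.0, 0.0, 1.0])
    theta = math.radians(109.47)
    for phi_deg in (180.0, 60.0, 300.0):  # one H anti-periplanar to the ring
        phi = math.radians(phi_deg)
        # Cm->H makes 109.47 deg with Cm->O (= -u): the +u component points away from O
        d = -math.cos(theta) * u + math.sin(theta) * (
            math.cos(phi) * v + math.sin(phi) * w
        )
        h = cm + ch * d
        elements.append("H")
        coords.append(h.tolist())
    return Molecule("anisole", elements, np.array(coords))


def _diatomic(name: str, a: str, b: str, d: float) -> Molecule:
    return Molecule(name, [a, b], np.array([[0.0, 0.0, 0.0], [0.0, 0.0, d]]))


def _square4() -> Molecule:
    pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    return Molecule("square4", ["C"] * 4, pts)


def _triangle3() -> Molecule:
    pts = np.array(
        [[0, 0, 0], [1, 0, 0], [0.5, math.sqrt(3) / 2, 0]], dtype=float
    )
    return Molecule("triangle3", ["C"] * 3, pts)


def _benzene() -> Molecule:
    cc, ch = 1.39, 1.09
    elements, coords = [], []
    for k in range(6):
        a = math.radians(60 * k)
        elements.append("C")
        coords.append([cc * math.cos(a), cc * math.sin(a), 0.0])
    for k in range(6):
        a = math.radians(60 * k)
        elements.append("H")
        coords.append([(cc + ch) * math.cos(a), (cc + ch) * math.sin(a), 0.0])
    return Molecule("benzene", elements, np.array(coords))


_FIXTURES = {
    "anisole": _anisole,
    "hbr": lambda: _diatomic("hbr", "H", "Br", 1.41),
    "f2": lambda: _diatomic("f2", "F", "F", 1.41),
    "benzene": _benzene,
    "square4": _square4,
    "triangle3": _triangle3,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def fixture(name: str) -> Molecule:
    """Return a deterministic built-in geometry by name.

    Known names: anisole (16 atoms), hbr and f2 (diatomics at 1.41 Å),
    benzene, square4 (unit square), triangle3 (unit equilateral triangle).
    """
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}") from None
    return builder()
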