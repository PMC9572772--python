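"""Molecular geometries and XYZ file handling for the NCI grid engine."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constants import BOHR_PER_ANGSTROM

__all__ = ["MolecularGeometry", "read_xyz", "write_xyz", "ATOMIC_NUMBERS"]

ATOMIC_NUMBERS = {"H": 1, "C": 6, "N": 7, "O": 8, "Cl": 17}


@dataclass(frozen=True)
class MolecularGeometry:
    """Element symbols and Cartesian coordinates in Angstrom.

    Supported elements are those with shipped promolecular densities
    (H, C, N, O, Cl).  A minimum interatomic distance of 0.5 A guards
    against corrupt or doubled coordinates.
    """

    elements: tuple[str, ...]
    coords_A: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords_A, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if len(self.elements) != len(coords):
            raise ValueError("element and coordinate counts differ")
        for el in self.elements:
            if el not in ATOMIC_NUMBERS:
                raise ValueError(f"unsupported element: {el!r}")
        if len(coords) >= 2:
            d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < 0.5:
                i, j = np.unravel_index(np.argmin(d), d.shape)
                raise ValueError(
                    f"atoms {i} and {j} are {d.min():.3f} A apart (< 0.5 A)")
        object.__setattr__(self, "elements", tuple(self.elements))
        object.__setattr__(self, "coords_A", coords)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def coords_bohr(self) -> np.ndarray:
        return self.coords_A * BOHR_PER_ANGSTROM

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBERS[e] for e in self.elements], dtype=int)


def read_xyz(path: str | Path) -> MolecularGeometry:
    """Read a standard XYZ file (count line, comment line, ``El x y z`` in A)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: first line must be the atom count") from None
    if len(lines) < n + 2:
        raise ValueError(f"{path}: expected {n} atom lines")
    elements, coords = [], []
    for ln in lines[2:2 + n]:
        parts = ln.split()
        elements.append(parts[0].capitalize())
        coords.append([float(x) for x in parts[1:4]])
    return MolecularGeometry(tuple(elements), np.array(coords))


def write_xyz(geom: MolecularGeometry, path: str | Path, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{geom.n_atoms}\n{comment}\n")
        for el, (x, y, z) in zip(geom.elements, geom.coords_A):
            fh.write(f"{el:2s} {x:15.8f} {y:15.8f} {z:15.8f}\n")
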