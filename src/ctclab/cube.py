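"""Gaussian cube file and scatter CSV export/import.

Cube files let any standard isosurface viewer render the RDG and signed
density grids.  Layout: two comment lines; atom count and grid origin
(bohr); three axis records (points, step vector); one record per atom
(Z, charge, x, y, z in bohr); then values with the innermost (z) axis
varying fastest, at most six per line, scientific notation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import MolecularGeometry, ATOMIC_NUMBERS
from .promolecular import DensityGrid

__all__ = ["export_cube", "read_cube", "export_scatter_csv", "read_scatter_csv"]

_SYMBOLS = {z: el for el, z in ATOMIC_NUMBERS.items()}


def export_cube(grid: DensityGrid, geom: MolecularGeometry, path: str | Path,
                comment: str = "ctclab grid") -> None:
    vals = np.asarray(grid.values, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("grid contains non-finite values")
    nx, ny, nz = vals.shape
    ox, oy, oz = grid.origin_bohr
    sx, sy, sz = grid.axis_steps_bohr
    with open(path, "w") as fh:
        fh.write(f"{comment}\n")
        fh.write("generated by ctclab (values in a.u., axes in bohr)\n")
        fh.write(f"{geom.n_atoms:5d} {ox:12.6f} {oy:12.6f} {oz:12.6f}\n")
        fh.write(f"{nx:5d} {sx:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{ny:5d} {0.0:12.6f} {sy:12.6f} {0.0:12.6f}\n")
        fh.write(f"{nz:5d} {0.0:12.6f} {0.0:12.6f} {sz:12.6f}\n")
        for z, (x, y, zz) in zip(geom.atomic_numbers, geom.coords_bohr):
            fh.write(f"{z:5d} {float(z):12.6f} {x:12.6f} {y:12.6f} {zz:12.6f}\n")
        flat = vals.reshape(nx * ny, nz)
        for row in flat:
            for start in range(0, nz, 6):
                chunk = row[start:start + 6]
                fh.write(" ".join(f"{v:13.5E}" for v in chunk) + "\n")


def read_cube(path: str | Path) -> tuple[DensityGrid, MolecularGeometry]:
    """Parse a cube file written by :func:`export_cube` (orthogonal axes)."""
    lines = Path(path).read_text().splitlines()
    natoms = int(lines[2].split()[0])
    origin = np.array([float(x) for x in lines[2].split()[1:4]])
    shape, steps = [], []
    for i in range(3):
        parts = lines[3 + i].split()
        shape.append(int(parts[0]))
        steps.append(float(parts[1 + i]))
    elements, coords = [], []
    for i in range(natoms):
        parts = lines[6 + i].split()
        elements.append(_SYMBOLS[int(parts[0])])
        coords.append([float(v) for v in parts[2:5]])
    from .constants import BOHR_PER_ANGSTROM

    geom = MolecularGeometry(tuple(elements),
                             np.array(coords) / BOHR_PER_ANGSTROM)
    data = np.array(" ".join(lines[6 + natoms:]).split(), dtype=float)
    grid = DensityGrid(origin_bohr=origin, axis_steps_bohr=np.array(steps),
                       values=data.reshape(shape))
    return grid, geom


def export_scatter_csv(pairs: np.ndarray, path: str | Path) -> None:
    """Write (signed_rho, rdg) pairs as a two-column CSV."""
    pairs = np.atleast_2d(np.asarray(pairs, dtype=float))
    with open(path, "w") as fh:
        fh.write("signed_rho,rdg\n")
        for sr, s in pairs if pairs.size else []:
            fh.write(f"{sr:.8e},{s:.8e}\n")


def read_scatter_csv(path: str | Path) -> np.ndarray:
    import pandas as pd

    df = pd.read_csv(path)
    return df[["signed_rho", "rdg"]].values
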