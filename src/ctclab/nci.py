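"""Reduced density gradient (RDG) and sign(lambda2)*rho NCI analysis.

The NCI index maps non-covalent interactions through two scalar fields on a
grid: the reduced density gradient

    s(r) = |grad rho| / (2 (3 pi^2)^(1/3) rho^(4/3)),

which dips toward zero wherever interatomic density flattens out, and the
density signed by the middle eigenvalue lambda2 of the density Hessian,
which separates attractive (lambda2 < 0, e.g. hydrogen bonds) from
repulsive (lambda2 > 0, steric crowding) contacts.  The 2-D scatter of
(sign(lambda2) rho, s) restricted to |rho| below ~0.05 a.u. is the standard
NCI plot: a low-s trough at negative signed density is the hydrogen-bond
signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import RHO_FLOOR
from .promolecular import DensityGrid, PromolecularField, promolecular_density
from .geometry import MolecularGeometry

__all__ = [
    "RDG_PREFACTOR",
    "compute_rdg",
    "eigvals3_symmetric",
    "signed_density",
    "RDGField",
    "nci_scatter",
    "nci_analysis",
    "hbond_trough_depth",
]

#: 2 (3 pi^2)^(1/3) — denominator prefactor of the RDG.
RDG_PREFACTOR = 2.0 * (3.0 * np.pi ** 2) ** (1.0 / 3.0)


def compute_rdg(density: np.ndarray, gradient: np.ndarray,
                rho_floor: float = RHO_FLOOR) -> np.ndarray:
    """Pointwise RDG = |grad rho| / (2 (3 pi^2)^(1/3) rho^(4/3)).

    ``gradient`` has the component axis first ((3, ...) matching density's
    shape).  Densities are floored at ``rho_floor`` before the 4/3 power so
    vacuum regions cannot overflow; those points are later excluded from
    scatter output.
    """
    rho = np.maximum(np.asarray(density, dtype=float), rho_floor)
    gnorm = np.sqrt(np.sum(np.asarray(gradient, dtype=float) ** 2, axis=0))
    return gnorm / (RDG_PREFACTOR * rho ** (4.0 / 3.0))


def eigvals3_symmetric(hess: np.ndarray) -> np.ndarray:
    """Closed-form ascending eigenvalues of symmetric 3x3 matrices.

    ``hess`` holds the six components (xx, yy, zz, xy, xz, yz) on the first
    axis.  Uses the trigonometric (Cardano) solution for real symmetric
    matrices — no iterative solver, fully vectorized.  Returns an array
    shaped (3, ...) with lambda1 <= lambda2 <= lambda3.
    """
    xx, yy, zz, xy, xz, yz = (np.asarray(h, dtype=float) for h in hess)
    q = (xx + yy + zz) / 3.0
    p2 = ((xx - q) ** 2 + (yy - q) ** 2 + (zz - q) ** 2
          + 2.0 * (xy ** 2 + xz ** 2 + yz ** 2))
    p = np.sqrt(np.maximum(p2 / 6.0, 0.0))
    p_safe = np.where(p > 0, p, 1.0)
    # B = (A - q I) / p, det(B)/2 in [-1, 1] up to rounding
    bxx, byy, bzz = (xx - q) / p_safe, (yy - q) / p_safe, (zz - q) / p_safe
    bxy, bxz, byz = xy / p_safe, xz / p_safe, yz / p_safe
    detb = (bxx * (byy * bzz - byz ** 2)
            - bxy * (bxy * bzz - byz * bxz)
            + bxz * (bxy * byz - byy * bxz))
    phi = np.arccos(np.clip(detb / 2.0, -1.0, 1.0)) / 3.0
    lam3 = q + 2.0 * p * np.cos(phi)
    lam1 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    lam2 = 3.0 * q - lam1 - lam3
    degenerate = p == 0
    if np.any(degenerate):
        lam1 = np.where(degenerate, q, lam1)
        lam2 = np.where(degenerate, q, lam2)
        lam3 = np.where(degenerate, q, lam3)
    return np.stack([lam1, lam2, lam3])


def signed_density(density: np.ndarray, hessian: np.ndarray) -> np.ndarray:
    """sign(lambda2) * rho with lambda2 the middle Hessian eigenvalue.

    lambda2 = 0 yields a signed value of exactly 0 (sign convention); a
    lambda2 below rounding noise relative to the extreme eigenvalues is
    snapped to zero so the closed-form solve cannot leak a spurious sign.
    """
    lam = eigvals3_symmetric(hessian)
    lam2 = lam[1]
    scale = np.maximum(np.abs(lam[0]), np.abs(lam[2]))
    lam2 = np.where(np.abs(lam2) <= 1e-12 * scale, 0.0, lam2)
    return np.sign(lam2) * np.asarray(density, dtype=float)


@dataclass(frozen=True)
class RDGField:
    """RDG and signed density sampled on the same grid as the density."""

    rdg: np.ndarray
    signed_rho: np.ndarray
    grid: DensityGrid

    def __post_init__(self):
        if self.rdg.shape != self.signed_rho.shape:
            raise ValueError("rdg and signed_rho shapes differ")
        if np.any(self.rdg < 0):
            raise ValueError("RDG must be nonnegative")


def nci_scatter(field: RDGField, rho_cut: float = 0.05,
                rho_floor: float = RHO_FLOOR) -> np.ndarray:
    """2-D NCI scatter data: (signed_rho, rdg) pairs with |signed_rho| <=
    rho_cut, sorted by signed_rho.  Sub-floor density points are dropped."""
    if rho_cut <= 0:
        raise ValueError("rho_cut must be positive")
    sr = field.signed_rho.ravel()
    rdg = field.rdg.ravel()
    mask = (np.abs(sr) <= rho_cut) & (np.abs(sr) > rho_floor)
    pairs = np.column_stack([sr[mask], rdg[mask]])
    return pairs[np.argsort(pairs[:, 0], kind="stable")]


def hbond_trough_depth(pairs: np.ndarray,
                       window: tuple[float, float] = (-0.05, -0.01)) -> float:
    """Minimum RDG over scatter points whose signed density falls inside
    ``window`` (default: the attractive hydrogen-bond band).  Returns +inf
    when no point lies in the window — i.e. no H-bond signature."""
    if len(pairs) == 0:
        return float("inf")
    m = (pairs[:, 0] >= window[0]) & (pairs[:, 0] <= window[1])
    return float(pairs[m, 1].min()) if m.any() else float("inf")


def nci_analysis(geom: MolecularGeometry, spacing_bohr: float = 0.1,
                 margin_A: float = 2.0, rho_cut: float = 0.05,
                 model: str = "shells",
                 ) -> tuple[PromolecularField, RDGField, np.ndarray]:
    """End-to-end NCI run: promolecular field -> RDG field -> scatter pairs."""
    field = promolecular_density(geom, spacing_bohr=spacing_bohr,
                                 margin_A=margin_A, model=model)
    rdg = compute_rdg(field.grid.values, field.gradient)
    srho = signed_density(field.grid.values, field.hessian)
    rdg_field = RDGField(rdg=rdg, signed_rho=srho, grid=field.grid)
    pairs = nci_scatter(rdg_field, rho_cut=rho_cut)
    return field, rdg_field, pairs
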