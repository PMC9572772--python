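"""QTAIM bond-critical-point descriptor algebra and classification.

A bond critical point (BCP) of the electron density carries local
descriptors: density rho, its Laplacian, the Lagrangian kinetic energy
density G(r) >= 0, the potential energy density V(r) <= 0, the total energy
density H(r) = G(r) + V(r) (with the Hamiltonian kinetic energy
K(r) = -H(r)), the ratio |V|/G, and the bond energy estimate
E_int = V(r)/2.  These obey the local virial relation

    (1/4) laplacian(rho) = 2 G(r) + V(r)      (atomic units)

which this module uses as a self-consistency check on externally supplied
descriptor tables: inconsistent rows are flagged, never silently repaired.

Hydrogen bonds are classified on the Rozas criteria:

* weak      — laplacian > 0 and H > 0
* moderate  — laplacian > 0 and H < 0
* strong    — laplacian < 0 and H < 0

and on the |V|/G regimes: closed-shell (< 1), intermediate (1..2),
shared (>= 2).  Counterpoise (BSSE) arithmetic for supermolecular
interaction energies lives here too.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import HARTREE_TO_KCAL, POPELIER_RHO_RANGE

__all__ = [
    "CriticalPoint",
    "InteractionEnergy",
    "derive_cp_fields",
    "check_virial_consistency",
    "VirialReport",
    "classify_hbond",
    "HBondClass",
    "count_hbonds",
    "bsse_correct",
    "read_critical_points_csv",
    "classification_report",
]

#: Default relative tolerance for consistency checks: tables carry ~3
#: significant figures, so 2 ulps of printed precision ~ 2%.
DEFAULT_REL_TOL = 0.02


@dataclass(frozen=True)
class CriticalPoint:
    """One BCP/RCP row of a topological descriptor table (atomic units)."""

    cp_id: int
    kind: str                    # "BCP" or "RCP"
    bond_label: str
    distance_A: float
    rho: float
    laplacian: float
    g: float
    v: float
    h: float
    k: float
    ratio_vg: float
    e_int_kcal: float
    ratio_undefined: bool = False

    def __post_init__(self):
        if self.kind not in ("BCP", "RCP"):
            raise ValueError("kind must be BCP or RCP")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.g < 0:
            raise ValueError("G(r) must be nonnegative")


def derive_cp_fields(cp_id: int, kind: str, bond_label: str, distance_A: float,
                     rho: float, laplacian: float, g: float | None = None,
                     v: float | None = None, h: float | None = None,
                     ) -> CriticalPoint:
    """Complete a critical point from any two of (G, V, H).

    Uses H = G + V, K = -H, |V|/G, and E_int = V/2 (converted to kcal/mol).
    A zero G with nonzero V leaves the ratio undefined and flags the row
    instead of raising.
    """
    known = sum(x is not None for x in (g, v, h))
    if known < 2:
        raise ValueError("need at least two of g, v, h")
    if g is None:
        g = h - v
    elif v is None:
        v = h - g
    elif h is None:
        h = g + v
    elif abs(h - (g + v)) > 1e-6 * max(abs(h), abs(g), abs(v), 1e-12):
        raise ValueError("supplied g, v, h violate H = G + V")
    if g < 0:
        raise ValueError("derived G(r) is negative; inputs inconsistent")
    undefined = g == 0 and v != 0
    ratio = abs(v) / g if g > 0 else (0.0 if v == 0 else float("nan"))
    return CriticalPoint(
        cp_id=cp_id, kind=kind, bond_label=bond_label, distance_A=distance_A,
        rho=rho, laplacian=laplacian, g=g, v=v, h=h, k=-h,
        ratio_vg=ratio, e_int_kcal=0.5 * v * HARTREE_TO_KCAL,
        ratio_undefined=undefined,
    )


@dataclass(frozen=True)
class VirialReport:
    cp_id: int
    lhs: float                   # (1/4) laplacian
    rhs: float                   # 2G + V
    rel_error: float
    consistent: bool


def check_virial_consistency(cp: CriticalPoint, rel_tol: float = DEFAULT_REL_TOL,
                             eps: float = 1e-12) -> VirialReport:
    """Check the local virial relation (1/4) lap(rho) = 2G + V on one row.

    The relative error is measured against max(|lhs|, eps); rows exceeding
    ``rel_tol`` are reported inconsistent.  Printed tables violating the
    relation are flagged so the discrepancy is visible, not repaired.
    """
    lhs = 0.25 * cp.laplacian
    rhs = 2.0 * cp.g + cp.v
    rel = abs(lhs - rhs) / max(abs(lhs), eps)
    return VirialReport(cp_id=cp.cp_id, lhs=lhs, rhs=rhs,
                        rel_error=rel, consistent=rel <= rel_tol)


@dataclass(frozen=True)
class HBondClass:
    """Classification outcome for one critical point."""

    cp_id: int
    rozas: str                   # weak | moderate | strong
    regime: str                  # closed_shell | intermediate | shared
    popelier_rho: bool           # rho within the standard H-bond range
    boundary: bool               # an exact zero hit a strict inequality


def classify_hbond(cp: CriticalPoint,
                   popelier_range: tuple[float, float] = POPELIER_RHO_RANGE,
                   ) -> HBondClass:
    """Rozas strength class plus the |V|/G interaction regime.

    Boundary convention (zeros are measure-zero but must classify
    deterministically): H = 0 takes the nonnegative-H branch (weak when the
    Laplacian is positive); laplacian = 0 classifies by the sign of H alone.
    Either exact zero raises the ``boundary`` flag.
    """
    lap, h = cp.laplacian, cp.h
    boundary = lap == 0.0 or h == 0.0
    if h < 0:
        rozas = "strong" if lap < 0 else "moderate"
    else:
        rozas = "weak"
    ratio = cp.ratio_vg
    if np.isnan(ratio):
        regime = "undefined"
    elif ratio < 1:
        regime = "closed_shell"
    elif ratio < 2:
        regime = "intermediate"
    else:
        regime = "shared"
    lo, hi = popelier_range
    return HBondClass(cp_id=cp.cp_id, rozas=rozas, regime=regime,
                      popelier_rho=lo <= cp.rho <= hi, boundary=boundary)


def count_hbonds(table: Iterable[CriticalPoint]) -> int:
    """Number of hydrogen bonds: BCPs with positive Laplacian classed weak
    or moderate."""
    rows = list(table)
    if not rows:
        raise ValueError("empty critical-point table")
    n = 0
    for cp in rows:
        if cp.kind != "BCP" or cp.laplacian <= 0:
            continue
        if classify_hbond(cp).rozas in ("weak", "moderate"):
            n += 1
    return n


@dataclass(frozen=True)
class InteractionEnergy:
    """Supermolecular interaction energy before/after counterpoise correction."""

    raw_kcal: float
    bsse_hartree: float
    corrected_kcal: float


def bsse_correct(raw_kcal: float, bsse_hartree: float) -> InteractionEnergy:
    """Apply the counterpoise correction: corrected = raw + BSSE.

    The raw interaction energy is in kcal/mol while the BSSE term is taken
    in hartree by default and converted at 627.5095 kcal/mol per hartree —
    the only unit reading under which published raw/corrected pairs
    reconcile.  The correction is positive (BSSE overbinds), so it is
    additive: splitting it into two steps commutes with one combined step.
    """
    if bsse_hartree < 0:
        raise ValueError("BSSE must be nonnegative")
    return InteractionEnergy(
        raw_kcal=raw_kcal, bsse_hartree=bsse_hartree,
        corrected_kcal=raw_kcal + bsse_hartree * HARTREE_TO_KCAL,
    )


# ---------------------------------------------------------------------------
# table I/O and reporting
# ---------------------------------------------------------------------------

def read_critical_points_csv(path: str | Path) -> list[CriticalPoint]:
    """Read a descriptor table CSV.

    Expected columns: ``cp_id,kind,bond_label,distance_A,rho`` plus at least
    two of ``g,v,h`` (``k`` accepted as -H when ``h`` is absent) and
    ``laplacian``.  Missing derived columns are recomputed; present ones are
    ignored in favour of the recomputation (deviations surface through
    :func:`check_virial_consistency`, not silent repair).
    """
    df = pd.read_csv(path, comment="#")
    need = {"cp_id", "kind", "bond_label", "distance_A", "rho", "laplacian"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    out = []
    for _, r in df.iterrows():
        h = r["h"] if "h" in df.columns and pd.notna(r.get("h")) else None
        if h is None and "k" in df.columns and pd.notna(r.get("k")):
            h = -float(r["k"])
        g = float(r["g"]) if "g" in df.columns and pd.notna(r.get("g")) else None
        v = float(r["v"]) if "v" in df.columns and pd.notna(r.get("v")) else None
        out.append(derive_cp_fields(
            cp_id=int(r["cp_id"]), kind=str(r["kind"]),
            bond_label=str(r["bond_label"]), distance_A=float(r["distance_A"]),
            rho=float(r["rho"]), laplacian=float(r["laplacian"]),
            g=g, v=v, h=float(h) if h is not None else None,
        ))
    return out


def classification_report(table: Sequence[CriticalPoint],
                          rel_tol: float = DEFAULT_REL_TOL) -> list[dict]:
    """Per-row JSON-ready report: class, regime, flags, E_int in both units."""
    report = []
    for cp in table:
        cls = classify_hbond(cp)
        vir = check_virial_consistency(cp, rel_tol=rel_tol)
        report.append({
            "cp_id": cp.cp_id,
            "kind": cp.kind,
            "bond_label": cp.bond_label,
            "distance_A": cp.distance_A,
            "rho_au": cp.rho,
            "laplacian_au": cp.laplacian,
            "g_au": cp.g, "v_au": cp.v, "h_au": cp.h, "k_au": cp.k,
            "ratio_vg": cp.ratio_vg,
            "e_int_au": 0.5 * cp.v,
            "e_int_kcal": cp.e_int_kcal,
            "rozas_class": cls.rozas,
            "interaction_regime": cls.regime,
            "popelier_rho_range": cls.popelier_rho,
            "boundary_flag": cls.boundary,
            "virial_rel_error": vir.rel_error,
            "virial_consistent": vir.consistent,
        })
    return report
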