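"""Binding equilibria of 1:1 (and small m:n) donor-acceptor complexes.

The experimental chain for a charge-transfer complex is:

1. *Job's continuous variation* — absorbance vs donor mole fraction at fixed
   total concentration peaks at x = m/(m+n) for an m:n complex
   (:class:`JobAnalysis`).
2. *Photometric molar-ratio titration* — absorbance vs [A]/[D] at fixed
   donor; two line segments meet at the stoichiometric ratio
   (:class:`MolarRatioAnalysis`).
3. *Benesi-Hildebrand* — for 1:1 binding with acceptor excess,

       [D]/A = 1/(Kc eps_c) * 1/[A] + 1/eps_c,

   so an OLS line of [D]/A on 1/[A] yields the association constant
   Kc = intercept/slope (L/mol) and the complex molar absorptivity
   eps_c = 1/intercept (:class:`BenesiHildebrand`).
4. *Thermodynamics* — dG0 = -2.303 R T log10(Kc)
   (:func:`gibbs_free_energy`).

All model classes follow the fit() -> Results pattern; the exact equilibrium
solvers (:func:`solve_equilibrium_1to1`, :func:`solve_equilibrium`) are the
ground-truth oracles behind the linearised treatments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .constants import DEFAULT_TEMPERATURE_K, J_PER_KCAL, R_J_PER_MOL_K

__all__ = [
    "JobSeries",
    "TitrationSeries",
    "solve_equilibrium_1to1",
    "solve_equilibrium",
    "JobAnalysis",
    "JobResults",
    "MolarRatioAnalysis",
    "MolarRatioResults",
    "BenesiHildebrand",
    "BenesiHildebrandResults",
    "ThermoResult",
    "gibbs_free_energy",
    "read_job_csv",
    "read_titration_csv",
]

# Candidate m:n assignments for Job's method and the mole fraction of the
# donor at which each peaks (x = m/(m+n)).
_STOICH_CANDIDATES: dict[str, float] = {
    "1:1": 1 / 2,
    "1:2": 1 / 3,
    "2:1": 2 / 3,
    "1:3": 1 / 4,
    "3:1": 3 / 4,
}
#: Max |x_max - m/(m+n)| accepted before the assignment is "indeterminate".
STOICH_TOLERANCE = 0.06


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JobSeries:
    """Continuous-variation data: absorbance vs donor mole fraction at fixed
    total molarity."""

    mole_fraction_donor: np.ndarray
    absorbance: np.ndarray
    total_conc_M: float
    lambda_nm: float = float("nan")

    def __post_init__(self):
        x = np.asarray(self.mole_fraction_donor, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if x.shape != a.shape or x.ndim != 1:
            raise ValueError("mole fractions and absorbances must match in length")
        if np.any((x < 0) | (x > 1)):
            raise ValueError("mole fractions must lie in [0, 1]")
        if x.size >= 2 and not np.all(np.diff(x) > 0):
            raise ValueError("mole fractions must be strictly increasing")
        if np.any(a < 0):
            raise ValueError("absorbances must be nonnegative")
        if self.total_conc_M <= 0:
            raise ValueError("total concentration must be positive")
        object.__setattr__(self, "mole_fraction_donor", x)
        object.__setattr__(self, "absorbance", a)


@dataclass(frozen=True)
class TitrationSeries:
    """Photometric titration: fixed donor, increasing acceptor."""

    donor_conc_M: float
    acceptor_conc_M: np.ndarray
    absorbance: np.ndarray
    lambda_nm: float = float("nan")

    def __post_init__(self):
        a0 = np.asarray(self.acceptor_conc_M, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if a0.shape != ab.shape or a0.ndim != 1:
            raise ValueError("concentration and absorbance lengths differ")
        if self.donor_conc_M <= 0 or np.any(a0 <= 0):
            raise ValueError("concentrations must be positive")
        if a0.size >= 2 and not np.all(np.diff(a0) > 0):
            raise ValueError("acceptor concentrations must be strictly increasing")
        object.__setattr__(self, "acceptor_conc_M", a0)
        object.__setattr__(self, "absorbance", ab)

    @property
    def ratio(self) -> np.ndarray:
        """[A]/[D] molar ratios."""
        return self.acceptor_conc_M / self.donor_conc_M


# ---------------------------------------------------------------------------
# exact equilibrium solvers
# ---------------------------------------------------------------------------

def solve_equilibrium_1to1(d0_M: float, a0_M: float, kc: float) -> float:
    """Exact complex concentration for D + A <=> DA.

    Solves c^2 - (d0 + a0 + 1/Kc) c + d0 a0 = 0 and returns the physical
    root 0 <= c <= min(d0, a0).  Written in the numerically stable form
    (smaller quadratic root via the product identity) so that strong binding
    (Kc ~ 1e12) does not lose precision to cancellation.
    """
    if d0_M < 0 or a0_M < 0:
        raise ValueError("initial concentrations must be nonnegative")
    if kc <= 0:
        raise ValueError("association constant must be positive")
    if d0_M == 0 or a0_M == 0:
        return 0.0
    s = d0_M + a0_M + 1.0 / kc
    disc = s * s - 4.0 * d0_M * a0_M
    # disc >= (d0-a0)^2 >= 0 analytically; clip rounding noise
    root = math.sqrt(max(disc, 0.0))
    # smaller root, stable form: c = 2 d0 a0 / (s + sqrt(disc))
    return 2.0 * d0_M * a0_M / (s + root)


def solve_equilibrium(d0_M: float, a0_M: float, kc: float,
                      m: int = 1, n: int = 1) -> float:
    """Complex concentration for m D + n A <=> D_m A_n (numeric).

    ``kc`` is the overall association constant c / (d^m a^n).  For m = n = 1
    this delegates to the closed form.  Otherwise the mass-action equation is
    bracketed on [0, min(d0/m, a0/n)] and solved with Brent's method.
    """
    if m == 1 and n == 1:
        return solve_equilibrium_1to1(d0_M, a0_M, kc)
    if d0_M < 0 or a0_M < 0:
        raise ValueError("initial concentrations must be nonnegative")
    if kc <= 0:
        raise ValueError("association constant must be positive")
    hi = min(d0_M / m, a0_M / n)
    if hi <= 0:
        return 0.0

    def f(c: float) -> float:
        return kc * (d0_M - m * c) ** m * (a0_M - n * c) ** n - c

    if f(hi) > 0:  # only possible through rounding at the saturation limit
        return hi
    return optimize.brentq(f, 0.0, hi, xtol=1e-30, rtol=8.9e-16)


# ---------------------------------------------------------------------------
# Job's method
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JobResults:
    """Outcome of a continuous-variation analysis."""

    x_max: float
    stoichiometry: str          # "m:n" or "indeterminate"
    a_max: float
    n_points: int
    window: int
    series: JobSeries = field(repr=False)

    def summary(self) -> str:
        lines = [
            "Job's continuous variation",
            "-" * 40,
            f"points                 {self.n_points}",
            f"quadratic window       {self.window}",
            f"x_max (donor fraction) {self.x_max:.4f}",
            f"A at maximum           {self.a_max:.4f}",
            f"stoichiometry (D:A)    {self.stoichiometry}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.series
        ax.plot(s.mole_fraction_donor, s.absorbance, "o-", label="data")
        ax.axvline(self.x_max, ls="--", color="0.4",
                   label=f"x_max = {self.x_max:.3f}")
        ax.set_xlabel("donor mole fraction")
        ax.set_ylabel("absorbance (AU)")
        ax.legend()
        return ax


class JobAnalysis:
    """Stoichiometry from the absorbance maximum of a Job series.

    The peak abscissa is estimated by a local quadratic fit through the
    ``window`` highest points (default 5), which is robust to photometric
    noise compared with the raw argmax.  The fitted x_max is snapped to the
    nearest small-integer ratio among 1:1, 1:2, 2:1, 1:3, 3:1; anything
    farther than 0.06 in mole fraction is reported "indeterminate".
    """

    def __init__(self, series: JobSeries, window: int = 5):
        if len(series.mole_fraction_donor) < 5:
            raise ValueError("need at least 5 points")
        x = series.mole_fraction_donor
        i = int(np.argmax(series.absorbance))
        if i == 0 or i == len(x) - 1:
            raise ValueError(
                "absorbance maximum at the series boundary; the design does "
                "not bracket the peak"
            )
        if not (x.min() < 0.5 < x.max()):
            raise ValueError("series must span mole fractions on both sides of 0.5")
        self.series = series
        self.window = int(window)

    def fit(self) -> JobResults:
        s = self.series
        x, a = s.mole_fraction_donor, s.absorbance
        k = min(self.window, len(x))
        top = np.sort(np.argsort(a)[-k:])
        coeffs = np.polyfit(x[top], a[top], 2)
        if coeffs[0] < 0:  # proper concave vertex
            x_max = float(-coeffs[1] / (2.0 * coeffs[0]))
            a_max = float(np.polyval(coeffs, x_max))
            # keep vertex inside the fitted window; fall back to argmax if the
            # local fit extrapolates wildly (very noisy tops)
            if not (x[top].min() - 0.05 <= x_max <= x[top].max() + 0.05):
                x_max, a_max = float(x[np.argmax(a)]), float(a.max())
        else:
            x_max, a_max = float(x[np.argmax(a)]), float(a.max())

        best = min(_STOICH_CANDIDATES.items(), key=lambda kv: abs(kv[1] - x_max))
        stoich = best[0] if abs(best[1] - x_max) <= STOICH_TOLERANCE else "indeterminate"
        return JobResults(x_max=x_max, stoichiometry=stoich, a_max=a_max,
                          n_points=len(x), window=k, series=s)


# ---------------------------------------------------------------------------
# molar-ratio (photometric titration) breakpoint
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MolarRatioResults:
    ratio_at_break: float
    slope1: float
    intercept1: float
    slope2: float
    intercept2: float
    split_index: int
    ssr: float

    def summary(self) -> str:
        return "\n".join([
            "Molar-ratio breakpoint",
            "-" * 40,
            f"breakpoint [A]/[D]   {self.ratio_at_break:.4f}",
            f"rising segment       A = {self.slope1:.5g} r + {self.intercept1:.5g}",
            f"plateau segment      A = {self.slope2:.5g} r + {self.intercept2:.5g}",
            f"total SSR            {self.ssr:.3e}",
        ])


class MolarRatioAnalysis:
    """Two-segment least-squares elbow of absorbance vs [A]/[D].

    Every admissible split (>= 3 points per segment) is fitted exhaustively;
    series are at most dozens of points so the O(n) split scan is cheap.  The
    reported stoichiometric ratio is the abscissa where the two fitted lines
    intersect.
    """

    def __init__(self, ratio: Sequence[float], absorbance: Sequence[float]):
        r = np.asarray(ratio, dtype=float)
        a = np.asarray(absorbance, dtype=float)
        if r.shape != a.shape or r.ndim != 1:
            raise ValueError("ratio and absorbance lengths differ")
        if len(r) < 6:
            raise ValueError("need at least 6 points (3 per segment)")
        if not np.all(np.diff(r) > 0):
            raise ValueError("ratios must be strictly increasing")
        self.ratio, self.absorbance = r, a

    @classmethod
    def from_titration(cls, series: TitrationSeries) -> "MolarRatioAnalysis":
        return cls(series.ratio, series.absorbance)

    @staticmethod
    def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        return slope, intercept, float(resid @ resid)

    def fit(self) -> MolarRatioResults:
        r, a = self.ratio, self.absorbance
        best = None
        for k in range(3, len(r) - 2):
            m1, b1, s1 = self._ols(r[:k], a[:k])
            m2, b2, s2 = self._ols(r[k:], a[k:])
            if best is None or s1 + s2 < best[0]:
                best = (s1 + s2, k, m1, b1, m2, b2)
        ssr, k, m1, b1, m2, b2 = best
        if abs(m1 - m2) < 1e-12 * max(abs(m1), abs(m2), 1.0):
            raise ValueError("segments are parallel; no breakpoint")
        x_break = (b2 - b1) / (m1 - m2)
        return MolarRatioResults(ratio_at_break=float(x_break),
                                 slope1=m1, intercept1=b1,
                                 slope2=m2, intercept2=b2,
                                 split_index=k, ssr=ssr)


# ---------------------------------------------------------------------------
# Benesi-Hildebrand
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenesiHildebrandResults:
    """Fitted double-reciprocal line and the derived binding parameters.

    ``slope`` = 1/(Kc eps_c), ``intercept`` = 1/eps_c, so
    ``kc_L_per_mol`` = intercept/slope and ``epsilon_c`` = 1/intercept.
    """

    slope: float
    intercept: float
    r: float
    kc_L_per_mol: float
    epsilon_c: float
    n_points: int
    slope_se: float
    intercept_se: float
    degenerate: bool
    series: TitrationSeries = field(repr=False)

    def thermo(self, temperature_K: float = DEFAULT_TEMPERATURE_K) -> "ThermoResult":
        """Standard free-energy change at the given temperature."""
        return gibbs_free_energy(self.kc_L_per_mol, temperature_K)

    def summary(self) -> str:
        lines = [
            "Benesi-Hildebrand fit   [D]/A = 1/(Kc eps) 1/[A] + 1/eps",
            "-" * 56,
            f"points               {self.n_points}",
            f"slope                {self.slope:.6g}  (SE {self.slope_se:.2g})",
            f"intercept            {self.intercept:.6g}  (SE {self.intercept_se:.2g})",
            f"Pearson r            {self.r:.5f}",
            f"Kc                   {self.kc_L_per_mol:.4g} L/mol",
            f"eps_c                {self.epsilon_c:.4g} L mol^-1 cm^-1",
        ]
        if self.degenerate:
            lines.append("WARNING: nonpositive slope or intercept; Kc/eps_c unreliable")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Double-reciprocal plot with the fitted line and r annotated."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = 1.0 / self.series.acceptor_conc_M
        y = self.series.donor_conc_M / self.series.absorbance
        ax.plot(x, y, "o", label="data")
        xs = np.linspace(x.min(), x.max(), 100)
        ax.plot(xs, self.slope * xs + self.intercept, "-",
                label=f"y = {self.slope:.3g}x + {self.intercept:.3g}\nr = {self.r:.4f}")
        ax.set_xlabel("1/[A] (L/mol)")
        ax.set_ylabel("[D]/A (mol/L)")
        ax.legend()
        return ax


class BenesiHildebrand:
    """OLS fit of the 1:1 Benesi-Hildebrand linearisation.

    Valid when the acceptor is in large excess over the donor so that the
    free acceptor concentration equals its analytical concentration.  The
    regression is unweighted by default (a weighted variant exists for
    heteroscedastic data but is off by default, matching the conventional
    straight-line treatment).
    """

    def __init__(self, series: TitrationSeries, weighted: bool = False):
        if len(series.acceptor_conc_M) < 3:
            raise ValueError("need at least 3 titration points")
        if np.any(series.absorbance <= 0):
            raise ValueError("absorbances must be positive (division by A)")
        self.series = series
        self.weighted = weighted

    def fit(self) -> BenesiHildebrandResults:
        s = self.series
        x = 1.0 / s.acceptor_conc_M
        y = s.donor_conc_M / s.absorbance
        if self.weighted:
            # weights ~ A^2: variance of [D]/A under multiplicative noise on A
            w = s.absorbance ** 2
            coeffs, cov = np.polyfit(x, y, 1, w=np.sqrt(w), cov=True)
            slope, intercept = float(coeffs[0]), float(coeffs[1])
            slope_se, intercept_se = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
            r = float(stats.pearsonr(x, y)[0])
        else:
            lr = stats.linregress(x, y)
            slope, intercept, r = float(lr.slope), float(lr.intercept), float(lr.rvalue)
            slope_se, intercept_se = float(lr.stderr), float(lr.intercept_stderr)
        degenerate = slope <= 0 or intercept <= 0
        kc = intercept / slope if slope != 0 else float("nan")
        eps = 1.0 / intercept if intercept != 0 else float("nan")
        return BenesiHildebrandResults(
            slope=slope, intercept=intercept, r=r,
            kc_L_per_mol=kc, epsilon_c=eps, n_points=len(x),
            slope_se=slope_se, intercept_se=intercept_se,
            degenerate=degenerate, series=s,
        )


# ---------------------------------------------------------------------------
# thermodynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThermoResult:
    delta_g_kcal_per_mol: float
    temperature_K: float
    kc_L_per_mol: float


def gibbs_free_energy(kc: float, temperature_K: float = DEFAULT_TEMPERATURE_K
                      ) -> ThermoResult:
    """Standard free-energy change dG0 = -2.303 R T log10(Kc), in kcal/mol.

    R = 8.314 J mol^-1 K^-1; the thermochemical calorie (4184 J/kcal) is
    used for the conversion.  Negative for any Kc > 1.
    """
    if kc <= 0:
        raise ValueError("Kc must be positive")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    dg_j = -2.303 * R_J_PER_MOL_K * temperature_K * math.log10(kc)
    return ThermoResult(delta_g_kcal_per_mol=dg_j / J_PER_KCAL,
                        temperature_K=temperature_K, kc_L_per_mol=kc)


# ---------------------------------------------------------------------------
# CSV I/O (metadata carried as "# key=value" comment lines)
# ---------------------------------------------------------------------------

def _read_meta(path: str | Path) -> dict[str, float]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                try:
                    meta[k.strip()] = float(v.strip())
                except ValueError:
                    pass
    return meta


def read_titration_csv(path: str | Path) -> TitrationSeries:
    """``acceptor_conc_M,absorbance`` columns plus ``# donor_conc_M=`` /
    ``# lambda_nm=`` metadata lines."""
    meta = _read_meta(path)
    if "donor_conc_M" not in meta:
        raise ValueError(f"{path}: missing '# donor_conc_M=' metadata line")
    df = pd.read_csv(path, comment="#")
    return TitrationSeries(
        donor_conc_M=meta["donor_conc_M"],
        acceptor_conc_M=df["acceptor_conc_M"].values,
        absorbance=df["absorbance"].values,
        lambda_nm=meta.get("lambda_nm", float("nan")),
    )


def read_job_csv(path: str | Path) -> JobSeries:
    """``mole_fraction_donor,absorbance`` columns plus ``# total_conc_M=``."""
    meta = _read_meta(path)
    if "total_conc_M" not in meta:
        raise ValueError(f"{path}: missing '# total_conc_M=' metadata line")
    df = pd.read_csv(path, comment="#")
    return JobSeries(
        mole_fraction_donor=df["mole_fraction_donor"].values,
        absorbance=df["absorbance"].values,
        total_conc_M=meta["total_conc_M"],
        lambda_nm=meta.get("lambda_nm", float("nan")),
    )
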