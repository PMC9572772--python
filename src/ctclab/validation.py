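"""ICH-style assay validation statistics.

Covers the validation block of a spectrophotometric assay: calibration
linearity by ordinary least squares, detection and quantitation limits from
the calibration uncertainty (LOD = 3.3 sigma/S, LOQ = 10 sigma/S with sigma
the standard deviation of the intercept and S the slope), precision as the
relative standard deviation of replicates, and accuracy as percent recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import ICH_LOD_FACTOR, ICH_LOQ_FACTOR

__all__ = [
    "CalibrationModel",
    "CalibrationResults",
    "PrecisionAccuracyRecord",
    "lod_loq",
    "rsd_percent",
    "recovery_percent",
    "precision_accuracy_table",
    "validation_markdown",
]


def lod_loq(sd_intercept: float, slope: float) -> tuple[float, float]:
    """ICH detection and quantitation limits, in the concentration unit of
    the calibration design.

    LOD = 3.3 sigma / S and LOQ = 10 sigma / S; both are invariant under a
    common rescaling of sigma and S, and LOQ/LOD = 10/3.3 always.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    if sd_intercept < 0:
        raise ValueError("sd_intercept must be nonnegative")
    return (ICH_LOD_FACTOR * sd_intercept / slope,
            ICH_LOQ_FACTOR * sd_intercept / slope)


def rsd_percent(values: Sequence[float]) -> float:
    """Relative standard deviation, percent: 100 * s / mean with the sample
    (n-1) standard deviation."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    m = v.mean()
    if m == 0:
        raise ValueError("mean is zero; RSD undefined")
    return float(100.0 * v.std(ddof=1) / m)


def recovery_percent(taken: float, found: Sequence[float]) -> tuple[float, float]:
    """Accuracy as percent recovery: (100*mean(found)/taken,
    100*sd(found)/taken).  sd is 0 for a single replicate."""
    if taken <= 0:
        raise ValueError("taken concentration must be positive")
    f = np.asarray(found, dtype=float)
    if f.size == 0:
        raise ValueError("need at least one found value")
    sd = f.std(ddof=1) if f.size > 1 else 0.0
    return float(100.0 * f.mean() / taken), float(100.0 * sd / taken)


@dataclass(frozen=True)
class CalibrationResults:
    """Calibration line with its uncertainty terms and ICH limits."""

    slope: float
    intercept: float
    sd_slope: float
    sd_intercept: float
    r: float
    lod: float
    loq: float
    n: int
    linear_range: tuple[float, float]
    conc_unit: str = "uM"

    def predict(self, conc) -> np.ndarray:
        return self.slope * np.asarray(conc, dtype=float) + self.intercept

    def invert(self, absorbance) -> np.ndarray:
        """Back-calculate concentration from absorbance."""
        return (np.asarray(absorbance, dtype=float) - self.intercept) / self.slope

    def summary(self) -> str:
        u = self.conc_unit
        return "\n".join([
            "Calibration (ordinary least squares)",
            "-" * 44,
            f"n                     {self.n}",
            f"linear range          {self.linear_range[0]:g}-{self.linear_range[1]:g} {u}",
            f"slope                 {self.slope:.6g}  (SD {self.sd_slope:.4g})",
            f"intercept             {self.intercept:.6g}  (SD {self.sd_intercept:.4g})",
            f"correlation r         {self.r:.4f}",
            f"LOD                   {self.lod:.4f} {u}",
            f"LOQ                   {self.loq:.4f} {u}",
        ])

    def plot(self, conc=None, absorbance=None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if conc is not None:
            ax.plot(conc, absorbance, "o", label="data")
        xs = np.linspace(*self.linear_range, 100)
        ax.plot(xs, self.predict(xs), "-",
                label=f"A = {self.slope:.4g} c + {self.intercept:.4g}\nr = {self.r:.4f}")
        ax.set_xlabel(f"concentration ({self.conc_unit})")
        ax.set_ylabel("absorbance (AU)")
        ax.legend()
        return ax


class CalibrationModel:
    """OLS calibration of absorbance on concentration.

    ``fit()`` returns :class:`CalibrationResults` with residual-variance
    based standard errors of slope and intercept and the ICH LOD/LOQ derived
    from them.  Noiseless input returns r = +/-1 and zero SDs.
    """

    def __init__(self, conc: Sequence[float], absorbance: Sequence[float],
                 conc_unit: str = "uM"):
        c = np.asarray(conc, dtype=float)
        a = np.asarray(absorbance, dtype=float)
        if c.shape != a.shape or c.ndim != 1:
            raise ValueError("conc and absorbance lengths differ")
        if np.unique(c).size < 3:
            raise ValueError("need at least 3 distinct concentrations")
        if np.ptp(c) == 0:
            raise ValueError("zero concentration variance")
        self.conc, self.absorbance, self.conc_unit = c, a, conc_unit

    def fit(self) -> CalibrationResults:
        lr = stats.linregress(self.conc, self.absorbance)
        if lr.slope <= 0:
            raise ValueError("nonpositive calibration slope; degenerate design")
        lod, loq = lod_loq(float(lr.intercept_stderr), float(lr.slope))
        return CalibrationResults(
            slope=float(lr.slope), intercept=float(lr.intercept),
            sd_slope=float(lr.stderr), sd_intercept=float(lr.intercept_stderr),
            r=float(lr.rvalue), lod=lod, loq=loq, n=len(self.conc),
            linear_range=(float(self.conc.min()), float(self.conc.max())),
            conc_unit=self.conc_unit,
        )


@dataclass(frozen=True)
class PrecisionAccuracyRecord:
    """One concentration level of the precision/accuracy study."""

    taken: float
    intra_rsd_pct: float
    inter_rsd_pct: float
    recovery_pct: float
    recovery_sd: float

    def __post_init__(self):
        if self.intra_rsd_pct < 0 or self.inter_rsd_pct < 0 or self.recovery_sd < 0:
            raise ValueError("dispersion statistics must be nonnegative")


def precision_accuracy_table(replicates: pd.DataFrame) -> list[PrecisionAccuracyRecord]:
    """Summarise a replicate table with columns ``taken_uM,found_uM,assay_day``.

    Intra-assay RSD pools within-day replicates (mean of per-day RSDs);
    inter-assay RSD is computed across day means; recovery uses all
    replicates at the level.
    """
    req = {"taken_uM", "found_uM", "assay_day"}
    if not req <= set(replicates.columns):
        raise ValueError(f"replicate table needs columns {sorted(req)}")
    out = []
    for taken, grp in replicates.groupby("taken_uM", sort=True):
        per_day = grp.groupby("assay_day")["found_uM"]
        intra = float(np.mean([rsd_percent(v) for _, v in per_day if len(v) >= 2]))
        day_means = per_day.mean()
        inter = rsd_percent(day_means) if len(day_means) >= 2 else 0.0
        rec, rec_sd = recovery_percent(float(taken), grp["found_uM"].values)
        out.append(PrecisionAccuracyRecord(
            taken=float(taken), intra_rsd_pct=intra, inter_rsd_pct=inter,
            recovery_pct=rec, recovery_sd=rec_sd))
    return out


def validation_markdown(cal: CalibrationResults,
                        records: Sequence[PrecisionAccuracyRecord] | None = None,
                        title: str = "Assay validation") -> str:
    """Render calibration + precision/accuracy results as Markdown tables.

    LOD/LOQ printed at 4 decimals, RSD at 3, mirroring the customary report
    layout; full precision is retained on the result objects.
    """
    u = cal.conc_unit
    lines = [
        f"## {title}", "",
        "| Parameter | Value |", "|---|---|",
        f"| Linear range ({u}) | {cal.linear_range[0]:g}-{cal.linear_range[1]:g} |",
        f"| Intercept | {cal.intercept:.5g} |",
        f"| SD of intercept | {cal.sd_intercept:.4g} |",
        f"| Slope | {cal.slope:.5g} |",
        f"| SD of slope | {cal.sd_slope:.4g} |",
        f"| Correlation coefficient | {cal.r:.4f} |",
        f"| LOD ({u}) | {cal.lod:.4f} |",
        f"| LOQ ({u}) | {cal.loq:.4f} |",
    ]
    if records:
        lines += [
            "",
            f"| Taken ({u}) | Intra-assay RSD (%) | Inter-assay RSD (%) | Recovery (% +/- SD) |",
            "|---|---|---|---|",
        ]
        for r in records:
            lines.append(
                f"| {r.taken:g} | {r.intra_rsd_pct:.3f} | {r.inter_rsd_pct:.3f} "
                f"| {r.recovery_pct:.2f} +/- {r.recovery_sd:.2f} |")
    return "\n".join(lines)
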