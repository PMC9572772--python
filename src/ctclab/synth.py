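"""Synthetic data with known ground truth for every analysis stage.

Generators emulate the experimental designs of a donor-acceptor
charge-transfer study: photometric titrations at fixed donor concentration,
continuous-variation (Job) series at fixed total concentration, calibration
lines with Gaussian absorbance noise, replicate assay tables, and toy
hydrogen-bonded dimer geometries for the NCI engine.  Absorbances follow
Beer-Lambert (A = eps * [complex] * pathlength) with the complex
concentration from the exact equilibrium solvers, so fitted parameters can
always be compared against the truth that generated them.

Noise is multiplicative by default (photometric noise scales with signal at
these absorbance levels); an additive model is available behind a flag.
All generators are pure functions of (spec, seed): same inputs, bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .equilibrium import (JobSeries, TitrationSeries, solve_equilibrium)
from .geometry import MolecularGeometry

__all__ = [
    "SimulationSpec",
    "gen_titration",
    "gen_job_series",
    "gen_calibration",
    "gen_replicates",
    "gen_hbond_dimer",
    "PRESETS",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth and design of a binding-equilibrium simulation.

    ``stoichiometry`` is "m:n" for m donor + n acceptor; ``kc_true`` is the
    overall association constant (L/mol for 1:1).  ``noise_rel`` is the
    relative standard deviation of the absorbance noise (must stay below
    0.5 — beyond that the signal model is meaningless).
    """

    kc_true: float
    epsilon_c: float
    stoichiometry: str = "1:1"
    noise_rel: float = 0.0
    additive_noise: bool = False
    seed: int = 0
    donor_conc_M: float = 1e-6
    acceptor_conc_M: tuple[float, ...] = tuple(np.linspace(1e-4, 1e-3, 8))
    total_conc_M: float = 1e-4
    pathlength_cm: float = 1.0
    lambda_nm: float = 487.5

    def __post_init__(self):
        if self.kc_true <= 0 or self.epsilon_c <= 0:
            raise ValueError("kc_true and epsilon_c must be positive")
        if not (0 <= self.noise_rel < 0.5):
            raise ValueError("noise_rel must lie in [0, 0.5)")
        m, n = self.ratio
        if m < 1 or n < 1 or max(m, n) > 3:
            raise ValueError("stoichiometry limited to small m:n (max 3)")
        if self.donor_conc_M <= 0 or self.total_conc_M <= 0:
            raise ValueError("concentrations must be positive")
        if any(a <= 0 for a in self.acceptor_conc_M):
            raise ValueError("acceptor concentrations must be positive")

    @property
    def ratio(self) -> tuple[int, int]:
        m, n = self.stoichiometry.split(":")
        return int(m), int(n)


def _apply_noise(a: np.ndarray, spec: SimulationSpec, rng: np.random.Generator
                 ) -> np.ndarray:
    if spec.noise_rel == 0:
        return a
    if spec.additive_noise:
        scale = spec.noise_rel * float(np.mean(np.abs(a)))
        return a + rng.normal(0.0, scale, size=a.shape)
    return a * (1.0 + rng.normal(0.0, spec.noise_rel, size=a.shape))


def gen_titration(spec: SimulationSpec) -> TitrationSeries:
    """Simulate a photometric titration: fixed donor, swept acceptor."""
    rng = np.random.default_rng(spec.seed)
    m, n = spec.ratio
    a0 = np.asarray(spec.acceptor_conc_M, dtype=float)
    c = np.array([solve_equilibrium(spec.donor_conc_M, a, spec.kc_true, m, n)
                  for a in a0])
    absorb = spec.epsilon_c * c * spec.pathlength_cm
    absorb = _apply_noise(absorb, spec, rng)
    return TitrationSeries(donor_conc_M=spec.donor_conc_M, acceptor_conc_M=a0,
                           absorbance=np.maximum(absorb, 1e-12),
                           lambda_nm=spec.lambda_nm)


def gen_job_series(spec: SimulationSpec, n_points: int = 11) -> JobSeries:
    """Simulate a continuous-variation series at fixed total concentration.

    Mole fractions are equally spaced strictly inside (0, 1):
    x_i = i/(n_points+1), i = 1..n_points.
    """
    if n_points < 5:
        raise ValueError("need at least 5 points")
    rng = np.random.default_rng(spec.seed)
    m, n = spec.ratio
    x = np.arange(1, n_points + 1) / (n_points + 1.0)
    c = np.array([
        solve_equilibrium(xi * spec.total_conc_M, (1 - xi) * spec.total_conc_M,
                          spec.kc_true, m, n)
        for xi in x
    ])
    absorb = spec.epsilon_c * c * spec.pathlength_cm
    absorb = _apply_noise(absorb, spec, rng)
    return JobSeries(mole_fraction_donor=x, absorbance=np.maximum(absorb, 0.0),
                     total_conc_M=spec.total_conc_M, lambda_nm=spec.lambda_nm)


def gen_calibration(slope: float, intercept: float, sigma: float,
                    conc_design: np.ndarray, seed: int = 0,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Linear calibration data A = slope*c + intercept + N(0, sigma)."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    c = np.asarray(conc_design, dtype=float)
    a = slope * c + intercept
    if sigma > 0:
        a = a + rng.normal(0.0, sigma, size=c.shape)
    return c, a


def gen_replicates(levels: tuple[float, ...], rsd_pct: float, n_days: int = 3,
                   n_per_day: int = 3, bias_pct: float = 0.0, seed: int = 0):
    """Replicate assay table (taken, found, day) with a set relative noise."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for taken in levels:
        for day in range(1, n_days + 1):
            found = taken * (1 + bias_pct / 100.0) * (
                1 + rng.normal(0, rsd_pct / 100.0, size=n_per_day))
            for f in found:
                rows.append({"taken_uM": taken, "found_uM": f, "assay_day": day})
    return pd.DataFrame(rows)


# water monomer internal coordinates: O-H 0.9572 A, H-O-H 104.52 deg
_OH = 0.9572
_HOH = np.deg2rad(104.52)


def gen_hbond_dimer(separation_A: float = 1.9) -> MolecularGeometry:
    """A water dimer with the H...O hydrogen-bond distance set explicitly.

    The donor water lies in the xy plane with its bridging O-H bond on +x;
    the acceptor oxygen sits on the same axis at the requested H...O
    separation, its own hydrogens pointing away from the bond.  Near-linear
    O-H...O at ~1.9 A is a textbook moderate hydrogen bond; at 4 A the
    contact is broken and no NCI signature remains.
    """
    if separation_A < 1.2:
        raise ValueError("separation must be >= 1.2 A")
    # donor: O at origin, H1 (bridging) on +x, H2 rotated by the HOH angle
    d_o = np.zeros(3)
    d_h1 = np.array([_OH, 0.0, 0.0])
    d_h2 = np.array([_OH * np.cos(_HOH), _OH * np.sin(_HOH), 0.0])
    # acceptor O on the H-bond axis
    a_o = np.array([_OH + separation_A, 0.0, 0.0])
    # acceptor H's: bisector along +x, molecular plane xz
    half = _HOH / 2.0
    a_h1 = a_o + np.array([_OH * np.cos(half), 0.0, _OH * np.sin(half)])
    a_h2 = a_o + np.array([_OH * np.cos(half), 0.0, -_OH * np.sin(half)])
    return MolecularGeometry(
        ("O", "H", "H", "O", "H", "H"),
        np.array([d_o, d_h1, d_h2, a_o, a_h1, a_h2]),
    )


def _preset_specs() -> dict[str, SimulationSpec]:
    # Experiment-like designs: BH titration with donor 3 uM and acceptor
    # 1-4 uM; equimolar 1e-4 M Job series; calibration designs spanning the
    # published linear ranges with the published slopes/intercepts.
    return {
        "bh_experiment": SimulationSpec(
            kc_true=1e5, epsilon_c=1e4, donor_conc_M=3e-6,
            acceptor_conc_M=tuple(np.linspace(1e-6, 4e-6, 7)),
        ),
        "bh_excess": SimulationSpec(
            kc_true=1e4, epsilon_c=5e3, donor_conc_M=1e-6,
            acceptor_conc_M=tuple(np.linspace(1e-4, 1e-3, 8)),
        ),
        "job_experiment": SimulationSpec(
            kc_true=1e6, epsilon_c=1e4, total_conc_M=1e-4,
        ),
    }


#: Named experiment-like designs; calibration presets carry (slope,
#: intercept, design) tuples in uM / AU units.
PRESETS = _preset_specs()
CALIBRATION_PRESETS = {
    "calibration_ddq": {"slope": 0.002922, "intercept": 0.04729,
                        "design": tuple(np.linspace(2.5, 100.0, 8))},
    "calibration_cha": {"slope": 0.001234, "intercept": 0.01416,
                        "design": tuple(np.linspace(5.0, 100.0, 8))},
}
__all__.append("CALIBRATION_PRESETS")
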