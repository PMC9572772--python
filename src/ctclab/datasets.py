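"""Built-in reference data for the linagliptin charge-transfer complexes.

Linagliptin (LGN, an electron donor) forms coloured 1:1 charge-transfer
complexes with the pi-acceptors DDQ (2,3-dichloro-5,6-dicyano-1,4-
benzoquinone) and chloranilic acid (CHA) in acetonitrile.  The published
study characterises these complexes spectroscopically and computationally;
the small numeric tables below — association constants, calibration
parameters, QTAIM bond-critical-point descriptors, counterpoise energetics
and TD-DFT excitation lists — are the study's printed results and serve as
inputs for the descriptor algebra, unit conversions and validation
arithmetic in this package.
"""

from __future__ import annotations

import pandas as pd

from .qtaim import CriticalPoint, derive_cp_fields

__all__ = [
    "association_constants",
    "calibration_parameters",
    "critical_points",
    "interaction_energies",
    "excited_states",
    "band_maxima_nm",
]

#: Experimental CT band maxima in acetonitrile, nm.
band_maxima_nm = {"LGN-DDQ": 487.5, "LGN-CHA": 514.0}

#: Benesi-Hildebrand association constants, L/mol, at 298 K.
association_constants = {"LGN-DDQ": 1.47e12, "LGN-CHA": 4.91e10}


def calibration_parameters() -> pd.DataFrame:
    """Published calibration-line parameters (absorbance vs conc in uM)."""
    return pd.DataFrame(
        {
            "complex": ["LGN-DDQ", "LGN-CHA"],
            "linear_low_uM": [2.5, 5.0],
            "linear_high_uM": [100.0, 100.0],
            "intercept": [0.04729, 0.01416],
            "sd_intercept": [0.0009602, 0.0005387],
            "slope": [0.002922, 0.001234],
            "sd_slope": [1.980e-5, 1.048e-5],
            "r": [0.9997, 0.9996],
        }
    )


def interaction_energies() -> pd.DataFrame:
    """Counterpoise energetics: raw interaction energy (kcal/mol) and the
    BSSE term (hartree; the only unit reading reconciling raw vs corrected)."""
    return pd.DataFrame(
        {
            "complex": ["LGN-DDQ", "LGN-CHA"],
            "raw_kcal": [-75.32, -77.30],
            "bsse_hartree": [0.00338, 0.00638],
        }
    )


def excited_states() -> pd.DataFrame:
    """TD-DFT excitation lists (wavelength nm, oscillator strength) and the
    experimental band positions they correspond to."""
    return pd.DataFrame(
        {
            "complex": ["LGN-DDQ"] * 3 + ["LGN-CHA"] * 3,
            "lambda_nm": [546.28, 424.48, 371.66, 510.58, 420.17, 371.73],
            "osc_strength": [0.0245, 0.0448, 0.0000, 0.0039, 0.0000, 0.0012],
            "experimental_nm": [None, 487.5, 346.0, 514.0, 487.5, 379.0],
        }
    )


# Descriptor table rows: (cp_id, complex, bond label, distance A, rho, V, H,
# laplacian) in atomic units; G is recovered as H - V.
_CP_ROWS = [
    (121, "LGN-CHA", "O(71)...H(45)-C(10)", 2.78298, 5.15e-3, -3.16e-3,  6.84e-4, 1.81e-2),
    (149, "LGN-CHA", "O(71)...H(49)-N(12)", 1.76989, 3.87e-2, -36.6e-3, -1.34e-4, 14.5e-2),
    (126, "LGN-DDQ", "N(12)-H(49)...O(74)", 1.67704, 4.70e-2, -4.73e-2, -2.60e-3, 2.13e-2),
    (150, "LGN-DDQ", "C(13)-H(50)...O(74)", 2.46133, 9.95e-3, -6.27e-3,  1.14e-3, 3.42e-2),
    (163, "LGN-DDQ", "C(13)-H(50)...Cl(72)", 2.97070, 5.43e-3, -2.49e-3,  1.04e-3, 1.83e-2),
]


def critical_points(complex_id: str | None = None) -> list[CriticalPoint]:
    """Published BCP descriptor rows, completed via H = G + V algebra.

    Parameters
    ----------
    complex_id : "LGN-DDQ", "LGN-CHA", or None for all rows.
    """
    out = []
    for cp_id, cplx, label, dist, rho, v, h, lap in _CP_ROWS:
        if complex_id is not None and cplx != complex_id:
            continue
        out.append(derive_cp_fields(
            cp_id=cp_id, kind="BCP", bond_label=label, distance_A=dist,
            rho=rho, laplacian=lap, v=v, h=h,
        ))
    return out
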