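"""Physical constants and unit conversions used across the package.

Values are fixed project-wide so that every stage (spectra, thermodynamics,
QTAIM energetics, grids) agrees on the same conversions.
"""

#: Planck constant times speed of light, in eV.nm.  1239.84 reproduces all
#: experimental wavelength <-> band-gap pairs of the study at 2-dp rounding.
HC_EV_NM: float = 1239.84

#: Molar gas constant, J mol^-1 K^-1.
R_J_PER_MOL_K: float = 8.314

#: Thermochemical calorie convention.
J_PER_KCAL: float = 4184.0

#: Hartree -> kcal/mol.
HARTREE_TO_KCAL: float = 627.5095

#: 1 Angstrom in bohr radii (CODATA).
BOHR_PER_ANGSTROM: float = 1.8897259886

#: Default absolute temperature (25 C on the T = degC + 273 convention), K.
DEFAULT_TEMPERATURE_K: float = 298.0

#: ICH detection/quantitation factors: LOD = 3.3 sigma/S, LOQ = 10 sigma/S.
ICH_LOD_FACTOR: float = 3.3
ICH_LOQ_FACTOR: float = 10.0

#: Electron-density range (a.u.) of a standard hydrogen bond at its bond
#: critical point (Popelier criterion).
POPELIER_RHO_RANGE: tuple[float, float] = (0.002, 0.040)

#: Density floor (a.u.) applied before the rho^(4/3) division of the reduced
#: density gradient, guarding vacuum regions.
RHO_FLOOR: float = 1e-10
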