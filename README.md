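# ctclab

Analysis toolkit for UV–Vis **charge-transfer (CT) complex** studies, built
around the workflow used to characterise and assay the antidiabetic drug
linagliptin (LGN) through its coloured complexes with the π-acceptors DDQ
(2,3-dichloro-5,6-dicyano-1,4-benzoquinone) and chloranilic acid (CHA) in
acetonitrile.

A CT complex of an electron donor D and acceptor A shows a new visible band
absent from either partner. From titration spectra, `ctclab` determines:

* **Stoichiometry** — Job's continuous variation (absorbance vs donor mole
  fraction *x* at fixed total concentration peaks at *x* = m/(m+n) for an
  m:n complex) and the molar-ratio breakpoint (two-segment least squares on
  absorbance vs [A]/[D]).
* **Association constant and molar absorptivity** — the Benesi–Hildebrand
  double-reciprocal line for 1:1 binding with acceptor excess,

  [D]/A = 1/(K_c ε_c) · 1/[A] + 1/ε_c,

  so K_c = intercept/slope (L mol⁻¹) and ε_c = 1/intercept, with the exact
  quadratic equilibrium solver available as the ground-truth oracle.
* **Thermodynamics** — ΔG° = −2.303·R·T·log₁₀ K_c (kcal mol⁻¹).
* **ICH assay validation** — calibration linearity by OLS, LOD = 3.3 σ/S and
  LOQ = 10 σ/S from the intercept's standard deviation σ and slope S,
  precision (RSD %) and accuracy (recovery %).
* **QTAIM descriptor algebra** — completes bond-critical-point rows from any
  two of (G, V, H) via H = G + V, K = −H, |V|/G, E_int = V/2; checks the
  local virial relation ¼∇²ρ = 2G + V; classifies hydrogen bonds on the
  Rozas criteria and the |V|/G regimes; counterpoise (BSSE) energy
  arithmetic.
* **NCI/RDG grid engine** — a wavefunction-free promolecular density (sum of
  Slater-shell atomic densities with analytic gradients and Hessians) on a
  regular grid, the reduced density gradient
  s = |∇ρ| / (2(3π²)^{1/3} ρ^{4/3}), sign(λ₂)ρ colouring from a closed-form
  symmetric 3×3 eigen solve, NCI scatter data, and Gaussian cube export.

A synthetic-data module generates every input with known ground truth
(binding titrations, Job series, calibration lines, replicate tables, and
hydrogen-bonded water dimers at a set H···O distance), so each stage can be
exercised and validated end to end.

## Worked example

```python
import numpy as np
from ctclab import BenesiHildebrand, JobAnalysis
from ctclab.synth import SimulationSpec, gen_titration, gen_job_series

spec = SimulationSpec(kc_true=1e4, epsilon_c=5e3, donor_conc_M=1e-6,
                      acceptor_conc_M=tuple(np.linspace(1e-4, 1e-3, 8)),
                      noise_rel=0.01, seed=1)
res = BenesiHildebrand(gen_titration(spec)).fit()
print(res.summary())
```

```
Benesi-Hildebrand fit   [D]/A = 1/(Kc eps) 1/[A] + 1/eps
--------------------------------------------------------
points               8
slope                1.99429e-08  (SE 2.4e-10)
intercept            0.000199803  (SE 1e-06)
Pearson r            0.99956
Kc                   1.002e+04 L/mol
eps_c                5005 L mol^-1 cm^-1
```

With 1 % photometric noise the fit recovers the true K_c = 10⁴ L/mol to
0.2 % and ε_c = 5000 L mol⁻¹ cm⁻¹ to 0.1 %; `res.thermo(298).delta_g_kcal_per_mol`
gives −5.456 kcal/mol, the free energy a 10⁴ L/mol association constant
implies at 298 K. A strong simulated 1:1 Job series peaks where it should:

```python
job = JobAnalysis(gen_job_series(SimulationSpec(kc_true=1e6, epsilon_c=1e4,
                                                total_conc_M=1e-4), 11)).fit()
print(job.x_max, job.stoichiometry)   # 0.5000 1:1
```

The same stages are scriptable from the shell:

```bash
ctclab simulate --kind titration --kc 1e4 --epsilon 5e3 --out titration.csv
ctclab bh --input titration.csv           # Kc, eps_c, dG0 as JSON
ctclab qtaim --input table2.csv           # H-bond classes + virial flags
ctclab nci --xyz dimer.xyz --spacing 0.1  # RDG/signed-rho cubes + scatter
```

Every result JSON embeds the configuration used and a SHA-256 digest of each
input file, so re-running with identical inputs reproduces identical output.

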