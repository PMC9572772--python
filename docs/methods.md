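# Methods

This note documents the models, numerical choices and limitations behind
`ctclab`, in the order the analysis chain runs.

## Binding equilibria

For D + A ⇌ DA with association constant K_c = [DA]/([D][A]), the complex
concentration at analytical concentrations d₀, a₀ is the physical root of

c² − (d₀ + a₀ + 1/K_c)·c + d₀a₀ = 0,  0 ≤ c ≤ min(d₀, a₀).

The solver uses the product form of the smaller quadratic root,
c = 2d₀a₀ / (s + √(s² − 4d₀a₀)), which is stable against cancellation even
at K_c ~ 10¹² where the naive difference form loses most of its digits.
General m:n stoichiometries (m, n ≤ 3) are solved by bracketing the
mass-action equation on [0, min(d₀/m, a₀/n)] with Brent's method
(`scipy.optimize.brentq`, rtol at machine precision). These solvers are the
ground truth behind all linearised treatments and behind the synthetic-data
generators.

**Job analysis.** The absorbance maximum's abscissa is located by a local
quadratic fit through the five highest points (window configurable) rather
than the raw argmax — robust to photometric noise, and exact for symmetric
1:1 data. If the quadratic is not concave or its vertex extrapolates beyond
the fitted window, the raw argmax is used. The fitted x_max is snapped to
the nearest of {1:1, 1:2, 2:1, 1:3, 3:1} (peak at m/(m+n)); distances beyond
0.06 in mole fraction are reported "indeterminate" rather than forced. A
maximum on the series boundary is an error: the design does not bracket the
peak.

**Molar-ratio breakpoint.** All splits with at least three points per
segment are fitted by OLS exhaustively (series are dozens of points at
most); the split with minimal total squared residual defines the two lines,
and the breakpoint is their intersection. Parallel segments are an error,
not a NaN.

**Benesi–Hildebrand.** Unweighted OLS of [D]/A on 1/[A]
(`scipy.stats.linregress`), matching the conventional straight-line
treatment; a weighted option (weights ∝ A², the variance of [D]/A under
multiplicative noise) exists but is off by default. K_c = intercept/slope
and ε_c = 1/intercept; a nonpositive slope or intercept sets a `degenerate`
flag on the result instead of raising, since such fits are common on noisy
weak-binding data and the user should see the numbers. The linearisation
assumes acceptor excess; the synthetic recovery tests use ≥100-fold excess
designs, under which the fitted K_c reproduces the generator's truth to
within 5 % noiselessly and within 15 % median error at 1 % multiplicative
noise (20 seeds, K_c ∈ {10³, 10⁴, 10⁵}).

**Thermodynamics.** ΔG° = −2.303·R·T·log₁₀K_c with R = 8.314 J mol⁻¹ K⁻¹,
converted by the thermochemical calorie (4184 J/kcal). The default
temperature is 298 K (25 °C on the T = °C + 273 convention); using 298.15 K
moves ΔG° by under 0.01 kcal/mol, below reporting precision.

## ICH validation statistics

Calibration is OLS of absorbance on concentration with residual-variance
standard errors. Detection limits follow the ICH calibration-based route
with σ = the standard deviation of the intercept: LOD = 3.3 σ/S,
LOQ = 10 σ/S. Both are invariant under joint rescaling of σ and S, and
LOQ/LOD = 10/3.3 identically. RSD uses the sample (n−1) standard deviation;
recovery is 100·mean(found)/taken with its SD scaled the same way. Report
rendering rounds LOD/LOQ to 4 decimals and RSD to 3; result objects keep
full precision.

## QTAIM descriptor algebra

Critical-point rows are completed from any two of (G, V, H) using
H = G + V and K = −H; |V|/G and E_int = V/2 (627.5095 kcal/mol per hartree)
follow. G = 0 with V ≠ 0 flags the ratio undefined rather than raising.

The local virial relation ¼∇²ρ = 2G + V is a *consistency check* on
externally supplied tables, at a default relative tolerance of 2 %
(descriptor tables typically carry 3 significant figures). Rows that
violate it are flagged and reported — never repaired — because a printed
Laplacian that disagrees with its own G and V is exactly the kind of
transcription problem a reader needs surfaced. The built-in reference
descriptor table for the linagliptin complexes contains one such row
(BCP 126, whose printed ∇²ρ is ~8× too small to satisfy the relation); the
package reports it as inconsistent.

Rozas classes come from the signs of ∇²ρ and H (weak: both positive;
moderate: ∇²ρ>0, H<0; strong: both negative). Exact zeros are measure-zero
but must classify deterministically: H = 0 takes the nonnegative-H (weak)
branch, ∇²ρ = 0 classifies by the sign of H; either raises a boundary flag.
The |V|/G regimes are closed-shell (<1), intermediate (1–2), shared (≥2).
Hydrogen-bond counting takes BCPs with ∇²ρ > 0 classed weak or moderate.
The Popelier ρ-range flag defaults to [0.002, 0.040] a.u. and is
configurable.

BSSE arithmetic takes the raw interaction energy in kcal/mol and the BSSE
term in hartree — the only unit reading under which published raw/corrected
pairs reconcile — converted at 627.5095 kcal/mol. The correction is
additive by construction.

## Promolecular NCI/RDG engine

The promolecular density is Σ_atoms ρ_at(|r − R_a|) with spherically
averaged atomic densities. The shipped parameterisation sums normalized
Slater-type shell densities with Clementi–Raimondi effective exponents:
each shell (n, ζ, occ) contributes occ·|R_n|²/4π with
R_n(r) ∝ r^{n−1}e^{−ζr}, so every atom integrates exactly to its electron
count (verified to 1e-4 by radial quadrature in the tests). Elements H, C,
N, O, Cl are covered. A cruder single-exponential fallback with
Slater-rules valence exponents sits behind `model="slater"`. Promolecular
densities are the standard desk-scale substitute for SCF densities in
qualitative NCI mapping; they reproduce the hydrogen-bond trough and its
disappearance with separation, not quantitative isosurface values.

Gradients and Hessians are analytic (for t = A r^m e^{−br}:
t′ = t(m/r − b), t″ = t((m/r − b)² − m/r²), assembled via the chain rule),
which the tests pin against central finite differences at 1e-5 relative.
RDG = |∇ρ| / (2(3π²)^{1/3}ρ^{4/3}) with a density floor of 1e-10 a.u.
before the 4/3 power; sub-floor points are excluded from scatter output.
sign(λ₂) comes from the closed-form trigonometric eigenvalue solution for
symmetric 3×3 matrices (no iterative solver; validated against LAPACK to
1e-12), with |λ₂| below 1e-12 of the extreme eigenvalues snapped to zero so
rounding noise cannot leak a sign. Grids default to 0.1 bohr spacing with a
2 Å margin box; XYZ input is in Å, all internal math and cube output in
bohr (1 Å = 1.8897259886 bohr). Cube files follow the Gaussian convention
(z fastest, ≤6 values per line).

A note on saddle structure: at the midpoint between two isolated atoms the
promolecular λ₂ is the tangential curvature f′(r)/r, which is negative for
any decaying atomic density — the middle eigenvalue does not turn positive
at large separation. The hydrogen-bond signature vanishes with distance
because the midpoint density drops below the |ρ| ≤ 0.05 a.u. scatter
window and the low-RDG trough empties, which is what the separation tests
assert.

## Synthetic data: what it emulates, and what it does not

Generators mirror the experimental designs of the underlying study:
titrations at fixed donor with swept acceptor (including the 3 µM donor /
1–4 µM acceptor design), equimolar continuous-variation series at 10⁻⁴ M
total, calibration lines over the published linear ranges, replicate assay
tables, and a water dimer with the H···O distance as the only free
parameter. Noise is multiplicative Gaussian on absorbance (photometric
noise scales with signal at these absorbances; additive noise behind a
flag); all generators are pure functions of (spec, seed). Not emulated:
instrument drift, stray light, baseline structure, temperature dependence,
or free-acceptor absorption in Job series (correction optional and off by
default). Passing recovery tests therefore demonstrate correctness of the
estimators under the stated noise model, not robustness to systematic
instrumental error.

Note that the fixed-donor titration design with acceptor only 0.3–1.3× the
donor violates the acceptor-excess assumption of the Benesi–Hildebrand
linearisation; the generator reproduces that design faithfully, but
parameter-recovery claims are made only for excess-acceptor designs.

## Problem sizes

The test suite and the acceptance script run simulations at desk scale by
choice: titration series of 8 points, Job series of 11–19 points, 20-seed
recovery ensembles, and NCI grids at 0.1 bohr spacing over water-dimer
boxes (~10⁶ points, a few seconds). These sizes already put every estimator
well inside its asymptotic behaviour for the properties asserted.

## Known limitations

* Association constants of the magnitude reported for these complexes
  (10¹⁰–10¹² L/mol) cannot be re-derived without the raw titration
  absorbances, which are not published; only ΔG°(K_c) is reproduced.
* The QTAIM module consumes descriptors; it does not locate critical points
  or integrate basins.
* The NCI engine is promolecular by design — no SCF/DFT densities, no
  .wfn/.wfx input, no isosurface rendering (cube files delegate that to
  viewers).
* Excited-state spectra are convolved from supplied (λ, f) lists with a
  Gaussian in energy space (default FWHM 0.333 eV, amplitude = f in
  arbitrary units); no electronic-structure computation is performed.
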