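# Methods

## Scope and geometry

The package simulates a broadband continuous-wave (CW) plus two-wavelength
frequency-domain (FD) diffuse optical instrument probing a two-layer turbid
medium, and inverts the simulated data with the semi-infinite homogeneous
model — the mismatched forward/inverse pair that produces partial-volume
effects in practice.  The medium is a slab of thickness `z_top` (default
5 mm) on a semi-infinite substrate, both with refractive index n = 1.4.
Thirteen parameters describe it: per layer T (total hemoglobin, μM),
S (oxygen saturation, fraction), W, L (water/lipid volume fractions),
μs′(830 nm) (1/mm) and the scattering power-law exponent b, plus `z_top`.

The instrument defaults are CW 650–1024 nm in 0.5 nm steps (749 wavelengths),
FD at 690/830 nm with 140.625 MHz modulation, and source–detector distances
25 and 35 mm.  In a laterally uniform layered medium the two symmetric slopes
of a dual-slope arrangement coincide, so a single distance pair carries the
same information; no calibration factors are modeled and no noise is
injected — every result is deterministic.

## Spectral models

Layer absorption is the linear mix
μa(λ) = ε_O·S·T + ε_D·(1−S)·T + μa_W·W + μa_L·L.  The bundled basis spectra
(650–1030 nm, 2 nm grid, linearly interpolated onto instrument grids) are:

* **Hemoglobin** — the compiled Gratzer/Kollias tabulation of molar decadic
  extinction, converted once at load time to natural-log 1/mm per μM
  (factor ln10 × 10⁻⁷).  The compilation ends at 1000 nm; 1002–1030 nm is a
  smooth monotone extrapolation.
* **Water, lipid** — reconstructed stand-ins: monotone-cubic (PCHIP) curves
  through literature anchor points (Hale & Querry / Kou-style water in 1/cm;
  van Veen-style soybean-oil lipid in 1/mm), marked `synthetic` in their file
  names.  Anchor values in the poorly pinned bands (water above 1000 nm,
  lipid at 900/1024 nm) were chosen for consistency with the baseline
  medium's tabulated absorption values at 650/775/900/1024 nm.

Because the same basis enters the forward simulation and the unmixing,
moderate absolute errors in these spectra largely cancel; what survives into
the recovered chromophores is the *shape* mismatch with the exact (uncited
file versions of the) original compilations.  This is the main reason the
recovered water and lipid fractions here (52%, 33% at baseline) sit a few
points above the reference reconstruction (48%, 30%), while hemoglobin
(T = 94 μM, S = 69%) and the recovered μa spectrum agree closely.

Reduced scattering is the power law μs′(λ) = μs′(830)·(λ/830)^(−b),
evaluated exactly.

## Diffusion forward model

Both models use the diffusion approximation with an isotropic point source at
z₀ = 1/(μa+μs′), diffusion coefficient D = 1/(3(μa+μs′)), and an extrapolated
boundary at −z_b, z_b = 2D(1+R_eff)/(1−R_eff).  R_eff is computed from the
angular Fresnel integrals (0.4935 at n = 1.4, cached).  The measurand is the
outward Fick flux D·∂φ/∂z of the extrapolated-boundary fluence at the
physical surface; constant measurand factors cancel in the two-distance
slopes the inversion uses, and forward and inverse models share the
definition so the homogeneous limit is exact by construction.

FD quantities use the exp(−iωt) convention, giving the complex effective
attenuation μ̃_eff = sqrt(3(μa+μs′)(μa − iωn/c)) with ℜ > 0, ℑ < 0; ω = 0
reduces all expressions to CW forms.

The two-layer Green's function is solved in the spatial-frequency domain
(hyperbolic-function closed form in scaled exponentials, stable for
arbitrarily thick top layers) and inverted by an order-zero Hankel transform
on a Gauss–Legendre grid: the upper limit is set where the exp(−s·z₀)
envelope falls below e⁻³⁰ of its peak, with 2048 nodes by default.  Doubling
the nodes changes baseline reflectances by < 10⁻⁶ relative, and the
homogeneous-limit identity holds to ~10⁻¹⁰.  When z₀ exceeds `z_top`
(very thin top layers) the solution branch with the source in the bottom
layer is used; the expression is continuous across the branch crossing
(~4·10⁻⁴ numerical step).  Known limitation: as `z_top` → 0 the extrapolated
boundary retains top-layer character, so the thin-top limit approaches the
bottom-homogeneous solution only to within 2–4% rather than exactly; a
partial-current boundary condition would remove this at the cost of the
closed-form homogeneous model.

## Homogeneous inversion

Per wavelength, the only datum is the two-distance slope of the linearized
reflectance ln(ρ²R).  The fit initializes the effective attenuation at the
asymptotic slope and refines it with secant iterations on the full
homogeneous model (relative tolerance 10⁻⁹, max 200 iterations); on data
generated by the homogeneous model itself the round trip is exact to the
tolerance.  Order of operations:

1. FD: complex μ̃_eff at 690/830 nm → μt′ = −2c·ℜℑ/(3nω),
   μa = (ℜ²−ℑ²)/(3μt′), μs′ = μt′ − μa (exact algebraic inverses);
2. b_rec from the two FD μs′ values; μs′(λ) extrapolated over the CW band
   anchored at 830 nm;
3. CW: real μ_eff(λ) by the same fit with μs′(λ) pinned (vectorized over the
   grid); μa(λ) = sqrt(μs′²/4 + μ_eff²/3) − μs′/2;
4. chromophores by unconstrained QR least squares, T = O+D, S = O/T
   (S reported as NaN when T = 0).  Recovered values are *not* clipped to
   physical ranges — out-of-range values are part of the result.

FD data therefore influence the chromophores only through μs′; perturbing CW
data leaves μs′ and b_rec bit-identical.

## Sensitivity analysis

Sensitivities are central finite differences of the recovered (T, S, W, L)
with respect to the eight layer absorption parameters, with the μs′ spectrum
and b pinned at the baseline recovery (only CW is re-simulated — the analogue
of one FD measurement at baseline plus CW monitoring).  Steps are ±0.5%
relative for T and ±0.005 absolute for the fractional parameters; halving
them changes every co-sensitivity by < 1%, and on homogeneous media the
top+bottom co-sensitivities of the linear parameters (T, W, L) sum to
1 ± 0.02.  Steps that would leave the physical range are sign-reversed and
logged.  Mixed-unit entries carry the ratio's units (e.g. δT/δS_top in μM);
nothing is expressed in percent.

## Study conditions and sweeps

The baseline medium (top: 12 μM, 83%, 5%, 70%, 0.60/mm, 0.1; bottom: 120 μM,
67%, 90%, 20%, 0.40/mm, 1.5; z_top = 5 mm) is fixed by the study design.
Sweeps vary exactly one parameter at a time: default grids are 15 evenly
spaced points over ±80% of baseline for T and μs′(830), [0, 1] for S/W/L,
0–2.5 for b, and 1–15 mm for z_top — covering the qualitative behaviors
(bottom-dominated hemoglobin recovery, sigmoid-like thickness transition)
without asserting figure-level pixel values, which are not tabulated.
Per-point failures are recorded in the output table and do not abort a sweep.

## What the simulations do and do not show

Everything here is diffusion theory on noise-free, laterally uniform
two-layer media with matched refractive indices and exactly four
chromophores.  Passing tests demonstrate internal consistency of the
forward/inverse pair and the partial-volume structure of this geometry; they
say nothing about instrument noise, calibration drift, curved or
three-layered anatomy, sub-diffusive distances (ρ below one transport mean
free path triggers a warning, not an error), or chromophores outside the
basis.  Reference comparisons inherit the uncertainty of the reconstructed
water/lipid spectra discussed above: scattering recovery lands at
μs′(830) = 0.44/mm and b = 0.78 against reference values 0.42/0.9, with the
remaining gap attributable to unpublished details of the original slope-fit
and boundary conventions (an asymptotic, non-iterative fit variant moves
b to 0.86 but breaks the exact homogeneous round trip, and was rejected).
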