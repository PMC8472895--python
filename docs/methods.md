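# Methods

## Problem and scope

`slablight` analyses how visible/near-infrared light distributes itself
inside thin sheets of a turbid polymer — developed for pristine and
gamma-irradiated ultra-high molecular weight polyethylene (UHMWPE,
0.05 cm molded sheets, dose groups P-0, P-30 and P-100 for 0/30/100 kGy)
over 630–800 nm. The workflow has three stages:

1. **Extraction.** Integrating-sphere measurements of diffuse reflectance
   `R_d` and diffuse transmittance `T_d` are inverted, wavelength by
   wavelength, with the two-flux Kubelka–Munk model into flux coefficients
   `S`, `K` and then transport coefficients `mu_a`, `mu_s`.
2. **Derivation.** Per-wavelength summary quantities: total attenuation
   `mu_t = mu_a + mu_s`, transport attenuation
   `mu_eff = mu_a + mu_s (1 - g)`, penetration depth `delta = 1/mu_eff`,
   and albedo `mu_s / (mu_a + mu_s)`.
3. **Simulation.** An MCML-style Monte Carlo transports photon packets
   through the slab at the extracted coefficients, scoring total
   reflectance/transmittance/absorbance, angularly resolved escape, and
   the cylindrical absorption map `A(r, z)`.

## Two-flux model

With auxiliaries `x = (1 - T_d^2 + R_d^2) / (2 R_d)` and
`y = sqrt(x^2 - 1)`, the inversion is

    S = ln[(1 - R_d (x - y)) / T_d] / (y t),   K = S (x - 1),
    mu_a = K / 2,                              mu_s = (4 S + mu_a) / (3 (1 - g)).

The bracket is the argument of a natural logarithm: that is what the
hyperbolic solution of the two-flux differential system demands, and it is
the only reading under which the matching forward model

    a = (S + K) / S,  b = sqrt(a^2 - 1),
    R_d = sinh(bSt) / (a sinh(bSt) + b cosh(bSt)),
    T_d = b / (a sinh(bSt) + b cosh(bSt))

inverts it exactly (the round trip recovers coefficients to 1e-6 relative;
the forward closed form is itself checked against matrix-exponential
integration of the two-flux ODE system to 1e-8).

Numerical choices:

* The non-absorbing limit `K -> 0` (equivalently `R_d + T_d = 1`) makes
  the inversion degenerate; it raises a dedicated error rather than
  silently returning `mu_a = 0`. A tolerance of 1e-9 on `y` guards the
  division; in the forward direction the limit
  `R_d = St/(1+St), T_d = 1/(1+St)` is taken analytically once
  `K < 1e-12 S`, where the hyperbolic form becomes 0/0.
* The `mu -> (S, K)` conversion requires `3 (1 - g) mu_s > mu_a`; outside
  that region the two-flux description does not exist and a domain error
  is raised.
* Anisotropy defaults to `g = 0.9` (strongly forward-scattering
  polyethylene) but is a parameter everywhere. All coefficients are in
  cm^-1, lengths in cm; wavelength is metadata only.

## Derived quantities

`mu_eff` is the *transport* attenuation `mu_a + mu_s (1 - g)`, not the
diffusion-theory `sqrt(3 mu_a (mu_a + mu_s (1 - g)))`. Only the transport
form reproduces the millimetre-scale penetration depths implied by the
reference coefficients for the irradiated sheets (2.15 mm at 630 nm for
P-30, 0.97 mm for P-100); the diffusion form is provided under a separate
name for comparison. Penetration depth is stored in cm and reported in mm.

The albedo is `mu_s / (mu_a + mu_s)` — the single-scattering albedo, 1 for
a non-absorbing medium and 0 for a purely absorbing one. The conventional
*transport* albedo would use `mu_s (1 - g)`; the ratio without the
`(1 - g)` factor is the definition fixed by the reference values for these
materials (0.9545 pristine, 0.9392 at 30 kGy, both at 800 nm), so that is
what the package computes.

## Monte Carlo simulator

Single homogeneous slab, infinitely narrow normally incident beam.
Specular reflection at entry from the normal-incidence Fresnel
coefficient; inside the slab packets alternate exponential flights
(`s = -ln(xi)/mu_t`, `xi` drawn on (0, 1] so the logarithm is finite),
fractional absorption deposits `dw = w mu_a/mu_t` into a cylindrical
(r, z) grid, Henyey–Greenstein direction updates (inverse-CDF sampling),
and Fresnel-governed escape or internal reflection at the faces. Because
the slab is homogeneous and the exponential is memoryless, an internally
reflected packet redraws a fresh step from the boundary — statistically
identical to carrying the unused step fraction, which only matters across
layers with different `mu_t`. The implementation is vectorised over
photon packets with numpy and processes photons in chunks (default 1e6)
with per-chunk substreams spawned from the run seed, so results are
bit-reproducible and memory-bounded.

Defaults: 200 radial bins of 50 um (radial overflow accumulates in the
outermost bin), 100 depth bins spanning the slab, 30 polar x 48 azimuthal
escape bins, Russian roulette below weight 1e-4 with survival probability
0.1 (classic MCML values), slab refractive index 1.54 (literature value
for polyethylene) in air — all configurable, including a fully matched
boundary mode.

Weight bookkeeping is exact rather than only asymptotically conserved:
roulette kills deposit the packet's weight into its current (r, z) bin,
and the weight amplification of roulette survivors is tracked as a
separate `roulette_boost` ledger subtracted from the absorbed total, so
`r_specular + r_diffuse + t_diffuse + a_total = 1` to round-off on every
run. The spatial grid therefore sums to `a_total + roulette_boost`; the
boost is of order the roulette threshold and is not spatially resolved.

Engine validation (in the test suite): the finite-slab reference case
`mu_a = 10, mu_s = 90, g = 0.75, t = 0.02 cm` with matched boundaries
reproduces `R_d = 0.0974, T_d = 0.6610`, and the semi-infinite isotropic
medium with single-scattering albedo 0.9 behind a relative-index-1.5
boundary reproduces total reflectance 0.26139 — both within Monte Carlo
error. A pure absorber reproduces Beer–Lambert transmission, scored
errors shrink as `1/sqrt(n)`, and the azimuthal escape distribution is
uniform for isotropic scattering.

### Absorption maps and the iso-level depth

`A(r, z)` is reported as a raw absorbed-weight fraction per bin, as
photons per cm^2 (dividing by the annulus area of each radial bin, the
natural unit for comparing absorbed photon densities across doses), or
per cm^3. The "how deep does absorption visibly reach" reading of a
contour map is operationalised as the deepest depth bin whose on-axis
(max over r) value still exceeds a configurable fraction of the global
peak. The default iso level is 0.2: at much lower levels the absorption
floor near the back face of a slab whose transport optical thickness is
below one stays above the level and the reading saturates at the slab
thickness for every material, discriminating nothing. At 0.2 the depth
falls mid-slab and orders the dose groups as their `mu_eff` values imply
(the 30 kGy sheet absorbs deeper than pristine).

### Monte Carlo versus two-flux: an honest discrepancy

`validate_against_twoflux` compares MC totals R/T/A against the forward
two-flux closed form at the same coefficients, in both matched- and
mismatched-boundary conventions. For the UHMWPE coefficients at 800 nm
the two models differ by roughly 20–40% relative, far beyond Monte Carlo
noise, and no boundary or incidence convention closes the gap (matched,
slab-in-air, Lambertian illumination and the `g = 0` similarity transform
were all examined). This is expected physics, not an implementation
defect: with a reduced single-scattering albedo of ~0.68 and a transport
optical thickness of ~0.94, a thin forward-scattering slab under a
collimated beam is far from the diffuse regime in which the two-flux
approximation (and the diffusion-based `S = (3(1-g)mu_s - mu_a)/4`,
`K = 2 mu_a` mapping) is accurate. Consequently the package reports the
discrepancy as measured; claims that a correct MCML run reproduces
two-flux-extracted coefficients of such slabs within a few percent should
be treated with suspicion. The validation comparator and its 5% default
threshold are retained so the comparison is explicit and reproducible.

## Synthetic measurements

The generator emulates integrating-sphere spectra: monotone piecewise
cubic (PCHIP) interpolants through the packaged per-dose coefficient
knots (exact at the knots, no overshoot in the steep 630–700 nm region of
the irradiated groups) are pushed through the forward two-flux model, and
each `R_d`/`T_d` value is multiplied by `1 + eps`,
`eps ~ Normal(0, 0.03)` — 3% being the stated bound on the measurement
standard deviation. Noise is independent across wavelengths and between
channels because no replicate-level correlation information exists; draws
violating physicality (`r_d + t_d >= 1` or values outside (0, 1)) are
resampled with a bounded retry budget. What passing recovery tests show
is therefore that the *inversion* tolerates 3% uncorrelated multiplicative
noise (median coefficient bias under 5% across 100 replicates); they do
not certify robustness to correlated instrument artifacts (sphere
substitution error, stray light, specular leakage), which the generator
deliberately does not model.

A note on trends: under the self-consistent two-flux model the packaged
coefficient table implies that noise-free `T_d` *decreases* with
wavelength for the pristine group (its coefficients rise with wavelength)
and that the 30 kGy sheet out-transmits the 100 kGy one (its `mu_t` is
lower). Qualitative descriptions of the original measured spectra differ
on both points, which is possible only if the original coefficient
extraction was not self-consistent; the generator is anchored to the
coefficient table, and the orderings it does guarantee (pristine reflects
most, irradiated sheets transmit more than pristine) are the ones tested.

## Problem sizes

Statistical tests use 5e4–1.5e5 photons per run and 12 replicates for
convergence checks; the headline MC-versus-two-flux comparison uses 1e6
photons per dose group, at which the Monte Carlo standard error on each
scored total is below 0.1% relative and immaterial next to the model
discrepancy being measured. Parameter-recovery simulations use 100
replicates of 18-wavelength spectra.

## Known limitations

* Single homogeneous layer only; no oblique/Gaussian beams, polarization,
  time resolution, or multi-layer media.
* The two-flux inversion is exact as an inverse of its own forward model
  but, like all Kubelka–Munk analysis of thin forward-scattering slabs,
  is a biased estimator of true transport coefficients (see the
  discrepancy section above).
* The refractive index enters only through Fresnel boundary terms; 1.54
  is a literature value for polyethylene, not a fitted quantity.
* Absorption-map photon densities depend on the photon budget and bin
  geometry; only ratios and orderings across equally configured runs are
  physically meaningful.
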