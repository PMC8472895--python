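# slablight

Optical-property extraction and photon transport for turbid polymer
slabs: a Kubelka–Munk two-flux inversion of integrating-sphere diffuse
reflectance/transmittance spectra, the derived attenuation and
penetration-depth quantities, and an MCML-style Monte Carlo simulator of
light distribution inside a single homogeneous slab.

The package was built around the optical characterisation of thin
(0.05 cm) sheets of ultra-high molecular weight polyethylene (UHMWPE) —
the implant-grade biomaterial — before and after gamma sterilisation
doses of 30 and 100 kGy, over 630–800 nm. It is useful to anyone who
measures `R_d`/`T_d` of a scattering slab with an integrating sphere and
wants per-wavelength absorption and scattering coefficients, penetration
depths, albedos, and simulated photon absorption maps.

## Model

Per wavelength, with sample thickness `t` and anisotropy `g`
(default 0.9, strongly forward-scattering polyethylene):

```
x = (1 - T_d^2 + R_d^2) / (2 R_d)        y = sqrt(x^2 - 1)
S = ln[(1 - R_d (x - y)) / T_d] / (y t)  K = S (x - 1)
mu_a = K / 2                             mu_s = (4 S + mu_a) / (3 (1 - g))
```

Derived: `mu_t = mu_a + mu_s`, `mu_eff = mu_a + mu_s (1 - g)`,
penetration depth `delta = 1 / mu_eff`, albedo `mu_s / (mu_a + mu_s)`.
The matching closed-form forward model makes the inversion an exact round
trip and doubles as the reference for Monte Carlo comparisons. The
simulator follows the classic MCML recipe: exponential free flights,
fractional absorption deposits on a cylindrical (r, z) grid,
Henyey–Greenstein scattering, Fresnel boundaries, Russian roulette — with
exact weight bookkeeping and bit-reproducible seeding. See
`docs/methods.md` for assumptions, numerical choices and limitations,
including an honest account of how far two-flux and Monte Carlo
predictions diverge for thin forward-scattering slabs.

## Worked example

```python
import numpy as np
from slablight import (SyntheticSpec, generate_spectrum, km_invert, derive,
                       OpticalProperties, SlabGeometry, MCConfig, mc_run,
                       iso_level_depth)

# a noise-free synthetic measurement of the 30 kGy sheet
spectrum = generate_spectrum(SyntheticSpec(dose_label="P-30", noise_rel_sd=0.0))
coeffs, props = km_invert(spectrum)   # two-flux inversion, g = 0.9
d = derive(props)
i = 0                                  # 630 nm
print(spectrum.r_d[i], spectrum.t_d[i], props.mu_a[i], props.mu_s[i])

# photon transport at the 800 nm coefficients of the same sheet
res = mc_run(OpticalProperties(6.65, 102.78), SlabGeometry(0.05),
             MCConfig(n_photons=200_000, seed=1))
print(res.r_total, res.t_diffuse_total, res.a_total)
```

prints (formatted):

```
630 nm: R_d=0.0709 T_d=0.7756
  mu_a=1.67 cm^-1  mu_s=29.72 cm^-1
  mu_t=31.39 cm^-1  mu_eff=4.642 cm^-1
  penetration depth=2.15 mm  albedo=0.9468
MC 800 nm P-30: R=0.1093 T=0.3680 A=0.5227
  iso-level depth=0.400 mm  conservation error=0.0e+00
```

Reading: at 630 nm the irradiated sheet's measured pair inverts to a weak
absorber/scatterer, so 1/e light penetration reaches 2.15 mm — four times
the sheet thickness — which is why red light is a candidate for bulk
(not just surface) treatment of irradiated polyethylene. The Monte Carlo
run at the 800 nm coefficients splits the incident beam into 11%
reflected, 37% transmitted and 52% absorbed weight, with every photon's
weight accounted for exactly.

A command-line interface mirrors the workflow
(`slablight synth | invert | derive | validate | simulate | report`);
`slablight report --out table.csv` writes the full derived table for the
packaged UHMWPE reference coefficients (54 wavelength x dose rows).

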