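# barrelpaint

Geometry, Exchange-PAINT simulation and morphometry for DNA-origami
barrel "pegboards".

DNA-origami barrels are cylindrical origami (30-90 nm diameter,
19-65 nm tall) whose inner and outer surfaces present a rhombic
lattice of addressable "pixel" sites at ~8 nm pitch. They are
characterised by DNA-PAINT / Exchange-PAINT super-resolution
microscopy (docking-site rings imaged through transient imager
binding) and by negative-stain TEM. This package is for people who
want to reproduce, test or extend that quantitative analysis chain:

* a parametric barrel geometry model (layer diameters, pixel
  lattices, coaxial stacks, designed-dimension arithmetic),
* a synthetic Exchange-PAINT localization generator with exact ground
  truth (per-site Bernoulli labeling, Poisson binding kinetics,
  Gaussian localization noise, random-walk drift, per-round
  misregistration, registration markers) and a synthetic TEM
  generator,
* the processing chain: redundant cross-correlation (RCC) drift
  correction, density-based particle picking, coarse + marker-based
  round registration, template-free particle averaging,
* the estimators: radial-histogram diameter, axial ring-spacing
  frequency analysis, NeNA localization precision, Gaussian FWHM / z
  resolution, per-site staple availability, and TEM morphometry
  (circular Hough diameters, rectangle-template heights).

The core quantities, in the field's standard notation: external
diameter D_ext = D_outer-midpoint + t with duplex thickness
t = 2.6 nm; localization precision sigma from the NeNA
correlated-pair model p(d) = d/(2 sigma^2) exp(-d^2 / 4 sigma^2);
resolution FWHM = 2 sqrt(2 ln 2) sigma; a blurred ring's radial
density is Rice(R, sigma), which the diameter estimator fits to avoid
the +sigma^2/2R mode bias.

## Worked example

Simulate a field of upright 30-nm barrels, each carrying 6 docking
handles on its designed 31-nm ring, then pick the particles, sum them
by centre-of-mass alignment and measure the diameter:

```python
from barrelpaint.scenarios import RunConfig, run_scenario

cfg = RunConfig(scenario="monomer_diameter", preset="30-27",
                seed=1, n_particles=110)
report = run_scenario(cfg)["reports"]["diameter"]
print(f"{report.estimate:.1f} +/- {report.dispersion:.1f} nm "
      f"({report.method['n_particles']} particles)")
```

prints

```
30.6 +/- 4.2 nm (108 particles)
```

i.e. the summed super-resolution image of 108 simulated barrels reads
back the designed 31-nm docking ring to within half a nanometre; the
dispersion is the fitted radial blur of the sum (localization error
plus residual alignment error), not the uncertainty of the diameter.

The same interface runs the other scenarios (`polymer_spacing`,
`trimer_z`, `decamer_12round`, `availability`, `tem`), and a thin CLI
wraps the individual stages:

```sh
barrelpaint simulate --preset 30-27 --n 50 --seed 1 --out locs.h5
barrelpaint drift --segment-frames 250 --out corrected.h5 locs.h5
barrelpaint measure --quantity diameter corrected.h5
barrelpaint run --scenario availability --preset 30-27 --seed 1 --out run1/
```

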