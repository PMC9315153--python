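# polarscope

Simulation and analysis toolkit for transmission Mueller-matrix
microscopy of fibrous scattering media.

The package covers the full computational chain of a multi-magnification
polarization-imaging study:

- **`polarscope.stokes` / `polarscope.drr`** — Stokes/Mueller algebra and
  a dual-rotating-retarder (DRR) polarimeter forward model: polarizer +
  rotating quarter-wave plate trains before and after the sample
  (retarders at θ and 5θ), 30 steps of 6°, with matrix and Fourier
  reconstruction routes.
- **`polarscope.decomposition`** — Lu–Chipman polar decomposition
  `M = M_Δ · M_R · M_D` into diattenuation `D`, linear retardance `δ`
  and depolarization `Δ`, scalar and vectorized per-pixel forms.
- **`polarscope.texture`** — first-order moments (Mean, Entropy) and
  GLCM Haralick features (Contrast, Correlation, Energy, Homogeneity)
  of parameter images, 64 gray levels, displacement per magnification.
- **`polarscope.cylinder`** — exact infinite-cylinder scattering series
  (oblique incidence), phase functions, forward-scattering fractions and
  objective acceptance angles.
- **`polarscope.montecarlo`** — polarized Monte Carlo transport through
  a thin slab of oriented cylindrical scatterers with angle-resolved
  transmission Mueller matrices.
- **`polarscope.phantom` / `polarscope.pipeline`** — seeded synthetic
  fibrous regions with planted ground truth, an NA/magnification
  degradation model, and the end-to-end resolution study.

See `docs/methods.md` for the underlying methods and conventions.

## Worked example

### Measure and decompose a sample

Forward-simulate the 30-step DRR measurement of a retarding, weakly
diattenuating sample, reconstruct its Mueller matrix, and decompose it:

```python
import numpy as np
from polarscope import (
    simulate_measurement, reconstruct_mueller, lu_chipman,
    mueller_linear_retarder, mueller_diattenuator,
)

sample = mueller_linear_retarder(1.2, 30.0) @ mueller_diattenuator(0.15, 30.0)
trace = simulate_measurement(sample)          # 30 steps of 6 degrees
M_hat = reconstruct_mueller(trace)
print("max reconstruction error:", np.max(np.abs(M_hat - sample)))

res = lu_chipman(M_hat)
print(f"D = {res.D:.4f}, delta = {res.delta:.4f} rad, Delta = {res.Delta:.4f}")
```

Output:

```
max reconstruction error: 9.992007221626409e-16
D = 0.1500, delta = 1.2000 rad, Delta = 0.0000
```

### Single-fiber scattering

Coarse fibers scatter far more forward than fine ones — the physical
driver of magnification-dependent contrast:

```python
from polarscope import CylinderSpec, phase_function, forward_fraction
from polarscope.cylinder import DEFAULT_MEDIUM, STUDY_RADII_NM

for r in STUDY_RADII_NM:
    pf = phase_function(CylinderSpec(r, 1.43), DEFAULT_MEDIUM)
    print(f"radius {r:6.0f} nm: fraction within +/-15 deg = {forward_fraction(pf, 15.0):.4f}")
```

```
radius    100 nm: fraction within +/-15 deg = 0.2286
radius    200 nm: fraction within +/-15 deg = 0.4220
radius   1000 nm: fraction within +/-15 deg = 0.9654
radius   1500 nm: fraction within +/-15 deg = 0.9757
```

### Monte Carlo: diattenuation vs collection angle

Transmission through a 6 µm slab of oriented cylinders (µs = 200 cm⁻¹,
30° orientation fluctuation, 633 nm). Fine fibers produce a strongly
diattenuated forward beam that wide-angle collection dilutes; coarse
fibers barely diattenuate:

```python
from polarscope import CylinderSpec, SimConfig, run_simulation, d_vs_angle
from polarscope.cylinder import DEFAULT_MEDIUM

for r in (100.0, 1500.0):
    cfg = SimConfig(spec=CylinderSpec(r, 1.43), med=DEFAULT_MEDIUM, n_photons=100_000, seed=0)
    res = run_simulation(cfg)
    D = d_vs_angle(res, [5.0, 15.0, 30.0, 55.0])
    print(f"radius {r:6.0f} nm: D(5)= {D[0]:.4f}  D(15)={D[1]:.4f}  D(30)={D[2]:.4f}  D(55)={D[3]:.4f}")
```

```
radius    100 nm: D(5)= 0.0151  D(15)=0.0143  D(30)=0.0120  D(55)=0.0068
radius   1500 nm: D(5)= 0.0001  D(15)=0.0001  D(30)=0.0001  D(55)=0.0000
```

### End-to-end resolution study

Generate seeded synthetic fibrous regions, render each at the five
objective configurations (4×/0.10 … 60×/0.80), decompose, and compute
texture statistics and correlations:

```python
from polarscope import StudyConfig, run_study, delta_Delta_correlation, pearson_matrix

cfg = StudyConfig(n_regions=8, seed=0)
result = run_study(cfg)
print(result.features.head(3)[["region_id", "magnification", "parameter", "mean_value", "contrast"]])
print("delta-Delta Pearson r (60x):", round(delta_Delta_correlation(result), 3))
print(pearson_matrix(result, "delta", "mean_value").round(3))
```

```
   region_id magnification parameter  mean_value   contrast
0          0            4x         D    0.001042  27.277058
1          0            4x     delta    0.658912  31.552266
2          0            4x     Delta    0.310291  17.011563
delta-Delta Pearson r (60x): 0.998
magnification     4x    10x    20x    40x    60x
magnification                                   
4x             1.000  0.995  0.992  0.989  0.989
10x            0.995  1.000  1.000  0.999  0.999
20x            0.992  1.000  1.000  1.000  1.000
40x            0.989  0.999  1.000  1.000  1.000
60x            0.989  0.999  1.000  1.000  1.000
```

## Command line

The `polarscope` console script wraps the library:

```
polarscope generate --n-regions 27 --seed 0 --out regions/   # Mueller TIFF stacks
polarscope analyze regions/region_000.tif --glcm-d 5         # decompose + texture
polarscope phase --radius-nm 100                             # phase-function summary
polarscope simulate --radius-nm 100 --n-photons 100000       # slab Monte Carlo
polarscope report --n-regions 27 --seed 0 --out study/       # full study CSVs
```

## Tests

```sh
python -m pytest
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(analytic values, reconstruction fidelity, decomposition recovery, GLCM
oracle equivalence, phase-function direction, Monte Carlo trends,
conservation invariants, and the end-to-end study). The acceptance
target is recomputed by:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which reports `t2`, the maximum normalized Mueller-element
reconstruction error (in %) of the simulated DRR polarimeter over ideal
standard samples.
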