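# susi — spectral ultrasound imaging for engineered-tissue constructs

`susi` is a quantitative-ultrasound (QUS) toolkit for non-destructive
monitoring of cell-seeded hydrogel constructs with high-frequency ultrasound
(55 MHz centre, 20–75 MHz bandwidth).  From raw backscattered RF scans — a
3-D stack of A-lines plus a matching reference scan without the specimen — it
estimates:

* **bulk acoustics**: construct thickness and speed of sound by the
  substitution method, the frequency-dependent attenuation coefficient from
  gel-pad insertion loss, and the construct volume from serial B-mode
  contours;
* **microstructure**: the effective scatterer (cell) diameter, acoustic
  concentration `CQ²`, number concentration `C` and relative acoustic
  impedance `Q` from calibrated backscatter spectra;
* **mineralization**: the mass of calcium deposited by differentiating
  pre-osteoblasts, sensed as a rise in scatterer impedance between imaging
  days.

It is aimed at tissue-engineering and QUS researchers who want
instrument-independent, longitudinal readouts of cell number, size and
differentiation state without sacrificing samples to biochemical assays.
Because no public RF data sets exist for this preparation, the package ships
a ground-truth RF simulator (`susi.simulate`) that emulates the acquisition
(420 MS/s sampling, 31 µm A-line spacing, 200 µm slice spacing) and the
specimen classes (bead phantoms, cell constructs, mineralizing timecourses),
so every estimator is validated by parameter recovery.

## The model

The calibrated power spectrum of an RF window is
`S(f) = 10·log10(|FFT(sample window)|² / |FFT(reference echo)|²)` dB, which
removes the system and transducer response.  For identical spherical
scatterers of radius `a` in a medium of sound speed `c`, Poisson-distributed
at number concentration `C` with relative impedance
`Q = (ρᵢcᵢ − ρc)/(ρc)`, the expected calibrated spectrum follows the
Gaussian-form-factor model

```
S(f) = E + 10·log10(C Q² a⁶) + 10·n·log10(f) − (10/ln10)·0.827·(2πfa/c)²
```

with `n` the geometry power-law exponent (4 for small spheres) and `E` a
shape/system constant (dB).  Ordinary least squares over the −9 dB band of
the reference spectrum yields the spectral slope `m'` (dB/MHz) and the
mid-band fit `MBF'` (dB, the fitted value at the band centre `f_c`).  Both
are attenuation-corrected with the measured coefficient
`α` (dB/(cm·MHz)) and the one-way in-sample depth `z` (cm):

```
m = m' + 2αz          MBF = MBF' + 2αz·f_c
```

The corrected slope inverts in closed form for the scatterer radius, and the
corrected MBF for the acoustic concentration `CQ²`; given one known factor
the other follows (`Q = √(CQ²/C)` or `C = CQ²/Q²`).  An impedance rise from
a baseline `Q₀` to `Qᵢ` converts to a deposited calcium mass

```
M = Nᵢ · Vᵢ · ρc · (Qᵢ − Q₀) / cᵢ ,    Vᵢ = (4/3)πa³
```

where `Nᵢ` is the number of scatterers.  See `docs/methods.md` for the
derivations, unit conventions and numerical choices.

## Worked example

Simulate a day-0 construct (14 µm cells at 2×10⁶ /ml, Q = 0.6, matrix at
1520 m/s, α = 0.1 dB/(cm·MHz), 1.5 mm thick) and quantify it:

```python
from susi import PhantomConfig, SusiConfig, SusiModel, simulate_scan, AcquisitionGrid

config = PhantomConfig(
    scatterer_diameter_um=14.0, number_concentration=2000.0,
    relative_impedance=0.6, medium_speed=1520.0,
    attenuation_coeff=0.1, thickness_mm=1.5, gelpad_depth_mm=4.2,
)
sample, reference = simulate_scan(config, grid=AcquisitionGrid(n_lines=60, n_slices=1), seed=5)
results = SusiModel(sample, reference, SusiConfig(known_c=2000.0)).fit()
print(results.summary())
```

which prints

```
Spectral ultrasound quantification
==================================================
thickness                        1.500  mm
speed of sound                  1520.0  m/s
attenuation coefficient          0.100  dB/(cm MHz)
construct volume                  0.55  mm^3
--------------------------------------------------
analysis band                 22.4 - 87.8  MHz
analysis windows                    48
spectral slope m                0.0129  dB/MHz
mid-band fit MBF                -20.62  dB
scatterer diameter               13.95  um
acoustic conc. CQ^2              709.4  /mm^3
relative impedance Q             0.596
number concentration C          2000.0  /mm^3
```

Every bulk quantity matches its configured truth; the recovered diameter
(13.95 µm vs 14), acoustic concentration (709 vs 720 = C·Q² /mm³) and
impedance (0.596 vs 0.6) are recovered to a few percent from the spectra
alone.  `results.render_map("diameter", "map.png")` overlays the per-window
diameter estimates in colour on the B-mode image,
`results.window_table` is the per-window parameter table, and
`results.roi_table` holds mean ± SD per 0.6 mm × 5.0 mm × thickness
statistical element.

The same workflow is available from the shell:

```
susi simulate --config cfg.yaml --out sim/ --seed 5
susi run --sample sim/sample --reference sim/reference --config cfg.yaml --out results/
susi map --sample sim/sample --reference sim/reference --parameter diameter --out map.png
```

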