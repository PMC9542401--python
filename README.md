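# splitpin

Phasor-based optical-sectioning enhancement for confocal microscopes with a
tunable pinhole.

In a confocal microscope the pinhole size sets the trade-off between optical
sectioning and signal: closing the pinhole from 1 to 0.2 Airy Units (A.U.)
rejects most out-of-focus light but also ~95% of the photons. `splitpin`
sidesteps the trade-off by acquiring a short *series* of images at different
pinhole sizes and exploiting the fact that, as the pinhole closes,
out-of-focus intensity decays faster than in-focus intensity. The pinhole
dimension thus carries a per-pixel fingerprint that separates the two
components — no model fit required.

The package is aimed at microscopists and image-analysis developers who want
closed-pinhole sectioning without closed-pinhole noise, and at method
developers who need a reproducible simulation and quality-evaluation
harness for pinhole-series algorithms.

## Method

For each pixel of an n-frame series F_j (j = 1…n, ordered by decreasing
pinhole size) the first-harmonic phasor is

    g = Σ_j F_j cos(2π(j−1)/n) / Σ_j F_j
    s = Σ_j F_j sin(2π(j−1)/n) / Σ_j F_j .

Pure in-focus and pure out-of-focus signals map to fixed points P_IN and
P_OUT in the (g, s) plane, and any mixture falls on the segment between them
at its intensity fraction. Projecting the pixel phasor P onto that segment,

    f_IN = (P_OUT − P)·(P_OUT − P_IN) / |P_OUT − P_IN|² ,

gives the in-focus fraction, which is regularised by a logistic filter
f = 1/(1+e^(−k_L(f−1/2))) (k_L = 4) and multiplied by a confocal image
(any frame or their sum) to synthesise the sectioned image.

Image quality is graded by image correlation spectroscopy: from the FFT
autocorrelation G(δ) of intensity fluctuations, a Gaussian fit that skips
the zero-lag point yields

    R = √(2 ln 2)·w   (ACF FWHM — resolution)
    B = G_NF(0)·I_av  (brightness/contrast)
    N = (G(0) − G_NF(0)) / G_NF(0)   (relative noise variance),

so the noise spike at zero lag is measured separately from structure.

A built-in simulator renders pinhole-tuned xz sections of random point
emitters with separable Gaussian PSFs (axial waist and amplitude tabulated
per pinhole size) and Poisson photon noise, plus a membrane-like phantom
(bright sheets over out-of-focus haze).

## Worked example

```python
from splitpin import (PhasorCalibration, SimulationConfig, decompose,
                      quics_report, simulate_stack)

stack, closed = simulate_stack(SimulationConfig(S=100.0, seed=7))
split = decompose(stack, PhasorCalibration.simulation_default(), "sum").split_image
for name, img in [("sectioned (sum)", split), ("closed 0.2 A.U.", closed)]:
    rep = quics_report(img, axis="z")
    print(f"{name:16s} R_z = {rep.R:6.1f} nm   B = {rep.B:7.1f}   N = {rep.N:6.3f}")
```

prints

```
sectioned (sum)  R_z =  513.9 nm   B =   119.2   N =  0.040
closed 0.2 A.U.  R_z =  630.1 nm   B =    14.8   N =  0.051
```

The sectioned image built from three bright frames (1.5/1.0/0.5 A.U.)
resolves a *thinner* axial slice than the photon-starved 0.2 A.U.
acquisition of equal total integration time (smaller R_z), with higher
contrast (B) and a lower noise level (N). The `examples/` directory holds
one short script per capability: simulation, decomposition, quality
metrics, the replicated benchmark, the subtractive-imaging comparison and
phasor auto-calibration.

The same workflow is available from the shell:

```bash
splitpin simulate --out stack.tif --closed closed.tif --seed 7
splitpin split --stack stack.tif --meta stack.json --out split.tif
splitpin quics --image split.tif --axis z
splitpin benchmark --seed 1 --out bench.csv
```

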