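# Methods

## Signal model

A tunable-pinhole series is n co-registered confocal frames F_j(x, z),
j = 1…n, ordered by strictly decreasing pinhole size (the canonical order
throughout the package; readers reverse increasing series on load). The
detection PSF is modelled as separable,

    PSF(x, z, s) = exp(−2x²/w_x²) · A(s) · exp(−2z²/w_z²(s)),

with only the axial response depending on the pinhole size s: the 1/e²
waist w_z(s) shrinks and the transmitted amplitude A(s) drops as the
pinhole closes. The default table — s = 1.5/1.0/0.5 A.U. with
w_z = 680/620/590 nm and A = 1.4/1.0/0.38·S, lateral waist w_x = 169 nm —
describes a high-NA oil objective; S is the peak expected photon count of
a single in-focus emitter in the 1 A.U. frame. The closed-pinhole
comparison frame (0.2 A.U., w_z = 550 nm, amplitude 0.3·S) represents
three accumulated closed-pinhole scans of 0.1·S each, so the comparison is
at matched total integration time.

## Phasor decomposition

Each pixel's frame profile is reduced to its first-harmonic phasor
(g, s) = Σ F_j (cos, sin)(2π(j−1)/n) / Σ F_j. For nonnegative profiles the
phasor lies in the convex hull of the n roots of unity (modulation ≤ 1),
and mixtures are linear: the phasor of a·A + b·B lies on the segment
joining the component phasors at the intensity fraction of A. The in-focus
fraction is the scalar projection onto the IN–OUT segment; with an exact
two-point calibration and noiseless data this recovers the true in-focus
intensity fraction to machine precision. Only the first harmonic is used.

Raw fractions are passed through the logistic filter
f = 1/(1+e^(−k_L(f−1/2))) with k_L = 4. The filter is applied exactly as
stated, with no prior clamping: endpoints map to 1/(1+e^∓²) ≈ 0.12/0.88,
not to 0/1. Raw fractions outside [−5, 6] trigger a diagnostic warning
(they usually indicate calibration mismatch — or, at very low counts,
pure shot noise). Zero-total pixels are flagged, forced to f_IN = 0, and
stay dark in the output.

### Phasor-map smoothing

The IN–OUT segment of the default conditions is only 0.1 long in the
phasor plane, while the per-pixel phasor inherits shot noise of order
1/√(total counts) — 0.06 even at the brightest pixels at S = 100. Used
raw, the per-pixel fraction is therefore noise-dominated, and the
synthesised image's zero-lag noise N exceeds the closed-pinhole frame's,
inverting the method's expected noise advantage. Following standard
practice in phasor-based separation, the g/s maps are median-filtered
(3×3 by default) before projection; this removes pixel-level phasor noise
without moving component positions, and restores both the noise ordering
(lowest N for the full-sum variant, below the closed pinhole at every S)
and the resolution ordering. `smooth=0` disables it for analytic work;
the window size is a parameter everywhere it applies.

### Calibration

P_IN and P_OUT are set manually — the documented path — either from known
pure-component profiles via `profile_phasor` or from the shipped
simulation preset (0.25, 0.19)/(0.35, 0.19), which corresponds to the
default amplitude table (in-focus profile ∝ A(s)) and to out-of-focus
light at ≈500 nm axial offset. `auto_calibrate` offers an advisory
proposal: the 1st/99th-percentile points of the intensity-weighted phasor
cloud along its principal axis, labelling the lower-modulation endpoint
P_IN (a flatter pinhole profile has a phasor nearer the origin). It is
never applied silently.

### Synthesis

The sectioned image is f_IN·I_conf, where I_conf is a single frame or a
frame sum. The default is the sum of all frames, which carries the most
photons and yields the lowest-noise result; presets cover the last frame
("last"/"3") and 1-based ranges ("2-3", "1-3"). A weighted-subtraction
baseline I_PH2 − γ(I_PH1 − I_PH2) (γ = 0.15, negatives clamped) is
provided for comparison with two-frame approaches.

## Quality metrics

The 2-D autocorrelation G(δx, δz) = ⟨I·I_shifted⟩/⟨I⟩² − 1 is computed by
FFT with periodic wrap and no zero padding; G(0,0) equals Var(I)/⟨I⟩²
exactly, and G is invariant under intensity rescaling. Axis profiles are
the zero-other-lag slices (first image axis = optical axis for xz data);
the radial profile is an angular mean over unit-width annuli. Wrapped
products can bias large-lag values on images with strong edge gradients;
the fit's offset term absorbs this in practice.

The noise-free part is a Gaussian a·e^(−δ²/w²) + c fitted over lags
1…δ_max, skipping lag 0 so the uncorrelated-noise spike never biases the
fit. δ_max = "auto" uses a deterministic rule: offset estimated as the
median of the outer quartile of lags, bound at the first lag below
offset + 10% of (G(1) − offset), clamped to [4, L/4]; it is always
user-overridable, and a width hitting its bound is flagged. Initial
guesses: amplitude from G(1), width from the half-amplitude lag, offset
from the outer-quartile median; amplitude and width constrained positive.

Read-outs: R = √(2 ln 2)·w·pixel_size (the ACF FWHM; for images of
well-separated Gaussian spots of intensity waist w_psf the ACF decays as
e^(−δ²/w_psf²), so R equals the PSF FWHM), B = G_NF(0)·I_av with I_av the
plain all-pixel mean (an optional mask restricts it), and
N = (G(0) − G_NF(0))/G_NF(0). On effectively noiseless or smoothed images
N can be slightly negative; it is reported as computed.

## Simulator

Point emitters are drawn uniformly at pixel centres (a subpixel option is
deliberately absent: no interpolation scheme is imposed). Frames are
rendered by direct evaluation of the separable Gaussian, truncated at 4
waists (truncation error < e^−32), clipped at frame edges without wrap.
Noise is independent per-pixel Poisson with the rendered mean — photon
counting implies shot noise, and the N metric is meaningless without it —
with a "none" switch for analytic tests. Default field: 20 emitters on a
256×256 grid at 50 nm pixels.

The membrane phantom (synthetic stand-in for epithelial xz data) renders
two horizontal Gaussian sheets whose per-frame weights follow the
in-focus fingerprint A(s), over a uniform haze weighted by the
out-of-focus fingerprint A(s)·e^(−2d²/w_z²(s)) at d = 500 nm; it returns
the exact component weights so tests can calibrate exactly.

What the simulator does not emulate: diffraction-integral PSF shapes and
their pinhole-dependent lateral variation, detector read noise and dark
counts, background autofluorescence, stage drift between frames, and
label/structure complexity of real specimens. Passing benchmarks
therefore demonstrate the algorithm's behaviour under its stated model,
not performance on arbitrary real acquisitions.

## Replicated benchmark

`run_benchmark` mirrors the standard study protocol: photon scales
S ∈ {50, 100, 500}, five replicates each; per replicate a fresh-noise
stack plus closed-pinhole frame over one shared emitter field (a
`resample_field` flag redraws the field), the three sectioned variants,
and the z-axis quality triplet for all four images, emitted as a tidy
CSV. Per-replicate seeds are root_seed + 1000·S_index + replicate, so any
single run re-executes in isolation; replicate comparisons use means for
R and medians for N (medians are robust to occasional fit outliers at
S = 50). Representative outcome at S = 100 (seed 1): mean R_z ≈ 527 nm
for the full-sum sectioned image vs ≈ 644 nm for the 0.2 A.U. frame, with
median N 0.023 vs 0.038 — the sectioned image is both sharper axially and
less noisy.

## Numerical and degenerate-input choices

Floating-point frames regardless of input bit depth, no rescaling on
read. All-zero stacks produce a fully-flagged phasor field with a logged
warning rather than an error. Coincident calibration points, empty frame
selections, negative γ, zero-mean images and non-monotonic pinhole lists
raise validation errors. Fit non-convergence raises an error carrying the
initial guesses and window. The logistic filter saturates in float64 for
|k_L·(f−½)| ≳ 37; values are guaranteed in [0, 1].

## Known limitations

Two-component decomposition only (no multi-component unmixing); first
harmonic only; frames must be co-registered (no drift correction); the
circular ACF assumes quasi-periodic statistics; the auto-δ_max rule is a
heuristic for "one Gaussian component" and should be overridden when the
ACF has close-range structure; quantitative agreement with published
cell-imaging numbers requires the original raw images and is out of
scope.
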