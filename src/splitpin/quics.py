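"""Image-quality assessment by image correlation spectroscopy (QuICS).

The normalised spatial autocorrelation of intensity fluctuations,

    G_2D(dx, dz) = <I(x,z) I(x+dx, z+dz)> / <I>^2 - 1,

carries three quality read-outs.  Its decay width tracks the size of the
smallest resolved structure (resolution), its fluctuation amplitude tracks
contrast, and uncorrelated noise appears only at zero lag, as a spike above
the smooth part.  Fitting a Gaussian to the profile while *skipping the
zero-lag point* separates the noise-free correlation

    G_NF(d) = G_NF(0) exp(-d^2 / w^2) + G_NF(inf)

from the spike, yielding

    R = sqrt(2 ln 2) w     (the ACF's FWHM, reported in physical units)
    B = G_NF(0) * I_av     (brightness / contrast)
    N = (G(0) - G_NF(0)) / G_NF(0)   (relative noise variance)

The 2-D correlation is computed by FFT with periodic wrap (circular
correlation, no zero padding); for images with strong edge gradients the
wrapped products can bias large-lag values, which the fit's offset term
absorbs in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import curve_fit

from .stack import Image, StackValidationError

Axis = Literal["x", "z", "radial"]


class AcfFitError(RuntimeError):
    """The noise-free Gaussian fit did not converge."""


@dataclass
class AcfProfile:
    """1-D autocorrelation profile versus nonnegative pixel lag."""

    lags: np.ndarray
    values: np.ndarray
    axis: Axis

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags[0] != 0 or np.any(np.diff(self.lags) <= 0):
            raise StackValidationError("lags must start at 0, strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise StackValidationError("profile values must be finite")


@dataclass
class AcfFit:
    """Noise-free Gaussian fit of an ACF profile (zero lag excluded)."""

    amplitude: float  # G_NF(0)
    width: float      # w, 1/e^2 Gaussian width in lag (pixel) units
    offset: float     # G_NF(inf)
    delta_max: int
    zero_lag_value: float  # raw G(0), including the noise spike
    width_at_bound: bool = False


@dataclass
class QuicsReport:
    """The (R, B, N) quality triplet for one image and analysis axis.

    R: resolution, the ACF FWHM in nm.  B: brightness, G_NF(0) * I_av.
    N: relative noise variance, (G(0) - G_NF(0)) / G_NF(0); small negative
    values can occur on effectively noiseless images and are reported as-is.
    """

    R: float
    B: float
    N: float
    I_av: float
    axis: Axis
    fit: AcfFit


def acf_2d(img: Image) -> np.ndarray:
    """Normalised 2-D circular autocorrelation of the image.

    Computed via FFT (Wiener-Khinchin), averaging the wrap-around product
    over all pixels.  The zero-lag value equals Var(I)/<I>^2 exactly.  The
    returned surface is indexed ``[dz, dx]`` (row lag first) with lag 0 at
    index ``[0, 0]`` and negative lags wrapped to the high end.
    """
    pixels = img.pixels
    mean = pixels.mean()
    if mean <= 0:
        raise StackValidationError("image mean must be positive for the ACF")
    n_pix = pixels.size
    power = np.abs(np.fft.fft2(pixels)) ** 2
    corr = np.fft.ifft2(power).real / n_pix  # <I(x) I(x+d)> over all pixels
    return corr / mean**2 - 1.0


def acf_profile(surface: np.ndarray, axis: Axis) -> AcfProfile:
    """Extract a 1-D lag profile from the correlation surface.

    ``"z"`` and ``"x"`` take the zero-other-lag slice along the first and
    second image axis respectively; ``"radial"`` averages over annuli of
    unit pixel width (angular mean).  Profiles run from lag 0 to half the
    axis length.
    """
    h, w = surface.shape
    if axis == "z":
        m = h // 2
        return AcfProfile(np.arange(m + 1), surface[: m + 1, 0], axis)
    if axis == "x":
        m = w // 2
        return AcfProfile(np.arange(m + 1), surface[0, : m + 1], axis)
    if axis == "radial":
        # circular lags: distance to the nearest periodic image of lag 0
        dz = np.minimum(np.arange(h), h - np.arange(h))[:, None]
        dx = np.minimum(np.arange(w), w - np.arange(w))[None, :]
        r = np.hypot(dz, dx)
        m = min(h, w) // 2
        bins = np.rint(r).astype(int)
        keep = bins <= m
        counts = np.bincount(bins[keep], minlength=m + 1)
        sums = np.bincount(bins[keep], weights=surface[keep], minlength=m + 1)
        values = sums / np.maximum(counts, 1)
        return AcfProfile(np.arange(m + 1), values, axis)
    raise ValueError(f"unknown axis {axis!r}")


def _auto_delta_max(profile: AcfProfile) -> int:
    """Deterministic single-Gaussian lag bound.

    Offset is estimated as the median of the outer quartile of lags; the
    bound is the first lag where the profile drops below
    ``offset + 10% of (G(1) - offset)``, clamped to [4, L/4] where L is the
    image axis length.  User-overridable via an explicit ``delta_max``.
    """
    lags = profile.lags
    values = profile.values
    axis_len = 2 * (len(lags) - 1)
    outer = values[lags > 0.75 * lags[-1]]
    offset_est = float(np.median(outer))
    threshold = offset_est + 0.1 * (values[1] - offset_est)
    below = np.nonzero((lags >= 1) & (values < threshold))[0]
    delta = int(lags[below[0]]) if len(below) else int(lags[-1])
    return int(np.clip(delta, 4, max(4, axis_len // 4)))


def fit_noise_free(
    profile: AcfProfile, delta_max: int | Literal["auto"] = "auto"
) -> AcfFit:
    """Fit ``G_NF(d) = a exp(-d^2/w^2) + c`` over lags 1..delta_max.

    The zero-lag point is skipped, so any uncorrelated noise spike at
    G(0) does not bias the fit; it is recorded separately for the noise
    read-out.  Initial guesses: amplitude from G(1), width from the lag at
    half of G(1), offset from the outer-quartile median; amplitude and
    width constrained positive, offset unbounded.
    """
    if delta_max == "auto":
        delta_max = _auto_delta_max(profile)
    delta_max = int(delta_max)
    sel = (profile.lags >= 1) & (profile.lags <= delta_max)
    lags = profile.lags[sel]
    values = profile.values[sel]
    if len(lags) < 4:
        raise StackValidationError(
            f"need >= 4 lags in (0, {delta_max}] to fit, have {len(lags)}"
        )

    outer = profile.values[profile.lags > 0.75 * profile.lags[-1]]
    c0 = float(np.median(outer))
    a0 = max(float(values[0]) - c0, 1e-12)
    half = np.nonzero(values <= c0 + a0 / 2)[0]
    w0 = float(lags[half[0]]) if len(half) else float(lags[-1] / 2)
    w0 = max(w0, 1.0)

    def model(d, a, w, c):
        return a * np.exp(-(d**2) / w**2) + c

    w_hi = 10.0 * float(lags[-1])
    try:
        popt, _ = curve_fit(
            model,
            lags,
            values,
            p0=(a0, w0, c0),
            bounds=([0.0, 1e-6, -np.inf], [np.inf, w_hi, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise AcfFitError(
            f"Gaussian ACF fit did not converge (p0={(a0, w0, c0)}, "
            f"delta_max={delta_max}, n={len(lags)})"
        ) from exc
    a, w, c = (float(v) for v in popt)
    return AcfFit(
        amplitude=a,
        width=w,
        offset=c,
        delta_max=delta_max,
        zero_lag_value=float(profile.values[0]),
        width_at_bound=bool(w > 0.99 * w_hi),
    )


def report_from_fit(fit: AcfFit, pixel_size: float, i_av: float, axis: Axis) -> QuicsReport:
    """Assemble the (R, B, N) triplet from a completed fit."""
    r_nm = np.sqrt(2.0 * np.log(2.0)) * fit.width * pixel_size
    b = fit.amplitude * i_av
    n = (fit.zero_lag_value - fit.amplitude) / fit.amplitude
    return QuicsReport(R=float(r_nm), B=float(b), N=float(n), I_av=float(i_av),
                       axis=axis, fit=fit)


def quics_report(
    img: Image,
    axis: Axis = "radial",
    delta_max: int | Literal["auto"] = "auto",
    mask: np.ndarray | None = None,
) -> QuicsReport:
    """Full QuICS analysis of one image along one axis.

    ``I_av`` is averaged over all pixels by default; an optional boolean
    ``mask`` restricts the average (the correlation itself is always
    computed on the full frame).
    """
    surface = acf_2d(img)
    profile = acf_profile(surface, axis)
    fit = fit_noise_free(profile, delta_max=delta_max)
    i_av = float(img.pixels[mask].mean() if mask is not None else img.pixels.mean())
    return report_from_fit(fit, img.pixel_size, i_av, axis)
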