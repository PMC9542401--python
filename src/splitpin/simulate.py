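"""Synthetic tunable-pinhole confocal xz stacks.

The simulator places point emitters at random pixel positions on a 2-D
grid representing an xz-section and images them with a separable Gaussian
point spread function

    PSF(x, z, s) = exp(-2 x^2 / w_x^2) * A(s) * exp(-2 z^2 / w_z(s)^2),

where ``s`` is the pinhole diameter in Airy Units.  Only the axial (z)
response depends on the pinhole: closing the pinhole shrinks the axial
1/e^2 waist ``w_z(s)`` and scales the detected amplitude by ``A(s)``,
expressed as a multiple of the photon scale ``S`` (the peak expected count
of a single in-focus emitter at 1 A.U.).

The default pinhole series is three frames at 1.5 / 1.0 / 0.5 A.U. with
waists 680 / 620 / 590 nm and amplitudes 1.4 / 1.0 / 0.38 x S, plus a
closed-pinhole comparison frame at 0.2 A.U. with a 550 nm waist and
amplitude 0.3 x S — i.e. three accumulated acquisitions of a dim 0.1 x S
closed-pinhole image, giving the comparison the same integration time as
the three-frame series.  Optional per-pixel Poisson noise models photon
counting (shot noise); there is no detector read noise or background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .stack import Image, PinholeStack, StackValidationError

#: (pinhole size A.U., axial 1/e^2 waist nm, amplitude in multiples of S)
DEFAULT_PINHOLE_SERIES: tuple[tuple[float, float, float], ...] = (
    (1.5, 680.0, 1.4),
    (1.0, 620.0, 1.0),
    (0.5, 590.0, 0.38),
)
#: Closed-pinhole comparison frame, same total integration time as the series.
DEFAULT_CLOSED_PINHOLE: tuple[float, float, float] = (0.2, 550.0, 0.3)
#: Lateral 1/e^2 waist in nm, pinhole-independent in this model.
DEFAULT_LATERAL_WAIST = 169.0

# Gaussian support truncation radius in waists: exp(-2*4^2) = e^-32.
_TRUNCATE_WAISTS = 4.0


@dataclass
class PSFModel:
    """Separable Gaussian PSF with pinhole-dependent axial response.

    ``w_z_of_s`` and ``A_of_s`` map pinhole size (A.U.) to the axial 1/e^2
    waist (nm) and the amplitude factor (multiple of S).  Only tabulated
    sizes are valid lookups.
    """

    w_x: float = DEFAULT_LATERAL_WAIST
    w_z_of_s: dict[float, float] = field(default_factory=dict)
    A_of_s: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.w_x <= 0:
            raise StackValidationError("lateral waist must be positive")
        for s, w in self.w_z_of_s.items():
            if w <= 0:
                raise StackValidationError(f"w_z({s}) must be positive")
        for s, a in self.A_of_s.items():
            if a <= 0:
                raise StackValidationError(f"A({s}) must be positive")

    @classmethod
    def from_series(
        cls,
        series: Sequence[tuple[float, float, float]],
        w_x: float = DEFAULT_LATERAL_WAIST,
    ) -> "PSFModel":
        return cls(
            w_x=w_x,
            w_z_of_s={s: wz for s, wz, _ in series},
            A_of_s={s: a for s, _, a in series},
        )


@dataclass
class SimulationConfig:
    """Study conditions for one simulated acquisition.

    ``S`` is the photon scale: the maximum expected count for a single
    in-focus emitter in the 1 A.U. frame.  ``pinhole_series`` and
    ``closed_pinhole`` are ``(size A.U., w_z nm, A)`` triples with A in
    multiples of S.
    """

    grid: tuple[int, int] = (256, 256)
    pixel_size: float = 50.0
    n_emitters: int = 20
    S: float = 100.0
    w_x: float = DEFAULT_LATERAL_WAIST
    pinhole_series: tuple[tuple[float, float, float], ...] = DEFAULT_PINHOLE_SERIES
    closed_pinhole: tuple[float, float, float] = DEFAULT_CLOSED_PINHOLE
    noise: Literal["poisson", "none"] = "poisson"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.S <= 0:
            raise StackValidationError("photon scale S must be positive")
        if self.n_emitters < 1:
            raise StackValidationError("n_emitters must be >= 1")
        if self.pixel_size <= 0:
            raise StackValidationError("pixel_size must be positive")
        sizes = [s for s, _, _ in self.pinhole_series]
        if any(a <= b for a, b in zip(sizes, sizes[1:])):
            raise StackValidationError(
                "pinhole_series must have strictly decreasing sizes"
            )

    def psf_model(self) -> PSFModel:
        series = list(self.pinhole_series) + [self.closed_pinhole]
        return PSFModel.from_series(series, w_x=self.w_x)


@dataclass
class EmitterField:
    """Point emitters at (row, col) pixel positions with relative brightness."""

    positions: np.ndarray  # (m, 2) integer pixel coordinates (row=z, col=x)
    amplitudes: np.ndarray  # (m,) relative brightness, default 1
    grid: tuple[int, int]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise StackValidationError("positions must have shape (m, 2)")
        if len(self.amplitudes) != len(self.positions):
            raise StackValidationError("one amplitude per emitter required")
        h, w = self.grid
        rows, cols = self.positions[:, 0], self.positions[:, 1]
        if np.any((rows < 0) | (rows >= h) | (cols < 0) | (cols >= w)):
            raise StackValidationError("emitter positions outside the grid")


def make_emitters(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> EmitterField:
    """Draw ``n_emitters`` positions uniformly over the grid.

    Positions are pixel-centred (integer coordinates).  Reproducible given
    ``config.seed`` (or an explicit generator).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w = config.grid
    rows = rng.integers(0, h, size=config.n_emitters)
    cols = rng.integers(0, w, size=config.n_emitters)
    return EmitterField(
        positions=np.stack([rows, cols], axis=1),
        amplitudes=np.ones(config.n_emitters),
        grid=config.grid,
    )


def render_frame(
    emitters: EmitterField,
    psf: PSFModel,
    size: float,
    S: float,
    pixel_size: float = 50.0,
    noise: Literal["poisson", "none"] = "none",
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> Image:
    """Render one frame of the series at pinhole size ``size`` (A.U.).

    The expected image is the sum over emitters of
    ``amp * A(s) * S * exp(-2 dx^2/w_x^2) * exp(-2 dz^2/w_z(s)^2)``;
    an isolated unit emitter peaks at ``A(s) * S``.  Gaussians are evaluated
    directly and truncated at 4 waists (truncation error < e^-32); emitters
    near the border are clipped by the frame edge, with no wrap-around.
    With ``noise="poisson"`` every pixel is an independent Poisson draw with
    the rendered mean.
    """
    try:
        w_z = psf.w_z_of_s[size]
        A = psf.A_of_s[size]
    except KeyError as exc:
        raise StackValidationError(
            f"pinhole size {size} A.U. is not tabulated in the PSF model"
        ) from exc
    if w_z <= 0 or psf.w_x <= 0:
        raise StackValidationError("PSF waists must be positive")

    h, w = emitters.grid
    wz_px = w_z / pixel_size
    wx_px = psf.w_x / pixel_size
    half_z = int(np.ceil(_TRUNCATE_WAISTS * wz_px))
    half_x = int(np.ceil(_TRUNCATE_WAISTS * wx_px))

    # separable kernel evaluated once, placed per emitter with edge clipping
    dz = np.arange(-half_z, half_z + 1)
    dx = np.arange(-half_x, half_x + 1)
    kz = np.exp(-2.0 * dz**2 / wz_px**2)
    kx = np.exp(-2.0 * dx**2 / wx_px**2)
    kernel = np.outer(kz, kx)

    expected = np.zeros((h, w))
    for (r, c), amp in zip(emitters.positions, emitters.amplitudes):
        r0, r1 = max(0, r - half_z), min(h, r + half_z + 1)
        c0, c1 = max(0, c - half_x), min(w, c + half_x + 1)
        kr0, kc0 = r0 - (r - half_z), c0 - (c - half_x)
        expected[r0:r1, c0:c1] += (
            amp * A * S * kernel[kr0 : kr0 + (r1 - r0), kc0 : kc0 + (c1 - c0)]
        )

    if noise == "poisson":
        if rng is None:
            rng = np.random.default_rng(seed)
        pixels = rng.poisson(expected).astype(float)
    else:
        pixels = expected
    return Image(pixels, pixel_size=pixel_size)


def simulate_stack(
    config: SimulationConfig,
    emitters: EmitterField | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PinholeStack, Image]:
    """Simulate the tunable-pinhole stack and the closed-pinhole comparison.

    All frames image one shared emitter field; noise draws are independent
    per frame.  Returns ``(stack, closed_frame)`` where the stack frames
    follow the canonical decreasing-size order of the configured series and
    the closed frame uses the ``closed_pinhole`` parameters.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if emitters is None:
        emitters = make_emitters(config, rng=rng)
    psf = config.psf_model()

    frames = []
    for size, _, _ in config.pinhole_series:
        img = render_frame(
            emitters,
            psf,
            size=size,
            S=config.S,
            pixel_size=config.pixel_size,
            noise=config.noise,
            rng=rng,
        )
        frames.append(img.pixels)
    stack = PinholeStack(
        frames=np.stack(frames),
        pinhole_sizes=tuple(s for s, _, _ in config.pinhole_series),
        pixel_size=config.pixel_size,
    )
    closed = render_frame(
        emitters,
        psf,
        size=config.closed_pinhole[0],
        S=config.S,
        pixel_size=config.pixel_size,
        noise=config.noise,
        rng=rng,
    )
    return stack, closed


def simulate_membrane_stack(
    sheet_rows: Sequence[int] = (96, 160),
    grid: tuple[int, int] = (256, 256),
    pixel_size: float = 50.0,
    S: float = 500.0,
    series: Sequence[tuple[float, float, float]] = (
        DEFAULT_PINHOLE_SERIES[0],
        DEFAULT_PINHOLE_SERIES[2],
    ),
    background_offset_nm: float = 500.0,
    background_level: float = 0.6,
    noise: Literal["poisson", "none"] = "poisson",
    seed: int | None = None,
) -> tuple[PinholeStack, np.ndarray, np.ndarray]:
    """Synthetic membrane-like phantom: bright horizontal sheets plus haze.

    Emulates an epithelial xz-section — two membrane sheets stacked along
    the optical axis with diffuse out-of-focus background between and
    around them.  Each frame ``j`` is

        A_j * sheets(z; w_z_j) + A_j * exp(-2 d^2 / w_z_j^2) * b,

    where the sheets are Gaussian z-profiles of waist ``w_z_j`` centred on
    ``sheet_rows``, ``d = background_offset_nm`` is the effective axial
    offset of the haze and ``b = background_level`` its relative strength.
    The haze therefore carries the out-of-focus pinhole fingerprint while
    the sheets carry the in-focus one.  Returns the stack together with the
    exact per-frame in-focus weights ``A_j S`` and out-of-focus weights
    ``A_j exp(-2 d^2/w_z_j^2) b S``, from which an exact phasor calibration
    can be computed.
    """
    h, w = grid
    z = np.arange(h)[:, None]
    frames = []
    w_in = []
    w_out = []
    for size, wz, A in series:
        wz_px = wz / pixel_size
        sheets = np.zeros((h, 1))
        for row in sheet_rows:
            sheets += np.exp(-2.0 * (z - row) ** 2 / wz_px**2)
        haze = np.exp(-2.0 * (background_offset_nm / wz) ** 2) * background_level
        expected = A * S * (sheets + haze) * np.ones((1, w))
        frames.append(expected)
        w_in.append(A * S)
        w_out.append(A * np.exp(-2.0 * (background_offset_nm / wz) ** 2)
                     * background_level * S)
    frames = np.stack(frames)
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        frames = rng.poisson(frames).astype(float)
    stack = PinholeStack(
        frames=frames,
        pinhole_sizes=tuple(s for s, _, _ in series),
        pixel_size=pixel_size,
    )
    return stack, np.asarray(w_in), np.asarray(w_out)
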