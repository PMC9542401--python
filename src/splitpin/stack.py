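"""Pinhole-indexed image stacks and TIFF/JSON input-output.

A tunable-pinhole acquisition is a short series of co-registered grayscale
confocal frames, one per pinhole diameter (in Airy Units, A.U.).  The
canonical in-memory order is *decreasing* pinhole size: frame index
``j = 0..n-1`` runs from the most open to the most closed pinhole.  The
phasor transform depends on this index, so the order is fixed here, once,
and every downstream module relies on it.

Frames are stored as floating point regardless of the on-disk bit depth and
no rescaling is applied on read, preserving photon-count semantics.  Pixel
coordinates are 0-based ``(row, column)``; for an xz-section the first axis
is the optical (z) axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile


class StackFormatError(ValueError):
    """The file on disk is not a stack this package can interpret."""


class StackValidationError(ValueError):
    """The stack contents or metadata violate an invariant."""


@dataclass
class Image:
    """A single 2-D nonnegative grayscale frame with physical pixel size.

    Parameters
    ----------
    pixels
        2-D array of finite, nonnegative intensities.
    pixel_size
        Physical edge length of one pixel in nanometres (isotropic).
    """

    pixels: np.ndarray
    pixel_size: float = 50.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise StackValidationError(
                f"Image requires a 2-D array, got ndim={self.pixels.ndim}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise StackValidationError("Image contains non-finite pixels")
        if np.any(self.pixels < 0):
            raise StackValidationError("Image contains negative intensities")
        if self.pixel_size <= 0:
            raise StackValidationError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class PinholeStack:
    """n co-registered frames ordered by strictly decreasing pinhole size.

    Parameters
    ----------
    frames
        Array of shape ``(n, H, W)``; nonnegative, finite intensities.
    pinhole_sizes
        n pinhole diameters in Airy Units, strictly decreasing.
    pixel_size
        Pixel edge length in nm, shared by both image axes.
    axis_labels
        Names of the two image axes; ``("z", "x")`` for an xz-section,
        where the first (row) axis is the optical axis.
    """

    frames: np.ndarray
    pinhole_sizes: tuple[float, ...]
    pixel_size: float = 50.0
    axis_labels: tuple[str, str] = ("z", "x")

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.pinhole_sizes = tuple(float(s) for s in self.pinhole_sizes)
        if self.frames.ndim != 3:
            raise StackValidationError(
                f"frames must have shape (n, H, W), got {self.frames.shape}"
            )
        n = self.frames.shape[0]
        if n < 2:
            raise StackValidationError("a pinhole stack needs at least 2 frames")
        if len(self.pinhole_sizes) != n:
            raise StackValidationError(
                f"{n} frames but {len(self.pinhole_sizes)} pinhole sizes"
            )
        if any(s <= 0 for s in self.pinhole_sizes):
            raise StackValidationError("pinhole sizes must be positive")
        if any(
            a <= b for a, b in zip(self.pinhole_sizes, self.pinhole_sizes[1:])
        ):
            raise StackValidationError(
                "pinhole sizes must be strictly decreasing with frame index; "
                f"got {self.pinhole_sizes}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise StackValidationError("stack contains non-finite intensities")
        if np.any(self.frames < 0):
            raise StackValidationError("stack contains negative intensities")
        if self.pixel_size <= 0:
            raise StackValidationError("pixel_size must be positive")
        self.axis_labels = (str(self.axis_labels[0]), str(self.axis_labels[1]))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def frame(self, j: int) -> Image:
        """Frame ``j`` (0-based, decreasing-size order) as an :class:`Image`."""
        return Image(self.frames[j], pixel_size=self.pixel_size)

    def sum_image(self, selection: Sequence[int] | None = None) -> Image:
        """Sum of the selected frames (all frames when ``selection`` is None)."""
        if selection is None:
            summed = self.frames.sum(axis=0)
        else:
            idx = list(selection)
            if not idx:
                raise StackValidationError("empty frame selection")
            summed = self.frames[idx].sum(axis=0)
        return Image(summed, pixel_size=self.pixel_size)


def _load_pages(path: Path) -> np.ndarray:
    with tifffile.TiffFile(path) as tif:
        if any(page.samplesperpixel > 1 for page in tif.pages):
            raise StackFormatError(
                f"{path}: RGB/multichannel pages are not supported; "
                "supply grayscale frames"
            )
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise StackFormatError(f"{path}: page shape mismatch: {shapes}")
        arr = tif.asarray()
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise StackFormatError(
            f"{path}: expected grayscale pages, got array of shape {arr.shape}"
        )
    return arr


def read_stack(
    path: str | Path | Sequence[str | Path],
    sizes: Sequence[float] | str | Path | None = None,
    pixel_size: float | None = None,
    axis_labels: tuple[str, str] = ("z", "x"),
) -> PinholeStack:
    """Read a pinhole series from TIFF plus per-frame pinhole metadata.

    ``path`` is a multi-page grayscale TIFF or an ordered list of single-page
    TIFFs.  ``sizes`` gives the pinhole diameter (A.U.) of each page in file
    order, either directly or as the path of a JSON sidecar with keys
    ``pinhole_au`` and (optionally) ``pixel_size_nm``.  If the supplied sizes
    are increasing, the frames are reversed so that the canonical
    decreasing-size order holds; any other non-monotonic ordering is an
    error.  Integer pixel data is converted losslessly to float.
    """
    if isinstance(path, (str, Path)):
        pages = _load_pages(Path(path))
    else:
        loaded = [_load_pages(Path(p)) for p in path]
        shapes = {a.shape[1:] for a in loaded}
        if len(shapes) > 1:
            raise StackFormatError(f"page shape mismatch across files: {shapes}")
        pages = np.concatenate(loaded, axis=0)

    if sizes is None:
        raise StackValidationError("pinhole sizes are required (list or sidecar)")
    if isinstance(sizes, (str, Path)):
        meta = json.loads(Path(sizes).read_text())
        size_list = [float(s) for s in meta["pinhole_au"]]
        if pixel_size is None and "pixel_size_nm" in meta:
            pixel_size = float(meta["pixel_size_nm"])
        axis_labels = tuple(meta.get("axis_labels", axis_labels))
    else:
        size_list = [float(s) for s in sizes]

    if len(size_list) != pages.shape[0]:
        raise StackValidationError(
            f"{pages.shape[0]} pages but {len(size_list)} pinhole sizes"
        )
    decreasing = all(a > b for a, b in zip(size_list, size_list[1:]))
    increasing = all(a < b for a, b in zip(size_list, size_list[1:]))
    if increasing:
        pages = pages[::-1]
        size_list = size_list[::-1]
    elif not decreasing:
        raise StackValidationError(
            f"pinhole sizes must be strictly monotonic, got {size_list}"
        )
    return PinholeStack(
        frames=pages.astype(float),
        pinhole_sizes=tuple(size_list),
        pixel_size=50.0 if pixel_size is None else float(pixel_size),
        axis_labels=axis_labels,
    )


def write_image(img: Image, path: str | Path) -> None:
    """Write an image as a single-page float32 grayscale TIFF.

    Round-tripping through :func:`read_image` reproduces float32 values
    exactly.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"directory does not exist: {path.parent}")
    tifffile.imwrite(path, np.asarray(img.pixels, dtype=np.float32),
                     photometric="minisblack")


def read_image(path: str | Path, pixel_size: float = 50.0) -> Image:
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise StackFormatError(f"{path}: expected a single grayscale page")
    return Image(arr.astype(float), pixel_size=pixel_size)


def write_stack(
    stack: PinholeStack, path: str | Path, sidecar: str | Path | None = None
) -> None:
    """Write a stack as a multi-page float32 TIFF plus a JSON sidecar."""
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"directory does not exist: {path.parent}")
    tifffile.imwrite(path, stack.frames.astype(np.float32),
                     photometric="minisblack")
    if sidecar is None:
        sidecar = path.with_suffix(".json")
    meta = {
        "pinhole_au": list(stack.pinhole_sizes),
        "pixel_size_nm": stack.pixel_size,
        "axis_labels": list(stack.axis_labels),
    }
    Path(sidecar).write_text(json.dumps(meta, indent=2) + "\n")
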