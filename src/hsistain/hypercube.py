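"""Hypercube container and TIFF-stack I/O.

A hypercube is a 3-D intensity array ``(rows, cols, bands)`` acquired by
scanning a tunable filter across the visible range.  The default
acquisition axis is 420–720 nm in 2 nm steps, i.e. 151 bands.  On disk a
hypercube is a multi-page grayscale TIFF (one page per wavelength, in
ascending wavelength order) plus a plain-text sidecar listing one
wavelength in nm per line; TIFF tags are too unreliable across writers to
carry the axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Hypercube", "band_axis", "load_hypercube", "save_hypercube"]

#: Default acquisition axis: 420–720 nm in 2 nm steps (151 bands).
DEFAULT_AXIS = (420.0, 720.0, 2.0)


def band_axis(start_nm: float, stop_nm: float, step_nm: float) -> np.ndarray:
    """Inclusive arithmetic wavelength axis from *start_nm* to *stop_nm*.

    Raises
    ------
    ValueError
        If ``stop <= start``, ``step <= 0`` or the range is not divisible
        by the step.
    """
    if step_nm <= 0:
        raise ValueError(f"step_nm must be positive, got {step_nm}")
    if stop_nm <= start_nm:
        raise ValueError(f"stop_nm ({stop_nm}) must exceed start_nm ({start_nm})")
    span = stop_nm - start_nm
    n_steps = span / step_nm
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(
            f"range {start_nm}–{stop_nm} nm is not divisible by step {step_nm} nm"
        )
    n = int(round(n_steps)) + 1
    return start_nm + step_nm * np.arange(n, dtype=float)


def default_axis() -> np.ndarray:
    return band_axis(*DEFAULT_AXIS)


@dataclass
class Hypercube:
    """Spectral image stack: ``data[row, col, band]`` with a nm axis.

    Intensities are stored as acquired (typically uint16 counts) and
    promoted to floating point when computations require it, so raw
    counts survive for calibration.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (rows, cols, bands), got ndim={self.data.ndim}")
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be 1-D")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"band count mismatch: data has {self.data.shape[2]} bands but "
                f"{self.wavelengths.size} wavelengths were given"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength axis must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("hypercube intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("hypercube intensities must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def astype_float(self) -> np.ndarray:
        return self.data.astype(np.float64, copy=False)

    def band(self, index: int) -> np.ndarray:
        return self.data[:, :, index]

    def crop(self, row0: int, row1: int, col0: int, col1: int) -> "Hypercube":
        return Hypercube(self.data[row0:row1, col0:col1], self.wavelengths, dict(self.meta))


def _read_axis(wavelength_path) -> np.ndarray:
    lines = Path(wavelength_path).read_text().split()
    return np.array([float(v) for v in lines])


def load_hypercube(tiff_path, wavelength_path) -> Hypercube:
    """Read a multi-page TIFF stack plus wavelength sidecar.

    Page order maps to ascending wavelength.  Errors name the offending
    file and the mismatching counts.
    """
    pages = tifffile.imread(tiff_path)
    if pages.ndim == 2:  # single page
        pages = pages[None]
    wavelengths = _read_axis(wavelength_path)
    if pages.shape[0] != wavelengths.size:
        raise ValueError(
            f"{tiff_path}: stack has {pages.shape[0]} pages but sidecar "
            f"{wavelength_path} lists {wavelengths.size} wavelengths"
        )
    if not np.all(np.diff(wavelengths) > 0):
        raise ValueError(f"{wavelength_path}: wavelength axis is not strictly increasing")
    data = np.moveaxis(pages, 0, 2)
    return Hypercube(data, wavelengths, meta={"source": str(tiff_path)})


def save_hypercube(cube: Hypercube, tiff_path, wavelength_path) -> None:
    """Write the cube as a multi-page TIFF plus one-nm-per-line sidecar."""
    pages = np.moveaxis(cube.data, 2, 0)
    tifffile.imwrite(tiff_path, pages)
    Path(wavelength_path).write_text(
        "\n".join(f"{w:g}" for w in cube.wavelengths) + "\n"
    )
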