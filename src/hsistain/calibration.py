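"""Per-band light-source / camera-response calibration.

The tunable-filter camera responds unevenly across wavelength, so raw
band images are corrected with coefficients estimated from a blank-slide
acquisition and a reference fiber-spectrometer reading of the lamp:
``coefficient(lambda) = mean blank-image intensity / spectrometer
intensity``, with the spectrometer linearly interpolated onto the cube
axis.  Calibration divides each band by its coefficient, which by
construction flattens a blank acquisition to the spectrometer-implied
profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hypercube import Hypercube

__all__ = ["CalibrationTable", "estimate_coefficients", "apply_calibration",
           "unity_table"]


@dataclass
class CalibrationTable:
    wavelengths: np.ndarray
    coefficients: np.ndarray  # unitless multiplier per band; applied by division
    source: str = "blank_slide+spectrometer"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.wavelengths.shape != self.coefficients.shape:
            raise ValueError("wavelengths and coefficients must have the same length")
        if not np.all(np.isfinite(self.coefficients)) or np.any(self.coefficients <= 0):
            raise ValueError("calibration coefficients must be finite and positive")

    def to_csv(self, path) -> None:
        pd.DataFrame({"wavelength_nm": self.wavelengths,
                      "coefficient": self.coefficients}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, source="file") -> "CalibrationTable":
        df = pd.read_csv(path)
        return cls(df["wavelength_nm"].to_numpy(), df["coefficient"].to_numpy(), source)


def unity_table(wavelengths) -> CalibrationTable:
    wavelengths = np.asarray(wavelengths, dtype=float)
    return CalibrationTable(wavelengths, np.ones_like(wavelengths), source="unity")


def estimate_coefficients(blank_cube: Hypercube, spectrometer) -> CalibrationTable:
    """Coefficients from a blank-FOV cube and a (nm, intensity) reference.

    *spectrometer* is a 2-column array-like (wavelength nm, intensity).
    The reference must cover the cube's wavelength range and be positive
    wherever it is interpolated.
    """
    spec = np.asarray(spectrometer, dtype=float)
    if spec.ndim != 2 or spec.shape[1] != 2:
        raise ValueError("spectrometer table must be two columns (wavelength_nm, intensity)")
    order = np.argsort(spec[:, 0])
    ref_w, ref_i = spec[order, 0], spec[order, 1]
    w = blank_cube.wavelengths
    if w[0] < ref_w[0] or w[-1] > ref_w[-1]:
        raise ValueError(
            f"spectrometer coverage {ref_w[0]}–{ref_w[-1]} nm does not span the "
            f"cube axis {w[0]}–{w[-1]} nm"
        )
    ref = np.interp(w, ref_w, ref_i)
    bad = ref <= 0
    if np.any(bad):
        raise ValueError(
            f"spectrometer intensity is non-positive at {w[bad][0]:g} nm; "
            "cannot form calibration coefficients"
        )
    band_means = blank_cube.astype_float().mean(axis=(0, 1))
    return CalibrationTable(w, band_means / ref)


def apply_calibration(obj, table: CalibrationTable):
    """Divide each band of a cube or spectrum by its coefficient.

    Accepts a :class:`Hypercube` or a 1-D per-band spectrum sharing the
    table's wavelength axis.
    """
    if isinstance(obj, Hypercube):
        if obj.wavelengths.shape != table.wavelengths.shape or not np.allclose(
            obj.wavelengths, table.wavelengths
        ):
            raise ValueError("cube and calibration table wavelength axes differ")
        return Hypercube(obj.astype_float() / table.coefficients[None, None, :],
                         obj.wavelengths, dict(obj.meta))
    spectrum = np.asarray(obj, dtype=float)
    if spectrum.shape != table.coefficients.shape:
        raise ValueError("spectrum and calibration table wavelength axes differ")
    return spectrum / table.coefficients
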