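"""Region-averaged spectral signatures and their categorization.

Signatures are obtained by averaging pixel spectra over a selected area
(minimum 3 pixels), calibrating with the per-band coefficients, and
normalizing each spectrum to its own peak.  Categorization scores the
two published signature features:

* the pTau "flat hat" — elevated, uniform transmittance over
  550–650 nm, scored by ``flatness = 1 - CV`` over the window and by the
  plateau prominence ``mean(550–650) / mean(450–550)``;
* the Abeta short-wavelength deficit — lower transmission over
  450–600 nm, scored by ``dip = 1 - mean(450–600)/mean(600–700)``.

Spectra matching neither signature are internal controls ("lack of
signal" regions).  All scores are scale-invariant ratios, so they are
unaffected by illumination or exposure scaling.  The default thresholds
(flatness > 0.98, prominence > 1.5, dip > 0.19) sit midway between the
analytic score values of the phantom's tissue baseline and its
amplitude-1 deposit spectra; they are configurable for other material.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationTable, apply_calibration
from .hypercube import Hypercube

__all__ = [
    "RegionSpectrum",
    "SignatureCategory",
    "SpectrumCategorizer",
    "extract_region_spectrum",
    "categorize_spectrum",
    "scan_strip",
    "MIN_REGION_PIXELS",
]

MIN_REGION_PIXELS = 3


@dataclass
class RegionSpectrum:
    label: str
    pixel_count: int
    raw: np.ndarray  # mean intensity per band, uncalibrated
    calibrated_normalized: np.ndarray  # peak-normalized (max exactly 1)
    wavelengths: np.ndarray
    region: np.ndarray  # (n, 2) pixel (row, col) coordinates


@dataclass
class SignatureCategory:
    name: str  # abeta | ptau | control | other
    representative: np.ndarray  # mean of member spectra, re-normalized to peak 1
    members: list
    band_features: dict = field(default_factory=dict)


def _region_coords(region, shape) -> np.ndarray:
    region = np.asarray(region)
    if region.dtype == bool:
        if region.shape != shape:
            raise ValueError("boolean region mask must match cube (rows, cols)")
        coords = np.argwhere(region)
    else:
        coords = region.reshape(-1, 2).astype(int)
    if len(coords) < MIN_REGION_PIXELS:
        raise ValueError(
            f"region has {len(coords)} pixels; a minimum of {MIN_REGION_PIXELS} is required"
        )
    rows, cols = shape
    if (coords[:, 0].min() < 0 or coords[:, 0].max() >= rows
            or coords[:, 1].min() < 0 or coords[:, 1].max() >= cols):
        raise ValueError("region contains out-of-bounds pixels")
    return coords


def extract_region_spectrum(cube: Hypercube, region, table: CalibrationTable | None = None,
                            label: str = "", normalize: str = "peak") -> RegionSpectrum:
    """Mean spectrum over a pixel region, calibrated and normalized.

    *region* is either an (n, 2) array of (row, col) coordinates or a
    boolean mask.  ``normalize="peak"`` scales the calibrated spectrum so
    its maximum is exactly 1; ``"area"`` scales to unit mean.
    """
    coords = _region_coords(region, cube.shape[:2])
    raw = cube.astype_float()[coords[:, 0], coords[:, 1], :].mean(axis=0)
    calibrated = apply_calibration(raw, table) if table is not None else raw.copy()
    if normalize == "peak":
        peak = calibrated.max()
    elif normalize == "area":
        peak = calibrated.mean()
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    if peak <= 0:
        raise ValueError("region spectrum is non-positive; cannot normalize")
    return RegionSpectrum(label, len(coords), raw, calibrated / peak,
                          cube.wavelengths.copy(), coords)


def _window_mean(values, wavelengths, lo, hi) -> float:
    sel = (wavelengths >= lo) & (wavelengths <= hi)
    return float(np.mean(values[sel]))


class SpectrumCategorizer:
    """Assigns signature categories from flat-hat and dip scores.

    Rules (checked in order):

    1. ``ptau`` if flatness over 550–650 nm exceeds ``flatness_threshold``
       and the plateau prominence ``mean(550–650)/mean(450–550)`` exceeds
       ``level_threshold``;
    2. ``abeta`` if ``dip = 1 - mean(450–600)/mean(600–700)`` exceeds
       ``dip_threshold``;
    3. ``control`` otherwise.
    """

    def __init__(self, flatness_threshold: float = 0.98,
                 level_threshold: float = 1.5,
                 dip_threshold: float = 0.19):
        self.flatness_threshold = flatness_threshold
        self.level_threshold = level_threshold
        self.dip_threshold = dip_threshold

    def get_params(self) -> dict:
        return {
            "flatness_threshold": self.flatness_threshold,
            "level_threshold": self.level_threshold,
            "dip_threshold": self.dip_threshold,
        }

    def set_params(self, **params) -> "SpectrumCategorizer":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def scores(self, values: np.ndarray, wavelengths: np.ndarray) -> dict:
        if wavelengths[0] > 450.0 or wavelengths[-1] < 700.0:
            raise ValueError(
                f"spectrum axis {wavelengths[0]}–{wavelengths[-1]} nm does not "
                "cover the 450–700 nm scoring windows"
            )
        sel = (wavelengths >= 550.0) & (wavelengths <= 650.0)
        plateau = values[sel]
        mean_plateau = float(plateau.mean())
        cv = float(plateau.std() / mean_plateau) if mean_plateau > 0 else np.inf
        flatness = 1.0 - cv
        level = mean_plateau / _window_mean(values, wavelengths, 450.0, 550.0)
        dip = 1.0 - (_window_mean(values, wavelengths, 450.0, 600.0)
                     / _window_mean(values, wavelengths, 600.0, 700.0))
        return {"flatness": flatness, "level": level, "dip": dip}

    def predict_one(self, values: np.ndarray, wavelengths: np.ndarray):
        s = self.scores(values, wavelengths)
        if s["flatness"] > self.flatness_threshold and s["level"] > self.level_threshold:
            return "ptau", s
        if s["dip"] > self.dip_threshold:
            return "abeta", s
        return "control", s

    def predict(self, spectra) -> list:
        return [self.predict_one(sp.calibrated_normalized, sp.wavelengths)[0]
                for sp in spectra]


def categorize_spectrum(spectrum: RegionSpectrum,
                        categorizer: SpectrumCategorizer | None = None):
    """Category name plus feature scores for one region spectrum."""
    cat = categorizer or SpectrumCategorizer()
    return cat.predict_one(spectrum.calibrated_normalized, spectrum.wavelengths)


def scan_strip(cube: Hypercube, stride: int, table: CalibrationTable | None = None,
               window: int = 5, categorizer: SpectrumCategorizer | None = None) -> list:
    """Tile the cube with stride-spaced windows and categorize each one.

    Returns a list of ``(bounds, category, scores)`` where *bounds* is
    ``(row0, col0, row1, col1)``.  Window positions always include the
    image border tiles, so a stride larger than the image yields a single
    window.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    rows, cols = cube.shape[:2]
    window = min(window, rows, cols)
    cat = categorizer or SpectrumCategorizer()
    row_starts = list(range(0, max(rows - window, 0) + 1, stride)) or [0]
    col_starts = list(range(0, max(cols - window, 0) + 1, stride)) or [0]
    results = []
    for r0 in row_starts:
        for c0 in col_starts:
            r1, c1 = r0 + window, c0 + window
            mask = np.zeros((rows, cols), dtype=bool)
            mask[r0:r1, c0:c1] = True
            sp = extract_region_spectrum(cube, mask, table)
            name, scores = cat.predict_one(sp.calibrated_normalized, sp.wavelengths)
            results.append(((r0, c0, r1, c1), name, scores))
    return results


def group_categories(spectra, names) -> list:
    """Group labelled spectra into :class:`SignatureCategory` summaries."""
    groups: dict = {}
    for sp, name in zip(spectra, names):
        groups.setdefault(name, []).append(sp)
    out = []
    for name, members in groups.items():
        rep = np.mean([m.calibrated_normalized for m in members], axis=0)
        rep = rep / rep.max()
        w = members[0].wavelengths
        feats = {
            "mean_450_600": _window_mean(rep, w, 450.0, 600.0),
            "mean_550_650": _window_mean(rep, w, 550.0, 650.0),
        }
        out.append(SignatureCategory(name, rep, members, feats))
    return out


def spectra_to_csv(spectra, path) -> None:
    """Export spectra as tidy CSV (wavelength_nm, value, label)."""
    frames = [
        pd.DataFrame({"wavelength_nm": sp.wavelengths,
                      "value": sp.calibrated_normalized,
                      "label": sp.label or "unlabeled"})
        for sp in spectra
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
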