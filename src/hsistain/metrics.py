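"""SSIM and PSNR image-quality metrics with per-model aggregation.

SSIM compares two images in luminance, contrast and structure:

    SSIM(i, j) = (2 mu_i mu_j + c1)(2 sigma_ij + c2)
                 / ((mu_i^2 + mu_j^2 + c1)(sigma_i^2 + sigma_j^2 + c2))

with the standard regularization constants ``c1 = (0.01 L)^2`` and
``c2 = (0.03 L)^2`` for dynamic range ``L``.  The default evaluation mode
computes the statistics globally over each patch (one SSIM value per
patch); a Gaussian-windowed mode averaging the local index is available
and is what the training loss uses when configured.  Reports always
record the mode and constants, since both affect absolute values.

PSNR is ``10 log10(peak^2 / MSE)`` in dB, with an infinity sentinel for
identical images.  Multi-channel images are scored per channel and
averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = ["SSIMParams", "ModelReport", "ssim", "psnr", "evaluate_model"]


@dataclass
class SSIMParams:
    dynamic_range: float = 255.0
    k1: float = 0.01
    k2: float = 0.03
    window: str = "global"  # "global" | "gaussian"
    gaussian_sigma: float = 1.5
    truncate: float = 3.5  # gaussian_filter truncation, ~11-px window at sigma 1.5

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2


def _check_geometry(i: np.ndarray, j: np.ndarray) -> None:
    if i.shape != j.shape:
        raise ValueError(f"image geometry mismatch: {i.shape} vs {j.shape}")


def _ssim_single(i: np.ndarray, j: np.ndarray, params: SSIMParams) -> float:
    c1, c2 = params.c1, params.c2
    if params.window == "global":
        mu_i, mu_j = i.mean(), j.mean()
        var_i, var_j = i.var(), j.var()
        cov = ((i - mu_i) * (j - mu_j)).mean()
        num = (2 * mu_i * mu_j + c1) * (2 * cov + c2)
        den = (mu_i**2 + mu_j**2 + c1) * (var_i + var_j + c2)
        return float(num / den)
    if params.window == "gaussian":
        sig, tr = params.gaussian_sigma, params.truncate
        mu_i = gaussian_filter(i, sig, truncate=tr)
        mu_j = gaussian_filter(j, sig, truncate=tr)
        var_i = gaussian_filter(i * i, sig, truncate=tr) - mu_i**2
        var_j = gaussian_filter(j * j, sig, truncate=tr) - mu_j**2
        cov = gaussian_filter(i * j, sig, truncate=tr) - mu_i * mu_j
        s = ((2 * mu_i * mu_j + c1) * (2 * cov + c2)
             / ((mu_i**2 + mu_j**2 + c1) * (var_i + var_j + c2)))
        return float(s.mean())
    raise ValueError(f"unknown SSIM window mode {params.window!r}")


def ssim(i, j, params: SSIMParams | None = None) -> float:
    """Structural similarity in [-1, 1]; 1 means a perfect match."""
    params = params or SSIMParams()
    i = np.asarray(i, dtype=float)
    j = np.asarray(j, dtype=float)
    _check_geometry(i, j)
    if i.ndim == 3:
        return float(np.mean([_ssim_single(i[..., c], j[..., c], params)
                              for c in range(i.shape[2])]))
    return _ssim_single(i, j, params)


def psnr(i, j, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB (``inf`` for identical images)."""
    if peak <= 0:
        raise ValueError("peak must be positive")
    i = np.asarray(i, dtype=float)
    j = np.asarray(j, dtype=float)
    _check_geometry(i, j)
    mse = float(np.mean((i - j) ** 2))
    if mse == 0:
        return math.inf
    return 10.0 * math.log10(peak**2 / mse)


@dataclass
class ModelReport:
    """Per-patch SSIM/PSNR with mean and sample SD for one model."""

    model: str
    ssim_values: list
    psnr_values: list
    params: SSIMParams = field(default_factory=SSIMParams)

    def __post_init__(self) -> None:
        if len(self.ssim_values) != len(self.psnr_values):
            raise ValueError("ssim and psnr lists must have equal length")

    @property
    def ssim_mean(self) -> float:
        return float(np.mean(self.ssim_values))

    @property
    def ssim_sd(self) -> float:
        v = self.ssim_values
        return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0

    @property
    def psnr_mean(self) -> float:
        return float(np.mean(self.psnr_values))

    @property
    def psnr_sd(self) -> float:
        v = self.psnr_values
        return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0

    def per_patch_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "patch_id": np.arange(len(self.ssim_values)),
            "ssim": self.ssim_values,
            "psnr": self.psnr_values,
        })

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model": [self.model] * 2,
            "metric": ["ssim", "psnr"],
            "mean": [self.ssim_mean, self.psnr_mean],
            "sd": [self.ssim_sd, self.psnr_sd],
            "window": [self.params.window] * 2,
            "dynamic_range": [self.params.dynamic_range] * 2,
        })


def evaluate_model(pred_patches, truth_patches, params: SSIMParams | None = None,
                   model: str = "model") -> ModelReport:
    """Per-patch SSIM and PSNR for matched prediction/truth lists."""
    params = params or SSIMParams()
    if len(pred_patches) == 0:
        raise ValueError("cannot evaluate an empty patch list")
    if len(pred_patches) != len(truth_patches):
        raise ValueError(
            f"prediction and truth lists differ in length: "
            f"{len(pred_patches)} vs {len(truth_patches)}"
        )
    ssim_values = [ssim(p, t, params) for p, t in zip(pred_patches, truth_patches)]
    psnr_values = [psnr(p, t, peak=params.dynamic_range)
                   for p, t in zip(pred_patches, truth_patches)]
    return ModelReport(model, ssim_values, psnr_values, params)
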