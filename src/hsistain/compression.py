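"""PCA compression of hypercubes into 3-channel images for the GAN.

Pixel spectra (bands as features) are reduced to their first three
principal components, which are fed in order into the red, green and
blue channels of an 8-bit image.  The basis is fitted once per strip —
all fields of view of one cross-section pooled — so that patch channels
are mutually consistent and stitched predictions stay coherent; the
per-channel min/max used for 8-bit scaling is recorded at fit time and
reused for every projection from the same basis.

Component signs are fixed (largest-magnitude loading positive) so
outputs are deterministic across runs and platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .hypercube import Hypercube

__all__ = ["SpectralPCA", "CompressedImage", "fit_pca", "project_to_rgb"]


@dataclass
class CompressedImage:
    data: np.ndarray  # (rows, cols, 3) uint8; PC1->R, PC2->G, PC3->B
    channel_order: tuple = ("PC1->red", "PC2->green", "PC3->blue")
    explained_variance: np.ndarray = field(default_factory=lambda: np.zeros(3))
    fit_stats: dict = field(default_factory=dict)  # per-channel scaling used

    def __post_init__(self) -> None:
        ev = np.asarray(self.explained_variance, dtype=float)
        if np.any(ev < 0) or np.any(ev > 1) or ev.sum() > 1 + 1e-9:
            raise ValueError("explained variance fractions must be in [0,1] and sum <= 1")
        if np.any(np.diff(ev) > 1e-12):
            raise ValueError("explained variance fractions must be non-increasing")


class SpectralPCA:
    """Three-component PCA over pixel spectra, sklearn-estimator style.

    Parameters
    ----------
    n_components:
        Number of components; 3 for RGB output.
    background_crop:
        Optional ``(row0, row1, col0, col1)`` crop applied before fitting,
        used to keep only a small portion of background next to the
        tissue so most fitted spectra carry tissue information.

    Attributes (after :meth:`fit`)
    ------------------------------
    components_ : (n_components, bands) loading vectors
    mean_ : (bands,) per-band mean
    explained_variance_ratio_ : (n_components,) fractions
    channel_min_, channel_max_ : per-channel score range used for scaling
    """

    def __init__(self, n_components: int = 3, background_crop=None):
        self.n_components = n_components
        self.background_crop = background_crop

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components, "background_crop": self.background_crop}

    def set_params(self, **params) -> "SpectralPCA":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- fitting -----------------------------------------------------------

    def _pixel_matrix(self, cube: Hypercube, crop) -> np.ndarray:
        data = cube.astype_float()
        if crop is not None:
            r0, r1, c0, c1 = crop
            data = data[r0:r1, c0:c1]
        return data.reshape(-1, data.shape[2])

    def fit(self, cubes) -> "SpectralPCA":
        """Fit on one cube or a pooled sequence of cubes (one strip)."""
        if isinstance(cubes, Hypercube):
            cubes = [cubes]
        mats = [self._pixel_matrix(c, self.background_crop) for c in cubes]
        x = np.vstack(mats)
        if x.shape[1] < self.n_components:
            raise ValueError(
                f"cube has {x.shape[1]} bands; need at least {self.n_components}"
            )
        pca = PCA(n_components=self.n_components, svd_solver="full")
        scores = pca.fit_transform(x)
        if pca.explained_variance_[-1] <= 1e-12 * max(pca.explained_variance_[0], 1e-30):
            raise ValueError(
                f"fewer than {self.n_components} non-degenerate spectral components "
                "(cube is spectrally constant or near-constant)"
            )
        components = pca.components_.copy()
        # deterministic sign: largest-|loading| entry of each component positive
        for i in range(components.shape[0]):
            j = int(np.argmax(np.abs(components[i])))
            if components[i, j] < 0:
                components[i] = -components[i]
                scores[:, i] = -scores[:, i]
        self.components_ = components
        self.mean_ = pca.mean_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_.copy()
        self.wavelengths_ = np.asarray(cubes[0].wavelengths, float)
        self.channel_min_ = scores.min(axis=0)
        self.channel_max_ = scores.max(axis=0)
        return self

    # -- projection --------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "components_"):
            raise RuntimeError("SpectralPCA instance is not fitted yet")

    def scores(self, cube: Hypercube) -> np.ndarray:
        self._check_fitted()
        if cube.wavelengths.shape != self.wavelengths_.shape or not np.allclose(
            cube.wavelengths, self.wavelengths_
        ):
            raise ValueError("cube wavelength axis differs from the fitted basis axis")
        rows, cols, _ = cube.shape
        x = cube.astype_float().reshape(-1, cube.n_bands) - self.mean_
        return (x @ self.components_.T).reshape(rows, cols, self.n_components)

    def transform(self, cube: Hypercube) -> CompressedImage:
        """Project to PC scores and scale each channel to 8-bit.

        Scaling uses the per-channel min/max recorded at fit time, so all
        patches of one strip share one mapping; out-of-range scores are
        clipped.  A zero-variance channel maps to 0.
        """
        s = self.scores(cube)
        out = np.zeros(s.shape, dtype=float)
        for c in range(self.n_components):
            span = self.channel_max_[c] - self.channel_min_[c]
            if span <= 0:
                continue  # degenerate channel stays 0
            out[:, :, c] = (s[:, :, c] - self.channel_min_[c]) / span * 255.0
        data = np.clip(np.round(out), 0, 255).astype(np.uint8)
        stats = {
            "channel_min": self.channel_min_.tolist(),
            "channel_max": self.channel_max_.tolist(),
        }
        return CompressedImage(data, explained_variance=self.explained_variance_ratio_,
                               fit_stats=stats)

    def fit_transform(self, cube: Hypercube) -> CompressedImage:
        return self.fit(cube).transform(cube)

    def reconstruct(self, cube: Hypercube) -> np.ndarray:
        """Back-project the retained components (for fidelity checks)."""
        s = self.scores(cube)
        flat = s.reshape(-1, self.n_components) @ self.components_ + self.mean_
        return flat.reshape(cube.shape)

    # -- serialization -----------------------------------------------------

    def to_json(self, path) -> None:
        self._check_fitted()
        payload = {
            "components": self.components_.tolist(),
            "mean": self.mean_.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio_.tolist(),
            "wavelengths": self.wavelengths_.tolist(),
            "channel_min": self.channel_min_.tolist(),
            "channel_max": self.channel_max_.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SpectralPCA":
        with open(path) as fh:
            payload = json.load(fh)
        obj = cls(n_components=len(payload["components"]))
        obj.components_ = np.asarray(payload["components"], float)
        obj.mean_ = np.asarray(payload["mean"], float)
        obj.explained_variance_ratio_ = np.asarray(payload["explained_variance_ratio"], float)
        obj.wavelengths_ = np.asarray(payload["wavelengths"], float)
        obj.channel_min_ = np.asarray(payload["channel_min"], float)
        obj.channel_max_ = np.asarray(payload["channel_max"], float)
        return obj


def fit_pca(cube, background_crop=None) -> SpectralPCA:
    """Fit a 3-component spectral PCA basis (thin functional wrapper)."""
    return SpectralPCA(n_components=3, background_crop=background_crop).fit(cube)


def project_to_rgb(cube: Hypercube, basis: SpectralPCA) -> CompressedImage:
    """Project a cube onto a fitted basis: PC1->R, PC2->G, PC3->B."""
    return basis.transform(cube)
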