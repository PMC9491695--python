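"""Co-registration of stain images to the hyperspectral frame.

Stain images (brightfield DAB or fluorescence) are aligned to a
transmission band image in three steps: an 8-bit complement so that both
modalities show signal as bright-on-dark, a nonreflective similarity fit
(rotation, isotropic scale, translation — no reflection), and an optional
control-point refinement by a local weighted mean (LWM) of second-degree
polynomial transforms, which absorbs the spatially varying deformation
that staining introduces.

The similarity metric is normalized cross-correlation (NCC), optimized
multi-resolution: a coarse grid over rotation and scale with
phase-correlation translation estimates, then Nelder–Mead refinement up
the pyramid.  NCC is invariant to affine intensity maps, so registering
complemented images gives the same optimum as registering the originals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage import transform as sktransform
from skimage.registration import phase_cross_correlation

__all__ = [
    "SimilarityTransform",
    "ControlPointSet",
    "RegistrationResult",
    "complement_8bit",
    "warp_similarity",
    "most_contrast_band",
    "register_similarity",
    "fit_lwm",
    "register_lwm",
    "load_control_points",
]

MIN_LWM_PAIRS = 6  # a second-degree 2-D polynomial has 6 coefficients


@dataclass(frozen=True)
class SimilarityTransform:
    """Nonreflective similarity about the image center, xy convention.

    Maps content as ``q = s R (p - c) + c + t`` where ``c`` is the image
    center, ``R`` the rotation and ``t = (dx, dy)`` the translation in px.
    """

    rotation_deg: float = 0.0
    scale: float = 1.0
    translation: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    def matrix(self, shape) -> np.ndarray:
        """3x3 homogeneous forward matrix for an image of this shape."""
        rows, cols = shape[:2]
        cx, cy = (cols - 1) / 2.0, (rows - 1) / 2.0
        th = math.radians(self.rotation_deg)
        a = self.scale * math.cos(th)
        b = self.scale * math.sin(th)
        dx, dy = self.translation
        # q = A (p - c) + c + t
        m = np.array(
            [
                [a, -b, cx + dx - (a * cx - b * cy)],
                [b, a, cy + dy - (b * cx + a * cy)],
                [0.0, 0.0, 1.0],
            ]
        )
        return m

    def inverse(self) -> "SimilarityTransform":
        th = math.radians(self.rotation_deg)
        s = self.scale
        a, b = math.cos(-th) / s, math.sin(-th) / s
        dx, dy = self.translation
        # inverse translation is -A^{-1} t
        inv_t = (-(a * dx - b * dy), -(b * dx + a * dy))
        return SimilarityTransform(-self.rotation_deg, 1.0 / s, inv_t)


def warp_similarity(image: np.ndarray, transform: SimilarityTransform, cval=0.0,
                    order: int = 1) -> np.ndarray:
    """Apply a similarity to an image (bilinear, constant fill).

    uint8 inputs come back as uint8; float inputs stay float.
    """
    m = transform.matrix(image.shape)
    tf = sktransform.AffineTransform(matrix=m)
    out = sktransform.warp(
        image.astype(float), tf.inverse, order=order, cval=float(cval),
        preserve_range=True, mode="constant",
    )
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.round(out), 0, np.iinfo(image.dtype).max).astype(image.dtype)
    return out


def complement_8bit(image: np.ndarray) -> np.ndarray:
    """Complement of an 8-bit image: ``255 - pixel`` (an involution)."""
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ValueError(f"complement_8bit requires an 8-bit image, got dtype {image.dtype}")
    return (255 - image).astype(np.uint8)


def most_contrast_band(cube) -> int:
    """Index of the band with the largest spatial intensity SD."""
    data = cube.data if hasattr(cube, "wavelengths") else np.asarray(cube)
    return int(np.argmax(data.reshape(-1, data.shape[2]).std(axis=0)))


def _as_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        return image.mean(axis=2)
    return image


def _ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    if mask is not None:
        a, b = a[mask], b[mask]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return float("nan")
    return float((a * b).sum() / denom)


@dataclass
class RegistrationResult:
    transform: SimilarityTransform
    warped: np.ndarray
    score: float  # NCC of warped moving vs fixed
    degenerate: bool = False


class RegistrationError(RuntimeError):
    def __init__(self, message: str, best_score: float):
        super().__init__(f"{message} (best NCC so far: {best_score:.4f})")
        self.best_score = best_score


def _score_params(params, moving, fixed, cval):
    rot, log_s, dx, dy = params
    tf = SimilarityTransform(rot, math.exp(log_s), (dx, dy))
    warped = warp_similarity(moving, tf, cval=cval)
    valid = warp_similarity(np.ones_like(moving), tf, cval=0.0) > 0.5
    if valid.sum() < 16:
        return 1.0
    score = _ncc(warped, fixed, valid)
    if math.isnan(score):
        return 1.0
    return -score


def register_similarity(moving, fixed, init: SimilarityTransform | None = None,
                        rotation_range=(-15.0, 15.0), scale_range=(0.8, 1.25),
                        min_score: float = 0.2) -> RegistrationResult:
    """Recover the nonreflective similarity aligning *moving* to *fixed*.

    Maximizes NCC over rotation, scale and translation with a 3-level
    pyramid (coarse grid + phase correlation, then Nelder–Mead
    refinement).  Raises :class:`RegistrationError` if the final score
    stays below *min_score*; constant inputs are flagged degenerate and
    returned with the identity transform.
    """
    moving_arr = moving.data if hasattr(moving, "kind") else np.asarray(moving)
    fixed_arr = fixed.data if hasattr(fixed, "kind") else np.asarray(fixed)
    mg, fg = _as_gray(moving_arr), _as_gray(fixed_arr)
    cval = float(np.median(mg))

    if mg.std() == 0 or fg.std() == 0:
        return RegistrationResult(SimilarityTransform(), moving_arr.copy(),
                                  float("nan"), degenerate=True)

    if init is None:
        # coarse exhaustive grid over rotation x scale at 1/4 resolution,
        # translation from phase correlation
        factor = 4
        mg_c = sktransform.rescale(mg, 1 / factor, anti_aliasing=True)
        fg_c = sktransform.rescale(fg, 1 / factor, anti_aliasing=True)
        best = (0.0, 1.0, 0.0, 0.0, -np.inf)
        for rot in np.arange(rotation_range[0], rotation_range[1] + 1e-9, 3.0):
            for scale in np.arange(scale_range[0], scale_range[1] + 1e-9, 0.05):
                tf = SimilarityTransform(rot, scale, (0.0, 0.0))
                warped = warp_similarity(mg_c, tf, cval=float(np.median(mg_c)))
                shift, _, _ = phase_cross_correlation(fg_c, warped, normalization=None)
                dy, dx = shift
                tf2 = SimilarityTransform(rot, scale, (dx, dy))
                warped2 = warp_similarity(mg_c, tf2, cval=float(np.median(mg_c)))
                score = _ncc(warped2, fg_c)
                if not math.isnan(score) and score > best[4]:
                    best = (rot, scale, dx * factor, dy * factor, score)
        init = SimilarityTransform(best[0], best[1], (best[2], best[3]))

    params = np.array([init.rotation_deg, math.log(init.scale),
                       init.translation[0], init.translation[1]])
    for factor in (4, 2, 1):
        if factor > 1:
            mg_l = sktransform.rescale(mg, 1 / factor, anti_aliasing=True)
            fg_l = sktransform.rescale(fg, 1 / factor, anti_aliasing=True)
        else:
            mg_l, fg_l = mg, fg
        scaled = params.copy()
        scaled[2:] /= factor
        # explicit simplex: default perturbations vanish for parameters
        # sitting at 0 (identity rotation / unit scale), stalling the search
        steps = np.array([1.0, 0.02, 1.5, 1.5])
        simplex = np.vstack([scaled] + [scaled + np.eye(4)[i] * steps[i]
                                        for i in range(4)])
        res = optimize.minimize(
            _score_params, scaled, args=(mg_l, fg_l, float(np.median(mg_l))),
            method="Nelder-Mead",
            options={"xatol": 0.01 / factor, "fatol": 1e-7, "maxiter": 600,
                     "initial_simplex": simplex},
        )
        params = res.x.copy()
        params[2:] *= factor

    final = SimilarityTransform(float(params[0]), math.exp(float(params[1])),
                                (float(params[2]), float(params[3])))
    warped_full = warp_similarity(moving_arr, final, cval=cval)
    score = -_score_params(params, mg, fg, cval)
    if score < min_score:
        raise RegistrationError("similarity registration did not converge", score)
    return RegistrationResult(final, warped_full, score)


# ---------------------------------------------------------------------------
# control-point local weighted mean


@dataclass
class ControlPointSet:
    """Matched landmark pairs in xy pixel coordinates."""

    fixed_points: np.ndarray  # (n, 2)
    moving_points: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.fixed_points = np.asarray(self.fixed_points, dtype=float).reshape(-1, 2)
        self.moving_points = np.asarray(self.moving_points, dtype=float).reshape(-1, 2)
        if len(self.fixed_points) != len(self.moving_points):
            raise ValueError("fixed and moving point lists must have equal length")

    def __len__(self) -> int:
        return len(self.fixed_points)


def load_control_points(path) -> ControlPointSet:
    """Read whitespace-separated ``x_fixed y_fixed x_moving y_moving`` lines."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] != 4:
        raise ValueError(f"{path}: expected 4 columns (x_fixed y_fixed x_moving y_moving)")
    return ControlPointSet(arr[:, :2], arr[:, 2:])


def _quad_design(points: np.ndarray) -> np.ndarray:
    x, y = points[:, 0], points[:, 1]
    return np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])


class LWMTransform:
    """Local-weighted-mean mapping from fixed to moving coordinates.

    Around every control point a second-degree polynomial transform is
    fitted on its K nearest control points; at any location the mapping is
    the weighted mean of the nearby polynomials, with weight falling off
    quadratically to zero at each point's Kth-neighbor radius.
    """

    def __init__(self, cps: ControlPointSet, k: int = 12):
        n = len(cps)
        if n < MIN_LWM_PAIRS:
            raise ValueError(
                f"LWM requires at least {MIN_LWM_PAIRS} control point pairs "
                f"(a second-degree polynomial has {MIN_LWM_PAIRS} coefficients); got {n}"
            )
        self.k = min(k, n)
        self.fixed = cps.fixed_points
        self.moving = cps.moving_points
        d = np.linalg.norm(self.fixed[:, None, :] - self.fixed[None, :, :], axis=2)
        order = np.argsort(d, axis=1)
        self.radii = np.empty(n)
        self.coeffs = np.empty((n, 6, 2))
        for i in range(n):
            nbr = order[i, : self.k]
            self.radii[i] = d[i, nbr[-1]]
            if self.radii[i] == 0:
                raise ValueError(f"control point {i} coincides with its neighborhood")
            design = _quad_design(self.fixed[nbr])
            sol, _, rank, _ = np.linalg.lstsq(design, self.moving[nbr], rcond=None)
            if rank < 6:
                raise ValueError(
                    f"degenerate (collinear) neighborhood around control point {i} "
                    f"at {tuple(self.fixed[i])}"
                )
            self.coeffs[i] = sol

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float).reshape(-1, 2)
        d = np.linalg.norm(points[:, None, :] - self.fixed[None, :, :], axis=2)
        w = np.clip(1.0 - (d / self.radii[None, :]) ** 2, 0.0, None)
        total = w.sum(axis=1)
        fallback = total <= 1e-12
        if np.any(fallback):
            nearest = np.argmin(d[fallback], axis=1)
            w[fallback] = 0.0
            w[np.flatnonzero(fallback), nearest] = 1.0
            total = w.sum(axis=1)
        design = _quad_design(points)  # (m, 6)
        # per-control-point polynomial evaluations: (m, n, 2)
        vals = np.einsum("mj,njc->mnc", design, self.coeffs)
        return (w[:, :, None] * vals).sum(axis=1) / total[:, None]


def fit_lwm(cps: ControlPointSet, k: int = 12) -> LWMTransform:
    return LWMTransform(cps, k)


def register_lwm(cps: ControlPointSet, moving, output_shape=None, k: int = 12,
                 cval: float = 0.0) -> np.ndarray:
    """Warp *moving* onto the fixed frame with an LWM mapping."""
    moving_arr = moving.data if hasattr(moving, "kind") else np.asarray(moving)
    tf = fit_lwm(cps, k)
    if output_shape is None:
        output_shape = moving_arr.shape[:2]
    rows, cols = output_shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    mapped = tf(pts)  # moving-frame xy
    coords = np.stack([mapped[:, 1].reshape(rows, cols),
                       mapped[:, 0].reshape(rows, cols)])
    if moving_arr.ndim == 3:
        out = np.stack(
            [ndimage.map_coordinates(moving_arr[:, :, c].astype(float), coords,
                                     order=1, cval=cval, mode="constant")
             for c in range(moving_arr.shape[2])], axis=2)
    else:
        out = ndimage.map_coordinates(moving_arr.astype(float), coords, order=1,
                                      cval=cval, mode="constant")
    if np.issubdtype(moving_arr.dtype, np.integer):
        return np.clip(np.round(out), 0, np.iinfo(moving_arr.dtype).max).astype(moving_arr.dtype)
    return out
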