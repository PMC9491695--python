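"""Paired training patches: cropping, splitting, cleaning, augmentation.

From a registered (compressed-HSI, stain) image pair this module cuts
fixed-size patches, holds out the analysis region as test patches with
1/3–1/2 overlap (so stitched predictions have no intensity jumps),
splits the remainder into train/validation, removes spurious lumen
autofluorescence by negative labeling, discards damaged patches, and
enlarges the training set exactly 12-fold with geometric augmentation.
Augmented variants apply the same transform to both images of a pair
plus a small translation jitter on the compressed image only, emulating
the residual registration error between modalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import transform as sktransform

__all__ = [
    "TrainingPair",
    "AugmentationPolicy",
    "DiscardRules",
    "make_patches",
    "mask_lumen_negative",
    "augment",
    "discard_damaged",
]


@dataclass
class TrainingPair:
    """A (compressed patch x, ground-truth patch y) of identical geometry."""

    x: np.ndarray  # (p, p, 3) uint8
    y: np.ndarray  # (p, p[, C]) uint8
    role: str = "train"  # train | val | test
    stain_kind: str = "dab"  # dab | fluorescence
    provenance: dict = field(default_factory=dict)  # strip, origin (row, col)
    registration_error: float | None = None  # landmark error in px, if known

    def __post_init__(self) -> None:
        if self.x.shape[:2] != self.y.shape[:2]:
            raise ValueError(
                f"x and y must share geometry: {self.x.shape[:2]} vs {self.y.shape[:2]}"
            )
        if self.role not in ("train", "val", "test"):
            raise ValueError(f"unknown role {self.role!r}")


def _grid_origins(extent: int, patch: int, stride: int) -> list:
    """Stride grid of origins covering [0, extent], tail-aligned."""
    if extent < patch:
        return [0]
    origins = list(range(0, extent - patch + 1, stride))
    if origins[-1] != extent - patch:
        origins.append(extent - patch)
    return origins


def _intersects(origin, patch, region) -> bool:
    r0, c0 = origin
    rr0, cc0, rr1, cc1 = region
    return r0 < rr1 and r0 + patch > rr0 and c0 < cc1 and c0 + patch > cc0


def make_patches(x_image: np.ndarray, y_image: np.ndarray, patch_size: int = 256,
                 holdout=None, overlap_test: float = 0.5, val_fraction: float = 0.1,
                 seed: int = 0, stain_kind: str = "dab", strip: str = "strip") -> list:
    """Cut a registered strip pair into train/val/test patches.

    *holdout* is the analysis region ``(row0, col0, row1, col1)`` reserved
    for testing; its patches tile the region with *overlap_test* (a
    fraction in [1/3, 1/2]) so stitching the predictions back produces no
    discontinuous intensities.  Train patches tile the rest without
    overlap and never intersect the held-out region; validation is a
    seeded random subset of the training patches.
    """
    x_image = np.asarray(x_image)
    y_image = np.asarray(y_image)
    if x_image.shape[:2] != y_image.shape[:2]:
        raise ValueError("x and y strip images must share (rows, cols)")
    rows, cols = x_image.shape[:2]
    if not (1 / 3 - 1e-9 <= overlap_test <= 1 / 2 + 1e-9):
        raise ValueError(f"overlap_test must lie in [1/3, 1/2], got {overlap_test}")

    pairs = []
    if holdout is not None:
        r0, c0, r1, c1 = holdout
        if r0 < 0 or c0 < 0 or r1 > rows or c1 > cols or r0 >= r1 or c0 >= c1:
            raise ValueError(
                f"held-out region {holdout} does not fit the {rows}x{cols} image"
            )
        stride = max(1, int(round(patch_size * (1.0 - overlap_test))))
        row_origins = [min(r0 + o, rows - patch_size)
                       for o in _grid_origins(r1 - r0, patch_size, stride)]
        col_origins = [min(c0 + o, cols - patch_size)
                       for o in _grid_origins(c1 - c0, patch_size, stride)]
        for rr in sorted(set(row_origins)):
            for cc in sorted(set(col_origins)):
                pairs.append(TrainingPair(
                    x_image[rr:rr + patch_size, cc:cc + patch_size].copy(),
                    y_image[rr:rr + patch_size, cc:cc + patch_size].copy(),
                    role="test", stain_kind=stain_kind,
                    provenance={"strip": strip, "origin": (rr, cc)},
                ))

    train_origins = [
        (rr, cc)
        for rr in _grid_origins(rows, patch_size, patch_size)
        for cc in _grid_origins(cols, patch_size, patch_size)
        if holdout is None or not _intersects((rr, cc), patch_size, holdout)
    ]
    train_pairs = [
        TrainingPair(
            x_image[rr:rr + patch_size, cc:cc + patch_size].copy(),
            y_image[rr:rr + patch_size, cc:cc + patch_size].copy(),
            role="train", stain_kind=stain_kind,
            provenance={"strip": strip, "origin": (rr, cc)},
        )
        for rr, cc in train_origins
    ]
    # validation drawn at random from the training pool, fixed seed
    rng = np.random.default_rng(seed)
    n_val = int(round(val_fraction * len(train_pairs)))
    val_idx = set(rng.choice(len(train_pairs), size=n_val, replace=False).tolist()
                  ) if n_val else set()
    for i, p in enumerate(train_pairs):
        if i in val_idx:
            p.role = "val"
    return pairs + train_pairs


def mask_lumen_negative(y: np.ndarray, lumen_mask: np.ndarray,
                        stretch_percentile: float = 99.0) -> np.ndarray:
    """Zero spurious lumen signal and contrast-stretch the true signal.

    Pixels inside the lumen mask are labeled negative (set to 0).  The
    remaining positive signal is stretched per channel so its
    *stretch_percentile* maps to 255 (clipped); zero pixels stay zero, so
    the black fluorescence background is preserved.
    """
    y = np.asarray(y)
    lumen_mask = np.asarray(lumen_mask, dtype=bool)
    if lumen_mask.shape != y.shape[:2]:
        raise ValueError(
            f"lumen mask geometry {lumen_mask.shape} does not match patch {y.shape[:2]}"
        )
    out = y.astype(float).copy()
    out[lumen_mask] = 0.0
    channels = out[..., None] if out.ndim == 2 else out
    for c in range(channels.shape[2]):
        ch = channels[:, :, c]
        positive = ch[ch > 0]
        if positive.size == 0:
            continue
        ref = np.percentile(positive, stretch_percentile)
        if ref > 0:
            ch *= 255.0 / ref
    result = np.clip(np.round(channels), 0, 255).astype(np.uint8)
    return result[:, :, 0] if y.ndim == 2 else result


@dataclass
class AugmentationPolicy:
    """Ordered roster of geometric variants; 12 outputs per input.

    The roster (identity; +/-8 px translations; +/-5 and +/-10 degree
    rotations; horizontal and vertical flips; 0.9x and 1.1x scalings; one
    1.0x1.1 anisotropic stretch) fixes the op families — translation,
    rotation, flipping, scaling, stretching — into an explicit 12-entry
    list.  *jitter_px* is the registration-error translation applied to x
    only on non-identity variants.
    """

    ops: tuple = (
        ("identity", {}),
        ("translate", {"dx": 8, "dy": 0}),
        ("translate", {"dx": -8, "dy": 0}),
        ("rotate", {"deg": 5.0}),
        ("rotate", {"deg": -5.0}),
        ("rotate", {"deg": 10.0}),
        ("rotate", {"deg": -10.0}),
        ("flip", {"axis": "horizontal"}),
        ("flip", {"axis": "vertical"}),
        ("scale", {"sx": 0.9, "sy": 0.9}),
        ("scale", {"sx": 1.1, "sy": 1.1}),
        ("scale", {"sx": 1.0, "sy": 1.1}),  # anisotropic stretch
    )
    target_factor: int = 12
    jitter_px: float = 2.0

    def __post_init__(self) -> None:
        if len(self.ops) != self.target_factor:
            raise ValueError(
                f"policy lists {len(self.ops)} ops but target_factor is {self.target_factor}"
            )


def _apply_geometric(img: np.ndarray, op: str, params: dict) -> np.ndarray:
    if op == "identity":
        return img.copy()
    if op == "flip":
        axis = 1 if params["axis"] == "horizontal" else 0
        return np.flip(img, axis=axis).copy()
    rows, cols = img.shape[:2]
    center = np.array([(cols - 1) / 2.0, (rows - 1) / 2.0])
    if op == "translate":
        tf = sktransform.AffineTransform(translation=(params["dx"], params["dy"]))
    elif op == "rotate":
        rad = np.deg2rad(params["deg"])
        tf = (sktransform.AffineTransform(translation=-center)
              + sktransform.AffineTransform(rotation=rad)
              + sktransform.AffineTransform(translation=center))
    elif op == "scale":
        tf = (sktransform.AffineTransform(translation=-center)
              + sktransform.AffineTransform(scale=(params["sx"], params["sy"]))
              + sktransform.AffineTransform(translation=center))
    else:
        raise ValueError(f"unknown augmentation op {op!r}")
    out = sktransform.warp(img.astype(float), tf.inverse, order=1, mode="edge",
                           preserve_range=True)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def augment(pair: TrainingPair, policy: AugmentationPolicy | None = None,
            seed: int = 0) -> list:
    """Original plus 11 geometric variants (12 pairs per input).

    Each variant applies one roster transform to both x and y, then a
    uniform translation jitter of up to ``policy.jitter_px`` to x alone,
    mimicking the registration offset between the hyperspectral and
    stained frames.  The identity entry is returned bit-identical.
    Deterministic under *seed*.
    """
    policy = policy or AugmentationPolicy()
    rng = np.random.default_rng(seed)
    out = []
    for idx, (op, params) in enumerate(policy.ops):
        x_t = _apply_geometric(pair.x, op, params)
        y_t = _apply_geometric(pair.y, op, params)
        if op != "identity" and policy.jitter_px > 0:
            jx, jy = rng.uniform(-policy.jitter_px, policy.jitter_px, size=2)
            x_t = _apply_geometric(x_t, "translate", {"dx": jx, "dy": jy})
        prov = dict(pair.provenance)
        prov["transform_id"] = idx
        prov["transform"] = (op, dict(params))
        out.append(TrainingPair(x_t, y_t, role=pair.role, stain_kind=pair.stain_kind,
                                provenance=prov,
                                registration_error=pair.registration_error))
    return out


@dataclass
class DiscardRules:
    """Thresholds for dropping damaged or unusable patches."""

    max_blank_fraction: float = 0.99  # y almost entirely background
    max_registration_error: float = 2.0  # landmark error in px
    dab_background_level: int = 235  # >= this in all channels counts as blank
    fluo_background_level: int = 10  # <= this in all channels counts as blank


def _blank_fraction(pair: TrainingPair, rules: DiscardRules) -> float:
    y = pair.y if pair.y.ndim == 3 else pair.y[:, :, None]
    if pair.stain_kind == "dab":
        blank = np.all(y >= rules.dab_background_level, axis=2)
    else:
        blank = np.all(y <= rules.fluo_background_level, axis=2)
    return float(blank.mean())


def discard_damaged(pairs, rules: DiscardRules | None = None):
    """Drop patches that fail any rule; returns (kept, report).

    Rules: nearly all-background ground truth (blank fraction above the
    threshold) and registration landmark error above the threshold (pairs
    with no recorded error pass that rule).
    """
    rules = rules or DiscardRules()
    kept, report = [], {"blank": 0, "registration_error": 0, "kept": 0}
    for pair in pairs:
        if _blank_fraction(pair, rules) > rules.max_blank_fraction:
            report["blank"] += 1
            continue
        if (pair.registration_error is not None
                and pair.registration_error > rules.max_registration_error):
            report["registration_error"] += 1
            continue
        kept.append(pair)
    report["kept"] = len(kept)
    return kept, report
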