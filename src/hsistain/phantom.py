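"""Synthetic retinal cross-section phantoms with planted deposit spectra.

The phantom emulates a transmission-mode hyperspectral acquisition of a
layered retinal cross-section strip (NFL/GCL/IPL/INL/OPL/ONL bands)
containing amyloid-beta (Abeta42) and phosphorylated-tau (pS396-Tau)
deposits, plus blood vessels whose lumen can carry a spurious
autofluorescence artifact.  Each phantom comes with perfectly registered
ground-truth stain renderings (DAB brightfield and two-channel
immunofluorescence) and a per-pixel class mask, so every downstream stage
— spectral signature extraction, registration, PCA compression, GAN
training, stitching, metric evaluation — can be exercised and scored
against known truth.

Spectral model
--------------
* tissue baseline: smooth transmittance bump peaking near 600 nm,
  ``b(l) = 0.25 + 0.45 exp(-((l-600)/120)^2)``;
* pTau: the baseline blended toward a flat plateau over 550–650 nm
  (the "flat hat"): elevated, uniform transmittance whose coefficient of
  variation decreases with deposit amplitude; plateau level is 1.3x the
  baseline mean over the window at amplitude 1;
* Abeta: the baseline multiplied by a Rayleigh-like attenuation
  ``1 - 0.3 a (500/l)^4`` — a short-wavelength transmission deficit
  proportional to ``l^-4``, about 30% at 500 nm for amplitude 1.

Amplitude magnitudes are free parameters of the phantom (real signature
magnitudes are not quantified), so downstream tests are kept
scale-invariant wherever possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hypercube import Hypercube, default_axis
from .registration import SimilarityTransform, warp_similarity

__all__ = [
    "PhantomSpec",
    "Deposit",
    "Vessel",
    "StainImage",
    "GroundTruthPair",
    "make_tissue_spectrum",
    "render_phantom",
    "apply_known_warp",
    "MASK_BACKGROUND",
    "MASK_TISSUE",
    "MASK_ABETA",
    "MASK_PTAU",
    "MASK_LUMEN",
]

# label_mask class codes (documented interchange values, also used on disk)
MASK_BACKGROUND = 0
MASK_TISSUE = 1
MASK_ABETA = 2
MASK_PTAU = 3
MASK_LUMEN = 4

# transmittance of pixels with no tissue (slide + mounting medium)
_BACKGROUND_T = 0.92
_LUMEN_T = 0.88
_VESSEL_WALL_FACTOR = 0.75

# per-layer multiplicative shading of the tissue baseline (6 retinal bands)
_LAYER_FACTORS = (1.00, 0.88, 0.97, 0.84, 0.94, 0.90)

_DAB_BACKGROUND = np.array([243, 240, 236], dtype=float)
_DAB_TISSUE = np.array([225, 219, 210], dtype=float)
_DAB_BROWN = np.array([96, 60, 22], dtype=float)
_LUMEN_ARTIFACT_LEVEL = 160


@dataclass(frozen=True)
class Deposit:
    cls: str  # "abeta" | "ptau"
    center: tuple  # (row, col) px
    radius: float  # px
    amplitude: float  # in (0, 1]


@dataclass(frozen=True)
class Vessel:
    center: tuple  # (row, col) px
    lumen_radius: float
    wall_thickness: float
    lumen_artifact: bool = False


@dataclass
class StainImage:
    """8-bit ground-truth stain image with channel semantics."""

    data: np.ndarray  # uint8, (rows, cols, 3)
    kind: str  # "dab" | "fluorescence"
    channels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != np.uint8:
            raise ValueError(f"stain images are 8-bit; got dtype {self.data.dtype}")
        if self.kind not in ("dab", "fluorescence"):
            raise ValueError(f"unknown stain kind {self.kind!r}")

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class PhantomSpec:
    image_shape: tuple = (128, 192)
    wavelengths: np.ndarray = field(default_factory=default_axis)
    # ordered row fractions delimiting NFL, GCL, IPL, INL, OPL, ONL
    layer_boundaries: tuple = (0.12, 0.22, 0.34, 0.48, 0.60, 0.72, 0.88)
    deposits: tuple = ()
    vessels: tuple = ()
    noise_sd: float = 0.02
    dab_target: str = "ptau"  # which marker the DAB rendering stains
    seed: int = 0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        lb = np.asarray(self.layer_boundaries, float)
        if not (np.all(np.diff(lb) > 0) and lb[0] > 0 and lb[-1] < 1):
            raise ValueError("layer_boundaries must be strictly increasing fractions in (0,1)")
        for d in self.deposits:
            if d.cls not in ("abeta", "ptau"):
                raise ValueError(f"unknown deposit class {d.cls!r}")
            if d.radius <= 0:
                raise ValueError("deposit radius must be positive")
            if not 0 < d.amplitude <= 1:
                raise ValueError("deposit amplitude must be in (0, 1]")
        for v in self.vessels:
            if v.lumen_radius <= 0 or v.wall_thickness <= 0:
                raise ValueError("vessel radii must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dab_target not in ("abeta", "ptau"):
            raise ValueError(f"dab_target must be 'abeta' or 'ptau', got {self.dab_target!r}")

    @classmethod
    def example(cls, image_shape=(128, 192), noise_sd=0.02, seed=0) -> "PhantomSpec":
        """A representative strip: two deposits of each class plus vessels."""
        rows, cols = image_shape

        def rc(fr, fc):
            return (int(fr * rows), int(fc * cols))

        deposits = (
            Deposit("ptau", rc(0.64, 0.20), radius=0.09 * rows, amplitude=1.0),
            Deposit("ptau", rc(0.30, 0.70), radius=0.07 * rows, amplitude=0.8),
            Deposit("abeta", rc(0.18, 0.40), radius=0.08 * rows, amplitude=1.0),
            Deposit("abeta", rc(0.76, 0.85), radius=0.06 * rows, amplitude=0.7),
        )
        vessels = (
            Vessel(rc(0.45, 0.12), lumen_radius=0.05 * rows, wall_thickness=0.025 * rows),
            Vessel(rc(0.50, 0.55), lumen_radius=0.06 * rows, wall_thickness=0.03 * rows,
                   lumen_artifact=True),
        )
        return cls(image_shape=image_shape, deposits=deposits, vessels=vessels,
                   noise_sd=noise_sd, seed=seed)


@dataclass
class GroundTruthPair:
    hypercube: Hypercube
    dab_image: StainImage
    fluor_image: StainImage
    fluor_image_clean: StainImage  # artifact-free rendering (lumen signal absent)
    label_mask: np.ndarray  # uint8 class codes

    def __post_init__(self) -> None:
        rc = self.label_mask.shape
        for img in (self.dab_image, self.fluor_image, self.fluor_image_clean):
            if img.data.shape[:2] != rc:
                raise ValueError("all ground-truth images must share (rows, cols)")
        if self.hypercube.shape[:2] != rc:
            raise ValueError("hypercube and mask must share (rows, cols)")


# ---------------------------------------------------------------------------
# spectra


def _baseline(wavelengths: np.ndarray) -> np.ndarray:
    w = np.asarray(wavelengths, dtype=float)
    return 0.25 + 0.45 * np.exp(-(((w - 600.0) / 120.0) ** 2))


def _plateau_window(wavelengths: np.ndarray, lo=550.0, hi=650.0, taper=20.0) -> np.ndarray:
    """1 inside [lo, hi], smoothstep taper to 0 over ``taper`` nm outside."""
    w = np.asarray(wavelengths, dtype=float)
    rise = np.clip((w - (lo - taper)) / taper, 0.0, 1.0)
    fall = np.clip(((hi + taper) - w) / taper, 0.0, 1.0)
    s = np.minimum(rise, fall)
    return s * s * (3.0 - 2.0 * s)


def make_tissue_spectrum(wavelengths, cls: str, amplitude: float = 1.0) -> np.ndarray:
    """Transmittance spectrum in (0, 1] for a pixel class.

    ``tissue`` ignores *amplitude*; ``ptau`` blends the baseline toward a
    flat elevated plateau over 550–650 nm; ``abeta`` applies a
    Rayleigh-like ``lambda^-4`` attenuation scaled to a ~30% deficit at
    500 nm for amplitude 1.
    """
    if not 0.0 <= amplitude <= 1.0:
        raise ValueError(f"amplitude must be in [0, 1], got {amplitude}")
    w = np.asarray(wavelengths, dtype=float)
    if np.any(w < 420.0) or np.any(w > 720.0):
        raise ValueError("wavelengths must lie within [420, 720] nm")
    b = _baseline(w)
    if cls == "tissue":
        return b
    if cls == "ptau":
        window = _plateau_window(w)
        in_band = (w >= 550.0) & (w <= 650.0)
        plateau = 1.3 * float(np.mean(b[in_band])) if np.any(in_band) else 1.3 * float(np.mean(b))
        return b + amplitude * window * (plateau - b)
    if cls == "abeta":
        attenuation = 1.0 - 0.3 * amplitude * (500.0 / w) ** 4
        return b * attenuation
    raise ValueError(f"unknown spectrum class {cls!r}")


# ---------------------------------------------------------------------------
# rendering


def _disk_mask(shape, center, radius) -> np.ndarray:
    rows, cols = shape
    rr, cc = np.ogrid[:rows, :cols]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _illumination(shape) -> np.ndarray:
    """Separable smooth vignetting profile, identical for every band."""
    rows, cols = shape
    nr = np.linspace(-1.0, 1.0, rows)[:, None]
    nc = np.linspace(-1.0, 1.0, cols)[None, :]
    return (1.0 - 0.15 * nr**2) * (1.0 - 0.15 * nc**2)


def render_phantom(spec: PhantomSpec) -> GroundTruthPair:
    """Render a phantom into a hypercube, stain images, and a truth mask.

    The hypercube is ``class transmittance x illumination + noise``
    (clipped to [0, 1]); DAB colors deposits of ``spec.dab_target`` brown
    with intensity proportional to amplitude on a light background; the
    fluorescence rendering puts Abeta amplitude in green and pTau in red
    on black.  Vessels flagged ``lumen_artifact`` add spurious signal
    inside the lumen in the fluorescence image only; the artifact-free
    rendering is returned alongside.  Output is deterministic per seed.
    """
    rows, cols = spec.image_shape
    lb = np.asarray(spec.layer_boundaries, float)
    tissue_top = int(round(lb[0] * rows))
    tissue_bottom = int(round(lb[-1] * rows))

    mask = np.full((rows, cols), MASK_BACKGROUND, dtype=np.uint8)
    mask[tissue_top:tissue_bottom, :] = MASK_TISSUE

    # per-pixel layer shading factor (tissue only)
    layer_factor = np.ones((rows, cols), dtype=float)
    edges = np.round(lb * rows).astype(int)
    for i in range(len(edges) - 1):
        f = _LAYER_FACTORS[i % len(_LAYER_FACTORS)]
        layer_factor[edges[i]:edges[i + 1], :] = f

    wall_mask = np.zeros((rows, cols), dtype=bool)
    lumen_mask = np.zeros((rows, cols), dtype=bool)
    artifact_mask = np.zeros((rows, cols), dtype=bool)
    for v in spec.vessels:
        outer = _disk_mask((rows, cols), v.center, v.lumen_radius + v.wall_thickness)
        inner = _disk_mask((rows, cols), v.center, v.lumen_radius)
        wall_mask |= outer & ~inner
        lumen_mask |= inner
        if v.lumen_artifact:
            artifact_mask |= inner
    mask[lumen_mask] = MASK_LUMEN

    # amplitude maps per deposit class; deposits override vessels
    amp = {"abeta": np.zeros((rows, cols)), "ptau": np.zeros((rows, cols))}
    for d in spec.deposits:
        r, c = d.center
        if not (d.radius <= r <= rows - 1 - d.radius and d.radius <= c <= cols - 1 - d.radius):
            raise ValueError(
                f"deposit at {d.center} with radius {d.radius} exceeds image bounds {spec.image_shape}"
            )
        dm = _disk_mask((rows, cols), d.center, d.radius)
        amp[d.cls][dm] = d.amplitude
        mask[dm] = MASK_ABETA if d.cls == "abeta" else MASK_PTAU

    w = spec.wavelengths
    spectra = {
        "tissue": make_tissue_spectrum(w, "tissue"),
        "background": np.full(w.size, _BACKGROUND_T),
        "lumen": np.full(w.size, _LUMEN_T),
    }

    transmittance = np.empty((rows, cols, w.size), dtype=float)
    transmittance[:] = spectra["background"]
    tissue_px = mask == MASK_TISSUE
    transmittance[tissue_px] = spectra["tissue"][None, :] * layer_factor[tissue_px, None]
    transmittance[wall_mask & tissue_px] = spectra["tissue"] * _VESSEL_WALL_FACTOR
    transmittance[mask == MASK_LUMEN] = spectra["lumen"]
    for cls, code in (("abeta", MASK_ABETA), ("ptau", MASK_PTAU)):
        px = mask == code
        if not np.any(px):
            continue
        amps = amp[cls][px]
        for a in np.unique(amps):
            s = make_tissue_spectrum(w, cls, float(a))
            sel = np.zeros((rows, cols), dtype=bool)
            sel[px] = amps == a
            transmittance[sel] = s

    illum = _illumination((rows, cols))
    cube_data = transmittance * illum[:, :, None]
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        cube_data = cube_data + rng.normal(0.0, spec.noise_sd, cube_data.shape)
    cube_data = np.clip(cube_data, 0.0, 1.0)
    cube = Hypercube(cube_data, w, meta={"phantom_seed": spec.seed})

    # DAB rendering: brown-on-light brightfield for the targeted marker
    dab = np.empty((rows, cols, 3), dtype=float)
    dab[:] = _DAB_BACKGROUND
    dab[tissue_px] = _DAB_TISSUE * (0.92 + 0.08 * layer_factor[tissue_px, None])
    dab[wall_mask & tissue_px] = _DAB_TISSUE * 0.85
    dab[mask == MASK_LUMEN] = _DAB_BACKGROUND * 0.98
    # untargeted deposits look like plain tissue in DAB (single-marker stain)
    other = "abeta" if spec.dab_target == "ptau" else "ptau"
    other_px = mask == (MASK_ABETA if other == "abeta" else MASK_PTAU)
    dab[other_px] = _DAB_TISSUE
    target_px = mask == (MASK_ABETA if spec.dab_target == "abeta" else MASK_PTAU)
    a_t = amp[spec.dab_target][target_px][:, None]
    dab[target_px] = (1.0 - a_t) * _DAB_TISSUE + a_t * _DAB_BROWN
    dab_img = StainImage(np.clip(np.round(dab), 0, 255).astype(np.uint8), "dab",
                         channels={"scheme": "brown-on-light", "target": spec.dab_target})

    # fluorescence rendering: red = pTau, green = Abeta, black background
    fluo_clean = np.zeros((rows, cols, 3), dtype=float)
    fluo_clean[:, :, 0] = amp["ptau"] * 255.0
    fluo_clean[:, :, 1] = amp["abeta"] * 255.0
    fluo = fluo_clean.copy()
    fluo[artifact_mask, 0] = _LUMEN_ARTIFACT_LEVEL
    fluo[artifact_mask, 1] = _LUMEN_ARTIFACT_LEVEL
    ch = {"red": "ptau", "green": "abeta", "blue": "unused"}
    fluo_img = StainImage(np.clip(np.round(fluo), 0, 255).astype(np.uint8),
                          "fluorescence", channels=dict(ch))
    fluo_clean_img = StainImage(np.clip(np.round(fluo_clean), 0, 255).astype(np.uint8),
                                "fluorescence", channels=dict(ch))

    return GroundTruthPair(cube, dab_img, fluo_img, fluo_clean_img, mask)


def random_phantom_spec(image_shape, rng: np.random.Generator, noise_sd: float = 0.02,
                        deposit_range=(2, 5), vessel_range=(0, 2),
                        dab_target: str = "ptau") -> PhantomSpec:
    """Draw a randomized strip layout: deposit/vessel counts, positions,
    radii and amplitudes sampled within realistic ranges."""
    rows, cols = image_shape
    lb = PhantomSpec.__dataclass_fields__["layer_boundaries"].default
    tissue_top, tissue_bottom = lb[0] * rows, lb[-1] * rows
    deposits = []
    for _ in range(rng.integers(deposit_range[0], deposit_range[1] + 1)):
        cls = "ptau" if rng.random() < 0.5 else "abeta"
        radius = float(rng.uniform(0.06, 0.11) * rows)
        r = float(rng.uniform(tissue_top + radius, tissue_bottom - radius))
        c = float(rng.uniform(radius + 1, cols - radius - 1))
        amplitude = float(rng.uniform(0.6, 1.0))
        deposits.append(Deposit(cls, (int(r), int(c)), radius, amplitude))
    vessels = []
    for _ in range(rng.integers(vessel_range[0], vessel_range[1] + 1)):
        lumen = float(rng.uniform(0.04, 0.07) * rows)
        wall = float(rng.uniform(0.02, 0.035) * rows)
        r = float(rng.uniform(tissue_top + lumen + wall, tissue_bottom - lumen - wall))
        c = float(rng.uniform(lumen + wall + 1, cols - lumen - wall - 1))
        vessels.append(Vessel((int(r), int(c)), lumen, wall,
                              lumen_artifact=bool(rng.random() < 0.3)))
    return PhantomSpec(image_shape=image_shape, deposits=tuple(deposits),
                       vessels=tuple(vessels), noise_sd=noise_sd,
                       dab_target=dab_target, seed=int(rng.integers(2**31)))


def phantom_patch_dataset(n_pairs: int, patch_size: int = 64, stain: str = "dab",
                          dab_target: str = "ptau", channel: str | None = None,
                          noise_sd: float = 0.02, seed: int = 0,
                          patches_per_strip: int = 12) -> list:
    """Paired (compressed RGB, stain) patches from randomized phantom strips.

    Each strip is rendered, PCA-compressed with its own per-strip basis,
    and cut into non-overlapping ``patch_size`` tiles; the stain rendering
    is perfectly registered by construction.  For fluorescence pairs,
    *channel* selects the single trained channel ("abeta" -> green,
    "ptau" -> red).  Deterministic under *seed*.
    """
    from .compression import SpectralPCA
    from .dataset import TrainingPair

    rng = np.random.default_rng(seed)
    pairs: list = []
    strip_idx = 0
    while len(pairs) < n_pairs:
        shape = (patch_size, patch_size * patches_per_strip)
        spec = random_phantom_spec(shape, rng, noise_sd=noise_sd, dab_target=dab_target)
        gt = render_phantom(spec)
        rgb = SpectralPCA(n_components=3).fit(gt.hypercube).transform(gt.hypercube).data
        if stain == "dab":
            y_strip = gt.dab_image.data
        else:
            idx = {"ptau": 0, "abeta": 1}[channel or dab_target]
            y_strip = gt.fluor_image_clean.data[:, :, idx]
        for j in range(patches_per_strip):
            if len(pairs) >= n_pairs:
                break
            c0 = j * patch_size
            pairs.append(TrainingPair(
                rgb[:, c0:c0 + patch_size].copy(),
                y_strip[:, c0:c0 + patch_size].copy(),
                role="train", stain_kind=stain if stain == "dab" else "fluorescence",
                provenance={"strip": f"strip{strip_idx}", "origin": (0, c0)},
            ))
        strip_idx += 1
    return pairs


def apply_known_warp(image: StainImage, transform: SimilarityTransform):
    """Warp a stain image by a known similarity; return it with the exact
    inverse parameters, for registration-recovery scoring.

    Rotation is limited to +/-15 degrees and scale to [0.8, 1.25], the
    range the registration stage is specified to handle.
    """
    if transform.scale == 0:
        raise ValueError("degenerate transform: scale must be non-zero")
    if abs(transform.rotation_deg) > 15.0:
        raise ValueError(f"|rotation| must be <= 15 degrees, got {transform.rotation_deg}")
    if not 0.8 <= transform.scale <= 1.25:
        raise ValueError(f"scale must be in [0.8, 1.25], got {transform.scale}")
    cval = 0.0 if image.kind == "fluorescence" else 255.0
    warped = warp_similarity(image.data, transform, cval=cval)
    inverse = transform.inverse()
    return StainImage(warped, image.kind, dict(image.channels)), inverse
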