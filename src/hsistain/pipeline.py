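"""End-to-end workflow orchestration with on-disk artifacts.

Every stage reads its inputs from, and writes its outputs to, a
workspace directory in documented plain formats (TIFF stacks, PNG, CSV,
JSON), so any stage can be rerun from its persisted upstream artifacts.
A run manifest records, per executed stage, the inputs, outputs, config
hash, derived seed, duration, and a hash of the artifacts produced.

The stage order is: simulate -> calibrate -> compress -> register ->
dataset -> train -> predict -> stitch -> evaluate.  One global seed is
fanned out per stage by stable hashing of the stage name.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import calibration as cal
from . import dataset as ds
from . import gan, metrics, registration, stitching
from .compression import SpectralPCA
from .hypercube import Hypercube, load_hypercube, save_hypercube
from .phantom import PhantomSpec, StainImage, render_phantom, apply_known_warp

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "STAGES",
           "stage_seed"]

STAGES = ("simulate", "calibrate", "compress", "register", "dataset", "train",
          "predict", "stitch", "evaluate")

# artifacts each stage needs, and the stage that produces them
_REQUIRES = {
    "simulate": {},
    "calibrate": {"simulate": ["blank.tif", "lamp_spectrum.csv"]},
    "compress": {"simulate": ["cube.tif", "wavelengths.txt"],
                 "calibrate": ["coefficients.csv"]},
    "register": {"simulate": ["stain.png"], "compress": ["rgb.png"]},
    "dataset": {"compress": ["rgb.png"], "register": ["stain_registered.png"]},
    "train": {"dataset": ["manifest.csv"]},
    "predict": {"train": ["model.npz"], "dataset": ["manifest.csv"]},
    "stitch": {"predict": ["predictions.npz"], "dataset": ["manifest.csv"]},
    "evaluate": {"predict": ["predictions.npz"], "dataset": ["manifest.csv"]},
}


@dataclass
class PipelineConfig:
    """All knobs of the workflow, loadable from one YAML file."""

    workdir: str = "workspace"
    seed: int = 0
    # phantom stage
    image_shape: tuple = (96, 288)
    noise_sd: float = 0.02
    dab_target: str = "ptau"
    stain: str = "dab"  # which ground truth drives the dataset: dab | fluorescence
    # registration stage (known warp applied then recovered, so the stage
    # is exercised end to end on synthetic data)
    warp_rotation_deg: float = 3.0
    warp_scale: float = 1.05
    warp_translation: tuple = (4.0, -2.0)
    # dataset stage
    patch_size: int = 64
    overlap_test: float = 0.5
    holdout_fraction: float = 0.25  # right-hand portion of the strip
    val_fraction: float = 0.1
    augment: bool = False
    # training stage
    target: str = "dab_ptau"
    tiny: bool = True
    epochs: int = 2
    learning_rate: float | None = None
    batch_size: int = 1
    lambda_l1: float = 100.0
    nu_ssim: float = 100.0
    # metrics
    ssim_window: str = "global"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        cfg = cls(**payload)
        for key in ("image_shape", "warp_translation"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> list:
    """Collect every constraint violation (empty list means valid)."""
    errors = []
    if config.batch_size != 1:
        errors.append(f"batch_size must be 1 under instance normalization, got {config.batch_size}")
    if config.lambda_l1 < 0:
        errors.append(f"lambda_l1 must be non-negative, got {config.lambda_l1}")
    if config.nu_ssim < 0:
        errors.append(f"nu_ssim must be non-negative, got {config.nu_ssim}")
    if not (1 / 3 - 1e-9 <= config.overlap_test <= 1 / 2 + 1e-9):
        errors.append(f"overlap_test must lie in [1/3, 1/2], got {config.overlap_test}")
    if config.target not in gan.TARGETS:
        errors.append(f"target must be one of {gan.TARGETS}, got {config.target!r}")
    if config.stain not in ("dab", "fluorescence"):
        errors.append(f"stain must be dab or fluorescence, got {config.stain!r}")
    if config.noise_sd < 0:
        errors.append(f"noise_sd must be >= 0, got {config.noise_sd}")
    if config.epochs < 0:
        errors.append(f"epochs must be >= 0, got {config.epochs}")
    if not (0 < config.holdout_fraction < 1):
        errors.append(f"holdout_fraction must be in (0,1), got {config.holdout_fraction}")
    if not Path(config.workdir).parent.exists():
        errors.append(f"parent of workdir {config.workdir!r} does not exist")
    if config.patch_size < 8 or config.patch_size % 8 != 0:
        errors.append(f"patch_size must be a multiple of 8 (>= 8), got {config.patch_size}")
    return errors


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _save_png(path, array) -> None:
    Image.fromarray(np.asarray(array)).save(path)


def _load_png(path) -> np.ndarray:
    return np.asarray(Image.open(path))


def _hash_outputs(paths) -> str:
    h = hashlib.sha256()
    for p in sorted(map(str, paths)):
        h.update(Path(p).name.encode())
        h.update(Path(p).read_bytes())
    return h.hexdigest()[:16]


class MissingArtifactError(FileNotFoundError):
    pass


def _check_requirements(work: Path, stage: str) -> None:
    for producer, files in _REQUIRES[stage].items():
        for f in files:
            if not (work / producer / f).exists():
                raise MissingArtifactError(
                    f"stage {stage!r} needs {producer}/{f}; run stage "
                    f"{producer!r} first"
                )


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(cfg: PipelineConfig, work: Path, seed: int) -> list:
    out = work / "simulate"
    out.mkdir(parents=True, exist_ok=True)
    spec = PhantomSpec.example(cfg.image_shape, noise_sd=cfg.noise_sd, seed=seed)
    spec.dab_target = cfg.dab_target
    pair = render_phantom(spec)
    save_hypercube(pair.hypercube, out / "cube.tif", out / "wavelengths.txt")
    stain = pair.dab_image if cfg.stain == "dab" else pair.fluor_image_clean
    _save_png(out / "stain.png", stain.data)
    _save_png(out / "fluor.png", pair.fluor_image.data)
    _save_png(out / "mask.png", pair.label_mask)
    # blank acquisition + lamp spectrometer reading for calibration
    rows, cols = 16, 16
    w = spec.wavelengths
    lamp = 0.5 + 0.5 * np.exp(-(((w - 580.0) / 110.0) ** 2))  # smooth lamp spectrum
    response = 0.7 + 0.3 * np.sin((w - 420.0) / 300.0 * np.pi)  # camera response
    blank = np.ones((rows, cols, w.size)) * (lamp * response)[None, None, :]
    save_hypercube(Hypercube(blank, w), out / "blank.tif", out / "blank_wavelengths.txt")
    pd.DataFrame({"wavelength_nm": w, "intensity": lamp}).to_csv(
        out / "lamp_spectrum.csv", index=False)
    return [out / f for f in ("cube.tif", "wavelengths.txt", "stain.png", "fluor.png",
                              "mask.png", "blank.tif", "blank_wavelengths.txt",
                              "lamp_spectrum.csv")]


def _stage_calibrate(cfg: PipelineConfig, work: Path, seed: int) -> list:
    out = work / "calibrate"
    out.mkdir(parents=True, exist_ok=True)
    blank = load_hypercube(work / "simulate" / "blank.tif",
                           work / "simulate" / "blank_wavelengths.txt")
    spec = pd.read_csv(work / "simulate" / "lamp_spectrum.csv")
    table = cal.estimate_coefficients(blank, spec.to_numpy())
    table.to_csv(out / "coefficients.csv")
    return [out / "coefficients.csv"]


def _stage_compress(cfg: PipelineConfig, work: Path, seed: int) -> list:
    out = work / "compress"
    out.mkdir(parents=True, exist_ok=True)
    cube = load_hypercube(work / "simulate" / "cube.tif",
                          work / "simulate" / "wavelengths.txt")
    table = cal.CalibrationTable.from_csv(work / "calibrate" / "coefficients.csv")
    cube = cal.apply_calibration(cube, table)
    pca = SpectralPCA(n_components=3).fit(cube)
    compressed = pca.transform(cube)
    pca.to_json(out / "basis.json")
    _save_png(out / "rgb.png", compressed.data)
    (out / "explained_variance.json").write_text(
        json.dumps(compressed.explained_variance.tolist()))
    return [out / "basis.json", out / "rgb.png", out / "explained_variance.json"]


def _stage_register(cfg: PipelineConfig, work: Path, seed: int) -> list:
    out = work / "register"
    out.mkdir(parents=True, exist_ok=True)
    stain_arr = _load_png(work / "simulate" / "stain.png")
    stain = StainImage(stain_arr, cfg.stain)
    warp = registration.SimilarityTransform(cfg.warp_rotation_deg, cfg.warp_scale,
                                            tuple(cfg.warp_translation))
    moved, _ = apply_known_warp(stain, warp)
    rgb = _load_png(work / "compress" / "rgb.png")
    # the compressed image shares the hyperspectral frame; recover the warp
    result = registration.register_similarity(moved.data, stain_arr)
    _save_png(out / "stain_registered.png", result.warped.astype(np.uint8))
    (out / "transform.json").write_text(json.dumps({
        "rotation_deg": result.transform.rotation_deg,
        "scale": result.transform.scale,
        "translation": list(result.transform.translation),
        "score": result.score,
        "fixed_shape": list(rgb.shape[:2]),
    }))
    return [out / "stain_registered.png", out / "transform.json"]


def _stage_dataset(cfg: PipelineConfig, work: Path, seed: int) -> list:
    out = work / "dataset"
    out.mkdir(parents=True, exist_ok=True)
    rgb = _load_png(work / "compress" / "rgb.png")
    stain = _load_png(work / "register" / "stain_registered.png")
    rows, cols = rgb.shape[:2]
    holdout = (0, int(cols * (1 - cfg.holdout_fraction)), rows, cols)
    pairs = ds.make_patches(rgb, stain, patch_size=cfg.patch_size, holdout=holdout,
                            overlap_test=cfg.overlap_test,
                            val_fraction=cfg.val_fraction, seed=seed,
                            stain_kind=cfg.stain)
    if cfg.augment:
        augmented = []
        for i, p in enumerate(pairs):
            if p.role == "test":
                augmented.append(p)
            else:
                augmented.extend(ds.augment(p, seed=seed + i))
        pairs = augmented
    pairs, report = ds.discard_damaged(pairs)
    (out / "discard_report.json").write_text(json.dumps(report))
    records = []
    xs, ys = [], []
    for i, p in enumerate(pairs):
        records.append({"patch_id": i, "role": p.role,
                        "origin_row": p.provenance.get("origin", (0, 0))[0],
                        "origin_col": p.provenance.get("origin", (0, 0))[1],
                        "transform_id": p.provenance.get("transform_id", 0)})
        xs.append(p.x)
        ys.append(p.y)
    pd.DataFrame(records).to_csv(out / "manifest.csv", index=False)
    np.savez_compressed(out / "patches.npz", x=np.stack(xs), y=np.stack(ys))
    return [out / "manifest.csv", out / "patches.npz", out / "discard_report.json"]


def _load_dataset(work: Path, cfg: PipelineConfig):
    manifest = pd.read_csv(work / "dataset" / "manifest.csv")
    arrays = np.load(work / "dataset" / "patches.npz")
    pairs = []
    for i, row in manifest.iterrows():
        pairs.append(ds.TrainingPair(
            arrays["x"][i], arrays["y"][i], role=row["role"], stain_kind=cfg.stain,
            provenance={"origin": (int(row["origin_row"]), int(row["origin_col"])),
                        "transform_id": int(row["transform_id"])},
        ))
    return pairs


def _stage_train(cfg: PipelineConfig, work: Path, seed: int) -> list:
    out = work / "train"
    out.mkdir(parents=True, exist_ok=True)
    pairs = _load_dataset(work, cfg)
    tc = gan.TrainConfig.tiny(epochs=cfg.epochs, seed=seed) if cfg.tiny else \
        gan.TrainConfig(epochs=cfg.epochs, seed=seed)
    if cfg.learning_rate is not None:
        tc.learning_rate = cfg.learning_rate
    bundle = gan.train_model(pairs, cfg.target, tc,
                             gan.LossWeights(cfg.lambda_l1, cfg.nu_ssim))
    bundle.save(out / "model.npz")
    pd.DataFrame(bundle.train_log).to_csv(out / "train_log.csv", index=False)
    return [out / "model.npz", out / "train_log.csv"]


def _stage_predict(cfg: PipelineConfig, work: Path, seed: int) -> list:
    out = work / "predict"
    out.mkdir(parents=True, exist_ok=True)
    bundle = gan.ModelBundle.load(work / "train" / "model.npz")
    pairs = _load_dataset(work, cfg)
    test = [p for p in pairs if p.role == "test"]
    preds = gan.predict_patches(bundle, [p.x for p in test])
    np.savez_compressed(out / "predictions.npz",
                        pred=np.stack(preds), truth=np.stack([p.y for p in test]),
                        origin=np.array([p.provenance["origin"] for p in test]))
    return [out / "predictions.npz"]


def _stage_stitch(cfg: PipelineConfig, work: Path, seed: int) -> list:
    out = work / "stitch"
    out.mkdir(parents=True, exist_ok=True)
    arrays = np.load(work / "predict" / "predictions.npz")
    preds, origins = arrays["pred"], arrays["origin"]
    row_mosaics = []
    for r in np.unique(origins[:, 0]):
        sel = origins[:, 0] == r
        order = np.argsort(origins[sel, 1])
        tiles = [preds[sel][i] for i in order]
        if len(tiles) == 1:
            row_mosaics.append(tiles[0])
            continue
        plan = stitching.plan_mosaic(tiles, nominal_overlap_fraction=cfg.overlap_test,
                                     margin=4)
        row_mosaics.append(stitching.stitch(plan, tiles))
    width = min(m.shape[1] for m in row_mosaics)
    mosaic = np.concatenate([m[:, :width] for m in row_mosaics], axis=0)
    _save_png(out / "mosaic.png", mosaic)
    return [out / "mosaic.png"]


def _stage_evaluate(cfg: PipelineConfig, work: Path, seed: int) -> list:
    out = work / "evaluate"
    out.mkdir(parents=True, exist_ok=True)
    arrays = np.load(work / "predict" / "predictions.npz")
    params = metrics.SSIMParams(window=cfg.ssim_window)
    report = metrics.evaluate_model(list(arrays["pred"]), list(arrays["truth"]),
                                    params, model=cfg.target)
    report.per_patch_frame().to_csv(out / "per_patch.csv", index=False)
    report.summary_frame().to_csv(out / "summary.csv", index=False)
    return [out / "per_patch.csv", out / "summary.csv"]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "calibrate": _stage_calibrate,
    "compress": _stage_compress,
    "register": _stage_register,
    "dataset": _stage_dataset,
    "train": _stage_train,
    "predict": _stage_predict,
    "stitch": _stage_stitch,
    "evaluate": _stage_evaluate,
}


def run_pipeline(config: PipelineConfig, stages=None) -> list:
    """Execute the requested stages in order; returns the run manifest.

    Raises :class:`MissingArtifactError` (naming the stage to run first)
    when an upstream artifact is absent, and ``ValueError`` when the
    config does not validate.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid pipeline config:\n" + "\n".join(errors))
    stages = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    work = Path(config.workdir)
    work.mkdir(parents=True, exist_ok=True)
    manifest_path = work / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else []
    for stage in stages:
        _check_requirements(work, stage)
        seed = stage_seed(config.seed, stage)
        t0 = time.perf_counter()
        outputs = _STAGE_FN[stage](config, work, seed)
        entry = {
            "stage": stage,
            "inputs": {prod: files for prod, files in _REQUIRES[stage].items()},
            "outputs": [str(Path(p).relative_to(work)) for p in outputs],
            "config_hash": config.config_hash(),
            "seed": seed,
            "duration_s": round(time.perf_counter() - t0, 3),
            "output_hash": _hash_outputs(outputs),
        }
        manifest = [m for m in manifest if m["stage"] != stage] + [entry]
        manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
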