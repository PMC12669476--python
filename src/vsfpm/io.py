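"""Reading and writing pipeline artifacts.

Raw stacks travel as multi-page TIFF plus a JSON sidecar carrying the LED
plan and capture metadata; reconstructed fields as 32-bit amplitude/phase
TIFFs; stained images as 8-bit RGB TIFF/PNG. Model checkpoints are ``.npz``
archives with the config and normalisation constants embedded.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .forward import FPMStack, NoiseParams
from .optics import LEDPlan
from .recon import ComplexField

__all__ = [
    "write_stack", "read_stack", "write_field", "read_field",
    "write_rgb", "read_rgb", "save_model", "load_model",
]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_stack(path: str | Path, stack: FPMStack) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    sidecar = {
        "plan": {
            "positions": stack.plan.positions, "k_illum": stack.plan.k_illum,
            "radial_dist": stack.plan.radial_dist,
            "is_brightfield": stack.plan.is_brightfield,
            "exposure_scale": stack.plan.exposure_scale,
            "height": stack.plan.height, "wavelength": stack.plan.wavelength,
        },
        "exposure": stack.exposure, "wavelength": stack.wavelength,
        "downsample_factor": stack.downsample_factor,
        "pixel_size_obj": stack.pixel_size_obj, "gain": stack.gain,
        "noise_params": vars(stack.noise_params) if np.isfinite(stack.noise_params.full_well)
        else {**vars(stack.noise_params), "full_well": "inf"},
        "seed": stack.seed, "metadata": stack.metadata,
    }
    path.with_suffix(".json").write_text(json.dumps(_jsonable(sidecar), indent=1))


def read_stack(path: str | Path) -> FPMStack:
    path = Path(path)
    frames = np.asarray(tifffile.imread(path), dtype=np.float64)
    meta = json.loads(path.with_suffix(".json").read_text())
    p = meta["plan"]
    plan = LEDPlan(
        positions=np.asarray(p["positions"], float),
        k_illum=np.asarray(p["k_illum"], float),
        radial_dist=np.asarray(p["radial_dist"], float),
        is_brightfield=np.asarray(p["is_brightfield"], bool),
        exposure_scale=np.asarray(p["exposure_scale"], float),
        height=p["height"], wavelength=p["wavelength"],
    )
    np_ = dict(meta["noise_params"])
    if np_.get("full_well") == "inf":
        np_["full_well"] = np.inf
    return FPMStack(
        frames=frames, plan=plan, exposure=np.asarray(meta["exposure"], float),
        wavelength=meta["wavelength"], downsample_factor=meta["downsample_factor"],
        pixel_size_obj=meta["pixel_size_obj"], gain=meta["gain"],
        noise_params=NoiseParams(**np_), seed=meta["seed"],
        metadata=meta.get("metadata", {}),
    )


def write_field(path_base: str | Path, fld: ComplexField) -> None:
    base = Path(path_base)
    tifffile.imwrite(base.with_suffix(".amplitude.tiff"), fld.amplitude.astype(np.float32))
    tifffile.imwrite(base.with_suffix(".phase.tiff"), fld.phase.astype(np.float32))
    meta = {"pixel_size": fld.pixel_size, "na_limit": fld.na_limit,
            "wavelength": fld.wavelength, "provenance": fld.provenance}
    base.with_suffix(".json").write_text(json.dumps(_jsonable(meta), indent=1))


def read_field(path_base: str | Path) -> ComplexField:
    base = Path(path_base)
    amp = np.asarray(tifffile.imread(base.with_suffix(".amplitude.tiff")), float)
    ph = np.asarray(tifffile.imread(base.with_suffix(".phase.tiff")), float)
    meta = json.loads(base.with_suffix(".json").read_text())
    return ComplexField(amp, ph, meta["pixel_size"], meta["na_limit"],
                        meta["wavelength"], meta.get("provenance", {}))


def write_rgb(path: str | Path, rgb: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), (np.clip(rgb, 0, 1) * 255).astype(np.uint8))


def read_rgb(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(Path(path)), float) / 255.0


def save_model(path: str | Path, model) -> None:
    from .vstain import VSModel  # noqa: F401

    arrays = {}
    for i, p in enumerate(model.generator.params()):
        arrays[f"g{i}"] = p.value
    for i, p in enumerate(model.discriminator.params()):
        arrays[f"d{i}"] = p.value
    for i, b in enumerate(model.generator.buffers()):
        arrays[f"gb{i}"] = b
    for i, b in enumerate(model.discriminator.buffers()):
        arrays[f"db{i}"] = b
    cfg = json.dumps(_jsonable(vars(model.config)))
    np.savez_compressed(Path(path), __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
                        __phase_norm__=np.asarray(model.phase_norm), **arrays)


def load_model(path: str | Path):
    from .vstain import PatchDiscriminator, UNetGenerator, VSModel, VSModelConfig

    data = np.load(Path(path))
    cfg_dict = json.loads(bytes(data["__config__"]).decode())
    cfg_dict["betas"] = tuple(cfg_dict["betas"])
    cfg = VSModelConfig(**cfg_dict)
    model = VSModel(
        generator=UNetGenerator(cfg.depth, cfg.base_width),
        discriminator=PatchDiscriminator(cfg.disc_width),
        config=cfg,
        phase_norm=tuple(data["__phase_norm__"]),
    )
    for i, p in enumerate(model.generator.params()):
        p.value[...] = data[f"g{i}"]
    for i, p in enumerate(model.discriminator.params()):
        p.value[...] = data[f"d{i}"]
    for i, b in enumerate(model.generator.buffers()):
        b[...] = data[f"gb{i}"]
    for i, b in enumerate(model.discriminator.buffers()):
        b[...] = data[f"db{i}"]
    return model
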