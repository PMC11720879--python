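"""Dataset and image file plumbing.

The primary on-disk container is HDF5 (datasets ``inputs`` and
``targets``, float32, N x 128 x 128, gzip-compressed, with the producing
configuration embedded as a JSON attribute); ``.npz`` is a drop-in
fallback.  Single images can be exported/imported as 16-bit grayscale PNG
with a linear mapping of [0, 1].
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np

from .reconstruct import PairedDataset, split_indices

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_ground_truth",
    "write_sensor_data",
    "save_png",
    "load_png",
    "save_checkpoint",
    "load_checkpoint",
]

_RANGE_TOL = 1e-4


def _validate_stack(name: str, arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 3:
        raise ValueError(f"dataset {name!r} must be (N, H, W), got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.floating):
        raise ValueError(f"dataset {name!r} must be floating point, got {arr.dtype}")
    if arr.size and (arr.min() < -_RANGE_TOL or arr.max() > 1.0 + _RANGE_TOL):
        raise ValueError(
            f"dataset {name!r} has values outside [0, 1] "
            f"(min {arr.min():.4g}, max {arr.max():.4g})"
        )
    return arr.astype(np.float32)


def write_dataset(path: str | Path, dataset: PairedDataset, config: dict | None = None) -> None:
    """Write a paired dataset to HDF5 (or NPZ when the suffix is .npz)."""
    path = Path(path)
    inputs = _validate_stack("inputs", dataset.inputs)
    targets = _validate_stack("targets", dataset.targets)
    meta = {
        "n_sensors": int(dataset.n_sensors),
        "seed": int(dataset.seed),
        "config": config or {},
    }
    if path.suffix == ".npz":
        np.savez_compressed(
            path,
            inputs=inputs,
            targets=targets,
            train_idx=dataset.train_idx,
            val_idx=dataset.val_idx,
            test_idx=dataset.test_idx,
            meta=json.dumps(meta),
        )
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("inputs", data=inputs, compression="gzip")
        f.create_dataset("targets", data=targets, compression="gzip")
        f.create_dataset("train_idx", data=dataset.train_idx)
        f.create_dataset("val_idx", data=dataset.val_idx)
        f.create_dataset("test_idx", data=dataset.test_idx)
        f.attrs["n_sensors"] = dataset.n_sensors
        f.attrs["seed"] = dataset.seed
        f.attrs["config"] = json.dumps(meta["config"])


def read_dataset(path: str | Path) -> PairedDataset:
    """Load a paired dataset, validating keys, dtypes, shapes and ranges."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as f:
            for key in ("inputs", "targets"):
                if key not in f:
                    raise KeyError(f"container {path} is missing dataset {key!r}")
            meta = json.loads(str(f["meta"]))
            return _build_dataset(
                f["inputs"], f["targets"],
                f.get("train_idx"), f.get("val_idx"), f.get("test_idx"),
                meta.get("n_sensors", -1), meta.get("seed", 0),
            )
    with h5py.File(path, "r") as f:
        for key in ("inputs", "targets"):
            if key not in f:
                raise KeyError(f"container {path} is missing dataset {key!r}")
        return _build_dataset(
            f["inputs"][()], f["targets"][()],
            f["train_idx"][()] if "train_idx" in f else None,
            f["val_idx"][()] if "val_idx" in f else None,
            f["test_idx"][()] if "test_idx" in f else None,
            int(f.attrs.get("n_sensors", -1)),
            int(f.attrs.get("seed", 0)),
        )


def _build_dataset(inputs, targets, tr, va, te, n_sensors, seed) -> PairedDataset:
    inputs = _validate_stack("inputs", inputs)
    targets = _validate_stack("targets", targets)
    if inputs.shape != targets.shape:
        raise ValueError(
            f"inputs shape {inputs.shape} does not match targets {targets.shape}"
        )
    if tr is None:
        tr, va, te = split_indices(inputs.shape[0], np.random.default_rng(seed))
    return PairedDataset(
        inputs=inputs,
        targets=targets,
        train_idx=np.asarray(tr),
        val_idx=np.asarray(va),
        test_idx=np.asarray(te),
        n_sensors=int(n_sensors),
        seed=int(seed),
    )


def write_ground_truth(path: str | Path, scenes: np.ndarray) -> None:
    """Store ground-truth pressure stacks under dataset ``p0``."""
    scenes = _validate_stack("p0", scenes)
    with h5py.File(path, "w") as f:
        f.create_dataset("p0", data=scenes, compression="gzip")


def write_sensor_data(
    path: str | Path,
    series: np.ndarray,
    dt: float,
    angles: np.ndarray,
    snr_db: np.ndarray | None = None,
) -> None:
    """Store sinograms: groups ``sino/series``, ``sino/dt``, ``sino/snr_db``
    and ``sensors/angles``."""
    with h5py.File(path, "w") as f:
        f.create_dataset("sino/series", data=np.asarray(series, dtype=np.float32))
        f.create_dataset("sino/dt", data=float(dt))
        if snr_db is not None:
            f.create_dataset("sino/snr_db", data=np.asarray(snr_db, dtype=np.float64))
        f.create_dataset("sensors/angles", data=np.asarray(angles, dtype=np.float64))


def save_png(path: str | Path, image: np.ndarray) -> None:
    """16-bit grayscale PNG with a linear mapping of [0, 1] to [0, 65535]."""
    image = np.asarray(image, dtype=np.float64)
    if image.min() < -_RANGE_TOL or image.max() > 1.0 + _RANGE_TOL:
        raise ValueError("image values must be in [0, 1] for PNG export")
    scaled = np.round(np.clip(image, 0, 1) * 65535.0).astype(np.uint16)
    iio.imwrite(Path(path), scaled)


def load_png(path: str | Path) -> np.ndarray:
    raw = iio.imread(Path(path))
    if raw.dtype == np.uint16:
        return raw.astype(np.float64) / 65535.0
    if raw.dtype == np.uint8:
        return raw.astype(np.float64) / 255.0
    raise ValueError(f"unsupported PNG dtype {raw.dtype}")


def save_checkpoint(path: str | Path, model, config_json: str = "") -> None:
    """Serialise model weights (npz) with the architecture config embedded."""
    state = model.state_dict()
    state["__config_json"] = np.array(config_json or json.dumps(_cfg_dict(model)))
    np.savez_compressed(path, **state)


def load_checkpoint(path: str | Path):
    """Rebuild the model recorded in a checkpoint and load its weights."""
    from .models import ModelConfig, MSDNet

    with np.load(path, allow_pickle=False) as f:
        cfg_raw = json.loads(str(f["__config_json"]))
        state = {k: f[k] for k in f.files if k != "__config_json"}
    cfg_raw["encoder_channels"] = tuple(cfg_raw["encoder_channels"])
    cfg_raw["decoder_channels"] = tuple(cfg_raw["decoder_channels"])
    cfg_raw["dilations"] = tuple(cfg_raw["dilations"])
    cfg = ModelConfig(**cfg_raw)
    model = MSDNet(cfg)
    model.load_state_dict(state)
    return model


def _cfg_dict(model) -> dict:
    from dataclasses import asdict

    return asdict(model.cfg)
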