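"""Time-reversal reconstruction and paired-dataset assembly.

Time reversal re-emits the recorded sensor series in reversed time order
as enforced pressure values at the sensor nodes while the same k-space
solver steps backward through the window; the final interior field is the
reconstruction.  With few transducers the reconstruction carries the
streak artifacts that the post-processing network is trained to remove.
Every reconstruction is min-max normalised to [0, 1] per image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import phantoms
from .acoustics import (
    Grid2D,
    KSpaceSolver,
    Medium,
    SensorArray,
    SensorData,
    add_gaussian_noise,
    build_sensor_array,
)

__all__ = [
    "normalize_minmax",
    "time_reversal",
    "time_reversal_batch",
    "PairedDataset",
    "make_paired_dataset",
]


def normalize_minmax(image: np.ndarray) -> np.ndarray:
    """Min-max normalise to [0, 1]; a constant image maps to all zeros."""
    image = np.asarray(image, dtype=np.float64)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def time_reversal(
    data: SensorData,
    grid: Grid2D,
    medium: Medium,
    sensors: SensorArray,
    normalize: bool = True,
) -> np.ndarray:
    """Reconstruct one initial-pressure image from its sensor series.

    Negative pressures produced by the backward run are kept until the
    final min-max normalisation so streak artifacts stay visible.
    """
    if data.series.shape[0] != sensors.n_sensors:
        raise ValueError(
            f"sensor data has {data.series.shape[0]} channels but the array "
            f"has {sensors.n_sensors} transducers"
        )
    if data.series.shape[1] != grid.nt:
        raise ValueError(
            f"series length {data.series.shape[1]} does not match grid.nt={grid.nt}"
        )
    solver = KSpaceSolver(grid, medium, use_pml=True, smooth_p0=False)
    recon = solver.run_time_reversal(data.series, sensors)[0]
    return normalize_minmax(recon) if normalize else recon


def time_reversal_batch(
    series: np.ndarray,
    grid: Grid2D,
    medium: Medium,
    sensors: SensorArray,
    normalize: bool = True,
    dtype=np.float64,
) -> np.ndarray:
    """Batched variant: series (B, n_sensors, nt) -> images (B, nx, ny)."""
    solver = KSpaceSolver(grid, medium, use_pml=True, smooth_p0=False, dtype=dtype)
    recon = solver.run_time_reversal(series, sensors)
    if normalize:
        recon = np.stack([normalize_minmax(r) for r in recon])
    return recon


@dataclass
class PairedDataset:
    """Paired (sparse TR reconstruction, ground truth) image stacks with a
    seeded 8:1:1 train/val/test split."""

    inputs: np.ndarray  # (N, H, W) float32 in [0, 1]
    targets: np.ndarray  # (N, H, W) float32 in [0, 1]
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    n_sensors: int
    seed: int

    def __post_init__(self) -> None:
        if self.inputs.shape != self.targets.shape:
            raise ValueError("inputs and targets must have equal shapes")

    def __len__(self) -> int:
        return self.inputs.shape[0]

    def subset(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        idx = {"train": self.train_idx, "val": self.val_idx, "test": self.test_idx}[
            which
        ]
        return self.inputs[idx], self.targets[idx]


def split_indices(
    n: int, rng: np.random.Generator, ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded shuffle split into train/val/test by the given ratios."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    perm = rng.permutation(n)
    n_train = int(round(ratios[0] * n))
    n_val = int(round(ratios[1] * n))
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def make_paired_dataset(
    scenes: np.ndarray,
    n_sensors: int,
    rng: np.random.Generator,
    grid: Grid2D | None = None,
    medium: Medium | None = None,
    snr_db_range: tuple[float, float] | None = (40.0, 60.0),
    batch_size: int = 32,
    dtype=np.float32,
) -> PairedDataset:
    """Simulate, add sensor noise, reconstruct, and split.

    ``scenes`` is (N, 128, 128) ground truth initial pressure.  Each scene
    is propagated to the ring, corrupted with Gaussian noise at a random
    40-60 dB SNR (``snr_db_range=None`` for clean data), reconstructed by
    time reversal and min-max normalised.  The split is 8:1:1 by a seeded
    shuffle drawn from ``rng``.
    """
    scenes = np.asarray(scenes, dtype=np.float64)
    if scenes.ndim != 3:
        raise ValueError("scenes must be (N, H, W)")
    grid = grid or Grid2D()
    medium = medium or Medium()
    sensors = build_sensor_array(n_sensors, grid)
    fwd = KSpaceSolver(grid, medium, use_pml=True, smooth_p0=True, dtype=dtype)
    bwd = KSpaceSolver(grid, medium, use_pml=True, smooth_p0=False, dtype=dtype)
    inputs = np.empty(scenes.shape, dtype=np.float32)
    seed = int(rng.integers(2**31))
    for start in range(0, scenes.shape[0], batch_size):
        chunk = scenes[start : start + batch_size]
        series, _ = fwd.run_forward(chunk, sensors)
        if snr_db_range is not None:
            for i in range(series.shape[0]):
                noisy = add_gaussian_noise(
                    SensorData(series[i], grid.dt), rng, snr_db_range
                )
                series[i] = noisy.series
        recon = bwd.run_time_reversal(series, sensors)
        for i, r in enumerate(recon):
            inputs[start + i] = normalize_minmax(r).astype(np.float32)
    train_idx, val_idx, test_idx = split_indices(
        scenes.shape[0], np.random.default_rng(seed)
    )
    return PairedDataset(
        inputs=inputs,
        targets=scenes.astype(np.float32),
        train_idx=train_idx,
        val_idx=val_idx,
        test_idx=test_idx,
        n_sensors=n_sensors,
        seed=seed,
    )


def generate_scenes(
    n_scenes: int,
    rng: np.random.Generator,
    vessel_fraction: float = 0.0,
) -> np.ndarray:
    """Stack of random ground-truth scenes; a ``vessel_fraction`` of them
    are vessel-like phantoms, the rest geometric absorber scenes."""
    out = np.empty((n_scenes, phantoms.GRID_SIZE, phantoms.GRID_SIZE))
    for i in range(n_scenes):
        if rng.uniform() < vessel_fraction:
            out[i] = phantoms.generate_vessel_scene(rng)
        else:
            out[i] = phantoms.generate_scene(rng)
    return out
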