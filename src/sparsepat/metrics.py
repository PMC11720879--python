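"""Image-quality metrics for reconstruction evaluation.

Implements the four metrics used throughout the pipeline: mean squared
error, peak signal-to-noise ratio, structural similarity and mean absolute
error.  SSIM is implemented literally with the additive constants
``c1 = 0.01`` and ``c2 = 0.03`` (a deliberate deviation from the usual
``(k * L)**2`` parameterisation; pass ``standard_constants=True`` for the
conventional values at unit data range).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = ["mse", "psnr", "mae", "ssim", "MetricsReport", "compute_report"]

#: additive SSIM stabilisation constants (luminance, contrast/structure)
SSIM_C1 = 0.01
SSIM_C2 = 0.03
#: standard SSIM constants for data range 1: (0.01*L)^2 and (0.03*L)^2
SSIM_C1_STD = 0.01**2
SSIM_C2_STD = 0.03**2


def _check_pair(y: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if y.shape != g.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {g.shape}")
    return y, g


def mse(y: np.ndarray, g: np.ndarray) -> float:
    """Mean squared pixel difference."""
    y, g = _check_pair(y, g)
    return float(np.mean((y - g) ** 2))


def mae(y: np.ndarray, g: np.ndarray) -> float:
    """Mean absolute pixel difference."""
    y, g = _check_pair(y, g)
    return float(np.mean(np.abs(y - g)))


def psnr(y: np.ndarray, g: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB.

    The peak is the maximum value over both images, so the ratio is
    invariant to a common rescaling of the pair.  Identical images have no
    defined noise floor and return ``math.inf``.
    """
    y, g = _check_pair(y, g)
    err = mse(y, g)
    if err == 0.0:
        return math.inf
    peak = float(max(y.max(), g.max()))
    return 10.0 * math.log10(peak**2 / err)


def ssim(
    y: np.ndarray,
    g: np.ndarray,
    mode: str = "global",
    win_size: int = 7,
    standard_constants: bool = False,
) -> float:
    """Structural similarity between two images.

    ``mode="global"`` evaluates the SSIM formula once over the whole image
    using population statistics.  ``mode="windowed"`` averages the formula
    over uniform ``win_size`` x ``win_size`` sliding windows (the evaluation
    default; the border of win_size // 2 pixels is excluded so every window
    is fully populated).
    """
    y, g = _check_pair(y, g)
    c1 = SSIM_C1_STD if standard_constants else SSIM_C1
    c2 = SSIM_C2_STD if standard_constants else SSIM_C2
    if mode == "global":
        mu_y, mu_g = y.mean(), g.mean()
        var_y, var_g = y.var(), g.var()
        cov = float(np.mean((y - mu_y) * (g - mu_g)))
        num = (2.0 * mu_y * mu_g + c1) * (2.0 * cov + c2)
        den = (mu_y**2 + mu_g**2 + c1) * (var_y + var_g + c2)
        return float(num / den)
    if mode == "windowed":
        if win_size % 2 == 0 or win_size < 3:
            raise ValueError("win_size must be odd and >= 3")
        mu_y = uniform_filter(y, win_size)
        mu_g = uniform_filter(g, win_size)
        var_y = uniform_filter(y * y, win_size) - mu_y**2
        var_g = uniform_filter(g * g, win_size) - mu_g**2
        cov = uniform_filter(y * g, win_size) - mu_y * mu_g
        num = (2.0 * mu_y * mu_g + c1) * (2.0 * cov + c2)
        den = (mu_y**2 + mu_g**2 + c1) * (var_y + var_g + c2)
        smap = num / den
        pad = win_size // 2
        return float(smap[pad:-pad, pad:-pad].mean())
    raise ValueError(f"unknown SSIM mode {mode!r}")


@dataclass
class MetricsReport:
    """Per-image metrics plus aggregate mean and population SD."""

    ssim: list[float] = field(default_factory=list)
    psnr: list[float] = field(default_factory=list)
    mae: list[float] = field(default_factory=list)
    mse: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.ssim)

    def append(self, y: np.ndarray, g: np.ndarray, ssim_mode: str = "windowed") -> None:
        self.ssim.append(ssim(y, g, mode=ssim_mode))
        self.psnr.append(psnr(y, g))
        self.mae.append(mae(y, g))
        self.mse.append(mse(y, g))

    def summary(self) -> dict[str, dict[str, float]]:
        """Mean and population standard deviation of each metric."""
        out: dict[str, dict[str, float]] = {}
        for name in ("ssim", "psnr", "mae", "mse"):
            vals = np.asarray(getattr(self, name), dtype=np.float64)
            if vals.size == 0:
                raise ValueError("empty report")
            # identical image pairs give infinite PSNR; the aggregate is then
            # inf with an undefined spread rather than a warning
            with np.errstate(invalid="ignore"):
                out[name] = {"mean": float(vals.mean()), "sd": float(vals.std())}
        return out


def compute_report(
    outputs: np.ndarray, targets: np.ndarray, ssim_mode: str = "windowed"
) -> MetricsReport:
    """Evaluate stacks of images (N, H, W) pairwise into a report."""
    outputs = np.asarray(outputs)
    targets = np.asarray(targets)
    if outputs.shape != targets.shape:
        raise ValueError("outputs and targets must have the same shape")
    if outputs.ndim != 3 or outputs.shape[0] == 0:
        raise ValueError("expected non-empty (N, H, W) stacks")
    report = MetricsReport()
    for y, g in zip(outputs, targets):
        report.append(y, g, ssim_mode=ssim_mode)
    return report
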