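"""Stain-image quantification: oil-red-O channel arithmetic and GFP color isolation.

Oil red O absorbs green light (~510 nm), so stained pixels are darker in
the green channel than in the red; the per-pixel stain signal is the
clamped difference ``max(0, R - G)``, and an animal's readout is the mean
signal over a region of interest after background subtraction.  GFP
isolation mimics an editing tool's selective color matching: a pixel is
selected when its maximum per-channel distance from the target color is
within the fuzziness setting.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return arr


def read_image(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return _validate_rgb(arr)


def write_image(path: str | Path, image: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def oro_signal(image: np.ndarray, orientation: str = "red_minus_green") -> np.ndarray:
    """Per-pixel ORO stain signal from red/green channel subtraction.

    ``orientation='red_minus_green'`` (default) yields max(0, R - G), the
    direction in which stain gives positive signal; ``'green_minus_red'``
    is available for the opposite convention.
    """
    arr = _validate_rgb(image).astype(np.int64)
    diff = arr[:, :, 0] - arr[:, :, 1]
    if orientation == "green_minus_red":
        diff = -diff
    elif orientation != "red_minus_green":
        raise ValueError(f"unknown orientation {orientation!r}")
    return np.maximum(diff, 0).astype(np.float64)


def mean_intensity_over_background(
    signal: np.ndarray,
    roi: np.ndarray,
    background_level: float | None = None,
) -> float:
    """Mean of max(0, signal - background) over the region of interest.

    ``background_level`` defaults to the median signal outside the ROI
    (the unstained surround).
    """
    sig = np.asarray(signal, dtype=float)
    mask = np.asarray(roi, dtype=bool)
    if sig.shape != mask.shape:
        raise ValueError("signal and roi shapes differ")
    if not mask.any():
        raise ValueError("region of interest is empty")
    if background_level is None:
        outside = sig[~mask]
        background_level = float(np.median(outside)) if outside.size else 0.0
    return float(np.maximum(sig[mask] - background_level, 0.0).mean())


def isolate_color(
    image: np.ndarray,
    target_rgb: tuple[int, int, int],
    fuzziness: float,
) -> np.ndarray:
    """Selective-color mask: Chebyshev distance to target within fuzziness."""
    arr = _validate_rgb(image).astype(np.int64)
    target = np.asarray(target_rgb, dtype=np.int64)
    if target.shape != (3,) or target.min() < 0 or target.max() > 255:
        raise ValueError("target_rgb must be three values in [0, 255]")
    if not 0 <= fuzziness <= 255:
        raise ValueError("fuzziness must be in [0, 255]")
    dist = np.abs(arr - target[None, None, :]).max(axis=2)
    return dist <= fuzziness
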