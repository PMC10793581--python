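"""Stimulus-image luminance normalization.

Object images on a transparent background are standardized so that, over the
visible region, mean pixel intensity and root-mean-square contrast take fixed
values (0.5 and 0.275 by default, on a 0–1 intensity scale).  This equates
mean luminance and contrast energy across the stimulus set so that decoding
differences cannot stem from trivial luminance cues.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["normalize_stimulus_image", "make_test_image"]

BACKGROUND = 0.5


def normalize_stimulus_image(
    image: np.ndarray,
    mask: np.ndarray,
    target_mean: float = 0.5,
    target_rms: float = 0.275,
) -> np.ndarray:
    """Affinely rescale the visible region to a fixed mean and RMS contrast.

    Parameters
    ----------
    image : 2-D array of intensities in [0, 1].
    mask : boolean array of the same shape, True over the visible region.
    target_mean : desired mean intensity of the visible region.
    target_rms : desired root-mean-square deviation from that mean.

    Returns
    -------
    A new image in which masked pixels satisfy ``mean == target_mean`` and
    ``rms == target_rms`` exactly (up to floating point), and unmasked pixels
    are set to the background gray level 0.5.  The transform is affine in
    pixel values; results falling outside [0, 1] are clipped with a warning.
    """
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if img.ndim != 2 or m.shape != img.shape:
        raise ValueError("image must be 2-D and mask must match its shape")
    if m.sum() < 2:
        raise ValueError("mask must select at least 2 pixels")

    vis = img[m]
    mu = vis.mean()
    rms = np.sqrt(np.mean((vis - mu) ** 2))
    if rms == 0.0:
        if target_rms > 0.0:
            raise ValueError(
                "visible region is constant: RMS contrast undefined for target_rms > 0"
            )
        scale = 0.0
    else:
        scale = target_rms / rms

    out = np.full_like(img, BACKGROUND)
    out[m] = target_mean + scale * (vis - mu)

    n_clip = int(np.sum((out[m] < 0.0) | (out[m] > 1.0)))
    if n_clip:
        warnings.warn(
            f"normalization pushed {n_clip} pixel(s) outside [0, 1]; clipping",
            RuntimeWarning,
            stacklevel=2,
        )
        out = np.clip(out, 0.0, 1.0)
    return out


def make_test_image(size: int = 160, radius_frac: float = 0.4) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic object image: an oblique grating inside a disk aperture.

    Returns ``(image, mask)`` where the mask marks the disk interior.  A
    stand-in for the object photographs, which are not redistributable; the
    sinusoidal luminance profile keeps the standardized pixel values within
    the range where normalization to RMS contrast 0.275 needs no clipping.
    """
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    r = np.hypot(yy - c, xx - c)
    mask = r <= radius_frac * size
    image = 0.5 + 0.25 * np.sin(2.0 * np.pi * (xx + 0.6 * yy) / (0.22 * size))
    return image, mask
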