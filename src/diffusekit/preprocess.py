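"""Per-frame cleaning: static masking, windowed outlier rejection,
exposure-scaled background subtraction, Bragg-pixel flagging and median
replacement.

All statistics respect the frame mask (True = usable pixel).  Masks only
grow as steps are applied; median replacement preserves the mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

logger = logging.getLogger(__name__)

__all__ = [
    "DetectorFrame",
    "static_mask",
    "windowed_outlier_mask",
    "subtract_background",
    "flag_bragg_pixels",
    "replace_bragg_with_median",
]


@dataclass
class DetectorFrame:
    """One exposure: photon counts, usable-pixel mask, exposure metadata.

    A background frame uses the same type, paired to its crystal frame by
    ``frame_index``.
    """

    intensities: np.ndarray
    mask: np.ndarray = None
    exposure_time: float = 1.0
    frame_index: int = 0
    spindle_angle: float = 0.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if not np.issubdtype(self.intensities.dtype, np.floating):
            self.intensities = self.intensities.astype(np.float32)
        if self.mask is None:
            self.mask = np.ones(self.intensities.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.intensities.shape:
            raise ValueError("mask shape mismatch")
        if self.exposure_time <= 0:
            raise ValueError("exposure_time must be positive")

    def copy(self) -> "DetectorFrame":
        return DetectorFrame(
            self.intensities.copy(),
            self.mask.copy(),
            self.exposure_time,
            self.frame_index,
            self.spindle_angle,
        )


def static_mask(
    frame: DetectorFrame,
    saturation: float = 10_000.0,
    user_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mask user regions plus non-positive or saturated raw intensities.

    Pixels with I <= 0 or I > ``saturation`` (default 10 000 photons) are
    rejected; ``user_mask`` (True = usable) covers panel gaps, beamstop
    and shadows.  Returns the new mask (does not modify the frame).
    """
    mask = frame.mask.copy()
    if user_mask is not None:
        mask &= np.asarray(user_mask, dtype=bool)
    mask &= frame.intensities > 0
    mask &= frame.intensities <= saturation
    if not mask.any():
        raise ValueError("static mask rejected every pixel")
    return mask


def _window_moments(values: np.ndarray, mask: np.ndarray, window: int):
    """Mask-aware windowed count, mean and variance with truncated borders."""
    m = mask.astype(np.float64)
    # shift by the global masked mean before squaring: variance is shift
    # invariant and this avoids cancellation in s2/cnt - mean^2
    offset = float(values[mask].mean()) if mask.any() else 0.0
    v = np.where(mask, values - offset, 0.0)
    # uniform_filter with constant padding sums zeros outside => truncated
    # windows at the borders, no invented data.
    scale = float(window * window)
    cnt = uniform_filter(m, size=window, mode="constant", cval=0.0) * scale
    s1 = uniform_filter(v, size=window, mode="constant", cval=0.0) * scale
    s2 = uniform_filter(v * v, size=window, mode="constant", cval=0.0) * scale
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / cnt
        var = s2 / cnt - mean ** 2
    var = np.clip(var, 0.0, None)
    return cnt, mean + offset, var


def windowed_outlier_mask(
    frame: DetectorFrame,
    window: int = 11,
    nsigma: float = 5.0,
) -> np.ndarray:
    """Mask pixels deviating > ``nsigma`` standard deviations from their
    window mean (default 11x11 window, 5 sigma).

    Window statistics include the center pixel and use only currently
    unmasked pixels; borders use truncated windows.  Windows whose sd is
    zero mask nothing (constant regions are clean by construction), and
    windows with fewer than 2 usable pixels leave the pixel unmasked.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    cnt, mean, var = _window_moments(frame.intensities, frame.mask, window)
    sd = np.sqrt(var)
    usable = frame.mask & (cnt >= 2)
    n_thin = int((frame.mask & ~(cnt >= 2)).sum())
    if n_thin:
        logger.info("windowed_outlier_mask: %d pixels had <2 usable neighbors", n_thin)
    dev = np.abs(frame.intensities - mean)
    outlier = usable & (sd > 0) & (dev > nsigma * sd)
    return frame.mask & ~outlier


def subtract_background(frame: DetectorFrame, background: DetectorFrame) -> DetectorFrame:
    """Exposure-scaled, frame-by-frame background subtraction.

    I <- I_crystal - (t_crystal / t_background) * I_background.  Masks
    are united; negative results are retained (unbiased merging).
    """
    if background is None:
        raise ValueError("background frame required for subtraction")
    if background.intensities.shape != frame.intensities.shape:
        raise ValueError("background shape mismatch")
    ratio = frame.exposure_time / background.exposure_time
    out = frame.copy()
    out.intensities = frame.intensities - ratio * background.intensities
    out.mask = frame.mask & background.mask
    return out


def flag_bragg_pixels(fractional_hkl: np.ndarray, delta: float = 0.25) -> np.ndarray:
    """True where all of (h, k, l) lie within ``delta`` of integers.

    ``fractional_hkl`` has shape (..., 3); comparison is inclusive
    (offset exactly ``delta`` is flagged).
    """
    hkl = np.asarray(fractional_hkl)
    off = np.abs(hkl - np.round(hkl))
    return np.max(off, axis=-1) <= delta


def replace_bragg_with_median(
    frame: DetectorFrame,
    bragg_flags: np.ndarray,
    window: int = 11,
) -> DetectorFrame:
    """Replace each flagged pixel with the median of unflagged, unmasked
    pixels in the surrounding window (default 11x11).

    A flagged pixel whose window holds no usable pixel is masked instead.
    The merge stage additionally rejects by reciprocal-space box, so the
    pipeline may also run in reject mode (mask flagged pixels outright).
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    flags = np.asarray(bragg_flags, dtype=bool)
    out = frame.copy()
    idx = np.argwhere(flags)
    if idx.size == 0:
        return out
    half = window // 2
    padded = np.pad(frame.intensities, half, constant_values=np.nan)
    good = frame.mask & ~flags
    padded_good = np.pad(good, half, constant_values=False)
    offs = np.arange(-half, half + 1)
    dr, dc = np.meshgrid(offs, offs, indexing="ij")
    dr = dr.ravel()
    dc = dc.ravel()
    # gather windows only for flagged pixels; padded coords are idx + half
    rows = idx[:, 0, None] + half + dr[None, :]
    cols = idx[:, 1, None] + half + dc[None, :]
    vals = padded[rows, cols]
    ok = padded_good[rows, cols]
    vals = np.where(ok, vals, np.nan)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(vals, axis=1)
    empty = ~np.isfinite(med)
    out.intensities[idx[:, 0], idx[:, 1]] = np.where(empty, 0.0, med)
    if empty.any():
        out.mask[idx[empty, 0], idx[empty, 1]] = False
    return out
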