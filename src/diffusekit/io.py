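"""Frame-stack and mask I/O: HDF5 stacks (primary) and per-frame TIFF.

Layout of an HDF5 stack: dataset ``data`` of shape (n_frames, fast,
slow), optional ``mask`` (same shape or a single 2D map, nonzero =
usable), and attributes ``exposure_time`` (scalar or per-frame) and
``spindle_angles``.  Pixel indices are 0-based with the fast axis first.
"""

from __future__ import annotations

import h5py
import numpy as np
import tifffile

from .preprocess import DetectorFrame

__all__ = ["write_frame_stack", "read_frame_stack", "read_tiff_frames", "write_mask", "read_mask"]


def write_frame_stack(path, frames: list[DetectorFrame]) -> None:
    data = np.stack([f.intensities for f in frames])
    mask = np.stack([f.mask for f in frames]).astype(np.uint8)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=data, compression="gzip", compression_opts=1)
        fh.create_dataset("mask", data=mask, compression="gzip", compression_opts=1)
        fh.attrs["exposure_time"] = [f.exposure_time for f in frames]
        fh.attrs["spindle_angles"] = [f.spindle_angle for f in frames]


def read_frame_stack(path) -> list[DetectorFrame]:
    with h5py.File(path, "r") as fh:
        data = fh["data"][...]
        mask = fh["mask"][...] if "mask" in fh else None
        exp = np.atleast_1d(fh.attrs.get("exposure_time", 1.0))
        ang = np.atleast_1d(fh.attrs.get("spindle_angles", np.zeros(len(data))))
    frames = []
    for i in range(len(data)):
        m = None
        if mask is not None:
            m = (mask[i] if mask.ndim == 3 else mask) != 0
        frames.append(DetectorFrame(
            data[i], m,
            float(exp[i % len(exp)]), i, float(ang[i % len(ang)]),
        ))
    return frames


def read_tiff_frames(paths, exposure_time=1.0, spindle_angles=None) -> list[DetectorFrame]:
    frames = []
    for i, p in enumerate(paths):
        ang = 0.0 if spindle_angles is None else float(spindle_angles[i])
        frames.append(DetectorFrame(tifffile.imread(p), None, exposure_time, i, ang))
    return frames


def write_mask(path, mask: np.ndarray) -> None:
    np.savetxt(path, np.asarray(mask, dtype=np.uint8), fmt="%d")


def read_mask(path) -> np.ndarray:
    return np.loadtxt(path, dtype=int) != 0
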