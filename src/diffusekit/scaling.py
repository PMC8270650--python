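"""Per-frame scale factors and radial-profile variance removal.

Four scale-factor methods are supported: ``radial_profile`` (least-squares
match of each frame's radial intensity profile to a fixed reference frame,
the standard), ``water_ring`` and ``overall`` (ratios of mean intensity in
a resolution region), and ``bragg`` (factors imported from an external
Bragg-scaling report).  Residual frame-to-frame isotropic variation is
then removed by subtracting the projection of each scaled radial profile
onto the leading principal components of the profile matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "RadialProfile",
    "ScaleSet",
    "radial_profile",
    "scale_factor",
    "read_bragg_scale_report",
    "remove_radial_variance",
]


@dataclass
class RadialProfile:
    """Mean intensity vs |q| (A^-1): bin centers, means, pixel counts."""

    bin_centers: np.ndarray
    mean: np.ndarray
    count: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return self.count > 0


@dataclass
class ScaleSet:
    """Per-frame scale factors produced by one method."""

    method: str
    factors: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0):
            raise ValueError("scale factors must be positive")


def default_bins(q_max: float, n_bins: int = 200) -> np.ndarray:
    """Uniform |q| bin edges from 0 to the resolution cutoff."""
    return np.linspace(0.0, q_max, n_bins + 1)


def radial_profile(
    intensities: np.ndarray,
    mask: np.ndarray,
    qmag: np.ndarray,
    bin_edges: np.ndarray,
) -> RadialProfile:
    """Masked mean intensity in |q| bins (empty bins carry NaN means)."""
    q = np.asarray(qmag).ravel()
    v = np.asarray(intensities, dtype=float).ravel()
    m = np.asarray(mask, dtype=bool).ravel()
    nb = len(bin_edges) - 1
    idx = np.digitize(q, bin_edges) - 1
    ok = m & (idx >= 0) & (idx < nb)
    cnt = np.bincount(idx[ok], minlength=nb).astype(float)
    tot = np.bincount(idx[ok], weights=v[ok], minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, tot / np.where(cnt == 0, 1, cnt), np.nan)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    return RadialProfile(centers, mean, cnt)


def _region_mean(intensities, mask, qmag, d_range):
    d_lo, d_hi = max(d_range), min(d_range)  # d-spacings, decreasing
    sel = np.asarray(mask, bool) & (qmag >= 1.0 / d_lo) & (qmag <= 1.0 / d_hi)
    if not sel.any():
        raise ValueError("no usable pixels in resolution region")
    return float(np.asarray(intensities, float)[sel].mean())


def scale_factor(
    intensities: np.ndarray,
    mask: np.ndarray,
    qmag: np.ndarray,
    reference: "RadialProfile | tuple",
    method: str = "radial_profile",
    bin_edges: np.ndarray | None = None,
    water_ring: tuple[float, float] = (5.0, 1.82),
    resolution_limit: float = 1.4,
) -> float:
    """Multiplicative factor bringing this frame onto the reference scale.

    * ``radial_profile``: s = argmin_s sum_bins (s p_frame - p_ref)^2
      = <p_frame, p_ref> / <p_frame, p_frame> over bins valid in both,
      within the resolution range.  ``reference`` is the reference
      frame's RadialProfile (the first frame of the series; its own
      factor is 1).
    * ``water_ring``: mean_ref / mean_frame over the water-ring region
      (default 5-1.82 A).  ``reference`` is (ref_intensities, ref_mask)
      or a precomputed reference mean (float).
    * ``overall``: same ratio over the full resolution range (d >=
      ``resolution_limit``).
    * ``bragg``: not computed here; use :func:`read_bragg_scale_report`.
    """
    if method == "radial_profile":
        if bin_edges is None:
            raise ValueError("radial_profile method needs bin_edges")
        prof = radial_profile(intensities, mask, qmag, bin_edges)
        ref: RadialProfile = reference
        ok = prof.valid & ref.valid & (prof.bin_centers <= 1.0 / resolution_limit)
        pf = prof.mean[ok]
        pr = ref.mean[ok]
        denom = float(pf @ pf)
        if denom <= 0:
            raise ValueError("degenerate frame profile")
        return float(pf @ pr) / denom
    if method in ("water_ring", "overall"):
        d_range = water_ring if method == "water_ring" else (np.inf, resolution_limit)
        if isinstance(reference, (int, float)):
            ref_mean = float(reference)
        else:
            ref_mean = _region_mean(reference[0], reference[1], qmag, d_range)
        frame_mean = _region_mean(intensities, mask, qmag, d_range)
        if frame_mean <= 0:
            raise ValueError("non-positive frame mean in scaling region")
        return ref_mean / frame_mean
    raise ValueError(f"unknown scale method {method!r}")


def read_bragg_scale_report(path, n_frames: int | None = None) -> ScaleSet:
    """Import per-frame Bragg scale factors from a two-column text file
    (frame index, factor), as produced by an external Bragg-scaling
    program."""
    data = np.loadtxt(path, ndmin=2)
    idx = data[:, 0].astype(int)
    fac = np.empty(idx.max() + 1 if n_frames is None else n_frames)
    fac.fill(np.nan)
    fac[idx] = data[:, 1]
    if np.any(~np.isfinite(fac)):
        raise ValueError("Bragg scale report does not cover every frame")
    return ScaleSet("bragg", fac)


def remove_radial_variance(
    profiles: np.ndarray,
    n_components: int = 3,
):
    """Principal-component subtraction on the matrix of scaled radial
    profiles.

    ``profiles`` is (n_frames, n_bins), rows already multiplied by the
    per-frame scale factors.  The rows are mean-centered across frames,
    the top ``n_components`` principal components of the centered matrix
    are found, and each row's reconstruction in that subspace is
    returned as the per-frame radial correction (same shape).  The mean
    profile is retained — the isotropic component proper is removed
    later in reciprocal space.

    Subtract the returned correction from each frame's pixels according
    to |q| (linear interpolation between bin centers; see
    ``apply_radial_correction``).  ``n_components = 0`` returns zeros.
    Bins with any NaN across frames are ignored (zero correction there).
    """
    profiles = np.asarray(profiles, dtype=float)
    n_frames, n_bins = profiles.shape
    if n_components == 0:
        return np.zeros_like(profiles)
    if n_frames < n_components + 1:
        raise ValueError("need more frames than components")
    good = np.all(np.isfinite(profiles), axis=0)
    correction = np.zeros_like(profiles)
    if good.sum() <= n_components:
        return correction
    sub = profiles[:, good]
    if np.allclose(sub, sub.mean(axis=0), atol=1e-12):
        return correction
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(sub)  # centered projections
    recon = scores @ pca.components_  # deviation captured by the subspace
    correction[:, good] = recon
    return correction


def apply_radial_correction(
    intensities: np.ndarray,
    qmag: np.ndarray,
    bin_centers: np.ndarray,
    correction_row: np.ndarray,
    interpolation: str = "linear",
) -> np.ndarray:
    """Subtract a per-bin radial correction from every pixel by |q|.

    ``interpolation`` is ``linear`` (between bin centers, avoids ring
    artifacts) or ``nearest``.
    """
    corr = np.nan_to_num(correction_row, nan=0.0)
    if interpolation == "linear":
        per_pixel = np.interp(qmag, bin_centers, corr)
    elif interpolation == "nearest":
        idx = np.clip(
            np.searchsorted(
                0.5 * (bin_centers[:-1] + bin_centers[1:]), qmag
            ),
            0,
            len(bin_centers) - 1,
        )
        per_pixel = corr[idx]
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return intensities - per_pixel
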