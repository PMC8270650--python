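"""3D reciprocal-space diffuse volume: merging, Laue/Friedel
symmetrization, isotropic subtraction, completeness, and I/O.

The volume samples integer Miller indices H, K, L in [-hmax, hmax]
(default 121^3 grid, hmax = 60), optionally oversampled for
visualization.  Each voxel stores the running intensity sum and the
observation count; the mean is defined only where the count is
positive.  Voxel |q| = 1/d comes from the reciprocal metric tensor of
the unit cell (monoclinic-safe).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "ShellScheme",
    "DiffuseVolume",
    "merge_frames_into",
    "symmetrize",
    "subtract_isotropic",
    "completeness",
]

# Laue-group orbits as axis-flip maps on the centrosymmetric integer grid.
# 2/m is given for unique axis b: (h,k,l), (-h,k,-l), (-h,-k,-l), (h,-k,l).
_LAUE_FLIPS = {
    "-1": [(), (0, 1, 2)],
    "2/m": [(), (0, 2), (0, 1, 2), (1,)],
}


def _apply_flips(arr: np.ndarray, axes: tuple) -> np.ndarray:
    return np.flip(arr, axis=axes) if axes else arr


@dataclass
class ShellScheme:
    """Resolution shells: boundaries as d-spacings (A), strictly decreasing.

    ``equal_volume`` builds shells of equal reciprocal-space volume
    (uniform in |q|^3) from infinity down to ``d_min``; ``uniform_q``
    builds shells uniform in |q|.
    """

    d_edges: np.ndarray

    def __post_init__(self) -> None:
        self.d_edges = np.asarray(self.d_edges, dtype=float)
        if np.any(np.diff(self.d_edges) >= 0):
            raise ValueError("shell boundaries must be strictly decreasing in d")

    @classmethod
    def equal_volume(cls, d_min: float = 1.4, n_shells: int = 15) -> "ShellScheme":
        q_max = 1.0 / d_min
        q_edges = q_max * (np.arange(n_shells + 1) / n_shells) ** (1.0 / 3.0)
        with np.errstate(divide="ignore"):
            d = 1.0 / q_edges
        return cls(d)

    @classmethod
    def uniform_q(cls, d_min: float = 1.4, n_shells: int = 100) -> "ShellScheme":
        q_edges = np.linspace(0.0, 1.0 / d_min, n_shells + 1)
        with np.errstate(divide="ignore"):
            d = 1.0 / q_edges
        return cls(d)

    @property
    def q_edges(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return 1.0 / self.d_edges

    @property
    def n_shells(self) -> int:
        return len(self.d_edges) - 1

    def assign(self, qmag: np.ndarray) -> np.ndarray:
        """Shell index per value (-1 outside the scheme)."""
        idx = np.digitize(qmag, self.q_edges) - 1
        idx[(idx < 0) | (idx >= self.n_shells)] = -1
        return idx


@dataclass
class DiffuseVolume:
    """Merged intensities over integer-sampled Miller indices.

    ``sum`` and ``count`` have shape (n, n, n) with n = 2*hmax*oversample
    + 1 (odd, so the origin voxel exists); axis order is (H, K, L) and
    index 0 corresponds to -hmax.
    """

    hmax: int
    cell: gemmi.UnitCell
    laue_group: str = "2/m"
    oversample: int = 1
    sum: np.ndarray = None
    count: np.ndarray = None

    def __post_init__(self) -> None:
        n = 2 * self.hmax * self.oversample + 1
        if self.sum is None:
            self.sum = np.zeros((n, n, n))
        if self.count is None:
            self.count = np.zeros((n, n, n))
        if self.laue_group not in _LAUE_FLIPS:
            raise ValueError(f"unsupported Laue group {self.laue_group!r} (only -1 and 2/m)")

    @property
    def n(self) -> int:
        return self.sum.shape[0]

    def mean(self) -> np.ndarray:
        """Per-voxel mean intensity; NaN where unobserved."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.count > 0, self.sum / np.where(self.count == 0, 1, self.count), np.nan)

    def index_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Miller index value along each axis (fractional if oversampled)."""
        ax = (np.arange(self.n) - self.hmax * self.oversample) / self.oversample
        return np.meshgrid(ax, ax, ax, indexing="ij")

    def qmag(self) -> np.ndarray:
        """|q| = 1/d per voxel from the reciprocal metric tensor."""
        ax = (np.arange(self.n) - self.hmax * self.oversample) / self.oversample
        # reciprocal cell vectors as rows of B = inv(orth)^T
        orth = np.array(self.cell.orth.mat.tolist())
        bstar = np.linalg.inv(orth)  # rows are a*, b*, c* in Cartesian
        g = bstar @ bstar.T  # reciprocal metric tensor
        h, k, l = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
        q2 = (
            g[0, 0] * h * h + g[1, 1] * k * k + g[2, 2] * l * l
            + 2 * (g[0, 1] * h * k + g[0, 2] * h * l + g[1, 2] * k * l)
        )
        return np.sqrt(q2)

    def copy(self) -> "DiffuseVolume":
        return DiffuseVolume(
            self.hmax, self.cell, self.laue_group, self.oversample,
            self.sum.copy(), self.count.copy(),
        )

    # -- I/O ---------------------------------------------------------------

    def write_hkl_table(self, path) -> None:
        """Plain-text (H K L mean count) table of observed voxels."""
        mean = self.mean()
        obs = self.count > 0
        h, k, l = self.index_grids()
        with open(path, "w") as fh:
            fh.write(f"# cell {self.cell.a} {self.cell.b} {self.cell.c} "
                     f"{self.cell.alpha} {self.cell.beta} {self.cell.gamma}\n")
            fh.write(f"# laue {self.laue_group} hmax {self.hmax} oversample {self.oversample}\n")
            fh.write("#   H       K       L            I        count\n")
            for hv, kv, lv, iv, cv in zip(
                h[obs], k[obs], l[obs], mean[obs], self.count[obs]
            ):
                fh.write(f"{hv:8.3f}{kv:8.3f}{lv:8.3f} {iv:16.8g} {cv:10.1f}\n")

    @classmethod
    def read_hkl_table(cls, path) -> "DiffuseVolume":
        with open(path) as fh:
            lines = fh.readlines()
        cell_vals = [float(x) for x in lines[0].split()[2:8]]
        toks = lines[1].split()
        laue = toks[2]
        hmax = int(toks[4])
        ov = int(toks[6])
        vol = cls(hmax, gemmi.UnitCell(*cell_vals), laue, ov)
        data = np.loadtxt(lines[3:], ndmin=2) if len(lines) > 3 else np.empty((0, 5))
        if data.size:
            off = hmax * ov
            hi = np.round(data[:, 0] * ov).astype(int) + off
            ki = np.round(data[:, 1] * ov).astype(int) + off
            li = np.round(data[:, 2] * ov).astype(int) + off
            vol.sum[hi, ki, li] = data[:, 3] * data[:, 4]
            vol.count[hi, ki, li] = data[:, 4]
        return vol

    def write_ccp4(self, path) -> None:
        """CCP4/MRC map of voxel means (unobserved voxels written as 0)."""
        mean = np.nan_to_num(self.mean(), nan=0.0).astype(np.float32)
        grid = gemmi.FloatGrid(np.ascontiguousarray(mean))
        grid.set_unit_cell(self.cell)
        m = gemmi.Ccp4Map()
        m.grid = grid
        m.update_ccp4_header()
        m.write_ccp4_map(str(path))


def merge_frames_into(
    volume: DiffuseVolume,
    fractional_hkl: np.ndarray,
    intensities: np.ndarray,
    mask: np.ndarray,
    bragg_delta: float = 0.25,
) -> dict:
    """Accumulate one frame's usable pixels into the voxel grid.

    Every pixel whose fractional indices lie within the
    ``2*bragg_delta`` box around an integer point (max offset <=
    ``bragg_delta``, i.e. the 0.5^3 Bragg exclusion box) is rejected
    regardless of earlier median replacement.  Pixels mapping outside
    the grid fall out silently but are tallied in the returned report.
    """
    hkl = np.asarray(fractional_hkl, dtype=float).reshape(-1, 3)
    v = np.asarray(intensities, dtype=float).ravel()
    m = np.asarray(mask, dtype=bool).ravel()

    off = np.abs(hkl - np.round(hkl))
    not_bragg = np.max(off, axis=1) > bragg_delta
    use = m & not_bragg

    ov = volume.oversample
    idx = np.round(hkl[use] * ov).astype(np.int64)
    lim = volume.hmax * ov
    inside = np.all(np.abs(idx) <= lim, axis=1)
    n_outside = int((~inside).sum())
    idx = idx[inside] + lim
    vals = v[use][inside]

    n = volume.n
    flat = (idx[:, 0] * n + idx[:, 1]) * n + idx[:, 2]
    volume.sum.ravel()[:] += np.bincount(flat, weights=vals, minlength=n ** 3)
    volume.count.ravel()[:] += np.bincount(flat, minlength=n ** 3)
    return {
        "n_pixels": int(m.sum()),
        "n_bragg_rejected": int((m & ~not_bragg).sum()),
        "n_outside_grid": n_outside,
        "n_merged": int(vals.size),
    }


def symmetrize(volume: DiffuseVolume, mode: str = "laue") -> DiffuseVolume:
    """Count-weighted orbit averaging (Friedel inversion pair or the
    four-member 2/m orbit).  Empty orbit members are ignored; output
    counts are orbit count sums, so averaging pools the underlying pixel
    observations exactly.  Idempotent."""
    if mode == "friedel":
        flips = _LAUE_FLIPS["-1"]
    elif mode == "laue":
        flips = _LAUE_FLIPS[volume.laue_group]
    else:
        raise ValueError(f"unknown symmetrization mode {mode!r}")
    s = np.zeros_like(volume.sum)
    c = np.zeros_like(volume.count)
    for axes in flips:
        s += _apply_flips(volume.sum, axes)
        c += _apply_flips(volume.count, axes)
    return DiffuseVolume(
        volume.hmax, volume.cell, volume.laue_group, volume.oversample, s, c
    )


def subtract_isotropic(
    volume: DiffuseVolume,
    shells: ShellScheme | None = None,
    interpolation: str = "linear",
) -> DiffuseVolume:
    """Remove the radially averaged component, leaving the anisotropic map.

    The radial average is estimated as the count-weighted mean over |q|
    shells (default: 100 shells uniform in |q| to the grid's maximum),
    interpolated to each voxel's |q| (linearly between shell centers, or
    ``nearest``), and subtracted.  A final exact pass removes each
    shell's residual count-weighted mean, so every shell's
    observation-weighted mean is zero to machine precision.  Shells with
    no observations are bridged by the interpolation.
    """
    qmag = volume.qmag()
    if shells is None:
        q_max = float(qmag.max())
        q_edges = np.linspace(0.0, q_max * (1 + 1e-9), 101)
    else:
        q_edges = shells.q_edges.copy()
    nb = len(q_edges) - 1
    mean = volume.mean()
    obs = volume.count > 0
    idx = np.digitize(qmag, q_edges) - 1
    # voxels outside the scheme still receive the interpolated radial
    # estimate but are excluded from shell statistics (same binning rule
    # as ShellScheme.assign)
    in_scheme = (idx >= 0) & (idx < nb)
    obs_in = obs & in_scheme

    w = volume.count[obs_in]
    b = idx[obs_in]
    vals = mean[obs_in]
    wsum = np.bincount(b, weights=w, minlength=nb)
    vsum = np.bincount(b, weights=w * vals, minlength=nb)
    qsum = np.bincount(b, weights=w * qmag[obs_in], minlength=nb)
    have = wsum > 0
    shell_mean = vsum[have] / wsum[have]
    shell_q = qsum[have] / wsum[have]

    out = volume.copy()
    if interpolation == "linear":
        radial = np.interp(qmag[obs_in], shell_q, shell_mean)
    elif interpolation == "nearest":
        pos = np.clip(np.searchsorted(0.5 * (shell_q[:-1] + shell_q[1:]), qmag[obs_in]),
                      0, len(shell_q) - 1)
        radial = shell_mean[pos]
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    new_vals = vals - radial
    # exact pass: zero each shell's count-weighted mean
    rsum = np.bincount(b, weights=w * new_vals, minlength=nb)
    resid = np.zeros(nb)
    resid[have] = rsum[have] / wsum[have]
    out.sum[obs_in] = (new_vals - resid[b]) * w
    stray = obs & ~in_scheme
    if stray.any():
        rad_stray = np.interp(qmag[stray], shell_q, shell_mean)
        out.sum[stray] = (mean[stray] - rad_stray) * volume.count[stray]
    return out


def completeness(
    volume: DiffuseVolume,
    shells: ShellScheme,
) -> tuple[np.ndarray, float]:
    """Fraction of symmetry-unique voxels observed, per shell and overall.

    A unique voxel is an orbit of the volume's Laue group on the integer
    grid; it counts as observed when any orbit member has count > 0.
    """
    flips = _LAUE_FLIPS[volume.laue_group]
    obs = volume.count > 0
    orbit_obs = np.zeros_like(obs)
    for axes in flips:
        orbit_obs |= _apply_flips(obs, axes)
    # canonical representative: voxel with max flattened orbit index
    n = volume.n
    base = np.arange(n ** 3).reshape(n, n, n)
    canon = base.copy()
    for axes in flips:
        canon = np.maximum(canon, _apply_flips(base, axes))
    is_rep = base == canon

    qmag = volume.qmag()
    sel = is_rep & (qmag <= shells.q_edges[-1])
    shell_idx = shells.assign(qmag[sel])
    seen = orbit_obs[sel]
    nb = shells.n_shells
    tot = np.bincount(shell_idx[shell_idx >= 0], minlength=nb).astype(float)
    hit = np.bincount(shell_idx[(shell_idx >= 0) & seen], minlength=nb).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_shell = np.where(tot > 0, hit / np.where(tot == 0, 1, tot), np.nan)
    overall = float(hit.sum() / tot.sum()) if tot.sum() else float("nan")
    return per_shell, overall
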