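"""Map-quality correlation metrics: CC_Friedel, CC_Laue, CC_1/2, CC_Rep,
CC_Cross, overall and per resolution shell.

All metrics are centered Pearson correlations over the voxels observed in
both operands, computed on anisotropic (isotropic-subtracted) maps.  For
an i.i.d. random map, correlating the map with its own orbit average of
size m inflates the CC to 1/sqrt(m) — about 0.7 for a Friedel pair —
which is why the symmetry metrics are complemented by the half-set
(CC_1/2) and replicate (CC_Rep) statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import DiffuseVolume, ShellScheme, _LAUE_FLIPS, _apply_flips, symmetrize

__all__ = [
    "CCReport",
    "pearson_cc",
    "cc_volumes",
    "cc_symmetry",
    "cc_half",
    "cc_rep",
    "cc_cross",
]


@dataclass
class CCReport:
    """One metric: overall value, per-shell values and voxel counts."""

    metric: str
    overall: float
    shells: ShellScheme | None = None
    per_shell: np.ndarray | None = None
    n_per_shell: np.ndarray | None = None
    companions: list = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {"metric": self.metric, "overall": self.overall}
        if self.per_shell is not None:
            d["per_shell"] = [None if not np.isfinite(v) else float(v) for v in self.per_shell]
            d["n_per_shell"] = [int(n) for n in self.n_per_shell]
            d["d_edges"] = [float(x) for x in self.shells.d_edges]
        if self.companions:
            d["companions"] = list(self.companions)
        return d


def pearson_cc(x: np.ndarray, y: np.ndarray) -> float:
    """Centered Pearson correlation; NaN (undefined) on zero variance or
    fewer than 3 points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc @ xc) * (yc @ yc))
    if den == 0:
        return float("nan")
    return float((xc @ yc) / den)


def _shelled_cc(x, y, qmag, shells: ShellScheme | None, metric: str) -> CCReport:
    overall = pearson_cc(x, y)
    if shells is None:
        return CCReport(metric, overall)
    idx = shells.assign(qmag)
    nb = shells.n_shells
    per = np.full(nb, np.nan)
    npts = np.zeros(nb, dtype=int)
    for b in range(nb):
        sel = idx == b
        npts[b] = int(sel.sum())
        if npts[b] >= 3:
            per[b] = pearson_cc(x[sel], y[sel])
    return CCReport(metric, overall, shells, per, npts)


def cc_volumes(
    a: DiffuseVolume,
    b: DiffuseVolume,
    shells: ShellScheme | None = None,
    d_max: float | None = None,
    metric: str = "CC",
) -> CCReport:
    """Pearson CC between two volumes over common observed voxels within
    the shell scheme's resolution range (optionally excluding d >
    ``d_max``)."""
    if a.sum.shape != b.sum.shape:
        raise ValueError("incompatible grids")
    qmag = a.qmag()
    common = (a.count > 0) & (b.count > 0)
    if shells is not None:
        common &= qmag <= shells.q_edges[-1]
    if d_max is not None:
        common &= qmag >= 1.0 / d_max
    x = a.mean()[common]
    y = b.mean()[common]
    return _shelled_cc(x, y, qmag[common], shells, metric)


def cc_symmetry(
    volume: DiffuseVolume,
    mode: str = "friedel",
    shells: ShellScheme | None = None,
) -> CCReport:
    """CC between the unsymmetrized anisotropic map and its own
    Friedel-/Laue-symmetrized version (CC_Friedel / CC_Laue)."""
    sym = symmetrize(volume, mode)
    name = "CC_Friedel" if mode == "friedel" else "CC_Laue"
    return cc_volumes(volume, sym, shells, metric=name)


def cc_half(
    volume: DiffuseVolume,
    shells: ShellScheme | None = None,
    rng: np.random.Generator | int | None = None,
) -> CCReport:
    """Half-dataset correlation (CC_1/2) from symmetry redundancy.

    The observed orbit members of each symmetry-unique voxel of the
    unsymmetrized anisotropic map are randomly partitioned into two
    halves; the half means are correlated over unique voxels.  Voxels
    with fewer than two observed members are excluded.
    """
    rng = np.random.default_rng(rng)
    flips = _LAUE_FLIPS[volume.laue_group]
    n_ops = len(flips)
    mean = volume.mean()
    obs = volume.count > 0
    # stack orbit members along axis 0
    members = np.stack([_apply_flips(mean, axes) for axes in flips])
    present = np.stack([_apply_flips(obs, axes) for axes in flips])
    # unique-voxel representatives
    n = volume.n
    base = np.arange(n ** 3).reshape(n, n, n)
    canon = base.copy()
    for axes in flips:
        canon = np.maximum(canon, _apply_flips(base, axes))
    is_rep = base == canon
    multi = present.sum(axis=0) >= 2
    sel = is_rep & multi

    vals = members[:, sel]        # (n_ops, n_unique)
    have = present[:, sel]
    # random half assignment: rank a uniform draw within the observed
    # members of each orbit; first half = ranks below half the count
    u = rng.random(vals.shape)
    u[~have] = np.inf
    order = np.argsort(u, axis=0)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(n_ops)[:, None].repeat(vals.shape[1], 1), axis=0)
    cnt = have.sum(axis=0)
    first = ranks < np.ceil(cnt / 2)
    first &= have
    second = have & ~first
    with np.errstate(invalid="ignore", divide="ignore"):
        h1 = np.where(first, vals, 0.0).sum(axis=0) / first.sum(axis=0)
        h2 = np.where(second, vals, 0.0).sum(axis=0) / second.sum(axis=0)
    ok = np.isfinite(h1) & np.isfinite(h2)
    qmag = volume.qmag()[sel][ok]
    return _shelled_cc(h1[ok], h2[ok], qmag, shells, "CC_1/2")


def cc_rep(
    target: DiffuseVolume,
    replicates: list[DiffuseVolume],
    shells: ShellScheme | None = None,
    labels: list[str] | None = None,
    metric: str = "CC_Rep",
) -> CCReport:
    """Mean pairwise CC between the target map and replicate maps from
    independent crystals of the same form (Laue-symmetrized anisotropic
    maps, same grid)."""
    if not replicates:
        raise ValueError("need at least one replicate")
    reports = [cc_volumes(target, r, shells, metric=metric) for r in replicates]
    overall = float(np.mean([r.overall for r in reports]))
    out = CCReport(metric, overall, companions=labels or [])
    if shells is not None:
        per = np.stack([r.per_shell for r in reports])
        with np.errstate(invalid="ignore"):
            out.per_shell = np.nanmean(per, axis=0)
        out.n_per_shell = reports[0].n_per_shell
        out.shells = shells
    return out


def cc_cross(
    target: DiffuseVolume,
    other_form: list[DiffuseVolume],
    shells: ShellScheme | None = None,
    labels: list[str] | None = None,
) -> CCReport:
    """Mean pairwise CC against maps of a different sample form (same
    grid and Laue group); coincides with CC_Rep when the other form is
    the same sample."""
    return cc_rep(target, other_form, shells, labels, metric="CC_Cross")
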