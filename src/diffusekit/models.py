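"""Diffuse-intensity models: reference (Bragg) intensities from an atomic
model under three ADP treatments, the liquid-like motions (LLM) model,
the independent rigid-body translation (RBT) model, CC-target fitting,
and ADP utilities.

Model summary
-------------
The LLM assumes atomic displacement correlations decay exponentially with
distance, ``exp(-r/gamma)``.  Its 3D Fourier transform is the kernel

    Gamma_gamma(q) = 8 pi gamma^3 / (1 + gamma^2 q_rad^2)^2,

with ``q_rad = 2 pi |q|`` and ``|q| = 1/d``.  The diffuse intensity with
zero individual ADPs is

    I_d(q)  ~  sigma^2 q_rad^2 exp(-sigma^2 q_rad^2) [I_0(q) * Gamma(q)],

where ``I_0`` is the squared structure factor with all B-factors zeroed
and ``*`` is a convolution.  Keeping the individual ADPs (isotropic or
anisotropic) replaces ``I_0`` by ``I_B`` and the overall Debye-Waller
factor by unity,

    I_d(q)  ~  sigma^2 q_rad^2 [I_B(q) * Gamma(q)],

in which sigma only sets the overall scale.  The RBT model instead gives
``I_d(q) = I_0(q) (1 - exp(-sigma^2 q_rad^2))`` with no convolution.
Model maps are Laue-symmetrized and isotropic-subtracted exactly like
the data before any CC is computed, so the fit target (a Pearson CC,
scale-free) sees both maps processed identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy import fft as sp_fft
from scipy.optimize import minimize

from .metrics import pearson_cc
from .volume import DiffuseVolume, subtract_isotropic, symmetrize

logger = logging.getLogger(__name__)

__all__ = [
    "AtomicModel",
    "ModelFit",
    "reference_intensity",
    "llm_kernel",
    "grid_qmag",
    "convolve_periodic",
    "llm_intensity",
    "rbt_intensity",
    "process_model_map",
    "fit_model",
    "beq_from_u",
    "anisotropy_ratio",
    "traceless",
    "rescale_adps",
]

TWO_PI = 2.0 * np.pi
U_TO_B = 8.0 * np.pi ** 2  # B = 8 pi^2 U


# ---------------------------------------------------------------------------
# atomic model
# ---------------------------------------------------------------------------

@dataclass
class AtomicModel:
    """Atoms with positions, occupancies, altlocs and ADPs, plus cell and
    space group.

    ``frac`` are fractional coordinates (n, 3); ``u_cart`` are anisotropic
    U tensors (n, 3, 3) in the Cartesian A^2 convention of ANISOU records
    (NaN rows where absent); ``b_iso`` are isotropic B values (A^2).
    """

    elements: list
    frac: np.ndarray
    occ: np.ndarray
    altloc: list
    b_iso: np.ndarray
    u_cart: np.ndarray
    cell: gemmi.UnitCell
    spacegroup: str = "P 1"

    def __post_init__(self) -> None:
        self.frac = np.asarray(self.frac, dtype=float).reshape(-1, 3)
        n = len(self.frac)
        self.occ = np.asarray(self.occ, dtype=float).reshape(n)
        self.b_iso = np.asarray(self.b_iso, dtype=float).reshape(n)
        self.u_cart = np.asarray(self.u_cart, dtype=float).reshape(n, 3, 3)

    @property
    def n_atoms(self) -> int:
        return len(self.frac)

    @property
    def has_u(self) -> np.ndarray:
        return np.all(np.isfinite(self.u_cart), axis=(1, 2))

    def select_conformer(self, keep: str = "A") -> "AtomicModel":
        """Keep single-conformer atoms plus the ``keep`` altloc, with all
        occupancies reset to unity."""
        sel = [i for i, a in enumerate(self.altloc) if a in ("", " ", keep)]
        sel = np.asarray(sel, dtype=int)
        return AtomicModel(
            [self.elements[i] for i in sel],
            self.frac[sel],
            np.ones(len(sel)),
            [""] * len(sel),
            self.b_iso[sel],
            self.u_cart[sel],
            self.cell,
            self.spacegroup,
        )

    # -- PDB I/O (gemmi) ---------------------------------------------------

    @classmethod
    def from_pdb(cls, path) -> "AtomicModel":
        st = gemmi.read_structure(str(path))
        return cls.from_gemmi(st)

    @classmethod
    def from_gemmi(cls, st: gemmi.Structure) -> "AtomicModel":
        elements, fracs, occs, alts, bs, us = [], [], [], [], [], []
        for chain in st[0]:
            for res in chain:
                for at in res:
                    elements.append(at.element.name)
                    f = st.cell.fractionalize(at.pos)
                    fracs.append([f.x, f.y, f.z])
                    occs.append(at.occ)
                    alts.append(at.altloc.strip() if isinstance(at.altloc, str) else (at.altloc or ""))
                    bs.append(at.b_iso)
                    a = at.aniso
                    if a.nonzero():
                        us.append([[a.u11, a.u12, a.u13],
                                   [a.u12, a.u22, a.u23],
                                   [a.u13, a.u23, a.u33]])
                    else:
                        us.append(np.full((3, 3), np.nan))
        return cls(elements, np.array(fracs), np.array(occs), alts,
                   np.array(bs), np.array(us), st.cell,
                   st.spacegroup_hm or "P 1")

    def to_gemmi(self) -> gemmi.Structure:
        st = gemmi.Structure()
        st.cell = self.cell
        st.spacegroup_hm = self.spacegroup
        model = gemmi.Model("1")
        chain = gemmi.Chain("A")
        for i in range(self.n_atoms):
            res = gemmi.Residue()
            res.name = "DUM"
            res.seqid = gemmi.SeqId(i + 1, " ")
            at = gemmi.Atom()
            at.name = f"{self.elements[i]}{i % 100}"
            at.element = gemmi.Element(self.elements[i])
            at.pos = gemmi.Position(*self.cell.orthogonalize(gemmi.Fractional(*self.frac[i])).tolist())
            at.occ = float(self.occ[i])
            at.b_iso = float(self.b_iso[i])
            if np.all(np.isfinite(self.u_cart[i])):
                u = self.u_cart[i]
                at.aniso = gemmi.SMat33f(u[0, 0], u[1, 1], u[2, 2], u[0, 1], u[0, 2], u[1, 2])
            al = self.altloc[i]
            if al:
                at.altloc = al
            res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
        return st

    def to_pdb(self, path) -> None:
        self.to_gemmi().write_pdb(str(path))


@dataclass
class ModelFit:
    """Result of fitting an LLM or RBT model to a diffuse map."""

    kind: str
    adp_mode: str
    sigma: float
    gamma: float | None
    cc: float
    n_voxels: int
    trace: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "kind": self.kind,
            "adp_mode": self.adp_mode,
            "sigma": self.sigma,
            "gamma": self.gamma,
            "cc": self.cc,
            "n_voxels": self.n_voxels,
        }


# ---------------------------------------------------------------------------
# reference (Bragg) intensity on the voxel grid
# ---------------------------------------------------------------------------

def _form_factor_coeffs(elements):
    """IT92 four-Gaussian coefficients per atom: (a[4], b[4], c)."""
    a = np.empty((len(elements), 4))
    b = np.empty((len(elements), 4))
    c = np.empty(len(elements))
    for i, el in enumerate(elements):
        g = gemmi.Element(el)
        if g.atomic_number == 0:
            raise ValueError(f"unknown element {el!r}")
        it = g.it92
        a[i] = it.a
        b[i] = it.b
        c[i] = it.c
    return a, b, c


def _symmetry_expand(model: AtomicModel):
    """Fractional coordinates and Cartesian U tensors for the full unit
    cell (space-group ops applied to the given atoms)."""
    sg = gemmi.SpaceGroup(model.spacegroup)
    orth = np.array(model.cell.orth.mat.tolist())
    orth_inv = np.linalg.inv(orth)
    fracs, us, src = [], [], []
    u_filled = np.where(np.isfinite(model.u_cart), model.u_cart, 0.0)
    for op in sg.operations():
        r = np.array(op.rot, dtype=float) / op.DEN
        t = np.array(op.tran, dtype=float) / op.DEN
        rc = orth @ r @ orth_inv  # Cartesian rotation of this op
        fracs.append(model.frac @ r.T + t)
        us.append(np.einsum("ab,nbc,dc->nad", rc, u_filled, rc))
        src.append(np.arange(model.n_atoms))
    return np.concatenate(fracs), np.concatenate(us), np.concatenate(src)


def grid_qmag(cell: gemmi.UnitCell, hmax: int, offset=None) -> np.ndarray:
    """|q| = 1/d on the integer grid via the reciprocal metric tensor
    (memory-light: no per-voxel q vectors), optionally for indices
    shifted by ``offset``."""
    ax = np.arange(-hmax, hmax + 1, dtype=float)
    orth = np.array(cell.orth.mat.tolist())
    bstar = np.linalg.inv(orth)
    g = bstar @ bstar.T
    if offset is not None:
        h = (ax - offset[0])[:, None, None]
        k = (ax - offset[1])[None, :, None]
        l = (ax - offset[2])[None, None, :]
    else:
        h = ax[:, None, None]
        k = ax[None, :, None]
        l = ax[None, None, :]
    q2 = (g[0, 0] * h * h + g[1, 1] * k * k + g[2, 2] * l * l
          + 2 * (g[0, 1] * h * k + g[0, 2] * h * l + g[1, 2] * k * l))
    return np.sqrt(q2)


def grid_qvectors(cell: gemmi.UnitCell, hmax: int):
    """Cartesian q vectors (|q| = 1/d) for the integer grid, plus |q|."""
    ax = np.arange(-hmax, hmax + 1, dtype=float)
    orth = np.array(cell.orth.mat.tolist())
    bstar = np.linalg.inv(orth)  # rows: a*, b*, c*
    h, k, l = np.meshgrid(ax, ax, ax, indexing="ij")
    hkl = np.stack([h, k, l], axis=-1)
    q = hkl @ bstar
    return q, np.linalg.norm(q, axis=-1)


def reference_intensity(
    model: AtomicModel,
    hmax: int,
    mode: str = "zero",
    chunk: int = 65536,
) -> np.ndarray:
    """Squared structure factor on the integer (H, K, L) grid.

    ``mode`` selects the ADP treatment: ``zero`` (all B = 0, I_0),
    ``isotropic`` (B_eq per atom), or ``anisotropic`` (full U tensors);
    atoms lacking U in anisotropic mode fall back to isotropic, logged.
    Conformers should already be filtered (see
    :meth:`AtomicModel.select_conformer`).  Symmetry mates of the full
    unit cell are included so the map carries the correct Laue symmetry.
    """
    if mode not in ("zero", "isotropic", "anisotropic"):
        raise ValueError(f"unknown ADP mode {mode!r}")
    fa, fb, fc = _form_factor_coeffs(model.elements)
    frac, u_cart, src = _symmetry_expand(model)
    occ = model.occ[src]
    b_iso = model.b_iso[src]
    has_u = model.has_u[src]
    fa, fb, fc = fa[src], fb[src], fc[src]

    if mode == "anisotropic":
        n_missing = int((~model.has_u).sum())
        if n_missing:
            logger.warning(
                "anisotropic mode: %d atoms lack U tensors; using isotropic B", n_missing
            )
        beq = np.where(model.has_u, beq_from_u_batch(np.where(np.isfinite(model.u_cart), model.u_cart, 0.0)), model.b_iso)[src]
    elif mode == "isotropic":
        beq = np.where(model.has_u, beq_from_u_batch(np.where(np.isfinite(model.u_cart), model.u_cart, 0.0)), model.b_iso)[src]

    q, qmag = grid_qvectors(model.cell, hmax)
    shape = qmag.shape
    qf = q.reshape(-1, 3)
    s2 = (qmag ** 2).ravel()  # (1/d)^2

    F = np.zeros(qf.shape[0], dtype=np.complex128)
    for lo in range(0, qf.shape[0], chunk):
        hi = min(lo + chunk, qf.shape[0])
        qc = qf[lo:hi]
        s2c = s2[lo:hi]
        # form factors: f_j(s) = sum_i a_i exp(-b_i s^2/4) + c
        f = fc[None, :] + np.einsum(
            "ji,mji->mj", fa, np.exp(-fb[None, :, :] * (s2c[:, None, None] / 4.0))
        )
        if mode == "zero":
            T = 1.0
        elif mode == "isotropic":
            T = np.exp(-beq[None, :] * s2c[:, None] / 4.0)
        else:
            quq = np.einsum("ma,jab,mb->mj", qc, u_cart, qc)
            T_aniso = np.exp(-2.0 * np.pi ** 2 * quq)
            T_iso = np.exp(-beq[None, :] * s2c[:, None] / 4.0)
            T = np.where(has_u[None, :], T_aniso, T_iso)
        # hkl . x_j: recover integer hkl from q is unnecessary -- the
        # phase uses fractional coordinates with the grid's own indices
        phase = np.exp(TWO_PI * 1j * (self_hkl(lo, hi, shape) @ frac.T))
        F[lo:hi] = np.sum(occ[None, :] * f * T * phase, axis=1)
    return (np.abs(F) ** 2).reshape(shape)


def self_hkl(lo: int, hi: int, shape) -> np.ndarray:
    """Integer (h, k, l) rows for flattened grid positions lo..hi."""
    n = shape[0]
    hmax = (n - 1) // 2
    flat = np.arange(lo, hi)
    l = flat % n
    k = (flat // n) % n
    h = flat // (n * n)
    return np.stack([h, k, l], axis=-1) - hmax


# ---------------------------------------------------------------------------
# LLM / RBT
# ---------------------------------------------------------------------------

def llm_kernel(gamma: float, cell: gemmi.UnitCell, hmax: int, normalize: bool = True) -> np.ndarray:
    """Displacement-correlation kernel on the integer grid.

    The 3D Fourier transform of exp(-r/gamma):
    ``8 pi gamma^3 / (1 + gamma^2 q_rad^2)^2`` with q_rad = 2 pi |q|.
    With ``normalize`` the grid sum is scaled to 1 so convolution
    preserves total intensity.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    q_rad = TWO_PI * grid_qmag(cell, hmax)
    ker = 8.0 * np.pi * gamma ** 3 / (1.0 + gamma ** 2 * q_rad ** 2) ** 2
    if normalize:
        ker = ker / ker.sum()
    return ker


class BoxAveragedKernel:
    """LLM kernel averaged over a voxel's merge acceptance region.

    A merged voxel pools pixels with fractional-index offsets in the
    [-0.5, 0.5]^3 box minus the central Bragg exclusion box, so its
    expected value is the continuous diffuse intensity averaged over
    that region — equivalently, I_0 convolved with the kernel averaged
    over the region.  This evaluates that effective kernel by fixed
    quadrature (an ``m``^3 offset grid with Bragg-box points dropped),
    which de-biases correlation-length fits to merged maps.
    """

    def __init__(self, cell: gemmi.UnitCell, hmax: int, bragg_delta: float = 0.25,
                 m: int = 4):
        u = (np.arange(m) + 0.5) / m - 0.5
        uu = np.stack(np.meshgrid(u, u, u, indexing="ij"), -1).reshape(-1, 3)
        uu = uu[np.max(np.abs(uu), axis=1) > bragg_delta]
        n = 2 * hmax + 1
        self._qr2 = np.empty((len(uu), n, n, n), dtype=np.float32)
        for i, off in enumerate(uu):
            self._qr2[i] = (TWO_PI * grid_qmag(cell, hmax, off)) ** 2

    def __call__(self, gamma: float) -> np.ndarray:
        if gamma <= 0:
            raise ValueError("gamma must be positive")
        ker = (8.0 * np.pi * gamma ** 3 / (1.0 + gamma ** 2 * self._qr2) ** 2).mean(axis=0)
        return ker / ker.sum()


def convolve_periodic(volume: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Circular (periodic-grid) convolution of two same-shape volumes.

    The kernel is indexed by signed offset with the zero offset at the
    array center (same layout as the intensity grids).
    """
    if volume.shape != kernel.shape:
        raise ValueError("volume and kernel shapes differ")
    kshift = np.fft.ifftshift(kernel)
    return sp_fft.irfftn(
        sp_fft.rfftn(volume) * sp_fft.rfftn(kshift), s=volume.shape
    )


def llm_intensity(
    reference: np.ndarray,
    sigma: float,
    gamma: float,
    cell: gemmi.UnitCell,
    overall_dw: bool = True,
    include_scale: bool = True,
    kernel: np.ndarray | None = None,
) -> np.ndarray:
    """LLM diffuse intensity on the grid (before symmetrization).

    ``overall_dw=True`` applies the zero-ADP form
    sigma^2 q_rad^2 exp(-sigma^2 q_rad^2) (I * Gamma); ``False`` applies
    the individual-ADP form sigma^2 q_rad^2 (I * Gamma) whose sigma only
    sets the scale.  ``include_scale=False`` drops the sigma^2 factor
    (irrelevant to the scale-free CC target and well-behaved at
    sigma = 0).  ``kernel`` overrides the point-sampled LLM kernel
    (e.g. a :class:`BoxAveragedKernel` evaluation).
    """
    hmax = (reference.shape[0] - 1) // 2
    q_rad2 = (TWO_PI * grid_qmag(cell, hmax)) ** 2
    if kernel is None:
        kernel = llm_kernel(gamma, cell, hmax)
    conv = convolve_periodic(reference, kernel)
    pref = q_rad2.copy()
    if include_scale:
        pref = pref * sigma ** 2
    if overall_dw:
        pref = pref * np.exp(-(sigma ** 2) * q_rad2)
    return pref * conv


def rbt_intensity(reference: np.ndarray, sigma: float, cell: gemmi.UnitCell) -> np.ndarray:
    """Independent rigid-body translation model:
    I_d(q) = I_0(q) (1 - exp(-sigma^2 q_rad^2)); no convolution."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    hmax = (reference.shape[0] - 1) // 2
    q_rad2 = (TWO_PI * grid_qmag(cell, hmax)) ** 2
    return reference * -np.expm1(-(sigma ** 2) * q_rad2)


def process_model_map(
    arr: np.ndarray,
    cell: gemmi.UnitCell,
    laue_group: str = "2/m",
    like: DiffuseVolume | None = None,
) -> DiffuseVolume:
    """Laue-symmetrize and isotropic-subtract a model intensity grid so
    model and data maps are processed identically before comparison.

    With ``like``, the grid inherits that volume's observation counts
    (zero-count voxels stay unobserved and the radial average uses the
    same weights as the data), which is the appropriate reference when
    correlating against a measured map.
    """
    hmax = (arr.shape[0] - 1) // 2
    if like is None:
        counts = np.ones_like(arr)
        sums = arr.copy()
    else:
        counts = like.count.copy()
        sums = arr * counts
    vol = DiffuseVolume(hmax, cell, laue_group, 1, sums, counts)
    return subtract_isotropic(symmetrize(vol, "laue"))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_DEFAULT_SIGMA_STARTS = (0.2, 0.4, 0.8)
_DEFAULT_GAMMA_STARTS = (4.0, 8.0, 16.0)


def fit_model(
    data: DiffuseVolume,
    reference: np.ndarray,
    kind: str = "llm",
    adp_mode: str = "zero",
    d_min: float = 1.4,
    d_max: float = 10.0,
    sigma_bounds: tuple[float, float] = (0.0, 3.0),
    gamma_bounds: tuple[float, float] = (0.5, 100.0),
    sigma_starts=_DEFAULT_SIGMA_STARTS,
    gamma_starts=_DEFAULT_GAMMA_STARTS,
    overall_dw: bool | None = None,
    voxel_average: bool = False,
    xtol: float = 1e-4,
) -> ModelFit:
    """Maximize the Pearson CC between a model map and the data map by
    Powell search over sigma (and gamma for the LLM).

    ``data`` must be a Laue-symmetrized anisotropic map; ``reference`` is
    the matching-mode squared-structure-factor grid (I_0 for zero ADPs,
    I_B otherwise).  The comparison uses voxels observed in the data with
    d in [``d_min``, ``d_max``] (the low-resolution cut reflects the
    absence of a bulk-solvent model).  ``overall_dw`` defaults to the
    mode-appropriate choice (True for zero ADPs, False otherwise); pass
    True with an I_B reference to probe whether sigma refines to zero.
    ``voxel_average`` replaces the point-sampled LLM kernel with the
    :class:`BoxAveragedKernel` (recommended when the data are merged
    voxel averages rather than integer samples).  Deterministic given
    the start grid.
    """
    if kind not in ("llm", "rbt"):
        raise ValueError(f"unknown model kind {kind!r}")
    if overall_dw is None:
        overall_dw = adp_mode == "zero"

    qmag = data.qmag()
    sel = (data.count > 0) & (qmag <= 1.0 / d_min) & (qmag >= 1.0 / d_max)
    y = data.mean()[sel]
    n_vox = int(sel.sum())
    cell = data.cell
    laue = data.laue_group
    trace = []

    def cc_of(arr: np.ndarray) -> float:
        proc = process_model_map(arr, cell, laue)
        return pearson_cc(proc.mean()[sel], y)

    if kind == "rbt":
        def neg(p):
            s = float(p[0])
            c = cc_of(rbt_intensity(reference, s, cell))
            trace.append((s, None, c))
            if not np.isfinite(c):
                return 1.0
            return -c

        best = None
        for s0 in sigma_starts:
            res = minimize(neg, [s0], method="Powell",
                           bounds=[(max(sigma_bounds[0], 1e-4), sigma_bounds[1])],
                           options={"xtol": xtol, "ftol": xtol})
            if best is None or res.fun < best.fun:
                best = res
        return ModelFit("rbt", adp_mode, float(best.x[0]), None, -float(best.fun), n_vox, trace)

    hmax = (reference.shape[0] - 1) // 2
    box_kernel = BoxAveragedKernel(cell, hmax) if voxel_average else None

    def neg(p):
        s, g = float(p[0]), float(p[1])
        ker = box_kernel(g) if box_kernel is not None else None
        arr = llm_intensity(reference, s, g, cell,
                            overall_dw=overall_dw, include_scale=False,
                            kernel=ker)
        c = cc_of(arr)
        trace.append((s, g, c))
        if not np.isfinite(c):
            return 1.0
        return -c

    best = None
    for s0 in sigma_starts:
        for g0 in gamma_starts:
            res = minimize(neg, [s0, g0], method="Powell",
                           bounds=[sigma_bounds, gamma_bounds],
                           options={"xtol": xtol, "ftol": xtol})
            if best is None or res.fun < best.fun:
                best = res
    return ModelFit("llm", adp_mode, float(best.x[0]), float(best.x[1]),
                    -float(best.fun), n_vox, trace)


# ---------------------------------------------------------------------------
# ADP utilities
# ---------------------------------------------------------------------------

def beq_from_u(u: np.ndarray) -> float:
    """Equivalent isotropic B: (8 pi^2 / 3) trace(U)."""
    u = np.asarray(u, dtype=float)
    return float(U_TO_B / 3.0 * np.trace(u))


def beq_from_u_batch(u: np.ndarray) -> np.ndarray:
    return U_TO_B / 3.0 * np.trace(np.asarray(u, float), axis1=-2, axis2=-1)


def anisotropy_ratio(u: np.ndarray) -> float:
    """Smallest/largest eigenvalue of U (1 = isotropic).

    Non-positive-semidefinite tensors are flagged in the log and the
    ratio computed on eigenvalues clipped at zero.
    """
    w = np.linalg.eigvalsh(np.asarray(u, dtype=float))
    if w[0] < -1e-12 * max(abs(w[-1]), 1e-300):
        logger.warning("anisotropy_ratio: non-PSD U (eigenvalues %s); clipping", w)
    w = np.clip(w, 0.0, None)
    if w[-1] == 0:
        return float("nan")
    return float(w[0] / w[-1])


def traceless(delta: np.ndarray) -> np.ndarray:
    """Subtract trace/3 from the diagonal (preserves B_eq when added)."""
    delta = np.asarray(delta, dtype=float)
    return delta - np.eye(3) * (np.trace(delta) / 3.0)


def rescale_adps(model: AtomicModel, delta_b: np.ndarray) -> AtomicModel:
    """Add a traceless difference anisotropic scale matrix to every U.

    ``delta_b`` is symmetric, in the B convention (A^2); it is made
    traceless (so every atom's B_eq is unchanged) and converted to the U
    convention (divided by 8 pi^2) before being added to each atom's U
    tensor.  Atoms without U tensors are left untouched.  Resulting
    non-PSD tensors are reported in the log, never fatal.
    """
    delta_b = np.asarray(delta_b, dtype=float)
    if not np.allclose(delta_b, delta_b.T):
        raise ValueError("delta must be symmetric")
    du = traceless(delta_b) / U_TO_B
    out = AtomicModel(
        list(model.elements), model.frac.copy(), model.occ.copy(),
        list(model.altloc), model.b_iso.copy(), model.u_cart.copy(),
        model.cell, model.spacegroup,
    )
    has = model.has_u
    out.u_cart[has] = model.u_cart[has] + du
    n_bad = 0
    for i in np.where(has)[0]:
        if np.linalg.eigvalsh(out.u_cart[i])[0] < 0:
            n_bad += 1
    if n_bad:
        logger.warning("rescale_adps: %d atoms now have non-PSD U tensors", n_bad)
    return out
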