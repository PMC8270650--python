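"""Synthetic ground truth: toy atomic models, noiseless diffuse volumes,
and full rotation series with controllable experimental artifacts.

The generator emulates what a rotation-series diffuse experiment hands
the pipeline: Ewald-sphere slices of a ground-truth diffuse volume, an
isotropic background with a water-ring hump, Bragg spikes at integer
Miller indices, polarization / solid-angle / absorption modulation,
parallax displacement, Poisson counting noise, and dead or hot pixels —
each switchable so every pipeline stage can be exercised in isolation.
Background frames are rendered at a longer exposure (1 s vs 0.3 s) to
exercise the exposure-ratio path.  Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial.transform import Rotation

from .geometry import CrystalOrientation, ExperimentGeometry, correction_factors, pixel_to_q
from .models import AtomicModel, U_TO_B, llm_intensity, rbt_intensity, reference_intensity
from .preprocess import DetectorFrame

__all__ = [
    "SyntheticSpec",
    "default_geometry",
    "make_toy_model",
    "make_truth_volume",
    "make_orientation",
    "render_frames",
]


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic standard fixture.

    The toy crystal is monoclinic P2_1 with a cell sized so that integer
    Miller indices out to ``hmax`` = 30 (a 61^3 grid) reach about 1.4 A.
    Ground-truth motion parameters follow the scale of refined protein
    models: sigma* = 0.4 A, gamma* = 7 A.  Exposures are 0.3 s for
    crystal frames and 1 s for background frames; 0.5 deg per frame.
    """

    cell: tuple = (40.0, 42.0, 44.0, 90.0, 95.0, 90.0)
    spacegroup: str = "P 1 21 1"
    n_atoms: int = 32
    n_altloc_pairs: int = 0
    sigma: float = 0.4
    gamma: float = 7.0
    hmax: int = 30
    # frame rendering
    rotation_start: float = 0.0
    rotation_step: float = 0.5
    n_frames: int = 360
    crystal_exposure: float = 0.3
    background_exposure: float = 1.0
    diffuse_photons: float = 150.0      # mean diffuse photons/pixel at peak scale
    background_photons: float = 600.0   # isotropic background level (photons/s-ish)
    background_anisotropy: float = 0.5  # lab-fixed azimuthal modulation of the
    # background (capillary/mount shadowing); removed by background subtraction
    background_jitter: float = 0.1      # per-frame drift of the background
    # profile shape in crystal exposures relative to the paired background
    # exposure (beam/capillary instability); removed by PCA variance removal
    bragg_amplitude: float = 4000.0
    bragg_width: float = 0.08           # fractional-index half-width of spikes
    bad_pixel_rate: float = 2e-4
    poisson_noise: bool = True
    apply_polarization: bool = True
    apply_solid_angle: bool = True
    apply_absorption: bool = True
    apply_parallax: bool = True
    add_background: bool = True
    add_bragg: bool = True
    interpolation_order: int = 1  # Ewald slicing: 1 = trilinear (smoothing
    # floor of the generator), 0 = nearest voxel (exact identity path)
    seed: int = 0
    replicate: int = 0  # replicate index: same crystal form (same model),
    # independent orientation, artifacts and noise

    @property
    def unit_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(*self.cell)


def default_geometry(n_pixels: int = 512) -> ExperimentGeometry:
    """Detector geometry reaching ~1.4 A at the edge for 16 keV x-rays."""
    # 2theta at d = 1.35 A, lambda = 0.7749 A: q lambda / 2 = sin(theta)
    lam = 0.7749
    q_edge = 1.0 / 1.35
    theta = np.arcsin(q_edge * lam / 2.0)
    z_d = 100.0
    half = z_d * np.tan(2.0 * theta)
    pix = 2.0 * half / n_pixels
    c = (n_pixels - 1) / 2.0
    return ExperimentGeometry(
        wavelength=lam,
        detector_distance=z_d,
        pixel_size=pix,
        beam_center=(c, c),
        detector_shape=(n_pixels, n_pixels),
    )


def make_toy_model(spec: SyntheticSpec) -> AtomicModel:
    """Pseudo-protein of random C/N/O/S atoms in the asymmetric unit.

    Anisotropic U tensors are drawn with anisotropy ratios
    (lambda_min / lambda_max) centered near 0.45, the bell-shaped
    distribution typical of refined protein models, with random
    principal axes; B_eq values fall in the 8-20 A^2 range.  Optional
    altloc pairs (A at 0.6 / B at 0.4 occupancy) exercise A-conformer
    filtering.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_atoms
    elements = list(rng.choice(["C", "C", "C", "N", "O", "S"], size=n))
    # cluster atoms into a blob occupying about half the asymmetric unit
    center = np.array([0.25, 0.25, 0.25])
    frac = center + rng.uniform(-0.18, 0.18, size=(n, 3))
    b_iso = rng.uniform(8.0, 20.0, size=n)
    u = np.empty((n, 3, 3))
    for i in range(n):
        ratio = float(np.clip(rng.normal(0.45, 0.08), 0.15, 0.95))
        mid = rng.uniform(ratio, 1.0)
        lam = np.array([ratio, mid, 1.0])
        lam *= 3.0 * b_iso[i] / (U_TO_B * lam.sum())  # B_eq = b_iso exactly
        r = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
        u[i] = r @ np.diag(lam) @ r.T
    occ = np.ones(n)
    altloc = [""] * n
    if spec.n_altloc_pairs:
        for _ in range(spec.n_altloc_pairs):
            j = int(rng.integers(n))
            elements.append(elements[j])
            frac = np.vstack([frac, frac[j] + rng.normal(0, 0.01, 3)])
            b_iso = np.append(b_iso, b_iso[j])
            u = np.concatenate([u, u[j][None]])
            occ[j] = 0.6
            occ = np.append(occ, 0.4)
            altloc[j] = "A"
            altloc.append("B")
    return AtomicModel(elements, frac, occ, altloc, b_iso, u,
                       spec.unit_cell, spec.spacegroup)


def make_truth_volume(
    model: AtomicModel,
    sigma: float,
    gamma: float | None,
    kind: str = "llm",
    mode: str = "zero",
    hmax: int | None = None,
    oversample: int = 1,
) -> np.ndarray:
    """Noiseless model diffuse volume (raw, before symmetrization; it
    already carries the crystal's Laue symmetry).

    With ``oversample`` > 1 the volume is sampled on a grid ``oversample``
    times finer than integer Miller indices: Bragg-node intensities are
    placed at the integer positions only and the correlation kernel is
    evaluated on the fine grid, so the result approximates the continuous
    diffuse intensity between nodes (the physically meaningful target for
    Ewald-slice rendering) rather than its integer sampling.
    """
    hmax = hmax if hmax is not None else 30
    work = model.select_conformer("A")
    ref = reference_intensity(work, hmax, mode)
    if oversample > 1:
        n_fine = 2 * hmax * oversample + 1
        fine = np.zeros((n_fine, n_fine, n_fine))
        fine[::oversample, ::oversample, ::oversample] = ref
        ref = fine
    cell = model.cell
    if oversample > 1:
        # fine grid spacing corresponds to a cell oversample times larger
        cell = gemmi.UnitCell(cell.a * oversample, cell.b * oversample,
                              cell.c * oversample, cell.alpha, cell.beta, cell.gamma)
    if kind == "llm":
        return llm_intensity(ref, sigma, gamma, cell, overall_dw=(mode == "zero"))
    if kind == "rbt":
        return rbt_intensity(ref, sigma, cell)
    raise ValueError(f"unknown kind {kind!r}")


def make_orientation(
    spec: SyntheticSpec,
    align_unique_axis: bool = False,
) -> CrystalOrientation:
    """Crystal setting A = R0 B* with a seeded random rotation.

    ``align_unique_axis`` instead orients b* (the 2-fold axis of 2/m)
    along the spindle/polarization axis (lab x), the geometry in which
    uncorrected polarization artifacts mimic the crystal symmetry.
    """
    rng = np.random.default_rng(spec.seed + 1 + 104729 * spec.replicate)
    orth = np.array(spec.unit_cell.orth.mat.tolist())
    bstar_cols = np.linalg.inv(orth).T  # columns a*, b*, c*
    if align_unique_axis:
        b_dir = bstar_cols[:, 1] / np.linalg.norm(bstar_cols[:, 1])
        target = np.array([1.0, 0.0, 0.0])
        v = np.cross(b_dir, target)
        s = np.linalg.norm(v)
        if s < 1e-12:
            r_align = np.eye(3)
        else:
            r_align = Rotation.from_rotvec(
                v / s * np.arctan2(s, float(b_dir @ target))).as_matrix()
        spin = Rotation.from_rotvec(target * rng.uniform(0, 2 * np.pi)).as_matrix()
        r0 = spin @ r_align
    else:
        r0 = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
    angles = spec.rotation_start + spec.rotation_step * np.arange(spec.n_frames)
    return CrystalOrientation(r0 @ bstar_cols, angles)


def _background_components(qmag: np.ndarray, level: float):
    """Smooth background components: air-scatter decay, a water-ring hump
    centered near d = 3.3 A, and a flat floor."""
    water = level * np.exp(-((qmag - 1.0 / 3.3) ** 2) / (2 * 0.045 ** 2))
    air = level * 0.6 * np.exp(-qmag / 0.12)
    flat = level * 0.15 * np.ones_like(qmag)
    return air, water, flat


def render_frames(
    truth: np.ndarray,
    spec: SyntheticSpec,
    geometry: ExperimentGeometry,
    orientation: CrystalOrientation,
):
    """Rotation series of crystal and paired background frames.

    Per frame the truth volume is sliced on the Ewald sphere (trilinear
    interpolation at each pixel's fractional Miller indices), the
    isotropic background and Bragg spikes are added, the polarization /
    solid-angle / absorption modulations are applied (so the pipeline
    must undo them), counts are scaled by exposure time, Poisson noise
    is drawn, and static bad pixels are planted.  Background frames
    carry only the background signal at the background exposure.

    Returns ``(crystal_frames, background_frames)`` as lists of
    :class:`DetectorFrame`.
    """
    rng = np.random.default_rng(spec.seed + 1000 + 104729 * spec.replicate)
    half = (truth.shape[0] - 1) // 2
    ov = half // spec.hmax  # truth may be oversampled (finer than integers)
    if half != ov * spec.hmax:
        raise ValueError("truth grid size inconsistent with spec.hmax")
    nf, ns = geometry.detector_shape
    fast, slow = geometry.pixel_grid()

    q = pixel_to_q(geometry, fast, slow, apply_parallax=spec.apply_parallax)
    qmag = np.linalg.norm(q, axis=-1)
    corr = correction_factors(geometry, fast, slow)
    modulation = np.ones_like(qmag)
    if spec.apply_polarization:
        modulation = modulation * corr["polarization"]
    if spec.apply_solid_angle:
        modulation = modulation * corr["solid_angle"]
    if spec.apply_absorption:
        modulation = modulation * corr["absorption"]

    if spec.add_background:
        air, water, flat = _background_components(qmag, spec.background_photons)
        # lab-fixed azimuthal modulation (capillary/mount shadowing),
        # growing with scattering angle; identical in the paired
        # background exposure, so subtraction removes it
        pos = np.stack([(np.asarray(fast, float) - geometry.beam_center[0]),
                        (np.asarray(slow, float) - geometry.beam_center[1])])
        azimuth = np.arctan2(pos[1], pos[0])
        phase = rng.uniform(0, 2 * np.pi)
        radial = qmag / max(float(qmag.max()), 1e-12)
        aniso = 1.0 + spec.background_anisotropy * radial * np.cos(azimuth - phase) ** 2
        base_bg = (air + water + flat) * aniso
        # per-frame shape drift of the crystal exposure's background
        # relative to the paired background exposure
        jitter_air = 1.0 + spec.background_jitter * rng.standard_normal(spec.n_frames)
        jitter_water = 1.0 + spec.background_jitter * rng.standard_normal(spec.n_frames)
    else:
        air = water = flat = np.zeros_like(qmag)
        aniso = np.ones_like(qmag)
        base_bg = np.zeros_like(qmag)
        jitter_air = jitter_water = np.ones(spec.n_frames)

    # static bad pixels: half dead (0), half hot (above saturation)
    n_bad = rng.binomial(nf * ns, spec.bad_pixel_rate)
    bad_idx = rng.choice(nf * ns, size=n_bad, replace=False)
    hot = rng.random(n_bad) < 0.5

    # scale the truth volume so the mean sliced signal sits near the
    # requested photon level
    t_scale = spec.diffuse_photons / max(float(truth.mean()), 1e-30)

    ra_inv_cache = {}
    crystal_frames, background_frames = [], []
    for i in range(spec.n_frames):
        ang = orientation.spindle_angles[i]
        rot = Rotation.from_rotvec(np.deg2rad(ang) * orientation.rotation_axis).as_matrix()
        ra_inv = np.linalg.inv(rot @ orientation.a_matrix)
        hkl = q @ ra_inv.T
        coords = (hkl * ov + half).T  # sampling of the (possibly fine) truth grid
        diffuse = t_scale * map_coordinates(truth, coords, order=spec.interpolation_order,
                                            mode="constant", cval=0.0)
        frame_bg = (jitter_air[i] * air + jitter_water[i] * water + flat) * aniso
        signal = diffuse + frame_bg
        if spec.add_bragg:
            off = np.abs(hkl - np.round(hkl))
            inside = np.all(np.abs(np.round(hkl)) <= spec.hmax, axis=1)
            w = np.clip(1.0 - np.max(off, axis=1) / spec.bragg_width, 0.0, 1.0)
            signal = signal + spec.bragg_amplitude * w * inside
        counts = signal * modulation * spec.crystal_exposure
        bg_counts = base_bg * modulation * spec.background_exposure
        if spec.poisson_noise:
            counts = rng.poisson(counts).astype(np.float32)
            bg_counts = rng.poisson(bg_counts).astype(np.float32)
        else:
            counts = counts.astype(np.float32)
            bg_counts = bg_counts.astype(np.float32)
        counts.ravel()[bad_idx[hot]] = 65535.0
        counts.ravel()[bad_idx[~hot]] = 0.0
        bg_counts.ravel()[bad_idx[hot]] = 65535.0
        bg_counts.ravel()[bad_idx[~hot]] = 0.0
        crystal_frames.append(DetectorFrame(
            counts.reshape(nf, ns), None, spec.crystal_exposure, i, float(ang)))
        background_frames.append(DetectorFrame(
            bg_counts.reshape(nf, ns), None, spec.background_exposure, i, float(ang)))
    return crystal_frames, background_frames
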