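"""Detector geometry: pixel -> scattering vector -> fractional Miller indices.

Conventions
-----------
* Lab frame: the incident beam travels along +z; the detector is a flat
  plane normal to the beam at distance ``detector_distance`` (mm).  The
  detector fast axis is lab x, the slow axis is lab y.  Pixel indices are
  0-based, given as (fast, slow).
* Scattering vector: ``q = (s - s0) / wavelength`` with ``|s| = |s0| = 1``,
  so ``|q| = 2 sin(theta) / wavelength = 1/d`` (inverse d-spacing, A^-1).
  Model formulas that need the angular-frequency convention use
  ``q_rad = 2 pi |q|`` and say so explicitly.
* Fractional Miller indices: ``hkl = (R_phi A)^-1 q`` where ``A`` is the
  indexing matrix (reciprocal cell vectors as columns, lab frame, A^-1)
  and ``R_phi`` the spindle rotation for the frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "ExperimentGeometry",
    "CrystalOrientation",
    "ScatteringVectorGrid",
    "pixel_to_lab",
    "pixel_to_q",
    "q_to_hkl",
    "hkl_to_q",
    "spindle_rotation",
    "correction_factors",
    "parallax_shift",
]


@dataclass
class ExperimentGeometry:
    """Beam and detector parameters mapping pixels to scattering vectors.

    Parameters
    ----------
    wavelength : float
        Incident wavelength in Angstrom.
    detector_distance : float
        Crystal-to-detector distance z_d in mm.
    pixel_size : float
        Square pixel edge in mm.
    beam_center : tuple of float
        Direct-beam position in pixels, (fast, slow).
    detector_shape : tuple of int
        Number of pixels (fast, slow).
    polarization_fraction : float
        Fraction of the beam polarized along lab x (horizontal).  0.5
        reproduces the unpolarized Thomson factor.
    sensor_thickness : float
        Sensor slab thickness in mm (parallax / absorption corrections).
    sensor_attenuation_length : float
        1/e attenuation length of the sensor material in mm at the
        experiment energy.
    """

    wavelength: float
    detector_distance: float
    pixel_size: float
    beam_center: tuple[float, float]
    detector_shape: tuple[int, int] = (512, 512)
    polarization_fraction: float = 0.99
    sensor_thickness: float = 0.32
    sensor_attenuation_length: float = 0.55

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.detector_distance <= 0:
            raise ValueError("detector_distance must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not 0.0 <= self.polarization_fraction <= 1.0:
            raise ValueError("polarization_fraction must be in [0, 1]")

    def pixel_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (fast, slow) index arrays for every pixel, shape (n, 2)."""
        nf, ns = self.detector_shape
        fast, slow = np.meshgrid(np.arange(nf), np.arange(ns), indexing="ij")
        return fast.ravel(), slow.ravel()


@dataclass
class CrystalOrientation:
    """Indexing result: reciprocal-cell matrix plus per-frame spindle angles.

    ``a_matrix`` holds the reciprocal cell vectors a*, b*, c* as columns in
    the lab frame at spindle angle zero (units A^-1).  ``spindle_angles``
    are degrees, strictly monotone across the series.  ``rotation_axis``
    is a unit vector in the lab frame (default: lab x, perpendicular to
    the beam).
    """

    a_matrix: np.ndarray
    spindle_angles: np.ndarray
    rotation_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self) -> None:
        self.a_matrix = np.asarray(self.a_matrix, dtype=float).reshape(3, 3)
        if abs(np.linalg.det(self.a_matrix)) < 1e-15:
            raise ValueError("A matrix is singular")
        self.spindle_angles = np.atleast_1d(np.asarray(self.spindle_angles, dtype=float))
        d = np.diff(self.spindle_angles)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("spindle angles must be strictly monotone")
        self.rotation_axis = np.asarray(self.rotation_axis, dtype=float)
        self.rotation_axis = self.rotation_axis / np.linalg.norm(self.rotation_axis)

    @classmethod
    def from_text(cls, path) -> "CrystalOrientation":
        """Read the plain-text orientation dialect.

        Line 1: nine floats, row-major A matrix (A^-1).
        Line 2: three floats, rotation axis (lab frame).
        Remaining lines: one spindle angle (deg) per frame.
        """
        with open(path) as fh:
            lines = [ln for ln in (l.strip() for l in fh) if ln and not ln.startswith("#")]
        a = np.array([float(x) for x in lines[0].split()]).reshape(3, 3)
        axis = np.array([float(x) for x in lines[1].split()])
        angles = np.array([float(ln.split()[0]) for ln in lines[2:]])
        return cls(a, angles, axis)

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(" ".join(f"{x:.12g}" for x in self.a_matrix.ravel()) + "\n")
            fh.write(" ".join(f"{x:.12g}" for x in self.rotation_axis) + "\n")
            for ang in self.spindle_angles:
                fh.write(f"{ang:.8f}\n")


@dataclass
class ScatteringVectorGrid:
    """Per-pixel q vectors (A^-1) and fractional Miller indices."""

    q: np.ndarray
    hkl: np.ndarray | None = None


# ---------------------------------------------------------------------------
# pixel -> q
# ---------------------------------------------------------------------------

def pixel_to_lab(geometry: ExperimentGeometry, fast, slow) -> np.ndarray:
    """Lab-frame coordinates (mm) of pixel centers, shape (..., 3)."""
    fast = np.asarray(fast, dtype=float)
    slow = np.asarray(slow, dtype=float)
    x = (fast - geometry.beam_center[0]) * geometry.pixel_size
    y = (slow - geometry.beam_center[1]) * geometry.pixel_size
    z = np.full_like(x, geometry.detector_distance)
    return np.stack([x, y, z], axis=-1)


def pixel_to_q(
    geometry: ExperimentGeometry,
    fast,
    slow,
    apply_parallax: bool = False,
) -> np.ndarray:
    """Scattering vectors q = (s - s0)/lambda for pixel centers.

    |q| = 2 sin(theta)/lambda = 1/d.  With ``apply_parallax`` the pixel
    positions are first shifted back along the in-plane beam-penetration
    direction by the mean absorption depth (see :func:`parallax_shift`).
    """
    fast = np.asarray(fast, dtype=float)
    slow = np.asarray(slow, dtype=float)
    nf, ns = geometry.detector_shape
    if np.any(fast < 0) or np.any(fast > nf - 1) or np.any(slow < 0) or np.any(slow > ns - 1):
        raise ValueError("pixel outside detector bounds")
    pos = pixel_to_lab(geometry, fast, slow)
    if apply_parallax:
        pos = pos - parallax_shift(geometry, pos)
    s = pos / np.linalg.norm(pos, axis=-1, keepdims=True)
    s0 = np.array([0.0, 0.0, 1.0])
    return (s - s0) / geometry.wavelength


# ---------------------------------------------------------------------------
# q <-> hkl
# ---------------------------------------------------------------------------

def spindle_rotation(orientation: CrystalOrientation, angle_deg: float) -> np.ndarray:
    """3x3 rotation matrix for the spindle at ``angle_deg``."""
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * orientation.rotation_axis).as_matrix()


def q_to_hkl(orientation: CrystalOrientation, frame_angle: float, q: np.ndarray) -> np.ndarray:
    """Fractional Miller indices hkl = (R_phi A)^-1 q."""
    ra = spindle_rotation(orientation, frame_angle) @ orientation.a_matrix
    return np.asarray(q) @ np.linalg.inv(ra).T


def hkl_to_q(orientation: CrystalOrientation, frame_angle: float, hkl: np.ndarray) -> np.ndarray:
    """Inverse of :func:`q_to_hkl`."""
    ra = spindle_rotation(orientation, frame_angle) @ orientation.a_matrix
    return np.asarray(hkl) @ ra.T


# ---------------------------------------------------------------------------
# per-pixel correction factors
# ---------------------------------------------------------------------------

def parallax_shift(geometry: ExperimentGeometry, pos: np.ndarray) -> np.ndarray:
    """In-plane displacement (mm) of the recorded centroid vs the entry point.

    Photons entering the sensor obliquely are absorbed at a mean depth

        t_eff = l (1 - (1 + t/l) e^(-t/l)) / (1 - e^(-t/l)),

    (t = thickness, l = attenuation length), displacing the recorded
    position outward along the in-plane component of the scattered ray by
    t_eff tan(theta_pix).  The returned vector has zero z component; the
    shift vanishes as t -> 0.
    """
    t = geometry.sensor_thickness
    ell = geometry.sensor_attenuation_length
    if t <= 0:
        return np.zeros_like(pos)
    r = t / ell
    t_eff = ell * (1.0 - (1.0 + r) * np.exp(-r)) / (1.0 - np.exp(-r))
    xy = pos[..., :2]
    rho = np.linalg.norm(xy, axis=-1, keepdims=True)
    tan_theta = rho / pos[..., 2:3]
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.where(rho > 0, xy / np.where(rho == 0, 1.0, rho), 0.0)
    shift_mag = t_eff * tan_theta
    out = np.zeros_like(pos)
    out[..., :2] = shift_mag * rhat
    return out


def correction_factors(
    geometry: ExperimentGeometry,
    fast,
    slow,
    polarization_floor: float = 0.01,
) -> dict:
    """Per-pixel geometric factors, each normalized to 1 at the beam center.

    Returns a dict with keys ``polarization``, ``solid_angle``,
    ``absorption``, ``total`` (their product), and ``low_polarization``
    (mask of pixels whose polarization factor fell below the floor; such
    pixels should be masked, not divided).

    Corrected intensity = raw / total.  The factors:

    * polarization: ``f (1 - (s.x)^2) + (1 - f) (1 - (s.y)^2)`` for a
      horizontally polarized fraction f; at f = 0.5 this is the
      unpolarized Thomson form (1 + cos^2 2theta)/2.
    * solid angle: cos^3(theta_pix) for a flat detector of equal-area
      pixels.
    * absorption: relative sensor efficiency
      ``(1 - exp(-t/(l cos theta))) / (1 - exp(-t/l))``.
    """
    pos = pixel_to_lab(geometry, fast, slow)
    dist = np.linalg.norm(pos, axis=-1)
    s = pos / dist[..., None]
    cos_t = pos[..., 2] / dist  # incidence angle from detector normal

    f = geometry.polarization_fraction
    pol = f * (1.0 - s[..., 0] ** 2) + (1.0 - f) * (1.0 - s[..., 1] ** 2)

    solid = cos_t ** 3

    t = geometry.sensor_thickness
    ell = geometry.sensor_attenuation_length
    if t > 0:
        eff0 = 1.0 - np.exp(-t / ell)
        absorb = (1.0 - np.exp(-t / (ell * cos_t))) / eff0
    else:
        absorb = np.ones_like(cos_t)

    low = pol < polarization_floor
    return {
        "polarization": pol,
        "solid_angle": solid,
        "absorption": absorb,
        "total": pol * solid * absorb,
        "low_polarization": low,
    }
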