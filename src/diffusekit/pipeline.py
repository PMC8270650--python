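"""End-to-end orchestration: configuration, the standard processing
pipeline (frames -> Laue-symmetrized anisotropic diffuse map -> quality
metrics), and the ablation / scale-factor study driver.

Step order is fixed: static masking, windowed outlier rejection,
background subtraction, geometric corrections, Bragg cleaning, then
image scaling and radial-profile variance removal — Bragg peaks must be
cleaned before scaling and variance removal.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

from . import geometry as geom
from . import metrics as qm
from . import preprocess as pp
from . import scaling as sc
from . import volume as vol

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "ablation_matrix", "ABLATION_VARIANTS"]


@dataclass
class PipelineConfig:
    """Every tunable of the standard pipeline; serialized config plus
    inputs fully determine deterministic outputs."""

    # step (1)-(2): masking
    saturation: float = 10_000.0
    outlier_window: int = 11
    outlier_nsigma: float = 5.0
    # step (3)
    background_subtraction: bool = True
    # step (4): corrections
    polarization: bool = True
    solid_angle: bool = True
    detector_absorption: bool = True
    parallax: bool = True
    polarization_floor: float = 0.01
    # step (5): Bragg cleaning
    bragg_delta: float = 0.25
    bragg_mode: str = "mask"  # or "replace"
    median_window: int = 11
    # step (6): scaling + variance removal
    scale: bool = True
    scale_method: str = "radial_profile"
    bragg_scale_file: str | None = None
    n_profile_bins: int = 200
    variance_removal: bool = True
    pca_components: int = 3
    radial_interpolation: str = "linear"
    water_ring: tuple = (5.0, 1.82)
    # merge / volume
    hmax: int = 60
    laue_group: str = "2/m"
    resolution_limit: float = 1.4
    # metrics
    n_shells: int = 15
    seed: int = 0

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "water_ring" in data and isinstance(data["water_ring"], list):
            data["water_ring"] = tuple(data["water_ring"])
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def run_pipeline(
    frames,
    backgrounds,
    geometry: geom.ExperimentGeometry,
    orientation: geom.CrystalOrientation,
    cell: gemmi.UnitCell,
    config: PipelineConfig | None = None,
    user_mask: np.ndarray | None = None,
) -> dict:
    """Standard pipeline from raw frames to diffuse maps and metrics.

    Returns a dict with the raw unsymmetrized volume, Friedel- and
    Laue-symmetrized volumes, their anisotropic (isotropic-subtracted)
    counterparts, per-shell metric reports, merge statistics and a
    provenance record.
    """
    cfg = config or PipelineConfig()
    if cfg.background_subtraction and backgrounds is None:
        raise ValueError("background frames required when subtraction is enabled")

    nf, ns = geometry.detector_shape
    fast, slow = geometry.pixel_grid()
    q = geom.pixel_to_q(geometry, fast, slow, apply_parallax=cfg.parallax)
    qmag = np.linalg.norm(q, axis=-1)
    corr = geom.correction_factors(geometry, fast, slow, cfg.polarization_floor)
    divisor = np.ones_like(qmag)
    if cfg.polarization:
        divisor = divisor * corr["polarization"]
    if cfg.solid_angle:
        divisor = divisor * corr["solid_angle"]
    if cfg.detector_absorption:
        divisor = divisor * corr["absorption"]
    pol_bad = corr["low_polarization"] if cfg.polarization else np.zeros_like(qmag, bool)

    bin_edges = sc.default_bins(1.0 / cfg.resolution_limit, cfg.n_profile_bins)
    bin_centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])

    n_frames = len(frames)
    cleaned, masks, profiles, region_means = [], [], [], []
    region = (
        cfg.water_ring if cfg.scale_method == "water_ring"
        else (np.inf, cfg.resolution_limit)
    )
    ra_inv = _frame_matrices(orientation, n_frames)

    for i, frame in enumerate(frames):
        f = frame.copy()
        f.mask = pp.static_mask(f, cfg.saturation, user_mask)
        f.mask = pp.windowed_outlier_mask(f, cfg.outlier_window, cfg.outlier_nsigma)
        if cfg.background_subtraction:
            b = backgrounds[i].copy()
            b.mask = pp.static_mask(b, cfg.saturation, user_mask)
            b.mask = pp.windowed_outlier_mask(b, cfg.outlier_window, cfg.outlier_nsigma)
            f = pp.subtract_background(f, b)
        intens = f.intensities.reshape(-1).astype(np.float64) / divisor
        mask = f.mask.reshape(-1) & ~pol_bad

        hkl = q @ ra_inv[i].T
        flags = pp.flag_bragg_pixels(hkl, cfg.bragg_delta)
        if cfg.bragg_mode == "replace":
            tmp = pp.DetectorFrame(intens.reshape(nf, ns), mask.reshape(nf, ns),
                                   f.exposure_time, f.frame_index, f.spindle_angle)
            tmp = pp.replace_bragg_with_median(tmp, flags.reshape(nf, ns), cfg.median_window)
            intens = tmp.intensities.reshape(-1)
            mask = tmp.mask.reshape(-1)
        else:
            mask = mask & ~flags

        profiles.append(sc.radial_profile(intens, mask, qmag, bin_edges))
        if cfg.scale and cfg.scale_method in ("water_ring", "overall"):
            region_means.append(sc._region_mean(intens, mask, qmag, region))
        cleaned.append(intens.astype(np.float32))
        masks.append(mask)

    # --- per-frame scale factors -----------------------------------------
    if cfg.scale:
        if cfg.scale_method == "radial_profile":
            ref = profiles[0]
            factors = np.array([
                sc.scale_factor(cleaned[i], masks[i], qmag, ref,
                                "radial_profile", bin_edges,
                                resolution_limit=cfg.resolution_limit)
                for i in range(n_frames)
            ])
        elif cfg.scale_method in ("water_ring", "overall"):
            factors = region_means[0] / np.asarray(region_means)
        elif cfg.scale_method == "bragg":
            if cfg.bragg_scale_file is None:
                raise ValueError("bragg scale method needs bragg_scale_file")
            factors = sc.read_bragg_scale_report(cfg.bragg_scale_file, n_frames).factors
        else:
            raise ValueError(f"unknown scale method {cfg.scale_method!r}")
    else:
        factors = np.ones(n_frames)
    scale_set = sc.ScaleSet(cfg.scale_method if cfg.scale else "none", factors)

    # --- radial-profile variance removal ----------------------------------
    profile_matrix = np.stack([p.mean * s for p, s in zip(profiles, factors)])
    if cfg.variance_removal:
        correction = sc.remove_radial_variance(profile_matrix, cfg.pca_components)
    else:
        correction = np.zeros_like(profile_matrix)

    # --- merge -------------------------------------------------------------
    volume = vol.DiffuseVolume(cfg.hmax, cell, cfg.laue_group)
    merge_stats = {"n_pixels": 0, "n_bragg_rejected": 0, "n_outside_grid": 0, "n_merged": 0}
    for i in range(n_frames):
        intens = cleaned[i].astype(np.float64) * factors[i]
        if cfg.variance_removal:
            intens = sc.apply_radial_correction(
                intens, qmag, bin_centers, correction[i], cfg.radial_interpolation)
        hkl = q @ ra_inv[i].T
        st = vol.merge_frames_into(volume, hkl, intens, masks[i], cfg.bragg_delta)
        for k in merge_stats:
            merge_stats[k] += st[k]

    # --- volume processing and metrics ------------------------------------
    shells = vol.ShellScheme.equal_volume(cfg.resolution_limit, cfg.n_shells)
    raw_aniso = vol.subtract_isotropic(volume)
    friedel = vol.symmetrize(volume, "friedel")
    laue = vol.symmetrize(volume, "laue")
    laue_aniso = vol.subtract_isotropic(laue)
    per_shell_compl, overall_compl = vol.completeness(volume, shells)

    reports = {
        "completeness": {"overall": overall_compl, "per_shell": per_shell_compl.tolist()},
        "cc_friedel": qm.cc_symmetry(raw_aniso, "friedel", shells),
        "cc_laue": qm.cc_symmetry(raw_aniso, "laue", shells),
        "cc_half": qm.cc_half(raw_aniso, shells, rng=cfg.seed),
    }
    provenance = {
        "config_hash": cfg.config_hash(),
        "config": asdict(cfg),
        "n_frames": n_frames,
        "scale_factors": factors.tolist(),
        "step_order": [
            "static_mask", "windowed_outlier", "background_subtraction",
            "corrections", "bragg_cleaning", "scaling", "variance_removal",
            "merge", "symmetrize", "isotropic_subtraction",
        ],
    }
    return {
        "raw": volume,
        "raw_aniso": raw_aniso,
        "friedel": friedel,
        "laue": laue,
        "laue_aniso": laue_aniso,
        "shells": shells,
        "scale_set": scale_set,
        "merge_stats": merge_stats,
        "reports": reports,
        "provenance": provenance,
    }


def _frame_matrices(orientation: geom.CrystalOrientation, n_frames: int):
    out = []
    for i in range(n_frames):
        ang = orientation.spindle_angles[i]
        rot = Rotation.from_rotvec(np.deg2rad(ang) * orientation.rotation_axis).as_matrix()
        out.append(np.linalg.inv(rot @ orientation.a_matrix))
    return out


# ---------------------------------------------------------------------------
# ablation study
# ---------------------------------------------------------------------------

ABLATION_VARIANTS = {
    "standard": {},
    "no_background": {"background_subtraction": False},
    "no_polarization": {"polarization": False},
    "no_variance_removal": {"variance_removal": False},
    "no_solid_angle": {"solid_angle": False},
    "no_absorption": {"detector_absorption": False},
    "no_parallax": {"parallax": False},
}


def ablation_matrix(
    datasets: list,
    geometry: geom.ExperimentGeometry,
    cell: gemmi.UnitCell,
    config: PipelineConfig | None = None,
    variants: dict | None = None,
) -> pd.DataFrame:
    """CC metrics per processing variant, with deltas vs the standard
    pipeline.

    ``datasets`` is a list of (frames, backgrounds, orientation) tuples —
    independent replicate measurements, needed for the CC_Rep columns
    (>= 2).  ``variants`` maps a variant name to PipelineConfig field
    overrides (defaults to the step-omission set).  Scale-factor variants
    are expressed the same way, e.g. ``{"scale_method": "overall"}`` or
    ``{"scale_method": "water_ring", "variance_removal": False}``.
    """
    cfg = config or PipelineConfig()
    variants = dict(variants) if variants is not None else dict(ABLATION_VARIANTS)
    if "standard" not in variants:
        variants = {"standard": {}, **variants}
    allowed = set(asdict(cfg))
    rows = []
    results_cache = {}
    for name, overrides in variants.items():
        unknown = set(overrides) - allowed
        if unknown:
            raise ValueError(f"variant {name!r} names unknown steps: {sorted(unknown)}")
        vcfg = replace(cfg, **overrides)
        runs = [
            run_pipeline(fr, bg, geometry, orient, cell, vcfg)
            for fr, bg, orient in datasets
        ]
        results_cache[name] = runs
        shells = None
        for i, run in enumerate(runs):
            others = [runs[j]["laue_aniso"] for j in range(len(runs)) if j != i]
            row = {
                "variant": name,
                "dataset": i,
                "CC_Friedel": run["reports"]["cc_friedel"].overall,
                "CC_Laue": run["reports"]["cc_laue"].overall,
                "CC_1/2": run["reports"]["cc_half"].overall,
            }
            if others:
                row["CC_Rep"] = qm.cc_rep(run["laue_aniso"], others).overall
            rows.append(row)
    df = pd.DataFrame(rows).set_index(["variant", "dataset"])
    std = df.loc["standard"]
    deltas = df.sub(std, level="dataset")
    deltas.columns = [f"d{c}" for c in deltas.columns]
    out = pd.concat([df, deltas], axis=1)
    out.attrs["results"] = results_cache
    return out
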