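"""Shared fixtures.

Expensive synthetic datasets are session-scoped and hold only the
pipeline products (volumes, reports), never the frame stacks, so memory
is released as soon as each fixture body finishes.
"""

from dataclasses import replace

import numpy as np
import pytest

import diffusekit as dk
from diffusekit.models import process_model_map, reference_intensity
from diffusekit.pipeline import PipelineConfig, ablation_matrix, run_pipeline


@pytest.fixture(scope="session")
def tiny_spec():
    """Desk-scale fixture: 25^3 grid, small toy crystal."""
    return dk.SyntheticSpec(seed=11, n_atoms=16, hmax=12)


@pytest.fixture(scope="session")
def tiny_model(tiny_spec):
    return dk.make_toy_model(tiny_spec)


@pytest.fixture(scope="session")
def tiny_ref_zero(tiny_model):
    return reference_intensity(tiny_model.select_conformer("A"), 12, "zero")


@pytest.fixture(scope="session")
def std_spec():
    """Standard synthetic conditions: 61^3 grid, sigma*=0.4 A, gamma*=7 A."""
    return dk.SyntheticSpec(seed=7)


@pytest.fixture(scope="session")
def std_model(std_spec):
    return dk.make_toy_model(std_spec)


@pytest.fixture(scope="session")
def std_ref_zero(std_model):
    return reference_intensity(std_model.select_conformer("A"), 30, "zero")


@pytest.fixture(scope="session")
def std_ref_aniso(std_model):
    return reference_intensity(std_model.select_conformer("A"), 30, "anisotropic")


@pytest.fixture(scope="session")
def reduced_dataset_results(tiny_spec):
    """Two replicate rotation series at moderate resolution (2.6 A,
    256^2 detector, 120 x 1.5 deg) with the step-omission matrix."""
    base = dk.SyntheticSpec(seed=23, hmax=16, n_frames=120, rotation_step=1.5)
    model = dk.make_toy_model(base)
    truth = dk.make_truth_volume(model, base.sigma, base.gamma, "llm", "zero",
                                 base.hmax, oversample=2)
    geometry = dk.default_geometry(256)
    datasets = []
    for rep in range(2):
        spec = replace(base, replicate=rep)
        orient = dk.make_orientation(spec)
        cr, bg = dk.render_frames(truth, spec, geometry, orient)
        datasets.append((cr, bg, orient))
    cfg = PipelineConfig(hmax=16, resolution_limit=2.6, n_profile_bins=120,
                         n_shells=10)
    variants = {
        "standard": {},
        "no_background": {"background_subtraction": False},
        "no_polarization": {"polarization": False},
        "no_variance_removal": {"variance_removal": False},
        "scale_overall": {"scale_method": "overall"},
        "scale_water_ring": {"scale_method": "water_ring"},
    }
    df = ablation_matrix(datasets, geometry, model.cell, cfg, variants)
    return {"df": df, "cell": model.cell, "cfg": cfg, "truth": truth,
            "model": model, "spec": base}


@pytest.fixture(scope="session")
def e2e_run(std_spec, std_model):
    """Full standard-scale run: 512^2 detector, 360 x 0.5 deg frames,
    merged to the 61^3 grid; frames are discarded on return."""
    truth = dk.make_truth_volume(std_model, std_spec.sigma, std_spec.gamma,
                                 "llm", "zero", std_spec.hmax, oversample=2)
    geometry = dk.default_geometry(512)
    orient = dk.make_orientation(std_spec)
    crystal, background = dk.render_frames(truth, std_spec, geometry, orient)
    res = run_pipeline(crystal, background, geometry, orient, std_model.cell,
                       PipelineConfig(hmax=30))
    truth_int = truth[::2, ::2, ::2]
    processed_truth = process_model_map(truth_int, std_model.cell, "2/m",
                                        like=res["raw"])
    return {
        "laue_aniso": res["laue_aniso"],
        "raw_aniso": res["raw_aniso"],
        "raw_count": res["raw"].count,
        "shells": res["shells"],
        "reports": res["reports"],
        "merge_stats": res["merge_stats"],
        "processed_truth": processed_truth,
    }


@pytest.fixture(scope="session")
def aligned_polarization_results():
    """Polarization-omission study with the crystal 2-fold axis of the
    first dataset aligned to the spindle/polarization axis; full 1.4 A
    resolution (384^2 detector, 180 x 1 deg)."""
    base = dk.SyntheticSpec(seed=23, n_frames=180, rotation_step=1.0)
    model = dk.make_toy_model(base)
    truth = dk.make_truth_volume(model, base.sigma, base.gamma, "llm", "zero",
                                 base.hmax, oversample=2)
    geometry = dk.default_geometry(384)
    datasets = []
    for rep in range(2):
        spec = replace(base, replicate=rep)
        orient = dk.make_orientation(spec, align_unique_axis=(rep == 0))
        cr, bg = dk.render_frames(truth, spec, geometry, orient)
        datasets.append((cr, bg, orient))
    df = ablation_matrix(datasets, geometry, model.cell, PipelineConfig(hmax=30),
                         {"standard": {}, "no_polarization": {"polarization": False}})
    return df
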