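"""Shared phantom fixtures.

Phantom studies are generated once per session at the scale the analyses
need (0.6 mm isotropic grids around a 10 mm x 30 mm device) and shared
across test modules; everything downstream of the generator is
deterministic, so sharing is safe.
"""

from __future__ import annotations

import time

import numpy as np
import pytest

from tavi4d import PhantomSpec, PipelineConfig, generate_phantom, run_pipeline

# phantom-scale th2: the synthetic frame has ~1e4 strut voxels at 0.6 mm
# spacing, so the minimum island size is rescaled from the clinical value
PHANTOM_CFG = PipelineConfig(th2=1000)

CYL_R = 10.0
CYL_L = 30.0
CYL_SPACING = 0.6


@pytest.fixture(scope="session")
def cyl_phantom():
    """Straight cylinder device, nested in a 14 mm lumen, one phase."""
    spec = PhantomSpec(
        grid_shape=(96, 96, 96),
        spacing=(CYL_SPACING,) * 3,
        frame_radius_mm=CYL_R,
        frame_length_mm=CYL_L,
        lumen_radius_mm=14.0,
        lumen_extension_outflow_mm=12.0,
        n_phases=1,
        seed=11,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def cyl_result(cyl_phantom):
    """Full pipeline on the straight cylinder, with wall-clock time."""
    study, truth = cyl_phantom
    t0 = time.perf_counter()
    res = run_pipeline(study, PHANTOM_CFG, patient_id="cyl")
    elapsed = time.perf_counter() - t0
    return res, truth, elapsed


@pytest.fixture(scope="session")
def artifact_phantom():
    """Cylinder plus 10 sub-threshold speckles and a solid calcification."""
    spec = PhantomSpec(
        grid_shape=(104, 104, 96),
        spacing=(CYL_SPACING,) * 3,
        frame_radius_mm=CYL_R,
        frame_length_mm=CYL_L,
        lumen_radius_mm=14.0,
        lumen_extension_outflow_mm=12.0,
        n_phases=1,
        n_speckles=10,
        calcification={"offset_mm": (24.0, 0.0, 0.0), "radii_mm": (7.0, 6.5, 6.0)},
        seed=12,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def branch_phantom():
    """Nested tubes with a 2 mm coronary-like side branch on the lumen."""
    spec = PhantomSpec(
        grid_shape=(96, 96, 96),
        spacing=(CYL_SPACING,) * 3,
        frame_radius_mm=CYL_R,
        frame_length_mm=CYL_L,
        lumen_radius_mm=14.0,
        lumen_extension_outflow_mm=12.0,
        n_phases=1,
        branch={"h": 0.35, "radius_mm": 2.0, "length_mm": 12.0, "azimuth_deg": 30.0},
        seed=13,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def moving_phantom():
    """Four phases translated 2 mm along z per phase."""
    tr = np.array([[0.0, 0.0, 2.0 * t] for t in range(4)])
    spec = PhantomSpec(
        grid_shape=(96, 96, 104),
        spacing=(CYL_SPACING,) * 3,
        frame_radius_mm=CYL_R,
        frame_length_mm=CYL_L,
        lumen_radius_mm=14.0,
        lumen_extension_outflow_mm=8.0,
        n_phases=4,
        per_phase_translation_mm=tr,
        seed=14,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def moving_result(moving_phantom):
    study, _ = moving_phantom
    return run_pipeline(study, PHANTOM_CFG, patient_id="moving")


@pytest.fixture(scope="session")
def static_result():
    """Four identical phases (no motion, no noise): masks repeat exactly."""
    spec = PhantomSpec(
        grid_shape=(96, 96, 96),
        spacing=(CYL_SPACING,) * 3,
        frame_radius_mm=CYL_R,
        frame_length_mm=CYL_L,
        lumen_radius_mm=14.0,
        lumen_extension_outflow_mm=12.0,
        n_phases=4,
        noise_sd=0.0,
        seed=15,
    )
    study, truth = generate_phantom(spec)
    return run_pipeline(study, PHANTOM_CFG, patient_id="static"), truth


@pytest.fixture(scope="session")
def tilt_recovery():
    """Axis-angle estimation error and post-reformat residual per tilt."""
    from tavi4d import (
        SegmentationParams,
        build_rotation,
        fill_largest_cavity,
        principal_axis,
        reformat,
        segment_frame,
    )

    out = []
    for tilt in (5.0, 10.0, 20.0, 30.0):
        spec = PhantomSpec(
            grid_shape=(96, 96, 96), spacing=(CYL_SPACING,) * 3,
            frame_radius_mm=CYL_R, frame_length_mm=CYL_L,
            lumen_radius_mm=14.0, lumen_extension_outflow_mm=10.0,
            tilt_deg=tilt, n_phases=1, seed=21,
        )
        study, truth = generate_phantom(spec)
        frame = segment_frame(study[0], SegmentationParams(th1=800, th2=1000))
        filling = fill_largest_cavity(frame)
        v = principal_axis(filling)
        err = np.degrees(np.arccos(min(abs(float(v @ truth.axis_direction[0])), 1.0)))
        ax = build_rotation(v, study[0].physical_center())
        v_ref = principal_axis(reformat(filling, ax))
        resid = np.degrees(np.arccos(min(abs(float(v_ref[2])), 1.0)))
        out.append({"tilt": tilt, "theta_deg": np.degrees(ax.theta),
                    "err_deg": err, "resid_deg": resid})
    return out


def barrel_radius(h):
    return 10.0 + 2.0 * np.exp(-(((h - 0.45) / 0.18) ** 2))


def taper_radius(h):
    return 12.0 - 3.0 * h


@pytest.fixture(scope="session")
def barrel_result():
    spec = PhantomSpec(
        grid_shape=(104, 104, 96),
        spacing=(CYL_SPACING,) * 3,
        frame_radius_mm=barrel_radius,
        frame_length_mm=CYL_L,
        lumen_radius_mm=16.0,
        lumen_extension_outflow_mm=10.0,
        n_phases=2,
        seed=16,
    )
    study, truth = generate_phantom(spec)
    return run_pipeline(study, PHANTOM_CFG, patient_id="barrel"), truth


@pytest.fixture(scope="session")
def taper_result():
    """Monotone caliber decrease from the outflow (CoreValve-like)."""
    spec = PhantomSpec(
        grid_shape=(104, 104, 96),
        spacing=(CYL_SPACING,) * 3,
        frame_radius_mm=taper_radius,
        frame_length_mm=CYL_L,
        lumen_radius_mm=16.0,
        lumen_extension_outflow_mm=10.0,
        n_phases=2,
        seed=17,
    )
    study, truth = generate_phantom(spec)
    return run_pipeline(study, PHANTOM_CFG, patient_id="taper"), truth
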