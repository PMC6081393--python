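"""Shared fixtures: one noise-free synthetic maxilla with its detection and
one full plate pipeline, built once per session (they back many tests)."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from nammold import plate_builder as pb
from nammold.ridge_detection import detect_ridge
from nammold.synthetic_anatomy import AnatomyParams, generate_cleft_maxilla


@pytest.fixture(scope="session")
def clean_params() -> AnatomyParams:
    return dataclasses.replace(AnatomyParams(), noise_sigma=0.0)


@pytest.fixture(scope="session")
def maxilla(clean_params):
    """Noise-free default cleft maxilla: (mesh, ground truth)."""
    return generate_cleft_maxilla(clean_params)


@pytest.fixture(scope="session")
def noisy_maxilla():
    """Default (scanner-noise) cleft maxilla."""
    return generate_cleft_maxilla(AnatomyParams())


@pytest.fixture(scope="session")
def detection(maxilla):
    return detect_ridge(maxilla[0])


@pytest.fixture(scope="session")
def plate_chain(maxilla, detection):
    """Full plate pipeline on the default cast at default settings."""
    mesh, _ = maxilla
    spec = pb.PlateSpec()
    regions = pb.select_bridge_regions(mesh, detection)
    bridged = pb.bridge_gap(
        mesh, regions, detection.ellipse, detection=detection, pitch=spec.voxel_pitch
    )
    plate = pb.build_plate(bridged, detection, spec)
    pin = pb.add_retention_pin(plate, spec)
    hole = pb.add_ventilation_hole(pin, spec)
    smooth = pb.smooth_plate(hole, spec)
    return {
        "cast": mesh,
        "spec": spec,
        "regions": regions,
        "bridged": bridged,
        "plate": plate,
        "pin": pin,
        "hole": hole,
        "smooth": smooth,
    }


@pytest.fixture(scope="session")
def hole_center_world(detection):
    """World position of the default ventilation-hole axis (for exclusions)."""
    from nammold._geometry import ellipse_point
    from nammold.plate_builder import _anterior_arc_param

    ell = detection.ellipse
    t = _anterior_arc_param(detection)
    xy = ellipse_point(ell.center, ell.a, ell.b, ell.theta, t)
    inward = np.array([ell.center[0] - xy[0], ell.center[1] - xy[1]])
    inward /= np.linalg.norm(inward)
    cxy = xy + 6.0 * inward  # default hole_offset
    return detection.frame.to_world(np.array([[cxy[0], cxy[1], 2.0]]))[0]
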