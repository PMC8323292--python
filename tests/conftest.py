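"""Shared fixtures: all image fixtures are generated at test time from the
synthetic scene module (ground truth included), never stored on disk."""

import numpy as np
import pytest

from atnav.detection import detect_all_sections
from atnav.geometry import SectionQuad
from atnav.imageproc import preprocess_overview
from atnav.synthetic import SceneParams, generate_scene, render_overview

PPM_20X = 2.96  # overview pixels per micrometre (20x lens)


@pytest.fixture(scope="session")
def small_scene():
    """One ribbon of 8 sections with one tracked ROI; cheap to render."""
    params = SceneParams(n_ribbons=1, total_sections=8, sections_per_ribbon=(8,))
    return generate_scene(params, seed=42)


@pytest.fixture(scope="session")
def small_overview(small_scene):
    return render_overview(small_scene, PPM_20X)


@pytest.fixture(scope="session")
def small_edges(small_overview):
    return preprocess_overview(small_overview)


@pytest.fixture(scope="session")
def small_truth_quads_px(small_scene):
    return [SectionQuad(c * PPM_20X) for c in small_scene.ribbons_um[0]]


@pytest.fixture(scope="session")
def full_scene():
    """The proof-of-concept layout: 6 ribbons, 126 sections of 15-27 each."""
    return generate_scene(SceneParams(), seed=1)


@pytest.fixture(scope="session")
def full_overview(full_scene):
    return render_overview(full_scene, PPM_20X)


@pytest.fixture(scope="session")
def full_edges(full_overview):
    return preprocess_overview(full_overview)


@pytest.fixture(scope="session")
def full_detection(full_scene, full_edges):
    seeds = [
        SectionQuad(full_scene.ribbons_um[r][0] * PPM_20X)
        for r in range(len(full_scene.ribbons_um))
    ]
    return detect_all_sections(full_edges, seeds)
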