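"""Shared fixtures: phantoms and (expensive, session-scoped) pipeline runs."""

import numpy as np
import pytest

from headmesher.phantoms import PRESETS, make_layered_phantom
from headmesher.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def five_layer():
    """Default five-layer sphere phantom (96^3, 1 mm, blur 1 mm)."""
    stack, volumes = make_layered_phantom(PRESETS["five-layer"])
    return stack, volumes


@pytest.fixture(scope="session")
def merged_phantom():
    """Phantom with the CSF/GM boundary merged over a polar cap."""
    stack, volumes = make_layered_phantom(PRESETS["merged-csf-gm"])
    return stack, volumes


@pytest.fixture(scope="session")
def cavity_phantom():
    """Phantom with an air cavity inside the skull layer."""
    stack, volumes = make_layered_phantom(PRESETS["cavity"])
    return stack, volumes


@pytest.fixture(scope="session")
def pipeline_result(five_layer):
    """Full pipeline run on the default phantom (used by many tests)."""
    stack, _ = five_layer
    return run_pipeline(PipelineConfig(), stack)


def merged_config():
    """Pipeline config for the merged phantom: thin the inner (GM) tissue at
    the merged CSF/GM boundary."""
    return PipelineConfig(gap_strategy={("gm", "csf"): "thin_inner"},
                          relabel=False)


@pytest.fixture(scope="session")
def merged_results(merged_phantom):
    """Merged-phantom pipeline: (result_without_relabel, mesh_with_relabel).

    One meshing run; the boundary-recovery step is applied separately so the
    with/without comparison shares all geometry.
    """
    from headmesher.tetmesh import relabel_shared_boundaries

    stack, _ = merged_phantom
    res = run_pipeline(merged_config(), stack)
    relabeled = relabel_shared_boundaries(res.mesh, stack, res.model)
    return res, relabeled


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
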