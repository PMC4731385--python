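"""Shared fixtures: phantoms, the synthetic atlas, and one cached pipeline run."""

import numpy as np
import pytest

from flairmap import phantom as ph
from flairmap.fp_filters import synthetic_atlas
from flairmap.pipeline import run_pipeline_on_volume


@pytest.fixture(scope="session")
def atlas():
    return synthetic_atlas()


@pytest.fixture(scope="session")
def default_phantom():
    """Default 96^3 phantom, ~1% lesion load, noise_sd 4."""
    spec = ph.PhantomSpec(lesions=ph.default_lesions(), noise_sd=4.0, seed=1)
    vol, truth = ph.generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def default_report(default_phantom, atlas):
    _, vol, _ = default_phantom
    return run_pipeline_on_volume(vol, atlas=atlas)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
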