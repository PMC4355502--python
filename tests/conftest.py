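"""Shared fixtures: phantoms and (expensive) end-to-end pipeline runs."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from skimage.transform import resize

from lungseg.phantom import PhantomSpec, make_phantom
from lungseg.pipeline import PipelineConfig, run_one


@pytest.fixture(scope="session")
def standard_phantom():
    """One standard-profile phantom with its ground truth (seed 1)."""
    return make_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(standard_phantom):
    """One full pipeline run on the standard phantom, shared across tests."""
    img, _ = standard_phantom
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_one(img, PipelineConfig(profile="standard"))


@pytest.fixture(scope="session")
def truth_work(standard_phantom):
    """Ground truth downsampled to the fill/FCM working resolution."""
    _, truth = standard_phantom
    return resize(truth.astype(float), (256, 256), order=0, anti_aliasing=False) > 0.5


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
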