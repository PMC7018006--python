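import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from usradiomics.pipeline import run_end_to_end
from usradiomics.roi import RoiPatch
from usradiomics.simulate import SimConfig


def random_patch(rng, max_side=8, levels=8):
    """Small random quantized patch with a random (mostly-true) mask."""
    h = rng.integers(3, max_side + 1)
    w = rng.integers(3, max_side + 1)
    vals = rng.integers(0, levels, size=(h, w))
    mask = rng.random((h, w)) < 0.85
    if mask.sum() < 4:
        mask[:2, :2] = True
    return RoiPatch(values=vals.astype(float), mask=mask, levels=levels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def end_to_end_results():
    """Training/held-out C-indices over 20 seeds, planted-effect and null.

    Computed once per session; shared by the end-to-end recovery tests.
    n=400 per cohort, generator defaults otherwise.
    """
    out = {"strong": [], "null": []}
    for effect in ("strong", "null"):
        for seed in range(20):
            r = run_end_to_end(
                SimConfig(n_patients=400, texture_effect=effect, seed=seed))
            out[effect].append((r.train_c, r.validation_c))
    return out
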