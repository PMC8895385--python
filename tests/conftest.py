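"""Shared fixtures: one filter bank and one small but real fit per session.

The small fit (800 surrogate-texture patches) is what the mechanics tests
(state, adaptation, otc, io) operate on; the acceptance tests build their
own larger fits.  Everything is seeded, so the whole suite is deterministic.
"""

import numpy as np
import pytest

from v1mgsm.estimator import EMConfig, fit_mgsm
from v1mgsm.filterbank import build_filterbank, response_matrix
from v1mgsm.stimuli import TextureParams, texture_patches

SMALL_FIT_SEED = 20260101


@pytest.fixture(scope="session")
def bank():
    return build_filterbank()


@pytest.fixture(scope="session")
def small_X(bank):
    """(800, 72) response matrix of seeded surrogate textures."""
    rng = np.random.default_rng(SMALL_FIT_SEED)
    patches = texture_patches(TextureParams(), 800, rng)
    return response_matrix(patches, bank)


@pytest.fixture(scope="session")
def small_fit(bank, small_X):
    """(state, report) of a quick but converged-ish fit for mechanics tests."""
    cfg = EMConfig(n_iter_max=60, init_seed=SMALL_FIT_SEED)
    return fit_mgsm(small_X, bank, cfg)


@pytest.fixture(scope="session")
def small_state(small_fit):
    return small_fit[0]
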