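import numpy as np
import pytest

import xravessel as xv


@pytest.fixture(scope="session")
def default_phantom():
    """Default fixed-seed phantom sequence with ground truth."""
    return xv.generate_sequence(xv.PhantomConfig())


@pytest.fixture(scope="session")
def fitted(default_phantom):
    """Full pipeline run on the default phantom (shared across tests)."""
    seq, gt = default_phantom
    model = xv.VesselSegmentationModel(seq, truth_masks=gt.vessel_mask)
    return model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
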