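import numpy as np
import pytest

from gstreams.experiments import ExperimentConfig, run_pipeline
from gstreams.l1 import L1Config
from gstreams.l2 import L2Config


@pytest.fixture(scope="session")
def tiny_model():
    """Fast, deterministic end-to-end model for plumbing tests."""
    cfg = ExperimentConfig(
        seed=7,
        ensemble_seconds=30,
        l1=L1Config(n_hidden=24, n_epochs=3, batch_size=256, seed=7),
        l2=L2Config(n_hidden=16, taus_ms=(120, 480), n_epochs=2,
                    batch_size=256, seed=7),
    )
    model, manifest = run_pipeline(cfg)
    return model, manifest, cfg


@pytest.fixture(scope="session")
def scaled_model():
    """Desk-scale study-condition model shared by the behavioral tests:
    64 L1 units, two cRBM contexts, 10 minutes of synthetic ensemble."""
    cfg = ExperimentConfig.scaled_down(seed=1)
    model, manifest = run_pipeline(cfg)
    return model, manifest, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
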