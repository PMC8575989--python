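import numpy as np
import pytest

from perirf import (
    GroundTruthConfig,
    ProbeGrid,
    build_basis,
    make_ground_truth_model,
    simulate_trials,
)


@pytest.fixture(scope="session")
def basis():
    return build_basis()


@pytest.fixture(scope="session")
def small_grid():
    """3x3 probe grid: RF1 and RF2 on opposite edges, FP cells distinct."""
    return ProbeGrid(
        n_cols=3, n_rows=3, rf1_index=1, rf2_index=7, fp1_index=4, fp2_index=8
    )


@pytest.fixture(scope="session")
def planted_model(small_grid):
    """Ground-truth neuron with the default perisaccadic dynamics."""
    return make_ground_truth_model(GroundTruthConfig(), grid=small_grid)


@pytest.fixture(scope="session")
def small_trials(planted_model):
    """200 simulated trials from the planted neuron (shared, read-only)."""
    return simulate_trials(planted_model, 200, seed=1234)


@pytest.fixture(scope="session")
def quiet_model(small_grid):
    """Stimulus-blind constant-rate neuron (no kernels, no history)."""
    cfg = GroundTruthConfig(
        rf1_gain=0.0, late_gain=0.0, rf2_gain=0.0, suppression_gain=0.0,
        history_weights=(0.0,) * 8,
    )
    return make_ground_truth_model(cfg, grid=small_grid)
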