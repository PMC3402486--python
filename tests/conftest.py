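import time
import warnings

import pytest

from oftmech import PhantomConfig, RunConfig, render_sequences, run_pipeline


@pytest.fixture(scope="session")
def phantom_default():
    """Default-condition phantom (intensity only) with ground truth."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seqs, truth = render_sequences(PhantomConfig(seed=1),
                                       include_doppler=False)
    return seqs, truth


@pytest.fixture(scope="session")
def pipeline_default():
    """One full default pipeline run (seed 1), timed for the runtime check."""
    t0 = time.perf_counter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline(RunConfig(seed=1))
    elapsed = time.perf_counter() - t0
    return result, elapsed


@pytest.fixture()
def tiny_config():
    """Two-plane, short phantom for fast end-to-end determinism tests."""
    phantom = PhantomConfig.with_n_planes(2, n_cycles=2, seed=11)
    return RunConfig(phantom=phantom, n_phases=48, seed=11)
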