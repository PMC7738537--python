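import numpy as np
import pytest

import txends as tx


@pytest.fixture
def params():
    return tx.CallingParams()


@pytest.fixture
def replicon():
    return tx.Replicon("chr1", 10_000)


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared across read-only tests."""
    return tx.simulate(tx.SimulationParams(seed=424242))


def make_spiky_track(length, spike_positions, spike_height, strand="+",
                     end_type=tx.FIVE_PRIME, label="t", background="alternating"):
    """Deterministic track: 0/2 alternating background plus spikes.

    The alternating background has mean 1 and population SD 1 in any
    balanced window, which makes expected z-scores easy to state.
    """
    counts = np.tile([0, 2], (length + 1) // 2)[:length].astype(np.int64)
    for pos in spike_positions:
        counts[pos - 1] = spike_height
    if background == "flat0":
        counts[:] = 0
        for pos in spike_positions:
            counts[pos - 1] = spike_height
    return tx.EndCountTrack(
        replicon_id="chr1", strand=strand, end_type=end_type,
        counts=counts, library_label=label, library_size=int(counts.sum()) or 1,
    )
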