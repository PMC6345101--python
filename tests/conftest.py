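import numpy as np
import pytest

from gammacoh.io import Epoch, Event, StateAnnotation
from gammacoh.synth import SyntheticConfig, SyntheticStateParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_annotation(state_blocks, events=()):
    """Build a StateAnnotation from [(state, duration_s), ...] blocks."""
    epochs = []
    t = 0.0
    for state, dur in state_blocks:
        n = int(dur // 10)
        for k in range(n):
            epochs.append(Epoch(t + 10.0 * k, 10.0, state))
        t += 10.0 * n
    return StateAnnotation(epochs=epochs, events=list(events))


def coupled_pair_config(coupling, dur_s=200.0, rate=1.5, amp=25.0, seed=0,
                        background=0.0, jitter_ms=0.0, amp_scatter=0.0):
    """Two-channel config with a single always-on state; used wherever a
    pair with known coupling is needed."""
    bg = [((30.0, 45.0), background)] if background > 0 else []
    params = SyntheticStateParams(
        state_label="AW", burst_rate=rate, burst_amp=amp,
        coupling_fraction=coupling, background_spec=bg,
        jitter_ms=jitter_ms, amp_scatter=amp_scatter)
    return SyntheticConfig(per_state={"AW": params},
                           state_sequence=[("AW", dur_s)], seed=seed)
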