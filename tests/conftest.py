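import numpy as np
import pytest

from plee import (
    BreathModelParams,
    SignalRecording,
    parse_signal_file,
    simulate_recording,
)
from plee.fluxmed_io import EXAMPLE_SIGNALS_TEXT


@pytest.fixture
def example_file(tmp_path):
    """The 13-sample documentation excerpt of the monitor dialect, on disk."""
    path = tmp_path / "P001" / "signals.txt"
    path.parent.mkdir()
    path.write_text(EXAMPLE_SIGNALS_TEXT)
    return path


@pytest.fixture
def example_rec(example_file):
    return parse_signal_file(example_file)


#: The 12 transpulmonary pressures of the excerpt that pass the
#: end-expiratory filter at set PEEP 6 (every row except the all-zero
#: first one), transcribed by hand for oracle computations.
EXAMPLE_RETAINED_PL = [6.1, 6.3, 6.4, 6.4, 6.1, 6.3, 6.4, 6.4, 6.1, 6.1, 6.3, 6.3]


@pytest.fixture(scope="session")
def short_sim():
    """One-minute default-conditions recording plus its ground truth."""
    params = BreathModelParams(set_peep=10.0, duration_s=60.0, seed=11)
    rec, truth = simulate_recording(params)
    return params, rec, truth


def make_recording(
    paw, flow, pl, sampling_hz=256.0, source_id="synthetic", **extra
) -> SignalRecording:
    """Small hand-made recording on a uniform grid (test helper)."""
    paw = np.asarray(paw, dtype=float)
    n = paw.size
    return SignalRecording(
        time=np.arange(n) / sampling_hz,
        flow=np.asarray(flow, dtype=float),
        paw=paw,
        pl=np.asarray(pl, dtype=float),
        sampling_hz=sampling_hz,
        source_id=source_id,
        **extra,
    )
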