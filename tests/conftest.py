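import numpy as np
import pytest

from ssbkit.core import RatioMeasurement, Role


def acq(role, mean_ratio, std_error=0.0, seq=None, label=None, n_cycles=1, _counter=[0]):
    """Shorthand constructor for a RatioMeasurement with auto seq_index."""
    if seq is None:
        seq = _counter[0]
    _counter[0] = seq + 1
    if label is None:
        label = "STD" if Role.parse(role) is Role.STANDARD else "SMP"
    return RatioMeasurement(
        label=label,
        role=role,
        seq_index=seq,
        mean_ratio=mean_ratio,
        std_error=std_error,
        n_cycles=n_cycles,
    )


def make_run(pattern, ratio_std=1.0, ratio_smp=1.001, sigma=0.0):
    """Build a run from a pattern string like 'sXs' (s=standard, X=sample)."""
    run = []
    for i, ch in enumerate(pattern):
        if ch in "sS":
            run.append(acq("standard", ratio_std, sigma, seq=i))
        else:
            run.append(acq("sample", ratio_smp, sigma, seq=i, label="SMP"))
    return run


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
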