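import numpy as np
import pytest

from nfsonic.connectivity import CorrTrace, fisher_z
from nfsonic.paradigm import build_localizer_schedule, build_nf_schedule
from nfsonic.synthbold import SimConfig, simulate_pair


@pytest.fixture
def nf_schedule():
    """Default neurofeedback schedule: 4 × (30 s rest + 30 s imagery), TR 1.5 s."""
    return build_nf_schedule()


@pytest.fixture
def localizer_schedule():
    return build_localizer_schedule()


@pytest.fixture
def sim_run(nf_schedule):
    """One simulated run under default coupling (imagery 0.7, rest 0.1)."""
    return simulate_pair(nf_schedule, SimConfig(seed=123))


def make_trace(r, tr=1.5, window=8, valid=None):
    """Build a CorrTrace directly from given r values (valid everywhere
    unless a mask is passed) — for driving the sonifier in isolation."""
    r = np.asarray(r, dtype=float)
    valid = np.ones(r.size, dtype=bool) if valid is None else np.asarray(valid, bool)
    z = np.full(r.size, np.nan)
    z[valid] = fisher_z(np.clip(r[valid], -1, 1))
    return CorrTrace(r=r, z=z, valid=valid, window=window, tr=tr)
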