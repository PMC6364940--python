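import numpy as np
import pytest

from isletsync.model import ModelParams, simulate


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def unperturbed_2h(default_params):
    """Shared 2-hour unperturbed default-parameter trajectory."""
    return simulate(default_params, None, t_end=7200.0, dt_out=1.0)


@pytest.fixture(scope="session")
def ca_trace_2h(unperturbed_2h):
    from isletsync.analysis import Trace

    tr = unperturbed_2h
    mask = tr.times >= 1200.0
    return Trace(tr.times[mask], tr["ca_c"][mask])
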