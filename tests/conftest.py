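import numpy as np
import pytest

import optomap as om


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def voltage_trace_clean():
    """Noiseless rat-like voltage phantom trace, already upright."""
    spec = om.PhantomSpec(emit_inverted=False)
    trace, truth = om.make_trace(spec)
    return trace, truth


@pytest.fixture()
def calcium_trace_clean():
    spec = om.PhantomSpec(signal_kind="calcium", emit_inverted=False)
    trace, truth = om.make_trace(spec)
    return trace, truth


@pytest.fixture()
def full_window():
    def _make(trace, percent=80.0, max_interval=400.0):
        return om.AnalysisWindow(
            start_marker=float(trace.times_ms[0]),
            end_marker=float(trace.times_ms[-1]),
            max_interval=max_interval,
            percent=percent,
        )

    return _make


@pytest.fixture()
def small_stack(rng):
    """Tiny 10x10 noiseless planar-wave voltage stack with ground truth."""
    spec = om.PhantomSpec(
        shape=(10, 10), scale=10.0, geometry="full", emit_inverted=False
    )
    return om.make_stack(spec)
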