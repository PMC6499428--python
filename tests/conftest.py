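"""Shared fixtures: the expensive simulation runs are session-scoped so the
planar temperature study and the reentry scenarios are each computed once."""

import numpy as np
import pytest

from cardioheat.measurements import Trace
from cardioheat.protocols import build_protocol, run_protocol
from cardioheat.time_stepping import SolverConfig


def planar_strip_run(tstar, dx=0.025, dt=0.1, duration=750.0, snapshot_stride=30.0):
    """Planar MS wave on a thin strip (y-invariant, equivalent to the sheet)."""
    proto = build_protocol(
        "planar_q10",
        tstar=tstar,
        domain=(10.0, 4 * dx),
        dx=dx,
        dt=dt,
        duration=duration,
        probes=((6.0, 2 * dx), (6.5, 2 * dx), (7.0, 2 * dx)),
        snapshot_stride=snapshot_stride,
    )
    res = run_protocol(proto, SolverConfig(dt=dt))
    traces = [
        Trace(x=p[0], y=p[1], t=res.times, Vm=res.trace(i))
        for i, p in enumerate(proto.probes)
    ]
    return res, traces


@pytest.fixture(scope="session")
def planar_runner():
    """The strip-run helper, exposed to test modules as a fixture."""
    return planar_strip_run


@pytest.fixture(scope="session")
def planar37():
    return planar_strip_run(37.0)


@pytest.fixture(scope="session")
def planar27():
    return planar_strip_run(27.0)
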