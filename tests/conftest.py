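"""Shared fixtures: default parameter sets and the handful of expensive
reference simulations (session-scoped so the depression/recovery runs are
integrated once and shared between unit and acceptance tests)."""

import pytest

from svpools.engine import SimOptions, integrate_scheme, run_recovery_restart
from svpools.kinetic_models import (make_one_pool_scheme, make_parallel_scheme,
                                    make_sequential_scheme, resting_state)
from svpools.stimulus import CaParams, build_regular_train


@pytest.fixture(scope="session")
def ca():
    return CaParams()


@pytest.fixture(scope="session")
def ca_no_residual(ca):
    """Sensor driven by the AP train alone (allosteric comparators)."""
    return ca.replace(sensor_sees_residual=False)


@pytest.fixture(scope="session")
def opts():
    return SimOptions()


@pytest.fixture(scope="session")
def seq_scheme():
    return make_sequential_scheme()


@pytest.fixture(scope="session")
def seq_rest(seq_scheme, ca):
    return resting_state(seq_scheme, ca.ca_rest)


@pytest.fixture(scope="session")
def seq_100hz(seq_scheme, seq_rest, ca, opts):
    """Sequential model, 50 pulses at 100 Hz from rest."""
    return integrate_scheme(seq_scheme, build_regular_train(100.0, 50),
                            ca, seq_rest, opts)


@pytest.fixture(scope="session")
def seq_50hz(seq_scheme, seq_rest, ca, opts):
    return integrate_scheme(seq_scheme, build_regular_train(50.0, 50),
                            ca, seq_rest, opts)


@pytest.fixture(scope="session")
def recovery_bundle(seq_scheme, seq_rest, ca, opts):
    """Low-frequency depression (300 x 2 Hz), the restarted 100 Hz train,
    and a control 100 Hz train from rest (same lead-in)."""
    lfd = build_regular_train(2.0, 300)
    traj_lfd, traj_rec = run_recovery_restart(seq_scheme, lfd, 100.0, 50,
                                              ca, opts)
    t_lead = traj_rec.protocol.pulse_times[0]
    ctrl = integrate_scheme(seq_scheme,
                            build_regular_train(100.0, 50, t0=t_lead),
                            ca, seq_rest, opts)
    return traj_lfd, traj_rec, ctrl


@pytest.fixture(scope="session")
def seq_2hz(recovery_bundle):
    """Sequential model, 300 pulses at 2 Hz (the LFD protocol)."""
    return recovery_bundle[0]


@pytest.fixture(scope="session")
def onepool_runs(ca_no_residual, opts):
    scheme = make_one_pool_scheme()
    rest = resting_state(scheme, ca_no_residual.ca_rest)
    low = integrate_scheme(scheme, build_regular_train(2.0, 50),
                           ca_no_residual, rest, opts)
    high = integrate_scheme(scheme, build_regular_train(100.0, 50),
                            ca_no_residual, rest, opts)
    return low, high


@pytest.fixture(scope="session")
def parallel_runs(ca_no_residual, opts):
    scheme = make_parallel_scheme()
    rest = resting_state(scheme, ca_no_residual.ca_rest)
    low = integrate_scheme(scheme, build_regular_train(2.0, 50),
                           ca_no_residual, rest, opts)
    high = integrate_scheme(scheme, build_regular_train(100.0, 50),
                            ca_no_residual, rest, opts)
    return low, high
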