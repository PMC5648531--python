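"""Scheme construction, ladder equilibria and resting states."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import null_space

from svpools.kinetic_models import (AllostericParams, InfluxTerm,
                                    ParallelPoolParams, SensorParams,
                                    SequentialPoolParams, ladder_weights,
                                    make_one_pool_scheme, make_parallel_scheme,
                                    make_sequential_scheme, params_from_dict,
                                    params_to_json, resting_state,
                                    sensor_equilibrium)


class TestSequentialScheme:
    def test_structure(self, seq_scheme):
        assert seq_scheme.labels == ("R0", "R1", "V0", "V1", "V2", "V3", "V4", "V5")
        assert seq_scheme.n_states == 8
        assert seq_scheme.recycle_to == seq_scheme.index("R0")
        assert seq_scheme.recycle_fraction == 0.9

    def test_rates_vanish_at_zero_calcium(self, seq_scheme):
        K = seq_scheme.rate_matrix(0.0, 0.0)
        # Ca-dependent transitions: R0->R1 priming and all V-ladder binding
        assert K[seq_scheme.index("R0"), seq_scheme.index("R1")] == 0.0
        for j in range(5):
            assert K[seq_scheme.index(f"V{j}"), seq_scheme.index(f"V{j+1}")] == 0.0

    def test_cooperative_unbinding_ladder(self, seq_scheme):
        # off-rate from Vj to Vj-1 is j * k_off * b**(j-1)
        Q0 = seq_scheme.Q0
        idx = seq_scheme.index
        assert Q0[idx("V3"), idx("V2")] == pytest.approx(3 * 3000 * 0.25 ** 2)
        assert Q0[idx("V3"), idx("V2")] == pytest.approx(562.5)
        assert Q0[idx("V1"), idx("V0")] == pytest.approx(3000.0)
        assert Q0[idx("V5"), idx("V4")] == pytest.approx(5 * 3000 * 0.25 ** 4)

    def test_fusion_only_from_fully_bound_state(self, seq_scheme):
        fuse = seq_scheme.fuse
        assert fuse[seq_scheme.index("V5")] == 5000.0
        assert np.all(fuse[:7] == 0.0)

    @given(cs=st.floats(0, 1e-3), cr=st.floats(0, 1e-4))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rate_matrix_nonnegative_for_any_calcium(self, seq_scheme, cs, cr):
        K = seq_scheme.rate_matrix(cs, cr)
        assert np.all(K >= 0.0)


class TestOnePoolScheme:
    def test_fusion_ladder_scaling(self):
        scheme = make_one_pool_scheme()
        p = scheme.params
        assert scheme.fuse[0] == pytest.approx(p.l_plus)  # spontaneous release
        assert scheme.fuse[5] / scheme.fuse[0] == pytest.approx(p.f ** 5)

    def test_constant_reload_refills_empty_pool_linearly(self, ca, opts):
        # 2 SV/ms into an empty pool of 100 -> full at 50 ms (no release)
        from svpools.engine import integrate_scheme
        from svpools.stimulus import PulseProtocol
        params = AllostericParams(l_plus=1e-12, pool_size=100.0,
                                  reload_rate=2000.0, reload_capped=True)
        scheme = make_one_pool_scheme(params)
        traj = integrate_scheme(scheme, PulseProtocol(np.array([])), ca,
                                np.zeros(6), opts, t_end=0.08)
        total = traj.states.sum(axis=1)
        assert np.interp(0.025, traj.t, total) == pytest.approx(50.0, rel=1e-3)
        assert total[-1] == pytest.approx(100.0, rel=2e-3)  # capped at pool size
        assert np.interp(0.05, traj.t, total) >= 99.5

    def test_reload_cap_rejected_for_parallel_scheme(self):
        params = ParallelPoolParams(
            fast=AllostericParams(reload_capped=True),
            slow=AllostericParams(l_plus=2e-5, reload_capped=True))
        with pytest.raises(NotImplementedError):
            make_parallel_scheme(params)


class TestParallelScheme:
    def test_structure(self):
        scheme = make_parallel_scheme()
        assert scheme.n_states == 12
        assert scheme.labels[:6] == ("F0", "F1", "F2", "F3", "F4", "F5")

    def test_slow_pool_must_be_slower(self):
        with pytest.raises(ValueError):
            ParallelPoolParams(fast=AllostericParams(),
                               slow=AllostericParams())

    def test_release_is_sum_of_independent_pools(self, ca_no_residual, opts):
        # non-interacting pools: parallel p_r equals fast-alone + slow-alone
        from svpools.engine import integrate_scheme
        from svpools.stimulus import build_regular_train
        par = make_parallel_scheme()
        prot = build_regular_train(100.0, 3)
        rest = resting_state(par, ca_no_residual.ca_rest)
        traj = integrate_scheme(par, prot, ca_no_residual, rest, opts)
        total = np.zeros(3)
        for params in (par.params.fast, par.params.slow):
            one = make_one_pool_scheme(params)
            tr = integrate_scheme(one, prot, ca_no_residual,
                                  resting_state(one, ca_no_residual.ca_rest),
                                  opts)
            total += tr.p_r
        assert np.allclose(traj.p_r, total, rtol=1e-6)
        assert np.all(traj.p_r >= np.maximum(total - traj.p_r, 0))


class TestSensorEquilibrium:
    def test_all_unbound_at_zero_calcium(self):
        pi = sensor_equilibrium(SensorParams(), 0.0)
        assert np.allclose(pi, [1, 0, 0, 0, 0, 0])

    def test_saturation_at_high_calcium(self):
        pi = sensor_equilibrium(SensorParams(), 1.0)  # 1 M
        assert pi[5] > 0.999999

    def test_binomial_limit_without_cooperativity(self):
        # b = 1 and Ca = k_off/k_on = 30 uM -> independent sites at p = 1/2
        params = SensorParams(b=1.0)
        pi = sensor_equilibrium(params, 30e-6)
        from math import comb
        expected = np.array([comb(5, j) for j in range(6)]) / 32.0
        assert np.allclose(pi, expected, rtol=1e-12)

    @pytest.mark.parametrize("ca_level", [10e-9, 1e-6, 30e-6, 1e-3])
    def test_matches_null_space_of_ladder_generator(self, ca_level):
        # independent oracle: stationary vector of the gamma=0 birth-death
        # ladder obtained by brute-force null space
        p = SensorParams()
        n = 6
        M = np.zeros((n, n))
        for j in range(5):
            up = (5 - j) * p.k_on * ca_level
            down = (j + 1) * p.k_off * p.b ** j
            M[j, j] -= up
            M[j + 1, j] += up
            M[j + 1, j + 1] -= down
            M[j, j + 1] += down
        ns = null_space(M)
        assert ns.shape[1] == 1
        ref = np.abs(ns[:, 0])
        ref /= ref.sum()
        pi = sensor_equilibrium(p, ca_level)
        # 1e-9 relative agreement, with the float64 oracle's own absolute
        # resolution (~1e-16) as the floor for vanishing occupancies
        assert np.all(np.abs(pi - ref) <= 1e-9 * ref + 1e-16)


class TestRestingState:
    def test_sequential_flux_balance(self, seq_scheme, ca):
        rest = resting_state(seq_scheme, ca.ca_rest)
        idx = seq_scheme.index
        v0, r1, r0 = rest[idx("V0")], rest[idx("R1")], rest[idx("R0")]
        p = seq_scheme.params
        # closed-form flux balance: R1/V0 = k_unfil/k_fill,
        # R0/R1 = k_unprim/(k_prim * Ca)
        assert r1 / v0 == pytest.approx(p.k_unfil / p.k_fill, rel=1e-6)
        assert r0 / r1 == pytest.approx(
            p.k_unprim / (p.k_prim * ca.ca_rest), rel=1e-6)
        assert rest[2:].sum() == pytest.approx(1.0)  # normalized V pool
        assert r1 == pytest.approx(0.75, rel=1e-2)
        assert r0 == pytest.approx(2.25, rel=1e-2)

    def test_sequential_low_calcium_limit(self, seq_scheme):
        # as Ca -> 0 priming stalls and R0 dwarfs the other pools
        rest = resting_state(seq_scheme, 1e-12)
        assert rest[seq_scheme.index("R0")] > 1e5

    def test_sequential_rest_undefined_at_zero_calcium(self, seq_scheme):
        with pytest.raises(ValueError):
            resting_state(seq_scheme, 0.0)

    def test_allosteric_rest_is_ladder_equilibrium_over_pool(self, ca):
        scheme = make_one_pool_scheme()
        p = scheme.params
        rest = resting_state(scheme, ca.ca_rest)
        w = ladder_weights(p.k_on, p.k_off, p.b, ca.ca_rest)
        assert rest.sum() == pytest.approx(p.pool_size)
        assert np.allclose(rest, p.pool_size * w / w.sum(), rtol=1e-12)


class TestParamsIO:
    def test_json_round_trip(self, tmp_path):
        import json
        params = SequentialPoolParams(k_prim=5e8,
                                      sensor=SensorParams(b=0.3))
        path = tmp_path / "params.json"
        params_to_json(params, path)
        with open(path) as fh:
            payload = json.load(fh)
        rebuilt = params_from_dict("sequential", payload)
        assert rebuilt == params

    def test_every_default_overridable(self):
        p = params_from_dict("one_pool", {"l_plus": 1e-3, "pool_size": 10})
        assert p.l_plus == 1e-3 and p.pool_size == 10
        p = params_from_dict("parallel", {"slow": {"l_plus": 1e-6}})
        assert p.slow.l_plus == 1e-6

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            SensorParams(b=1.5)
        with pytest.raises(ValueError):
            AllostericParams(f=0.5)
        with pytest.raises(ValueError):
            SequentialPoolParams(recycle_fraction=1.5)
        assert InfluxTerm("constant", 0, 1.0).flux(np.zeros(1)) == 1.0
        with pytest.raises(ValueError):
            InfluxTerm("bogus", 0, 1.0).flux(np.zeros(1))
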