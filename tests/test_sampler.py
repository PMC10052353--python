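"""Metropolis propagation, replica exchange and mixing diagnostics."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from reedsnet.eds_core import EDSParameters, reference_energy_from_states
from reedsnet.sampler import (
    EnergyTrajectory,
    ExchangeRecord,
    ReplicaState,
    attempt_exchange,
    default_proposal_width,
    propagate,
    roundtrip_stats,
    run_re_eds,
    trajectory_from_csv,
    trajectory_to_csv,
)
from reedsnet.toy_model import EndStateSystem, SiteSpec, ThermoConditions, Well


def fresh_replica(system, s, offsets, seed, x=None):
    r = ReplicaState(
        0, s, np.zeros(system.n_sites), np.empty(system.n_states), 0.0,
        np.random.default_rng(seed),
    )
    if x is not None:
        r.x = np.asarray(x, dtype=float)
    r.refresh_energies(system, offsets)
    return r


@pytest.fixture(scope="module")
def symmetric_two_state():
    """Mirror-image water/probe wells: exactly symmetric two-state system."""
    return EndStateSystem(
        [SiteSpec(1, Well(-0.25, 4.0), Well(0.25, 4.0), Well(0.0, 0.5))],
        (),
        ThermoConditions(),
    )


class TestPropagate:
    def test_same_seed_gives_identical_trajectories(self, two_state_system):
        offs = [0.0, 0.0]
        r1 = fresh_replica(two_state_system, 1.0, offs, seed=5)
        r2 = fresh_replica(two_state_system, 1.0, offs, seed=5)
        _, t1 = propagate(r1, two_state_system, offs, 300, 0.1)
        _, t2 = propagate(r2, two_state_system, offs, 300, 0.1)
        np.testing.assert_array_equal(t1.v_states, t2.v_states)
        np.testing.assert_array_equal(t1.v_ref, t2.v_ref)
        np.testing.assert_array_equal(r1.x, r2.x)

    def test_vanishing_proposal_width_accepts_everything_in_place(self, two_state_system):
        offs = [0.0, 0.0]
        r = fresh_replica(two_state_system, 1.0, offs, seed=1, x=[0.05])
        x0 = r.x.copy()
        _, traj = propagate(r, two_state_system, offs, 500, 1e-12)
        assert abs(r.x[0] - x0[0]) < 1e-8
        assert np.ptp(traj.v_ref) < 1e-8

    def test_harmonic_stationary_variance(self):
        # single end state: stationary law is Gaussian with var = kT/k_eff
        system = EndStateSystem(
            [SiteSpec(1, Well(0.0, 20.0), Well(0.0, 20.0), Well(0.0, 5.0))],
            (), ThermoConditions(),
        )
        offs = [0.0, 0.0]
        k_eff = 25.0
        var_target = system.conditions.kt / k_eff
        r = fresh_replica(system, 1.0, offs, seed=9)
        xs = []
        for _ in range(3000):
            propagate(r, system, offs, 20, default_proposal_width(system))
            xs.append(r.x[0])
        xs = np.array(xs[200:])  # discard burn-in; thinned by 20 steps
        se = var_target * math.sqrt(2.0 / (xs.size - 1))
        # 3 sigma with a mild inflation for residual thinning correlation
        assert abs(xs.var(ddof=1) - var_target) < 4.5 * se

    def test_invalid_arguments(self, two_state_system):
        r = fresh_replica(two_state_system, 1.0, [0.0, 0.0], seed=0)
        with pytest.raises(ValueError):
            propagate(r, two_state_system, [0.0, 0.0], 0, 0.1)
        with pytest.raises(ValueError):
            propagate(r, two_state_system, [0.0, 0.0], 10, -1.0)


class TestExchange:
    def test_identical_configurations_always_swap(self, two_state_system):
        params = EDSParameters([1.0, 0.2], [0.0, 0.0])
        rng = np.random.default_rng(3)
        for _ in range(20):
            rm = fresh_replica(two_state_system, 1.0, params.offsets, 1, x=[0.1])
            rn = fresh_replica(two_state_system, 0.2, params.offsets, 2, x=[0.1])
            assert attempt_exchange(rm, rn, two_state_system, params, rng)

    def test_non_adjacent_pair_rejected(self, two_state_system):
        params = EDSParameters([1.0, 0.3, 0.1], [0.0, 0.0])
        rm = fresh_replica(two_state_system, 1.0, params.offsets, 1)
        rn = fresh_replica(two_state_system, 0.1, params.offsets, 2)
        with pytest.raises(ValueError, match="not adjacent"):
            attempt_exchange(rm, rn, two_state_system, params, np.random.default_rng(0))

    def test_acceptance_frequency_matches_closed_form_exponent(self, two_state_system):
        params = EDSParameters([1.0, 0.2], [0.0, 0.0])
        beta = two_state_system.conditions.beta
        xm, xn = [0.05], [0.55]
        vm = two_state_system.energies(np.array(xm))
        vn = two_state_system.energies(np.array(xn))
        def vr(v, s):
            return float(reference_energy_from_states(v, s, params.offsets, beta))
        delta = beta * (
            vr(vn, 1.0) + vr(vm, 0.2) - vr(vm, 1.0) - vr(vn, 0.2)
        )
        p_expect = min(1.0, math.exp(-delta))
        assert 0.02 < p_expect < 0.98, "pick a discriminating configuration"
        rng = np.random.default_rng(17)
        n, acc = 4000, 0
        for _ in range(n):
            rm = fresh_replica(two_state_system, 1.0, params.offsets, 1, x=xm)
            rn = fresh_replica(two_state_system, 0.2, params.offsets, 2, x=xn)
            acc += attempt_exchange(rm, rn, two_state_system, params, rng)
        se = math.sqrt(p_expect * (1 - p_expect) / n)
        assert abs(acc / n - p_expect) < 3 * se

    def test_acceptance_decreases_with_ladder_gap(self, coupled_pair):
        rates = []
        for s_min in (0.8, 0.3, 0.03):
            params = EDSParameters([1.0, s_min], np.zeros(8))
            _, rec = run_re_eds(coupled_pair.pocket, params, 120, 40, 4, seed=21)
            rates.append(rec.acceptance_rate())
        assert all(0 < r <= 1 for r in rates)
        assert rates[0] > rates[1] > rates[2]


class TestRunReEds:
    def test_single_replica_reduces_to_plain_metropolis(self, two_state_system):
        params = EDSParameters([1.0], [0.0, 0.0])
        trajs, rec = run_re_eds(two_state_system, params, 5, 50, 1, seed=2)
        assert rec.attempts == []
        assert trajs[1.0].n_frames == 250

    def test_symmetric_system_samples_both_states_equally(self, symmetric_two_state):
        params = EDSParameters([1.0, 0.3], [0.0, 0.0])
        trajs, _ = run_re_eds(symmetric_two_state, params, 40, 500, 5, seed=4)
        traj = trajs[1.0]
        dominant = np.argmax(-(traj.v_states), axis=1)
        f1 = dominant.mean()
        assert abs(f1 - 0.5) < 0.06  # 3 sigma of the thinned binomial spread

    def test_same_seed_reproduces_exchange_record(self, two_state_system):
        params = EDSParameters([1.0, 0.3], [0.0, 0.0])
        _, rec1 = run_re_eds(two_state_system, params, 12, 40, 2, seed=6)
        _, rec2 = run_re_eds(two_state_system, params, 12, 40, 2, seed=6)
        assert rec1.attempts == rec2.attempts
        np.testing.assert_array_equal(rec1.rung_history, rec2.rung_history)

    def test_stored_reference_energy_reproducible_from_state_energies(self, coupled_pocket_run):
        params, traj = coupled_pocket_run
        vr = reference_energy_from_states(traj.v_states, 1.0, params.offsets, traj.beta)
        assert np.abs(vr - traj.v_ref).max() < 1e-9


class TestRoundtrips:
    @staticmethod
    def record_from_history(hist):
        return ExchangeRecord(attempts=[], rung_history=np.asarray(hist))

    def test_pinned_walker_makes_no_roundtrips(self):
        rec = self.record_from_history([[0, 1]] * 9)
        counts, mean = roundtrip_stats(rec)
        assert counts.tolist() == [0, 0]
        assert math.isnan(mean)

    def test_hand_built_top_bottom_top_history(self):
        hist = [[0], [1], [1], [2], [1], [1], [0]]
        counts, mean = roundtrip_stats(self.record_from_history(hist))
        assert counts.tolist() == [1]
        assert mean == pytest.approx(6.0)

    def test_concatenated_history_doubles_trip_count(self):
        hist = np.array([[0], [1], [1], [2], [1], [1], [0]])
        double = np.vstack([hist, hist])
        counts, _ = roundtrip_stats(self.record_from_history(double))
        assert counts.tolist() == [2]


class TestDetailedBalance:
    """Empirical x-distributions vs the quadrature marginal (KS, alpha=0.01).

    The chain is thinned (one sample per 20 steps) so the KS independence
    assumption approximately holds.
    """

    @staticmethod
    def reference_cdf(system, s, offsets):
        beta = system.conditions.beta
        grid = np.linspace(-1.2, 1.5, 4001)
        v = system.energies(grid[:, None])
        a = -beta * s * (v - np.asarray(offsets))
        logrho = (np.logaddexp.reduce(a, axis=1)) / s
        rho = np.exp(logrho - logrho.max())
        cdf = np.cumsum(rho)
        cdf /= cdf[-1]
        return lambda x: np.interp(x, grid, cdf)

    def test_fixed_s_marginal_matches_quadrature(self, two_state_system):
        offs = [0.0, 1.8]
        r = fresh_replica(two_state_system, 1.0, offs, seed=23)
        width = default_proposal_width(two_state_system)
        xs = []
        for _ in range(2700):
            propagate(r, two_state_system, offs, 20, width)
            xs.append(r.x[0])
        xs = np.array(xs[200:])
        cdf = self.reference_cdf(two_state_system, 1.0, offs)
        assert sps.kstest(xs, cdf).pvalue > 0.01

    def test_exchange_preserves_physical_marginal(self, two_state_system):
        params = EDSParameters([1.0, 0.25], [0.0, 1.8])
        rng_ex = np.random.default_rng(31)
        r1 = fresh_replica(two_state_system, 1.0, params.offsets, seed=41)
        r2 = fresh_replica(two_state_system, 0.25, params.offsets, seed=42)
        width = default_proposal_width(two_state_system)
        xs = []
        for phase in range(2700):
            propagate(r1, two_state_system, params.offsets, 20, width)
            propagate(r2, two_state_system, params.offsets, 20, width)
            attempt_exchange(r1, r2, two_state_system, params, rng_ex)
            xs.append(r1.x[0])
        xs = np.array(xs[200:])
        cdf = self.reference_cdf(two_state_system, 1.0, params.offsets)
        assert sps.kstest(xs, cdf).pvalue > 0.01


def test_trajectory_csv_round_trip(tmp_path, coupled_pocket_run):
    _, traj = coupled_pocket_run
    path = tmp_path / "energies.csv"
    trajectory_to_csv(traj.prefix(200), str(path), seed=7)
    back = trajectory_from_csv(str(path))
    assert back.labels == traj.labels
    assert back.beta == pytest.approx(traj.beta, rel=1e-12)
    np.testing.assert_allclose(back.v_states, traj.v_states[:200], rtol=1e-9)
    np.testing.assert_allclose(back.v_ref, traj.v_ref[:200], rtol=1e-9)


def test_trajectory_csv_schema_errors(tmp_path, coupled_pocket_run):
    _, traj = coupled_pocket_run
    path = tmp_path / "energies.csv"
    trajectory_to_csv(traj.prefix(50), str(path))
    text = (tmp_path / "energies.csv").read_text().replace("V_R", "V_X")
    bad = tmp_path / "bad.csv"
    bad.write_text(text)
    with pytest.raises(ValueError, match="V_R"):
        trajectory_from_csv(str(bad))
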