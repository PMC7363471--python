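"""Node equations, network coupling, and the stochastic Heun integrator."""

import numpy as np
import pytest
from scipy.optimize import root

from epileptornet import (
    BlowUpError,
    Connectome,
    CouplingParameters,
    IntegrationConfig,
    NodeParameters,
    heun_stochastic_step,
    mixed_output,
    network_drift,
    node_derivatives,
    simulate,
    single_node_connectome,
)
from conftest import run_single_node


class TestNodeDerivatives:
    def test_equilibrium_found_by_root_finder_has_tiny_drift(self, base_params):
        guess = np.array([-1.7, -13.0, 3.2, -1.0, 0.0, -0.17, 0.18, -0.1])
        sol = root(lambda s: node_derivatives(s, base_params), guess, tol=1e-13)
        assert sol.success
        assert np.linalg.norm(node_derivatives(sol.x, base_params)) < 1e-10

    def test_nonfinite_state_rejected(self, base_params):
        state = np.full(8, np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            node_derivatives(state, base_params)

    def test_subcritical_node_settles_to_equilibrium(self, equilibrium):
        # x0 = -2.5 < threshold: noise-free run from a perturbed start converges
        ic = equilibrium + 0.05
        traj = run_single_node(x0=-2.5, a=1.5, duration=120.0, noise=False,
                               initial_state=ic)
        z = traj.variable("z")[0]
        assert abs(z[-1] - equilibrium[2]) < 1e-2
        assert np.abs(np.diff(z[-1000:])).max() < 1e-6


class TestMixedOutput:
    def test_p_zero_ignores_epileptiform_variables(self, equilibrium):
        s1, s2 = equilibrium.copy(), equilibrium.copy()
        s2[[0, 3]] += 5.0  # change x1, x2 only
        assert mixed_output(s1, 0.0) == mixed_output(s2, 0.0)

    def test_p_one_ignores_healthy_variable(self, equilibrium):
        s1, s2 = equilibrium.copy(), equilibrium.copy()
        s2[6] += 5.0  # change x3 only
        assert mixed_output(s1, 1.0) == mixed_output(s2, 1.0)

    def test_affine_in_p(self, equilibrium):
        o0, o1 = mixed_output(equilibrium, 0.0), mixed_output(equilibrium, 1.0)
        for p in (0.25, 0.5, 0.9):
            assert mixed_output(equilibrium, p) == pytest.approx(
                (1 - p) * o0 + p * o1, abs=1e-12)

    @pytest.mark.parametrize("p", [-0.1, 1.5])
    def test_p_out_of_range_rejected(self, equilibrium, p):
        with pytest.raises(ValueError, match="mixing ratio"):
            mixed_output(equilibrium, p)


class TestNetworkDrift:
    def _params(self, n):
        return [NodeParameters(x0=-2.5, a=1.6, p=0.1)] * n

    def test_identical_states_have_zero_coupling(self, equilibrium):
        # dense symmetric C, all nodes in the same state: both difference
        # couplings vanish exactly, so drift equals the isolated-node drift
        C = np.array([[0, 0.5, 1.0], [0.5, 0, 0.3], [1.0, 0.3, 0]])
        conn = Connectome(labels=["a", "b", "c"], C=C)
        states = np.tile(equilibrium, (3, 1))
        coupling = CouplingParameters(K_s=0.1, K_rs=7.0)
        dS = network_drift(states, conn, coupling, self._params(3))
        iso = node_derivatives(equilibrium, self._params(3)[0])
        for i in range(3):
            np.testing.assert_allclose(dS[i], iso, rtol=0, atol=1e-14)

    def test_zero_connectome_decouples(self, equilibrium):
        conn = Connectome(labels=["a", "b"], C=np.zeros((2, 2)))
        rng = np.random.default_rng(0)
        states = np.tile(equilibrium, (2, 1)) + 0.1 * rng.standard_normal((2, 8))
        dS = network_drift(states, conn, CouplingParameters(K_s=0.1, K_rs=9.0),
                           self._params(2))
        for i in range(2):
            np.testing.assert_allclose(
                dS[i], node_derivatives(states[i], self._params(2)[0]),
                rtol=0, atol=1e-14)

    def test_line_graph_coupling_matches_hand_computation(self, equilibrium):
        # 0 -- 1 -- 2 line graph with weights 1.0 and 0.4
        C = np.array([[0, 1.0, 0], [1.0, 0, 0.4], [0, 0.4, 0]])
        conn = Connectome(labels=["a", "b", "c"], C=C)
        rng = np.random.default_rng(3)
        states = np.tile(equilibrium, (3, 1)) + 0.2 * rng.standard_normal((3, 8))
        Ks, Krs = 0.1, 5.0
        params = self._params(3)
        dS = network_drift(states, conn, CouplingParameters(Ks, Krs), params)
        x1, x3 = states[:, 0], states[:, 6]
        cx1 = [C[i] @ x1 - C[i].sum() * x1[i] for i in range(3)]
        cx3 = [C[i] @ x3 - C[i].sum() * x3[i] for i in range(3)]
        tau0, d = params[0].tau0, params[0].d
        for i in range(3):
            iso = node_derivatives(states[i], params[i])
            assert dS[i, 2] == pytest.approx(iso[2] - Ks * cx1[i] / tau0, abs=1e-13)
            assert dS[i, 6] == pytest.approx(iso[6] + d * Krs * cx3[i], abs=1e-13)

    def test_dimension_mismatch_rejected(self, equilibrium):
        conn = Connectome(labels=["a", "b"], C=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="does not match"):
            network_drift(np.tile(equilibrium, (3, 1)), conn,
                          CouplingParameters(), self._params(3))


class TestHeunStep:
    def test_linear_drift_matches_exponential_to_second_order(self):
        # x' = -x: Heun gives the second-order Taylor factor 1 - dt + dt^2/2
        x = np.array([1.0])
        dt = 0.01
        nxt = heun_stochastic_step(x, lambda s: -s, dt, 0.0,
                                   np.random.default_rng(0))
        assert nxt[0] == pytest.approx(1 - dt + dt ** 2 / 2, abs=1e-15)
        assert nxt[0] == pytest.approx(np.exp(-dt), abs=dt ** 3)

    def test_pure_noise_increment_variance(self):
        # zero drift: after N steps the state is a random walk with variance
        # N * sigma_step^2
        rng = np.random.default_rng(42)
        sigma = 0.05
        n_walkers, n_steps = 2000, 100
        x = np.zeros(n_walkers)
        for _ in range(n_steps):
            x = heun_stochastic_step(x, lambda s: np.zeros_like(s), 0.1,
                                     sigma, rng)
        assert x.var() == pytest.approx(n_steps * sigma ** 2, rel=0.1)

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            heun_stochastic_step(np.zeros(2), lambda s: s, -0.1, 0.0,
                                 np.random.default_rng(0))


class TestSimulate:
    def test_same_seed_bitwise_identical(self, toy_connectome):
        cfg = IntegrationConfig(duration=25.0, discard=20.0, seed=5)
        run = lambda: simulate(toy_connectome, NodeParameters(),
                               CouplingParameters(K_rs=3.0), cfg)
        t1, t2 = run(), run()
        np.testing.assert_array_equal(t1.states, t2.states)

    def test_trajectory_starts_at_discard_and_keeps_labels(self, toy_connectome):
        cfg = IntegrationConfig(duration=25.0, discard=20.0, seed=5)
        traj = simulate(toy_connectome, NodeParameters(), CouplingParameters(),
                        cfg)
        assert traj.t[0] == pytest.approx(20.0)
        assert traj.t[-1] == pytest.approx(25.0)
        assert traj.labels == toy_connectome.labels
        assert traj.states.shape[0] == toy_connectome.n
        assert traj.output.shape == traj.states.shape[:2]

    def test_zero_connectome_equals_isolated_nodes(self):
        # a decoupled network is sample-path identical to separate
        # single-node runs given the same per-node noise streams
        n = 3
        conn = Connectome(labels=[f"n{i}" for i in range(n)], C=np.zeros((n, n)))
        cfg = IntegrationConfig(duration=24.0, discard=20.0, seed=11)
        seeds = np.random.SeedSequence(cfg.seed).spawn(n)
        net = simulate(conn, NodeParameters(), CouplingParameters(K_s=0.1),
                       cfg, seed_sequences=seeds)
        for i in range(n):
            iso = simulate(single_node_connectome(), NodeParameters(),
                           CouplingParameters(K_s=0.1), cfg,
                           seed_sequences=[seeds[i]])
            np.testing.assert_array_equal(net.states[i], iso.states[0])

    def test_blowup_names_node_and_time(self, toy_connectome):
        cfg = IntegrationConfig(duration=21.0, discard=20.0, seed=5)
        bad = np.full((4, 8), 1e7)
        with pytest.raises(BlowUpError, match="node"):
            simulate(toy_connectome, NodeParameters(), CouplingParameters(),
                     cfg, initial_state=bad)

    def test_heterogeneous_fixed_constants_rejected(self, toy_connectome):
        cfg = IntegrationConfig(duration=21.0, discard=20.0, seed=5)
        params = [NodeParameters()] * 3 + [NodeParameters(tau2=10.0)]
        with pytest.raises(ValueError, match="identical across nodes"):
            simulate(toy_connectome, params, CouplingParameters(), cfg)


class TestHopfSignature:
    def test_subcritical_amplitude_decays(self, equilibrium):
        ic = equilibrium.copy()
        ic[6] += 0.5
        traj = run_single_node(x0=-2.5, a=1.5, duration=150.0, noise=False,
                               initial_state=ic)
        x3 = traj.variable("x3")[0]
        fs = traj.fs
        early = x3[: int(20 * fs)]
        late = x3[-int(20 * fs):]
        assert np.ptp(late) < 0.01 * np.ptp(early)

    def test_supercritical_amplitude_ic_independent(self, equilibrium):
        amps = []
        for kick in (0.2, 1.5):
            ic = equilibrium.copy()
            ic[6] += kick
            traj = run_single_node(x0=-2.5, a=2.0, duration=200.0, noise=False,
                                   initial_state=ic)
            tail = traj.variable("x3")[0][-int(30 * traj.fs):]
            amps.append(np.ptp(tail))
        assert amps[0] > 0.5  # bounded away from zero
        assert amps[0] == pytest.approx(amps[1], rel=1e-3)
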