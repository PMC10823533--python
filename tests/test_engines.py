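"""Integrator, hopping, decoherence, and ensemble-driver checks."""


import numpy as np
import pytest

from hoprates import (
    ElectronicState,
    EnsembleSpec,
    InitialConditionSpec,
    TrajectoryState,
    run_ensemble,
    run_trajectory,
)
from hoprates.engines import (
    apply_decoherence,
    fssh_hop_probability,
    fssh_update,
    langevin_nuclear_step,
    mash_update,
    validate_timestep,
)
from hoprates.model import adiabatic_surfaces, crossing_point
from hoprates.observables import product_projector

from conftest import make_params


def total_energy(Q, P, n, params):
    v_minus, v_plus, _ = adiabatic_surfaces(Q, params)
    v = np.where(np.asarray(n) > 0, v_plus, v_minus)
    return v + np.asarray(P) ** 2 / 2.0


def pure_state(n):
    return ElectronicState(1.0 + 0j, 0j) if n > 0 else ElectronicState(0j, 1.0 + 0j)


class TestLangevin:
    def test_symplectic_limit_energy_drift(self, rng):
        # γ = 0 reduces to velocity Verlet; energy drift stays tiny
        p = make_params(gamma=0.0, delta=1000.0)  # deep lower adiabat, harmonic
        q, mom = 0.5 * p.q_shift + 2.0, 0.7
        e0 = total_energy(q, mom, -1, p)
        q_arr = np.full(1, q)
        p_arr = np.full(1, mom)
        drift = 0.0
        for _ in range(200):
            # 200 outer iterations x 250 inner steps = 5e4 steps
            for _ in range(250):
                q_arr, p_arr = langevin_nuclear_step(q_arr, p_arr, -1, p, 0.01, rng)
            drift = max(drift, abs(total_energy(q_arr, p_arr, -1, p)[0] - e0))
        assert drift < 1e-6

    def test_equipartition_boltzmann_stationarity(self, rng):
        # Δ → large makes the lower adiabat harmonic (curvature Ω², centre
        # Q₀/2): classical equipartition fixes both variances
        p = make_params(delta=1000.0, gamma=0.25)
        n_traj, burn, steps = 4000, 2000, 4000
        q = np.full(n_traj, 0.5 * p.q_shift)
        mom = np.zeros(n_traj)
        for _ in range(burn + steps):
            q, mom = langevin_nuclear_step(q, mom, -1, p, 0.01, rng)
        p2 = mom**2
        se_p = p2.std() / np.sqrt(n_traj)
        assert abs(p2.mean() - 1.0 / p.beta) < 3 * se_p
        dq2 = (q - 0.5 * p.q_shift) ** 2
        se_q = dq2.std() / np.sqrt(n_traj)
        assert abs(dq2.mean() - 1.0 / (p.beta * p.omega**2)) < 3 * se_q

    def test_seeded_determinism(self):
        p = make_params()
        out = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            q, mom = 1.0, 0.5
            for _ in range(100):
                q, mom = langevin_nuclear_step(q, mom, -1, p, 0.01, rng)
            out.append((q, mom))
        assert out[0] == out[1]


class TestHops:
    def test_mash_downward_rescaling_exact(self):
        # hop down releases the full gap into kinetic energy
        p = make_params(delta=0.5, gamma=0.0)
        qd = crossing_point(p)
        # position where the adiabatic gap is 1.5
        d_gap = np.sqrt(1.5**2 - (2 * p.delta) ** 2)
        q = qd + d_gap / p.diabatic_slope
        mom = np.sqrt(2.0)  # kinetic energy 1
        state = TrajectoryState(Q=q, P=mom, elec=pure_state(-1), n=1)
        dt = 1e-8  # step so small that only the hop changes anything
        new = mash_update(state, p, dt, np.random.default_rng(0))
        assert new.n == -1
        assert new.hops == 1
        assert new.P == pytest.approx(np.sqrt(5.0), rel=1e-6)  # sign preserved
        assert new.P**2 / 2 == pytest.approx(1.0 + 1.5, rel=1e-6)
        e_before = total_energy(state.Q, state.P, state.n, p)
        e_after = total_energy(new.Q, new.P, new.n, p)
        assert e_after == pytest.approx(e_before, rel=1e-9)

    def test_mash_upward_frustrated_reflection(self):
        p = make_params(delta=0.5, gamma=0.0)
        qd = crossing_point(p)
        d_gap = np.sqrt(1.5**2 - (2 * p.delta) ** 2)
        q = qd + d_gap / p.diabatic_slope
        mom = np.sqrt(2.0)  # kinetic energy 1 < gap 1.5: frustrated
        state = TrajectoryState(Q=q, P=mom, elec=pure_state(1), n=-1)
        new = mash_update(state, p, 1e-8, np.random.default_rng(0))
        assert new.n == -1
        assert new.hops == 0
        assert new.P == pytest.approx(-mom, rel=1e-6)

    def test_mash_no_hop_without_sign_change(self):
        p = make_params()
        state = TrajectoryState(Q=0.0, P=1.0, elec=pure_state(-1), n=-1)
        new = mash_update(state, p, 0.01, np.random.default_rng(0))
        assert new.n == -1
        assert new.hops == 0

    def test_fssh_probability_zero_without_coupling(self):
        elec = ElectronicState((1 + 1j) / 2, (1 - 1j) / 2)
        assert fssh_hop_probability(elec, qdot=1.0, d=0.0, n=-1, dt=0.01) == 0.0

    def test_fssh_negative_probability_clamped(self):
        # coherence feeding the active state: raw probability negative
        elec = ElectronicState(np.sqrt(0.2) + 0j, np.sqrt(0.8) + 0j)
        g_minus = fssh_hop_probability(elec, qdot=1.0, d=1.0, n=-1, dt=0.01)
        g_plus = fssh_hop_probability(elec, qdot=1.0, d=1.0, n=1, dt=0.01)
        # S_x > 0 here: flux 2 Q̇ d Re(c₊*c₋) drains the upper state
        assert g_plus > 0
        assert g_minus == 0.0

    def test_fssh_probability_value(self):
        elec = ElectronicState(np.sqrt(0.2) + 0j, np.sqrt(0.8) + 0j)
        s_x = 2 * np.sqrt(0.2 * 0.8)
        expected = 0.7 * 1.3 * s_x * 0.01 / 0.2
        assert fssh_hop_probability(elec, qdot=0.7, d=1.3, n=1, dt=0.01) == (
            pytest.approx(expected, rel=1e-12)
        )

    def test_fssh_frustrated_hop_reflects_without_counting(self):
        # at the crossing with a fully coherent state the attempt rate is
        # high, while the kinetic energy stays below the gap: every accepted
        # attempt must reflect the momentum and leave n and hops unchanged
        p = make_params(delta=0.5, gamma=0.0)
        qd = crossing_point(p)
        # S_x < 0 so the coherence flux drains the lower (active) state
        elec = ElectronicState(np.sqrt(0.5) + 0j, -np.sqrt(0.5) + 0j)
        state = TrajectoryState(Q=qd, P=1.3, elec=elec, n=-1)
        reflected = 0
        for seed in range(200):
            new = fssh_update(state, p, 0.02, np.random.default_rng(seed))
            assert new.n == -1
            assert new.hops == 0
            reflected += int(new.P < 0)
        assert reflected > 0  # reflections observed among the attempts

    def test_fssh_seeded_determinism(self):
        p = make_params()
        state = TrajectoryState(Q=crossing_point(p), P=1.0,
                                elec=pure_state(-1), n=-1)
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(9)
            s = state
            for _ in range(200):
                s = fssh_update(s, p, 0.01, rng)
            runs.append((s.Q, s.P, s.n, s.hops))
        assert runs[0] == runs[1]


class TestDecoherence:
    def test_mash_resample_keeps_hemisphere(self, rng):
        p = make_params()
        state = TrajectoryState(Q=0.0, P=0.0, elec=pure_state(-1), n=-1)
        s_z_vals = []
        for _ in range(500):
            new = apply_decoherence(state, "MASH", p, rng)
            s_x, s_y, s_z = new.elec.bloch
            assert s_z < 0
            assert s_x**2 + s_y**2 + s_z**2 == pytest.approx(1.0, abs=1e-10)
            s_z_vals.append(s_z)
        mean = np.mean(s_z_vals)
        se = np.std(s_z_vals) / np.sqrt(len(s_z_vals))
        assert abs(mean + 2.0 / 3.0) < 3 * se

    def test_fssh_collapse(self, rng):
        p = make_params()
        elec = ElectronicState(np.sqrt(0.3) + 0j, np.sqrt(0.7) + 0j)
        state = TrajectoryState(Q=0.0, P=0.0, elec=elec, n=-1)
        new = apply_decoherence(state, "FSSH", p, rng)
        assert abs(new.elec.c_minus) == pytest.approx(1.0)
        assert abs(new.elec.c_plus) == pytest.approx(0.0)

    def test_mash_inconsistent_state_raises(self, rng):
        p = make_params()
        state = TrajectoryState(Q=0.0, P=0.0, elec=pure_state(1), n=-1)
        with pytest.raises(RuntimeError):
            apply_decoherence(state, "MASH", p, rng)

    def test_small_gap_rejected(self, rng):
        p = make_params()
        qd = crossing_point(p)  # gap = 2Δ << 4 k_BT there
        state = TrajectoryState(Q=qd, P=0.0, elec=pure_state(-1), n=-1)
        with pytest.raises(ValueError):
            apply_decoherence(state, "MASH", p, rng)


class TestTrajectory:
    def test_zero_horizon_trace(self):
        p = make_params()
        spec = EnsembleSpec(method="MASH", n_traj=1, t_max=0.0, seed=0)
        init = TrajectoryState(Q=1.0, P=0.5, elec=pure_state(-1), n=-1)
        trace = run_trajectory(init, spec, p)
        assert len(trace["t"]) == 1
        assert trace["Q"][0] == 1.0
        assert trace["hops"][0] == 0

    def test_adiabatic_limit_no_hops(self):
        # huge Δ: start on the lower adiabat well below the barrier
        p = make_params(delta=8.0, gamma=0.0)
        spec = EnsembleSpec(method="MASH", n_traj=1, t_max=50.0, dt=0.01, seed=0)
        init = TrajectoryState(Q=0.5 * p.q_shift, P=0.5, elec=pure_state(-1), n=-1)
        trace = run_trajectory(init, spec, p)
        assert np.all(trace["hops"] == 0)
        energies = total_energy(trace["Q"], trace["P"], trace["n"], p)
        assert np.max(np.abs(energies - energies[0])) < 1e-6

    def test_energy_conserved_across_hops(self):
        # γ = 0 MASH: energy is exactly conserved at hops and to integrator
        # accuracy between them, so the total drift stays tiny even with
        # several surface switches
        p = make_params(delta=0.15, gamma=0.0)
        spec = EnsembleSpec(method="MASH", n_traj=1, t_max=60.0, dt=0.002, seed=0)
        rng = np.random.default_rng(3)
        elec = ElectronicState(np.sqrt(0.45) + 0j, np.sqrt(0.55) + 0j)
        init = TrajectoryState(Q=crossing_point(p) - 1.0, P=1.5, elec=elec, n=-1)
        trace = run_trajectory(init, spec, p, rng)
        assert trace["hops"][-1] >= 2  # the trajectory actually switches
        energies = total_energy(trace["Q"], trace["P"], trace["n"], p)
        assert np.max(np.abs(energies - energies[0])) < 1e-5

    def test_mash_consistency_on_frustration_free_run(self):
        # with enough energy no upward hop can be frustrated, so the active
        # state must track sign(S_z) at every sample
        p = make_params(delta=0.5, gamma=0.0)
        spec = EnsembleSpec(method="MASH", n_traj=1, t_max=80.0, dt=0.005, seed=0)
        elec = ElectronicState(np.sqrt(0.4) + 0j, np.sqrt(0.6) + 0j)
        init = TrajectoryState(Q=crossing_point(p) - 1.0, P=2.5, elec=elec, n=-1)
        trace = run_trajectory(init, spec, p)
        s_z = trace["S"][2]
        assert np.all(np.sign(s_z) == trace["n"])


class TestEnsemble:
    def test_single_trajectory_curve_is_binary(self, weak_coupling_params):
        spec = EnsembleSpec(method="MASH", n_traj=1, t_max=5.0, seed=4)
        curve = run_ensemble(spec, weak_coupling_params)
        assert set(np.unique(curve.p_mean)).issubset({0.0, 1.0})

    def test_strata_partition_sums_exactly(self, weak_coupling_params):
        spec = EnsembleSpec(method="MASH", n_traj=3000, t_max=10.0, seed=4)
        curve = run_ensemble(spec, weak_coupling_params, strata=(0, 1, 2))
        total = sum(curve.strata.values())
        np.testing.assert_array_almost_equal(total, curve.p_mean, decimal=14)

    def test_bitwise_reproducibility(self, weak_coupling_params):
        spec = EnsembleSpec(method="FSSH", n_traj=2000, t_max=5.0, seed=8)
        a = run_ensemble(spec, weak_coupling_params)
        b = run_ensemble(spec, weak_coupling_params)
        np.testing.assert_array_equal(a.p_mean, b.p_mean)
        assert a.diagnostics == b.diagnostics

    def test_backends_agree_without_noise(self):
        # γ = 0 MASH consumes no random numbers during propagation, so the
        # compiled and vectorized cores must produce identical ensembles
        p = make_params(gamma=0.0)
        spec = EnsembleSpec(method="MASH", n_traj=500, t_max=10.0, seed=3)
        a = run_ensemble(spec, p, backend="numpy")
        b = run_ensemble(spec, p, backend="numba")
        np.testing.assert_array_equal(a.p_mean, b.p_mean)

    def test_symmetric_model_equilibrates_to_half(self):
        # small reorganization energy: fast relaxation; detailed balance
        # demands ⟨P_p(∞)⟩ = 1/2 for ε = 0
        p = make_params(lam=1.0, delta=0.3, omega=0.25, gamma=0.25)
        spec = EnsembleSpec(method="MASH", n_traj=3000, t_max=120.0, dt=0.01,
                            sample_stride=100, seed=6)
        curve = run_ensemble(spec, p)
        tail = curve.p_mean[curve.times > 80.0]
        se = np.mean(curve.p_stderr[curve.times > 80.0])
        assert abs(tail.mean() - 0.5) < 3 * se + 0.02

    def test_decoherence_events_only_at_large_gap(self, weak_coupling_params):
        spec = EnsembleSpec(method="MASH", n_traj=500, t_max=10.0, seed=2,
                            decoherence="gap_triggered")
        curve = run_ensemble(spec, weak_coupling_params)
        assert curve.diagnostics["decoherence_events"] > 0

    def test_timestep_validation(self, weak_coupling_params):
        with pytest.raises(ValueError):
            validate_timestep(weak_coupling_params, dt=0.03)
        spec = EnsembleSpec(method="MASH", n_traj=10, dt=0.03, seed=0)
        with pytest.raises(ValueError):
            run_ensemble(spec, weak_coupling_params)

    def test_mismatched_init_method_rejected(self, weak_coupling_params):
        spec = EnsembleSpec(method="MASH", n_traj=10, seed=0)
        init = InitialConditionSpec(region="reactant", method="FSSH", seed=0)
        with pytest.raises(ValueError):
            run_ensemble(spec, weak_coupling_params, init)

    def test_projector_complement(self, weak_coupling_params):
        p = weak_coupling_params
        qd = crossing_point(p)
        assert product_projector(qd + 1.0, -1, p) == 1
        assert product_projector(qd - 1.0, -1, p) == 0
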