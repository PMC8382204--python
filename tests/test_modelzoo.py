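"""Model builders, non-dimensionalization, schedules and delays."""

import numpy as np
import pytest
from scipy.optimize import brentq

from switchcycle.dynalysis import integrate, oscillation_metrics
from switchcycle.modelzoo import (DelaySpec, EmbryonicParams,
                                  MassActionParams, ParameterSchedule,
                                  ScheduleWindow, SomaticParams,
                                  build_delayed, build_embryonic,
                                  build_interlinked, build_mass_action,
                                  embryonic_nondim, nondimensionalize)
from switchcycle.switchcore import (ScalingFunction, SwitchModule,
                                    steady_response_values)


class TestEmbryonicBuilders:
    def test_ultrasensitive_unique_stable_state(self):
        """System (i-a) steady state solves x*h(x) = c (scalar oracle)."""
        from switchcycle.dynalysis import steady_states

        c = 0.5
        system = build_embryonic(embryonic_nondim(c=c, alpha_apc=0.0))
        sss = steady_states(system)
        assert len(sss) == 1 and sss[0].stable
        h = lambda x: x**15 / (1.0 + x**15)
        x_star = brentq(lambda x: x * h(x) - c, 1e-6, 10.0, xtol=1e-14)
        assert sss[0].state[0] == pytest.approx(x_star, rel=1e-8)
        assert sss[0].state[1] == pytest.approx(h(x_star), rel=1e-8)

    def test_s_shaped_oscillates(self):
        """Narrow S-region at mid relative synthesis sustains oscillations."""
        system = build_embryonic(embryonic_nondim(c=0.5, alpha_apc=5.0))
        traj = integrate(system, t_span=(0.0, 60.0), n_out=3001)
        assert oscillation_metrics(traj).sustained

    def test_cdk_switch_needs_multiply_flag(self):
        cdk = SwitchModule(K=2.0, n=15.0, xi=ScalingFunction(alpha=5.0),
                           multiply_by_input=False)
        with pytest.raises(ValueError, match="multiply_by_input"):
            EmbryonicParams(b_syn=0.5, b_deg=1.0, cdk_switch=cdk)

    def test_clamped_cycb_matches_switch_response(self):
        """With [CycB] clamped and a fast Cdk1 switch, the [Cdk1] steady
        value is [CycB] times a branch of the ratio switch response."""
        params = embryonic_nondim(c=0.5, alpha_apc=0.0, alpha_cdk=5.0,
                                  d=2.0, eps_cdk=1e-4)
        system = build_embryonic(params)
        rhs = system.rhs_at()
        cycb = 3.0
        vals = steady_response_values(params.cdk_switch, cycb)
        for branch, y in vals.items():
            cdk1 = y * cycb
            dcdk1 = rhs(0.0, np.array([cycb, cdk1, 0.3]), None)[1]
            # residual of the Cdk1 equation, scaled by the fast rate
            assert abs(dcdk1) * params.cdk_switch.epsilon < 1e-6, branch


class TestNondimensionalization:
    def test_direct_arithmetic(self):
        apc = SwitchModule(K=20.0, n=15.0, epsilon=0.1)
        nd = nondimensionalize(EmbryonicParams(b_syn=1.0, b_deg=0.1,
                                               apc_switch=apc))
        assert nd.c == pytest.approx(0.5)
        assert nd.eps_star["apc"] == pytest.approx(0.01)

    def test_threshold_ratio(self):
        apc = SwitchModule(K=20.0, n=15.0, epsilon=0.1)
        cdk = SwitchModule(K=40.0, n=15.0, epsilon=0.1,
                           multiply_by_input=True)
        nd = nondimensionalize(EmbryonicParams(b_syn=1.0, b_deg=0.1,
                                               apc_switch=apc,
                                               cdk_switch=cdk))
        assert nd.d == pytest.approx(2.0)

    @pytest.mark.parametrize("with_cdk", [False, True])
    def test_change_of_variables_identity(self, rng, with_cdk):
        """Simulating the dimensional system then rescaling equals
        simulating the non-dimensional system."""
        for _ in range(5):
            b_deg = rng.uniform(0.05, 0.3)
            K = rng.uniform(10.0, 30.0)
            c = rng.uniform(0.3, 0.7)
            alpha = rng.uniform(2.0, 8.0)
            eps_star = 0.01
            apc = SwitchModule(K=K, n=15.0, xi=ScalingFunction(alpha=alpha),
                               epsilon=eps_star / b_deg)
            cdk = None
            if with_cdk:
                cdk = SwitchModule(K=2.0 * K, n=15.0,
                                   xi=ScalingFunction(alpha=3.0),
                                   epsilon=eps_star / b_deg,
                                   multiply_by_input=True)
            dim = build_embryonic(EmbryonicParams(
                b_syn=c * K * b_deg, b_deg=b_deg, apc_switch=apc,
                cdk_switch=cdk))
            nod = build_embryonic(embryonic_nondim(
                c=c, alpha_apc=alpha, eps_apc=eps_star,
                alpha_cdk=3.0 if with_cdk else None, d=2.0,
                eps_cdk=eps_star))
            T = 20.0
            # the non-dimensional builder measures every concentration in
            # units of the APC/C threshold (K_cdk,apc = 1)
            scale = np.array([K, K, 1.0] if with_cdk else [K, 1.0])
            init_nd = np.array([0.4, 0.2, 0.1])[:len(scale)]
            init_dim = init_nd * scale
            td = integrate(dim, init=init_dim, t_span=(0.0, T / b_deg),
                           n_out=801, rtol=1e-11, atol=1e-13)
            tn = integrate(nod, init=init_nd, t_span=(0.0, T),
                           n_out=801, rtol=1e-11, atol=1e-13)
            err = np.max(np.abs(td.y / scale[:, None] - tn.y))
            assert err < 1e-6


class TestDelays:
    def test_effective_tau_blend(self):
        d = DelaySpec(tau1=2.0, tau2=6.0, p=5.0)
        assert d.effective(0.5) == pytest.approx(4.0)  # Hill(0.5) = 0.5
        assert DelaySpec(3.0, 3.0).effective(0.9) == 3.0

    def test_step_limit_at_high_exponent(self):
        d = DelaySpec(tau1=2.0, tau2=6.0, p=50.0)
        assert d.effective(0.9) == pytest.approx(6.0, abs=1e-3)
        assert d.effective(0.1) == pytest.approx(2.0, abs=1e-3)

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            DelaySpec(tau1=-1.0, tau2=0.0)

    def test_zero_delay_reduces_to_ode(self):
        p = embryonic_nondim(c=0.5, alpha_apc=5.0,
                             delay=DelaySpec(0.0, 0.0))
        ode = build_embryonic(embryonic_nondim(c=0.5, alpha_apc=5.0))
        t1 = integrate(build_delayed(p), init=[0.5, 0.2], t_span=(0, 20),
                       n_out=801, rtol=1e-10, atol=1e-12)
        t2 = integrate(ode, init=[0.5, 0.2], t_span=(0, 20),
                       n_out=801, rtol=1e-10, atol=1e-12)
        assert np.max(np.abs(t1.y - t2.y)) < 1e-6

    def test_dde_step_convergence(self):
        """Halving the DDE step changes the trajectory only marginally."""
        p = embryonic_nondim(c=0.5, alpha_apc=5.0, delay=DelaySpec(1.0, 1.0))
        sys_ = build_delayed(p)
        a = integrate(sys_, t_span=(0, 15), n_out=601, dde_step=1e-3)
        b = integrate(sys_, t_span=(0, 15), n_out=601, dde_step=5e-4)
        assert np.max(np.abs(a.y - b.y)) < 1e-4

    def test_requires_delay_spec(self):
        with pytest.raises(ValueError):
            build_delayed(embryonic_nondim(c=0.5, alpha_apc=5.0))


@pytest.fixture(scope="module")
def params():
    return MassActionParams(b_syn=1.0, b_deg=0.1)


class TestMassAction:
    def test_conservation_pools(self, params):
        system = build_mass_action(params)
        traj = integrate(system, init=[0, 0, 0, 0, 0], t_span=(0, 300),
                         n_out=1501)
        gwlp, c, ensap = traj.var("GWLp"), traj.var("C"), traj.var("ENSAp")
        # the algebraic substitution enforces the pools; bounds must hold
        assert np.all(gwlp >= -1e-8) and np.all(gwlp <= params.GWL_tot + 1e-8)
        assert np.all(c >= -1e-8) and np.all(c <= params.PP2A_tot + 1e-8)
        assert np.all(ensap + c <= params.ENSA_tot + 1e-8)

    def test_apc_confined_to_unit_interval(self, params):
        system = build_mass_action(params)
        for apc0 in (0.0, 0.5, 1.0):
            traj = integrate(system, init=[5.0, 1.0, 1.0, 5.0, apc0],
                             t_span=(0, 200), n_out=1001)
            apc = traj.var("APC")
            assert np.all(apc >= -1e-8) and np.all(apc <= 1.0 + 1e-8)

    def test_invalid_initial_condition(self, params):
        system = build_mass_action(params)
        with pytest.raises(ValueError, match="PP2A_tot"):
            integrate(system, init=[0, 0, 100.0, 0, 0], t_span=(0, 1))

    def test_rate_divisor_spares_synthesis(self):
        p = MassActionParams(b_syn=1.0, b_deg=0.1, rate_divisor=16.5)
        rates = p.effective_rates()
        assert rates["k_pg"] == pytest.approx(0.07 / 16.5)
        assert p.b_syn == 1.0 and p.b_deg == 0.1

    def test_divisor_16p5_still_oscillates(self, params):
        """Reduced timescale separation keeps the oscillator alive."""
        p = MassActionParams(b_syn=1.0, b_deg=0.1, rate_divisor=16.5)
        traj = integrate(build_mass_action(p), init=[0, 0, 0, 0, 0],
                         t_span=(0, 2000), n_out=4001)
        assert oscillation_metrics(traj, var="Cdk1",
                                   height_tol=0.05).sustained


class TestInterlinked:
    def test_table_defaults_oscillate_through_phases(self, somatic_defaults):
        from switchcycle.dynalysis import segment_phases

        system = build_interlinked(somatic_defaults)
        traj = integrate(system, t_span=(0, 20000), n_out=8001, rtol=1e-7)
        summ = oscillation_metrics(traj, var="Cdk1", height_tol=0.05)
        assert summ.sustained and summ.regular
        seg = segment_phases(traj)
        assert {"G1", "S/G2", "M"} <= set(seg.labels)
        # phases appear in cell-cycle order within a cycle
        labs = seg.labels
        order = [labs[0]]
        for lab in labs[1:]:
            if lab != order[-1]:
                order.append(lab)
        s = "".join({"G1": "g", "S/G2": "s", "M": "m"}[x] for x in order)
        assert "gsm" in s  # G1 -> S/G2 -> M progression occurs

    def test_no_cycd_synthesis_no_commitment(self, somatic_defaults):
        p = SomaticParams(**{**vars(somatic_defaults), "d_syn": 1e-9})
        traj = integrate(build_interlinked(p), t_span=(0, 3000), n_out=3001,
                         rtol=1e-7)
        assert np.max(traj.var("E2F")) < 0.05
        assert np.all(np.diff(traj.var("CycD")) < 1e-3)

    def test_unbounded_growth_without_degradation(self, somatic_defaults):
        """With delta_d = 0 and APC* = 0 the CycD equation is pure
        synthesis."""
        p = SomaticParams(**{**vars(somatic_defaults), "delta_d": 0.0,
                             "delta_b": 0.0})
        rhs = build_interlinked(p).rhs_at()
        dy = rhs(0.0, np.array([50.0, 0.0, 0.0, 0.0, 0.0]), None)
        assert dy[0] == pytest.approx(p.d_syn)


class TestParameterSchedule:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ParameterSchedule((ScheduleWindow(0, 10, "b_syn", 1.0),
                               ScheduleWindow(5, 15, "b_syn", 2.0)))

    def test_disjoint_and_other_parameter_ok(self):
        ParameterSchedule((ScheduleWindow(0, 10, "b_syn", 1.0),
                           ScheduleWindow(10, 15, "b_syn", 2.0),
                           ScheduleWindow(5, 8, "b_deg", 1.0)))

    def test_empty_schedule_identity(self):
        system = build_embryonic(embryonic_nondim(c=0.5, alpha_apc=5.0))
        t1 = integrate(system, t_span=(0, 20), n_out=801)
        t2 = integrate(system.with_schedule(ParameterSchedule()),
                       t_span=(0, 20), n_out=801)
        assert np.allclose(t1.y, t2.y)

    def test_window_values_apply_inside_only(self):
        system = build_embryonic(embryonic_nondim(c=0.5, alpha_apc=5.0))
        sched = ParameterSchedule((ScheduleWindow(5.0, 10.0, "b_syn", 0.0,
                                                  mode="multiply"),))
        traj = integrate(system.with_schedule(sched), t_span=(0, 20),
                         n_out=2001)
        inside = (traj.t > 5.2) & (traj.t < 10.0)
        # without synthesis Cdk1 only decays inside the window
        assert np.all(np.diff(traj.var("Cdk1")[inside]) <= 1e-12)

    def test_unknown_path_rejected(self):
        system = build_embryonic(embryonic_nondim(c=0.5, alpha_apc=5.0))
        with pytest.raises(KeyError):
            system.with_schedule(ParameterSchedule(
                (ScheduleWindow(0, 1, "nope", 1.0),)))
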