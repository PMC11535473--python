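"""Kinetic rate laws, maturation closed form, events and the integrator."""

import math

import numpy as np
import pytest

from chosoft.core import Channel
from chosoft.kinetics import (DEFAULT_PARAMS, FeedEvent, FeedSchedule,
                              ModelState, SampleEvent, ScheduleError,
                              apply_feed_event, apply_sample_event,
                              glycan_instantaneous_fractions, mm_bi_ternary,
                              mm_uni, monod_mu, rhs, simulate_fedbatch,
                              STATE_NAMES)


class TestRateLaws:
    def test_monod_half_saturation(self, params):
        assert monod_mu(params.K_glc, params) == pytest.approx(params.mu_max / 2)

    def test_monod_zero_and_bound(self, params):
        assert monod_mu(0.0, params) == 0.0
        assert monod_mu(1e9, params) <= params.mu_max

    def test_monod_value(self, params):
        p = params.replace(mu_max=0.04, K_glc=1.0)
        assert monod_mu(9.0, p) == pytest.approx(0.036)

    @pytest.mark.parametrize("S,Vmax,Km,expected", [
        (0.5, 2.0, 0.5, 1.0),     # half saturation
        (0.0, 2.0, 0.5, 0.0),
        (1.5, 2.0, 0.5, 1.5),
    ])
    def test_mm_uni(self, S, Vmax, Km, expected):
        assert mm_uni(S, Vmax, Km) == pytest.approx(expected)

    def test_mm_bi_ternary(self):
        assert mm_bi_ternary(0.0, 5.0, 4.0, 1.0, 1.0) == 0.0
        assert mm_bi_ternary(1.0, 1.0, 4.0, 1.0, 1.0) == pytest.approx(1.0)
        # double half-saturation and substrate/constant exchange symmetry
        assert mm_bi_ternary(2.0, 3.0, 4.0, 2.0, 3.0) == pytest.approx(1.0)
        assert (mm_bi_ternary(1.2, 3.4, 5.0, 0.7, 0.9)
                == pytest.approx(mm_bi_ternary(3.4, 1.2, 5.0, 0.9, 0.7)))


class TestMaturationFractions:
    def test_no_donor_all_g0f(self, params):
        assert glycan_instantaneous_fractions(0.0, params) == (1.0, 0.0, 0.0)

    def test_equal_rate_closed_form(self, params):
        # kappa1*tau = kappa2*tau = 1: (1/e, 1/e, 1 - 2/e)
        U = 1.0
        p = params.replace(tau_G=1.0, k_gal1=2.0, K_gal1=U,
                           k_gal2=2.0, K_gal2=U)
        phi = glycan_instantaneous_fractions(U, p)
        np.testing.assert_allclose(
            phi, (math.exp(-1), math.exp(-1), 1 - 2 * math.exp(-1)),
            rtol=1e-12)

    def test_complete_conversion_limit(self, params):
        p = params.replace(tau_G=1e4, k_gal1=10.0, K_gal1=1e-6,
                           k_gal2=10.0, K_gal2=2e-6)
        phi = glycan_instantaneous_fractions(5.0, p)
        np.testing.assert_allclose(phi, (0, 0, 1), atol=1e-12)

    @pytest.mark.parametrize("u", [0.0, 1e-6, 0.05, 0.4, 2.0, 50.0])
    def test_unit_simplex(self, u, params):
        phi = glycan_instantaneous_fractions(u, params)
        assert all(-1e-15 <= f <= 1.0 for f in phi)
        assert abs(sum(phi) - 1.0) < 1e-12


class TestRHS:
    def test_no_biomass_no_cell_driven_fluxes(self, params):
        state = ModelState(Xv=0.0, Glc_in=0.0, Gln_in=0.0, Gal_in=0.0,
                           UDP_Glc=0.0, UDP_Gal=0.0, UDP_GlcNAc=0.0,
                           UDP_GalNAc=0.0, Glc=0.0, Gln=0.0, Gal=0.0)
        dy = rhs(0.0, state.to_vector(), params, FeedSchedule())
        np.testing.assert_allclose(dy, 0.0, atol=1e-15)

    def test_glycoform_mass_rate_sums_to_production(self, params):
        state = ModelState(Xv=5e6, UDP_Gal=0.7)
        dy = rhs(10.0, state.to_vector(), params, FeedSchedule())
        idx = {n: i for i, n in enumerate(STATE_NAMES)}
        dm = dy[idx["M_G0F"]] + dy[idx["M_G1F"]] + dy[idx["M_G2F"]]
        assert dm == pytest.approx(dy[idx["mAb"]], rel=0, abs=0)

    def test_nonfinite_state_raises(self, params):
        y = ModelState().to_vector()
        y[2] = np.nan
        with pytest.raises(Exception, match="Glc"):
            rhs(0.0, y, params, FeedSchedule())

    def test_pure_monod_batch_matches_euler_oracle(self, params):
        """With NSD/transport/production machinery off, the (Xv, Glc)
        subsystem is pure Monod growth; a fine-step explicit Euler
        integration is the independent oracle."""
        p = params.replace(
            alpha_mab=0, beta_mab=0, V_gal=0, Vt_glc=0, Vt_gln=0, Vt_gal=0,
            Vmax_udpglc=0, Vmax_udpgal_epi=0, Vmax_udpgal_sal=0,
            Vmax_udpglcnac=0, Vmax_udpgalnac=0,
            f_udpglc=0, f_udpgal=0, f_udpglcnac=0, f_udpgalnac=0,
            Y_lac=0, Y_nh4=0, Y_glu=0, m_gln=0, Y_xgln=1e30)
        init = ModelState(Glc=20.0)
        grid = np.linspace(0, 72, 13)
        traj = simulate_fedbatch(p, init, FeedSchedule(), grid,
                                 rtol=1e-10, atol=1e-12)
        # explicit-Euler oracle, Richardson-extrapolated (dt and dt/2) to
        # remove the O(dt) discretization term of the oracle itself
        def euler_run(dt):
            xv, glc, t = init.Xv, init.Glc, 0.0
            out = {0.0: (xv, glc)}
            for _ in range(round(72 / dt)):
                mu = p.mu_max * max(glc, 0) / (p.K_glc + max(glc, 0))
                gate = max(glc, 0) / (max(glc, 0) + 1e-9)
                dxv = (mu - p.k_d) * xv
                dglc = -(mu / p.Y_xglc + p.m_glc) * xv * gate
                xv, glc, t = xv + dt * dxv, glc + dt * dglc, t + dt
                out[round(t, 6)] = (xv, glc)
            return out
        full, half = euler_run(5e-4), euler_run(2.5e-4)
        for i, tg in enumerate(grid[1:], start=1):
            key = round(tg, 6)
            xv_e = 2 * half[key][0] - full[key][0]
            glc_e = 2 * half[key][1] - full[key][1]
            assert traj.series("Xv")[i] == pytest.approx(xv_e, rel=1e-6)
            assert traj.series("Glc")[i] == pytest.approx(glc_e, rel=1e-6, abs=1e-8)


class TestEvents:
    def test_feed_increment(self):
        s = ModelState(Gal=0.5)
        s2 = apply_feed_event(s, FeedEvent(72.0, Channel.GAL, 25.0))
        assert s2.Gal == pytest.approx(25.5)
        assert s2.V == s.V and s2.Glc == s.Glc

    def test_feed_zero_dose_identity(self):
        s = ModelState()
        s2 = apply_feed_event(s, FeedEvent(72.0, Channel.GAL, 0.0))
        assert s2 == s

    def test_feed_stock_mode_equal_concentration(self):
        s = ModelState(Gal=3.0, Glc=0.0, Gln=0.0, Glu=0.0, Lac=0.0, NH4=0.0,
                       Xv=0.0, mAb=0.0, Glc_in=0, Gln_in=0, Gal_in=0,
                       UDP_Glc=0, UDP_Gal=0, UDP_GlcNAc=0, UDP_GalNAc=0,
                       M_G0F=0, M_G1F=0, M_G2F=0)
        s2 = apply_feed_event(
            s, FeedEvent(0.0, Channel.GAL, 3.0, stock_volume_mL=s.V))
        assert s2.Gal == pytest.approx(3.0)
        assert s2.V == pytest.approx(2 * s.V)

    def test_feed_unknown_species_rejected(self):
        with pytest.raises(ScheduleError):
            apply_feed_event(ModelState(), FeedEvent(0.0, Channel.VCD, 1.0))

    def test_sample_intensive_invariance(self):
        s = ModelState(V=70.0, Glc=12.0, Xv=2e6)
        s2 = apply_sample_event(s, SampleEvent(24.0, 35.0))
        assert s2.V == 35.0 and s2.Glc == 12.0 and s2.Xv == 2e6

    def test_sample_composition(self):
        s = ModelState(V=70.0)
        a = apply_sample_event(apply_sample_event(
            s, SampleEvent(0, 10.0)), SampleEvent(1, 5.0))
        b = apply_sample_event(s, SampleEvent(0, 15.0))
        assert a == b

    def test_sample_overdraw_rejected(self):
        with pytest.raises(ScheduleError):
            apply_sample_event(ModelState(V=10.0), SampleEvent(0, 10.0))


class TestSimulate:
    def test_zero_rate_params_constant_trajectory(self):
        zero = {f: 0.0 for f in ("mu_max", "k_d", "m_glc", "m_gln",
                                 "alpha_mab", "beta_mab", "V_gal",
                                 "Vt_glc", "Vt_gln", "Vt_gal",
                                 "Vmax_udpglc", "Vmax_udpgal_epi",
                                 "Vmax_udpgal_sal", "Vmax_udpglcnac",
                                 "Vmax_udpgalnac", "f_udpglc", "f_udpgal",
                                 "f_udpglcnac", "f_udpgalnac",
                                 "Y_lac", "Y_nh4", "Y_glu")}
        p = DEFAULT_PARAMS.replace(**zero)
        init = ModelState()
        traj = simulate_fedbatch(p, init, FeedSchedule(), np.linspace(0, 48, 5))
        np.testing.assert_allclose(traj.states,
                                   np.tile(init.to_vector(), (5, 1)),
                                   rtol=1e-12, atol=1e-12)

    def test_glycan_fractions_sum_to_100(self, params):
        init = ModelState(mAb=1.0, M_G0F=0.7, M_G1F=0.25, M_G2F=0.05)
        sched = FeedSchedule(feed_events=[FeedEvent(72.0, Channel.GAL, 25.0)])
        grid = np.arange(0.0, 145.0, 12.0)
        traj = simulate_fedbatch(params, init, sched, grid)
        total = (traj.channel_series(Channel.G0F)
                 + traj.channel_series(Channel.G1F)
                 + traj.channel_series(Channel.G2F))
        np.testing.assert_allclose(total, 100.0, atol=1e-9)

    def test_glycoform_mass_conservation(self, params):
        init = ModelState(mAb=1.0, M_G0F=0.7, M_G1F=0.25, M_G2F=0.05)
        grid = np.arange(0.0, 145.0, 12.0)
        traj = simulate_fedbatch(params, init, FeedSchedule(), grid)
        msum = (traj.series("M_G0F") + traj.series("M_G1F")
                + traj.series("M_G2F"))
        np.testing.assert_allclose(msum, traj.series("mAb"), rtol=1e-8)

    def test_matches_fixed_step_rk4_oracle(self, params):
        """Full default parameter set vs a hand-rolled classical RK4
        integration at dt = 0.01 h."""
        init = ModelState(mAb=1.0, M_G0F=0.7, M_G1F=0.25, M_G2F=0.05)
        sched = FeedSchedule()
        grid = np.linspace(0, 36, 7)
        traj = simulate_fedbatch(params, init, sched, grid,
                                 rtol=1e-10, atol=1e-12)
        y = init.to_vector()
        dt = 0.01
        t = 0.0
        ref = {0.0: y.copy()}
        for _ in range(3600):
            k1 = rhs(t, y, params, sched)
            k2 = rhs(t + dt / 2, y + dt / 2 * k1, params, sched)
            k3 = rhs(t + dt / 2, y + dt / 2 * k2, params, sched)
            k4 = rhs(t + dt, y + dt * k3, params, sched)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += dt
            ref[round(t, 6)] = y.copy()
        for i, tg in enumerate(grid[1:], start=1):
            np.testing.assert_allclose(traj.states[i], ref[round(tg, 6)],
                                       rtol=1e-5, atol=1e-10)

    def test_event_consistency_split_simulation(self, params):
        sched = FeedSchedule(feed_events=[FeedEvent(24.0, Channel.GAL, 25.0)])
        init = ModelState(mAb=1.0, M_G0F=0.7, M_G1F=0.25, M_G2F=0.05)
        grid = np.arange(0.0, 49.0, 12.0)
        full = simulate_fedbatch(params, init, sched, grid)
        first = simulate_fedbatch(params, init, sched, grid[grid <= 24.0])
        mid = first.state_at(int(np.argmax(grid == 24.0)))
        # events at t <= 24 already applied; restart cleanly from 24 h
        rest = simulate_fedbatch(params, mid, FeedSchedule(),
                                 grid[grid >= 24.0])
        np.testing.assert_allclose(rest.states[-1], full.states[-1],
                                   rtol=1e-6, atol=1e-9)

    def test_non_negativity_under_clipping(self, params):
        grid = np.arange(0.0, 217.0, 12.0)
        sched = FeedSchedule(feed_events=[FeedEvent(72.0, Channel.GAL, 25.0)])
        traj = simulate_fedbatch(params, ModelState(), sched, grid)
        assert traj.states.min() >= 0.0

    def test_monotone_galactose_dose_response(self, params):
        """A bigger galactose bolus never reduces the final cumulative
        UDP-Gal pool plus what was exported/diluted (proxied here by the
        final UDP-Gal concentration on a fixed grid)."""
        finals = []
        for dose in (0.0, 10.0, 25.0, 50.0):
            sched = FeedSchedule(
                feed_events=[FeedEvent(24.0, Channel.GAL, dose)])
            traj = simulate_fedbatch(params, ModelState(), sched,
                                     np.arange(0.0, 97.0, 24.0))
            finals.append(traj.series("UDP_Gal")[-1])
        assert all(b >= a - 1e-9 for a, b in zip(finals, finals[1:]))

    def test_event_off_grid_rejected(self, params):
        sched = FeedSchedule(feed_events=[FeedEvent(13.0, Channel.GAL, 5.0)])
        with pytest.raises(ScheduleError):
            simulate_fedbatch(params, ModelState(), sched,
                              np.array([0.0, 12.0, 24.0]))
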