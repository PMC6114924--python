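"""Equilibrium, tipping-point and sweep-machinery tests."""

import numpy as np
import pytest

from landpop import (
    DomainError,
    Scenario,
    SystemState,
    Trajectory,
    detect_peak,
    find_equilibria,
    integrate,
    key_factor_sweep,
    perception_plane,
    proactive_reactive_grid,
    tipping_onset,
)


class TestFindEquilibria:
    def test_human_free_closed_form(self, params):
        """With H = A = 0 the N balance r*D = delta_N*N gives N* = L*r/(r+delta_N)."""
        eqs = find_equilibria(params, [SystemState(N=6.0, A=0.0, D=7.0, H=0.0)])
        assert len(eqs) == 1
        expect = params.L * params.r / (params.r + params.delta_N)
        assert eqs[0].state.N == pytest.approx(expect, rel=1e-10)
        assert eqs[0].state.A == pytest.approx(0.0, abs=1e-9)
        assert eqs[0].state.H == pytest.approx(0.0, abs=1e-9)
        assert eqs[0].state.D == pytest.approx(params.L - expect, rel=1e-10)
        # people introduced at this point would grow: unstable to invasion
        assert eqs[0].stability == "unstable"

    def test_pristine_land_without_disturbance(self, params):
        """No natural disturbance, no humans: all land ends up natural."""
        p = params.replace(delta_N=0.0, b=0.0, m=0.0, d_N=0.0, d_A=0.0,
                           c_NA=0.0, c_ND=0.0, c_AN=0.0, c_AD=0.0)
        eqs = find_equilibria(p, [SystemState(N=12.0, A=0.5, D=0.5, H=0.0)])
        assert len(eqs) == 1
        assert eqs[0].state.N == pytest.approx(p.L, rel=1e-9)

    def test_long_run_endpoint_is_stable_equilibrium(self, params, initial):
        """The attractor an integration converges to must be a stable root."""
        scen = Scenario(params=params, initial=initial, t_start=1960.0,
                        t_end=1960.0 + 3000.0, output_step=10.0)
        end = integrate(scen).state_at(-1)
        eqs = find_equilibria(params, [end])
        assert len(eqs) == 1
        eq = eqs[0]
        assert eq.stability == "stable"
        for v in ("N", "A", "D", "H"):
            assert getattr(eq.state, v) == pytest.approx(getattr(end, v), abs=1e-5)

    def test_stable_root_recovers_from_perturbation(self, params, initial):
        scen = Scenario(params=params, initial=initial, t_start=1960.0,
                        t_end=1960.0 + 3000.0, output_step=10.0)
        end = integrate(scen).state_at(-1)
        eq = find_equilibria(params, [end])[0].state
        pert = SystemState(N=eq.N * 1.01, A=eq.A * 0.99,
                           D=params.L - eq.N * 1.01 - eq.A * 0.99, H=eq.H * 1.01)
        back = integrate(Scenario(params=params, initial=pert, t_start=0.0,
                                  t_end=2000.0, output_step=10.0)).state_at(-1)
        assert back.N == pytest.approx(eq.N, rel=1e-4)
        assert back.H == pytest.approx(eq.H, rel=1e-4)

    def test_no_start_rejected(self, params):
        with pytest.raises(DomainError):
            find_equilibria(params, [])


class TestTippingOnset:
    def test_monotone_growth_never_tips(self):
        t = np.arange(2000.0, 2101.0)
        z = np.full_like(t, 4.0)
        traj = Trajectory(t=t, N=z, A=z, D=5.0 * np.ones_like(t) , H=np.linspace(1, 2, len(t)))
        assert not tipping_onset(traj).detected

    def test_brief_dip_is_not_sustained_decline(self):
        t = np.arange(0.0, 41.0)
        H = np.concatenate([np.linspace(1.0, 2.0, 20),
                            [1.99, 1.98], np.linspace(2.0, 3.0, 19)])
        z = np.full_like(t, 4.0)
        traj = Trajectory(t=t, N=z, A=z, D=z, H=H)
        assert not tipping_onset(traj).detected

    def test_baseline_projection_tips_inside_plausible_band(self, bau_trajectory, params):
        """Sustained decline begins while N is between the ES threshold and ~half of it."""
        tip = tipping_onset(bau_trajectory)
        assert tip.detected
        assert 0.0 < tip.N_at_decline_onset < params.L
        peak = detect_peak(bau_trajectory, "H")
        assert tip.t_onset == pytest.approx(peak.t_peak, abs=2.0)

    def test_onset_robust_to_output_resampling(self, bau_scenario):
        half = Scenario(params=bau_scenario.params, initial=bau_scenario.initial,
                        t_start=bau_scenario.t_start, t_end=bau_scenario.t_end,
                        output_step=0.5)
        t1 = tipping_onset(integrate(bau_scenario)).t_onset
        t2 = tipping_onset(integrate(half)).t_onset
        assert abs(t1 - t2) <= 1.0


class TestSweeps:
    def test_single_cell_plane_equals_direct_run(self, params, initial, bau_scenario):
        res = perception_plane([params.p_N], [params.p_A], bau_scenario, horizon=100.0)
        direct = integrate(Scenario(params=params, initial=initial,
                                    t_start=1960.0, t_end=2060.0))
        assert res.metrics["late_H"][0, 0] == pytest.approx(direct.H[-1], rel=1e-12)
        assert res.metrics["peak_H"][0, 0] == pytest.approx(
            detect_peak(direct, "H").peak_value, rel=1e-12)
        assert res.metrics["final_N"][0, 0] == pytest.approx(direct.N[-1], rel=1e-12)
        assert res.converged.all()

    def test_cell_metrics_match_independent_runs(self, bau_scenario):
        """The sweep machinery must add nothing beyond per-cell simulation."""
        res = proactive_reactive_grid([1e-4, 1e-2], [1e-4, 2e-3], bau_scenario,
                                      horizon=120.0)
        for i, dn in enumerate((1e-4, 1e-2)):
            for j, cnd in enumerate((1e-4, 2e-3)):
                scen = bau_scenario.with_params(d_N=dn, c_ND=cnd)
                direct = integrate(Scenario(params=scen.params, initial=scen.initial,
                                            t_start=1960.0, t_end=2080.0))
                assert res.metrics["late_H"][i, j] == pytest.approx(direct.H[-1], rel=1e-12)
                assert res.metrics["final_N"][i, j] == pytest.approx(direct.N[-1], rel=1e-12)

    def test_envelopes_bound_member_trajectories(self, bau_scenario):
        res = proactive_reactive_grid([1e-4], [1e-4, 5e-4, 2e-3], bau_scenario,
                                      horizon=120.0)
        env = res.envelopes[1e-4]
        member = integrate(Scenario(params=bau_scenario.params.replace(d_N=1e-4, c_ND=5e-4),
                                    initial=bau_scenario.initial,
                                    t_start=1960.0, t_end=2080.0))
        assert np.all(member.H >= env["H_min"] - 1e-12)
        assert np.all(member.H <= env["H_max"] + 1e-12)

    def test_sweep_at_base_value_never_diverges(self, params, bau_scenario):
        res = key_factor_sweep("d_N", [params.d_N], bau_scenario, horizon=100.0)
        assert np.isnan(res.metrics["divergence_year"][0])

    def test_extreme_degradation_diverges_late_not_immediately(self, bau_scenario):
        """Trajectories under very different d_N coincide for years before separating."""
        res = key_factor_sweep("d_N", [1e-4, 1e-2], bau_scenario, horizon=160.0)
        year = res.metrics["divergence_year"]
        assert np.isfinite(year[1])  # heavy degradation does diverge
        assert year[1] >= bau_scenario.t_start + 10.0
        # milder change than base never exceeds the 5% band within the horizon
        assert np.isnan(year[0]) or year[0] > year[1]

    def test_peak_population_finite_across_demand_sweep(self, bau_scenario):
        res = key_factor_sweep("eta_A", [0.8, 1.0, 1.2, 1.4], bau_scenario, horizon=160.0)
        assert np.isfinite(res.metrics["peak_H"]).all()

    def test_unknown_parameter_rejected(self, bau_scenario):
        with pytest.raises(DomainError):
            key_factor_sweep("m", [0.01], bau_scenario)

    def test_long_format_export_round_trips(self, bau_scenario, tmp_path):
        res = proactive_reactive_grid([1e-4, 1e-2], [1e-4, 2e-3], bau_scenario,
                                      horizon=60.0)
        out = tmp_path / "grid.csv"
        res.write_csv(out)
        import json

        import pandas as pd
        df = pd.read_csv(out)
        assert len(df) == 4
        assert set(["d_N", "c_ND", "late_H", "peak_H", "final_N"]).issubset(df.columns)
        side = json.loads((tmp_path / "grid.json").read_text())
        assert side["axes"]["d_N"] == [1e-4, 1e-2]
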