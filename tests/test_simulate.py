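"""Integrator correctness: oracle agreement, invariants, binding equilibrium."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import odeint

from clotfilm import (
    ModelConfig,
    ParameterError,
    build_parameters,
    model,
    simulate,
    steady_state_oracle,
)


def _linear_rates(params, all_elute=True, tf0=None):
    """Rates for the linearized verification configuration: TF decay off,
    FXI feedback off, binding off."""
    cfg = ModelConfig(
        fxi_knockout=True,
        gprp_mode=True,
        eluting_species=("IXa", "Xa", "XIa", "IIa") if all_elute else ("Xa", "IIa"),
    )
    rates = build_parameters(params, cfg)
    changes = {"kTF": 0.0}
    if tf0 is not None:
        changes["TF0"] = tf0
    return dataclasses.replace(rates, **changes), cfg


class TestSteadyStateOracle:
    def test_hand_computed_level(self, params):
        # IXa* = r2 TF0 / (k_in + k_el) with every free enzyme eluting:
        # 0.3176/s * 2.214e-4 uM / (ln2/60 + ln2/2) = 1.964e-4 uM
        rates, _ = _linear_rates(params, all_elute=True, tf0=0.2214e-3)
        ss = steady_state_oracle(rates)
        # hand arithmetic: 0.3176/s * 2.214e-4 uM / 0.358126/s = 1.9635e-4 uM
        assert ss["IXa_uM"] == pytest.approx(1.9635e-4, rel=1e-3)

    def test_no_tf_all_zero(self, params):
        rates, _ = _linear_rates(params, tf0=0.0)
        ss = steady_state_oracle(rates)
        assert all(v == 0.0 for v in ss.values())

    def test_rejects_feedback_or_binding(self, params, config, baseline_rates):
        with pytest.raises(ParameterError):
            steady_state_oracle(baseline_rates)  # TF decay + feedback + binding on
        rates, _ = _linear_rates(params)
        with pytest.raises(ParameterError):
            steady_state_oracle(dataclasses.replace(rates, sw=1.0))

    @pytest.mark.parametrize("all_elute", [True, False])
    def test_integrator_converges_to_oracle(self, params, all_elute):
        """Long-time integration of the linear cascade agrees with algebra
        to 0.1% under either elution assignment."""
        rates, cfg = _linear_rates(params, all_elute=all_elute)
        cfg = cfg.replace(t_end=2000.0, output_dt=10.0)
        traj = simulate(rates, cfg)
        ss = steady_state_oracle(rates)
        end = traj.end()
        assert end["IXa_nM"] == pytest.approx(ss["IXa_uM"] * 1e3, rel=1e-3)
        assert end["Xa_nM"] == pytest.approx(ss["Xa_uM"] * 1e3, rel=1e-3)
        assert end["IIa_free_nM"] == pytest.approx(ss["IIa_uM"] * 1e3, rel=1e-3)


class TestTrajectoryInvariants:
    def test_no_initiation_stays_identically_zero(self, params, config):
        rates = dataclasses.replace(build_parameters(params, config), TF0=0.0)
        traj = simulate(rates, config)
        assert np.all(traj.data.drop(columns="time_s").to_numpy() == 0.0)

    def test_states_nonnegative(self, baseline_traj):
        assert (traj_min := baseline_traj.data.drop(columns="time_s").min().min()) >= 0.0, traj_min

    def test_fibrin_nondecreasing(self, baseline_traj):
        fn = baseline_traj.data["fibrin_uM"].to_numpy()
        assert np.all(np.diff(fn) >= -1e-9 * fn.max())

    def test_total_thrombin_is_sum_of_pools(self, baseline_traj):
        d = baseline_traj.data
        np.testing.assert_allclose(
            d["total_thrombin_nM"],
            d["IIa_free_nM"] + d["IIa_weakE_nM"] + d["IIa_gamma_nM"],
            rtol=1e-12,
        )

    def test_bound_thrombin_never_exceeds_sites(self, baseline_traj, baseline_rates):
        d = baseline_traj.data
        sites_w = baseline_rates.sw * d["fibrin_uM"] * 1e3  # nM
        sites_g = baseline_rates.sg * d["fibrin_uM"] * 1e3
        assert np.all(d["IIa_weakE_nM"] <= sites_w + 1e-6)
        assert np.all(d["IIa_gamma_nM"] <= sites_g + 1e-6)

    def test_thrombin_mass_balance(self, baseline_traj, config):
        assert baseline_traj.mass_balance_residual() <= 10 * config.rtol

    def test_cumulative_fluxes_nondecreasing(self, baseline_traj):
        for col in ("f12_cum_per_um2", "tat_cum_per_um2"):
            assert np.all(np.diff(baseline_traj.data[col]) >= 0.0)

    def test_bitwise_reproducible(self, baseline_rates, config, baseline_traj):
        again = simulate(baseline_rates, config)
        assert again.data.equals(baseline_traj.data)

    def test_solver_tolerance_convergence(self, baseline_rates, config, baseline_traj):
        tight = config.replace(rtol=config.rtol / 2, atol=config.atol / 2)
        fn_ref = baseline_traj.end()["fibrin_uM"]
        fn_tight = simulate(baseline_rates, tight).end()["fibrin_uM"]
        assert abs(fn_tight - fn_ref) / fn_ref < 1e-4


class TestBindingEquilibrium:
    def test_frozen_binding_relaxes_to_kd_ratio(self, baseline_rates):
        """With production, decay and fibrin growth off, free and bound
        thrombin relax to the equilibrium of reversible adsorption,
        B = S_tot * IIa / (Kd + IIa), within a few binding time constants."""
        r = baseline_rates
        rates = dataclasses.replace(
            r,
            r=(0.0,) * 7,
            kTF=0.0,
            kIXa=0.0,
            kXa=0.0,
            kXIa=0.0,
            kIIa=0.0,
            kin=0.0,
            kel_IIa=0.0,
        )
        fn0, iia0 = 10.0, 0.05  # uM
        y0 = np.zeros(model.N_STATE)
        y0[model.I_FN] = fn0
        y0[model.I_IIA] = iia0
        # slowest relaxation mode is site-to-site redistribution limited by
        # gamma'-desorption (kr = 10/s, tau ~ 0.1 s); 5 s is >> 5 tau
        t = np.array([0.0, 2.0, 5.0])
        y = odeint(model.rhs, y0, t, args=(rates.packed(),), Dfun=model.jacobian,
                   rtol=1e-10, atol=1e-14, mxstep=100000)
        iia, be, bg = y[-1, model.I_IIA], y[-1, model.I_BE], y[-1, model.I_BG]
        kd_w, kd_g = rates.krw / rates.kfw, rates.krg / rates.kfg
        assert be == pytest.approx(rates.sw * fn0 * iia / (kd_w + iia), rel=1e-6)
        assert bg == pytest.approx(rates.sg * fn0 * iia / (kd_g + iia), rel=1e-6)
        # thrombin conserved
        assert iia + be + bg == pytest.approx(iia0, rel=1e-9)

    def test_no_sites_no_bound_thrombin(self, params, config):
        traj = simulate(build_parameters(params, config.replace(gprp_mode=True)), config)
        assert np.all(traj.data["IIa_weakE_nM"] == 0.0)
        assert np.all(traj.data["IIa_gamma_nM"] == 0.0)


class TestDerivedObservables:
    def test_zero_tat_fraction_silences_tat(self, baseline_rates, config):
        traj = simulate(baseline_rates, config.replace(tat_fraction=0.0))
        assert np.all(traj.data["tat_flux_per_um2_s"] == 0.0)
        assert np.all(traj.data["tat_cum_per_um2"] == 0.0)

    def test_f12_tracks_thrombin_production(self, baseline_traj, baseline_rates, config):
        d = baseline_traj.data
        depth = config.delta * config.porosity
        conv = 1e-6 * 6.02214076e23 / 1e15 * depth
        np.testing.assert_allclose(
            d["f12_flux_per_um2_s"],
            baseline_rates.r[3] * d["Xa_nM"] * 1e-3 * conv,
            rtol=1e-12,
        )

    def test_blocking_fibrin_polymerization_raises_effluent_thrombin(
        self, params, config, baseline_traj
    ):
        """Without fibrin binding sites (polymerization blocked), thrombin
        is not sequestered in the film, so cumulative effluent TAT rises."""
        gprp = simulate(build_parameters(params, config.replace(gprp_mode=True)), config)
        assert (
            gprp.end()["tat_cum_per_um2"] >= baseline_traj.end()["tat_cum_per_um2"]
        )
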