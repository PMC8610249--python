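"""Parameterization: linearized rates, unit conversions, variant scaling."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clotfilm import (
    ModelConfig,
    ParameterError,
    ParameterSet,
    ReactionSpec,
    VariantVector,
    alpha_discrepancy_report,
    build_parameters,
    compute_alpha,
    load_parameters,
    save_parameters,
    surface_to_volume_concentration,
)


class TestComputeAlpha:
    @pytest.mark.parametrize(
        "kcat, Km, S0, expected",
        [
            (1.8, 0.42, 0.09, 0.32),  # FIX activation by extrinsic tenase
            (30.0, 0.3, 1.4, 24.7),  # prothrombinase
        ],
    )
    def test_published_rates_recovered(self, kcat, Km, S0, expected):
        # published values carry 2-3 significant figures
        assert compute_alpha(kcat, Km, S0) == pytest.approx(expected, rel=1e-2)

    def test_no_substrate_no_rate(self):
        assert compute_alpha(1.8, 0.42, 0.0) == 0.0

    def test_saturation_limit(self):
        assert compute_alpha(1.8, 0.42, 1e12) == pytest.approx(1.8, rel=1e-9)

    def test_invalid_km_rejected(self):
        with pytest.raises(ParameterError):
            compute_alpha(1.8, 0.0, 0.09)
        with pytest.raises(ParameterError):
            compute_alpha(1.8, -0.42, 0.09)

    @given(
        s_low=st.floats(0.0, 100.0),
        s_inc=st.floats(0.0, 100.0),
        kcat=st.floats(1e-6, 1e3),
        km=st.floats(1e-6, 1e3),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_substrate_and_bounded(self, s_low, s_inc, kcat, km):
        a1 = compute_alpha(kcat, km, s_low)
        a2 = compute_alpha(kcat, km, s_low + s_inc)
        assert a1 <= a2 <= kcat


class TestSurfaceConversion:
    def test_reference_density(self):
        # 1 molecule/um^2 in a 15-um film at porosity 0.5:
        # (1/7.5) molecules/um^3 * 1e15 um^3/L / 6.022e23 /mol = 0.2214 nM
        assert surface_to_volume_concentration(1.0, 15.0, 0.5) == pytest.approx(
            0.22140, rel=1e-4
        )

    def test_zero_density(self):
        assert surface_to_volume_concentration(0.0, 15.0, 0.5) == 0.0

    def test_linearity(self):
        one = surface_to_volume_concentration(1.0, 15.0, 0.5)
        assert surface_to_volume_concentration(2.0, 15.0, 0.5) == 2.0 * one

    @pytest.mark.parametrize("delta, porosity", [(0.0, 0.5), (-1.0, 0.5), (15.0, 0.0), (15.0, 1.5)])
    def test_invalid_geometry(self, delta, porosity):
        with pytest.raises(ParameterError):
            surface_to_volume_concentration(1.0, delta, porosity)


class TestPublishedTable:
    def test_binding_dissociation_constants_exact(self, params):
        assert params.site("weak_E").Kd == 2.8
        assert params.site("gamma_prime").Kd == 0.1

    def test_alpha_regression_report(self, params):
        report = alpha_discrepancy_report(params)
        # reactions whose recomputed rate agrees with the published one
        assert report.loc[[2, 4, 6, 7], "matches_2sf"].all()
        # known discrepancies, retained rather than silently patched
        assert not report.loc[[1, 3, 5], "matches_2sf"].any()
        assert report.loc[5, "ratio"] == pytest.approx(10.0, rel=0.05)

    def test_parameter_file_roundtrip(self, params, tmp_path):
        path = tmp_path / "params.yaml"
        save_parameters(params, path)
        assert load_parameters(path) == params


class TestVariantVector:
    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            VariantVector(FIX=0.4)
        with pytest.raises(ParameterError):
            VariantVector.from_array([1, 1, 1, 1, 1, 1, 1.6])

    def test_unknown_variable_rejected(self):
        with pytest.raises(ParameterError):
            VariantVector.from_mapping({"FVIII": 1.2})

    def test_roundtrip(self):
        v = VariantVector(FIX=1.5, gamma_prime_sites=0.5)
        assert VariantVector.from_array(v.as_array()) == v


class TestBuildParameters:
    def test_identity_variant_is_bitwise_baseline(self, params, config, baseline_rates):
        scaled = build_parameters(params, config, VariantVector.baseline())
        assert scaled == baseline_rates  # exact float equality, field by field

    def test_fix_multiplier_rescales_reactions_2_and_7(self, params, config, baseline_rates):
        rs = build_parameters(params, config, {"FIX": 1.5})
        # alpha2 = 1.8*0.135/(0.42+0.135), alpha7 = 0.21*0.135/(0.2+0.135)
        assert rs.r[1] == pytest.approx(0.43784, rel=1e-4)
        assert rs.r[6] == pytest.approx(0.084627, rel=1e-4)
        # all other reactions untouched
        for i in (0, 2, 3, 4, 5):
            assert rs.r[i] == baseline_rates.r[i]

    def test_fx_multiplier_rescales_reactions_1_and_3(self, params, config, baseline_rates):
        rs = build_parameters(params, config, {"FX": 0.5})
        assert rs.r[0] != baseline_rates.r[0]
        assert rs.r[2] != baseline_rates.r[2]
        for i in (1, 3, 4, 5, 6):
            assert rs.r[i] == baseline_rates.r[i]

    def test_fxi_knockout_zeroes_feedback(self, params, config):
        rs = build_parameters(params, config.replace(fxi_knockout=True))
        assert rs.r[5] == 0.0 and rs.r[6] == 0.0

    def test_gprp_mode_disables_site_generation(self, params, config):
        rs = build_parameters(params, config.replace(gprp_mode=True))
        assert rs.sw == 0.0 and rs.sg == 0.0

    def test_site_multipliers_scale_site_densities(self, params, config, baseline_rates):
        rs = build_parameters(params, config, {"weak_E_sites": 1.5, "gamma_prime_sites": 0.5})
        assert rs.sw == pytest.approx(1.5 * baseline_rates.sw)
        assert rs.sg == pytest.approx(0.5 * baseline_rates.sg)

    def test_printed_alpha_mode_reproduces_published_column(self, params, config):
        rs = build_parameters(params, config.replace(use_printed_alpha=True))
        for spec, r in zip(params.reactions, rs.r):
            assert r == pytest.approx(spec.eta * spec.alpha_printed, rel=1e-12)

    def test_decay_constants(self, baseline_rates):
        ln2 = np.log(2.0)
        assert baseline_rates.kin == pytest.approx(ln2 / 60)
        assert baseline_rates.kTF == pytest.approx(ln2 / 180)
        # soluble species elute with the 2-s half-life on top of inactivation
        assert baseline_rates.kXa == pytest.approx(ln2 / 60 + ln2 / 2)
        assert baseline_rates.kIIa == pytest.approx(ln2 / 60 + ln2 / 2)
        # platelet-associated feedback enzymes are retained
        assert baseline_rates.kIXa == pytest.approx(ln2 / 60)
        assert baseline_rates.kXIa == pytest.approx(ln2 / 60)


class TestSpecValidation:
    def test_negative_km_rejected(self):
        with pytest.raises(ParameterError):
            ReactionSpec(id=2, enzyme="TF:VIIa", product="IXa", substrate="FIX",
                         S0=0.09, kcat=1.8, Km=-0.42, eta=1.0)

    def test_eta_range(self):
        with pytest.raises(ParameterError):
            ReactionSpec(id=2, enzyme="TF:VIIa", product="IXa", substrate="FIX",
                         S0=0.09, kcat=1.8, Km=0.42, eta=1.2)

    def test_incomplete_reaction_set_rejected(self, params):
        with pytest.raises(ParameterError):
            ParameterSet(reactions=params.reactions[:6], sites=params.sites)

    def test_config_validation(self):
        with pytest.raises(ParameterError):
            ModelConfig(tat_fraction=1.2)
        with pytest.raises(ParameterError):
            ModelConfig(t_half_elution=0.0)
        with pytest.raises(ParameterError):
            ModelConfig(eluting_species=("IIa", "TFstar"))
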