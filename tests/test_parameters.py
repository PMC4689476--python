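"""Dimensional parameters, dimensionless groups and scaling laws."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smacsim.parameters import (
    DimensionlessGroups,
    InvalidParameterError,
    PhysicalParameters,
    bending_modulus,
    default_parameters,
    dimensionalize,
    dimensionless_groups,
    load_parameters,
    nondimensionalize,
    save_parameters,
    scaling_predictions,
)


def round_sig(x, sig=1):
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


class TestPhysicalParameters:
    def test_defaults_match_reference_table(self, params):
        assert params.mu == 4e-2
        assert params.C0 == 2e14
        assert params.C20 == 2 * params.C0
        assert params.l1 == 15e-9
        assert params.l2 == 45e-9
        assert params.L == 1e-5
        assert params.sigma_on == 0.2
        assert params.sigma_off == 0.6
        assert params.kappa == 1.2e-6
        assert params.D == 5e-13
        assert params.kBT == 4.34e-21

    def test_packaged_default_file_equals_class_defaults(self, params):
        assert params == PhysicalParameters()

    @pytest.mark.parametrize("field,value", [
        ("E", 0.0), ("b", -1e-9), ("mu", 0.0), ("nu", 1.5), ("nu", 0.0),
        ("l1", 50e-9),  # violates l1 < l2
        ("gamma", -1.0), ("tau_k", 0.0),
    ])
    def test_invalid_parameters_rejected(self, field, value):
        with pytest.raises(InvalidParameterError):
            PhysicalParameters(**{field: value})

    def test_species_derived_quantities(self, params):
        # stiffness and diffusivity inversely proportional to bond length
        assert params.kappa_i(1) == params.kappa
        assert params.kappa_i(2) == pytest.approx(params.kappa / 3.0)
        assert params.D_i(1) == params.D
        assert params.D_i(2) == pytest.approx(params.D / 3.0)


class TestBendingModulus:
    def test_reference_value(self, params):
        # default E is chosen to land on the lower literature endpoint
        assert bending_modulus(params) == pytest.approx(4.5e-21, rel=1e-12)

    def test_zero_modulus_rejected(self):
        with pytest.raises(InvalidParameterError):
            PhysicalParameters(E=0.0)

    def test_cubic_thickness_dependence(self, params):
        thicker = dataclasses.replace(params, b=2 * params.b)
        assert bending_modulus(thicker) == pytest.approx(8 * bending_modulus(params), rel=1e-12)


class TestDimensionlessGroups:
    def test_peclet_number(self, groups):
        assert round_sig(groups.Pe, 1) == 5e4

    def test_sliding_mobility_ratio(self, groups):
        assert round(groups.M, 1) == 2.0

    def test_aspect_ratio(self, groups):
        assert groups.eps == pytest.approx(4.5e-3, rel=1e-12)

    def test_bending_ratio_at_lower_stiffness(self, params, groups):
        # Bm = 4.5e-21 J -> B = Bm/(kappa C0 L^4) = 1.875e-9 (~2e-9)
        assert groups.B == pytest.approx(1.875e-9, rel=1e-12)
        assert round_sig(groups.B, 1) == 2e-9

    def test_length_ratio(self, groups, params):
        assert groups.lam1 == params.l1 / params.l2

    def test_tau_is_time_ratio(self, groups, params):
        assert groups.tau == pytest.approx(params.tau_mu / params.tau_k, rel=1e-12)

    def test_unit_system_invariance(self, params):
        """Groups are unchanged (12 digits) under a mm/mg/ms unit system."""
        # conversion factors from SI to (mm, mg, ms)
        length, mass, time = 1e3, 1e6, 1e3
        scaled = PhysicalParameters(
            mu=params.mu * mass / (length * time),
            E=params.E * mass / (length * time**2),
            b=params.b * length,
            nu=params.nu,
            kappa=params.kappa * mass / time**2,
            C0=params.C0 / length**2,
            C10=params.C10 / length**2,
            C20=params.C20 / length**2,
            l1=params.l1 * length,
            l2=params.l2 * length,
            D=params.D * length**2 / time,
            tau_k=params.tau_k * time,
            L=params.L * length,
            kBT=params.kBT * mass * length**2 / time**2,
            gamma=0.0,
            sigma_on=params.sigma_on,
            sigma_off=params.sigma_off,
        )
        a = dataclasses.asdict(dimensionless_groups(params))
        b = dataclasses.asdict(dimensionless_groups(scaled))
        for key in a:
            assert b[key] == pytest.approx(a[key], rel=1e-12), key


class TestScalingPredictions:
    def test_hydrodynamic_time(self, params):
        pred = scaling_predictions(params)
        assert round_sig(pred.tau_mu, 2) == 3.7e-3

    def test_pressure_scale(self, params):
        assert scaling_predictions(params).p0 == pytest.approx(10.8, rel=1e-12)

    def test_cluster_length_endpoints(self, params):
        lo = scaling_predictions(params)
        assert round_sig(lo.l_c * 1e9, 1) == 70  # nm at Bm = 4.5e-21 J
        hi = scaling_predictions(dataclasses.replace(params, E=params.E * 100))
        assert round_sig(hi.l_c * 1e9, 1) == 200  # nm at Bm = 4.5e-19 J

    def test_cell_scale_drainage_time(self, params):
        pred = scaling_predictions(params)
        assert round_sig(pred.tau_L / 60.0, 1) == 40  # minutes

    def test_cluster_drainage_time_upper_endpoint(self, params):
        hi = scaling_predictions(dataclasses.replace(params, E=params.E * 100))
        assert round(hi.tau_c) == 1  # seconds

    def test_quarter_power_scaling(self, params):
        base = scaling_predictions(params)
        x16 = scaling_predictions(dataclasses.replace(params, E=params.E * 16))
        assert x16.l_c == pytest.approx(2 * base.l_c, rel=1e-12)

    def test_time_scale_identity(self, params):
        pred = scaling_predictions(params)
        assert pred.tau_L / pred.tau_c == pytest.approx((params.L / pred.l_c) ** 2, rel=1e-9)


class TestNondimensionalize:
    def test_pressure_scale_maps_to_unity(self, params):
        assert nondimensionalize(params, 10.8, "pressure") == pytest.approx(1.0, rel=1e-12)

    def test_time_scale_maps_to_unity(self, params):
        assert nondimensionalize(params, params.tau_mu, "time") == 1.0

    def test_unknown_kind_rejected(self, params):
        with pytest.raises(ValueError):
            nondimensionalize(params, 1.0, "mass")

    @settings(derandomize=True, max_examples=50)
    @given(
        q=st.floats(min_value=1e-12, max_value=1e12, allow_nan=False),
        kind=st.sampled_from(["length_xy", "height", "pressure", "time", "density"]),
    )
    def test_round_trip(self, q, kind):
        params = default_parameters()
        back = dimensionalize(params, nondimensionalize(params, q, kind), kind)
        assert back == pytest.approx(q, rel=1e-12)


class TestConfigIO:
    def test_round_trip(self, tmp_path, params):
        path = tmp_path / "p.toml"
        save_parameters(params, path)
        assert load_parameters(path) == params

    def test_infinite_off_width_round_trip(self, tmp_path, params):
        path = tmp_path / "p.toml"
        save_parameters(dataclasses.replace(params, sigma_off=math.inf), path)
        assert math.isinf(load_parameters(path).sigma_off)

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "p.toml"
        path.write_text("viscosity = 1.0\n")
        with pytest.raises(InvalidParameterError):
            load_parameters(path)
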