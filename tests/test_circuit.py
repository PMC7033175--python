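"""Circuit-model tests against an independently coded complex-arithmetic oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from impedcyto.circuit import (
    ElectrodeCircuit,
    FrequencyGrid,
    InvalidParameterError,
    ParticleKind,
    ParticleModel,
    aggregate_particle,
    baseline_impedance,
    bead_particle,
    cell_particle,
    circuit_from_config,
    default_config,
    delta_impedance_magnitude,
    frequency_response_curve,
    grid_from_config,
    load_config,
    occlusion_resistance,
    particles_from_config,
    total_impedance,
    write_response_csv,
)


def oracle_total_impedance(C_dl, R_s, dR, C_m, R_c, f):
    """Independent evaluation via admittances rather than series/parallel forms."""
    w = 2.0 * math.pi * f
    z_dl = complex(0.0, -2.0 / (w * C_dl))
    if C_m is None:
        z_branch = complex(dR)
    elif dR == 0:
        z_branch = 0j
    else:
        y_membrane = 1.0 / (complex(R_c, -2.0 / (w * C_m)))
        z_branch = 1.0 / (1.0 / dR + y_membrane)
    return z_dl + R_s + z_branch


class TestBaselineImpedance:
    def test_frozen_value_at_500khz(self):
        z = baseline_impedance(ElectrodeCircuit(1e-9, 1e4), 500e3)
        assert z.real == pytest.approx(10000.0, rel=1e-12)
        assert z.imag == pytest.approx(-636.6197723675813, rel=1e-12)

    def test_high_frequency_limit_is_solution_resistance(self):
        z = baseline_impedance(ElectrodeCircuit(1e-9, 1e4), 1e15)
        assert abs(z) == pytest.approx(1e4, rel=1e-6)

    def test_huge_double_layer_capacitance_shorts_out(self):
        z = baseline_impedance(ElectrodeCircuit(1e6, 1e4), 100e3)
        assert z == pytest.approx(1e4 + 0j, abs=1e-4)

    def test_magnitude_decreasing_in_frequency(self):
        c = ElectrodeCircuit()
        mags = [abs(baseline_impedance(c, f)) for f in (1e5, 3e5, 1e6, 5e6, 2e7)]
        assert all(a > b for a, b in zip(mags, mags[1:]))

    def test_invalid_frequency_rejected(self):
        with pytest.raises(InvalidParameterError):
            baseline_impedance(ElectrodeCircuit(), 0.0)

    @pytest.mark.parametrize("kwargs", [{"C_dl_farads": -1e-9}, {"R_s_ohms": 0.0}])
    def test_invalid_circuit_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            ElectrodeCircuit(**kwargs)


class TestTotalImpedance:
    def test_frozen_cell_value_at_500khz(self):
        z = total_impedance(ElectrodeCircuit(), cell_particle(), 500e3)
        assert z.real == pytest.approx(10799.558695401185, rel=1e-10)
        assert z.imag == pytest.approx(-646.6534592690698, rel=1e-10)

    def test_zero_occlusion_equals_baseline(self):
        c = ElectrodeCircuit()
        p = ParticleModel(0.0, 2e3, 2.8, ParticleKind.CELL, 1e-11)
        for f in FrequencyGrid():
            assert total_impedance(c, p, f) == pytest.approx(baseline_impedance(c, f))

    def test_membrane_shorts_at_high_frequency(self):
        c = ElectrodeCircuit()
        p = cell_particle()
        z_branch = total_impedance(c, p, 1e14) - baseline_impedance(c, 1e14)
        expected = p.delta_R_ohms * p.R_c_ohms / (p.delta_R_ohms + p.R_c_ohms)
        assert abs(z_branch) == pytest.approx(expected, rel=1e-4)

    def test_oracle_equivalence_100_random_parameter_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            C_dl = 10 ** rng.uniform(-11, -7)
            R_s = 10 ** rng.uniform(2, 6)
            dR = 10 ** rng.uniform(0, 5)
            C_m = 10 ** rng.uniform(-13, -9)
            R_c = 10 ** rng.uniform(1, 6)
            f = 10 ** rng.uniform(4, 8)
            circ = ElectrodeCircuit(C_dl, R_s)
            cell = ParticleModel(dR, R_c, 1.0, ParticleKind.CELL, C_m)
            got = total_impedance(circ, cell, f)
            want = oracle_total_impedance(C_dl, R_s, dR, C_m, R_c, f)
            assert got == pytest.approx(want, rel=1e-12)
            bead = ParticleModel(dR, R_c, 1.0, ParticleKind.BEAD, None)
            got_b = total_impedance(circ, bead, f)
            want_b = oracle_total_impedance(C_dl, R_s, dR, None, R_c, f)
            assert got_b == pytest.approx(want_b, rel=1e-12)


class TestDeltaImpedance:
    def test_bead_response_flat_across_band(self):
        c = ElectrodeCircuit()
        p = bead_particle()
        v_low = delta_impedance_magnitude(c, p, 100e3)
        v_high = delta_impedance_magnitude(c, p, 20e6)
        assert v_high == pytest.approx(v_low, rel=1e-9)
        assert v_low == pytest.approx(p.delta_R_ohms, rel=1e-12)

    def test_cell_response_lower_at_20mhz_than_500khz(self):
        c = ElectrodeCircuit()
        p = cell_particle()
        assert delta_impedance_magnitude(c, p, 20e6) < delta_impedance_magnitude(c, p, 500e3)

    def test_cell_curve_matches_oracle_pointwise(self):
        c = ElectrodeCircuit()
        p = cell_particle()
        for f in FrequencyGrid():
            base = oracle_total_impedance(c.C_dl_farads, c.R_s_ohms, 0.0, None, 1.0, f)
            tot = oracle_total_impedance(
                c.C_dl_farads, c.R_s_ohms, p.delta_R_ohms, p.C_m_farads, p.R_c_ohms, f
            )
            assert delta_impedance_magnitude(c, p, f) == pytest.approx(
                abs(tot - base), rel=1e-12
            )

    def test_cell_response_non_increasing_and_drops_after_1mhz(self):
        c = ElectrodeCircuit()
        p = cell_particle()
        curve = [delta_impedance_magnitude(c, p, f) for f in FrequencyGrid()]
        assert all(a >= b for a, b in zip(curve, curve[1:]))
        i_1mhz = list(FrequencyGrid()).index(1e6)
        assert curve[-1] < curve[i_1mhz] * (1 - 1e-6)


class TestOcclusionResistance:
    def test_identity_and_cube_law_values(self):
        assert occlusion_resistance(100.0, 1.0) == 100.0
        assert occlusion_resistance(100.0, 2.0) == pytest.approx(800.0)
        assert occlusion_resistance(100.0, 3.0) == pytest.approx(2700.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        ref=st.floats(1e-3, 1e6),
        k=st.floats(0.01, 100.0),
    )
    def test_volume_law_property(self, ref, k):
        assert occlusion_resistance(ref, k) / occlusion_resistance(ref, 1.0) == pytest.approx(
            k ** 3, rel=1e-12
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            occlusion_resistance(100.0, 0.0)
        with pytest.raises(InvalidParameterError):
            occlusion_resistance(-1.0, 2.0)


class TestFrequencyResponseCurve:
    def test_single_point_consistency(self):
        c, p = ElectrodeCircuit(), cell_particle()
        curve = frequency_response_curve(c, p, FrequencyGrid((500e3,)))
        assert curve == [(500e3, delta_impedance_magnitude(c, p, 500e3))]

    def test_bead_flatness_ratio_below_one_percent(self):
        c = ElectrodeCircuit()
        vals = [dz for _, dz in frequency_response_curve(c, bead_particle(), FrequencyGrid())]
        assert max(vals) / min(vals) < 1.01

    def test_cell_normalized_curve_falls_below_0p9_by_20mhz(self):
        # frozen from the direct-evaluation oracle with default parameters:
        # |dZ| at 20 MHz is 0.7937x the 300 kHz value
        c = ElectrodeCircuit()
        curve = frequency_response_curve(c, cell_particle(), FrequencyGrid())
        assert curve[-1][1] / curve[0][1] == pytest.approx(0.79374, abs=1e-4)
        assert curve[-1][1] / curve[0][1] < 0.9

    def test_grid_validation(self):
        with pytest.raises(InvalidParameterError):
            FrequencyGrid(())
        with pytest.raises(InvalidParameterError):
            FrequencyGrid((5e5, 3e5))

    def test_csv_export(self, tmp_path):
        c = ElectrodeCircuit()
        curve = frequency_response_curve(c, bead_particle(), FrequencyGrid())
        path = tmp_path / "curve.csv"
        write_response_csv(path, curve)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "frequency_hz,delta_z_ohms"
        assert len(lines) == 1 + len(FrequencyGrid())


class TestParticleDefaults:
    def test_cell_is_8x_bead_volume(self):
        assert cell_particle().delta_R_ohms == pytest.approx(8 * bead_particle().delta_R_ohms)

    def test_aggregate_adds_bead_volumes(self):
        agg = aggregate_particle(n_beads=2)
        assert agg.delta_R_ohms == pytest.approx(cell_particle().delta_R_ohms * 10 / 8)
        assert agg.kind is ParticleKind.AGGREGATE

    def test_bead_membrane_branch_open(self):
        assert bead_particle().membrane_open
        assert not cell_particle().membrane_open


class TestConfigRoundtrip:
    @pytest.mark.parametrize("fmt", ["yaml", "json"])
    def test_defaults_roundtrip(self, tmp_path, fmt):
        import json

        import yaml

        cfg = default_config()
        path = tmp_path / f"cfg.{fmt}"
        if fmt == "json":
            path.write_text(json.dumps(cfg))
        else:
            path.write_text(yaml.safe_dump(cfg))
        loaded = load_config(path)
        assert circuit_from_config(loaded) == ElectrodeCircuit()
        assert grid_from_config(loaded) == FrequencyGrid()
        parts = particles_from_config(loaded)
        assert parts[ParticleKind.CELL] == cell_particle()
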