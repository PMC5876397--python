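"""Cumulative transport, permeability estimators, TEER, series-resistance math."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from placentrans import (
    DomainError,
    DoseSpec,
    InsertGeometry,
    SamplingSchedule,
    TEERRecord,
    additivity_deviation,
    analyze_series,
    apparent_permeability,
    cumulative_mass,
    equilibrium_fraction,
    naf_exclusion_endpoint,
    percent_of_initial_dose,
    permeability,
    series_composition,
    teer_normalized,
)
from placentrans.kinetics import OVER_EQUILIBRIUM, PE_UNDEFINED
from placentrans.synthetic import (
    BarrierModel,
    SimConfig,
    closed_form_basolateral_mass,
    simulate_insert,
)

from conftest import make_series

GEOM = InsertGeometry.transwell_12mm()


class TestCumulativeMass:
    def test_first_timepoint_has_no_correction(self):
        s = make_series([0.002], schedule=SamplingSchedule((1.0,), 0.05))
        assert cumulative_mass(s) == pytest.approx([0.003])

    def test_correction_restores_withdrawn_mass(self):
        # Delta-Q2 = 0.002*1.5 + 0.05*0.001 = 0.00305 mg, by hand
        s = make_series([0.001, 0.002], schedule=SamplingSchedule((1.0, 2.0), 0.05))
        assert cumulative_mass(s) == pytest.approx([0.0015, 0.00305])

    def test_zero_series_stays_zero(self):
        s = make_series([0.0] * 7, schedule=SamplingSchedule.fluorescence_24h())
        assert cumulative_mass(s) == pytest.approx([0.0] * 7)

    def test_length_mismatch_is_structural_error(self):
        s = make_series([0.0, 0.0])
        object.__setattr__(s, "concentrations_mg_ml", (0.0,))
        with pytest.raises(DomainError):
            cumulative_mass(s)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1e-3), min_size=1, max_size=10)
    )
    def test_nondecreasing_for_physical_readings(self, increments):
        # Under sample-and-replace, each post-draw concentration is the
        # previous reading diluted by (1 - Vs/Vw) and transport can only add
        # to it, so any physically realizable series obeys
        # C_n >= C_{n-1} * (1 - Vs/Vw); cumulative mass is then monotone.
        v_w, v_s = 1.5, 0.05
        c, concentrations = 0.0, []
        for delta in increments:
            c = c * (1.0 - v_s / v_w) + delta
            concentrations.append(c)
        s = make_series(concentrations)
        dq = cumulative_mass(s)
        assert np.all(np.diff(dq) >= -1e-15)


class TestPercentID:
    def test_full_dose_is_100_percent(self, dose):
        assert percent_of_initial_dose([dose.initial_dose_mg], dose) == pytest.approx(
            [100.0]
        )

    def test_zero_mass_is_zero_percent(self, dose):
        assert percent_of_initial_dose([0.0], dose) == pytest.approx([0.0])

    def test_nonpositive_dose_unconstructible(self, geometry):
        with pytest.raises(DomainError):
            DoseSpec(initial_concentration_mg_ml=1.0, initial_dose_mg=0.0)

    def test_long_run_single_draw_approaches_equilibrium_fraction(self, geometry):
        # one draw at 200 h with a fast barrier: basolateral content ~ 75% ID
        dose = DoseSpec.from_concentration(0.01, geometry, "probe")
        cfg = SimConfig(
            geometry=geometry,
            schedule=SamplingSchedule((200.0,), 0.05),
            dose=dose,
            barrier=BarrierModel((("membrane", 3e-5),)),
        )
        series, _ = simulate_insert(cfg)
        pct = percent_of_initial_dose(cumulative_mass(series), dose)
        assert pct[-1] == pytest.approx(75.0, rel=1e-6)


class TestEquilibriumFraction:
    def test_default_insert_is_three_quarters(self, geometry):
        assert equilibrium_fraction(geometry) == pytest.approx(0.75)

    def test_equal_volumes_split_evenly(self):
        g = InsertGeometry(apical_volume_ml=1.0, basolateral_volume_ml=1.0)
        assert equilibrium_fraction(g) == pytest.approx(0.5)

    def test_scale_invariance(self):
        g = InsertGeometry(apical_volume_ml=1.0, basolateral_volume_ml=3.0)
        assert equilibrium_fraction(g) == pytest.approx(0.75)


class TestPermeability:
    def test_identity_construction(self, geometry, dose):
        # Delta-Q(2 h) = A*C0*7200 gives P = 1 cm/s exactly
        dq = geometry.membrane_area_cm2 * dose.initial_concentration_mg_ml * 7200.0
        p = permeability([0.0, dq], dose, geometry, (0.0, 2.0), 2.0)
        assert p == pytest.approx(1.0, rel=1e-12)

    def test_zero_transport_gives_zero(self, geometry, dose):
        assert permeability([0.0, 0.0], dose, geometry, (0.0, 2.0), 2.0) == 0.0

    def test_t0_is_domain_error(self, geometry, dose):
        with pytest.raises(DomainError):
            permeability([0.0, 1.0], dose, geometry, (0.0, 2.0), 0.0)

    def test_unscheduled_time_is_lookup_error(self, geometry, dose):
        with pytest.raises(KeyError):
            permeability([0.0, 1.0], dose, geometry, (0.0, 2.0), 3.0)

    def test_early_secant_matches_closed_form_oracle(self, geometry):
        # noiseless single-layer barrier; the secant estimate must equal the
        # closed-form prediction to near machine precision, and its downward
        # (back-flux) bias at 0.25 h stays small for P <= 1e-5 cm/s
        dose = DoseSpec.from_concentration(0.01, geometry, "probe")
        for p_true in (1e-7, 1e-6, 1e-5, 5e-5):
            cfg = SimConfig(
                geometry=geometry,
                schedule=SamplingSchedule((0.0, 0.25), 0.05),
                dose=dose,
                barrier=BarrierModel((("layer", p_true),)),
            )
            series, _ = simulate_insert(cfg)
            p_est = permeability(
                cumulative_mass(series), dose, geometry, series.schedule.times_h, 0.25
            )
            expected_mass = closed_form_basolateral_mass(
                900.0, p_true, geometry, dose.initial_dose_mg, 0.0
            )
            p_oracle = expected_mass / (
                900.0 * geometry.membrane_area_cm2 * dose.initial_concentration_mg_ml
            )
            assert p_est == pytest.approx(p_oracle, rel=1e-9)
            if p_true <= 1e-5:
                assert p_est == pytest.approx(p_true, rel=0.05)

    def test_secant_bias_grows_monotonically_with_permeability(self, geometry):
        # documented bias curve: the 0.25 h secant underestimates more as the
        # true P rises (apical depletion / basolateral back-flux)
        dose = DoseSpec.from_concentration(0.01, geometry, "probe")
        biases = []
        for p_true in (1e-7, 1e-6, 1e-5, 3e-5, 1e-4):
            cfg = SimConfig(
                geometry=geometry,
                schedule=SamplingSchedule((0.0, 0.25), 0.05),
                dose=dose,
                barrier=BarrierModel((("layer", p_true),)),
            )
            series, _ = simulate_insert(cfg)
            p_est = permeability(
                cumulative_mass(series), dose, geometry, series.schedule.times_h, 0.25
            )
            biases.append(1.0 - p_est / p_true)
        assert all(b2 > b1 for b1, b2 in zip(biases, biases[1:]))
        assert all(0 <= b < 1 for b in biases)


class TestApparentPermeability:
    def test_membrane_correction(self):
        assert apparent_permeability(10e-6, 30e-6) == pytest.approx(15e-6)

    def test_very_permeable_membrane_limit(self):
        p_c = 1e-6
        assert apparent_permeability(p_c, 1e6 * p_c) == pytest.approx(p_c, rel=1e-4)

    def test_pole_returns_not_computable(self):
        assert apparent_permeability(2e-5, 2e-5) is None
        assert apparent_permeability(3e-5, 2e-5) is None

    def test_zero_cell_permeability_maps_to_zero(self):
        assert apparent_permeability(0.0, 2e-5) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            apparent_permeability(-1e-6, 2e-5)
        with pytest.raises(DomainError):
            apparent_permeability(1e-6, 0.0)

    @given(
        st.floats(min_value=1e-9, max_value=1e-3),
        st.floats(min_value=1e-9, max_value=1e-3),
    )
    def test_pe_exceeds_pc_below_the_pole(self, p_c, p_m):
        pe = apparent_permeability(p_c, p_m)
        if p_c < p_m:
            assert pe is not None and pe > p_c
        else:
            assert pe is None


class TestTEER:
    def test_blank_subtraction_and_area_correction(self):
        rec = TEERRecord(total_resistance_ohm=545.0, blank_resistance_ohm=200.0)
        value, negative = teer_normalized(rec)
        assert value == pytest.approx(345.0 * 1.12)  # 386.4 ohm cm2
        assert not negative

    def test_blank_identity_is_zero(self):
        rec = TEERRecord(300.0, 300.0)
        assert teer_normalized(rec).resistance_ohm_cm2 == 0.0

    def test_negative_value_flagged_not_clamped(self):
        rec = TEERRecord(250.0, 300.0)
        value, negative = teer_normalized(rec)
        assert value == pytest.approx(-50.0 * 1.12)
        assert negative


class TestNaFExclusion:
    def test_zero_reading_is_zero_percent(self, geometry, dose):
        s = make_series([0.0], schedule=SamplingSchedule((3.0,), 0.05), dose=dose)
        assert naf_exclusion_endpoint(s) == 0.0

    def test_missing_3h_timepoint_is_lookup_error(self, dose):
        s = make_series([0.0], schedule=SamplingSchedule((2.0,), 0.05), dose=dose)
        with pytest.raises(KeyError):
            naf_exclusion_endpoint(s)

    @pytest.mark.parametrize("p_true,upper", [(1e-7, 1.0), (3e-5, 100.0)])
    def test_matches_closed_form_oracle(self, geometry, p_true, upper):
        dose = DoseSpec.from_concentration(1.88e-3, geometry, "na_f")
        cfg = SimConfig(
            geometry=geometry,
            schedule=SamplingSchedule((3.0,), 0.05),
            dose=dose,
            barrier=BarrierModel((("barrier", p_true),)),
        )
        series, _ = simulate_insert(cfg)
        pct = naf_exclusion_endpoint(series)
        oracle = (
            100.0
            * closed_form_basolateral_mass(
                3 * 3600.0, p_true, geometry, dose.initial_dose_mg, 0.0
            )
            / dose.initial_dose_mg
        )
        assert pct == pytest.approx(oracle, rel=1e-9)
        assert pct < upper  # tight barrier stays under 1% ID


class TestSeriesResistance:
    def test_single_layer_is_identity(self):
        assert series_composition([2e-5]) == pytest.approx(2e-5)

    def test_two_equal_layers_halve_permeability(self):
        assert series_composition([10e-6, 10e-6]) == pytest.approx(5e-6)

    def test_permutation_symmetry(self):
        a = series_composition([1e-6, 3e-5, 2e-4])
        b = series_composition([2e-4, 1e-6, 3e-5])
        assert a == pytest.approx(b, rel=1e-12)

    def test_nonpositive_layer_rejected(self):
        with pytest.raises(DomainError):
            series_composition([1e-6, 0.0])

    @given(
        st.floats(min_value=1e-8, max_value=1e-3),
        st.floats(min_value=1e-8, max_value=1e-3),
    )
    def test_composition_then_correction_is_identity(self, pe, p_m):
        # apparent_permeability(series_composition([Pe, Pm]), Pm) == Pe
        combined = series_composition([pe, p_m])
        assert apparent_permeability(combined, p_m) == pytest.approx(pe, rel=1e-9)

    def test_additivity_ratio_one_for_perfectly_additive(self):
        layers = [2e-5, 4e-5]
        assert additivity_deviation(series_composition(layers), layers) == pytest.approx(
            1.0
        )

    def test_coculture_no_tighter_than_one_layer_gives_half(self):
        # combined barrier equals a single layer although two identical
        # layers were stacked -> observed/predicted resistance = 0.5
        p = 2e-5
        assert additivity_deviation(p, [p, p]) == pytest.approx(0.5)


class TestAnalyzeSeries:
    def test_flags_below_lod_and_undefined_pe(self, geometry):
        dose = DoseSpec.from_concentration(0.01, geometry, "probe")
        s = make_series(
            [0.0, 1e-6, 2e-6],
            schedule=SamplingSchedule((0.0, 1.0, 2.0), 0.05),
            dose=dose,
        )
        res = analyze_series(s, p_membrane_cm_s=1e-12, lod_mg_ml=1e-5)
        assert PE_UNDEFINED in res.flags
        assert "below_lod" in res.flags
        assert res.pe_at_cm_s[2.0] is None

    def test_over_equilibrium_flagged_not_clipped(self, geometry):
        dose = DoseSpec.from_concentration(0.01, geometry, "probe")
        # reading inflated beyond what the chambers could hold at equilibrium
        s = make_series(
            [0.0, 0.004], schedule=SamplingSchedule((0.0, 2.0), 0.05), dose=dose
        )
        res = analyze_series(s)
        assert OVER_EQUILIBRIUM in res.flags
        assert res.percent_id[-1] > 100.0
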