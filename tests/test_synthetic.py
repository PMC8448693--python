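"""Mechanistic generators: determinism, mass conservation, round trips."""

import numpy as np
import pandas as pd
import pytest

from mixtk import schemas as S
from mixtk.dose_response import ExponentialModelParams, exponential_model
from mixtk.membrane import anisotropy, atpase_delta_rlu, g_factor
from mixtk.synthetic import (
    InhibitionCurve,
    IntegrationError,
    TransportSimConfig,
    generate_anisotropy_readings,
    generate_atpase_plate,
    generate_dose_response,
    simulate_transport,
)
from mixtk.transport import cumulative_amount, relative_percent


def _final_pct(res):
    q = cumulative_amount(res.parent)
    return relative_percent(q, res.parent.donor_c0, res.parent.v_donor_ul)[-1]


def _efflux_ratio(cfg, inh=0.0):
    pct = {d: _final_pct(simulate_transport(cfg, d, 1.0, inhibitor_conc=inh))
           for d in S.DIRECTIONS}
    return pct["BL_to_AP"] / pct["AP_to_BL"]


class TestDoseResponseGenerator:
    def test_zero_noise_lies_exactly_on_curve(self, known_params, grid):
        data = generate_dose_response(known_params, grid, residual_sd=0.0,
                                      bio_intercept_sd=0.0, seed=4)
        expected = exponential_model(data[S.CONC].to_numpy(), known_params)
        np.testing.assert_array_equal(data[S.VIABILITY].to_numpy(), expected)

    def test_same_seed_is_bit_identical(self, known_params, grid):
        a = generate_dose_response(known_params, grid, seed=123)
        b = generate_dose_response(known_params, grid, seed=123)
        pd.testing.assert_frame_equal(a, b)
        c = generate_dose_response(known_params, grid, seed=124)
        assert not a[S.VIABILITY].equals(c[S.VIABILITY])

    def test_control_mean_near_a(self, known_params, grid):
        data = generate_dose_response(known_params, grid, residual_sd=5.0,
                                      bio_intercept_sd=0.0, seed=0)
        control = data.loc[data[S.CONC] == 0.0, S.VIABILITY]
        assert control.mean() == pytest.approx(known_params.a, abs=4 * 5.0 / np.sqrt(18))

    def test_design_shape(self, known_params, grid):
        data = generate_dose_response(known_params, grid, seed=0)
        assert len(data) == len(grid) * 3 * 6
        assert data[S.BIO_REP].nunique() == 3
        assert data[S.TECH_REP].nunique() == 6

    def test_nonfinite_parameter_rejected_by_name(self, grid):
        with pytest.raises(ValueError, match="'b'"):
            generate_dose_response(
                ExponentialModelParams(100.0, np.inf, 0.2, 1.0), grid, seed=0)

    def test_grid_must_include_zero(self, known_params):
        with pytest.raises(ValueError, match="including 0"):
            generate_dose_response(known_params, [1.0, 2.0, 4.0, 8.0], seed=0)


class TestTransportSimulator:
    def test_symmetric_passive_transport_has_unit_efflux_ratio(self):
        cfg = TransportSimConfig(efflux_weight=0.0, k_mic_l_mg=0.0,
                                 v_ap_ul=1000.0, v_bl_ul=1000.0,
                                 sample_volumes_ul={"AP": 200.0, "BL": 200.0})
        assert _efflux_ratio(cfg) == pytest.approx(1.0, abs=1e-9)

    def test_uninhibited_efflux_gives_net_secretion(self):
        cfg = TransportSimConfig(efflux_weight=0.4, v_ap_ul=1000.0, v_bl_ul=1000.0,
                                 sample_volumes_ul={"AP": 200.0, "BL": 200.0})
        er_uninhibited = _efflux_ratio(cfg, inh=0.0)
        er_inhibited = _efflux_ratio(cfg, inh=1000.0)  # [I] >> IC50
        assert er_uninhibited > 1.0
        assert er_inhibited < er_uninhibited

    def test_mass_conserved_to_tolerance(self):
        cfg = TransportSimConfig(k_hydrolysis_per_h=0.3)
        for direction in S.DIRECTIONS:
            res = simulate_transport(cfg, direction, 1.0, inhibitor_conc=10.0)
            assert res.mass_balance_error < 1e-6

    def test_ledger_matches_bruteforce_bookkeeping(self):
        """Sum of receiver mass and removed aliquots equals the reduced Q."""
        cfg = TransportSimConfig()
        res = simulate_transport(cfg, "AP_to_BL", 1.0)
        q_final = cumulative_amount(res.parent)[-1]
        ledger_q = res.ledger["receiver_parent"] + res.ledger["removed_parent"]
        assert abs(q_final - ledger_q) / ledger_q < 1e-9

    def test_micellar_sequestration_reduces_absorption(self):
        cfg = TransportSimConfig(efflux_weight=0.0)
        free = _final_pct(simulate_transport(cfg, "AP_to_BL", 1.0, inhibitor_conc=0.0))
        sequestered = _final_pct(simulate_transport(cfg, "AP_to_BL", 1.0,
                                                    inhibitor_conc=200.0))
        assert sequestered < free

    def test_metabolite_tracked_and_parent_depleted(self):
        cfg = TransportSimConfig(k_hydrolysis_per_h=0.3)
        res = simulate_transport(cfg, "AP_to_BL", 1.0)
        assert res.metabolite is not None
        met_total = (res.ledger["donor_metabolite"] + res.ledger["receiver_metabolite"]
                     + res.ledger["removed_metabolite"])
        assert met_total > 0.5 * res.ledger["initial"]  # 8 h at 0.3/h converts most

    def test_noise_seeded_and_deterministic(self):
        cfg = TransportSimConfig(noise_cv=0.05)
        r1 = simulate_transport(cfg, "AP_to_BL", 1.0, seed=9)
        r2 = simulate_transport(cfg, "AP_to_BL", 1.0, seed=9)
        assert r1.parent.samples == r2.parent.samples
        r3 = simulate_transport(cfg, "AP_to_BL", 1.0, seed=10)
        assert r1.parent.samples != r3.parent.samples

    def test_unstable_step_raises_integration_error(self):
        cfg = TransportSimConfig(p_passive_cm_s=5e-3, dt_h=0.5, timepoints_h=(2.0, 4.0))
        with pytest.raises(IntegrationError, match="dt_h"):
            simulate_transport(cfg, "AP_to_BL", 1.0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="sample volume"):
            TransportSimConfig(sample_volumes_ul={"AP": 600.0, "BL": 600.0})
        with pytest.raises(ValueError, match="strictly increasing"):
            TransportSimConfig(timepoints_h=(2.0, 2.0, 4.0))


class TestAnisotropyGenerator:
    def test_zero_noise_round_trip_recovers_r_exactly(self):
        # untreated Caco-2 calibration point r = 0.150
        reading = generate_anisotropy_readings(0.150, noise_cv=0.0, n=1, seed=0)[0]
        assert anisotropy(reading) == pytest.approx(0.150, abs=1e-12)

    def test_depolarised_limit_has_ivv_equal_g_ivh(self):
        reading = generate_anisotropy_readings(0.0, g_true=1.3, noise_cv=0.0, n=1, seed=0)[0]
        g = g_factor(reading.i_hv, reading.i_hh)
        assert reading.i_vv == pytest.approx(g * reading.i_vh, rel=1e-12)

    def test_g_factor_recovered(self):
        reading = generate_anisotropy_readings(0.2, g_true=1.1, noise_cv=0.0, n=1, seed=0)[0]
        assert g_factor(reading.i_hv, reading.i_hh) == pytest.approx(1.1, rel=1e-12)

    def test_monte_carlo_mean_within_two_se(self):
        n = 100
        readings = generate_anisotropy_readings(0.150, noise_cv=0.02, n=n, seed=42)
        rs = np.array([anisotropy(rd) for rd in readings])
        se = rs.std(ddof=1) / np.sqrt(n)
        assert abs(rs.mean() - 0.150) < 2 * se

    def test_out_of_range_r_rejected(self):
        with pytest.raises(ValueError, match="theoretical range"):
            generate_anisotropy_readings(1.2, seed=0)


class TestAtpaseGenerator:
    def test_no_inhibition_limit_matches_verapamil_wells(self):
        plate = generate_atpase_plate(inhibition_curve=InhibitionCurve(np.inf),
                                      noise_cv=0.0, seed=0)
        res = atpase_delta_rlu(plate)
        ratios = res.per_article["ratio_vs_verapamil"]
        np.testing.assert_allclose(ratios, 1.0, rtol=1e-12)

    def test_full_inhibition_limit_gives_zero_delta_rlu(self):
        plate = generate_atpase_plate(inhibition_curve=InhibitionCurve(1e-9),
                                      concentrations=(1000.0,), noise_cv=0.0, seed=0)
        res = atpase_delta_rlu(plate)
        assert res.per_article["delta_rlu"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_navo4_wells_have_highest_expected_rlu(self):
        plate = generate_atpase_plate(noise_cv=0.0, seed=0)
        means = plate.groupby(S.CONDITION)[S.RLU].mean()
        assert means.idxmax() == "navo4"

    def test_negative_stimulation_rejected(self):
        with pytest.raises(ValueError, match="stimulation"):
            generate_atpase_plate(stimulation_factor=-1.0, seed=0)

    def test_programmed_inhibition_recovered_at_zero_noise(self):
        plate = generate_atpase_plate(inhibition_curve=InhibitionCurve(10.0),
                                      concentrations=(10.0,), noise_cv=0.0, seed=0)
        res = atpase_delta_rlu(plate)
        assert 1.0 - res.per_article["ratio_vs_verapamil"].iloc[0] == pytest.approx(0.5, abs=1e-12)
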