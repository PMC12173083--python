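"""Clock ODE surrogate: oscillation, calibration, toxicity profiles."""

import numpy as np
import pytest

from chronotox.clockmodel import (
    CalibrationCriteria,
    ClockParameterSet,
    ClockState,
    align_to_clock_time,
    calibrate_defaults,
    clock_to_model_time,
    default_parameters,
    free_running_period,
    model_to_clock_time,
    simulate_clock,
    state_acrophase,
    toxicity_profile,
)
from chronotox.errors import CalibrationError
from chronotox.rhythm import circular_phase_difference


class TestSimulateClock:
    def test_zero_production_zero_state_is_absorbing(self):
        params = ClockParameterSet(
            V1max=0.0, V5max=0.0, kiz6=0.0, kiz7=0.0,
        )
        zero = ClockState(**{n: 0.0 for n in
                             ("m_B", "m_P", "c_A", "n_A", "c_R", "n_R")})
        traj = simulate_clock(params, initial=zero, t_span=(0, 48), dt_out=0.5)
        assert np.allclose(traj.states.to_numpy(), 0.0, atol=1e-12)

    def test_default_fixture_oscillates_at_24h(self, reference_params):
        traj = simulate_clock(reference_params, t_span=(0, 400), dt_out=0.05)
        period = free_running_period(traj, "m_B", cycles=(5, 10))
        assert 23.5 <= period <= 24.5

    def test_default_fixture_bmal1_per2_antiphase(self, reference_params):
        traj = simulate_clock(reference_params, t_span=(0, 400), dt_out=0.05)
        gap = (
            state_acrophase(traj, "m_P") - state_acrophase(traj, "m_B")
        ) % 24.0
        assert 8.0 <= gap <= 16.0

    def test_states_stay_non_negative(self, reference_params):
        traj = simulate_clock(reference_params, t_span=(0, 300), dt_out=0.1)
        assert traj.states.to_numpy().min() >= 0.0

    def test_apoptosis_output_non_decreasing_under_drug(self, reference_params):
        state = ClockState(D_ext=2.0)
        traj = simulate_clock(reference_params, initial=state,
                              t_span=(0, 96), dt_out=0.1)
        apo = traj["APO"]
        assert np.all(np.diff(apo) >= -1e-9)
        assert apo[-1] > 0.0

    def test_invalid_span_rejected(self, reference_params):
        with pytest.raises(ValueError):
            simulate_clock(reference_params, t_span=(10, 10))


class TestCalibration:
    def test_time_rescaling_halves_period(self, reference_params):
        traj = simulate_clock(reference_params, t_span=(0, 400), dt_out=0.05)
        period = free_running_period(traj, cycles=(5, 10))
        fast = reference_params.rescale_time(2.0)
        traj2 = simulate_clock(fast, t_span=(0, 200), dt_out=0.025)
        period2 = free_running_period(traj2, cycles=(5, 10))
        assert period2 == pytest.approx(period / 2.0, rel=1e-3)

    def test_calibrate_meets_criteria_and_is_deterministic(self):
        crit = CalibrationCriteria()
        p1, s1 = calibrate_defaults(seed=11, n_random=150, n_refine=30)
        p2, s2 = calibrate_defaults(seed=11, n_random=150, n_refine=30)
        assert p1 == p2
        assert s1["period_h"] == s2["period_h"]
        # re-assert the criteria by re-simulation
        traj = simulate_clock(p1, t_span=(0, 400), dt_out=0.05)
        period = free_running_period(traj, cycles=(5, 10))
        assert crit.period_band_h[0] <= period <= crit.period_band_h[1]
        mB = traj["m_B"][traj.t >= 200]
        rel_amp = np.ptp(mB) / (mB.max() + mB.min())
        assert rel_amp >= crit.min_rel_amplitude

    def test_packaged_fixture_matches_its_recorded_metrics(self, reference_params):
        import json
        from importlib import resources

        payload = json.loads(
            (resources.files("chronotox") / "data" /
             "default_clock_params.json").read_text()
        )
        assert payload["calibration"]["seed"] is not None
        traj = simulate_clock(reference_params, t_span=(0, 500), dt_out=0.05)
        period = free_running_period(traj, cycles=(5, 12))
        assert period == pytest.approx(payload["calibration"]["period_h"], abs=0.05)

    def test_hopeless_budget_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_defaults(seed=0, n_random=1, n_refine=0)


class TestAlignment:
    def test_zero_shift_is_identity(self, reference_params):
        assert align_to_clock_time(reference_params, 0.0) == reference_params

    def test_modular_shift(self):
        p = ClockParameterSet(phi_apop=22.0, phi_protein=10.0)
        shifted = align_to_clock_time(p, 4.0)
        assert shifted.phi_apop == pytest.approx(2.0)
        assert shifted.phi_protein == pytest.approx(14.0)

    def test_shift_and_unshift_restore(self, reference_params):
        back = align_to_clock_time(
            align_to_clock_time(reference_params, 5.5), -5.5
        )
        assert back.phi_apop == pytest.approx(reference_params.phi_apop)
        assert back.phi_protein == pytest.approx(reference_params.phi_protein)

    def test_clock_model_time_conversions_invert(self):
        for clock in (0.0, 6.9, 7.0, 23.5):
            assert model_to_clock_time(clock_to_model_time(clock)) == pytest.approx(
                clock % 24.0
            )


class TestToxicityProfile:
    def test_no_gating_gives_flat_curve(self, reference_params):
        flat = reference_params.with_values(rho_repair=0.0, alpha_apop=0.0)
        profile = toxicity_profile(flat, dose=1.0, start_grid=12)
        assert profile.relative_amplitude < 1e-6

    def test_zero_dose_accrues_nothing(self, reference_params):
        profile = toxicity_profile(reference_params, dose=0.0, start_grid=8)
        assert np.allclose(profile.toxicity, 0.0, atol=1e-10)
        assert profile.relative_amplitude < 1e-6

    def test_gate_shift_translates_curve(self, reference_params):
        base = toxicity_profile(reference_params, dose=1.0)
        shifted_params = reference_params.with_values(
            phi_protein=(reference_params.phi_protein + 6.0) % 24.0,
            phi_apop=(reference_params.phi_apop + 6.0) % 24.0,
        )
        shifted = toxicity_profile(shifted_params, dose=1.0)
        assert circular_phase_difference(
            shifted.phase_min_h, (base.phase_min_h + 6.0) % 24.0
        ) <= 1.0
        assert shifted.average_toxicity == pytest.approx(
            base.average_toxicity, rel=0.02
        )

    def test_monotone_in_dose(self, reference_params):
        low = toxicity_profile(reference_params, dose=0.5, start_grid=8)
        high = toxicity_profile(reference_params, dose=1.0, start_grid=8)
        assert np.all(high.toxicity >= low.toxicity - 1e-9)

    def test_24h_periodicity_of_start_time(self, reference_params):
        """Starting one full cycle later gives the same curve (extra burn-in
        period shifts the dosing time by exactly 24 h)."""
        a = toxicity_profile(reference_params, dose=1.0, start_grid=6,
                             burn_in_periods=10)
        b = toxicity_profile(reference_params, dose=1.0, start_grid=6,
                             burn_in_periods=11)
        assert np.allclose(a.toxicity, b.toxicity, rtol=1e-3)

    def test_bid_regimen_accumulates_more_than_single(self, reference_params):
        single = toxicity_profile(reference_params, dose=1.0, start_grid=4)
        bid = toxicity_profile(reference_params, dose=1.0, start_grid=4,
                               regimen="bid")
        assert np.all(bid.toxicity >= single.toxicity - 1e-9)

    def test_summary_fields_consistent(self, reference_params):
        profile = toxicity_profile(reference_params, dose=1.0, start_grid=12)
        tox = profile.toxicity
        assert profile.average_toxicity == pytest.approx(tox.mean())
        assert profile.absolute_amplitude == pytest.approx(
            (tox.max() - tox.min()) / 2
        )
        assert profile.phase_min_h == profile.start_times_h[np.argmin(tox)]
        assert tox.min() >= 0.0

    def test_invalid_arguments_rejected(self, reference_params):
        with pytest.raises(ValueError):
            toxicity_profile(reference_params, dose=-1.0)
        with pytest.raises(ValueError):
            toxicity_profile(reference_params, horizon_h=0.0)
        with pytest.raises(ValueError):
            toxicity_profile(reference_params, regimen="weekly")


class TestParameterSet:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            ClockParameterSet(dy1=-1.0)
        with pytest.raises(ValueError):
            ClockParameterSet(alpha_apop=1.5)

    def test_freed_subset_is_the_documented_one(self):
        from chronotox.clockmodel import FREED_PARAMETERS

        assert set(FREED_PARAMETERS) == {
            "dy1", "dy5", "a", "i", "V1max", "V5max",
            "kt1", "ki1", "kt5", "ki5",
            "dx1", "dx2", "dx5", "dx6",
            "kiz9", "kex1", "kiz4", "kex2", "kiz6", "kiz7",
        }

    def test_json_round_trip(self, reference_params):
        import json

        again = ClockParameterSet.from_dict(json.loads(reference_params.to_json()))
        assert again == reference_params
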