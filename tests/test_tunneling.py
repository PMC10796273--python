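"""Survival algebra, charging-rate aggregation, the barrier-decay fit and the
classical-transport bound."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from qbetkit.errors import FitError, InputError
from qbetkit.simulate import MetabolicSimParams, simulate_metabolic_dataset
from qbetkit.tunneling import (
    SurvivalState,
    aggregate_charging_rates,
    charging_rate_from_activity,
    classical_feasibility,
    evolve_survival,
    fit_barrier_decay,
    linker_length_from_mw,
    max_hop_distance,
    predicted_activity,
    round_to_sig_figs,
)


class TestChargingRate:
    def test_no_loss_means_zero_rate(self):
        assert charging_rate_from_activity(1.0, 12.0) == 0.0

    def test_unit_case(self):
        assert charging_rate_from_activity(math.exp(-1), 1.0) == pytest.approx(1.0, rel=1e-12)

    def test_half_activity_at_twelve_hours(self):
        assert charging_rate_from_activity(0.5, 12.0) == pytest.approx(
            math.log(2) / 12, rel=1e-12
        )

    def test_supranormal_activity_gives_negative_rate(self):
        assert charging_rate_from_activity(1.2, 12.0) < 0

    @pytest.mark.parametrize("activity,time", [(0.5, 0.0), (0.0, 12.0), (-0.1, 12.0)])
    def test_invalid_inputs_rejected(self, activity, time):
        with pytest.raises(InputError):
            charging_rate_from_activity(activity, time)

    @given(r=st.floats(0.0, 10.0), t=st.floats(0.001, 48.0))
    def test_inverse_of_predicted_activity(self, r, t):
        m = predicted_activity(r, t)
        if m > 0:  # deep decay underflows to exactly 0, which is unmeasurable anyway
            assert charging_rate_from_activity(m, t) == pytest.approx(r, abs=1e-9, rel=1e-9)

    def test_round_trip_machine_precision(self):
        for r in (0.01, 0.1, 1.0):
            assert charging_rate_from_activity(predicted_activity(r, 12.0), 12.0) == pytest.approx(
                r, rel=1e-12
            )


class TestSurvival:
    def test_zero_rate_is_identity(self):
        s = evolve_survival(SurvivalState(1000, 0), 0.0, 5.0)
        assert s.alive == 1000 and s.dead == 0

    def test_half_life(self):
        s = evolve_survival(SurvivalState(1000, 0), math.log(2), 1.0)
        assert s.alive == pytest.approx(500, rel=1e-12)
        assert s.dead == pytest.approx(500, rel=1e-12)

    def test_semigroup_property(self):
        s0 = SurvivalState(1000, 0)
        one_step = evolve_survival(s0, 0.3, 2.0)
        two_steps = evolve_survival(evolve_survival(s0, 0.3, 1.0), 0.3, 1.0)
        assert two_steps.alive == pytest.approx(one_step.alive, rel=1e-12)

    @given(
        rates=st.lists(st.floats(0.0, 2.0), min_size=1, max_size=6),
        dts=st.lists(st.floats(0.0, 10.0), min_size=1, max_size=6),
    )
    def test_total_conserved_under_any_sequence(self, rates, dts):
        s = SurvivalState(1000.0, 5.0)
        total = s.total
        for r, dt in zip(rates, dts):
            s = evolve_survival(s, r, dt)
            assert s.total == total  # exact by construction
            assert s.alive >= 0 and s.dead >= 0

    def test_state_activity_matches_closed_form(self):
        s = evolve_survival(SurvivalState(1000, 0), 0.2, 3.0)
        assert s.activity == pytest.approx(predicted_activity(0.2, 3.0), rel=1e-12)

    def test_negative_dt_rejected(self):
        with pytest.raises(InputError):
            evolve_survival(SurvivalState(10, 0), 0.1, -1.0)


class TestLinkerLength:
    def test_contour_length_two_kda(self):
        assert linker_length_from_mw(2.0) == pytest.approx(15.9, abs=0.05)

    def test_contour_length_one_kda(self):
        assert linker_length_from_mw(1.0) == pytest.approx(7.9, abs=0.05)

    def test_custom_monomer_rise(self):
        L = linker_length_from_mw(2.0, convention="custom", nm_per_monomer=0.28)
        assert L == pytest.approx(12.7, abs=0.05)
        # linear in the per-monomer rise
        assert L == pytest.approx(linker_length_from_mw(2.0) * 0.28 / 0.35, rel=1e-12)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(InputError):
            linker_length_from_mw(0.0)


def _metabolic_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["cell_line", "diameter_nm", "linker_kda", "time_h", "activity_fraction", "replicate"],
    )


class TestAggregation:
    def test_identical_replicates_have_zero_se(self):
        frame = _metabolic_frame([("c", 100, 2.0, 12.0, 0.5, i) for i in range(1, 4)])
        (rate,) = aggregate_charging_rates(frame)
        assert rate.r_d == pytest.approx(math.log(2) / 12, rel=1e-12)
        assert rate.se == 0.0
        assert rate.n_replicates == 3

    def test_mean_of_rates_not_rate_of_mean(self):
        frame = _metabolic_frame(
            [("c", 100, 2.0, 12.0, m, i) for i, m in enumerate([0.4, 0.5, 0.6], 1)]
        )
        (rate,) = aggregate_charging_rates(frame)
        expected = np.mean([-math.log(m) / 12 for m in (0.4, 0.5, 0.6)])
        not_expected = -math.log(0.5) / 12  # == Eq applied to the mean activity
        assert rate.r_d == pytest.approx(expected, rel=1e-12)
        assert abs(rate.r_d - not_expected) > 1e-6

    def test_supranormal_condition_tagged_and_excluded(self):
        frame = _metabolic_frame(
            [("c", 100, 2.0, 12.0, 1.1, 1), ("c", 100, 2.0, 12.0, 1.2, 2)]
        )
        (rate,) = aggregate_charging_rates(frame)
        assert rate.r_d < 0
        assert rate.supranormal
        assert not rate.usable_for_fit

    def test_zero_time_rejected(self):
        frame = _metabolic_frame([("c", 100, 2.0, 0.0, 0.5, 1)])
        with pytest.raises(InputError, match="time"):
            aggregate_charging_rates(frame)


class TestBarrierFit:
    def test_noiseless_recovery_is_exact(self):
        alpha, beta = 0.10, 0.10
        L = np.array([8.0, 16.0, 28.0, 40.0])
        points = [(l, beta * math.exp(-alpha * l), 0.0) for l in L]
        fit = fit_barrier_decay(points)
        assert fit.alpha_loc == pytest.approx(alpha, rel=1e-6)
        assert fit.beta == pytest.approx(beta, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_loglinear_and_nonlinear_agree_noiseless(self):
        points = [(l, 0.2 * math.exp(-0.08 * l), 0.0) for l in (5.0, 12.0, 20.0, 35.0)]
        fit = fit_barrier_decay(points)
        assert fit.loglinear_alpha == pytest.approx(fit.alpha_loc, rel=1e-2)
        assert fit.loglinear_beta == pytest.approx(fit.beta, rel=1e-2)

    def test_flat_rates_give_zero_decay_with_warning(self):
        fit = fit_barrier_decay([(l, 0.05, 0.0) for l in (8.0, 16.0, 28.0)])
        assert abs(fit.alpha_loc) < 1e-8
        assert fit.beta == pytest.approx(0.05, rel=1e-6)
        assert any("no barrier decay" in w for w in fit.warnings)

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError, match=">= 3"):
            fit_barrier_decay([(8.0, 0.1, 0.0), (16.0, 0.05, 0.0)])

    def test_equal_lengths_rejected(self):
        with pytest.raises(FitError, match="equal"):
            fit_barrier_decay([(8.0, 0.1, 0.0), (8.0, 0.05, 0.0), (8.0, 0.02, 0.0)])

    def test_synthetic_dataset_recovery_within_two_se(self):
        """Full generator -> aggregation -> fit chain on the standard grid."""
        params = MetabolicSimParams(
            beta_true=0.1, alpha_loc_true=0.1, diameters=(100.0,),
            noise_sd_activity=0.05, replicates=9, seed=11,
        )
        ds = simulate_metabolic_dataset(params)
        rates = aggregate_charging_rates(ds)
        fit = fit_barrier_decay(rates)
        assert abs(fit.alpha_loc - 0.1) <= 2 * fit.alpha_se


class TestClassicalBound:
    def test_printed_worked_example(self):
        d = max_hop_distance(3.75e-3, 3e6)
        assert d == pytest.approx(1.25e-2, rel=1e-12)
        assert round_to_sig_figs(d, 1) == pytest.approx(0.01, rel=1e-12)

    def test_unhindered_particle_rate(self):
        assert max_hop_distance(9.6e-3, 3e6) == pytest.approx(3.2e-2, rel=1e-12)

    def test_inverse_in_frequency(self):
        assert max_hop_distance(3.75e-3, 6e6) == pytest.approx(
            max_hop_distance(3.75e-3, 3e6) / 2, rel=1e-12
        )

    def test_dimensional_identity(self):
        k0, f = 7.3e-3, 2.2e6
        assert max_hop_distance(k0, f) == pytest.approx(k0 * 1e7 / f, rel=1e-12)

    def test_feasibility_verdicts(self):
        assert not classical_feasibility(0.0125, 15.9).classical_possible
        assert classical_feasibility(20.0, 15.9).classical_possible
        assert classical_feasibility(15.9, 15.9).classical_possible  # boundary inclusive

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(InputError):
            max_hop_distance(0.0, 3e6)
        with pytest.raises(InputError):
            classical_feasibility(-1.0, 10.0)
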