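"""LQ metrics, the timing matrix Θ, and the IED evaluation."""

import math

import numpy as np
import pytest
from oracles import theta_matrix_trapezoid

from iedose import (
    ImmuneKinetics,
    InputError,
    RadiosensitivityParams,
    Schedule,
    bed,
    eqd2,
    evaluate,
    ied,
    ied_efficacy,
    immunogenic_contributions,
    kill_fraction,
    make_uniform,
    survival_weights,
    theta_entry,
    theta_matrix,
)


class TestLQMetrics:
    @pytest.mark.parametrize(
        "dose, expected",
        [
            (0.0, 0.0),
            (8.0, 1.0 - math.exp(-3.6)),  # alpha*8 + beta*64 = 3.6
            (6.0, 1.0 - math.exp(-2.25)),
            (2.0, 1.0 - math.exp(-0.45)),
        ],
    )
    def test_kill_fraction(self, dose, expected, params):
        assert kill_fraction(dose, params) == pytest.approx(expected, rel=1e-12)

    def test_kill_fraction_rejects_negative_dose(self, params):
        with pytest.raises(InputError):
            kill_fraction(-1.0, params)

    def test_kill_fraction_increasing(self, params):
        doses = np.linspace(0.0, 20.0, 200)
        k = np.array([kill_fraction(d, params) for d in doses])
        assert np.all(np.diff(k) > 0)
        assert np.all((k >= 0) & (k < 1))

    def test_survival_weights_geometric(self, sched_3x8, params):
        s = survival_weights(sched_3x8, params)
        expected = [1.0, math.exp(-3.6), math.exp(-7.2)]
        assert s == pytest.approx(expected, rel=1e-12)

    def test_survival_weights_single_dose(self, params):
        assert survival_weights(Schedule([(0.0, 8.0)]), params).tolist() == [1.0]

    def test_bed_eqd2_worked_values(self, sched_3x8, sched_5x6, params):
        assert bed(sched_3x8, params) == pytest.approx(72.0)
        assert bed(sched_5x6, params) == pytest.approx(75.0)
        assert eqd2(sched_3x8, params) == pytest.approx(48.0)
        assert eqd2(sched_5x6, params) == pytest.approx(50.0)
        assert bed(Schedule([(0.0, 2.0)]), params) == pytest.approx(3.0)

    def test_eqd2_fixed_point_at_2gy_fractions(self, params):
        course = make_uniform(10, 2.0)
        assert eqd2(course, params) == pytest.approx(course.total_dose_gy, rel=1e-12)


class TestTheta:
    def test_lower_triangle_is_zero(self, sched_5x6, kinetics):
        for i in range(1, 6):
            for j in range(1, i):
                assert theta_entry(i, j, sched_5x6, kinetics) == 0.0

    def test_last_window_closed_form(self, sched_3x8, kinetics):
        # T_N - T_1 = 2 days, T_D = 3: tail mass 2^(-4/9)
        assert theta_entry(1, 3, sched_3x8, kinetics) == pytest.approx(
            2.0 ** (-4.0 / 9.0), abs=1e-12
        )
        # last dose, last window: the whole release happens after T_N
        assert theta_entry(3, 3, sched_3x8, kinetics) == 1.0

    def test_index_out_of_range(self, sched_3x8, kinetics):
        for i, j in [(0, 1), (1, 0), (4, 1), (1, 4)]:
            with pytest.raises(InputError):
                theta_entry(i, j, sched_3x8, kinetics)

    def test_single_dose_matrix(self, kinetics):
        mat = theta_matrix(Schedule([(0.0, 8.0)]), kinetics)
        assert mat.shape == (1, 1) and mat[0, 0] == 1.0

    def test_structure_and_row_sums(self, sched_5x6, kinetics):
        mat = theta_matrix(sched_5x6, kinetics)
        assert np.allclose(mat, np.triu(mat))
        assert np.all((mat >= 0.0) & (mat <= 1.0))
        assert np.all(mat.sum(axis=1) <= 1.0 + 1e-9)

    def test_daily_3x8_row_sum(self, sched_3x8, kinetics):
        # frozen from the 1e6-point trapezoid oracle
        assert theta_matrix(sched_3x8, kinetics)[0].sum() == pytest.approx(
            0.73584076, abs=1e-6
        )

    def test_translation_invariance(self, sched_5x6, kinetics):
        shifted = sched_5x6.shifted(17.3)
        diff = theta_matrix(sched_5x6, kinetics) - theta_matrix(shifted, kinetics)
        assert np.max(np.abs(diff)) <= 1e-12

    def test_slow_death_limit(self, kinetics):
        """T_D >> schedule span: nothing is released between fractions, so
        off-diagonal columns vanish and the open-ended last column is 1."""
        sched = make_uniform(5, 6.0)
        mat = theta_matrix(sched, ImmuneKinetics(t_d=1e6, t_ir=kinetics.t_ir))
        assert np.max(np.abs(mat[:, :-1])) <= 1e-9
        assert mat[:, -1] == pytest.approx(np.ones(5), abs=1e-9)

    def test_matches_trapezoid_oracle(self, kinetics):
        rng = np.random.default_rng(20260919)
        for _ in range(10):
            n = int(rng.integers(2, 11))
            gaps = rng.uniform(0.1, 30.0, size=n - 1)
            times = np.concatenate(([0.0], np.cumsum(gaps)))
            sched = Schedule((t, 2.0) for t in times)
            ours = theta_matrix(sched, kinetics)
            ref = theta_matrix_trapezoid(times, kinetics.t_d, kinetics.t_ir)
            assert np.max(np.abs(ours - ref)) <= 1e-6


class TestEvaluation:
    def test_single_dose_contributions_equal_kill(self, params, kinetics):
        for d in (1.0, 2.0, 6.0, 8.0, 10.0):
            sched = Schedule([(0.0, d)])
            e_vec = immunogenic_contributions(sched, params, kinetics)
            assert e_vec.tolist() == pytest.approx([kill_fraction(d, params)], abs=1e-12)

    def test_single_dose_ied_closed_form(self, params, kinetics):
        """For one instantaneous dose, IED = D + (beta/alpha) D^2 exactly."""
        for d in (1.0, 2.0, 6.0, 8.0, 10.0):
            sched = Schedule([(0.0, d)])
            expected = d + (params.beta / params.alpha) * d * d
            assert ied(sched, params, kinetics) == pytest.approx(expected, rel=1e-9)
        assert ied(Schedule([(0.0, 8.0)]), params, kinetics) == pytest.approx(24.0)

    def test_single_2gy_efficacy(self, params, kinetics):
        eff = ied_efficacy(Schedule([(0.0, 2.0)]), params, kinetics)
        assert eff == pytest.approx(1.0 - math.exp(-0.45), abs=1e-12)

    def test_early_doses_dominate(self, sched_5x6, params, kinetics):
        e_vec = immunogenic_contributions(sched_5x6, params, kinetics)
        assert np.all(e_vec >= 0.0)
        assert e_vec[0] == max(e_vec)
        assert e_vec.sum() < 1.0

    def test_table_worked_examples(self, sched_3x8, sched_5x6, params, kinetics):
        assert ied_efficacy(sched_3x8, params, kinetics) == pytest.approx(0.74, abs=5e-3)
        assert ied_efficacy(sched_5x6, params, kinetics) == pytest.approx(0.32, abs=5e-3)

    def test_evaluate_consistency(self, sched_3x8, params, kinetics):
        res = evaluate(sched_3x8, params, kinetics)
        assert res.efficacy == pytest.approx(float(res.contributions.sum()), abs=1e-12)
        assert res.ied_gy == pytest.approx(
            -math.log1p(-res.efficacy) / params.alpha, rel=1e-9
        )
        assert res.bed_gy == pytest.approx(72.0)
        assert res.eqd2_gy == pytest.approx(48.0)
        assert res.theta is not None and res.theta.shape == (3, 3)
        assert res.efficacy_percent == 74

    def test_slow_death_limit_equals_total_kill(self, params):
        """With T_D = 1e6 d, timing is irrelevant: efficacy -> 1 - prod(1-k)."""
        kin = ImmuneKinetics(t_d=1e6, t_ir=7.0)
        for sched in (make_uniform(5, 6.0), make_uniform(3, 8.0), make_uniform(25, 2.0)):
            k = np.array([kill_fraction(d, params) for d in sched.doses])
            total_kill = 1.0 - np.prod(1.0 - k)
            assert abs(ied_efficacy(sched, params, kin) - total_kill) <= 1e-3

    def test_well_separated_limit_equals_total_kill(self, params, kinetics):
        """Gaps >> T_D + T_IR: every dose's immune response completes."""
        sched = Schedule([(0.0, 2.0), (300.0, 6.0), (600.0, 8.0), (900.0, 4.0)])
        k = np.array([kill_fraction(d, params) for d in sched.doses])
        total_kill = 1.0 - np.prod(1.0 - k)
        assert abs(ied_efficacy(sched, params, kinetics) - total_kill) <= 1e-3

    def test_drop_and_recovery(self, params, kinetics):
        """2 x 2 Gy: efficacy dips at intermediate gaps (~T_D..T_D+T_IR) and
        recovers for very short or very long gaps."""
        eff = {g: ied_efficacy(make_uniform(2, 2.0, interval=g), params, kinetics)
               for g in (0.25, 3.0, 21.0)}
        assert eff[0.25] > eff[3.0]
        assert eff[21.0] > eff[3.0]

    def test_efficacy_translation_invariance(self, sched_3x8, params, kinetics):
        assert ied_efficacy(sched_3x8.shifted(100.0), params, kinetics) == pytest.approx(
            ied_efficacy(sched_3x8, params, kinetics), abs=1e-12
        )

    def test_dose_transform_hook(self, params, kinetics):
        """A user-supplied per-fraction transform (e.g. a high-dose cap)
        changes K and S but not the timing matrix."""
        sched = make_uniform(2, 12.0)
        capped = ied_efficacy(sched, params, kinetics, dose_transform=lambda d: min(d, 10.0))
        assert capped == pytest.approx(
            ied_efficacy(make_uniform(2, 10.0), params, kinetics), abs=1e-12
        )

    def test_coincident_events_merged(self, params, kinetics):
        merged = Schedule([(0.0, 2.0), (0.0, 2.0)])
        assert len(merged) == 1 and merged.events[0][1] == 4.0
        assert ied_efficacy(merged, params, kinetics) == pytest.approx(
            kill_fraction(4.0, params), abs=1e-12
        )


class TestValidation:
    def test_bad_parameters(self):
        with pytest.raises(InputError):
            RadiosensitivityParams(alpha=-0.1)
        with pytest.raises(InputError):
            RadiosensitivityParams(alpha_beta=0.0)
        with pytest.raises(InputError):
            ImmuneKinetics(t_d=0.0)

    def test_bad_schedules(self):
        with pytest.raises(InputError):
            Schedule([])
        with pytest.raises(InputError):
            Schedule([(-1.0, 2.0)])
        with pytest.raises(InputError):
            Schedule([(0.0, 0.0)])

    def test_beta_derived(self):
        p = RadiosensitivityParams(alpha=0.15, alpha_beta=4.0)
        assert p.beta == pytest.approx(0.0375, rel=1e-12)
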