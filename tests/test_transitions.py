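import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from obesim.params import Arm, BmiCategory, InterventionEffect, RelativeRisk, Sex
from obesim.synth import simulate_panel
from obesim.transitions import (
    IntervalTransition,
    PanelDataError,
    SmoothingConfig,
    annualize_multistate,
    annualize_two_state,
    apply_relative_risk,
    estimate_from_panel,
)


class TestAnnualizeTwoState:
    def test_zero_rate(self):
        assert annualize_two_state(0.0, 5) == 0.0

    def test_closed_form_example(self):
        # derived: (1 - 0.1)^2 = 0.81 = 1 - 0.19
        p1 = annualize_two_state(0.19, 2)
        assert p1 == pytest.approx(0.10, abs=1e-12)

    def test_identity_at_t1(self):
        assert annualize_two_state(0.5, 1) == pytest.approx(0.5)

    def test_p_one_rejected(self):
        with pytest.raises(ValueError):
            annualize_two_state(1.0, 3)

    @given(
        p=st.floats(min_value=0.0, max_value=0.999, allow_nan=False),
        t=st.integers(min_value=1, max_value=25),
    )
    def test_exact_inverse_of_composition(self, p, t):
        p1 = annualize_two_state(p, t)
        assert 0.0 <= p1 < 1.0
        assert 1.0 - (1.0 - p1) ** t == pytest.approx(p, abs=1e-9)


class TestAnnualizeMultistate:
    def test_identity_row_unchanged(self):
        row = IntervalTransition(BmiCategory.NORMAL, (1.0, 0.0, 0.0, 0.0), 7)
        np.testing.assert_allclose(annualize_multistate(row), [1.0, 0.0, 0.0, 0.0])

    def test_single_destination_reduces_to_two_state(self):
        row = IntervalTransition(BmiCategory.NORMAL, (0.81, 0.19, 0.0, 0.0), 2)
        annual = annualize_multistate(row)
        assert annual[1] == pytest.approx(0.10, abs=1e-12)
        assert annual[0] == pytest.approx(0.90, abs=1e-12)
        assert annual.sum() == pytest.approx(1.0)

    def test_dense_row_against_composition_oracle(self):
        # Brute-force oracle: embed the annual row in a matrix whose other
        # states are absorbing and compose it t times.  Under competing risks
        # the per-destination rate conversion is approximate, so the check
        # carries an explicit tolerance (2% absolute per destination).
        interval = IntervalTransition(
            BmiCategory.NORMAL, (0.70, 0.20, 0.08, 0.02), 3
        )
        annual = annualize_multistate(interval)
        mat = np.eye(4)
        mat[0] = annual
        composed = np.linalg.matrix_power(mat, 3)[0]
        np.testing.assert_allclose(
            composed, interval.to_distribution, atol=0.02
        )

    def test_interval_probability_one_rejected(self):
        row = IntervalTransition(BmiCategory.NORMAL, (0.0, 1.0, 0.0, 0.0), 2)
        with pytest.raises(ValueError):
            annualize_multistate(row)

    def test_negative_residual_rescaled(self, caplog):
        # huge off-diagonal interval masses over a short interval force the
        # annual off-diagonal sum above 1
        row = IntervalTransition(BmiCategory.NORMAL, (0.0, 0.5, 0.45, 0.05), 1)
        annual = annualize_multistate(row)
        assert annual.sum() == pytest.approx(1.0)
        assert annual.min() >= 0.0


class TestApplyRelativeRisk:
    def test_identity_when_rr_one(self):
        effect = InterventionEffect(RelativeRisk(1.0, 1.0, 1.0), RelativeRisk(1.0, 1.0, 1.0))
        row = np.array([0.85, 0.10, 0.04, 0.01])
        np.testing.assert_array_equal(apply_relative_risk(row, effect), row)

    def test_half_risk_example(self):
        effect = InterventionEffect(RelativeRisk(0.5, 0.5, 0.5), RelativeRisk(0.5, 0.5, 0.5))
        out = apply_relative_risk(np.array([0.90, 0.08, 0.02, 0.0]), effect)
        np.testing.assert_allclose(out, [0.95, 0.04, 0.01, 0.0], atol=1e-15)

    def test_vanishing_risk_limit(self):
        effect = InterventionEffect(RelativeRisk(1e-300, 1e-300, 1.0), RelativeRisk(1e-300, 1e-300, 1.0))
        row = np.array([0.80, 0.10, 0.05, 0.05])
        out = apply_relative_risk(row, effect)
        assert out[1] == pytest.approx(0.0, abs=1e-12)
        assert out[2] == pytest.approx(0.0, abs=1e-12)
        assert out[0] == pytest.approx(1.0 - 0.05)
        assert out[3] == 0.05  # death untouched

    def test_rr_times_p_above_one_rejected(self):
        effect = InterventionEffect(RelativeRisk(20.0, 20.0, 20.0), RelativeRisk(1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            apply_relative_risk(np.array([0.3, 0.7, 0.0, 0.0]), effect)

    @given(
        pn=st.floats(min_value=0.0, max_value=1.0),
        pow_=st.floats(min_value=0.0, max_value=1.0),
        pob=st.floats(min_value=0.0, max_value=1.0),
        pd_=st.floats(min_value=0.0, max_value=1.0),
        rr1=st.floats(min_value=0.01, max_value=1.0),
        rr2=st.floats(min_value=0.01, max_value=1.0),
    )
    def test_preserves_row_sum_and_death(self, pn, pow_, pob, pd_, rr1, rr2):
        total = pn + pow_ + pob + pd_
        if total < 1e-6:
            return
        row = np.array([pn, pow_, pob, pd_]) / total
        effect = InterventionEffect(
            RelativeRisk(rr1, rr1, rr1), RelativeRisk(rr2, rr2, rr2)
        )
        out = apply_relative_risk(row, effect)
        assert out.sum() == pytest.approx(row.sum(), abs=1e-12)
        assert out[3] == row[3]
        assert np.all(out >= -1e-15)


def _panel(rows):
    return pd.DataFrame(rows, columns=["subject_id", "arm", "sex", "age", "category"])


class TestEstimateFromPanel:
    def test_all_stay_gives_identity_rows(self):
        rows = []
        for sid, cat in [("a", "NORMAL"), ("b", "OVERWEIGHT"), ("c", "OBESE")]:
            for age in range(4):
                rows.append((sid, "COMMON", "MALE", age, cat))
        est = estimate_from_panel(_panel(rows))
        for (_, _, age), mat in est.entries.items():
            np.testing.assert_array_equal(mat, np.eye(4))

    def test_two_subject_count_ratio(self):
        rows = [
            ("a", "COMMON", "FEMALE", 3, "NORMAL"),
            ("a", "COMMON", "FEMALE", 4, "OVERWEIGHT"),
            ("b", "COMMON", "FEMALE", 3, "NORMAL"),
            ("b", "COMMON", "FEMALE", 4, "NORMAL"),
        ]
        est = estimate_from_panel(_panel(rows))
        mat = est.entries[(Arm.COMMON, Sex.FEMALE, 3)]
        np.testing.assert_allclose(mat[0], [0.5, 0.5, 0.0, 0.0])

    def test_empty_panel_rejected(self):
        with pytest.raises(PanelDataError, match="empty"):
            estimate_from_panel(_panel([]))

    def test_decreasing_age_rejected(self):
        rows = [
            ("a", "COMMON", "MALE", 4, "NORMAL"),
            ("a", "COMMON", "MALE", 3, "NORMAL"),
        ]
        with pytest.raises(PanelDataError, match="non-increasing"):
            estimate_from_panel(_panel(rows))

    def test_sparse_row_filled_and_flagged(self):
        # no OBESE subjects observed at age 2 -> OBESE row imputed
        rows = [
            ("a", "COMMON", "MALE", 2, "NORMAL"),
            ("a", "COMMON", "MALE", 3, "NORMAL"),
        ]
        est = estimate_from_panel(_panel(rows), SmoothingConfig(method="uniform"))
        mat = est.entries[(Arm.COMMON, Sex.MALE, 2)]
        assert (Arm.COMMON, Sex.MALE, 2, BmiCategory.OBESE) in est.filled
        np.testing.assert_allclose(mat[BmiCategory.OBESE, :3], np.full(3, 1 / 3))

    def test_recovery_from_synthetic_panel(self, baseline_truth):
        # parameter recovery at a modest panel size; the full-size version
        # (n = 2000) is an acceptance criterion
        panel = simulate_panel(baseline_truth, n_per_arm=800, seed=5)
        est = estimate_from_panel(panel)
        from obesim.engine import build_arm_matrices

        failures = []
        for arm in (Arm.LP, Arm.HP):
            for sex in Sex:
                true = build_arm_matrices(baseline_truth.params, Arm(arm), sex)
                for (e_arm, e_sex, age), counts in est.counts.items():
                    if e_arm is not Arm(arm) or e_sex is not sex:
                        continue
                    for frm in range(3):
                        n_row = counts[frm].sum()
                        if n_row == 0:
                            continue
                        for to in range(3):
                            p = true[age, frm, to] / (1.0 - true[age, frm, 3])
                            # require both np >= 5 and n(1-p) >= 5 so the
                            # normal approximation behind the 3-SE band holds
                            if n_row * p < 5 or n_row * (1.0 - p) < 5:
                                continue
                            se = np.sqrt(p * (1 - p) / n_row)
                            est_p = counts[frm, to] / n_row
                            if abs(est_p - p) > 3 * se:
                                failures.append((arm, sex, age, frm, to))
        assert not failures, f"cells beyond 3 binomial SE: {failures}"


class TestIntervalTransition:
    def test_distribution_must_sum_to_one(self):
        with pytest.raises(ValueError):
            IntervalTransition(BmiCategory.NORMAL, (0.5, 0.4, 0.0, 0.0), 2)

    def test_interval_years_positive(self):
        with pytest.raises(ValueError):
            IntervalTransition(BmiCategory.NORMAL, (1.0, 0.0, 0.0, 0.0), 0)
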