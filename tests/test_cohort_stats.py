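import math

import numpy as np
import pandas as pd
import pytest

from octacnv.cohort_stats import (
    IMPROVED,
    NOT_IMPROVED,
    CohortError,
    EyeRecord,
    TwoByTwoTable,
    chi_square_2x2,
    classify_outcome,
    cohort_to_frame,
    compare_groups,
    ez_subgroup_change,
    linear_regression_change,
    logistic_from_table,
    mann_whitney,
    screen_and_fit_multivariable,
    univariable_logistic,
)
from octacnv.synthetic import CohortSpec, make_cohort, null_cohort_spec

from conftest import make_table_cohort


class TestClassifyOutcome:
    def test_gain_20_improved(self):
        assert classify_outcome(65, 85) == IMPROVED

    def test_boundary_gain_15_inclusive(self):
        assert classify_outcome(50, 65) == IMPROVED

    def test_loss_maintained(self):
        assert classify_outcome(70, 65) == NOT_IMPROVED

    def test_missing_rejected(self):
        with pytest.raises(CohortError):
            classify_outcome(None, 65)

    def test_out_of_range_rejected(self):
        with pytest.raises(CohortError, match="bcva_12m"):
            classify_outcome(50, 120)


class TestChiSquare:
    # printed two-group categorical p-values, frozen from the published table
    @pytest.mark.parametrize(
        "cells,expected_p",
        [
            ((10, 7, 4, 13), 0.037),   # ellipsoid zone integrity
            ((7, 10, 12, 5), 0.084),   # age >= 55
            ((11, 6, 6, 11), 0.086),   # ELM integrity
            ((11, 6, 8, 9), 0.300),    # dark halo
            ((6, 11, 4, 13), 0.452),   # morphology
            ((8, 9, 6, 11), 0.486),    # branching vessels
            ((2, 15, 3, 14), 0.628),   # subretinal fluid
            ((6, 11, 7, 10), 0.724),   # anastomotic loops
        ],
    )
    def test_published_p_values(self, cells, expected_p):
        _, p = chi_square_2x2(TwoByTwoTable(*cells))
        assert round(p, 3) == expected_p

    def test_identical_groups(self):
        chi2, p = chi_square_2x2(TwoByTwoTable(5, 5, 5, 5))
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_zero_margin_names_margin(self):
        with pytest.raises(CohortError, match="col2"):
            chi_square_2x2(TwoByTwoTable(5, 0, 5, 0))

    def test_group_relabel_invariance(self):
        _, p1 = chi_square_2x2(TwoByTwoTable(10, 7, 4, 13))
        _, p2 = chi_square_2x2(TwoByTwoTable(4, 13, 10, 7))
        assert p1 == pytest.approx(p2)


class TestMannWhitney:
    def test_exact_enumeration_separated(self):
        # oracle: all C(6,3)=20 labelings; U=0 in 1, U=9 in 1 -> p = 2/20
        u, p = mann_whitney([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_exact_oracle_small_sample(self, rng):
        # enumerate all labelings explicitly and compare
        from itertools import combinations

        x = [0.3, 2.7, 5.1, 1.9]
        y = [4.2, 0.8, 6.6]
        pooled = np.array(x + y)
        n1 = len(x)
        u_obs = sum(xi > yj for xi in x for yj in y)
        mu = n1 * len(y) / 2
        count = total = 0
        for idx in combinations(range(7), n1):
            xs = pooled[list(idx)]
            ys = pooled[[i for i in range(7) if i not in idx]]
            u = sum(xi > yj for xi in xs for yj in ys)
            total += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(count / total)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_permutation_oracle_17v17(self, rng):
        x = rng.normal(0.0, 1.0, 17)
        y = rng.normal(0.4, 1.2, 17)
        _, p = mann_whitney(x, y)
        pooled = np.concatenate([x, y])
        n1 = len(x)
        mu = n1 * len(y) / 2
        u_obs = (x[:, None] > y[None, :]).sum() + 0.5 * (x[:, None] == y[None, :]).sum()
        n_perm = 100_000
        order = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
        perm = pooled[order]
        xs, ys = perm[:, :n1], perm[:, n1:]
        u = (xs[:, :, None] > ys[:, None, :]).sum(axis=(1, 2))
        p_perm = np.mean(np.abs(u - mu) >= abs(u_obs - mu) - 1e-12)
        assert p == pytest.approx(p_perm, abs=0.02)

    def test_empty_sample_errors(self):
        with pytest.raises(CohortError):
            mann_whitney([], [1.0])


class TestCompareGroups:
    def test_published_ez_row(self):
        cohort = make_table_cohort(10, 7, 4, 13, "ez_grade", 0, 1)
        report = compare_groups(cohort)
        row = report["ez_grade"]
        assert row.test == "chi-square"
        assert round(row.p_value, 3) == 0.037

    def test_single_group_errors(self):
        records = [EyeRecord(eye_id="a", outcome=IMPROVED, age=50.0)] * 4
        with pytest.raises(CohortError):
            compare_groups(records)

    def test_constant_variable_flagged(self):
        records = []
        for i, grp in enumerate([IMPROVED] * 5 + [NOT_IMPROVED] * 5):
            records.append(EyeRecord(eye_id=str(i), outcome=grp, sfct=100.0, age=40.0 + i))
        report = compare_groups(records)
        assert report["sfct"].test == "none"
        assert report["sfct"].flag == "constant in both groups"
        assert report["age"].p_value is not None

    def test_record_order_invariance(self, rng):
        cohort = make_cohort(CohortSpec(seed=4))
        frame = cohort_to_frame(cohort)
        shuffled = frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
        r1 = compare_groups(frame)
        r2 = compare_groups(shuffled)
        for a, b in zip(r1.rows, r2.rows):
            assert a.variable == b.variable
            if a.p_value is None:
                assert b.p_value is None
            else:
                assert a.p_value == pytest.approx(b.p_value)

    def test_type_one_error_small_screen(self):
        # coarse calibration check; the full 2000-seed version is acceptance
        rejections = {"sfct": 0, "dark_halo": 0}
        n_seeds = 300
        for seed in range(n_seeds):
            frame = cohort_to_frame(make_cohort(null_cohort_spec(seed=seed)))
            report = compare_groups(frame)
            for var in rejections:
                if report[var].p_value is not None and report[var].p_value < 0.05:
                    rejections[var] += 1
        for var, k in rejections.items():
            assert 0.02 <= k / n_seeds <= 0.09, (var, k / n_seeds)

    def test_missing_values_logged_as_excluded(self):
        records = []
        for i in range(6):
            records.append(EyeRecord(eye_id=str(i), outcome=IMPROVED, sfct=80.0 + i))
        for i in range(6):
            records.append(EyeRecord(eye_id=str(6 + i), outcome=NOT_IMPROVED,
                                     sfct=None if i == 0 else 50.0 + i))
        report = compare_groups(records)
        assert report["sfct"].n_excluded == 1


def loglik_grid_oracle(a, b, c, d):
    """Coarse-to-fine grid search of the 2-parameter logistic likelihood."""
    y = np.repeat([1.0, 1.0, 0.0, 0.0], [a, b, c, d])
    x = np.repeat([1.0, 0.0, 1.0, 0.0], [a, b, c, d])

    def ll(b0, b1):
        eta = b0 + b1 * x
        return float((y * eta - np.logaddexp(0.0, eta)).sum())

    center = np.array([0.0, 0.0])
    width = 8.0
    for _ in range(12):
        g0 = np.linspace(center[0] - width, center[0] + width, 21)
        g1 = np.linspace(center[1] - width, center[1] + width, 21)
        vals = [[ll(b0, b1) for b1 in g1] for b0 in g0]
        i, j = np.unravel_index(np.argmax(vals), (21, 21))
        center = np.array([g0[i], g1[j]])
        width /= 4.0
    return center  # (intercept, slope)


class TestUnivariableLogistic:
    def test_published_ez_row(self):
        cohort = make_table_cohort(10, 7, 4, 13, "ez_grade", 0, 1)
        res = univariable_logistic(cohort, "ez_grade")
        assert res.odds_ratio == pytest.approx(4.643, abs=5e-4)
        assert res.ci_low == pytest.approx(1.057, abs=5e-4)
        assert res.ci_high == pytest.approx(20.385, abs=5e-4)
        assert "grade 0" in res.predictor_coding

    def test_symmetric_table_or_one(self):
        res = logistic_from_table(TwoByTwoTable(5, 5, 5, 5))
        assert res.odds_ratio == pytest.approx(1.0)

    def test_mle_equals_cross_product_and_grid_oracle(self, rng):
        for _ in range(5):
            a, b, c, d = rng.integers(1, 20, 4)
            res = logistic_from_table(TwoByTwoTable(int(a), int(b), int(c), int(d)))
            assert res.odds_ratio == pytest.approx(a * d / (b * c), rel=1e-4)
            _, slope = loglik_grid_oracle(a, b, c, d)
            assert res.coef == pytest.approx(slope, abs=1e-3)

    def test_wald_se_closed_form(self):
        res = logistic_from_table(TwoByTwoTable(10, 7, 4, 13))
        assert res.se == pytest.approx(math.sqrt(1 / 10 + 1 / 7 + 1 / 4 + 1 / 13), rel=1e-5)

    def test_separation_flagged_without_ci(self):
        res = logistic_from_table(TwoByTwoTable(5, 0, 3, 4))
        assert res.separation
        assert res.ci_low is None and res.ci_high is None

    def test_group_relabel_inverts_or(self):
        r1 = logistic_from_table(TwoByTwoTable(10, 7, 4, 13))
        r2 = logistic_from_table(TwoByTwoTable(4, 13, 10, 7))
        assert r1.odds_ratio == pytest.approx(1.0 / r2.odds_ratio, rel=1e-6)

    def test_constant_predictor_errors(self):
        cohort = make_table_cohort(5, 0, 5, 0, "ez_grade", 0, 0)
        with pytest.raises(CohortError, match="constant"):
            univariable_logistic(cohort, "ez_grade")


class TestScreening:
    def _effect_cohort(self, seed):
        """Only dark_halo carries a true effect; everything else is null."""
        spec = null_cohort_spec(seed=seed)
        strong = {**spec.improved.proportions, "dark_halo": 0.9}
        weak = {**spec.not_improved.proportions, "dark_halo": 0.15}
        from octacnv.synthetic import GroupParams

        improved = GroupParams(dict(spec.improved.continuous), strong)
        not_improved = GroupParams(dict(spec.not_improved.continuous), weak)
        return CohortSpec(
            n_per_group=(25, 25), improved=improved, not_improved=not_improved,
            seed=seed, enforce_outcome_consistency=False,
        )

    def test_single_true_effect_selected(self):
        hits = 0
        for seed in range(5):
            frame = cohort_to_frame(make_cohort(self._effect_cohort(seed)))
            uni, multi = screen_and_fit_multivariable(
                frame, ["dark_halo", "branching", "loops"], entry_alpha=0.1
            )
            selected = {r.variable for r in multi}
            if "dark_halo" in selected:
                hits += 1
                uni_or = next(r for r in uni if r.variable == "dark_halo").odds_ratio
                multi_or = next(r for r in multi if r.variable == "dark_halo").odds_ratio
                assert multi_or == pytest.approx(uni_or, rel=0.5)
        assert hits >= 4

    def test_alpha_one_admits_all(self):
        frame = cohort_to_frame(make_cohort(CohortSpec(seed=3)))
        variables = ["sfct", "cft", "dark_halo"]
        uni, multi = screen_and_fit_multivariable(frame, variables, entry_alpha=1.0)
        assert {r.variable for r in multi} == {
            r.variable for r in uni if not r.separation
        }

    def test_threshold_monotone(self):
        frame = cohort_to_frame(make_cohort(CohortSpec(seed=8)))
        variables = ["sfct", "cft", "age_lt_55", "dark_halo", "fractal_dimension"]
        _, multi_small = screen_and_fit_multivariable(frame, variables, entry_alpha=0.1)
        _, multi_big = screen_and_fit_multivariable(frame, variables, entry_alpha=0.5)
        assert {r.variable for r in multi_small} <= {r.variable for r in multi_big}

    def test_none_selected_returns_empty(self):
        frame = cohort_to_frame(make_cohort(null_cohort_spec(seed=1)))
        uni, multi = screen_and_fit_multivariable(frame, ["loops"], entry_alpha=1e-9)
        assert multi == []
        assert len(uni) == 1


class TestLinearRegression:
    def test_collinear_points(self):
        records = [
            EyeRecord(eye_id=str(i), outcome=IMPROVED, sfct=50.0 + 10 * i,
                      bcva_baseline=50.0, bcva_12m=50.0 + 2.0 * i)
            for i in range(6)
        ]
        slope, r, p = linear_regression_change(records)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(0.2)
        assert p < 1e-6

    def test_null_p_uniform(self, rng):
        # under independence the p-value is U(0,1): Kolmogorov-Smirnov check
        from scipy import stats

        ps = []
        for _ in range(400):
            x = np.clip(rng.normal(60, 20, 30), 5.0, None)
            base = rng.uniform(20, 60, 30)
            delta = rng.normal(0, 10, 30)
            records = [
                EyeRecord(eye_id=str(i), outcome=IMPROVED, sfct=float(x[i]),
                          bcva_baseline=float(base[i]),
                          bcva_12m=float(np.clip(base[i] + delta[i], 0, 100)))
                for i in range(30)
            ]
            ps.append(linear_regression_change(records)[2])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_parameter_recovery(self, rng):
        # true correlation 0.5 at n=34: recovered r within its sampling CI
        rs = []
        for seed in range(40):
            g = np.random.default_rng(seed)
            x = g.normal(0, 1, 34)
            ydelta = 0.5 * x + math.sqrt(1 - 0.25) * g.normal(0, 1, 34)
            base = np.full(34, 50.0)
            records = [
                EyeRecord(eye_id=str(i), outcome=IMPROVED,
                          sfct=float(max(5.0, x[i] * 30 + 65)),
                          bcva_baseline=50.0,
                          bcva_12m=float(np.clip(50 + ydelta[i] * 10, 0, 100)))
                for i in range(34)
            ]
            rs.append(linear_regression_change(records)[1])
        assert np.mean(rs) == pytest.approx(0.5, abs=0.1)

    def test_constant_x_errors(self):
        records = [
            EyeRecord(eye_id=str(i), outcome=IMPROVED, sfct=50.0,
                      bcva_baseline=40.0, bcva_12m=60.0)
            for i in range(5)
        ]
        with pytest.raises(CohortError, match="constant"):
            linear_regression_change(records)


class TestEzSubgroup:
    def _records(self, delta0, delta1):
        records = []
        for i, d in enumerate(delta0):
            records.append(EyeRecord(eye_id=f"a{i}", outcome=IMPROVED, ez_grade=0,
                                     bcva_baseline=50.0,
                                     bcva_12m=float(np.clip(50 + d, 0, 100))))
        for i, d in enumerate(delta1):
            records.append(EyeRecord(eye_id=f"b{i}", outcome=NOT_IMPROVED, ez_grade=1,
                                     bcva_baseline=50.0,
                                     bcva_12m=float(np.clip(50 + d, 0, 100))))
        return records

    def test_identical_distributions_p_near_one(self):
        d = list(range(10))
        groups, p = ez_subgroup_change(self._records(d, d))
        assert p > 0.9

    def test_power_with_shift(self):
        # +10-letter shift at n=14 vs 20: power above one half
        rejections = 0
        for seed in range(30):
            g = np.random.default_rng(seed)
            d0 = g.normal(12, 10, 14)
            d1 = g.normal(2, 10, 20)
            _, p = ez_subgroup_change(self._records(d0, d1))
            rejections += p < 0.05
        assert rejections / 30 > 0.5

    def test_one_grade_absent_errors(self):
        with pytest.raises(CohortError, match="grade 1"):
            ez_subgroup_change(self._records([1.0, 2.0], [])[:2])


class TestRoundTripFrame:
    def test_cohort_to_frame_outcome_derived(self):
        rec = EyeRecord(eye_id="x", bcva_baseline=50.0, bcva_12m=70.0)
        frame = cohort_to_frame([rec])
        assert frame.loc[0, "outcome"] == IMPROVED

    def test_invalid_grade_rejected(self):
        with pytest.raises(CohortError):
            EyeRecord(eye_id="x", ez_grade=2)

    def test_age_indicator_autofilled(self):
        assert EyeRecord(eye_id="x", age=60.0).age_ge_55 is True
        assert EyeRecord(eye_id="y", age=40.0).age_ge_55 is False
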