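"""Outcome statistics: dichotomization, t tests, logistic fits, report tables."""

import numpy as np
import pandas as pd
import pytest

from perifocal.stats import (
    cohort_report,
    dichotomize,
    independent_t,
    logistic_single,
    paired_t,
)


class TestDichotomize:
    @pytest.mark.parametrize("cls,expected", [
        ("I", "satisfactory"), ("IA", "satisfactory"), ("IB", "satisfactory"),
        ("II", "unsatisfactory"), ("III", "unsatisfactory"), ("IV", "unsatisfactory"),
    ])
    def test_mapping(self, cls, expected):
        assert dichotomize(cls) == expected

    def test_reference_split(self):
        from perifocal.reference import engel_outcome_counts

        counts = engel_outcome_counts()
        split = {"satisfactory": 0, "unsatisfactory": 0}
        for cls, n in counts.items():
            split[dichotomize(cls)] += n
        assert split == {"satisfactory": 25, "unsatisfactory": 7}

    def test_unknown_rejected(self):
        with pytest.raises(ValueError):
            dichotomize("V")


class TestPairedT:
    def test_identical_vectors_rejected_as_zero_variance(self):
        with pytest.raises(ValueError):
            paired_t(np.ones(5), np.ones(5))

    def test_closed_form_three_differences(self):
        # differences (1, 2, 3): mean 2, sd 1, t = 2*sqrt(3), df 2
        r = paired_t(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert r.estimate == pytest.approx(2.0, abs=1e-10)
        assert r.p_value == pytest.approx(0.07417990022744855, abs=1e-10)
        assert r.ci_low == pytest.approx(-0.48413771175033027, abs=1e-10)
        assert r.ci_high == pytest.approx(4.48413771175033, abs=1e-10)

    def test_estimate_within_ci(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(5, 1, 20), rng.normal(4, 1, 20)
        r = paired_t(x, y)
        assert r.ci_low <= r.estimate <= r.ci_high


class TestIndependentT:
    def test_closed_form_three_per_group(self):
        # (1,2,3) vs (2,3,4): diff -1, pooled sd 1, t = -sqrt(3/2), df 4
        r = independent_t(np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0]))
        assert r.estimate == pytest.approx(-1.0, abs=1e-12)
        assert r.p_value == pytest.approx(0.28786413472669053, abs=1e-10)
        assert r.n == (3, 3)

    def test_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0])
        r = independent_t(g, g)
        assert r.estimate == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_type_i_error_rate_under_null(self):
        rng = np.random.default_rng(77)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            r = independent_t(rng.normal(0, 1, 16), rng.normal(0, 1, 16))
            rejections += r.p_value < 0.05
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 2 * se

    def test_welch_differs_under_heteroscedasticity(self):
        rng = np.random.default_rng(1)
        g1, g2 = rng.normal(0, 1, 10), rng.normal(0, 5, 40)
        assert independent_t(g1, g2).p_value != independent_t(g1, g2, welch=True).p_value


def _brute_concordance(y, x):
    pos = x[y == 1]
    neg = x[y == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            wins += p > q
            ties += p == q
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestLogisticSingle:
    def test_constant_predictor_or_one(self):
        y = np.array([1, 0, 1, 0, 1])
        r = logistic_single(y, np.full(5, 3.0))
        assert r.estimate == 1.0
        assert r.c_statistic == 0.5

    def test_perfect_separation_reported_not_raised(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        x = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        r = logistic_single(y, x)
        assert not r.converged
        assert r.c_statistic == 1.0

    def test_c_statistic_equals_rank_concordance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 50)
        y = (rng.random(50) < 1 / (1 + np.exp(-x))).astype(float)
        r = logistic_single(y, x)
        assert r.converged
        assert r.c_statistic == pytest.approx(_brute_concordance(y, x), abs=1e-12)

    def test_or_invariance_under_rescaling(self):
        rng = np.random.default_rng(4)
        x = rng.normal(20000, 5000, 200)
        y = (rng.random(200) < 1 / (1 + np.exp(-0.0002 * (x - 20000)))).astype(float)
        r1 = logistic_single(y, x)
        rk = logistic_single(y, x / 1000.0)
        # slope scales by k, C-statistic unchanged
        assert np.log(rk.estimate) == pytest.approx(1000 * np.log(r1.estimate), rel=1e-4)
        assert rk.c_statistic == pytest.approx(r1.c_statistic, abs=1e-12)

    def test_wald_ci_coverage_for_volume_scale_slope(self):
        # slope 0.001 per mm^3 at n = 500; CI coverage over 200 replicates
        rng = np.random.default_rng(5)
        beta = 0.001
        covered = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.normal(20000, 2000, 500)
            p = 1 / (1 + np.exp(-beta * (x - 20000)))
            y = (rng.random(500) < p).astype(float)
            r = logistic_single(y, x)
            if r.converged and r.ci_low <= np.exp(beta) <= r.ci_high:
                covered += 1
        assert covered / n_rep >= 0.93

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            logistic_single(np.ones(10), np.arange(10.0))


def _toy_cohort():
    """Four-subject cohort with hand-set volumes (two per outcome group)."""
    rows = []
    vols = [
        # (engel, fdg_ahph_pre, fdg_ahph_res, fmz_ahph_pre, fmz_ahph_res)
        ("I", 3000.0, 700.0, 3100.0, 400.0),
        ("I", 3400.0, 900.0, 2900.0, 500.0),
        ("II", 2800.0, 500.0, 2600.0, 450.0),
        ("IV", 3200.0, 600.0, 2800.0, 350.0),
    ]
    for i, (engel, fp, fr, zp, zr) in enumerate(vols):
        row = {"subject_id": f"T{i}", "engel_class": engel, "side": "left"}
        for voi in ("ahph", "tl"):
            scale = 1.0 if voi == "ahph" else 8.0
            row[f"fdg_{voi}_pre_mm3"] = fp * scale
            row[f"fdg_{voi}_resected_mm3"] = fr * scale
            row[f"fdg_{voi}_nonres_pct"] = 100 * (1 - fr / fp)
            row[f"fmz_{voi}_pre_mm3"] = zp * scale
            row[f"fmz_{voi}_resected_mm3"] = zr * scale
            row[f"fmz_{voi}_nonres_pct"] = 100 * (1 - zr / zp)
            row[f"mri_{voi}_resected_mm3"] = (fr + zr) * scale
            row[f"mri_{voi}_resected_pct"] = 20.0 + i
        rows.append(row)
    return pd.DataFrame(rows)


class TestCohortReport:
    def test_hand_audited_cells(self):
        report = cohort_report(_toy_cohort())
        row = report.pre_post[
            (report.pre_post.voi == "ahph") & (report.pre_post.tracer == "FDG")
            & (report.pre_post.outcome == "satisfactory")
        ].iloc[0]
        assert row.pre_mean_mm3 == 3200.0
        assert row.resected_mean_mm3 == 800.0
        assert row.post_mean_mm3 == 2400.0
        sub = report.subgroup[
            (report.subgroup.voi == "ahph")
            & (report.subgroup.variable == "FDG pre-surgical volume")
        ].iloc[0]
        assert sub.satisfactory_mean == 3200.0
        assert sub.unsatisfactory_mean == 3000.0
        assert sub.difference_mean == 200.0
        # hand-derived pooled t for (3000, 3400) vs (2800, 3200)
        r = independent_t(np.array([3000.0, 3400.0]), np.array([2800.0, 3200.0]))
        assert sub.p_value == pytest.approx(r.p_value)

    def test_additivity_in_every_row(self):
        report = cohort_report(_toy_cohort())
        for _, row in report.pre_post.iterrows():
            assert row.post_mean_mm3 == pytest.approx(
                row.pre_mean_mm3 - row.resected_mean_mm3
            )

    def test_single_class_cohort_rejected(self):
        df = _toy_cohort()
        df["engel_class"] = "I"
        with pytest.raises(ValueError):
            cohort_report(df)

    def test_logistic_rows_present_for_all_variables(self):
        report = cohort_report(_toy_cohort())
        assert len(report.logistic) == 16
        assert report.logistic.c_statistic.between(0, 1).all()
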