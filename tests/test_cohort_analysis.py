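import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ntatlas.cohort_analysis import (
    Cutoffs,
    PatientRecord,
    ae_summary,
    analyze_cohort,
    binarize_qol,
    classify_by_cutoffs,
    cohort_from_dataframe,
    cohort_to_dataframe,
    fisher_exact_2x2,
    kruskal_wallis,
    linear_r2,
    roc_youden,
    youden_index,
)

from util import fisher_oracle, kruskal_oracle, mann_whitney_auc


def _rec(qol="better", **kw):
    defaults = dict(id="p1", qol=qol)
    defaults.update(kw)
    return PatientRecord(**defaults)


class TestBinarizeQol:
    @pytest.mark.parametrize("qol,expected", [
        ("better", "better_same"), ("same", "better_same"), ("worse", "worse"),
    ])
    def test_mapping(self, qol, expected):
        assert binarize_qol(_rec(qol=qol)) == expected

    def test_invalid_qol_rejected_at_construction(self):
        with pytest.raises(ValueError):
            _rec(qol="unknown")


class TestYoudenIndex:
    @pytest.mark.parametrize("sens,spec,expected", [
        (0.745, 0.889, 0.634),  # accumulated-dose-volume operating point
        (0.549, 0.889, 0.438),  # NTC operating point
        (1.0, 1.0, 1.0),
    ])
    def test_published_operating_points(self, sens, spec, expected):
        assert youden_index(sens, spec) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            youden_index(1.2, 0.5)
        with pytest.raises(ValueError):
            youden_index(0.5, -0.1)


class TestRocYouden:
    def test_perfect_separation(self):
        values = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        labels = np.array([0, 0, 0, 1, 1, 1])
        roc = roc_youden(values, labels, "high_is_positive")
        assert roc.auc == pytest.approx(1.0)
        assert roc.youden_j == pytest.approx(1.0)
        assert roc.sensitivity == 1.0 and roc.specificity == 1.0
        assert 3 < roc.optimal_cutoff < 10  # midpoint between straddling values

    def test_independent_labels_auc_near_half(self):
        rng = np.random.default_rng(0)
        n = 2000
        values = rng.normal(size=n)
        labels = rng.integers(0, 2, size=n)
        roc = roc_youden(values, labels, "high_is_positive")
        n1, n0 = labels.sum(), n - labels.sum()
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(roc.auc - 0.5) <= 3 * se

    @pytest.mark.parametrize("direction", ["low_is_positive", "high_is_positive"])
    def test_trapezoid_equals_mann_whitney(self, direction):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = rng.integers(8, 60)
            values = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=rng.integers(2, n - 1), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            roc = roc_youden(values, labels, direction)
            assert roc.auc == pytest.approx(
                mann_whitney_auc(values, labels, direction), abs=1e-12
            )

    def test_matches_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        values = rng.normal(size=200)
        labels = (rng.random(200) < 0.4).astype(int)
        roc = roc_youden(values, labels, "high_is_positive")
        assert roc.auc == pytest.approx(roc_auc_score(labels, values), abs=1e-12)

    def test_monotone_transform_invariance_and_direction_flip(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(1, 10, 100)
        labels = (rng.random(100) < 0.5).astype(int)
        if labels.sum() in (0, 100):
            labels[0] = 1 - labels[0]
        base = roc_youden(values, labels, "high_is_positive")
        logged = roc_youden(np.log(values), labels, "high_is_positive")
        assert logged.auc == pytest.approx(base.auc, abs=1e-12)
        flipped = roc_youden(values, labels, "low_is_positive")
        assert flipped.auc == pytest.approx(1.0 - base.auc, abs=1e-12)
        assert -1.0 <= base.youden_j <= 1.0

    def test_clean_threshold_cutoff_between_straddling_observations(self):
        rng = np.random.default_rng(4)
        values = np.concatenate([rng.uniform(0, 95, 120), rng.uniform(105, 200, 80)])
        labels = (values < 100).astype(int)  # low values are the positive class
        roc = roc_youden(values, labels, "low_is_positive")
        below = values[values < 100].max()
        above = values[values > 100].min()
        assert below <= roc.optimal_cutoff <= above
        assert roc.cutoff_label.startswith("<")

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_youden(np.array([1.0, 2.0]), np.array([1, 1]), "high_is_positive")


class TestKruskalWallis:
    def test_matches_rank_sum_oracle(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(kruskal_oracle(groups), abs=1e-10)
        assert res.dof == 2

    def test_ties_match_oracle(self):
        rng = np.random.default_rng(5)
        groups = [list(rng.integers(0, 5, size=n)) for n in (8, 12, 6)]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(kruskal_oracle(groups), abs=1e-10)

    def test_identical_groups_h_zero(self):
        res = kruskal_wallis([[2.0, 2.0, 2.0], [2.0, 2.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        groups = [list(rng.uniform(1, 10, n)) for n in (7, 9, 5)]
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis([[np.exp(v) for v in g] for g in groups]).statistic
        assert h1 == pytest.approx(h2, abs=1e-10)

    def test_mean_padding_variant(self):
        groups = [[80.0, 90.0, 95.0, 100.0], [40.0, 50.0, 45.0, 55.0, 60.0]]
        padded = kruskal_wallis(groups, pad_to_min_n=5)
        # oracle: first group gains one copy of its mean (91.25)
        manual = kruskal_oracle([[80.0, 90.0, 95.0, 100.0, 91.25],
                                 [40.0, 50.0, 45.0, 55.0, 60.0]])
        assert padded.statistic == pytest.approx(manual, abs=1e-10)
        assert padded.group_sizes == (4, 5)  # sizes report the raw data

    def test_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestFisherExact:
    def test_diagonal_identity_table(self):
        assert fisher_exact_2x2([[1, 0], [0, 1]]) == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        table = [[10, 0], [0, 10]]
        assert fisher_exact_2x2(table) == pytest.approx(fisher_oracle(table), abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=10), min_size=4, max_size=4))
    def test_matches_enumeration_for_small_tables(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0 or a + b + c + d > 30:
            return
        table = [[a, b], [c, d]]
        assert fisher_exact_2x2(table) == pytest.approx(fisher_oracle(table), abs=1e-9)

    def test_symmetry_under_transpose_and_swap(self):
        table = np.array([[7, 2], [3, 6]])
        p = fisher_exact_2x2(table)
        assert fisher_exact_2x2(table.T) == pytest.approx(p)
        assert fisher_exact_2x2(table[::-1]) == pytest.approx(p)

    def test_published_ae_association(self):
        # 7/9 worse vs 6/37 better patients with persistent AEs
        p = fisher_exact_2x2([[7, 2], [6, 31]])
        assert p == pytest.approx(fisher_oracle([[7, 2], [6, 31]]), abs=1e-12)
        assert p < 0.01

    def test_invalid_tables(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [0, 0]])


class TestLinearR2:
    def test_exact_line(self):
        x = np.arange(10, dtype=float)
        slope, intercept, r2 = linear_r2(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        _, _, r2 = linear_r2(x, y)
        assert r2 < 0.01

    def test_matches_algebraic_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 300, 50)
        y = 0.02 * x + rng.normal(0, 2, 50)
        slope, intercept, r2 = linear_r2(x, y)
        # brute-force normal equations + residual decomposition
        X = np.c_[np.ones_like(x), x]
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        expected_r2 = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        assert slope == pytest.approx(beta[1])
        assert intercept == pytest.approx(beta[0])
        assert r2 == pytest.approx(expected_r2, abs=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestClassifyByCutoffs:
    def test_all_favorable(self):
        res = classify_by_cutoffs(_rec(lesion_volume_mm3=100.0, adv_cc=0.05, ntc=0.6))
        assert res["all_favorable"]
        assert res["flags"] == {"lesion_volume_mm3": True, "adv_cc": True, "ntc": True}

    @pytest.mark.parametrize("kw,variable", [
        (dict(lesion_volume_mm3=127.4), "lesion_volume_mm3"),
        (dict(adv_cc=0.0594), "adv_cc"),
        (dict(ntc=0.544), "ntc"),
    ])
    def test_boundary_values_unfavorable(self, kw, variable):
        res = classify_by_cutoffs(_rec(**kw))
        assert res["flags"][variable] is False

    def test_missing_variables_none_and_all_missing_raises(self):
        res = classify_by_cutoffs(_rec(ntc=0.7))
        assert res["flags"]["lesion_volume_mm3"] is None
        assert res["n_present"] == 1
        with pytest.raises(ValueError):
            classify_by_cutoffs(_rec())


class TestAeSummary:
    def test_published_dysarthria_fraction(self):
        cohort = (
            [_rec(id=f"w{i}", qol="worse", ae_flags={"dysarthria"}) for i in range(3)]
            + [_rec(id="b1", qol="better", ae_flags={"dysarthria"})]
            + [_rec(id=f"x{i}", qol="better") for i in range(4)]
        )
        df = ae_summary(cohort)
        row = df[df.ae == "dysarthria"].iloc[0]
        assert row.n == 4
        assert row.worse_fraction == pytest.approx(0.75)

    def test_unexperienced_ae_excluded_and_ranked(self):
        cohort = [
            _rec(id="a", qol="worse", ae_flags={"gait_ataxia"}),
            _rec(id="b", qol="better", ae_flags={"gait_ataxia", "fatigue"}),
            _rec(id="c", qol="better"),
        ]
        df = ae_summary(cohort)
        assert "dysarthria" not in set(df.ae)
        assert list(df.worse_fraction) == sorted(df.worse_fraction, reverse=True)

    def test_fractions_match_brute_force_tally(self):
        rng = np.random.default_rng(9)
        from ntatlas.cohort_analysis import AE_FLAGS

        cohort = []
        for i in range(50):
            qol = ("better", "same", "worse")[rng.integers(0, 3)]
            flags = {f for f in AE_FLAGS if rng.random() < 0.15}
            cohort.append(_rec(id=f"p{i}", qol=qol, ae_flags=flags))
        df = ae_summary(cohort)
        for _, row in df.iterrows():
            members = [r for r in cohort if row.ae in r.ae_flags]
            assert row.n == len(members)
            worse = sum(1 for r in members if r.qol == "worse")
            assert row.worse_fraction == pytest.approx(worse / len(members))


class TestCohortRoundTripAndReport:
    def test_csv_round_trip_preserves_all_fields(self, tmp_path):
        cohort = [
            _rec(id="p1", qol="worse", lesion_volume_mm3=150.25, adv_cc=0.071,
                 ntc=0.432, sdr=0.61, crst_a_pre=3.0, crst_a_post=1.5,
                 crst_b_pre=6.0, crst_b_post=2.0, crst_c_pre=4.0, crst_c_post=1.0,
                 subjective_suppression_pct=88.5,
                 ae_flags={"dysarthria", "gait_ataxia"}, persistent_ae=True,
                 followup_days=400.0),
            _rec(id="p2", qol="same"),
        ]
        path = tmp_path / "cohort.csv"
        cohort_to_dataframe(cohort).to_csv(path, index=False)
        back = cohort_from_dataframe(pd.read_csv(path))
        assert back == cohort

    def test_analyze_cohort_report_structure(self, paper_like_cohort):
        report = analyze_cohort(paper_like_cohort.records)
        assert report["n_patients"] == 60
        assert set(report["roc"]) == {"lesion_volume_mm3", "adv_cc", "ntc"}
        lesion = report["roc"]["lesion_volume_mm3"]
        assert lesion["cutoff_label"].startswith("<")
        assert report["roc"]["ntc"]["cutoff_label"].startswith(">")
        assert 0 <= report["persistent_ae_vs_qol"]["p_value"] <= 1
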