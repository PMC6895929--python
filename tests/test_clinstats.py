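"""Clinical statistics: group tests, ROC, survival, EMT."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mirseq import clinstats as cs
from mirseq import simdata


def _cohort(**kw):
    spec = simdata.CohortSimSpec(**kw)
    return simdata.simulate_cohort(spec).set_index("patient_id")


class TestFilterCohort:
    def test_low_coverage_mirna_removed(self):
        df = _cohort(rng_seed=0, n_patients=30)
        df["mir-low"] = 1.0                     # max coverage 1 < 2
        out, removed = cs.filter_cohort(df)
        assert "mir-low" not in out.columns
        assert removed["mirnas_removed"] >= 1

    def test_truncating_patients_dropped(self):
        df = _cohort(rng_seed=1, n_patients=100, mutant_fraction=0.5,
                     truncating_fraction=0.4)
        out, removed = cs.filter_cohort(df)
        assert (out["p53_status"] != "truncating").all()
        assert removed["patients_removed"] > 0

    def test_unknown_node_status_excluded_from_node_analysis(self):
        df = _cohort(rng_seed=2, n_patients=230, node_unknown_rate=0.03)
        node = df[df["node_status"].isin(["N+", "N0"])]
        n_unknown = (df["node_status"] == "unknown").sum()
        assert len(node) == len(df) - n_unknown
        assert n_unknown > 0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            cs.filter_cohort(pd.DataFrame())


class TestOutliers:
    def test_gross_outlier_flagged(self):
        rng = np.random.default_rng(3)
        E = pd.DataFrame(rng.normal(0, 1, (20, 5)))
        E.iloc[4] += 50
        retained, flagged = cs.cluster_outliers(E)
        assert flagged == [4]
        assert 4 not in retained

    def test_homogeneous_cohort_rarely_flags(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            E = pd.DataFrame(rng.normal(0, 1, (30, 8)))
            _, flagged = cs.cluster_outliers(E)
            if not flagged:
                hits += 1
        assert hits >= 45

    def test_complete_linkage_heights_monotone(self):
        from scipy.cluster.hierarchy import linkage
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 6))
        Z = linkage(X, method="complete")
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            cs.cluster_outliers(pd.DataFrame(np.zeros((2, 3))))


class TestModeratedT:
    def test_identical_groups_give_zero_t_unit_p(self):
        X = pd.DataFrame({"m": [5.0, 6.0, 5.0, 6.0]})
        g = pd.Series(["A", "A", "B", "B"], index=X.index)
        # same values in both groups
        X.loc[:, "m"] = [5.0, 6.0, 5.0, 6.0]
        res = cs.moderated_t(X, g, log_transform=False)
        assert res.table["t"].iloc[0] == pytest.approx(0.0)
        assert res.table["pval"].iloc[0] == pytest.approx(1.0)

    def test_zero_prior_df_recovers_ordinary_t(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(5, 1, (20, 40)))
        g = pd.Series(["A"] * 10 + ["B"] * 10, index=X.index)
        res = cs.moderated_t(X, g, log_transform=False,
                             prior_df_override=0.0)
        for k in range(5):
            a, b = X.iloc[:10, k], X.iloc[10:, k]
            t, p = sps.ttest_ind(b, a)
            assert res.table["t"].iloc[k] == pytest.approx(t, abs=1e-10)
            assert res.table["pval"].iloc[k] == pytest.approx(p, abs=1e-10)

    def test_infinite_prior_uses_prior_variance_exactly(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(5, 1, (20, 30)))
        g = pd.Series(["A"] * 10 + ["B"] * 10, index=X.index)
        res = cs.moderated_t(X, g, log_transform=False,
                             prior_df_override=np.inf)
        assert np.allclose(res.table["posterior_var"], res.prior_var)

    def test_posterior_variance_between_prior_and_sample(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(5, 1, (16, 100)))
        g = pd.Series(["A"] * 8 + ["B"] * 8, index=X.index)
        res = cs.moderated_t(X, g, log_transform=False)
        lo = np.minimum(res.table["sample_var"], res.prior_var)
        hi = np.maximum(res.table["sample_var"], res.prior_var)
        assert ((res.table["posterior_var"] >= lo - 1e-12)
                & (res.table["posterior_var"] <= hi + 1e-12)).all()

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(2.0 ** rng.normal(6, 1, (20, 800)))
        g = pd.Series(["A"] * 10 + ["B"] * 10, index=X.index)
        res = cs.moderated_t(X, g)
        assert sps.kstest(res.table["pval"], "uniform").pvalue > 0.01

    def test_single_group_rejected(self):
        X = pd.DataFrame(np.ones((4, 3)))
        g = pd.Series(["A"] * 4, index=X.index)
        with pytest.raises(ValueError):
            cs.moderated_t(X, g)


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        u, p = cs.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)     # 2/C(6,3) enumerated

    def test_identical_groups_unit_p(self):
        _, p = cs.mann_whitney([2, 2, 2], [2, 2, 2])
        assert p == 1.0

    def test_large_sample_type_one_error(self):
        rng = np.random.default_rng(9)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            a = rng.normal(size=25)
            b = rng.normal(size=25)
            _, p = cs.mann_whitney(a, b)
            if p < 0.05:
                rejections += 1
        assert abs(rejections / n_sim - 0.05) <= 0.02


class TestROC:
    def test_perfect_separation_auc_one(self):
        r = cs.roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        r = cs.roc_auc(scores, labels)
        assert abs(r.auc - 0.5) < 0.1

    def test_auc_equals_pair_enumeration_small_cases(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            scores = rng.integers(0, 5, n).astype(float)   # force ties
            labels = np.zeros(n, int)
            labels[rng.choice(n, max(1, n // 2), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            r = cs.roc_auc(scores, labels)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            conc = sum((p > q) + 0.5 * (p == q)
                       for p, q in itertools.product(pos, neg))
            assert r.auc == pytest.approx(conc / (len(pos) * len(neg)))

    def test_auc_u_statistic_identity(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            pos = rng.normal(1, 1, 8)
            neg = rng.normal(0, 1, 7)
            scores = np.concatenate([pos, neg])
            labels = np.array([1] * 8 + [0] * 7)
            r = cs.roc_auc(scores, labels)
            u = sps.mannwhitneyu(pos, neg,
                                 alternative="two-sided").statistic
            assert r.auc * 8 * 7 == pytest.approx(u)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            cs.roc_auc([1, 2, 3], [1, 1, 1])


class TestPercentileGroups:
    def test_quarter_split_sizes(self):
        v = pd.Series(np.arange(1, 101, dtype=float))
        hi, lo = cs.percentile_groups(v)
        assert 25 <= len(hi) <= 26
        assert 25 <= len(lo) <= 26
        assert len(hi) + len(lo) <= 100

    def test_four_distinct_values(self):
        v = pd.Series([1.0, 2.0, 3.0, 4.0])
        hi, lo = cs.percentile_groups(v)
        assert list(v[hi]) == [4.0] or 3.25 <= min(v[hi])
        assert 1.0 in set(v[lo])

    def test_ties_at_quantile_inclusive(self):
        v = pd.Series([1.0, 1.0, 2.0, 3.0, 3.0, 3.0, 3.0, 4.0])
        hi, lo = cs.percentile_groups(v)
        assert (v[hi] >= v.quantile(0.75)).all()
        # every tied value at the boundary is included
        q75 = v.quantile(0.75)
        assert set(v.index[v == q75]) <= set(hi) or q75 not in set(v)

    def test_degenerate_all_equal_rejected(self):
        with pytest.raises(ValueError):
            cs.percentile_groups(pd.Series([2.0, 2.0, 2.0, 2.0]))


class TestKaplanMeier:
    def test_no_censoring_matches_empirical_survival(self):
        f = cs.kaplan_meier([1, 2, 3, 4], [1, 1, 1, 1])
        assert np.allclose(f.survival, [0.75, 0.5, 0.25, 0.0])
        assert f.median == 2.0

    def test_all_censored_curve_stays_at_one(self):
        f = cs.kaplan_meier([5, 8, 2], [0, 0, 0])
        assert len(f.times) == 0
        assert np.isnan(f.median)
        assert f.at(100) == 1.0

    def test_late_censoring_adds_no_drop_and_tail_stays_flat(self):
        f1 = cs.kaplan_meier([1, 2, 3], [1, 1, 1])
        f2 = cs.kaplan_meier([1, 2, 3, 9], [1, 1, 1, 0])
        assert np.allclose(f1.times, f2.times)   # no new drop times
        assert f2.at(100) == f2.survival[-1]     # flat after last event

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            cs.kaplan_meier([-1, 2], [1, 1])

    def test_agrees_with_lifelines(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(13)
        t = rng.exponential(10, 60)
        e = rng.integers(0, 2, 60)
        if e.sum() == 0:
            e[0] = 1
        ours = cs.kaplan_meier(t, e)
        km = KaplanMeierFitter().fit(t, e)
        for ti in np.quantile(t, [0.2, 0.5, 0.8]):
            assert ours.at(ti) == pytest.approx(
                float(km.predict(ti)), abs=1e-9)


class TestLogRank:
    def test_identical_groups_hr_one(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 0, 1, 1, 0]
        r = cs.log_rank(t, e, t, e)
        assert r.hazard_ratio == pytest.approx(1.0)
        assert r.pvalue > 0.9

    def test_time_rescaling_invariance(self):
        rng = np.random.default_rng(14)
        ta, tb = rng.exponential(5, 40), rng.exponential(10, 40)
        ea = np.ones(40, int)
        r1 = cs.log_rank(ta, ea, tb, ea)
        r2 = cs.log_rank(ta * 12, ea, tb * 12, ea)
        assert r1.chi_square == pytest.approx(r2.chi_square)
        assert r1.hazard_ratio == pytest.approx(r2.hazard_ratio)

    def test_single_event_hand_table(self):
        # one event in A at t=1 with 2 at risk per group:
        # E_A = 1 * 2/4 = 0.5, O_A - E_A = 0.5
        r = cs.log_rank([1, 5], [1, 0], [5, 5], [0, 0])
        assert r.expected[0] == pytest.approx(0.5)
        assert r.observed[0] == 1.0

    def test_agrees_with_lifelines_statistic(self):
        from lifelines.statistics import logrank_test
        rng = np.random.default_rng(15)
        ta = rng.exponential(5, 50)
        tb = rng.exponential(12, 50)
        ea = rng.integers(0, 2, 50)
        eb = rng.integers(0, 2, 50)
        ea[0] = eb[0] = 1
        ours = cs.log_rank(ta, ea, tb, eb)
        ll = logrank_test(ta, tb, ea, eb)
        assert ours.chi_square == pytest.approx(ll.test_statistic,
                                                rel=1e-6)
        assert ours.pvalue == pytest.approx(ll.p_value, rel=1e-6)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cs.log_rank([1, 2], [0, 0], [3], [0])


class TestEMT:
    def test_equal_expression_is_mesenchymal_by_strict_rule(self):
        assert cs.emt_classify(5.0, 5.0) == "mesenchymal"

    def test_ecadherin_dominant_is_epithelial(self):
        assert cs.emt_classify(100.0, 1.0) == "epithelial"

    def test_nonpositive_raw_values_rejected(self):
        with pytest.raises(ValueError):
            cs.emt_classify(0.0, 1.0)

    def test_bimodal_panel_classified_correctly(self):
        rng = np.random.default_rng(16)
        correct = 0
        n = 60
        for i in range(n):
            epithelial = i % 2 == 0
            if epithelial:
                ecad = 2.0 ** rng.normal(4, 0.5)
                vim = 2.0 ** rng.normal(0, 0.5)
            else:
                ecad = 2.0 ** rng.normal(0, 0.5)
                vim = 2.0 ** rng.normal(4, 0.5)
            got = cs.emt_classify(ecad, vim)
            if got == ("epithelial" if epithelial else "mesenchymal"):
                correct += 1
        assert correct / n >= 0.95
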