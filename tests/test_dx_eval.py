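"""Diagnostic statistics: case rules, ROC/AUC, correlated comparison,
group comparison, performance reporting, repeatability."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from sudoquant.config import CategoryConfig
from sudoquant.dx_eval import (
    CATEGORY_ORDER,
    compare_auc_correlated,
    compare_groups,
    dichotomize,
    evaluate_performance,
    hanley_mcneil_se,
    normative_cutoff,
    repeatability,
    roc_curve,
    toronto_dpn,
    youden_cutoff,
)
from sudoquant.errors import (
    ConfigError,
    DegenerateLabelsError,
    InputError,
    InsufficientDataError,
    MissingDataError,
)
from sudoquant.registry import ReferenceTest, default_registry
from sudoquant.synth import CohortSimConfig, generate_cohort, generate_paired_scores


def brute_force_auc(scores, labels):
    """O(n^2) pair-counting oracle, ties one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (pos.size * neg.size)


class TestCaseRules:
    @pytest.mark.parametrize(
        "pmncv,nds,expected",
        [
            (39.3, 5.5, True),   # disease-group medians
            (44.1, 0.5, False),  # control-group medians
            (42.0, 5, False),    # boundary: exactly 42 is normal
            (41.9, 2, False),    # boundary: exactly 2 is normal
            (41.9, 3, True),
        ],
    )
    def test_toronto_truth_table(self, pmncv, nds, expected):
        assert toronto_dpn({"PMNCV": pmncv, "NDS": nds}) is expected

    @pytest.mark.parametrize("missing", ["PMNCV", "NDS"])
    def test_toronto_missing_field_named(self, missing):
        record = {"PMNCV": 40.0, "NDS": 4, missing: float("nan")}
        with pytest.raises(MissingDataError, match=missing):
            toronto_dpn(record)

    @pytest.mark.parametrize(
        "values,direction,expected",
        [
            ([25, 30, 35], "below", 20.0),   # sample SD = 5
            ([40, 42, 44], "above", 46.0),   # sample SD = 2
            ([7, 7, 7, 7], "below", 7.0),    # zero variance
        ],
    )
    def test_normative_cutoff(self, values, direction, expected):
        assert normative_cutoff(values, direction) == pytest.approx(expected)

    def test_normative_cutoff_needs_two_values(self):
        with pytest.raises(InsufficientDataError):
            normative_cutoff([5.0], "below")

    def test_dichotomize_clinical_examples(self):
        reg = default_registry()
        assert dichotomize([21.4], reg["CNFD"]).iloc[0] == 1
        assert dichotomize([25.0], reg["DB_HRV"]).iloc[0] == 0
        # values exactly at a threshold are normal (strict inequality)
        for name, test in reg.items():
            assert dichotomize([test.threshold], test).iloc[0] == 0

    def test_dichotomize_excludes_missing(self):
        reg = default_registry()
        labels = dichotomize(pd.Series([50.0, np.nan, 1.0]), reg["SNAP"])
        assert list(labels.index) == [0, 2]
        assert list(labels) == [0, 1]

    def test_unknown_direction_rejected(self):
        with pytest.raises(ConfigError):
            ReferenceTest("XYZ", 1.0, "sideways")


class TestROC:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),
            ([1, 3, 2, 4], [0, 0, 1, 1], 0.75),
            ([5, 5, 5, 5], [0, 0, 1, 1], 0.5),
        ],
    )
    def test_small_examples_match_pair_counting(self, scores, labels, expected):
        assert roc_curve(scores, labels, direction="high").auc == expected
        assert brute_force_auc(scores, labels) == expected

    def test_curve_is_monotone_from_origin_to_corner(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=60)
        labels = np.r_[np.zeros(30, int), np.ones(30, int)]
        roc = roc_curve(scores, labels, direction="high")
        assert roc.fpr[0] == roc.tpr[0] == 0.0
        assert roc.fpr[-1] == roc.tpr[-1] == 1.0
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.data())
    def test_rank_auc_matches_brute_force_and_negation(self, data):
        n_pos = data.draw(st.integers(1, 10))
        n_neg = data.draw(st.integers(1, 10))
        scores = data.draw(
            st.lists(
                st.integers(0, 5), min_size=n_pos + n_neg, max_size=n_pos + n_neg
            )
        )
        scores = np.array(scores, float)
        labels = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
        roc = roc_curve(scores, labels, direction="high")
        assert roc.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
        flipped = roc_curve(-scores, labels, direction="high")
        assert flipped.auc == pytest.approx(1.0 - roc.auc, abs=1e-12)

    def test_direction_low_negates(self):
        scores = [90.0, 80.0, 20.0, 10.0]
        labels = [0, 0, 1, 1]
        assert roc_curve(scores, labels, direction="low").auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            roc_curve([1, 2, 3], [1, 1, 1])

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(InputError):
            roc_curve([1.0, np.nan, 2.0], [0, 1, 1])

    def test_hanley_mcneil_se_closed_form_at_half(self):
        """At A = 0.5, Q1 = Q2 = 1/3 and the SE formula collapses to a
        closed form checked here by direct evaluation."""
        for n_pos, n_neg in [(5, 7), (30, 40), (100, 100)]:
            expected = np.sqrt(
                (0.25 + (n_pos - 1) * (1 / 3 - 0.25) + (n_neg - 1) * (1 / 3 - 0.25))
                / (n_pos * n_neg)
            )
            assert hanley_mcneil_se(0.5, n_pos, n_neg) == pytest.approx(expected, rel=1e-12)


class TestYouden:
    def _oracle(self, scores, labels, direction="high"):
        """Exhaustive search over all candidate operating rules."""
        scores = np.asarray(scores, float)
        labels = np.asarray(labels, int)
        s = -scores if direction == "low" else scores
        best = None
        for thr in np.unique(s):
            pred = s >= thr
            sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
            spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
            native = -thr if direction == "low" else thr
            key = (round(sens + spec - 1, 12), round(sens, 12), native)
            if best is None or key > best:
                best = key
        return best

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 8, size=30).astype(float)
        labels = np.r_[np.ones(12, int), np.zeros(18, int)]
        roc = roc_curve(scores, labels, direction="high")
        cutoff, sens, spec = youden_cutoff(roc)
        j_oracle, sens_oracle, thr_oracle = self._oracle(scores, labels)
        assert (sens / 100 + spec / 100 - 1) == pytest.approx(j_oracle, abs=1e-9)
        assert sens / 100 == pytest.approx(sens_oracle, abs=1e-9)
        assert cutoff == pytest.approx(thr_oracle)

    def test_perfect_separation_picks_highest_separating_threshold(self):
        roc = roc_curve([1, 2, 3, 4], [0, 0, 1, 1], direction="high")
        cutoff, sens, spec = youden_cutoff(roc)
        assert (sens, spec) == (100.0, 100.0)
        assert cutoff == 3.0  # highest threshold that still separates

    def test_flat_curve_has_zero_youden(self):
        roc = roc_curve([5, 5, 5, 5], [0, 0, 1, 1], direction="high")
        _, sens, spec = youden_cutoff(roc)
        assert sens + spec - 100.0 == pytest.approx(0.0)


class TestCompareAUC:
    def test_self_comparison_is_null(self):
        s1, _, y = generate_paired_scores(50, 50, 0.8, 0.8, 0.5, seed=0)
        for method in ("delong", "hanley-mcneil"):
            res = compare_auc_correlated(s1, s1, y, method=method, direction="high")
            assert res.z == pytest.approx(0.0, abs=1e-12)
            assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(InputError):
            compare_auc_correlated([1, 2], [1, 2, 3], [0, 1, 1])

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            compare_auc_correlated([1, 2], [3, 4], [1, 1])

    def test_delong_agrees_with_permutation_oracle(self):
        """Label-preserving swaps of the paired scores give an exact null
        reference distribution for the AUC difference."""
        s1, s2, y = generate_paired_scores(200, 200, 0.75, 0.70, 0.5, seed=11)
        res = compare_auc_correlated(s1, s2, y, direction="high")
        n_swaps = 2000
        rng = np.random.default_rng(42)
        d_obs = abs(res.auc1 - res.auc2)
        count = 0
        for _ in range(n_swaps):
            swap = rng.random(y.size) < 0.5
            a = np.where(swap, s2, s1)
            b = np.where(swap, s1, s2)
            d = abs(brute_auc_rank(a, y) - brute_auc_rank(b, y))
            count += d >= d_obs - 1e-12
        p_perm = count / n_swaps
        mc_err = 3 * np.sqrt(max(p_perm, res.p) * (1 - min(p_perm, res.p)) / n_swaps)
        assert abs(res.p - p_perm) <= mc_err + 0.005

    @pytest.mark.parametrize("auc", [0.6, 0.75, 0.9])
    @pytest.mark.parametrize("rho", [0.0, 0.3, 0.6])
    def test_hanley_mcneil_delong_same_order_of_magnitude(self, auc, rho):
        s1, s2, y = generate_paired_scores(200, 200, auc, auc, rho, seed=5)
        p_d = compare_auc_correlated(s1, s2, y, direction="high").p
        p_h = compare_auc_correlated(s1, s2, y, method="hanley-mcneil", direction="high").p
        assert 0.2 <= p_h / p_d <= 5.0

    def test_correlation_term_tracks_rho(self):
        """Stronger within-class score correlation should raise the
        estimated between-AUC correlation r."""
        rs = []
        for rho in (0.0, 0.9):
            s1, s2, y = generate_paired_scores(1000, 1000, 0.8, 0.8, rho, seed=3)
            rs.append(compare_auc_correlated(s1, s2, y, direction="high").r)
        assert rs[1] > rs[0] + 0.3


def brute_auc_rank(s, y):
    r = rankdata(s)
    n1 = int(y.sum())
    n0 = y.size - n1
    return (r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


class TestCompareGroups:
    def test_exact_small_sample(self):
        res = compare_groups([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0
        assert res.p == pytest.approx(0.1)

    def test_identical_groups_null(self):
        res = compare_groups(list(range(10)), list(range(10)))
        assert res.p >= 0.99

    def test_percentile_convention(self):
        res = compare_groups(np.arange(0, 101, 10), [1.0])
        assert res.median_a == 50.0
        assert res.p5_a == pytest.approx(5.0)   # linear interpolation
        assert res.p95_a == pytest.approx(95.0)

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_groups([], [1.0])


class TestEvaluatePerformance:
    def test_independent_neuropad_gives_chance_aucs(self):
        rng = np.random.default_rng(0)
        n = 400
        cohort = pd.DataFrame(
            {
                "neuropad_percent": rng.uniform(0, 100, n),
                "PMNCV": rng.normal(42, 4, n),
            }
        )
        table = evaluate_performance(cohort)
        row = table.set_index("reference_test").loc["PMNCV"]
        assert row["auc_continuous"] == pytest.approx(0.5, abs=0.08)
        assert row["auc_categorical"] == pytest.approx(0.5, abs=0.08)

    def test_informative_cohort_continuous_beats_categorical(self):
        wins = 0
        reg = {"CNFD": default_registry()["CNFD"]}
        for rep in range(50):
            coh = generate_cohort(CohortSimConfig(seed=1000 + rep))
            table = evaluate_performance(coh, reg)
            row = table.iloc[0]
            wins += row["auc_continuous"] >= row["auc_categorical"]
        assert wins >= 45

    def test_constant_categorical_output_flagged(self):
        rng = np.random.default_rng(1)
        cohort = pd.DataFrame(
            {
                # all values land in the 'normal' category
                "neuropad_percent": rng.uniform(95, 100, 60),
                "PMNCV": rng.normal(42, 4, 60),
            }
        )
        table = evaluate_performance(cohort)
        assert "constant" in table.iloc[0]["note"]

    def test_absent_measure_skipped(self):
        cohort = pd.DataFrame({"neuropad_percent": [10.0, 90.0, 50.0, 70.0]})
        table = evaluate_performance(cohort)
        assert table.empty

    def test_supplied_categorical_column_used(self):
        cohort = pd.DataFrame(
            {
                "neuropad_percent": [5.0, 15.0, 70.0, 95.0] * 10,
                "neuropad_category": ["abnormal", "abnormal", "intermediate", "normal"] * 10,
                "SNAP": [1.0, 2.0, 10.0, 20.0] * 10,
            }
        )
        table = evaluate_performance(cohort)
        assert table.iloc[0]["auc_categorical"] == 1.0


class TestRepeatability:
    def test_identical_runs_perfect_agreement(self):
        run = [10.0, 45.0, 80.0, 99.0, 3.0]
        res = repeatability(run, run)
        assert res.icc == 1.0
        assert res.bland_altman_coefficient == 0.0
        assert not res.zero_variance

    def test_icc_decreases_with_noise(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 100, 200)
        iccs = []
        for sigma in (1.0, 5.0, 10.0):
            noisy = base + np.random.default_rng(1).normal(0, sigma, base.size)
            iccs.append(repeatability(base, noisy).icc)
        assert iccs[0] > iccs[1] > iccs[2]
        assert all(i < 1.0 for i in iccs)

    def test_constant_runs_flagged(self):
        res = repeatability([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.icc == 1.0
        assert res.zero_variance

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            repeatability([1.0, 2.0], [1.0])

    def test_matches_independent_icc_implementation(self):
        """Cross-check ICC(2,1) against pingouin's ANOVA-based estimate."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        r1 = rng.uniform(0, 100, 40)
        r2 = r1 + rng.normal(0, 6, 40)
        ours = repeatability(r1, r2).icc
        long = pd.DataFrame(
            {
                "subject": np.r_[np.arange(40), np.arange(40)],
                "rater": ["a"] * 40 + ["b"] * 40,
                "score": np.r_[r1, r2],
            }
        )
        icc_table = pingouin.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="score"
        )
        theirs = float(icc_table.set_index("Type").loc["ICC(A,1)", "ICC"])
        assert ours == pytest.approx(theirs, abs=1e-9)
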