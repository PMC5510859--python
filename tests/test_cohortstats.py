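"""Statistical layer: normality, t-test, chi-square, ANCOVA, ROC, DeLong."""

import math

import numpy as np
import pandas as pd
import pytest

from myxtex import (
    ancova_group_p,
    classify_auc,
    compare_aucs,
    group_ttest,
    ks_normality,
    roc_analysis,
    sex_chisq,
)
from myxtex.cohortstats import clopper_pearson, delong_auc_variance

from .oracles import (
    bootstrap_auc_variance,
    pair_count_auc,
    permutation_ttest_p,
    youden_scan,
)


# ---------------------------------------------------------------------------
# Normality


def test_ks_level_on_gaussian_samples():
    """Lilliefors p > 0.05 for >= 90% of seeded Gaussian replicates."""
    keep = 0
    for seed in range(100):
        x = np.random.default_rng(seed).normal(3.0, 2.0, size=200)
        if ks_normality(x) > 0.05:
            keep += 1
    assert keep >= 90


def test_ks_power_on_exponential_samples():
    """Lilliefors p < 0.05 for >= 95% of exponential replicates."""
    reject = 0
    for seed in range(100):
        x = np.random.default_rng(seed).exponential(1.0, size=200)
        if ks_normality(x) < 0.05:
            reject += 1
    assert reject >= 95


def test_ks_location_scale_invariance():
    x = np.random.default_rng(0).normal(size=80)
    assert ks_normality(x) == pytest.approx(ks_normality(5.0 + 2.5 * x),
                                            abs=1e-10)


def test_ks_constant_flagged():
    assert math.isnan(ks_normality(np.ones(20)))


# ---------------------------------------------------------------------------
# t-test and chi-square


def test_ttest_identical_groups_p_one():
    vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    groups = np.array([0, 0, 0, 1, 1, 1])
    assert group_ttest(vals, groups) == pytest.approx(1.0)


def test_ttest_label_swap_symmetry():
    rng = np.random.default_rng(1)
    vals = rng.normal(size=20)
    groups = rng.integers(0, 2, size=20)
    while len(np.unique(groups)) < 2 or min((groups == 0).sum(),
                                            (groups == 1).sum()) < 2:
        groups = rng.integers(0, 2, size=20)
    assert group_ttest(vals, groups) == pytest.approx(
        group_ttest(vals, 1 - groups)
    )


def test_ttest_against_permutation_oracle():
    """Strongly separated small groups: Student p in line with the exact
    permutation p (the permutation law is discrete; agreement is coarse)."""
    a = [1.0, 2.0, 3.0, 4.0]
    b = [11.0, 12.0, 13.0, 14.0]
    p_t = group_ttest(a + b, [0] * 4 + [1] * 4)
    p_perm = permutation_ttest_p(a, b)  # exhaustive 70 splits -> 2/70
    assert p_t < 0.001
    assert p_perm == pytest.approx(2 / 70)


def test_ttest_zero_variance_flagged():
    assert math.isnan(group_ttest([1, 1, 1, 2, 2, 2], [0, 0, 0, 1, 1, 1]))


def test_sex_chisq_cohort_table():
    """The 2x2 sex table [[12,11],[6,11]] gives p ~ 0.289 (uncorrected)."""
    assert sex_chisq([[12, 11], [6, 11]]) == pytest.approx(0.289, abs=0.005)


def test_sex_chisq_proportional_table():
    assert sex_chisq([[10, 10], [5, 5]]) == pytest.approx(1.0)


def test_sex_chisq_perfect_association():
    from scipy.stats import chi2

    p = sex_chisq([[20, 0], [0, 20]])
    assert p == pytest.approx(float(chi2.sf(40.0, 1)), rel=1e-9)


def test_sex_chisq_zero_marginal_rejected():
    with pytest.raises(ValueError):
        sex_chisq([[0, 0], [5, 5]])


# ---------------------------------------------------------------------------
# ANCOVA


def _cohort(rng, n, delta=0.0, beta_vol=0.0):
    group = rng.integers(0, 2, size=n)
    age = rng.normal(55, 12, size=n)
    sex = rng.integers(0, 2, size=n)
    volume = rng.lognormal(2.5, 0.8, size=n) * (1 + 0.5 * group)
    feature = delta * group + beta_vol * volume + rng.normal(size=n)
    return feature, group, age, sex, volume


def test_ancova_converges_to_ttest_under_null_covariates():
    """Independent covariates: adjusted p converges to the unadjusted t-test
    p as n grows (the adjustment's chance contribution is O(1/sqrt(n)))."""

    def p_diffs(n):
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            group = rng.integers(0, 2, size=n)
            feature = 0.05 * group + rng.normal(size=n)
            age = rng.normal(55, 12, size=n)
            sex = rng.integers(0, 2, size=n)
            volume = rng.lognormal(2.5, 0.8, size=n)
            p_adj = ancova_group_p(feature, group, age, sex, volume)
            p_t = group_ttest(feature, group)
            diffs.append(abs(p_adj - p_t))
        return np.asarray(diffs)

    small, large = p_diffs(100), p_diffs(2000)
    assert large.max() < 0.1
    assert np.median(large) < np.median(small)


def test_ancova_absorbs_covariate_effect():
    """feature = 2*volume exactly: the group effect vanishes after adjustment."""
    rng = np.random.default_rng(4)
    n = 60
    group = np.repeat([0, 1], n // 2)
    volume = rng.lognormal(2.0, 0.5, size=n)  # independent of group
    feature = 2.0 * volume + rng.normal(scale=1e-8, size=n)
    p = ancova_group_p(feature, group, rng.normal(55, 10, n),
                       rng.integers(0, 2, n), volume)
    assert p > 0.5


def test_ancova_matches_normal_equations_oracle():
    """Group-coefficient t-test agrees with an independent normal-equations
    solve; power to detect a confounded group effect is high."""
    from scipy import stats as sps

    detected = 0
    for seed in range(25):
        rng = np.random.default_rng(seed)
        feature, group, age, sex, volume = _cohort(rng, 120, delta=1.0,
                                                   beta_vol=0.05)
        p = ancova_group_p(feature, group, age, sex, volume)

        X = np.column_stack([np.ones_like(feature), group, age, sex, volume])
        beta, *_ = np.linalg.lstsq(X, feature, rcond=None)
        resid = feature - X @ beta
        dof = len(feature) - X.shape[1]
        s2 = resid @ resid / dof
        cov = s2 * np.linalg.inv(X.T @ X)
        t = beta[1] / math.sqrt(cov[1, 1])
        p_oracle = 2 * sps.t.sf(abs(t), dof)
        assert p == pytest.approx(p_oracle, abs=1e-10)
        if p < 0.05:
            detected += 1
    assert detected >= 20  # >= 80% power at this effect size


def test_ancova_rank_deficient_names_column():
    n = 30
    rng = np.random.default_rng(0)
    feature = rng.normal(size=n)
    group = rng.integers(0, 2, size=n)
    with pytest.raises(ValueError, match="sex"):
        ancova_group_p(feature, group, rng.normal(55, 10, n),
                       np.zeros(n), rng.lognormal(2, 0.5, n))


# ---------------------------------------------------------------------------
# ROC


def test_roc_perfect_separation():
    r = roc_analysis([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
    assert r.auc == 1.0
    assert r.sensitivity == 100.0 and r.specificity == 100.0
    assert r.youden_j == pytest.approx(1.0)
    assert r.direction == ">"


def test_roc_tie_credit():
    """benign [1,2], malignant [2,3]: wins 3 of 4 pairs + one tie -> 0.875."""
    r = roc_analysis([1, 2, 2, 3], [0, 0, 1, 1])
    assert r.auc == pytest.approx(0.875)


def test_roc_orientation_flip():
    """Positives scoring low: direction '<=' and oriented AUC >= 0.5."""
    r = roc_analysis([5, 6, 7, 1, 2, 3], [0, 0, 0, 1, 1, 1])
    assert r.direction == "<="
    assert r.auc == 1.0
    # threshold is on the original scale: call positive when score <= t
    assert r.threshold >= 3.0


def test_auc_equals_pair_count_oracle():
    rng = np.random.default_rng(2)
    for _ in range(30):
        n = int(rng.integers(6, 50))
        scores = rng.integers(0, 10, size=n).astype(float)  # many ties
        labels = rng.integers(0, 2, size=n).astype(bool)
        if labels.all() or not labels.any():
            continue
        auc, _ = delong_auc_variance(scores, labels)
        assert auc == pytest.approx(
            pair_count_auc(scores[labels], scores[~labels]), abs=1e-12
        )


def test_youden_threshold_equals_exhaustive_scan():
    rng = np.random.default_rng(8)
    for _ in range(20):
        pos = rng.normal(1.0, 1.0, size=15)
        neg = rng.normal(0.0, 1.0, size=20)
        scores = np.concatenate([neg, pos])
        labels = np.array([0] * 20 + [1] * 15, dtype=bool)
        r = roc_analysis(scores, labels)
        j, sens, spec, t = youden_scan(pos, neg)
        if r.direction == ">":
            assert r.youden_j == pytest.approx(j, abs=1e-12)
            assert r.threshold == pytest.approx(t, abs=1e-12)
            assert r.sensitivity == pytest.approx(100 * sens)
            assert r.specificity == pytest.approx(100 * spec)


def test_permuted_scores_mean_auc_half():
    """Label-independent scores: unoriented AUC averages 0.5 +/- 0.02."""
    rng = np.random.default_rng(6)
    scores = rng.normal(size=40)
    labels = np.array([True] * 17 + [False] * 23)
    aucs = []
    for _ in range(500):
        perm = rng.permutation(labels)
        auc, _ = delong_auc_variance(scores, perm)
        aucs.append(auc)
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


def test_delong_variance_close_to_bootstrap():
    """Single-AUC DeLong variance within 15% of a 2000-rep stratified
    bootstrap on a 40-subject cohort."""
    rng = np.random.default_rng(10)
    scores = np.concatenate([rng.normal(0, 1, 23), rng.normal(1.2, 1, 17)])
    labels = np.array([False] * 23 + [True] * 17)
    _, v_delong = delong_auc_variance(scores, labels)
    v_boot = bootstrap_auc_variance(scores, labels, n_boot=2000, seed=1)
    assert v_delong == pytest.approx(v_boot, rel=0.15)


def test_roc_one_class_raises():
    with pytest.raises(ValueError):
        roc_analysis([1, 2, 3], [1, 1, 1])


def test_clopper_pearson_bounds():
    lo, hi = clopper_pearson(0, 10)
    assert lo == 0.0 and hi < 0.35
    lo, hi = clopper_pearson(10, 10)
    assert hi == 1.0 and lo > 0.65


# ---------------------------------------------------------------------------
# Paired AUC comparison


def test_compare_feature_with_itself():
    rng = np.random.default_rng(3)
    scores = rng.normal(size=30)
    labels = np.array([True, False] * 15)
    c = compare_aucs(scores, scores, labels)
    assert c.difference == 0.0
    assert c.raw_p == 1.0


def test_bonferroni_monotone_and_capped():
    rng = np.random.default_rng(5)
    labels = np.array([True] * 10 + [False] * 12)
    a, b = rng.normal(size=22), rng.normal(size=22)
    c = compare_aucs(a, b, labels, n_pairs_for_bonferroni=15)
    assert c.bonferroni_p >= c.raw_p
    assert c.bonferroni_p <= 1.0
    assert c.bonferroni_p == pytest.approx(min(1.0, c.raw_p * 15))


def test_paired_null_p_uniform():
    """Two independent null features: raw p roughly uniform on [0,1]."""
    from scipy import stats as sps

    rng = np.random.default_rng(11)
    labels = np.array([True] * 17 + [False] * 23)
    ps = []
    for _ in range(500):
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        ps.append(compare_aucs(a, b, labels).raw_p)
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_mismatched_subjects_rejected():
    with pytest.raises(ValueError):
        compare_aucs([1, 2, 3], [1, 2], [True, False, True])


# ---------------------------------------------------------------------------
# AUC bins


@pytest.mark.parametrize(
    "auc, label",
    [
        (0.923, "excellent"),
        (0.9, "excellent"),
        (0.85, "good"),
        (0.8, "good"),
        (0.75, "fair"),
        (0.65, "poor"),
        (0.55, "failure"),
        (0.5, "failure"),
        (1.0, "excellent"),
    ],
)
def test_classify_auc_bins(auc, label):
    assert classify_auc(auc) == label


def test_classify_auc_out_of_range():
    with pytest.raises(ValueError):
        classify_auc(0.4)
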