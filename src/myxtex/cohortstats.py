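"""Group comparison and ROC statistics for the benign/malignant cohort.

Implements the statistical layer applied to the per-subject feature table:

* Kolmogorov-Smirnov normality with the Lilliefors correction (population
  mean/SD are estimated from the sample);
* pooled-variance (Student) two-sample t-test for group mean differences;
* Pearson chi-square (no continuity correction) for the 2x2 sex table;
* ANCOVA: ordinary least squares of feature on group + age + sex + volume,
  reporting the partial two-sided p of the group coefficient;
* ROC analysis: Mann-Whitney AUC with half credit for ties, automatic
  orientation (AUC >= 0.5), Youden-optimal threshold, Clopper-Pearson
  binomial-exact CIs for sensitivity/specificity, DeLong variance for the
  AUC CI and the test against chance;
* paired (correlated-ROC) AUC comparison by the DeLong method with
  Bonferroni adjustment over the number of pairs actually compared.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "RocResult",
    "AucPairComparison",
    "ks_normality",
    "group_ttest",
    "sex_chisq",
    "ancova_group_p",
    "roc_analysis",
    "compare_aucs",
    "classify_auc",
    "group_comparison_table",
    "roc_table",
    "pairwise_auc_table",
]


# ---------------------------------------------------------------------------
# Univariate tests


def ks_normality(values) -> float:
    """Lilliefors-corrected KS p-value against a normal with estimated moments.

    Returns NaN for (near-)constant input, where normality is undefined.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    if np.std(x) == 0.0:
        return math.nan
    _, p = lilliefors(x, dist="norm")
    return float(p)


def group_ttest(values, groups) -> float:
    """Two-sided pooled-variance Student t-test p-value between two groups.

    ``groups`` is a boolean or two-level array; returns NaN when the pooled
    variance is zero.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError("exactly two groups required")
    a, b = x[g == levels[0]], x[g == levels[1]]
    if min(a.size, b.size) < 2:
        raise ValueError("need at least 2 observations per group")
    pooled = ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled == 0.0:
        return math.nan
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.pvalue)


def sex_chisq(counts) -> float:
    """Pearson chi-square p (df=1, no continuity correction) for a 2x2 table."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def ancova_group_p(feature, group, age, sex, volume) -> float:
    """Covariate-adjusted group p: OLS of feature on group + age + sex + volume.

    ``group`` and ``sex`` may be labels or 0/1; the returned value is the
    two-sided partial t-test p of the group coefficient.  Raises on a
    rank-deficient design, naming the collinear column.
    """
    import statsmodels.api as sm

    y = np.asarray(feature, dtype=float)
    g = _binarize(group, "group")
    s = _binarize(sex, "sex")
    cols = {
        "intercept": np.ones_like(y),
        "group": g,
        "age": np.asarray(age, dtype=float),
        "sex": s,
        "volume": np.asarray(volume, dtype=float),
    }
    X = np.column_stack(list(cols.values()))
    if y.size <= X.shape[1]:
        raise ValueError("need more subjects than design columns")
    _check_full_rank(X, list(cols.keys()))
    model = sm.OLS(y, X).fit()
    return float(model.pvalues[1])


def _binarize(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind in "biuf":
        return arr.astype(float)
    levels = sorted(set(arr.tolist()))
    if len(levels) > 2:
        raise ValueError(f"{name} has more than two levels: {levels}")
    return np.asarray([levels.index(v) for v in arr], dtype=float)


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = 0
    for j in range(X.shape[1]):
        new_rank = np.linalg.matrix_rank(X[:, : j + 1])
        if new_rank == rank:
            raise ValueError(f"design matrix is rank-deficient: column "
                             f"{names[j]!r} is collinear with earlier columns")
        rank = new_rank


# ---------------------------------------------------------------------------
# ROC machinery


@dataclass(frozen=True)
class RocResult:
    """Oriented ROC summary for one feature."""

    auc: float
    auc_ci_low: float
    auc_ci_high: float
    direction: str  # ">" if positives score high, "<=" otherwise
    threshold: float
    sensitivity: float  # percent
    specificity: float  # percent
    sens_ci_low: float
    sens_ci_high: float
    spec_ci_low: float
    spec_ci_high: float
    youden_j: float
    p_vs_chance: float
    auc_se: float


@dataclass(frozen=True)
class AucPairComparison:
    """Paired DeLong comparison of two features' AUCs on the same subjects."""

    feature_a: str
    feature_b: str
    auc_a: float
    auc_b: float
    difference: float
    diff_ci_low: float
    diff_ci_high: float
    raw_p: float
    bonferroni_p: float


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney statistic, half credit for ties."""
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components (V10 per positive, V01 per negative).

    Fast midrank formulation; returns (auc, v10, v01).
    """
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    tx = _midranks(pos)
    ty = _midranks(neg)
    tz = _midranks(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


def _delong_var(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = v10.size, v01.size
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    return float(auc), float(var)


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) CI for a proportion."""
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def roc_analysis(scores, labels, alpha: float = 0.05) -> RocResult:
    """Full ROC summary of one score against binary labels (True = positive).

    The direction is chosen so the oriented AUC is >= 0.5: ``">"`` means a
    subject is called positive when its score exceeds the threshold,
    ``"<="`` when it does not.  The threshold is the observed score value
    maximizing the Youden index J = sensitivity + specificity - 1, ties
    broken toward higher specificity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    pos, neg = s[y], s[~y]
    raw_auc = _mann_whitney_auc(pos, neg)
    if raw_auc >= 0.5:
        direction, oriented = ">", s
    else:
        direction, oriented = "<=", -s

    auc, var = _delong_var(oriented, y)
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(1 - alpha / 2)
    ci_low = max(0.0, auc - z * se)
    ci_high = min(1.0, auc + z * se)
    if se > 0:
        p_chance = 2.0 * stats.norm.sf(abs(auc - 0.5) / se)
    else:
        p_chance = 1.0 if auc == 0.5 else 0.0

    # Youden scan over observed thresholds (oriented: positive iff score > t).
    opos, oneg = oriented[y], oriented[~y]
    best = None
    for t in np.unique(oriented):
        sens = float((opos > t).mean())
        spec = float((oneg <= t).mean())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12 or (
            abs(j - best[0]) <= 1e-12 and spec > best[2]
        ):
            best = (j, sens, spec, t)
    j, sens, spec, t_oriented = best
    threshold = float(t_oriented if direction == ">" else -t_oriented)

    k_sens = int(round(sens * opos.size))
    k_spec = int(round(spec * oneg.size))
    slo, shi = clopper_pearson(k_sens, opos.size, alpha)
    plo, phi = clopper_pearson(k_spec, oneg.size, alpha)
    return RocResult(
        auc=float(auc),
        auc_ci_low=ci_low,
        auc_ci_high=ci_high,
        direction=direction,
        threshold=threshold,
        sensitivity=100.0 * sens,
        specificity=100.0 * spec,
        sens_ci_low=100.0 * slo,
        sens_ci_high=100.0 * shi,
        spec_ci_low=100.0 * plo,
        spec_ci_high=100.0 * phi,
        youden_j=float(j),
        p_vs_chance=float(p_chance),
        auc_se=se,
    )


def delong_auc_variance(scores, labels) -> tuple[float, float]:
    """(AUC, DeLong variance) of a single unoriented score."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    return _delong_var(s, y)


def compare_aucs(
    scores_a,
    scores_b,
    labels,
    n_pairs_for_bonferroni: int = 1,
    feature_a: str = "a",
    feature_b: str = "b",
    alpha: float = 0.05,
) -> AucPairComparison:
    """Paired DeLong test of the AUC difference of two features.

    Both scores must be measured on the same subjects in the same order and
    are used as given: callers that report oriented (AUC >= 0.5) areas, as
    the cohort tables do, must orient the scores themselves.  Comparing a
    score with itself gives difference 0 and p = 1.
    ``bonferroni_p = min(1, raw_p * n_pairs_for_bonferroni)``.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(bool)
    if sa.size != y.size or sb.size != y.size:
        raise ValueError("scores and labels must cover the same subjects")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")

    auc_a, v10_a, v01_a = _delong_components(sa, y)
    auc_b, v10_b, v01_b = _delong_components(sb, y)
    m, n = v10_a.size, v01_a.size
    # 2x2 covariance of (auc_a, auc_b)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = float(auc_a - auc_b)
    se = math.sqrt(max(var_diff, 0.0))
    z = stats.norm.ppf(1 - alpha / 2)
    if se > 0:
        raw_p = 2.0 * stats.norm.sf(abs(diff) / se)
    else:
        raw_p = 1.0 if diff == 0.0 else 0.0
    return AucPairComparison(
        feature_a=feature_a,
        feature_b=feature_b,
        auc_a=float(auc_a),
        auc_b=float(auc_b),
        difference=diff,
        diff_ci_low=diff - z * se,
        diff_ci_high=diff + z * se,
        raw_p=float(raw_p),
        bonferroni_p=float(min(1.0, raw_p * n_pairs_for_bonferroni)),
    )


_AUC_BINS = (
    (0.9, "excellent"),
    (0.8, "good"),
    (0.7, "fair"),
    (0.6, "poor"),
    (0.5, "failure"),
)


def classify_auc(auc: float) -> str:
    """Five-bin discriminatory-power label, lower bound inclusive."""
    if not 0.5 <= auc <= 1.0:
        raise ValueError("AUC must lie in [0.5, 1]")
    for lo, label in _AUC_BINS:
        if auc >= lo:
            return label
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Cohort tables


def group_comparison_table(
    table: pd.DataFrame, features: list[str]
) -> pd.DataFrame:
    """Per-feature group means +/- SD, KS normality p, t-test p and ANCOVA p.

    ``table`` must have columns ``group`` (benign/malignant), ``age``,
    ``sex``, ``volume_cm3`` and the requested features.
    """
    is_mal = (table["group"] == "malignant").to_numpy()
    rows = []
    for feat in features:
        x = table[feat].to_numpy(dtype=float)
        rows.append(
            {
                "feature": feat,
                "benign_mean": x[~is_mal].mean(),
                "benign_sd": x[~is_mal].std(ddof=1),
                "malignant_mean": x[is_mal].mean(),
                "malignant_sd": x[is_mal].std(ddof=1),
                "ks_normality_p": ks_normality(x),
                "unadjusted_p": group_ttest(x, is_mal),
                "adjusted_p": ancova_group_p(
                    x, is_mal, table["age"], table["sex"], table["volume_cm3"]
                ),
            }
        )
    return pd.DataFrame(rows)


def roc_table(table: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    """Table-style ROC summary (one row per feature), malignant = positive."""
    y = (table["group"] == "malignant").to_numpy()
    rows = []
    for feat in features:
        r = roc_analysis(table[feat].to_numpy(dtype=float), y)
        rows.append(
            {
                "feature": feat,
                "auc": r.auc,
                "auc_ci_low": r.auc_ci_low,
                "auc_ci_high": r.auc_ci_high,
                "power": classify_auc(r.auc),
                "direction": r.direction,
                "threshold": r.threshold,
                "sensitivity_pct": r.sensitivity,
                "specificity_pct": r.specificity,
                "youden_j": r.youden_j,
                "p_vs_chance": r.p_vs_chance,
            }
        )
    return pd.DataFrame(rows)


def pairwise_auc_table(table: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    """All pairwise DeLong AUC comparisons with Bonferroni adjustment.

    Each feature's scores are oriented first (sign-flipped when the raw
    AUC is below 0.5) so areas are reported on the conventional [0.5, 1]
    scale, mirroring the per-feature ROC table.
    """
    y = (table["group"] == "malignant").to_numpy()

    def oriented(feat: str) -> np.ndarray:
        s = table[feat].to_numpy(dtype=float)
        return s if _mann_whitney_auc(s[y], s[~y]) >= 0.5 else -s

    pairs = list(itertools.combinations(features, 2))
    rows = []
    for fa, fb in pairs:
        c = compare_aucs(
            oriented(fa),
            oriented(fb),
            y,
            n_pairs_for_bonferroni=len(pairs),
            feature_a=fa,
            feature_b=fb,
        )
        rows.append(
            {
                "feature_a": fa,
                "feature_b": fb,
                "auc_a": c.auc_a,
                "auc_b": c.auc_b,
                "difference": c.difference,
                "diff_ci_low": c.diff_ci_low,
                "diff_ci_high": c.diff_ci_high,
                "raw_p": c.raw_p,
                "bonferroni_p": c.bonferroni_p,
            }
        )
    return pd.DataFrame(rows)
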