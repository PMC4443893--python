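"""Diagnostic-accuracy statistics for continuous vs categorical test outputs.

The layer mirrors a standard clinical-evaluation workflow:

* case definition — :func:`toronto_dpn` (motor conduction velocity below
  42 m/s together with a disability score above 2) and
  :func:`normative_cutoff` (mean +/- 2 SD of a control population);
* dichotomization of reference measures against registry cut-offs;
* nonparametric ROC analysis — :func:`roc_curve` computes the empirical
  curve, the AUC (checked two ways: trapezoid and tie-corrected
  Mann-Whitney rank statistic) and the Hanley-McNeil standard error;
* :func:`youden_cutoff` for optimal operating points;
* :func:`compare_auc_correlated` for two tests measured on the same
  subjects, via DeLong placement-value covariances (default) or the
  Hanley-McNeil intermediate-correlation method;
* :func:`compare_groups` (Mann-Whitney with median and 5th/95th
  percentile summaries), :func:`evaluate_performance` (one report row per
  reference test) and :func:`repeatability` (intraclass correlation plus
  the Bland-Altman repeatability coefficient).

Conventions, fixed throughout: lower indicator percentage = more disease;
all diagnostic thresholds are strict inequalities, so values exactly at a
threshold are normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri

from .config import CategoryConfig
from .errors import (
    ConfigError,
    DegenerateLabelsError,
    InputError,
    InsufficientDataError,
    MissingDataError,
)
from .pad_quant import categorize
from .registry import ReferenceTest, default_registry

logger = logging.getLogger(__name__)

#: ordinal coding of the three-level visual read-out, lowest = most diseased
CATEGORY_ORDER: dict[str, int] = {"abnormal": 0, "intermediate": 1, "normal": 2}


# ---------------------------------------------------------------------------
# case definitions


def toronto_dpn(record: Mapping[str, object]) -> bool:
    """Consensus case definition of diabetic peripheral neuropathy.

    True iff PMNCV < 42 m/s AND NDS > 2, both strict.  ``record`` is any
    mapping (dict, pandas Series) with keys ``PMNCV`` and ``NDS``.
    """
    for field in ("PMNCV", "NDS"):
        value = record.get(field) if hasattr(record, "get") else record[field]
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise MissingDataError(f"cannot classify: field {field!r} is missing")
    return float(record["PMNCV"]) < 42.0 and float(record["NDS"]) > 2.0


def normative_cutoff(control_values: Sequence[float], direction: str) -> float:
    """Mean +/- 2 SD abnormality cut-off from a control population.

    ``direction`` is ``"below"`` (abnormal if below; cut-off = mean - 2 SD)
    or ``"above"`` (cut-off = mean + 2 SD).  SD is the sample standard
    deviation (n - 1 denominator).
    """
    values = np.asarray(control_values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise InsufficientDataError(
            f"need >= 2 control values for a normative cut-off, got {values.size}"
        )
    if direction not in ("below", "above"):
        raise ConfigError(f"direction must be 'below' or 'above', got {direction!r}")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return mean - 2.0 * sd if direction == "below" else mean + 2.0 * sd


def dichotomize(values: pd.Series | Sequence[float], test: ReferenceTest) -> pd.Series:
    """Binary abnormality labels (1 = abnormal) under a registry rule.

    Missing values are excluded from the result (complete-case), with the
    excluded count logged.  The inequality is strict: a value exactly at
    the threshold is normal.
    """
    series = pd.Series(values, dtype=float)
    missing = int(series.isna().sum())
    if missing:
        logger.info("%s: excluding %d record(s) with missing values", test.measure, missing)
    present = series.dropna()
    if test.direction == "below":
        labels = (present < test.threshold).astype(int)
    else:
        labels = (present > test.threshold).astype(int)
    return labels


# ---------------------------------------------------------------------------
# ROC machinery


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC curve with Hanley-McNeil standard error.

    ``fpr``/``tpr`` run from (0, 0) to (1, 1) over all distinct score
    thresholds.  ``thresholds`` are in the score's native units; the
    operating rule at ``thresholds[i]`` is "call disease when the score is
    on the diseased side of the threshold (inclusive)".  ``direction`` is
    ``"low"`` when low scores indicate disease (the convention for the
    indicator percentage) or ``"high"`` otherwise.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    se: float
    n_pos: int
    n_neg: int
    direction: str


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an empirical AUC.

    SE^2 = [A(1-A) + (n_pos-1)(Q1 - A^2) + (n_neg-1)(Q2 - A^2)] / (n_pos n_neg)
    with Q1 = A / (2 - A) and Q2 = 2 A^2 / (1 + A).
    """
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1.0 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    return float(np.sqrt(max(var, 0.0)))


def _check_binary(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos + n_neg != labels.size:
        raise InputError("labels must be 0/1")
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError(
            f"need both classes present, got {n_pos} positives / {n_neg} negatives"
        )
    return n_pos, n_neg


def _rank_auc(s: np.ndarray, y: np.ndarray, n_pos: int, n_neg: int) -> float:
    """Tie-corrected Mann-Whitney AUC (ties count one half)."""
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(
    scores: Sequence[float],
    labels: Sequence[int],
    direction: str = "low",
) -> ROCCurve:
    """Empirical ROC curve of a continuous (or ordinal) diagnostic score.

    The AUC is computed two ways — trapezoid over the curve points and the
    tie-corrected rank statistic U / (n_pos n_neg) — and the two are
    required to agree to 1e-12, which pins the tie convention.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise InputError("scores and labels must have the same length")
    if not np.isfinite(scores).all():
        raise InputError("scores must be finite")
    n_pos, n_neg = _check_binary(labels)
    if direction not in ("low", "high"):
        raise ConfigError(f"direction must be 'low' or 'high', got {direction!r}")
    s = -scores if direction == "low" else scores

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = labels[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # keep the last index of each tie group of thresholds
    last = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tpr = np.r_[0.0, tp[last] / n_pos]
    fpr = np.r_[0.0, fp[last] / n_neg]
    thr_internal = np.r_[np.inf, s_sorted[last]]
    thresholds = -thr_internal if direction == "low" else thr_internal

    auc_trap = float(np.trapezoid(tpr, fpr))
    auc_rank = _rank_auc(s, labels, n_pos, n_neg)
    if abs(auc_trap - auc_rank) > 1e-12:
        raise RuntimeError(
            f"internal inconsistency: trapezoid AUC {auc_trap!r} != rank AUC {auc_rank!r}"
        )
    return ROCCurve(
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        auc=auc_rank,
        se=hanley_mcneil_se(auc_rank, n_pos, n_neg),
        n_pos=n_pos,
        n_neg=n_neg,
        direction=direction,
    )


def youden_cutoff(roc: ROCCurve) -> tuple[float, float, float]:
    """Operating point maximizing Youden's J = sensitivity + specificity - 1.

    Returns ``(cutoff, sensitivity_pct, specificity_pct)`` with the cutoff
    in the score's native units.  Ties are broken toward higher
    sensitivity, then toward the higher native threshold.
    """
    j = roc.tpr - roc.fpr
    native = roc.thresholds
    best = 0
    for i in range(1, j.size):
        better = j[i] > j[best] + 1e-15
        tie = abs(j[i] - j[best]) <= 1e-15
        if better:
            best = i
        elif tie:
            if roc.tpr[i] > roc.tpr[best] + 1e-15:
                best = i
            elif abs(roc.tpr[i] - roc.tpr[best]) <= 1e-15 and not (
                np.isinf(native[i]) or native[i] <= native[best]
            ):
                best = i
    cutoff = float(native[best]) if np.isfinite(native[best]) else float(native[best])
    return cutoff, float(100.0 * roc.tpr[best]), float(100.0 * (1.0 - roc.fpr[best]))


# ---------------------------------------------------------------------------
# correlated-AUC comparison


@dataclass(frozen=True)
class AUCComparison:
    """Result of comparing two ROC curves measured on the same subjects."""

    auc1: float
    auc2: float
    se1: float
    se2: float
    r: float
    z: float
    p: float
    method: str


def _placements(s: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values (V10 per positive, V01 per negative)."""
    pos = s[y == 1]
    neg = s[y == 0]
    neg_sorted = np.sort(neg)
    lo = np.searchsorted(neg_sorted, pos, side="left")
    hi = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / neg.size  # P(this positive > negative), ties half
    pos_sorted = np.sort(pos)
    lo = np.searchsorted(pos_sorted, neg, side="left")
    hi = np.searchsorted(pos_sorted, neg, side="right")
    v01 = (pos.size - hi + 0.5 * (hi - lo)) / pos.size  # P(positive > this negative)
    return v10, v01


def _binormal_orthant(a1: float, a2: float, corr: float) -> float:
    """P(Z1 < Phi^-1(a1), Z2 < Phi^-1(a2)) for standard bivariate normal."""
    mean = np.zeros(2)
    cov = np.array([[1.0, corr], [corr, 1.0]])
    return float(
        stats.multivariate_normal(mean=mean, cov=cov, allow_singular=True).cdf(
            np.array([ndtri(a1), ndtri(a2)])
        )
    )


def hm_intermediate_r(
    rho_avg: float, auc1: float, auc2: float, n_pos: int, n_neg: int
) -> float:
    """Correlation between two empirical AUCs under the binormal model.

    This evaluates, exactly, the quantity that the classical
    Hanley-McNeil look-up table tabulates on a coarse grid of (average
    within-class score correlation, average AUC): the correlation induced
    between the two Mann-Whitney AUC estimates when the paired scores are
    bivariate normal with within-class correlation ``rho_avg``.  The
    covariance decomposes over shared-subject pair terms, each a bivariate
    normal orthant probability.
    """
    a1 = min(max(auc1, 1e-9), 1 - 1e-9)
    a2 = min(max(auc2, 1e-9), 1 - 1e-9)
    q0 = _binormal_orthant(a1, a2, rho_avg)          # same pos, same neg
    q_sp = _binormal_orthant(a1, a2, rho_avg / 2.0)  # shared positive
    q_sn = _binormal_orthant(a1, a2, rho_avg / 2.0)  # shared negative
    a12 = a1 * a2
    cov = (
        (q0 - a12) + (n_neg - 1) * (q_sp - a12) + (n_pos - 1) * (q_sn - a12)
    ) / (n_pos * n_neg)
    se1 = hanley_mcneil_se(a1, n_pos, n_neg)
    se2 = hanley_mcneil_se(a2, n_pos, n_neg)
    if se1 == 0.0 or se2 == 0.0:
        return 0.0
    return float(np.clip(cov / (se1 * se2), -1.0, 1.0))


def compare_auc_correlated(
    scores1: Sequence[float],
    scores2: Sequence[float],
    labels: Sequence[int],
    method: str = "delong",
    direction: str = "low",
) -> AUCComparison:
    """Two-sided z-test for a difference between correlated AUCs.

    Both score vectors must be measured on the same subjects (equal
    length, shared labels).  ``method="delong"`` (default) estimates the
    full covariance of the two AUCs from placement values;
    ``method="hanley-mcneil"`` uses the Hanley-McNeil standard errors and
    the binormal intermediate correlation derived from the average of the
    within-class Pearson correlations between the two scores.
    """
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (s1.shape == s2.shape == y.shape):
        raise InputError("scores1, scores2 and labels must have equal lengths")
    n_pos, n_neg = _check_binary(y)
    if direction == "low":
        s1, s2 = -s1, -s2
    elif direction != "high":
        raise ConfigError(f"direction must be 'low' or 'high', got {direction!r}")

    a1 = _rank_auc(s1, y, n_pos, n_neg)
    a2 = _rank_auc(s2, y, n_pos, n_neg)

    if method == "delong":
        v10 = np.column_stack([_placements(s1, y)[0], _placements(s2, y)[0]])
        v01 = np.column_stack([_placements(s1, y)[1], _placements(s2, y)[1]])
        s10 = np.cov(v10, rowvar=False)
        s01 = np.cov(v01, rowvar=False)
        var1 = s10[0, 0] / n_pos + s01[0, 0] / n_neg
        var2 = s10[1, 1] / n_pos + s01[1, 1] / n_neg
        cov12 = s10[0, 1] / n_pos + s01[0, 1] / n_neg
        se1, se2 = float(np.sqrt(max(var1, 0.0))), float(np.sqrt(max(var2, 0.0)))
        r = float(cov12 / (se1 * se2)) if se1 > 0 and se2 > 0 else 0.0
        var_diff = var1 + var2 - 2.0 * cov12
    elif method == "hanley-mcneil":
        pos, neg = y == 1, y == 0
        rho_parts = []
        for sel in (pos, neg):
            if np.std(s1[sel]) > 0 and np.std(s2[sel]) > 0:
                rho_parts.append(float(np.corrcoef(s1[sel], s2[sel])[0, 1]))
        rho_avg = float(np.mean(rho_parts)) if rho_parts else 0.0
        se1 = hanley_mcneil_se(a1, n_pos, n_neg)
        se2 = hanley_mcneil_se(a2, n_pos, n_neg)
        r = hm_intermediate_r(rho_avg, a1, a2, n_pos, n_neg)
        var_diff = se1**2 + se2**2 - 2.0 * r * se1 * se2
    else:
        raise ConfigError(f"method must be 'delong' or 'hanley-mcneil', got {method!r}")

    diff = a1 - a2
    if var_diff <= 0.0:
        z = 0.0 if diff == 0.0 else np.sign(diff) * np.inf
    else:
        z = float(diff / np.sqrt(var_diff))
    p = float(2.0 * ndtr(-abs(z))) if np.isfinite(z) else 0.0
    return AUCComparison(
        auc1=a1, auc2=a2, se1=se1, se2=se2, r=np.clip(r, -1.0, 1.0), z=z, p=p, method=method
    )


# ---------------------------------------------------------------------------
# group comparison and reporting


@dataclass(frozen=True)
class GroupComparison:
    u_statistic: float
    p: float
    median_a: float
    p5_a: float
    p95_a: float
    median_b: float
    p5_b: float
    p95_b: float


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> GroupComparison:
    """Mann-Whitney U test with median (5th, 95th percentile) summaries.

    Exact null distribution when both groups are small and untied (SciPy's
    automatic policy), normal approximation with tie correction otherwise.
    Percentiles use linear interpolation between order statistics.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both groups need at least one non-missing value")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    pa = np.percentile(a, [5, 50, 95])
    pb = np.percentile(b, [5, 50, 95])
    return GroupComparison(
        u_statistic=float(res.statistic),
        p=float(min(res.pvalue, 1.0)),
        median_a=float(pa[1]), p5_a=float(pa[0]), p95_a=float(pa[2]),
        median_b=float(pb[1]), p5_b=float(pb[0]), p95_b=float(pb[2]),
    )


def _categorical_scores(cohort: pd.DataFrame, categories: CategoryConfig) -> pd.Series:
    if "neuropad_category" in cohort.columns and cohort["neuropad_category"].notna().all():
        cats = cohort["neuropad_category"]
    else:
        cats = cohort["neuropad_percent"].map(lambda v: categorize(float(v), categories))
    unknown = set(cats.unique()) - set(CATEGORY_ORDER)
    if unknown:
        raise InputError(f"unknown neuropad_category value(s): {sorted(unknown)}")
    return cats.map(CATEGORY_ORDER).astype(float)


def evaluate_performance(
    cohort: pd.DataFrame,
    registry: Mapping[str, ReferenceTest] | None = None,
    categories: CategoryConfig | None = None,
) -> pd.DataFrame:
    """Diagnostic-performance table: continuous vs categorical output.

    For each reference test in the registry: dichotomize the reference
    measure, run ROC analysis of the continuous percentage (AUC,
    Hanley-McNeil SE, Youden sensitivity/specificity and cut-off), ROC of
    the three-level categorical output treated as an ordinal score
    (abnormal < intermediate < normal), and a DeLong correlated-AUC
    p-value for continuous vs categorical.  Reference measures absent
    from the cohort are skipped with a log message; degenerate label sets
    produce a flagged row rather than an exception.
    """
    registry = registry or default_registry()
    categories = categories or CategoryConfig()
    if "neuropad_percent" not in cohort.columns:
        raise InputError("cohort is missing the mandatory column 'neuropad_percent'")
    cat_scores_all = _categorical_scores(cohort, categories)
    rows = []
    for name, test in registry.items():
        if name not in cohort.columns:
            logger.info("reference measure %s absent from cohort; skipped", name)
            continue
        usable = cohort[name].notna() & cohort["neuropad_percent"].notna()
        sub = cohort.loc[usable]
        labels = dichotomize(sub[name], test).to_numpy()
        row: dict[str, object] = {
            "reference_test": name,
            "threshold": test.threshold,
            "direction": test.direction,
            "n_used": int(usable.sum()),
            "n_abnormal": int(labels.sum()),
            "note": "",
        }
        try:
            roc_c = roc_curve(sub["neuropad_percent"].to_numpy(), labels, direction="low")
            cutoff, sens, spec = youden_cutoff(roc_c)
            row.update(
                auc_continuous=roc_c.auc, se_continuous=roc_c.se,
                sens_continuous=sens, spec_continuous=spec,
                optimal_cutoff_continuous=cutoff,
            )
        except DegenerateLabelsError as exc:
            row["note"] = f"continuous ROC degenerate: {exc}"
            rows.append(row)
            continue
        try:
            cat_scores = cat_scores_all.loc[usable].to_numpy()
            roc_k = roc_curve(cat_scores, labels, direction="low")
            _, sens_k, spec_k = youden_cutoff(roc_k)
            cmp_res = compare_auc_correlated(
                sub["neuropad_percent"].to_numpy(), cat_scores, labels,
                method="delong", direction="low",
            )
            row.update(
                auc_categorical=roc_k.auc, se_categorical=roc_k.se,
                sens_categorical=sens_k, spec_categorical=spec_k,
                p_auc_difference=cmp_res.p,
            )
        except DegenerateLabelsError as exc:  # pragma: no cover - guarded above
            row["note"] = f"categorical ROC degenerate: {exc}"
        except InputError as exc:
            row["note"] = f"categorical ROC unavailable: {exc}"
        if len(np.unique(_categorical_scores(sub, categories))) == 1:
            row["note"] = (row["note"] + "; " if row["note"] else "") + (
                "categorical output constant on this subset"
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# repeatability


@dataclass(frozen=True)
class RepeatabilityResult:
    """Agreement between two repeated quantifications of the same specimens.

    ``icc`` is the two-way random-effects, absolute-agreement, single
    measurement intraclass correlation ICC(2,1);
    ``bland_altman_coefficient`` is 1.96 * SD of the paired differences
    (the smallest difference expected to separate 95% of repeated pairs).
    ``zero_variance`` flags the degenerate all-identical case, where the
    ICC is returned as 1 by convention.
    """

    icc: float
    bland_altman_coefficient: float
    zero_variance: bool = False


def repeatability(
    run1: Sequence[float], run2: Sequence[float]
) -> RepeatabilityResult:
    """ICC(2,1) and Bland-Altman coefficient between two measurement runs."""
    x1 = np.asarray(run1, dtype=float)
    x2 = np.asarray(run2, dtype=float)
    if x1.shape != x2.shape:
        raise InputError("the two runs must have equal lengths")
    if x1.size < 2:
        raise InsufficientDataError("need >= 2 paired measurements")
    x = np.column_stack([x1, x2])
    n, k = x.shape
    diffs = x1 - x2
    ba = float(1.96 * diffs.std(ddof=1))
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    mse = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum() / (
        (n - 1) * (k - 1)
    )
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0.0 or np.isclose(denom, 0.0):
        # all measurements identical: perfect agreement by convention
        return RepeatabilityResult(icc=1.0, bland_altman_coefficient=ba, zero_variance=True)
    icc = float((msr - mse) / denom)
    return RepeatabilityResult(icc=icc, bland_altman_coefficient=ba)
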