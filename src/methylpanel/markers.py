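"""Per-marker inferential statistics and ROC analysis.

Case-vs-control comparisons are rank-based (Mann-Whitney U with a
Bonferroni correction over the nine markers; Kruskal-Wallis across the
control subtypes), and discrimination is summarized by the empirical ROC
curve with a trapezoidal AUC, a DeLong confidence interval and the
conventional qualitative discrimination bands (0.5-0.6 very poor up to
0.9-1.0 excellent).

Orientation is fixed throughout: a higher methylation ratio is more
case-like, and a sample is called positive when its score is >= the
threshold.  Candidate thresholds are the midpoints between consecutive
distinct scores, plus sentinels beyond the extremes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

N_MARKERS_TESTED = 9

#: Qualitative discrimination bands, left-closed ([0.9, 1.0] closed).
DISCRIMINATION_BANDS = (
    (0.6, "very poor"),
    (0.7, "poor"),
    (0.8, "fair"),
    (0.9, "good"),
    (np.inf, "excellent"),
)


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve over midpoint candidate thresholds.

    ``thresholds`` descend from +inf to -inf; ``fpr``/``tpr`` are
    non-decreasing and run from (0, 0) to (1, 1), one vertex per distinct
    score (ties grouped).
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def _as_case_control(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not labels.any() or labels.all():
        raise ValueError("need both cases and controls")
    return scores[labels], scores[~labels]


def candidate_thresholds(scores) -> np.ndarray:
    """Midpoints between consecutive distinct scores, bracketed by finite
    sentinels one unit beyond the extremes.  With the >= positivity rule
    these cuts realize every achievable operating point."""
    distinct = np.unique(np.asarray(scores, dtype=float))
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])


def empirical_roc(scores, labels) -> RocCurve:
    """ROC curve of case/control scores (higher score = more case-like).

    ``labels`` is boolean (True = case).  Raises on single-class input.
    """
    cases, controls = _as_case_control(scores, labels)
    cuts = candidate_thresholds(np.concatenate([cases, controls]))
    # descending cuts, +inf sentinel first => curve starts at (0,0)
    cuts = np.concatenate([[np.inf], cuts[::-1], [-np.inf]])
    cases_sorted = np.sort(cases)
    controls_sorted = np.sort(controls)
    tpr = 1.0 - np.searchsorted(cases_sorted, cuts, side="left") / cases.size
    fpr = 1.0 - np.searchsorted(controls_sorted, cuts, side="left") / controls.size
    return RocCurve(thresholds=cuts, fpr=fpr, tpr=tpr)


def auc_mann_whitney(scores, labels) -> float:
    """Tie-adjusted U-statistic AUC: P(case > control) + 0.5 P(tie).

    Rank-based; numerically identical to the trapezoidal area under
    :func:`empirical_roc` (a tested invariant).
    """
    cases, controls = _as_case_control(scores, labels)
    n1, n2 = cases.size, controls.size
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def auc_band(auc: float) -> str:
    """Qualitative discrimination label for an AUC (left-closed bands;
    0.90 is already 'excellent')."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    for upper, label in DISCRIMINATION_BANDS:
        if auc < upper:
            return label
    return "excellent"


def auc_with_band(curve: RocCurve) -> tuple[float, str]:
    auc = curve.auc()
    return auc, auc_band(auc)


def delong_auc_variance(scores, labels) -> tuple[float, float]:
    """DeLong's (1988) nonparametric AUC estimate and sampling variance.

    Uses mid-rank placements: for each case the fraction of controls it
    beats (ties count one half), and vice versa; the variance combines the
    two placement variances scaled by the group sizes.
    """
    cases, controls = _as_case_control(scores, labels)
    m, n = cases.size, controls.size
    if m < 2 or n < 2:
        raise ValueError("DeLong variance needs >= 2 cases and >= 2 controls")
    psi = (cases[:, None] > controls[None, :]).astype(float)
    psi += 0.5 * (cases[:, None] == controls[None, :])
    v10 = psi.mean(axis=1)  # per-case placement
    v01 = 1.0 - psi.mean(axis=0)  # per-control placement of the complement
    theta = float(v10.mean())
    var = v10.var(ddof=1) / m + (1.0 - v01).var(ddof=1) / n
    return theta, float(var)


def auc_ci(scores, labels, alpha: float = 0.05) -> tuple[float, float]:
    """Two-sided DeLong confidence interval for the AUC, truncated to [0, 1].

    Degenerate perfect (or null) separation has zero DeLong variance; the
    point interval is returned with a warning.
    """
    theta, var = delong_auc_variance(scores, labels)
    if var <= 0.0:
        warnings.warn(
            "degenerate AUC (zero DeLong variance); returning point interval",
            stacklevel=2,
        )
        return theta, theta
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(var)
    return float(max(0.0, theta - half)), float(min(1.0, theta + half))


def mann_whitney_marker(
    case_ratios, control_ratios, n_markers: int = N_MARKERS_TESTED
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U p-value with Bonferroni adjustment.

    Exact enumeration when both groups have <= 8 observations and no ties;
    otherwise the tie- and continuity-corrected normal approximation.
    Returns ``(p_raw, min(1, n_markers * p_raw))``.
    """
    cases = np.asarray(case_ratios, dtype=float)
    controls = np.asarray(control_ratios, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both groups must be non-empty")
    method = (
        "exact"
        if cases.size <= 8
        and controls.size <= 8
        and np.unique(np.concatenate([cases, controls])).size == cases.size + controls.size
        else "asymptotic"
    )
    p_raw = float(
        stats.mannwhitneyu(cases, controls, alternative="two-sided", method=method).pvalue
    )
    return p_raw, min(1.0, n_markers * p_raw)


def kruskal_wallis_controls(groups: Sequence[Sequence[float]]) -> float:
    """Tie-corrected Kruskal-Wallis p-value across control subtypes
    (chi-squared reference with k-1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty subgroups")
    return float(stats.kruskal(*groups).pvalue)


@dataclass(frozen=True)
class MarkerResult:
    """Per-marker discrimination summary on valid samples."""

    marker: str
    auc: float
    auc_ci: tuple[float, float]
    discrimination_band: str
    p_raw: float
    p_adjusted: float
    n_cases_valid: int
    n_controls_valid: int


def evaluate_marker(
    marker: str, case_ratios, control_ratios, alpha: float = 0.05,
    n_markers: int = N_MARKERS_TESTED,
) -> MarkerResult:
    """Full single-marker evaluation: rank test plus ROC/AUC with CI."""
    cases = np.asarray(case_ratios, dtype=float)
    controls = np.asarray(control_ratios, dtype=float)
    p_raw, p_adj = mann_whitney_marker(cases, controls, n_markers=n_markers)
    scores = np.concatenate([cases, controls])
    labels = np.concatenate([np.ones(cases.size, bool), np.zeros(controls.size, bool)])
    auc, band = auc_with_band(empirical_roc(scores, labels))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ci = auc_ci(scores, labels, alpha=alpha)
    return MarkerResult(
        marker=marker,
        auc=auc,
        auc_ci=ci,
        discrimination_band=band,
        p_raw=p_raw,
        p_adjusted=p_adj,
        n_cases_valid=int(cases.size),
        n_controls_valid=int(controls.size),
    )


def marker_results_frame(results: Sequence[MarkerResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker": [r.marker for r in results],
            "auc": [r.auc for r in results],
            "auc_ci_lower": [r.auc_ci[0] for r in results],
            "auc_ci_upper": [r.auc_ci[1] for r in results],
            "discrimination": [r.discrimination_band for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "n_cases_valid": [r.n_cases_valid for r in results],
            "n_controls_valid": [r.n_controls_valid for r in results],
        }
    )
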