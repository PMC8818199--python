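"""Youden-thresholded believe-the-positive marker panel.

The diagnostic panel (by default *GHSR*/*MAL*) derives one Youden-optimal
cut per marker on the Ct-ratio scale and calls a sample positive if at
least one panel marker is at or above its cut ("believe-the-positive").
This OR rule trades specificity for sensitivity by construction: the
panel is at least as sensitive and at most as specific as each member
marker.

When a panel marker's multiplex failed ACTB QC the marker cannot vote; a
sample is indeterminate only if no *valid* marker is positive and at
least one marker is invalid (a single valid positive marker already
settles the OR).  Indeterminate samples are excluded from performance
denominators and counted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .markers import auc_ci, auc_mann_whitney, candidate_thresholds
from .qmsp import LOG2_EPSILON, MethylationProfile

DEFAULT_PANEL = ("GHSR", "MAL")

POSITIVE = "positive"
NEGATIVE = "negative"
INDETERMINATE = "indeterminate"


@dataclass
class PanelModel:
    """Per-marker ratio-scale thresholds combined with the fixed OR rule."""

    markers: tuple[str, ...] = DEFAULT_PANEL
    thresholds: dict[str, float] = field(default_factory=dict)
    #: cohort or stratum the thresholds were derived on (e.g. "all", "male")
    derivation_stratum: str = "all"

    def __post_init__(self) -> None:
        for marker, thr in self.thresholds.items():
            if not math.isfinite(thr):
                raise ValueError(f"threshold for {marker} must be finite")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "markers": list(self.markers),
            "thresholds": self.thresholds,
            "thresholds_log2": {
                m: math.log2(t + LOG2_EPSILON) for m, t in self.thresholds.items()
            },
            "combination_rule": "believe-the-positive (OR)",
            "derivation_stratum": self.derivation_stratum,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PanelModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            markers=tuple(payload["markers"]),
            thresholds=dict(payload["thresholds"]),
            derivation_stratum=payload.get("derivation_stratum", "all"),
        )


@dataclass(frozen=True)
class PerformanceEstimate:
    """Sensitivity/specificity with exact binomial CIs and raw counts."""

    sensitivity: float
    specificity: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    tp: int
    fn: int
    tn: int
    fp: int
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    n_indeterminate: int = 0


def youden_threshold(scores, labels) -> float:
    """Cut maximizing Youden's J = sensitivity + specificity - 1.

    Positive call is score >= threshold.  Candidates are the midpoints
    between consecutive distinct scores plus finite sentinels beyond the
    extremes.  Ties in J are broken toward the highest specificity, then
    the larger threshold (both favour fewer false positives, i.e. fewer
    unnecessary confirmatory cystoscopies).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not labels.any() or labels.all():
        raise ValueError("need both cases and controls")
    cases = np.sort(scores[labels])
    controls = np.sort(scores[~labels])
    cuts = candidate_thresholds(scores)
    sens = 1.0 - np.searchsorted(cases, cuts, side="left") / cases.size
    spec = np.searchsorted(controls, cuts, side="left") / controls.size
    j = sens + spec - 1.0
    # lexicographic argmax over (J, specificity, threshold)
    order = np.lexsort((cuts, spec, j))
    return float(cuts[order[-1]])


def fit_panel(
    profiles: Sequence[MethylationProfile],
    labels: Mapping[str, bool],
    markers: Iterable[str] = DEFAULT_PANEL,
    stratum: str = "all",
) -> PanelModel:
    """Derive per-marker Youden thresholds on the valid samples of each
    marker's multiplex.  ``labels`` maps sample_id -> is_case."""
    markers = tuple(markers)
    thresholds: dict[str, float] = {}
    for marker in markers:
        scores, lab = [], []
        for prof in profiles:
            if prof.sample_id in labels and prof.is_valid(marker):
                scores.append(prof.ratio(marker))
                lab.append(labels[prof.sample_id])
        if not scores:
            raise ValueError(f"no valid observations for marker {marker}")
        thresholds[marker] = youden_threshold(scores, lab)
    return PanelModel(markers=markers, thresholds=thresholds, derivation_stratum=stratum)


def classify(profile: MethylationProfile, model: PanelModel) -> str:
    """Believe-the-positive panel call.

    Positive if any valid panel marker is at or above its threshold
    (boundary counts positive); negative if all panel markers are valid
    and none is positive; otherwise indeterminate.
    """
    any_invalid = False
    for marker in model.markers:
        if profile.is_valid(marker):
            if profile.ratio(marker) >= model.thresholds[marker]:
                return POSITIVE
        else:
            any_invalid = True
    return INDETERMINATE if any_invalid else NEGATIVE


def panel_score(
    profile: MethylationProfile, model: PanelModel, epsilon: float = LOG2_EPSILON
) -> float | None:
    """Continuous panel score: max over valid panel markers of the log2
    margin above threshold.  Score >= 0 iff the OR rule calls positive, so
    the score's ROC passes through the panel's operating point.  ``None``
    when no panel marker is valid.
    """
    margins = [
        math.log2(profile.ratio(marker) + epsilon)
        - math.log2(model.thresholds[marker] + epsilon)
        for marker in model.markers
        if profile.is_valid(marker)
    ]
    return max(margins) if margins else None


def _binom_ci(x: int, n: int, alpha: float) -> tuple[float, float]:
    lo, hi = proportion_confint(x, n, alpha=alpha, method="beta")
    return (float(np.nan_to_num(lo, nan=0.0)), float(np.nan_to_num(hi, nan=1.0)))


def performance(
    calls: Sequence[str],
    labels: Sequence[bool],
    alpha: float = 0.05,
    scores: Sequence[float | None] | None = None,
) -> PerformanceEstimate:
    """Diagnostic performance of panel calls against case/control labels.

    Indeterminate calls are excluded from the denominators (their count is
    reported).  CIs are exact Clopper-Pearson intervals.  When continuous
    ``scores`` are supplied, the panel AUC and its DeLong CI are computed
    over the non-missing scores.
    """
    calls = list(calls)
    labels = [bool(l) for l in labels]
    if len(calls) != len(labels):
        raise ValueError("calls and labels must align")
    det = [(c, l) for c, l in zip(calls, labels) if c != INDETERMINATE]
    n_ind = len(calls) - len(det)
    tp = sum(1 for c, l in det if l and c == POSITIVE)
    fn = sum(1 for c, l in det if l and c == NEGATIVE)
    tn = sum(1 for c, l in det if not l and c == NEGATIVE)
    fp = sum(1 for c, l in det if not l and c == POSITIVE)
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("need >= 1 determinate case and control")
    auc = ci = None
    if scores is not None:
        pairs = [(s, l) for s, l in zip(scores, labels) if s is not None]
        if pairs:
            s_arr = np.array([p[0] for p in pairs])
            l_arr = np.array([p[1] for p in pairs])
            if l_arr.any() and not l_arr.all():
                auc = auc_mann_whitney(s_arr, l_arr)
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ci = auc_ci(s_arr, l_arr, alpha=alpha)
    return PerformanceEstimate(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        sensitivity_ci=_binom_ci(tp, tp + fn, alpha),
        specificity_ci=_binom_ci(tn, tn + fp, alpha),
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        auc=auc,
        auc_ci=ci,
        n_indeterminate=n_ind,
    )
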