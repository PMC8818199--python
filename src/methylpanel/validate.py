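"""Cross-validation and subgroup analyses for the marker panel.

Leave-one-out cross-validation re-derives the per-marker Youden
thresholds on every fold (all samples but one) and classifies the
held-out sample with the fold's model, so each call is honestly
out-of-sample; resubstitution ("preclinical") performance on the full
derivation cohort is optimistically biased relative to it.

Subgroup sensitivity is evaluated with the pooled-cohort thresholds
across the clinically dichotomized partitions (WHO-1973 G3 vs G1-G2,
WHO-2004 HG vs LG, stage >= T2 vs Ta/T1/Tis, primary vs recurrent,
male vs female), each contrast tested with a Pearson chi-square without
continuity correction.  The gender post hoc analysis instead splits the
cohort and re-derives thresholds, performance and LOOCV entirely within
each gender stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import (
    DEFAULT_PANEL,
    INDETERMINATE,
    PanelModel,
    PerformanceEstimate,
    classify,
    fit_panel,
    panel_score,
    performance,
    _binom_ci,
)
from .qmsp import MethylationProfile

logger = logging.getLogger(__name__)

#: Dichotomized case partitions: name -> (column, stratum A, strata B).
SUBGROUP_PARTITIONS: dict[str, tuple[str, tuple[str, ...], tuple[str, ...]]] = {
    "grade_1973": ("grade_1973", ("G3",), ("G1", "G2")),
    "grade_2004": ("grade_2004", ("HG",), ("LG",)),
    "stage": ("stage", ("T2plus",), ("Ta", "T1", "Tis")),
    "status": ("status", ("primary",), ("recurrent",)),
    "gender": ("gender", ("male",), ("female",)),
}


@dataclass
class LoocvResult:
    """Out-of-fold panel calls, scores and aggregated performance."""

    calls: dict[str, str]
    scores: dict[str, float | None]
    performance: PerformanceEstimate
    n_folds: int


@dataclass
class SubgroupRow:
    partition: str
    stratum: str
    n: int
    n_positive: int
    sensitivity: float
    sensitivity_ci: tuple[float, float]


@dataclass
class SubgroupTable:
    rows: list[SubgroupRow] = field(default_factory=list)
    #: partition -> (chi-square statistic, p) for the dichotomized contrast
    contrasts: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "partition": [r.partition for r in self.rows],
                "stratum": [r.stratum for r in self.rows],
                "n": [r.n for r in self.rows],
                "n_positive": [r.n_positive for r in self.rows],
                "sensitivity": [r.sensitivity for r in self.rows],
                "ci_lower": [r.sensitivity_ci[0] for r in self.rows],
                "ci_upper": [r.sensitivity_ci[1] for r in self.rows],
                "p_contrast": [self.contrasts.get(r.partition, (np.nan, np.nan))[1] for r in self.rows],
            }
        )


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    Requires all expected counts positive (zero marginals error out).
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in 2x2 table")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if (expected <= 0).any():
        raise ValueError("expected counts must be positive")
    return float(chi2), float(p)


def _case_labels(clinical: pd.DataFrame) -> dict[str, bool]:
    return dict(zip(clinical["sample_id"], clinical["group"] == "case"))


def loocv_panel(
    profiles: Sequence[MethylationProfile],
    clinical: pd.DataFrame,
    markers: Iterable[str] = DEFAULT_PANEL,
    alpha: float = 0.05,
) -> LoocvResult:
    """Leave-one-out cross-validation with per-fold threshold re-estimation.

    Each sample is classified (and scored) by a panel whose Youden
    thresholds were derived on all other samples; its own label never
    enters its fold's model.  Aggregates sensitivity/specificity with
    exact CIs and the AUC of the out-of-fold scores.
    """
    markers = tuple(markers)
    labels = _case_labels(clinical)
    eligible = [p for p in profiles if p.sample_id in labels]
    n_cases = sum(labels[p.sample_id] for p in eligible)
    if n_cases < 2 or len(eligible) - n_cases < 2:
        raise ValueError("LOOCV needs >= 2 cases and >= 2 controls")
    calls: dict[str, str] = {}
    scores: dict[str, float | None] = {}
    for i, prof in enumerate(eligible):
        train = eligible[:i] + eligible[i + 1 :]
        train_labels = {p.sample_id: labels[p.sample_id] for p in train}
        model = fit_panel(train, train_labels, markers, stratum="loocv-fold")
        calls[prof.sample_id] = classify(prof, model)
        scores[prof.sample_id] = panel_score(prof, model)
    ordered = [p.sample_id for p in eligible]
    perf = performance(
        [calls[s] for s in ordered],
        [labels[s] for s in ordered],
        alpha=alpha,
        scores=[scores[s] for s in ordered],
    )
    n_folds = sum(1 for s in ordered if calls[s] != INDETERMINATE)
    return LoocvResult(calls=calls, scores=scores, performance=perf, n_folds=n_folds)


def subgroup_sensitivity(
    calls: Mapping[str, str],
    clinical: pd.DataFrame,
    partitions: Mapping[str, tuple[str, tuple[str, ...], tuple[str, ...]]] | None = None,
    alpha: float = 0.05,
) -> SubgroupTable:
    """Panel sensitivity per case subgroup, with a chi-square contrast per
    dichotomized partition.

    ``calls`` are panel calls made with pooled-cohort thresholds.  Cases
    with indeterminate calls are excluded; empty strata are dropped with a
    warning.  Contrast p-values are reported unadjusted.
    """
    partitions = dict(partitions or SUBGROUP_PARTITIONS)
    cases = clinical[clinical["group"] == "case"]
    table = SubgroupTable()
    for name, (column, strata_a, strata_b) in partitions.items():
        counts = {}
        for label, strata in (("A", strata_a), ("B", strata_b)):
            members = cases[cases[column].isin(strata)]
            det = [
                calls[s]
                for s in members["sample_id"]
                if calls.get(s, INDETERMINATE) != INDETERMINATE
            ]
            n, pos = len(det), sum(c == "positive" for c in det)
            counts[label] = (pos, n - pos)
            stratum_name = "/".join(strata)
            if n == 0:
                logger.warning("partition %s: empty stratum %s dropped", name, stratum_name)
                continue
            table.rows.append(
                SubgroupRow(
                    partition=name,
                    stratum=stratum_name,
                    n=n,
                    n_positive=pos,
                    sensitivity=pos / n,
                    sensitivity_ci=_binom_ci(pos, n, alpha),
                )
            )
        contingency = np.array([counts["A"], counts["B"]])
        if (contingency.sum(axis=1) > 0).all():
            if (contingency.sum(axis=0) == 0).any():
                # all calls agree in both strata: no association, p = 1
                table.contrasts[name] = (0.0, 1.0)
            else:
                table.contrasts[name] = chi_square_2x2(contingency)
    return table


def gender_stratified_eval(
    profiles: Sequence[MethylationProfile],
    clinical: pd.DataFrame,
    markers: Iterable[str] = DEFAULT_PANEL,
    alpha: float = 0.05,
    run_loocv: bool = True,
) -> dict[str, dict]:
    """Post hoc per-gender evaluation with stratum-specific thresholds.

    The cohort is split by gender and, within each stratum, thresholds are
    re-derived with Youden's J, resubstitution performance is computed,
    and (optionally) LOOCV is run — nothing is shared across strata.
    """
    markers = tuple(markers)
    out: dict[str, dict] = {}
    for gender in ("male", "female"):
        sub = clinical[clinical["gender"] == gender]
        labels = _case_labels(sub)
        strat_profiles = [p for p in profiles if p.sample_id in labels]
        values = set(labels.values())
        if values != {True, False}:
            raise ValueError(f"gender stratum {gender!r} lacks cases or controls")
        model = fit_panel(strat_profiles, labels, markers, stratum=gender)
        calls = [classify(p, model) for p in strat_profiles]
        scores = [panel_score(p, model) for p in strat_profiles]
        labs = [labels[p.sample_id] for p in strat_profiles]
        perf = performance(calls, labs, alpha=alpha, scores=scores)
        entry = {"model": model, "performance": perf}
        if run_loocv:
            entry["loocv"] = loocv_panel(strat_profiles, sub, markers, alpha=alpha)
        out[gender] = entry
    return out


def resubstitution_performance(
    profiles: Sequence[MethylationProfile],
    clinical: pd.DataFrame,
    markers: Iterable[str] = DEFAULT_PANEL,
    alpha: float = 0.05,
) -> tuple[PanelModel, PerformanceEstimate]:
    """Fit thresholds on the whole cohort and evaluate on the same cohort
    (the "preclinical validation" column: optimistic by construction)."""
    labels = _case_labels(clinical)
    eligible = [p for p in profiles if p.sample_id in labels]
    model = fit_panel(eligible, labels, markers, stratum="all")
    calls = [classify(p, model) for p in eligible]
    scores = [panel_score(p, model) for p in eligible]
    labs = [labels[p.sample_id] for p in eligible]
    return model, performance(calls, labs, alpha=alpha, scores=scores)
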