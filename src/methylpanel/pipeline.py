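"""End-to-end orchestration: read or simulate, QC, evaluate, report.

``run_full_analysis`` chains every stage — Ct normalization and ACTB QC,
per-marker rank tests and ROC analysis, Youden threshold derivation, the
believe-the-positive panel's resubstitution ("preclinical") performance,
LOOCV, subgroup sensitivities, the optional gender post hoc analysis and
the sample-size design summary — into one JSON-serializable report.
All randomness flows from the single configured seed, so a rerun with
the same inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import design as design_mod
from . import markers as markers_mod
from .panel import DEFAULT_PANEL, PerformanceEstimate
from .qmsp import (
    MARKERS,
    build_profiles,
    qc_summary,
    read_clinical_table,
    read_ct_table,
    validate_clinical,
    write_ct_table,
)
from .simulate import CohortConfig, simulate_cohort
from .validate import (
    gender_stratified_eval,
    loocv_panel,
    resubstitution_performance,
    subgroup_sensitivity,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"


@dataclass
class RunConfig:
    """One analysis run: real input files or a simulation config."""

    ct_table: str | Path | None = None
    clinical_table: str | Path | None = None
    simulation: CohortConfig | None = None
    panel_markers: tuple[str, ...] = DEFAULT_PANEL
    alpha: float = 0.05
    run_loocv: bool = True
    run_subgroups: bool = True
    stratify_gender: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.ct_table is not None and self.clinical_table is not None
        if has_files == (self.simulation is not None):
            raise ValueError(
                "provide either both input files or a simulation config, not both"
            )


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Display rounding with ties away from zero (0.795 -> 0.80)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _perf_dict(perf: PerformanceEstimate) -> dict:
    return {
        "sensitivity": perf.sensitivity,
        "sensitivity_display": round_half_up(perf.sensitivity, 2),
        "sensitivity_ci": list(perf.sensitivity_ci),
        "specificity": perf.specificity,
        "specificity_display": round_half_up(perf.specificity, 2),
        "specificity_ci": list(perf.specificity_ci),
        "counts": {"tp": perf.tp, "fn": perf.fn, "tn": perf.tn, "fp": perf.fp},
        "auc": perf.auc,
        "auc_ci": list(perf.auc_ci) if perf.auc_ci else None,
        "n_indeterminate": perf.n_indeterminate,
    }


def _stage(name: str):
    """Re-raise stage errors with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


class PipelineError(RuntimeError):
    pass


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline and return the report dictionary."""
    report: dict = {"schema_version": SCHEMA_VERSION, "seed": config.seed}

    with _stage("input"):
        if config.simulation is not None:
            sim = config.simulation
            records, clinical = simulate_cohort(sim)
            report["input"] = {"source": "simulated", "seed": sim.seed}
        else:
            records = read_ct_table(config.ct_table)
            clinical = read_clinical_table(config.clinical_table)
            report["input"] = {
                "source": "files",
                "ct_table": str(config.ct_table),
                "clinical_table": str(config.clinical_table),
            }
        clinical = validate_clinical(clinical)

    with _stage("qc_normalize"):
        profiles = build_profiles(records)
        qc = qc_summary(profiles)
        report["qc"] = {
            "n_samples": qc.n_samples,
            "n_flagged": qc.n_flagged,
            "flagged_percent": qc.flagged_percent,
        }
        logger.info(
            "QC: %d/%d samples with >= 1 invalid multiplex (%.1f%%)",
            qc.n_flagged,
            qc.n_samples,
            qc.flagged_percent,
        )

    labels = dict(zip(clinical["sample_id"], clinical["group"] == "case"))

    with _stage("marker_eval"):
        marker_results = []
        for marker in MARKERS:
            cases, controls = [], []
            for prof in profiles:
                if prof.is_valid(marker) and prof.sample_id in labels:
                    (cases if labels[prof.sample_id] else controls).append(
                        prof.ratio(marker)
                    )
            marker_results.append(
                markers_mod.evaluate_marker(marker, cases, controls, alpha=config.alpha)
            )
        report["markers"] = [
            {
                "marker": r.marker,
                "auc": r.auc,
                "auc_ci": list(r.auc_ci),
                "discrimination": r.discrimination_band,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "n_cases_valid": r.n_cases_valid,
                "n_controls_valid": r.n_controls_valid,
            }
            for r in marker_results
        ]

    with _stage("control_subtypes"):
        controls_df = clinical[clinical["group"] == "control"]
        subtype_p = {}
        by_sample = {p.sample_id: p for p in profiles}
        for marker in MARKERS:
            groups = []
            for _, sub in controls_df.groupby("control_subtype"):
                vals = [
                    by_sample[s].ratio(marker)
                    for s in sub["sample_id"]
                    if s in by_sample and by_sample[s].is_valid(marker)
                ]
                groups.append(vals)
            if sum(len(g) > 0 for g in groups) >= 2:
                subtype_p[marker] = markers_mod.kruskal_wallis_controls(groups)
        report["control_subtype_kruskal_wallis"] = subtype_p

    with _stage("panel"):
        model, preclinical = resubstitution_performance(
            profiles, clinical, config.panel_markers, alpha=config.alpha
        )
        report["panel"] = {
            "markers": list(model.markers),
            "thresholds": model.thresholds,
            "preclinical": _perf_dict(preclinical),
        }

    if config.run_loocv:
        with _stage("loocv"):
            loocv = loocv_panel(
                profiles, clinical, config.panel_markers, alpha=config.alpha
            )
            report["panel"]["loocv"] = _perf_dict(loocv.performance)
            report["panel"]["loocv"]["n_folds"] = loocv.n_folds

    if config.run_subgroups:
        with _stage("subgroups"):
            from .panel import classify

            calls = {p.sample_id: classify(p, model) for p in profiles}
            table = subgroup_sensitivity(calls, clinical, alpha=config.alpha)
            report["subgroups"] = {
                "rows": table.to_frame().to_dict(orient="records"),
                "contrasts": {
                    k: {"chi2": v[0], "p": v[1]} for k, v in table.contrasts.items()
                },
            }
    else:
        report["subgroups"] = None

    if config.stratify_gender:
        with _stage("gender_post_hoc"):
            strata = gender_stratified_eval(
                profiles,
                clinical,
                config.panel_markers,
                alpha=config.alpha,
                run_loocv=config.run_loocv,
            )
            report["gender"] = {}
            for gender, entry in strata.items():
                block = {
                    "thresholds": entry["model"].thresholds,
                    "preclinical": _perf_dict(entry["performance"]),
                }
                if "loocv" in entry:
                    block["loocv"] = _perf_dict(entry["loocv"].performance)
                report["gender"][gender] = block
    else:
        report["gender"] = None

    with _stage("design"):
        report["design"] = design_mod.design_summary(design_mod.DesignSpec())

    return report


def write_report(report: dict, outdir: str | Path, formats: Sequence[str] = ("json", "csv")) -> list[Path]:
    """Write the report as JSON and/or a CSV bundle (one file per table)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "json" in formats:
        path = outdir / "report.json"
        path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        written.append(path)
    if "csv" in formats:
        if report.get("markers"):
            path = outdir / "markers.csv"
            pd.DataFrame(report["markers"]).to_csv(path, index=False, float_format="%.17g")
            written.append(path)
        if report.get("subgroups"):
            path = outdir / "subgroups.csv"
            pd.DataFrame(report["subgroups"]["rows"]).to_csv(path, index=False, float_format="%.17g")
            written.append(path)
        perf_rows = []
        for stratum_key, stratum in (("all", report.get("panel")),):
            if not stratum:
                continue
            for phase in ("preclinical", "loocv"):
                if phase in stratum:
                    perf_rows.append({"stratum": "all", "phase": phase, **_flatten(stratum[phase])})
        if report.get("gender"):
            for gender, block in report["gender"].items():
                for phase in ("preclinical", "loocv"):
                    if phase in block:
                        perf_rows.append(
                            {"stratum": gender, "phase": phase, **_flatten(block[phase])}
                        )
        if perf_rows:
            path = outdir / "performance.csv"
            pd.DataFrame(perf_rows).to_csv(path, index=False, float_format="%.17g")
            written.append(path)
    return written


def _flatten(perf: dict) -> dict:
    out = {}
    for k, v in perf.items():
        if isinstance(v, dict):
            out.update({f"{k}_{kk}": vv for kk, vv in v.items()})
        elif isinstance(v, list):
            out[f"{k}_lower"], out[f"{k}_upper"] = v
        else:
            out[k] = v
    return out


def simulate_to_files(
    config: CohortConfig, ct_path: str | Path, clinical_path: str | Path
) -> None:
    """Simulate a cohort and write the Ct table and clinical CSVs (the
    simulator's seed is recorded in a header comment)."""
    records, clinical = simulate_cohort(config)
    write_ct_table(records, ct_path, header_comment=f"seed={config.seed}")
    with open(clinical_path, "w") as fh:
        fh.write(f"# seed={config.seed}\n")
        clinical.to_csv(fh, index=False)
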