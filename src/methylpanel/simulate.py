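"""Synthetic qMSP cohort generator.

The study's patient-level data are not publicly deposited, so every
downstream stage is exercised against simulated cohorts that share the
statistical structure the analysis assumes:

* a case/control cohort whose covariate composition matches the published
  baseline table (108 bladder-cancer cases / 100 matched controls by
  default), filled by exact quota rather than i.i.d. draws so the default
  cohort reproduces the published counts exactly;
* per-marker log2 Ct ratios that are Gaussian within group, with the case
  shift scaled by a shared lognormal tumour-burden factor (inducing
  positive inter-marker correlation) and multiplied up or down for
  high-grade, muscle-invasive, recurrent and female cases — female
  dilution reflects abundant unmethylated DNA of gynaecological origin in
  female urine;
* a three-multiplex assay layout with a per-multiplex ACTB reference Ct
  and sporadic ACTB failures (Ct > 32) that invalidate whole multiplexes.

Target Ct values are back-computed as ``actb_ct - log2(ratio/100)`` so
that comparative-Ct normalization exactly inverts generation; the full
pipeline is therefore round-trip testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .qmsp import (
    CtRecord,
    MARKERS,
    MARKER_TO_MULTIPLEX,
    MULTIPLEX_MAP,
    REFERENCE_GENE,
)

__all__ = [
    "CohortConfig",
    "default_config_table1",
    "simulate_cohort",
    "inject_qc_failures",
    "largest_remainder_counts",
]


def _default_delta() -> dict[str, float]:
    # Case shifts in within-group SD units; strongest for the panel markers
    # and ZIC1, consistent with the published per-marker discrimination
    # ordering (good-to-excellent AUCs).
    return {
        "GHSR": 2.0,
        "MAL": 1.6,
        "ZIC1": 1.9,
        "SST": 1.7,
        "FAM19A4": 1.6,
        "miR-129": 1.6,
        "PHACTR3": 1.5,
        "PRDM14": 1.4,
        "miR-935": 1.3,
    }


def _default_mu0() -> dict[str, float]:
    # Control-group mean log2 Ct ratio; ~2^-6*100 = 1.6% methylation signal
    # relative to ACTB, a typical background for tumour-marker qMSP in urine.
    return {m: -6.0 for m in MARKERS}


@dataclass
class CohortConfig:
    """Generative parameters for a synthetic qMSP case/control cohort.

    Defaults emulate the published study population: 108 cases / 100
    controls, published covariate composition, ~3% sporadic ACTB failures
    per multiplex, and covariate-dependent effect sizes (high grade and
    stage amplify the methylation shift, recurrence and female gender
    attenuate it).
    """

    n_cases: int = 108
    n_controls: int = 100
    # covariate composition (category -> frequency, each summing to 1)
    gender_cases: dict[str, float] = field(
        default_factory=lambda: {"male": 0.73, "female": 0.27}
    )
    gender_controls: dict[str, float] = field(
        default_factory=lambda: {"male": 0.63, "female": 0.37}
    )
    grade_1973: dict[str, float] = field(
        default_factory=lambda: {"G1": 0.16, "G2": 0.36, "G3": 0.48}
    )
    grade_2004: dict[str, float] = field(
        default_factory=lambda: {"LG": 0.42, "HG": 0.58}
    )
    stage: dict[str, float] = field(
        default_factory=lambda: {"Ta": 0.55, "T1": 0.15, "Tis": 0.09, "T2plus": 0.21}
    )
    status: dict[str, float] = field(
        default_factory=lambda: {"primary": 0.70, "recurrent": 0.30}
    )
    control_subtype: dict[str, float] = field(
        default_factory=lambda: {"haematuria": 0.34, "other_benign": 0.43, "healthy": 0.23}
    )
    # marker model
    mu0: dict[str, float] = field(default_factory=_default_mu0)
    sigma: float = 2.0
    delta: dict[str, float] = field(default_factory=_default_delta)
    grade_multiplier: float = 1.5
    stage_multiplier: float = 1.3
    recurrence_multiplier: float = 0.6
    female_dilution: float = 0.6
    burden_sd: float = 0.5
    # reference-gene model
    actb_mean: float = 26.0
    actb_sd: float = 1.5
    actb_failure_rate: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        for name in ("gender_cases", "gender_controls", "grade_1973",
                     "grade_2004", "stage", "status", "control_subtype"):
            comp: Mapping[str, float] = getattr(self, name)
            if any(v < 0 for v in comp.values()):
                raise ValueError(f"{name}: negative frequency")
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name}: frequencies must sum to 1")
        if not 0.0 <= self.actb_failure_rate <= 1.0:
            raise ValueError("actb_failure_rate must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.burden_sd < 0:
            raise ValueError("burden_sd must be non-negative")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if set(self.delta) != set(MARKERS) or set(self.mu0) != set(MARKERS):
            raise ValueError("delta and mu0 must cover exactly the nine markers")


def default_config_table1(**overrides) -> CohortConfig:
    """The published study composition: 108 cases / 100 controls with the
    baseline-table covariate frequencies.  Keyword overrides are applied on
    top (e.g. ``seed=7`` or ``n_cases=500``)."""
    return replace(CohortConfig(), **overrides) if overrides else CohortConfig()


def largest_remainder_counts(n: int, freqs: Mapping[str, float]) -> dict[str, int]:
    """Integer category counts summing to ``n`` that match ``freqs`` by the
    largest-remainder rule (ties broken by category order)."""
    cats = list(freqs)
    exact = np.array([freqs[c] * n for c in cats])
    counts = np.floor(exact).astype(int)
    short = n - int(counts.sum())
    # stable argsort descending on remainder; earlier categories win ties
    order = np.argsort(-(exact - counts), kind="stable")
    for i in order[:short]:
        counts[i] += 1
    return dict(zip(cats, counts.tolist()))


def _quota_fill(n: int, freqs: Mapping[str, float], rng: np.random.Generator) -> np.ndarray:
    counts = largest_remainder_counts(n, freqs)
    values = np.repeat(list(counts), list(counts.values()))
    return rng.permutation(values)


def _severity_fill(n: int, freqs: Mapping[str, float], order: np.ndarray) -> np.ndarray:
    """Assign quota counts along a shared latent severity ordering: the
    categories (listed mild -> severe) fill positions of increasing
    severity, so e.g. G3, HG and high stage co-occur in the same cases."""
    counts = largest_remainder_counts(n, freqs)
    sorted_values = np.repeat(list(counts), list(counts.values()))
    out = np.empty(n, dtype=object)
    out[order] = sorted_values
    return out


def simulate_cohort(config: CohortConfig) -> tuple[list[CtRecord], pd.DataFrame]:
    """Draw one synthetic cohort; deterministic given ``config.seed``.

    Returns the raw long-format Ct records (markers + ACTB per multiplex)
    and the clinical metadata frame in the dialect consumed by
    :mod:`methylpanel.qmsp`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_cases, n_controls = config.n_cases, config.n_controls
    n = n_cases + n_controls
    width = len(str(n))

    sample_ids = [f"case_{i+1:0{width}d}" for i in range(n_cases)] + [
        f"ctrl_{i+1:0{width}d}" for i in range(n_controls)
    ]
    is_case = np.array([True] * n_cases + [False] * n_controls)

    # covariates: grades and stage share one latent severity ordering;
    # gender and disease status are independent quota fills
    severity_order = rng.permutation(n_cases)
    grade_1973 = _severity_fill(n_cases, config.grade_1973, severity_order)
    grade_2004 = _severity_fill(n_cases, config.grade_2004, severity_order)
    stage_order = {"Ta": 0, "T1": 1, "Tis": 2, "T2plus": 3}
    stage_freqs = dict(sorted(config.stage.items(), key=lambda kv: stage_order.get(kv[0], 9)))
    stage = _severity_fill(n_cases, stage_freqs, severity_order)
    status = _quota_fill(n_cases, config.status, rng)
    gender_cases = _quota_fill(n_cases, config.gender_cases, rng)
    gender_controls = _quota_fill(n_controls, config.gender_controls, rng)
    subtype = _quota_fill(n_controls, config.control_subtype, rng)

    # effect-size modifier per case
    g = np.ones(n_cases)
    g *= np.where(grade_2004 == "HG", config.grade_multiplier, 1.0)
    g *= np.where(stage == "T2plus", config.stage_multiplier, 1.0)
    g *= np.where(status == "recurrent", config.recurrence_multiplier, 1.0)
    g *= np.where(gender_cases == "female", config.female_dilution, 1.0)

    # shared tumour-burden factor (lognormal, median 1)
    if config.burden_sd > 0:
        burden = rng.lognormal(mean=0.0, sigma=config.burden_sd, size=n_cases)
    else:
        burden = np.ones(n_cases)

    # per-marker true log2 ratios
    log2_ratios = np.empty((n, len(MARKERS)))
    for j, marker in enumerate(MARKERS):
        mean = np.full(n, config.mu0[marker])
        mean[:n_cases] += config.delta[marker] * config.sigma * burden * g
        log2_ratios[:, j] = rng.normal(mean, config.sigma)
    ratios = 2.0 ** log2_ratios

    # reference gene per (sample, multiplex), with sporadic failures
    plex_ids = list(MULTIPLEX_MAP)
    actb = rng.normal(config.actb_mean, config.actb_sd, size=(n, len(plex_ids)))
    fails = rng.random(size=(n, len(plex_ids))) < config.actb_failure_rate
    actb[fails] = rng.uniform(32.5, 38.0, size=int(fails.sum()))

    records: list[CtRecord] = []
    for i, sid in enumerate(sample_ids):
        for k, mx in enumerate(plex_ids):
            records.append(CtRecord(sid, mx, REFERENCE_GENE, float(actb[i, k])))
            for marker in MULTIPLEX_MAP[mx]:
                j = MARKERS.index(marker)
                ct = actb[i, k] - math.log2(ratios[i, j] / 100.0)
                records.append(CtRecord(sid, mx, marker, float(ct)))

    # clinical metadata (ages: cases slightly older, matching the study's
    # medians; tumour descriptors quota-filled from the baseline table)
    age = np.where(
        is_case,
        rng.normal(70.0, 8.0, size=n),
        rng.normal(67.0, 9.0, size=n),
    ).clip(35, 95).round().astype(int)
    tumour_count = _quota_fill(n_cases, {"solitary": 0.55, "multiple": 0.45}, rng)
    n_tumours = np.where(tumour_count == "solitary", 1, rng.integers(2, 7, size=n_cases))
    size_class = _quota_fill(n_cases, {"small": 0.51, "large": 0.40, "unknown": 0.09}, rng)
    tumour_size = np.select(
        [size_class == "small", size_class == "large"],
        [rng.uniform(0.3, 2.9, size=n_cases).round(1), rng.uniform(3.0, 8.0, size=n_cases).round(1)],
        default=np.nan,
    )
    cis = _quota_fill(n_cases, {"no": 0.90, "yes": 0.10}, rng)

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": np.where(is_case, "case", "control"),
            "gender": np.concatenate([gender_cases, gender_controls]),
            "age": age,
            "grade_1973": _pad(grade_1973, n_controls),
            "grade_2004": _pad(grade_2004, n_controls),
            "stage": _pad(stage, n_controls),
            "status": _pad(status, n_controls),
            "control_subtype": _pad_front(subtype, n_cases),
            "tumour_count": _pad(n_tumours.astype(object), n_controls),
            "tumour_size_cm": _pad(tumour_size.astype(object), n_controls),
            "concomitant_cis": _pad(cis, n_controls),
        }
    )
    return records, clinical


def _pad(case_values: np.ndarray, n_controls: int) -> np.ndarray:
    return np.concatenate([case_values, np.full(n_controls, np.nan, dtype=object)])


def _pad_front(control_values: np.ndarray, n_cases: int) -> np.ndarray:
    return np.concatenate([np.full(n_cases, np.nan, dtype=object), control_values])


def inject_qc_failures(
    records: Sequence[CtRecord], rate: float, seed: int
) -> list[CtRecord]:
    """Independently, per (sample, multiplex), replace the ACTB Ct with a
    draw above 32 with the given probability; all other values untouched."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if rate == 0.0:
        return list(records)
    rng = np.random.default_rng(seed)
    out: list[CtRecord] = []
    for rec in records:
        if rec.target == REFERENCE_GENE:
            if rng.random() < rate:
                rec = CtRecord(
                    rec.sample_id,
                    rec.multiplex_id,
                    rec.target,
                    float(rng.uniform(32.5, 38.0)),
                )
        out.append(rec)
    return out


def force_actb_failures(
    records: Sequence[CtRecord],
    sample_ids: Iterable[str],
    multiplex_id: str = "A",
    failed_ct: float = 33.0,
) -> list[CtRecord]:
    """Deterministically set the ACTB Ct of the named samples' multiplex
    above 32 — for constructing QC worked examples with an exact failure
    count."""
    targets = set(sample_ids)
    out = []
    for rec in records:
        if (
            rec.target == REFERENCE_GENE
            and rec.multiplex_id == multiplex_id
            and rec.sample_id in targets
        ):
            rec = CtRecord(rec.sample_id, rec.multiplex_id, rec.target, failed_ct)
        out.append(rec)
    return out
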