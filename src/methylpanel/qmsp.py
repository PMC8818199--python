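"""Raw qMSP data model, QC and comparative-Ct normalization.

Quantitative methylation-specific PCR (qMSP) measures, per urine sample,
a quantification cycle (Ct) for each methylation marker and for the
reference gene *ACTB*.  Markers are assayed in three fixed multiplexes:

    A: FAM19A4, PHACTR3, PRDM14  (+ ACTB)
    B: GHSR, SST, ZIC1           (+ ACTB)
    C: MAL, miR-129, miR-935     (+ ACTB)

A multiplex is valid only if its ACTB Ct is detected and <= 32 cycles;
an ACTB Ct above 32 signals insufficient or degraded input DNA and
invalidates every target in that multiplex.  Valid targets are
normalized with the comparative Ct method: ratio = 2**(-(Ct_target -
Ct_ACTB)) * 100.  An undetected target with valid ACTB is scored as
ratio 0 (no detectable methylated template).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Reference gene used for normalization and sample QC.
REFERENCE_GENE = "ACTB"

#: Maximum valid ACTB Ct; strictly greater values invalidate the multiplex.
ACTB_CT_MAX = 32.0

#: Fixed assay map: markers carried by each multiplex (ACTB runs in all three).
MULTIPLEX_MAP: dict[str, tuple[str, ...]] = {
    "A": ("FAM19A4", "PHACTR3", "PRDM14"),
    "B": ("GHSR", "SST", "ZIC1"),
    "C": ("MAL", "miR-129", "miR-935"),
}

#: All nine methylation markers, in multiplex order.
MARKERS: tuple[str, ...] = tuple(m for mm in MULTIPLEX_MAP.values() for m in mm)

#: Reverse lookup marker -> multiplex.
MARKER_TO_MULTIPLEX: dict[str, str] = {
    marker: mx for mx, markers in MULTIPLEX_MAP.items() for marker in markers
}

#: Default pseudocount for log2 display of Ct ratios.  Display-only: all
#: rank-based tests, ROC curves and threshold calls operate on raw ratios,
#: so this value cannot change any inferential result.
LOG2_EPSILON = 1e-4

CT_COLUMNS = ("sample_id", "multiplex_id", "target", "ct")

CLINICAL_COLUMNS = (
    "sample_id",
    "group",
    "gender",
    "age",
    "grade_1973",
    "grade_2004",
    "stage",
    "status",
    "control_subtype",
    "tumour_count",
    "tumour_size_cm",
    "concomitant_cis",
)

_CASE_ONLY = ("grade_1973", "grade_2004", "stage", "status")


class CtTableError(ValueError):
    """Malformed Ct table: unknown target, multiplex mismatch or duplicate row."""


@dataclass(frozen=True)
class CtRecord:
    """One raw qPCR measurement.

    ``ct`` is the quantification cycle, or ``None`` for an undetected well
    (no amplification within the run).
    """

    sample_id: str
    multiplex_id: str
    target: str
    ct: float | None

    def __post_init__(self) -> None:
        if self.multiplex_id not in MULTIPLEX_MAP:
            raise CtTableError(f"unknown multiplex {self.multiplex_id!r}")
        if self.target != REFERENCE_GENE:
            if self.target not in MARKER_TO_MULTIPLEX:
                raise CtTableError(f"unknown target {self.target!r}")
            if MARKER_TO_MULTIPLEX[self.target] != self.multiplex_id:
                raise CtTableError(
                    f"target/multiplex mismatch: {self.target!r} does not run "
                    f"in multiplex {self.multiplex_id!r}"
                )
        if self.ct is not None and not (math.isfinite(self.ct) and self.ct > 0):
            raise CtTableError(
                f"Ct must be finite and positive, got {self.ct!r} "
                f"({self.sample_id}/{self.target})"
            )

    @property
    def undetected(self) -> bool:
        return self.ct is None


@dataclass
class MethylationProfile:
    """Per-sample normalized Ct ratios with per-multiplex validity.

    ``ratios[marker]`` is the 2^-dCt x 100 Ct ratio when the marker's
    multiplex passed ACTB QC, else ``None``.  All markers in one multiplex
    share the same validity state.
    """

    sample_id: str
    ratios: dict[str, float | None] = field(default_factory=dict)
    valid: dict[str, bool] = field(default_factory=dict)
    actb_ct: dict[str, float | None] = field(default_factory=dict)
    #: per-multiplex QC status: "valid", "failed" (ACTB undetected or > 32)
    #: or "absent" (multiplex not run for this sample)
    multiplex_status: dict[str, str] = field(default_factory=dict)

    def ratio(self, marker: str) -> float | None:
        return self.ratios.get(marker)

    def is_valid(self, marker: str) -> bool:
        return bool(self.valid.get(marker, False))


@dataclass(frozen=True)
class QcSummary:
    """Cohort-level ACTB QC tally."""

    n_samples: int
    n_flagged: int

    @property
    def flagged_fraction(self) -> float:
        return self.n_flagged / self.n_samples if self.n_samples else 0.0

    @property
    def flagged_percent(self) -> float:
        """Flagged fraction as a percentage rounded to one decimal."""
        return round(100.0 * self.flagged_fraction, 1)


def _parse_ct(text: str) -> float | None:
    text = text.strip()
    if text == "" or text.upper() in {"NA", "NAN", "UNDETECTED"}:
        return None
    return float(text)


def read_ct_table(path: str | Path, delimiter: str = ",") -> list[CtRecord]:
    """Read a long-format Ct table (sample_id, multiplex_id, target, ct).

    Undetected wells are encoded as an empty field or "NA".  Lines starting
    with '#' are comments (the simulator records its seed this way).  Any
    malformed row raises :class:`CtTableError` naming the offending line.
    """
    records: list[CtRecord] = []
    seen: set[tuple[str, str, str]] = set()
    path = Path(path)
    with path.open(newline="") as fh:
        rows = (line for line in fh if not line.startswith("#"))
        reader = csv.DictReader(rows, delimiter=delimiter)
        if reader.fieldnames is None or set(CT_COLUMNS) - set(reader.fieldnames):
            raise CtTableError(
                f"{path}: header must name columns {', '.join(CT_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = CtRecord(
                    sample_id=row["sample_id"].strip(),
                    multiplex_id=row["multiplex_id"].strip(),
                    target=row["target"].strip(),
                    ct=_parse_ct(row["ct"]),
                )
            except (CtTableError, ValueError) as exc:
                raise CtTableError(f"{path} line {lineno}: {exc}") from exc
            key = (rec.sample_id, rec.multiplex_id, rec.target)
            if key in seen:
                raise CtTableError(
                    f"{path} line {lineno}: duplicate measurement for {key}"
                )
            seen.add(key)
            records.append(rec)
    return records


def write_ct_table(
    records: Iterable[CtRecord], path: str | Path, header_comment: str | None = None
) -> None:
    """Write records in the long CSV dialect read by :func:`read_ct_table`."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh)
        writer.writerow(CT_COLUMNS)
        for rec in records:
            ct = "" if rec.ct is None else repr(rec.ct)
            writer.writerow([rec.sample_id, rec.multiplex_id, rec.target, ct])


def apply_qc(records: Sequence[CtRecord]) -> bool:
    """ACTB validity rule for one sample/multiplex worth of records.

    Valid iff the multiplex's single ACTB well is detected with Ct <= 32
    (the boundary value 32.0 itself is valid).  A missing ACTB record is
    invalid, with a warning logged.
    """
    actb = [r for r in records if r.target == REFERENCE_GENE]
    if len(actb) > 1:
        raise CtTableError(
            f"multiple ACTB records for sample {records[0].sample_id!r} "
            f"multiplex {records[0].multiplex_id!r}"
        )
    if not actb:
        if records:
            logger.warning(
                "sample %s multiplex %s: no ACTB record, marking invalid",
                records[0].sample_id,
                records[0].multiplex_id,
            )
        return False
    ct = actb[0].ct
    return ct is not None and ct <= ACTB_CT_MAX


def ct_ratio(ct_target: float | None, ct_actb: float) -> float:
    """Comparative-Ct methylation ratio, 2**(-(Ct_target - Ct_ACTB)) * 100.

    An undetected target (``None``) maps to ratio 0: in methylation-specific
    PCR, absence of amplification means no detectable methylated template.
    """
    if ct_target is None:
        return 0.0
    return 2.0 ** (-(ct_target - ct_actb)) * 100.0


def log2_ratio(ratio, epsilon: float = LOG2_EPSILON):
    """log2(ratio + epsilon), the display scale for Ct ratios.

    Accepts scalars or arrays.  Strictly monotone in ``ratio``, so panel
    calls and rank statistics are unchanged whether made on this scale or
    on the raw ratio.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return np.log2(np.asarray(ratio, dtype=float) + epsilon) if np.ndim(ratio) else math.log2(ratio + epsilon)


def build_profiles(records: Iterable[CtRecord]) -> list[MethylationProfile]:
    """Normalize raw Ct records into per-sample methylation profiles.

    Markers in a multiplex failing ACTB QC get ``valid=False`` and no ratio.
    A sample with zero multiplexes cannot occur (records imply >= 1); a
    sample missing some multiplex simply has those markers invalid.
    Profiles preserve first-seen sample order.
    """
    by_sample: dict[str, dict[str, list[CtRecord]]] = {}
    for rec in records:
        by_sample.setdefault(rec.sample_id, {}).setdefault(rec.multiplex_id, []).append(rec)

    profiles: list[MethylationProfile] = []
    for sample_id, plexes in by_sample.items():
        prof = MethylationProfile(sample_id=sample_id)
        for mx, markers in MULTIPLEX_MAP.items():
            recs = plexes.get(mx, [])
            valid = apply_qc(recs) if recs else False
            actb = next((r.ct for r in recs if r.target == REFERENCE_GENE), None)
            prof.actb_ct[mx] = actb
            prof.multiplex_status[mx] = (
                "valid" if valid else ("absent" if not recs else "failed")
            )
            targets = {r.target: r.ct for r in recs if r.target != REFERENCE_GENE}
            for marker in markers:
                prof.valid[marker] = valid and marker in targets
                prof.ratios[marker] = (
                    ct_ratio(targets[marker], actb) if prof.valid[marker] else None
                )
        profiles.append(prof)
    return profiles


def qc_summary(profiles: Sequence[MethylationProfile]) -> QcSummary:
    """Count samples with at least one ACTB-failed multiplex.

    A multiplex counts as failed only when it was run but its ACTB was
    undetected or above 32 cycles (absent multiplexes are missing data,
    not QC failures).
    """
    flagged = sum(
        1
        for prof in profiles
        if any(status == "failed" for status in prof.multiplex_status.values())
    )
    return QcSummary(n_samples=len(profiles), n_flagged=flagged)


def profiles_to_frame(
    profiles: Sequence[MethylationProfile],
) -> pd.DataFrame:
    """Wide per-sample table: one ratio column per marker, one validity
    column per multiplex (``valid_A``..``valid_C``).  Invalid ratios are NaN.
    """
    rows = []
    for prof in profiles:
        row: dict[str, object] = {"sample_id": prof.sample_id}
        for marker in MARKERS:
            r = prof.ratios.get(marker)
            row[marker] = np.nan if r is None else r
        for mx, markers in MULTIPLEX_MAP.items():
            row[f"valid_{mx}"] = all(prof.valid.get(m, False) for m in markers)
        rows.append(row)
    return pd.DataFrame(rows)


def write_profiles(profiles: Sequence[MethylationProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def read_clinical_table(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    """Read and validate clinical metadata.

    Columns: sample_id, group (case|control), gender (male|female), age,
    grade_1973, grade_2004, stage, status, control_subtype, tumour_count,
    tumour_size_cm, concomitant_cis.  Empty fields mean "absent".  Cases
    must carry grade/stage/status and no control subtype; controls the
    reverse.
    """
    df = pd.read_csv(path, delimiter=delimiter, comment="#", dtype={"sample_id": str})
    missing = set(CLINICAL_COLUMNS[:9]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: clinical table missing columns {sorted(missing)}")
    return validate_clinical(df)


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce the case/control field invariants on a clinical frame."""
    bad_group = set(df["group"]) - {"case", "control"}
    if bad_group:
        raise ValueError(f"unknown group labels {sorted(bad_group)}")
    cases = df[df["group"] == "case"]
    controls = df[df["group"] == "control"]
    for col in _CASE_ONLY:
        if cases[col].isna().any():
            raise ValueError(f"cases must carry {col}")
    if cases["control_subtype"].notna().any():
        raise ValueError("cases must not carry control_subtype")
    if controls["control_subtype"].isna().any():
        raise ValueError("controls must carry control_subtype")
    for col in _CASE_ONLY:
        if controls[col].notna().any():
            raise ValueError(f"controls must not carry {col}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in clinical table")
    return df
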