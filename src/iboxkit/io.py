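"""Cohort CSV input/output with strict schema validation.

The cohort file is plain RFC-4180 CSV (UTF-8) with one row per subject.
Mandatory columns: ``subject_id``, ``assessment_time_years``, ``egfr``,
``upcr_g_per_g``, ``dsa_mfi``, ``followup_years``, ``graft_loss``,
``died_with_function``.  Optional: ``arm``, and the Banff block
``banff_ifta, banff_g, banff_ptc, banff_i, banff_t, banff_cg`` (present
as a whole or absent as a whole; absent means only the abbreviated
variant can be scored).  Column order is free.

A subject who failed before the scheduled assessment has all assessment
numerics empty; partially empty assessments are row errors, as is a
missing DSA value on an otherwise assessed row — DSA is a qualified
component and is never silently imputed negative.
"""

from __future__ import annotations

import csv
from typing import List, Optional, Tuple

from .cohort import Cohort, Subject
from .scoring import Assessment, BanffProfile
from .survival import Outcome

__all__ = ["MANDATORY_COLUMNS", "BANFF_COLUMNS", "read_cohort", "write_cohort",
           "CohortSchemaError"]

MANDATORY_COLUMNS = (
    "subject_id",
    "assessment_time_years",
    "egfr",
    "upcr_g_per_g",
    "dsa_mfi",
    "followup_years",
    "graft_loss",
    "died_with_function",
)
BANFF_COLUMNS = (
    "banff_ifta", "banff_g", "banff_ptc", "banff_i", "banff_t", "banff_cg",
)
OPTIONAL_COLUMNS = ("arm",) + BANFF_COLUMNS
ASSESSMENT_COLUMNS = ("assessment_time_years", "egfr", "upcr_g_per_g", "dsa_mfi")


class CohortSchemaError(ValueError):
    """Schema or row-level validation failure, with row numbers."""

    def __init__(self, errors: List[str]):
        self.errors = errors
        super().__init__("; ".join(errors[:10]) + ("" if len(errors) <= 10 else f" (+{len(errors) - 10} more)"))


def _parse_float(value: str, column: str, row: int, errors: List[str]) -> Optional[float]:
    if value.strip() == "":
        return None
    try:
        return float(value)
    except ValueError:
        errors.append(f"row {row}: non-numeric value {value!r} in column {column!r}")
        return None


def _parse_flag(value: str, column: str, row: int, errors: List[str]) -> Optional[bool]:
    v = value.strip()
    if v in ("0", "1"):
        return v == "1"
    errors.append(f"row {row}: column {column!r} must be 0 or 1, got {value!r}")
    return None


def _parse_lesion(value: str, column: str, row: int, errors: List[str]) -> Optional[int]:
    v = value.strip()
    if v == "":
        return None
    try:
        score = int(v)
    except ValueError:
        errors.append(f"row {row}: non-integer value {value!r} in column {column!r}")
        return None
    if not 0 <= score <= 3:
        errors.append(f"row {row}: {column} lesion score out of range 0-3: {score}")
        return None
    return score


def read_cohort(path, delimiter: str = ",") -> Cohort:
    """Read and validate a cohort CSV; raises :class:`CohortSchemaError`
    with every row-level issue collected."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in MANDATORY_COLUMNS if c not in header]
        if missing:
            raise CohortSchemaError([f"missing mandatory column(s): {missing}"])
        unknown = [c for c in header if c not in MANDATORY_COLUMNS + OPTIONAL_COLUMNS]
        if unknown:
            raise CohortSchemaError([f"unknown column(s): {unknown}"])
        banff_present = [c for c in BANFF_COLUMNS if c in header]
        if banff_present and len(banff_present) != len(BANFF_COLUMNS):
            raise CohortSchemaError(
                [f"banff_* columns must appear as a complete block; found only {banff_present}"]
            )
        has_banff = bool(banff_present)
        has_arm = "arm" in header

        errors: List[str] = []
        subjects: List[Subject] = []
        seen_ids = set()
        for rownum, row in enumerate(reader, start=2):
            sid = row["subject_id"].strip()
            if not sid:
                errors.append(f"row {rownum}: empty subject_id")
                continue
            if sid in seen_ids:
                errors.append(f"row {rownum}: duplicate subject_id {sid!r}")
                continue
            seen_ids.add(sid)

            assess_vals = {
                c: _parse_float(row[c], c, rownum, errors) for c in ASSESSMENT_COLUMNS
            }
            present = [c for c in ASSESSMENT_COLUMNS if assess_vals[c] is not None]
            followup = _parse_float(row["followup_years"], "followup_years", rownum, errors)
            graft_loss = _parse_flag(row["graft_loss"], "graft_loss", rownum, errors)
            died = _parse_flag(row["died_with_function"], "died_with_function", rownum, errors)
            if followup is None or graft_loss is None or died is None:
                continue

            assessment = None
            if present:
                if len(present) != len(ASSESSMENT_COLUMNS):
                    absent = sorted(set(ASSESSMENT_COLUMNS) - set(present))
                    errors.append(
                        f"row {rownum}: assessment is partially missing "
                        f"(empty: {absent}); DSA and all kidney-function fields "
                        "are required for a scored assessment"
                    )
                    continue
                banff = None
                if has_banff:
                    lesions = {
                        c: _parse_lesion(row[c], c, rownum, errors) for c in BANFF_COLUMNS
                    }
                    lesion_vals = list(lesions.values())
                    if all(v is not None for v in lesion_vals):
                        banff = BanffProfile(
                            ifta=lesions["banff_ifta"], g=lesions["banff_g"],
                            ptc=lesions["banff_ptc"], i=lesions["banff_i"],
                            t=lesions["banff_t"], cg=lesions["banff_cg"],
                        )
                    elif any(v is not None for v in lesion_vals):
                        errors.append(f"row {rownum}: Banff profile is partially missing")
                        continue
                try:
                    assessment = Assessment(
                        subject_id=sid,
                        time_from_transplant=assess_vals["assessment_time_years"],
                        egfr=assess_vals["egfr"],
                        upcr=assess_vals["upcr_g_per_g"],
                        dsa_mfi=assess_vals["dsa_mfi"],
                        banff=banff,
                    )
                except ValueError as exc:
                    errors.append(f"row {rownum}: {exc}")
                    continue
            try:
                outcome = Outcome(
                    subject_id=sid, followup_years=followup,
                    graft_loss=graft_loss, died_with_function=died,
                )
            except ValueError as exc:
                errors.append(f"row {rownum}: {exc}")
                continue
            arm = row["arm"].strip() if has_arm else None
            subjects.append(
                Subject(subject_id=sid, outcome=outcome, assessment=assessment,
                        arm=arm or None)
            )
        if errors:
            raise CohortSchemaError(errors)
    return Cohort(subjects)


def write_cohort(cohort: Cohort, path, delimiter: str = ",") -> None:
    """Write a cohort back to the standard CSV contract (lossless round-trip)."""
    any_banff = any(
        s.assessment is not None and s.assessment.banff is not None for s in cohort
    )
    any_arm = any(s.arm is not None for s in cohort)
    columns = ["subject_id"]
    if any_arm:
        columns.append("arm")
    columns += list(ASSESSMENT_COLUMNS)
    if any_banff:
        columns += list(BANFF_COLUMNS)
    columns += ["followup_years", "graft_loss", "died_with_function"]

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(columns)
        for s in cohort:
            row = {c: "" for c in columns}
            row["subject_id"] = s.subject_id
            if any_arm:
                row["arm"] = s.arm or ""
            a = s.assessment
            if a is not None:
                row["assessment_time_years"] = repr(a.time_from_transplant)
                row["egfr"] = repr(a.egfr)
                row["upcr_g_per_g"] = repr(a.upcr)
                row["dsa_mfi"] = repr(a.dsa_mfi)
                if a.banff is not None:
                    for c, v in zip(
                        BANFF_COLUMNS,
                        (a.banff.ifta, a.banff.g, a.banff.ptc, a.banff.i, a.banff.t, a.banff.cg),
                    ):
                        row[c] = str(v)
            o = s.outcome
            row["followup_years"] = repr(o.followup_years)
            row["graft_loss"] = "1" if o.graft_loss else "0"
            row["died_with_function"] = "1" if o.died_with_function else "0"
            writer.writerow([row[c] for c in columns])
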