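"""Report corpus data model, I/O, cohort filtering, and annotation merging.

Corpora are exchanged as JSONL (one object per line) or CSV with a fixed
header. Inclusion filtering enforces the cohort rules (one radiograph per
encounter, pediatric age window, non-empty report text) and logs every
exclusion by reason. Splitting is disposition-stratified and seeded.
"""

from __future__ import annotations

import csv
import json
import math
from collections import Counter
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "Report",
    "LabelRecord",
    "SplitSpec",
    "CorpusSchemaError",
    "read_corpus",
    "write_corpus",
    "apply_inclusion",
    "stratified_split",
    "adjudicate",
    "read_labels",
    "write_labels",
    "write_exclusion_log",
    "AGE_MIN_MONTHS",
    "AGE_MAX_MONTHS",
]

DISPOSITIONS = ("admitted", "discharged")

# Pediatric inclusion window: 3 months through 18 years inclusive.
AGE_MIN_MONTHS = 3
AGE_MAX_MONTHS = 216

CSV_FIELDS = ("report_id", "encounter_id", "acquired_at", "age_months", "disposition", "site", "text")


class CorpusSchemaError(ValueError):
    """A corpus record is missing or malforms a required field."""


@dataclass(frozen=True)
class Report:
    """One free-text chest-radiograph report with encounter metadata."""

    report_id: str
    encounter_id: str
    acquired_at: str  # ISO-8601; lexicographic order == chronological order
    age_months: int
    disposition: str
    text: str
    site: Optional[str] = None

    def __post_init__(self) -> None:
        if self.disposition not in DISPOSITIONS:
            raise ValueError(f"disposition must be one of {DISPOSITIONS}, got {self.disposition!r}")
        if self.age_months < 0:
            raise ValueError("age_months must be >= 0")
        # validate timestamp eagerly so ordering is trustworthy downstream
        datetime.fromisoformat(self.acquired_at)


@dataclass(frozen=True)
class LabelRecord:
    """Reference labels for one encounter (expert and diagnosis-code)."""

    encounter_id: str
    expert_label: Optional[int] = None
    code_label: Optional[int] = None
    reviewer1: Optional[int] = None
    reviewer2: Optional[int] = None
    adjudicated_by_third: bool = False

    def __post_init__(self) -> None:
        for name in ("expert_label", "code_label", "reviewer1", "reviewer2"):
            v = getattr(self, name)
            if v is not None and v not in (0, 1):
                raise ValueError(f"{name} must be binary 0/1 or None, got {v!r}")


@dataclass(frozen=True)
class SplitSpec:
    """Parameters of the derivation/validation split."""

    validation_fraction: float = 0.01
    admitted_share: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if not 0 <= self.admitted_share <= 1:
            raise ValueError("admitted_share must be in [0, 1]")


def _report_from_mapping(obj: Mapping, where: str) -> Report:
    required = ("report_id", "encounter_id", "acquired_at", "age_months", "disposition", "text")
    for key in required:
        if key not in obj or obj[key] is None:
            raise CorpusSchemaError(f"missing required field {key!r} at {where}")
    try:
        age = int(obj["age_months"])
    except (TypeError, ValueError) as exc:
        raise CorpusSchemaError(f"age_months not an integer at {where}") from exc
    site = obj.get("site")
    if site == "":
        site = None
    try:
        return Report(
            report_id=str(obj["report_id"]),
            encounter_id=str(obj["encounter_id"]),
            acquired_at=str(obj["acquired_at"]),
            age_months=age,
            disposition=str(obj["disposition"]),
            text=str(obj["text"]),
            site=site,
        )
    except ValueError as exc:
        raise CorpusSchemaError(f"{exc} at {where}") from exc


def read_corpus(path, format: Optional[str] = None) -> list[Report]:
    """Read a corpus from JSONL or CSV, preserving input order.

    ``format`` defaults from the file extension. Records with empty text
    are returned as-is (inclusion filtering flags them later); records
    with missing fields raise :class:`CorpusSchemaError` naming the field
    and line.
    """
    path = str(path)
    if format is None:
        format = "csv" if path.endswith(".csv") else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"format must be 'jsonl' or 'csv', got {format!r}")
    reports: list[Report] = []
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusSchemaError(f"invalid JSON at line {lineno}: {exc}") from exc
                reports.append(_report_from_mapping(obj, f"line {lineno}"))
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise CorpusSchemaError("CSV corpus has no header row")
            missing = set(CSV_FIELDS) - set(reader.fieldnames) - {"site"}
            if missing:
                raise CorpusSchemaError(f"CSV header missing columns: {sorted(missing)}")
            for row in reader:
                reports.append(_report_from_mapping(row, f"line {reader.line_num}"))
    seen: set[str] = set()
    for r in reports:
        if r.report_id in seen:
            raise CorpusSchemaError(f"duplicate report_id {r.report_id!r}")
        seen.add(r.report_id)
    return reports


def write_corpus(reports: Iterable[Report], path, format: Optional[str] = None) -> None:
    """Write a corpus as JSONL or CSV (UTF-8, text CSV-quoted)."""
    path = str(path)
    if format is None:
        format = "csv" if path.endswith(".csv") else "jsonl"
    reports = list(reports)
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for r in reports:
                obj = {
                    "report_id": r.report_id,
                    "encounter_id": r.encounter_id,
                    "acquired_at": r.acquired_at,
                    "age_months": r.age_months,
                    "disposition": r.disposition,
                    "site": r.site,
                    "text": r.text,
                }
                fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
    elif format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
            writer.writerow(CSV_FIELDS)
            for r in reports:
                writer.writerow(
                    [r.report_id, r.encounter_id, r.acquired_at, r.age_months, r.disposition, r.site or "", r.text]
                )
    else:
        raise ValueError(f"format must be 'jsonl' or 'csv', got {format!r}")


def apply_inclusion(reports: Sequence[Report]) -> tuple[list[Report], Counter]:
    """Apply cohort inclusion rules; return kept reports and exclusion counts.

    Rules are applied per record in a fixed order so each exclusion has
    exactly one reason:

    1. ``missing_report`` — empty or whitespace-only text;
    2. ``age`` — age outside [3, 216] months;
    3. ``duplicate_cxr`` — a later radiograph within an encounter that
       already has an earlier one (ties on timestamp broken by
       lexicographic report_id).

    Output order follows input order. Idempotent: re-filtering the kept
    set removes nothing.
    """
    log: Counter = Counter()
    eligible: list[Report] = []
    for r in reports:
        if not r.text.strip():
            log["missing_report"] += 1
            continue
        if not AGE_MIN_MONTHS <= r.age_months <= AGE_MAX_MONTHS:
            log["age"] += 1
            continue
        eligible.append(r)

    first_by_encounter: dict[str, Report] = {}
    for r in eligible:
        cur = first_by_encounter.get(r.encounter_id)
        if cur is None or (r.acquired_at, r.report_id) < (cur.acquired_at, cur.report_id):
            first_by_encounter[r.encounter_id] = r
    kept_ids = {r.report_id for r in first_by_encounter.values()}
    included = []
    for r in eligible:
        if r.report_id in kept_ids:
            included.append(r)
        else:
            log["duplicate_cxr"] += 1
    return included, log


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def stratified_split(reports: Sequence[Report], spec: SplitSpec) -> tuple[list[Report], list[Report]]:
    """Seeded disposition-stratified derivation/validation split.

    Validation size is ``round(validation_fraction * N)`` (half away from
    zero, minimum 1); its admitted share is held within one report of
    ``admitted_share``. Identical spec (including seed) yields an
    identical split.
    """
    n = len(reports)
    if n == 0:
        raise ValueError("cannot split an empty corpus")
    size = max(1, _round_half_away(spec.validation_fraction * n))
    n_admitted_target = _round_half_away(spec.admitted_share * size)
    n_discharged_target = size - n_admitted_target

    admitted = [r for r in reports if r.disposition == "admitted"]
    discharged = [r for r in reports if r.disposition == "discharged"]
    if len(admitted) < n_admitted_target:
        raise ValueError(
            f"admitted stratum too small: need {n_admitted_target}, have {len(admitted)} "
            f"(achievable admitted share <= {len(admitted) / size:.3f})"
        )
    if len(discharged) < n_discharged_target:
        raise ValueError(
            f"discharged stratum too small: need {n_discharged_target}, have {len(discharged)} "
            f"(achievable discharged share <= {len(discharged) / size:.3f})"
        )

    rng = np.random.default_rng(spec.seed)
    val_ids: set[str] = set()
    for stratum, k in ((admitted, n_admitted_target), (discharged, n_discharged_target)):
        # sample on sorted ids so the draw is independent of input order
        ids = sorted(r.report_id for r in stratum)
        chosen = rng.choice(len(ids), size=k, replace=False)
        val_ids.update(ids[i] for i in chosen)

    validation = [r for r in reports if r.report_id in val_ids]
    derivation = [r for r in reports if r.report_id not in val_ids]
    return derivation, validation


def adjudicate(
    r1: Mapping[str, int],
    r2: Mapping[str, int],
    tiebreak: Optional[Mapping[str, int]] = None,
) -> list[LabelRecord]:
    """Merge two reviewers' binary labels into consensus records.

    Concordant ids take the shared label; discordant ids take the
    third-reviewer ``tiebreak`` label and are flagged. ``tiebreak`` must
    cover exactly the discordant ids (extras are ignored; gaps raise).
    Output is sorted by encounter id.
    """
    if set(r1) != set(r2):
        only1 = sorted(set(r1) - set(r2))[:5]
        only2 = sorted(set(r2) - set(r1))[:5]
        raise ValueError(f"reviewers cover different id-sets (e.g., {only1} vs {only2})")
    discordant = sorted(eid for eid in r1 if r1[eid] != r2[eid])
    tiebreak = tiebreak or {}
    missing = [eid for eid in discordant if eid not in tiebreak]
    if missing:
        raise ValueError(f"tiebreak labels missing for discordant ids: {missing}")
    records = []
    for eid in sorted(r1):
        if r1[eid] == r2[eid]:
            records.append(
                LabelRecord(
                    encounter_id=eid,
                    expert_label=int(r1[eid]),
                    reviewer1=int(r1[eid]),
                    reviewer2=int(r2[eid]),
                    adjudicated_by_third=False,
                )
            )
        else:
            records.append(
                LabelRecord(
                    encounter_id=eid,
                    expert_label=int(tiebreak[eid]),
                    reviewer1=int(r1[eid]),
                    reviewer2=int(r2[eid]),
                    adjudicated_by_third=True,
                )
            )
    return records


_LABEL_FIELDS = ("encounter_id", "expert_label", "code_label", "reviewer1", "reviewer2", "adjudicated_by_third")


def write_labels(records: Iterable[LabelRecord], path) -> None:
    """Label CSV with 0/1 encoding; empty cell = not available."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_LABEL_FIELDS)
        for rec in records:
            writer.writerow(
                [
                    rec.encounter_id,
                    "" if rec.expert_label is None else rec.expert_label,
                    "" if rec.code_label is None else rec.code_label,
                    "" if rec.reviewer1 is None else rec.reviewer1,
                    "" if rec.reviewer2 is None else rec.reviewer2,
                    int(rec.adjudicated_by_third),
                ]
            )


def read_labels(path) -> list[LabelRecord]:
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "encounter_id" not in reader.fieldnames:
            raise CorpusSchemaError("label CSV must have an encounter_id column")

        def _opt(row, key):
            v = row.get(key, "")
            return None if v in ("", None) else int(v)

        for row in reader:
            records.append(
                LabelRecord(
                    encounter_id=row["encounter_id"],
                    expert_label=_opt(row, "expert_label"),
                    code_label=_opt(row, "code_label"),
                    reviewer1=_opt(row, "reviewer1"),
                    reviewer2=_opt(row, "reviewer2"),
                    adjudicated_by_third=row.get("adjudicated_by_third", "0") in ("1", "True", "true"),
                )
            )
    return records


def write_exclusion_log(log: Mapping[str, int], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["reason", "n"])
        for reason in sorted(log):
            writer.writerow([reason, log[reason]])
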