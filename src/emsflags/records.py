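"""EMS encounter data model, readers/writers, splitting, and summaries.

An encounter is one EMS response. Six free-text fields carry the clinical
signal — the 9-1-1 call nature, the provider's primary impression, the
chief complaint, the chief narrative, the medication list, and the medical
history — alongside demographics, the county, and an optional binary
opioid-overdose label. Labels are three-state: positive, negative, or
unlabeled (so pools awaiting annotation are representable).
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: The six free-text fields, in canonical column order.
TEXT_FIELDS = (
    "call_nature",
    "primary_impression",
    "chief_complaint",
    "chief_narrative",
    "medication_list",
    "medical_history",
)

#: Canonical column order for tabular round-trips.
COLUMNS = (
    "record_id",
    "county",
    *TEXT_FIELDS,
    "ethnicity",
    "gender",
    "age",
    "label",
    "phase",
)

UNKNOWN = "unknown"

_TRUE_LABELS = {"1", "true", "ood", "positive", "pos", "yes"}
_FALSE_LABELS = {"0", "false", "non-ood", "negative", "neg", "no"}
_MISSING = {"", "na", "nan", "none", "null", "unlabeled"}


def parse_label(value, row=None):
    """Parse a label token from any supported dialect.

    Accepts 0/1, true/false, OOD/Non-OOD (case-insensitive); missing values
    map to ``None`` (unlabeled). Anything else is a hard error naming the row.
    """
    if value is None:
        return None
    if isinstance(value, bool):
        return int(value)
    if isinstance(value, (int, np.integer)) and value in (0, 1):
        return int(value)
    if isinstance(value, float):
        if math.isnan(value):
            return None
        if value in (0.0, 1.0):
            return int(value)
    token = str(value).strip().lower()
    if token in _TRUE_LABELS:
        return 1
    if token in _FALSE_LABELS:
        return 0
    if token in _MISSING:
        return None
    where = f" at row {row}" if row is not None else ""
    raise ValueError(f"unparseable label value {value!r}{where}")


@dataclass
class EncounterRecord:
    """One EMS encounter row."""

    record_id: str
    county: str = ""
    call_nature: str = ""
    primary_impression: str = ""
    chief_complaint: str = ""
    chief_narrative: str = ""
    medication_list: str = ""
    medical_history: str = ""
    ethnicity: str = UNKNOWN
    gender: str = UNKNOWN
    age: float | None = None
    label: int | None = None
    phase: str | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not str(self.record_id):
            raise ValueError("record_id must be a non-empty string")
        self.record_id = str(self.record_id)
        for f in TEXT_FIELDS:
            v = getattr(self, f)
            setattr(self, f, "" if v is None else str(v))
        if self.age is not None:
            self.age = float(self.age)
            if not 0 <= self.age <= 130:
                raise ValueError(
                    f"record {self.record_id}: age {self.age} outside [0, 130]"
                )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.record_id}: label must be 0/1/None")

    def text(self, fields=TEXT_FIELDS) -> str:
        """Space-join the requested text fields."""
        return " ".join(getattr(self, f) for f in fields)


@dataclass
class Cohort:
    """An ordered collection of encounters with unique record ids."""

    records: list
    provenance: str = ""

    def __post_init__(self) -> None:
        self.records = list(self.records)
        seen = set()
        for r in self.records:
            if r.record_id in seen:
                raise ValueError(f"duplicate record_id {r.record_id!r}")
            seen.add(r.record_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def record_ids(self) -> list:
        return [r.record_id for r in self.records]

    def labels(self) -> np.ndarray:
        """Labels as a float array with NaN for unlabeled records."""
        return np.array(
            [np.nan if r.label is None else float(r.label) for r in self.records]
        )

    def subset(self, indices, provenance=None) -> "Cohort":
        return Cohort(
            [self.records[i] for i in indices],
            provenance if provenance is not None else self.provenance,
        )


# ---------------------------------------------------------------------------
# Readers / writers


def _record_from_mapping(row: dict, rownum: int) -> EncounterRecord:
    if "record_id" not in row or row["record_id"] in (None, ""):
        raise ValueError(f"row {rownum}: missing record_id")
    known = set(COLUMNS)
    age = row.get("age")
    if age in (None, ""):
        age = None
    else:
        age = float(age)
    phase = row.get("phase")
    if phase in (None, ""):
        phase = None
    kwargs = {
        "record_id": str(row["record_id"]),
        "county": str(row.get("county") or ""),
        "ethnicity": str(row.get("ethnicity") or UNKNOWN) or UNKNOWN,
        "gender": str(row.get("gender") or UNKNOWN) or UNKNOWN,
        "age": age,
        "label": parse_label(row.get("label"), row=rownum),
        "phase": None if phase is None else str(phase),
    }
    for f in TEXT_FIELDS:
        v = row.get(f)
        kwargs[f] = "" if v is None else str(v)
    extras = {k: row[k] for k in row if k not in known}
    return EncounterRecord(extras=extras, **kwargs)


def read_encounters(path, format: str | None = None) -> Cohort:
    """Read a cohort from CSV or JSON-lines.

    Missing text-field values become empty strings (logged once per column);
    unknown columns are preserved as pass-through ``extras``. Duplicate
    record ids and unparseable labels are hard errors.
    """
    path = str(path)
    if format is None:
        format = "jsonl" if path.endswith((".jsonl", ".ndjson", ".json")) else "csv"
    if format not in ("csv", "jsonl"):
        raise ValueError(f"unknown format {format!r}")

    rows: list[dict] = []
    if format == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "record_id" not in reader.fieldnames:
                raise ValueError(f"{path}: header must include record_id")
            missing_cols = [f for f in TEXT_FIELDS if f not in reader.fieldnames]
            if missing_cols:
                logger.warning(
                    "%s: text columns %s absent; treated as empty strings",
                    path,
                    missing_cols,
                )
            rows = list(reader)
    else:
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if line:
                    rows.append(json.loads(line))

    records = []
    seen = set()
    for i, row in enumerate(rows, start=1):
        rec = _record_from_mapping(row, rownum=i)
        if rec.record_id in seen:
            raise ValueError(f"duplicate record_id {rec.record_id!r}")
        seen.add(rec.record_id)
        records.append(rec)
    return Cohort(records, provenance=path)


def _record_to_row(rec: EncounterRecord) -> dict:
    row = {
        "record_id": rec.record_id,
        "county": rec.county,
        **{f: getattr(rec, f) for f in TEXT_FIELDS},
        "ethnicity": rec.ethnicity,
        "gender": rec.gender,
        "age": "" if rec.age is None else (
            str(int(rec.age)) if float(rec.age).is_integer() else str(rec.age)
        ),
        "label": "" if rec.label is None else str(rec.label),
        "phase": "" if rec.phase is None else rec.phase,
    }
    row.update(rec.extras)
    return row


def write_encounters(cohort: Cohort, path, format: str | None = None) -> None:
    """Write a cohort to CSV (RFC-4180, UTF-8) or JSON-lines."""
    path = str(path)
    if format is None:
        format = "jsonl" if path.endswith((".jsonl", ".ndjson", ".json")) else "csv"
    extra_cols: list[str] = []
    for r in cohort:
        for k in r.extras:
            if k not in extra_cols:
                extra_cols.append(k)
    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=[*COLUMNS, *extra_cols])
            writer.writeheader()
            for rec in cohort:
                writer.writerow(_record_to_row(rec))
    elif format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in cohort:
                row = _record_to_row(rec)
                row["age"] = rec.age
                row["label"] = rec.label
                row["phase"] = rec.phase
                fh.write(json.dumps(row, sort_keys=False) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Summaries


@dataclass
class CohortSummary:
    """Counts and demographic shares for a cohort.

    Shares are computed over *labeled positives only*; unlabeled records are
    excluded from the positive denominators. Percentages are retained
    unrounded (rounding to one decimal is a display concern).
    """

    n_total: int
    n_by_county: dict
    n_positive: int
    n_negative: int
    n_unlabeled: int
    positive_share_by_ethnicity: dict
    positive_share_by_gender: dict
    age_range: tuple | None
    mean_age: float | None

    def display_shares(self, by: str = "ethnicity") -> dict:
        src = (
            self.positive_share_by_ethnicity
            if by == "ethnicity"
            else self.positive_share_by_gender
        )
        return {k: (c, round(p, 1)) for k, (c, p) in src.items()}


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """Tabulate counts per county and demographic shares among positives."""
    n_by_county: dict = {}
    for r in cohort:
        n_by_county[r.county] = n_by_county.get(r.county, 0) + 1
    positives = [r for r in cohort if r.label == 1]
    negatives = [r for r in cohort if r.label == 0]
    npos = len(positives)

    def shares(attr):
        counts: dict = {}
        for r in positives:
            key = getattr(r, attr) or UNKNOWN
            counts[key] = counts.get(key, 0) + 1
        return {
            k: (c, 100.0 * c / npos if npos else 0.0) for k, c in counts.items()
        }

    ages = [r.age for r in positives if r.age is not None]
    return CohortSummary(
        n_total=len(cohort),
        n_by_county=n_by_county,
        n_positive=npos,
        n_negative=len(negatives),
        n_unlabeled=len(cohort) - npos - len(negatives),
        positive_share_by_ethnicity=shares("ethnicity"),
        positive_share_by_gender=shares("gender"),
        age_range=(min(ages), max(ages)) if ages else None,
        mean_age=float(np.mean(ages)) if ages else None,
    )


# ---------------------------------------------------------------------------
# Splitting


def _half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_train_test(
    cohort: Cohort,
    test_fraction: float,
    seed: int,
    stratify_on_label: bool = True,
):
    """Partition a cohort into (train, test) cohorts.

    Per-stratum test size is round(test_fraction * stratum size) with
    half-up rounding; any remainder against the overall rounded target is
    resolved in the largest stratum. Deterministic for a fixed seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(cohort)
    rng = np.random.default_rng(seed)
    if stratify_on_label:
        strata: dict = {}
        for i, r in enumerate(cohort):
            if r.label is not None:
                strata.setdefault(r.label, []).append(i)
        if not strata:
            raise ValueError("stratified split requested on fully unlabeled cohort")
        unlabeled = [i for i, r in enumerate(cohort) if r.label is None]
        if unlabeled:
            strata["unlabeled"] = unlabeled
        sizes = {k: _half_up(test_fraction * len(v)) for k, v in strata.items()}
        target = _half_up(test_fraction * n)
        diff = target - sum(sizes.values())
        if diff:
            largest = max(strata, key=lambda k: (len(strata[k]), str(k)))
            sizes[largest] = min(max(sizes[largest] + diff, 0), len(strata[largest]))
        test_idx: list[int] = []
        for k in sorted(strata, key=str):
            idx = np.array(strata[k])
            take = rng.choice(len(idx), size=sizes[k], replace=False)
            test_idx.extend(idx[np.sort(take)])
    else:
        size = _half_up(test_fraction * n)
        take = rng.choice(n, size=size, replace=False)
        test_idx = list(np.sort(take))
    test_set = set(test_idx)
    train_idx = [i for i in range(n) if i not in test_set]
    test_idx = sorted(test_set)
    return (
        cohort.subset(train_idx, provenance=f"{cohort.provenance} [train]"),
        cohort.subset(test_idx, provenance=f"{cohort.provenance} [test]"),
    )


# ---------------------------------------------------------------------------
# Report serialization


def _jsonable(obj):
    if obj is None or isinstance(obj, (str, int, bool)):
        return obj
    if isinstance(obj, float):
        return None if math.isnan(obj) else obj
    if isinstance(obj, (np.floating, np.integer)):
        return _jsonable(obj.item())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    raise TypeError(f"cannot serialize object of type {type(obj)!r}")


def write_report(report, path) -> None:
    """Serialize any report object to JSON with stable key order.

    Dataclasses become objects, tuples/arrays become lists, NaN becomes
    null. The output round-trips losslessly modulo those conversions.
    """
    payload = _jsonable(report)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
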