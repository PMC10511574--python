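"""Data model and plain-text I/O for ambulatory pH recordings and cohorts.

Time base: seconds from recording start, 0-based.  Every interval in this
package is half-open ``[start, end)``.  Traces are regularly sampled and each
sample carries the interval ``[t, t + sample_interval_s)``; "time below pH 4"
is always the summed length of such intervals, never an interpolation.

File formats (all plain text):

* trace: CSV with header ``time_s,ph``; an optional companion annotation CSV
  with header ``start_s,end_s,kind`` where kind is ``upright``, ``supine`` or
  ``meal``;
* symptom log: JSON with ``recording_id``, ``tracked_symptoms`` and
  ``events`` (list of ``{"time_s": ..., "symptom": ...}``);
* cohort: CSV, one row per patient, columns exactly the
  :class:`PatientRecord` fields in canonical order, missing values as empty
  cells, per-symptom association results as an embedded JSON cell.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "UPRIGHT",
    "SUPINE",
    "TYPICAL_SYMPTOMS",
    "ATYPICAL_SYMPTOMS",
    "NON_REFLUX_SYMPTOMS",
    "KNOWN_SYMPTOMS",
    "symptom_category",
    "SymptomLabel",
    "PHTrace",
    "SymptomEventLog",
    "PatientRecord",
    "CohortTable",
    "read_trace",
    "write_trace",
    "read_symptom_log",
    "write_symptom_log",
    "read_cohort",
    "write_cohort",
]

UPRIGHT = "upright"
SUPINE = "supine"
POSTURES = (UPRIGHT, SUPINE)

TYPICAL_SYMPTOMS = ("heartburn", "regurgitation", "dysphagia")
ATYPICAL_SYMPTOMS = ("chest_pain", "cough", "globus", "throat_clearing")
NON_REFLUX_SYMPTOMS = ("abdominal_pain", "nausea")
KNOWN_SYMPTOMS = TYPICAL_SYMPTOMS + ATYPICAL_SYMPTOMS + NON_REFLUX_SYMPTOMS

SEXES = ("female", "male")
FUNDOPLICATION_TYPES = ("nissen", "partial")

HRQL_MAX = 80  # 16 items x 0-5


class ValidationError(ValueError):
    """An input violated a data-model invariant."""


def symptom_category(name: str) -> str:
    """Map a symptom label to its fixed category.

    typical = heartburn / regurgitation / dysphagia; atypical = chest_pain /
    cough / globus / throat_clearing; non_reflux = abdominal_pain / nausea;
    anything else (free text) maps to ``other``.
    """
    if name in TYPICAL_SYMPTOMS:
        return "typical"
    if name in ATYPICAL_SYMPTOMS:
        return "atypical"
    if name in NON_REFLUX_SYMPTOMS:
        return "non_reflux"
    return "other"


@dataclass(frozen=True)
class SymptomLabel:
    """A symptom name with its derived category."""

    name: str

    @property
    def category(self) -> str:
        return symptom_category(self.name)


def _fmt(x: float) -> str:
    """Canonical, lossless text form of a float (shortest round-trip repr)."""
    return repr(float(x))


# ---------------------------------------------------------------------------
# pH trace
# ---------------------------------------------------------------------------

@dataclass
class PHTrace:
    """One continuous pH recording with posture and meal annotations.

    ``times`` and ``ph`` are parallel arrays; ``posture_intervals`` is a list
    of ``(start_s, end_s, posture)`` tuples that must tile ``[0, duration_s)``
    without overlap; ``meal_intervals`` is a list of ``(start_s, end_s)``
    tuples inside the recording.
    """

    recording_id: str
    times: np.ndarray
    ph: np.ndarray
    sample_interval_s: float = 6.0
    duration_s: float | None = None
    posture_intervals: list[tuple[float, float, str]] | None = None
    meal_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ph = np.asarray(self.ph, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.ph.shape:
            raise ValidationError("times and ph must be parallel 1-d arrays")
        if self.times.size == 0:
            raise ValidationError("trace has no samples")
        if np.any(np.diff(self.times) <= 0):
            i = int(np.argmax(np.diff(self.times) <= 0))
            raise ValidationError(
                f"non-monotone time at sample {i + 1} "
                f"(t={self.times[i + 1]!r} after t={self.times[i]!r})"
            )
        if self.sample_interval_s <= 0:
            raise ValidationError("sample_interval_s must be positive")
        if self.duration_s is None:
            self.duration_s = float(self.times[-1] + self.sample_interval_s)
        if self.times[0] < 0 or self.times[-1] > self.duration_s:
            raise ValidationError("sample times outside [0, duration_s]")
        if np.any(self.ph < 0) or np.any(self.ph > 9):
            bad = int(np.argmax((self.ph < 0) | (self.ph > 9)))
            raise ValidationError(
                f"ph out of [0, 9] at sample {bad} (ph={self.ph[bad]!r})"
            )
        if self.posture_intervals is None:
            self.posture_intervals = [(0.0, float(self.duration_s), UPRIGHT)]
        self._check_posture_coverage()
        self._check_meals()

    def _check_posture_coverage(self) -> None:
        ivs = sorted(self.posture_intervals)
        cursor = 0.0
        for start, end, kind in ivs:
            if kind not in POSTURES:
                raise ValidationError(f"unknown posture {kind!r}")
            if end <= start:
                raise ValidationError(f"empty posture interval ({start}, {end})")
            if not np.isclose(start, cursor):
                raise ValidationError(
                    f"posture intervals must tile the recording: gap/overlap "
                    f"at {start} (expected {cursor})"
                )
            cursor = end
        if not np.isclose(cursor, self.duration_s):
            raise ValidationError(
                f"posture intervals end at {cursor}, not duration {self.duration_s}"
            )
        self.posture_intervals = ivs

    def _check_meals(self) -> None:
        ivs = sorted(self.meal_intervals)
        prev_end = -np.inf
        for start, end in ivs:
            if end <= start:
                raise ValidationError(f"empty meal interval ({start}, {end})")
            if start < prev_end:
                raise ValidationError("overlapping meal intervals")
            if start < 0 or end > self.duration_s:
                raise ValidationError("meal interval outside the recording")
            prev_end = end
        self.meal_intervals = [(float(s), float(e)) for s, e in ivs]

    @property
    def n_samples(self) -> int:
        return int(self.times.size)

    def posture_at(self, t: np.ndarray | float) -> np.ndarray:
        """Posture label for each time (vectorised interval lookup)."""
        starts = np.array([s for s, _, _ in self.posture_intervals])
        kinds = np.array([k for _, _, k in self.posture_intervals])
        idx = np.clip(np.searchsorted(starts, np.atleast_1d(t), "right") - 1, 0, None)
        return kinds[idx]

    def in_meal(self, t: np.ndarray | float) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros(t.shape, dtype=bool)
        for s, e in self.meal_intervals:
            out |= (t >= s) & (t < e)
        return out


# ---------------------------------------------------------------------------
# Symptom event log
# ---------------------------------------------------------------------------

@dataclass
class SymptomEventLog:
    """Patient-reported symptom events for one recording.

    At most three distinct tracked symptoms; every event's symptom must be
    among them.
    """

    recording_id: str
    tracked_symptoms: tuple[str, ...]
    events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tracked_symptoms = tuple(dict.fromkeys(self.tracked_symptoms))
        if not 1 <= len(self.tracked_symptoms) <= 3:
            raise ValidationError(
                f"at most 3 tracked symptoms (and at least 1), "
                f"got {len(self.tracked_symptoms)}"
            )
        tracked = set(self.tracked_symptoms)
        cleaned: list[tuple[float, str]] = []
        for t, s in self.events:
            if s not in tracked:
                raise ValidationError(f"event symptom {s!r} is not tracked")
            if t < 0:
                raise ValidationError(f"negative event time {t!r}")
            cleaned.append((float(t), s))
        self.events = sorted(cleaned)

    def events_for(self, symptom: str) -> np.ndarray:
        """Event times of one tracked symptom, sorted."""
        if symptom not in self.tracked_symptoms:
            raise ValidationError(f"symptom {symptom!r} is not tracked")
        return np.array([t for t, s in self.events if s == symptom])

    def __len__(self) -> int:
        return len(self.events)


# ---------------------------------------------------------------------------
# Patient record / cohort table
# ---------------------------------------------------------------------------

COHORT_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "bmi",
    "preop_hrql",
    "postop_hrql",
    "satisfied",
    "ppi_free",
    "fundoplication",
    "followup_months",
    "demeester",
    "sap_positive_count",
    "per_symptom_sap",
)


@dataclass
class PatientRecord:
    """One surgical patient with demographics, outcomes and reflux metrics.

    ``per_symptom_sap`` maps symptom name to a SAP result object (see
    ``symptom_association.SAPResult``); postoperative fields may each be
    missing (``None``) independently — analyses use per-variable complete
    cases.
    """

    patient_id: str
    age: float
    sex: str
    bmi: float
    preop_hrql: int
    postop_hrql: int | None
    satisfied: bool | None
    ppi_free: bool | None
    fundoplication: str
    followup_months: float
    demeester: float
    sap_positive_count: int
    per_symptom_sap: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.fundoplication not in FUNDOPLICATION_TYPES:
            raise ValidationError(
                f"fundoplication must be one of {FUNDOPLICATION_TYPES}, "
                f"got {self.fundoplication!r}"
            )
        for name, val in (("preop_hrql", self.preop_hrql),
                          ("postop_hrql", self.postop_hrql)):
            if val is not None and not 0 <= val <= HRQL_MAX:
                raise ValidationError(f"{name} out of [0, {HRQL_MAX}]: {val!r}")
        n_pos = sum(1 for r in self.per_symptom_sap.values() if r.positive)
        if self.per_symptom_sap and n_pos != self.sap_positive_count:
            raise ValidationError(
                f"sap_positive_count={self.sap_positive_count} but "
                f"{n_pos} per-symptom results are flagged positive"
            )

    @property
    def sap_positive(self) -> bool:
        """Patient-level flag: at least one SAP-positive symptom."""
        return self.sap_positive_count >= 1

    def tracked_symptoms(self) -> tuple[str, ...]:
        return tuple(self.per_symptom_sap)


@dataclass
class CohortTable:
    """An ordered collection of patient records."""

    patients: list[PatientRecord]

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.patients)

    def __getitem__(self, i):
        return self.patients[i]


# ---------------------------------------------------------------------------
# Trace I/O
# ---------------------------------------------------------------------------

def _read_csv_rows(path, expected_header: Sequence[str]):
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file") from None
        if [h.strip() for h in header] != list(expected_header):
            raise ValidationError(
                f"{path}: malformed header {header!r}, "
                f"expected {','.join(expected_header)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            yield lineno, row


def read_trace(path, annotations=None, recording_id: str | None = None,
               sample_interval_s: float | None = None) -> PHTrace:
    """Read a pH trace CSV (header ``time_s,ph``) and optional annotations.

    Unparseable rows raise :class:`ValidationError` naming the line number.
    The sample interval defaults to the modal spacing of the time column.
    """
    times: list[float] = []
    phs: list[float] = []
    for lineno, row in _read_csv_rows(path, ("time_s", "ph")):
        if len(row) != 2:
            raise ValidationError(f"{path}:{lineno}: expected 2 fields, got {len(row)}")
        try:
            times.append(float(row[0]))
            phs.append(float(row[1]))
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from None
    if not times:
        raise ValidationError(f"{path}: no samples")
    if sample_interval_s is None:
        if len(times) > 1:
            diffs = np.diff(times)
            sample_interval_s = float(np.median(diffs))
        else:
            sample_interval_s = 6.0

    posture: list[tuple[float, float, str]] | None = None
    meals: list[tuple[float, float]] = []
    if annotations is not None:
        posture = []
        for lineno, row in _read_csv_rows(annotations, ("start_s", "end_s", "kind")):
            try:
                start, end = float(row[0]), float(row[1])
            except ValueError as exc:
                raise ValidationError(f"{annotations}:{lineno}: {exc}") from None
            kind = row[2].strip()
            if kind in POSTURES:
                posture.append((start, end, kind))
            elif kind == "meal":
                meals.append((start, end))
            else:
                raise ValidationError(
                    f"{annotations}:{lineno}: unknown annotation kind {kind!r}"
                )
        if not posture:
            posture = None

    if recording_id is None:
        import os
        recording_id = os.path.splitext(os.path.basename(str(path)))[0]
    return PHTrace(
        recording_id=recording_id,
        times=np.array(times),
        ph=np.array(phs),
        sample_interval_s=sample_interval_s,
        posture_intervals=posture,
        meal_intervals=meals,
    )


def write_trace(trace: PHTrace, path, annotations=None) -> None:
    """Write a trace (and optionally its annotations) in canonical form."""
    with open(path, "w", newline="") as fh:
        fh.write("time_s,ph\n")
        for t, p in zip(trace.times, trace.ph):
            fh.write(f"{_fmt(t)},{_fmt(p)}\n")
    if annotations is not None:
        with open(annotations, "w", newline="") as fh:
            fh.write("start_s,end_s,kind\n")
            rows = [(s, e, k) for s, e, k in trace.posture_intervals]
            rows += [(s, e, "meal") for s, e in trace.meal_intervals]
            for s, e, k in sorted(rows):
                fh.write(f"{_fmt(s)},{_fmt(e)},{k}\n")


# ---------------------------------------------------------------------------
# Symptom log I/O
# ---------------------------------------------------------------------------

def read_symptom_log(path, strict: bool = False) -> SymptomEventLog:
    """Read a symptom log JSON file.

    In strict mode unknown symptom labels raise; otherwise they are kept as
    free text (category ``other``) with a warning.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"{path}: invalid JSON: {exc}") from None
    for key in ("recording_id", "tracked_symptoms", "events"):
        if key not in doc:
            raise ValidationError(f"{path}: missing key {key!r}")
    tracked = tuple(doc["tracked_symptoms"])
    for name in tracked:
        if name not in KNOWN_SYMPTOMS:
            if strict:
                raise ValidationError(f"{path}: unknown symptom label {name!r}")
            warnings.warn(
                f"unknown symptom label {name!r}: treating as category 'other'"
            )
    events = [(float(e["time_s"]), str(e["symptom"])) for e in doc["events"]]
    return SymptomEventLog(
        recording_id=str(doc["recording_id"]),
        tracked_symptoms=tracked,
        events=events,
    )


def write_symptom_log(log: SymptomEventLog, path) -> None:
    doc = {
        "recording_id": log.recording_id,
        "tracked_symptoms": list(log.tracked_symptoms),
        "events": [{"time_s": t, "symptom": s} for t, s in log.events],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------

def _sap_to_json(per_symptom_sap: dict) -> str:
    out = {}
    for name, r in per_symptom_sap.items():
        entry = {
            "p_value": r.p_value,
            "sap_pct": r.sap_pct,
            "positive": bool(r.positive),
            "assessable": bool(r.assessable),
        }
        if r.table is not None:
            entry["table"] = [r.table.a, r.table.b, r.table.c, r.table.d]
        out[name] = entry
    return json.dumps(out, sort_keys=True, separators=(",", ":"))


def _sap_from_json(cell: str) -> dict:
    from .symptom_association import ContingencyTable2x2, SAPResult

    out = {}
    for name, entry in json.loads(cell).items():
        table = None
        if "table" in entry:
            table = ContingencyTable2x2(*entry["table"])
        out[name] = SAPResult(
            symptom=name,
            table=table,
            p_value=entry["p_value"],
            sap_pct=entry["sap_pct"],
            positive=entry["positive"],
            assessable=entry.get("assessable", True),
        )
    return out


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        return _fmt(value)
    return str(value)


def _parse_bool(cell: str, where: str) -> bool:
    if cell == "true":
        return True
    if cell == "false":
        return False
    raise ValidationError(f"{where}: expected true/false, got {cell!r}")


def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort table as CSV in canonical column order."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(COHORT_COLUMNS)
        for p in table:
            writer.writerow([
                p.patient_id,
                _cell(float(p.age)),  # canonical: numeric fields as floats
                p.sex,
                _cell(float(p.bmi)),
                _cell(p.preop_hrql),
                _cell(p.postop_hrql),
                _cell(p.satisfied),
                _cell(p.ppi_free),
                p.fundoplication,
                _cell(p.followup_months),
                _cell(p.demeester),
                _cell(p.sap_positive_count),
                _sap_to_json(p.per_symptom_sap),
            ])


def read_cohort(path) -> CohortTable:
    """Read a cohort CSV written by :func:`write_cohort`."""
    patients: list[PatientRecord] = []
    for lineno, row in _read_csv_rows(path, COHORT_COLUMNS):
        if len(row) != len(COHORT_COLUMNS):
            raise ValidationError(
                f"{path}:{lineno}: expected {len(COHORT_COLUMNS)} fields, "
                f"got {len(row)}"
            )
        d = dict(zip(COHORT_COLUMNS, row))
        where = f"{path}:{lineno}"
        try:
            patients.append(PatientRecord(
                patient_id=d["patient_id"],
                age=float(d["age"]),
                sex=d["sex"],
                bmi=float(d["bmi"]),
                preop_hrql=int(d["preop_hrql"]),
                postop_hrql=int(d["postop_hrql"]) if d["postop_hrql"] else None,
                satisfied=_parse_bool(d["satisfied"], where) if d["satisfied"] else None,
                ppi_free=_parse_bool(d["ppi_free"], where) if d["ppi_free"] else None,
                fundoplication=d["fundoplication"],
                followup_months=float(d["followup_months"]),
                demeester=float(d["demeester"]),
                sap_positive_count=int(d["sap_positive_count"]),
                per_symptom_sap=_sap_from_json(d["per_symptom_sap"]) if d["per_symptom_sap"] else {},
            ))
        except (ValueError, KeyError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ValidationError(f"{where}: {exc}") from None
    return CohortTable(patients)
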