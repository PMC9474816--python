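"""Event-stream data model for ICU admissions.

An admission is a timestamped stream of clinical events drawn from seven
token-bearing domains (medical history, surgical history, examinations,
high-frequency device data, chart entries, medications, lab values) plus two
static numeric features (age, pre-ICU hospital length of stay). Times are
stored in hours relative to ICU admission (negative = before admission);
outcomes are stored in days.

On disk a cohort is JSONL: one admission object per line, events inline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterator

#: The seven token-bearing event domains.
DOMAINS = (
    "medical_history",
    "surgical_history",
    "examination",
    "high_frequency",
    "chart",
    "medication",
    "lab",
)

#: Domains whose payload is a code.
CODE_DOMAINS = frozenset({"medical_history", "surgical_history", "examination"})
#: Domains whose payload is numeric (variable_name, value, unit).
NUMERIC_DOMAINS = frozenset({"high_frequency", "lab"})


class CohortParseError(ValueError):
    """Malformed JSONL line; carries the 1-based line number."""

    def __init__(self, lineno: int, msg: str):
        super().__init__(f"line {lineno}: {msg}")
        self.lineno = lineno


class CohortValidationError(ValueError):
    """Semantically invalid record; names the offending admission."""

    def __init__(self, admission_id: str, msg: str):
        super().__init__(f"admission {admission_id!r}: {msg}")
        self.admission_id = admission_id


@dataclass(frozen=True)
class Event:
    """One timestamped observation in one domain.

    Exactly one payload kind is populated, determined by the domain:
    codes for medical/surgical/examination history; numeric for
    high-frequency and lab; numeric or text for chart; medication events
    carry a code (ATC + route) and optionally a numeric dose so tokens such
    as ``J01DH01_IV@50`` can be formed downstream.
    """

    domain: str
    time_h: float
    code: str | None = None
    variable_name: str | None = None
    value: float | None = None
    unit: str | None = None
    text: str | None = None

    def validate(self, admission_id: str = "?") -> None:
        if self.domain not in DOMAINS:
            raise CohortValidationError(admission_id, f"unknown domain {self.domain!r}")
        if not math.isfinite(self.time_h):
            raise CohortValidationError(admission_id, "non-finite time_h")
        has_code = self.code is not None
        has_num = self.value is not None or self.variable_name is not None
        has_text = self.text is not None
        d = self.domain
        # medication doses ride on the code; everywhere else numeric payloads
        # need a variable name
        if has_num and d != "medication" and (self.value is None or self.variable_name is None):
            raise CohortValidationError(
                admission_id, "numeric payload needs both variable_name and value"
            )
        if d in CODE_DOMAINS:
            if not has_code or has_num or has_text:
                raise CohortValidationError(admission_id, f"{d} event must carry a code only")
        elif d in NUMERIC_DOMAINS:
            if not has_num or has_code or has_text:
                raise CohortValidationError(
                    admission_id, f"{d} event must carry a numeric payload only"
                )
        elif d == "chart":
            if has_code or (has_num == has_text):
                raise CohortValidationError(
                    admission_id, "chart event must carry numeric or text payload"
                )
        elif d == "medication":
            if not has_code or has_text:
                raise CohortValidationError(
                    admission_id, "medication event must carry a code (optionally a dose)"
                )
        if has_num and not math.isfinite(self.value):
            raise CohortValidationError(admission_id, "non-finite numeric value")


@dataclass
class AdmissionRecord:
    """One ICU admission: static features, event stream and outcome."""

    patient_id: str
    admission_id: str
    age_years: float
    sex: str
    hospital_los_days: float
    birth_day_of_month: int
    outcome_time_d: float
    event_indicator: bool
    events: list[Event] = field(default_factory=list)

    def validate(self) -> None:
        aid = self.admission_id
        if self.age_years < 16:
            raise CohortValidationError(aid, f"age_years {self.age_years} < 16")
        if self.sex not in ("F", "M"):
            raise CohortValidationError(aid, f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.hospital_los_days < 0:
            raise CohortValidationError(aid, "negative hospital_los_days")
        if not 1 <= int(self.birth_day_of_month) <= 31:
            raise CohortValidationError(aid, f"birth_day_of_month {self.birth_day_of_month}")
        if not self.outcome_time_d > 0:
            raise CohortValidationError(aid, f"outcome_time_d {self.outcome_time_d} must be > 0")
        for ev in self.events:
            ev.validate(aid)
        self.events.sort(key=lambda e: e.time_h)


@dataclass
class CohortIndex:
    """A validated collection of admissions with a patient→admissions map."""

    admissions: list[AdmissionRecord]
    by_patient: dict[str, list[AdmissionRecord]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        self.by_patient = {}
        for adm in self.admissions:
            if adm.admission_id in seen:
                raise CohortValidationError(adm.admission_id, "duplicate admission_id")
            seen.add(adm.admission_id)
            self.by_patient.setdefault(adm.patient_id, []).append(adm)

    def __len__(self) -> int:
        return len(self.admissions)

    def __iter__(self) -> Iterator[AdmissionRecord]:
        return iter(self.admissions)

    def patients(self) -> list[str]:
        return list(self.by_patient)

    def subset(self, admissions: list[AdmissionRecord]) -> "CohortIndex":
        return CohortIndex(admissions=list(admissions))


def _event_to_json(ev: Event) -> dict:
    out = {"domain": ev.domain, "time_h": ev.time_h}
    for k in ("code", "variable_name", "value", "unit", "text"):
        v = getattr(ev, k)
        if v is not None:
            out[k] = v
    return out


def _admission_to_json(adm: AdmissionRecord) -> dict:
    out = asdict(adm)
    out["events"] = [_event_to_json(ev) for ev in adm.events]
    return out


_EVENT_KEYS = {"domain", "time_h", "code", "variable_name", "value", "unit", "text"}
_ADM_KEYS = {
    "patient_id", "admission_id", "age_years", "sex", "hospital_los_days",
    "birth_day_of_month", "outcome_time_d", "event_indicator", "events",
}


def read_cohort(path) -> CohortIndex:
    """Read and validate a JSONL cohort file (one admission per line).

    Events are returned sorted ascending by ``time_h``. Malformed JSON raises
    :class:`CohortParseError` naming the line; domain/payload mismatches raise
    :class:`CohortValidationError` naming the admission.
    """
    admissions: list[AdmissionRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CohortParseError(lineno, str(exc)) from exc
            if not isinstance(obj, dict) or not _ADM_KEYS - {"events"} <= set(obj):
                missing = _ADM_KEYS - {"events"} - set(obj if isinstance(obj, dict) else ())
                raise CohortParseError(lineno, f"missing keys {sorted(missing)}")
            unknown = set(obj) - _ADM_KEYS
            if unknown:
                raise CohortParseError(lineno, f"unknown keys {sorted(unknown)}")
            events = []
            for ej in obj.get("events", []):
                bad = set(ej) - _EVENT_KEYS
                if bad or "domain" not in ej or "time_h" not in ej:
                    raise CohortParseError(lineno, f"bad event object {ej!r}")
                events.append(Event(**ej))
            adm = AdmissionRecord(
                patient_id=str(obj["patient_id"]),
                admission_id=str(obj["admission_id"]),
                age_years=float(obj["age_years"]),
                sex=str(obj["sex"]),
                hospital_los_days=float(obj["hospital_los_days"]),
                birth_day_of_month=int(obj["birth_day_of_month"]),
                outcome_time_d=float(obj["outcome_time_d"]),
                event_indicator=bool(obj["event_indicator"]),
                events=events,
            )
            adm.validate()
            admissions.append(adm)
    return CohortIndex(admissions=admissions)


def write_cohort(cohort: CohortIndex, path) -> None:
    """Write a cohort as UTF-8 JSONL; inverse of :func:`read_cohort`."""
    with open(path, "w", encoding="utf-8") as fh:
        for adm in cohort:
            fh.write(json.dumps(_admission_to_json(adm), ensure_ascii=False))
            fh.write("\n")
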