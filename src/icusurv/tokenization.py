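"""Tokenization of heterogeneous clinical events.

Every event becomes one or more discrete tokens:

* numeric observations → ``<variable>@<percentile>`` (percentile of the value
  within the training distribution of that variable, mid-rank ECDF);
* free text → lowercased words;
* codes → themselves (medical-history ICD-10 codes truncated to block level).

High-frequency streams are first aggregated to hourly summary statistics
(min / max / median / std), each becoming its own derived variable.

Time is discretized relative to a prediction baseline (0/24/48/72 h after ICU
admission): events before baseline fall into six coarse bins (<1, 2–7, 8–30,
31–90, 91–365, >365 days before baseline), events after admission but before
baseline are stamped with their clock hour. Events at or after the baseline
are never visible (leakage guard).

Per domain, the unique training tokens form a vocabulary with reserved PAD(0)
and OOV(1) indices; its size drives the embedding dimensionality
``D = 6·alpha·V^(1/4)``.
"""

from __future__ import annotations

import json
import math
import re
import statistics
from dataclasses import dataclass, field

import numpy as np

from .data_model import DOMAINS, AdmissionRecord, CohortIndex, Event

PAD_INDEX = 0
OOV_INDEX = 1
PAD_SURFACE = "<PAD>"
OOV_SURFACE = "<OOV>"

#: Pre-baseline bins, oldest → newest, as (label, lower_days, upper_days)
#: measured backwards from baseline; half-open [lower, upper).
PRE_BINS = (
    (">365d", 365.0, math.inf),
    ("91–365d", 90.0, 365.0),
    ("31–90d", 30.0, 90.0),
    ("8–30d", 7.0, 30.0),
    ("2–7d", 1.0, 7.0),
    ("<1d", 0.0, 1.0),
)
PRE_BIN_LABELS = tuple(b[0] for b in PRE_BINS)


@dataclass(frozen=True)
class Token:
    domain: str
    surface: str


@dataclass(frozen=True)
class TimeSlot:
    """Either a coarse pre-baseline bin or a post-admission clock hour."""

    kind: str  # "pre" | "post"
    pre_bin: str | None = None
    post_hour: int | None = None

    def __post_init__(self):
        if self.kind == "pre":
            assert self.pre_bin in PRE_BIN_LABELS and self.post_hour is None
        elif self.kind == "post":
            assert self.post_hour is not None and self.post_hour >= 0 and self.pre_bin is None
        else:
            raise ValueError(f"bad slot kind {self.kind!r}")


def slot_layout(baseline_h: float) -> list[TimeSlot]:
    """The ordered slot sequence for a baseline: six pre bins, then hourly
    post slots 0 .. baseline_h−1 (none at or beyond the baseline)."""
    slots = [TimeSlot("pre", pre_bin=lbl) for lbl in PRE_BIN_LABELS]
    slots += [TimeSlot("post", post_hour=h) for h in range(int(baseline_h))]
    return slots


class PercentileTable:
    """Sorted training values per numeric variable (training split only)."""

    def __init__(self, values: dict[str, np.ndarray] | None = None):
        self.values: dict[str, np.ndarray] = {
            k: np.sort(np.asarray(v, dtype=float)) for k, v in (values or {}).items()
        }

    def __contains__(self, variable: str) -> bool:
        return variable in self.values

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({k: v.tolist() for k, v in self.values.items()}, fh)

    @classmethod
    def from_json(cls, path) -> "PercentileTable":
        with open(path, encoding="utf-8") as fh:
            return cls(json.load(fh))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def percentile_of(table: PercentileTable, variable: str, value: float) -> int:
    """Mid-rank empirical percentile of ``value`` in the training values.

    ``p = round(100 · F(v))`` with ``F(v) = (#{x < v} + 0.5·#{x = v}) / n``,
    clipped to [0, 100]. A value at the median of a symmetric sample maps to
    50. Raises ``KeyError`` for unknown variables (callers map to OOV).
    """
    if variable not in table:
        raise KeyError(variable)
    a = table.values[variable]
    lo = np.searchsorted(a, value, side="left")
    hi = np.searchsorted(a, value, side="right")
    f = (lo + 0.5 * (hi - lo)) / len(a)
    return min(100, max(0, _round_half_up(100.0 * f)))


def numeric_to_token(domain: str, variable: str, value: float, table: PercentileTable) -> Token:
    """``<variable>@<percentile>`` token; unknown variable → domain OOV token."""
    if not math.isfinite(value):
        raise ValueError(f"non-finite value for {variable!r}")
    try:
        p = percentile_of(table, variable, value)
    except KeyError:
        return Token(domain, OOV_SURFACE)
    return Token(domain, f"{variable}@{p}")


_HOURLY_STATS = ("min", "max", "median", "std")


def aggregate_hourly(events: list[Event]) -> list[Event]:
    """Collapse high-frequency numeric events to hourly summary statistics.

    Per (variable, clock hour) with at least one observation, emits four
    derived numeric events named ``<var>_min|_max|_median|_std`` stamped at
    that hour. Sample (ddof=1) standard deviation; a single observation in an
    hour yields std 0 so the four derived streams stay aligned.
    """
    groups: dict[tuple[str, int], list[float]] = {}
    for ev in events:
        if ev.value is None or ev.variable_name is None:
            raise ValueError("aggregate_hourly expects numeric events")
        hour = math.floor(ev.time_h)
        groups.setdefault((ev.variable_name, hour), []).append(ev.value)
    out: list[Event] = []
    for (var, hour), vals in sorted(groups.items()):
        stats = {
            "min": min(vals),
            "max": max(vals),
            "median": statistics.median(vals),
            "std": statistics.stdev(vals) if len(vals) > 1 else 0.0,
        }
        for name in _HOURLY_STATS:
            out.append(
                Event(
                    domain="high_frequency",
                    time_h=float(hour),
                    variable_name=f"{var}_{name}",
                    value=float(stats[name]),
                    unit=None,
                )
            )
    return out


_WORD_SPLIT = re.compile(r"[^a-z0-9æøå]+")


def text_to_tokens(text: str) -> list[Token]:
    """Lowercase and split on non-alphanumerics; empty fragments dropped."""
    return [Token("chart", w) for w in _WORD_SPLIT.split(text.lower()) if w]


def icd10_block(code: str) -> str:
    """Truncate an ICD-10 code to its 3-character category (the configurable
    default for 'block level'); a Danish 'D' prefix before the chapter letter
    is stripped, dots removed. E.g. ``DJ18.9`` → ``J18``."""
    c = code.replace(".", "").strip().upper()
    if len(c) >= 2 and c[0] == "D" and c[1].isalpha():
        c = c[1:]
    return c[:3]


def code_to_token(domain: str, code: str, block_fn=icd10_block) -> Token:
    """Codes become tokens; medical-history codes truncated to block level."""
    if domain == "medical_history":
        return Token(domain, block_fn(code))
    return Token(domain, code)


@dataclass
class Vocabulary:
    """Per-domain token→index map with reserved PAD=0 and OOV=1."""

    domain: str
    index: dict[str, int] = field(default_factory=dict)

    @classmethod
    def build(cls, domain: str, tokens) -> "Vocabulary":
        surfaces = sorted({t.surface if isinstance(t, Token) else str(t) for t in tokens})
        return cls(domain, {s: i + 2 for i, s in enumerate(surfaces)})

    @property
    def size(self) -> int:
        """Number of real tokens V (PAD/OOV excluded)."""
        return len(self.index)

    def __getitem__(self, surface: str) -> int:
        return self.index.get(surface, OOV_INDEX)

    def __contains__(self, surface: str) -> bool:
        return surface in self.index

    def to_json(self) -> dict:
        return {"domain": self.domain, "index": self.index}

    @classmethod
    def from_json(cls, obj: dict) -> "Vocabulary":
        return cls(obj["domain"], {k: int(v) for k, v in obj["index"].items()})


def build_vocabulary(domain: str, tokens) -> Vocabulary:
    return Vocabulary.build(domain, tokens)


def embedding_size(V: int, alpha: float) -> int:
    """Embedding dimensionality ``D = 6·alpha·V^(1/4)``, rounded half-up,
    floored at 1 (a degenerate PAD/OOV-only domain is still embeddable)."""
    if V <= 0:
        return 1
    return max(1, _round_half_up(6.0 * alpha * V ** 0.25))


def discretize_time(time_h: float, baseline_h: float) -> TimeSlot:
    """Map an event time to its slot for a given baseline.

    Events at or after the baseline raise: information after the prediction
    time must never reach the model.
    """
    if time_h >= baseline_h:
        raise ValueError(f"event at {time_h} h is not before baseline {baseline_h} h")
    if 0.0 <= time_h < baseline_h:
        return TimeSlot("post", post_hour=int(math.floor(time_h)))
    delta_d = (baseline_h - time_h) / 24.0
    for label, lo, hi in PRE_BINS:
        if lo <= delta_d < hi:
            return TimeSlot("pre", pre_bin=label)
    raise AssertionError("unreachable")


def _event_tokens(ev: Event, table: PercentileTable) -> list[Token]:
    d = ev.domain
    if d in ("medical_history", "surgical_history", "examination"):
        return [code_to_token(d, ev.code)]
    if d == "medication":
        if ev.value is not None:
            var = ev.code
            if var in table:
                return [numeric_to_token(d, var, ev.value, table)]
            return [Token(d, OOV_SURFACE)]
        return [Token(d, ev.code)]
    if d == "chart":
        if ev.text is not None:
            return text_to_tokens(ev.text)
        return [numeric_to_token(d, ev.variable_name, ev.value, table)]
    # lab and (already aggregated) high-frequency
    return [numeric_to_token(d, ev.variable_name, ev.value, table)]


def iter_admission_tokens(adm: AdmissionRecord, baseline_h: float, table: PercentileTable):
    """Yield (TimeSlot, Token) for every visible event of an admission.

    High-frequency events are hourly-aggregated first; events at or after the
    baseline are skipped (they are invisible, not an error here — the hard
    guard lives in :func:`discretize_time` / :func:`tokenize_admission`).
    """
    hf = [ev for ev in adm.events if ev.domain == "high_frequency"]
    rest = [ev for ev in adm.events if ev.domain != "high_frequency"]
    derived = [ev for ev in aggregate_hourly(hf) if ev.time_h < baseline_h]
    for ev in rest + derived:
        if ev.time_h >= baseline_h:
            continue
        slot = discretize_time(ev.time_h, baseline_h)
        for tok in _event_tokens(ev, table):
            yield slot, tok


def fit_percentiles(training_cohort: CohortIndex, baseline_h: float = math.inf) -> PercentileTable:
    """Collect per-variable training values for percentile tokenization.

    Tokenizable numeric streams: medication doses (keyed by the medication
    code), chart numerics, lab values, and the derived hourly statistics of
    high-frequency streams (which get their own entries, e.g.
    ``InvSysBP_max``). Only events before ``baseline_h`` contribute, so the
    table never sees post-baseline data.
    """
    if len(training_cohort) == 0:
        raise ValueError("empty training cohort")
    acc: dict[str, list[float]] = {}
    for adm in training_cohort:
        hf = [ev for ev in adm.events if ev.domain == "high_frequency"]
        rest = [ev for ev in adm.events if ev.domain != "high_frequency"]
        for ev in rest + aggregate_hourly(hf):
            if ev.time_h >= baseline_h or ev.value is None:
                continue
            key = ev.code if ev.domain == "medication" else ev.variable_name
            if key is None:
                continue
            acc.setdefault(key, []).append(ev.value)
    return PercentileTable(acc)


@dataclass
class TokenizedAdmission:
    """Per-(slot, domain) token-index lists for one admission."""

    admission_id: str
    slots: list[TimeSlot]
    #: domain → list (per slot) of token-index lists
    indices: dict[str, list[list[int]]]
    age_years: float
    hospital_los_days: float


def tokenize_admission(
    adm: AdmissionRecord,
    baseline_h: float,
    table: PercentileTable,
    vocabularies: dict[str, Vocabulary],
) -> TokenizedAdmission:
    """Tokenize every visible event of an admission into its (slot, domain)
    bucket. The admission must be alive at the baseline."""
    if not adm.outcome_time_d * 24.0 > baseline_h:
        raise ValueError(
            f"admission {adm.admission_id!r} not alive at baseline {baseline_h} h"
        )
    slots = slot_layout(baseline_h)
    pos = {s: i for i, s in enumerate(slots)}
    indices = {d: [[] for _ in slots] for d in DOMAINS}
    for slot, tok in iter_admission_tokens(adm, baseline_h, table):
        indices[tok.domain][pos[slot]].append(vocabularies[tok.domain][tok.surface])
    return TokenizedAdmission(
        admission_id=adm.admission_id,
        slots=slots,
        indices=indices,
        age_years=adm.age_years,
        hospital_los_days=adm.hospital_los_days,
    )


class Tokenizer:
    """Fitted tokenization state: percentile table + per-domain vocabularies.

    Fit on the training split only; at transform time unseen tokens map to
    OOV, so every test-time token has a valid index.
    """

    def __init__(self, baseline_h: float, table: PercentileTable,
                 vocabularies: dict[str, Vocabulary]):
        self.baseline_h = baseline_h
        self.table = table
        self.vocabularies = vocabularies

    @classmethod
    def fit(cls, training_cohort: CohortIndex, baseline_h: float) -> "Tokenizer":
        table = fit_percentiles(training_cohort, baseline_h)
        per_domain: dict[str, set[str]] = {d: set() for d in DOMAINS}
        for adm in training_cohort:
            if not adm.outcome_time_d * 24.0 > baseline_h:
                continue
            for _slot, tok in iter_admission_tokens(adm, baseline_h, table):
                per_domain[tok.domain].add(tok.surface)
        vocabs = {
            d: Vocabulary(d, {s: i + 2 for i, s in enumerate(sorted(toks - {OOV_SURFACE}))})
            for d, toks in per_domain.items()
        }
        return cls(baseline_h, table, vocabs)

    def transform(self, adm: AdmissionRecord) -> TokenizedAdmission:
        return tokenize_admission(adm, self.baseline_h, self.table, self.vocabularies)

    def transform_cohort(self, cohort: CohortIndex) -> list[TokenizedAdmission]:
        return [self.transform(a) for a in cohort]

    def save(self, path) -> None:
        obj = {
            "baseline_h": self.baseline_h,
            "percentiles": {k: v.tolist() for k, v in self.table.values.items()},
            "vocabularies": {d: v.to_json() for d, v in self.vocabularies.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh)

    @classmethod
    def load(cls, path) -> "Tokenizer":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        return cls(
            obj["baseline_h"],
            PercentileTable(obj["percentiles"]),
            {d: Vocabulary.from_json(v) for d, v in obj["vocabularies"].items()},
        )
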