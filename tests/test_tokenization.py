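"""Tokenization: percentiles, hourly aggregation, words, codes, time slots,
vocabularies and embedding sizing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import icusurv.tokenization as tk
from icusurv.data_model import CohortIndex, Event
from .conftest import make_admission


# ---------------------------------------------------------------- percentiles
def _table(**kw):
    return tk.PercentileTable(kw)


@pytest.mark.parametrize(
    "values, query, expected",
    [
        ([1, 2, 3], 2, 50),       # mid-rank: (1 + 0.5)/3
        ([1, 2, 3], 3, 83),       # (2 + 0.5)/3 = 0.8333
        ([1, 2, 3], 99, 100),     # clipped above training range
        ([1, 2, 3], -5, 0),       # clipped below
        (list(range(1, 100)), 50, 50),  # median of symmetric sample → 50
    ],
)
def test_percentile_examples(values, query, expected):
    assert tk.percentile_of(_table(x=values), "x", query) == expected


def test_percentile_unknown_variable_raises():
    with pytest.raises(KeyError):
        tk.percentile_of(_table(x=[1.0]), "y", 1.0)


@given(
    values=st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=40),
    queries=st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=10),
)
@settings(max_examples=100, deadline=None)
def test_percentile_monotone_and_bounded(values, queries):
    table = _table(v=values)
    ps = [tk.percentile_of(table, "v", q) for q in sorted(queries)]
    assert all(0 <= p <= 100 for p in ps)
    assert ps == sorted(ps)


def test_numeric_token_at_median_and_oov():
    table = _table(J01DH01_IV=list(range(1, 100)))
    tok = tk.numeric_to_token("medication", "J01DH01_IV", 50.0, table)
    assert tok.surface == "J01DH01_IV@50"
    assert tk.numeric_to_token("lab", "NPU03429", 1e9, _table(NPU03429=[1, 2])).surface == "NPU03429@100"
    assert tk.numeric_to_token("lab", "unseen", 1.0, table).surface == tk.OOV_SURFACE
    with pytest.raises(ValueError):
        tk.numeric_to_token("lab", "J01DH01_IV", float("nan"), table)


# ------------------------------------------------------------- hourly summary
def test_aggregate_hourly_summary_statistics():
    evs = [
        Event("high_frequency", 3.1, variable_name="InvSysBP", value=120.0),
        Event("high_frequency", 3.5, variable_name="InvSysBP", value=125.0),
        Event("high_frequency", 3.9, variable_name="InvSysBP", value=130.0),
    ]
    out = {e.variable_name: e for e in tk.aggregate_hourly(evs)}
    assert out["InvSysBP_min"].value == 120
    assert out["InvSysBP_max"].value == 130
    assert out["InvSysBP_median"].value == 125
    assert out["InvSysBP_std"].value == pytest.approx(5.0)
    assert all(e.time_h == 3.0 for e in out.values())


def test_aggregate_hourly_single_reading_and_empty():
    single = tk.aggregate_hourly(
        [Event("high_frequency", -2.5, variable_name="HR", value=80.0)]
    )
    vals = {e.variable_name: e.value for e in single}
    assert vals == {"HR_min": 80, "HR_max": 80, "HR_median": 80, "HR_std": 0.0}
    assert {e.time_h for e in single} == {-3.0}
    assert tk.aggregate_hourly([]) == []


# --------------------------------------------------------------- words, codes
@pytest.mark.parametrize(
    "text, words",
    [
        ("a three-word note", ["a", "three", "word", "note"]),
        ("", []),
        ("BP stable", ["bp", "stable"]),
        ("  Pt.  afebrile!! ", ["pt", "afebrile"]),
    ],
)
def test_text_to_tokens(text, words):
    assert [t.surface for t in tk.text_to_tokens(text)] == words


@pytest.mark.parametrize(
    "domain, code, surface",
    [
        ("medical_history", "DJ18.9", "J18"),
        ("medical_history", "I50.0", "I50"),
        ("surgical_history", "KNGB40", "KNGB40"),
        ("examination", "UXRC001", "UXRC001"),
    ],
)
def test_code_to_token(domain, code, surface):
    assert tk.code_to_token(domain, code).surface == surface


# ----------------------------------------------------------------- time slots
@pytest.mark.parametrize(
    "time_h, baseline_h, expected",
    [
        (-120.0, 0.0, ("pre", "2–7d")),      # 5 days before a 0 h baseline
        (3.2, 24.0, ("post", 3)),
        (-0.5, 0.0, ("pre", "<1d")),
        (-24.0 * 400, 0.0, ("pre", ">365d")),
        (23.99, 24.0, ("post", 23)),
        (-144.0, 24.0, ("pre", "8–30d")),    # exactly 7 days → half-open [7,30)
    ],
)
def test_discretize_time(time_h, baseline_h, expected):
    slot = tk.discretize_time(time_h, baseline_h)
    if expected[0] == "pre":
        assert (slot.kind, slot.pre_bin) == expected
    else:
        assert (slot.kind, slot.post_hour) == expected


def test_discretize_time_rejects_future():
    with pytest.raises(ValueError):
        tk.discretize_time(30.0, 24.0)
    with pytest.raises(ValueError):
        tk.discretize_time(0.0, 0.0)


# --------------------------------------------------------- vocabulary, sizing
def test_vocabulary_sorted_dense_indices():
    v = tk.build_vocabulary("lab", [tk.Token("lab", "b"), tk.Token("lab", "a"),
                                    tk.Token("lab", "b")])
    assert v.size == 2
    assert v["a"] == 2 and v["b"] == 3
    assert v["unseen"] == tk.OOV_INDEX


def test_vocabulary_empty_domain():
    v = tk.build_vocabulary("chart", [])
    assert v.size == 0
    assert v["anything"] == tk.OOV_INDEX


@pytest.mark.parametrize(
    "V, alpha, D",
    [(10_000, 1.0, 60), (1000, 1.0, 34), (1, 1.0, 6), (16, 0.5, 6), (0, 1.0, 1)],
)
def test_embedding_size_examples(V, alpha, D):
    assert tk.embedding_size(V, alpha) == D


@given(v1=st.integers(1, 10**6), v2=st.integers(1, 10**6),
       a=st.floats(0.2, 2.0))
@settings(max_examples=100, deadline=None)
def test_embedding_size_monotone(v1, v2, a):
    lo, hi = sorted((v1, v2))
    assert tk.embedding_size(lo, a) <= tk.embedding_size(hi, a)
    assert tk.embedding_size(v1, 0.2) <= tk.embedding_size(v1, a)


@given(v=st.integers(1000, 10**6), a=st.floats(0.2, 1.0))
@settings(max_examples=50, deadline=None)
def test_embedding_reduces_dimensionality_30_fold(v, a):
    assert v / tk.embedding_size(v, a) >= 30


# ------------------------------------------------------ fitted tokenizer path
def test_fit_percentiles_collects_derived_variables(tiny_cohort):
    table = tk.fit_percentiles(tiny_cohort)
    assert "NPU03429" in table
    assert "InvSysBP_max" in table        # derived hourly statistic
    assert "J01DH01_IV" in table          # medication dose keyed by code
    assert list(table.values["NPU03429"]) == [5.0, 7.0]


def test_fit_percentiles_empty_cohort_errors():
    with pytest.raises(ValueError):
        tk.fit_percentiles(CohortIndex([]))


def test_tokenize_admission_composition(tiny_cohort):
    tok = tk.Tokenizer.fit(tiny_cohort, baseline_h=0.0)
    adm = make_admission(
        "B1", "P9",
        [Event("medical_history", -240.0, code="DJ189")],  # 10 days before
        outcome_time_d=5.0, event_indicator=True,
    )
    ta = tok.transform(adm)
    idx = [i for i, s in enumerate(ta.slots) if s.pre_bin == "8–30d"][0]
    assert len(ta.indices["medical_history"][idx]) == 1
    assert all(not lst for d, sl in ta.indices.items() for j, lst in enumerate(sl)
               if (d, j) != ("medical_history", idx))


def test_tokenize_admission_post_baseline_words():
    cohort = CohortIndex([make_admission(
        "C1", "P1", [Event("chart", 5.4, text="bp stable")], outcome_time_d=10.0)])
    tok = tk.Tokenizer.fit(cohort, baseline_h=24.0)
    ta = tok.transform(cohort.admissions[0])
    idx = [i for i, s in enumerate(ta.slots) if s.post_hour == 5][0]
    assert len(ta.indices["chart"][idx]) == 2


def test_tokenize_requires_alive_at_baseline(tiny_cohort):
    tok = tk.Tokenizer.fit(tiny_cohort, baseline_h=24.0)
    dead = make_admission("D1", "P5", [], outcome_time_d=0.5, event_indicator=True)
    with pytest.raises(ValueError):
        tok.transform(dead)


def test_no_future_leakage(tiny_cohort):
    """Mutating events at/after the baseline never changes the tokenization."""
    tok = tk.Tokenizer.fit(tiny_cohort, baseline_h=24.0)
    base = make_admission(
        "E1", "P7",
        [Event("lab", 2.0, variable_name="NPU03429", value=6.0, unit="au")],
        outcome_time_d=50.0,
    )
    mutated = make_admission(
        "E1", "P7",
        base.events + [
            Event("chart", 24.0, text="future information galore"),
            Event("lab", 500.0, variable_name="NPU03429", value=-99.0, unit="au"),
        ],
        outcome_time_d=50.0,
    )
    assert tok.transform(base).indices == tok.transform(mutated).indices


def test_unseen_tokens_map_to_oov(tiny_cohort):
    tok = tk.Tokenizer.fit(tiny_cohort, baseline_h=0.0)
    novel = make_admission(
        "F1", "P8",
        [Event("medical_history", -50.0, code="DZ999"),
         Event("lab", -1.0, variable_name="NPU_NEW", value=1.0, unit="au")],
        outcome_time_d=9.0,
    )
    ta = tok.transform(novel)
    flat = [i for d in ta.indices.values() for sl in d for i in sl]
    assert flat and all(i == tk.OOV_INDEX for i in flat)
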