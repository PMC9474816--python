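"""Discrete-time survival labels.

Follow-up is partitioned into windows [0,1), [1,7), [7,14), [14,30), [30,90),
[90,365) days from baseline. Each outcome becomes two indicator vectors:
``surv_s[i]`` = survived window i, ``surv_f[i]`` = died in window i. Windows
after death or censoring are all-zero, so they contribute nothing to the
likelihood.

Censoring rule: a patient right-censored in the second half of a window is
considered to have survived that window; censored in the first half, only the
preceding windows. Follow-up is administratively censored at the last window
edge (365 days): survivors past it are labelled all-survived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import CohortIndex

DEFAULT_WINDOW_EDGES = (1.0, 7.0, 14.0, 30.0, 90.0, 365.0)


@dataclass(frozen=True)
class WindowSpec:
    """Strictly increasing window upper edges, in days from baseline."""

    edges: tuple[float, ...] = DEFAULT_WINDOW_EDGES

    def __post_init__(self):
        e = self.edges
        if not e or any(b <= a for a, b in zip((0.0,) + e, e)):
            raise ValueError("edges must be positive and strictly increasing")

    @property
    def n(self) -> int:
        return len(self.edges)

    def bounds(self, i: int) -> tuple[float, float]:
        """Half-open bounds [lower, upper) of window i."""
        lower = 0.0 if i == 0 else self.edges[i - 1]
        return lower, self.edges[i]

    def window_of(self, t: float) -> int:
        """Index of the window containing time t (half-open intervals); t at
        or past the last edge returns n (beyond follow-up)."""
        return int(np.searchsorted(np.asarray(self.edges), t, side="right"))


@dataclass(frozen=True)
class SurvivalLabel:
    surv_s: tuple[int, ...]
    surv_f: tuple[int, ...]

    def __post_init__(self):
        s, f = self.surv_s, self.surv_f
        assert len(s) == len(f)
        assert sum(f) <= 1
        assert all(si + fi <= 1 for si, fi in zip(s, f))
        # surv_s is a prefix of ones; a failure at k follows exactly k ones
        k = sum(s)
        assert s == tuple([1] * k + [0] * (len(s) - k))
        if 1 in f:
            assert f.index(1) == k


def make_labels(
    outcome_time_d: float,
    event: bool,
    windows: WindowSpec = WindowSpec(),
    baseline_h: float = 0.0,
) -> SurvivalLabel:
    """Label one outcome relative to a prediction baseline.

    ``t = outcome_time_d − baseline_h/24`` must be positive (alive at
    baseline). Deaths at or past the last edge are treated as administratively
    censored survivors of all windows.
    """
    n = windows.n
    t = outcome_time_d - baseline_h / 24.0
    if not t > 0:
        raise ValueError("subject not alive at baseline")
    k = windows.window_of(t)
    if k >= n:  # survived the whole follow-up (administrative censoring)
        return SurvivalLabel(tuple([1] * n), tuple([0] * n))
    s = [0] * n
    f = [0] * n
    if event:
        for i in range(k):
            s[i] = 1
        f[k] = 1
    else:
        lo, hi = windows.bounds(k)
        survived_k = t >= (lo + hi) / 2.0  # ties at the midpoint → survived
        for i in range(k + (1 if survived_k else 0)):
            s[i] = 1
    return SurvivalLabel(tuple(s), tuple(f))


def labels_to_arrays(labels: list[SurvivalLabel]) -> tuple[np.ndarray, np.ndarray]:
    """Stack labels into (n_subjects, n_windows) int arrays (s, f)."""
    s = np.array([lb.surv_s for lb in labels], dtype=np.int8)
    f = np.array([lb.surv_f for lb in labels], dtype=np.int8)
    return s, f


def filter_alive_at_baseline(cohort: CohortIndex, baseline_h: float) -> CohortIndex:
    """Retain admissions whose outcome (death or censoring) falls strictly
    after the baseline; predictions are only defined for subjects at risk."""
    keep = [a for a in cohort if a.outcome_time_d * 24.0 > baseline_h]
    return cohort.subset(keep)
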