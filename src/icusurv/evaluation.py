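"""Discrimination and calibration of survival predictions.

* Kaplan–Meier product-limit estimation (delegated to lifelines) with
  Greenwood-based 95% confidence intervals.
* The time-dependent concordance index C^td: over comparable pairs (i, j)
  with T_i < T_j and subject i uncensored, the fraction where the model
  assigns i the lower survival score. Tied scores earn no credit (the
  original estimator without the tie modification).
* Percentile-bootstrap confidence intervals over subjects.
* Decile calibration tables: mean predicted survival per decile group versus
  the KM estimate within the group at the window's upper edge.
* Life-table (empirical discrete-hazard) estimates, from raw outcomes or
  from survive/fail label matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from .labels import WindowSpec


@dataclass
class KMCurve:
    times: np.ndarray            # distinct event times (days)
    survival: np.ndarray         # S(t) at those times, nonincreasing
    at_risk: np.ndarray          # risk-set size just before each time
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None

    def at(self, t: float) -> float:
        """Step-function evaluation S(t) (right-continuous)."""
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])


def kaplan_meier(times, events, ci: bool = True) -> KMCurve:
    """Product-limit estimator; censored subjects leave the risk set after
    their censoring time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    keep = grid > 0
    grid, surv = grid[keep], surv[keep]
    at_risk = np.array([(times >= t).sum() for t in grid])
    lo = hi = None
    if ci:
        band = kmf.confidence_interval_survival_function_
        lo = band.iloc[:, 0].to_numpy(dtype=float)[keep]
        hi = band.iloc[:, 1].to_numpy(dtype=float)[keep]
    return KMCurve(grid, surv, at_risk, lo, hi)


def _c_td_single(scores, times, events) -> tuple[float, int]:
    """Vectorized concordance over comparable pairs for one score vector."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    # pair (i, j) comparable iff t_i < t_j and i had the event
    earlier = t[:, None] < t[None, :]
    comparable = earlier & e[:, None]
    np.fill_diagonal(comparable, False)
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    concordant = comparable & (s[:, None] < s[None, :])  # ties count 0
    return float(concordant.sum() / n_pairs), n_pairs


def c_td(
    surv_scores,
    times,
    events,
    windows: WindowSpec | None = None,
    truncate: bool = True,
):
    """Time-dependent concordance.

    With a 1-D score vector, returns ``(C, n_pairs)`` for that single score.
    With a (n_subjects, n_windows) matrix of cumulative predicted survival,
    returns per-window ``(C_w, n_pairs_w)`` lists; by default follow-up is
    administratively truncated at each window's upper edge (deaths beyond it
    count as censored at the edge).
    """
    s = np.asarray(surv_scores, dtype=float)
    if s.ndim == 1:
        return _c_td_single(s, times, events)
    assert windows is not None, "windows required for per-window scores"
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    out_c, out_n = [], []
    for w, edge in enumerate(windows.edges):
        if truncate:
            tw = np.minimum(t, edge)
            ew = e & (t < edge)
        else:
            tw, ew = t, e
        cw, nw = _c_td_single(s[:, w], tw, ew)
        out_c.append(cw)
        out_n.append(nw)
    return out_c, out_n


@dataclass
class ConcordanceResult:
    windows: WindowSpec
    c_td: list[float]
    ci_lower: list[float]
    ci_upper: list[float]
    n_pairs: list[int]


def bootstrap_ci(metric_fn, n_subjects: int, n_boot: int = 1000, seed: int = 0,
                 alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap over subjects: ``metric_fn(idx)`` is evaluated on
    ``n_boot`` seeded resamples (with replacement) of subject indices."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, n_subjects, size=n_subjects)
        try:
            stats.append(metric_fn(idx))
        except ValueError:  # degenerate resample without comparable pairs
            continue
    stats = np.asarray(stats, dtype=float)
    return (float(np.percentile(stats, 100 * alpha / 2)),
            float(np.percentile(stats, 100 * (1 - alpha / 2))))


def concordance_with_ci(
    surv_matrix, times, events, windows: WindowSpec,
    n_boot: int = 1000, seed: int = 0, truncate: bool = True,
) -> ConcordanceResult:
    """Per-window C^td with 1000-resample percentile bootstrap CIs."""
    s = np.asarray(surv_matrix, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    point, n_pairs = c_td(s, t, e, windows, truncate=truncate)
    lo, hi = [], []
    for w in range(windows.n):
        def metric(idx, w=w):
            c, _ = c_td(s[idx][:, [w]], t[idx], e[idx],
                        WindowSpec((windows.edges[w],)), truncate=truncate)
            return c[0]
        l, h = bootstrap_ci(metric, len(t), n_boot=n_boot, seed=seed + w)
        lo.append(l)
        hi.append(h)
    return ConcordanceResult(windows, point, lo, hi, n_pairs)


@dataclass
class CalibrationTable:
    """Per window: decile-group mean predicted vs KM-observed survival."""

    edge_days: float
    mean_predicted: np.ndarray   # (10,) NaN where the group is empty
    km_observed: np.ndarray      # (10,)
    group_size: np.ndarray       # (10,) int
    empty_groups: np.ndarray     # (10,) bool


def calibration_table(predicted, times, events, edge_days: float) -> CalibrationTable:
    """Group subjects by deciles of predicted survival for one window and
    compare the group-mean prediction with the group KM estimate at the
    window's upper edge. Degenerate prediction distributions (ties across
    decile edges) leave some groups empty; those are flagged."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if p.size < 10:
        raise ValueError("need at least 10 subjects")
    edges = np.quantile(p, np.linspace(0.1, 0.9, 9))
    group = np.searchsorted(edges, p, side="left")  # 0..9, ascending in p
    mean_pred = np.full(10, np.nan)
    km_obs = np.full(10, np.nan)
    size = np.zeros(10, dtype=int)
    for g in range(10):
        mask = group == g
        size[g] = int(mask.sum())
        if size[g] == 0:
            continue
        mean_pred[g] = p[mask].mean()
        km_obs[g] = kaplan_meier(t[mask], e[mask], ci=False).at(edge_days)
    return CalibrationTable(edge_days, mean_pred, km_obs, size, size == 0)


def life_table_hazards(times, events, windows: WindowSpec) -> np.ndarray:
    """Empirical discrete hazards: deaths in each window divided by subjects
    at risk entering it (censored subjects leave the risk set at the start of
    the window containing their censoring time)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    haz = np.zeros(windows.n)
    for w in range(windows.n):
        lo, hi = windows.bounds(w)
        n_risk = int((t >= lo).sum())
        deaths = int((e & (t >= lo) & (t < hi)).sum())
        haz[w] = deaths / n_risk if n_risk else np.nan
    return haz


def life_table_from_labels(surv_s: np.ndarray, surv_f: np.ndarray) -> np.ndarray:
    """Discrete hazards under the labelling convention: failures in a window
    divided by subjects contributing to it (s_i + f_i = 1). This is the
    maximum-likelihood hazard of the intercept-only discrete-time model."""
    s = np.asarray(surv_s, dtype=float)
    f = np.asarray(surv_f, dtype=float)
    denom = (s + f).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, f.sum(axis=0) / denom, np.nan)
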