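"""Cox proportional-hazards comparison model on (age, sex, hospital LOS).

The fit delegates to scikit-survival's partial-likelihood maximizer with
Breslow tie handling and a Breslow baseline cumulative hazard; predictions
are ``S(t) = exp(−Λ₀(t)·exp(xβ))`` evaluated at the prediction-window edges.
Because risk scores are time-constant under proportional hazards, the
concordance of Cox predictions is identical at every window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sksurv.linear_model import CoxPHSurvivalAnalysis

from .data_model import CohortIndex
from .labels import WindowSpec

_COVARIATES = ("age_years", "sex_male", "hospital_los_days")


class ConstantCovariateError(ValueError):
    def __init__(self, name: str):
        super().__init__(f"covariate {name!r} is constant in the training data")
        self.name = name


@dataclass
class CoxFit:
    coefficients: dict[str, float]
    model: CoxPHSurvivalAnalysis

    def risk_score(self, X: np.ndarray) -> np.ndarray:
        """Linear predictor xβ per subject (columns in coefficient order)."""
        beta = np.array(list(self.coefficients.values()))
        return X @ beta

    def baseline_cumulative_hazard(self):
        fn = self.model.cum_baseline_hazard_
        return fn.x, fn.y


def _design(cohort: CohortIndex, baseline_h: float):
    X = np.array(
        [[a.age_years, 1.0 if a.sex == "M" else 0.0, a.hospital_los_days]
         for a in cohort],
        dtype=float,
    )
    times = np.array([a.outcome_time_d - baseline_h / 24.0 for a in cohort])
    events = np.array([a.event_indicator for a in cohort], dtype=bool)
    return X, times, events


def fit_cox_design(X, times, events, names=None, tol: float = 1e-9) -> CoxFit:
    """Fit a Cox model on an explicit design matrix (columns = covariates).

    Breslow tie handling; convergence controlled by the partial-likelihood
    coefficient tolerance. Constant covariates are rejected by name.
    """
    X = np.asarray(X, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    if events.sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise ConstantCovariateError(name)
    y = np.empty(len(times), dtype=[("event", "?"), ("time", "<f8")])
    y["event"], y["time"] = events, times
    est = CoxPHSurvivalAnalysis(alpha=0.0, ties="breslow", tol=tol, n_iter=200)
    est.fit(X, y)
    coefs = {name: float(b) for name, b in zip(names, est.coef_)}
    if not all(np.isfinite(list(coefs.values()))):
        raise FloatingPointError(f"Cox fit did not converge: {coefs}")
    return CoxFit(coefficients=coefs, model=est)


def fit_cox(cohort: CohortIndex, baseline_h: float = 0.0, tol: float = 1e-9) -> CoxFit:
    """Fit the Cox model on (age, sex, pre-ICU LOS) for admissions alive at
    the baseline."""
    X, times, events = _design(cohort, baseline_h)
    return fit_cox_design(X, times, events, _COVARIATES, tol=tol)


def cox_survival(
    fit: CoxFit, cohort: CohortIndex, windows: WindowSpec, baseline_h: float = 0.0
) -> np.ndarray:
    """Predicted survival ``S(t) = exp(−Λ₀(t)·exp(xβ))`` at the window
    edges, (n_subjects, n_windows)."""
    X, _, _ = _design(cohort, baseline_h)
    fns = fit.model.predict_survival_function(X)
    edges = np.asarray(windows.edges)
    out = np.empty((len(X), windows.n))
    for i, fn in enumerate(fns):
        # right-continuous step evaluation, clamped to the observed range
        t = np.clip(edges, fn.x[0], fn.x[-1])
        out[i] = fn(t)
    return out
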