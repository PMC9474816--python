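"""Synthetic ICU cohorts with known discrete-time hazard structure.

Each patient carries a latent risk ``z ~ N(0, 1)``. The true conditional
death probability (hazard) of window i is

    h_i(z) = expit(logit(h*_i) + gamma_i · z)

so ``gamma = 0`` gives the configured base hazards for everyone and positive
``gamma`` induces non-proportional, window-specific risk shifts. Death
windows are sampled from these hazards; death times fall uniformly inside
their window. A configured fraction of patients receives an early uniform
censoring time; everyone else is administratively censored at the last
window edge (365 days).

Event streams emulate the nine input domains: ICD-10-style history codes,
procedure and examination codes, medication events with ATC+route codes and
doses, lab values, chart entries (free-text notes and a numeric score), and
two high-frequency vitals sampled 1–12 times per hour as noisy sinusoids
with drift. Token frequencies, doses, lab values and vitals are linked to
``z``, so a model can recover risk from tokens alone; the static covariates
(age, sex, LOS) are deliberately independent of ``z``, which makes the Cox
baseline on them an uninformative control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data_model import AdmissionRecord, CohortIndex, Event
from .labels import WindowSpec

_MONTH_LENGTHS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
_MONTH_PROBS = np.asarray(_MONTH_LENGTHS) / 365.0

RISKY_DX = ("DC349", "DI500", "DK704", "DJ960", "DC911")
BENIGN_DX = tuple(f"D{c}" for c in (
    "E119", "I109", "J459", "M545", "K219", "N390", "H259", "L209", "G439", "F329"))
SURGICAL_CODES = tuple(f"KN{g}B{i}0" for g in "ABCDE" for i in range(2))
EXAM_CODES = tuple(f"UXRC{i:03d}" for i in range(8))
ATC_CODES = ("J01DH01_IV", "N05CD08_IV", "C01CA04_IV", "B05BB01_IV", "N02BE01_PO")
LAB_VARS = ("NPU03429", "NPU02319", "NPU01685", "NPU19763")
RISK_WORDS = ("unresponsive", "hypotensive", "pressors", "oliguric", "critical")
CALM_WORDS = ("stable", "comfortable", "awake", "mobilised", "eating",
              "resting", "oriented", "calm")


@dataclass
class SimulationConfig:
    """Generator settings; the defaults define the standard study cohort."""

    n_patients: int = 1000
    base_hazards: tuple[float, ...] = (0.10, 0.15, 0.08, 0.12, 0.20, 0.25)
    gamma: float | tuple[float, ...] = 1.0   # log-odds risk shift per unit z
    censoring_fraction: float = 0.2          # early uniform censoring
    windows: WindowSpec = field(default_factory=WindowSpec)
    post_horizon_h: float = 72.0             # generate ICU events up to here
    event_rate_scale: float = 1.0            # 0 disables event streams
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if len(self.base_hazards) != self.windows.n:
            raise ValueError("one base hazard per window required")
        if any(not 0.0 <= h < 1.0 for h in self.base_hazards):
            raise ValueError("base hazards must lie in [0, 1)")

    @property
    def gamma_vector(self) -> np.ndarray:
        g = self.gamma
        if np.isscalar(g):
            return np.full(self.windows.n, float(g))
        return np.asarray(g, dtype=float)


@dataclass
class GroundTruth:
    """Per-admission latent risk and true survival structure."""

    table: pd.DataFrame  # admission_id, patient_id, z, death_window, p_1..p_n

    def survival(self, admission_id: str) -> np.ndarray:
        return true_survival(self, admission_id)

    def survival_matrix(self, admission_ids: list[str]) -> np.ndarray:
        t = self.table.set_index("admission_id").loc[admission_ids]
        p = t[[c for c in t.columns if c.startswith("p_")]].to_numpy(dtype=float)
        return np.cumprod(p, axis=1)


def true_survival(truth: GroundTruth, admission_id: str) -> np.ndarray:
    """Cumulative true survival S*_k = prod_{i<=k} p*_i of one admission."""
    row = truth.table.set_index("admission_id").loc[admission_id]
    p = row[[c for c in truth.table.columns if c.startswith("p_")]].to_numpy(dtype=float)
    return np.cumprod(p)


def conditional_hazards(z: np.ndarray, base_hazards, gamma) -> np.ndarray:
    """(n, windows) true hazards; a base hazard of exactly 0 stays 0."""
    h = np.asarray(base_hazards, dtype=float)
    g = np.asarray(gamma, dtype=float)
    out = np.zeros((len(z), len(h)))
    pos = h > 0
    if pos.any():
        out[:, pos] = expit(logit(h[pos])[None, :] + np.outer(z, g[pos]))
    return out


def _sample_outcomes(rng, hazards: np.ndarray, windows: WindowSpec,
                     censoring_fraction: float):
    """Vectorized death-window sampling + censoring. Returns (time_d, event)."""
    n, W = hazards.shape
    u = rng.random((n, W))
    dies = u < hazards
    alive = np.ones(n, dtype=bool)
    death_window = np.full(n, -1)
    for w in range(W):
        now = alive & dies[:, w]
        death_window[now] = w
        alive &= ~dies[:, w]
    horizon = windows.edges[-1]
    death_time = np.full(n, np.inf)
    for w in range(W):
        m = death_window == w
        lo, hi = windows.bounds(w)
        death_time[m] = rng.uniform(lo, hi, size=m.sum())
    censor_time = np.full(n, horizon)
    early = rng.random(n) < censoring_fraction
    censor_time[early] = rng.uniform(0.25, horizon, size=early.sum())
    time = np.minimum(death_time, censor_time)
    event = death_time <= censor_time
    return time, event, death_window


def _birth_day(rng) -> int:
    month = int(rng.choice(12, p=_MONTH_PROBS))
    return int(rng.integers(1, _MONTH_LENGTHS[month] + 1))


def _note_words(rng, z: float) -> str:
    n_words = int(rng.integers(3, 9))
    p_risk = expit(0.8 * z)
    words = [
        RISK_WORDS[rng.integers(len(RISK_WORDS))] if rng.random() < p_risk else CALM_WORDS[rng.integers(len(CALM_WORDS))]
        for _ in range(n_words)
    ]
    return " ".join(words)


def _admission_events(rng, z: float, horizon_h: float, scale: float) -> list[Event]:
    if scale <= 0:
        return []
    ev: list[Event] = []
    p_risk = expit(z)
    # --- pre-admission registry history -------------------------------
    for _ in range(rng.poisson(4 * scale)):
        code = RISKY_DX[rng.integers(len(RISKY_DX))] if rng.random() < p_risk else BENIGN_DX[rng.integers(len(BENIGN_DX))]
        ev.append(Event("medical_history", float(-rng.uniform(1, 26280)), code=code))
    for _ in range(rng.poisson(1 * scale)):
        ev.append(Event("surgical_history", float(-rng.uniform(1, 26280)),
                        code=SURGICAL_CODES[rng.integers(len(SURGICAL_CODES))]))
    for _ in range(rng.poisson(1.5 * scale)):
        ev.append(Event("examination", float(-rng.uniform(1, 8760)),
                        code=EXAM_CODES[rng.integers(len(EXAM_CODES))]))
    for _ in range(rng.poisson(2 * scale)):
        code = ATC_CODES[rng.integers(len(ATC_CODES))]
        mu = 0.5 * z if code == "J01DH01_IV" else 0.0
        ev.append(Event("medication", float(-rng.uniform(1, 720)), code=code,
                        value=float(np.exp(rng.normal(mu, 0.3)))))
    for _ in range(rng.poisson(2 * scale)):
        var = LAB_VARS[rng.integers(len(LAB_VARS))]
        mu = z if var in LAB_VARS[:2] else 0.0
        ev.append(Event("lab", float(-rng.uniform(1, 720)), variable_name=var,
                        value=float(rng.normal(mu, 0.7)), unit="au"))
    # --- in-ICU streams, hourly up to the horizon ---------------------
    hours = int(math.floor(horizon_h))
    for h in range(hours):
        if rng.random() < 0.30 * scale:  # medication administrations
            code = ATC_CODES[rng.integers(len(ATC_CODES))]
            mu = 0.5 * z if code == "J01DH01_IV" else 0.0
            ev.append(Event("medication", h + float(rng.random()), code=code,
                            value=float(np.exp(rng.normal(mu, 0.3)))))
        if rng.random() < 0.40 * scale:  # lab draws
            var = LAB_VARS[rng.integers(len(LAB_VARS))]
            mu = z if var in LAB_VARS[:2] else 0.0
            ev.append(Event("lab", h + float(rng.random()), variable_name=var,
                            value=float(rng.normal(mu, 0.7)), unit="au"))
        if rng.random() < 0.35 * scale:  # free-text nursing note
            ev.append(Event("chart", h + float(rng.random()), text=_note_words(rng, z)))
        if rng.random() < 0.15 * scale:  # numeric chart entry (GCS-like)
            ev.append(Event("chart", h + float(rng.random()), variable_name="GCS",
                            value=float(np.clip(rng.normal(13 - 1.5 * z, 2), 3, 15))))
        # high-frequency vitals: 1-12 samples per present hour
        for var, base, amp, zeff, sd in (("InvSysBP", 120.0, 10.0, -8.0, 5.0),
                                         ("HR", 85.0, 5.0, 6.0, 4.0)):
            if rng.random() < 0.6 * scale:
                for _ in range(int(rng.integers(1, 13))):
                    t = h + float(rng.random())
                    val = (base + amp * math.sin(2 * math.pi * t / 24.0)
                           + 0.05 * t + zeff * z + rng.normal(0, sd))
                    ev.append(Event("high_frequency", t, variable_name=var,
                                    value=float(val), unit="au"))
    return ev


def simulate_cohort(config: SimulationConfig) -> tuple[CohortIndex, GroundTruth]:
    """Draw a fully seeded synthetic cohort plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    z = rng.standard_normal(n)
    hazards = conditional_hazards(z, config.base_hazards, config.gamma_vector)
    # ~18% of patients have more than one admission
    n_adm = 1 + (rng.random(n) < 0.18) + (rng.random(n) < 0.03)
    admissions: list[AdmissionRecord] = []
    truth_rows: list[dict] = []
    for i in range(n):
        pid = f"P{i:06d}"
        age = float(np.clip(rng.normal(66, 15), 16, 100))
        sex = "F" if rng.random() < 0.43 else "M"
        birth_day = _birth_day(rng)
        for j in range(int(n_adm[i])):
            aid = f"{pid}-A{j}"
            time_d, event, death_w = _sample_outcomes(
                rng, hazards[i][None, :], config.windows, config.censoring_fraction)
            time_d, event, death_w = float(time_d[0]), bool(event[0]), int(death_w[0])
            horizon = min(config.post_horizon_h, time_d * 24.0)
            events = _admission_events(rng, z[i], horizon, config.event_rate_scale)
            adm = AdmissionRecord(
                patient_id=pid,
                admission_id=aid,
                age_years=age,
                sex=sex,
                hospital_los_days=float(np.clip(rng.lognormal(0.0, 1.0), 0.0, 30.0)),
                birth_day_of_month=birth_day,
                outcome_time_d=time_d,
                event_indicator=event,
                events=events,
            )
            adm.validate()
            admissions.append(adm)
            row = {"admission_id": aid, "patient_id": pid, "z": float(z[i]),
                   "death_window": death_w if event else -1,
                   "time_d": time_d, "event": event}
            for w in range(config.windows.n):
                row[f"p_{w + 1}"] = float(1.0 - hazards[i, w])
            truth_rows.append(row)
    return CohortIndex(admissions), GroundTruth(pd.DataFrame(truth_rows))
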