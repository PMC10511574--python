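"""Generators: pH traces with planted episodes, coupled symptom logs, cohorts.

Every generator is a pure function of its config (including the seed).

* ``simulate_trace`` — Gaussian baseline around a configurable mean with
  posture-dependent Poisson reflux episodes.  Episode onsets/offsets are
  snapped to the sampling grid so the planted truth is recoverable exactly
  by the detector; the post-episode recovery ramp starts just above pH 4 so
  it never adds sub-4 time.
* ``simulate_symptoms`` — events are coupled to reflux at the *window*
  level: with probability ``coupling`` an event lands uniformly inside a
  randomly chosen reflux-positive 2-min window, otherwise uniformly inside
  a reflux-negative window.
* ``simulate_cohort`` — a surgical cohort whose marginals default to the
  reference targets (n=597, 71.4% female, age median 59 IQR 49-67, ...)
  with a configurable (default null) SAP->outcome effect on the favorable
  outcome.  Continuous marginals are matched with piecewise-linear quantile
  functions through the target median/IQR points.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from . import symptom_association as sa
from .acid_exposure import RefluxEpisode
from .trace_model import (
    CohortTable,
    PatientRecord,
    PHTrace,
    SUPINE,
    SymptomEventLog,
    UPRIGHT,
    ValidationError,
)

__all__ = [
    "TraceSimConfig",
    "SymptomSimConfig",
    "CohortSimConfig",
    "simulate_trace",
    "simulate_symptoms",
    "simulate_cohort",
]

HOUR_S = 3600.0
DAY_S = 86400.0


# ---------------------------------------------------------------------------
# Trace simulation
# ---------------------------------------------------------------------------

@dataclass
class TraceSimConfig:
    duration_s: float = 172800.0          # 48 h
    sample_interval_s: float = 6.0        # Bravo-style sampling
    baseline_ph_mean: float = 6.2
    baseline_ph_sd: float = 0.25
    episode_rate_per_h_upright: float = 2.0
    episode_rate_per_h_supine: float = 0.5
    episode_duration_median_s: float = 60.0
    episode_duration_sigma: float = 0.6   # lognormal shape
    nadir_ph_low: float = 1.0
    nadir_ph_high: float = 3.5
    recovery_s: float = 30.0
    start_clock_h: float = 8.0            # recording starts 08:00
    supine_start_h: float = 23.0          # supine 23:00-07:00 daily
    supine_end_h: float = 7.0
    meal_clock_intervals: tuple = ()      # e.g. ((12.5, 13.0),)
    seed: int = 0

    def __post_init__(self):
        if self.episode_rate_per_h_upright < 0 or self.episode_rate_per_h_supine < 0:
            raise ValidationError("episode rates must be >= 0")
        if not self.nadir_ph_high < 4.0:
            raise ValidationError("nadir_ph_high must be below 4")
        if self.duration_s < self.sample_interval_s:
            raise ValidationError("duration shorter than one sample interval")
        if not 0 <= self.supine_end_h < self.supine_start_h <= 24:
            raise ValidationError(
                "supine schedule must wrap midnight: need "
                "0 <= supine_end_h < supine_start_h <= 24"
            )

    @classmethod
    def from_json(cls, path) -> "TraceSimConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _clock_intervals(config: TraceSimConfig, start_h: float, end_h: float
                     ) -> list[tuple[float, float]]:
    """Recording-time intervals where clock time lies in [start_h, end_h),
    for a window that wraps midnight when start_h > end_h."""
    out = []
    # walk day by day from one day before the recording start
    day0 = -DAY_S
    t_end = config.duration_s
    day = day0
    while day < t_end + DAY_S:
        if start_h > end_h:  # wraps midnight
            spans = [(start_h, 24.0), (0.0, end_h)]
        else:
            spans = [(start_h, end_h)]
        for s_h, e_h in spans:
            s = day + (s_h - config.start_clock_h) * HOUR_S
            e = day + (e_h - config.start_clock_h) * HOUR_S
            s, e = max(s, 0.0), min(e, t_end)
            if e > s:
                out.append((s, e))
        day += DAY_S
    # merge touching intervals (midnight wrap produces adjacent pieces)
    merged: list[tuple[float, float]] = []
    for s, e in sorted(out):
        if merged and s <= merged[-1][1] + 1e-9:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _posture_intervals(config: TraceSimConfig) -> list[tuple[float, float, str]]:
    supine = _clock_intervals(config, config.supine_start_h, config.supine_end_h)
    out: list[tuple[float, float, str]] = []
    cursor = 0.0
    for s, e in supine:
        if s > cursor:
            out.append((cursor, s, UPRIGHT))
        out.append((s, e, SUPINE))
        cursor = e
    if cursor < config.duration_s:
        out.append((cursor, config.duration_s, UPRIGHT))
    return out


def simulate_trace(config: TraceSimConfig) -> tuple[PHTrace, list[RefluxEpisode]]:
    """Simulate a recording and return it with the planted episode truth.

    Baseline noise is winsorised at +-4.5 sd, so with the default config no
    baseline sample can fall below pH 4.  Episodes follow a posture-dependent
    Poisson process; overlapping/too-close candidates (within the recovery
    ramp plus two samples of a previous episode) are dropped so planted
    episodes stay well separated and exactly recoverable.
    """
    rng = np.random.default_rng(config.seed)
    dt = config.sample_interval_s
    n = int(round(config.duration_s / dt))
    times = np.arange(n) * dt
    noise = rng.normal(0.0, config.baseline_ph_sd, n)
    np.clip(noise, -4.5 * config.baseline_ph_sd, 4.5 * config.baseline_ph_sd,
            out=noise)
    ph = np.clip(config.baseline_ph_mean + noise, 0.0, 9.0)

    posture = _posture_intervals(config)

    # candidate episode onsets from a posture-dependent Poisson process
    candidates: list[tuple[float, float]] = []  # (onset, duration)
    for s, e, kind in posture:
        rate = (config.episode_rate_per_h_supine if kind == SUPINE
                else config.episode_rate_per_h_upright)
        count = rng.poisson(rate * (e - s) / HOUR_S)
        for onset in np.sort(rng.uniform(s, e, count)):
            dur = config.episode_duration_median_s * math.exp(
                config.episode_duration_sigma * rng.standard_normal())
            candidates.append((float(onset), float(dur)))
    candidates.sort()

    episodes: list[RefluxEpisode] = []
    min_gap = config.recovery_s + 2 * dt
    prev_end = -np.inf
    for onset, dur in candidates:
        onset_g = round(onset / dt) * dt
        n_samp = max(1, int(round(dur / dt)))
        offset_g = onset_g + n_samp * dt
        if onset_g < prev_end + min_gap or offset_g > config.duration_s:
            continue
        i0, i1 = int(round(onset_g / dt)), int(round(offset_g / dt))
        frac = (times[i0:i1] - onset_g) / (offset_g - onset_g)
        nadir = rng.uniform(config.nadir_ph_low, config.nadir_ph_high)
        # V-shaped excursion: edges just below threshold, nadir mid-episode
        ph[i0:i1] = nadir + (3.9 - nadir) * np.abs(2.0 * frac - 1.0)
        # recovery ramp from just above threshold back to baseline
        r1 = min(i1 + int(round(config.recovery_s / dt)), n)
        if r1 > i1:
            w = (times[i1:r1] - offset_g) / config.recovery_s
            ph[i1:r1] = 4.05 + (ph[i1:r1] - 4.05) * np.clip(w, 0.0, 1.0)
        episodes.append(RefluxEpisode(onset_g, offset_g,
                                      float(ph[i0:i1].min())))
        prev_end = offset_g

    meals = []
    for s_h, e_h in config.meal_clock_intervals:
        meals.extend(_clock_intervals(config, s_h, e_h))

    trace = PHTrace(
        recording_id=f"sim-{config.seed}",
        times=times,
        ph=ph,
        sample_interval_s=dt,
        duration_s=config.duration_s,
        posture_intervals=posture,
        meal_intervals=meals,
    )
    return trace, episodes


# ---------------------------------------------------------------------------
# Symptom simulation
# ---------------------------------------------------------------------------

@dataclass
class SymptomSimConfig:
    symptoms: dict = field(default_factory=lambda: {"heartburn": 20})
    # per-symptom value: int event count, or float rate per hour if rates=True
    rates: bool = False
    coupling: float = 0.9     # P(event placed in a reflux-positive window)
    lag_s: float = 0.0        # offset of placement after window start
    window_s: float = sa.DEFAULT_WINDOW_S
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.coupling <= 1.0:
            raise ValidationError("coupling must be in [0, 1]")
        if not 1 <= len(self.symptoms) <= 3:
            raise ValidationError("1-3 tracked symptoms required")

    @classmethod
    def from_json(cls, path) -> "SymptomSimConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def simulate_symptoms(trace: PHTrace, episodes: list[RefluxEpisode],
                      config: SymptomSimConfig) -> SymptomEventLog:
    """Place symptom events with window-level coupling to reflux.

    For each event: with probability ``coupling`` choose a reflux-positive
    window uniformly and place the event uniformly inside it; otherwise do
    the same with a reflux-negative window.  Event counts are honoured
    exactly when given as counts.  If one side has no windows the other is
    used (with the implied change of coupling noted by construction).
    """
    rng = np.random.default_rng(config.seed)
    grid = sa.partition_windows(trace, config.window_s)
    reflux = sa.label_reflux_windows(trace, grid)
    pos_windows = np.flatnonzero(reflux)
    neg_windows = np.flatnonzero(~reflux)
    starts, ends = grid.starts, grid.ends

    events: list[tuple[float, str]] = []
    for symptom, value in config.symptoms.items():
        if config.rates:
            count = rng.poisson(float(value) * trace.duration_s / HOUR_S)
        else:
            count = int(value)
        for _ in range(count):
            coupled = rng.uniform() < config.coupling
            pool = pos_windows if coupled else neg_windows
            if len(pool) == 0:
                pool = neg_windows if coupled else pos_windows
            w = int(rng.choice(pool))
            t = rng.uniform(starts[w], ends[w])
            if config.lag_s:
                t = min(t + config.lag_s, ends[w] - 1e-6)
            events.append((float(t), symptom))

    return SymptomEventLog(
        recording_id=trace.recording_id,
        tracked_symptoms=tuple(config.symptoms),
        events=events,
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _quantile_draw(rng, n, points):
    """Draw n values from the piecewise-linear quantile function `points`
    given as [(prob, value), ...] with probs covering [0, 1]."""
    ps = np.array([p for p, _ in points])
    qs = np.array([q for _, q in points])
    return np.interp(rng.uniform(size=n), ps, qs)


@dataclass
class CohortSimConfig:
    n: int = 597
    pct_female: float = 71.4
    age_quantiles: tuple = ((0.0, 22.0), (0.25, 49.0), (0.5, 59.0),
                            (0.75, 67.0), (1.0, 89.0))
    bmi_quantiles: tuple = ((0.0, 18.0), (0.25, 26.0), (0.5, 29.1),
                            (0.75, 33.0), (1.0, 48.0))
    hrql_quantiles: tuple = ((0.0, 3.0), (0.25, 21.0), (0.5, 36.0),
                             (0.75, 51.0), (1.0, 80.0))
    # DeMeester mixture: severity stratum first, then a within-stratum
    # quantile curve calibrated so the overall median/IQR land on the
    # 44.1 (29-62) targets.
    pct_mild: float = 7.4            # DeMeester in (14.7, 20]
    pct_severe: float = 40.7         # DeMeester > 50
    moderate_quantiles: tuple = ((0.0, 20.0), (0.339, 29.0), (0.821, 44.1),
                                 (1.0, 50.0))
    severe_quantiles: tuple = ((0.0, 50.0), (0.386, 62.0), (0.9, 95.0),
                               (1.0, 140.0))
    pct_nissen: float = 89.1
    base_favorable_rate: float = 0.82
    satisfaction_rate: float = 0.874
    ppi_free_rate: float = 0.917
    sap_effect_log_odds: float = 0.0
    pct_sap_positive: float = 72.0
    # split of 1/2/3 SAP-positive symptoms among SAP-positive patients
    sap_count_weights: tuple = (221, 164, 45)
    followup_mean_months: float = 10.5
    followup_sd_months: float = 8.0
    hrql_improve_prob_favorable: float = 0.85
    hrql_improve_prob_unfavorable: float = 0.30
    missing_satisfied: float = 0.30
    missing_ppi_free: float = 0.01
    missing_postop_hrql: float = 0.45
    symptom_weights: dict = field(default_factory=lambda: {
        "heartburn": 0.26, "regurgitation": 0.17, "cough": 0.16,
        "chest_pain": 0.08, "dysphagia": 0.08, "throat_clearing": 0.07,
        "nausea": 0.07, "abdominal_pain": 0.06, "globus": 0.05,
    })
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        for name in ("pct_female", "pct_mild", "pct_severe", "pct_nissen",
                     "pct_sap_positive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"{name} out of [0, 100]: {v}")
        for name in ("base_favorable_rate", "satisfaction_rate",
                     "ppi_free_rate", "missing_satisfied",
                     "missing_ppi_free", "missing_postop_hrql"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} out of [0, 1]: {v}")
        if self.pct_mild + self.pct_severe > 100.0:
            raise ValidationError("pct_mild + pct_severe exceeds 100")
        fav = self.base_favorable_rate
        if fav < 1.0:
            s0 = (self.satisfaction_rate - fav) / (1.0 - fav)
            p0 = (self.ppi_free_rate - fav) / (1.0 - fav)
            if s0 < 0 or p0 < 0:
                raise ValidationError(
                    "satisfaction_rate and ppi_free_rate must each be >= "
                    "base_favorable_rate (favorable = satisfied AND ppi_free)"
                )
            if s0 + p0 > 1.0:
                raise ValidationError(
                    "infeasible marginals: satisfaction_rate + ppi_free_rate "
                    "- 2*base_favorable_rate must be <= 1 - base_favorable_rate"
                )

    @classmethod
    def from_json(cls, path) -> "CohortSimConfig":
        with open(path) as fh:
            doc = json.load(fh)
        for key in ("age_quantiles", "bmi_quantiles", "hrql_quantiles",
                    "moderate_quantiles", "severe_quantiles"):
            if key in doc:
                doc[key] = tuple(tuple(p) for p in doc[key])
        if "sap_count_weights" in doc:
            doc["sap_count_weights"] = tuple(doc["sap_count_weights"])
        return cls(**doc)


def _fake_sap_results(rng, tracked, positive_set):
    """Per-symptom SAP records consistent with the drawn positivity flags.

    Cohort rows carry no window data, so the 2x2 table is absent and the
    p-value is drawn on the correct side of 0.05.
    """
    from .symptom_association import SAPResult

    out = {}
    for s in tracked:
        pos = s in positive_set
        p = rng.uniform(0.0005, 0.0499) if pos else rng.uniform(0.0501, 0.999)
        out[s] = SAPResult(symptom=s, table=None, p_value=p,
                           sap_pct=(1 - p) * 100.0, positive=pos)
    return out


def simulate_cohort(config: CohortSimConfig) -> CohortTable:
    """Simulate a surgical cohort with the configured marginal targets."""
    rng = np.random.default_rng(config.seed)
    n = config.n

    age = np.round(_quantile_draw(rng, n, config.age_quantiles)).astype(int)
    bmi = np.round(_quantile_draw(rng, n, config.bmi_quantiles), 1)
    preop = np.round(_quantile_draw(rng, n, config.hrql_quantiles)).astype(int)
    female = rng.uniform(size=n) < config.pct_female / 100.0
    nissen = rng.uniform(size=n) < config.pct_nissen / 100.0

    # DeMeester: severity stratum then within-stratum quantile curve
    u = rng.uniform(size=n)
    mild = u < config.pct_mild / 100.0
    severe = u >= 1.0 - config.pct_severe / 100.0
    moderate = ~mild & ~severe
    demeester = np.empty(n)
    demeester[mild] = rng.uniform(14.7 + 1e-6, 20.0, mild.sum())
    demeester[moderate] = _quantile_draw(rng, moderate.sum(),
                                         config.moderate_quantiles)
    demeester[severe] = _quantile_draw(rng, severe.sum(),
                                       config.severe_quantiles)
    demeester = np.round(np.maximum(demeester, 14.8), 1)

    # SAP positivity and the 1/2/3-symptom split
    sap_pos = rng.uniform(size=n) < config.pct_sap_positive / 100.0
    w = np.asarray(config.sap_count_weights, dtype=float)
    w /= w.sum()
    counts = np.zeros(n, dtype=int)
    counts[sap_pos] = rng.choice([1, 2, 3], size=int(sap_pos.sum()), p=w)

    # favorable outcome with a (default null) SAP effect on the log-odds
    p_fav = expit(logit(config.base_favorable_rate)
                  + config.sap_effect_log_odds * sap_pos.astype(float))
    favorable = rng.uniform(size=n) < p_fav

    # satisfaction / PPI freedom: conjunction equals the favorable flag;
    # conditional rates among unfavorable patients reproduce the configured
    # marginals exactly when the SAP effect is null.
    fav_rate = config.base_favorable_rate
    if fav_rate < 1.0:
        s0 = (config.satisfaction_rate - fav_rate) / (1.0 - fav_rate)
        p0 = (config.ppi_free_rate - fav_rate) / (1.0 - fav_rate)
    else:
        s0 = p0 = 0.0
    satisfied = favorable.copy()
    ppi_free = favorable.copy()
    unfav = ~favorable
    u2 = rng.uniform(size=n)
    satisfied[unfav & (u2 < s0)] = True                 # satisfied, on PPI
    ppi_free[unfav & (u2 >= s0) & (u2 < s0 + p0)] = True  # PPI-free, unsatisfied

    # postoperative HRQL: favorable patients improve more often
    improve = np.where(favorable, config.hrql_improve_prob_favorable,
                       config.hrql_improve_prob_unfavorable)
    improved = rng.uniform(size=n) < improve
    ratio = np.where(improved, rng.uniform(0.0, 0.5, n),
                     rng.uniform(0.5001, 1.2, n))
    postop = np.clip(np.round(preop * ratio), 0, 80).astype(int)

    followup = np.round(np.maximum(
        rng.normal(config.followup_mean_months, config.followup_sd_months, n),
        1.0), 1)

    # tracked symptoms and per-symptom SAP records
    names = list(config.symptom_weights)
    weights = np.array([config.symptom_weights[k] for k in names], dtype=float)
    weights /= weights.sum()

    miss_sat = rng.uniform(size=n) < config.missing_satisfied
    miss_ppi = rng.uniform(size=n) < config.missing_ppi_free
    miss_post = rng.uniform(size=n) < config.missing_postop_hrql

    patients = []
    for i in range(n):
        tracked = rng.choice(names, size=3, replace=False, p=weights)
        positive = set(rng.choice(tracked, size=counts[i], replace=False))
        patients.append(PatientRecord(
            patient_id=f"P{i:04d}",
            age=int(age[i]),
            sex="female" if female[i] else "male",
            bmi=float(bmi[i]),
            preop_hrql=int(preop[i]),
            postop_hrql=None if miss_post[i] else int(postop[i]),
            satisfied=None if miss_sat[i] else bool(satisfied[i]),
            ppi_free=None if miss_ppi[i] else bool(ppi_free[i]),
            fundoplication="nissen" if nissen[i] else "partial",
            followup_months=float(followup[i]),
            demeester=float(demeester[i]),
            sap_positive_count=int(counts[i]),
            per_symptom_sap=_fake_sap_results(rng, tracked, positive),
        ))
    return CohortTable(patients)
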