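"""Reflux episode detection and composite acid-exposure (DeMeester) scoring.

An acid reflux episode is a maximal run of samples with pH below the
threshold (default 4.0); each sample covers ``[t, t + sample_interval_s)``.
Runs separated by at most ``merge_gap_s`` of above-threshold recording can
optionally be merged (default: no merging).

The composite score sums, over six components, ``max(0, (value - mean)/sd
+ 1)``.  The component reference means/SDs are external constants from the
classical 24-h reference series and are shipped as a configurable
:class:`DeMeesterNormals`; only the severity thresholds (14.7 / 20 / 50)
are treated as fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trace_model import PHTrace, SUPINE, UPRIGHT, ValidationError

__all__ = [
    "RefluxEpisode",
    "AcidExposureProfile",
    "DeMeesterNormals",
    "DEFAULT_NORMALS",
    "detect_reflux_episodes",
    "acid_exposure_components",
    "demeester_score",
    "classify_severity",
    "score_trace",
]

PH_THRESHOLD = 4.0
LONG_EPISODE_S = 300.0  # an episode lasting >= 5 min

SEVERITIES = ("normal", "mild", "moderate", "severe")


@dataclass(frozen=True)
class RefluxEpisode:
    """One acid reflux episode as a half-open interval with its nadir pH."""

    onset_s: float
    offset_s: float
    nadir_ph: float

    def __post_init__(self):
        if self.offset_s <= self.onset_s:
            raise ValidationError("episode must have positive duration")
        if not self.nadir_ph < PH_THRESHOLD:
            raise ValidationError(f"episode nadir {self.nadir_ph} not below 4")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class AcidExposureProfile:
    """Six acid-exposure components, optionally with composite and severity."""

    pct_time_ph_lt4_total: float
    pct_time_ph_lt4_upright: float
    pct_time_ph_lt4_supine: float
    n_episodes: int
    n_episodes_ge_5min: int
    longest_episode_min: float
    demeester: float | None = None
    severity: str | None = None

    def __post_init__(self):
        for name in ("pct_time_ph_lt4_total", "pct_time_ph_lt4_upright",
                     "pct_time_ph_lt4_supine"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"{name} out of [0, 100]: {v}")
        if self.n_episodes_ge_5min > self.n_episodes:
            raise ValidationError("n_episodes_ge_5min exceeds n_episodes")

    def components(self) -> tuple[float, float, float, float, float, float]:
        return (
            self.pct_time_ph_lt4_total,
            self.pct_time_ph_lt4_upright,
            self.pct_time_ph_lt4_supine,
            float(self.n_episodes),
            float(self.n_episodes_ge_5min),
            self.longest_episode_min,
        )

    def as_dict(self) -> dict:
        return {
            "pct_time_ph_lt4_total": self.pct_time_ph_lt4_total,
            "pct_time_ph_lt4_upright": self.pct_time_ph_lt4_upright,
            "pct_time_ph_lt4_supine": self.pct_time_ph_lt4_supine,
            "n_episodes": self.n_episodes,
            "n_episodes_ge_5min": self.n_episodes_ge_5min,
            "longest_episode_min": self.longest_episode_min,
            "demeester": self.demeester,
            "severity": self.severity,
        }


# Reference means/SDs for the six components (external constants from the
# classical 24-h normal series; configurable, deliberately never asserted
# against in tests).
@dataclass(frozen=True)
class DeMeesterNormals:
    pct_total: tuple[float, float] = (1.51, 1.36)
    pct_upright: tuple[float, float] = (2.34, 2.34)
    pct_supine: tuple[float, float] = (0.63, 1.00)
    n_episodes: tuple[float, float] = (19.00, 12.76)
    n_episodes_ge_5min: tuple[float, float] = (0.84, 1.18)
    longest_episode_min: tuple[float, float] = (6.74, 7.85)
    composite_threshold: float = 14.7
    mild_upper: float = 20.0
    severe_lower: float = 50.0

    def __post_init__(self):
        for name in ("pct_total", "pct_upright", "pct_supine", "n_episodes",
                     "n_episodes_ge_5min", "longest_episode_min"):
            _, sd = getattr(self, name)
            if sd <= 0:
                raise ValidationError(f"normals sd must be > 0 for {name}")

    def pairs(self) -> tuple[tuple[float, float], ...]:
        return (self.pct_total, self.pct_upright, self.pct_supine,
                self.n_episodes, self.n_episodes_ge_5min,
                self.longest_episode_min)


DEFAULT_NORMALS = DeMeesterNormals()


def detect_reflux_episodes(trace: PHTrace, threshold_ph: float = PH_THRESHOLD,
                           merge_gap_s: float = 0.0) -> list[RefluxEpisode]:
    """Maximal sub-threshold runs on the trace, optionally gap-merged.

    Episodes are returned sorted by onset.  A run of samples ``i..j`` below
    the threshold yields the episode ``[t_i, t_j + sample_interval_s)``.
    """
    if trace.n_samples == 0:
        raise ValidationError("empty trace")
    dt = trace.sample_interval_s
    below = trace.ph < threshold_ph
    if not below.any():
        return []
    # run boundaries on the boolean mask
    padded = np.concatenate([[False], below, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])  # exclusive sample index

    episodes: list[RefluxEpisode] = []
    cur_on = cur_off = None
    cur_nadir = np.inf
    for s, e in zip(starts, ends):
        onset = float(trace.times[s])
        offset = float(trace.times[e - 1] + dt)
        nadir = float(trace.ph[s:e].min())
        if cur_on is not None and onset - cur_off <= merge_gap_s:
            cur_off = offset
            cur_nadir = min(cur_nadir, nadir)
        else:
            if cur_on is not None:
                episodes.append(RefluxEpisode(cur_on, cur_off, cur_nadir))
            cur_on, cur_off, cur_nadir = onset, offset, nadir
    episodes.append(RefluxEpisode(cur_on, cur_off, cur_nadir))
    return episodes


def acid_exposure_components(trace: PHTrace,
                             episodes: list[RefluxEpisode] | None = None,
                             threshold_ph: float = PH_THRESHOLD,
                             exclude_meals: bool = False) -> AcidExposureProfile:
    """Compute the six acid-exposure components (composite left unscored).

    Percent-time fields are 100 x (sub-threshold sample time in stratum) /
    (stratum sample time); strata follow the trace's posture intervals.  A
    stratum with zero duration contributes 0% with a warning.  With
    ``exclude_meals`` the meal intervals are removed from both numerator and
    denominator.
    """
    if episodes is None:
        episodes = detect_reflux_episodes(trace, threshold_ph=threshold_ph)
    dt = trace.sample_interval_s
    below = trace.ph < threshold_ph
    keep = np.ones(trace.n_samples, dtype=bool)
    if exclude_meals:
        keep &= ~trace.in_meal(trace.times)
    supine = trace.posture_at(trace.times) == SUPINE

    def pct(mask: np.ndarray, label: str) -> float:
        denom = float(np.count_nonzero(mask & keep)) * dt
        if denom == 0:
            warnings.warn(f"stratum {label!r} has zero duration; reporting 0%")
            return 0.0
        num = float(np.count_nonzero(mask & keep & below)) * dt
        return 100.0 * num / denom

    all_mask = np.ones(trace.n_samples, dtype=bool)
    longest = max((e.duration_s for e in episodes), default=0.0) / 60.0
    return AcidExposureProfile(
        pct_time_ph_lt4_total=pct(all_mask, "total"),
        pct_time_ph_lt4_upright=pct(~supine, UPRIGHT),
        pct_time_ph_lt4_supine=pct(supine, SUPINE),
        n_episodes=len(episodes),
        n_episodes_ge_5min=sum(1 for e in episodes if e.duration_s >= LONG_EPISODE_S),
        longest_episode_min=longest,
    )


def demeester_score(profile: AcidExposureProfile,
                    normals: DeMeesterNormals = DEFAULT_NORMALS) -> float:
    """Composite score: sum of max(0, (value - mean)/sd + 1) over components."""
    score = 0.0
    for value, (mean, sd) in zip(profile.components(), normals.pairs()):
        score += max(0.0, (value - mean) / sd + 1.0)
    return score


def classify_severity(score: float,
                      normals: DeMeesterNormals = DEFAULT_NORMALS) -> str:
    """Severity stratum: normal <= 14.7 < mild <= 20 < moderate <= 50 < severe.

    All upper comparisons are strict, matching the ">14.7" abnormality and
    ">50" severe cutoffs; "14.7-20" is read as the half-open (14.7, 20].
    """
    if score < 0:
        raise ValidationError("score must be >= 0")
    if score <= normals.composite_threshold:
        return "normal"
    if score <= normals.mild_upper:
        return "mild"
    if score <= normals.severe_lower:
        return "moderate"
    return "severe"


def score_trace(trace: PHTrace, normals: DeMeesterNormals = DEFAULT_NORMALS,
                threshold_ph: float = PH_THRESHOLD, merge_gap_s: float = 0.0,
                exclude_meals: bool = False) -> AcidExposureProfile:
    """Full pipeline: detect episodes, compute components, score, classify."""
    episodes = detect_reflux_episodes(trace, threshold_ph=threshold_ph,
                                      merge_gap_s=merge_gap_s)
    profile = acid_exposure_components(trace, episodes,
                                       threshold_ph=threshold_ph,
                                       exclude_meals=exclude_meals)
    profile.demeester = demeester_score(profile, normals)
    profile.severity = classify_severity(profile.demeester, normals)
    return profile
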