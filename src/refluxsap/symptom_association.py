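"""Windowed symptom-reflux association: SAP with SI and SSI companions.

The recording is divided into consecutive 2-min half-open windows.  A window
is reflux-positive if pH stays below 4 for at least 5 consecutive seconds
inside it (criterion A, where each sample covers its sampling interval), or
if some pair of samples inside it shows a drop of more than 1 pH unit within
5 s (criterion B).  Per tracked symptom a window is symptom-positive if at
least one event of that symptom falls in it.  The symptom association
probability is ``(1 - p) x 100`` with ``p`` from Fisher's exact test on the
2x2 cross-tabulation of window labels; a symptom is SAP-positive at >= 95%
and a patient is SAP-positive if at least one symptom is.

Notes on conventions (these change results at coarse sampling and are
therefore deliberately explicit):

* a single sub-4 sample at a 6-s interval covers 6 s >= 5 s and hence
  satisfies criterion A on its own;
* with regular 6-s sampling criterion B (pairs within 5 s) can never fire;
  the span is a parameter so finer-sampled traces exercise it;
* a sub-4 run straddling a window boundary counts toward criterion A in
  every window in which it covers at least ``sustained_s`` seconds;
* a symptom with zero reported events is *not assessable* (p is forced to 1
  but carries no information) and is excluded from positivity counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import stats_core
from .acid_exposure import RefluxEpisode, detect_reflux_episodes
from .trace_model import PHTrace, SymptomEventLog, ValidationError

__all__ = [
    "WindowGrid",
    "ContingencyTable2x2",
    "SAPResult",
    "AssociationSummary",
    "partition_windows",
    "label_reflux_windows",
    "label_symptom_windows",
    "build_table",
    "sap",
    "symptom_index",
    "symptom_sensitivity_index",
    "associate",
]

DEFAULT_WINDOW_S = 120.0
SAP_POSITIVE_PCT = 95.0
SI_POSITIVE_PCT = 50.0
SSI_POSITIVE_PCT = 10.0
ANY_SYMPTOM = "any_symptom"


@dataclass(frozen=True)
class WindowGrid:
    """Consecutive half-open windows tiling ``[0, duration_s)``.

    All windows have length ``window_s`` except possibly the last, which is
    truncated at the recording end.
    """

    window_s: float
    duration_s: float

    def __post_init__(self):
        if self.window_s <= 0:
            raise ValidationError("window_s must be positive")
        if self.duration_s < self.window_s:
            raise ValidationError(
                f"duration {self.duration_s} shorter than one window "
                f"({self.window_s})"
            )

    @property
    def n_windows(self) -> int:
        return int(math.ceil(self.duration_s / self.window_s))

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.n_windows) * self.window_s

    @property
    def ends(self) -> np.ndarray:
        return np.minimum(self.starts + self.window_s, self.duration_s)

    def windows(self) -> list[tuple[float, float]]:
        return list(zip(self.starts.tolist(), self.ends.tolist()))

    def index_of(self, t: np.ndarray | float) -> np.ndarray:
        """Window index containing each time (half-open convention)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.floor(t / self.window_s).astype(int)
        return np.clip(idx, 0, self.n_windows - 1)


def partition_windows(trace_or_duration, window_s: float = DEFAULT_WINDOW_S) -> WindowGrid:
    """Partition a recording into consecutive half-open windows."""
    duration = getattr(trace_or_duration, "duration_s", trace_or_duration)
    return WindowGrid(window_s=float(window_s), duration_s=float(duration))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cross-tabulation of window labels.

    a = symptom+/reflux+, b = symptom+/reflux-, c = symptom-/reflux+,
    d = symptom-/reflux-.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class SAPResult:
    """Per-symptom SAP: the 2x2 table, exact p, percentage, positivity."""

    symptom: str | None
    table: ContingencyTable2x2 | None
    p_value: float
    sap_pct: float
    positive: bool
    assessable: bool = True

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p_value out of [0, 1]: {self.p_value}")


@dataclass
class AssociationSummary:
    """Full per-recording association report across tracked symptoms."""

    results: dict[str, SAPResult]
    any_symptom: SAPResult
    si_pct: dict[str, float | None]
    si_positive: dict[str, bool | None]
    ssi_pct: dict[str, float | None]
    ssi_positive: dict[str, bool | None]
    n_sap_positive: int
    patient_sap_positive: bool
    n_assessable: int


def _sub4_runs(trace: PHTrace, threshold_ph: float) -> list[tuple[float, float]]:
    """Covered intervals of maximal sub-threshold sample runs."""
    below = trace.ph < threshold_ph
    if not below.any():
        return []
    padded = np.concatenate([[False], below, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    dt = trace.sample_interval_s
    return [(float(trace.times[s]), float(trace.times[e - 1] + dt))
            for s, e in zip(starts, ends)]


def label_reflux_windows(trace: PHTrace, grid: WindowGrid,
                         threshold_ph: float = 4.0,
                         sustained_s: float = 5.0,
                         drop_units: float = 1.0,
                         drop_span_s: float = 5.0) -> np.ndarray:
    """Boolean reflux-positive label per window.

    Criterion A: a sub-threshold run covers >= ``sustained_s`` seconds inside
    the window.  Criterion B: two samples inside the window, at most
    ``drop_span_s`` apart, show a pH drop greater than ``drop_units``.
    """
    labels = np.zeros(grid.n_windows, dtype=bool)
    starts, ends = grid.starts, grid.ends

    for run_s, run_e in _sub4_runs(trace, threshold_ph):
        first = int(np.searchsorted(starts, run_s, "right") - 1)
        last = int(np.searchsorted(starts, run_e - 1e-12, "right") - 1)
        for w in range(max(first, 0), min(last, grid.n_windows - 1) + 1):
            overlap = min(run_e, ends[w]) - max(run_s, starts[w])
            if overlap >= sustained_s:
                labels[w] = True

    t, ph = trace.times, trace.ph
    widx = grid.index_of(t)
    k = 1
    while k < len(t):
        gaps = t[k:] - t[:-k]
        if gaps.min() > drop_span_s:
            break
        hit = (gaps <= drop_span_s) & (ph[:-k] - ph[k:] > drop_units) \
            & (widx[:-k] == widx[k:])
        labels[widx[:-k][hit]] = True
        k += 1
    return labels


def label_symptom_windows(grid: WindowGrid, log: SymptomEventLog,
                          symptom: str) -> np.ndarray:
    """Boolean symptom-positive label per window (>= 1 event, no multiplicity).

    An event exactly on a window boundary belongs to the later window
    (half-open convention).
    """
    times = log.events_for(symptom)  # raises if symptom not tracked
    labels = np.zeros(grid.n_windows, dtype=bool)
    if len(times):
        labels[grid.index_of(times)] = True
    return labels


def build_table(reflux_vec: np.ndarray, symptom_vec: np.ndarray) -> ContingencyTable2x2:
    """Cross-tabulate window label vectors into a 2x2 table."""
    r = np.asarray(reflux_vec, dtype=bool)
    s = np.asarray(symptom_vec, dtype=bool)
    if r.shape != s.shape:
        raise ValidationError(
            f"label vectors differ in length: {r.shape} vs {s.shape}"
        )
    return ContingencyTable2x2(
        a=int(np.count_nonzero(s & r)),
        b=int(np.count_nonzero(s & ~r)),
        c=int(np.count_nonzero(~s & r)),
        d=int(np.count_nonzero(~s & ~r)),
    )


def sap(table: ContingencyTable2x2, sidedness: str = "two_sided",
        symptom: str | None = None, assessable: bool = True) -> SAPResult:
    """SAP from a 2x2 window table: ``(1 - p) x 100``, positive at >= 95%.

    A table with an empty symptom margin yields p = 1 and SAP 0%.
    """
    alternative = {"two_sided": "two_sided", "one_sided": "greater",
                   "greater": "greater", "less": "less"}[sidedness]
    p = stats_core.fisher_exact_2x2(table, alternative=alternative).p_value
    sap_pct = (1.0 - p) * 100.0
    return SAPResult(
        symptom=symptom,
        table=table,
        p_value=p,
        sap_pct=sap_pct,
        positive=bool(assessable and sap_pct >= SAP_POSITIVE_PCT),
        assessable=assessable,
    )


def symptom_index(log: SymptomEventLog, symptom: str, reflux_vec: np.ndarray,
                  grid: WindowGrid, lag_s: float = DEFAULT_WINDOW_S
                  ) -> tuple[float | None, bool | None]:
    """SI: percent of events with reflux in the preceding ``lag_s`` seconds.

    An event at time t is reflux-associated if any window overlapping
    ``[t - lag_s, t]`` is reflux-positive.  With zero events the SI is not
    defined and ``(None, None)`` is returned.
    """
    times = log.events_for(symptom)
    if len(times) == 0:
        return None, None
    reflux_vec = np.asarray(reflux_vec, dtype=bool)
    n_assoc = 0
    for t in times:
        lo = int(grid.index_of(max(t - lag_s, 0.0))[0])
        hi = int(grid.index_of(min(t, grid.duration_s - 1e-9))[0])
        if reflux_vec[lo:hi + 1].any():
            n_assoc += 1
    pct = 100.0 * n_assoc / len(times)
    return pct, pct >= SI_POSITIVE_PCT


def symptom_sensitivity_index(log: SymptomEventLog, symptom: str,
                              episodes: list[RefluxEpisode],
                              lag_s: float = DEFAULT_WINDOW_S
                              ) -> tuple[float | None, bool | None]:
    """SSI: percent of reflux episodes with >= 1 event within the lag.

    An episode counts if an event of the symptom occurs in
    ``[onset, offset + lag_s)``.  With zero episodes the SSI is undefined.
    """
    if not episodes:
        return None, None
    times = log.events_for(symptom)
    n_hit = 0
    for ep in episodes:
        if np.any((times >= ep.onset_s) & (times < ep.offset_s + lag_s)):
            n_hit += 1
    pct = 100.0 * n_hit / len(episodes)
    return pct, pct >= SSI_POSITIVE_PCT


def associate(trace: PHTrace, log: SymptomEventLog,
              window_s: float = DEFAULT_WINDOW_S,
              sidedness: str = "two_sided",
              threshold_ph: float = 4.0,
              sustained_s: float = 5.0,
              drop_units: float = 1.0,
              drop_span_s: float = 5.0,
              lag_s: float = DEFAULT_WINDOW_S,
              merge_gap_s: float = 0.0) -> AssociationSummary:
    """Run the full association chain for every tracked symptom.

    Per-symptom tables drive positivity counts; an "any-symptom" combined
    SAP is also reported.  Zero-event symptoms are flagged not assessable
    and excluded from ``n_sap_positive``.
    """
    grid = partition_windows(trace, window_s)
    reflux_vec = label_reflux_windows(trace, grid, threshold_ph=threshold_ph,
                                      sustained_s=sustained_s,
                                      drop_units=drop_units,
                                      drop_span_s=drop_span_s)
    episodes = detect_reflux_episodes(trace, threshold_ph=threshold_ph,
                                      merge_gap_s=merge_gap_s)

    results: dict[str, SAPResult] = {}
    si_pct: dict[str, float | None] = {}
    si_pos: dict[str, bool | None] = {}
    ssi_pct: dict[str, float | None] = {}
    ssi_pos: dict[str, bool | None] = {}
    any_vec = np.zeros(grid.n_windows, dtype=bool)

    for symptom in log.tracked_symptoms:
        vec = label_symptom_windows(grid, log, symptom)
        any_vec |= vec
        n_events = len(log.events_for(symptom))
        results[symptom] = sap(build_table(reflux_vec, vec), sidedness,
                               symptom=symptom, assessable=n_events > 0)
        si_pct[symptom], si_pos[symptom] = symptom_index(
            log, symptom, reflux_vec, grid, lag_s=lag_s)
        ssi_pct[symptom], ssi_pos[symptom] = symptom_sensitivity_index(
            log, symptom, episodes, lag_s=lag_s)

    any_result = sap(build_table(reflux_vec, any_vec), sidedness,
                     symptom=ANY_SYMPTOM, assessable=len(log.events) > 0)
    n_pos = sum(1 for r in results.values() if r.positive)
    return AssociationSummary(
        results=results,
        any_symptom=any_result,
        si_pct=si_pct,
        si_positive=si_pos,
        ssi_pct=ssi_pct,
        ssi_positive=ssi_pos,
        n_sap_positive=n_pos,
        patient_sap_positive=n_pos >= 1,
        n_assessable=sum(1 for r in results.values() if r.assessable),
    )
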