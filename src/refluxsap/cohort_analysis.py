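"""Cohort-level analyses: outcome flags, SAP-group comparisons, subgroups.

All percentages are computed on per-variable complete cases, with the
denominator carried explicitly in every emitted row; display rounding is
half-up to one decimal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import stats_core
from .trace_model import (
    CohortTable,
    KNOWN_SYMPTOMS,
    PatientRecord,
    ValidationError,
    symptom_category,
)

__all__ = [
    "OutcomeFlags",
    "ComparisonRow",
    "SubgroupSpec",
    "DEFAULT_SUBGROUPS",
    "round_half_up",
    "outcome_flags",
    "patient_sap_breakdown",
    "compare_groups",
    "sap_count_analysis",
    "symptom_type_analysis",
    "subgroup_sweep",
    "report",
]

SYMPTOM_CATEGORIES = ("typical", "atypical", "non_reflux")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (matching clinical-table style)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OutcomeFlags:
    """Derived outcome indicators; missing components propagate to None."""

    favorable: bool | None
    hrql_improved_50: bool | None
    satisfied: bool | None
    ppi_free: bool | None


def outcome_flags(record: PatientRecord) -> OutcomeFlags:
    """favorable = satisfied AND ppi_free; >= 50% HRQL improvement flag.

    ``favorable`` is missing if either component is missing.  The HRQL flag
    is missing if the postoperative score is missing or the preoperative
    score is zero (improvement fraction undefined).
    """
    if record.satisfied is None or record.ppi_free is None:
        favorable = None
    else:
        favorable = record.satisfied and record.ppi_free
    if record.postop_hrql is None:
        improved = None
    elif record.preop_hrql == 0:
        warnings.warn(
            f"{record.patient_id}: preop HRQL is 0; improvement undefined")
        improved = None
    else:
        improved = (record.preop_hrql - record.postop_hrql) / record.preop_hrql >= 0.5
    return OutcomeFlags(favorable=favorable, hrql_improved_50=improved,
                        satisfied=record.satisfied, ppi_free=record.ppi_free)


def patient_sap_breakdown(counts: Iterable[int]) -> dict:
    """Patient-level SAP aggregation from per-patient positive-symptom counts.

    A patient is SAP-positive if at least one tracked symptom is
    SAP-positive.  Returns totals, the positive/negative split and the
    percentage (one decimal, half-up) of each exact count 0-3.
    """
    counts = np.asarray(list(counts), dtype=int)
    if np.any(counts < 0) or np.any(counts > 3):
        raise ValidationError("per-patient counts must be in 0..3")
    n = len(counts)
    n_pos = int(np.count_nonzero(counts >= 1))
    out = {
        "n_total": n,
        "n_sap_positive": n_pos,
        "pct_sap_positive": round_half_up(100.0 * n_pos / n),
        "n_sap_negative": n - n_pos,
        "pct_sap_negative": round_half_up(100.0 * (n - n_pos) / n),
    }
    for k in range(4):
        nk = int(np.count_nonzero(counts == k))
        out[f"n_{k}_positive"] = nk
        out[f"pct_{k}_positive"] = round_half_up(100.0 * nk / n)
    return out


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

@dataclass
class ComparisonRow:
    """One table row: per-group summaries, explicit denominators, test, p."""

    variable: str
    kind: str                      # "continuous" | "binary"
    group_names: tuple[str, ...]
    summaries: tuple[str, ...]     # display strings per group
    numerators: tuple[float, ...]  # medians (continuous) or counts (binary)
    denominators: tuple[int, ...]  # complete-case n per group
    test: str | None
    p_value: float | None
    flag: str | None = None        # e.g. "not assessable"

    def as_dict(self) -> dict:
        return {
            "variable": self.variable,
            "kind": self.kind,
            **{f"{g}": s for g, s in zip(self.group_names, self.summaries)},
            **{f"n_{g}": d for g, d in zip(self.group_names, self.denominators)},
            "test": self.test,
            "p_value": self.p_value,
            "flag": self.flag,
        }


@dataclass(frozen=True)
class VariableSpec:
    name: str
    accessor: Callable[[PatientRecord], float | bool | None]
    kind: str  # "continuous" | "binary"


def _median_iqr(values: np.ndarray) -> str:
    med = np.median(values)
    q1, q3 = np.percentile(values, [25, 75])
    return f"{round_half_up(med)} ({round_half_up(q1)}-{round_half_up(q3)})"


def _count_pct(k: int, n: int) -> str:
    pct = round_half_up(100.0 * k / n) if n else float("nan")
    return f"{k} ({pct}%)"


def _compare_one(name: str, kind: str, group_values: list[np.ndarray],
                 group_names: tuple[str, ...]) -> ComparisonRow:
    denominators = tuple(len(v) for v in group_values)
    if min(denominators) == 0:
        return ComparisonRow(name, kind, group_names,
                             tuple("-" for _ in group_values),
                             tuple(0.0 for _ in group_values),
                             denominators, None, None, flag="not assessable")
    if kind == "continuous":
        summaries = tuple(_median_iqr(v) for v in group_values)
        numerators = tuple(float(np.median(v)) for v in group_values)
        if len(group_values) == 2:
            res = stats_core.mann_whitney_u(group_values[0], group_values[1])
        else:
            res = stats_core.kruskal_wallis(group_values)
    elif kind == "binary":
        ks = [int(np.count_nonzero(v)) for v in group_values]
        summaries = tuple(_count_pct(k, n) for k, n in zip(ks, denominators))
        numerators = tuple(float(k) for k in ks)
        table = np.array([[k, n - k] for k, n in zip(ks, denominators)])
        if len(group_values) == 2:
            res = stats_core.fisher_exact_2x2(table)
        else:
            res = stats_core.exact_rxc_test(table.T, seed=0)
    else:
        raise ValueError(f"unknown variable kind {kind!r}")
    return ComparisonRow(name, kind, group_names, summaries, numerators,
                         denominators, res.method, res.p_value)


def _collect(cohort, grouping, spec: VariableSpec):
    """Per-group complete-case value arrays for one variable."""
    groups: dict[bool, list] = {True: [], False: []}
    for rec in cohort:
        g = grouping(rec)
        if g is None:
            continue
        v = spec.accessor(rec)
        if v is None:
            continue
        groups[bool(g)].append(float(v))
    return [np.array(groups[True]), np.array(groups[False])]


def _sap_grouping(rec: PatientRecord):
    return rec.sap_positive


def baseline_variables() -> list[VariableSpec]:
    """Table 2 analog: demographics and preoperative characteristics."""
    return [
        VariableSpec("age", lambda r: r.age, "continuous"),
        VariableSpec("sex_female", lambda r: r.sex == "female", "binary"),
        VariableSpec("bmi", lambda r: r.bmi, "continuous"),
        VariableSpec("bmi_gt_30", lambda r: r.bmi > 30, "binary"),
        VariableSpec("demeester", lambda r: r.demeester, "continuous"),
        VariableSpec("mild_objective_reflux",
                     lambda r: 14.7 < r.demeester <= 20, "binary"),
        VariableSpec("severe_objective_reflux",
                     lambda r: r.demeester > 50, "binary"),
        VariableSpec("preop_hrql", lambda r: r.preop_hrql, "continuous"),
        VariableSpec("fundoplication_partial",
                     lambda r: r.fundoplication == "partial", "binary"),
    ]


def outcome_variables() -> list[VariableSpec]:
    """Table 3 analog: surgical outcomes (per-variable complete cases)."""
    return [
        VariableSpec("favorable_outcome",
                     lambda r: outcome_flags(r).favorable, "binary"),
        VariableSpec("satisfaction", lambda r: r.satisfied, "binary"),
        VariableSpec("freedom_from_ppi", lambda r: r.ppi_free, "binary"),
        VariableSpec("hrql_improved_50",
                     lambda r: outcome_flags(r).hrql_improved_50, "binary"),
    ]


def compare_groups(cohort: CohortTable,
                   grouping: Callable[[PatientRecord], bool | None] = _sap_grouping,
                   variables: Sequence[VariableSpec] | None = None,
                   group_names: tuple[str, str] = ("sap_positive", "sap_negative"),
                   ) -> list[ComparisonRow]:
    """Two-group comparison table: median(IQR)+Mann-Whitney for continuous
    variables, n(%)+Fisher for binary ones.

    ``grouping`` maps a record to True/False (or None to exclude).  Raises
    if either group is empty.
    """
    if variables is None:
        variables = baseline_variables()
    sizes = {True: 0, False: 0}
    for rec in cohort:
        g = grouping(rec)
        if g is not None:
            sizes[bool(g)] += 1
    if sizes[True] == 0 or sizes[False] == 0:
        raise ValidationError(
            f"grouping {getattr(grouping, '__name__', grouping)!r} yields an "
            f"empty group (sizes {sizes[True]} vs {sizes[False]})"
        )
    return [_compare_one(spec.name, spec.kind,
                         _collect(cohort, grouping, spec), group_names)
            for spec in variables]


def sap_count_analysis(cohort: CohortTable, n_resamples: int = 10000,
                       seed=0) -> ComparisonRow:
    """Favorable-outcome rate by number (0/1/2/3) of SAP-positive symptoms.

    Builds the 2x4 favorable-by-count table on complete cases and tests it
    with the Monte Carlo exact r x c test.
    """
    buckets = {k: [] for k in range(4)}
    for rec in cohort:
        fav = outcome_flags(rec).favorable
        if fav is None:
            continue
        buckets[rec.sap_positive_count].append(bool(fav))
    names = tuple(f"{k}_sap_positive" for k in range(4))
    values = [np.array(buckets[k], dtype=bool) for k in range(4)]
    denominators = tuple(len(v) for v in values)
    ks = [int(v.sum()) for v in values]
    summaries = tuple(_count_pct(k, n) for k, n in zip(ks, denominators))
    if min(denominators) == 0:
        return ComparisonRow("favorable_by_sap_count", "binary", names,
                             summaries, tuple(map(float, ks)), denominators,
                             None, None, flag="not assessable")
    table = np.array([ks, [n - k for k, n in zip(ks, denominators)]])
    res = stats_core.exact_rxc_test(table, n_resamples=n_resamples, seed=seed)
    return ComparisonRow("favorable_by_sap_count", "binary", names, summaries,
                         tuple(map(float, ks)), denominators,
                         res.method, res.p_value)


def _category_positive(rec: PatientRecord, category: str) -> bool | None:
    """SAP positivity for a symptom category; None if none of the patient's
    tracked symptoms fall in the category."""
    tracked = [s for s in rec.per_symptom_sap if symptom_category(s) == category]
    if not tracked:
        return None
    return any(rec.per_symptom_sap[s].positive for s in tracked)


def symptom_type_analysis(cohort: CohortTable) -> list[ComparisonRow]:
    """Favorable outcome by SAP positivity per symptom category and symptom.

    Each row is restricted to patients tracking the symptom (or at least one
    symptom of the category); groups are SAP-positive vs SAP-negative *for
    that symptom*.  Rows with an empty group are flagged not assessable.
    """
    rows: list[ComparisonRow] = []
    names = ("sap_positive", "sap_negative")

    for category in SYMPTOM_CATEGORIES:
        groups = {True: [], False: []}
        for rec in cohort:
            pos = _category_positive(rec, category)
            fav = outcome_flags(rec).favorable
            if pos is None or fav is None:
                continue
            groups[pos].append(float(fav))
        rows.append(_compare_one(f"type_{category}", "binary",
                                 [np.array(groups[True]), np.array(groups[False])],
                                 names))

    for symptom in KNOWN_SYMPTOMS:
        groups = {True: [], False: []}
        for rec in cohort:
            if symptom not in rec.per_symptom_sap:
                continue
            fav = outcome_flags(rec).favorable
            if fav is None:
                continue
            groups[rec.per_symptom_sap[symptom].positive].append(float(fav))
        rows.append(_compare_one(symptom, "binary",
                                 [np.array(groups[True]), np.array(groups[False])],
                                 names))
    return rows


@dataclass(frozen=True)
class SubgroupSpec:
    """A named predicate over patient records; missing data -> excluded."""

    name: str
    predicate: Callable[[PatientRecord], bool]


DEFAULT_SUBGROUPS: tuple[SubgroupSpec, ...] = (
    SubgroupSpec("age_lt_40", lambda r: r.age < 40),
    SubgroupSpec("age_ge_70", lambda r: r.age >= 70),
    SubgroupSpec("female", lambda r: r.sex == "female"),
    SubgroupSpec("male", lambda r: r.sex == "male"),
    SubgroupSpec("bmi_ge_30", lambda r: r.bmi >= 30),
    SubgroupSpec("mild_reflux", lambda r: 14.7 < r.demeester <= 20),
    SubgroupSpec("severe_reflux", lambda r: r.demeester > 50),
    SubgroupSpec("nissen", lambda r: r.fundoplication == "nissen"),
    SubgroupSpec("partial", lambda r: r.fundoplication == "partial"),
)


def hrql_median_split_subgroups(cohort: CohortTable) -> tuple[SubgroupSpec, ...]:
    """Preop-HRQL above/below cohort-median subgroup pair."""
    med = float(np.median([r.preop_hrql for r in cohort]))
    return (
        SubgroupSpec("preop_hrql_ge_median", lambda r, m=med: r.preop_hrql >= m),
        SubgroupSpec("preop_hrql_lt_median", lambda r, m=med: r.preop_hrql < m),
    )


def subgroup_sweep(cohort: CohortTable,
                   specs: Sequence[SubgroupSpec] | None = None,
                   adjust: str | None = None) -> list[ComparisonRow]:
    """Favorable-by-SAP Fisher test within each subgroup.

    Subgroups with an empty SAP group are flagged (no test).  With
    ``adjust='holm'`` a Holm-adjusted p is appended to each tested row's
    ``flag`` field as ``holm=<p>``.
    """
    if specs is None:
        specs = DEFAULT_SUBGROUPS
    rows: list[ComparisonRow] = []
    names = ("sap_positive", "sap_negative")
    for spec in specs:
        groups = {True: [], False: []}
        for rec in cohort:
            if not spec.predicate(rec):
                continue
            fav = outcome_flags(rec).favorable
            if fav is None:
                continue
            groups[rec.sap_positive].append(float(fav))
        row = _compare_one(spec.name, "binary",
                           [np.array(groups[True]), np.array(groups[False])],
                           names)
        rows.append(row)
    if adjust == "holm":
        tested = [r for r in rows if r.p_value is not None]
        adj = stats_core.holm_adjust([r.p_value for r in tested])
        for r, a in zip(tested, adj):
            r.flag = f"holm={a:.4g}"
    return rows


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

def _cohort_summary(cohort: CohortTable) -> dict:
    """Table 1 analog: whole-cohort marginals with explicit denominators."""
    n = len(cohort)
    age = np.array([r.age for r in cohort], dtype=float)
    bmi = np.array([r.bmi for r in cohort], dtype=float)
    dms = np.array([r.demeester for r in cohort], dtype=float)
    hrql = np.array([r.preop_hrql for r in cohort], dtype=float)
    counts = [r.sap_positive_count for r in cohort]
    return {
        "n": n,
        "age_median_iqr": _median_iqr(age),
        "sex_female": _count_pct(sum(r.sex == "female" for r in cohort), n),
        "bmi_median_iqr": _median_iqr(bmi),
        "bmi_gt_30": _count_pct(int(np.count_nonzero(bmi > 30)), n),
        "demeester_median_iqr": _median_iqr(dms),
        "mild_objective_reflux": _count_pct(
            int(np.count_nonzero((dms > 14.7) & (dms <= 20))), n),
        "severe_objective_reflux": _count_pct(int(np.count_nonzero(dms > 50)), n),
        "preop_hrql_median_iqr": _median_iqr(hrql),
        "fundoplication_nissen": _count_pct(
            sum(r.fundoplication == "nissen" for r in cohort), n),
        "fundoplication_partial": _count_pct(
            sum(r.fundoplication == "partial" for r in cohort), n),
        "sap_breakdown": patient_sap_breakdown(counts),
    }


def report(cohort: CohortTable, out_dir=None, seed=0,
           adjust: str | None = None, extend_subgroups: bool = False) -> dict:
    """Full analysis document: cohort summary plus every comparison table.

    With ``out_dir`` the tables are also exported as CSV files
    (``table1.csv`` ... ``table5.csv``, ``fig1_counts.csv``,
    ``fig2_subgroups.csv``) plus the whole document as ``report.json``.
    """
    specs = list(DEFAULT_SUBGROUPS)
    if extend_subgroups:
        specs += list(hrql_median_split_subgroups(cohort))
    table2 = compare_groups(cohort, variables=baseline_variables())
    table3 = compare_groups(cohort, variables=outcome_variables())
    fig1 = sap_count_analysis(cohort, seed=seed)
    types_and_symptoms = symptom_type_analysis(cohort)
    table4 = [r for r in types_and_symptoms if r.variable.startswith("type_")]
    table5 = [r for r in types_and_symptoms if not r.variable.startswith("type_")]
    fig2 = subgroup_sweep(cohort, specs, adjust=adjust)

    doc = {
        "table1": _cohort_summary(cohort),
        "table2": [r.as_dict() for r in table2],
        "table3": [r.as_dict() for r in table3],
        "table4": [r.as_dict() for r in table4],
        "table5": [r.as_dict() for r in table5],
        "fig1_counts": fig1.as_dict(),
        "fig2_subgroups": [r.as_dict() for r in fig2],
    }

    if out_dir is not None:
        import os
        os.makedirs(out_dir, exist_ok=True)
        pd.DataFrame([doc["table1"]]).drop(columns=["sap_breakdown"]).to_csv(
            os.path.join(out_dir, "table1.csv"), index=False)
        for key, fname in (("table2", "table2.csv"), ("table3", "table3.csv"),
                           ("table4", "table4.csv"), ("table5", "table5.csv"),
                           ("fig2_subgroups", "fig2_subgroups.csv")):
            pd.DataFrame(doc[key]).to_csv(os.path.join(out_dir, fname),
                                          index=False)
        pd.DataFrame([doc["fig1_counts"]]).to_csv(
            os.path.join(out_dir, "fig1_counts.csv"), index=False)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(doc, fh, indent=1, default=str)
            fh.write("\n")
    return doc
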