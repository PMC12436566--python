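"""Cohort-level statistics: contingency tables, exact Fisher r x c
test by complete enumeration, Kruskal-Wallis, and report builders.

Small screening cohorts (tens of patients split over five aetiology
subgroups) put contingency-table cells well below the counts where a
chi-square approximation is trustworthy, so subgroup-by-outcome tables
are tested with Fisher's exact test generalized to r x c: conditioning
on the margins, every compatible table is enumerated and the two-sided
p-value is the total multivariate-hypergeometric probability of the
tables no more probable than the observed one.  Probabilities are
computed with log-factorials, and a complete enumeration always sums
to 1 — an internal consistency check exposed for testing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from scipy.special import gammaln

from .screening import PatientScreeningResult, ThresholdSet, threshold_label

logger = logging.getLogger(__name__)

#: Tables whose enumeration would exceed this many candidate tables
#: are refused (use a Monte-Carlo approximation instead).
ENUMERATION_BUDGET = 50_000_000

#: Relative tolerance when comparing table probabilities for the
#: "no more probable than observed" rule; guards float ties.
_PROB_RTOL = 1e-7


@dataclass
class CohortTable:
    """An outcome-by-subgroup count table with margins."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("table total must be positive")
        r, c = self.counts.shape
        if len(self.row_labels) != r or len(self.col_labels) != c:
            raise ValueError("label lengths must match table shape")

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))


@dataclass
class TestResult:
    """Outcome of a significance test."""

    p_value: float
    method: str
    n: int
    statistic: float = math.nan

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")
        self.p_value = min(self.p_value, 1.0)


def _log_table_prob(counts: np.ndarray, log_margin_term: float) -> float:
    return log_margin_term - gammaln(counts + 1).sum()


def _enumeration_size_bound(row_margins, col_margins) -> float:
    """Crude upper bound on the number of tables with the given margins."""
    bound = 1.0
    for _ in range(len(row_margins) - 1):
        for c in col_margins:
            bound *= c + 1
            if bound > 1e18:
                return bound
    return bound


def enumerate_table_log_probs(row_margins, col_margins):
    """Yield log-probabilities of every table with the given margins.

    Conditional null distribution: multivariate hypergeometric,
    P(T) = (prod R_i! prod C_j!) / (N! prod_ij n_ij!).
    Tables are generated by recursive row filling with margin
    feasibility pruning.
    """
    R = np.asarray(row_margins, dtype=int)
    C = np.asarray(col_margins, dtype=int)
    if R.sum() != C.sum():
        raise ValueError("margin sums disagree")
    n = int(R.sum())
    log_margin_term = (gammaln(R + 1).sum() + gammaln(C + 1).sum()
                       - gammaln(n + 1))
    n_rows, n_cols = len(R), len(C)

    def fill_row(i: int, remaining_cols: np.ndarray, log_acc: float):
        if i == n_rows - 1:
            # last row is forced by the column margins
            yield log_acc - gammaln(remaining_cols + 1).sum()
            return
        row_total = R[i]

        def fill_cell(j: int, left: int, rem: np.ndarray, acc: float):
            if j == n_cols - 1:
                if left <= rem[j]:
                    rem2 = rem.copy()
                    rem2[j] -= left
                    yield from fill_row(i + 1, rem2, acc - gammaln(left + 1))
                return
            # value in cell (i, j): bounded by the column's remaining
            # margin and by what later columns can still absorb
            tail_capacity = rem[j + 1:].sum()
            lo = max(0, left - tail_capacity)
            hi = min(rem[j], left)
            for v in range(lo, hi + 1):
                rem2 = rem.copy()
                rem2[j] -= v
                yield from fill_cell(j + 1, left - v, rem2, acc - gammaln(v + 1))

        yield from fill_cell(0, row_total, remaining_cols, log_acc)

    yield from fill_row(0, C.copy(), log_margin_term)


def fisher_exact_rxc(table: CohortTable | np.ndarray) -> TestResult:
    """Two-sided exact Fisher test on an r x c table by enumeration.

    p = sum of conditional probabilities of all margin-compatible
    tables whose probability does not exceed the observed table's
    (within a small relative tolerance).  Rows or columns with a zero
    margin carry no information and are dropped with a warning.
    """
    counts = table.counts if isinstance(table, CohortTable) else np.asarray(table, int)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    n = int(counts.sum())
    keep_rows = counts.sum(axis=1) > 0
    keep_cols = counts.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        logger.warning("dropping zero-margin rows/columns from Fisher table")
        counts = counts[keep_rows][:, keep_cols]
    if counts.size == 0:
        raise ValueError("table is empty after dropping zero margins")
    R, C = counts.sum(axis=1), counts.sum(axis=0)
    if counts.shape[0] == 1 or counts.shape[1] == 1:
        return TestResult(p_value=1.0, method="fisher_exact_rxc", n=n)
    if _enumeration_size_bound(R, C) > ENUMERATION_BUDGET:
        raise ValueError(
            "table too large for complete enumeration; "
            "use a Monte-Carlo approximation"
        )
    log_margin_term = (gammaln(R + 1).sum() + gammaln(C + 1).sum()
                       - gammaln(n + 1))
    log_p_obs = _log_table_prob(counts, log_margin_term)
    cutoff = log_p_obs + math.log1p(_PROB_RTOL)
    p = 0.0
    for lp in enumerate_table_log_probs(R, C):
        if lp <= cutoff:
            p += math.exp(lp)
    return TestResult(p_value=min(p, 1.0), method="fisher_exact_rxc", n=n)


def kruskal_wallis(groups: list) -> TestResult:
    """Kruskal-Wallis rank-sum test (tie-corrected H, chi-square p).

    Identical values across all groups give H = 0, p = 1 by
    convention (no evidence of any difference).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must contain at least one value")
    n = sum(a.size for a in arrays)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return TestResult(p_value=1.0, statistic=0.0, method="kruskal_wallis", n=n)
    h, p = sp_stats.kruskal(*arrays)
    return TestResult(p_value=float(p), statistic=float(h),
                      method="kruskal_wallis", n=n)


# ---------------------------------------------------------------------------
# report builders
# ---------------------------------------------------------------------------

#: Canonical subgroup column order for reports.
SUBGROUP_ORDER = ("ACHD", "HCM", "HF", "Normal", "S-ICD")


def _ordered_subgroups(results: list[PatientScreeningResult]) -> tuple[str, ...]:
    present = {r.subgroup for r in results}
    ordered = [g for g in SUBGROUP_ORDER if g in present]
    ordered += sorted(present - set(SUBGROUP_ORDER))
    return tuple(ordered)


def contingency_table(results: list[PatientScreeningResult],
                      threshold: float) -> CohortTable:
    """2 x K fail/pass-by-subgroup table at one threshold."""
    if not results:
        raise ValueError("empty cohort")
    groups = _ordered_subgroups(results)
    counts = np.zeros((2, len(groups)), dtype=int)
    for r in results:
        j = groups.index(r.subgroup)
        row = 1 if r.passes[threshold] else 0
        counts[row, j] += 1
    return CohortTable(counts=counts, row_labels=("fail", "pass"),
                       col_labels=groups)


def format_fraction(k: int, n: int) -> str:
    """Render a count as ``k/N (x%)`` with 2-significant-figure percent."""
    if n == 0:
        return f"{k}/0 (-)"
    pct = 100.0 * k / n
    if pct == 0 or pct >= 9.95:
        return f"{k}/{n} ({pct:.0f}%)"
    return f"{k}/{n} ({pct:.1f}%)"


def _vector_table(results: list[PatientScreeningResult], threshold: float,
                  role: str, groups: tuple[str, ...]) -> CohortTable | None:
    """Fail/pass-by-subgroup counts for one vector, missing excluded."""
    counts = np.zeros((2, len(groups)), dtype=int)
    for r in results:
        vec = r.vector_results[threshold].get(role)
        if vec is None or vec.missing:
            continue
        counts[1 if vec.passed else 0, groups.index(r.subgroup)] += 1
    if counts.sum() == 0:
        return None
    return CohortTable(counts=counts, row_labels=("fail", "pass"),
                       col_labels=groups)


def _table_report(tab: CohortTable) -> dict:
    fail, pa = tab.counts[0], tab.counts[1]
    cols = tab.col_labels
    n_by_col = tab.col_margins
    try:
        p = fisher_exact_rxc(tab).p_value
    except ValueError:
        p = math.nan
    overall_n = tab.total
    report = {
        "fisher_p": p,
        "overall": {
            "fail": format_fraction(int(fail.sum()), overall_n),
            "pass": format_fraction(int(pa.sum()), overall_n),
        },
        "by_subgroup": {
            g: {
                "fail": format_fraction(int(fail[j]), int(n_by_col[j])),
                "pass": format_fraction(int(pa[j]), int(n_by_col[j])),
            }
            for j, g in enumerate(cols)
        },
        "counts": tab,
    }
    return report


def build_report(results: list[PatientScreeningResult],
                 thresholds: ThresholdSet | None = None) -> dict:
    """Assemble the cohort report.

    Returns a dict with:

    * ``standard`` — per-subgroup mean (SD) of the standard-practice
      pass probability plus a Kruskal-Wallis p across subgroups;
    * ``overall`` — per-threshold patient-level fail/pass tables with
      exact Fisher p;
    * ``per_vector`` — the same per sensing vector, with missing
      vectors excluded from denominators.
    """
    if not results:
        raise ValueError("empty cohort")
    thresholds = thresholds or ThresholdSet()
    groups = _ordered_subgroups(results)

    probs_by_group = {g: [] for g in groups}
    for r in results:
        probs_by_group[r.subgroup].append(r.standard_pass_probability)
    all_probs = [r.standard_pass_probability for r in results]
    if len([g for g in groups if probs_by_group[g]]) >= 2:
        kw = kruskal_wallis([probs_by_group[g] for g in groups])
        kw_p = kw.p_value
    else:
        kw_p = math.nan
    standard = {
        "overall_mean": float(np.mean(all_probs)),
        "overall_sd": float(np.std(all_probs, ddof=1)) if len(all_probs) > 1 else 0.0,
        "by_subgroup": {
            g: {
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                "n": len(v),
            }
            for g, v in probs_by_group.items()
        },
        "kruskal_wallis_p": kw_p,
    }

    overall = {}
    per_vector = {}
    roles_seen: list[str] = []
    for r in results:
        for thr_map in r.vector_results.values():
            for role in thr_map:
                if role not in roles_seen:
                    roles_seen.append(role)
            break
    for thr in thresholds.ratios:
        lab = threshold_label(thr)
        overall[lab] = _table_report(contingency_table(results, thr))
        per_vector[lab] = {}
        for role in roles_seen:
            tab = _vector_table(results, thr, role, groups)
            if tab is not None:
                per_vector[lab][role] = _table_report(tab)
    return {"standard": standard, "overall": overall, "per_vector": per_vector}


def render_text(report: dict) -> str:
    """Plain-text rendering of the per-threshold overall tables."""
    lines = []
    std = report["standard"]
    lines.append("Standard-practice pass probability (T:R < 1:3):")
    lines.append(
        f"  overall mean (SD): {std['overall_mean']:.2f} ({std['overall_sd']:.2f}),"
        f" Kruskal-Wallis p = {std['kruskal_wallis_p']:.3g}"
    )
    for lab, rep in report["overall"].items():
        lines.append(f"T:R threshold {lab}  (Fisher p = {rep['fisher_p']:.3g})")
        for outcome in ("fail", "pass"):
            row = [f"{outcome:>5}: {rep['overall'][outcome]:>13}"]
            for g, cell in rep["by_subgroup"].items():
                row.append(f"{g} {cell[outcome]}")
            lines.append("  " + "  ".join(row))
    return "\n".join(lines)
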