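"""Eligibility screening rules over per-segment T:R series.

Two computations:

* **Standard-practice pass probability** — the chance a patient would
  pass today's one-off screening if it happened at a random time of
  day: the fraction of 10-s segments in which at least one sensing
  vector shows a favourable (T:R strictly below 1:3) ratio.
* **Prolonged screening** — each vector is followed over the whole
  recording and fails a threshold if its T:R stays unfavourable for at
  least 20 consecutive seconds (two consecutive 10-s segments at the
  defaults — the surrogate for the device's detect-charge-redetect-
  shock time).  Isolated "silent" unfavourable segments do not fail a
  vector.  A patient passes a threshold when at least one non-missing
  vector passes it.

Favourable means strictly ``tr < threshold``: a ratio exactly at the
cutoff is unfavourable.  The five default cutoffs are 1:3, 1:2, 2:3,
3:4 and 1:1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tr_estimation import TRSeries

#: The five candidate T:R cutoffs, from strictest to most permissive.
DEFAULT_THRESHOLDS = (1 / 3, 1 / 2, 2 / 3, 3 / 4, 1.0)

#: Human-readable labels for the default cutoffs.
THRESHOLD_LABELS = {1 / 3: "1:3", 1 / 2: "1:2", 2 / 3: "2:3", 3 / 4: "3:4", 1.0: "1:1"}

#: Failure rule: unfavourable for at least this long, consecutively.
DEFAULT_MIN_FAIL_S = 20.0


def threshold_label(threshold: float) -> str:
    for t, lab in THRESHOLD_LABELS.items():
        if math.isclose(threshold, t, abs_tol=1e-4):
            return lab
    return f"{threshold:g}"


@dataclass(frozen=True)
class ThresholdSet:
    """Strictly increasing T:R cutoffs in (0, 1]."""

    ratios: tuple[float, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        r = self.ratios
        if not r:
            raise ValueError("at least one threshold required")
        if any(x <= 0 or x > 1 for x in r):
            raise ValueError("thresholds must lie in (0, 1]")
        if any(b <= a for a, b in zip(r, r[1:])):
            raise ValueError("thresholds must be strictly increasing")


def favourability(series: TRSeries | np.ndarray, threshold: float) -> np.ndarray:
    """Per-segment favourability: True, False, or NaN for missing.

    Returned as a float array (1.0 favourable, 0.0 unfavourable, NaN
    missing) so estimator dropouts stay distinguishable from genuine
    unfavourable segments.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = series.values if isinstance(series, TRSeries) else np.asarray(series, float)
    out = np.where(values < threshold, 1.0, 0.0)
    out[~np.isfinite(values)] = np.nan
    return out


@dataclass
class VectorScreeningResult:
    """Prolonged-screening outcome of one vector at one threshold."""

    channel_role: str
    threshold: float
    passed: bool
    n_failing_runs: int
    longest_unfavourable_s: float
    n_missing_segments: int = 0
    missing: bool = False


@dataclass
class PatientScreeningResult:
    """Per-patient screening outcome across thresholds.

    ``vector_results[threshold][role]`` holds the per-vector outcome;
    ``passes[threshold]`` is True when at least one non-missing vector
    passed.  ``standard_pass_probability`` is evaluated at the 1:3
    cutoff regardless of the prolonged-screening thresholds in use.
    """

    subject_id: str
    subgroup: str
    standard_pass_probability: float
    passes: dict[float, bool]
    vector_results: dict[float, dict[str, VectorScreeningResult]]


def _runs_of_unfavourable(fav: np.ndarray) -> list[int]:
    """Lengths of maximal runs of consecutive unfavourable segments.

    Missing segments (NaN) break runs — a dropout is treated as
    favourable for run-building, so estimator gaps never fabricate a
    20-s failure; the count of missing segments is reported alongside
    so the conservatism is auditable.
    """
    runs: list[int] = []
    current = 0
    for v in fav:
        if v == 0.0:  # unfavourable; NaN compares False
            current += 1
        else:
            if current:
                runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


def vector_prolonged_pass(series: TRSeries, threshold: float,
                          min_fail_duration_s: float = DEFAULT_MIN_FAIL_S,
                          segment_s: float = 10.0) -> VectorScreeningResult:
    """Apply the consecutive-failure rule to one vector at one threshold.

    The vector fails iff some run of consecutive unfavourable segments
    spans at least ``min_fail_duration_s`` — i.e. at least
    ``ceil(min_fail_duration_s / segment_s)`` consecutive segments
    (2 at the 20 s / 10 s defaults).  Runs do not wrap across the
    recording boundary.
    """
    if series.missing:
        return VectorScreeningResult(
            channel_role=series.channel_role, threshold=threshold, passed=False,
            n_failing_runs=0, longest_unfavourable_s=0.0, missing=True,
        )
    fav = favourability(series, threshold)
    runs = _runs_of_unfavourable(fav)
    needed = max(1, math.ceil(min_fail_duration_s / segment_s))
    longest = max(runs, default=0)
    return VectorScreeningResult(
        channel_role=series.channel_role,
        threshold=threshold,
        passed=longest < needed,
        n_failing_runs=sum(1 for r in runs if r >= needed),
        longest_unfavourable_s=longest * segment_s,
        n_missing_segments=int(np.isnan(fav).sum()),
    )


def standard_pass_probability(series_by_role: dict[str, TRSeries],
                              threshold: float = 1 / 3) -> float:
    """Fraction of segment indices with >= 1 vector favourable.

    This is the probability of passing the current one-off screening
    at a uniformly random time of the monitoring period.  Missing
    per-segment values count as not favourable; whole-missing channels
    are excluded.
    """
    present = [s for s in series_by_role.values() if not s.missing]
    if not present:
        raise ValueError("need at least one non-missing vector")
    lengths = {len(s) for s in present}
    if len(lengths) != 1:
        raise ValueError("vectors have unequal segment counts")
    n = lengths.pop()
    if n == 0:
        raise ValueError("zero segments")
    any_fav = np.zeros(n, dtype=bool)
    for s in present:
        fav = favourability(s, threshold)
        any_fav |= fav == 1.0
    return float(any_fav.sum() / n)


def patient_screen(series_by_role: dict[str, TRSeries],
                   thresholds: ThresholdSet | None = None,
                   min_fail_duration_s: float = DEFAULT_MIN_FAIL_S,
                   segment_s: float = 10.0,
                   subject_id: str = "", subgroup: str = "") -> PatientScreeningResult:
    """Screen one patient: per-vector and per-patient outcomes.

    A patient passes a threshold iff at least one non-missing vector
    passes; patients with missing vectors are evaluated on the
    available vectors only.
    """
    thresholds = thresholds or ThresholdSet()
    if all(s.missing for s in series_by_role.values()):
        raise ValueError("all vectors missing: cannot screen patient")
    vector_results: dict[float, dict[str, VectorScreeningResult]] = {}
    passes: dict[float, bool] = {}
    for thr in thresholds.ratios:
        per_vec = {
            role: vector_prolonged_pass(s, thr, min_fail_duration_s, segment_s)
            for role, s in series_by_role.items()
        }
        vector_results[thr] = per_vec
        passes[thr] = any(r.passed for r in per_vec.values() if not r.missing)
    return PatientScreeningResult(
        subject_id=subject_id,
        subgroup=subgroup,
        standard_pass_probability=standard_pass_probability(series_by_role),
        passes=passes,
        vector_results=vector_results,
    )


def cohort_screen(cohort_series: list[tuple[str, str, dict[str, TRSeries]]],
                  thresholds: ThresholdSet | None = None,
                  min_fail_duration_s: float = DEFAULT_MIN_FAIL_S,
                  segment_s: float = 10.0
                  ) -> tuple[list[PatientScreeningResult], dict]:
    """Screen a cohort and tally per-threshold pass counts by subgroup.

    ``cohort_series`` holds ``(subject_id, subgroup, series_by_role)``
    triples.  Returns the per-patient results plus a summary mapping
    ``threshold -> subgroup -> (n_pass, n_total)``.
    """
    thresholds = thresholds or ThresholdSet()
    results = [
        patient_screen(series, thresholds, min_fail_duration_s, segment_s,
                       subject_id=sid, subgroup=grp)
        for sid, grp, series in cohort_series
    ]
    summary: dict[float, dict[str, tuple[int, int]]] = {}
    for thr in thresholds.ratios:
        by_group: dict[str, list[bool]] = {}
        for r in results:
            by_group.setdefault(r.subgroup, []).append(r.passes[thr])
        summary[thr] = {g: (sum(v), len(v)) for g, v in by_group.items()}
    return results, summary
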