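"""Per-arm summaries and the crossover study's statistical test battery.

The replayed study compares missed-contraindication counts between the
control arm (shared EMR only) and the intervention arm (EMR plus the
screening tool) over 54 opportunities per arm: unpaired t and
Mann-Whitney on the per-item (and, when available, per-physician) count
vectors, and a chi-square on the 2x2 of missed vs caught opportunities.

The pooled t and the chi-square delegate to scipy; the EXACT
Mann-Whitney is a full enumeration over rank assignments with mid-ranks
for ties, because the count vectors are heavily tied and the exact null
distribution under ties is not available off the shelf.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats as sps

from ..synthetic_ehr import PhysicianCaseResult
from .design import StudyAssignment, n_opportunities

__all__ = [
    "TVariant",
    "MWMode",
    "TestResult",
    "ArmResults",
    "ArmSummary",
    "StudyReport",
    "summarize_arm",
    "two_sample_t",
    "mann_whitney",
    "chi_square_2x2",
    "analyze_study",
    "arm_results_from_responses",
    "replay_published_counts",
    "STUDY_ITEM_IDS",
    "PUBLISHED_PER_ITEM_MISSES",
]

#: The six catalog items carried by the mock cases, in display order.
STUDY_ITEM_IDS: tuple[int, ...] = (1, 3, 13, 15, 16, 17)

#: The unambiguous per-item missed counts from the published evaluation
#: (bottom rows of its per-physician table): control misses 23 of 54
#: opportunities, intervention 7 of 54.
PUBLISHED_PER_ITEM_MISSES: dict[str, dict[int, int]] = {
    "control": {1: 2, 3: 6, 13: 5, 15: 2, 16: 1, 17: 7},
    "intervention": {1: 0, 3: 1, 13: 1, 15: 1, 16: 0, 17: 4},
}


class TVariant(str, Enum):
    POOLED = "POOLED"
    WELCH = "WELCH"


class MWMode(str, Enum):
    EXACT = "EXACT"
    NORMAL_APPROX = "NORMAL_APPROX"


class TestResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    statistic: Optional[float] = None
    df: Optional[float] = None
    p_value: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    flags: dict[str, object] = {}


def round_display(x: float, places: int = 1) -> float:
    """Half-up rounding for the 1-decimal display convention."""
    q = Decimal(10) ** -places
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class ArmResults(BaseModel):
    """Missed-count bookkeeping for one arm.

    Per-item counts are always present; per-physician counts are present
    when individual responses are available (a replay from published
    per-item margins alone leaves them None).
    """

    model_config = ConfigDict(frozen=True)

    arm: str
    item_ids: tuple[int, ...]
    per_item_missed: dict[int, int]
    per_physician_missed: Optional[dict[int, int]] = None
    per_physician_times: Optional[dict[int, float]] = None
    opportunities: int = Field(gt=0)
    n_physicians: int = Field(gt=0)

    @model_validator(mode="after")
    def _consistent(self) -> "ArmResults":
        if set(self.per_item_missed) != set(self.item_ids):
            raise ValueError("per_item_missed keys must equal item_ids")
        total = sum(self.per_item_missed.values())
        if not 0 <= total <= self.opportunities:
            raise ValueError(f"total missed {total} outside [0, {self.opportunities}]")
        if any(v < 0 for v in self.per_item_missed.values()):
            raise ValueError("negative per-item count")
        if self.per_physician_missed is not None:
            phys_total = sum(self.per_physician_missed.values())
            if phys_total != total:
                raise ValueError(
                    f"per-physician total {phys_total} != per-item total {total}"
                )
        return self

    @property
    def total_missed(self) -> int:
        return sum(self.per_item_missed.values())


class ArmSummary(BaseModel):
    model_config = ConfigDict(frozen=True)

    arm: str
    total_missed: int
    opportunities: int
    pct_missed: float
    per_physician_mean: float
    per_physician_sd: Optional[float] = None
    per_physician_median: Optional[float] = None
    per_item_mean: float
    per_item_sd: float
    per_item_median: float

    def display(self) -> dict[str, object]:
        """The 1-decimal rounded view matching the published table style."""
        out = {
            "arm": self.arm,
            "total_missed": self.total_missed,
            "pct_missed": round_display(self.pct_missed),
            "per_physician_mean": round_display(self.per_physician_mean),
            "per_item_mean": round_display(self.per_item_mean),
            "per_item_sd": round_display(self.per_item_sd),
            "per_item_median": round_display(self.per_item_median),
        }
        if self.per_physician_sd is not None:
            out["per_physician_sd"] = round_display(self.per_physician_sd)
        if self.per_physician_median is not None:
            out["per_physician_median"] = round_display(self.per_physician_median)
        return out


def summarize_arm(arm: ArmResults) -> ArmSummary:
    """Totals, percentage of opportunities, and per-item / per-physician
    mean, sample SD (n-1) and median."""
    item_counts = np.array([arm.per_item_missed[i] for i in arm.item_ids], dtype=float)
    total = int(item_counts.sum())
    summary: dict[str, object] = {
        "arm": arm.arm,
        "total_missed": total,
        "opportunities": arm.opportunities,
        "pct_missed": 100.0 * total / arm.opportunities,
        "per_physician_mean": total / arm.n_physicians,
        "per_item_mean": float(item_counts.mean()),
        "per_item_sd": float(item_counts.std(ddof=1)) if len(item_counts) > 1 else 0.0,
        "per_item_median": float(np.median(item_counts)),
    }
    if arm.per_physician_missed is not None:
        phys = np.array(
            [arm.per_physician_missed[p] for p in sorted(arm.per_physician_missed)],
            dtype=float,
        )
        summary["per_physician_sd"] = float(phys.std(ddof=1)) if len(phys) > 1 else 0.0
        summary["per_physician_median"] = float(np.median(phys))
    return ArmSummary(**summary)


def two_sample_t(x: Sequence[float], y: Sequence[float],
                 variant: TVariant = TVariant.POOLED) -> TestResult:
    """Unpaired two-sample t test, pooled-variance by default (Welch as a
    flag).  Raises on degenerate data (zero combined variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            # identical constant samples: no evidence of difference
            df = len(x) + len(y) - 2 if variant is TVariant.POOLED else float("nan")
            return TestResult(name="two_sample_t", statistic=0.0, df=df, p_value=1.0,
                              flags={"variant": variant.value, "degenerate": True})
        raise ValueError("zero combined variance: t statistic undefined")
    res = sps.ttest_ind(x, y, equal_var=(variant is TVariant.POOLED))
    df = float(res.df)
    return TestResult(name="two_sample_t", statistic=float(res.statistic), df=df,
                      p_value=float(res.pvalue), flags={"variant": variant.value})


def mann_whitney(x: Sequence[float], y: Sequence[float],
                 mode: MWMode = MWMode.EXACT) -> TestResult:
    """Mann-Whitney U test.

    EXACT enumerates all C(n1+n2, n1) rank assignments with mid-ranks for
    ties (allowed up to a combined sample size of 20) and reports the
    symmetric two-sided tail probability of U.  NORMAL_APPROX uses the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("samples must be non-empty")
    if mode is MWMode.NORMAL_APPROX:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                               use_continuity=True)
        return TestResult(name="mann_whitney", statistic=float(res.statistic),
                          p_value=float(res.pvalue),
                          flags={"mode": mode.value, "continuity": True})
    if n1 + n2 > 20:
        raise ValueError(
            f"EXACT enumeration limited to combined n <= 20 (got {n1 + n2}); "
            "use NORMAL_APPROX"
        )
    ranks = sps.rankdata(np.concatenate([x, y]))
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mean_u = n1 * n2 / 2.0
    dev_obs = abs(u_obs - mean_u)
    total = 0
    extreme = 0
    offset = n1 * (n1 + 1) / 2.0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if abs(u - mean_u) >= dev_obs - 1e-9:
            extreme += 1
    return TestResult(name="mann_whitney", statistic=u_obs, p_value=extreme / total,
                      flags={"mode": mode.value, "arrangements": total})


def chi_square_2x2(table: Sequence[Sequence[int]], correction: bool = True) -> TestResult:
    """Chi-square test on a 2x2 table, with Yates continuity correction
    when requested (df = 1).  Raises on a zero marginal."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("table entries must be non-negative integers")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero marginal: chi-square undefined")
    stat, p, dof, _ = sps.chi2_contingency(arr, correction=correction)
    return TestResult(name="chi_square_2x2", statistic=float(stat), df=float(dof),
                      p_value=float(p), flags={"yates_correction": correction})


def arm_results_from_responses(
    arm: str,
    responses: Sequence[PhysicianCaseResult],
    assignment: StudyAssignment,
    case_truth: dict[int, frozenset[int]],
) -> ArmResults:
    """Aggregate simulated (or recorded) per-case responses into one arm's
    bookkeeping, verifying that every assigned (physician, case) cell is
    present exactly once."""
    expected = {
        (pa.physician_id, c)
        for pa in assignment.assignments
        for c in (pa.control_cases if arm == "control" else pa.intervention_cases)
    }
    seen: set[tuple[int, int]] = set()
    item_ids = tuple(sorted({i for s in case_truth.values() for i in s}))
    per_item = {i: 0 for i in item_ids}
    per_phys = {pa.physician_id: 0 for pa in assignment.assignments}
    per_times = {pa.physician_id: 0.0 for pa in assignment.assignments}
    for r in responses:
        if r.arm != arm:
            continue
        cell = (r.physician_id, r.case_id)
        if cell in seen:
            raise ValueError(f"duplicate response for {arm} cell {cell}")
        seen.add(cell)
        for item in r.missed_items:
            per_item[item] += 1
            per_phys[r.physician_id] += 1
        per_times[r.physician_id] += r.time_min
    missing = sorted(expected - seen)
    if missing:
        raise ValueError(f"missing {arm} responses for (physician, case) cells: {missing}")
    extra = sorted(seen - expected)
    if extra:
        raise ValueError(f"responses outside the {arm} assignment: {extra}")
    return ArmResults(
        arm=arm, item_ids=item_ids, per_item_missed=per_item,
        per_physician_missed=per_phys, per_physician_times=per_times,
        opportunities=n_opportunities(assignment, case_truth),
        n_physicians=assignment.n_physicians,
    )


class StudyReport(BaseModel):
    model_config = ConfigDict(frozen=True)

    control: ArmSummary
    intervention: ArmSummary
    per_item_missed: dict[str, dict[int, int]]
    missed_table: tuple[tuple[int, int], tuple[int, int]]
    tests: dict[str, TestResult]

    def to_json(self) -> str:
        return self.model_dump_json(indent=1)

    def per_item_frame(self):
        """Per-item missed counts as a pandas DataFrame (for CSV export)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "control_missed": self.per_item_missed["control"],
                "intervention_missed": self.per_item_missed["intervention"],
            }
        ).rename_axis("item_id")


def _vector(per_item: dict[int, int], item_ids: Sequence[int]) -> list[int]:
    return [per_item[i] for i in item_ids]


def _safe(test_fn, name: str, *args, **kwargs) -> TestResult:
    try:
        result = test_fn(*args, **kwargs)
        return result.model_copy(update={"name": name})
    except ValueError as exc:
        return TestResult(name=name, flags={"degenerate": True, "reason": str(exc)})


def analyze_study(
    assignment: StudyAssignment,
    responses: Sequence[PhysicianCaseResult],
    case_truth: dict[int, frozenset[int]] | None = None,
) -> StudyReport:
    """Full crossover analysis: per-arm summaries plus the test battery.

    t and Mann-Whitney are applied to the per-item and per-physician count
    vectors; the chi-square to the 2x2 of missed vs caught opportunities
    (reported both with and without Yates correction).  Degenerate inputs
    (e.g. a zero-miss study) yield flagged, skipped tests rather than
    errors.
    """
    from ..synthetic_ehr import CASE_TRUTH

    case_truth = CASE_TRUTH if case_truth is None else case_truth
    arms = {
        arm: arm_results_from_responses(arm, responses, assignment, case_truth)
        for arm in ("control", "intervention")
    }
    summaries = {arm: summarize_arm(res) for arm, res in arms.items()}
    opp = arms["control"].opportunities
    table = (
        (arms["control"].total_missed, opp - arms["control"].total_missed),
        (arms["intervention"].total_missed, opp - arms["intervention"].total_missed),
    )
    item_ids = arms["control"].item_ids
    c_items = _vector(arms["control"].per_item_missed, item_ids)
    i_items = _vector(arms["intervention"].per_item_missed, item_ids)
    c_phys = [arms["control"].per_physician_missed[p]
              for p in sorted(arms["control"].per_physician_missed)]
    i_phys = [arms["intervention"].per_physician_missed[p]
              for p in sorted(arms["intervention"].per_physician_missed)]
    mw_item_mode = MWMode.EXACT if len(c_items) + len(i_items) <= 20 else MWMode.NORMAL_APPROX
    tests = {
        "per_item_t": _safe(two_sample_t, "per_item_t", c_items, i_items),
        "per_item_mann_whitney": _safe(mann_whitney, "per_item_mann_whitney",
                                       c_items, i_items, mw_item_mode),
        "per_physician_t": _safe(two_sample_t, "per_physician_t", c_phys, i_phys),
        "per_physician_mann_whitney": _safe(mann_whitney, "per_physician_mann_whitney",
                                            c_phys, i_phys, MWMode.NORMAL_APPROX),
        "chi2_missed": _safe(chi_square_2x2, "chi2_missed", table, True),
        "chi2_missed_uncorrected": _safe(chi_square_2x2, "chi2_missed_uncorrected",
                                         table, False),
    }
    if arms["control"].per_physician_times is not None:
        c_t = [arms["control"].per_physician_times[p]
               for p in sorted(arms["control"].per_physician_times)]
        i_t = [arms["intervention"].per_physician_times[p]
               for p in sorted(arms["intervention"].per_physician_times)]
        tests["review_time_t"] = _safe(two_sample_t, "review_time_t", c_t, i_t)
    return StudyReport(
        control=summaries["control"],
        intervention=summaries["intervention"],
        per_item_missed={arm: dict(res.per_item_missed) for arm, res in arms.items()},
        missed_table=table,
        tests=tests,
    )


def replay_published_counts() -> tuple[ArmSummary, ArmSummary, dict[str, TestResult]]:
    """Replay the published per-item missed counts through the summary and
    test battery: control [2,6,5,2,1,7] of 54, intervention [0,1,1,1,0,4]
    of 54, 12 physicians per arm."""
    summaries = []
    for arm in ("control", "intervention"):
        results = ArmResults(
            arm=arm, item_ids=STUDY_ITEM_IDS,
            per_item_missed=PUBLISHED_PER_ITEM_MISSES[arm],
            opportunities=54, n_physicians=12,
        )
        summaries.append(summarize_arm(results))
    control, intervention = summaries
    c = _vector(PUBLISHED_PER_ITEM_MISSES["control"], STUDY_ITEM_IDS)
    i = _vector(PUBLISHED_PER_ITEM_MISSES["intervention"], STUDY_ITEM_IDS)
    table = ((control.total_missed, 54 - control.total_missed),
             (intervention.total_missed, 54 - intervention.total_missed))
    tests = {
        "per_item_t": two_sample_t(c, i, TVariant.POOLED),
        "per_item_mann_whitney": mann_whitney(c, i, MWMode.EXACT),
        "chi2_missed": chi_square_2x2(table, correction=True),
        "chi2_missed_uncorrected": chi_square_2x2(table, correction=False),
    }
    return control, intervention, tests
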