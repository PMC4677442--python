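"""Counterbalanced fixed-sequence two-period crossover design.

Each physician screens two cases without the decision-support tool (the
control arm) and two different cases with it (the intervention arm).
Counterbalancing requires every case to appear the same number of times
in each arm; with 4 cases and 12 physicians that is six appearances per
case per arm, obtained by cycling through the six ordered pair-splits of
the case set twice.
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "PhysicianAssignment",
    "StudyAssignment",
    "AssignmentError",
    "counterbalanced_assignment",
    "validate_assignment",
    "n_opportunities",
    "REFERENCE_ASSIGNMENT",
]


class AssignmentError(ValueError):
    """Infeasible or unbalanced study assignment."""


class PhysicianAssignment(BaseModel):
    model_config = ConfigDict(frozen=True)

    physician_id: int
    control_cases: tuple[int, ...]
    intervention_cases: tuple[int, ...]

    @model_validator(mode="after")
    def _disjoint(self) -> "PhysicianAssignment":
        control, intervention = set(self.control_cases), set(self.intervention_cases)
        if len(control) != len(self.control_cases) or len(intervention) != len(self.intervention_cases):
            raise ValueError(f"physician {self.physician_id}: repeated case within an arm")
        if control & intervention:
            raise ValueError(f"physician {self.physician_id}: arms share cases {sorted(control & intervention)}")
        return self


class StudyAssignment(BaseModel):
    model_config = ConfigDict(frozen=True)

    case_ids: tuple[int, ...]
    assignments: tuple[PhysicianAssignment, ...]

    @property
    def n_physicians(self) -> int:
        return len(self.assignments)


def validate_assignment(assignment: StudyAssignment) -> dict[str, dict[int, int]]:
    """Check the counterbalance invariants and return per-arm case counts.

    Raises :class:`AssignmentError` unless each physician's two arms are
    disjoint and cover distinct cases, and each case appears exactly
    ``n_physicians / 2`` times per arm.
    """
    cases = set(assignment.case_ids)
    counts = {"control": {c: 0 for c in assignment.case_ids},
              "intervention": {c: 0 for c in assignment.case_ids}}
    for pa in assignment.assignments:
        for arm, arm_cases in (("control", pa.control_cases), ("intervention", pa.intervention_cases)):
            for c in arm_cases:
                if c not in cases:
                    raise AssignmentError(f"physician {pa.physician_id}: unknown case {c}")
                counts[arm][c] += 1
        if set(pa.control_cases) | set(pa.intervention_cases) != cases:
            raise AssignmentError(
                f"physician {pa.physician_id}: arms do not cover all cases {sorted(cases)}"
            )
    expected = assignment.n_physicians / 2
    for arm, per_case in counts.items():
        for c, k in per_case.items():
            if k != expected:
                raise AssignmentError(
                    f"case {c} appears {k} times in the {arm} arm; "
                    f"counterbalance requires {expected:g}"
                )
    return counts


def counterbalanced_assignment(
    n_physicians: int = 12,
    cases: Sequence[int] = (1, 2, 3, 4),
    seed: Optional[int] = None,
) -> StudyAssignment:
    """Build a counterbalanced assignment over the ordered half-splits of
    the case set.

    ``n_physicians`` must be a multiple of the number of ordered splits
    (6 for four cases) so each split is used equally often.  With
    ``seed=None`` the splits are assigned in canonical order, which for
    (12 physicians, 4 cases) reproduces the reference study layout; a
    seed shuffles which physician receives which split while preserving
    balance exactly.
    """
    cases = tuple(cases)
    if len(cases) % 2 or len(cases) < 2:
        raise AssignmentError("need an even number (>= 2) of distinct cases")
    half = len(cases) // 2
    splits = []
    for control in combinations(cases, half):
        intervention = tuple(c for c in cases if c not in control)
        splits.append((control, intervention))
    if n_physicians % len(splits):
        raise AssignmentError(
            f"n_physicians must be a multiple of {len(splits)} "
            f"(the ordered half-splits of {len(cases)} cases); got {n_physicians}"
        )
    slots = splits * (n_physicians // len(splits))
    if seed is not None:
        rng = np.random.default_rng(seed)
        slots = [slots[i] for i in rng.permutation(len(slots))]
    assignments = tuple(
        PhysicianAssignment(physician_id=i + 1, control_cases=ctrl, intervention_cases=itv)
        for i, (ctrl, itv) in enumerate(slots)
    )
    out = StudyAssignment(case_ids=cases, assignments=assignments)
    validate_assignment(out)
    return out


#: The reference 12-physician layout: physicians 1-6 cycle the six ordered
#: pair-splits {1,2|3,4}, {1,3|2,4}, {1,4|2,3}, {2,3|1,4}, {2,4|1,3},
#: {3,4|1,2}; physicians 7-12 repeat it, giving every case six
#: appearances per arm.
REFERENCE_ASSIGNMENT: StudyAssignment = counterbalanced_assignment(12, (1, 2, 3, 4), seed=None)


def n_opportunities(assignment: StudyAssignment,
                    case_truth: dict[int, frozenset[int]]) -> int:
    """Contraindication-item opportunities per arm: the sum of each
    assigned case's true item count.  In the reference design each case
    appears six times per arm, 6 x 9 = 54 opportunities."""
    per_arm_control = sum(len(case_truth[c]) for pa in assignment.assignments
                          for c in pa.control_cases)
    per_arm_intervention = sum(len(case_truth[c]) for pa in assignment.assignments
                               for c in pa.intervention_cases)
    if per_arm_control != per_arm_intervention:
        raise AssignmentError(
            f"arms have unequal opportunity counts: {per_arm_control} vs {per_arm_intervention}"
        )
    return per_arm_control
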