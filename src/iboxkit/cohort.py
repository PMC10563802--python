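"""Cohort container: aligned assessments, outcomes and optional arm labels.

A :class:`Cohort` is the unit every pipeline operation consumes.  A
subject's assessment may be absent when the subject failed (graft loss,
death, or loss to follow-up) before the scheduled assessment; such
subjects are retained so trial analyses can impute worst-case scores
instead of silently dropping them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .scoring import Assessment
from .survival import Outcome

__all__ = ["Subject", "Cohort"]


@dataclass(frozen=True)
class Subject:
    """One randomized/enrolled subject: outcome always, assessment if reached."""

    subject_id: str
    outcome: Outcome
    assessment: Optional[Assessment] = None
    arm: Optional[str] = None

    def __post_init__(self) -> None:
        if self.outcome.subject_id != self.subject_id:
            raise ValueError(
                f"outcome subject_id {self.outcome.subject_id!r} does not match "
                f"{self.subject_id!r}"
            )
        if self.assessment is not None and self.assessment.subject_id != self.subject_id:
            raise ValueError(
                f"assessment subject_id {self.assessment.subject_id!r} does not "
                f"match {self.subject_id!r}"
            )


@dataclass
class Cohort:
    subjects: List[Subject] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def outcomes(self) -> List[Outcome]:
        return [s.outcome for s in self.subjects]

    @property
    def assessments(self) -> List[Optional[Assessment]]:
        return [s.assessment for s in self.subjects]

    @property
    def arms(self) -> Optional[np.ndarray]:
        labels = [s.arm for s in self.subjects]
        if all(a is None for a in labels):
            return None
        if any(a is None for a in labels):
            raise ValueError("arm labels must be present for all subjects or none")
        return np.array(labels)

    @property
    def has_banff(self) -> bool:
        """True if every present assessment carries a Banff profile."""
        present = [s.assessment for s in self.subjects if s.assessment is not None]
        return bool(present) and all(a.banff is not None for a in present)

    def assessed(self) -> "Cohort":
        """Sub-cohort of subjects who reached their assessment."""
        return Cohort([s for s in self.subjects if s.assessment is not None])

    def select_arm(self, label: str) -> "Cohort":
        sel = [s for s in self.subjects if s.arm == label]
        if not sel:
            raise ValueError(f"no subjects in arm {label!r}")
        return Cohort(sel)

    def arm_labels(self) -> Sequence[str]:
        arms = self.arms
        if arms is None:
            raise ValueError("cohort has no arm labels")
        return sorted(set(arms.tolist()))
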