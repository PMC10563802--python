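"""Endpoint validation statistics: discrimination and calibration.

Discrimination is Harrell's c-statistic under censoring: the probability
that, of two comparable subjects, the one with the higher score (higher
predicted hazard) has the shorter death-censored graft survival.  A
pair is usable iff the member with the shorter observed time had an
event; tied observed times are not usable; tied scores count 1/2.  The
standard error is a leave-one-subject-out jackknife.

Calibration compares the observed event count O with the model-expected
count E (the sum of per-subject predicted event probabilities at the
horizon) with the Poisson-approximation test z = (O - E)/sqrt(E),
two-sided normal p.  For a single stratum this is the score test of a
Poisson intercept against the model offset.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import Cohort
from .scoring import ModelCoefficients, load_coefficients, score_assessment
from .survival import BaselineHazard, Outcome, event_arrays, predict_event_probability

__all__ = [
    "ConcordanceResult",
    "CalibrationResult",
    "ValidationReport",
    "concordance",
    "expected_events",
    "poisson_calibration",
    "validate_cohort",
]


@dataclass(frozen=True)
class ConcordanceResult:
    c: float
    se: float
    n_usable_pairs: int

    @property
    def defined(self) -> bool:
        return self.n_usable_pairs > 0


def _pair_weights(scores: np.ndarray, t: np.ndarray, e: np.ndarray):
    """(usable, concordance weight) matrices over ordered pairs (i, j), i<j.

    usable[i, j] is True iff the subject with the strictly shorter
    observed time had an event; weight[i, j] is 1 if the shorter-time
    subject has the strictly higher score, 0.5 on score ties, else 0.
    """
    ti, tj = t[:, None], t[None, :]
    ei = e[:, None]
    si, sj = scores[:, None], scores[None, :]
    # "i is the earlier failure" orientation; full matrix, we keep i<j later
    i_short = (ti < tj) & ei
    win = np.where(si > sj, 1.0, np.where(si == sj, 0.5, 0.0))
    usable = i_short | i_short.T
    weight = np.where(i_short, win, np.where(i_short.T, win.T, 0.0))
    return usable, weight


def concordance(
    scores: Sequence, outcomes: Sequence[Outcome], all_cause: bool = False
) -> ConcordanceResult:
    """Harrell's c over usable pairs, with jackknife SE over subjects."""
    s = np.asarray([getattr(v, "value", v) for v in scores], dtype=float)
    t, e = event_arrays(outcomes, all_cause=all_cause)
    n = len(s)
    if n != len(t):
        raise ValueError("scores and outcomes must be aligned")
    if n < 2:
        raise ValueError("concordance requires at least 2 subjects")
    usable, weight = _pair_weights(s, t, e)
    iu = np.triu_indices(n, k=1)
    U = usable[iu].sum()
    C = weight[iu].sum()
    if U == 0:
        return ConcordanceResult(c=math.nan, se=math.nan, n_usable_pairs=0)
    c = C / U
    # leave-one-out via per-subject pair totals; both matrices are
    # symmetric with zero diagonal, so a row sum is the subject's pairs
    u_i = usable.sum(axis=1).astype(float)
    c_i = weight.sum(axis=1)
    denom = U - u_i
    keep = denom > 0
    loo = (C - c_i[keep]) / denom[keep]
    m = len(loo)
    if m < 2:
        se = math.nan
    else:
        se = math.sqrt((m - 1) / m * np.sum((loo - loo.mean()) ** 2))
    return ConcordanceResult(c=float(c), se=float(se), n_usable_pairs=int(U))


def expected_events(event_probabilities: Sequence[float]) -> float:
    """Model-expected event count: the sum of per-subject probabilities."""
    p = np.asarray(list(event_probabilities), dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p))):
        raise ValueError("event probabilities must lie in [0, 1]")
    return float(p.sum())


@dataclass(frozen=True)
class CalibrationResult:
    observed: int
    expected: float
    z: float
    p: float


def poisson_calibration(observed: int, expected: float) -> CalibrationResult:
    """Two-sided Poisson-approximation calibration test.

    z = (O - E) / sqrt(E); p = 2 * P(|Z| > |z|) under the standard
    normal.  E = O = 0 gives p = 1; E = 0 with O > 0 is an infinite-z
    miscalibration (p = 0).
    """
    if observed < 0 or expected < 0:
        raise ValueError("counts must be non-negative")
    if expected == 0:
        if observed == 0:
            return CalibrationResult(observed=0, expected=0.0, z=0.0, p=1.0)
        return CalibrationResult(observed=observed, expected=0.0, z=math.inf, p=0.0)
    z = (observed - expected) / math.sqrt(expected)
    p = 2.0 * stats.norm.sf(abs(z))
    return CalibrationResult(observed=int(observed), expected=float(expected), z=float(z), p=float(p))


@dataclass(frozen=True)
class ValidationReport:
    """Discrimination + calibration at one assessment time and horizon."""

    variant: str
    assessment_time: float
    horizon: float
    n: int
    concordance: ConcordanceResult
    calibration: CalibrationResult
    exclusions: dict
    baseline_provenance: str

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_frame(self):
        """Single-row table: n, c (SE), observed, expected, p."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "variant": self.variant,
                    "assessment_time_years": self.assessment_time,
                    "horizon_years": self.horizon,
                    "n": self.n,
                    "c_statistic": self.concordance.c,
                    "c_se": self.concordance.se,
                    "observed_events": self.calibration.observed,
                    "predicted_events": self.calibration.expected,
                    "calibration_p": self.calibration.p,
                }
            ]
        )


def validate_cohort(
    cohort: Cohort,
    variant: str,
    assessment_time: float,
    horizon: float,
    baseline: BaselineHazard,
    coefficients: Optional[ModelCoefficients] = None,
    time_window: float = 0.5,
) -> ValidationReport:
    """Score a cohort and report discrimination + calibration at a horizon.

    Subjects without an assessment, or assessed further than
    ``time_window`` years from ``assessment_time``, are excluded and
    itemized.  Discrimination uses all follow-up under standard Harrell
    pair rules; calibration truncates at the horizon: observed events
    are graft losses by ``horizon``, expected events are the summed
    predicted probabilities at ``horizon``.
    """
    if coefficients is None:
        coefficients = load_coefficients(variant)
    exclusions = {"no_assessment": [], "assessment_time_outside_window": []}
    kept = []
    for subj in cohort:
        if subj.assessment is None:
            exclusions["no_assessment"].append(subj.subject_id)
        elif abs(subj.assessment.time_from_transplant - assessment_time) > time_window:
            exclusions["assessment_time_outside_window"].append(subj.subject_id)
        else:
            kept.append(subj)
    if len(kept) < 2:
        raise ValueError(
            f"cohort has {len(kept)} subject(s) after exclusions; need at least 2"
        )
    scores = [score_assessment(s.assessment, variant, coefficients) for s in kept]
    outcomes = [s.outcome for s in kept]
    conc = concordance(scores, outcomes)
    probs = [predict_event_probability(sc, baseline, horizon) for sc in scores]
    expected = expected_events(probs)
    observed = sum(
        1 for o in outcomes if o.graft_loss and o.followup_years <= horizon
    )
    calib = poisson_calibration(observed, expected)
    return ValidationReport(
        variant=variant,
        assessment_time=assessment_time,
        horizon=horizon,
        n=len(kept),
        concordance=conc,
        calibration=calib,
        exclusions=exclusions,
        baseline_provenance=baseline.provenance,
    )
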