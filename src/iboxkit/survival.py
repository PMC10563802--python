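"""Survival machinery: baseline hazard, absolute risk, Kaplan-Meier, two-group Cox.

The qualified iBOX weights come with no published baseline survival, so
absolute risk requires a cumulative baseline hazard estimated from some
cohort.  :func:`breslow_baseline` provides the standard Breslow step
estimator treating the iBOX scores as fixed linear predictors; the
resulting :class:`BaselineHazard` carries a provenance tag so
cohort-estimated absolute risks are never mistaken for qualified model
output.

Death with a functioning graft is censoring in all death-censored
analyses (the qualified outcome); every operation also accepts
``all_cause=True``, in which case death with function counts as an
event.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = [
    "Outcome",
    "BaselineHazard",
    "KMCurve",
    "EffectEstimate",
    "breslow_baseline",
    "predict_event_probability",
    "km_curve",
    "cox_two_group_loghr",
]


@dataclass(frozen=True)
class Outcome:
    """Death-censored graft-loss follow-up for one subject.

    ``graft_loss`` flags return to dialysis / retransplantation;
    ``died_with_function`` flags death with a functioning graft, which
    is censoring under the death-censored convention.  The two flags are
    mutually exclusive.
    """

    subject_id: str
    followup_years: float
    graft_loss: bool
    died_with_function: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.followup_years) or self.followup_years <= 0:
            raise ValueError(f"followup_years must be finite and > 0, got {self.followup_years!r}")
        if self.graft_loss and self.died_with_function:
            raise ValueError(
                f"subject {self.subject_id!r}: graft_loss and died_with_function "
                "cannot both be true"
            )


def event_arrays(outcomes: Sequence[Outcome], all_cause: bool = False):
    """(times, event flags) under the chosen censoring convention."""
    t = np.array([o.followup_years for o in outcomes], dtype=float)
    if all_cause:
        e = np.array([o.graft_loss or o.died_with_function for o in outcomes], dtype=bool)
    else:
        e = np.array([o.graft_loss for o in outcomes], dtype=bool)
    return t, e


@dataclass(frozen=True)
class BaselineHazard:
    """Cumulative baseline hazard H0(t) as a right-continuous step function.

    ``provenance`` records where the estimate came from
    (``"estimated-from-cohort"`` or ``"user-supplied"``); downstream
    reports carry it so cohort-derived absolute risks are labelled.
    """

    times: np.ndarray
    cumhaz: np.ndarray
    provenance: str = "estimated-from-cohort"
    support_end: float = field(default=math.nan)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        h = np.asarray(self.cumhaz, dtype=float)
        if t.shape != h.shape:
            raise ValueError("times and cumhaz must have the same length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(h < 0) or np.any(np.diff(h) < 0):
            raise ValueError("cumulative hazard must be non-negative and non-decreasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cumhaz", h)
        if math.isnan(self.support_end):
            object.__setattr__(self, "support_end", float(t[-1]) if len(t) else 0.0)

    def cumulative_hazard(self, t: float) -> float:
        """H0(t); 0 before the first event, clamped (with a warning) past support."""
        if t < 0:
            raise ValueError("time must be >= 0")
        if t > self.support_end:
            warnings.warn(
                f"horizon {t:g} y beyond baseline support (ends {self.support_end:g} y); "
                "clamping to the last estimated value",
                stacklevel=2,
            )
            t = self.support_end
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.cumhaz[idx])


def breslow_baseline(
    scores: Sequence[float], outcomes: Sequence[Outcome], all_cause: bool = False
) -> BaselineHazard:
    """Breslow estimator of H0(t) with the scores as fixed linear predictors.

    dH0(t_k) = d_k / sum_{j in risk set} exp(score_j).  With all scores
    zero this is the Nelson-Aalen estimator.
    """
    lp = np.asarray([getattr(s, "value", s) for s in scores], dtype=float)
    t, e = event_arrays(outcomes, all_cause=all_cause)
    if len(lp) != len(t):
        raise ValueError("scores and outcomes must be aligned")
    if not e.any():
        raise ValueError("no events to anchor baseline")
    w = np.exp(lp)
    event_times = np.unique(t[e])
    increments = np.empty_like(event_times)
    for k, tk in enumerate(event_times):
        at_risk = t >= tk
        d = int(np.sum(e & (t == tk)))
        increments[k] = d / w[at_risk].sum()
    return BaselineHazard(
        times=event_times,
        cumhaz=np.cumsum(increments),
        provenance="estimated-from-cohort",
        support_end=float(t.max()),
    )


def predict_event_probability(score, baseline: BaselineHazard, horizon: float) -> float:
    """Absolute event probability by ``horizon`` years: 1 - exp(-H0(h) e^score)."""
    value = float(getattr(score, "value", score))
    h0 = baseline.cumulative_hazard(horizon)
    return 1.0 - math.exp(-h0 * math.exp(value))


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit curve with Greenwood standard errors."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    se: np.ndarray             # Greenwood SE of S(t)
    at_risk: np.ndarray        # number at risk just before each event time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def se_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.se[idx])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "se": self.se,
                "at_risk": self.at_risk,
            }
        )


def km_curve(outcomes: Sequence[Outcome], all_cause: bool = False) -> KMCurve:
    """Product-limit estimate with Greenwood variance.

    All-censored input yields a flat curve at 1 (no event times).
    """
    if len(outcomes) == 0:
        raise ValueError("empty cohort")
    t, e = event_arrays(outcomes, all_cause=all_cause)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    rows = table[table["observed"] > 0]
    if len(rows) == 0:
        z = np.array([], dtype=float)
        return KMCurve(times=z, survival=z.copy(), se=z.copy(), at_risk=z.copy())
    times = rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[rows.index, "KM_estimate"].to_numpy(dtype=float)
    # Greenwood: Var S(t) = S(t)^2 * sum_{t_k <= t} d_k / (n_k (n_k - d_k))
    d = rows["observed"].to_numpy(dtype=float)
    n = rows["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), np.inf)
    var = surv**2 * np.cumsum(terms)
    var = np.where(np.isfinite(var), var, 0.0)  # S=0 after last event: SE 0
    return KMCurve(times=times, survival=surv, se=np.sqrt(var), at_risk=n)


@dataclass(frozen=True)
class EffectEstimate:
    """Two-group treatment effect as a log hazard ratio with Wald inference."""

    log_hr: float
    se: Optional[float]
    p: Optional[float]
    converged: bool = True


def _breslow_neg_loglik_parts(beta, d, d1, n0, n1):
    """Breslow-ties partial log-likelihood pieces at one event time grid."""
    eb = np.exp(beta)
    denom = n0 + n1 * eb
    ll = np.sum(d1 * beta - d * np.log(denom))
    grad = np.sum(d1 - d * n1 * eb / denom)
    hess = -np.sum(d * n0 * n1 * eb / denom**2)
    return ll, grad, hess


def _efron_neg_loglik_parts(beta, d, d1, n0, n1):
    eb = np.exp(beta)
    ll = grad = hess = 0.0
    for dk, d1k, n0k, n1k in zip(d, d1, n0, n1):
        ll += d1k * beta
        d0k = dk - d1k
        for l in range(int(dk)):
            f = l / dk
            a = n1k * eb - f * d1k * eb  # treated mass in adjusted risk set
            denom = (n0k - f * d0k) + a
            ll -= math.log(denom)
            grad_term = a / denom
            grad -= grad_term
            hess -= grad_term * (1 - grad_term)
        grad += d1k
    return ll, grad, hess


def cox_two_group_loghr(
    outcomes: Sequence[Outcome],
    arm: Sequence,
    all_cause: bool = False,
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-10,
) -> EffectEstimate:
    """Single-covariate Cox fit for a binary arm indicator.

    Maximizes the two-group partial likelihood by Newton iteration
    (Breslow tie handling by default, Efron optionally).  The log-HR is
    for the arm coded 1 relative to the arm coded 0.  When one arm has
    no events the likelihood is monotone: a bounded estimate is returned
    flagged non-convergent, with no usable SE or p.
    """
    t, e = event_arrays(outcomes, all_cause=all_cause)
    x = np.asarray(arm)
    if x.dtype != bool and not np.issubdtype(x.dtype, np.number):
        labels = sorted(set(x.tolist()))
        if len(labels) != 2:
            raise ValueError(f"arm must be binary, got labels {labels}")
        x = x == labels[1]
    x = x.astype(bool)
    if len(x) != len(t):
        raise ValueError("outcomes and arm labels must be aligned")
    if x.all() or (~x).all():
        raise ValueError("both arms must have subjects")
    if not e.any():
        raise ValueError("no events overall")
    if ties not in ("breslow", "efron"):
        raise ValueError(f"ties must be 'breslow' or 'efron', got {ties!r}")

    event_times = np.unique(t[e])
    d = np.array([np.sum(e & (t == tk)) for tk in event_times], dtype=float)
    d1 = np.array([np.sum(e & (t == tk) & x) for tk in event_times], dtype=float)
    n1 = np.array([np.sum((t >= tk) & x) for tk in event_times], dtype=float)
    n0 = np.array([np.sum((t >= tk) & ~x) for tk in event_times], dtype=float)

    monotone = d1.sum() == 0 or (d - d1).sum() == 0
    parts = _breslow_neg_loglik_parts if ties == "breslow" else _efron_neg_loglik_parts

    beta = 0.0
    bound = 20.0
    converged = False
    for _ in range(max_iter):
        _, grad, hess = parts(beta, d, d1, n0, n1)
        if hess == 0:
            break
        step = -grad / hess
        beta = float(np.clip(beta + step, -bound, bound))
        if abs(step) < tol or abs(beta) >= bound:
            converged = abs(beta) < bound
            break

    if monotone or not converged:
        warnings.warn(
            "monotone partial likelihood (no events in one arm); estimate is "
            "bounded and reported as non-convergent",
            stacklevel=2,
        )
        return EffectEstimate(log_hr=beta, se=None, p=None, converged=False)

    _, _, hess = parts(beta, d, d1, n0, n1)
    se = math.sqrt(-1.0 / hess)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return EffectEstimate(log_hr=beta, se=se, p=float(p), converged=True)
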