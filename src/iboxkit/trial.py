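"""iBOX as a between-arm trial endpoint.

Subjects who lose their graft, die, or are lost to follow-up before the
scheduled assessment cannot be scored from measurements; dropping them
would bias the endpoint toward survivors.  They instead receive a
worst-case score, by default *worst-rank*: strictly worse than every
computed score, which is exactly what a rank-based comparison needs.
A *worst-bounds* alternative assigns the score of a configurable worst
covariate profile, for uses that need a concrete value on the score
scale.

Arms are compared by the difference in median scores (bootstrap SD,
Wilcoxon rank-sum p), by Kaplan-Meier graft survival at a horizon, and
by the two-group Cox log hazard ratio.  Power for the rank-sum endpoint
is estimated by Monte-Carlo simulation over a grid of sample sizes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .cohort import Cohort
from .scoring import (
    Assessment,
    BanffProfile,
    ModelCoefficients,
    Score,
    load_coefficients,
    score_assessment,
)
from .simulate import SimConfig, simulate_trial
from .survival import EffectEstimate, cox_two_group_loghr, km_curve

__all__ = [
    "ImputationPolicy",
    "TrialResult",
    "PowerConfig",
    "PowerCurve",
    "worst_case_impute",
    "median_difference_test",
    "analyze_trial",
    "power_curve",
]

logger = logging.getLogger(__name__)

#: Default worst-bounds covariate profile: failing kidney function,
#: nephrotic-range proteinuria, DSA-positive, severe lesions throughout.
DEFAULT_WORST_PROFILE = dict(
    egfr=10.0, upcr=3.0, dsa_mfi=5000.0,
    banff=BanffProfile(ifta=3, g=3, ptc=3, i=3, t=3, cg=3),
)


@dataclass(frozen=True)
class ImputationPolicy:
    """How pre-assessment failures receive a worst-case score.

    ``worst-rank``: max computed score + ``epsilon`` (rank-safe).
    ``worst-bounds``: the score of ``worst_profile``, identical for all
    imputed subjects.
    """

    mode: str = "worst-rank"
    epsilon: float = 0.1
    worst_profile: dict = field(default_factory=lambda: dict(DEFAULT_WORST_PROFILE))

    def __post_init__(self) -> None:
        if self.mode not in ("worst-rank", "worst-bounds"):
            raise ValueError("mode must be 'worst-rank' or 'worst-bounds'")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")

    def worst_profile_score(
        self, variant: str, assessment_time: float, coefficients: ModelCoefficients
    ) -> float:
        a = Assessment(
            subject_id="__worst__",
            time_from_transplant=assessment_time,
            egfr=self.worst_profile["egfr"],
            upcr=self.worst_profile["upcr"],
            dsa_mfi=self.worst_profile["dsa_mfi"],
            banff=self.worst_profile.get("banff") if variant == "full" else None,
        )
        return score_assessment(a, variant, coefficients).value


def worst_case_impute(
    cohort: Cohort,
    variant: str,
    assessment_time: float,
    policy: Optional[ImputationPolicy] = None,
    coefficients: Optional[ModelCoefficients] = None,
) -> List[Score]:
    """Score every subject, imputing worst-case for pre-assessment failures.

    A subject must have either an assessment or an observed end of
    follow-up (event or censoring) before ``assessment_time``; anything
    else is a data-integrity error.  Under worst-rank, imputed scores
    are the maximum computed score plus epsilon, so they rank strictly
    worse than every computed score.
    """
    if policy is None:
        policy = ImputationPolicy()
    if coefficients is None:
        coefficients = load_coefficients(variant)
    computed: Dict[str, float] = {}
    imputed_ids: List[str] = []
    for subj in cohort:
        if subj.assessment is not None:
            computed[subj.subject_id] = score_assessment(
                subj.assessment, variant, coefficients
            ).value
        elif subj.outcome.followup_years < assessment_time:
            imputed_ids.append(subj.subject_id)
        else:
            raise ValueError(
                f"subject {subj.subject_id!r} has no assessment but follow-up "
                f"({subj.outcome.followup_years:g} y) reaches the scheduled "
                f"assessment at {assessment_time:g} y"
            )
    if policy.mode == "worst-rank":
        if computed:
            worst = max(computed.values()) + policy.epsilon
        else:
            worst = policy.worst_profile_score(variant, assessment_time, coefficients)
    else:
        worst = policy.worst_profile_score(variant, assessment_time, coefficients)
    if imputed_ids:
        logger.info(
            "worst-case imputation (%s): %d of %d subjects assigned score %.4f",
            policy.mode, len(imputed_ids), len(cohort), worst,
        )
    out = []
    for subj in cohort:
        if subj.subject_id in computed:
            out.append(
                Score(subj.subject_id, variant, computed[subj.subject_id], imputed=False)
            )
        else:
            out.append(Score(subj.subject_id, variant, worst, imputed=True))
    return out


@dataclass(frozen=True)
class MedianDifference:
    difference: float      # median(a) - median(b)
    sd: float              # bootstrap SD of the difference
    p: float               # two-sided Wilcoxon rank-sum


def median_difference_test(
    scores_a: Sequence,
    scores_b: Sequence,
    n_boot: int = 2000,
    seed: int = 0,
) -> MedianDifference:
    """Difference in medians with bootstrap SD and Wilcoxon rank-sum p.

    The rank-sum p is exact for combined n <= 20, otherwise the normal
    approximation with tie correction.
    """
    a = np.asarray([getattr(v, "value", v) for v in scores_a], dtype=float)
    b = np.asarray([getattr(v, "value", v) for v in scores_b], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each arm needs at least 2 subjects")
    diff = float(np.median(a) - np.median(b))
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for k in range(n_boot):
        boot[k] = np.median(rng.choice(a, len(a))) - np.median(rng.choice(b, len(b)))
    method = "exact" if len(a) + len(b) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=False)
    return MedianDifference(difference=diff, sd=float(boot.std(ddof=1)), p=float(res.pvalue))


@dataclass(frozen=True)
class TrialResult:
    """Between-arm endpoint comparison (first arm label vs second)."""

    variant: str
    arm_labels: Tuple[str, str]
    n_per_arm: Dict[str, int]
    n_imputed_per_arm: Dict[str, int]
    medians: Dict[str, float]
    median_sds: Dict[str, float]
    median_difference: MedianDifference
    km_survival: Dict[str, float]       # S(horizon) per arm
    km_se: Dict[str, float]
    cox_effect: EffectEstimate          # log HR of first arm vs second
    horizon: float


def _bootstrap_median_sd(values: np.ndarray, rng: np.random.Generator, n_boot: int) -> float:
    boots = np.empty(n_boot)
    for k in range(n_boot):
        boots[k] = np.median(rng.choice(values, len(values)))
    return float(boots.std(ddof=1))


def analyze_trial(
    cohort: Cohort,
    variant: str,
    assessment_time: float,
    horizon: float,
    policy: Optional[ImputationPolicy] = None,
    coefficients: Optional[ModelCoefficients] = None,
    seed: int = 0,
    n_boot: int = 2000,
    all_cause: bool = False,
) -> TrialResult:
    """Full survivor-bias-safe endpoint analysis of a two-arm cohort.

    Every randomized subject contributes exactly once: assessed subjects
    through their computed score, pre-assessment failures through the
    imputed worst-case score.  The Cox log-HR is for the first arm label
    (sorted order) relative to the second.
    """
    labels = cohort.arm_labels()
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 arms, got {labels}")
    scores = worst_case_impute(cohort, variant, assessment_time, policy, coefficients)
    arms = cohort.arms
    values = np.array([s.value for s in scores])
    imputed = np.array([s.imputed for s in scores])
    rng = np.random.default_rng(seed)

    per_arm_values = {lab: values[arms == lab] for lab in labels}
    medians = {lab: float(np.median(v)) for lab, v in per_arm_values.items()}
    median_sds = {
        lab: _bootstrap_median_sd(v, rng, n_boot) for lab, v in per_arm_values.items()
    }
    mdiff = median_difference_test(
        per_arm_values[labels[0]], per_arm_values[labels[1]], n_boot=n_boot,
        seed=int(rng.integers(2**31)),
    )
    km_survival, km_se = {}, {}
    for lab in labels:
        curve = km_curve(cohort.select_arm(lab).outcomes, all_cause=all_cause)
        km_survival[lab] = curve.survival_at(horizon)
        km_se[lab] = curve.se_at(horizon)
    # arm coded 1 = first label, so the log-HR is first-vs-second
    effect = cox_two_group_loghr(
        cohort.outcomes, np.asarray(arms == labels[0], dtype=float), all_cause=all_cause
    )
    return TrialResult(
        variant=variant,
        arm_labels=(labels[0], labels[1]),
        n_per_arm={lab: int((arms == lab).sum()) for lab in labels},
        n_imputed_per_arm={lab: int(imputed[arms == lab].sum()) for lab in labels},
        medians=medians,
        median_sds=median_sds,
        median_difference=mdiff,
        km_survival=km_survival,
        km_se=km_se,
        cox_effect=effect,
        horizon=horizon,
    )


@dataclass(frozen=True)
class PowerConfig:
    """Monte-Carlo power study for the rank-sum score endpoint.

    ``treatment_overrides`` shifts the treated arm's generator (e.g.
    ``{"egfr_mean": 65.0}``); ``score_shift`` instead adds a constant to
    treated scores after imputation, useful for calibrating against
    closed-form location-shift power.  Power at each candidate per-arm n
    is the fraction of replicates whose rank-sum p falls below alpha.
    """

    base: SimConfig
    candidate_ns: Tuple[int, ...]
    treatment_overrides: dict = field(default_factory=dict)
    score_shift: float = 0.0
    n_replicates: int = 200
    alpha: float = 0.05
    variant: str = "full"
    policy: ImputationPolicy = field(default_factory=ImputationPolicy)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_replicates < 100:
            logger.warning(
                "n_replicates=%d < 100: power estimates will be very noisy",
                self.n_replicates,
            )
        if not self.candidate_ns or any(n < 2 for n in self.candidate_ns):
            raise ValueError("candidate_ns must be non-empty with n >= 2")


@dataclass(frozen=True)
class PowerCurve:
    ns: Tuple[int, ...]
    power: np.ndarray
    mc_se: np.ndarray
    smoothed: np.ndarray    # isotonic (non-decreasing in n) fit
    alpha: float
    n_replicates: int

    def required_n(self, target_power: float) -> Optional[int]:
        """Smallest candidate n whose smoothed power meets the target."""
        for n, p in zip(self.ns, self.smoothed):
            if p >= target_power:
                return n
        return None


def power_curve(config: PowerConfig) -> PowerCurve:
    """Estimate rank-sum endpoint power over a grid of per-arm sample sizes."""
    coefficients = load_coefficients(
        config.variant if config.base.include_banff else "abbreviated"
    )
    ns = tuple(sorted(config.candidate_ns))
    power = np.empty(len(ns))
    seeds = np.random.SeedSequence(config.seed).spawn(len(ns))
    for j, n in enumerate(ns):
        ctrl = config.base.with_overrides(n=n, arm="control")
        trt = config.base.with_overrides(n=n, arm="treatment", **config.treatment_overrides)
        rep_seeds = seeds[j].spawn(config.n_replicates)
        hits = 0
        for rs in rep_seeds:
            rep_seed = int(rs.generate_state(1)[0] % (2**31))
            sim = simulate_trial(ctrl, trt, rep_seed, coefficients=coefficients)
            scores = worst_case_impute(
                sim.cohort, coefficients.variant, config.base.assessment_time,
                config.policy, coefficients,
            )
            arms = sim.cohort.arms
            vals = np.array([s.value for s in scores])
            a = vals[arms == "control"]
            b = vals[arms == "treatment"] + config.score_shift
            method = "exact" if len(a) + len(b) <= 20 else "asymptotic"
            p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                   use_continuity=False).pvalue
            hits += p < config.alpha
        power[j] = hits / config.n_replicates
    mc_se = np.sqrt(power * (1 - power) / config.n_replicates)
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
    smoothed = iso.fit_transform(np.asarray(ns, dtype=float), power)
    return PowerCurve(
        ns=ns, power=power, mc_se=mc_se, smoothed=smoothed,
        alpha=config.alpha, n_replicates=config.n_replicates,
    )
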