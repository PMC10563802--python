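"""iBOX score computation for kidney-transplant recipients.

The iBOX is a Cox-model linear predictor for death-censored graft loss
built from measurements taken at a single posttransplant assessment:
time from transplant, eGFR, proteinuria (urine protein-to-creatinine
ratio), anti-HLA donor-specific antibody (DSA) status, and — in the
*full* variant only — six Banff biopsy lesion scores.  The score of
subject *i* is ``sum_j beta_j * x_ij`` where the ``beta_j`` are the
natural logs of the qualified hazard ratios and ``x_ij`` are the encoded
covariates.  Higher scores mean a higher hazard of graft loss.

Two variants are packaged: ``"full"`` (with biopsy) and
``"abbreviated"`` (without biopsy).  The coefficient table ships with
the package as a human-readable CSV (``data/coefficients_v1.csv``) so
the weights can be audited without reading code.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np

__all__ = [
    "BanffProfile",
    "Assessment",
    "EncodedCovariates",
    "ModelCoefficients",
    "Score",
    "VARIANTS",
    "UPCR_FLOOR",
    "DSA_MFI_CUTOFF",
    "COEFFICIENT_VERSION",
    "load_coefficients",
    "encode_covariates",
    "compute_score",
]

VARIANTS = ("full", "abbreviated")

#: Proteinuria values below this floor (g/g) are raised to it before the
#: log transform, so very low UPCR cannot drive the score to -inf.
UPCR_FLOOR = 0.05

#: MFI at or above this value counts as DSA-positive (inclusive cutoff).
DSA_MFI_CUTOFF = 1400.0

#: Version tag of the packaged coefficient table, logged in provenance.
COEFFICIENT_VERSION = "v1"

# Design-matrix column order per variant.  Categorical factors expand to
# one indicator column per non-reference level.
_FULL_TERMS = [
    ("time_years", ""),
    ("egfr", ""),
    ("log_upcr", ""),
    ("dsa_mfi", ">=1400"),
    ("ifta", "2"),
    ("ifta", "3"),
    ("gptc", "3-4"),
    ("gptc", "5-6"),
    ("it", ">=3"),
    ("cg", ">=1"),
]
_ABBREVIATED_TERMS = _FULL_TERMS[:4]


@dataclass(frozen=True)
class BanffProfile:
    """Banff lesion scores from one allograft biopsy.

    All six scores are semi-quantitative grades in {0, 1, 2, 3}:
    ``ifta`` (interstitial fibrosis / tubular atrophy), ``g``
    (glomerulitis), ``ptc`` (peritubular capillaritis), ``i``
    (interstitial inflammation), ``t`` (tubulitis) and ``cg``
    (transplant glomerulopathy).
    """

    ifta: int
    g: int
    ptc: int
    i: int
    t: int
    cg: int

    def __post_init__(self) -> None:
        for name in ("ifta", "g", "ptc", "i", "t", "cg"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValueError(f"Banff {name} score must be an integer, got {v!r}")
            if not 0 <= v <= 3:
                raise ValueError(f"Banff {name} score out of range 0-3: {v}")


@dataclass(frozen=True)
class Assessment:
    """One subject's posttransplant assessment.

    ``time_from_transplant`` is in years; ``egfr`` in mL/min/1.73 m^2;
    ``upcr`` in g/g; ``dsa_mfi`` is the anti-HLA DSA mean fluorescence
    intensity.  ``banff`` may be absent, in which case only the
    abbreviated variant can be scored.
    """

    subject_id: str
    time_from_transplant: float
    egfr: float
    upcr: float
    dsa_mfi: float
    banff: Optional[BanffProfile] = None

    def __post_init__(self) -> None:
        for name in ("time_from_transplant", "egfr", "upcr", "dsa_mfi"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.time_from_transplant <= 0:
            raise ValueError("time_from_transplant must be > 0 years")
        for name in ("egfr", "upcr", "dsa_mfi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class EncodedCovariates:
    """Design-matrix row for one assessment, in coefficient order."""

    variant: str
    names: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        expected = _FULL_TERMS if self.variant == "full" else _ABBREVIATED_TERMS
        if len(self.values) != len(expected):
            raise ValueError(
                f"{self.variant} encoding must have {len(expected)} entries, "
                f"got {len(self.values)}"
            )


@dataclass(frozen=True)
class ModelCoefficients:
    """Ordered log-hazard-ratio weights for one iBOX variant.

    ``terms`` holds ``(factor, level, log_hr)`` for each design column
    (non-reference levels only; reference levels carry weight 0 and are
    not columns).  ``log_hazard_ratios`` is the weight vector aligned
    with :class:`EncodedCovariates`.
    """

    variant: str
    terms: tuple
    version: str = COEFFICIENT_VERSION

    @property
    def log_hazard_ratios(self) -> np.ndarray:
        return np.array([b for _, _, b in self.terms], dtype=float)

    def hazard_ratio(self, factor: str, level: str = "") -> float:
        """Exponentiated weight for one factor level (1.0 for reference)."""
        for f, lvl, b in self.terms:
            if f == factor and lvl == level:
                return math.exp(b)
        # reference levels are not design columns but have HR 1
        if factor in {f for f, _, _ in self.terms}:
            return 1.0
        raise KeyError(f"unknown factor {factor!r} for variant {self.variant!r}")


@dataclass(frozen=True)
class Score:
    """An iBOX score in log-hazard units (unbounded real, higher = worse)."""

    subject_id: str
    variant: str
    value: float
    imputed: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"score must be finite, got {self.value!r}")


def _read_coefficient_table() -> list:
    path = resources.files("iboxkit.data") / f"coefficients_{COEFFICIENT_VERSION}.csv"
    with path.open("r", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def load_coefficients(variant: str) -> ModelCoefficients:
    """Load the packaged coefficients for ``"full"`` or ``"abbreviated"``.

    Weights are the natural logs of the qualified hazard ratios.  The
    shipped CSV also carries a log-HR column for auditing; it is checked
    against ``ln(HR)`` at load time.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown iBOX variant {variant!r}; expected one of {VARIANTS}")
    rows = {
        (r["factor"], r["level"]): r
        for r in _read_coefficient_table()
        if r["variant"] == variant
    }
    order = _FULL_TERMS if variant == "full" else _ABBREVIATED_TERMS
    terms = []
    for factor, level in order:
        row = rows[(factor, level)]
        hr = float(row["hazard_ratio"])
        log_hr = math.log(hr)
        if abs(log_hr - float(row["log_hazard_ratio"])) > 1e-8:
            raise RuntimeError(
                f"coefficient table inconsistent for {factor}/{level}: "
                f"log-HR column does not match ln(HR)"
            )
        terms.append((factor, level, log_hr))
    return ModelCoefficients(variant=variant, terms=tuple(terms))


def encode_covariates(assessment: Assessment, variant: str) -> EncodedCovariates:
    """Encode raw measurements into the model's design-matrix row.

    Rules: UPCR is floored at 0.05 g/g then natural-log transformed; DSA
    is the indicator MFI >= 1,400 (boundary inclusive); Banff factors
    are categorized from summed lesion scores (g+ptc in 0-2/3-4/5-6,
    i+t in 0-2/>=3, cg in 0/>=1) with one indicator per non-reference
    level and at most one indicator set per factor.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown iBOX variant {variant!r}; expected one of {VARIANTS}")
    if assessment.egfr > 120:
        # fixed message so repeated warnings deduplicate per process
        warnings.warn(
            "eGFR exceeds 120 mL/min/1.73 m^2; entered as-is (no cap)",
            stacklevel=2,
        )
    base = [
        assessment.time_from_transplant,
        assessment.egfr,
        math.log(max(assessment.upcr, UPCR_FLOOR)),
        1.0 if assessment.dsa_mfi >= DSA_MFI_CUTOFF else 0.0,
    ]
    if variant == "abbreviated":
        return EncodedCovariates(
            variant=variant,
            names=tuple(_ABBREVIATED_TERMS),
            values=np.array(base, dtype=float),
        )
    if assessment.banff is None:
        raise ValueError(
            f"biopsy required: subject {assessment.subject_id!r} has no Banff "
            "profile, so the full iBOX cannot be scored (use 'abbreviated')"
        )
    b = assessment.banff
    gptc = b.g + b.ptc
    it = b.i + b.t
    banff_cols = [
        1.0 if b.ifta == 2 else 0.0,
        1.0 if b.ifta == 3 else 0.0,
        1.0 if 3 <= gptc <= 4 else 0.0,
        1.0 if gptc >= 5 else 0.0,
        1.0 if it >= 3 else 0.0,
        1.0 if b.cg >= 1 else 0.0,
    ]
    return EncodedCovariates(
        variant=variant,
        names=tuple(_FULL_TERMS),
        values=np.array(base + banff_cols, dtype=float),
    )


def compute_score(
    encoded: EncodedCovariates, coefficients: ModelCoefficients, subject_id: str = ""
) -> Score:
    """Dot product of the encoded covariates with the log-HR weights."""
    if encoded.variant != coefficients.variant:
        raise ValueError(
            f"variant mismatch: covariates are {encoded.variant!r} but "
            f"coefficients are {coefficients.variant!r}"
        )
    value = float(np.dot(encoded.values, coefficients.log_hazard_ratios))
    return Score(subject_id=subject_id, variant=encoded.variant, value=value, imputed=False)


def score_assessment(
    assessment: Assessment, variant: str, coefficients: Optional[ModelCoefficients] = None
) -> Score:
    """Convenience: encode + compute in one call."""
    if coefficients is None:
        coefficients = load_coefficients(variant)
    encoded = encode_covariates(assessment, variant)
    score = compute_score(encoded, coefficients, subject_id=assessment.subject_id)
    return score
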