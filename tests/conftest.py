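import warnings

import pytest

from iboxkit import (
    Assessment,
    BanffProfile,
    SimConfig,
    load_coefficients,
)


@pytest.fixture(scope="session")
def full_coefficients():
    return load_coefficients("full")


@pytest.fixture(scope="session")
def abbreviated_coefficients():
    return load_coefficients("abbreviated")


@pytest.fixture
def worked_assessment():
    """1 y posttransplant, eGFR 50, UPCR 0.3 g/g, DSA-positive, IFTA 2."""
    return Assessment(
        subject_id="worked",
        time_from_transplant=1.0,
        egfr=50.0,
        upcr=0.3,
        dsa_mfi=2000.0,
        banff=BanffProfile(ifta=2, g=0, ptc=0, i=0, t=0, cg=0),
    )


@pytest.fixture
def reference_banff():
    return BanffProfile(ifta=0, g=0, ptc=0, i=0, t=0, cg=0)


@pytest.fixture
def small_sim_config():
    return SimConfig(n=200)


@pytest.fixture(autouse=True)
def _silence_high_egfr_warning():
    """Simulated eGFRs occasionally exceed 120; the warning is by design."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="eGFR .* exceeds 120")
        yield


def homogeneous_config(**overrides) -> SimConfig:
    """Near-degenerate covariate spread: every subject gets ~the same score,
    so the marginal two-group hazard ratio equals the conditional one."""
    base = dict(
        egfr_sd=0.01,
        upcr_log_sd=0.01,
        dsa_prevalence=0.0,
        ifta_probs=(1.0, 0.0, 0.0),
        gptc_probs=(1.0, 0.0, 0.0),
        it_ge3_prob=0.0,
        cg_ge1_prob=0.0,
    )
    base.update(overrides)
    return SimConfig(**base)
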