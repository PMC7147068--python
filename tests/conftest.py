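import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mmclust import LCAParameters, OutcomeCoefficients, SimulationTruth, StratumSpec

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def two_class_params() -> LCAParameters:
    """Well-separated two-class model: rho 0.9 vs 0.1 on all of J=10."""
    return LCAParameters(
        pi=np.array([0.5, 0.5]),
        rho=np.vstack([np.full(10, 0.9), np.full(10, 0.1)]),
    )


@pytest.fixture
def three_class_params() -> LCAParameters:
    """Three classes, J=20, block-structured rho separated by 0.65."""
    rho = np.full((3, 20), 0.15)
    rho[0, :7] = 0.8
    rho[1, 7:14] = 0.8
    rho[2, 14:] = 0.8
    return LCAParameters(pi=np.array([0.4, 0.35, 0.25]), rho=rho)


def _stratum_outcomes(K: int) -> tuple[dict, dict]:
    coeffs = {
        "gp_consults": OutcomeCoefficients(np.log(8.0), tuple(0.2 * k for k in range(K))),
        "hospitalisations": OutcomeCoefficients(np.log(0.5), tuple(0.3 * k for k in range(K))),
        "regular_meds": OutcomeCoefficients(np.log(2.0), tuple(0.25 * k for k in range(K))),
        "died_2yr": OutcomeCoefficients(-3.5, tuple(0.5 * k for k in range(K))),
        "died_5yr": OutcomeCoefficients(-2.5, tuple(0.5 * k for k in range(K))),
    }
    return coeffs, {"gp_consults": 0.4, "hospitalisations": 0.8, "regular_meds": 0.5}


def separated_truth(n_per_stratum=(2000, 3000, 3500, 1500), seed: int = 0) -> SimulationTruth:
    """A 4-stratum design with well-separated classes (K = 2, 3, 3, 2) used
    for integration tests that must recover the generating K; block profiles
    guarantee nearly every patient is multimorbid."""
    labels = ["18-44", "45-64", "65-84", "85+"]
    ranges = [(18, 44), (45, 64), (65, 84), (85, 99)]
    Ks = [2, 3, 3, 2]
    strata = []
    J = 38
    for lab, rg, K, n in zip(labels, ranges, Ks, n_per_stratum):
        rho = np.full((K, J), 0.06)
        block = J // K
        for k in range(K):
            rho[k, k * block : k * block + 5] = 0.85
        pi = np.linspace(1.5, 1.0, K)
        pi /= pi.sum()
        coeffs, disp = _stratum_outcomes(K)
        strata.append(
            StratumSpec(
                label=lab, n_patients=n, age_range=rg,
                params=LCAParameters(pi=pi, rho=rho),
                female_prop=0.55,
                smoking_missing_rate=0.005, bmi_missing_rate=0.02,
                outcomes=coeffs, dispersion=disp,
            )
        )
    return SimulationTruth(strata=strata, seed=seed)
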