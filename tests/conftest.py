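import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import triolinear as tl

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

TRUE_P = (0.49, 0.42, 0.09)
FALSE_P1 = (0.81, 0.18, 0.01)
FALSE_P2 = (0.25, 0.50, 0.25)


@pytest.fixture(scope="session")
def true_p():
    return TRUE_P


@pytest.fixture(scope="session")
def pop():
    return tl.PopulationParams.hwe(0.3, 0.3)


@pytest.fixture(scope="session")
def dominant_full_spec():
    return tl.ModelSpec.full("eq1", tl.GeneticCoding.DOMINANT, p=TRUE_P)


@pytest.fixture(scope="session")
def codominant_full_spec():
    return tl.ModelSpec.full("eq1", tl.GeneticCoding.CODOMINANT, p=TRUE_P)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def coef_vector(design, risk, pop, scale=1.0):
    """Map a RiskModel + PopulationParams to the design's coefficient vector.

    Valid for codominant eq1/eq2 designs; strata coefficients are the log
    mating-type factors (plus the count scale), lambda columns absorb the
    genotype-frequency ratios under eq2.
    """
    mu = pop.mating_mu()
    spec = design.spec
    values = {}
    for m in range(1, 7):
        values[f"mu_{m}"] = np.log(mu[m - 1] * scale)
    if spec.variant == "eq2":
        values["mu_1"] = np.log(mu[0] * scale * pop.p[0])
        for m in range(2, 7):
            values[f"mu_{m}"] = np.log(mu[m - 1] * scale * pop.p[0])
        values["lambda_1"] = np.log(pop.p[1] / pop.p[0])
        values["lambda_2"] = np.log(pop.p[2] / pop.p[0])
    values["ln_S_1"], values["ln_S_2"] = np.log(risk.s)
    values["ln_R_1"], values["ln_R_2"] = np.log(risk.r)
    values["delta_1"], values["delta_2"] = np.log(risk.tau)
    for i in (1, 2):
        for k in (1, 2):
            values[f"ln_theta_{i}{k}"] = np.log(risk.theta[i - 1][k - 1])
            values[f"ln_phi_{i}{k}"] = np.log(risk.phi[i - 1][k - 1])
    return np.array([values[lab] for lab in design.labels])
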