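import numpy as np
import pytest

from thinpbr import (
    FitSpec,
    KineticParams,
    OperatingPoint,
    paper_design,
    reference_parameter_sets,
    simulate_observations,
)


@pytest.fixture(scope="session")
def ref_params() -> dict[float, KineticParams]:
    """Bundled fitted parameter sets, keyed by thickness in mm."""
    return reference_parameter_sets()


@pytest.fixture(scope="session")
def p35(ref_params) -> KineticParams:
    return ref_params[35.0]


@pytest.fixture(scope="session")
def p2(ref_params) -> KineticParams:
    return ref_params[2.0]


@pytest.fixture(scope="session")
def noise_free_table(ref_params):
    """Noise-free synthetic observations on the default design: identical to
    the model's stable-root predictions."""
    return simulate_observations(paper_design(noise_cv=0.0, seed=0), ref_params)


def simpson_mean_rate(X, W, I0, p: KineticParams, n: int = 100001) -> float:
    """Independent brute-force oracle for the depth-averaged gross specific
    rate: fixed-grid Simpson integration of the Haldane response composed
    with Lambert-Beer attenuation."""
    from scipy.integrate import simpson

    z = np.linspace(0.0, W, n)
    I = I0 * np.exp(-p.k_a * X * z)
    mu = p.mu_max * I / (I + p.K_I * (I / p.I_opt - 1.0) ** 2)
    return float(simpson(mu, x=z) / W)
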