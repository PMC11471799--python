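import numpy as np
import pytest

from rheostat import CoreParameters, ExtendedParameters, TruthScenario


def draw_core_params(rng, reversible=True):
    """Random positive core parameters, log-uniform over [0.1, 10]."""
    k = 10.0 ** rng.uniform(-1, 1, 7)
    if not reversible:
        k[[1, 3, 5]] = 0.0  # k1r, k2r, k3r
    return CoreParameters(*k)


def draw_extended_params(rng):
    k = 10.0 ** rng.uniform(-1, 1, 7)
    return ExtendedParameters(
        *k, alpha_hai1a=rng.uniform(0.5, 0.99), alpha_cer=rng.uniform(-1.0, 0.0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def reversible_params():
    """A representative fully reversible core parameter set."""
    return CoreParameters(k0=1.0, k1r=0.2, k2f=0.9, k2r=0.3, k3=1.1, k3r=0.15, k4=1.0)


@pytest.fixture
def shared_s1p_truth():
    """Feedback truth whose two conditions share the latent S1P initial,
    so the default (shared) calibration problem can reproduce it exactly."""
    return TruthScenario(
        variant="feedback",
        params=ExtendedParameters(
            k00=0.9, k01=0.5, k2f=0.45, k2r=0.3, k3=1.1, k3r=0.15, k4=1.0,
            alpha_hai1a=0.6, alpha_cer=-1.0,
        ),
        x0={
            "wild_type": np.array([0.70, 1.10, 0.50, 0.40]),
            "mutant": np.array([0.60, 0.75, 0.50, 0.40]),
        },
    )


def truth_theta(truth):
    """Full native parameter mapping that reproduces ``truth`` under the
    default (shared-latent) problem layout."""
    p = truth.params
    theta = {k: getattr(p, k) for k in
             ("k00", "k01", "k2f", "k2r", "k3", "k3r", "k4")}
    theta["alpha_hai1a"] = p.alpha_hai1a
    theta["alpha_cer"] = p.alpha_cer
    for sp, s in truth.scalings.items():
        theta[f"s_{sp}"] = s
    for sp, s in truth.sigmas.items():
        theta[f"sigma_{sp}"] = s
    theta["x0_s1p"] = float(truth.x0["wild_type"][3])
    return theta
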