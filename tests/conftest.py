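import numpy as np
import pytest

from hisicc import (InputCondition, NoiseSpec, generate_flasks, ta1415_model,
                    ta2445_model)

NO_NOISE = NoiseSpec(0.0, 0.0, 0.0, 0.0)


@pytest.fixture(scope="session")
def ta1415():
    return ta1415_model()


@pytest.fixture(scope="session")
def ta2445():
    return ta2445_model()


@pytest.fixture(scope="session")
def noiseless_flasks_1415(ta1415):
    """One flask per design condition, exact model observations."""
    return generate_flasks(ta1415, n_replicates=1, noise=NO_NOISE, seed=0)


def random_valid_model(rng: np.random.Generator, strain: str = "TA1415"):
    """A random structurally valid model: rates scattered around the
    published values, ratios uniform in (0, 1), X_A0 under its cap."""
    base = ta1415_model() if strain == "TA1415" else ta2445_model()
    factor = lambda: float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
    shared = base.shared.replace(
        k1=base.shared.k1 * factor(),
        k2=base.shared.k2 * factor(),
        k3=base.shared.k3 * factor(),
        r_leak=float(rng.uniform(0.0, 1.0)),
        a_E=float(rng.uniform(0.0, 0.5)),
        K_E=base.shared.K_E * factor(),
        X_A0=float(rng.uniform(0.2, 9.9)) * base.X_G0,
        N_m=base.shared.N_m * factor(),
    )
    model = base.replace(shared=shared)
    if strain == "TA2445":
        model = model.replace(quorum=base.quorum.replace(
            k_A=base.quorum.k_A * factor(), d_A=base.quorum.d_A * factor()))
    return model


def random_condition(rng: np.random.Generator, model):
    if model.strain == "TA1415":
        return InputCondition("TA1415", t_add=float(rng.uniform(0.0, 15.0)))
    return InputCondition("TA2445",
                          u_conc=float(10 ** rng.uniform(-2.0, 0.0)))
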