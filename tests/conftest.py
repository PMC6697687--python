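import numpy as np
import pytest

from perturbprop import DynamicalModel, GeneratorConfig, generate_ensemble, generate_model


@pytest.fixture
def chain_model():
    """Two-species linear chain: x1 degrades, x1 drives x2."""
    jac = np.array([[-1.0, 0.0], [1.0, -1.0]])
    x_star = np.array([1.0, 1.0])
    return DynamicalModel(
        species=["x1", "x2"],
        steady_state=x_star,
        jacobian=jac,
        rhs=lambda x: jac @ (x - x_star),
        model_id="chain2",
    )


@pytest.fixture
def decoupled_model():
    jac = -np.eye(4)
    x_star = np.ones(4)
    return DynamicalModel(
        species=[f"x{i}" for i in range(4)],
        steady_state=x_star,
        jacobian=jac,
        rhs=lambda x: jac @ (x - x_star),
        model_id="decoupled4",
    )


@pytest.fixture
def random_model():
    return generate_model(GeneratorConfig(n_species=8, edge_density=0.3, seed=3))


@pytest.fixture(scope="session")
def small_ensemble():
    return generate_ensemble(12, seed=5, n_min=5, n_max=20)
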