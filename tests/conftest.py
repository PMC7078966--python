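import numpy as np
import pytest

from civrank import CorrelationSpec, JointEffects, OutcomeEffects, load_example_network


@pytest.fixture
def three_treatment_effects() -> OutcomeEffects:
    """Small oriented network with a star-geometry covariance plus overlap."""
    sigma = np.array(
        [
            [0.0, 0.0, 0.0],
            [0.0, 0.04, 0.01],
            [0.0, 0.01, 0.09],
        ]
    )
    return OutcomeEffects(
        outcome_name="efficacy",
        treatments=("A", "B", "C"),
        reference="A",
        mu=np.array([0.0, 0.3, -0.2]),
        sigma=sigma,
        oriented=True,
    )


@pytest.fixture
def two_treatment_effects() -> OutcomeEffects:
    return OutcomeEffects(
        outcome_name="efficacy",
        treatments=("A", "B"),
        reference="A",
        mu=np.array([0.0, 0.3]),
        sigma=np.array([[0.0, 0.0], [0.0, 0.01]]),
        oriented=True,
    )


@pytest.fixture(scope="session")
def example_network() -> JointEffects:
    return load_example_network()


@pytest.fixture
def two_outcome_joint(three_treatment_effects) -> JointEffects:
    """Two correlated outcomes over the same three treatments."""
    second = OutcomeEffects(
        outcome_name="safety",
        treatments=("A", "B", "C"),
        reference="A",
        mu=np.array([0.0, -0.4, 0.25]),
        sigma=np.array(
            [
                [0.0, 0.0, 0.0],
                [0.0, 0.0625, 0.015],
                [0.0, 0.015, 0.04],
            ]
        ),
        oriented=True,
    )
    rho = CorrelationSpec(("efficacy", "safety"),
                          np.array([[1.0, -0.5], [-0.5, 1.0]]))
    return JointEffects(outcomes=(three_treatment_effects, second),
                        correlation=rho)
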