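import numpy as np
import pytest

from hsatdyn import ModelParameters, get_preset


@pytest.fixture(scope="session")
def reference() -> ModelParameters:
    return get_preset("reference")


@pytest.fixture(scope="session")
def bistable() -> ModelParameters:
    return get_preset("bistable")


def random_parameters(rng: np.random.Generator, base: ModelParameters,
                      spread: float = 1.0) -> ModelParameters:
    """A random well-conditioned parameter set: log-uniform factors around base."""
    d = base.to_dict()
    factors = np.exp(rng.uniform(-spread, spread, size=len(d)))
    return ModelParameters(**{k: v * f for (k, v), f in zip(d.items(), factors)})
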