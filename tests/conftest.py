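import numpy as np
import pytest

from fvgame import SimConfig, compute_series, generate_meal_records


def ar1_series(seed: int, phi: float, n: int, sd: float = 1.0) -> np.ndarray:
    """Stationary AR(1) Gaussian series used as a null process in tests."""
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.standard_normal() * sd
    innov = sd * np.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + rng.standard_normal() * innov
    return x


@pytest.fixture(scope="session")
def default_study():
    """One synthetic study at the default design (10+13 days, 180 students)."""
    records, truth = generate_meal_records(SimConfig(rng_seed=42))
    return records, truth


@pytest.fixture(scope="session")
def default_points(default_study):
    records, _ = default_study
    return compute_series(records)
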