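import numpy as np
import pytest

from icefalcon.simulate import ScenarioSpec, calibrate, simulate_pairs


@pytest.fixture(scope="session")
def example_like_spec():
    """Diagram-b spec calibrated to the worked example's correlational
    structure (rho_x=0.79, rho_y=0.37, r_xy=0.30)."""
    return calibrate(0.79, 0.37, 0.30, "b", n_pairs=500, seed=20240)


@pytest.fixture(scope="session")
def diagram_b_data(example_like_spec):
    """A sample large enough (2000 pairs) that the qualitative pattern of
    the generating diagram is identifiable above sampling noise."""
    return simulate_pairs(example_like_spec.with_(n_pairs=2000))


@pytest.fixture(scope="session")
def confounding_spec():
    """Diagram-a spec with symmetric loadings."""
    return calibrate(0.6, 0.6, 0.30, "a", n_pairs=500, seed=77)


@pytest.fixture(scope="session")
def random_valid_specs():
    """A handful of seeded, feasible specs per diagram for property checks."""
    from icefalcon.simulate import InfeasibleTargetsError, SpecValidationError

    rng = np.random.default_rng(12345)
    specs = []
    for diagram in "abcd":
        found = 0
        while found < 5:
            rho_x, rho_y = rng.uniform(0.2, 0.85, 2)
            r_xy = rng.uniform(0.05, 0.5)
            w = rng.uniform(0.1, 0.9) if diagram == "d" else 0.0
            try:
                spec = calibrate(rho_x, rho_y, r_xy, diagram,
                                 mixture_weight_confounding=w,
                                 seed=int(rng.integers(0, 2**31 - 1)))
            except (InfeasibleTargetsError, SpecValidationError):
                continue
            specs.append(spec)
            found += 1
    return specs
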