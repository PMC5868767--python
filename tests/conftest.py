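import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same draws no matter which
    # subset of the suite runs
    return np.random.default_rng(20240317)


@pytest.fixture(scope="session")
def tiny_family():
    """Four ~700-residue members of one synthetic 10-TMS family."""
    from superfam.synthetic import FamilySpec, generate_family, rate_for_identity

    spec = FamilySpec(
        label="9.S.4.1", n_members=4,
        substitution_rate=rate_for_identity(0.90),
    )
    return generate_family(spec, seed=42)


@pytest.fixture(scope="session")
def membrane_protein():
    from superfam.synthetic import FamilySpec, generate_membrane_protein

    return generate_membrane_protein(FamilySpec(), seed=7, record_id="M1")
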