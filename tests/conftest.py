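import pytest

from stenoflow import (
    SimilarityParams,
    SolverOptions,
    get_material,
    hybrid_mixture,
    solve_profile,
)


@pytest.fixture(scope="session")
def blood():
    return get_material("blood")


@pytest.fixture(scope="session")
def al2o3():
    return get_material("Al2O3")


@pytest.fixture(scope="session")
def cu():
    return get_material("Cu")


@pytest.fixture(scope="session")
def mix_5_5():
    """Hybrid mixture at phi1 = phi2 = 0.05 (the reproduction default)."""
    return hybrid_mixture(0.05, 0.05)


@pytest.fixture(scope="session")
def crane_profile():
    """Flat-limit stretching solve whose closed form is F = 1 - e^-eta."""
    params = SimilarityParams(
        gamma=0.0, pr=3.0, phi1=0.0, phi2=0.0, eta_edge=15.0, closure="quiescent-edge"
    )
    return solve_profile(params, SolverOptions(tol=1e-8))


@pytest.fixture(scope="session")
def default_profile():
    """Solve at the package defaults (stretching-wall closure)."""
    return solve_profile(SimilarityParams())
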