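import numpy as np
import pytest

from scramblekit import AssayDesign, ScramblingParams


@pytest.fixture
def canonical_params() -> ScramblingParams:
    """A well-identified mid-range parameter set used across tests."""
    return ScramblingParams(alpha=0.05, beta=0.03, gamma=0.02, f0=0.3, li_pf=0.5)


@pytest.fixture
def noiseless_design() -> AssayDesign:
    return AssayDesign(noise_sd=0.0)


@pytest.fixture
def param_grid() -> list[ScramblingParams]:
    """Randomized but reproducible parameter grid over the valid domain."""
    rng = np.random.default_rng(20240917)
    grid = []
    for _ in range(120):
        a, b, g = 10 ** rng.uniform(-4, 0, size=3)
        grid.append(
            ScramblingParams(
                alpha=a,
                beta=b,
                gamma=g,
                f0=rng.uniform(0.0, 0.95),
                li_pf=rng.uniform(0.0, 1.0),
            )
        )
    return grid
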