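import numpy as np
import pytest

from descosmo import (
    InteractionParams,
    SigmaGrid,
    SigmaProfile,
    Species,
    default_params,
    make_gaussian_profile,
)


@pytest.fixture(scope="session")
def grid() -> SigmaGrid:
    return SigmaGrid()


@pytest.fixture(scope="session")
def params() -> InteractionParams:
    return default_params()


@pytest.fixture(scope="session")
def conductor_params(params) -> InteractionParams:
    """Conductor limit: all interaction energies switched off."""
    return params.with_(c_misfit=0.0, c_hb=0.0)


@pytest.fixture
def water_like_profile(grid) -> SigmaProfile:
    """Symmetric donor+acceptor profile reminiscent of a small HB liquid."""
    return make_gaussian_profile(
        grid,
        [(0.0, 0.004, 60.0), (-0.015, 0.0025, 25.0), (0.015, 0.0025, 25.0)],
    )


def random_profile(rng: np.random.Generator, grid: SigmaGrid) -> SigmaProfile:
    """Random physically structured profile: 2–4 Gaussian peaks whose
    centres stay in the chemically populated |σ| ≲ 0.018 band (real
    molecular surfaces carry negligible area at the grid extremes)."""
    n_peaks = int(rng.integers(2, 5))
    peaks = [
        (
            float(rng.uniform(-0.018, 0.018)),
            float(rng.uniform(0.002, 0.005)),
            float(rng.uniform(10.0, 120.0)),
        )
        for _ in range(n_peaks)
    ]
    return make_gaussian_profile(grid, peaks)


def random_species(
    rng: np.random.Generator, grid: SigmaGrid, name: str = "X", **kwargs
) -> Species:
    return Species(
        name=name,
        molar_mass=float(rng.uniform(50, 500)),
        profile=random_profile(rng, grid),
        **kwargs,
    )
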