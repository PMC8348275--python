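import numpy as np
import pytest

from jetraman import (
    PlaczekInvariants,
    PolarizabilityTensor,
    RotorConstants,
    VibBand,
    invariants,
)
from jetraman.fixtures import synthetic_molecule


@pytest.fixture(scope="session")
def toy_rotor() -> RotorConstants:
    """Asymmetric toy rotor (A=1.0, B=0.6, C=0.4 cm⁻¹, B̄=0.5)."""
    return RotorConstants(1.0, 0.6, 0.4)


@pytest.fixture(scope="session")
def mixed_tensor() -> PolarizabilityTensor:
    """A generic tensor with isotropic part and all three ΔK channels active."""
    return PolarizabilityTensor(xx=0.3, yy=-0.2, zz=0.5, xy=0.1, xz=0.4, yz=-0.3)


@pytest.fixture(scope="session")
def mixed_band(mixed_tensor) -> VibBand:
    return VibBand(label="toy", nu_calc=500.0, invariants=invariants(mixed_tensor))


@pytest.fixture(scope="session")
def gamma_only_band() -> VibBand:
    """Band with a′ = 0 (fully depolarised), anisotropy split over all channels."""
    t = PolarizabilityTensor(xx=1.0, yy=-1.0, zz=0.0, xy=0.3, xz=0.5, yz=0.2)
    return VibBand(label="gamma", nu_calc=400.0, invariants=invariants(t))


@pytest.fixture(scope="session")
def polarized_band() -> VibBand:
    """Isotropic-only band (γ′² = 0): single sharp Q₀ peak."""
    return VibBand(
        label="polar", nu_calc=600.0, invariants=PlaczekInvariants.from_values(1.0, 0.0)
    )


@pytest.fixture(scope="session")
def two_conformers():
    """Two synthetic near-prolate conformers with disjoint band regions."""
    c1 = synthetic_molecule(11, -0.9, n_bands=3, polarisation_mix=1.0,
                            name="alpha", nu_range=(300.0, 700.0))
    c2 = synthetic_molecule(12, -0.85, n_bands=3, polarisation_mix=1.0,
                            name="beta", nu_range=(800.0, 1200.0))
    return c1, c2
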