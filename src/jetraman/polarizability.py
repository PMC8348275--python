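"""Placzek invariants and the ΔK-channel partition of the Raman anisotropy.

For a vibration k, the transition-polarisability tensor α (symmetric, rank 2)
determines the Raman scattering activity through two rotational invariants:
the isotropic part a′ = tr(α)/3 and the anisotropy

    γ′² = ½[(αxx−αyy)² + (αyy−αzz)² + (αzz−αxx)²] + 3(αxy² + αxz² + αyz²).

For a symmetric top the anisotropic scattering separates exactly into
ΔK = 0, ±1, ±2 channels according to the rank-2 spherical components of α
expressed in the principal frame with z along the unique rotor axis:

    γ₀² = (3/2)|α₂₀|²,  γ₁² = (3/2)(|α₂₊₁|² + |α₂₋₁|²),
    γ₂² = (3/2)(|α₂₊₂|² + |α₂₋₂|²),   γ₀² + γ₁² + γ₂² = γ′².

For a C1 molecule all three channels are generally non-zero; partitioning
γ′² this way preserves the total band intensity in the contour sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PolarizabilityTensor",
    "PlaczekInvariants",
    "invariants",
    "channel_partition",
    "rotate_tensor",
]


@dataclass(frozen=True)
class PolarizabilityTensor:
    """Symmetric transition-polarisability tensor (principal frame, z = unique axis)."""

    xx: float
    yy: float
    zz: float
    xy: float = 0.0
    xz: float = 0.0
    yz: float = 0.0

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.xx, self.xy, self.xz],
                [self.xy, self.yy, self.yz],
                [self.xz, self.yz, self.zz],
            ]
        )

    @classmethod
    def from_matrix(cls, M) -> "PolarizabilityTensor":
        M = np.asarray(M, dtype=float)
        if M.shape != (3, 3):
            raise ValueError("expected a 3x3 matrix")
        if not np.allclose(M, M.T, atol=1e-8 * max(1.0, float(np.abs(M).max()))):
            raise ValueError("tensor must be symmetric")
        S = 0.5 * (M + M.T)
        return cls(S[0, 0], S[1, 1], S[2, 2], S[0, 1], S[0, 2], S[1, 2])


@dataclass(frozen=True)
class PlaczekInvariants:
    """Raman invariants of one band: a′, γ′² and its ΔK-channel split."""

    a_prime: float
    gamma2: float
    gamma2_dk0: float
    gamma2_dk1: float
    gamma2_dk2: float

    @property
    def depol_ratio(self) -> float:
        """Depolarisation ratio ρ = 3γ′²/(45a′² + 4γ′²) ∈ [0, 0.75]."""
        den = 45.0 * self.a_prime**2 + 4.0 * self.gamma2
        if den == 0.0:
            return 0.0
        return 3.0 * self.gamma2 / den

    @classmethod
    def from_values(
        cls, a_prime: float, gamma2: float, channels=None
    ) -> "PlaczekInvariants":
        """Build from precomputed numbers; without channels, all anisotropy → ΔK=0."""
        if gamma2 < 0:
            raise ValueError("gamma2 must be >= 0")
        if channels is None:
            channels = (gamma2, 0.0, 0.0)
        c0, c1, c2 = (float(c) for c in channels)
        tot = c0 + c1 + c2
        if tot > 0 and abs(tot - gamma2) > 1e-6 * max(gamma2, 1.0):
            raise ValueError(f"channel weights sum to {tot}, expected gamma2={gamma2}")
        return cls(float(a_prime), float(gamma2), c0, c1, c2)


def invariants(t: PolarizabilityTensor) -> PlaczekInvariants:
    """Placzek invariants a′ and γ′² of a tensor, with the ΔK-channel split."""
    M = t.as_matrix()
    if not np.all(np.isfinite(M)):
        raise ValueError("tensor components must be finite")
    a = (t.xx + t.yy + t.zz) / 3.0
    g2 = 0.5 * ((t.xx - t.yy) ** 2 + (t.yy - t.zz) ** 2 + (t.zz - t.xx) ** 2) + 3.0 * (
        t.xy**2 + t.xz**2 + t.yz**2
    )
    c0, c1, c2 = channel_partition(t)
    # guard against rounding: rescale channels to the exact invariant
    tot = c0 + c1 + c2
    if tot > 0.0:
        s = g2 / tot
        c0, c1, c2 = c0 * s, c1 * s, c2 * s
    return PlaczekInvariants(a, g2, c0, c1, c2)


def channel_partition(t: PolarizabilityTensor) -> tuple[float, float, float]:
    """Split γ′² into ΔK = 0, ±1, ±2 channel weights (spherical-tensor partition).

    Requires the tensor in the principal frame with z = unique rotor axis.
    """
    a20 = (2.0 * t.zz - t.xx - t.yy) / np.sqrt(6.0)
    # α₂±₁ = ∓(αxz ± i αyz): |α₂₊₁|² = |α₂₋₁|² = αxz² + αyz²
    abs_21 = t.xz**2 + t.yz**2
    # α₂±₂ = ½(αxx − αyy ± 2i αxy): |α₂₊₂|² = |α₂₋₂|² = ¼(αxx−αyy)² + αxy²
    abs_22 = 0.25 * (t.xx - t.yy) ** 2 + t.xy**2
    c0 = 1.5 * a20**2
    c1 = 1.5 * 2.0 * abs_21
    c2 = 1.5 * 2.0 * abs_22
    return float(c0), float(c1), float(c2)


def rotate_tensor(t: PolarizabilityTensor, R) -> PolarizabilityTensor:
    """Return R·α·Rᵀ for an orthogonal rotation matrix R (tolerance 1e-8)."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
        raise ValueError("R must be a 3x3 orthogonal matrix")
    return PolarizabilityTensor.from_matrix(R @ t.as_matrix() @ R.T)
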