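"""Rigid-rotor machinery for near-symmetric tops.

A near-prolate (κ → −1) or near-oblate (κ → +1) asymmetric top is reduced to
an effective symmetric top: the two constants perpendicular to the unique
axis are averaged into B̄ and the familiar symmetric-top energy expression

    E(J, K) = B̄·J(J+1) + (X − B̄)·K²

is used for both vibrational states (X = A for prolate, C for oblate).
Thermal rotational populations are plain Boltzmann weights with the
(2J+1)(2 − δ_K0) degeneracy; nuclear-spin statistical weights are taken as
unity (appropriate for C1/Cs molecules).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import HC_OVER_KB, INERTIA_TO_CM, MHZ_PER_CM

__all__ = [
    "RotorConstants",
    "RotationalState",
    "ray_kappa",
    "constants_from_geometry",
    "rot_energy",
    "rot_populations",
    "LinearRotorError",
]


class LinearRotorError(ValueError):
    """Raised when a geometry has a vanishing moment of inertia (linear rotor)."""


def ray_kappa(A: float, B: float, C: float) -> float:
    """Ray's asymmetry parameter κ = (2B − A − C)/(A − C).

    κ = −1 for a prolate symmetric top (B = C), +1 for an oblate one (A = B).

    Parameters must satisfy A ≥ B ≥ C > 0 (cm⁻¹ or any common unit).
    """
    if not (A >= B >= C):
        raise ValueError(f"rotational constants must be ordered A >= B >= C, got {A}, {B}, {C}")
    if C <= 0:
        raise ValueError("rotational constants must be positive")
    if A == C:
        raise ValueError("spherical top (A == C): Ray's kappa is undefined")
    return (2.0 * B - A - C) / (A - C)


@dataclass(frozen=True)
class RotorConstants:
    """Rotational constants of a (near-)symmetric top, cm⁻¹, A ≥ B ≥ C."""

    A: float
    B: float
    C: float

    def __post_init__(self) -> None:
        if not (self.A >= self.B >= self.C > 0):
            raise ValueError(
                f"require A >= B >= C > 0, got A={self.A}, B={self.B}, C={self.C}"
            )

    @property
    def kappa(self) -> float:
        """Ray's asymmetry parameter."""
        return ray_kappa(self.A, self.B, self.C)

    @property
    def top_type(self) -> str:
        """'near_prolate' if κ ≤ 0 (convention: tie goes to prolate) else 'near_oblate'."""
        if self.A == self.C:
            return "near_prolate"  # spherical; degenerate, treat as prolate
        return "near_prolate" if self.kappa <= 0.0 else "near_oblate"

    @property
    def B_bar(self) -> float:
        """Effective perpendicular constant: (B+C)/2 for prolate, (A+B)/2 for oblate."""
        if self.top_type == "near_prolate":
            return 0.5 * (self.B + self.C)
        return 0.5 * (self.A + self.B)

    @property
    def axis_constant(self) -> float:
        """Constant of the unique axis: A (prolate) or C (oblate)."""
        return self.A if self.top_type == "near_prolate" else self.C

    @classmethod
    def from_values(cls, values, unit: str = "cm-1") -> "RotorConstants":
        """Build from three constants in ``cm-1`` or ``MHz`` (any order)."""
        v = sorted(float(x) for x in values)[::-1]
        if unit.lower() in ("cm-1", "cm^-1", "cm"):
            pass
        elif unit.lower() == "mhz":
            v = [x / MHZ_PER_CM for x in v]
        else:
            raise ValueError(f"unknown unit {unit!r}; use 'cm-1' or 'MHz'")
        return cls(*v)


@dataclass(frozen=True)
class RotationalState:
    """One (J, K) level with its energy and (unnormalised) Boltzmann weight."""

    J: int
    K: int
    energy: float  # cm⁻¹ above (J=0, K=0)
    weight: float  # includes (2J+1) and ±K degeneracy


def rot_energy(rc: RotorConstants, J, K) -> float | np.ndarray:
    """Symmetric-top rotational energy in cm⁻¹ (same constants for both vib states).

    Prolate: B̄·J(J+1) + (A − B̄)·K²; oblate: B̄·J(J+1) + (C − B̄)·K².
    Accepts scalars or arrays; |K| ≤ J is enforced for scalar input.
    """
    J_arr = np.asarray(J)
    K_arr = np.asarray(K)
    if J_arr.ndim == 0 and (abs(int(K_arr)) > int(J_arr) or int(J_arr) < 0):
        raise ValueError(f"require 0 <= |K| <= J, got J={J}, K={K}")
    Bb = rc.B_bar
    return Bb * J_arr * (J_arr + 1.0) + (rc.axis_constant - Bb) * K_arr.astype(float) ** 2


def rot_populations(
    rc: RotorConstants,
    T_rot: float,
    coverage: float = 0.9999,
    J_cap: int = 200,
) -> tuple[list[RotationalState], float]:
    """Thermally populated (J, K ≥ 0) levels and the rotational partition function.

    Weights are (2 − δ_K0)(2J+1)·exp(−(hc/kB)·E/T); the ±K degeneracy is folded
    into the factor 2 with K enumerated ≥ 0. Levels are returned for J up to the
    smallest J whose cumulative normalised population reaches ``coverage``
    (capped at ``J_cap`` with a warning). The returned partition function is the
    converged full sum, so sum(retained weights)/Z is the achieved coverage.
    """
    if T_rot <= 0:
        raise ValueError(f"T_rot must be > 0, got {T_rot}")
    if not (0 < coverage <= 1):
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")

    beta = HC_OVER_KB / T_rot
    per_J = []  # total weight of each J shell
    Z = 0.0
    J = 0
    # converge the partition sum: stop when a shell adds < 1e-14 of the total
    while True:
        K = np.arange(J + 1)
        E = rot_energy(rc, np.full(J + 1, J), K)
        w = (2.0 - (K == 0)) * (2 * J + 1) * np.exp(-beta * E)
        shell = float(w.sum())
        per_J.append(shell)
        Z += shell
        if J >= 1 and shell < 1e-14 * Z:
            break
        if J > max(4 * J_cap, 2000):  # hard safety stop
            break
        J += 1

    cum = np.cumsum(per_J) / Z
    J_max = int(np.searchsorted(cum, coverage))
    if J_max > J_cap:
        warnings.warn(
            f"J_cap={J_cap} binds: coverage {coverage} would need J={J_max}",
            stacklevel=2,
        )
        J_max = J_cap
    J_max = min(J_max, len(per_J) - 1)

    states: list[RotationalState] = []
    for Jv in range(J_max + 1):
        K = np.arange(Jv + 1)
        E = rot_energy(rc, np.full(Jv + 1, Jv), K)
        w = (2.0 - (K == 0)) * (2 * Jv + 1) * np.exp(-beta * E)
        for Kv, Ev, wv in zip(K, E, w):
            states.append(RotationalState(J=Jv, K=int(Kv), energy=float(Ev), weight=float(wv)))
    return states, Z


def constants_from_geometry(
    coordinates, masses
) -> tuple[RotorConstants, np.ndarray]:
    """Rotational constants and principal-frame rotation from a geometry.

    ``coordinates``: (n, 3) array in Å; ``masses``: length-n array in amu.
    Diagonalises the inertia tensor about the centre of mass; constant
    X = 16.8576304 / I_X (I in amu·Å², X in cm⁻¹), sorted A ≥ B ≥ C.

    Returns ``(RotorConstants, R)`` where the rows of R are the principal axes
    ordered so that row 0 = a-axis (smallest inertia), row 2 = c-axis; the
    unique rotor axis z is the a-axis for a near-prolate top and the c-axis
    for a near-oblate one (apply the mapping when orienting tensors).
    """
    xyz = np.asarray(coordinates, dtype=float)
    m = np.asarray(masses, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3 or xyz.shape[0] != m.shape[0]:
        raise ValueError("coordinates must be (n, 3) with matching masses")
    if xyz.shape[0] < 2:
        raise ValueError("need at least two atoms")
    com = (m[:, None] * xyz).sum(axis=0) / m.sum()
    r = xyz - com
    # inertia tensor
    r2 = (r**2).sum(axis=1)
    I = np.einsum("a,ij->ij", m, np.zeros((3, 3)))
    I = np.diag((m * r2).sum() * np.ones(3)) - np.einsum("a,ai,aj->ij", m, r, r)
    moments, axes = np.linalg.eigh(I)  # ascending: Ia <= Ib <= Ic
    tol = 1e-10 * max(moments[-1], 1.0)
    if moments[0] < tol:
        raise LinearRotorError("geometry is (near-)linear: smallest moment of inertia is zero")
    consts = INERTIA_TO_CM / moments  # descending: A >= B >= C
    R = axes.T  # rows = principal axes (a, b, c)
    # enforce a right-handed frame
    if np.linalg.det(R) < 0:
        R[2] *= -1.0
    return RotorConstants(*consts), R
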