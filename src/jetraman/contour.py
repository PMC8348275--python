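"""Rovibrational line lists and band contours for near-symmetric tops.

Raman selection rules for a symmetric top are ΔJ = 0, ±1, ±2 with ΔK = 0,
±1 or ±2 carried by the corresponding channel weight of the anisotropy
(γ₀², γ₁², γ₂²); the isotropic part a′² scatters only in ΔJ = ΔK = 0.
Each populated lower level (J, K) emits

    position:  ν̃₀ + E(J′, K+ΔK) − E(J, K)
    intensity: p(J,K) · C_g · g(ΔK) · b(J,K → J′,K+ΔK)

with p the normalised Boltzmann population, g(0) = γ₀², g(±1) = γ₁²/2,
g(±2) = γ₂²/2 and b the Placzek–Teller factor — the squared Clebsch–Gordan
coefficient ⟨J K; 2 ΔK | J′ K+ΔK⟩², which obeys the completeness sum rule
Σ_J′ b = 1.  Because the same rigid constants serve both vibrational states,
every ΔJ = ΔK = 0 line sits exactly at the band origin, producing the sharp
Q₀ peak, and the summed line intensity of a band equals the detected
activity (C_a·a′² + C_g·γ′²) times the population coverage.

Lines are folded with area-preserving Gaussians (standard deviation σ,
truncated at ±5σ) on a uniform grid; positions are rounded to 0.01 cm⁻¹ and
co-added before folding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .polarizability import PlaczekInvariants, PolarizabilityTensor, invariants
from .rotor import RotorConstants, rot_energy, rot_populations

__all__ = [
    "VibBand",
    "LineList",
    "Spectrum",
    "ConformerSpec",
    "placzek_teller_b",
    "build_linelist",
    "gaussian_fold",
    "simulate_conformer",
]

#: ideal 90°, unanalysed detection coefficients of a′² and γ′²
IDEAL_C_A = 45.0
IDEAL_C_G = 7.0


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class VibBand:
    """One vibrational band: wavenumbers plus Raman invariants."""

    label: str
    nu_calc: float
    invariants: PlaczekInvariants
    nu_exp: Optional[float] = None
    symmetry: Optional[str] = None
    cross_section: Optional[float] = None

    def __post_init__(self) -> None:
        if self.nu_calc <= 0:
            raise ValueError(f"band {self.label}: nu_calc must be > 0")
        if self.nu_exp is not None and self.nu_exp <= 0:
            raise ValueError(f"band {self.label}: nu_exp must be > 0")


@dataclass
class LineList:
    """Rovibrational lines of one band (parallel arrays)."""

    position: np.ndarray
    intensity: np.ndarray
    J: np.ndarray
    K: np.ndarray
    dJ: np.ndarray
    dK: np.ndarray
    origin: float = 0.0

    def __len__(self) -> int:
        return self.position.size

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "position": self.position,
                "intensity": self.intensity,
                "J": self.J,
                "K": self.K,
                "dJ": self.dJ,
                "dK": self.dK,
            }
        )

    @staticmethod
    def concatenate(lists: Sequence["LineList"]) -> "LineList":
        return LineList(
            position=np.concatenate([l.position for l in lists]),
            intensity=np.concatenate([l.intensity for l in lists]),
            J=np.concatenate([l.J for l in lists]),
            K=np.concatenate([l.K for l in lists]),
            dJ=np.concatenate([l.dJ for l in lists]),
            dK=np.concatenate([l.dK for l in lists]),
            origin=lists[0].origin if lists else 0.0,
        )


@dataclass
class Spectrum:
    """Intensities on a uniform wavenumber grid, with provenance metadata."""

    wavenumber: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumber.shape != self.intensity.shape:
            raise ValueError("wavenumber and intensity must have the same shape")
        if self.wavenumber.size >= 2:
            d = np.diff(self.wavenumber)
            if np.any(d <= 0):
                raise ValueError("wavenumber axis must be strictly increasing")

    @property
    def spacing(self) -> float:
        # snapped to 1e-9 so index arithmetic on anchored grids stays exact
        return float(np.round(np.median(np.diff(self.wavenumber)), 9))

    def integral(self) -> float:
        return float(np.trapezoid(self.intensity, self.wavenumber))

    def copy(self) -> "Spectrum":
        return Spectrum(self.wavenumber.copy(), self.intensity.copy(), dict(self.metadata))

    def __add__(self, other: "Spectrum") -> "Spectrum":
        """Sum of two spectra on a merged common grid (same spacing required)."""
        h = self.spacing
        if abs(other.spacing - h) > 1e-9:
            raise ValueError("spectra have different grid spacings")
        lo = min(self.wavenumber[0], other.wavenumber[0])
        hi = max(self.wavenumber[-1], other.wavenumber[-1])
        n = int(round((hi - lo) / h)) + 1
        grid = (round(lo / h) + np.arange(n)) * h
        out = np.zeros(n)
        for s in (self, other):
            i0 = int(round((s.wavenumber[0] - lo) / h))
            out[i0 : i0 + s.wavenumber.size] += s.intensity
        meta = dict(self.metadata)
        meta.update(other.metadata)
        return Spectrum(grid, out, meta)


@dataclass
class ConformerSpec:
    """A named conformer: rotor constants, vibrational bands, energetics."""

    name: str
    rotor: RotorConstants
    bands: list[VibBand]
    energetics: Optional[object] = None  # populations.ConformerEnergetics
    provenance: str = ""


# --------------------------------------------------------------------------
# Placzek–Teller factors
# --------------------------------------------------------------------------

def _wigner3j2_sq(J, Jp, K, m):
    """Squared Wigner 3j symbol (J 2 J'; K m −(K+m)), vectorised.

    Evaluated by the Racah sum with log-gamma factorials (≤ 5 terms for
    rank 2), numerically stable to J of a few hundred. Inputs broadcast;
    triangle- or projection-forbidden entries return 0.
    """
    J = np.asarray(J, dtype=np.int64)
    Jp = np.asarray(Jp, dtype=np.int64)
    K = np.asarray(K, dtype=np.int64)
    m = np.asarray(m, dtype=np.int64)
    J, Jp, K, m = np.broadcast_arrays(J, Jp, K, m)
    j2 = 2
    m3 = -(K + m)
    ok = (
        (Jp >= 0)
        & (np.abs(J - Jp) <= j2)
        & (J + Jp >= j2)
        & (np.abs(K) <= J)
        & (np.abs(K + m) <= np.maximum(Jp, 0))
        & (np.abs(m) <= j2)
    )
    Js = np.where(ok, J, 2)
    Jps = np.where(ok, Jp, 2)
    Ks = np.where(ok, K, 0)
    ms = np.where(ok, m, 0)
    m3s = -(Ks + ms)

    def lf(n):
        return gammaln(np.asarray(n, dtype=float) + 1.0)

    # triangle coefficient (log)
    log_delta = lf(Js + j2 - Jps) + lf(Js - j2 + Jps) + lf(-Js + j2 + Jps) - lf(Js + j2 + Jps + 1)
    log_pref = 0.5 * (
        log_delta
        + lf(Js + Ks)
        + lf(Js - Ks)
        + lf(j2 + ms)
        + lf(j2 - ms)
        + lf(Jps + m3s)
        + lf(Jps - m3s)
    )
    t_lo = np.maximum.reduce([np.zeros_like(Js), j2 - Jps - Ks, Js - Jps + ms])
    t_hi = np.minimum.reduce([Js + j2 - Jps, Js - Ks, j2 + ms])
    total = np.zeros(Js.shape, dtype=float)
    # at most 5 admissible t values for rank 2
    for dt in range(5):
        t = t_lo + dt
        act = t <= t_hi
        ts = np.where(act, t, 0)
        log_term = -(
            lf(ts)
            + lf(Jps - j2 + ts + Ks)
            + lf(Jps - Js + ts - ms)
            + lf(Js + j2 - Jps - ts)
            + lf(Js - ts - Ks)
            + lf(j2 - ts + ms)
        )
        sign = np.where(ts % 2 == 0, 1.0, -1.0)
        total = total + np.where(act, sign * np.exp(log_pref + log_term), 0.0)
    # overall phase squares away
    return np.where(ok, total**2, 0.0)


def placzek_teller_b(J, K, dJ, dK):
    """Placzek–Teller line-strength factor b = (2J′+1)·3j(J 2 J′; K ΔK −(K+ΔK))².

    Equals the squared Clebsch–Gordan coefficient ⟨J K; 2 ΔK | J′ K+ΔK⟩² with
    J′ = J + ΔJ; satisfies the completeness sum rule Σ_ΔJ b = 1 for any
    admissible (J, K, ΔK). Forbidden target states return 0. Scalars or
    broadcastable arrays accepted.
    """
    J_a = np.asarray(J)
    K_a = np.asarray(K)
    dJ_a = np.asarray(dJ)
    dK_a = np.asarray(dK)
    if np.any(J_a < 0) or np.any(np.abs(K_a) > J_a):
        raise ValueError("require 0 <= |K| <= J")
    if np.any(np.abs(dJ_a) > 2) or np.any(np.abs(dK_a) > 2):
        raise ValueError("require |dJ| <= 2 and |dK| <= 2")
    Jp = J_a + dJ_a
    val = (2.0 * np.maximum(Jp, 0) + 1.0) * _wigner3j2_sq(J_a, Jp, K_a, dK_a)
    if val.ndim == 0:
        return float(val)
    return val


# --------------------------------------------------------------------------
# line lists and folding
# --------------------------------------------------------------------------

def build_linelist(
    band: VibBand,
    rc: RotorConstants,
    T_rot: float,
    coverage: float = 0.9999,
    J_cap: int = 200,
    C_a: float = IDEAL_C_A,
    C_g: float = IDEAL_C_G,
    origin: Optional[float] = None,
) -> LineList:
    """Rovibrational line list of one band at rotational temperature ``T_rot``.

    The total line intensity equals coverage·(C_a·a′² + C_g·γ′²) — the
    rigid-rotor intensity-preservation identity.
    """
    inv = band.invariants
    nu0 = float(band.nu_calc if origin is None else origin)
    states, Z = rot_populations(rc, T_rot, coverage=coverage, J_cap=J_cap)
    Js = np.array([s.J for s in states], dtype=np.int64)
    Ks = np.array([s.K for s in states], dtype=np.int64)
    Es = np.array([s.energy for s in states])
    ps = np.array([s.weight for s in states]) / Z

    g_of_m = {
        0: inv.gamma2_dk0,
        1: inv.gamma2_dk1 / 2.0,
        -1: inv.gamma2_dk1 / 2.0,
        2: inv.gamma2_dk2 / 2.0,
        -2: inv.gamma2_dk2 / 2.0,
    }

    pos_parts, int_parts, J_parts, K_parts, dJ_parts, dK_parts = [], [], [], [], [], []

    # isotropic (rank-0) scattering: Q0 lines only
    if inv.a_prime != 0.0 and C_a != 0.0:
        pos_parts.append(np.full(Js.size, nu0))
        int_parts.append(ps * C_a * inv.a_prime**2)
        J_parts.append(Js)
        K_parts.append(Ks)
        dJ_parts.append(np.zeros(Js.size, dtype=np.int64))
        dK_parts.append(np.zeros(Js.size, dtype=np.int64))

    # anisotropic (rank-2) scattering
    if inv.gamma2 > 0.0 and C_g != 0.0:
        for m in (-2, -1, 0, 1, 2):
            gm = g_of_m[m]
            if gm == 0.0:
                continue
            for dJ in (-2, -1, 0, 1, 2):
                Jp = Js + dJ
                Kp = Ks + m
                b = placzek_teller_b(Js, Ks, np.full(Js.size, dJ), np.full(Js.size, m))
                inten = ps * C_g * gm * b
                keep = inten > 0.0
                if not np.any(keep):
                    continue
                shift = rot_energy(rc, Jp[keep], Kp[keep]) - Es[keep]
                pos_parts.append(nu0 + shift)
                int_parts.append(inten[keep])
                J_parts.append(Js[keep])
                K_parts.append(Ks[keep])
                dJ_parts.append(np.full(int(keep.sum()), dJ, dtype=np.int64))
                dK_parts.append(np.full(int(keep.sum()), m, dtype=np.int64))

    if not pos_parts:
        empty_i = np.empty(0, dtype=np.int64)
        return LineList(np.empty(0), np.empty(0), empty_i, empty_i, empty_i, empty_i, origin=nu0)
    return LineList(
        position=np.concatenate(pos_parts),
        intensity=np.concatenate(int_parts),
        J=np.concatenate(J_parts),
        K=np.concatenate(K_parts),
        dJ=np.concatenate(dJ_parts),
        dK=np.concatenate(dK_parts),
        origin=nu0,
    )


_ROUND = 0.01  # cm⁻¹ line-position rounding before folding


def gaussian_fold(
    lines: LineList,
    sigma: float,
    grid_spacing: float = 0.1,
    grid_range: Optional[tuple[float, float]] = None,
) -> Spectrum:
    """Fold a line list with area-preserving Gaussians onto a uniform grid.

    Line positions are rounded to 0.01 cm⁻¹ and co-added; each line adds a
    Gaussian of standard deviation ``sigma`` truncated at ±5σ. The grid is
    anchored at integer multiples of ``grid_spacing`` (which must itself be
    an integer multiple of 0.01 cm⁻¹) so outputs are bit-reproducible.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    ratio = grid_spacing / _ROUND
    if abs(ratio - round(ratio)) > 1e-9 or grid_spacing <= 0:
        raise ValueError("grid_spacing must be a positive integer multiple of 0.01 cm⁻¹")
    ratio = int(round(ratio))
    if len(lines) == 0:
        raise ValueError("cannot fold an empty line list")

    pos = np.round(lines.position / _ROUND) * _ROUND
    if grid_range is None:
        lo = np.floor((pos.min() - 5.0 * sigma) / grid_spacing) * grid_spacing
        hi = np.ceil((pos.max() + 5.0 * sigma) / grid_spacing) * grid_spacing
    else:
        lo = np.floor(grid_range[0] / grid_spacing) * grid_spacing
        hi = np.ceil(grid_range[1] / grid_spacing) * grid_spacing
    n_fine = int(round((hi - lo) / _ROUND)) + 1

    # deposit co-added line intensities on the 0.01 cm⁻¹ fine grid
    idx = np.round((pos - lo) / _ROUND).astype(np.int64)
    inside = (idx >= 0) & (idx < n_fine)
    sticks = np.bincount(idx[inside], weights=lines.intensity[inside], minlength=n_fine)

    half = int(np.floor(5.0 * sigma / _ROUND))
    x = _ROUND * np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (x / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))
    folded = np.convolve(sticks, kernel, mode="same")

    # lo is a multiple of grid_spacing, so the coarse grid is exact multiples of it
    start = int(round(lo / grid_spacing))
    n_coarse = (n_fine - 1) // ratio + 1
    grid = (start + np.arange(n_coarse)) * grid_spacing
    return Spectrum(grid, folded[::ratio], {"sigma": sigma})


def simulate_conformer(
    spec: ConformerSpec,
    T_rot: float = 30.0,
    sigma: float = 1.0,
    use_experimental_centers: bool = False,
    instrument=None,
    coverage: float = 0.9999,
    J_cap: int = 200,
    grid_spacing: float = 0.1,
    grid_range: Optional[tuple[float, float]] = None,
    calc_scale: float = 1.0,
) -> Spectrum:
    """Full rovibrational contour of one conformer (sum over its bands).

    Band centres come from ``nu_exp`` when ``use_experimental_centers`` is
    set (an error names any band missing one), else from ``nu_calc`` times
    ``calc_scale``. Detection coefficients, the vibrational temperature
    factor and the ν⁴ frequency factor are taken from ``instrument`` when
    provided (ideal 45/7 coefficients and no thermal/frequency weighting
    otherwise). Defaults T_rot = 30 K, σ = 1.0 cm⁻¹ are the jet-spectrum
    simulation conditions.
    """
    if not spec.bands:
        raise ValueError(f"conformer {spec.name!r} has no bands")

    per_band = []
    for band in spec.bands:
        if use_experimental_centers:
            if band.nu_exp is None:
                raise ValueError(
                    f"band {band.label!r} of conformer {spec.name!r} has no experimental "
                    "wavenumber but experimental centers were requested"
                )
            center = band.nu_exp
        else:
            center = band.nu_calc * calc_scale

        if instrument is None:
            C_a, C_g = IDEAL_C_A, IDEAL_C_G
            weight = 1.0
        else:
            C_a, C_g = instrument.detection_coefficients()
            weight = instrument.band_weight(center)

        ll = build_linelist(
            band, spec.rotor, T_rot, coverage=coverage, J_cap=J_cap,
            C_a=C_a * weight, C_g=C_g * weight, origin=center,
        )
        per_band.append(ll)

    all_lines = LineList.concatenate(per_band)
    out = gaussian_fold(all_lines, sigma, grid_spacing=grid_spacing, grid_range=grid_range)
    out.metadata.update(
        {
            "conformer": spec.name,
            "T_rot": T_rot,
            "sigma": sigma,
            "centers": "experimental" if use_experimental_centers else "calculated",
        }
    )
    return out
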