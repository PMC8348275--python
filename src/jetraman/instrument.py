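"""Detection-side corrections and the combined experimental error budget.

A 90°-scattering Raman setup with unanalysed detection records intensity
proportional to A(⊥i,⊥s) + A(⊥i,‖s). For an ideal point aperture these are
45a′² + 4γ′² and 3γ′²; for a finite collection cone the prefactors shift
(defaults below are for the reference setup: 45/4.1133 and 0.0423/3.1142).
The monochromator transmits the parallel-polarised component a factor f
(≈1.5–2.5) less than the perpendicular one, which is absorbed by dividing
the calculated parallel coefficients by f.

The temperature (visibility) factor of a harmonic mode,

    I_T(ν̃, T) = 1 / (1 − exp(−hc·ν̃/(kB·T))),

scales a band's apparent intensity when hot transitions coincide with cold
ones. Jet vibrational temperatures are bracketed as 20–180 K; calculated
intensities carry the mean of the two bracket factors and half their
difference enters the error budget. All error terms combine additively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import HC_OVER_KB

__all__ = [
    "InstrumentModel",
    "detected_activity",
    "temperature_factor",
    "thermal_scale",
    "excitation_scale",
    "error_budget",
    "epsilon_deviation",
    "normalisation_set",
]


@dataclass
class InstrumentModel:
    """Geometry coefficients, transmittance, and error-budget settings."""

    c_perp_a: float = 45.0
    c_perp_g: float = 4.1133
    c_par_a: float = 0.0423
    c_par_g: float = 3.1142
    transmittance_factor: float = 1.0  # f >= 1; monochromator polarisation bias
    transmittance_uncertainty: float = 0.05
    laser_wavenumber: float = 1e7 / 532.27  # cm⁻¹
    illumination_error: float = 0.015
    polarisation_error: float = 0.015
    impurity_floor: float = 0.01
    T_vib_low: float = 20.0
    T_vib_high: float = 180.0
    apply_thermal: bool = False  # weight simulated bands by mean[I_T(20K), I_T(180K)]
    apply_frequency: bool = False  # weight simulated bands by the relative ν⁴ factor

    def __post_init__(self) -> None:
        for name in ("c_perp_a", "c_perp_g", "c_par_a", "c_par_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.transmittance_factor < 1:
            raise ValueError("transmittance factor f must be >= 1")
        for name in ("illumination_error", "polarisation_error", "impurity_floor"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a fraction in [0, 1]")

    @classmethod
    def ideal(cls, f: float = 1.0) -> "InstrumentModel":
        """Ideal point-aperture 90° geometry: coefficients 45/4 and 0/3."""
        return cls(c_perp_a=45.0, c_perp_g=4.0, c_par_a=0.0, c_par_g=3.0,
                   transmittance_factor=f)

    def detection_coefficients(self) -> tuple[float, float]:
        """(C_a, C_g) with the parallel component divided by the transmittance f."""
        f = self.transmittance_factor
        return (self.c_perp_a + self.c_par_a / f, self.c_perp_g + self.c_par_g / f)

    def band_weight(self, nu: float) -> float:
        """Thermal × frequency weight applied to a simulated band at ν̃ (cm⁻¹)."""
        w = 1.0
        if self.apply_thermal:
            w *= 0.5 * (
                temperature_factor(nu, self.T_vib_low)
                + temperature_factor(nu, self.T_vib_high)
            )
        if self.apply_frequency:
            w *= ((self.laser_wavenumber - nu) / self.laser_wavenumber) ** 4
        return w


def detected_activity(inv, model: InstrumentModel | None = None,
                      geometry: str = "corrected") -> tuple[float, float, float]:
    """Detected Raman activity of a band: (C_a, C_g, C_a·a′² + C_g·γ′²).

    ``geometry='ideal'`` uses 45/4 + 0/3 coefficients (→ 45a′² + 7γ′² at
    f = 1); ``'corrected'`` uses the model's finite-aperture coefficients.
    """
    if model is None:
        model = InstrumentModel()
    if geometry == "ideal":
        model = InstrumentModel.ideal(model.transmittance_factor)
    elif geometry != "corrected":
        raise ValueError("geometry must be 'ideal' or 'corrected'")
    C_a, C_g = model.detection_coefficients()
    return C_a, C_g, C_a * inv.a_prime**2 + C_g * inv.gamma2


def temperature_factor(nu: float, T_vib: float) -> float:
    """Harmonic hot-band visibility factor I_T(ν̃, T) = 1/(1 − exp(−hcν̃/kBT))."""
    nu_arr = np.asarray(nu, dtype=float)
    if np.any(nu_arr <= 0):
        raise ValueError("wavenumber must be > 0")
    if T_vib < 0:
        raise ValueError("temperature must be >= 0")
    if T_vib == 0:
        return float(np.ones_like(nu_arr)) if nu_arr.ndim == 0 else np.ones_like(nu_arr)
    out = 1.0 / (1.0 - np.exp(-HC_OVER_KB * nu_arr / T_vib))
    return float(out) if out.ndim == 0 else out


def thermal_scale(
    I: float,
    nu_used: float,
    from_convention: str,
    to_T: float,
    model: InstrumentModel | None = None,
) -> float:
    """Rescale an intensity from its source thermal convention to ``to_T``.

    ``from_convention='zero_K'`` divides by 1; ``'avg_20_180'`` divides by
    the mean of I_T at the model's bracket temperatures (default 20/180 K).
    """
    if nu_used <= 0:
        raise ValueError("wavenumber must be > 0")
    if model is None:
        model = InstrumentModel()
    target = temperature_factor(nu_used, to_T)
    if from_convention == "zero_K":
        source = 1.0
    elif from_convention == "avg_20_180":
        source = 0.5 * (
            temperature_factor(nu_used, model.T_vib_low)
            + temperature_factor(nu_used, model.T_vib_high)
        )
    else:
        raise ValueError("from_convention must be 'zero_K' or 'avg_20_180'")
    return I * target / source


def excitation_scale(I: float, nu_k: float, nu0_from: float, nu0_to: float) -> float:
    """Rescale a Stokes intensity between laser excitation wavenumbers (ν₀−ν̃k)⁴ law."""
    if nu0_from <= nu_k or nu0_to <= nu_k:
        raise ValueError("anti-Stokes regime: excitation wavenumber must exceed the shift")
    return I * ((nu0_to - nu_k) / (nu0_from - nu_k)) ** 4


def error_budget(
    I_signal: float,
    sigma_integration: float,
    nu_exp: float,
    I_strongest: float,
    model: InstrumentModel | None = None,
) -> float:
    """Total (additive) uncertainty of one integrated signal intensity.

    σ_total = σ_integration + I·(illumination + polarisation errors)
            + I·½·[I_T(ν̃,T_high) − I_T(ν̃,T_low)] + impurity_floor·I_strongest.
    """
    if min(I_signal, sigma_integration, nu_exp, I_strongest) < 0:
        raise ValueError("all inputs must be >= 0")
    if model is None:
        model = InstrumentModel()
    dT = temperature_factor(nu_exp, model.T_vib_high) - temperature_factor(
        nu_exp, model.T_vib_low
    )
    return (
        sigma_integration
        + I_signal * model.illumination_error
        + I_signal * model.polarisation_error
        + I_signal * 0.5 * dT
        + I_strongest * model.impurity_floor
    )


def epsilon_deviation(I_calc, I_exp, sigma_exp, nu_calc, nu_max: float = 1800.0):
    """Per-band relative deviation ε between calculated and measured intensities.

    ε_k = max(0, |I_calc,k − I_exp,k| − σ_exp,k) / Σ_{ν̃_calc < nu_max} I_calc —
    the error-reduced absolute deviation against the summed calculated
    fundamental intensity below ``nu_max``. Theory inside the experimental
    error bar clamps to 0.
    """
    I_calc = np.asarray(I_calc, dtype=float)
    I_exp = np.asarray(I_exp, dtype=float)
    sigma_exp = np.asarray(sigma_exp, dtype=float)
    nu_calc = np.asarray(nu_calc, dtype=float)
    if I_calc.size == 0:
        raise ValueError("empty calculated intensity set")
    denom = I_calc[nu_calc < nu_max].sum()
    if denom <= 0:
        raise ValueError(f"no calculated intensity below {nu_max} cm⁻¹")
    return np.maximum(0.0, np.abs(I_calc - I_exp) - sigma_exp) / denom


def normalisation_set(
    intensities,
    wavenumbers,
    nu_min: float = 500.0,
    share_min: float = 0.10,
    explicit: list[int] | None = None,
) -> tuple[list[int], np.ndarray]:
    """Select the normalisation bands and rescale the table so they sum to 100.

    Iterates to a fixed point: start from all bands above ``nu_min``,
    normalise their sum to 100, drop members contributing less than
    ``share_min``·100, repeat. An ``explicit`` index set bypasses the
    iteration. Returns (selected indices, fully rescaled intensity table).
    """
    I = np.asarray(intensities, dtype=float)
    nu = np.asarray(wavenumbers, dtype=float)
    if explicit is not None:
        sel = sorted(explicit)
    else:
        sel = [i for i in range(I.size) if nu[i] > nu_min]
        if not sel:
            raise ValueError(f"no band above {nu_min} cm⁻¹")
        while True:
            total = I[sel].sum()
            keep = [i for i in sel if I[i] / total * 100.0 >= share_min * 100.0]
            if not keep:
                raise ValueError(
                    "normalisation iteration emptied the set; supply an explicit set"
                )
            if keep == sel:
                break
            sel = keep
    total = I[sel].sum()
    if total <= 0:
        raise ValueError("selected bands carry no intensity")
    return sel, I * (100.0 / total)
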