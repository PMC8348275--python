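"""Conformer abundance determination from jet spectra.

Two complementary routes:

* **Peak-height method** — a two-step analysis: the rovibrational simulation
  with harmonically predicted band centres assigns the signals, the
  simulation is redone with the experimental centres, and the factor by
  which each simulated peak height must be multiplied to match the
  experiment is recorded per signal.
* **Integral method** — spectrally separated signals are integrated
  (Monte-Carlo, see :mod:`jetraman.mcint`), divided by calculated Raman
  cross sections, and normalised to a reference signal.

Either way, per-conformer scale factors x are averaged (mean x̄ and
population standard deviation s = √((1/N)Σ(x−x̄)²)), converted to shares
p_i = 100·x̄_i/Σx̄, and the uncertainty is propagated to the shares treating
the conformer means as independent with σ = s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .contour import ConformerSpec, Spectrum, simulate_conformer
from .spectra import peak_height

__all__ = [
    "SignalAssignment",
    "QuantResult",
    "assign_signals",
    "fit_peak_factors",
    "shares_from_factors",
    "shares_from_integrals",
]


@dataclass
class SignalAssignment:
    """One predicted band matched (or not) to an experimental signal."""

    conformer: str
    band: str
    nu_calc: float
    nu_exp: Optional[float] = None
    factor: Optional[float] = None
    integral: Optional[float] = None
    integral_err: Optional[float] = None
    excluded: bool = False
    reason: str = ""


@dataclass
class QuantResult:
    """Per-conformer mean factors and normalised shares (percent)."""

    mean: dict[str, float]
    sd: dict[str, float]
    n: dict[str, int]
    shares: dict[str, float]
    share_sigma: dict[str, float]
    share_sigma_alt: Optional[dict[str, float]] = None

    def rounded(self) -> dict[str, tuple[int, int]]:
        """Presentation form: integer-percent shares and uncertainties."""
        return {
            k: (int(round(self.shares[k])), int(round(self.share_sigma[k])))
            for k in self.shares
        }


def assign_signals(
    exp: Spectrum,
    specs: Sequence[ConformerSpec],
    tolerance: float = 15.0,
    calc_scale: float = 1.0,
    prominence_frac: float = 0.01,
) -> list[SignalAssignment]:
    """Match each predicted band to the nearest experimental peak within tolerance.

    Experimental peak positions come from local maxima with prominence of at
    least ``prominence_frac`` of the strongest signal. Unmatched bands are
    flagged excluded; two bands landing on one peak are both flagged
    ambiguous (kept for manual resolution, excluded from quantification).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    prom = prominence_frac * float(exp.intensity.max())
    peaks, _ = find_peaks(exp.intensity, prominence=prom)
    peak_pos = exp.wavenumber[peaks]

    out: list[SignalAssignment] = []
    claimed: dict[int, list[int]] = {}
    for spec in specs:
        for band in spec.bands:
            target = band.nu_calc * calc_scale
            a = SignalAssignment(conformer=spec.name, band=band.label, nu_calc=band.nu_calc)
            if peak_pos.size:
                j = int(np.argmin(np.abs(peak_pos - target)))
                if abs(peak_pos[j] - target) <= tolerance:
                    a.nu_exp = float(peak_pos[j])
                    claimed.setdefault(j, []).append(len(out))
                else:
                    a.excluded, a.reason = True, "no experimental peak within tolerance"
            else:
                a.excluded, a.reason = True, "no experimental peaks found"
            out.append(a)
    for j, owners in claimed.items():
        if len(owners) > 1:
            for i in owners:
                out[i].excluded = True
                out[i].reason = "ambiguous: multiple bands match one peak"
    return out


def fit_peak_factors(
    exp: Spectrum,
    assignments: Sequence[SignalAssignment],
    specs: Sequence[ConformerSpec],
    T_rot: float = 30.0,
    sigma: float = 1.0,
    instrument=None,
    window: float = 1.0,
    coverage: float = 0.9999,
    J_cap: int = 200,
) -> list[SignalAssignment]:
    """Per-signal experimental/simulated peak-height factors.

    Each conformer is re-simulated with its assigned bands centred at the
    experimental wavenumbers; the factor of an assignment is the
    experimental peak height divided by the simulated one inside ±``window``
    cm⁻¹ of the signal. Excluded/ambiguous assignments keep ``factor=None``.
    """
    by_conf = {s.name: s for s in specs}
    sims: dict[str, Spectrum] = {}
    for name, spec in by_conf.items():
        bands = []
        for band in spec.bands:
            hit = next(
                (a for a in assignments
                 if a.conformer == name and a.band == band.label and a.nu_exp is not None),
                None,
            )
            bands.append(replace(band, nu_exp=hit.nu_exp) if hit else band)
        shifted = ConformerSpec(name=name, rotor=spec.rotor, bands=bands,
                                energetics=spec.energetics)
        # bands without an assignment fall back to their harmonic centre
        for b in shifted.bands:
            if b.nu_exp is None:
                b.nu_exp = b.nu_calc
        sims[name] = simulate_conformer(
            shifted, T_rot=T_rot, sigma=sigma, use_experimental_centers=True,
            instrument=instrument, coverage=coverage, J_cap=J_cap,
        )

    out = []
    for a in assignments:
        a = replace(a)
        if not a.excluded and a.nu_exp is not None:
            sim = sims[a.conformer]
            h_sim, _, _ = peak_height(sim, a.nu_exp, window)
            if h_sim <= 0:
                raise ValueError(
                    f"simulated peak height of band {a.band!r} ({a.conformer}) is zero"
                )
            h_exp, _, _ = peak_height(exp, a.nu_exp, window)
            a.factor = h_exp / h_sim
        out.append(a)
    return out


def _shares(means: dict[str, float], sigmas: dict[str, float]):
    """Normalise means to 100 and propagate independent per-conformer sigmas."""
    names = list(means)
    x = np.array([means[k] for k in names])
    s = np.array([sigmas[k] for k in names])
    S = x.sum()
    if S <= 0:
        raise ValueError("all conformer means are zero")
    p = 100.0 * x / S
    # ∂p_i/∂x_j = 100·(δ_ij·S − x_i)/S²
    jac = 100.0 * (np.eye(len(x)) * S - x[:, None]) / S**2
    sig = np.sqrt((jac**2 * s[None, :] ** 2).sum(axis=1))
    return dict(zip(names, p)), dict(zip(names, sig))


def _group(assignments: Sequence[SignalAssignment], attr: str) -> dict[str, list[float]]:
    g: dict[str, list[float]] = {}
    for a in assignments:
        v = getattr(a, attr)
        if a.excluded or v is None:
            continue
        g.setdefault(a.conformer, []).append(float(v))
    return g


def shares_from_factors(factors: dict[str, Sequence[float]] | Sequence[SignalAssignment]) -> QuantResult:
    """Conformer shares from per-signal peak-height factors.

    Accepts either ``{conformer: [factors...]}`` or a list of fitted
    assignments. Uses the population standard deviation (divisor N) and
    first-order propagation with independent conformer means.
    """
    if not isinstance(factors, dict):
        factors = _group(factors, "factor")
    if len(factors) < 2:
        raise ValueError("need at least two conformers")
    mean = {k: float(np.mean(v)) for k, v in factors.items()}
    sd = {k: float(np.std(v)) for k, v in factors.items()}  # divisor N
    n = {k: len(v) for k, v in factors.items()}
    shares, sig = _shares(mean, sd)
    return QuantResult(mean=mean, sd=sd, n=n, shares=shares, share_sigma=sig)


def shares_from_integrals(
    assignments: Sequence[SignalAssignment],
    cross_sections: dict[str, float],
    reference: str,
    exclusions: Sequence[str] = (),
) -> QuantResult:
    """Conformer shares from integrated intensities over calculated cross sections.

    Every signal's X = integral / cross-section is rescaled so the
    ``reference`` signal (band label) has X = 1; shares follow from the
    per-conformer means as in :func:`shares_from_factors`. Two uncertainties
    are reported: from the scatter of X within each conformer
    (``share_sigma``) and from the propagated per-signal integration errors
    (``share_sigma_alt``).
    """
    for label, cs in cross_sections.items():
        if cs <= 0:
            raise ValueError(f"cross section of {label!r} must be > 0")
    ref = next((a for a in assignments if a.band == reference and a.integral is not None), None)
    if ref is None or ref.excluded or reference in exclusions:
        raise ValueError(f"reference signal {reference!r} missing or excluded")
    X_ref = ref.integral / cross_sections[reference]
    if X_ref == 0:
        raise ValueError("reference signal integral is zero")

    xs: dict[str, list[float]] = {}
    errs: dict[str, list[float]] = {}
    for a in assignments:
        if a.excluded or a.integral is None or a.band in exclusions:
            continue
        X = a.integral / cross_sections[a.band] / X_ref
        xs.setdefault(a.conformer, []).append(X)
        e = (a.integral_err or 0.0) / cross_sections[a.band] / abs(X_ref)
        errs.setdefault(a.conformer, []).append(e)
    if len(xs) < 2:
        raise ValueError("need at least two conformers with usable integrals")

    mean = {k: float(np.mean(v)) for k, v in xs.items()}
    sd = {k: float(np.std(v)) for k, v in xs.items()}
    n = {k: len(v) for k, v in xs.items()}
    shares, sig = _shares(mean, sd)
    # alternative: propagate individual integration errors through the mean
    sig_mean = {k: float(np.sqrt(np.sum(np.square(errs[k]))) / n[k]) for k in xs}
    _, sig_alt = _shares(mean, sig_mean)
    return QuantResult(
        mean=mean, sd=sd, n=n, shares=shares, share_sigma=sig, share_sigma_alt=sig_alt
    )
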