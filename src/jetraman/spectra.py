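"""Reading, writing and post-processing measured spectra.

File format: two-column whitespace text (wavenumber / cm⁻¹, intensity) with
``#``-prefixed metadata headers, matching the deposited ``.dat`` layout.
Processing steps — readout-offset subtraction, multi-scan despiking, pixel
→ wavenumber Jacobian correction, and intensity-matched stitching of
overlapping spectral windows — append provenance lines to the metadata.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np

from .contour import Spectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "despike",
    "jacobian_correct",
    "stitch_segments",
    "peak_height",
    "concentration_scaling",
]


def read_spectrum(path, offset: float = 0.0) -> Spectrum:
    """Read a two-column whitespace ``.dat`` spectrum; ``#`` lines are metadata.

    A constant readout ``offset`` is subtracted on request. An unsorted axis
    is sorted with a warning recorded in the metadata.
    """
    meta: dict = {}
    xs, ys = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            if text.startswith("#"):
                body = text.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                elif body:
                    meta.setdefault("comments", []).append(body)
                continue
            parts = text.split()
            try:
                x, y = float(parts[0]), float(parts[1])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: non-numeric data at line {lineno}: {text!r}") from exc
            xs.append(x)
            ys.append(y)
    x = np.array(xs)
    y = np.array(ys) - offset
    if x.size >= 2 and np.any(np.diff(x) <= 0):
        order = np.argsort(x, kind="stable")
        x, y = x[order], y[order]
        meta["warning"] = "axis was unsorted; sorted on read"
        warnings.warn(f"{path}: wavenumber axis was unsorted; sorted on read", stacklevel=2)
    if offset:
        meta["offset_subtracted"] = repr(offset)
    return Spectrum(x, y, meta)


def write_spectrum(s: Spectrum, path) -> None:
    """Write a spectrum as two-column text with metadata header (full precision)."""
    with open(path, "w") as fh:
        for key, val in s.metadata.items():
            if key == "comments":
                for c in val:
                    fh.write(f"# {c}\n")
            else:
                fh.write(f"# {key}: {val}\n")
        for x, y in zip(s.wavenumber, s.intensity):
            fh.write(f"{float(x)!r} {float(y)!r}\n")


def despike(scans: Sequence[np.ndarray]) -> np.ndarray:
    """Combine repeated scans, rejecting cosmic-ray spikes.

    Per-point median across ≥3 scans, per-point minimum for exactly 2; a
    single scan passes through with a warning (no rejection possible).
    """
    arrs = [np.asarray(s, dtype=float) for s in scans]
    if not arrs:
        raise ValueError("no scans given")
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError("scans must have equal lengths")
    if len(arrs) == 1:
        warnings.warn("single scan: despiking skipped", stacklevel=2)
        return arrs[0].copy()
    stack = np.vstack(arrs)
    if len(arrs) == 2:
        return stack.min(axis=0)
    return np.median(stack, axis=0)


def jacobian_correct(counts, pixel_to_wavenumber) -> Spectrum:
    """Convert pixel counts to a wavenumber spectrum, dividing by spectral width.

    ``pixel_to_wavenumber`` is the strictly monotone wavenumber of each pixel
    centre; each count is divided by |Δν̃| from centred differences
    (one-sided at the edges), so the integral over ν̃ matches the pixel sum.
    """
    y = np.asarray(counts, dtype=float)
    nu = np.asarray(pixel_to_wavenumber, dtype=float)
    if y.shape != nu.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("counts and mapping must be equal-length 1-D arrays (n >= 2)")
    d = np.diff(nu)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("pixel→wavenumber mapping must be strictly monotone")
    width = np.abs(np.gradient(nu))
    inten = y / width
    if d[0] < 0:
        nu, inten = nu[::-1], inten[::-1]
    return Spectrum(nu, inten, {"jacobian_corrected": "true"})


def _nearest_index(x: np.ndarray, value: float) -> int:
    return int(np.argmin(np.abs(x - value)))


def stitch_segments(segments: Sequence[Spectrum], anchors: Sequence[float]) -> Spectrum:
    """Catenate overlapping spectral windows, matched at shared anchor signals.

    Segments are chained left to right: each is rescaled so its intensity at
    the anchor between it and its predecessor equals the predecessor's;
    overlapping grid ranges are averaged after scaling. Anchors are shared
    signal positions (cm⁻¹), one between each consecutive pair.
    """
    if not segments:
        raise ValueError("no segments")
    segs = [s.copy() for s in segments]
    if len(segs) == 1:
        return segs[0]
    if len(anchors) < len(segs) - 1:
        raise ValueError("need one anchor per consecutive segment pair")
    h = segs[0].spacing

    scales = [1.0]
    for i in range(1, len(segs)):
        a = anchors[i - 1]
        prev, cur = segs[i - 1], segs[i]
        if not (prev.wavenumber[0] <= a <= prev.wavenumber[-1]) or not (
            cur.wavenumber[0] <= a <= cur.wavenumber[-1]
        ):
            raise ValueError(
                f"anchor {a} cm⁻¹ not inside the overlap of segments {i-1} and {i}"
            )
        ref = prev.intensity[_nearest_index(prev.wavenumber, a)] * scales[i - 1]
        val = cur.intensity[_nearest_index(cur.wavenumber, a)]
        if val == 0:
            raise ValueError(f"anchor {a} cm⁻¹ has zero intensity in segment {i}")
        scales.append(ref / val)

    lo = min(s.wavenumber[0] for s in segs)
    hi = max(s.wavenumber[-1] for s in segs)
    n = int(round((hi - lo) / h)) + 1
    grid = lo + h * np.arange(n)
    total = np.zeros(n)
    count = np.zeros(n)
    for s, sc in zip(segs, scales):
        i0 = int(round((s.wavenumber[0] - lo) / h))
        total[i0 : i0 + s.wavenumber.size] += sc * s.intensity
        count[i0 : i0 + s.wavenumber.size] += 1.0
    if np.any(count == 0):
        raise ValueError("segments leave gaps in the stitched range")
    meta = {"stitched_segments": repr(len(segs)), "segment_scales": repr([float(x) for x in scales])}
    return Spectrum(grid, total / count, meta)


def peak_height(
    s: Spectrum,
    center: float,
    window: float,
    baseline: str = "none",
) -> tuple[float, float, bool]:
    """Maximum intensity in [center−window, center+window] and its position.

    ``baseline='linear_endpoints'`` subtracts the straight line through the
    window's endpoint intensities first. The returned flag is True when the
    maximum sits on the window boundary (peak probably outside the window).
    """
    mask = (s.wavenumber >= center - window) & (s.wavenumber <= center + window)
    if not np.any(mask):
        raise ValueError(f"empty window around {center} cm⁻¹")
    x = s.wavenumber[mask]
    y = s.intensity[mask].copy()
    if baseline == "linear_endpoints":
        if x.size >= 2:
            y -= y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    elif baseline != "none":
        raise ValueError("baseline must be 'none' or 'linear_endpoints'")
    i = int(np.argmax(y))
    at_edge = i in (0, x.size - 1)
    # poorly illuminated low part of a CCD window, if flagged on read/stitch
    low_edge = s.metadata.get("low_window_edge")
    if low_edge is not None and x[i] < float(low_edge):
        warnings.warn(
            f"peak at {x[i]:.1f} cm⁻¹ lies in the poorly illuminated low part of the "
            f"window (< {float(low_edge):.1f} cm⁻¹); its height may be underestimated",
            stacklevel=2,
        )
    return float(y[i]), float(x[i]), at_edge


def concentration_scaling(heights, concentrations) -> tuple[float, float]:
    """Power-law exponent of signal height vs concentration (log–log slope).

    Monomer signals scale with exponent ≈ 1, dimer signals ≈ 2. Returns
    (exponent, standard error of the slope). Requires ≥ 3 points.
    """
    h = np.asarray(heights, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if h.size < 3:
        raise ValueError("need at least 3 spectra for a concentration scaling")
    if np.any(h <= 0) or np.any(c <= 0):
        raise ValueError("heights and concentrations must be positive")
    x, y = np.log(c), np.log(h)
    n = x.size
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sxx = ((x - x.mean()) ** 2).sum()
    dof = max(n - 2, 1)
    se = float(np.sqrt((resid**2).sum() / dof / sxx))
    return float(slope), se
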