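# Methods

## Scope and model assumptions

`jetraman` treats a near-prolate (or near-oblate) asymmetric top as an
effective symmetric top. The two rotational constants perpendicular to the
unique axis are averaged (B̄ = (B+C)/2 for prolate, (A+B)/2 for oblate) and
the rigid symmetric-top energy E(J,K) = B̄·J(J+1) + (X−B̄)·K² is used with
the *same* constants for the lower and upper vibrational state. This is the
decisive simplification: it keeps every ΔJ=ΔK=0 line exactly at the band
origin (sharp Q₀ branches) and preserves the total band intensity in the
line sum. Centrifugal distortion, Coriolis coupling, vibrational dependence
of the constants, hot bands as resolved structure, tunnelling splittings and
true asymmetric-top eigenvalues are all outside the model. Nuclear-spin
statistical weights are set to unity, appropriate for the C1/Cs molecules
this package targets. The κ = 0 boundary is assigned to "near-prolate" by
convention.

Hot vibrational states are not simulated as separate lines; their coinciding
intensity enters only through the scalar visibility factor
I_T(ν̃,T) = 1/(1−exp(−hcν̃/k_BT)) of each harmonic mode.

## ΔK-channel partition of the anisotropy

For C1 molecules no single ΔK selection rule applies. To conserve the total
intensity, the anisotropic invariant γ′² is split into three channel
weights feeding ΔK = 0, ±1, ±2 exclusively, using the rank-2 spherical
components of the tensor in the rotor frame (z = unique axis):

    γ₀² = (3/2)|α₂₀|²,  γ₁² = (3/2)(|α₂+1|²+|α₂−1|²),  γ₂² = (3/2)(|α₂+2|²+|α₂−2|²)

with γ₀²+γ₁²+γ₂² = γ′² identically. This spherical-tensor reading is the
mathematically canonical decomposition "based on the tensor components";
the sum rule makes it testable, and the partition is invariant under
rotations about z (property-tested). For near-oblate tops the inertial
axes are remapped (z=c, x=a, y=b) before partitioning. |ΔK|=1,2 weights are
split equally between +m and −m, exact for real symmetric tensors.

Line strengths are Placzek–Teller factors computed as squared
Clebsch–Gordan coefficients, b = (2J′+1)·[3j(J 2 J′; K ΔK −K′)]², via a
log-gamma Racah sum (≤5 terms, stable to J ≈ 200, verified against sympy's
Wigner-3j and the classical Q-branch closed form). One expression covers
all branches and is checked by the completeness sum rule Σ_J′ b = 1.

## Numerical choices

* **Thermal populations.** Weights (2−δ_K0)(2J+1)e^(−hcE/k_BT) with
  hc/k_B = 1.4387770 cm·K; the partition sum is converged until a J shell
  adds <1e−14 of the total; retained shells cover ≥`coverage` (default
  0.9999) of the population, capped at `J_cap` = 200 with a warning. The
  population cutoff (rather than a fixed J_max) was an open design choice;
  coverage is reported so conservation checks are exact.
* **Folding.** Line positions are rounded to 0.01 cm⁻¹, co-added, deposited
  on a 0.01 cm⁻¹ fine grid and convolved with an area-preserving Gaussian
  kernel truncated at ±5σ, then decimated to the output grid (default
  0.1 cm⁻¹, anchored at integer multiples of the spacing so outputs are
  bit-reproducible). This is numerically identical to per-line evaluation
  under the rounding rule and handles 10⁶ lines in well under a second.
  σ is the Gaussian *standard deviation*, not FWHM.
* **Defaults.** T_rot = 30 K and σ = 1.0 cm⁻¹ for jet spectra — the
  conditions under which the simulation best matches cold-expansion
  contours. Constants live in one table (`constants.py`) so results are
  bit-stable: MHz→cm⁻¹ = ÷29979.2458, inertia→cm⁻¹ factor 16.8576304,
  R = 8.314462618e−3 kJ/(mol·K).

## Instrument corrections and error budget

Detection coefficients default to the finite-aperture values
(45 + 0.0423/f)·a′² + (4.1133 + 3.1142/f)·γ′², with the monochromator
transmittance factor f ≥ 1 dividing the parallel-polarised part; f's ±0.05
uncertainty is routed into the error budget (as a flat 1.5% polarisation
term), not sampled. Ideal 90° coefficients (45/7) are available for
comparison. Calculated band intensities carry the mean of I_T at the
20 K/180 K vibrational-temperature bracket; half the bracket spread is the
thermal error term. The total per-signal uncertainty is *additive*:
integration error + 1.5% illumination + 1.5% polarisation + thermal spread
+ 1% of the strongest signal (impurity/reproducibility floor). Additive
composition (not quadrature) is deliberate: the terms are systematic
bounds, not independent random variables. Inhomogeneous CCD illumination is
modelled only as the flat 1.5% term plus a low-spectral-window validity
flag; no pixel-response map exists to do better.

The deviation metric ε clamps at zero when theory lies inside the
experimental error bar: ε_k = max(0, |I_calc−I_exp|−σ_exp)/ΣI_calc(<1800 cm⁻¹).
The normalisation set is found iteratively (fundamentals >500 cm⁻¹
contributing ≥10%, renormalised to 100 to a fixed point), or supplied
explicitly.

## Monte-Carlo integration

Per draw: i.i.d. Gaussian noise is added to every grid point, the borders
are drawn uniformly (grid-snapped) within their ranges, a linear baseline
through the *input* spectrum's values at the drawn borders is subtracted,
and the residual is integrated by the trapezoid rule; the mean and standard
deviation over 10⁴ draws are the result. Taking the chord through the
pre-noise spectrum (rather than the noisy one) keeps the estimator unbiased
and makes the fixed-bounds variance exactly the trapezoidal i.i.d. form
noise_sd²·Δx²·(M−1.5); a noisy chord would add ~noise_sd²·width²/2 of
spurious variance dominated by the two border points. Noise is added before
border drawing (statistically immaterial at these levels). Correlated-noise
models and non-linear baselines are out of scope. For crowded signals,
`bounded_integrate` reports the plain integral with the magnitude of the
linear-baseline correction as its uncertainty.

## Quantification rules

Two-step peak-height analysis: assign signals with the harmonic-wavenumber
simulation (nearest experimental peak within 15 cm⁻¹ by default — chosen
from typical anharmonic shifts; configurable), re-simulate with the
experimental centres, then fit per-signal factors as experimental/simulated
peak height within ±1 cm⁻¹ of the assigned peak (a tight window so a strong
neighbour's flank cannot masquerade as the assigned signal). Ambiguous
assignments (two bands on one peak) are flagged and excluded, mirroring the
overlap cases that genuinely cannot be quantified. Per-conformer statistics
use the *population* standard deviation (divisor N), shares are normalised
means, and uncertainties propagate first-order treating conformer means as
independent. Conformers with different signal counts enter through plain
unweighted means. Rounding to integer percent happens only at presentation.
The integral route divides Monte-Carlo integrals by computed cross
sections, rescales to a reference signal, and reports both the scatter-based
and the propagated per-signal uncertainty.

## Population models

Pre-expansion populations are Boltzmann fractions g·e^(−ΔE/RT) (g = 2 for
chiral enantiomeric pairs); only energy differences matter
(shift-invariance is property-tested). Jet relaxation is modelled by
pooling torsional families (summing member fractions), with barriers
classified as easily overcome (<5 kJ/mol), frozen (>10 kJ/mol) or partial
in between. Gibbs-energy construction from frequencies is out of scope:
ΔE0/ΔG values are inputs from quantum chemistry.

## Synthetic data: what it does and does not show

The reference molecules' rotational constants and polarisability tensors
are not published, so end-to-end tests run on synthetic near-prolate
conformers: A ∈ [0.6, 1.0] cm⁻¹, B̄ ∈ [0.27, 0.36] cm⁻¹ (typical of
mid-size chain molecules and guaranteeing C > 0 at any κ ∈ [−1, 0]), with B
and C split to hit the requested κ exactly; random band positions in
100–1800 cm⁻¹ and random tensors with a chosen polarised/depolarised mix.
Mixture spectra add seeded Gaussian noise (1% of the strongest signal in
the recovery studies, matching the instrument's reproducibility floor) and
an optional linear baseline drift. The recovery study uses 7 + 4 signals
for the two conformers — the signal counts of the real analysis this
emulates; with far fewer signals the N-sample population-SD error bar
becomes too noisy for nominal coverage. Passing tests demonstrate the
*method's* correctness under rigid-rotor physics and white noise; they do
not probe anharmonicity, resonances, aggregation features or correlated
baselines present in real spectra. Oblate synthetic generation is not
implemented.

## Known limitations

Room-temperature contours of strongly asymmetric tops are only
qualitatively reproduced (rigid near-symmetric limit); ε printed for
strongly anharmonic outlier modes depends on the exact operand set and is
implemented strictly as defined above; the stitching overlap rule
(averaging after intensity matching) is a choice — the original procedure
is not published in that detail.
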