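"""Line lists, Placzek–Teller factors, Gaussian folding and contour simulation."""

import numpy as np
import pytest

from jetraman import (
    ConformerSpec,
    PlaczekInvariants,
    RotorConstants,
    Spectrum,
    VibBand,
    build_linelist,
    gaussian_fold,
    placzek_teller_b,
    rot_populations,
    simulate_conformer,
)
from jetraman.contour import LineList


class TestPlaczekTeller:
    def test_ground_state_s_branch(self):
        # only rank-2 branch out of (J=0, K=0) is ΔJ=+2
        assert placzek_teller_b(0, 0, 2, 0) == pytest.approx(1.0)

    def test_q_branch_closed_form(self):
        """b(J,K,0,0) equals the classical closed form [J(J+1)−3K²]²/[J(J+1)(2J−1)(2J+3)]."""
        for J in range(1, 30):
            for K in range(J + 1):
                closed = (J * (J + 1) - 3 * K**2) ** 2 / (
                    J * (J + 1) * (2 * J - 1) * (2 * J + 3)
                )
                assert placzek_teller_b(J, K, 0, 0) == pytest.approx(closed, abs=1e-12)
        assert placzek_teller_b(1, 0, 0, 0) == pytest.approx(0.4)

    def test_against_sympy_wigner(self):
        """Spot-check the factors against sympy's Wigner-3j on random quantum numbers."""
        from sympy.physics.wigner import wigner_3j

        rng = np.random.default_rng(3)
        for _ in range(30):
            J = int(rng.integers(0, 40))
            K = int(rng.integers(-J, J + 1)) if J else 0
            dJ = int(rng.integers(-2, 3))
            dK = int(rng.integers(-2, 3))
            Jp = J + dJ
            if Jp < 0 or abs(K + dK) > Jp:
                expected = 0.0
            else:
                expected = (2 * Jp + 1) * float(wigner_3j(J, 2, Jp, K, dK, -(K + dK))) ** 2
            assert placzek_teller_b(J, K, dJ, dK) == pytest.approx(expected, abs=1e-10)

    def test_completeness_sum_rule(self):
        """Σ_J′ b = 1 for every admissible (J, K, ΔK) up to J = 50."""
        for J in range(51):
            K = np.repeat(np.arange(J + 1), 5)
            dK_all = np.tile(np.arange(-2, 3), J + 1)
            total = np.zeros(K.size)
            for dJ in range(-2, 3):
                total += placzek_teller_b(
                    np.full(K.size, J), K, np.full(K.size, dJ), dK_all
                )
            ok = np.abs(K + dK_all) <= J + 2  # a target state exists somewhere
            assert np.allclose(total[ok], 1.0, atol=1e-9)

    def test_invalid_quantum_numbers(self):
        with pytest.raises(ValueError):
            placzek_teller_b(1, 2, 0, 0)
        with pytest.raises(ValueError):
            placzek_teller_b(1, 0, 3, 0)


class TestBuildLinelist:
    def test_polarised_band_single_line(self, toy_rotor, polarized_band):
        ll = build_linelist(polarized_band, toy_rotor, 30.0)
        assert np.allclose(ll.position, polarized_band.nu_calc)
        states, Z = rot_populations(toy_rotor, 30.0)
        cov = sum(s.weight for s in states) / Z
        assert ll.total_intensity == pytest.approx(45.0 * cov, rel=1e-12)

    def test_cold_limit_branches(self, toy_rotor, gamma_only_band):
        ll = build_linelist(gamma_only_band, toy_rotor, 0.01)
        # only (J=0,K=0) populated: Q0 plus S-branch (ΔJ=2) lines
        assert set(np.unique(ll.J)) == {0}
        assert set(np.unique(ll.dJ)) <= {0, 2}

    def test_intensity_conservation(self, toy_rotor, mixed_band):
        """Σ(lines) = coverage × (C_a a′² + C_g γ′²) — the rigid-rotor invariance."""
        inv = mixed_band.invariants
        for T in (5.0, 30.0, 100.0):
            ll = build_linelist(mixed_band, toy_rotor, T)
            states, Z = rot_populations(toy_rotor, T)
            cov = sum(s.weight for s in states) / Z
            expected = cov * (45.0 * inv.a_prime**2 + 7.0 * inv.gamma2)
            assert ll.total_intensity == pytest.approx(expected, rel=1e-9)

    def test_against_independent_sympy_loop(self, mixed_band):
        """Line intensities match an independent state-by-state Wigner-3j loop."""
        from sympy.physics.wigner import wigner_3j

        from jetraman.constants import HC_OVER_KB

        rc = RotorConstants(1.0, 0.6, 0.4)
        T = 5.0  # keeps the brute-force state count small
        inv = mixed_band.invariants
        ll = build_linelist(mixed_band, rc, T, coverage=0.9999)

        states, Z = rot_populations(rc, T, coverage=0.9999)
        g = {0: inv.gamma2_dk0, 1: inv.gamma2_dk1 / 2, -1: inv.gamma2_dk1 / 2,
             2: inv.gamma2_dk2 / 2, -2: inv.gamma2_dk2 / 2}
        brute = 0.0
        for s in states:
            p = s.weight / Z
            brute += p * 45.0 * inv.a_prime**2
            for m in (-2, -1, 0, 1, 2):
                for dJ in (-2, -1, 0, 1, 2):
                    Jp, Kp = s.J + dJ, s.K + m
                    if Jp < 0 or abs(Kp) > Jp:
                        continue
                    b = (2 * Jp + 1) * float(wigner_3j(s.J, 2, Jp, s.K, m, -Kp)) ** 2
                    brute += p * 7.0 * g[m] * b
        assert ll.total_intensity == pytest.approx(brute, rel=1e-9)

    def test_q0_lines_unshifted(self, toy_rotor, mixed_band):
        ll = build_linelist(mixed_band, toy_rotor, 30.0)
        q0 = (ll.dJ == 0) & (ll.dK == 0)
        assert np.allclose(ll.position[q0], mixed_band.nu_calc)


class TestGaussianFold:
    def _single_line(self, pos=100.0, inten=2.5):
        i = np.array([0], dtype=np.int64)
        return LineList(np.array([pos]), np.array([inten]), i, i, i, i)

    def test_single_line_peak_and_area(self):
        ll = self._single_line()
        s = gaussian_fold(ll, sigma=1.0)
        assert s.wavenumber[np.argmax(s.intensity)] == pytest.approx(100.0)
        assert s.integral() == pytest.approx(2.5, rel=1e-4)

    def test_positions_rounded_and_coadded(self):
        # two lines 0.004 cm⁻¹ apart round to the same 0.01 position
        i = np.zeros(2, dtype=np.int64)
        pair = LineList(np.array([100.001, 100.005]), np.array([1.0, 1.5]), i, i, i, i)
        j = np.zeros(1, dtype=np.int64)
        merged = LineList(np.array([100.0]), np.array([2.5]), j, j, j, j)
        a = gaussian_fold(pair, sigma=0.5)
        b = gaussian_fold(merged, sigma=0.5)
        assert np.array_equal(a.wavenumber, b.wavenumber)
        assert a.intensity == pytest.approx(b.intensity, rel=1e-12)

    def test_mass_conservation_many_lines(self):
        rng = np.random.default_rng(7)
        n = 100_000
        i = np.zeros(n, dtype=np.int64)
        ll = LineList(rng.uniform(100, 300, n), rng.exponential(1.0, n), i, i, i, i)
        s = gaussian_fold(ll, sigma=1.0)
        assert s.integral() == pytest.approx(ll.total_intensity, rel=1e-4)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            gaussian_fold(self._single_line(), sigma=0.0)


class TestSimulateConformer:
    def _spec(self, bands, name="c"):
        return ConformerSpec(name=name, rotor=RotorConstants(1.0, 0.6, 0.4), bands=bands)

    def test_polarised_band_peaks_at_center(self, polarized_band):
        s = simulate_conformer(self._spec([polarized_band]))
        assert s.wavenumber[np.argmax(s.intensity)] == pytest.approx(
            polarized_band.nu_calc, abs=0.11
        )

    def test_default_conditions_recorded(self, polarized_band):
        s = simulate_conformer(self._spec([polarized_band]))
        assert s.metadata["T_rot"] == 30.0
        assert s.metadata["sigma"] == 1.0

    def test_doubling_gamma2_doubles_anisotropic_integral(self, gamma_only_band):
        inv = gamma_only_band.invariants
        doubled = VibBand(
            label="g2",
            nu_calc=gamma_only_band.nu_calc,
            invariants=PlaczekInvariants.from_values(
                0.0,
                2 * inv.gamma2,
                (2 * inv.gamma2_dk0, 2 * inv.gamma2_dk1, 2 * inv.gamma2_dk2),
            ),
        )
        s1 = simulate_conformer(self._spec([gamma_only_band]))
        s2 = simulate_conformer(self._spec([doubled]))
        assert s2.integral() == pytest.approx(2 * s1.integral(), rel=1e-9)

    def test_missing_experimental_center_raises(self, polarized_band):
        with pytest.raises(ValueError, match="polar"):
            simulate_conformer(self._spec([polarized_band]), use_experimental_centers=True)

    def test_q0_peak_fraction_decreases_with_temperature(self, mixed_band):
        """Warming spreads intensity into rotational wings, never into the Q₀ peak."""
        spec = self._spec([mixed_band])
        fractions = []
        for T in (5.0, 15.0, 30.0, 60.0):
            s = simulate_conformer(spec, T_rot=T)
            fractions.append(s.intensity.max() / s.integral())
        assert np.all(np.diff(fractions) < 0)
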