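"""Cylinder structure-factor model, contrast decomposition, profile fitting."""

import numpy as np
import pytest

from nucleocompact import sans, synth
from nucleocompact.sans import RadialProfile, ScatteringCurve, StructureFactorModel

Q = np.linspace(0.01, 3.0, 60)
GAUSS = RadialProfile("gaussian", (5.0,))
SHELL = RadialProfile("shell", (1.0, 6.0))


class TestMomentumTransfer:
    def test_formula(self):
        got = sans.momentum_transfer(0.6, 0.1)
        assert got == pytest.approx(4 * np.pi / 0.6 * np.sin(0.05), rel=1e-12)
        assert got == pytest.approx(1.047, abs=2e-3)

    def test_small_angle_limits(self):
        assert sans.momentum_transfer(0.6, 1e-9) == pytest.approx(0.0, abs=1e-7)
        q1 = sans.momentum_transfer(0.6, 1e-4)
        q2 = sans.momentum_transfer(1.2, 1e-4)
        assert q1 / q2 == pytest.approx(2.0, rel=1e-6)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            sans.momentum_transfer(-1.0, 0.1)
        with pytest.raises(ValueError):
            sans.momentum_transfer(0.6, 4.0)


class TestAmplitudes:
    @pytest.mark.parametrize("profile", [GAUSS, SHELL], ids=["gaussian", "shell"])
    def test_normalized_at_zero(self, profile):
        assert np.asarray(profile.amplitude(np.array([1e-12])))[0] == pytest.approx(1.0, abs=1e-8)

    def test_gaussian_closed_form_value(self):
        assert sans.amplitude_gaussian(1.0, 5.0) == pytest.approx(np.exp(-6.25), rel=1e-12)

    def test_shell_reduces_to_uniform_disk(self):
        from scipy.special import j1

        q = Q
        disk = 2 * j1(q * 6.0) / (q * 6.0)
        np.testing.assert_allclose(sans.amplitude_shell(q, 0.0, 6.0), disk, rtol=1e-12)

    @pytest.mark.parametrize("profile", [GAUSS, SHELL], ids=["gaussian", "shell"])
    def test_closed_forms_match_quadrature(self, profile):
        """Hankel quadrature oracle agrees to 1e-8 relative over the q window."""
        a_closed = np.asarray(profile.amplitude(Q))
        a_num = np.asarray(sans.amplitude_numeric(profile, Q))
        assert np.all(np.abs(a_closed - a_num) <= 1e-8 * np.abs(a_num) + 1e-12)

    def test_narrow_shell_tends_to_bessel(self):
        from scipy.special import j0

        R = 4.0
        for eps, tol in ((0.5, 0.05), (0.05, 5e-4)):
            prof = RadialProfile("shell", (R - eps / 2, R + eps / 2))
            a = np.asarray(prof.amplitude(Q))
            assert np.max(np.abs(a - j0(Q * R))) < tol

    def test_amplitude_bounded_by_one(self):
        for prof in (GAUSS, SHELL):
            assert np.all(np.abs(np.asarray(prof.amplitude(Q))) <= 1.0 + 1e-12)

    def test_unnormalized_profile_rejected(self):
        with pytest.raises(ValueError):
            sans.amplitude_numeric(lambda r: np.exp(-(r**2)), np.array([0.1]))

    @pytest.mark.parametrize("profile", [GAUSS, SHELL], ids=["gaussian", "shell"])
    def test_guinier_limit_gives_cross_sectional_rg(self, profile):
        """-4 d ln a / d(q^2) -> Rg_c^2 as q -> 0, within 1%."""
        q1, q2 = 1e-3, 2e-3
        a1 = float(profile.amplitude(q1))
        a2 = float(profile.amplitude(q2))
        rg2 = -4.0 * (np.log(a2) - np.log(a1)) / (q2**2 - q1**2)
        assert rg2 == pytest.approx(sans.cross_sectional_rg(profile) ** 2, rel=0.01)


class TestStructureFactor:
    def test_asymptotic_identity(self):
        model = StructureFactorModel(SHELL, 10.0, 51.0)
        q = np.linspace(0.1, 3.0, 50)
        S = np.asarray(sans.structure_factor(model, q, warn_validity=False))
        np.testing.assert_allclose(S * q * 10.0 / np.pi, np.asarray(SHELL.amplitude(q)) ** 2, rtol=1e-12)

    def test_finite_length_normalized_to_protein_count(self):
        model = StructureFactorModel(SHELL, 10.0, 51.0, finite_length=True)
        S0 = sans.structure_factor(model, 1e-6)
        assert S0 == pytest.approx(model.n_proteins, rel=1e-6)

    def test_finite_matches_asymptotic_at_large_qL(self):
        long_rod = StructureFactorModel(SHELL, 10.0, 500.0, finite_length=True)
        asym = StructureFactorModel(SHELL, 10.0, 500.0)
        q = np.linspace(20.0 / 500.0, 0.5, 30)  # qL in [20, 250]
        Sf = np.asarray(sans.structure_factor(long_rod, q))
        Sa = np.asarray(sans.structure_factor(asym, q)) * long_rod.n_proteins / (500.0 / 10.0)
        np.testing.assert_allclose(Sf / Sa, 1.0, atol=0.05)

    def test_validity_warning_below_qL_3(self):
        model = StructureFactorModel(SHELL, 10.0, 51.0)
        with pytest.warns(UserWarning):
            sans.structure_factor(model, np.array([0.01]))

    def test_rod_factor_limits(self):
        assert sans.rod_factor(1e-10) == pytest.approx(1.0)
        x = 1e4
        assert sans.rod_factor(x) == pytest.approx(np.pi / x, rel=1e-3)


class TestContrastDecomposition:
    def test_noise_free_recovery_is_exact(self):
        curves, truth = synth.gen_sans_dataset(SHELL, 10.0, 51.0, noise_pct=0.0, seed=0)
        res = sans.decompose_contrasts(curves)
        np.testing.assert_allclose(res.S_protein, truth["S_protein"], rtol=1e-9)
        np.testing.assert_allclose(res.S_dna, truth["S_dna"], rtol=1e-9)

    def test_match_point_curves_lack_the_matched_component(self):
        curves, truth = synth.gen_sans_dataset(SHELL, 10.0, 51.0, noise_pct=0.0, seed=0)
        by_f = {c.d2o_fraction: c for c in curves}
        cp, cd = sans.contrast_coefficients(0.40)
        assert cp == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(by_f[0.40].I, cd**2 * truth["S_dna"], rtol=1e-12)
        cp, cd = sans.contrast_coefficients(0.64)
        assert cd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(by_f[0.64].I, cp**2 * truth["S_protein"], rtol=1e-12)

    def test_noisy_recovery_unbiased(self):
        errs = []
        for s in range(20):
            curves, truth = synth.gen_sans_dataset(SHELL, 10.0, 51.0, noise_pct=5.0, seed=400 + s)
            res = sans.decompose_contrasts(curves)
            errs.append((res.S_protein - truth["S_protein"]) / truth["S_protein"])
        mean_rel = np.mean(errs, axis=0)
        # bias of the per-q estimates well below the 5% noise level
        assert np.median(np.abs(mean_rel)) < 0.02

    def test_degenerate_designs_rejected(self):
        curves, _ = synth.gen_sans_dataset(SHELL, 10.0, 51.0, noise_pct=0.0, seed=0)
        with pytest.raises(ValueError):
            sans.decompose_contrasts(curves[:2])
        with pytest.raises(ValueError):
            sans.decompose_contrasts([curves[0], curves[0], curves[1]])


class TestProfileFit:
    def test_noise_free_shell_recovered_exactly(self):
        curves, _ = synth.gen_sans_dataset(SHELL, 10.0, 51.0, noise_pct=0.0, seed=0)
        dec = sans.decompose_contrasts(curves)
        curve = ScatteringCurve(curves[0].q, dec.S_protein, np.maximum(dec.stderr_protein, 1e-12))
        res = sans.fit_profile(curve, "shell", fixed={"r_1": 1.0})
        assert res.profile.params[1] == pytest.approx(6.0, abs=1e-5)
        assert res.interspersion_nm == pytest.approx(10.0, abs=1e-5)

    def test_noise_free_gaussian_recovered_exactly(self):
        curves, _ = synth.gen_sans_dataset(GAUSS, 10.0, 51.0, noise_pct=0.0, seed=0)
        dec = sans.decompose_contrasts(curves)
        curve = ScatteringCurve(curves[0].q, dec.S_protein, np.maximum(dec.stderr_protein, 1e-12))
        res = sans.fit_profile(curve, "gaussian")
        assert res.profile.params[0] == pytest.approx(5.0, abs=1e-5)

    def test_noisy_shell_recovery_within_reported_uncertainties(self):
        """r2 within 0.5 nm and interspersion within 1 nm for most noisy repeats."""
        hits = 0
        n = 15
        for s in range(n):
            curves, _ = synth.gen_sans_dataset(SHELL, 10.0, 51.0, noise_pct=5.0, seed=800 + s)
            dec = sans.decompose_contrasts(curves)
            res = sans.fit_profile(
                ScatteringCurve(curves[0].q, dec.S_protein, dec.stderr_protein),
                "shell",
                fixed={"r_1": 1.0},
            )
            if abs(res.profile.params[1] - 6.0) <= 0.5 and abs(res.interspersion_nm - 10.0) <= 1.0:
                hits += 1
        assert hits >= round(0.9 * n)

    def test_cross_sectional_rg_values(self):
        assert sans.cross_sectional_rg(GAUSS) == pytest.approx(5.0, rel=1e-12)
        assert sans.cross_sectional_rg(SHELL) == pytest.approx(np.sqrt(18.5), rel=1e-12)
        assert sans.cross_sectional_rg(RadialProfile("shell", (0.0, 3.0))) == pytest.approx(
            3.0 / np.sqrt(2), rel=1e-12
        )

    def test_too_few_points_rejected(self):
        q = np.linspace(0.2, 0.3, 5)
        c = ScatteringCurve(q, np.ones(5), np.ones(5) * 0.1)
        with pytest.raises(ValueError):
            sans.fit_profile(c, "shell")
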