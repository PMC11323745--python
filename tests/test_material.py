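"""Ogden material law: closed form, grading, 3D stress and tangent."""

import numpy as np
import pytest
from scipy.optimize import brentq

from sclerapuff.material import (
    OgdenMaterial,
    cauchy_from_pk2,
    graded_mu,
    stress_and_tangent,
    uniaxial_cauchy_stress,
)


@pytest.fixture(scope="module")
def mat():
    return OgdenMaterial(mu=0.083, alpha=40.0)


class TestUniaxialClosedForm:
    def test_zero_at_unit_stretch(self, mat):
        assert uniaxial_cauchy_stress(mat, 1.0) == 0.0

    def test_scalar_value(self, mat):
        # direct evaluation: 0.083 * (1.02**40 - 1.02**-20)
        expected = 0.083 * (1.02**40 - 1.02 ** (-20))
        assert uniaxial_cauchy_stress(mat, 1.02) == pytest.approx(expected)
        assert expected == pytest.approx(0.1274, abs=2e-4)

    def test_strictly_increasing(self, mat):
        lams = np.linspace(0.8, 1.1, 200)
        sig = uniaxial_cauchy_stress(mat, lams)
        assert np.all(np.diff(sig) > 0)

    def test_rejects_nonpositive_stretch(self, mat):
        with pytest.raises(ValueError):
            uniaxial_cauchy_stress(mat, 0.0)

    def test_invalid_material(self):
        with pytest.raises(ValueError):
            OgdenMaterial(mu=-1.0)
        with pytest.raises(ValueError):
            OgdenMaterial(mu=0.1, alpha=0.0)


class TestGradedMu:
    @pytest.mark.parametrize(
        "x,expected",
        [(0.0, 0.10), (9.0, 0.05), (4.5, 0.075), (-3.0, 0.10)],
    )
    def test_linear_grading(self, x, expected):
        # mu=0.10, mu_post=0.05, x_f=9: equator, pole, midpoint, anterior clamp
        assert graded_mu(x, 9.0, 0.10, 0.05) == pytest.approx(expected)

    def test_degenerate_geometry(self):
        with pytest.raises(ValueError):
            graded_mu(1.0, 0.0, 0.1, 0.05)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            graded_mu(1.0, 9.0, 0.05, 0.10)

    def test_band_clipping(self):
        xs = np.linspace(-5, 15, 50)
        mus = graded_mu(xs, 9.0, 0.10, 0.05)
        assert np.all(mus >= 0.05 - 1e-15) and np.all(mus <= 0.10 + 1e-15)


class TestStress3D:
    def test_identity_gives_zero_stress(self, mat):
        S, _ = stress_and_tangent(np.eye(3)[None], np.array([mat.mu]), 40.0)
        assert np.abs(S).max() < 1e-12

    def test_uniaxial_equivalence(self, mat):
        """With the lateral stretch solved for zero transverse stress, the
        3D law reproduces the incompressible uniaxial closed form to <0.5%
        (the residual is the volumetric-penalty leakage)."""
        lam = 1.02

        def transverse(lt):
            F = np.diag([lam, lt, lt])
            S, _ = stress_and_tangent(
                F[None], np.array([mat.mu]), 40.0, np.array([mat.kappa]),
                want_tangent=False,
            )
            return cauchy_from_pk2(F[None], S)[0, 1, 1]

        lt = brentq(transverse, 0.9 * lam**-0.5, 1.1 * lam**-0.5, xtol=1e-14)
        assert lt == pytest.approx(lam**-0.5, rel=1e-3)  # near-isochoric
        F = np.diag([lam, lt, lt])
        S, _ = stress_and_tangent(
            F[None], np.array([mat.mu]), 40.0, np.array([mat.kappa]),
            want_tangent=False,
        )
        sig_ax = cauchy_from_pk2(F[None], S)[0, 0, 0]
        assert sig_ax == pytest.approx(uniaxial_cauchy_stress(mat, lam), rel=5e-3)

    def test_small_strain_shear_modulus(self, mat):
        """Numeric differentiation of simple shear recovers G = mu*alpha/2."""
        g = 1e-6
        F = np.eye(3)
        F[0, 1] = g
        S, _ = stress_and_tangent(
            F[None], np.array([mat.mu]), 40.0, np.array([mat.kappa]),
            want_tangent=False,
        )
        sig = cauchy_from_pk2(F[None], S)[0]
        G = sig[0, 1] / g
        assert G == pytest.approx(mat.small_strain_shear_modulus, rel=1e-4)
        assert mat.small_strain_shear_modulus == pytest.approx(1.66, abs=0.01)

    def test_element_inversion_detected(self, mat):
        F = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(FloatingPointError):
            stress_and_tangent(F[None], np.array([mat.mu]), 40.0)

    def test_odd_alpha_rejected_in_3d(self, mat):
        with pytest.raises(ValueError):
            stress_and_tangent(np.eye(3)[None], np.array([0.1]), 39.0)


class TestTangentConsistency:
    def test_fd_match_on_random_deformations(self, rng):
        """Analytic tangent vs central finite differences of S(C), to 1e-6
        relative, on random admissible deformation gradients."""
        mu = np.array([0.083])
        kap = np.array([0.083 * 40 * 1e3])
        worst = 0.0
        for _ in range(5):
            F = np.eye(3) + 0.03 * rng.standard_normal((3, 3))
            if np.linalg.det(F) <= 0.5:
                continue
            C = F.T @ F
            _, DD = stress_and_tangent(F[None], mu, 40.0, kap)
            h = 1e-7
            for k in range(3):
                for l in range(k, 3):
                    dC = np.zeros((3, 3))
                    dC[k, l] += h / 2
                    dC[l, k] += h / 2
                    Fp = np.linalg.cholesky(C + dC).T
                    Fm = np.linalg.cholesky(C - dC).T
                    Sp, _ = stress_and_tangent(Fp[None], mu, 40.0, kap,
                                               want_tangent=False)
                    Sm, _ = stress_and_tangent(Fm[None], mu, 40.0, kap,
                                               want_tangent=False)
                    fd = (Sp[0] - Sm[0]) / h  # = DD : sym(e_kl) (dE = dC/2)
                    an = 0.5 * (DD[0][:, :, k, l] + DD[0][:, :, l, k])
                    worst = max(worst, np.abs(fd - an).max() / np.abs(DD).max())
        assert worst < 1e-6

    def test_frame_indifference(self, rng):
        """S(QF) = S(F): PK2 stress depends on F only through C."""
        mu = np.array([0.083])
        F = np.eye(3) + 0.02 * rng.standard_normal((3, 3))
        A = rng.standard_normal((3, 3))
        Q = np.linalg.qr(A)[0]
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        S1, _ = stress_and_tangent(F[None], mu, 40.0, want_tangent=False)
        S2, _ = stress_and_tangent((Q @ F)[None], mu, 40.0, want_tangent=False)
        np.testing.assert_allclose(S1, S2, rtol=1e-10, atol=1e-14)
        # and the Cauchy stress rotates accordingly
        sig1 = cauchy_from_pk2(F[None], S1)[0]
        sig2 = cauchy_from_pk2((Q @ F)[None], S2)[0]
        np.testing.assert_allclose(Q @ sig1 @ Q.T, sig2, rtol=1e-9, atol=1e-12)
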