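"""One-term Ogden hyperelasticity with linear axial stiffness grading.

The sclera is modelled as an isotropic, nearly incompressible one-term Ogden
solid.  Under incompressible uniaxial tension the law reduces to the closed
form

    sigma(lambda) = mu * (lambda**alpha - lambda**(-alpha/2))

with a fixed curve-shape exponent ``alpha`` (default 40, chosen to match the
steep strain stiffening of scleral tissue) and a magnitude coefficient ``mu``
in MPa.  Spatial variation is a linear decrease of ``mu`` from the equator
(``mu``) to the posterior pole (``mu_post``); anterior of the equator the
coefficient is held at the equatorial value.

The 3D stress and consistent tangent are derived from the strain energy

    W(C) = (mu/alpha) * (J**(-alpha/3) * tr(C**(alpha/2)) - 3)
           + (kappa/2) * (J - 1)**2

For even integer ``alpha`` the sum of principal-stretch powers equals the
trace of an integer matrix power of C, so both the second Piola-Kirchhoff
stress and the material tangent are polynomial in C and fully analytic —
no eigendecomposition and no special-casing of repeated stretches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OgdenMaterial",
    "MaterialField",
    "uniaxial_cauchy_stress",
    "graded_mu",
    "stress_and_tangent",
    "cauchy_from_pk2",
]

#: default ratio kappa / (mu * alpha) enforcing near-incompressibility
DEFAULT_KAPPA_RATIO = 1.0e3


@dataclass(frozen=True)
class OgdenMaterial:
    """One-term Ogden material point.

    Parameters
    ----------
    mu : float
        Magnitude coefficient, MPa.
    alpha : float
        Curve-shape exponent (dimensionless).  The 3D solver path requires
        an even positive integer; the uniaxial closed form does not.
    kappa : float or None
        Numerical bulk modulus, MPa.  Defaults to ``DEFAULT_KAPPA_RATIO *
        mu * alpha``; a solver parameter, not a tissue property.
    """

    mu: float
    alpha: float = 40.0
    kappa: float | None = None

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.kappa is None:
            object.__setattr__(self, "kappa", DEFAULT_KAPPA_RATIO * self.mu * self.alpha)
        if self.kappa < 10.0 * self.mu * self.alpha:
            raise ValueError("kappa must dominate mu*alpha for near-incompressibility")

    @property
    def small_strain_shear_modulus(self) -> float:
        """mu*alpha/2, the shear modulus of the linearised law, MPa."""
        return 0.5 * self.mu * self.alpha


def uniaxial_cauchy_stress(mat: OgdenMaterial, lam) -> np.ndarray | float:
    """Incompressible uniaxial Cauchy stress ``mu*(lam**a - lam**(-a/2))``.

    ``lam`` is the axial stretch ratio (strain + 1); scalar or array.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch ratio must be positive")
    a = mat.alpha
    out = mat.mu * (lam**a - lam ** (-a / 2.0))
    return out if out.ndim else float(out)


def graded_mu(x, x_f: float, mu: float, mu_post: float):
    """Linear axial grading mu(x) = mu - (mu - mu_post) * x / x_f.

    ``x`` is the signed axial distance from the equator toward the posterior
    pole (mm); ``x_f`` the distance from equator to the most posterior
    scleral point.  Anterior of the equator (x < 0) the coefficient is
    clamped at the equatorial ``mu``; values are clipped to
    [mu_post, mu] so round-off never leaves the admissible band.
    """
    if x_f <= 0:
        raise ValueError("x_f must be positive (degenerate geometry)")
    if mu_post > mu:
        raise ValueError("mu_post must not exceed mu")
    x = np.asarray(x, dtype=float)
    frac = np.clip(x / x_f, 0.0, 1.0)
    out = mu - (mu - mu_post) * frac
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# 3D stress and tangent (batched over leading axes)
# ---------------------------------------------------------------------------


def _matrix_powers(C: np.ndarray, n: int) -> list[np.ndarray]:
    """[C^0, C^1, ..., C^n] for batched 3x3 symmetric C."""
    eye = np.broadcast_to(np.eye(3), C.shape).copy()
    powers = [eye]
    for _ in range(n):
        powers.append(powers[-1] @ C)
    return powers


def _dpow_dC(powers: list[np.ndarray], p: int) -> np.ndarray:
    """d(C^p)/dC as a (..,3,3,3,3) tensor with minor symmetries.

    d(C^p)_ij/dC_kl = sum_{m=0}^{p-1} sym_kl[(C^m)_ik (C^{p-1-m})_lj]

    All p terms are outer products of matrix powers, so the sum collapses
    into one batched (9, p) x (p, 9) product M_abcd = sum_m (C^m)_ab
    (C^{p-1-m})_cd, of which the two symmetrised terms are re-indexings.
    """
    batch = powers[0].shape[:-2]
    if p == 0:
        return np.zeros(batch + (3, 3, 3, 3))
    A = np.stack(powers[:p], axis=-1).reshape(batch + (9, p))
    B = np.stack(powers[p - 1 :: -1], axis=-3).reshape(batch + (p, 9))
    M = (A @ B).reshape(batch + (3, 3, 3, 3))  # M[a,b,c,d]
    nb = len(batch)
    t1 = M.transpose(*range(nb), nb, nb + 3, nb + 1, nb + 2)  # A_ik B_lj
    t2 = M.transpose(*range(nb), nb, nb + 3, nb + 2, nb + 1)  # A_il B_kj
    return 0.5 * (t1 + t2)


def stress_and_tangent(
    F: np.ndarray, mu, alpha: float = 40.0, kappa=None, want_tangent: bool = True
):
    """Second Piola-Kirchhoff stress and material tangent of the Ogden law.

    Parameters
    ----------
    F : (..., 3, 3) array
        Deformation gradients; ``det F`` must be positive.
    mu : float or (...) array
        Material coefficient per point, MPa.
    alpha : float
        Even positive integer exponent.
    kappa : float or (...) array, optional
        Bulk penalty modulus; default ``DEFAULT_KAPPA_RATIO * mu * alpha``.

    Returns
    -------
    S : (..., 3, 3)
        Second Piola-Kirchhoff stress, MPa.
    DD : (..., 3, 3, 3, 3) or None
        Material tangent dS/dE = 2 dS/dC (minor-symmetric).
    """
    n2 = alpha / 2.0
    n = int(round(n2))
    if abs(n2 - n) > 1e-12 or n < 1:
        raise ValueError("3D Ogden path requires an even positive integer alpha")
    F = np.asarray(F, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if kappa is None:
        kappa = DEFAULT_KAPPA_RATIO * mu * alpha
    kappa = np.asarray(kappa, dtype=float)

    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise FloatingPointError("element inversion: non-positive deformation Jacobian")
    C = np.einsum("...ji,...jk->...ik", F, F)
    powers = _matrix_powers(C, n)
    Cn1 = powers[n - 1]  # C^{n-1}
    In = np.einsum("...ii->...", powers[n])  # tr C^n = sum lambda_i^alpha
    Ci = np.linalg.inv(C)
    c = J ** (-alpha / 3.0)

    mu_ = mu[..., None, None]
    k_ = kappa[..., None, None]
    c_ = c[..., None, None]
    In_ = In[..., None, None]
    J_ = J[..., None, None]

    dev = Cn1 - (In_ / 3.0) * Ci
    S = mu_ * c_ * dev + k_ * (J_ - 1.0) * J_ * Ci

    if not want_tangent:
        return S, None

    # dCi/dC (minor-symmetrised)
    Bt = -0.5 * (
        np.einsum("...ik,...jl->...ijkl", Ci, Ci)
        + np.einsum("...il,...jk->...ijkl", Ci, Ci)
    )
    At = _dpow_dC(powers, n - 1) if n >= 2 else np.zeros(C.shape + (3, 3))

    mu4 = mu_[..., None, None]
    k4 = k_[..., None, None]
    c4 = c_[..., None, None]
    In4 = In_[..., None, None]
    J4 = J_[..., None, None]

    dS = np.zeros(C.shape + (3, 3))
    # iso part: d(mu c dev)/dC
    dS += mu4 * (-alpha / 6.0) * c4 * np.einsum("...ij,...kl->...ijkl", dev, Ci)
    dS += mu4 * c4 * (
        At
        - (n / 3.0) * np.einsum("...ij,...kl->...ijkl", Ci, Cn1)
        - (In4 / 3.0) * Bt
    )
    # volumetric part: d(k (J-1) J Ci)/dC
    dS += k4 * (2.0 * J4 - 1.0) * (J4 / 2.0) * np.einsum(
        "...ij,...kl->...ijkl", Ci, Ci
    )
    dS += k4 * (J4 - 1.0) * J4 * Bt

    return S, 2.0 * dS


def cauchy_from_pk2(F: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Push-forward sigma = F S F^T / J."""
    J = np.linalg.det(F)
    return np.einsum("...iI,...IJ,...jJ->...ij", F, S, F) / J[..., None, None]


@dataclass
class MaterialField:
    """Per-element Ogden coefficients for a meshed globe.

    ``mu_elem`` holds the graded coefficient per element (scleral elements
    follow the axial grading; corneal elements use ``mu_cornea``).
    """

    mu_equator: float
    mu_post: float
    mu_elem: np.ndarray
    alpha: float = 40.0
    mu_cornea: float = 0.083
    kappa_ratio: float = DEFAULT_KAPPA_RATIO
    region: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.mu_post > self.mu_equator:
            raise ValueError("mu_post must not exceed mu_equator")
        lo = min(self.mu_post, self.mu_cornea) - 1e-12
        hi = max(self.mu_equator, self.mu_cornea) + 1e-12
        if np.any(self.mu_elem < lo) or np.any(self.mu_elem > hi):
            raise ValueError("per-element mu outside [mu_post, mu_equator] band")

    @property
    def kappa_elem(self) -> np.ndarray:
        return self.kappa_ratio * self.mu_elem * self.alpha

    @classmethod
    def from_mesh(
        cls,
        mesh,
        mu: float,
        mu_post: float | None = None,
        alpha: float = 40.0,
        mu_cornea: float | None = None,
        kappa_ratio: float = DEFAULT_KAPPA_RATIO,
    ) -> "MaterialField":
        """Grade ``mu`` along the axial coordinate of ``mesh`` (Eq.-style
        linear law), assigning ``mu_cornea`` to corneal elements."""
        from .geometry import compute_axial_coordinates

        if mu_post is None:
            mu_post = mu
        if mu_cornea is None:
            mu_cornea = mu
        axmap = compute_axial_coordinates(mesh)
        mu_elem = np.asarray(
            graded_mu(axmap.x, axmap.x_f, mu, mu_post), dtype=float
        ).copy()
        mu_elem[mesh.region == 1] = mu_cornea
        return cls(
            mu_equator=mu,
            mu_post=mu_post,
            mu_elem=mu_elem,
            alpha=alpha,
            mu_cornea=mu_cornea,
            kappa_ratio=kappa_ratio,
            region=mesh.region,
        )
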