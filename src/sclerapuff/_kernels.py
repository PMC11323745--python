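"""Compiled inner loops for the residual evaluation.

The Newton solver spends most of its iterations on residual-only
evaluations (the tangent is reused while the residual contracts), so the
internal-force kernel is compiled with numba.  The numpy implementation in
:mod:`sclerapuff.fe` remains the reference path and is used automatically
if numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap(a[0]) if a and callable(a[0]) else wrap


@njit(cache=True)
def fint_kernel(gradN, wdet, ue, mu, kap, n):
    """Internal nodal forces of the Ogden solid (S-only path).

    gradN: (E, G, A, 3) reference shape gradients; wdet: (E, G) weights;
    ue: (E, A, 3) nodal displacements; mu/kap: (E, G); n = alpha/2.
    Returns (fint (E, A, 3), min detF) — a non-positive determinant flags
    element inversion to the caller.
    """
    ne, ng, na, _ = gradN.shape
    fint = np.zeros((ne, na, 3))
    alpha = 2.0 * n
    mindet = 1.0e30
    F = np.empty((3, 3))
    C = np.empty((3, 3))
    Ci = np.empty((3, 3))
    Pm = np.empty((3, 3))  # C^(n-1)
    Pc = np.empty((3, 3))  # running power
    Pn = np.empty((3, 3))
    S = np.empty((3, 3))
    P1 = np.empty((3, 3))
    for e in range(ne):
        for g in range(ng):
            for i in range(3):
                for j in range(3):
                    s = 1.0 if i == j else 0.0
                    for a in range(na):
                        s += ue[e, a, i] * gradN[e, g, a, j]
                    F[i, j] = s
            detF = (
                F[0, 0] * (F[1, 1] * F[2, 2] - F[1, 2] * F[2, 1])
                - F[0, 1] * (F[1, 0] * F[2, 2] - F[1, 2] * F[2, 0])
                + F[0, 2] * (F[1, 0] * F[2, 1] - F[1, 1] * F[2, 0])
            )
            if detF < mindet:
                mindet = detF
            if detF <= 0.0:
                return fint, mindet
            for i in range(3):
                for j in range(3):
                    s = 0.0
                    for k in range(3):
                        s += F[k, i] * F[k, j]
                    C[i, j] = s
            # C^(n-1) and C^n by repeated multiplication
            for i in range(3):
                for j in range(3):
                    Pc[i, j] = 1.0 if i == j else 0.0
            for _p in range(n - 1):
                for i in range(3):
                    for j in range(3):
                        s = 0.0
                        for k in range(3):
                            s += Pc[i, k] * C[k, j]
                        Pn[i, j] = s
                for i in range(3):
                    for j in range(3):
                        Pc[i, j] = Pn[i, j]
            for i in range(3):
                for j in range(3):
                    Pm[i, j] = Pc[i, j]  # C^(n-1)
            trn = 0.0
            for i in range(3):
                s = 0.0
                for k in range(3):
                    s += Pm[i, k] * C[k, i]
                trn += s  # tr C^n
            detC = detF * detF
            # inverse of C via adjugate
            Ci[0, 0] = (C[1, 1] * C[2, 2] - C[1, 2] * C[2, 1]) / detC
            Ci[0, 1] = (C[0, 2] * C[2, 1] - C[0, 1] * C[2, 2]) / detC
            Ci[0, 2] = (C[0, 1] * C[1, 2] - C[0, 2] * C[1, 1]) / detC
            Ci[1, 0] = Ci[0, 1]
            Ci[1, 1] = (C[0, 0] * C[2, 2] - C[0, 2] * C[2, 0]) / detC
            Ci[1, 2] = (C[0, 2] * C[1, 0] - C[0, 0] * C[1, 2]) / detC
            Ci[2, 0] = Ci[0, 2]
            Ci[2, 1] = Ci[1, 2]
            Ci[2, 2] = (C[0, 0] * C[1, 1] - C[0, 1] * C[1, 0]) / detC
            c = detF ** (-alpha / 3.0)
            m_ = mu[e, g]
            k_ = kap[e, g]
            vol = k_ * (detF - 1.0) * detF
            for i in range(3):
                for j in range(3):
                    S[i, j] = (
                        m_ * c * (Pm[i, j] - trn / 3.0 * Ci[i, j])
                        + vol * Ci[i, j]
                    )
            # P1 = F S (first Piola-Kirchhoff)
            for i in range(3):
                for j in range(3):
                    s = 0.0
                    for k in range(3):
                        s += F[i, k] * S[k, j]
                    P1[i, j] = s
            w = wdet[e, g]
            for a in range(na):
                for i in range(3):
                    s = 0.0
                    for j in range(3):
                        s += P1[i, j] * gradN[e, g, a, j]
                    fint[e, a, i] += w * s
    return fint, mindet
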