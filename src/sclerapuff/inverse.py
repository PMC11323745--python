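"""Inverse estimation of the scleral material coefficient.

Given a measured apex displacement at the reference IOP of 10 mmHg, the
single unknown mu is found by bounded scalar minimisation (golden-section
search with parabolic interpolation — scipy's bounded Brent, the same
contract as MATLAB's fminbnd) of

    f_apex(mu) = (AD_sim(mu; IOP=10) - AD_meas(IOP=10))^2

over mu in [0.05, 0.15] MPa.  The fitted model then predicts AD at 15, 20
and 25 mmHg, reusing the stress-free geometry derived at 10 mmHg
(``fixed_at_reference`` mode: only the 10-mmHg state is anchored to the
measurement), and the prediction error is summarised as an RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .airpuff import AirPuffProfile
from .fe import BoundaryConditions, SolverConfig, SolverError
from .geometry import GlobeParams
from .material import MaterialField
from .pipeline import DEFAULT_RESOLUTION, cached_mesh, run_forward
from .prestress import stress_free_iterate

__all__ = ["ADvsIOPCurve", "InverseResult", "f_apex", "estimate_mu", "rmse"]

#: penalty returned by f_apex when the forward solve fails (keeps the
#: bounded search well-defined)
FAILURE_PENALTY = 1.0e6


@dataclass
class ADvsIOPCurve:
    """Measured (or synthetic) apex displacement vs IOP for one site."""

    iop_mmhg: np.ndarray
    ad_mm: np.ndarray
    location: str = "S"
    eye: str = "eye1"

    def __post_init__(self):
        self.iop_mmhg = np.asarray(self.iop_mmhg, dtype=float)
        self.ad_mm = np.asarray(self.ad_mm, dtype=float)
        if self.iop_mmhg.shape != self.ad_mm.shape:
            raise ValueError("iop and ad arrays must have equal length")
        if np.any(np.diff(self.iop_mmhg) <= 0):
            raise ValueError("IOP values must be strictly increasing")
        if np.any(self.ad_mm <= 0):
            raise ValueError("AD values must be positive")

    def ad_at(self, iop: float) -> float:
        i = np.where(np.isclose(self.iop_mmhg, iop))[0]
        if i.size == 0:
            raise KeyError(f"no AD entry at IOP = {iop} mmHg")
        return float(self.ad_mm[i[0]])


@dataclass
class InverseResult:
    mu: float
    objective: float
    predicted: dict  # IOP -> AD, mm
    rmse: float | None
    trace: list = field(default_factory=list)  # (mu, f_apex) evaluations
    boundary_warning: bool = False
    location: str = ""
    eye: str = ""


def rmse(predicted, measured) -> float:
    """Root-mean-square difference of two paired sequences (paired by IOP)."""
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape or predicted.size == 0:
        raise ValueError("predicted and measured must have equal nonzero length")
    return float(np.sqrt(np.mean((predicted - measured) ** 2)))


def f_apex(
    mu: float,
    target_ad: float,
    globe: GlobeParams | None = None,
    resolution: int = DEFAULT_RESOLUTION,
    cfg: SolverConfig | None = None,
    puff: AirPuffProfile | None = None,
    reference_iop: float = 10.0,
    trace: list | None = None,
    ad_cache: dict | None = None,
) -> float:
    """Squared mismatch of simulated vs target AD at the reference IOP.

    Solver failures return a large finite penalty rather than raising, so
    the bounded minimiser always completes.  ``ad_cache`` memoises the
    simulated AD by (rounded) mu across calls: the forward model is
    deterministic and different fitting targets probe overlapping mu.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    key = round(float(mu), 10)
    if ad_cache is not None and key in ad_cache:
        ad_sim = ad_cache[key]  # may be None: a cached solver failure
    else:
        try:
            res = run_forward(
                globe=globe, mu=float(mu), mu_post=float(mu),
                iop_mmhg=reference_iop, puff=puff, resolution=resolution,
                cfg=cfg,
            )
            ad_sim = res.outputs.ad
        except (SolverError, FloatingPointError, ValueError) as exc:
            import warnings

            warnings.warn(f"forward solve failed at mu={mu:.5f}: {exc}")
            ad_sim = None
        if ad_cache is not None:
            ad_cache[key] = ad_sim
    val = FAILURE_PENALTY if ad_sim is None else (ad_sim - target_ad) ** 2
    if trace is not None:
        trace.append((float(mu), float(val)))
    return float(val)


def estimate_mu(
    curve: ADvsIOPCurve,
    bounds: tuple = (0.05, 0.15),
    globe: GlobeParams | None = None,
    resolution: int = DEFAULT_RESOLUTION,
    cfg: SolverConfig | None = None,
    puff: AirPuffProfile | None = None,
    reference_iop: float = 10.0,
    xatol: float = 1.0e-4,
    predict_iops: tuple = (15.0, 20.0, 25.0),
    ad_cache: dict | None = None,
) -> InverseResult:
    """Fit mu to the reference-IOP AD, then predict the rest of the curve.

    The prediction solves reuse the stress-free geometry derived at the
    reference IOP with the fitted mu; RMSE is computed over whichever of
    ``predict_iops`` appear in the curve.  ``ad_cache`` (a plain dict)
    memoises simulated AD by mu across calls — the forward model is
    deterministic, and different sites probe overlapping mu values.
    """
    target = curve.ad_at(reference_iop)  # KeyError if absent
    trace: list = []
    cache: dict = {}

    def obj(m: float) -> float:
        key = round(float(m), 10)
        if key not in cache:
            cache[key] = f_apex(
                m, target, globe=globe, resolution=resolution, cfg=cfg,
                puff=puff, reference_iop=reference_iop, trace=trace,
                ad_cache=ad_cache,
            )
        return cache[key]

    opt = minimize_scalar(obj, bounds=bounds, method="bounded",
                          options={"xatol": xatol})
    mu_hat = float(opt.x)
    boundary = min(mu_hat - bounds[0], bounds[1] - mu_hat) < 4 * xatol

    # fixed-at-reference predictions with the fitted coefficient
    globe_ = globe or GlobeParams()
    mesh = cached_mesh(globe_, resolution)
    fieldm = MaterialField.from_mesh(mesh, mu=mu_hat, mu_post=mu_hat)
    bcs = BoundaryConditions.from_mesh(mesh)
    state = stress_free_iterate(mesh, fieldm, bcs, reference_iop, cfg=cfg)
    predicted = {}
    for iop in predict_iops:
        res = run_forward(
            globe=globe_, mu=mu_hat, mu_post=mu_hat, iop_mmhg=float(iop),
            puff=puff, resolution=resolution, cfg=cfg,
            stress_free_state=state, mesh=mesh,
        )
        predicted[float(iop)] = res.outputs.ad
    have = [i for i in predict_iops if np.any(np.isclose(curve.iop_mmhg, i))]
    err = (
        rmse([predicted[i] for i in have], [curve.ad_at(i) for i in have])
        if have
        else None
    )
    return InverseResult(
        mu=mu_hat,
        objective=float(opt.fun),
        predicted=predicted,
        rmse=err,
        trace=trace,
        boundary_warning=bool(boundary),
        location=curve.location,
        eye=curve.eye,
    )
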