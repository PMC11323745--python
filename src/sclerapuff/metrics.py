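"""Deformation output parameters from sagittal surface profiles.

The analysis mirrors how an air-puff OCT B-scan is read: the outer surface
is traced in the sagittal section, the most anterior point of the scanned
region (the local "scleral apex", which is also the puff centre) defines
the lateral origin x = 0, and surface heights are compared between the
pre-puff (Y) and peak-load (y) states at the fixed lateral stations
x = -2, 0, +2 mm.  Positive x points toward the posterior pole.  From the
three height drops the outputs are

    AD  = Y0 - y0                      apex displacement, mm
    CPR = (Y0 - y0) / (Y2 - y2)        central-peripheral ratio
    AR  = (Y2 - y2) / (Y-2 - y-2)      asymmetry ratio

Sampling is Eulerian (fixed lab-frame x, as a B-scan column), with
monotone cubic (PCHIP) interpolation along the traced curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .fe import Solution

__all__ = [
    "SagittalProfile",
    "OutputParams",
    "UndefinedRatioError",
    "extract_sagittal_profile",
    "displacement_at_x",
    "compute_output_params",
    "read_profile_csv",
]


class ProfileResolutionError(ValueError):
    """Too few surface nodes across the scan window."""


class UndefinedRatioError(ValueError):
    """A ratio denominator fell below the reporting threshold."""


@dataclass
class SagittalProfile:
    """Ordered outer-surface curve in the scan frame (x, height), mm."""

    x: np.ndarray
    y: np.ndarray
    apex_x_global: float = float("nan")  # lab-frame axial station of x = 0

    def __post_init__(self):
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("profile x stations must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("profile contains non-finite values")
        if self.x[0] > -2.0 or self.x[-1] < 2.0:
            raise ProfileResolutionError("profile must cover [-2, +2] mm")
        if np.count_nonzero((self.x >= -2.0) & (self.x <= 2.0)) < 5:
            raise ProfileResolutionError("fewer than 5 nodes across [-2, 2] mm")

    def interpolator(self) -> PchipInterpolator:
        return PchipInterpolator(self.x, self.y, extrapolate=False)

    def height(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if np.any(x < self.x[0]) or np.any(x > self.x[-1]):
            raise ValueError("height requested outside the profile range")
        return self.interpolator()(x)


@dataclass
class OutputParams:
    """The three deformation outputs plus the six sampled heights (mm)."""

    ad: float
    cpr: float
    ar: float
    heights: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {"AD": self.ad, "CPR": self.cpr, "AR": self.ar}
        out.update(self.heights)
        return out


def _sagittal_outer_nodes(mesh) -> np.ndarray:
    outer = np.unique(mesh.face_sets["outer_surface"])
    sag = mesh.node_sets["sagittal_section"]
    return np.intersect1d(outer, sag)


def extract_sagittal_profile(
    mesh,
    solution: Solution,
    step: int = -1,
    apex_x_global: float | None = None,
    window: float = 5.0,
) -> SagittalProfile:
    """Outer-surface sagittal curve of one solution step, in the scan frame.

    The apex (x = 0) is the lab-frame axial station of maximum height; pass
    ``apex_x_global`` (from the pre-puff profile) to pin the frame of a
    deformed state to the same lab-frame origin.  ``window`` limits the
    curve to |x| <= window mm around the apex.
    """
    if not solution.converged[step]:
        raise ValueError(f"solution step {step} did not converge")
    ids = _sagittal_outer_nodes(mesh)
    pos = solution.positions[step][ids]
    order = np.argsort(-pos[:, 0])  # scan x runs opposite the global axis
    gx, gy = pos[order, 0], pos[order, 1]
    keep = gy > 0.35 * mesh.params.b_out  # equatorial belt of the meridian
    gx, gy = gx[keep], gy[keep]
    if apex_x_global is None:
        # continuous apex: maximum of the interpolated curve
        f = PchipInterpolator(-gx, gy)
        xs = np.linspace(-gx[0], -gx[-1], 2001)
        apex_x_global = -xs[int(np.argmax(f(xs)))]
    x_scan = apex_x_global - gx
    inside = np.abs(x_scan) <= window
    return SagittalProfile(
        x=x_scan[inside], y=gy[inside], apex_x_global=float(apex_x_global)
    )


def displacement_at_x(
    initial: SagittalProfile, final: SagittalProfile, x
) -> np.ndarray | float:
    """Height drop Y(x) - y(x) at fixed lab-frame station(s) x (mm)."""
    d = initial.height(x) - final.height(x)
    return float(d) if np.ndim(d) == 0 else d


def compute_output_params(
    initial: SagittalProfile, final: SagittalProfile, eps: float = 1.0e-6
) -> OutputParams:
    """AD, CPR, AR and the six sampled heights from two profiles."""
    stations = np.array([-2.0, 0.0, 2.0])
    Y = initial.height(stations)
    y = final.height(stations)
    d_m2, d_0, d_p2 = Y - y
    heights = {
        "Y_-2": Y[0], "Y_0": Y[1], "Y_2": Y[2],
        "y_-2": y[0], "y_0": y[1], "y_2": y[2],
    }
    if abs(d_p2) < eps or abs(d_m2) < eps:
        raise UndefinedRatioError(
            f"peripheral displacement below {eps} mm: CPR/AR undefined"
        )
    return OutputParams(
        ad=float(d_0),
        cpr=float(d_0 / d_p2),
        ar=float(d_p2 / d_m2),
        heights={k: float(v) for k, v in heights.items()},
    )


def read_profile_csv(path) -> SagittalProfile:
    """Read an externally segmented two-column (x, y) profile CSV, so real
    segmented OCT curves can be scored by the same code path."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    xc = "x" if "x" in cols else cols[0]
    yc = "y" if "y" in cols else cols[1]
    order = np.argsort(df[xc].to_numpy())
    return SagittalProfile(
        x=df[xc].to_numpy(float)[order], y=df[yc].to_numpy(float)[order]
    )
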