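"""Synthetic AD-vs-IOP experiments (pseudo-measurements).

Real scleral APDI measurements pair an eye/location with apex
displacements at IOP 10, 15, 20 and 25 mmHg.  This module forward-
simulates such curves for eyes with known (drawn) material coefficients
and adds independent Gaussian measurement noise of a magnitude comparable
to experimental repeat-measurement scatter (≈0.1 mm), producing the CSV
consumed by the inverse-fit pipeline.  Because the truth is known, these
fixtures quantify parameter recovery and prediction error end to end.

The simulated "measurement" uses the same protocol as the inverse model:
the stress-free geometry is derived once at the 10-mmHg reference and
reused at higher pressures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .airpuff import AirPuffProfile
from .fe import BoundaryConditions, SolverConfig
from .geometry import GlobeParams
from .inverse import ADvsIOPCurve
from .material import MaterialField
from .pipeline import DEFAULT_RESOLUTION, cached_mesh, run_forward
from .prestress import stress_free_iterate

__all__ = ["SyntheticExperiment", "generate_synthetic_experiment", "write_curves_csv",
           "read_curves_csv"]

DEFAULT_LOCATIONS = ("S", "I", "EN", "ET")


@dataclass
class SyntheticExperiment:
    """A batch of synthetic AD-vs-IOP curves with known ground truth."""

    curves: list  # of ADvsIOPCurve (noisy)
    true_mu: dict  # (eye, location) -> mu*, MPa
    noiseless: dict  # (eye, location) -> np.ndarray of AD, mm
    noise_sigma: float
    seed: int
    iops: tuple

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.curves:
            for iop, ad in zip(c.iop_mmhg, c.ad_mm):
                rows.append(
                    {"eye": c.eye, "location": c.location,
                     "iop_mmhg": float(iop), "ad_mm": float(ad)}
                )
        return pd.DataFrame(rows)


def generate_synthetic_experiment(
    n_eyes: int = 3,
    locations: tuple = DEFAULT_LOCATIONS,
    mu_range: tuple = (0.06, 0.14),
    noise_sigma: float = 0.1,
    seed: int = 0,
    iops: tuple = (10.0, 15.0, 20.0, 25.0),
    globe: GlobeParams | None = None,
    resolution: int = DEFAULT_RESOLUTION,
    cfg: SolverConfig | None = None,
    puff: AirPuffProfile | None = None,
    reference_iop: float = 10.0,
    max_retries: int = 3,
) -> SyntheticExperiment:
    """Simulate noisy AD-vs-IOP curves for eyes with drawn stiffness.

    One mu* is drawn uniformly from ``mu_range`` per (eye, location) pair
    (each scanned site is fitted independently downstream).  A forward
    failure triggers a fresh draw for that site, up to ``max_retries``.
    """
    rng = np.random.default_rng(seed)
    globe_ = globe or GlobeParams()
    mesh = cached_mesh(globe_, resolution)
    bcs = BoundaryConditions.from_mesh(mesh)
    curves = []
    true_mu = {}
    noiseless = {}
    for e in range(1, n_eyes + 1):
        for loc in locations:
            for attempt in range(max_retries):
                mu = float(rng.uniform(*mu_range))
                try:
                    fieldm = MaterialField.from_mesh(mesh, mu=mu, mu_post=mu)
                    state = stress_free_iterate(
                        mesh, fieldm, bcs, reference_iop, cfg=cfg
                    )
                    ads = []
                    for iop in iops:
                        res = run_forward(
                            globe=globe_, mu=mu, mu_post=mu, iop_mmhg=float(iop),
                            puff=puff, resolution=resolution, cfg=cfg,
                            stress_free_state=state, mesh=mesh,
                        )
                        ads.append(res.outputs.ad)
                    break
                except Exception as exc:  # regenerate with a new draw
                    import warnings

                    warnings.warn(
                        f"forward failure for eye{e}/{loc} at mu={mu:.4f} "
                        f"(attempt {attempt + 1}): {exc}"
                    )
            else:
                raise RuntimeError(f"could not simulate eye{e}/{loc}")
            ads = np.asarray(ads)
            noisy = ads + noise_sigma * rng.standard_normal(len(iops))
            noisy = np.maximum(noisy, 1e-3)  # measured AD is positive
            key = (f"eye{e}", loc)
            true_mu[key] = mu
            noiseless[key] = ads
            curves.append(
                ADvsIOPCurve(
                    iop_mmhg=np.asarray(iops), ad_mm=noisy,
                    location=loc, eye=f"eye{e}",
                )
            )
    return SyntheticExperiment(
        curves=curves, true_mu=true_mu, noiseless=noiseless,
        noise_sigma=noise_sigma, seed=seed, iops=tuple(iops),
    )


def write_curves_csv(exp: SyntheticExperiment, path, header_meta: str = "") -> None:
    """CSV with columns eye, location, iop_mmhg, ad_mm (+ provenance header)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sclerapuff synthetic AD-vs-IOP curves; seed={exp.seed}; "
                 f"noise_sigma={exp.noise_sigma}"
                 + (f"; {header_meta}" if header_meta else "") + "\n")
        exp.to_frame().to_csv(fh, index=False)


def read_curves_csv(path) -> list:
    """Read an AD-vs-IOP CSV into a list of ADvsIOPCurve."""
    df = pd.read_csv(path, comment="#")
    curves = []
    for (eye, loc), g in df.groupby(["eye", "location"], sort=True):
        g = g.sort_values("iop_mmhg")
        curves.append(
            ADvsIOPCurve(
                iop_mmhg=g["iop_mmhg"].to_numpy(float),
                ad_mm=g["ad_mm"].to_numpy(float),
                location=str(loc), eye=str(eye),
            )
        )
    return curves
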