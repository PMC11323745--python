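"""Shared fixtures: coarse meshes and memoised forward evaluations.

All FE tests run on deliberately coarse meshes (the physics checks here
are about correctness of the formulation, not mesh-converged values); the
element budgets used are stated per fixture.  Forward evaluations are
memoised session-wide so direction/magnitude/acceptance tests share
solves.
"""

from __future__ import annotations

import numpy as np
import pytest

from sclerapuff.fe import BoundaryConditions
from sclerapuff.geometry import GlobeParams, generate_mesh
from sclerapuff.material import MaterialField
from sclerapuff.pipeline import run_forward
from sclerapuff.studies import INPUT_NAMES, ParameterRanges

#: element budget for single-physics checks
RES_UNIT = 100
#: element budget for study/acceptance sweeps — the coarsest mesh at which
#: the subtle CPR/AR trends are resolved (ratios and monotonicities
#: converge well before point values do, but not arbitrarily early)
RES_STUDY = 200
#: element budget for the many-solve inverse/round-trip suites, which
#: probe the estimation machinery, not point values
RES_FAST = 72
#: element budget for the random-sampling study: the coarsest mesh whose
#: sagittal profile resolves the peripheral-displacement ratios that CPR/AR
#: correlations are built from
RES_SAMPLING = 100


@pytest.fixture(scope="session")
def sphere_mesh():
    """Spherical shell R_mid = 9 mm, t = 0.5 mm (Laplace-law geometry)."""
    p = GlobeParams(AL=18.5, EL=18.5, THK=0.5, t_post=0.5, include_cornea=False)
    return generate_mesh(p, resolution=400)


@pytest.fixture(scope="session")
def globe_mesh():
    return generate_mesh(GlobeParams(), resolution=RES_UNIT)


@pytest.fixture(scope="session")
def globe_bcs(globe_mesh):
    return BoundaryConditions.from_mesh(globe_mesh)


@pytest.fixture(scope="session")
def globe_field(globe_mesh):
    return MaterialField.from_mesh(globe_mesh, mu=0.083)


_FORWARD_CACHE: dict = {}


def forward_cached(resolution: int = RES_STUDY, **inputs):
    """Memoised forward evaluation keyed by the six study inputs."""
    ranges = ParameterRanges()
    full = ranges.initial_inputs()
    full.update(inputs)
    key = tuple(round(float(full[n]), 12) for n in INPUT_NAMES) + (resolution,)
    if key not in _FORWARD_CACHE:
        globe = GlobeParams(AL=full["al"], EL=full["el"], THK=full["thk"])
        mu = float(full["mu"])
        _FORWARD_CACHE[key] = run_forward(
            globe=globe,
            mu=mu,
            mu_post=float(full["mu_post_ratio"]) * mu,
            iop_mmhg=float(full["iop"]),
            resolution=resolution,
        )
    return _FORWARD_CACHE[key]


@pytest.fixture(scope="session")
def baseline_forward():
    """Baseline model (all six inputs at their initial values)."""
    return forward_cached()


@pytest.fixture(scope="session")
def symmetric_forward():
    """Fore-aft symmetric globe: closed spherical shell, uniform wall and
    stiffness (AR must equal 1 on it)."""
    p = GlobeParams(AL=19, EL=19, THK=0.35, t_post=0.35, include_cornea=False)
    return run_forward(globe=p, resolution=RES_UNIT)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
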