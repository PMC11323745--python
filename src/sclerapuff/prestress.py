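"""IOP preload and stress-free (zero-pressure) geometry recovery.

The design geometry is what one would measure on a pressurised eye, but an
FE solve must start from an unloaded configuration.  The fixed-point scheme
used here inflates a trial unloaded geometry, compares the result with the
design geometry X0, and subtracts the mismatch:

    X1     = X0 - u0            (u0: displacement of the first inflation)
    X(i+1) = Xi - (xi - X0)     (xi: pressurised image of Xi)

Three iterations are the default; at scleral strain levels the map is
strongly contracting and the pressurised geometry then matches X0 to a few
microns.  Two usage modes exist: ``per_iop`` re-derives the unloaded shape
for every IOP evaluated (parametric studies, so the loaded geometry always
equals the design geometry), while ``fixed_at_reference`` derives it once at
a reference IOP and reuses it for other pressures (the inverse-fit
protocol, where only the 10-mmHg state is anchored to the measurement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fe import (
    MMHG_TO_MPA,
    BoundaryConditions,
    FEModel,
    PressureLoad,
    Solution,
    SolverConfig,
)
from .material import MaterialField

__all__ = ["StressFreeState", "stress_free_iterate", "pressurize"]


@dataclass
class StressFreeState:
    """Outcome of the stress-free iteration for one model at one IOP."""

    X0: np.ndarray  # design geometry, (N, 3) mm
    Xi: np.ndarray  # final stress-free estimate
    xi: np.ndarray  # pressurised image of the *previous* estimate
    history: list  # max nodal mismatch ||xi - X0||_inf per iteration, mm
    iop_mmhg: float
    u_guess: np.ndarray | None = field(default=None, repr=False)

    @property
    def mismatch(self) -> float:
        return self.history[-1]


def _inflation_model(mesh, fieldm, bcs, cfg, reference) -> FEModel:
    model = FEModel.from_mesh(mesh, fieldm, bcs, cfg, reference=reference)
    model.add_load(
        "iop", PressureLoad.uniform(mesh.face_sets["inner_surface"], 1.0,
                                    model.cfg.face_quad_order)
    )
    return model


def stress_free_iterate(
    mesh,
    fieldm: MaterialField,
    bcs: BoundaryConditions,
    iop_mmhg: float,
    n_iter: int = 3,
    cfg: SolverConfig | None = None,
) -> StressFreeState:
    """Recover the unloaded geometry whose inflation reproduces the mesh.

    Runs exactly ``n_iter`` fixed-point iterations (three by default, the
    reproducible choice; pass a larger count for tolerance studies).  Solver
    failure at any iterate re-raises with the iteration index attached.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    X0 = mesh.nodes.copy()
    p_iop = iop_mmhg * MMHG_TO_MPA
    Xi = X0
    xi = X0
    u_guess = None
    history: list[float] = []
    for i in range(n_iter):
        model = _inflation_model(mesh, fieldm, bcs, cfg, reference=Xi)
        try:
            sol = model.solve([{"iop": p_iop}], u0=u_guess)
        except Exception as exc:
            raise type(exc)(f"stress-free iteration {i}: {exc}") from exc
        xi = sol.final
        history.append(float(np.abs(xi - X0).max()))
        Xi = Xi - (xi - X0)
        # the next inflation starts near the same deformed state
        u_guess = (xi - Xi).ravel()
    return StressFreeState(X0=X0, Xi=Xi, xi=xi, history=history,
                           iop_mmhg=iop_mmhg, u_guess=u_guess)


def pressurize(
    mesh,
    fieldm: MaterialField,
    bcs: BoundaryConditions,
    state: StressFreeState,
    iop_mmhg: float | None = None,
    cfg: SolverConfig | None = None,
) -> Solution:
    """Inflate the stress-free geometry to an IOP-loaded state.

    With ``iop_mmhg`` omitted, the state's own IOP is applied and the
    resulting geometry reproduces the design geometry up to the final
    iteration mismatch.  This loaded state is the pre-puff ("initial")
    configuration for all deformation outputs.
    """
    iop = state.iop_mmhg if iop_mmhg is None else float(iop_mmhg)
    model = _inflation_model(mesh, fieldm, bcs, cfg, reference=state.Xi)
    guess = state.u_guess if iop == state.iop_mmhg else None
    return model.solve([{"iop": iop * MMHG_TO_MPA}], u0=guess)
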