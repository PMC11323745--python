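"""End-to-end forward model: one virtual eye in, AD/CPR/AR out.

This is the composition used by every study: build the parametric globe,
grade the Ogden coefficient axially, recover the stress-free geometry at
the requested IOP, inflate, apply the ramped air puff, and read the three
deformation outputs off the sagittal profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .airpuff import AirPuffProfile, run_airpuff
from .fe import BoundaryConditions, SolverConfig
from .geometry import GlobeParams, Mesh, generate_mesh
from .material import MaterialField
from .metrics import OutputParams, compute_output_params, extract_sagittal_profile
from .prestress import StressFreeState, pressurize, stress_free_iterate

__all__ = ["ForwardResult", "run_forward", "cached_mesh", "DEFAULT_RESOLUTION"]

#: element-count target used when no resolution is given; study runs pass
#: their own (coarser) targets
DEFAULT_RESOLUTION = 5000


@lru_cache(maxsize=32)
def cached_mesh(params: GlobeParams, resolution: int, symmetry: str = "quarter") -> Mesh:
    """Meshes are deterministic in (params, resolution): cache them."""
    return generate_mesh(params, resolution=resolution, symmetry=symmetry)


@dataclass
class ForwardResult:
    """Everything one forward evaluation produces."""

    outputs: OutputParams
    globe: GlobeParams
    iop_mmhg: float
    stress_free: StressFreeState
    prepuff: "object"  # Solution
    puff: "object"  # Solution
    profile_initial: "object"
    profile_final: "object"
    mesh: Mesh


def run_forward(
    globe: GlobeParams | None = None,
    mu: float = 0.083,
    mu_post: float | None = None,
    mu_cornea: float | None = None,
    alpha: float = 40.0,
    iop_mmhg: float = 18.0,
    puff: AirPuffProfile | None = None,
    resolution: int = DEFAULT_RESOLUTION,
    cfg: SolverConfig | None = None,
    n_stress_free: int = 3,
    stress_free_state: StressFreeState | None = None,
    mesh: Mesh | None = None,
) -> ForwardResult:
    """Run the full air-puff simulation for one parameter set.

    ``stress_free_state`` short-circuits the stress-free iteration (the
    ``fixed_at_reference`` mode of the inverse protocol: the unloaded shape
    found at the reference IOP is reused at other pressures).  Default
    corneal stiffness equals the equatorial scleral coefficient.
    """
    globe = globe or GlobeParams()
    puff = puff or AirPuffProfile()
    if mesh is None:
        mesh = cached_mesh(globe, resolution)
    fieldm = MaterialField.from_mesh(
        mesh, mu=mu, mu_post=mu_post, alpha=alpha, mu_cornea=mu_cornea
    )
    bcs = BoundaryConditions.from_mesh(mesh)
    state = stress_free_state
    if state is None:
        state = stress_free_iterate(
            mesh, fieldm, bcs, iop_mmhg, n_iter=n_stress_free, cfg=cfg
        )
    prepuff = pressurize(mesh, fieldm, bcs, state, iop_mmhg=iop_mmhg, cfg=cfg)
    sol = run_airpuff(
        mesh, fieldm, bcs, state, profile=puff, cfg=cfg,
        iop_mmhg=iop_mmhg, prepuff=prepuff,
    )
    prof0 = extract_sagittal_profile(mesh, sol, step=0)
    prof1 = extract_sagittal_profile(
        mesh, sol, step=-1, apex_x_global=prof0.apex_x_global
    )
    outputs = compute_output_params(prof0, prof1)
    return ForwardResult(
        outputs=outputs,
        globe=globe,
        iop_mmhg=iop_mmhg,
        stress_free=state,
        prepuff=prepuff,
        puff=sol,
        profile_initial=prof0,
        profile_final=prof1,
        mesh=mesh,
    )
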