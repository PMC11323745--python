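"""Run configuration: one file describing one virtual-eye experiment.

YAML (or JSON) with keys mirroring the model-input abbreviations (AL, EL,
THK, IOP, mu, mu_post / mu_post_ratio, alpha) plus air-puff, solver,
stress-free and study settings.  A configuration round-trips losslessly
through ``to_dict``/``from_dict``, and its canonical-JSON SHA-256 prefix
(``config_hash``) is embedded in every output file for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .airpuff import AirPuffProfile
from .fe import SolverConfig
from .geometry import GlobeParams

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one run."""

    globe: GlobeParams = GlobeParams()
    mu: float = 0.083
    mu_post: float | None = None  # absolute, MPa; overrides ratio if set
    mu_post_ratio: float | None = None  # in [0.25, 1]
    alpha: float = 40.0
    mu_cornea: float | None = None  # None -> same as mu
    kappa_ratio: float = 1.0e3
    iop_mmhg: float = 18.0
    puff: AirPuffProfile = AirPuffProfile()
    solver: SolverConfig = SolverConfig()
    stress_free_iterations: int = 3
    stress_free_mode: str = "per_iop"  # or "fixed_at_reference"
    reference_iop: float = 10.0
    resolution: int = 5000
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self):
        if self.stress_free_mode not in ("per_iop", "fixed_at_reference"):
            raise ValueError(f"unknown stress_free_mode {self.stress_free_mode!r}")
        if self.mu_post is not None and self.mu_post_ratio is not None:
            raise ValueError("give mu_post or mu_post_ratio, not both")

    @property
    def effective_mu_post(self) -> float:
        if self.mu_post is not None:
            return float(self.mu_post)
        if self.mu_post_ratio is not None:
            return float(self.mu_post_ratio) * self.mu
        return float(self.mu)

    # ------------------------------------------------------------------ #
    def to_dict(self) -> dict:
        d = {
            "AL": self.globe.AL, "EL": self.globe.EL, "THK": self.globe.THK,
            "t_post": self.globe.t_post, "t_cornea": self.globe.t_cornea,
            "cornea_angle": self.globe.cornea_angle,
            "apex_offset": self.globe.apex_offset,
            "include_cornea": self.globe.include_cornea,
            "mu": self.mu, "mu_post": self.mu_post,
            "mu_post_ratio": self.mu_post_ratio, "alpha": self.alpha,
            "mu_cornea": self.mu_cornea, "kappa_ratio": self.kappa_ratio,
            "IOP": self.iop_mmhg,
            "airpuff": {
                "peak_kpa": self.puff.peak_kpa, "steps": self.puff.n_steps,
                "total_time_ms": self.puff.total_time_ms,
                "kernel": self.puff.kernel, "fwhm_mm": self.puff.fwhm_mm,
            },
            "solver": asdict(self.solver),
            "stress_free": {
                "iterations": self.stress_free_iterations,
                "mode": self.stress_free_mode,
                "reference_iop": self.reference_iop,
            },
            "resolution": self.resolution,
            "seed": self.seed,
            "outdir": self.outdir,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gkeys = {
            "AL": "AL", "EL": "EL", "THK": "THK", "t_post": "t_post",
            "t_cornea": "t_cornea", "cornea_angle": "cornea_angle",
            "apex_offset": "apex_offset", "include_cornea": "include_cornea",
        }
        gp = {
            dst: d[src] for src, dst in gkeys.items() if src in d and d[src] is not None
        }
        ap = d.get("airpuff", {}) or {}
        puff = AirPuffProfile(
            peak_kpa=ap.get("peak_kpa", 15.4),
            n_steps=ap.get("steps", 6),
            total_time_ms=ap.get("total_time_ms", 20.0),
            kernel=ap.get("kernel", "gaussian"),
            fwhm_mm=ap.get("fwhm_mm", 2.4),
        )
        sv = d.get("solver", {}) or {}
        solver = SolverConfig(**sv) if sv else SolverConfig()
        sf = d.get("stress_free", {}) or {}
        return cls(
            globe=GlobeParams(**gp),
            mu=d.get("mu", 0.083),
            mu_post=d.get("mu_post"),
            mu_post_ratio=d.get("mu_post_ratio"),
            alpha=d.get("alpha", 40.0),
            mu_cornea=d.get("mu_cornea"),
            kappa_ratio=d.get("kappa_ratio", 1.0e3),
            iop_mmhg=d.get("IOP", 18.0),
            puff=puff,
            solver=solver,
            stress_free_iterations=sf.get("iterations", 3),
            stress_free_mode=sf.get("mode", "per_iop"),
            reference_iop=sf.get("reference_iop", 10.0),
            resolution=d.get("resolution", 5000),
            seed=d.get("seed", 0),
            outdir=d.get("outdir", "results"),
        )

    def save(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def config_hash(d: dict) -> str:
    """Short stable hash of a configuration dictionary."""
    blob = json.dumps(d, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Read a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    try:
        d = yaml.safe_load(text)  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed config {path}: {exc}") from exc
    if not isinstance(d, dict):
        raise ValueError(f"malformed config {path}: expected a mapping")
    return RunConfig.from_dict(d)
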