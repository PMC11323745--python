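"""Parametric studies: one-at-a-time sensitivity and random sampling.

Two in-silico experiments over the six model inputs (mu, THK, IOP,
mu_post ratio, AL, EL):

* ``sensitivity_study`` sweeps one input over its range with the other
  five at their initial values and summarises each output's percent change
  over the range.
* ``random_sampling_study`` draws all six inputs independently and
  uniformly (mu_post as a ratio of the drawn mu), evaluates the forward
  model per draw, and reports the squared Pearson correlation (R^2, with
  p-value) between every input and every output.

The stress-free preload is re-derived for every evaluation, so the loaded
geometry always matches the design geometry regardless of IOP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .airpuff import AirPuffProfile
from .fe import SolverConfig, SolverError
from .geometry import GlobeParams
from .pipeline import DEFAULT_RESOLUTION, run_forward

__all__ = [
    "ParamRange",
    "ParameterRanges",
    "percent_change",
    "r_squared",
    "evaluate_inputs",
    "sensitivity_study",
    "random_sampling_study",
    "INPUT_NAMES",
    "OUTPUT_NAMES",
]

INPUT_NAMES = ["mu", "thk", "iop", "mu_post_ratio", "al", "el"]
OUTPUT_NAMES = ["AD", "CPR", "AR"]


@dataclass(frozen=True)
class ParamRange:
    low: float
    high: float
    initial: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError("require low < high")
        if not self.low <= self.initial <= self.high:
            raise ValueError("initial must lie inside [low, high]")


@dataclass(frozen=True)
class ParameterRanges:
    """Evaluated ranges and initial values of the six model inputs.

    Defaults are the study conditions of the rabbit-eye model: mu
    0.06-0.10 MPa (initial 0.083, giving the reference deformation), wall
    thickness 0.34-0.40 mm, IOP 10-25 mmHg (initial 18), posterior/equator
    stiffness ratio 0.25-1, axial diameter 17-19 mm, equatorial diameter
    18.4-19.6 mm.
    """

    mu: ParamRange = ParamRange(0.06, 0.10, 0.083)
    thk: ParamRange = ParamRange(0.34, 0.40, 0.35)
    iop: ParamRange = ParamRange(10.0, 25.0, 18.0)
    mu_post_ratio: ParamRange = ParamRange(0.25, 1.0, 1.0)
    al: ParamRange = ParamRange(17.0, 19.0, 18.0)
    el: ParamRange = ParamRange(18.4, 19.6, 19.0)

    def initial_inputs(self) -> dict:
        return {n: getattr(self, n).initial for n in INPUT_NAMES}


def percent_change(y_low: float, y_high: float) -> float:
    """100 * (y_high - y_low) / y_low."""
    if y_low == 0:
        raise ZeroDivisionError("percent change undefined for zero baseline")
    return 100.0 * (y_high - y_low) / y_low


def r_squared(xs, ys):
    """Squared Pearson correlation and its p-value.

    Identical to the coefficient of determination of the simple linear
    least-squares fit of ys on xs.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    m = np.isfinite(xs) & np.isfinite(ys)
    xs, ys = xs[m], ys[m]
    if xs.size < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("zero variance: R^2 undefined")
    r, p = stats.pearsonr(xs, ys)
    return float(r * r), float(p)


def evaluate_inputs(
    inputs: dict,
    resolution: int = DEFAULT_RESOLUTION,
    cfg: SolverConfig | None = None,
    puff: AirPuffProfile | None = None,
    cache: dict | None = None,
):
    """Forward-evaluate one input vector; returns OutputParams.

    ``cache`` (a plain dict) memoises repeated vectors within a study —
    sweeps share their baseline point.
    """
    key = tuple(round(float(inputs[n]), 12) for n in INPUT_NAMES) + (resolution,)
    if cache is not None and key in cache:
        return cache[key]
    globe = GlobeParams(AL=inputs["al"], EL=inputs["el"], THK=inputs["thk"])
    mu = float(inputs["mu"])
    res = run_forward(
        globe=globe,
        mu=mu,
        mu_post=float(inputs["mu_post_ratio"]) * mu,
        iop_mmhg=float(inputs["iop"]),
        puff=puff,
        resolution=resolution,
        cfg=cfg,
    )
    out = res.outputs
    if cache is not None:
        cache[key] = out
    return out


def _record(inputs: dict, out, draw: int | None = None) -> dict:
    rec = dict(inputs)
    rec["mu_post"] = rec["mu_post_ratio"] * rec["mu"]
    if draw is not None:
        rec["draw"] = draw
    if out is not None:
        rec.update({"AD": out.ad, "CPR": out.cpr, "AR": out.ar})
        rec.update(out.heights)
        rec["status"] = "ok"
    else:
        rec.update({"AD": np.nan, "CPR": np.nan, "AR": np.nan, "status": "failed"})
    return rec


def sensitivity_study(
    ranges: ParameterRanges | None = None,
    n_points: int = 5,
    resolution: int = DEFAULT_RESOLUTION,
    cfg: SolverConfig | None = None,
    puff: AirPuffProfile | None = None,
    params: list | None = None,
):
    """One-at-a-time sweeps with percent-change summaries.

    Returns ``(records, summary)`` DataFrames.  ``summary`` holds, per
    (input, output), the percent change across the evaluated range
    (low end to high end) and, as an alternative reading, from the input's
    initial value to the high end.
    """
    ranges = ranges or ParameterRanges()
    params = params or INPUT_NAMES
    cache: dict = {}
    records = []
    rows = []
    for name in params:
        pr: ParamRange = getattr(ranges, name)
        values = np.linspace(pr.low, pr.high, n_points)
        outs = {}
        for v in values:
            inputs = ranges.initial_inputs()
            inputs[name] = float(v)
            try:
                out = evaluate_inputs(inputs, resolution, cfg, puff, cache)
            except (SolverError, FloatingPointError, ValueError) as exc:
                records.append(
                    _record(inputs, None) | {"param": name, "error": str(exc)}
                )
                continue
            outs[float(v)] = out
            records.append(_record(inputs, out) | {"param": name})
        if len(outs) < 2:
            continue
        vs = sorted(outs)
        lo, hi = outs[vs[0]], outs[vs[-1]]
        # nearest evaluated point to the initial value, for the
        # alternative (initial -> high) percent-change reading
        v_init = min(vs, key=lambda v: abs(v - pr.initial))
        init = outs[v_init]
        for oname, get in (("AD", "ad"), ("CPR", "cpr"), ("AR", "ar")):
            rows.append(
                {
                    "param": name,
                    "output": oname,
                    "low": getattr(lo, get),
                    "high": getattr(hi, get),
                    "pct_change_range": percent_change(
                        getattr(lo, get), getattr(hi, get)
                    ),
                    "pct_change_from_initial": percent_change(
                        getattr(init, get), getattr(hi, get)
                    ),
                }
            )
    return pd.DataFrame(records), pd.DataFrame(rows)


def random_sampling_study(
    ranges: ParameterRanges | None = None,
    n: int = 400,
    seed: int = 0,
    resolution: int = DEFAULT_RESOLUTION,
    cfg: SolverConfig | None = None,
    puff: AirPuffProfile | None = None,
):
    """Uniform random draws of all six inputs + per-pair R^2 matrix.

    Returns ``(records, r2_table)``.  ``r2_table`` is a long DataFrame with
    columns (input, output, r2, p); mu_post enters as the absolute
    posterior coefficient (ratio x drawn mu).  Failed draws are recorded
    with status='failed' and excluded from the correlations.
    """
    ranges = ranges or ParameterRanges()
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        inputs = {
            name: float(rng.uniform(getattr(ranges, name).low, getattr(ranges, name).high))
            for name in INPUT_NAMES
        }
        try:
            out = evaluate_inputs(inputs, resolution, cfg, puff)
        except (SolverError, FloatingPointError, ValueError):
            out = None
        records.append(_record(inputs, out, draw=i))
    df = pd.DataFrame(records)
    good = df[df["status"] == "ok"]
    rows = []
    for iname in INPUT_NAMES + ["mu_post"]:
        for oname in OUTPUT_NAMES:
            try:
                r2, p = r_squared(good[iname], good[oname])
            except ValueError:  # too few successful draws: undefined
                r2, p = float("nan"), float("nan")
            rows.append({"input": iname, "output": oname, "r2": r2, "p": p})
    return df, pd.DataFrame(rows)
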