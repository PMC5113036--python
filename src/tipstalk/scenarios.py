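"""Scenario generation: VEGF/D_ext grids, position-switch schedules and
Latin-hypercube parameter designs.

Everything downstream (sweeps, switch experiments, robustness screens)
consumes inputs built here, so no external data is ever needed.  Default
grid ranges and schedule durations are package choices documented in
``docs/methods.md`` and overridable either programmatically or through a
YAML config file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from scipy.stats import qmc

from .model import PARAM_NAMES, ExternalInputs, ModelParams

__all__ = [
    "GridSpec",
    "DextSchedule",
    "LhsDesign",
    "make_vegf_grid",
    "make_dext_grid",
    "make_switch_schedule",
    "sample_lhs",
    "inputs_from_schedule",
    "scenarios_to_frame",
    "scenarios_to_csv",
    "load_config",
]

#: Default VEGF axis for patterning-speed sweeps: 21 levels on [0, 10] c.u.
DEFAULT_VEGF_AXIS = tuple(np.linspace(0.0, 10.0, 21))
#: Default external-DLL axis: 21 levels on [0, 5] c.u.
DEFAULT_DEXT_AXIS = tuple(np.linspace(0.0, 5.0, 21))


@dataclass(frozen=True)
class GridSpec:
    """Cartesian grid over two input axes.

    axis_meaning selects whether the axes are the per-cell VEGF levels
    (``"V1xV2"``) or the per-cell external DLL levels (``"Dext1xDext2"``).
    """

    axis1_values: Sequence[float]
    axis2_values: Sequence[float]
    axis_meaning: Literal["V1xV2", "Dext1xDext2"] = "V1xV2"

    def __post_init__(self) -> None:
        for name, vals in (("axis1", self.axis1_values), ("axis2", self.axis2_values)):
            arr = np.asarray(vals, float)
            if arr.size == 0:
                raise ValueError(f"{name} is empty")
            if np.any(arr < 0):
                raise ValueError(f"{name} has negative values")
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        if self.axis_meaning not in ("V1xV2", "Dext1xDext2"):
            raise ValueError(f"unknown axis_meaning {self.axis_meaning!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.axis1_values), len(self.axis2_values))


@dataclass(frozen=True)
class DextSchedule:
    """Time course of the external DLL pair during a position switch.

    ``constant`` holds ``start_levels`` forever; ``abrupt_switch`` jumps
    from start to end levels at ``switch_time``; ``gradual_ramp``
    interpolates linearly over ``[0, ramp_window]``.  In the overtaking
    geometry the start is (0, high) — cell1 uninhibited, cell2 facing a
    strong neighbour — and the end is the mirror (high, 0).
    """

    kind: Literal["constant", "abrupt_switch", "gradual_ramp"]
    start_levels: tuple[float, float]
    end_levels: tuple[float, float]
    switch_time: float = 0.0  # step time (abrupt) or ramp window (gradual)

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "abrupt_switch", "gradual_ramp"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if min(*self.start_levels, *self.end_levels) < 0:
            raise ValueError("Dext levels must be >= 0")
        if self.kind == "constant" and self.start_levels != self.end_levels:
            raise ValueError("constant schedule requires start == end")
        if self.kind != "constant" and self.switch_time <= 0:
            raise ValueError("switch_time / ramp window must be > 0")

    def levels(self, t: float) -> tuple[float, float]:
        """(Dext1, Dext2) at time ``t``; total on all of [0, inf)."""
        if self.kind == "constant":
            return self.start_levels
        if self.kind == "abrupt_switch":
            return self.start_levels if t < self.switch_time else self.end_levels
        frac = min(max(t / self.switch_time, 0.0), 1.0)
        return (
            self.start_levels[0] + frac * (self.end_levels[0] - self.start_levels[0]),
            self.start_levels[1] + frac * (self.end_levels[1] - self.start_levels[1]),
        )

    def dext1(self, t: float) -> float:
        return self.levels(t)[0]

    def dext2(self, t: float) -> float:
        return self.levels(t)[1]

    @property
    def discontinuities(self) -> tuple[float, ...]:
        """Times at which the schedule jumps (for segment-wise integration)."""
        return (self.switch_time,) if self.kind == "abrupt_switch" else ()


@dataclass(frozen=True)
class LhsDesign:
    """Latin-hypercube design around a nominal parameter set.

    Each of the 14 kinetic parameters is sampled uniformly within
    ``nominal * (1 +/- fraction)``, with one sample per equal-width
    stratum per dimension (the Latin hypercube property).
    """

    n_sets: int
    fraction: float
    seed: int
    nominal: ModelParams = field(default_factory=ModelParams)

    def __post_init__(self) -> None:
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")


def make_vegf_grid(spec: GridSpec) -> list[ExternalInputs]:
    """All (V1, V2) combinations of the grid, with no external DLL.

    Rows iterate axis1 (V1), columns axis2 (V2), row-major.
    """
    if spec.axis_meaning != "V1xV2":
        raise ValueError("make_vegf_grid requires axis_meaning='V1xV2'")
    return [
        ExternalInputs(V1=float(v1), V2=float(v2))
        for v1 in spec.axis1_values
        for v2 in spec.axis2_values
    ]


def make_dext_grid(spec: GridSpec, V: float = 3.5) -> list[ExternalInputs]:
    """All (Dext1, Dext2) combinations of the grid at shared VEGF ``V``.

    Emulates two quiescent cells bracketed by neighbours of differing
    DLL exposure; the default ``V`` sits near the autonomous activation
    threshold so the external pre-pattern decides the race: the cell
    facing more external DLL loses, and strong DLL on both sides
    silences the pair.
    """
    if spec.axis_meaning != "Dext1xDext2":
        raise ValueError("make_dext_grid requires axis_meaning='Dext1xDext2'")
    if V < 0:
        raise ValueError("V must be >= 0")
    return [
        ExternalInputs(V1=float(V), V2=float(V), Dext1=float(d1), Dext2=float(d2))
        for d1 in spec.axis1_values
        for d2 in spec.axis2_values
    ]


def make_switch_schedule(
    kind: Literal["abrupt", "gradual"], high: float, duration: float
) -> DextSchedule:
    """Overtaking schedule: Dext1 rises 0 -> high while Dext2 falls high -> 0.

    ``abrupt`` steps at ``duration / 2``; ``gradual`` ramps linearly over
    the whole ``[0, duration]`` window (so at the midpoint both cells see
    ``high / 2`` — the equal-inhibition crossing where the pI state lives).
    """
    if high <= 0:
        raise ValueError("high must be > 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if kind == "abrupt":
        return DextSchedule(
            kind="abrupt_switch",
            start_levels=(0.0, high),
            end_levels=(high, 0.0),
            switch_time=duration / 2.0,
        )
    if kind == "gradual":
        return DextSchedule(
            kind="gradual_ramp",
            start_levels=(0.0, high),
            end_levels=(high, 0.0),
            switch_time=duration,
        )
    raise ValueError(f"unknown schedule kind {kind!r}")


def inputs_from_schedule(
    schedule: DextSchedule, V1: float, V2: float | None = None
) -> ExternalInputs:
    """Wrap a D_ext schedule as time-varying ExternalInputs at fixed VEGF."""
    if V2 is None:
        V2 = V1
    return ExternalInputs(V1=V1, V2=V2, Dext1=schedule.dext1, Dext2=schedule.dext2)


def sample_lhs(design: LhsDesign) -> list[ModelParams]:
    """Draw the design's parameter sets (deterministic under its seed)."""
    nominal = design.nominal.as_array()
    if design.fraction == 0.0:
        return [design.nominal] * design.n_sets
    lo = nominal * (1.0 - design.fraction)
    hi = nominal * (1.0 + design.fraction)
    sampler = qmc.LatinHypercube(d=len(PARAM_NAMES), seed=design.seed)
    unit = sampler.random(n=design.n_sets)
    scaled = qmc.scale(unit, lo, hi)
    # the Hill coefficient must stay >= 1; at fraction 0.5 the lower edge
    # of n's interval is exactly 1 and rounding can graze it
    n_idx = PARAM_NAMES.index("n")
    scaled[:, n_idx] = np.maximum(scaled[:, n_idx], 1.0)
    return [ModelParams.from_array(row) for row in scaled]


def scenarios_to_frame(scenarios: Iterable[ExternalInputs]) -> pd.DataFrame:
    """Tabulate constant scenarios (one row per scenario) for audit."""
    rows = []
    for i, sc in enumerate(scenarios):
        if not sc.is_constant:
            raise ValueError("only constant scenarios can be tabulated")
        v1, v2, d1, d2 = sc.at(0.0)
        rows.append({"scenario": i, "V1": v1, "V2": v2, "Dext1": d1, "Dext2": d2})
    return pd.DataFrame(rows)


def scenarios_to_csv(scenarios: Iterable[ExternalInputs], path: Union[str, Path]) -> None:
    scenarios_to_frame(scenarios).to_csv(path, index=False)


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML scenario config and build the objects it describes.

    Recognised top-level keys (all optional):

    - ``vegf_grid``: {axis1, axis2} lists -> list of ExternalInputs
    - ``dext_grid``: {axis1, axis2, V} -> list of ExternalInputs
    - ``switch``: {kind, high, duration} -> DextSchedule
    - ``lhs``: {n_sets, fraction, seed} -> LhsDesign
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out: dict = {}
    if "vegf_grid" in raw:
        g = raw["vegf_grid"]
        spec = GridSpec(g["axis1"], g["axis2"], "V1xV2")
        out["vegf_grid"] = make_vegf_grid(spec)
        out["vegf_grid_spec"] = spec
    if "dext_grid" in raw:
        g = raw["dext_grid"]
        spec = GridSpec(g["axis1"], g["axis2"], "Dext1xDext2")
        out["dext_grid"] = make_dext_grid(spec, V=float(g.get("V", 3.5)))
        out["dext_grid_spec"] = spec
    if "switch" in raw:
        s = raw["switch"]
        out["switch"] = make_switch_schedule(
            s["kind"], float(s["high"]), float(s["duration"])
        )
    if "lhs" in raw:
        d = raw["lhs"]
        out["lhs"] = LhsDesign(
            n_sets=int(d["n_sets"]), fraction=float(d["fraction"]), seed=int(d["seed"])
        )
    return out
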