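"""Time-domain integration of the two-cell model: single runs, pattern
classification, grid sweeps, position-switch experiments and modulator
scans.

Integration uses a stiff-capable adaptive solver (LSODA by default) with
the analytic Jacobian.  "Patterning" is defined operationally: the pair
has patterned once one cell's internal DLL exceeds the active threshold
(13 c.u.) while the other's falls below the
inactive threshold (0.5 c.u.), and both stay there until the end of the
simulation; the patterning time is the earliest such moment, resolved to
about one second.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    N_SPECIES,
    N_STATE,
    ExternalInputs,
    ModelParams,
    Modulators,
    default_initial_state,
    make_jacobian,
    make_rhs,
    swap_cells,
)
from .scenarios import DextSchedule, inputs_from_schedule

__all__ = [
    "ACTIVE_DLL",
    "INACTIVE_DLL",
    "DEFAULT_HORIZON",
    "SIRT1_SCAN_BASE",
    "LFNG_SCAN_BASE",
    "Trajectory",
    "PatternOutcome",
    "SweepResult",
    "ScanResult",
    "integrate",
    "classify_pattern",
    "sweep",
    "prepattern",
    "run_position_switch",
    "modulator_scan",
]

#: Internal DLL above which a cell counts as fully active (c.u.).
ACTIVE_DLL = 13.0
#: Internal DLL below which a cell counts as fully inactive (c.u.).
INACTIVE_DLL = 0.5
#: Default simulation horizon (s).
DEFAULT_HORIZON = 20000.0

#: Default environment for Sirt1 scans: a roughly 2:1 VEGF gradient
#: straddling the autonomous activation threshold, with a unit external
#: DLL bolus pre-patterning the pair.  At sirt1 = lfng = 1 this patterns
#: A:I; weakening or strengthening notch flips it to A:A or I:I.
SIRT1_SCAN_BASE = ExternalInputs(V1=3.52, V2=1.76, Dext1=0.0, Dext2=1.0)
#: Default environment for Lfng scans: a shallower gradient bracketing
#: the activation threshold, so halving Lfng releases both cells (A:A)
#: and doubling it silences both.
LFNG_SCAN_BASE = ExternalInputs(V1=3.6, V2=3.0)

_DLL1 = 2
_DLL2 = N_SPECIES + 2


@dataclass
class Trajectory:
    """Solution of one scenario: sampled states plus dense interpolants."""

    times: np.ndarray
    states: np.ndarray  # (n_times, 16)
    inputs_used: ExternalInputs | DextSchedule
    _segments: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("trajectory contains NaN/inf")

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def dll(self) -> np.ndarray:
        """(n_times, 2) internal DLL of both cells."""
        return self.states[:, [_DLL1, _DLL2]]

    def at(self, t: float) -> np.ndarray:
        """Dense-output state at time ``t``."""
        for t0, t1, sol in self._segments:
            if t0 <= t <= t1:
                return sol(t)
        raise ValueError(f"t={t} outside trajectory range")

    def to_frame(self) -> pd.DataFrame:
        from .model import SPECIES

        cols = [f"{s}_cell{c}" for c in (1, 2) for s in SPECIES]
        df = pd.DataFrame(self.states, columns=cols)
        df.insert(0, "time", self.times)
        return df


@dataclass
class PatternOutcome:
    """Outcome of one scenario under the DLL threshold rule."""

    label: Literal["A:I", "I:A", "A:A", "I:I", "unresolved"]
    patterning_time: float | None
    final_dll: tuple[float, float]
    error: str | None = None


def _solve_segment(rhs, jac, t0, t1, y0, n_eval, method, rtol, atol):
    t_eval = np.linspace(t0, t1, n_eval)
    sol = solve_ivp(
        rhs, (t0, t1), y0, method=method, jac=jac,
        t_eval=t_eval, dense_output=True, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"solver failed at t={sol.t[-1] if sol.t.size else t0}: {sol.message}")
    return sol


def integrate(
    initial: np.ndarray | None,
    inputs: ExternalInputs | DextSchedule,
    params: ModelParams = ModelParams(),
    mods: Modulators = Modulators(),
    horizon: float = DEFAULT_HORIZON,
    *,
    V: float | tuple[float, float] | None = None,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    dt_sample: float = 10.0,
) -> Trajectory:
    """Integrate the two-cell model over ``[0, horizon]``.

    ``initial`` defaults to the quiescent condition.  ``inputs`` may be a
    (possibly time-varying) :class:`ExternalInputs` or a
    :class:`DextSchedule`; in the latter case ``V`` supplies the constant
    VEGF level(s).  Abrupt-schedule discontinuities are handled by
    segment-wise integration.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    y0 = default_initial_state() if initial is None else np.asarray(initial, float)
    if y0.shape != (N_STATE,):
        raise ValueError(f"initial state must have length {N_STATE}")
    provenance: ExternalInputs | DextSchedule = inputs
    breaks: tuple[float, ...] = ()
    if isinstance(inputs, DextSchedule):
        if V is None:
            raise ValueError("a VEGF level V is required with a DextSchedule")
        v1, v2 = (V, V) if np.isscalar(V) else V
        breaks = tuple(t for t in inputs.discontinuities if 0.0 < t < horizon)
        inputs = inputs_from_schedule(inputs, v1, v2)

    rhs = make_rhs(inputs, params, mods)
    jac = make_jacobian(inputs, params, mods)
    edges = [0.0, *breaks, horizon]
    times, states, segments = [], [], []
    y = y0
    for t0, t1 in zip(edges[:-1], edges[1:]):
        n_eval = max(int(round((t1 - t0) / dt_sample)) + 1, 2)
        sol = _solve_segment(rhs, jac, t0, t1, y, n_eval, method, rtol, atol)
        keep = slice(None) if not times else slice(1, None)
        times.append(sol.t[keep])
        states.append(sol.y.T[keep])
        segments.append((t0, t1, sol.sol))
        y = sol.y[:, -1]
    return Trajectory(
        times=np.concatenate(times),
        states=np.vstack(states),
        inputs_used=provenance,
        _segments=segments,
    )


def _patterned(dll1: float, dll2: float, active: float, inactive: float) -> bool:
    return (dll1 > active and dll2 < inactive) or (dll2 > active and dll1 < inactive)


def classify_pattern(
    traj: Trajectory,
    active_thresh: float = ACTIVE_DLL,
    inactive_thresh: float = INACTIVE_DLL,
) -> PatternOutcome:
    """Label a trajectory and locate its patterning time.

    The patterning time is the earliest instant from which the
    differential condition (one DLL above ``active_thresh``, the other
    below ``inactive_thresh``) holds through the end of the trajectory,
    refined on the dense solution to <= 1 s.
    """
    if not active_thresh > inactive_thresh > 0:
        raise ValueError("need active_thresh > inactive_thresh > 0")
    d = traj.dll()
    d1, d2 = d[-1]
    a1, a2 = d1 > active_thresh, d2 > active_thresh
    i1, i2 = d1 < inactive_thresh, d2 < inactive_thresh
    if a1 and i2:
        label = "A:I"
    elif a2 and i1:
        label = "I:A"
    elif a1 and a2:
        label = "A:A"
    elif i1 and i2:
        label = "I:I"
    else:
        label = "unresolved"
    time = None
    if label in ("A:I", "I:A"):
        ok = np.array(
            [_patterned(x1, x2, active_thresh, inactive_thresh) for x1, x2 in d]
        )
        # earliest sample from which the condition persists to the horizon
        bad = np.nonzero(~ok)[0]
        first = 0 if bad.size == 0 else bad[-1] + 1
        if first == 0:
            time = float(traj.times[0])
        else:
            lo, hi = traj.times[first - 1], traj.times[first]
            while hi - lo > 1.0:
                mid = 0.5 * (lo + hi)
                y = traj.at(mid)
                if _patterned(y[_DLL1], y[_DLL2], active_thresh, inactive_thresh):
                    hi = mid
                else:
                    lo = mid
            time = float(hi)
    return PatternOutcome(label=label, patterning_time=time, final_dll=(float(d1), float(d2)))


@dataclass
class SweepResult:
    """Outcomes of a scenario list, optionally shaped as a grid."""

    outcomes: list[PatternOutcome]
    scenarios: list[ExternalInputs]
    shape: tuple[int, int] | None = None

    def label_matrix(self) -> np.ndarray:
        if self.shape is None:
            raise ValueError("no grid shape attached")
        return np.array([o.label for o in self.outcomes], object).reshape(self.shape)

    def time_matrix(self) -> np.ndarray:
        """Patterning times; NaN where no differential pattern formed."""
        if self.shape is None:
            raise ValueError("no grid shape attached")
        t = [np.nan if o.patterning_time is None else o.patterning_time for o in self.outcomes]
        return np.array(t).reshape(self.shape)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sc, o in zip(self.scenarios, self.outcomes):
            v1, v2, d1, d2 = sc.at(0.0)
            rows.append(
                {
                    "V1": v1, "V2": v2, "Dext1": d1, "Dext2": d2,
                    "label": o.label, "patterning_time": o.patterning_time,
                    "DLL1_final": o.final_dll[0], "DLL2_final": o.final_dll[1],
                    "error": o.error,
                }
            )
        return pd.DataFrame(rows)


def sweep(
    scenarios: Sequence[ExternalInputs],
    params: ModelParams = ModelParams(),
    mods: Modulators = Modulators(),
    horizon: float = DEFAULT_HORIZON,
    shape: tuple[int, int] | None = None,
    **integrate_kwargs,
) -> SweepResult:
    """Integrate and classify every scenario (order-independent).

    Per-scenario solver failures are recorded on the outcome instead of
    aborting the sweep.
    """
    outcomes = []
    for sc in scenarios:
        try:
            traj = integrate(None, sc, params, mods, horizon, **integrate_kwargs)
            outcomes.append(classify_pattern(traj))
        except Exception as exc:  # noqa: BLE001 - contract: record, continue
            outcomes.append(
                PatternOutcome("unresolved", None, (np.nan, np.nan), error=str(exc))
            )
    return SweepResult(outcomes=outcomes, scenarios=list(scenarios), shape=shape)


def prepattern(
    dext: tuple[float, float],
    V: float | tuple[float, float],
    params: ModelParams = ModelParams(),
    mods: Modulators = Modulators(),
    horizon: float = DEFAULT_HORIZON,
) -> np.ndarray:
    """Equilibrated A:I state under constant ``dext`` and VEGF ``V``.

    First tries the quiescent start; if the pair does not pattern (low
    VEGF cannot ignite a quiescent cell on its own), cell1 is first
    ignited under a transient strong VEGF gradient and the result is then
    equilibrated under the target inputs.  Raises if no A:I state is
    reachable.
    """
    v1, v2 = (V, V) if np.isscalar(V) else V
    target = ExternalInputs(V1=v1, V2=v2, Dext1=dext[0], Dext2=dext[1])
    traj = integrate(None, target, params, mods, horizon)
    y = traj.final_state
    if y[_DLL1] > ACTIVE_DLL and y[_DLL2] < INACTIVE_DLL:
        return y
    igniter = ExternalInputs(V1=5.0, V2=1.0)
    seed = integrate(None, igniter, params, mods, horizon).final_state
    y = integrate(seed, target, params, mods, horizon).final_state
    if y[_DLL1] > ACTIVE_DLL and y[_DLL2] < INACTIVE_DLL:
        return y
    raise RuntimeError(f"no A:I pre-pattern reachable at V={V}, Dext={dext}")


def run_position_switch(
    schedule: DextSchedule,
    params: ModelParams = ModelParams(),
    mods: Modulators = Modulators(),
    horizon: float | None = None,
    V: float = 1.0,
    equilibration: float = DEFAULT_HORIZON,
) -> tuple[Trajectory, pd.DataFrame]:
    """Simulate a neighbour position switch from a pre-patterned A:I state.

    The pair is equilibrated under the schedule's start levels (A:I),
    then the schedule clock starts at 0.  Returns the trajectory and a
    per-time-point annotation of each cell's A / pA / pI / I label under
    the threshold rule.
    """
    from .classify import label_timepoints

    if horizon is None:
        horizon = 2.0 * schedule.switch_time
    # An unmodulated pre-pattern keeps the start state comparable across
    # modulator settings; the modulators act from the moment the cells move.
    y0 = prepattern(schedule.start_levels, V, params, Modulators(), equilibration)
    traj = integrate(y0, schedule, params, mods, horizon, V=V)
    labels = label_timepoints(traj)
    return traj, labels


@dataclass
class ScanResult:
    """Modulator scan outcomes plus the two located transition levels."""

    table: pd.DataFrame
    differential_threshold: float | None
    both_active_threshold: float | None


def _scan_outcome(
    level: float,
    modulator: str,
    base_inputs: ExternalInputs,
    params: ModelParams,
    horizon: float,
) -> PatternOutcome:
    mods = Modulators(**{modulator: level})
    traj = integrate(None, base_inputs, params, mods, horizon)
    return classify_pattern(traj)


def modulator_scan(
    modulator: Literal["sirt1", "lfng"],
    levels: Sequence[float],
    base_inputs: ExternalInputs | None = None,
    params: ModelParams = ModelParams(),
    horizon: float = DEFAULT_HORIZON,
    threshold_tol: float = 0.01,
) -> ScanResult:
    """Outcome and patterning time per modulator level, plus thresholds.

    The two reported thresholds are the lowest level producing a
    differential (A:I or I:A) pattern and the lowest level producing
    A:A, each refined by bisection between neighbouring scan levels to
    ``threshold_tol`` (c.u.).  For Sirt1 the differential window lies
    between them (I:I below, A:A above); for Lfng the roles reverse
    (A:A at low, I:I at high Lfng).
    """
    if modulator not in ("sirt1", "lfng"):
        raise ValueError("modulator must be 'sirt1' or 'lfng'")
    if base_inputs is None:
        base_inputs = SIRT1_SCAN_BASE if modulator == "sirt1" else LFNG_SCAN_BASE
    levels = list(levels)
    if any(l <= 0 for l in levels) or sorted(levels) != levels:
        raise ValueError("levels must be positive and sorted")
    outcomes = [
        _scan_outcome(l, modulator, base_inputs, params, horizon) for l in levels
    ]
    table = pd.DataFrame(
        {
            "level": levels,
            "label": [o.label for o in outcomes],
            "patterning_time": [o.patterning_time for o in outcomes],
            "DLL1_final": [o.final_dll[0] for o in outcomes],
            "DLL2_final": [o.final_dll[1] for o in outcomes],
        }
    )

    def _bisect(lo: float, hi: float, pred: Callable[[str], bool]) -> float:
        # invariant: pred holds at hi, not at lo
        while hi - lo > threshold_tol:
            mid = 0.5 * (lo + hi)
            if pred(_scan_outcome(mid, modulator, base_inputs, params, horizon).label):
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    is_diff = lambda lab: lab in ("A:I", "I:A")
    is_aa = lambda lab: lab == "A:A"
    labels = [o.label for o in outcomes]

    diff_thresh = None
    idx = next((i for i, l in enumerate(labels) if is_diff(l) or is_aa(l)), None)
    if idx is not None:
        if idx == 0:
            diff_thresh = levels[0]
        else:
            diff_thresh = _bisect(
                levels[idx - 1], levels[idx], lambda lab: is_diff(lab) or is_aa(lab)
            )
    aa_thresh = None
    idx = next((i for i, l in enumerate(labels) if is_aa(l)), None)
    if idx is not None:
        if idx == 0:
            aa_thresh = levels[0]
        else:
            aa_thresh = _bisect(levels[idx - 1], levels[idx], is_aa)
    return ScanResult(
        table=table,
        differential_threshold=diff_thresh,
        both_active_threshold=aa_thresh,
    )
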