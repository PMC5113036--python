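"""Equilibrium analysis: root finding, linear stability, natural-parameter
continuation with fold (saddle-node) detection, and bistability screening.

Continuation follows a stable branch by root-tracking along the path
parameter with adaptive step halving; a fold is declared where the
branch ceases to continue smoothly (the root either disappears or the
tracker jumps to a distant attractor), and is bracketed in the parameter
to a configurable tolerance.  The branch is then restarted beyond the
fold from a long-time integration, which lands on the next stable
attractor.  This recovers exactly the objects the analysis needs —
stable segments, fold locations and hysteresis — without following
unstable segments through the folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import eig
from scipy.optimize import root

from .model import (
    N_STATE,
    ExternalInputs,
    ModelParams,
    Modulators,
    default_initial_state,
    make_jacobian,
    make_rhs,
    swap_cells,
)

__all__ = [
    "Equilibrium",
    "EquilibriumBranch",
    "DextPath",
    "ModulatorPath",
    "find_equilibria",
    "jacobian",
    "fd_jacobian",
    "continue_branch",
    "detect_bistability",
    "BistabilityEvidence",
]

_RESIDUAL_TOL = 1e-9
_MERGE_RTOL = 1e-4


@dataclass
class Equilibrium:
    """A verified fixed point of the two-cell system."""

    state: np.ndarray
    inputs: ExternalInputs
    mods: Modulators
    stable: bool
    leading_eigenvalue: float  # largest real part of the Jacobian spectrum

    @property
    def dll(self) -> tuple[float, float]:
        return float(self.state[2]), float(self.state[10])


@dataclass
class EquilibriumBranch:
    """Continuation output: one equilibrium per accepted parameter value."""

    parameter_values: list[float]
    equilibria: list[Equilibrium]
    folds: list[tuple[float, np.ndarray]]  # (parameter bracket midpoint, last state)

    def segments(self) -> list[tuple[list[float], list[Equilibrium]]]:
        """Split the branch at its folds into contiguous stable segments."""
        if not self.folds:
            return [(self.parameter_values, self.equilibria)]
        cuts = [f[0] for f in self.folds]
        segs, cur_p, cur_e = [], [], []
        ci = 0
        for p, e in zip(self.parameter_values, self.equilibria):
            while ci < len(cuts) and p > cuts[ci]:
                if cur_p:
                    segs.append((cur_p, cur_e))
                cur_p, cur_e = [], []
                ci += 1
            cur_p.append(p)
            cur_e.append(e)
        if cur_p:
            segs.append((cur_p, cur_e))
        return segs


@dataclass(frozen=True)
class DextPath:
    """Overtaking path: s in [0, 1] maps to Dext1 = s*Dmax, Dext2 = (1-s)*Dmax.

    The endpoints reproduce the pre-switch (cell1 free, cell2 inhibited)
    and post-switch neighbourhoods.  VEGF is held constant and low
    enough that external DLL can switch an active cell off.
    """

    Dmax: float = 12.0
    V: float = 1.0
    mods: Modulators = field(default_factory=Modulators)

    def inputs_at(self, s: float) -> ExternalInputs:
        if not 0.0 <= s <= 1.0:
            raise ValueError("path coordinate s must lie in [0, 1]")
        return ExternalInputs(
            V1=self.V, V2=self.V, Dext1=s * self.Dmax, Dext2=(1.0 - s) * self.Dmax
        )

    def mods_at(self, s: float) -> Modulators:
        return self.mods

    def mirrored(self) -> "DextPath":
        return self

    span: tuple[float, float] = (0.0, 1.0)


@dataclass(frozen=True)
class ModulatorPath:
    """Scalar continuation in a modulator (e.g. Sirt1) at fixed inputs."""

    name: str  # "sirt1" or "lfng"
    span: tuple[float, float] = (0.1, 10.0)
    inputs: ExternalInputs = field(
        default_factory=lambda: ExternalInputs(V1=1.0, V2=1.0, Dext1=1.0, Dext2=2.0)
    )
    other: float = 1.0

    def inputs_at(self, p: float) -> ExternalInputs:
        return self.inputs

    def mods_at(self, p: float) -> Modulators:
        if self.name == "sirt1":
            return Modulators(sirt1=p, lfng=self.other)
        if self.name == "lfng":
            return Modulators(sirt1=self.other, lfng=p)
        raise ValueError(f"unknown modulator {self.name!r}")


def jacobian(
    state: np.ndarray,
    inputs: ExternalInputs,
    params: ModelParams = ModelParams(),
    mods: Modulators = Modulators(),
    t: float = 0.0,
) -> np.ndarray:
    """Analytic 16x16 Jacobian of the derivative function at ``state``."""
    return make_jacobian(inputs, params, mods)(t, np.asarray(state, float))


def fd_jacobian(
    state: np.ndarray,
    inputs: ExternalInputs,
    params: ModelParams = ModelParams(),
    mods: Modulators = Modulators(),
    t: float = 0.0,
    eps: float = 1e-7,
) -> np.ndarray:
    """Central finite-difference Jacobian (independent check of the analytic one)."""
    rhs = make_rhs(inputs, params, mods)
    y = np.asarray(state, float)
    J = np.empty((N_STATE, N_STATE))
    for j in range(N_STATE):
        h = eps * max(abs(y[j]), 1.0)
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (rhs(t, yp) - rhs(t, ym)) / (2.0 * h)
    return J


def _stability(J: np.ndarray) -> tuple[bool, float]:
    lead = float(np.max(eig(J, right=False).real))
    return lead < 0.0, lead


def _polish(
    guess: np.ndarray,
    inputs: ExternalInputs,
    params: ModelParams,
    mods: Modulators,
) -> np.ndarray | None:
    rhs = make_rhs(inputs, params, mods)
    jac = make_jacobian(inputs, params, mods)
    sol = root(lambda y: rhs(0.0, y), guess, jac=lambda y: jac(0.0, y), method="hybr")
    if not sol.success:
        return None
    if np.max(np.abs(rhs(0.0, sol.x))) > _RESIDUAL_TOL:
        return None
    return sol.x


def _is_new(x: np.ndarray, found: list[np.ndarray]) -> bool:
    for f in found:
        if np.linalg.norm(x - f) <= _MERGE_RTOL * (1.0 + np.linalg.norm(f)):
            return False
    return True


class BudgetExceeded(RuntimeError):
    """Raised when a relaxation run exceeds its derivative-evaluation budget."""


def _settle(
    y0: np.ndarray,
    inputs: ExternalInputs,
    params: ModelParams,
    mods: Modulators,
    horizon: float = 20000.0,
    budget: list[int] | None = None,
) -> np.ndarray:
    rhs = make_rhs(inputs, params, mods)
    if budget is not None:
        inner = rhs

        def rhs(t, y):  # noqa: ANN001 - solver callback
            budget[0] -= 1
            if budget[0] < 0:
                raise BudgetExceeded("derivative-evaluation budget exhausted")
            return inner(t, y)

    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        y0,
        method="LSODA",
        jac=make_jacobian(inputs, params, mods),
        rtol=1e-8,
        atol=1e-10,
    )
    return sol.y[:, -1]


def _patterned_seed(
    V: float, params: ModelParams, mods: Modulators, budget: list[int] | None = None
) -> np.ndarray:
    """Candidate A:I state: ignite cell1 under a one-sided VEGF exposure."""
    return _settle(
        default_initial_state(),
        ExternalInputs(V1=max(V, 5.0), V2=0.0),
        params,
        mods,
        budget=budget,
    )


def find_equilibria(
    inputs: ExternalInputs,
    params: ModelParams = ModelParams(),
    mods: Modulators = Modulators(),
    n_seeds: int = 8,
    seed: int = 0,
) -> list[Equilibrium]:
    """Multi-start equilibrium search.

    Deterministic seeds (long-time integration endpoints from the
    quiescent start, a cell1-ignited start and its mirror) are augmented
    with ``n_seeds`` random states drawn over plausible concentration
    ranges.  Roots are polished, verified to residual < 1e-9, merged
    within relative tolerance and annotated with stability.  The result
    is a set: independent of seed ordering.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    if not inputs.is_constant:
        raise ValueError("equilibria are defined for constant inputs only")
    v1, v2, _, _ = inputs.at(0.0)
    guesses: list[np.ndarray] = []
    guesses.append(_settle(default_initial_state(), inputs, params, mods))
    pat = _settle(_patterned_seed(max(v1, v2), params, mods), inputs, params, mods)
    guesses.append(pat)
    guesses.append(_settle(swap_cells(pat), inputs, params, mods))
    rng = np.random.default_rng(seed)
    # plausible per-species scales: receptor/notch ~ gamma/phi, DLL/HE ~ theta/phi
    scales = np.array([5.0, 5.0, 100.0, 5.0, 2.0, 20.0, 100.0, 2500.0] * 2)
    for _ in range(n_seeds):
        guesses.append(rng.random(N_STATE) * scales)
    found: list[np.ndarray] = []
    out: list[Equilibrium] = []
    for g in guesses:
        x = _polish(g, inputs, params, mods)
        if x is None or not _is_new(x, found):
            continue
        found.append(x)
        stable, lead = _stability(jacobian(x, inputs, params, mods))
        out.append(Equilibrium(x, inputs, mods, stable, lead))
    return out


def continue_branch(
    start: Equilibrium,
    path: DextPath | ModulatorPath,
    params: ModelParams = ModelParams(),
    *,
    initial_step: float | None = None,
    min_step: float | None = None,
    jump_tol: float = 0.3,
    settle_horizon: float = 60000.0,
) -> EquilibriumBranch:
    """Trace the stable branch containing ``start`` along ``path``.

    Natural-parameter continuation with adaptive step halving; folds are
    bracketed to ``min_step`` (default 1e-3 of the span) and the branch
    restarts past each fold from a long-time integration.  Each accepted
    point is annotated with stability.
    """
    p0, p1 = path.span
    span = p1 - p0
    if span == 0:
        return EquilibriumBranch([p0], [start], [])
    h0 = abs(span) / 50.0 if initial_step is None else initial_step
    hmin = abs(span) * 1e-3 if min_step is None else min_step

    def solve_at(p: float, guess: np.ndarray) -> np.ndarray | None:
        return _polish(guess, path.inputs_at(p), params, path.mods_at(p))

    def accept(p: float, x: np.ndarray) -> Equilibrium:
        stable, lead = _stability(jacobian(x, path.inputs_at(p), params, path.mods_at(p)))
        return Equilibrium(x, path.inputs_at(p), path.mods_at(p), stable, lead)

    ps: list[float] = [p0]
    eqs: list[Equilibrium] = [accept(p0, start.state)]
    folds: list[tuple[float, np.ndarray]] = []
    p = p0
    x = np.asarray(start.state, float)
    h = h0
    direction = 1.0 if span > 0 else -1.0
    while direction * (p1 - p) > 1e-12:
        h = min(h, abs(p1 - p))
        p_try = p + direction * h
        x_try = solve_at(p_try, x)
        ok = x_try is not None and np.linalg.norm(x_try - x) <= jump_tol * (
            1.0 + np.linalg.norm(x)
        )
        if ok:
            p, x = p_try, x_try
            ps.append(p)
            eqs.append(accept(p, x))
            h = min(h * 1.5, h0)
            continue
        if h > hmin:
            h = h / 2.0
            continue
        # fold bracketed between p and p + direction*hmin
        fold_p = p + direction * h / 2.0
        folds.append((fold_p, x.copy()))
        # restart beyond the fold on whatever attractor the flow selects
        p_next = p + direction * max(h0, 2.0 * hmin)
        if direction * (p1 - p_next) < 0:
            p_next = p1
        y = _settle(
            x, path.inputs_at(p_next), params, path.mods_at(p_next), settle_horizon
        )
        x_next = solve_at(p_next, y)
        if x_next is None:
            break
        p, x = p_next, x_next
        ps.append(p)
        eqs.append(accept(p, x))
        h = h0
        if p == p1:
            break
    return EquilibriumBranch(ps, eqs, folds)


@dataclass
class BistabilityEvidence:
    """Witness for (or against) bistability over a VEGF range."""

    bistable: bool
    vegf: float | None = None
    states: list[np.ndarray] = field(default_factory=list)


def detect_bistability(
    params: ModelParams = ModelParams(),
    vegf_range: tuple[float, float] = (0.0, 10.0),
    mods: Modulators = Modulators(),
    n_vegf: int = 21,
    horizon: float = 20000.0,
    max_nfev: int = 250_000,
) -> BistabilityEvidence:
    """Test whether some symmetric VEGF level admits >= 2 stable equilibria.

    For each lattice VEGF value (ordered from the mid-range outward,
    where patterned and unpatterned states most often coexist), candidate
    attractors are generated by integration from the quiescent start and
    from a cell1-ignited start, polished to verified equilibria and
    compared; the search stops at the first VEGF value with two distinct
    stable states.  ``max_nfev`` caps the total derivative evaluations of
    one call so that pathologically stiff parameter sets fail loudly
    (:class:`BudgetExceeded`) instead of stalling a screen; the cap is a
    deterministic property of the problem, not of the host machine.
    """
    lattice = np.linspace(vegf_range[0], vegf_range[1], n_vegf)
    mid = 0.3 * (vegf_range[0] + vegf_range[1])
    order = np.argsort(np.abs(lattice - mid), kind="stable")
    budget = [max_nfev]
    for V in lattice[order]:
        inputs = ExternalInputs(V1=float(V), V2=float(V))
        candidates = [
            _settle(default_initial_state(), inputs, params, mods, horizon, budget),
            _settle(
                _patterned_seed(float(V), params, mods, budget),
                inputs,
                params,
                mods,
                horizon,
                budget,
            ),
        ]
        stable_states: list[np.ndarray] = []
        for c in candidates:
            x = _polish(c, inputs, params, mods)
            if x is None:
                continue
            stable, _ = _stability(jacobian(x, inputs, params, mods))
            if stable and _is_new(x, stable_states):
                stable_states.append(x)
        if len(stable_states) >= 2:
            return BistabilityEvidence(True, float(V), stable_states)
        # an asymmetric stable state at symmetric inputs implies its mirror
        for x in stable_states:
            if np.linalg.norm(x - swap_cells(x)) > _MERGE_RTOL * (1 + np.linalg.norm(x)):
                return BistabilityEvidence(True, float(V), [x, swap_cells(x)])
    return BistabilityEvidence(False)
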