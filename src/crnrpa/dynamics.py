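"""Numerical dynamics: step-response simulation, RPA verification, stability sweep.

Simulations integrate the mass-action system piecewise over a step protocol
for the chemostatted input, restarting at every switch so the input change
is exact.  The stability sweep draws random rate constants, evaluates the
closed-form steady state and the Jacobian there, and classifies each draw
by the sign of the largest eigenvalue real part.

Because a randomly drawn parameter set need not admit a positive steady
state, three classification modes are reported:

``formal``
    classify by the eigenvalues at the algebraic steady state whatever its
    sign — the behaviour of a symbolic solve-then-eigenvalue pipeline with
    no positivity screen (the default);
``strict``
    draws without a strictly positive steady state count as not stable;
``feasible_only``
    such draws are excluded from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import sympy as sp
from scipy.integrate import solve_ivp

from .crn import ParameterSet, ValidationError
from .mass_action import OdeSystem, SteadyState, closed_form_steady_state, jacobian

__all__ = [
    "StepProtocol",
    "Trajectory",
    "SweepResult",
    "RpaVerdict",
    "SimulationError",
    "DEFAULT_STEP_LEVELS",
    "DEFAULT_SEGMENT_LENGTH",
    "default_protocol",
    "simulate",
    "verify_rpa",
    "stability_sweep",
]

DEFAULT_STEP_LEVELS: tuple[float, ...] = (1.0, 2.0, 4.0)
DEFAULT_SEGMENT_LENGTH: float = 100.0

STABILITY_MARGIN = -1e-9  # strict left-half-plane test with a float guard


class SimulationError(Exception):
    """Integration failure; carries the failing protocol segment."""

    def __init__(self, message: str, segment: int):
        super().__init__(f"segment {segment}: {message}")
        self.segment = segment


@dataclass(frozen=True)
class StepProtocol:
    """Piecewise-constant input: (switch time, level) pairs plus an end time."""

    steps: tuple[tuple[float, float], ...]
    end_time: float

    def __post_init__(self) -> None:
        if not self.steps or self.steps[0][0] != 0.0:
            raise ValidationError("protocol must start at time 0")
        times = [t for t, _ in self.steps]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("switch times must be strictly increasing")
        if any(level <= 0 for _, level in self.steps):
            raise ValidationError("input levels must be positive")
        if self.end_time < self.steps[-1][0]:
            raise ValidationError("end time precedes the last switch")

    @property
    def levels(self) -> tuple[float, ...]:
        return tuple(level for _, level in self.steps)

    def segments(self) -> list[tuple[float, float, float]]:
        """(start, stop, level) triples; the last may have zero duration."""
        bounds = [t for t, _ in self.steps] + [self.end_time]
        return [
            (bounds[i], bounds[i + 1], self.steps[i][1])
            for i in range(len(self.steps))
        ]


def default_protocol() -> StepProtocol:
    steps = tuple(
        (i * DEFAULT_SEGMENT_LENGTH, level)
        for i, level in enumerate(DEFAULT_STEP_LEVELS)
    )
    return StepProtocol(steps, end_time=len(DEFAULT_STEP_LEVELS) * DEFAULT_SEGMENT_LENGTH)


@dataclass(frozen=True)
class Trajectory:
    """Dense simulation output with the protocol and parameters that produced it."""

    times: np.ndarray
    states: np.ndarray  # time x species
    species: tuple[str, ...]
    protocol: StepProtocol
    params: ParameterSet
    segment_ends: tuple[int, ...]  # index of the last sample of each segment

    def final_state(self, segment: int = -1) -> dict[str, float]:
        idx = self.segment_ends[segment]
        return dict(zip(self.species, self.states[idx]))

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.states, columns=list(self.species))
        frame.insert(0, "time", self.times)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _rhs_function(odes: OdeSystem) -> Callable:
    """Callable (state, param_values, input_levels) -> list of derivatives."""
    inputs = list(odes.inputs)
    args = (list(odes.variables), list(odes.parameters), inputs)
    fun = sp.lambdify(args, list(odes.rhs), modules="numpy")
    if inputs:
        return fun
    return lambda state, pvals, _levels: fun(state, pvals, [])


def simulate(
    odes: OdeSystem,
    params: ParameterSet,
    initial_state: Mapping[str, float],
    protocol: StepProtocol | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    points_per_segment: int = 200,
) -> Trajectory:
    """Integrate the ODE system under a step-input protocol.

    Integration restarts at every input switch with the new level; output
    is on a uniform grid within each segment.
    """
    params.require_complete(odes.crn)
    protocol = protocol or default_protocol()
    rhs = _rhs_function(odes)
    pvals = [params[p.name] for p in odes.parameters]
    y = np.array([float(initial_state[v.name]) for v in odes.variables])
    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    seg_ends: list[int] = []
    count = 0
    for seg_no, (start, stop, level) in enumerate(protocol.segments()):
        if stop == start:  # zero-duration tail: record the switch point only
            times.append(np.array([start]))
            states.append(y[None, :])
            count += 1
            seg_ends.append(count - 1)
            continue

        def fun(t, state, _level=level):
            return rhs(state, pvals, [_level])

        grid = np.linspace(start, stop, points_per_segment)
        sol = solve_ivp(
            fun, (start, stop), y, method=method, t_eval=grid, rtol=rtol, atol=atol
        )
        if not sol.success:
            raise SimulationError(sol.message, seg_no)
        y = sol.y[:, -1].copy()
        times.append(sol.t)
        states.append(sol.y.T)
        count += len(sol.t)
        seg_ends.append(count - 1)
    return Trajectory(
        times=np.concatenate(times),
        states=np.vstack(states),
        species=tuple(v.name for v in odes.variables),
        protocol=protocol,
        params=params,
        segment_ends=tuple(seg_ends),
    )


@dataclass(frozen=True)
class RpaVerdict:
    """Per-species adaptation verdict over the protocol's segment ends."""

    species: str
    verdict: str  # "rpa" | "not_rpa" | "inconclusive"
    end_values: tuple[float, ...]
    setpoint: float | None


def verify_rpa(
    trajectory: Trajectory,
    odes: OdeSystem,
    setpoints: Mapping[str, float],
    rel_tol: float = 1e-5,
    residual_tol: float = 1e-8,
) -> dict[str, RpaVerdict]:
    """Check which species return to a fixed setpoint after every input step.

    A species passes when its end-of-segment values agree with the declared
    setpoint (relative tolerance) at every input level; it fails when the
    end values spread across levels by more than the tolerance.  Segments
    whose right-hand-side residual has not converged yield an inconclusive
    verdict.
    """
    rhs = _rhs_function(odes)
    pvals = [trajectory.params[p.name] for p in odes.parameters]
    segments = trajectory.protocol.segments()
    converged = True
    for seg_no, end_idx in enumerate(trajectory.segment_ends):
        level = segments[seg_no][2]
        res = np.array(rhs(trajectory.states[end_idx], pvals, [level]), dtype=float)
        if np.linalg.norm(res) > residual_tol * max(1.0, np.max(np.abs(trajectory.states[end_idx]))):
            converged = False
    out: dict[str, RpaVerdict] = {}
    for i, name in enumerate(trajectory.species):
        ends = tuple(float(trajectory.states[idx, i]) for idx in trajectory.segment_ends)
        target = setpoints.get(name)
        scale = max(abs(v) for v in ends) or 1.0
        if not converged:
            out[name] = RpaVerdict(name, "inconclusive", ends, target)
        elif target is not None:
            hit = all(
                abs(v - target) <= rel_tol * max(abs(target), 1.0) for v in ends
            )
            out[name] = RpaVerdict(name, "rpa" if hit else "not_rpa", ends, target)
        else:
            flat = (max(ends) - min(ends)) <= rel_tol * scale
            out[name] = RpaVerdict(name, "rpa" if flat else "not_rpa", ends, target)
    return out


@dataclass(frozen=True)
class SweepResult:
    """Stability classification counts over random parameter draws.

    Per trial: ``stable_feasible`` (positive steady state, all eigenvalues
    strictly in the left-half plane), ``unstable_feasible``, ``infeasible``
    (no strictly positive steady state) and ``formal_stable`` (eigenvalue
    test at the algebraic steady state regardless of sign).
    """

    n_samples: int
    n_trials: int
    seed: int
    bounds: tuple[float, float]
    sample_input: bool
    input_level: float
    mode: str
    stable_feasible: tuple[int, ...]
    unstable_feasible: tuple[int, ...]
    infeasible: tuple[int, ...]
    formal_stable: tuple[int, ...]

    MODES = ("formal", "strict", "feasible_only")

    def fraction_stable(self, mode: str | None = None) -> tuple[float, ...]:
        mode = mode or self.mode
        if mode not in self.MODES:
            raise ValueError(f"unknown mode {mode!r}")
        out = []
        for t in range(self.n_trials):
            if mode == "formal":
                num, den = self.formal_stable[t], self.n_samples
            elif mode == "strict":
                num, den = self.stable_feasible[t], self.n_samples
            else:
                num = self.stable_feasible[t]
                den = self.stable_feasible[t] + self.unstable_feasible[t]
            out.append(num / den if den else float("nan"))
        return tuple(out)

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_trials": self.n_trials,
            "seed": self.seed,
            "bounds": list(self.bounds),
            "sample_input": self.sample_input,
            "input_level": self.input_level,
            "mode": self.mode,
            "stable_feasible": list(self.stable_feasible),
            "unstable_feasible": list(self.unstable_feasible),
            "infeasible": list(self.infeasible),
            "formal_stable": list(self.formal_stable),
            "fraction_stable": {
                m: list(self.fraction_stable(m)) for m in self.MODES
            },
        }


def stability_sweep(
    odes: OdeSystem,
    n_samples: int = 10_000,
    n_trials: int = 10,
    seed: int = 0,
    bounds: tuple[float, float] = (1.0, 50.0),
    sample_input: bool = True,
    input_level: float = 1.0,
    mode: str = "formal",
    steady_state: SteadyState | None = None,
) -> SweepResult:
    """Random-parameter stability classification of the closed-form steady state.

    Each draw assigns every rate constant — and, when ``sample_input`` is
    true, the input level — an i.i.d. uniform value on the open interval
    ``bounds``.  Deterministic for a fixed seed.
    """
    if mode not in SweepResult.MODES:
        raise ValueError(f"unknown mode {mode!r}")
    ss = steady_state or closed_form_steady_state(odes)
    (input_sym,) = odes.inputs
    psyms = list(odes.parameters)
    ss_fun = sp.lambdify(
        (psyms, input_sym), [ss[v] for v in odes.variables], modules="numpy"
    )
    jac_fun = sp.lambdify(
        (psyms, input_sym, list(odes.variables)),
        jacobian(odes),
        modules="numpy",
    )
    stable_l, unstable_l, infeas_l, formal_l = [], [], [], []
    for trial in range(n_trials):
        rng = np.random.default_rng(np.random.SeedSequence([seed, trial]))
        draws = _open_uniform(rng, bounds, (n_samples, len(psyms)))
        if sample_input:
            cl = _open_uniform(rng, bounds, (n_samples,))
        else:
            cl = np.full(n_samples, input_level)
        if n_samples:
            states = np.array(ss_fun(draws.T, cl), dtype=float).T
        else:
            states = np.empty((0, len(odes.variables)))
        stable = unstable = infeasible = formal = 0
        for i in range(n_samples):
            x = states[i]
            if not np.all(np.isfinite(x)):
                infeasible += 1
                continue
            jac = np.array(jac_fun(draws[i], cl[i], x), dtype=float)
            is_stable = bool(np.max(np.linalg.eigvals(jac).real) < STABILITY_MARGIN)
            formal += is_stable
            if np.all(x > 0):
                stable += is_stable
                unstable += not is_stable
            else:
                infeasible += 1
        stable_l.append(int(stable))
        unstable_l.append(int(unstable))
        infeas_l.append(int(infeasible))
        formal_l.append(int(formal))
    return SweepResult(
        n_samples=n_samples,
        n_trials=n_trials,
        seed=seed,
        bounds=bounds,
        sample_input=sample_input,
        input_level=input_level,
        mode=mode,
        stable_feasible=tuple(stable_l),
        unstable_feasible=tuple(unstable_l),
        infeasible=tuple(infeas_l),
        formal_stable=tuple(formal_l),
    )


def _open_uniform(
    rng: np.random.Generator, bounds: tuple[float, float], shape
) -> np.ndarray:
    """Uniform draws on the open interval (low, high); endpoints rejected."""
    low, high = bounds
    out = rng.uniform(low, high, size=shape)
    mask = (out == low) | (out == high)
    while np.any(mask):
        out[mask] = rng.uniform(low, high, size=int(mask.sum()))
        mask = (out == low) | (out == high)
    return out
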