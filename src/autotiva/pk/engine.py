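"""Exact three-compartment + effect-site simulation and TCI targeting.

The model is the standard linear mammillary system written in V1-normalised
concentrations x = (c1, c2, c3, ce):

    dc1/dt = -(k10+k12+k13)·c1 + k21·c2 + k31·c3 + r(t)/V1
    dc2/dt =  k12·c1 - k21·c2
    dc3/dt =  k13·c1 - k31·c3
    dce/dt =  ke0·(c1 - ce)

For a segment of constant infusion rate r the solution is exact:
x(t+dt) = e^{A dt} x(t) + r·g(dt), with g = A⁻¹(e^{A dt} − I)·e1/V1.
Both matrices are cached per (params, dt), so stepping a 1-s grid costs one
4×4 mat-vec per drug per second and is bit-reproducible.

Plasma TCI solves the one-step linear equation for the rate that lands c1 on
the target at the end of the control interval. Effect-site TCI finds, by
bisection, the transient plasma target whose predicted peak effect-site
concentration equals the requested target, and emits the current-interval
rate of that profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

from .params import PKParams

__all__ = ["PKState", "PKModel", "InfusionCommandHistory", "TciResult"]


@dataclass(frozen=True)
class PKState:
    """Compartment and effect-site concentrations at time ``t`` (seconds)."""

    c1: float = 0.0
    c2: float = 0.0
    c3: float = 0.0
    ce: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c1", "c2", "c3", "ce"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.c1, self.c2, self.c3, self.ce])


@dataclass(frozen=True)
class TciResult:
    """Outcome of a TCI computation: rate (mass/min) plus diagnostics."""

    rate: float
    mode: str  # "maintenance", "decay", "overshoot", "plasma", "fallback_plasma"
    converged: bool = True


@dataclass
class InfusionCommandHistory:
    """Time-ordered record of infusion segments and boluses for one drug."""

    segments: list[tuple[float, float, float]] = field(default_factory=list)  # (t0, t1, rate)
    boluses: list[tuple[float, float]] = field(default_factory=list)  # (t, dose)

    def add_segment(self, t0: float, t1: float, rate: float) -> None:
        if rate < 0 or t1 <= t0:
            raise ValueError("segment must have t1 > t0 and rate >= 0")
        if self.segments and t0 < self.segments[-1][1]:
            raise ValueError("segments must be non-overlapping and time-ordered")
        self.segments.append((t0, t1, rate))

    def add_bolus(self, t: float, dose: float) -> None:
        if dose < 0:
            raise ValueError("bolus dose must be >= 0")
        self.boluses.append((t, dose))

    def total_dose(self) -> float:
        seg = sum(r * (t1 - t0) / 60.0 for t0, t1, r in self.segments)
        return seg + sum(d for _, d in self.boluses)


def _system_matrix(p: PKParams) -> np.ndarray:
    return np.array(
        [
            [-(p.k10 + p.k12 + p.k13), p.k21, p.k31, 0.0],
            [p.k12, -p.k21, 0.0, 0.0],
            [p.k13, 0.0, -p.k31, 0.0],
            [p.ke0, 0.0, 0.0, -p.ke0],
        ]
    )


class PKModel:
    """Exact stepper and TCI solver bound to one parameter set.

    Rates are mass/min in the drug's mass unit (mg for propofol/rocuronium,
    µg for remifentanil); time arguments are seconds.
    """

    #: prediction grid (s) and horizon (s) for effect-site peak search
    _PRED_DT = 10.0
    _PRED_HORIZON = 1200.0

    def __init__(self, params: PKParams, max_rate: float = np.inf):
        self.params = params
        self.max_rate = max_rate
        self._A = _system_matrix(params)
        self._cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def _propagators(self, dt_s: float) -> tuple[np.ndarray, np.ndarray]:
        """(e^{A dt}, unit-rate input response g) for a dt-second segment."""
        got = self._cache.get(dt_s)
        if got is None:
            dt_min = dt_s / 60.0
            M = expm(self._A * dt_min)
            e1 = np.array([1.0 / self.params.v1, 0.0, 0.0, 0.0])
            g = np.linalg.solve(self._A, (M - np.eye(4)) @ e1)
            got = (M, g)
            self._cache[dt_s] = got
        return got

    # ------------------------------------------------------------------ step

    def step(self, state: PKState, rate: float, dt: float) -> PKState:
        """Advance ``dt`` seconds under a constant infusion ``rate`` (mass/min)."""
        if dt <= 0:
            raise ValueError("dt must be > 0")
        if rate < 0:
            raise ValueError("rate must be >= 0")
        M, g = self._propagators(dt)
        x = M @ state.as_array() + rate * g
        x = np.maximum(x, 0.0)  # guard round-off at zero
        return PKState(x[0], x[1], x[2], x[3], state.t + dt)

    def bolus(self, state: PKState, dose: float) -> PKState:
        """Instantaneous central-compartment dose (mass unit of the drug)."""
        if dose < 0:
            raise ValueError("dose must be >= 0")
        return replace(state, c1=state.c1 + dose / self.params.v1)

    def maintenance_rate(self, target: float) -> float:
        """Rate holding c1 at ``target`` at steady state: target·k10·V1."""
        return target * self.params.k10 * self.params.v1

    # ------------------------------------------------------------- plasma TCI

    def tci_plasma(self, state: PKState, target: float, horizon: float = 10.0) -> float:
        """Constant rate over ``horizon`` s that lands c1 on ``target``.

        Returns 0 when the plasma concentration is already above the target
        (non-negative actuation; the drug then decays naturally).
        """
        if target < 0:
            raise ValueError("target must be >= 0")
        M, g = self._propagators(horizon)
        free_c1 = float(M[0] @ state.as_array())
        if g[0] <= 0:
            return 0.0
        rate = (target - free_c1) / g[0]
        return float(np.clip(rate, 0.0, self.max_rate))

    # --------------------------------------------------------- effect-site TCI

    def _predict_peak_ce(self, state: PKState, plasma_target: float) -> float:
        """Peak ce reached while plasma-targeting ``plasma_target``."""
        M, g = self._propagators(self._PRED_DT)
        x = state.as_array().copy()
        peak = x[3]
        n = int(self._PRED_HORIZON / self._PRED_DT)
        for _ in range(n):
            free_c1 = float(M[0] @ x)
            rate = 0.0
            if g[0] > 0:
                rate = min(max((plasma_target - free_c1) / g[0], 0.0), self.max_rate)
            x = M @ x + rate * g
            if x[3] > peak:
                peak = x[3]
            elif x[3] < peak - 1e-9 and abs(x[0] - plasma_target) < 0.02 * max(plasma_target, 1e-9):
                break  # past the overshoot peak and settled on the plasma target
        return float(peak)

    def tci_effect(
        self,
        state: PKState,
        target: float,
        horizon: float = 10.0,
        rel_tol: float = 0.01,
    ) -> TciResult:
        """Rate for the next interval of an effect-site-targeting profile.

        Near the target the controller degenerates to plasma maintenance at
        the effect target; above it the pump stops and the drug decays;
        otherwise a transient plasma target is found by bisection so the
        predicted ce peak matches ``target``.
        """
        if target < 0:
            raise ValueError("target must be >= 0")
        if target == 0.0:
            return TciResult(0.0, "decay")
        tol = rel_tol * target
        if state.ce > target + tol:
            # Overshot: let it fall, but do not undershoot plasma below target.
            return TciResult(self.tci_plasma(state, target, horizon), "overshoot")
        if abs(state.ce - target) <= tol:
            return TciResult(self.tci_plasma(state, target, horizon), "maintenance")

        lo, hi = target, 10.0 * target
        peak_hi = self._predict_peak_ce(state, hi)
        for _ in range(6):  # expand bracket if even 10× cannot reach the target
            if peak_hi >= target:
                break
            hi *= 2.0
            peak_hi = self._predict_peak_ce(state, hi)
        else:
            return TciResult(self.tci_plasma(state, target, horizon), "fallback_plasma", False)

        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if self._predict_peak_ce(state, mid) < target:
                lo = mid
            else:
                hi = mid
            if (hi - lo) <= rel_tol * target:
                break
        return TciResult(self.tci_plasma(state, hi, horizon), "plasma")
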