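"""BrAC clamp controller: prescribed exposure dynamics under pump constraints.

The paradigm prescribes the entire BrAC path: each earned alcohol reward
raises BrAC by +13 mg/dL over 3.0 min, and between rewards BrAC falls
linearly at -0.8 mg/dL per minute (floored at zero) for as long as the
pharmacokinetics permit.  The controller holds an internal copy of the
subject's disposition model, inverts it each control step to obtain the pump
rate that meets the target at the end of the step (model-inversion
feedforward), adds a proportional feedback correction, and saturates at the
pump limits [0, 1998] ml/h.  Periodic breathalyzer readings re-calibrate the
model (multiplicative vmax rescale, bounded per update, plus assimilation of
the reading into the model state).

Saline ("water") rewards run 5 ml/min of normal saline for 3 min through the
same line and leave the BrAC target untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pharmacokinetics import (
    PKParameters,
    PKState,
    BrACReading,
    PUMP_MAX_ML_H,
    ethanol_mass_rate_to_infusion,
    measure_brac,
    step_pk,
    _as_rng,
)

__all__ = [
    "REWARD_INCREMENT_MG_DL",
    "REWARD_RAMP_MIN",
    "DECLINE_MG_DL_MIN",
    "SAFETY_LIMIT_MG_DL",
    "SALINE_RATE_ML_H",
    "SALINE_DURATION_MIN",
    "TargetTrajectory",
    "InfusionCommand",
    "ControllerState",
    "extend_target_for_reward",
    "feedforward_rate",
    "recalibrate",
    "reward_eligible",
    "ClampSession",
]

REWARD_INCREMENT_MG_DL = 13.0
REWARD_RAMP_MIN = 3.0
DECLINE_MG_DL_MIN = 0.8
SAFETY_LIMIT_MG_DL = 180.0
SALINE_RATE_ML_H = 300.0  # 5 ml/min
SALINE_DURATION_MIN = 3.0


@dataclass(frozen=True)
class TargetTrajectory:
    """Piecewise-linear prescribed BrAC path.

    Between alcohol rewards the slope is exactly -DECLINE_MG_DL_MIN until the
    zero floor; during an alcohol reward the path ramps +13 mg/dL over
    3.0 min.  ``ramps`` holds (t_start, v_start, v_end) triples in
    chronological order; ``reward_events`` records every reward, including
    saline rewards, which do not alter the path.
    """

    t0: float = 0.0
    v0: float = 0.0
    ramps: tuple = ()
    reward_events: tuple = ()

    def value(self, t: float) -> float:
        """Target BrAC (mg/dL) at time ``t``."""
        if t <= self.t0:
            return self.v0
        prev_t, prev_v = self.t0, self.v0
        for ts, vs, ve in self.ramps:
            if t < ts:
                return max(0.0, prev_v - DECLINE_MG_DL_MIN * (t - prev_t))
            if t <= ts + REWARD_RAMP_MIN:
                return vs + (ve - vs) * (t - ts) / REWARD_RAMP_MIN
            prev_t, prev_v = ts + REWARD_RAMP_MIN, ve
        return max(0.0, prev_v - DECLINE_MG_DL_MIN * (t - prev_t))

    @property
    def breakpoints(self) -> list[tuple[float, float]]:
        pts = [(self.t0, self.v0)]
        for ts, vs, ve in self.ramps:
            pts.append((ts, vs))
            pts.append((ts + REWARD_RAMP_MIN, ve))
        return pts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.breakpoints, columns=["t_min", "target_brac_mg_dl"])


def extend_target_for_reward(
    traj: TargetTrajectory,
    t: float,
    kind: str,
    anchor: Optional[float] = None,
) -> TargetTrajectory:
    """Append a reward at time ``t``.

    An alcohol reward appends a +13 mg/dL ramp over 3.0 min (starting from
    ``anchor`` if given, else from the trajectory's own value at ``t``) after
    which the -0.8 mg/dL/min decline resumes.  A saline reward appends
    nothing to the BrAC target; it is only recorded as an event.
    """
    if kind not in ("alcohol", "saline"):
        raise ValueError(f"unknown reward kind {kind!r}")
    if traj.ramps and t < traj.ramps[-1][0] + REWARD_RAMP_MIN - 1e-9:
        raise ValueError("reward time precedes the end of the last ramp")
    events = traj.reward_events + ((t, kind),)
    if kind == "saline":
        return replace(traj, reward_events=events)
    v = traj.value(t) if anchor is None else float(anchor)
    ramps = traj.ramps + ((t, v, v + REWARD_INCREMENT_MG_DL),)
    return replace(traj, ramps=ramps, reward_events=events)


@dataclass(frozen=True)
class InfusionCommand:
    t: float
    rate_ml_h: float
    kind: str = "ethanol_solution"  # or "saline"

    def __post_init__(self) -> None:
        limit = PUMP_MAX_ML_H if self.kind == "ethanol_solution" else SALINE_RATE_ML_H
        if not 0.0 <= self.rate_ml_h <= limit + 1e-9:
            raise ValueError(f"{self.kind} rate {self.rate_ml_h} outside [0, {limit}]")


@dataclass
class ControllerState:
    """The controller's current belief about the subject and its feedback gain."""

    params_est: PKParameters
    model: PKState
    gain: float = 0.5
    last_reading: Optional[BrACReading] = None


def feedforward_rate(
    ctrl: ControllerState, traj: TargetTrajectory, t: float, dt: float
) -> InfusionCommand:
    """Pump rate for the next ``dt`` minutes: model inversion plus feedback.

    The rate is the one that makes the estimated model's BrAC meet the target
    at ``t + dt``, plus ``gain`` times the current target error, saturated at
    the pump limits.  Saturation is not an error: a target decline steeper
    than the model can realize simply yields rate 0.
    """
    p, m = ctrl.params_est, ctrl.model
    target_next = traj.value(t + dt) / 100.0  # g/L
    target_now = traj.value(t) / 100.0
    vc = p.central_volume_l
    cc, cp = m.c_central, m.c_peripheral
    elim = p.vmax_g_min * cc / (p.km_g_l + cc) if cc > 0 else 0.0
    exch = p.k_per_min * p.vd_l * (cc - cp)
    mass_rate = (
        vc * (target_next - cc) / dt
        + exch
        + elim
        + ctrl.gain * (target_now - cc) * vc / dt
    )
    rate = ethanol_mass_rate_to_infusion(mass_rate)
    rate = min(max(rate, 0.0), PUMP_MAX_ML_H)
    return InfusionCommand(t=t, rate_ml_h=rate, kind="ethanol_solution")


def recalibrate(
    ctrl: ControllerState, reading: BrACReading, max_step: float = 0.3
) -> ControllerState:
    """Refine the model from a breathalyzer reading.

    The elimination estimate vmax is rescaled multiplicatively so the model
    tracks the reading (a reading above the prediction means the subject
    eliminated less than modeled), bounded to +-``max_step`` per update, and
    the reading is assimilated into the model's central concentration.
    """
    if ctrl.last_reading is not None and reading.t < ctrl.last_reading.t:
        raise ValueError("readings must be time-ordered")
    pred = ctrl.model.brac
    params = ctrl.params_est
    model = ctrl.model
    if pred > 1.0 and reading.brac > 1.0:
        factor = min(max(pred / reading.brac, 1.0 - max_step), 1.0 + max_step)
        params = replace(params, vmax_g_min=params.vmax_g_min * factor)
        model = replace(model, c_central=reading.brac / 100.0)
    return ControllerState(
        params_est=params, model=model, gain=ctrl.gain, last_reading=reading
    )


def reward_eligible(
    state_or_brac, limit: float = SAFETY_LIMIT_MG_DL, increment: float = REWARD_INCREMENT_MG_DL
) -> bool:
    """True iff an ensuing alcohol reward keeps BrAC at or below the safety limit.

    The gate is inclusive: current BrAC + 13 <= limit passes.  Checked at
    work-set start only.
    """
    if limit <= 0:
        raise ValueError("safety limit must be positive")
    brac = state_or_brac.brac if isinstance(state_or_brac, PKState) else float(state_or_brac)
    return brac + increment <= limit + 1e-9


class ClampSession:
    """One subject coupled to the clamp controller, stepped in lockstep.

    Integrates the *true* subject (``true_params``) and the controller's
    model (``est_params``, defaulting to the true ones) under the same
    command stream, takes breathalyzer readings every
    ``reading_interval_min`` and recalibrates.  The session engine drives
    this object; it can also be used stand-alone for clamp-fidelity studies.
    """

    def __init__(
        self,
        true_params: PKParameters,
        est_params: Optional[PKParameters] = None,
        *,
        t0: float = -25.0,
        initial_state: Optional[PKState] = None,
        dt_min: float = 0.05,
        gain: float = 0.5,
        reading_interval_min: float = 20.0,
        reading_noise_sd: float = 0.0,
        rng=None,
    ) -> None:
        self.true_params = true_params
        self.dt_min = dt_min
        self.rng = _as_rng(rng)
        self.reading_interval_min = reading_interval_min
        self.reading_noise_sd = reading_noise_sd
        if initial_state is None:
            initial_state = PKState(t=t0)
        self.state = initial_state
        model0 = PKState(t=initial_state.t, c_central=initial_state.c_central,
                         c_peripheral=initial_state.c_peripheral)
        self.ctrl = ControllerState(
            params_est=est_params if est_params is not None else true_params,
            model=model0,
            gain=gain,
        )
        self.traj = TargetTrajectory(t0=initial_state.t, v0=initial_state.brac)
        self.brac_series: list[tuple[float, float]] = [(initial_state.t, initial_state.brac)]
        self.infusion_series: list[tuple[float, float, str]] = []
        self.readings: list[BrACReading] = []
        self._saline_until = -np.inf
        self._next_reading = initial_state.t + reading_interval_min

    # -- time propagation ---------------------------------------------------

    @property
    def t(self) -> float:
        return self.state.t

    @property
    def brac(self) -> float:
        return self.state.brac

    @property
    def model_brac(self) -> float:
        return self.ctrl.model.brac

    def advance(self, duration_min: float) -> None:
        """Advance subject and controller by ``duration_min`` minutes."""
        t_end = self.t + duration_min
        while self.t < t_end - 1e-9:
            h = min(self.dt_min, t_end - self.t)
            cmd = feedforward_rate(self.ctrl, self.traj, self.t, h)
            self.infusion_series.append((self.t, cmd.rate_ml_h, cmd.kind))
            if self.t < self._saline_until - 1e-9:
                self.infusion_series.append((self.t, SALINE_RATE_ML_H, "saline"))
            self.state = step_pk(self.state, self.true_params, cmd.rate_ml_h, h)
            self.ctrl.model = step_pk(self.ctrl.model, self.ctrl.params_est, cmd.rate_ml_h, h)
            self.brac_series.append((self.t, self.brac))
            if self.t >= self._next_reading - 1e-9:
                reading = measure_brac(self.state, self.reading_noise_sd, self.rng)
                self.ctrl = recalibrate(self.ctrl, reading)
                self.readings.append(reading)
                self._next_reading += self.reading_interval_min

    def start_reward(self, kind: str) -> None:
        """Register a reward beginning now; caller advances through its 3 min."""
        anchor = self.model_brac if kind == "alcohol" else None
        self.traj = extend_target_for_reward(self.traj, self.t, kind, anchor=anchor)
        if kind == "saline":
            self._saline_until = self.t + SALINE_DURATION_MIN

    def eligible(self, limit: float = SAFETY_LIMIT_MG_DL) -> bool:
        return reward_eligible(self.brac, limit)

    # -- exports ------------------------------------------------------------

    def brac_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.brac_series, columns=["t_min", "brac_mg_dl"])

    def infusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.infusion_series, columns=["t_min", "rate_ml_h", "kind"])
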