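"""One self-administration session: priming, waiting, then 150 min of
voluntary work for rewards under a progressive-ratio schedule.

Timeline (analytical minutes; T = 0 is the start of voluntary work):

* priming interval from T = -25: the subject is prompted to complete two
  small work-sets for saline ("water") and four for alcohol, practicing the
  task and receiving an initial alcohol exposure;
* waiting until T = 0;
* voluntary-work-for-reward (VWR) phase, 150 min: the subject freely chooses
  to work for alcohol, work for water, or rest.  Alcohol work-sets may only
  start if the ensuing +13 mg/dL reward cannot push BrAC above the 180 mg/dL
  safety limit.

Work is a constant attention task (CAT): press and hold a button, release on
a visual prompt, ~7.3 s per trial, with an adaptive reaction-time window (a
multiplicative staircase) holding the success rate near 75 % regardless of
impairment or fatigue.  The number of correct trials per work-set grows
geometrically; the progression is identical for alcohol and water but
accounted separately.  The calibrated defaults make the first work-set last
about 30 s and the 15th about 23 min, past the "futility" point where the
BrAC lost while working exceeds the +13 mg/dL a reward returns.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .agent import BehavioralAgent, DecisionContext, SubjectiveState
from .clamp import (
    ClampSession,
    REWARD_RAMP_MIN,
    SAFETY_LIMIT_MG_DL,
    reward_eligible,
)
from .pharmacokinetics import PKParameters, SubjectProfile

__all__ = [
    "MEAN_TRIAL_S",
    "DEFAULT_RATIO",
    "CalibrationError",
    "WorkSchedule",
    "CATConfig",
    "LatencyModel",
    "SessionConfig",
    "SessionEvent",
    "SessionLog",
    "required_trials",
    "calibrate_schedule",
    "futility_index",
    "run_cat_trial",
    "adapt_window",
    "run_session",
]

MEAN_TRIAL_S = 7.3


class CalibrationError(ValueError):
    """The requested schedule anchors admit no increasing geometric progression."""


# ---------------------------------------------------------------------------
# progressive-ratio schedule


@dataclass(frozen=True)
class WorkSchedule:
    """Geometric progressive-ratio schedule: requirement(k) = round(n1 * ratio^(k-1))."""

    n1: int = 4
    ratio: float = (189.0 / 4.0) ** (1.0 / 14.0)

    def __post_init__(self) -> None:
        if self.n1 < 1:
            raise ValueError("n1 must be at least 1")
        if self.ratio <= 1.0:
            raise ValueError("ratio must exceed 1")


DEFAULT_RATIO = WorkSchedule().ratio


def required_trials(schedule: WorkSchedule, k: int) -> int:
    """Correct CAT trials required to complete the k-th work-set (k >= 1)."""
    if k < 1:
        raise IndexError("work-set index starts at 1")
    return int(schedule.n1 * schedule.ratio ** (k - 1) + 0.5)


def calibrate_schedule(
    first_duration_s: float = 30.0,
    last_index: int = 15,
    last_duration_min: float = 23.0,
    mean_trial_s: float = MEAN_TRIAL_S,
) -> WorkSchedule:
    """Solve the geometric schedule from two anchor durations.

    With the defaults (first set ~30 s, 15th set ~23 min, 7.3 s per trial)
    this yields n1 = 4 and ratio ~= 1.3170.
    """
    if min(first_duration_s, last_duration_min, mean_trial_s) <= 0:
        raise CalibrationError("durations must be positive")
    if last_index < 2:
        raise CalibrationError("last_index must be at least 2")
    n1 = max(1, int(first_duration_s / mean_trial_s + 0.5))
    n_last = int(last_duration_min * 60.0 / mean_trial_s + 0.5)
    if n_last <= n1:
        raise CalibrationError("anchors do not define an increasing progression")
    ratio = (n_last / n1) ** (1.0 / (last_index - 1))
    return WorkSchedule(n1=n1, ratio=ratio)


def futility_index(
    schedule: WorkSchedule,
    mean_trial_s: float = MEAN_TRIAL_S,
    reward_increment: float = 13.0,
    decline: float = 0.8,
    max_index: int = 500,
):
    """First work-set index whose expected work time costs more BrAC than a
    reward returns; ``math.inf`` if the schedule never reaches futility."""
    if decline <= 0:
        return math.inf
    for k in range(1, max_index + 1):
        if required_trials(schedule, k) * mean_trial_s / 60.0 * decline >= reward_increment:
            return k
    return math.inf


# ---------------------------------------------------------------------------
# constant attention task


@dataclass(frozen=True)
class CATConfig:
    """Adaptive attention-task parameters.

    The staircase multiplies the response window by ``window_up`` after a
    failure and ``window_down`` after a success; its equilibrium success
    probability solves p*ln(window_down) + (1-p)*ln(window_up) = 0, which for
    the defaults (1.06, 0.98) sits at ~0.74, near the 0.75 target.
    """

    mean_trial_s: float = MEAN_TRIAL_S
    success_target: float = 0.75
    window_up: float = 1.06
    window_down: float = 0.98
    initial_window_s: float = 0.40
    min_window_s: float = 1e-4
    duration_cv: float = 0.2

    def __post_init__(self) -> None:
        if self.mean_trial_s <= 0:
            raise ValueError("mean_trial_s must be positive")
        if not 0.0 < self.success_target < 1.0:
            raise ValueError("success_target must lie in (0, 1)")
        if self.window_up <= 1.0 or not 0.0 < self.window_down < 1.0:
            raise ValueError("need window_up > 1 and 0 < window_down < 1")

    @property
    def equilibrium_success(self) -> float:
        lu, ld = math.log(self.window_up), math.log(self.window_down)
        return lu / (lu - ld)


@dataclass(frozen=True)
class LatencyModel:
    """Lognormal reaction-time model with BrAC-proportional slowing."""

    base_s: float = 0.28
    sigma: float = 0.30
    impair_per_mg_dl: float = 0.004

    def sample(self, rng: np.random.Generator, brac: float = 0.0) -> float:
        median = self.base_s * (1.0 + self.impair_per_mg_dl * max(brac, 0.0))
        return median * math.exp(self.sigma * rng.standard_normal())


def run_cat_trial(
    cat: CATConfig,
    latency: LatencyModel,
    window_s: float,
    rng: np.random.Generator,
    brac: float = 0.0,
) -> tuple[float, float, bool]:
    """One press-hold-release trial.

    Returns ``(duration_s, reaction_time_s, success)``; draws the trial
    duration first, then the reaction time (the order matters for replay).
    """
    cv = cat.duration_cv
    shape = 1.0 / (cv * cv)
    duration = float(rng.gamma(shape, cat.mean_trial_s / shape))
    rt = latency.sample(rng, brac)
    return duration, rt, rt <= window_s


def adapt_window(cat: CATConfig, window_s: float, success: bool) -> float:
    """Weighted up-down staircase update of the response window."""
    if window_s < 0:
        raise ValueError("window must be non-negative")
    factor = cat.window_down if success else cat.window_up
    return max(cat.min_window_s, window_s * factor)


# ---------------------------------------------------------------------------
# session configuration / log


@dataclass(frozen=True)
class SessionConfig:
    priming_saline: int = 2
    priming_alcohol: int = 4
    priming_trials: int = 4  # fixed requirement per prompted set
    priming_pause_s: float = 0.0
    session_start_min: float = -25.0
    vwr_duration_min: float = 150.0
    safety_limit: float = SAFETY_LIMIT_MG_DL
    assessment_times: tuple = (-25.0, -10.0, 75.0, 150.0)
    dt_min: float = 0.05
    reading_interval_min: float = 20.0
    reading_noise_sd: float = 2.0
    controller_gain: float = 0.5
    schedule: WorkSchedule = field(default_factory=WorkSchedule)
    cat: CATConfig = field(default_factory=CATConfig)
    latency: LatencyModel = field(default_factory=LatencyModel)

    def __post_init__(self) -> None:
        if self.vwr_duration_min <= 0:
            raise ValueError("vwr_duration_min must be positive")
        if self.session_start_min >= 0:
            raise ValueError("session must start before T = 0")
        for ta in self.assessment_times:
            if not self.session_start_min <= ta <= self.vwr_duration_min:
                raise ValueError(f"assessment time {ta} outside the session")


@dataclass(frozen=True)
class SessionEvent:
    t: float
    kind: str  # trial_success | trial_fail | workset_start | workset_complete |
    #            reward_start | reward_end | rest_start | rest_end | assessment
    reward_kind: str = "none"  # alcohol | saline | none
    workset_index: Optional[int] = None


@dataclass
class SessionLog:
    """Time-stamped record of one session."""

    subject_id: str
    session_index: int
    events: list = field(default_factory=list)
    brac_series: list = field(default_factory=list)  # (t, mg/dL)
    infusion_series: list = field(default_factory=list)  # (t, ml/h, kind)
    assessments: list = field(default_factory=list)  # (t, SubjectiveState)
    vwr_duration_min: float = 150.0
    meta: dict = field(default_factory=dict)

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.events])

    def brac_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.brac_series, columns=["t_min", "brac_mg_dl"])

    def infusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.infusion_series, columns=["t_min", "rate_ml_h", "kind"])

    def assessments_frame(self) -> pd.DataFrame:
        rows = [{"t_min": t, **s.as_dict()} for t, s in self.assessments]
        return pd.DataFrame(rows)

    # -- serialization ------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "subject_id": self.subject_id,
            "session_index": self.session_index,
            "vwr_duration_min": self.vwr_duration_min,
            "meta": self.meta,
            "events": [asdict(e) for e in self.events],
            "assessments": [{"t_min": t, **s.as_dict()} for t, s in self.assessments],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "SessionLog":
        payload = json.loads(Path(path).read_text())
        log = cls(
            subject_id=payload["subject_id"],
            session_index=payload["session_index"],
            vwr_duration_min=payload["vwr_duration_min"],
            meta=payload.get("meta", {}),
        )
        log.events = [SessionEvent(**e) for e in payload["events"]]
        for row in payload.get("assessments", []):
            row = dict(row)
            t = row.pop("t_min")
            log.assessments.append((t, SubjectiveState(**row)))
        return log

    def write_csv(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        stem = f"{self.subject_id}_s{self.session_index}"
        self.brac_frame().to_csv(directory / f"{stem}_brac.csv", index=False)
        self.infusion_frame().to_csv(directory / f"{stem}_infusion.csv", index=False)


# ---------------------------------------------------------------------------
# session loop


def run_session(
    profile: SubjectProfile,
    pk_params: PKParameters,
    agent: BehavioralAgent,
    config: SessionConfig | None = None,
    seed: int = 0,
    *,
    est_params: PKParameters | None = None,
    drug_level: float = 0.0,
    session_index: int = 1,
) -> SessionLog:
    """Execute one full session and return its log.

    ``est_params`` is the controller's initial model of the subject (defaults
    to the true parameters); ``drug_level`` is the study-drug blood level in
    ng/ml, 0 for the drug-free or placebo condition.  Replays with the same
    seed are bit-identical.
    """
    cfg = config if config is not None else SessionConfig()
    rng = np.random.default_rng(seed)
    agent.reset(drug_level)

    clamp = ClampSession(
        pk_params,
        est_params,
        t0=cfg.session_start_min,
        dt_min=cfg.dt_min,
        gain=cfg.controller_gain,
        reading_interval_min=cfg.reading_interval_min,
        reading_noise_sd=cfg.reading_noise_sd,
        rng=rng,
    )
    log = SessionLog(
        subject_id=profile.id,
        session_index=session_index,
        vwr_duration_min=cfg.vwr_duration_min,
        meta={"seed": seed, "drug_level": drug_level},
    )
    events = log.events
    assessments = sorted(cfg.assessment_times)
    next_assessment = 0

    def advance(minutes: float) -> None:
        nonlocal next_assessment
        if minutes <= 0:
            return
        brac0 = clamp.brac
        clamp.advance(minutes)
        agent.observe(minutes, clamp.brac, (clamp.brac - brac0) / minutes)
        # the event is stamped at the actual time the rating is taken (the
        # subject may be mid-reward at the nominal time); the assessment row
        # keeps the nominal time point for slope analysis
        while next_assessment < len(assessments) and clamp.t >= assessments[next_assessment] - 1e-9:
            t_a = assessments[next_assessment]
            events.append(SessionEvent(t=clamp.t, kind="assessment"))
            log.assessments.append((t_a, agent.subjective))
            next_assessment += 1

    # baseline assessment (time has not advanced yet)
    while next_assessment < len(assessments) and assessments[next_assessment] <= clamp.t + 1e-9:
        events.append(SessionEvent(t=assessments[next_assessment], kind="assessment"))
        log.assessments.append((assessments[next_assessment], agent.subjective))
        next_assessment += 1

    window = cfg.cat.initial_window_s

    def do_trial(kind: str, workset_index: Optional[int]) -> bool:
        nonlocal window
        duration, rt, success = run_cat_trial(cfg.cat, cfg.latency, window, rng, clamp.brac)
        advance(duration / 60.0)
        window = adapt_window(cfg.cat, window, success)
        events.append(
            SessionEvent(
                t=clamp.t,
                kind="trial_success" if success else "trial_fail",
                reward_kind=kind,
                workset_index=workset_index,
            )
        )
        return success

    def deliver_reward(kind: str, workset_index: Optional[int]) -> None:
        events.append(SessionEvent(t=clamp.t, kind="reward_start", reward_kind=kind,
                                   workset_index=workset_index))
        clamp.start_reward(kind)
        advance(REWARD_RAMP_MIN)
        events.append(SessionEvent(t=clamp.t, kind="reward_end", reward_kind=kind,
                                   workset_index=workset_index))

    # ---- priming interval: prompted work, fixed small requirement --------
    priming_kinds = ["saline"] * cfg.priming_saline + ["alcohol"] * cfg.priming_alcohol
    for kind in priming_kinds:
        events.append(SessionEvent(t=clamp.t, kind="workset_start", reward_kind=kind))
        successes = 0
        while successes < cfg.priming_trials:
            successes += do_trial(kind, None)
        events.append(SessionEvent(t=clamp.t, kind="workset_complete", reward_kind=kind))
        deliver_reward(kind, None)
        if cfg.priming_pause_s > 0:
            advance(cfg.priming_pause_s / 60.0)

    # ---- waiting period until T = 0 ---------------------------------------
    if clamp.t < 0.0:
        advance(-clamp.t)

    # ---- voluntary work for reward ----------------------------------------
    vwr_end = cfg.vwr_duration_min
    next_index = {"alcohol": 1, "saline": 1}
    successes_in_set = {"alcohol": 0, "saline": 0}
    current: Optional[str] = None

    while clamp.t < vwr_end - 1e-9:
        remaining = vwr_end - clamp.t
        if current is None:
            lat = agent.latency_s(rng)
            if lat > 0:
                advance(min(lat / 60.0, remaining))
                if clamp.t >= vwr_end - 1e-9:
                    break
            ctx = DecisionContext(
                eligible_alcohol=reward_eligible(clamp.brac, cfg.safety_limit),
                current_workset=None,
            )
            action = agent.decide(ctx, rng, t_hours=max(clamp.t, 0.0) / 60.0)
            if action == "rest":
                events.append(SessionEvent(t=clamp.t, kind="rest_start"))
                advance(min(agent.rest_duration_s / 60.0, vwr_end - clamp.t))
                events.append(SessionEvent(t=clamp.t, kind="rest_end"))
                continue
            current = "alcohol" if action == "work_alcohol" else "saline"
            events.append(
                SessionEvent(t=clamp.t, kind="workset_start", reward_kind=current,
                             workset_index=next_index[current])
            )
        else:
            ctx = DecisionContext(
                eligible_alcohol=reward_eligible(clamp.brac, cfg.safety_limit),
                current_workset=current,
            )
            action = agent.decide(ctx, rng, t_hours=max(clamp.t, 0.0) / 60.0)
            if action == "rest":
                events.append(SessionEvent(t=clamp.t, kind="rest_start"))
                advance(min(agent.rest_duration_s / 60.0, vwr_end - clamp.t))
                events.append(SessionEvent(t=clamp.t, kind="rest_end"))
                continue
            k = next_index[current]
            successes_in_set[current] += do_trial(current, k)
            if successes_in_set[current] >= required_trials(cfg.schedule, k):
                events.append(
                    SessionEvent(t=clamp.t, kind="workset_complete", reward_kind=current,
                                 workset_index=k)
                )
                deliver_reward(current, k)
                next_index[current] += 1
                successes_in_set[current] = 0
                current = None

    # flush any assessments at/after the session end (e.g. the end rating)
    while next_assessment < len(assessments):
        t_a = assessments[next_assessment]
        events.append(SessionEvent(t=max(clamp.t, t_a), kind="assessment"))
        log.assessments.append((t_a, agent.subjective))
        next_assessment += 1

    log.brac_series = clamp.brac_series
    log.infusion_series = clamp.infusion_series
    return log
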