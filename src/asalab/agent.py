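"""Behavioral model of the participant.

The agent chooses between working for alcohol, working for saline ("water"),
and resting, via a softmax over utilities; it also carries a visual-analog
(0-100) subjective state that responds to the current BrAC level and slope.
Rising BrAC feeds stimulation and wellbeing (positive reinforcement);
falling BrAC feeds "desire" for more alcohol (negative reinforcement,
i.e. working to fight the unpleasant feeling of a dropping level).

A study drug enters through a single attenuation parameter: the positive-
reinforcement pathway (both the hedonic response to rising BrAC and its
weight in the work utility) is scaled by ``1 - delta * drug_level``, where
``drug_level`` is the blood level in ng/ml.  A config switch optionally
attenuates the negative-reinforcement weight as well, so contingency
hypotheses can be probed.

The subjective dynamics are linear gains with exponential return to
baseline, slope-asymmetric in the Mellanby spirit: the paradigm the model
emulates measures these scales but does not model them, so only signs and
directions are asserted anywhere; every gain is a parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "AgentParams",
    "SubjectiveState",
    "DecisionContext",
    "ACTIONS",
    "update_subjective",
    "decide_action",
    "BehavioralAgent",
    "ScriptedAgent",
    "scripted_agent",
]

ACTIONS = ("work_alcohol", "work_water", "rest")


@dataclass(frozen=True)
class SubjectiveState:
    """VAS-like internal state, each scale clipped to [0, 100]."""

    stimulation: float = 20.0
    sedation: float = 10.0
    wellbeing: float = 50.0
    desire: float = 30.0
    drunkenness: float = 0.0

    def __post_init__(self) -> None:
        for name in ("stimulation", "sedation", "wellbeing", "desire", "drunkenness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside VAS range [0, 100]")

    def as_dict(self) -> dict:
        return {
            "stimulation": self.stimulation,
            "sedation": self.sedation,
            "wellbeing": self.wellbeing,
            "desire": self.desire,
            "drunkenness": self.drunkenness,
        }


@dataclass(frozen=True)
class AgentParams:
    """Parameters of the behavioral model.

    Decision side (utilities are dimensionless; softmax ``temperature`` sets
    choice noise, 0 reduces to argmax):

    work_propensity
        Baseline utility of working for alcohol; the persistent per-subject
        component of this parameter is what carries test-retest stability
        across sessions.
    pos_weight, neg_weight
        Weights of the positive- (anticipated pleasure) and negative-
        (current desire) reinforcement terms in the work-for-alcohol utility.
    drug_attenuation
        delta, fraction per ng/ml of drug blood level; scales the positive-
        reinforcement pathway by ``max(0, 1 - delta * level)``.
    attenuate_negative
        If True, the drug also attenuates ``neg_weight`` (off by default).
    fatigue_rate
        Utility decay of working, per hour of voluntary-work time.
    latency_mean_s
        Mean pause before each work-set / rest decision.

    Subjective side (per-minute rates; ``*_gain_brac`` per mg/dL,
    ``*_gain_slope`` per mg/dL/min): linear drives with exponential return
    to the baselines of :class:`SubjectiveState`.
    """

    work_propensity: float = 0.0
    pos_weight: float = 0.8
    neg_weight: float = 0.5
    water_propensity: float = 0.15
    drug_attenuation: float = 0.0  # per ng/ml
    attenuate_negative: bool = False
    fatigue_rate: float = 0.35  # utility per hour
    temperature: float = 0.6
    latency_mean_s: float = 6.0
    rest_duration_s: float = 30.0

    return_rate: float = 0.04  # 1/min
    stim_gain_brac: float = 0.014
    stim_gain_slope: float = 0.4
    well_gain_brac: float = 0.008
    well_gain_slope: float = 0.5
    sed_gain_brac: float = 0.012
    desire_gain: float = 2.0  # per mg/dL/min of falling BrAC
    drunk_rate: float = 0.15  # 1/min
    drunk_scale: float = 0.55  # VAS points per mg/dL

    baseline: SubjectiveState = field(default_factory=SubjectiveState)

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.drug_attenuation < 0:
            raise ValueError("drug_attenuation must be non-negative")
        if self.latency_mean_s < 0 or self.rest_duration_s <= 0:
            raise ValueError("latencies must be non-negative, rest duration positive")

    def attenuation(self, drug_level: float) -> float:
        """Positive-reinforcement scale factor in [0, 1]."""
        return max(0.0, 1.0 - self.drug_attenuation * drug_level)


def _clip(v: float) -> float:
    return min(100.0, max(0.0, v))


def update_subjective(
    state: SubjectiveState,
    brac: float,
    brac_slope: float,
    params: AgentParams,
    drug_level: float = 0.0,
    dt_min: float = 1.0,
) -> SubjectiveState:
    """Advance the subjective state over ``dt_min`` minutes.

    Stimulation and wellbeing rise with BrAC and with a positive slope,
    scaled by the drug attenuation; desire rises while BrAC is falling; all
    scales decay exponentially toward baseline and stay within [0, 100].
    """
    if not all(map(math.isfinite, (brac, brac_slope, dt_min))) or dt_min <= 0:
        raise ValueError("brac, slope and dt must be finite, dt positive")
    att = params.attenuation(drug_level)
    b = params.baseline
    r = params.return_rate
    up = max(brac_slope, 0.0)
    down = max(-brac_slope, 0.0)

    stim = state.stimulation + dt_min * (
        r * (b.stimulation - state.stimulation)
        + att * (params.stim_gain_brac * brac + params.stim_gain_slope * up)
    )
    well = state.wellbeing + dt_min * (
        r * (b.wellbeing - state.wellbeing)
        + att * (params.well_gain_brac * brac + params.well_gain_slope * up)
    )
    sed = state.sedation + dt_min * (
        r * (b.sedation - state.sedation) + params.sed_gain_brac * brac
    )
    desire = state.desire + dt_min * (
        r * (b.desire - state.desire) + params.desire_gain * down
    )
    drunk = state.drunkenness + dt_min * params.drunk_rate * (
        params.drunk_scale * brac - state.drunkenness
    )
    return SubjectiveState(
        stimulation=_clip(stim),
        sedation=_clip(sed),
        wellbeing=_clip(well),
        desire=_clip(desire),
        drunkenness=_clip(drunk),
    )


@dataclass(frozen=True)
class DecisionContext:
    eligible_alcohol: bool = True
    current_workset: Optional[str] = None  # "alcohol" | "saline" | None


def _utilities(
    state: SubjectiveState,
    params: AgentParams,
    drug_level: float,
    t_hours: float,
) -> dict[str, float]:
    att = params.attenuation(drug_level)
    neg_w = params.neg_weight * (att if params.attenuate_negative else 1.0)
    pleasure = (state.stimulation + state.wellbeing) / 200.0  # 0..1
    fatigue = params.fatigue_rate * max(t_hours, 0.0)
    return {
        "work_alcohol": params.work_propensity
        + params.pos_weight * att * pleasure
        + neg_w * state.desire / 100.0
        - fatigue,
        "work_water": params.water_propensity - fatigue,
        "rest": 0.0,
    }


def decide_action(
    state: SubjectiveState,
    params: AgentParams,
    context: DecisionContext,
    rng: np.random.Generator,
    drug_level: float = 0.0,
    t_hours: float = 0.0,
) -> str:
    """Softmax choice among the currently available actions.

    An ineligible alcohol reward masks ``work_alcohol``; inside a work-set
    the only options are continuing that set or resting (the reward kind was
    fixed at set start).  Temperature 0 reduces to argmax with a fixed
    preference order for exact ties.
    """
    utils = _utilities(state, params, drug_level, t_hours)
    if context.current_workset is not None:
        kind_action = "work_alcohol" if context.current_workset == "alcohol" else "work_water"
        allowed = [kind_action, "rest"]
    else:
        allowed = list(ACTIONS)
        if not context.eligible_alcohol:
            allowed.remove("work_alcohol")
    if params.temperature == 0.0:
        return max(allowed, key=lambda a: (utils[a], -allowed.index(a)))
    u = np.array([utils[a] / params.temperature for a in allowed])
    u -= u.max()
    p = np.exp(u)
    p /= p.sum()
    return allowed[int(rng.choice(len(allowed), p=p))]


class BehavioralAgent:
    """Stateful wrapper pairing :class:`AgentParams` with a subjective state.

    The session engine calls :meth:`observe` as simulated time passes and
    :meth:`decide` at each decision point.
    """

    def __init__(self, params: AgentParams | None = None) -> None:
        self.params = params if params is not None else AgentParams()
        self.drug_level = 0.0
        self.subjective = self.params.baseline

    def reset(self, drug_level: float = 0.0) -> None:
        self.drug_level = drug_level
        self.subjective = self.params.baseline

    def observe(self, dt_min: float, brac: float, brac_slope: float) -> None:
        self.subjective = update_subjective(
            self.subjective, brac, brac_slope, self.params, self.drug_level, dt_min
        )

    def decide(self, context: DecisionContext, rng: np.random.Generator, t_hours: float = 0.0) -> str:
        return decide_action(
            self.subjective, self.params, context, rng, self.drug_level, t_hours
        )

    def latency_s(self, rng: np.random.Generator) -> float:
        if self.params.latency_mean_s <= 0:
            return 0.0
        return float(rng.exponential(self.params.latency_mean_s))

    @property
    def rest_duration_s(self) -> float:
        return self.params.rest_duration_s


class ScriptedAgent(BehavioralAgent):
    """Deterministic fixture agent: emits a scripted choice with zero latency.

    Policies: ``always_alcohol`` (work for alcohol whenever eligible, rest
    otherwise), ``never_work``, ``alternating`` (alcohol, saline, alcohol,
    ... across successive work-sets).
    """

    POLICIES = ("always_alcohol", "never_work", "alternating")

    def __init__(self, policy: str, params: AgentParams | None = None) -> None:
        if policy not in self.POLICIES:
            raise ValueError(f"unknown policy {policy!r}; expected one of {self.POLICIES}")
        base = params if params is not None else AgentParams(latency_mean_s=0.0)
        super().__init__(replace(base, latency_mean_s=0.0))
        self.policy = policy
        self._n_started = 0

    def reset(self, drug_level: float = 0.0) -> None:
        super().reset(drug_level)
        self._n_started = 0

    def decide(self, context: DecisionContext, rng: np.random.Generator, t_hours: float = 0.0) -> str:
        if self.policy == "never_work":
            return "rest"
        if context.current_workset is not None:
            return (
                "work_alcohol" if context.current_workset == "alcohol" else "work_water"
            )
        if self.policy == "always_alcohol":
            return "work_alcohol" if context.eligible_alcohol else "rest"
        # alternating: even starts go to alcohol, odd to water
        want = "work_alcohol" if self._n_started % 2 == 0 else "work_water"
        if want == "work_alcohol" and not context.eligible_alcohol:
            return "rest"
        self._n_started += 1
        return want


def scripted_agent(policy: str) -> ScriptedAgent:
    """Factory for the deterministic fixture agents."""
    return ScriptedAgent(policy)
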