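"""Structured configuration files (YAML or JSON) for the simulator.

A config file holds up to four sections, each optional and each mapping
directly onto the corresponding dataclass defaults:

```yaml
subject:            # SubjectProfile
  id: S001
  sex: male
  age: 30
  height_cm: 180
  weight_kg: 80
  genotype: AA
pk: {}              # PKParameters overrides (defaults derived from subject)
agent: {}           # AgentParams overrides
session: {}         # SessionConfig overrides (schedule/cat/latency nested)
cohort: {}          # CohortConfig overrides (agent/session nested)
```
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import yaml

from .agent import AgentParams
from .cohort import CohortConfig
from .pharmacokinetics import PKParameters, SubjectProfile
from .session import CATConfig, LatencyModel, SessionConfig, WorkSchedule

__all__ = [
    "load_config",
    "subject_from_config",
    "pk_params_from_config",
    "agent_params_from_config",
    "session_config_from_config",
    "cohort_config_from_config",
]

DEFAULT_SUBJECT = {
    "id": "S001",
    "sex": "male",
    "age": 30.0,
    "height_cm": 180.0,
    "weight_kg": 80.0,
    "genotype": "AA",
}


def load_config(path) -> dict:
    """Read a YAML or JSON config file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def subject_from_config(config: dict) -> SubjectProfile:
    fields = {**DEFAULT_SUBJECT, **config.get("subject", {})}
    return SubjectProfile(**fields)


def pk_params_from_config(config: dict, subject: SubjectProfile | None = None) -> PKParameters:
    if subject is None:
        subject = subject_from_config(config)
    params = PKParameters.for_subject(subject)
    overrides = config.get("pk", {})
    return replace(params, **overrides) if overrides else params


def agent_params_from_config(config: dict) -> AgentParams:
    overrides = config.get("agent", {})
    return replace(AgentParams(), **overrides) if overrides else AgentParams()


def session_config_from_config(config: dict) -> SessionConfig:
    section = dict(config.get("session", {}))
    nested = {}
    if "schedule" in section:
        nested["schedule"] = WorkSchedule(**section.pop("schedule"))
    if "cat" in section:
        nested["cat"] = CATConfig(**section.pop("cat"))
    if "latency" in section:
        nested["latency"] = LatencyModel(**section.pop("latency"))
    if "assessment_times" in section:
        section["assessment_times"] = tuple(section["assessment_times"])
    return replace(SessionConfig(), **section, **nested) if (section or nested) else SessionConfig()


def cohort_config_from_config(config: dict) -> CohortConfig:
    section = dict(config.get("cohort", {}))
    nested = {}
    if "agent" in section:
        nested["agent"] = replace(AgentParams(), **section.pop("agent"))
    if "session" in section:
        nested["session"] = session_config_from_config({"session": section.pop("session")})
    base = CohortConfig()
    return replace(base, **section, **nested) if (section or nested) else base
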