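"""Synthetic cohorts and the end-to-end two-session trial in silico.

Builds a screened cohort (sex, anthropometry, Hardy-Weinberg OPRM1 A118G
genotypes at ~15 % G-allele frequency, enriched for G-carriers by the
3-of-each-6 screening rule), randomizes it to drug vs. placebo with permuted
blocks stratified by sex and carrier status, runs the pre-treatment and
on-treatment sessions for every subject, and computes the trial statistics.

Subjects carry persistent random effects (work propensity, reinforcement
weights, desire sensitivity) that are shared across their two sessions plus
session-specific noise; the ratio of those variances sets the test-retest
correlation of cumulative work.  The treated arm receives a drug blood
level drawn from the configured distribution (default mean 55.4, SD 27.6
ng/ml, truncated at zero); the behavioral drug effect scales with
``delta * blood_level``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .agent import AgentParams, BehavioralAgent
from .analysis import (
    GroupSummary,
    analyze_endpoints,
    impute_missing_change,
    pearson_r,
    session_endpoints,
)
from .pharmacokinetics import PKParameters, SubjectProfile
from .session import SessionConfig, SessionLog, run_session

__all__ = [
    "CohortConfig",
    "TrialResult",
    "enrich_by_genotype",
    "stratified_randomize",
    "draw_genotype",
    "generate_cohort",
    "simulate_trial",
]

_GENOTYPE_PRIORITY = {"GG": 0, "AG": 1, "AA": 2}


@dataclass(frozen=True)
class CohortConfig:
    """Design of one simulated trial."""

    n_subjects: int = 46
    g_allele_freq: float = 0.15
    male_fraction: float = 0.87
    enrich: bool = True
    delta: float = 0.005  # drug attenuation per ng/ml of blood level
    blood_level_mean: float = 55.4
    blood_level_sd: float = 27.6
    n_zero_blood_level: int = 0  # noncompliant treated subjects forced to level 0
    n_dropouts: int = 0  # treated subjects missing session 2 (ITT-imputed)
    propensity_sd_between: float = 0.35
    propensity_sd_within: float = 0.22
    pos_weight_log_sd: float = 0.30
    neg_weight_log_sd: float = 0.40
    desire_gain_log_sd: float = 0.50
    pk_log_sd: float = 0.15  # lognormal multipliers on vmax and vd
    block_size: int = 4  # permuted-block randomization
    agent: AgentParams = field(default_factory=AgentParams)
    session: SessionConfig = field(default_factory=lambda: SessionConfig(dt_min=0.1))

    def __post_init__(self) -> None:
        if not 0.0 <= self.g_allele_freq <= 1.0:
            raise ValueError("g_allele_freq must lie in [0, 1]")
        if self.n_subjects < 4:
            raise ValueError("need at least 2 subjects per arm")
        if self.delta * self.blood_level_mean >= 1.0:
            raise ValueError("delta * mean blood level must stay below 1")


@dataclass
class TrialResult:
    """Endpoint table plus the group-level statistics of one simulated trial."""

    endpoints: pd.DataFrame
    stats: dict
    seed: int
    config: CohortConfig
    logs: Optional[list] = None


# ---------------------------------------------------------------------------
# screening, enrichment, randomization


def draw_genotype(rng: np.random.Generator, g_freq: float) -> str:
    """Hardy-Weinberg OPRM1 A118G draw at the given G-allele frequency."""
    alleles = rng.random(2) < g_freq
    n_g = int(alleles.sum())
    return ("AA", "AG", "GG")[n_g]


def enrich_by_genotype(block_of_6: Sequence[str]) -> list[int]:
    """Select 3 of 6 consecutively screened subjects by genotype priority.

    Priority GG > AG > AA, ties broken by consent (list) order; returns the
    selected indices into the block.
    """
    if len(block_of_6) != 6:
        raise ValueError("enrichment operates on blocks of exactly 6 screened subjects")
    for g in block_of_6:
        if g not in _GENOTYPE_PRIORITY:
            raise ValueError(f"unknown genotype {g!r}")
    order = sorted(range(6), key=lambda i: (_GENOTYPE_PRIORITY[block_of_6[i]], i))
    return sorted(order[:3])


def stratified_randomize(
    subjects: Sequence[SubjectProfile], seed: int, block_size: int = 4
) -> dict[str, str]:
    """Permuted-block arm assignment within sex x G-carrier strata.

    Returns a subject-id -> arm ("naltrexone" | "placebo") mapping; within
    every stratum the arm counts differ by at most 2 (one partial block).
    """
    rng = np.random.default_rng(seed)
    half = block_size // 2
    assignment: dict[str, str] = {}
    strata: dict[tuple, list] = {}
    for s in subjects:
        strata.setdefault((s.sex, s.is_g_carrier), []).append(s)
    for key in sorted(strata):
        members = strata[key]
        arms: list[str] = []
        while len(arms) < len(members):
            block = ["naltrexone"] * half + ["placebo"] * half
            arms.extend(rng.permutation(block).tolist())
        for s, arm in zip(members, arms):
            assignment[s.id] = arm
    return assignment


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class _Subject:
    profile: SubjectProfile
    pk_params: PKParameters
    pk_estimate: PKParameters  # controller's population-level starting model
    agent_base: AgentParams


def _draw_profile(rng: np.random.Generator, idx: int, male: bool, genotype: str) -> SubjectProfile:
    if male:
        height = float(np.clip(rng.normal(180.0, 7.0), 160.0, 205.0))
        weight = float(np.clip(rng.normal(82.0, 12.0), 55.0, 129.0))
    else:
        height = float(np.clip(rng.normal(167.0, 6.5), 150.0, 190.0))
        weight = float(np.clip(rng.normal(68.0, 11.0), 45.0, 129.0))
    age = float(np.clip(25.0 + rng.gamma(2.0, 3.0), 25.0, 55.0))
    return SubjectProfile(
        id=f"S{idx:03d}",
        sex="male" if male else "female",
        age=age,
        height_cm=height,
        weight_kg=weight,
        genotype=genotype,
    )


def generate_cohort(config: CohortConfig, rng: np.random.Generator) -> list[_Subject]:
    """Screen (with optional genotype enrichment) and parameterize subjects."""
    genotypes: list[str] = []
    while len(genotypes) < config.n_subjects:
        if config.enrich:
            block = [draw_genotype(rng, config.g_allele_freq) for _ in range(6)]
            genotypes.extend(block[i] for i in enrich_by_genotype(block))
        else:
            genotypes.append(draw_genotype(rng, config.g_allele_freq))
    genotypes = genotypes[: config.n_subjects]

    subjects: list[_Subject] = []
    base = config.agent
    for i, gt in enumerate(genotypes):
        male = bool(rng.random() < config.male_fraction)
        profile = _draw_profile(rng, i, male, gt)
        estimate = PKParameters.for_subject(profile)
        true = replace(
            estimate,
            vmax_g_min=estimate.vmax_g_min * float(np.exp(config.pk_log_sd * rng.standard_normal())),
            vd_l=estimate.vd_l * float(np.exp(config.pk_log_sd * rng.standard_normal())),
        )
        agent_base = replace(
            base,
            work_propensity=base.work_propensity
            + config.propensity_sd_between * float(rng.standard_normal()),
            pos_weight=base.pos_weight
            * float(np.exp(config.pos_weight_log_sd * rng.standard_normal())),
            neg_weight=base.neg_weight
            * float(np.exp(config.neg_weight_log_sd * rng.standard_normal())),
            desire_gain=base.desire_gain
            * float(np.exp(config.desire_gain_log_sd * rng.standard_normal())),
            drug_attenuation=config.delta,
        )
        subjects.append(_Subject(profile, true, estimate, agent_base))
    return subjects


# ---------------------------------------------------------------------------
# the two-session trial


def _session_agent(subject: _Subject, config: CohortConfig, rng: np.random.Generator) -> BehavioralAgent:
    params = replace(
        subject.agent_base,
        work_propensity=subject.agent_base.work_propensity
        + config.propensity_sd_within * float(rng.standard_normal()),
    )
    return BehavioralAgent(params)


def simulate_trial(
    config: CohortConfig | None = None,
    seed: int = 0,
    *,
    keep_logs: bool = False,
) -> TrialResult:
    """Run the full randomized two-session experiment and analyze it.

    Fully seeded and deterministic: the same (config, seed) pair reproduces
    the identical :class:`TrialResult`.
    """
    cfg = config if config is not None else CohortConfig()
    rng = np.random.default_rng(seed)
    subjects = generate_cohort(cfg, rng)
    arms = stratified_randomize(
        [s.profile for s in subjects], seed=int(rng.integers(2**31)), block_size=cfg.block_size
    )

    treated = [s for s in subjects if arms[s.profile.id] == "naltrexone"]
    levels: dict[str, float] = {}
    for j, s in enumerate(treated):
        if j < cfg.n_zero_blood_level:
            levels[s.profile.id] = 0.0
        else:
            levels[s.profile.id] = max(
                0.0, float(rng.normal(cfg.blood_level_mean, cfg.blood_level_sd))
            )
    dropouts = {s.profile.id for s in treated[-cfg.n_dropouts:]} if cfg.n_dropouts else set()

    rows = []
    logs: list[SessionLog] = []
    for s in subjects:
        arm = arms[s.profile.id]
        level = levels.get(s.profile.id, 0.0)
        row: dict = {
            "subject_id": s.profile.id,
            "group": arm,
            "sex": s.profile.sex,
            "genotype": s.profile.genotype,
            "blood_level": level if arm == "naltrexone" else 0.0,
            "dropout": s.profile.id in dropouts,
        }
        for session_index, drug in ((1, 0.0), (2, level if arm == "naltrexone" else 0.0)):
            if session_index == 2 and s.profile.id in dropouts:
                continue
            agent = _session_agent(s, cfg, rng)
            log = run_session(
                s.profile,
                s.pk_params,
                agent,
                cfg.session,
                seed=int(rng.integers(2**31)),
                est_params=s.pk_estimate,
                drug_level=drug,
                session_index=session_index,
            )
            ep = session_endpoints(log)
            for key, value in ep.items():
                if key in ("subject_id", "session_index"):
                    continue
                row[f"{key}_s{session_index}"] = value
            if keep_logs:
                logs.append(log)
        rows.append(row)
    endpoints = pd.DataFrame(rows)

    # intention-to-treat imputation of missing second sessions
    for var in ("cwfa", "cwfs", "cwfa_ascending", "cwfa_plateau"):
        s1, s2 = f"{var}_s1", f"{var}_s2"
        if s2 not in endpoints.columns:
            endpoints[s2] = np.nan
        for idx in endpoints.index[endpoints[s2].isna()]:
            arm = endpoints.at[idx, "group"]
            peers = endpoints[(endpoints["group"] == arm) & endpoints[s2].notna()]
            endpoints.at[idx, s2] = impute_missing_change(
                endpoints.at[idx, s1], (peers[s2] - peers[s1]).tolist()
            )

    stats = analyze_endpoints(
        endpoints,
        variables=[v for v in ("cwfa", "cwfa_ascending", "cwfa_plateau", "cwfs",
                                "peak_brac", "mean_brac")
                   if f"{v}_s2" in endpoints.columns
                   and endpoints[f"{v}_s2"].notna().all()],
    )

    trt = endpoints[endpoints["group"] == "naltrexone"]
    if len(trt) >= 3 and np.ptp(trt["blood_level"]) > 0:
        delta_cwfa = trt["cwfa_s2"] - trt["cwfa_s1"]
        if np.ptp(delta_cwfa) > 0:
            r, p = pearson_r(trt["blood_level"], delta_cwfa)
            stats["blood_level_vs_delta_cwfa"] = {"r": r, "p": p}
    plc = endpoints[(endpoints["group"] == "placebo") & ~endpoints["dropout"]]
    if len(plc) >= 3:
        for var in ("cwfa", "cwfs"):
            if np.ptp(plc[f"{var}_s1"]) > 0 and np.ptp(plc[f"{var}_s2"]) > 0:
                r, p = pearson_r(plc[f"{var}_s1"], plc[f"{var}_s2"])
                stats[f"test_retest_{var}"] = {"r": r, "p": p}

    return TrialResult(
        endpoints=endpoints,
        stats=stats,
        seed=seed,
        config=cfg,
        logs=logs if keep_logs else None,
    )
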