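"""Two-compartment ethanol pharmacokinetics for intravenous clamp simulation.

The model tracks the arterial-equivalent breath alcohol concentration (BrAC)
of one subject under an arbitrary intravenous infusion-rate schedule.
Infused ethanol enters a *central* compartment (arterial blood plus rapidly
perfused tissue, the pool a breathalyzer effectively samples), exchanges with
a larger and more slowly equilibrating *peripheral* compartment (lean tissue
water), and is eliminated from the central compartment with saturable
Michaelis-Menten kinetics.  The total distribution volume is whole-body
water estimated from the Watson anthropometric equations, the standard
choice in i.v. alcohol clamp methodology because it needs only fields
collected at screening.

The small central compartment is what makes the clamp paradigm work: a
reward ramp loads the central pool quickly and cheaply, and the
central-to-peripheral gradient it leaves behind lets the controller shape a
steep, linear BrAC descent between rewards that is several times faster than
whole-body metabolic elimination.

Units: time in minutes, concentrations in g/L (BrAC reported in mg/dL,
i.e. g/L x 100), volumes in liters, ethanol mass in grams, infusion rates in
ml/h of the 6.0 % v/v ethanol infusate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Union

import numpy as np
import pandas as pd

__all__ = [
    "ETHANOL_DENSITY_G_ML",
    "ETHANOL_VV_FRACTION",
    "PUMP_MAX_ML_H",
    "InvalidProfileError",
    "PumpLimitError",
    "SubjectProfile",
    "PKParameters",
    "PKState",
    "BrACReading",
    "watson_tbw",
    "infusion_to_ethanol_mass_rate",
    "ethanol_mass_rate_to_infusion",
    "step_pk",
    "measure_brac",
    "simulate_infusion_schedule",
]

ETHANOL_DENSITY_G_ML = 0.7893
ETHANOL_VV_FRACTION = 0.06  # 6.0 % v/v ethanol in 0.9 % saline
PUMP_MAX_ML_H = 1998.0
_GL_TO_MGDL = 100.0


class InvalidProfileError(ValueError):
    """Subject physiology violates an eligibility or plausibility bound."""


class PumpLimitError(ValueError):
    """Requested infusion rate is outside the pump's [0, 1998] ml/h range."""


@dataclass(frozen=True)
class SubjectProfile:
    """Physiology of one simulated participant.

    Eligibility bounds mirror the screening rules of the paradigm:
    age 25-55 years, body weight at most 130 kg.  ``genotype`` is the
    OPRM1 A118G (rs1799971) genotype used for enrichment and stratification.
    """

    id: str
    sex: str  # "male" | "female"
    age: float  # years
    height_cm: float
    weight_kg: float
    genotype: str = "AA"  # "AA" | "AG" | "GG"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise InvalidProfileError(f"unknown sex {self.sex!r}")
        if not 25.0 <= self.age <= 55.0:
            raise InvalidProfileError(f"age {self.age} outside eligible range 25-55")
        if self.height_cm <= 0:
            raise InvalidProfileError("height must be positive")
        if not 0 < self.weight_kg <= 130.0:
            raise InvalidProfileError(
                f"weight {self.weight_kg} outside eligible range (0, 130] kg"
            )
        if self.genotype not in ("AA", "AG", "GG"):
            raise InvalidProfileError(f"unknown OPRM1 genotype {self.genotype!r}")

    @property
    def is_g_carrier(self) -> bool:
        return "G" in self.genotype


def watson_tbw(profile: SubjectProfile) -> float:
    """Watson total body water (liters), used as the ethanol distribution volume."""
    if profile.sex == "male":
        tbw = (
            2.447
            - 0.09516 * profile.age
            + 0.1074 * profile.height_cm
            + 0.3362 * profile.weight_kg
        )
    else:
        tbw = -2.097 + 0.1069 * profile.height_cm + 0.2466 * profile.weight_kg
    if tbw <= 0:
        raise InvalidProfileError("Watson TBW is non-positive for this profile")
    return tbw


@dataclass(frozen=True)
class PKParameters:
    """Disposition parameters of the two-compartment model.

    vd_l
        Total distribution volume (Watson TBW).
    vmax_g_min, km_g_l
        Michaelis-Menten elimination from the central compartment.
    k_per_min
        Central<->peripheral exchange rate constant; the mass flux is
        ``k_per_min * vd_l * (c_central - c_peripheral)`` g/min.
    f_per
        Fraction of vd assigned to the peripheral compartment.  The default
        0.75 leaves a central volume of ~25 % of TBW (blood plus rapidly
        perfused tissue), which together with the slow exchange default
        (distribution half-time ~35 min) sustains the paradigm's steep
        between-reward BrAC declines; see docs/methods.md.
    """

    vd_l: float
    vmax_g_min: float
    km_g_l: float = 0.1
    k_per_min: float = 0.015
    f_per: float = 0.75

    def __post_init__(self) -> None:
        for name in ("vd_l", "vmax_g_min", "km_g_l", "k_per_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.f_per < 1.0:
            raise ValueError("f_per must lie strictly between 0 and 1")

    @property
    def central_volume_l(self) -> float:
        return self.vd_l * (1.0 - self.f_per)

    @classmethod
    def for_subject(
        cls,
        profile: SubjectProfile,
        *,
        decline_mg_dl_h: float = 15.0,
        ref_brac_mg_dl: float = 50.0,
        km_g_l: float = 0.1,
        k_per_min: float = 0.015,
        f_per: float = 0.75,
    ) -> "PKParameters":
        """Default parameters with vmax calibrated per subject.

        vmax is chosen so that the fully equilibrated, zero-infusion BrAC
        decline near ``ref_brac_mg_dl`` equals ``decline_mg_dl_h``
        (~15 mg/dL/h, the typical human value after oral ingestion).
        """
        vd = watson_tbw(profile)
        c = ref_brac_mg_dl / _GL_TO_MGDL
        decline_g_l_min = decline_mg_dl_h / 60.0 / _GL_TO_MGDL
        vmax = decline_g_l_min * vd * (km_g_l + c) / c
        return cls(
            vd_l=vd, vmax_g_min=vmax, km_g_l=km_g_l, k_per_min=k_per_min, f_per=f_per
        )


@dataclass(frozen=True)
class PKState:
    """Instantaneous state of one subject's ethanol disposition."""

    t: float = 0.0  # min
    c_central: float = 0.0  # g/L
    c_peripheral: float = 0.0  # g/L
    cumulative_infused_g: float = 0.0
    cumulative_eliminated_g: float = 0.0

    @property
    def brac(self) -> float:
        """Breath alcohol concentration in mg/dL."""
        return self.c_central * _GL_TO_MGDL

    def body_content_g(self, params: PKParameters) -> float:
        """Total ethanol mass currently in the body (both compartments)."""
        return params.vd_l * (
            (1.0 - params.f_per) * self.c_central + params.f_per * self.c_peripheral
        )


@dataclass(frozen=True)
class BrACReading:
    """One breathalyzer measurement, as used to refine the controller."""

    t: float
    brac: float  # mg/dL
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.brac < 0:
            raise ValueError("BrAC reading cannot be negative")


def infusion_to_ethanol_mass_rate(rate_ml_h: float) -> float:
    """Convert an infusate pump rate (ml/h) to an ethanol mass rate (g/min)."""
    if not 0.0 <= rate_ml_h <= PUMP_MAX_ML_H + 1e-9:
        raise PumpLimitError(
            f"rate {rate_ml_h} ml/h outside pump range [0, {PUMP_MAX_ML_H}]"
        )
    return rate_ml_h * ETHANOL_VV_FRACTION * ETHANOL_DENSITY_G_ML / 60.0


def ethanol_mass_rate_to_infusion(rate_g_min: float) -> float:
    """Inverse of :func:`infusion_to_ethanol_mass_rate` (no pump clamping)."""
    return rate_g_min * 60.0 / (ETHANOL_VV_FRACTION * ETHANOL_DENSITY_G_ML)


def _derivs(cc: float, cp: float, q: float, p: PKParameters):
    elim = p.vmax_g_min * cc / (p.km_g_l + cc) if cc > 0.0 else 0.0
    exch = p.k_per_min * p.vd_l * (cc - cp)
    dcc = (q - exch - elim) / (p.vd_l * (1.0 - p.f_per))
    dcp = exch / (p.vd_l * p.f_per)
    return dcc, dcp, elim


def step_pk(
    state: PKState, params: PKParameters, rate_ml_h: float, dt_min: float
) -> PKState:
    """Advance the disposition ODEs by ``dt_min`` under a constant pump rate.

    Fixed-step RK4.  The eliminated mass is integrated with the same stage
    weights as the concentrations, so the mass balance

        infused == eliminated + body content

    holds to floating-point precision for any schedule.
    """
    if dt_min <= 0:
        raise ValueError("dt_min must be positive")
    q = infusion_to_ethanol_mass_rate(rate_ml_h)
    cc, cp = state.c_central, state.c_peripheral
    h = dt_min

    d1c, d1p, e1 = _derivs(cc, cp, q, params)
    d2c, d2p, e2 = _derivs(cc + 0.5 * h * d1c, cp + 0.5 * h * d1p, q, params)
    d3c, d3p, e3 = _derivs(cc + 0.5 * h * d2c, cp + 0.5 * h * d2p, q, params)
    d4c, d4p, e4 = _derivs(cc + h * d3c, cp + h * d3p, q, params)

    new_cc = cc + h / 6.0 * (d1c + 2.0 * d2c + 2.0 * d3c + d4c)
    new_cp = cp + h / 6.0 * (d1p + 2.0 * d2p + 2.0 * d3p + d4p)
    elim_inc = h / 6.0 * (e1 + 2.0 * e2 + 2.0 * e3 + e4)
    return PKState(
        t=state.t + h,
        c_central=new_cc if new_cc > 0.0 else 0.0,
        c_peripheral=new_cp if new_cp > 0.0 else 0.0,
        cumulative_infused_g=state.cumulative_infused_g + q * h,
        cumulative_eliminated_g=state.cumulative_eliminated_g + elim_inc,
    )


RNGLike = Union[np.random.Generator, int, None]


def _as_rng(rng: RNGLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def measure_brac(state: PKState, noise_sd: float = 0.0, rng: RNGLike = None) -> BrACReading:
    """Breathalyzer reading: model BrAC plus zero-mean Gaussian noise, truncated at 0."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    value = state.brac
    if noise_sd > 0:
        value += noise_sd * _as_rng(rng).standard_normal()
    return BrACReading(t=state.t, brac=max(0.0, value), noise_sd=noise_sd)


def simulate_infusion_schedule(
    params: PKParameters,
    schedule: Callable[[float], float],
    duration_min: float,
    dt_min: float = 0.05,
    state: PKState | None = None,
) -> tuple[PKState, pd.DataFrame]:
    """Integrate an arbitrary rate schedule; returns the final state and a
    (t_min, brac_mg_dl, infusion_ml_h) time series.

    ``schedule`` maps time (min) to a pump rate (ml/h) held constant over the
    following step.
    """
    if state is None:
        state = PKState()
    rows = [(state.t, state.brac, float(schedule(state.t)))]
    t_end = state.t + duration_min
    while state.t < t_end - 1e-9:
        h = min(dt_min, t_end - state.t)
        rate = float(schedule(state.t))
        state = step_pk(state, params, rate, h)
        rows.append((state.t, state.brac, rate))
    frame = pd.DataFrame(rows, columns=["t_min", "brac_mg_dl", "infusion_ml_h"])
    return state, frame
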