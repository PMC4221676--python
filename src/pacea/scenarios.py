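"""Translate trial effect estimates into population model scenarios.

A scenario is a one-off, population-wide offer of an intervention: a
real-world uptake fraction (trial response rate scaled by an odds ratio for
the shorter real-life questionnaire), a per-subgroup population-average PA
shift (uptake x participant-level effect), and a persistence factor applied
from the second year onward (the first-year effect steps down once and is
then held constant, treating the changed behaviour as a habit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .effects import AGE_BANDS, SEXES, EffectEstimate, subgroup_key

__all__ = [
    "ScenarioSpec",
    "real_world_response_rate",
    "apply_uptake",
    "apply_persistence",
    "build_scenario",
    "RESPONSE_RATES",
]

#: Trial response rates and shorter-questionnaire odds ratios (with 95% CI)
#: used to project real-world uptake: printed 19% x OR 1.48 [1.06, 2.07],
#: web 12% x OR 1.73 [1.40, 2.13].
RESPONSE_RATES = {
    "printed": {"trial_rate": 0.19, "or": 1.48, "or_ci": (1.06, 2.07)},
    "web_based": {"trial_rate": 0.12, "or": 1.73, "or_ci": (1.40, 2.13)},
    # the basic/environmental pooling mixes one printed and one web arm;
    # their uptake is the mean of the two delivery modes' rates
    "basic": None,
    "environmental": None,
}

#: Post-year-1 persistence of the 12-month PA effect.
DEFAULT_PERSISTENCE = 0.72


def real_world_response_rate(trial_rate: float, odds_ratio: float,
                             exact_odds: bool = False) -> float:
    """Project a trial response rate to a real-world setting.

    Default reproduces the study's literal computation — the odds ratio
    multiplies the rate directly (e.g. 1.48 x 19% = 28%) — clipped to [0, 1].
    ``exact_odds=True`` instead applies the odds ratio on the odds scale:
    ``p' = OR p / (1 - p + OR p)``.
    """
    if not 0.0 < trial_rate < 1.0:
        raise ValueError("trial_rate must be in (0, 1)")
    if odds_ratio <= 0.0:
        raise ValueError("odds_ratio must be positive")
    if exact_odds:
        odds = odds_ratio * trial_rate / (1.0 - trial_rate)
        return odds / (1.0 + odds)
    return float(min(1.0, odds_ratio * trial_rate))


def apply_uptake(effect, uptake: float):
    """Population-average PA shift: uptake fraction x participant effect.

    ``effect`` may be a scalar, an :class:`EffectEstimate`, or a mapping of
    subgroup key to either; the result mirrors the input structure.
    """
    if not 0.0 <= uptake <= 1.0:
        raise ValueError("uptake must be in [0, 1]")
    if isinstance(effect, EffectEstimate):
        return uptake * effect.delta_pa
    if isinstance(effect, Mapping):
        return {k: apply_uptake(v, uptake) for k, v in effect.items()}
    return uptake * float(effect)


def apply_persistence(first_year_shift, factor: float, horizon: int,
                      decay: bool = False) -> np.ndarray:
    """Per-cycle shift schedule from a first-year shift and persistence.

    Default: ``[s, f*s, f*s, ...]`` — a single step-down held constant.
    ``decay=True`` uses geometric decay ``s * f**t`` instead.
    """
    if not 0.0 <= factor <= 1.0:
        raise ValueError("persistence factor must be in [0, 1]")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    s = np.asarray(first_year_shift, dtype=float)
    t = np.arange(horizon)
    if decay:
        mult = factor ** t
    else:
        mult = np.where(t == 0, 1.0, factor)
    return mult.reshape((horizon,) + (1,) * s.ndim) * s


@dataclass(frozen=True, eq=False)
class ScenarioSpec:
    """A fully-resolved model scenario.

    ``shift`` is the first-year population-average PA shift as a
    (2 age bands, 2 sexes) array in MET-hours/week (uptake already applied);
    the reference scenario has uptake 0 and an all-zero shift.
    """

    label: str
    uptake: float
    shift: np.ndarray
    persistence: float = DEFAULT_PERSISTENCE
    horizon: object = "lifetime"

    def __post_init__(self) -> None:
        shift = np.asarray(self.shift, dtype=float)
        if shift.shape != (2, 2):
            shift = np.broadcast_to(shift, (2, 2)).copy()
        object.__setattr__(self, "shift", shift)
        if not 0.0 <= self.uptake <= 1.0:
            raise ValueError("uptake must be in [0, 1]")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must be in [0, 1]")
        if self.label == "reference" and (
                self.uptake != 0.0 or np.any(self.shift != 0.0)):
            raise ValueError("the reference scenario has uptake 0, shift 0")

    def shift_schedule(self, n_cycles: int = 1024):
        """Callable t -> (bands, sexes) shift array for the model run."""
        sched = apply_persistence(self.shift, self.persistence,
                                  max(int(n_cycles), 1))

        def schedule(t: int):
            return sched[min(t, len(sched) - 1)]
        return schedule


REFERENCE = ScenarioSpec("reference", 0.0, np.zeros((2, 2)), 1.0)


def _shift_array(effects: Mapping[str, float]) -> np.ndarray:
    """Arrange subgroup shifts on the (age band, sex) grid.

    Missing subgroups fall back to the "overall" entry (or 0).
    """
    default = float(effects.get("overall", 0.0))
    arr = np.full((2, 2), default)
    for i, band in enumerate(AGE_BANDS):
        for j, sex in enumerate(SEXES):
            key = subgroup_key(band, sex)
            if key in effects:
                arr[i, j] = float(effects[key])
    return arr


def build_scenario(label: str,
                   effects: Mapping[str, EffectEstimate | float],
                   uptake: float,
                   persistence: float = DEFAULT_PERSISTENCE,
                   horizon: object = "lifetime") -> ScenarioSpec:
    """Assemble a ScenarioSpec from per-subgroup effect estimates.

    ``effects`` maps subgroup keys ("overall", "50-64/male", ...) to
    participant-level PA effects; uptake scales them to population-average
    shifts.
    """
    values = {k: (v.delta_pa if isinstance(v, EffectEstimate) else float(v))
              for k, v in effects.items()}
    shifted = apply_uptake(values, uptake)
    return ScenarioSpec(label, uptake, _shift_array(shifted),
                        persistence, horizon)
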