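"""Markov-type cohort state-transition model for PA-related chronic disease.

A deterministic (expected-value) population model over annual cycles.  The
cohort is stratified by integer age, sex and a discretised leisure-time
physical-activity (PA) class measured in MET-hours/week.  Five chronic
diseases — diabetes, colon cancer, breast cancer, acute myocardial
infarction (AMI) and stroke — evolve as independent marginal two-state
(disease-free / prevalent) processes on top of the shared alive population:
the model tracks, per stratum, the probability of having each disease but
not the joint distribution of comorbidity.

Per cycle and stratum:

1. incidence: disease-free mass acquires disease ``d`` with probability
   ``inc_d(age, sex) * RR_d(met)``, where the relative risk is log-linear in
   MET-hours/week (``RR = exp(beta * (met - reference))``, protective for
   ``beta < 0``);
2. mortality: survival combines background mortality with each disease's
   excess mortality multiplicatively,
   ``S = (1 - m) * prod_d (1 - e_d * pi_d)``, which is the exact expectation
   when disease statuses are independent; the prevalence share of disease
   ``d`` among survivors updates in closed form to
   ``pi_d (1 - e_d) / (1 - e_d pi_d)``;
3. outputs: person-years use a half-cycle correction (deaths contribute half
   a year), utilities multiply ``(1 - disutility_d * pi_d)`` across diseases
   (additive combination selectable), healthcare costs multiply prevalence
   counts by per-case annual costs plus an optional per-capita cost of being
   alive (costs in added life years);
4. ageing: everyone ages one year (the top age is absorbing) and a small
   fraction of PA-class mass drifts one class down, emulating the decline of
   PA with age.

An intervention enters as a per-cycle additive shift of effective
MET-hours/week by (age band x sex); a zero shift reproduces the reference
run bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Demography",
    "PADistribution",
    "DiseaseSpec",
    "PopulationState",
    "Trajectory",
    "ChronicDiseaseModel",
    "relative_risk",
]

DISEASE_NAMES = ("diabetes", "colon_cancer", "breast_cancer", "AMI", "stroke")


@dataclass(frozen=True)
class Demography:
    """Closed-cohort counts and background mortality by age and sex.

    ``counts`` and ``mortality`` have shape (n_ages, 2); sex index 0 = male,
    1 = female.  Ages run from ``age_min`` to ``age_min + n_ages - 1``; the
    top age is absorbing (survivors stay there).
    """

    age_min: int
    counts: np.ndarray
    mortality: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        mort = np.asarray(self.mortality, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "mortality", mort)
        if counts.ndim != 2 or counts.shape[1] != 2:
            raise ValueError("counts must have shape (n_ages, 2)")
        if mort.shape != counts.shape:
            raise ValueError("mortality must match counts' shape")
        if (counts < 0).any():
            raise ValueError("cohort counts must be non-negative")
        if ((mort < 0) | (mort > 1)).any():
            raise ValueError("mortality probabilities must lie in [0, 1]")

    @property
    def n_ages(self) -> int:
        return self.counts.shape[0]

    @property
    def ages(self) -> np.ndarray:
        return self.age_min + np.arange(self.n_ages)


@dataclass(frozen=True)
class PADistribution:
    """Discretised PA distribution in MET-hours/week.

    ``boundaries`` has length K+1 (last may be inf), ``values`` are the class
    representative MET-hour levels, ``occupancy`` the class probabilities —
    either shape (K,) shared by all strata or (n_ages, 2, K) per stratum.
    ``annual_drift`` is the fraction of each class's mass that moves one
    class down per year of ageing.
    """

    boundaries: np.ndarray
    values: np.ndarray
    occupancy: np.ndarray
    annual_drift: float = 0.005

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        v = np.asarray(self.values, dtype=float)
        occ = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "occupancy", occ)
        if len(b) != len(v) + 1:
            raise ValueError("need len(boundaries) == len(values) + 1")
        if not (np.diff(b) > 0).all():
            raise ValueError("class boundaries must be strictly increasing")
        if not ((b[:-1] <= v) & (v <= b[1:])).all():
            raise ValueError("each representative value must lie in its class")
        sums = occ.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("class occupancies must sum to 1 per stratum")
        if not 0.0 <= self.annual_drift <= 1.0:
            raise ValueError("annual_drift must be in [0, 1]")

    @property
    def n_classes(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class DiseaseSpec:
    """One disease's epidemiology and valuation inputs.

    ``incidence``, ``excess_mortality`` and ``annual_cost`` are arrays of
    shape (n_ages, 2) (or scalars, broadcast on use).  ``incidence`` is the
    annual probability of onset at the reference MET-hours level;
    ``beta`` the log relative risk per MET-hour/week (<= 0 protective);
    ``disutility`` the QALY weight lost while prevalent; ``annual_cost`` the
    yearly healthcare cost (euros) per prevalent case.  ``female_only``
    restricts onset to women (breast cancer default).
    """

    name: str
    incidence: np.ndarray | float
    beta: float
    reference_met: float
    excess_mortality: np.ndarray | float
    disutility: float
    annual_cost: np.ndarray | float
    female_only: bool = False

    def __post_init__(self) -> None:
        for attr in ("incidence", "excess_mortality", "annual_cost"):
            val = np.asarray(getattr(self, attr), dtype=float)
            object.__setattr__(self, attr, val)
            if (val < 0).any():
                raise ValueError(f"{self.name}: {attr} must be non-negative")
        for attr in ("incidence", "excess_mortality"):
            if (np.asarray(getattr(self, attr)) > 1).any():
                raise ValueError(f"{self.name}: {attr} is a probability")
        if not np.isfinite(self.beta):
            raise ValueError(f"{self.name}: dose-response slope must be finite")
        if not 0.0 <= self.disutility <= 1.0:
            raise ValueError(f"{self.name}: disutility must be in [0, 1]")


def relative_risk(met_hours, spec: DiseaseSpec):
    """Dose-response relative risk ``exp(beta * (met - reference))``.

    Equals 1 at the reference MET-hours level and for a null slope; always
    positive.  Negative MET-hours are rejected.
    """
    met = np.asarray(met_hours, dtype=float)
    if (met < 0).any():
        raise ValueError("MET-hours must be non-negative")
    return np.exp(spec.beta * (met - spec.reference_met))


@dataclass
class PopulationState:
    """Cohort state at the start of a cycle.

    ``alive``: counts, shape (n_ages, 2, K).  ``prevalence``: per disease,
    the probability of being prevalent given alive, same shape.
    """

    alive: np.ndarray
    prevalence: dict[str, np.ndarray]
    cum_deaths: float = 0.0
    cycle: int = 0

    def copy(self) -> "PopulationState":
        return PopulationState(self.alive.copy(),
                               {k: v.copy() for k, v in self.prevalence.items()},
                               self.cum_deaths, self.cycle)

    @property
    def total_alive(self) -> float:
        return float(self.alive.sum())

    def prevalent_counts(self, disease: str) -> np.ndarray:
        return self.alive * self.prevalence[disease]


@dataclass
class Trajectory:
    """Per-cycle outputs of a model run (results object).

    Stratum-level person-years and prevalence shares are retained so QALYs
    and costs can be recomputed under alternative valuation rules.
    """

    disease_names: tuple[str, ...]
    life_years: list[float] = field(default_factory=list)
    qalys: list[float] = field(default_factory=list)
    deaths: list[float] = field(default_factory=list)
    alive_end: list[float] = field(default_factory=list)
    costs: list[float] = field(default_factory=list)
    incidence: dict[str, list[float]] = field(default_factory=dict)
    prevalence: dict[str, list[float]] = field(default_factory=dict)
    # stratum-level detail per cycle
    person_years_strata: list[np.ndarray] = field(default_factory=list)
    prevalence_strata: list[dict[str, np.ndarray]] = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return len(self.life_years)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "cycle": np.arange(self.n_cycles),
            "life_years": self.life_years,
            "qalys": self.qalys,
            "deaths": self.deaths,
            "alive_end": self.alive_end,
            "healthcare_costs": self.costs,
        }
        for d in self.disease_names:
            data[f"incidence_{d}"] = self.incidence[d]
            data[f"prevalence_{d}"] = self.prevalence[d]
        return pd.DataFrame(data)

    def to_tidy(self) -> pd.DataFrame:
        """Long (cycle, measure, value) table for CSV export."""
        wide = self.to_frame()
        return wide.melt(id_vars="cycle", var_name="measure",
                         value_name="value").sort_values(
                             ["cycle", "measure"]).reset_index(drop=True)


class ChronicDiseaseModel:
    """Deterministic cohort model over (age x sex x PA class) strata.

    Parameters
    ----------
    demography : Demography
    pa : PADistribution
    diseases : sequence of DiseaseSpec
    utility_rule : {"multiplicative", "additive"}
        How disutilities of co-prevalent diseases combine into the stratum
        utility.  Multiplicative: ``prod(1 - u_d pi_d)``; additive:
        ``max(0, 1 - sum u_d pi_d)``.
    other_cost_per_capita : float
        Annual non-disease healthcare cost per person-year alive (captures
        costs of added life years); default 0.
    cap_probabilities : bool
        If True, transition probabilities that exceed 1 after relative-risk
        scaling are capped with a warning instead of raising.
    """

    def __init__(self, demography: Demography, pa: PADistribution,
                 diseases: Sequence[DiseaseSpec],
                 utility_rule: str = "multiplicative",
                 other_cost_per_capita: float = 0.0,
                 cap_probabilities: bool = False):
        if utility_rule not in ("multiplicative", "additive"):
            raise ValueError(f"unknown utility rule {utility_rule!r}")
        if other_cost_per_capita < 0:
            raise ValueError("per-capita cost must be non-negative")
        names = [d.name for d in diseases]
        if len(set(names)) != len(names):
            raise ValueError("disease names must be unique")
        self.demography = demography
        self.pa = pa
        self.diseases = tuple(diseases)
        self.utility_rule = utility_rule
        self.other_cost_per_capita = other_cost_per_capita
        self.cap_probabilities = cap_probabilities

        A, K = demography.n_ages, pa.n_classes
        occ = np.asarray(pa.occupancy, dtype=float)
        if occ.ndim == 1:
            occ = np.broadcast_to(occ, (A, 2, K))
        elif occ.shape != (A, 2, K):
            raise ValueError("occupancy must be (K,) or (n_ages, 2, K)")
        self._occ = occ
        # age-band index per age row, for subgroup-keyed MET shifts
        self._band = np.where(demography.ages <= 64, 0, 1)

    # -- state construction -------------------------------------------------

    def initial_state(self,
                      prevalence: dict[str, np.ndarray] | None = None
                      ) -> PopulationState:
        """Cohort at cycle 0: everyone disease-free unless given otherwise."""
        alive = self.demography.counts[:, :, None] * self._occ
        A, K = self.demography.n_ages, self.pa.n_classes
        prev = {}
        for d in self.diseases:
            if prevalence and d.name in prevalence:
                p = np.broadcast_to(np.asarray(prevalence[d.name], float),
                                    (A, 2, K)).copy()
                if ((p < 0) | (p > 1)).any():
                    raise ValueError("initial prevalence must be in [0, 1]")
            else:
                p = np.zeros((A, 2, K))
            prev[d.name] = p
        return PopulationState(alive.copy(), prev)

    # -- mechanics ----------------------------------------------------------

    def _expand(self, arr, A: int) -> np.ndarray:
        """Broadcast a scalar or (A, 2) array to (A, 2, 1)."""
        a = np.asarray(arr, dtype=float)
        if a.ndim == 0:
            return np.full((A, 2, 1), float(a))
        return a[:, :, None]

    def _met_levels(self, shift) -> np.ndarray:
        """Effective MET-hours per stratum after an intervention shift.

        ``shift`` is 0, a scalar, or an array (2 age bands, 2 sexes) of
        additive MET-hour/week shifts.  Shifted levels are floored at 0.
        """
        A, K = self.demography.n_ages, self.pa.n_classes
        met = np.broadcast_to(self.pa.values, (A, 2, K)).copy()
        if shift is None:
            return met
        s = np.asarray(shift, dtype=float)
        if s.ndim == 0:
            met = met + float(s)
        elif s.shape == (2, 2):
            met = met + s[self._band][:, :, None]
        else:
            raise ValueError("shift must be scalar or (2 bands, 2 sexes)")
        return np.clip(met, 0.0, None)

    def step_year(self, state: PopulationState, shift=None
                  ) -> tuple[PopulationState, dict]:
        """Advance the cohort one annual cycle; return new state and outputs."""
        A, K = self.demography.n_ages, self.pa.n_classes
        alive0 = state.alive
        met = self._met_levels(shift)

        # 1. incidence
        new_prev: dict[str, np.ndarray] = {}
        cycle_incidence: dict[str, float] = {}
        for d in self.diseases:
            rr = relative_risk(met, d)
            p_onset = self._expand(d.incidence, A) * rr
            if d.female_only:
                p_onset = p_onset.copy()
                p_onset[:, 0, :] = 0.0
            if (p_onset > 1.0).any():
                if self.cap_probabilities:
                    warnings.warn(f"{d.name}: onset probability capped at 1",
                                  stacklevel=2)
                    p_onset = np.clip(p_onset, None, 1.0)
                else:
                    raise ValueError(
                        f"{d.name}: incidence x RR exceeds 1; reduce incidence "
                        "or enable cap_probabilities")
            pi = state.prevalence[d.name]
            new_cases = alive0 * (1.0 - pi) * p_onset
            cycle_incidence[d.name] = float(new_cases.sum())
            new_prev[d.name] = pi + (1.0 - pi) * p_onset

        # 2. mortality: multiplicative survival sharing across diseases
        m = self._expand(self.demography.mortality, A)
        surv = np.broadcast_to(1.0 - m, (A, 2, K)).copy()
        excess = {}
        for d in self.diseases:
            e = np.broadcast_to(self._expand(d.excess_mortality, A), (A, 2, K))
            excess[d.name] = e
            surv = surv * (1.0 - e * new_prev[d.name])
        alive1 = alive0 * surv
        deaths = alive0 - alive1
        n_deaths = float(deaths.sum())
        pre_mort_prev = {k: v.copy() for k, v in new_prev.items()}
        for d in self.diseases:
            e = excess[d.name]
            pi = new_prev[d.name]
            denom = 1.0 - e * pi
            with np.errstate(invalid="ignore", divide="ignore"):
                pi_new = np.where(denom > 0, pi * (1.0 - e) / denom, 0.0)
            new_prev[d.name] = pi_new

        # 3. cycle outputs (half-cycle person-years).  QALYs are the exact
        # expectation over joint disease statuses: person-years per status
        # are n_s (1 + surv_s)/2, and for independent statuses both
        # E[util] and E[surv x util] factorise across diseases, using the
        # *pre-mortality* prevalence pi (posterior to incidence).
        py = alive0 - 0.5 * deaths
        one_minus_m = np.broadcast_to(1.0 - m, (A, 2, K))
        if self.utility_rule == "multiplicative":
            e_util = np.ones((A, 2, K))
            e_surv_util = one_minus_m.copy()
            for d in self.diseases:
                pi = pre_mort_prev[d.name]
                e = excess[d.name]
                u = d.disutility
                e_util *= 1.0 - u * pi
                e_surv_util *= 1.0 - pi * (e + u - e * u)
        else:
            # additive: utility 1 - sum u_d s_d (assumes burden <= 1)
            e_util = np.ones((A, 2, K))
            surv_all = np.ones((A, 2, K))
            for d in self.diseases:
                surv_all = surv_all * (1.0 - excess[d.name]
                                       * pre_mort_prev[d.name])
            cross = np.zeros((A, 2, K))
            for d in self.diseases:
                pi = pre_mort_prev[d.name]
                e = excess[d.name]
                denom = 1.0 - e * pi
                with np.errstate(invalid="ignore", divide="ignore"):
                    others = np.where(denom > 0, surv_all / denom, 0.0)
                e_util -= d.disutility * pi
                cross += d.disutility * (1.0 - e) * pi * others
            e_surv_util = one_minus_m * (surv_all - cross)
        qalys = float((0.5 * alive0 * (e_util + e_surv_util)).sum())
        cost = self.other_cost_per_capita * float(py.sum())
        cycle_prevalence: dict[str, float] = {}
        for d in self.diseases:
            prev_counts = alive1 * new_prev[d.name]
            cycle_prevalence[d.name] = float(prev_counts.sum())
            cost += float((prev_counts
                           * np.broadcast_to(self._expand(d.annual_cost, A),
                                             (A, 2, K))).sum())

        out = {
            "life_years": float(py.sum()),
            "qalys": qalys,
            "deaths": n_deaths,
            "alive_end": float(alive1.sum()),
            "costs": cost,
            "incidence": cycle_incidence,
            "prevalence": cycle_prevalence,
            "person_years_strata": py,
            "prevalence_strata": {k: v.copy() for k, v in new_prev.items()},
        }

        # 4. ageing (top age absorbing) and PA drift
        def age_up(arr_w):  # weighted mass ages one year
            shifted = np.zeros_like(arr_w)
            shifted[1:] = arr_w[:-1]
            shifted[-1] += arr_w[-1]
            return shifted

        alive2 = age_up(alive1)
        prev2 = {}
        for d in self.diseases:
            num = age_up(alive1 * new_prev[d.name])
            with np.errstate(invalid="ignore", divide="ignore"):
                prev2[d.name] = np.where(alive2 > 0, num / np.where(
                    alive2 > 0, alive2, 1.0), 0.0)

        drift = self.pa.annual_drift
        if drift > 0 and K > 1:
            moved = alive2 * drift
            alive3 = alive2 - moved
            alive3[:, :, 0] += moved[:, :, 0]      # bottom class keeps its mass
            alive3[:, :, :-1] += moved[:, :, 1:]
            prev3 = {}
            for d in self.diseases:
                mass = alive2 * prev2[d.name]
                moved_m = mass * drift
                mass3 = mass - moved_m
                mass3[:, :, 0] += moved_m[:, :, 0]
                mass3[:, :, :-1] += moved_m[:, :, 1:]
                with np.errstate(invalid="ignore", divide="ignore"):
                    prev3[d.name] = np.where(
                        alive3 > 0, mass3 / np.where(alive3 > 0, alive3, 1.0),
                        0.0)
            alive2, prev2 = alive3, prev3

        new_state = PopulationState(alive2, prev2,
                                    state.cum_deaths + n_deaths,
                                    state.cycle + 1)
        return new_state, out

    def run(self, horizon, shift_schedule: Callable[[int], object] | None = None,
            initial: PopulationState | None = None) -> Trajectory:
        """Run the cohort for ``horizon`` cycles (or "lifetime").

        ``shift_schedule(t)`` returns the MET-hour shift applied in cycle
        ``t`` (0-based); ``None`` means no intervention.  "lifetime" runs
        until the cohort is extinct (alive < 1e-9 of initial) or a hard cap
        of 150 cycles.
        """
        lifetime = isinstance(horizon, str)
        if lifetime:
            if horizon != "lifetime":
                raise ValueError(f"unknown horizon {horizon!r}")
            max_cycles = 150
        else:
            max_cycles = int(horizon)
            if max_cycles < 1:
                raise ValueError("horizon must be >= 1 cycle")

        state = (initial.copy() if initial is not None
                 else self.initial_state())
        total0 = state.total_alive
        traj = Trajectory(tuple(d.name for d in self.diseases))
        for d in self.diseases:
            traj.incidence[d.name] = []
            traj.prevalence[d.name] = []

        for t in range(max_cycles):
            shift = shift_schedule(t) if shift_schedule is not None else None
            state, out = self.step_year(state, shift)
            traj.life_years.append(out["life_years"])
            traj.qalys.append(out["qalys"])
            traj.deaths.append(out["deaths"])
            traj.alive_end.append(out["alive_end"])
            traj.costs.append(out["costs"])
            for d in self.diseases:
                traj.incidence[d.name].append(out["incidence"][d.name])
                traj.prevalence[d.name].append(out["prevalence"][d.name])
            traj.person_years_strata.append(out["person_years_strata"])
            traj.prevalence_strata.append(out["prevalence_strata"])
            if lifetime and state.total_alive < 1e-9 * max(total0, 1.0):
                break
        return traj


def qalys(trajectory: Trajectory, diseases: Sequence[DiseaseSpec],
          rule: str = "multiplicative") -> np.ndarray:
    """Recompute per-cycle QALYs from a trajectory's stratum-level detail.

    QALYs are person-years weighted by a utility that combines the
    prevalence-weighted disutilities of all diseases under ``rule``.
    """
    by_name = {d.name: d for d in diseases}
    for d in by_name.values():
        if not 0.0 <= d.disutility <= 1.0:
            raise ValueError(f"{d.name}: disutility must be in [0, 1]")
    out = []
    for py, prev in zip(trajectory.person_years_strata,
                        trajectory.prevalence_strata):
        if rule == "multiplicative":
            util = np.ones_like(py)
            for name, pi in prev.items():
                util *= 1.0 - by_name[name].disutility * pi
        elif rule == "additive":
            burden = np.zeros_like(py)
            for name, pi in prev.items():
                burden += by_name[name].disutility * pi
            util = np.clip(1.0 - burden, 0.0, None)
        else:
            raise ValueError(f"unknown utility rule {rule!r}")
        out.append(float((py * util).sum()))
    return np.asarray(out)


def healthcare_costs(trajectory: Trajectory, diseases: Sequence[DiseaseSpec],
                     other_cost_per_capita: float = 0.0) -> np.ndarray:
    """Per-cycle costs: prevalent cases x per-case cost (+ per-capita cost).

    Recomputed from the aggregate prevalence series; exact when per-case
    costs are scalars (the stratum-level path is used by the engine itself).
    """
    if other_cost_per_capita < 0:
        raise ValueError("per-capita cost must be non-negative")
    by_name = {d.name: d for d in diseases}
    out = np.zeros(trajectory.n_cycles)
    for name, series in trajectory.prevalence.items():
        cost = np.asarray(by_name[name].annual_cost, dtype=float)
        if cost.ndim != 0:
            raise ValueError("aggregate recomputation needs scalar costs; "
                             "use the engine's stratum-level accounting")
        out += float(cost) * np.asarray(series)
    out += other_cost_per_capita * np.asarray(trajectory.life_years)
    return out
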