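"""Health-economic evaluation: costing, discounting, ICERs, WTP decisions.

Costs and QALYs are discounted at independent annual rates (defaults: 4%
for costs, 1.5% for QALYs, the differential-discounting convention of the
Dutch pharmacoeconomic guideline), with the first model cycle at t = 0.
Incremental cost-effectiveness ratios follow
``ICER = (C_i - C_c) / (E_i - E_c)`` and carry a cost-effectiveness-plane
quadrant label; decisions at a willingness-to-pay (WTP) threshold use the
quadrant semantics: in the north-east an ICER at or below the WTP is
cost-effective, the south-east dominates, the north-west is dominated, and
in the south-west (cheaper but less effective) the option is preferred only
when the savings per QALY forgone are at least the WTP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CostSpec",
    "INTERVENTION_COSTS",
    "ICERResult",
    "CEResult",
    "discount",
    "scenario_cost",
    "icer",
    "wtp_decision",
    "compute_ce",
    "compare_scenarios",
    "ce_table",
]

DEFAULT_RATE_COSTS = 0.04
DEFAULT_RATE_QALYS = 0.015
DEFAULT_WTP = 20_000.0


@dataclass(frozen=True)
class CostSpec:
    """Real-life delivery costs of one intervention condition (euros,
    price level 2011): fixed costs independent of the number of
    participants, plus a variable cost per participant."""

    fixed: float
    variable: float

    def __post_init__(self) -> None:
        if self.fixed < 0 or self.variable < 0:
            raise ValueError("costs must be non-negative")

    def total(self, participants: float) -> float:
        return self.fixed + self.variable * participants


#: Per-condition delivery costs in a real-life setting.
INTERVENTION_COSTS = {
    "print_basic": CostSpec(3300.0, 18.0),
    "print_env": CostSpec(4270.0, 21.0),
    "web_basic": CostSpec(3420.0, 8.0),
    "web_env": CostSpec(4880.0, 8.0),
}

#: Scenario -> the two conditions whose costs are averaged.
SCENARIO_COST_ARMS = {
    "printed": ("print_basic", "print_env"),
    "web_based": ("web_basic", "web_env"),
    "basic": ("print_basic", "web_basic"),
    "environmental": ("print_env", "web_env"),
}


def discount(stream, rate: float) -> float:
    """Present value of a per-cycle stream, first cycle at t = 0.

    ``sum_t stream[t] / (1 + rate)^t``; rate 0 gives the plain sum.
    """
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    s = np.asarray(stream, dtype=float)
    if s.size == 0:
        return 0.0
    t = np.arange(s.size)
    return float((s / (1.0 + rate) ** t).sum())


def scenario_cost(spec_a: CostSpec, spec_b: CostSpec,
                  participants: float) -> float:
    """Delivery cost of a pooled two-condition scenario.

    The scenario averages the two conditions' fixed and variable costs,
    then applies the variable part to the participant count.
    """
    if participants <= 0:
        raise ValueError("participants must be positive")
    fixed = 0.5 * (spec_a.fixed + spec_b.fixed)
    variable = 0.5 * (spec_a.variable + spec_b.variable)
    return fixed + variable * participants


@dataclass(frozen=True)
class ICERResult:
    """An incremental cost-effectiveness ratio with its CE-plane quadrant.

    ``value`` is None when the effect difference is zero (undefined ratio —
    flagged, never printed as infinity).  Quadrants from the signs of
    (dE, dC): NE more effective & more costly, SE more effective & cheaper
    (dominant), NW less effective & more costly (dominated), SW less
    effective & cheaper.
    """

    value: float | None
    quadrant: str
    d_cost: float
    d_effect: float

    @property
    def defined(self) -> bool:
        return self.value is not None


def icer(cost_i: float, cost_c: float, eff_i: float, eff_c: float
         ) -> ICERResult:
    """ICER of intervention vs comparator with quadrant classification."""
    d_cost = cost_i - cost_c
    d_eff = eff_i - eff_c
    if d_eff == 0.0:
        quadrant = "N" if d_cost > 0 else "S"
        return ICERResult(None, quadrant, d_cost, d_eff)
    ew = "E" if d_eff > 0 else "W"
    ns = "N" if d_cost > 0 else "S"
    return ICERResult(d_cost / d_eff, ns + ew, d_cost, d_eff)


def wtp_decision(result: ICERResult, wtp: float = DEFAULT_WTP) -> str:
    """Verdict on an incremental comparison at a WTP threshold.

    Returns one of "cost-effective", "dominant", "dominated",
    "not cost-effective", "preferred (sufficient savings)",
    "not preferred (insufficient savings)", "indifferent".
    """
    if wtp <= 0:
        raise ValueError("WTP must be positive")
    if not result.defined:
        if result.d_cost == 0.0:
            return "indifferent"
        return "dominated" if result.d_cost > 0 else "dominant"
    q = result.quadrant
    if q == "NE":
        return ("cost-effective" if result.value <= wtp
                else "not cost-effective")
    if q == "SE":
        return "dominant"
    if q == "NW":
        return "dominated"
    # SW: cheaper and less effective; the ICER is savings per QALY forgone
    return ("preferred (sufficient savings)" if result.value >= wtp
            else "not preferred (insufficient savings)")


@dataclass(frozen=True)
class CEResult:
    """Discounted incremental outcome of one scenario vs the reference."""

    label: str
    horizon: object
    d_qalys: float
    intervention_cost: float
    d_healthcare_cost: float
    rate_costs: float = DEFAULT_RATE_COSTS
    rate_qalys: float = DEFAULT_RATE_QALYS

    @property
    def d_total_cost(self) -> float:
        return self.intervention_cost + self.d_healthcare_cost

    @property
    def icer_intervention(self) -> ICERResult:
        return icer(self.intervention_cost, 0.0, self.d_qalys, 0.0)

    @property
    def icer_total(self) -> ICERResult:
        return icer(self.d_total_cost, 0.0, self.d_qalys, 0.0)

    def decision(self, wtp: float = DEFAULT_WTP,
                 which: str = "total") -> str:
        res = self.icer_total if which == "total" else self.icer_intervention
        return wtp_decision(res, wtp)


def compute_ce(reference_traj, scenario_traj, label: str,
               intervention_cost: float, horizon: object = "lifetime",
               rate_costs: float = DEFAULT_RATE_COSTS,
               rate_qalys: float = DEFAULT_RATE_QALYS) -> CEResult:
    """Discounted incremental QALYs and costs of a scenario vs reference.

    The intervention is delivered once at t = 0, so its cost enters
    undiscounted; healthcare-cost and QALY streams come from the two
    trajectories.  Trajectories of unequal length (lifetime runs may stop
    at extinction in different cycles) are zero-padded.
    """
    def pad(a, n):
        a = np.asarray(a, dtype=float)
        return np.pad(a, (0, n - a.size)) if a.size < n else a

    n = max(len(reference_traj.qalys), len(scenario_traj.qalys))
    dq = (discount(pad(scenario_traj.qalys, n), rate_qalys)
          - discount(pad(reference_traj.qalys, n), rate_qalys))
    dc = (discount(pad(scenario_traj.costs, n), rate_costs)
          - discount(pad(reference_traj.costs, n), rate_costs))
    return CEResult(label, horizon, dq, intervention_cost, dc,
                    rate_costs, rate_qalys)


def compare_scenarios(res_i: CEResult, res_c: CEResult) -> ICERResult:
    """Head-to-head ICER of two scenarios (total costs), e.g. web vs printed.

    Incremental to the shared reference cancels out: the comparison uses the
    difference of the two scenarios' incremental totals.
    """
    return icer(res_i.d_total_cost, res_c.d_total_cost,
                res_i.d_qalys, res_c.d_qalys)


def ce_table(results: Sequence[CEResult],
             pairwise: Sequence[tuple[str, str]] = (),
             wtp: float = DEFAULT_WTP) -> pd.DataFrame:
    """Tidy CE summary: one row per scenario (vs reference) and pair.

    ICERs are reported unrounded; euros/QALY consumers may round to the
    nearest 10 for presentation.
    """
    by_label = {r.label: r for r in results}
    rows = []
    for r in results:
        rows.append({
            "horizon": r.horizon, "comparison": f"{r.label} vs reference",
            "d_qalys": r.d_qalys,
            "intervention_cost": r.intervention_cost,
            "d_total_cost": r.d_total_cost,
            "icer_intervention": r.icer_intervention.value,
            "icer_total": r.icer_total.value,
            "quadrant": r.icer_total.quadrant,
            "decision": r.decision(wtp),
        })
    for lab_i, lab_c in pairwise:
        res = compare_scenarios(by_label[lab_i], by_label[lab_c])
        res_int = icer(by_label[lab_i].intervention_cost,
                       by_label[lab_c].intervention_cost,
                       by_label[lab_i].d_qalys, by_label[lab_c].d_qalys)
        rows.append({
            "horizon": by_label[lab_i].horizon,
            "comparison": f"{lab_i} vs {lab_c}",
            "d_qalys": res.d_effect,
            "intervention_cost": res_int.d_cost,
            "d_total_cost": res.d_cost,
            "icer_intervention": res_int.value,
            "icer_total": res.value,
            "quadrant": res.quadrant,
            "decision": wtp_decision(res, wtp),
        })
    return pd.DataFrame(rows)
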