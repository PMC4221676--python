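"""Probabilistic sensitivity analysis, CE planes, CEACs and sweeps.

Trial-effect uncertainty is propagated by Monte Carlo: each draw samples a
participant-level PA effect per scenario from a normal whose mean is the
point estimate and whose SD comes from the 95% CI, reruns the deterministic
cohort pipeline, and records incremental QALYs and costs versus the
reference (default 100 draws).  Cost-effectiveness acceptability curves
(CEACs) report, at each willingness-to-pay, the share of draws in which an
option has the highest net monetary benefit ``NMB = WTP x dE - dC`` among
all compared options (ties split equally).  Deterministic sweeps rerun the
pipeline under alternative discount rates and participation bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .effects import EffectEstimate

__all__ = [
    "PSADraws",
    "sample_effects",
    "run_psa",
    "ceac",
    "SWEEP_AXES",
]

DEFAULT_N_DRAWS = 100

#: Deterministic sensitivity axes: common discount rates; participation at
#: the 95% CI bounds of the questionnaire-length odds ratios.
SWEEP_AXES = ("discount_both_4", "discount_both_0",
              "participation_min", "participation_max")


def sample_effects(estimate: EffectEstimate, n_draws: int,
                   seed_or_rng) -> np.ndarray:
    """Draw effects from N(point estimate, SD from the 95% CI).

    SD = (ci_high − ci_low) / (2 x 1.96); a zero-width CI yields constant
    draws.  Reproducible for a fixed seed.
    """
    if n_draws < 1:
        raise ValueError("need at least one draw")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    sd = estimate.se
    if sd == 0.0:
        return np.full(n_draws, estimate.delta_pa)
    return rng.normal(estimate.delta_pa, sd, n_draws)


@dataclass
class PSADraws:
    """Monte-Carlo PSA output: one (dE, dC) pair per draw per scenario.

    ``table`` columns: draw, scenario, effect, d_qalys, d_cost_intervention,
    d_cost_total.
    """

    table: pd.DataFrame
    n_draws: int
    seed: int | None

    def scenario(self, label: str) -> pd.DataFrame:
        return self.table[self.table["scenario"] == label].reset_index(
            drop=True)


def run_psa(driver: Callable[[Mapping[str, float]], Mapping[str, tuple]],
            estimates: Mapping[str, EffectEstimate],
            n_draws: int = DEFAULT_N_DRAWS,
            seed: int | None = 0) -> PSADraws:
    """Propagate sampled effects through a deterministic model driver.

    ``driver`` maps {scenario: sampled overall effect} to
    {scenario: (d_qalys, d_cost_intervention, d_cost_total)} and must be
    deterministic given its input.  One driver call per draw.
    """
    rng = np.random.default_rng(seed)
    labels = list(estimates)
    draws = {lab: sample_effects(estimates[lab], n_draws, rng)
             for lab in labels}
    rows = []
    for i in range(n_draws):
        sampled = {lab: float(draws[lab][i]) for lab in labels}
        result = driver(sampled)
        for lab in labels:
            dq, dci, dct = result[lab]
            rows.append({"draw": i, "scenario": lab, "effect": sampled[lab],
                         "d_qalys": dq, "d_cost_intervention": dci,
                         "d_cost_total": dct})
    return PSADraws(pd.DataFrame(rows), n_draws, seed)


def ceac(psa: PSADraws, wtp_grid: Sequence[float],
         cost: str = "total", include_reference: bool = True,
         scenarios: Sequence[str] | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves over a WTP grid.

    At each WTP the probability that an option has the highest net monetary
    benefit among all compared options; the reference option (dE = dC = 0,
    NMB = 0) is included by default so probabilities partition to 1 across
    {reference} ∪ scenarios.  Ties split equally.

    Returns a tidy frame (wtp, scenario, probability).
    """
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("WTP grid must be non-empty")
    col = "d_cost_total" if cost == "total" else "d_cost_intervention"
    labels = list(scenarios) if scenarios is not None else \
        list(psa.table["scenario"].unique())
    if len(labels) + int(include_reference) < 2:
        raise ValueError("need at least two options to compare")
    wide_e = psa.table.pivot(index="draw", columns="scenario",
                             values="d_qalys")[labels].to_numpy()
    wide_c = psa.table.pivot(index="draw", columns="scenario",
                             values=col)[labels].to_numpy()
    names = list(labels)
    if include_reference:
        wide_e = np.column_stack([np.zeros(len(wide_e)), wide_e])
        wide_c = np.column_stack([np.zeros(len(wide_c)), wide_c])
        names = ["reference"] + names

    rows = []
    for wtp in grid:
        nmb = wtp * wide_e - wide_c  # draws x options
        best = nmb.max(axis=1, keepdims=True)
        is_best = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        share = is_best / is_best.sum(axis=1, keepdims=True)
        probs = share.mean(axis=0)
        for name, p in zip(names, probs):
            rows.append({"wtp": wtp, "scenario": name,
                         "probability": float(p)})
    return pd.DataFrame(rows)
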