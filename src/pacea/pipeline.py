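"""End-to-end analysis pipeline and run manifest.

Stages: simulate the trial, estimate PA effects, build implementation
scenarios, run the cohort disease model per scenario and horizon, compute
cost-effectiveness tables, and run the PSA/CEAC and deterministic
sensitivity sweeps.  Every stage reads/writes plain CSV so stages can be
re-run independently; all randomness flows from named seeds in the
configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import econ as ec
from .cdm import ChronicDiseaseModel, Trajectory
from .config import (AnalysisConfig, build_demography, build_diseases,
                     build_pa_distribution, config_to_dict)
from .effects import TrialEffectsModel, TrialEffectsResults
from .psa import PSADraws, ceac, run_psa
from .scenarios import (REFERENCE, RESPONSE_RATES, ScenarioSpec,
                        build_scenario, real_world_response_rate)
from .trial import generate_trial, read_records, write_records

__all__ = ["Pipeline", "RunManifest", "uptake_rates"]

SCENARIOS = ("printed", "web_based", "basic", "environmental")
PAIRWISE = (("web_based", "printed"), ("environmental", "basic"))


def uptake_rates(or_quantile: str = "point") -> dict[str, float]:
    """Real-world participation per scenario.

    ``or_quantile``: "point", "low" or "high" — which value of the
    questionnaire-length odds ratio to use (point estimate or 95% CI bound).
    The pooled basic/environmental scenarios mix one printed and one web
    condition; their uptake is the mean of the two delivery-mode rates.
    """
    rates = {}
    for mode in ("printed", "web_based"):
        info = RESPONSE_RATES[mode]
        if or_quantile == "point":
            orr = info["or"]
        elif or_quantile == "low":
            orr = info["or_ci"][0]
        elif or_quantile == "high":
            orr = info["or_ci"][1]
        else:
            raise ValueError(f"unknown OR quantile {or_quantile!r}")
        rates[mode] = real_world_response_rate(info["trial_rate"], orr)
    mixed = 0.5 * (rates["printed"] + rates["web_based"])
    rates["basic"] = mixed
    rates["environmental"] = mixed
    return rates


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    seed: int
    package_version: str
    stages: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def record(self, path: Path) -> None:
        self.outputs[path.name] = hashlib.sha256(
            path.read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _discount_sliced(stream, rate, horizon) -> float:
    s = list(stream)
    if isinstance(horizon, int):
        s = s[:horizon]
    return ec.discount(s, rate)


class Pipeline:
    """Orchestrates the full analysis for one configuration."""

    def __init__(self, config: AnalysisConfig, outdir=None):
        self.config = config
        self.outdir = Path(outdir) if outdir is not None else None
        if self.outdir is not None:
            self.outdir.mkdir(parents=True, exist_ok=True)
        cfg_json = json.dumps(config_to_dict(config), sort_keys=True,
                              default=str)
        self.manifest = RunManifest(
            hashlib.sha256(cfg_json.encode()).hexdigest(),
            config.seed, __version__)
        self._model: ChronicDiseaseModel | None = None
        self._reference_traj: Trajectory | None = None

    # -- model access -------------------------------------------------------

    @property
    def model(self) -> ChronicDiseaseModel:
        if self._model is None:
            m = self.config.model
            self._model = ChronicDiseaseModel(
                build_demography(m), build_pa_distribution(m),
                build_diseases(m), utility_rule=m.utility_rule,
                other_cost_per_capita=m.other_cost_per_capita)
        return self._model

    def reference_trajectory(self) -> Trajectory:
        if self._reference_traj is None:
            self._reference_traj = self.model.run("lifetime")
        return self._reference_traj

    def _write(self, df: pd.DataFrame, name: str) -> None:
        if self.outdir is not None:
            path = self.outdir / name
            df.to_csv(path, index=False)
            self.manifest.record(path)

    # -- stages -------------------------------------------------------------

    def simulate_trial(self) -> pd.DataFrame:
        records = generate_trial(self.config.trial)
        self.manifest.stages.append("simulate_trial")
        if self.outdir is not None:
            path = self.outdir / "trial_records.csv"
            write_records(records, path)
            self.manifest.record(path)
        return records

    def estimate_effects(self, records: pd.DataFrame | None = None
                         ) -> TrialEffectsResults:
        if records is None:
            path = self.outdir / "trial_records.csv"
            records = read_records(path)
        results = TrialEffectsModel(records).fit()
        self.manifest.stages.append("estimate_effects")
        self._write(results.effects_table(), "effects_table.csv")
        return results

    def build_scenarios(self, effects: TrialEffectsResults,
                        or_quantile: str = "point"
                        ) -> dict[str, ScenarioSpec]:
        rates = uptake_rates(or_quantile)
        specs = {}
        for label in SCENARIOS:
            if label not in effects.scenario_estimates:
                continue
            specs[label] = build_scenario(
                label, effects.scenario_estimates[label], rates[label],
                persistence=self.config.persistence)
        return specs

    def run_model(self, specs: dict[str, ScenarioSpec],
                  write: bool = True) -> dict[str, Trajectory]:
        """Lifetime trajectory per scenario (reference included)."""
        trajs = {"reference": self.reference_trajectory()}
        for label, spec in specs.items():
            trajs[label] = self.model.run(
                "lifetime", shift_schedule=spec.shift_schedule())
        self.manifest.stages.append("run_model")
        if write and self.outdir is not None:
            tidy = pd.concat(
                [t.to_tidy().assign(scenario=lab)
                 for lab, t in trajs.items()], ignore_index=True)
            self._write(tidy, "trajectories.csv")
        return trajs

    def intervention_costs(self, rates: dict[str, float]
                           ) -> dict[str, float]:
        pop = self.config.model.population_total
        out = {}
        for label in SCENARIOS:
            arm_a, arm_b = ec.SCENARIO_COST_ARMS[label]
            participants = rates[label] * pop
            out[label] = ec.scenario_cost(ec.INTERVENTION_COSTS[arm_a],
                                          ec.INTERVENTION_COSTS[arm_b],
                                          participants)
        return out

    def economics(self, trajs: dict[str, Trajectory],
                  or_quantile: str = "point",
                  rate_costs: float | None = None,
                  rate_qalys: float | None = None,
                  write: bool = True) -> pd.DataFrame:
        """CE table over all configured horizons, scenarios and pairs."""
        rc = self.config.econ.rate_costs if rate_costs is None else rate_costs
        rq = self.config.econ.rate_qalys if rate_qalys is None else rate_qalys
        rates = uptake_rates(or_quantile)
        int_costs = self.intervention_costs(rates)
        ref = trajs["reference"]
        tables = []
        for horizon in self.config.horizons:
            results = []
            undisc = {}
            for label in SCENARIOS:
                if label not in trajs:
                    continue
                scen = trajs[label]
                dq = (_discount_sliced(scen.qalys, rq, horizon)
                      - _discount_sliced(ref.qalys, rq, horizon))
                dc = (_discount_sliced(scen.costs, rc, horizon)
                      - _discount_sliced(ref.costs, rc, horizon))
                undisc[label] = (_discount_sliced(scen.qalys, 0.0, horizon)
                                 - _discount_sliced(ref.qalys, 0.0, horizon))
                results.append(ec.CEResult(label, horizon, dq,
                                           int_costs[label], dc, rc, rq))
            pairs = [p for p in PAIRWISE
                     if p[0] in trajs and p[1] in trajs]
            table = ec.ce_table(results, pairs, wtp=self.config.econ.wtp)
            table["d_qalys_undiscounted"] = [
                undisc.get(r.label) for r in results] + [None] * len(pairs)
            tables.append(table)
        out = pd.concat(tables, ignore_index=True)
        self.manifest.stages.append("economics")
        if write:
            self._write(out, "ce_table.csv")
        return out

    # -- PSA ----------------------------------------------------------------

    def _psa_driver(self, horizon, rates, int_costs):
        """Deterministic driver: sampled overall effects -> (dE, dCi, dCt)."""
        ref = self.reference_trajectory()
        rc, rq = self.config.econ.rate_costs, self.config.econ.rate_qalys
        ref_q = _discount_sliced(ref.qalys, rq, horizon)
        ref_c = _discount_sliced(ref.costs, rc, horizon)

        def driver(sampled: dict[str, float]) -> dict[str, tuple]:
            out = {}
            for label, effect in sampled.items():
                spec = build_scenario(label, {"overall": effect},
                                      rates[label],
                                      persistence=self.config.persistence)
                traj = self.model.run("lifetime",
                                      shift_schedule=spec.shift_schedule())
                dq = _discount_sliced(traj.qalys, rq, horizon) - ref_q
                dc = _discount_sliced(traj.costs, rc, horizon) - ref_c
                out[label] = (dq, int_costs[label], int_costs[label] + dc)
            return out
        return driver

    def run_psa_stage(self, effects: TrialEffectsResults,
                      horizon=None, n_draws: int | None = None,
                      scenarios=("printed", "web_based")
                      ) -> tuple[PSADraws, pd.DataFrame]:
        """Monte-Carlo PSA and CEAC for the given horizon (default lifetime)."""
        horizon = "lifetime" if horizon is None else horizon
        n = self.config.psa.n_draws if n_draws is None else n_draws
        rates = uptake_rates()
        int_costs = self.intervention_costs(rates)
        estimates = {lab: effects.scenario_estimate(lab)
                     for lab in scenarios
                     if lab in effects.scenario_estimates}
        driver = self._psa_driver(horizon, rates, int_costs)
        draws = run_psa(driver, estimates, n_draws=n,
                        seed=self.config.seed + 1)
        curve = ceac(draws, self.config.psa.wtp_grid)
        self.manifest.stages.append("psa")
        self._write(draws.table, "ce_plane.csv")
        self._write(curve, "ceac.csv")
        return draws, curve

    # -- deterministic sweeps ------------------------------------------------

    def sensitivity_sweep(self, trajs: dict[str, Trajectory],
                          effects: TrialEffectsResults) -> pd.DataFrame:
        """Lifetime CE tables under the four deterministic sweep settings.

        Discount sweeps reuse the base trajectories with common rates 4%/4%
        and 0%/0%; participation sweeps rebuild the scenarios at the 95% CI
        bounds of the response-rate odds ratios (which changes both the PA
        shifts and the per-participant intervention cost).
        """
        frames = []
        for axis in ("discount_both_4", "discount_both_0"):
            rate = 0.04 if axis.endswith("4") else 0.0
            t = self.economics(trajs, rate_costs=rate, rate_qalys=rate,
                               write=False)
            frames.append(t.assign(analysis=axis))
        for axis, quant in (("participation_min", "low"),
                            ("participation_max", "high")):
            specs = self.build_scenarios(effects, or_quantile=quant)
            sweep_trajs = self.run_model(specs, write=False)
            t = self.economics(sweep_trajs, or_quantile=quant, write=False)
            frames.append(t.assign(analysis=axis))
        out = pd.concat(frames, ignore_index=True)
        self.manifest.stages.append("sensitivity_sweep")
        self._write(out, "sensitivity.csv")
        return out

    # -- full run -----------------------------------------------------------

    def run_all(self, with_psa: bool = True,
                with_sweep: bool = False) -> dict:
        records = self.simulate_trial()
        effects = self.estimate_effects(records)
        specs = self.build_scenarios(effects)
        trajs = self.run_model(specs)
        ce = self.economics(trajs)
        out = {"records": records, "effects": effects, "scenarios": specs,
               "trajectories": trajs, "ce_table": ce}
        if with_psa:
            draws, curve = self.run_psa_stage(effects)
            out["psa"] = draws
            out["ceac"] = curve
        if with_sweep:
            out["sensitivity"] = self.sensitivity_sweep(trajs, effects)
        if self.outdir is not None:
            self.manifest.write(self.outdir / "manifest.json")
        return out
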