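"""Trial effect estimation: filtering, imputation, change scores, adjustment.

Turns trial records into the physical-activity effect estimates that drive
the cohort disease model:

* exclusion of implausible baseline reports (> 6,720 minutes/week, i.e. more
  than 16 h/day on 7 days);
* conservative single imputation for dropouts — a non-responder's 12-month
  change is set equal to the mean control-group change in the matching
  age-band x sex subgroup (an intention-to-treat-style rule);
* within-person paired change per arm (paired t);
* covariate-adjusted between-arm comparison (OLS of follow-up PA on arm
  dummies, age, sex and baseline PA);
* logistic dropout model in (environmental add-on, web delivery, age);
* n-weighted pooling of two arms into the four implementation scenarios
  (printed, web_based, basic, environmental).

The estimation surface is exposed both as functions and as the
``TrialEffectsModel`` / ``TrialEffectsResults`` pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .trial import ENV_ARMS, WEB_ARMS

__all__ = [
    "AGE_BANDS",
    "EffectEstimate",
    "filter_unreliable",
    "impute_dropouts",
    "paired_change",
    "adjusted_effect",
    "dropout_model",
    "scenario_effect",
    "completion_rate",
    "TrialEffectsModel",
    "TrialEffectsResults",
]

#: Age bands used for subgroup estimation and for keying model scenarios.
AGE_BANDS = ("50-64", ">64")
SEXES = ("male", "female")
SUBGROUPS = tuple((b, s) for b in AGE_BANDS for s in SEXES)

#: Weekly minutes above which a PA self-report is considered unreliable
#: (active > 16 h/day, 7 days/week).
UNRELIABLE_MINUTES = 6720.0

#: Scenario label -> the two trial arms it pools.
SCENARIO_ARMS = {
    "printed": ("print_basic", "print_env"),
    "web_based": ("web_basic", "web_env"),
    "basic": ("print_basic", "web_basic"),
    "environmental": ("print_env", "web_env"),
}


@dataclass(frozen=True)
class EffectEstimate:
    """A mean PA change (MET-hours/week) with 95% CI, n and p-value."""

    label: str
    subgroup: str  # "overall" or "<band>/<sex>"
    delta_pa: float
    ci_low: float
    ci_high: float
    n: int
    p_value: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("an effect estimate needs n >= 2")
        if not self.ci_low <= self.delta_pa <= self.ci_high:
            raise ValueError("point estimate must lie inside its CI")

    @property
    def se(self) -> float:
        return (self.ci_high - self.ci_low) / (2.0 * 1.959963984540054)


def age_band(age) -> np.ndarray:
    """Map ages to the {50-64, >64} bands."""
    return np.where(np.asarray(age) <= 64, AGE_BANDS[0], AGE_BANDS[1])


def subgroup_key(band, sex) -> str:
    return f"{band}/{sex}"


def filter_unreliable(records: pd.DataFrame,
                      threshold: float = UNRELIABLE_MINUTES
                      ) -> tuple[pd.DataFrame, int]:
    """Drop records with baseline PA strictly above ``threshold`` min/week.

    Returns ``(retained_records, n_removed)``.  The boundary is retained:
    the rule is "more than", not "at least".  Idempotent.
    """
    if "baseline_minutes" not in records.columns:
        raise ValueError("records lack a baseline_minutes column")
    if records["baseline_minutes"].isna().any():
        raise ValueError("baseline_minutes contains missing values")
    keep = records["baseline_minutes"] <= threshold
    return records.loc[keep].reset_index(drop=True), int((~keep).sum())


def impute_dropouts(records: pd.DataFrame, mode: str = "change"
                    ) -> pd.DataFrame:
    """Fill missing follow-up PA from the control group, by subgroup.

    mode="change" (default): dropout follow-up = own baseline + mean
    control-completer change in the matching age-band x sex subgroup.
    mode="level": dropout follow-up = mean control-completer follow-up level
    in that subgroup.  Completers (and hence the control arm's own change
    distribution) are never altered.

    A subgroup with fewer than two control completers falls back to the
    overall control mean (with a warning); if the control arm has no
    completers at all the input is unimputable.
    """
    if mode not in ("change", "level"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    out = records.copy()
    ctrl = out[(out["arm"] == "control") & ~out["dropped_out"]]
    if len(ctrl) == 0:
        raise ValueError("no control-arm completers: cannot impute dropouts")

    stat = (ctrl["followup_pa"] - ctrl["baseline_pa"] if mode == "change"
            else ctrl["followup_pa"])
    overall = float(stat.mean())
    bands = age_band(ctrl["age"])
    per_subgroup: dict[tuple[str, str], float] = {}
    for band, sex in SUBGROUPS:
        mask = (bands == band) & (ctrl["sex"] == sex).to_numpy()
        if mask.sum() >= 2:
            per_subgroup[(band, sex)] = float(stat[mask].mean())
        else:
            per_subgroup[(band, sex)] = overall

    dropped = out["dropped_out"].to_numpy()
    if not dropped.any():
        return out
    d_bands = age_band(out["age"])
    fill = np.array([per_subgroup[(b, s)]
                     for b, s in zip(d_bands, out["sex"])])
    for band, sex in SUBGROUPS:
        mask = (bands == band) & (ctrl["sex"] == sex).to_numpy()
        if mask.sum() < 2 and (dropped & (d_bands == band)
                               & (out["sex"] == sex).to_numpy()).any():
            warnings.warn(
                f"subgroup {band}/{sex} has <2 control completers; "
                "using overall control mean", stacklevel=2)
    if mode == "change":
        imputed = out["baseline_pa"].to_numpy() + fill
    else:
        imputed = fill
    out.loc[dropped, "followup_pa"] = imputed[dropped]
    return out


def paired_change(records: pd.DataFrame, arm: str | None = None,
                  label: str | None = None, subgroup: str = "overall",
                  alpha: float = 0.05) -> EffectEstimate:
    """Mean within-person (follow-up − baseline) with paired-t CI and p.

    Requires imputed records (no missing follow-up in the selection).
    """
    sel = records if arm is None else records[records["arm"] == arm]
    if sel["followup_pa"].isna().any():
        raise ValueError("records contain missing follow-up; impute first")
    diff = (sel["followup_pa"] - sel["baseline_pa"]).to_numpy(dtype=float)
    n = diff.size
    if n < 2:
        raise ValueError("need at least two records for a paired change")
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    se = sd / np.sqrt(n)
    if se == 0.0:
        lo = hi = mean
        p = 1.0 if mean == 0.0 else 0.0
    else:
        tcrit = st.t.ppf(1.0 - alpha / 2.0, n - 1)
        lo, hi = mean - tcrit * se, mean + tcrit * se
        p = float(2.0 * st.t.sf(abs(mean / se), n - 1))
    return EffectEstimate(label or arm or "all", subgroup, mean,
                          float(lo), float(hi), int(n), p)


def paired_changes_by_subgroup(records: pd.DataFrame, arm: str
                               ) -> dict[str, EffectEstimate]:
    """Paired change per (age band x sex) subgroup plus overall, for one arm."""
    sel = records[records["arm"] == arm]
    out = {"overall": paired_change(sel, label=arm)}
    bands = age_band(sel["age"])
    for band, sex in SUBGROUPS:
        sub = sel[(bands == band) & (sel["sex"] == sex).to_numpy()]
        if len(sub) < 2:  # tiny fixtures: subgroup estimate unavailable
            continue
        key = subgroup_key(band, sex)
        out[key] = paired_change(sub, label=arm, subgroup=key)
    return out


def adjusted_effect(records: pd.DataFrame):
    """OLS of 12-month PA on intervention dummies, age, sex and baseline PA.

    Control is the reference category.  Returns the fitted statsmodels
    results; ``.params`` holds one coefficient per intervention dummy
    (named ``arm[T.<label>]``).
    """
    if records["followup_pa"].isna().any():
        raise ValueError("records contain missing follow-up; impute first")
    arms = sorted(records["arm"].unique())
    if "control" not in arms or len(arms) < 2:
        raise ValueError("need the control arm plus >=1 intervention arm")
    df = records.assign(
        male=(records["sex"] == "male").astype(float))
    df = pd.get_dummies(df, columns=["arm"], prefix="arm", dtype=float)
    xcols = ([f"arm_{a}" for a in arms if a != "control"]
             + ["age", "male", "baseline_pa"])
    X = sm.add_constant(df[xcols])
    X.columns = ["const"] + [
        f"arm[T.{a}]" for a in arms if a != "control"
    ] + ["age", "male", "baseline_pa"]
    model = sm.OLS(df["followup_pa"].to_numpy(dtype=float), X)
    res = model.fit()
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is collinear")
    return res


def dropout_model(records: pd.DataFrame):
    """ML logistic regression of dropout on (env, web, age).

    Returns the fitted statsmodels Logit results with coefficients named
    env, web, age.  Degenerate inputs (no dropouts, no completers, perfect
    separation) raise ``ValueError``.
    """
    y = records["dropped_out"].astype(float).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need both dropouts and completers")
    X = pd.DataFrame({
        "env": records["arm"].isin(ENV_ARMS).astype(float),
        "web": records["arm"].isin(WEB_ARMS).astype(float),
        "age": records["age"].to_numpy(dtype=float),
    })
    X = sm.add_constant(X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, X).fit(disp=0)
    except Exception as exc:  # statsmodels raises several separation types
        raise ValueError(f"degenerate dropout design: {exc}") from exc
    return res


def scenario_effect(est_a: EffectEstimate, est_b: EffectEstimate,
                    label: str) -> EffectEstimate:
    """Pool two arms' estimates into one scenario estimate (n-weighted).

    The point estimate is the n-weighted mean of the two deltas; the CI is
    propagated from the arms' CIs assuming independence.
    """
    if est_a.subgroup != est_b.subgroup:
        raise ValueError("cannot pool estimates from different subgroups")
    n = est_a.n + est_b.n
    wa, wb = est_a.n / n, est_b.n / n
    delta = wa * est_a.delta_pa + wb * est_b.delta_pa
    se = float(np.hypot(wa * est_a.se, wb * est_b.se))
    z = 1.959963984540054
    p = (1.0 if se == 0.0 and delta == 0.0 else
         0.0 if se == 0.0 else float(2.0 * st.norm.sf(abs(delta / se))))
    return EffectEstimate(label, est_a.subgroup, delta,
                          delta - z * se, delta + z * se, n, p)


def completion_rate(records: pd.DataFrame) -> float:
    """Share of participants with a 12-month measurement available."""
    if len(records) == 0:
        raise ValueError("no records")
    return float((~records["dropped_out"]).mean())


class TrialEffectsModel:
    """Estimation model for a five-arm PA trial record table.

    Statsmodels-style front end: construct from records, call :meth:`fit`,
    inspect the returned :class:`TrialEffectsResults`.
    """

    def __init__(self, records: pd.DataFrame):
        missing = {"arm", "age", "sex", "baseline_pa", "baseline_minutes",
                   "followup_pa", "dropped_out"} - set(records.columns)
        if missing:
            raise ValueError(f"records lack columns: {sorted(missing)}")
        self.records = records

    @classmethod
    def from_csv(cls, path) -> "TrialEffectsModel":
        from .trial import read_records
        return cls(read_records(path))

    def fit(self, filter_records: bool = True, impute: bool = True,
            imputation_mode: str = "change", fit_dropout: bool = True
            ) -> "TrialEffectsResults":
        records = self.records
        n_excluded = 0
        if filter_records:
            records, n_excluded = filter_unreliable(records)
        dropout = None
        if fit_dropout and records["dropped_out"].any() and \
                not records["dropped_out"].all():
            dropout = dropout_model(records)
        if impute:
            records = impute_dropouts(records, mode=imputation_mode)
        else:
            records = records[~records["dropped_out"]].reset_index(drop=True)

        arm_estimates = {arm: paired_changes_by_subgroup(records, arm)
                         for arm in sorted(records["arm"].unique())}
        scenarios: dict[str, dict[str, EffectEstimate]] = {}
        for scen, (a, b) in SCENARIO_ARMS.items():
            if a in arm_estimates and b in arm_estimates:
                shared = [k for k in arm_estimates[a] if k in arm_estimates[b]]
                scenarios[scen] = {
                    key: scenario_effect(arm_estimates[a][key],
                                         arm_estimates[b][key], scen)
                    for key in shared
                }
        adjusted = adjusted_effect(records)
        return TrialEffectsResults(records, n_excluded, arm_estimates,
                                   scenarios, adjusted, dropout)


class TrialEffectsResults:
    """Fitted trial effects: per-arm and per-scenario estimates plus models."""

    def __init__(self, records, n_excluded, arm_estimates, scenario_estimates,
                 adjusted, dropout):
        self.records = records
        self.n_excluded = n_excluded
        self.arm_estimates = arm_estimates
        self.scenario_estimates = scenario_estimates
        self.adjusted = adjusted
        self.dropout = dropout

    def effects_table(self) -> pd.DataFrame:
        """Tidy table of all estimates, keyed by (label, subgroup)."""
        rows = []
        for source in (self.arm_estimates, self.scenario_estimates):
            for label, by_sub in source.items():
                for key, est in by_sub.items():
                    rows.append({
                        "label": label, "subgroup": key,
                        "delta_pa": est.delta_pa, "ci_low": est.ci_low,
                        "ci_high": est.ci_high, "n": est.n,
                        "p_value": est.p_value,
                    })
        return pd.DataFrame(rows)

    def scenario_estimate(self, scenario: str,
                          subgroup: str = "overall") -> EffectEstimate:
        return self.scenario_estimates[scenario][subgroup]

    def summary(self) -> str:
        lines = ["Trial effects on physical activity (MET-hours/week)",
                 "=" * 56,
                 f"records used: {len(self.records)}  "
                 f"(excluded as unreliable: {self.n_excluded})", ""]
        lines.append(f"{'arm/scenario':<16}{'delta':>8}{'95% CI':>18}"
                     f"{'n':>7}{'p':>8}")
        for source in (self.arm_estimates, self.scenario_estimates):
            for label, by_sub in source.items():
                est = by_sub["overall"]
                lines.append(
                    f"{label:<16}{est.delta_pa:>8.2f}"
                    f"{'[%.2f, %.2f]' % (est.ci_low, est.ci_high):>18}"
                    f"{est.n:>7d}{est.p_value:>8.3f}")
        if self.dropout is not None:
            lines += ["", "dropout logistic model (log-odds):"]
            for name, val, se in zip(self.dropout.params.index,
                                     self.dropout.params,
                                     self.dropout.bse):
                lines.append(f"  {name:<8}{val:>8.3f}  (SE {se:.3f})")
        return "\n".join(lines)
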