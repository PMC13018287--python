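"""Outcome stratification by methylation instability, and power analysis.

Samples are split into high- and low-instability groups either at the
cohort-wide median DMI (ties go to low, making even-cohort splits
unambiguous) or by keeping only the top and bottom quartiles. Standard
Kaplan–Meier curves (log-log 95% CIs), log-rank tests and Cox
proportional-hazards fits are delegated to ``lifelines``; the bespoke
content of this module is the stratification rules, the orchestration, and
the simulation-based power/sample-size search.

Endpoint-specific exclusion of prevalent cases (participants who already
experienced the endpoint at sampling) belongs to data preparation upstream
of these functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .simulate import SimulationConfig, simulate_survival_cohort

__all__ = [
    "stratify",
    "km_analysis",
    "cox_adjusted",
    "power_sample_size",
    "schoenfeld_required_n",
    "KMResult",
    "PowerResult",
]


def stratify(dmi: pd.Series, rule: str = "median") -> pd.DataFrame:
    """High/low instability groups from DMI scores.

    ``median``: strictly above the cohort median → high, at or below → low.
    ``quartiles``: at or above Q3 → high, at or below Q1 → low, middle
    excluded (needs ≥4 samples). All-equal DMI cannot be split and is an
    error. Both rules are scale-invariant.
    """
    dmi = dmi.dropna()
    if dmi.nunique() <= 1:
        raise ValueError("all DMI values equal: no split possible")
    if rule == "median":
        med = float(np.median(dmi))
        group = np.where(dmi > med, "high", "low")
    elif rule == "quartiles":
        if len(dmi) < 4:
            raise ValueError("quartile rule requires at least 4 samples")
        q1, q3 = np.quantile(dmi, [0.25, 0.75])
        group = np.select([dmi >= q3, dmi <= q1], ["high", "low"], default="excluded")
    else:
        raise ValueError(f"unknown stratification rule {rule!r}")
    return pd.DataFrame({"dmi": dmi, "group": group, "rule": rule}, index=dmi.index)


@dataclass
class KMResult:
    """Kaplan–Meier comparison of the high vs low instability groups."""

    curves: dict[str, pd.DataFrame]
    logrank_p: float
    hazard_ratio: float
    hr_ci: tuple[float, float]
    hr_p: float
    n_per_group: dict[str, int]
    events_per_group: dict[str, int]


def km_analysis(
    survival: pd.DataFrame,
    groups: pd.Series,
    duration_col: str = "time",
    event_col: str = "event",
) -> KMResult:
    """Product-limit curves, log-rank test and univariate hazard ratio.

    ``groups`` must label samples "high"/"low"; other labels (e.g. the
    quartile rule's "excluded") are dropped. The hazard ratio (high vs low)
    comes from a univariate Cox fit; with zero events in a group it is
    undefined (NaN, with a warning) while curves are still returned.
    """
    groups = groups.reindex(survival.index).dropna()
    groups = groups[groups.isin(["high", "low"])]
    data = survival.loc[groups.index, [duration_col, event_col]].copy()
    data["high"] = (groups == "high").astype(int)

    curves: dict[str, pd.DataFrame] = {}
    n_per, events_per = {}, {}
    for label in ("low", "high"):
        sub = data[data["high"] == (label == "high")]
        n_per[label] = len(sub)
        events_per[label] = int(sub[event_col].sum())
        kmf = KaplanMeierFitter()
        kmf.fit(sub[duration_col], sub[event_col], label=label)
        ci = kmf.confidence_interval_survival_function_
        curves[label] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index,
                "survival": kmf.survival_function_[label].to_numpy(),
                "ci_low": ci.iloc[:, 0].to_numpy(),
                "ci_high": ci.iloc[:, 1].to_numpy(),
            }
        ).reset_index(drop=True)

    lr = logrank_test(
        data.loc[data["high"] == 1, duration_col],
        data.loc[data["high"] == 0, duration_col],
        event_observed_A=data.loc[data["high"] == 1, event_col],
        event_observed_B=data.loc[data["high"] == 0, event_col],
    )

    if min(events_per.values()) == 0:
        warnings.warn("a group has zero events: hazard ratio undefined", stacklevel=2)
        hr, ci_t, hr_p = float("nan"), (float("nan"), float("nan")), float("nan")
    else:
        cph = CoxPHFitter()
        cph.fit(data, duration_col=duration_col, event_col=event_col)
        row = cph.summary.loc["high"]
        hr = float(row["exp(coef)"])
        ci_t = (float(row["exp(coef) lower 95%"]), float(row["exp(coef) upper 95%"]))
        hr_p = float(row["p"])
    return KMResult(
        curves=curves,
        logrank_p=float(lr.p_value),
        hazard_ratio=hr,
        hr_ci=ci_t,
        hr_p=hr_p,
        n_per_group=n_per,
        events_per_group=events_per,
    )


def cox_adjusted(
    survival: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Multivariate Cox proportional-hazards fit.

    Returns one row per covariate with hazard ratio, 95% CI and p. Constant
    covariates are rejected up front; convergence failures (typically
    collinearity or complete separation) are re-raised as ``ValueError``
    with the offending diagnostics attached.
    """
    data = survival[[duration_col, event_col, *covariates]].dropna()
    constant = [c for c in covariates if data[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant covariates cannot be fitted: {constant}")
    corr = data[covariates].corr().abs()
    np.fill_diagonal(corr.to_numpy(), 0.0)
    if (corr > 1 - 1e-10).any(axis=None):
        i, j = np.argwhere(corr.to_numpy() > 1 - 1e-10)[0]
        raise ValueError(
            f"perfectly collinear covariates: {covariates[i]!r} and {covariates[j]!r}"
        )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # lifelines raises several convergence types
        raise ValueError(f"Cox model failed to converge: {exc}") from exc
    summary = cph.summary
    return pd.DataFrame(
        {
            "hr": summary["exp(coef)"],
            "ci_low": summary["exp(coef) lower 95%"],
            "ci_high": summary["exp(coef) upper 95%"],
            "coef": summary["coef"],
            "se": summary["se(coef)"],
            "p": summary["p"],
        }
    )


@dataclass
class PowerResult:
    """Result of the simulation-based sample-size search."""

    required_n: int | None
    target_power: float
    hazard_ratio: float
    alpha: float
    table: pd.DataFrame  # per grid n: estimated power and Monte-Carlo SE


def power_sample_size(
    target_power: float = 0.85,
    hazard_ratio: float = 1.5,
    alpha: float = 0.05,
    n_grid: tuple[int, ...] = (16, 32, 64, 128, 256, 512),
    n_iterations: int = 1000,
    allocation: float = 0.5,
    baseline_hazard: float = 0.2,
    censoring_rate: float = 0.2,
    seed: int = 0,
) -> PowerResult:
    """Smallest cohort size with simulated log-rank power ≥ ``target_power``.

    For each n in the (ascending) grid, ``n_iterations`` cohorts are drawn
    from the exponential proportional-hazards generator — ``allocation`` of
    samples assigned high instability, the rest low, mimicking a median
    split — and the power is the fraction of iterations with log-rank
    p < alpha. The Monte-Carlo SE of each power estimate is reported. If no
    grid point reaches the target, ``required_n`` is None.
    """
    if not 0 < target_power < 1:
        raise ValueError("target_power must be in (0, 1)")
    cfg_kw = dict(baseline_hazard=baseline_hazard,
                  log_hr_high=float(np.log(hazard_ratio)),
                  censoring_rate=censoring_rate)
    rng = np.random.default_rng(seed)
    rows = []
    required = None
    for n in sorted(n_grid):
        n_high = int(round(allocation * n))
        labels = pd.Series(["high"] * n_high + ["low"] * (n - n_high))
        cfg = SimulationConfig(**cfg_kw)
        hits = 0
        for _ in range(n_iterations):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            cohort = simulate_survival_cohort(cfg, labels, sub_seed)
            if cohort["event"].sum() == 0:
                continue
            hi = cohort[cohort["high"] == 1]
            lo = cohort[cohort["high"] == 0]
            lr = logrank_test(hi["time"], lo["time"],
                              event_observed_A=hi["event"],
                              event_observed_B=lo["event"])
            hits += lr.p_value < alpha
        power = hits / n_iterations
        mc_se = float(np.sqrt(power * (1 - power) / n_iterations))
        rows.append({"n": n, "power": power, "mc_se": mc_se})
        if required is None and power >= target_power:
            required = n
            break
    return PowerResult(
        required_n=required,
        target_power=target_power,
        hazard_ratio=hazard_ratio,
        alpha=alpha,
        table=pd.DataFrame(rows),
    )


def schoenfeld_required_n(
    target_power: float = 0.85,
    hazard_ratio: float = 1.5,
    alpha: float = 0.05,
    allocation: float = 0.5,
    event_probability: float = 0.8,
) -> int:
    """Closed-form (Schoenfeld) sample size, as a cross-check on simulation.

    Required events d = (z_{1−α/2} + z_power)² / (p(1−p) · ln²(HR)), scaled
    by the expected event probability to a total cohort size.
    """
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(target_power)
    p = allocation
    events = (z_a + z_b) ** 2 / (p * (1 - p) * np.log(hazard_ratio) ** 2)
    return int(np.ceil(events / event_probability))
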