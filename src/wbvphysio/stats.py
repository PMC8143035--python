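"""Repeated-measures multivariate inference and power analysis.

With only two conditions (baseline, vibration), the one-way
repeated-measures multivariate test of "condition" is the one-sample
Hotelling T² on the per-subject difference vectors d = vibration − baseline:

    T² = n · d̄ᵀ S⁻¹ d̄
    Λ  = 1 / (1 + T²/(n−1))          (Wilks)
    F  = T² (n−p) / (p (n−1))        with df (p, n−p)
    partial η² = 1 − Λ               (identity, by construction)

Post-hoc comparisons are two-sided paired t-tests with a Bonferroni
multiplier equal to the family size. The power routine uses the
noncentral-F distribution with the SPSS effect-size convention λ = f²·n
(configurable to λ = f²·n·m), f = sqrt(η²/(1−η²)).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .channels import MultivariateTestResult, PosthocRow

log = logging.getLogger(__name__)


def eta_to_f(partial_eta_sq: float) -> float:
    """Cohen's f from partial η²: f = sqrt(η² / (1 − η²))."""
    if not 0 <= partial_eta_sq < 1:
        raise ValueError(f"partial eta squared must lie in [0, 1), got {partial_eta_sq}")
    return float(np.sqrt(partial_eta_sq / (1.0 - partial_eta_sq)))


def f_to_eta(effect_size_f: float) -> float:
    """Inverse of :func:`eta_to_f`: η² = f² / (1 + f²)."""
    if effect_size_f < 0:
        raise ValueError(f"effect size f must be >= 0, got {effect_size_f}")
    return float(effect_size_f**2 / (1.0 + effect_size_f**2))


def wilks_to_f(wilks_lambda: float, p_vars: int, n: int) -> float:
    """Exact F transform of Wilks' Λ for the one-sample case:
    F = ((1−Λ)/Λ)·((n−p)/p) on (p, n−p) df."""
    if not 0 < wilks_lambda <= 1:
        raise ValueError(f"Wilks lambda must lie in (0, 1], got {wilks_lambda}")
    return float((1.0 - wilks_lambda) / wilks_lambda * (n - p_vars) / p_vars)


@dataclass
class PowerAnalysisSpec:
    """Inputs for the repeated-measures power computation."""

    effect_size_f: float
    n: int
    n_measurements: int
    alpha: float = 0.05
    epsilon: float = 1.0
    noncentrality: str = "spss"  # lambda = f^2 * n; "times_m" uses f^2 * n * m

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.n_measurements < 2:
            raise ValueError(f"n_measurements must be >= 2, got {self.n_measurements}")
        if not 0 < self.epsilon <= 1:
            raise ValueError(f"epsilon must lie in (0, 1], got {self.epsilon}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.effect_size_f < 0:
            raise ValueError(f"effect size f must be >= 0, got {self.effect_size_f}")


def rm_power(spec: PowerAnalysisSpec) -> float:
    """Noncentral-F power of the within-factor repeated-measures test.

    df1 = ε(m−1), df2 = ε(n−1)(m−1), λ = f²·n under the SPSS convention.
    f = 0 returns exactly α (central F).
    """
    m = spec.n_measurements
    df1 = spec.epsilon * (m - 1)
    df2 = spec.epsilon * (spec.n - 1) * (m - 1)
    lam = spec.effect_size_f**2 * spec.n
    if spec.noncentrality == "times_m":
        lam *= m
    crit = sps.f.ppf(1.0 - spec.alpha, df1, df2)
    if lam == 0:
        return float(spec.alpha)
    return float(sps.ncf.sf(crit, df1, df2, lam))


def _difference_matrix(table: pd.DataFrame, family: list) -> pd.DataFrame:
    """Per-subject (vibration − baseline) matrix, listwise-complete on the family."""
    required = {"subject", "variable", "baseline", "vibration"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"paired table missing columns: {sorted(missing)}")
    sub = table[table["variable"].isin(family)]
    dup = sub.duplicated(subset=["subject", "variable"])
    if dup.any():
        raise ValueError(
            f"duplicate (subject, variable) rows: "
            f"{sub.loc[dup, ['subject', 'variable']].values.tolist()}"
        )
    diff = (
        sub.assign(diff=sub["vibration"] - sub["baseline"])
        .pivot(index="subject", columns="variable", values="diff")
        .reindex(columns=family)
    )
    complete = diff.dropna()
    n_dropped = len(diff) - len(complete)
    if n_dropped:
        log.info("listwise deletion dropped %d incomplete subjects", n_dropped)
    return complete


def rm_condition_test(
    table: pd.DataFrame,
    family: list,
    family_name: str = "",
    *,
    max_condition_number: float = 1e10,
) -> MultivariateTestResult:
    """One-sample Hotelling T² on condition differences, Wilks-style report.

    Subjects enter only if complete on every family variable (listwise
    deletion). Rejects when the error degrees of freedom run out
    (n ≤ p) or the difference covariance is numerically singular.
    """
    d = _difference_matrix(table, list(family))
    n, p = d.shape
    if n <= p:
        raise ValueError(
            f"more variables than error df: {p} variables with only {n} complete subjects"
        )
    X = d.to_numpy()
    dbar = X.mean(axis=0)
    S = np.cov(X, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > max_condition_number:
        corr = np.corrcoef(X, rowvar=False)
        worst = np.unravel_index(
            np.argmax(np.abs(corr - np.eye(p))), corr.shape
        )
        raise ValueError(
            f"singular difference covariance (condition number {cond:.2e}); most "
            f"collinear pair: {family[worst[0]]!r} and {family[worst[1]]!r}"
        )
    t2 = float(n * dbar @ np.linalg.solve(S, dbar))
    lam = 1.0 / (1.0 + t2 / (n - 1))
    F = t2 * (n - p) / (p * (n - 1))
    df1, df2 = p, n - p
    return MultivariateTestResult(
        family=family_name,
        n_complete=n,
        p_vars=p,
        wilks_lambda=lam,
        F=F,
        df1=df1,
        df2=df2,
        p_value=float(sps.f.sf(F, df1, df2)),
        partial_eta_sq=1.0 - lam,
        variables=list(family),
    )


def posthoc_bonferroni(
    table: pd.DataFrame, family: list, alpha: float = 0.05
) -> list:
    """Two-sided paired t per variable with Bonferroni family correction.

    Variables with fewer than 2 complete pairs are skipped with a warning;
    zero-variance differences report p = 1 (no evidence of change).
    """
    m = len(family)
    rows = []
    for var in family:
        sub = table[table["variable"] == var].dropna(subset=["baseline", "vibration"])
        if len(sub) < 2:
            log.warning("post-hoc for %r skipped: fewer than 2 complete pairs", var)
            continue
        diff = (sub["vibration"] - sub["baseline"]).to_numpy()
        n = diff.size
        if np.allclose(diff.std(ddof=1), 0.0):
            t_stat, p_raw = (0.0, 1.0) if np.allclose(diff, 0) else (np.inf, 0.0)
        else:
            t_stat, p_raw = sps.ttest_rel(sub["vibration"], sub["baseline"])
        p_bonf = min(1.0, m * float(p_raw))
        rows.append(
            PosthocRow(
                variable=var,
                mean_diff=float(diff.mean()),
                t=float(t_stat),
                df=n - 1,
                p_raw=float(p_raw),
                p_bonferroni=p_bonf,
                significant=bool(p_bonf < alpha),
            )
        )
    return rows


def run_inference(
    activation_table: pd.DataFrame,
    metabolic_table: pd.DataFrame,
    nirs_table: pd.DataFrame,
    alpha: float = 0.05,
) -> dict:
    """Family-wise condition inference across the three outcome families.

    Each family (EMG muscles, metabolic variables, rSO2 sites) gets one
    multivariate condition test followed by Bonferroni-corrected paired-t
    post-hocs. Families are processed independently; listwise deletion and
    the per-family complete-case count are reported.
    """
    inputs = {
        "emg": activation_table,
        "metabolic": metabolic_table,
        "nirs": nirs_table,
    }
    report = {}
    for name, table in inputs.items():
        if table is None or len(table) == 0:
            raise ValueError(f"family {name!r} has an empty paired table")
        family = list(pd.unique(table["variable"]))
        omnibus = rm_condition_test(table, family, family_name=name)
        posthoc = posthoc_bonferroni(table, family, alpha=alpha)
        report[name] = {"omnibus": omnibus, "posthoc": posthoc, "alpha": alpha}
    return report
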