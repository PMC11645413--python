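"""Survival and association analyses for signature scores.

Kaplan-Meier curves, log-rank tests and Cox proportional-hazards fits
are backed by lifelines (Efron tie handling, Wald confidence
intervals); group and correlation tests are rank-based with tie
correction. p-values are reported without multiple-testing adjustment.
"""
from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "SurvivalCohort",
    "SurvivalFit",
    "km_curve",
    "logrank",
    "cox_fit",
    "group_association",
    "correlation",
]


class SurvivalCohort:
    """Per-patient time/event records with optional covariates.

    ``table`` must have columns ``time`` (> 0) and ``event`` (0/1); any
    further columns are treated as covariates. An optional ``quartile``
    column carries group labels.
    """

    def __init__(self, table: pd.DataFrame):
        if "time" not in table.columns or "event" not in table.columns:
            raise ValueError("cohort table needs 'time' and 'event' columns")
        if (table["time"] <= 0).any():
            raise ValueError("all follow-up times must be positive")
        if not table["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_events(self) -> int:
        return int(self.table["event"].sum())

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "SurvivalCohort":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class GroupCurve:
    label: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray


@dataclass
class SurvivalFit:
    curves: List[GroupCurve]
    statistics: Dict[str, float] = field(default_factory=dict)


def km_curve(
    cohort: SurvivalCohort, group_labels: Optional[Sequence[str]] = None
) -> SurvivalFit:
    """Product-limit survival estimate per group (single group when
    ``group_labels`` is None)."""
    if cohort.n_events < 1:
        pass  # all-censored cohorts yield the constant-1 curve
    labels = (
        np.asarray(group_labels)
        if group_labels is not None
        else np.array(["all"] * len(cohort))
    )
    if len(labels) != len(cohort):
        raise ValueError("group labels must match cohort size")
    curves: List[GroupCurve] = []
    for lab in sorted(set(labels.tolist())):
        mask = labels == lab
        if not mask.any():
            raise ValueError(f"empty group {lab!r}")
        sub = cohort.table[mask]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        sf = kmf.survival_function_
        ev = kmf.event_table
        curves.append(
            GroupCurve(
                label=str(lab),
                times=sf.index.to_numpy(dtype=float),
                survival=sf.iloc[:, 0].to_numpy(dtype=float),
                at_risk=ev["at_risk"].to_numpy(dtype=float),
                censor_times=sub.loc[sub["event"] == 0, "time"].to_numpy(
                    dtype=float
                ),
            )
        )
    return SurvivalFit(curves)


def logrank(
    cohort: SurvivalCohort, group_labels: Sequence[str]
) -> Dict[str, float]:
    """Log-rank test across groups; df = #groups - 1."""
    labels = np.asarray(group_labels)
    groups = set(labels.tolist())
    if len(groups) < 2:
        raise ValueError("log-rank requires at least 2 groups")
    if cohort.n_events < 1:
        raise ValueError("log-rank requires at least 1 event")
    res = multivariate_logrank_test(
        cohort.table["time"], labels, cohort.table["event"]
    )
    return {
        "chi_square": float(res.test_statistic),
        "df": len(groups) - 1,
        "pvalue": float(res.p_value),
    }


def cox_fit(
    cohort: SurvivalCohort, covariates: Sequence[str]
) -> Dict[str, Dict[str, float]]:
    """Cox proportional-hazards fit (Efron ties, Wald 95% CI) for the
    named covariates. Returns per-covariate beta, HR, CI, and p."""
    covariates = list(covariates)
    missing = [c for c in covariates if c not in cohort.table.columns]
    if missing:
        raise ValueError(f"covariates absent from cohort: {missing}")
    if cohort.n_events < len(covariates) + 5:
        raise ValueError(
            f"too few events ({cohort.n_events}) for "
            f"{len(covariates)} covariates"
        )
    df = cohort.table[["time", "event", *covariates]]
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(
            f"Cox fit failed for covariates {covariates}: {exc}"
        ) from exc
    summary = cph.summary
    out: Dict[str, Dict[str, float]] = {}
    for cov in covariates:
        row = summary.loc[cov]
        out[cov] = {
            "beta": float(row["coef"]),
            "hr": float(row["exp(coef)"]),
            "ci_low": float(np.exp(row["coef lower 95%"])),
            "ci_high": float(np.exp(row["coef upper 95%"])),
            "pvalue": float(row["p"]),
        }
    return out


def group_association(
    values: Sequence[float], group_labels: Sequence[str]
) -> Dict[str, float]:
    """Kruskal-Wallis H test of a numeric variable across groups."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if np.all(values == values[0]):
        raise ValueError("constant input: association undefined")
    samples = [values[labels == g] for g in groups]
    h, p = stats.kruskal(*samples)
    return {"H": float(h), "pvalue": float(p)}


def correlation(
    x: Sequence[float], y: Sequence[float], max_exact_n: int = 8
) -> Dict[str, float]:
    """Two-sided Spearman rank correlation with tie correction.

    For n <= ``max_exact_n`` the p-value is computed by exhaustive
    permutation enumeration; the t-approximation is used otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    n = len(x)
    if n <= max_exact_n:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            r = stats.spearmanr(x, y[list(perm)]).statistic
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return {"rho": rho, "pvalue": float(p)}
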