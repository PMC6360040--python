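"""Screening and conditioning of the cohort table.

Three steps precede any inference: outlier flagging (Grubbs or Tukey),
k-nearest-neighbour imputation of sparsely missing cells (only variables
missing in fewer than 3% of subjects are eligible), and an
assumption-gating decision per analysis — Shapiro-Wilk normality within
groups and Brown-Forsythe homoscedasticity across groups, with a Box-Cox
rescue before falling back to nonparametric tests.

Outliers are flagged and reported, never silently dropped.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable

__all__ = [
    "PreprocessReport",
    "detect_outliers",
    "impute_knn",
    "assumption_gate",
    "GateDecision",
    "MISSING_LIMIT",
]

MISSING_LIMIT = 0.03  # variables missing this often or more are not imputed


@dataclass
class GateDecision:
    decision: Literal["parametric", "transform-then-parametric", "nonparametric"]
    shapiro_p: list[float]
    brown_forsythe_p: float
    boxcox_lambda: float | None = None
    note: str = ""


@dataclass
class PreprocessReport:
    """Audit trail of screening and conditioning."""

    outliers: dict[str, dict] = field(default_factory=dict)
    imputations: list[dict] = field(default_factory=list)
    skipped_variables: dict[str, str] = field(default_factory=dict)
    gates: dict[str, GateDecision] = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(dataclasses.asdict(self), default=str, **kwargs)


def _grubbs_critical(n: int, alpha: float) -> float:
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))


def detect_outliers(
    values: Sequence[float],
    method: Literal["grubbs", "tukey"] = "tukey",
    alpha: float = 0.05,
    tukey_k: float = 1.5,
    max_removals: int = 2,
) -> set[int]:
    """Flag outlying observations in one variable.

    ``tukey`` flags points outside ``[Q1 - k*IQR, Q3 + k*IQR]``; ``grubbs``
    iteratively removes the single most extreme point while its two-sided
    test statistic exceeds the critical value at ``alpha`` (at most
    ``max_removals`` removals).  Indices refer to finite entries of the
    input; NaNs are ignored.
    """
    x = np.asarray(values, dtype=float)
    finite = np.flatnonzero(np.isfinite(x))
    xf = x[finite]
    if method == "tukey":
        if xf.size < 5:
            raise ValueError("tukey outlier screen needs at least 5 finite values")
        q1, q3 = np.percentile(xf, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - tukey_k * iqr, q3 + tukey_k * iqr
        return set(finite[(xf < lo) | (xf > hi)].tolist())
    if method != "grubbs":
        raise ValueError(f"unknown outlier method {method!r}")
    if xf.size < 3:
        raise ValueError("grubbs test needs at least 3 finite values")
    if np.ptp(xf) == 0:
        raise ValueError("grubbs test undefined for a zero-variance vector")
    flagged: set[int] = set()
    work = xf.copy()
    pos = finite.copy()
    for _ in range(max_removals):
        n = work.size
        if n < 3:
            break
        mean, sd = work.mean(), work.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(work - mean)
        i = int(np.argmax(dev))
        g = dev[i] / sd
        if g <= _grubbs_critical(n, alpha):
            break
        flagged.add(int(pos[i]))
        work = np.delete(work, i)
        pos = np.delete(pos, i)
    return flagged


def impute_knn(
    table: CohortTable,
    k: int = 5,
    report: PreprocessReport | None = None,
) -> tuple[CohortTable, PreprocessReport]:
    """Fill sparsely missing cells from the k nearest complete subjects.

    Distances are Euclidean over the standardized columns that are complete
    in both the recipient and the candidate donors; each missing cell is
    replaced by the mean of its donors' values.  Variables missing in 3% or
    more of subjects are left untouched and reported.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    report = report or PreprocessReport()
    data = table.data.copy()
    numeric = [
        c for c in data.columns
        if c not in ("subject_id", "sex") and pd.api.types.is_numeric_dtype(data[c])
    ]
    x = data[numeric].to_numpy(dtype=float)
    n = len(data)

    frac_missing = np.isnan(x).mean(axis=0)
    eligible = []
    for j, col in enumerate(numeric):
        if frac_missing[j] == 0:
            continue
        if frac_missing[j] >= MISSING_LIMIT:
            report.skipped_variables[col] = (
                f"{frac_missing[j]:.1%} missing, at or above the {MISSING_LIMIT:.0%} "
                "imputation limit"
            )
        else:
            eligible.append(j)
    if not eligible:
        return CohortTable(data=data, variable_sets=dict(table.variable_sets)), report

    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd

    complete_rows = np.flatnonzero(~np.isnan(x).any(axis=1))
    if complete_rows.size == 0:
        raise ValueError("no complete donor rows available for kNN imputation")
    k_eff = min(k, complete_rows.size)

    recipients = np.flatnonzero(np.isnan(x[:, eligible]).any(axis=1))
    for i in recipients:
        observed = np.flatnonzero(~np.isnan(z[i]))
        # distance over shared complete columns, scaled to a per-column mean
        d = np.sqrt(
            ((z[np.ix_(complete_rows, observed)] - z[i, observed]) ** 2).mean(axis=1)
        )
        order = np.argsort(d, kind="stable")
        donors = complete_rows[order[:k_eff]]
        for j in eligible:
            if np.isnan(x[i, j]):
                val = float(x[donors, j].mean())
                x[i, j] = val
                report.imputations.append(
                    {
                        "subject": str(data.iloc[i]["subject_id"])
                        if "subject_id" in data
                        else int(i),
                        "variable": numeric[j],
                        "value": val,
                        "donors": [int(v) for v in donors],
                    }
                )
    data[numeric] = x
    return CohortTable(data=data, variable_sets=dict(table.variable_sets)), report


def _boxcox_shift(x: np.ndarray) -> float:
    m = x.min()
    return 1.0 - m if m <= 0 else 0.0


def assumption_gate(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
) -> GateDecision:
    """Decide between parametric and nonparametric comparison of groups.

    Shapiro-Wilk per group and Brown-Forsythe across groups at ``alpha``.
    If either is violated, a Box-Cox transform (maximum-likelihood lambda on
    positivity-shifted data) is applied and the assumptions re-checked; if
    they still fail, the decision is nonparametric.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("assumption gate needs at least two groups")
    for g in arrays:
        if g.size < 3 or not np.isfinite(g).all():
            raise ValueError("each group needs at least 3 finite values")

    def _check(gs: list[np.ndarray]) -> tuple[bool, list[float], float]:
        sw = []
        for g in gs:
            if np.ptp(g) == 0:
                sw.append(0.0)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sw.append(float(stats.shapiro(g).pvalue))
        bf = float(stats.levene(*gs, center="median").pvalue)
        ok = all(p > alpha for p in sw) and bf > alpha
        return ok, sw, bf

    ok, sw, bf = _check(arrays)
    if ok:
        return GateDecision("parametric", sw, bf)

    pooled = np.concatenate(arrays)
    shift = _boxcox_shift(pooled)
    shifted = pooled + shift
    if shifted.min() <= 0 or np.ptp(shifted) == 0:
        return GateDecision(
            "nonparametric", sw, bf,
            note="no feasible positivity shift for Box-Cox",
        )
    try:
        _, lam = stats.boxcox(shifted)
    except Exception as exc:  # rare numerical failure
        return GateDecision("nonparametric", sw, bf, note=f"Box-Cox failed: {exc}")
    transformed = [stats.boxcox(g + shift, lmbda=lam) for g in arrays]
    ok2, sw2, bf2 = _check(transformed)
    if ok2:
        return GateDecision(
            "transform-then-parametric", sw2, bf2, boxcox_lambda=float(lam),
            note=f"shift={shift}",
        )
    return GateDecision("nonparametric", sw2, bf2, boxcox_lambda=float(lam))
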