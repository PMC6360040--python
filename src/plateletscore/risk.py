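"""Risk-factor stage: per-predictor odds ratios over median-dichotomized
variables, fixed-effects Mantel-Haenszel pooling for forest plots, and
multiple logistic regression with Hosmer-Lemeshow calibration.

The pooled OR across *different predictors* (as displayed in a forest of
median splits) is computed but labelled descriptive: predictors are
correlated within subjects, so the independence assumption of fixed-effects
pooling is knowingly violated; the value summarizes the forest, it is not a
meta-analytic estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .scoring import dichotomize

__all__ = [
    "OddsRatio",
    "ForestData",
    "LogisticResult",
    "or_2x2",
    "mh_pooled",
    "hosmer_lemeshow",
    "fit_logistic",
    "build_forest",
]


@dataclass
class OddsRatio:
    odds_ratio: float
    ci: tuple[float, float]
    p: float | None = None
    corrected: bool = False
    table: np.ndarray | None = None


def _as_2x2(table, integral: bool = True) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any() or (integral and not np.allclose(t, np.round(t))):
        raise ValueError("cells must be non-negative integers")
    return t


def or_2x2(table, level: float = 0.95) -> OddsRatio:
    """Odds ratio ``ad/bc`` of a 2x2 table with a Woolf log-scale CI.

    Zero cells get the Haldane-Anscombe 0.5 continuity correction (applied
    to every cell).  An empty margin leaves the OR undefined.
    """
    t = _as_2x2(table)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("empty margin: odds ratio undefined")
    corrected = bool((t == 0).any())
    if corrected:
        t = t + 0.5
    a, b, c, d = t.ravel()
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - (1 - level) / 2)
    lo, hi = math.exp(math.log(orr) - z * se), math.exp(math.log(orr) + z * se)
    p = float(2 * stats.norm.sf(abs(math.log(orr)) / se))
    return OddsRatio(float(orr), (lo, hi), p=p, corrected=corrected,
                     table=np.asarray(table, dtype=float))


def mh_pooled(strata: Sequence, level: float = 0.95,
              _corrected: bool = False) -> OddsRatio:
    """Fixed-effects Mantel-Haenszel pooled odds ratio over 2x2 strata.

    Point estimate ``sum(a_i d_i / n_i) / sum(b_i c_i / n_i)``; the CI uses
    the Robins-Breslow-Greenland variance of the log pooled OR, and the
    two-sided p comes from the corresponding z statistic.  If every stratum
    cross-product on one side vanishes, strata containing zero cells get the
    Haldane-Anscombe 0.5 correction and the estimate is flagged corrected.
    """
    tables = [_as_2x2(t, integral=not _corrected) for t in strata]
    if not tables:
        raise ValueError("need at least one stratum")
    num = den = 0.0
    s_pr = s_ps_qr = s_qs = 0.0
    for t in tables:
        a, b, c, d = t.ravel()
        n = t.sum()
        if n == 0:
            continue
        r_i, s_i = a * d / n, b * c / n
        p_i, q_i = (a + d) / n, (b + c) / n
        num += r_i
        den += s_i
        s_pr += p_i * r_i
        s_ps_qr += p_i * s_i + q_i * r_i
        s_qs += q_i * s_i
    if num == 0 and den == 0:
        raise ValueError("all cross-products zero: pooled OR undefined")
    if den == 0 or num == 0:
        if _corrected:
            raise ValueError("pooled OR degenerate even after correction")
        fixed = [t + 0.5 if (t == 0).any() else t for t in tables]
        res = mh_pooled(fixed, level=level, _corrected=True)
        res.corrected = True
        return res
    orr = num / den
    var = s_pr / (2 * num**2) + s_ps_qr / (2 * num * den) + s_qs / (2 * den**2)
    se = math.sqrt(var)
    z = stats.norm.ppf(1 - (1 - level) / 2)
    lo, hi = math.exp(math.log(orr) - z * se), math.exp(math.log(orr) + z * se)
    p = float(2 * stats.norm.sf(abs(math.log(orr)) / se))
    return OddsRatio(float(orr), (lo, hi), p=p)


def hosmer_lemeshow(y: np.ndarray, p_hat: np.ndarray, g: int = 10) -> tuple[float, float]:
    """Hosmer-Lemeshow goodness-of-fit statistic over ``g`` groups of
    predicted risk; returns (chi2, p) with ``g - 2`` degrees of freedom."""
    y = np.asarray(y, dtype=float)
    p_hat = np.asarray(p_hat, dtype=float)
    order = np.argsort(p_hat, kind="stable")
    ys, ps = y[order], p_hat[order]
    edges = np.linspace(0, y.size, g + 1).astype(int)
    chi2 = 0.0
    used = 0
    for k in range(g):
        sl = slice(edges[k], edges[k + 1])
        nk = edges[k + 1] - edges[k]
        if nk == 0:
            continue
        ok = ys[sl].sum()
        ek = ps[sl].sum()
        vk = ek * (1 - ps[sl].mean())
        if vk <= 0:
            continue
        chi2 += (ok - ek) ** 2 / vk
        used += 1
    df = max(used - 2, 1)
    return float(chi2), float(stats.chi2.sf(chi2, df))


@dataclass
class LogisticResult:
    outcome: str
    predictors: list[str]
    adjustment: list[str]
    odds_ratios: pd.DataFrame          # per predictor: OR, ci_lo, ci_hi, p
    lr_chi2: dict[str, tuple[float, float]]  # predictor -> (chi2, p) for its removal
    hl_chi2: float
    hl_p: float
    converged: bool
    n: int


def fit_logistic(
    data: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    adjustment: Sequence[str] = (),
    hl_groups: int = 10,
) -> LogisticResult:
    """Maximum-likelihood logistic fit of a dichotomized score class on the
    given predictors plus adjustment covariates.

    Per-predictor ORs are ``exp(beta)`` with Wald 95% CIs; each predictor
    additionally gets a likelihood-ratio chi-square for dropping it from the
    full model.  Calibration is summarized by the Hosmer-Lemeshow test on
    deciles of predicted risk.  Complete separation is flagged and refit
    with an L2 penalty.
    """
    predictors = list(predictors)
    adjustment = [a for a in adjustment if a not in predictors]
    cols = predictors + adjustment
    frame = data[[outcome] + cols].copy()
    if "sex" in cols:
        frame["sex"] = (frame["sex"].astype(str) == "male").astype(float)
    y = frame[outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be a 0/1 class vector")
    x = sm.add_constant(frame[cols].to_numpy(dtype=float))
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing cells present; impute before the logistic fit")

    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
        if not converged or np.any(~np.isfinite(fit.bse)):
            raise np.linalg.LinAlgError
    except Exception:
        converged = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, x).fit_regularized(
                alpha=1.0, L1_wt=0.0, disp=0, maxiter=500
            )

    params = np.asarray(fit.params)
    try:
        bse = np.asarray(fit.bse)
    except Exception:
        bse = np.full_like(params, np.nan)
    z = stats.norm.ppf(0.975)
    rows = []
    for i, name in enumerate(cols, start=1):
        beta, se = params[i], bse[i]
        rows.append(
            {
                "predictor": name,
                "odds_ratio": math.exp(beta),
                "ci_lo": math.exp(beta - z * se) if np.isfinite(se) else np.nan,
                "ci_hi": math.exp(beta + z * se) if np.isfinite(se) else np.nan,
                "p": float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else np.nan,
                "role": "predictor" if name in predictors else "adjustment",
            }
        )
    or_table = pd.DataFrame(rows)

    lr: dict[str, tuple[float, float]] = {}
    if converged:
        llf_full = float(fit.llf)
        for name in predictors:
            keep = [c for c in cols if c != name]
            xr = sm.add_constant(frame[keep].to_numpy(dtype=float)) if keep else np.ones((len(y), 1))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                red = sm.Logit(y, xr).fit(disp=0, maxiter=200)
            chi2 = max(2 * (llf_full - float(red.llf)), 0.0)
            lr[name] = (chi2, float(stats.chi2.sf(chi2, 1)))

    p_hat = np.asarray(fit.predict(x))
    hl_chi2, hl_p = hosmer_lemeshow(y, p_hat, g=hl_groups)
    return LogisticResult(
        outcome=outcome, predictors=predictors, adjustment=adjustment,
        odds_ratios=or_table, lr_chi2=lr, hl_chi2=hl_chi2, hl_p=hl_p,
        converged=converged, n=len(y),
    )


@dataclass
class ForestData:
    """Per-predictor 2x2 strata over a dichotomized outcome, with the
    descriptive MH pooled OR, optionally within each sex stratum."""

    outcome: str
    rows: pd.DataFrame           # predictor, stratum, a, b, c, d, OR, ci, p
    pooled: dict[str, OddsRatio]  # stratum label -> pooled OR
    excluded: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        pooled_rows = [
            {
                "predictor": "(pooled MH, descriptive)", "stratum": s,
                "a": np.nan, "b": np.nan, "c": np.nan, "d": np.nan,
                "odds_ratio": orr.odds_ratio, "ci_lo": orr.ci[0],
                "ci_hi": orr.ci[1], "p": orr.p, "flag": "",
            }
            for s, orr in self.pooled.items()
        ]
        return pd.concat([self.rows, pd.DataFrame(pooled_rows)], ignore_index=True)


def _predictor_table(x: np.ndarray, cls: np.ndarray) -> np.ndarray:
    """2x2 counts (predictor rank x outcome rank) from a median split."""
    _, xr = dichotomize(x)
    # orientation: rows = predictor rank 1/0, cols = outcome rank 1/0 so the
    # OR reads "odds of high outcome under high predictor"
    a = np.sum((xr == 1) & (cls == 1))
    b = np.sum((xr == 1) & (cls == 0))
    c = np.sum((xr == 0) & (cls == 1))
    d = np.sum((xr == 0) & (cls == 0))
    return np.array([[a, b], [c, d]], dtype=float)


def build_forest(
    data: pd.DataFrame,
    outcome_class: str,
    predictors: Sequence[str],
    stratify_by_sex: bool = False,
) -> ForestData:
    """Forest-plot data: each predictor is dichotomized at its own median,
    cross-tabulated against the outcome class, and summarized by a per-row
    OR and the descriptive MH pooled OR across predictor rows."""
    cls = data[outcome_class].to_numpy(dtype=int)
    strata = (
        {"all": np.ones(len(data), dtype=bool)}
        if not stratify_by_sex
        else {
            "men": (data["sex"].astype(str) == "male").to_numpy(),
            "women": (data["sex"].astype(str) == "female").to_numpy(),
        }
    )
    rows = []
    pooled: dict[str, OddsRatio] = {}
    excluded: dict[str, str] = {}
    for label, mask in strata.items():
        tables = []
        for pred in predictors:
            x = data.loc[mask, pred].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                excluded[f"{pred}/{label}"] = "constant predictor"
                warnings.warn(f"predictor {pred!r} constant in stratum {label!r}")
                continue
            t = _predictor_table(x, cls[mask])
            try:
                orr = or_2x2(t)
            except ValueError as exc:
                excluded[f"{pred}/{label}"] = str(exc)
                continue
            flag = "corrected" if orr.corrected else ""
            if not np.isfinite(orr.odds_ratio) or orr.odds_ratio > 100:
                flag = (flag + " extreme").strip()
            rows.append(
                {
                    "predictor": pred, "stratum": label,
                    "a": t[0, 0], "b": t[0, 1], "c": t[1, 0], "d": t[1, 1],
                    "odds_ratio": orr.odds_ratio,
                    "ci_lo": orr.ci[0], "ci_hi": orr.ci[1], "p": orr.p,
                    "flag": flag,
                }
            )
            tables.append(t)
        if tables:
            pooled[label] = mh_pooled(tables)
    return ForestData(
        outcome=outcome_class, rows=pd.DataFrame(rows), pooled=pooled,
        excluded=excluded,
    )
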