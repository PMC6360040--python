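"""Association stage: rank correlations with resampling diagnostics,
assumption-gated two-group tests, covariate-adjusted comparisons with a
permutation null, and the design-stage sample-size computation.

The headline estimator is the Spearman rank correlation computed via the
mid-rank Pearson formula, reported together with a percentile-bootstrap
confidence interval and a leave-one-out (jackknife) stability record: the
range of the statistic over single-subject deletions and a flag when any
deletion flips its sign or moves it by more than 0.1.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri
from scipy.stats import rankdata

from .preprocess import GateDecision, assumption_gate

__all__ = [
    "AssociationResult",
    "AdjustedComparison",
    "spearman_boosted",
    "spearman_stratified",
    "compare_groups",
    "ancova_boosted",
    "required_n",
    "associate_score",
]

_EXACT_PERM_MAX = 8
_INFLUENCE_DELTA = 0.1


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    den = math.sqrt((rx @ rx) * (ry @ ry))
    if den == 0:
        return np.nan
    return float((rx @ ry) / den)


def _rowwise_spearman(xb: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """Spearman correlation of paired rows of two (B, n) matrices."""
    rx = rankdata(xb, axis=1)
    ry = rankdata(yb, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    num = (rx * ry).sum(axis=1)
    den = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def _spearman_p(r: float, x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p: exact permutation for tiny n, t approximation otherwise."""
    n = x.size
    if n <= _EXACT_PERM_MAX:
        ry = rankdata(y)
        rx = rankdata(x)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            rp = ry[list(perm)]
            rs = _spearman(rx, rp)
            if abs(rs) >= abs(r) - 1e-12:
                count += 1
            total += 1
        return count / total
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), n - 2))


@dataclass
class AssociationResult:
    x_name: str
    y_name: str
    n: int
    r_s: float
    p: float
    ci_level: float
    ci: tuple[float, float]
    bootstrap_iterations: int
    seed: int
    jackknife_min: float = np.nan
    jackknife_max: float = np.nan
    influence_flag: bool = False


def spearman_boosted(
    x: Sequence[float],
    y: Sequence[float],
    level: float = 0.95,
    B: int = 2000,
    seed: int = 0,
    jackknife: bool = True,
    names: tuple[str, str] = ("x", "y"),
) -> AssociationResult:
    """Spearman correlation with percentile-bootstrap CI and jackknife
    stability diagnostics."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d vectors")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")

    r = _spearman(x, y)
    p = _spearman_p(r, x, y)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    rb = _rowwise_spearman(x[idx], y[idx])
    rb = rb[np.isfinite(rb)]
    a = (1 - level) / 2
    lo, hi = np.quantile(rb, [a, 1 - a])

    jk_min = jk_max = np.nan
    flag = False
    if jackknife:
        jk = np.empty(n)
        base_rx, base_ry = rankdata(x), rankdata(y)
        for i in range(n):
            m = np.ones(n, dtype=bool)
            m[i] = False
            jk[i] = _spearman(x[m], y[m])
        jk_min, jk_max = float(np.min(jk)), float(np.max(jk))
        flag = bool(
            np.any(np.sign(jk) != np.sign(r)) or np.any(np.abs(jk - r) > _INFLUENCE_DELTA)
        )
    return AssociationResult(
        x_name=names[0], y_name=names[1], n=n, r_s=r, p=p,
        ci_level=level, ci=(float(lo), float(hi)),
        bootstrap_iterations=B, seed=seed,
        jackknife_min=jk_min, jackknife_max=jk_max, influence_flag=flag,
    )


def spearman_stratified(
    x: Sequence[float],
    y: Sequence[float],
    strata: Sequence,
) -> tuple[float, float]:
    """Stratum-wise Spearman correlations pooled on the Fisher-z scale with
    weights ``n_k - 3`` (the adjustment used for sex).  Returns the pooled
    correlation and its two-sided normal-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    zs, ws = [], []
    for s in np.unique(strata):
        m = strata == s
        if m.sum() < 5:
            continue
        r = _spearman(x[m], y[m])
        r = np.clip(r, -0.999999, 0.999999)
        zs.append(np.arctanh(r))
        ws.append(m.sum() - 3)
    if not zs:
        raise ValueError("no stratum with at least 5 pairs")
    zs, ws = np.asarray(zs), np.asarray(ws, dtype=float)
    z = float((ws * zs).sum() / ws.sum())
    se = 1.0 / math.sqrt(ws.sum())
    p = float(2 * stats.norm.sf(abs(z) / se))
    return float(np.tanh(z)), p


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p: float
    gate: GateDecision


def compare_groups(
    values: Sequence[float],
    labels: Sequence,
    alpha_gate: float = 0.05,
) -> GroupComparison:
    """Compare groups with the test selected by the assumption gate:
    Student's t (possibly after Box-Cox) for two groups meeting the
    assumptions, Mann-Whitney U otherwise; one-way ANOVA or Kruskal-Wallis
    for more than two groups."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    gate = assumption_gate(groups, alpha=alpha_gate)
    if gate.decision == "transform-then-parametric":
        pooled = np.concatenate(groups)
        shift = 1.0 - pooled.min() if pooled.min() <= 0 else 0.0
        groups = [stats.boxcox(g + shift, lmbda=gate.boxcox_lambda) for g in groups]
    parametric = gate.decision != "nonparametric"
    if len(groups) == 2:
        if parametric:
            res = stats.ttest_ind(*groups)
            name = "student-t"
        else:
            res = stats.mannwhitneyu(*groups, alternative="two-sided")
            name = "mann-whitney-u"
    else:
        if parametric:
            res = stats.f_oneway(*groups)
            name = "anova"
        else:
            res = stats.kruskal(*groups)
            name = "kruskal-wallis"
    return GroupComparison(name, float(res.statistic), float(res.pvalue), gate)


@dataclass
class AdjustedComparison:
    dependent: str
    group: str
    covariates: list[str]
    adjusted_means: dict[str, float]
    f_statistic: float
    p_bootstrap: float
    iterations: int
    seed: int
    gate: GateDecision | None = None


def _design(covs: np.ndarray | None, n: int) -> np.ndarray:
    if covs is None or covs.size == 0:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), covs])


def ancova_boosted(
    dependent: Sequence[float],
    group: Sequence,
    covariates: np.ndarray | pd.DataFrame | None = None,
    B: int = 10000,
    seed: int = 0,
    names: tuple[str, str] = ("y", "group"),
    gate: GateDecision | None = None,
) -> AdjustedComparison:
    """Covariate-adjusted group comparison with a resampling p-value.

    The group-effect F statistic from the linear model
    ``dependent ~ covariates + group`` is referred to its permutation null:
    group labels are permuted while covariates stay attached to subjects,
    and the p-value is the fraction of resamples with ``F* >= F_obs``.
    """
    if B < 1000:
        raise ValueError("at least 1000 resampling iterations are required")
    y = np.asarray(dependent, dtype=float)
    g = np.asarray(group)
    n = y.size
    if covariates is not None:
        cov_df = pd.DataFrame(covariates)
        cov_names = [str(c) for c in cov_df.columns]
        covs = cov_df.to_numpy(dtype=float)
    else:
        cov_names, covs = [], None
    if not np.isfinite(y).all() or (covs is not None and not np.isfinite(covs).all()):
        raise ValueError("missing cells present; impute before ANCOVA")

    x0 = _design(covs, n)
    rank0 = np.linalg.matrix_rank(x0)
    if rank0 < x0.shape[1]:
        raise ValueError(f"collinear covariates: {cov_names}")

    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("group must have at least 2 levels")
    dummies = np.column_stack([(g == lv).astype(float) for lv in levels[1:]])
    m = len(levels) - 1

    # residualize against the covariate-only design
    q0, _ = np.linalg.qr(x0)
    ry = y - q0 @ (q0.T @ y)
    rss0 = float(ry @ ry)
    dfres = n - x0.shape[1] - m

    def f_of(d: np.ndarray) -> float:
        rd = d - q0 @ (q0.T @ d)
        qd, _ = np.linalg.qr(rd)
        proj = qd.T @ ry
        red = float(proj @ proj)
        denom = rss0 - red
        if denom <= 0:
            return np.inf
        return (red / m) / (denom / dfres)

    f_obs = f_of(dummies)

    rng = np.random.default_rng(seed)
    if m == 1:
        # vectorized permutation null for a binary group
        d = dummies[:, 0]
        perm = np.argsort(rng.random((B, n)), axis=1)
        dp = d[perm].T                       # (n, B)
        rdp = dp - q0 @ (q0.T @ dp)
        num = ry @ rdp
        den = (rdp * rdp).sum(axis=0)
        ok = den > 0
        red = np.zeros(B)
        red[ok] = num[ok] ** 2 / den[ok]
        with np.errstate(divide="ignore", invalid="ignore"):
            f_null = (red / 1.0) / ((rss0 - red) / dfres)
        exceed = int(np.sum(f_null >= f_obs - 1e-12))
    else:
        exceed = 0
        for _ in range(B):
            exceed += f_of(dummies[rng.permutation(n)]) >= f_obs - 1e-12
    p = (1 + exceed) / (B + 1)

    # covariate-adjusted group means at the covariate grand mean
    xg = np.column_stack([x0, dummies])
    beta, *_ = np.linalg.lstsq(xg, y, rcond=None)
    base = float(beta[0])
    if covs is not None:
        base += float(covs.mean(axis=0) @ beta[1 : 1 + covs.shape[1]])
    adj = {str(levels[0]): base}
    for j, lv in enumerate(levels[1:]):
        adj[str(lv)] = base + float(beta[x0.shape[1] + j])

    return AdjustedComparison(
        dependent=names[0], group=names[1], covariates=cov_names,
        adjusted_means=adj, f_statistic=float(f_obs), p_bootstrap=float(p),
        iterations=B, seed=seed, gate=gate,
    )


def required_n(r: float, alpha: float = 0.01, power: float = 0.90) -> tuple[int, int]:
    """Sample size for detecting a correlation ``r`` at two-sided ``alpha``
    with the given power, via the Fisher-z closed form
    ``n = ((z_{1-alpha/2} + z_{power}) / atanh r)^2 + 3``.

    Returns ``(ceiling, rounded-to-ten)``.
    """
    if not 0 < r < 1:
        raise ValueError("r must lie strictly in (0, 1); the formula diverges at 0")
    if not 0 < alpha < 1 or not 0.5 < power < 1:
        raise ValueError("need 0 < alpha < 1 and 0.5 < power < 1")
    z = ndtri(1 - alpha / 2) + ndtri(power)
    n = (z / math.atanh(r)) ** 2 + 3
    return int(math.ceil(n)), int(round(n / 10.0) * 10)


def associate_score(
    data: pd.DataFrame,
    score_column: str,
    against: Sequence[str],
    level: float = 0.95,
    B: int = 2000,
    seed: int = 0,
    jackknife: bool = True,
    fdr: bool = False,
) -> pd.DataFrame:
    """Batch correlation of one score column against many cohort variables;
    returns a tidy frame (pair, n, R_s, p, CI, stability flags).

    No multiplicity correction is applied by default; ``fdr=True`` appends a
    Benjamini-Hochberg q-value column.
    """
    rows = []
    y = data[score_column].to_numpy(dtype=float)
    for i, col in enumerate(against):
        res = spearman_boosted(
            data[col].to_numpy(dtype=float), y,
            level=level, B=B, seed=seed + i, jackknife=jackknife,
            names=(col, score_column),
        )
        rows.append(
            {
                "variable": col, "score": score_column, "n": res.n,
                "r_s": res.r_s, "p": res.p,
                "ci_lo": res.ci[0], "ci_hi": res.ci[1],
                "jackknife_min": res.jackknife_min,
                "jackknife_max": res.jackknife_max,
                "influence_flag": res.influence_flag,
                "bootstrap_B": res.bootstrap_iterations, "seed": res.seed,
            }
        )
    out = pd.DataFrame(rows)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        out["q_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
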