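"""Multivariate discrimination stage.

Three complementary views of which variables separate the lower- and
higher-reactivity classes:

* forward-stepwise linear discriminant analysis ranked by partial Wilks'
  lambda (the ratio of the model lambda with a variable to the lambda
  without it; smaller means more unique discriminatory contribution), with
  the F approximation tied to Mahalanobis distance;
* canonical correlation analysis between the reactivity set and each
  explanatory set, with per-set extracted variance and redundancy indices
  and Bartlett chi-square tests on Wilks' lambda;
* a classifier panel (kNN with Chebyshev distance, linear SVM, Gaussian
  naive Bayes, a minimal MARS) evaluated under leave-one-out and combined
  by majority vote ("voting of k judges").
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .mars import MarsClassifier

__all__ = [
    "DiscriminantRanking",
    "CanonicalSummary",
    "PanelConfig",
    "PanelResult",
    "lda_rank",
    "canonical",
    "run_panel",
    "vote_judges",
]


# ---------------------------------------------------------------------------
# stepwise LDA


def _wilks_lambda(x: np.ndarray, classes: np.ndarray, cols: list[int],
                  ridge: float = 0.0) -> float:
    """Overall Wilks' lambda det(W)/det(T) for the given column subset."""
    if not cols:
        return 1.0
    xs = x[:, cols]
    grand = xs.mean(axis=0)
    t = (xs - grand).T @ (xs - grand)
    w = np.zeros_like(t)
    for g in np.unique(classes):
        xg = xs[classes == g]
        w += (xg - xg.mean(axis=0)).T @ (xg - xg.mean(axis=0))
    if ridge > 0:
        scale = np.trace(t) / len(cols)
        w = w + ridge * scale * np.eye(len(cols))
        t = t + ridge * scale * np.eye(len(cols))
    sign_w, ld_w = np.linalg.slogdet(w)
    sign_t, ld_t = np.linalg.slogdet(t)
    if sign_w <= 0 or sign_t <= 0:
        raise np.linalg.LinAlgError("singular scatter matrix")
    return float(np.exp(ld_w - ld_t))


def _partial_f(lam_partial: float, n: int, g: int, p_in: int) -> tuple[float, float]:
    """F statistic and p for a partial Wilks' lambda with ``p_in`` other
    variables already in the model (g groups)."""
    df1 = g - 1
    df2 = n - g - p_in
    if df2 <= 0 or lam_partial <= 0:
        return np.nan, np.nan
    f = (df2 / df1) * (1 - lam_partial) / lam_partial
    return float(f), float(stats.f.sf(f, df1, df2))


@dataclass
class DiscriminantRanking:
    grouping: str
    entered: list[str]                   # in entry order
    partial_lambda: dict[str, float]     # within the final model
    partial_p: dict[str, float]
    path: list[dict] = field(default_factory=list)
    ridge_used: bool = False

    def ranking(self) -> list[str]:
        return sorted(self.entered, key=lambda v: self.partial_lambda[v])


def lda_rank(
    features: pd.DataFrame,
    classes: Sequence[int],
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    grouping: str = "class",
) -> DiscriminantRanking:
    """Forward-stepwise discriminant variable selection.

    At each step the candidate with the smallest partial Wilks' lambda
    (largest F-to-enter) joins the model if its p-value clears ``p_enter``;
    entered variables whose partial p rises above ``p_remove`` are dropped.
    Singular within-group scatter is ridge-stabilized with a warning.
    """
    x = features.to_numpy(dtype=float)
    names = list(features.columns)
    cls = np.asarray(classes)
    levels = np.unique(cls)
    n, p = x.shape
    g = len(levels)
    if g < 2 or min((cls == lv).sum() for lv in levels) == 0:
        raise ValueError("need at least two non-empty classes")
    if p < 2:
        raise ValueError("need at least two candidate predictors")
    if n <= p + 2:
        raise ValueError("need n > p + 2 subjects")

    ridge = 0.0

    def lam(cols: list[int]) -> float:
        nonlocal ridge
        try:
            return _wilks_lambda(x, cls, cols, ridge)
        except np.linalg.LinAlgError:
            if ridge == 0.0:
                ridge = 1e-8
                warnings.warn("singular within-group scatter; ridge-stabilized")
            return _wilks_lambda(x, cls, cols, ridge)

    in_model: list[int] = []
    path: list[dict] = []
    while True:
        lam_cur = lam(in_model)
        # entry scan
        best_j, best_lam = None, 1.0
        for j in range(p):
            if j in in_model:
                continue
            lp = lam(in_model + [j]) / lam_cur
            if lp < best_lam:
                best_lam, best_j = lp, j
        moved = False
        if best_j is not None:
            f, pv = _partial_f(best_lam, n, g, len(in_model))
            if np.isfinite(pv) and pv < p_enter:
                in_model.append(best_j)
                path.append({"action": "enter", "variable": names[best_j],
                             "partial_lambda": best_lam, "F": f, "p": pv})
                moved = True
        # removal scan
        if len(in_model) > 1:
            lam_full = lam(in_model)
            worst_j, worst_p, worst_lam = None, -1.0, 1.0
            for j in in_model:
                rest = [k for k in in_model if k != j]
                lp = lam_full / lam(rest)
                _, pv = _partial_f(lp, n, g, len(rest))
                if np.isfinite(pv) and pv > worst_p:
                    worst_p, worst_j, worst_lam = pv, j, lp
            if worst_j is not None and worst_p > p_remove:
                in_model.remove(worst_j)
                path.append({"action": "remove", "variable": names[worst_j],
                             "partial_lambda": worst_lam, "p": worst_p})
                moved = True
        if not moved:
            break

    lam_full = lam(in_model)
    partial_lambda: dict[str, float] = {}
    partial_p: dict[str, float] = {}
    for j in in_model:
        rest = [k for k in in_model if k != j]
        lp = lam_full / lam(rest) if rest else lam_full
        _, pv = _partial_f(lp, n, g, len(rest))
        partial_lambda[names[j]] = lp
        partial_p[names[j]] = pv
    return DiscriminantRanking(
        grouping=grouping,
        entered=[names[j] for j in in_model],
        partial_lambda=partial_lambda,
        partial_p=partial_p,
        path=path,
        ridge_used=ridge > 0,
    )


# ---------------------------------------------------------------------------
# canonical correlation


@dataclass
class CanonicalSummary:
    correlations: np.ndarray            # non-increasing, in [0, 1]
    determination: np.ndarray           # squared correlations
    wilks_lambda: np.ndarray            # lambda_k for variates k..end
    bartlett_p: np.ndarray
    loadings1: np.ndarray               # variables x variates
    loadings2: np.ndarray
    n_reported: int                     # variates entering the summaries
    extracted_variance: tuple[float, float]   # % per set over reported variates
    total_redundancy: tuple[float, float]     # % per set
    contributors1: list[str]
    contributors2: list[str]
    names1: list[str]
    names2: list[str]


def _standardize_full_rank(m: pd.DataFrame, label: str) -> tuple[np.ndarray, list[str]]:
    x = m.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [c for c, s in zip(m.columns, sd) if s == 0]
        raise ValueError(f"constant columns in {label}: {bad}; remove them")
    z = (x - x.mean(axis=0)) / sd
    if np.linalg.matrix_rank(z) < z.shape[1]:
        raise ValueError(
            f"{label} is rank deficient after standardization; remove "
            "linearly dependent variables"
        )
    return z, [str(c) for c in m.columns]


def canonical(
    set1: pd.DataFrame,
    set2: pd.DataFrame,
    alpha: float = 0.05,
    loading_threshold: float = 0.3,
) -> CanonicalSummary:
    """Canonical correlation analysis between two variable sets.

    Correlations come from the SVD of the whitened cross-correlation
    matrix.  Extracted variance (per set, per variate) is the mean squared
    structure loading; redundancy multiplies it by the paired variate's
    squared correlation.  Both are reported summed over the variates whose
    Bartlett chi-square p is below ``alpha`` (at least one).
    """
    if len(set1) != len(set2):
        raise ValueError("sets must share subjects")
    z1, names1 = _standardize_full_rank(set1, "set1")
    z2, names2 = _standardize_full_rank(set2, "set2")
    n = len(z1)
    p, q = z1.shape[1], z2.shape[1]

    r11 = np.corrcoef(z1, rowvar=False).reshape(p, p)
    r22 = np.corrcoef(z2, rowvar=False).reshape(q, q)
    r12 = (z1.T @ z2) / (n - 1)

    def inv_sqrt(r: np.ndarray) -> np.ndarray:
        w, v = np.linalg.eigh(r)
        if w.min() <= 1e-10:
            raise ValueError("correlation matrix numerically singular")
        return (v / np.sqrt(w)) @ v.T

    k = inv_sqrt(r11) @ r12 @ inv_sqrt(r22)
    u, s, vt = np.linalg.svd(k)
    d = min(p, q)
    s = np.clip(s[:d], 0.0, 1.0)

    a = inv_sqrt(r11) @ u[:, :d]       # coefficients on standardized set1
    b = inv_sqrt(r22) @ vt.T[:, :d]
    load1 = r11 @ a                     # structure loadings
    load2 = r22 @ b

    lam = np.empty(d)
    bart_p = np.empty(d)
    for kk in range(d):
        lam[kk] = float(np.prod(1 - s[kk:] ** 2))
        chi2 = -(n - 1 - (p + q + 1) / 2) * math.log(max(lam[kk], 1e-300))
        df = (p - kk) * (q - kk)
        bart_p[kk] = float(stats.chi2.sf(chi2, df))

    n_rep = int(np.sum(bart_p < alpha))
    n_rep = max(n_rep, 1)

    ev1 = float(100 * np.sum(np.mean(load1[:, :n_rep] ** 2, axis=0)))
    ev2 = float(100 * np.sum(np.mean(load2[:, :n_rep] ** 2, axis=0)))
    red1 = float(100 * np.sum(np.mean(load1[:, :n_rep] ** 2, axis=0) * s[:n_rep] ** 2))
    red2 = float(100 * np.sum(np.mean(load2[:, :n_rep] ** 2, axis=0) * s[:n_rep] ** 2))

    contrib1 = [names1[i] for i in range(p) if abs(load1[i, 0]) >= loading_threshold]
    contrib2 = [names2[i] for i in range(q) if abs(load2[i, 0]) >= loading_threshold]

    return CanonicalSummary(
        correlations=s, determination=s**2, wilks_lambda=lam, bartlett_p=bart_p,
        loadings1=load1, loadings2=load2, n_reported=n_rep,
        extracted_variance=(ev1, ev2), total_redundancy=(red1, red2),
        contributors1=contrib1, contributors2=contrib2,
        names1=names1, names2=names2,
    )


# ---------------------------------------------------------------------------
# classifier panel


@dataclass
class PanelConfig:
    knn_metric: str = "chebyshev"
    knn_grid: tuple[int, ...] = (3, 5, 7, 9)
    svm_c: float = 1.0
    mars_max_terms: int = 10
    evaluation: Literal["loo", "insample"] = "loo"


@dataclass
class PanelResult:
    predictions: pd.DataFrame            # subject x classifier predictions
    accuracy: dict[str, float]           # percent correct per classifier
    truth: np.ndarray
    config: PanelConfig
    seed: int
    knn_k: int | None = None


def _loo_knn(x: np.ndarray, y: np.ndarray, k: int, metric: str) -> np.ndarray:
    """Leave-one-out kNN prediction by querying k+1 neighbours and dropping
    the query point itself."""
    model = KNeighborsClassifier(n_neighbors=min(k + 1, len(y)), metric=metric)
    model.fit(x, y)
    _, idx = model.kneighbors(x)
    preds = np.empty(len(y), dtype=int)
    for i in range(len(y)):
        nb = [j for j in idx[i] if j != i][:k]
        preds[i] = int(np.round(y[nb].mean() + 1e-9))
    return preds


def _loo_predict(fit_predict, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    preds = np.empty(len(y), dtype=int)
    mask = np.ones(len(y), dtype=bool)
    for i in range(len(y)):
        mask[i] = False
        preds[i] = int(fit_predict(x[mask], y[mask], x[i : i + 1])[0])
        mask[i] = True
    return preds


def run_panel(
    features: pd.DataFrame,
    classes: Sequence[int],
    config: PanelConfig | None = None,
    seed: int = 0,
) -> PanelResult:
    """Train and evaluate the four judges against the true allocation.

    Features are standardized once; kNN's neighbourhood size is chosen by
    leave-one-out over the configured grid (Chebyshev distance by default).
    """
    config = config or PanelConfig()
    y = np.asarray(classes, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    x = features.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("feature matrix must be complete")
    mu, sd = x.mean(axis=0), x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    x = (x - mu) / sd
    rng = np.random.default_rng(seed)

    loo = config.evaluation == "loo"
    preds: dict[str, np.ndarray] = {}

    # kNN: pick k by LOO accuracy, deterministic tie-break toward smaller k
    accs = []
    for k in config.knn_grid:
        pk = _loo_knn(x, y, k, config.knn_metric)
        accs.append((pk == y).mean())
    best_k = int(config.knn_grid[int(np.argmax(accs))])
    if loo:
        preds["knn"] = _loo_knn(x, y, best_k, config.knn_metric)
    else:
        m = KNeighborsClassifier(n_neighbors=best_k, metric=config.knn_metric).fit(x, y)
        preds["knn"] = m.predict(x)

    def svm_fp(xt, yt, xq):
        return SVC(kernel="linear", C=config.svm_c).fit(xt, yt).predict(xq)

    def nb_fp(xt, yt, xq):
        return GaussianNB().fit(xt, yt).predict(xq)

    def mars_fp(xt, yt, xq):
        return MarsClassifier(max_terms=config.mars_max_terms).fit(xt, yt).predict(xq)

    for name, fp in (("svm", svm_fp), ("naive_bayes", nb_fp), ("mars", mars_fp)):
        if loo:
            preds[name] = _loo_predict(fp, x, y)
        else:
            preds[name] = np.asarray(fp(x, y, x), dtype=int)

    table = pd.DataFrame(preds, index=features.index)
    accuracy = {c: float(100 * (table[c].to_numpy() == y).mean()) for c in table}
    return PanelResult(
        predictions=table, accuracy=accuracy, truth=y, config=config,
        seed=seed, knn_k=best_k,
    )


@dataclass
class ConsensusRecord:
    consensus: np.ndarray
    accuracy: float                      # percent, abstentions counted wrong
    abstentions: int
    agreement: dict[str, float]          # per judge, % agreement with consensus
    tie_rule: str = "abstain (counted incorrect)"


def vote_judges(panel: PanelResult) -> ConsensusRecord:
    """Majority vote across the panel; a tied vote abstains and is counted
    as incorrect."""
    votes = panel.predictions.to_numpy(dtype=int)
    if votes.shape[1] < 2:
        raise ValueError("need at least two judges")
    ones = votes.sum(axis=1)
    half = votes.shape[1] / 2.0
    consensus = np.where(ones > half, 1, np.where(ones < half, 0, -1))
    correct = consensus == panel.truth
    acc = float(100 * correct.mean())
    agreement = {
        c: float(100 * np.mean(panel.predictions[c].to_numpy() == consensus))
        for c in panel.predictions
    }
    return ConsensusRecord(
        consensus=consensus, accuracy=acc,
        abstentions=int(np.sum(consensus == -1)), agreement=agreement,
    )
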