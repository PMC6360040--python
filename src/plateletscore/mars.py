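"""Minimal multivariate adaptive regression splines (MARS) classifier.

Additive (degree-1) hinge basis: candidate knots sit at feature quantiles,
terms are added greedily by residual-sum-of-squares reduction on the 0/1
class labels, pruned backward by generalized cross-validation, and the
surviving basis is refit with a logistic link.  This is deliberately a small
member of the classifier panel, not a full MARS implementation: no
interactions, a hard cap on the number of basis functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

__all__ = ["MarsClassifier"]


def _hinge(x: np.ndarray, knot: float, sign: int) -> np.ndarray:
    return np.maximum(0.0, sign * (x - knot))


@dataclass
class _Term:
    feature: int
    knot: float
    sign: int  # +1: max(0, x-t); -1: max(0, t-x)


class MarsClassifier:
    """Forward-backward additive hinge regression with a logistic refit."""

    def __init__(
        self,
        max_terms: int = 10,
        n_knots: int = 7,
        gcv_penalty: float = 3.0,
    ) -> None:
        self.max_terms = max_terms
        self.n_knots = n_knots
        self.gcv_penalty = gcv_penalty

    def _candidates(self, x: np.ndarray) -> list[_Term]:
        qs = np.linspace(0.1, 0.9, self.n_knots)
        terms: list[_Term] = []
        for j in range(x.shape[1]):
            knots = np.unique(np.quantile(x[:, j], qs))
            for t in knots:
                terms.append(_Term(j, float(t), +1))
                terms.append(_Term(j, float(t), -1))
        return terms

    @staticmethod
    def _basis(x: np.ndarray, terms: list[_Term]) -> np.ndarray:
        cols = [np.ones(len(x))]
        cols += [_hinge(x[:, t.feature], t.knot, t.sign) for t in terms]
        return np.column_stack(cols)

    def fit(self, x: np.ndarray, y: np.ndarray) -> "MarsClassifier":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(y)
        candidates = self._candidates(x)
        cand_mat = np.column_stack(
            [_hinge(x[:, t.feature], t.knot, t.sign) for t in candidates]
        )

        # forward pass: orthonormal basis Q of selected columns, greedy RSS
        q = np.ones((n, 1)) / np.sqrt(n)
        resid = y - q @ (q.T @ y)
        chosen: list[int] = []
        for _ in range(self.max_terms):
            c = cand_mat - q @ (q.T @ cand_mat)
            norms = np.linalg.norm(c, axis=0)
            ok = norms > 1e-8 * np.sqrt(n)
            if not ok.any():
                break
            score = np.zeros(len(candidates))
            score[ok] = (c[:, ok].T @ resid) ** 2 / norms[ok] ** 2
            score[chosen] = -np.inf
            best = int(np.argmax(score))
            if score[best] <= 1e-12:
                break
            u = c[:, best] / norms[best]
            q = np.column_stack([q, u])
            resid = resid - u * (u @ resid)
            chosen.append(best)

        # backward prune by GCV; never prune to the empty (constant) model
        terms = [candidates[i] for i in chosen]
        best_terms = list(terms)
        best_gcv = self._gcv(x, y, best_terms)
        work = list(terms)
        while len(work) > 1:
            gcvs = []
            for i in range(len(work)):
                sub = work[:i] + work[i + 1:]
                gcvs.append(self._gcv(x, y, sub))
            i = int(np.argmin(gcvs))
            work = work[:i] + work[i + 1:]
            if gcvs[i] <= best_gcv:
                best_gcv = gcvs[i]
                best_terms = list(work)

        self.terms_ = best_terms
        basis = self._basis(x, self.terms_)[:, 1:]
        if basis.shape[1] == 0 or len(np.unique(y)) < 2:
            self._logit = None
            self._const = float(y.mean() >= 0.5)
        else:
            self._logit = LogisticRegression(max_iter=1000, C=1e3)
            self._logit.fit(basis, y.astype(int))
        return self

    def _gcv(self, x: np.ndarray, y: np.ndarray, terms: list[_Term]) -> float:
        n = len(y)
        b = self._basis(x, terms)
        beta, *_ = np.linalg.lstsq(b, y, rcond=None)
        rss = float(((y - b @ beta) ** 2).sum())
        m = b.shape[1]
        eff = m + self.gcv_penalty * (m - 1) / 2.0
        denom = (1 - eff / n) ** 2
        if denom <= 0:
            return np.inf
        return rss / (n * denom)

    def predict_proba1(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self._logit is None:
            return np.full(len(x), self._const)
        basis = self._basis(x, self.terms_)[:, 1:]
        return self._logit.predict_proba(basis)[:, 1]

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (self.predict_proba1(x) > 0.5).astype(int)
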