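"""Composite platelet-reactivity scoring.

Raw reactivity readouts (per-agonist maximal aggregation, stimulated and
resting surface-antigen expression) are rank-normalized with van der Waerden
normal scores — the value with mid-rank ``r`` among ``n`` maps to
``Phi^{-1}(r / (n + 1))`` — then summed over a named component set to give a
cumulative score, and finally dichotomized at the sample median: scores at
or below the median are class 0 ("lower reactivity"), scores above it class
1 ("higher reactivity").

Because normal scores depend only on ranks, every downstream classification
is invariant under strictly monotone transformations of the raw readouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

__all__ = [
    "integrative_indicator",
    "vdw_scores",
    "NormalScoreMatrix",
    "CumulativeScore",
    "ScoreSet",
    "SCORE_SETS",
    "cumulate",
    "dichotomize",
    "score_cohort",
]


def integrative_indicator(amax: float, auc: float) -> float:
    """Integrative aggregometry indicator ``(Amax * AUC) / 1000``."""
    amax = float(amax)
    auc = float(auc)
    if not (np.isfinite(amax) and np.isfinite(auc)):
        raise ValueError("Amax and AUC must be finite")
    if amax < 0 or auc < 0:
        raise ValueError("Amax and AUC must be non-negative")
    return amax * auc / 1000.0


def vdw_scores(values: Sequence[float]) -> np.ndarray:
    """Van der Waerden normal scores of one variable.

    Ties receive the average rank and therefore share a score.  Scores of a
    tie-free sample are symmetric about zero and sum to zero.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-d vector")
    if x.size < 2:
        raise ValueError("normal scores need at least 2 values")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values present; impute before scoring")
    r = rankdata(x, method="average")
    return ndtri(r / (x.size + 1))


@dataclass
class NormalScoreMatrix:
    """Subjects x variables matrix of van der Waerden scores."""

    scores: pd.DataFrame
    source_columns: list[str]
    n: int
    tie_counts: dict[str, int]

    @classmethod
    def from_table(cls, data: pd.DataFrame, columns: Sequence[str]) -> "NormalScoreMatrix":
        missing = [c for c in columns if c not in data.columns]
        if missing:
            raise KeyError(f"columns absent from table: {missing}")
        out = {}
        ties = {}
        for c in columns:
            v = data[c].to_numpy(dtype=float)
            out[c] = vdw_scores(v)
            ties[c] = int(v.size - np.unique(v).size)
        return cls(
            scores=pd.DataFrame(out, index=data.index),
            source_columns=list(columns),
            n=len(data),
            tie_counts=ties,
        )


@dataclass(frozen=True)
class ScoreSet:
    """A named cumulative-score definition: component columns and weights."""

    label: str
    components: tuple[tuple[str, float], ...]

    @property
    def columns(self) -> list[str]:
        return [c for c, _ in self.components]


# Component sets for the published cumulative scores.  The global score
# carries the three per-agonist aggregation readouts at full weight and each
# stimulated antigen (P-selectin, activated GPIIb/IIIa) as the mean of its
# AA/COL responses — five effective components.
SCORE_SETS: dict[str, ScoreSet] = {
    "aggregation": ScoreSet(
        "cumulative platelet reactivity_aggregation",
        (("amax_aa", 1.0), ("amax_col", 1.0), ("amax_adp", 1.0)),
    ),
    "activation": ScoreSet(
        "cumulative platelet activation",
        (("cd62p_rest", 1.0), ("pac1_rest", 1.0)),
    ),
    "p_selectin": ScoreSet(
        "cumulative P-selectin expression",
        (("cd62p_aa", 1.0), ("cd62p_col", 1.0)),
    ),
    "gpiib_iiia": ScoreSet(
        "cumulative active GPIIb/IIIa expression",
        (("pac1_aa", 1.0), ("pac1_col", 1.0)),
    ),
    "flow_cytometry": ScoreSet(
        "cumulative platelet reactivity_flow cytometry",
        (("cd62p_aa", 1.0), ("cd62p_col", 1.0), ("pac1_aa", 1.0), ("pac1_col", 1.0)),
    ),
    "global": ScoreSet(
        "cumulative global platelet reactivity",
        (
            ("amax_aa", 1.0), ("amax_col", 1.0), ("amax_adp", 1.0),
            ("cd62p_aa", 0.5), ("cd62p_col", 0.5),
            ("pac1_aa", 0.5), ("pac1_col", 0.5),
        ),
    ),
}


@dataclass
class CumulativeScore:
    """A cumulative normal score with its median split."""

    name: str
    label: str
    components: tuple[tuple[str, float], ...]
    values: np.ndarray
    median: float = field(init=False)
    classes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.median, self.classes = dichotomize(self.values)

    @property
    def class_counts(self) -> tuple[int, int]:
        return int((self.classes == 0).sum()), int((self.classes == 1).sum())


def dichotomize(values: Sequence[float]) -> tuple[float, np.ndarray]:
    """Median split: class 0 for values at or below the interpolated sample
    median, class 1 above it."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("median split needs at least 2 values")
    me = float(np.median(x))
    if np.ptp(x) == 0:
        warnings.warn("constant score: every subject falls in class 0")
    return me, (x > me).astype(int)


def cumulate(
    scores: NormalScoreMatrix,
    score_name: str,
    aggregate: Literal["sum", "mean"] = "sum",
    score_sets: Mapping[str, ScoreSet] = SCORE_SETS,
) -> CumulativeScore:
    """Combine component normal scores into a named cumulative score."""
    if score_name not in score_sets:
        raise KeyError(
            f"unknown score {score_name!r}; known: {sorted(score_sets)}"
        )
    sset = score_sets[score_name]
    missing = [c for c, _ in sset.components if c not in scores.scores.columns]
    if missing:
        raise KeyError(f"score {score_name!r} needs missing columns: {missing}")
    acc = np.zeros(scores.n)
    wsum = 0.0
    for col, w in sset.components:
        acc += w * scores.scores[col].to_numpy()
        wsum += w
    if aggregate == "mean":
        acc = acc / wsum
    elif aggregate != "sum":
        raise ValueError("aggregate must be 'sum' or 'mean'")
    return CumulativeScore(
        name=score_name, label=sset.label, components=sset.components, values=acc
    )


def score_cohort(
    data: pd.DataFrame,
    score_names: Sequence[str] = ("aggregation", "activation", "p_selectin",
                                  "gpiib_iiia", "flow_cytometry", "global"),
    aggregate: Literal["sum", "mean"] = "sum",
    score_sets: Mapping[str, ScoreSet] = SCORE_SETS,
) -> tuple[pd.DataFrame, dict[str, CumulativeScore]]:
    """Append ``vdw_``, ``cum_`` and ``class_`` columns for the requested
    cumulative scores; returns the augmented copy and the score objects."""
    needed = sorted({c for s in score_names for c in score_sets[s].columns})
    matrix = NormalScoreMatrix.from_table(data, needed)
    out = data.copy()
    for c in needed:
        out[f"vdw_{c}"] = matrix.scores[c].to_numpy()
    results: dict[str, CumulativeScore] = {}
    for s in score_names:
        cs = cumulate(matrix, s, aggregate=aggregate, score_sets=score_sets)
        out[f"cum_{s}"] = cs.values
        out[f"class_{s}"] = cs.classes
        results[s] = cs
    return out, results
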