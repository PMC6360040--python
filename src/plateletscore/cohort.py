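"""Synthetic cohort generation.

The study population is emulated with a Gaussian copula: target pairwise
Spearman correlations are mapped to the Pearson scale of the latent normal
(``rho_P = 2 sin(pi * rho_S / 6)``), a multivariate normal draw is taken on
that scale, and each latent column is pushed through the quantile function of
its configured marginal family.  Marginals are parametrised the way clinical
tables report them: ``normal`` by mean/SD, ``shifted-lognormal`` by
median/quartiles (back-solved), ``scaled-beta`` by support and median for
bounded indices.  Sex-specific parameter sets mirror the female/male columns
of a descriptive table.

Only the pairwise rank structure and the marginals are modelled; no attempt
is made to emulate higher-order dependence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri

__all__ = [
    "MarginalSpec",
    "SimulationConfig",
    "CohortTable",
    "generate_cohort",
    "inject_missing",
    "nearest_positive_definite",
    "spearman_to_pearson",
]

_FAMILIES = ("normal", "shifted-lognormal", "scaled-beta")

# quartile z-score, used to back-solve lognormal sigma from a printed IQR
_Z75 = ndtri(0.75)


def spearman_to_pearson(rho_s: np.ndarray | float) -> np.ndarray | float:
    """Map a Spearman correlation to the Pearson correlation of the
    latent bivariate normal that induces it under a Gaussian copula."""
    return 2.0 * np.sin(np.pi * np.asarray(rho_s) / 6.0)


def nearest_positive_definite(a: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix onto the positive-definite cone by
    eigenvalue clipping, then rescale to unit diagonal."""
    sym = (a + a.T) / 2.0
    w, v = np.linalg.eigh(sym)
    w = np.clip(w, eps, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


@dataclass(frozen=True)
class MarginalSpec:
    """Marginal distribution of one cohort variable.

    Parameters are given per family:

    * ``normal`` — ``loc`` = mean, ``scale`` = SD;
    * ``shifted-lognormal`` — ``loc`` = median, ``scale`` = (q25, q75),
      optional ``shift`` added after exponentiation;
    * ``scaled-beta`` — support ``(lo, hi)`` with shape ``(a, b)``.

    ``by_sex`` optionally overrides ``loc``/``scale`` per sex, mirroring
    sex-split descriptive tables.
    """

    family: str
    loc: float | None = None
    scale: float | tuple[float, float] | None = None
    shift: float = 0.0
    lo: float = 0.0
    hi: float = 1.0
    a: float = 2.0
    b: float = 2.0
    by_sex: Mapping[str, Mapping[str, float | tuple[float, float]]] | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown marginal family {self.family!r}")

    def _params_for(self, sex: str | None):
        loc, scale = self.loc, self.scale
        if sex is not None and self.by_sex and sex in self.by_sex:
            over = self.by_sex[sex]
            loc = over.get("loc", loc)
            scale = over.get("scale", scale)
        return loc, scale

    def ppf(self, u: np.ndarray, sex: str | None = None) -> np.ndarray:
        """Quantile function evaluated at uniform(0,1) draws."""
        loc, scale = self._params_for(sex)
        if self.family == "normal":
            return loc + scale * ndtri(u)
        if self.family == "shifted-lognormal":
            q25, q75 = scale
            if not (self.shift < q25 < loc < q75):
                raise ValueError(
                    f"lognormal quartiles must straddle the median above the "
                    f"shift: median={loc}, q25={q25}, q75={q75}, shift={self.shift}"
                )
            med = loc - self.shift
            sigma = np.log((q75 - self.shift) / (q25 - self.shift)) / (2 * _Z75)
            return self.shift + med * np.exp(sigma * ndtri(u))
        # scaled-beta
        return self.lo + (self.hi - self.lo) * stats.beta.ppf(u, self.a, self.b)


@dataclass
class SimulationConfig:
    """Full recipe for one synthetic cohort draw."""

    n_subjects: int
    female_fraction: float
    seed: int
    marginals: dict[str, MarginalSpec]
    rank_correlation: np.ndarray | None = None
    variable_sets: dict[str, list[str]] = field(default_factory=dict)
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")
        if not 0.0 <= self.missing_rate <= 0.03:
            raise ValueError("missing_rate must lie in [0, 0.03]")
        p = len(self.marginals)
        if self.rank_correlation is None:
            self.rank_correlation = np.eye(p)
        self.rank_correlation = np.asarray(self.rank_correlation, dtype=float)
        if self.rank_correlation.shape != (p, p):
            raise ValueError(
                f"rank_correlation must be {p}x{p} to match the marginals"
            )
        self._validate_corr()

    def _validate_corr(self) -> None:
        r = self.rank_correlation
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValueError("rank_correlation must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-10):
            raise ValueError("rank_correlation must have a unit diagonal")
        bad = np.argwhere(np.abs(r) > 1 + 1e-12)
        if bad.size:
            names = list(self.marginals)
            pairs = {tuple(sorted((names[i], names[j]))) for i, j in bad}
            raise ValueError(f"rank correlations outside [-1,1]: {sorted(pairs)}")

    @property
    def variables(self) -> list[str]:
        return list(self.marginals)


@dataclass
class CohortTable:
    """A per-subject variable matrix with variable-set tags.

    ``data`` carries ``subject_id``, ``sex``, ``age`` and one numeric column
    per configured variable; ``variable_sets`` tags each analysis variable
    with the block (morphology / metabolic / oxidative / reactivity) it
    belongs to.
    """

    data: pd.DataFrame
    variable_sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        tagged: dict[str, str] = {}
        for set_name, cols in self.variable_sets.items():
            for c in cols:
                if c in tagged:
                    raise ValueError(
                        f"column {c!r} tagged in both {tagged[c]!r} and {set_name!r}"
                    )
                if c not in self.data.columns:
                    raise ValueError(f"variable-set column {c!r} missing from data")
                tagged[c] = set_name

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def columns_of(self, *set_names: str) -> list[str]:
        cols: list[str] = []
        for name in set_names:
            if name not in self.variable_sets:
                raise KeyError(f"unknown variable set {name!r}")
            cols.extend(self.variable_sets[name])
        return cols

    def to_csv(self, path: str | Path, sidecar: bool = True, **kwargs) -> None:
        path = Path(path)
        self.data.to_csv(path, index=False, **kwargs)
        if sidecar:
            lookup = {
                c: s for s, cols in self.variable_sets.items() for c in cols
            }
            columns = [
                {"name": c, "variable_set": lookup.get(c, "identity")}
                for c in self.data.columns
            ]
            sidecar_path = path.with_suffix(path.suffix + ".dict.json")
            sidecar_path.write_text(
                json.dumps({"columns": columns}, indent=1) + "\n"
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        path = Path(path)
        data = pd.read_csv(path, comment="#")
        sidecar_path = path.with_suffix(path.suffix + ".dict.json")
        variable_sets: dict[str, list[str]] = {}
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text())
            for col in meta["columns"]:
                if col["variable_set"] != "identity":
                    variable_sets.setdefault(col["variable_set"], []).append(
                        col["name"]
                    )
        return cls(data=data, variable_sets=variable_sets)


def generate_cohort(config: SimulationConfig) -> CohortTable:
    """Draw one cohort from the configured Gaussian copula.

    The female row count is ``round(female_fraction * n)`` exactly; sexes are
    interleaved by a seeded shuffle.  The same seed and config reproduce the
    table bitwise.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    names = config.variables
    p = len(names)

    pearson = spearman_to_pearson(config.rank_correlation)
    np.fill_diagonal(pearson, 1.0)
    try:
        chol = np.linalg.cholesky(pearson)
    except np.linalg.LinAlgError:
        pearson = nearest_positive_definite(pearson)
        try:
            chol = np.linalg.cholesky(pearson)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            w = np.linalg.eigvalsh(pearson)
            raise ValueError(
                "rank_correlation not repairable to positive definite "
                f"(eigenvalue range {w.min():.3g}..{w.max():.3g})"
            ) from exc

    z = rng.standard_normal((n, p)) @ chol.T
    u = ndtr(z)
    # keep copula uniforms strictly inside (0,1)
    u = np.clip(u, 1e-12, 1 - 1e-12)

    n_female = int(round(config.female_fraction * n))
    sex = np.array(["female"] * n_female + ["male"] * (n - n_female))
    rng.shuffle(sex)

    cols: dict[str, np.ndarray] = {}
    female = sex == "female"
    for j, name in enumerate(names):
        spec = config.marginals[name]
        x = np.empty(n)
        if spec.by_sex:
            x[female] = spec.ppf(u[female, j], sex="female")
            x[~female] = spec.ppf(u[~female, j], sex="male")
        else:
            x[:] = spec.ppf(u[:, j])
        cols[name] = x

    data = pd.DataFrame(cols)
    data.insert(0, "subject_id", [f"S{i + 1:04d}" for i in range(n)])
    data.insert(1, "sex", pd.Categorical(sex, categories=["female", "male"]))
    table = CohortTable(data=data, variable_sets=dict(config.variable_sets))
    if config.missing_rate > 0:
        table = inject_missing(
            table, config.missing_rate, seed=int(rng.integers(2**31))
        )
    return table


_PROTECTED = ("subject_id", "sex", "age")


def inject_missing(table: CohortTable, rate: float, seed: int) -> CohortTable:
    """Mask analysis cells missing-completely-at-random at the given rate.

    Identity columns and age are never masked.  Rates above 3% are refused:
    the downstream imputation contract only covers variables missing less
    often than 3%.
    """
    if not 0.0 <= rate <= 0.03:
        raise ValueError(
            f"missing rate {rate} outside [0, 0.03]: variables missing 3% "
            "or more are not eligible for imputation"
        )
    data = table.data.copy()
    if rate == 0.0:
        return CohortTable(data=data, variable_sets=dict(table.variable_sets))
    rng = np.random.default_rng(seed)
    eligible = [
        c
        for c in data.columns
        if c not in _PROTECTED and pd.api.types.is_numeric_dtype(data[c])
    ]
    mask = rng.random((len(data), len(eligible))) < rate
    block = data[eligible].to_numpy(dtype=float)
    block[mask] = np.nan
    data[eligible] = block
    return CohortTable(data=data, variable_sets=dict(table.variable_sets))
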