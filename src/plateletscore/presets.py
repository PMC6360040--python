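"""Default study configuration for the synthetic cohort.

Encodes the published descriptive statistics of the 60-65-year-old cohort
(n = 251; 125 women, 126 men): per-sex medians/IQRs or means/SDs for blood
morphology, serum biochemistry, oxidative markers and platelet-reactivity
readouts, together with the reported rank-correlation structure between
platelet reactivity and the morphological/metabolic/oxidative blocks.

Right-skewed laboratory variables use the shifted-lognormal family
(back-solved from median and quartiles); variables reported as mean +/- SD
(RBC, P-LCR, uric acid) use the normal family; age uses a scaled beta on the
recruitment window [60, 65].

A handful of panel variables have no published marginals (per-agonist AUC,
TAS, TOS, thromboxane); for these, field-typical values are supplied once as
package defaults and are documented in the methods note.  Every entry can be
overridden by the user.
"""

from __future__ import annotations

import numpy as np

from .cohort import MarginalSpec, SimulationConfig

__all__ = ["study_config", "STUDY_N", "STUDY_FEMALE_FRACTION", "VARIABLE_SETS"]

STUDY_N = 251
STUDY_FEMALE_FRACTION = 125 / 251


def _ln(med, q25, q75, f=None, m=None, shift=0.0):
    by_sex = None
    if f is not None and m is not None:
        by_sex = {
            "female": {"loc": f[0], "scale": (f[1], f[2])},
            "male": {"loc": m[0], "scale": (m[1], m[2])},
        }
    return MarginalSpec(
        family="shifted-lognormal", loc=med, scale=(q25, q75),
        shift=shift, by_sex=by_sex,
    )


def _norm(mean, sd, f=None, m=None):
    by_sex = None
    if f is not None and m is not None:
        by_sex = {
            "female": {"loc": f[0], "scale": f[1]},
            "male": {"loc": m[0], "scale": m[1]},
        }
    return MarginalSpec(family="normal", loc=mean, scale=sd, by_sex=by_sex)


def _marginals() -> dict[str, MarginalSpec]:
    return {
        "age": MarginalSpec(family="scaled-beta", lo=60.0, hi=65.0, a=2.0, b=1.6),
        # --- blood morphology -------------------------------------------
        "wbc": _ln(5.8, 5.0, 6.9, f=(5.6, 4.9, 6.6), m=(6.0, 5.2, 7.1)),
        "rbc": _norm(4.5, 0.4, f=(4.3, 0.3), m=(4.6, 0.4)),
        "hgb": _ln(13.8, 13.0, 14.6, f=(13.3, 12.7, 13.8), m=(14.4, 13.8, 15.1)),
        "hct": _ln(39.9, 37.6, 41.7, f=(38.6, 36.9, 40.0), m=(41.1, 39.5, 43.0)),
        "mcv": _ln(88.3, 86.2, 91.3),
        "mch": _ln(30.7, 29.8, 31.6),
        "mchc": _ln(34.7, 34.1, 35.3),
        "plt": _ln(212.5, 181.0, 243.0, f=(225.5, 198.5, 265.0), m=(196.0, 168.0, 226.0)),
        "mpv": _ln(11.3, 10.8, 12.1),
        "pct": _ln(0.24, 0.21, 0.28, f=(0.26, 0.23, 0.29), m=(0.22, 0.19, 0.25)),
        "pdw": _ln(13.6, 12.5, 15.6),
        "p_lcr": _norm(36.2, 7.7, f=(36.6, 8.0), m=(36.0, 7.5)),
        "lymphocytes": _ln(1.96, 1.6, 2.4),
        "monocytes": _ln(0.53, 0.45, 0.66, f=(0.50, 0.40, 0.58), m=(0.57, 0.48, 0.72)),
        "neutrophils": _ln(3.09, 2.56, 3.87),
        "eosinophils": _ln(0.15, 0.10, 0.22, f=(0.13, 0.09, 0.18), m=(0.16, 0.11, 0.25)),
        # basophil IQR collapses at the printed precision; normal family
        # with SD from IQR/1.349
        "basophils": _norm(0.03, 0.0074),
        # --- metabolic ---------------------------------------------------
        "total_cholesterol": _ln(205.0, 175.0, 237.0,
                                 f=(222.0, 183.5, 253.1), m=(187.2, 166.4, 219.0)),
        "triglycerides": _ln(111.5, 77.8, 163.0,
                             f=(111.7, 76.8, 159.8), m=(111.2, 78.4, 167.1)),
        "hdl_cholesterol": _ln(48.4, 40.9, 59.1,
                               f=(54.1, 45.7, 64.3), m=(44.3, 38.7, 51.1)),
        # female LDL median unprinted; geometric mid-quartile used
        "ldl_cholesterol": _ln(131.2, 103.3, 156.3,
                               f=(136.3, 108.8, 170.8), m=(115.6, 100.1, 146.5)),
        "glucose": _ln(99.2, 91.4, 108.5,
                       f=(96.3, 89.3, 105.8), m=(101.0, 93.8, 113.1)),
        "uric_acid": _norm(4.9, 1.2, f=(4.3, 1.2), m=(5.4, 1.1)),
        "homocysteine": _ln(14.7, 12.5, 17.2,
                            f=(14.2, 12.3, 16.2), m=(15.7, 13.1, 18.1)),
        "vwf": _ln(5.55, 4.9, 6.15),
        "vcam": _ln(271.0, 248.0, 295.0),
        "icam": _ln(210.0, 203.0, 217.0),
        "txb2": _ln(120.0, 70.0, 200.0),
        # --- oxidative ---------------------------------------------------
        "nh2_plt": _ln(0.2, 0.05, 2.2),
        "nh2_plasma": _ln(17.0, 11.0, 26.0),
        "sh_plt": _ln(2.9, 2.0, 40.0),
        "sh_plasma": _ln(0.03, 0.02, 0.045),
        "pox_plt": _ln(1.2, 0.5, 26.0),
        "pox_plasma": _ln(0.25, 0.03, 1.3),
        "o2_plt": _ln(0.45, 0.15, 5.0),
        "o2_plt_hcy": _ln(0.55, 0.15, 6.8),
        "tas": _ln(1.1, 0.9, 1.3),
        "tos": _ln(12.0, 6.0, 22.0),
        # --- reactivity --------------------------------------------------
        "amax_aa": _ln(127.9, 109.1, 145.1,
                       f=(134.6, 117.4, 152.4), m=(123.2, 101.3, 137.3)),
        "amax_col": _ln(152.6, 132.4, 176.6,
                        f=(158.3, 137.3, 184.9), m=(146.8, 121.9, 166.5)),
        "amax_adp": _ln(122.3, 103.9, 140.3,
                        f=(128.3, 114.8, 144.8), m=(113.0, 94.0, 131.0)),
        "auc_aa": _ln(1280.0, 1090.0, 1450.0),
        "auc_col": _ln(1530.0, 1320.0, 1770.0),
        "auc_adp": _ln(1220.0, 1040.0, 1400.0),
        "cd62p_rest": _ln(6.1, 2.2, 14.4),
        "pac1_rest": _ln(7.0, 2.0, 22.0),
        "cd62p_aa": _ln(33.0, 15.0, 51.0),
        "cd62p_col": _ln(28.0, 13.0, 48.0),
        "pac1_aa": _ln(35.0, 19.0, 53.0),
        "pac1_col": _ln(36.0, 17.0, 56.0),
    }


VARIABLE_SETS: dict[str, list[str]] = {
    "morphology": [
        "wbc", "rbc", "hgb", "hct", "mcv", "mch", "mchc", "plt", "mpv",
        "pct", "pdw", "p_lcr", "lymphocytes", "monocytes", "neutrophils",
        "eosinophils", "basophils",
    ],
    "metabolic": [
        "total_cholesterol", "triglycerides", "hdl_cholesterol",
        "ldl_cholesterol", "glucose", "uric_acid", "homocysteine", "vwf",
        "vcam", "icam", "txb2",
    ],
    "oxidative": [
        "nh2_plt", "nh2_plasma", "sh_plt", "sh_plasma", "pox_plt",
        "pox_plasma", "o2_plt", "o2_plt_hcy", "tas", "tos",
    ],
    "reactivity": [
        "amax_aa", "amax_col", "amax_adp", "auc_aa", "auc_col", "auc_adp",
        "cd62p_rest", "pac1_rest", "cd62p_aa", "cd62p_col", "pac1_aa",
        "pac1_col",
    ],
}

# Reported simple-correlation structure (Spearman targets) between platelet
# reactivity readouts and the candidate predictors, plus coherence entries
# for physiologically coupled analytes.  Jointly infeasible combinations are
# repaired by nearest-positive-definite projection at generation time.
_TARGET_PAIRS: list[tuple[str, str, float]] = [
    # platelet morphology vs aggregation
    ("plt", "amax_aa", 0.173), ("plt", "amax_col", 0.283), ("plt", "amax_adp", 0.345),
    ("pct", "amax_aa", 0.182), ("pct", "amax_col", 0.312), ("pct", "amax_adp", 0.423),
    ("p_lcr", "amax_aa", 0.123), ("p_lcr", "amax_adp", 0.176),
    ("mpv", "amax_adp", 0.169), ("pdw", "amax_adp", 0.173),
    # white cells
    ("monocytes", "amax_aa", -0.121),
    ("neutrophils", "amax_col", 0.121), ("neutrophils", "amax_adp", 0.120),
    # red cells (ADP only)
    ("rbc", "amax_adp", -0.127), ("hgb", "amax_adp", -0.206), ("hct", "amax_adp", -0.152),
    # demographics
    ("age", "amax_aa", -0.113), ("age", "amax_adp", -0.118),
    # biochemistry
    ("uric_acid", "amax_aa", -0.140), ("uric_acid", "amax_adp", -0.184),
    ("pox_plt", "amax_aa", 0.147), ("pox_plt", "amax_adp", 0.149),
    ("sh_plt", "amax_aa", 0.116), ("sh_plasma", "amax_col", 0.116),
    # within-block physiological coupling
    ("rbc", "hgb", 0.80), ("rbc", "hct", 0.88), ("hgb", "hct", 0.90),
    ("mcv", "mch", 0.70), ("mch", "mchc", 0.55),
    ("plt", "pct", 0.90), ("mpv", "p_lcr", 0.90), ("mpv", "pdw", 0.80),
    ("pdw", "p_lcr", 0.85), ("plt", "mpv", -0.30),
    ("wbc", "neutrophils", 0.85), ("wbc", "lymphocytes", 0.55),
    ("wbc", "monocytes", 0.45),
    ("total_cholesterol", "ldl_cholesterol", 0.85),
    ("total_cholesterol", "hdl_cholesterol", 0.30),
    ("total_cholesterol", "triglycerides", 0.25),
    ("hdl_cholesterol", "triglycerides", -0.35),
    ("o2_plt", "o2_plt_hcy", 0.75), ("nh2_plt", "nh2_plasma", 0.25),
    ("sh_plt", "sh_plasma", 0.25), ("pox_plt", "pox_plasma", 0.30),
    ("tas", "tos", -0.20), ("tas", "uric_acid", 0.45),
    # reactivity readouts cohere across agonists and assays
    ("amax_aa", "amax_col", 0.60), ("amax_aa", "amax_adp", 0.60),
    ("amax_col", "amax_adp", 0.60),
    ("amax_aa", "auc_aa", 0.90), ("amax_col", "auc_col", 0.90),
    ("amax_adp", "auc_adp", 0.90),
    ("cd62p_aa", "cd62p_col", 0.60), ("pac1_aa", "pac1_col", 0.60),
    ("cd62p_rest", "pac1_rest", 0.45),
    ("cd62p_aa", "pac1_aa", 0.50), ("cd62p_col", "pac1_col", 0.50),
    ("cd62p_rest", "cd62p_aa", 0.35), ("pac1_rest", "pac1_aa", 0.35),
    ("amax_aa", "cd62p_aa", 0.25), ("amax_col", "cd62p_col", 0.25),
    ("amax_aa", "pac1_aa", 0.25), ("amax_col", "pac1_col", 0.25),
]


def _rank_correlation(names: list[str]) -> np.ndarray:
    idx = {n: i for i, n in enumerate(names)}
    r = np.eye(len(names))
    for a, b, rho in _TARGET_PAIRS:
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = rho
    return r


def study_config(
    n_subjects: int = STUDY_N,
    female_fraction: float = STUDY_FEMALE_FRACTION,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> SimulationConfig:
    """The shipped cohort recipe: study marginals, sex split 125/126 at the
    default size, and the reported rank-correlation structure."""
    marginals = _marginals()
    return SimulationConfig(
        n_subjects=n_subjects,
        female_fraction=female_fraction,
        seed=seed,
        marginals=marginals,
        rank_correlation=_rank_correlation(list(marginals)),
        variable_sets={k: list(v) for k, v in VARIABLE_SETS.items()},
        missing_rate=missing_rate,
    )
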