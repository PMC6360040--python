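"""Stepwise LDA, canonical correlations, the classifier panel and the
voting consensus."""

import numpy as np
import pandas as pd
import pytest

from plateletscore.mars import MarsClassifier
from plateletscore.multivariate import (
    PanelConfig,
    PanelResult,
    canonical,
    lda_rank,
    run_panel,
    vote_judges,
)


def make_two_class(n=500, shift=2.0, seed=0, noise_cols=1):
    rng = np.random.default_rng(seed)
    cls = np.repeat([0, 1], n // 2)
    cols = {"signal": rng.standard_normal(n) + shift * cls}
    for j in range(noise_cols):
        cols[f"noise{j}"] = rng.standard_normal(n)
    return pd.DataFrame(cols), cls


class TestLdaRank:
    def test_informative_beats_noise(self):
        x, cls = make_two_class(shift=2.0, seed=1)
        rank = lda_rank(x, cls)
        assert "signal" in rank.entered
        lam_sig = rank.partial_lambda["signal"]
        for v, lam in rank.partial_lambda.items():
            if v != "signal":
                assert lam_sig < lam

    def test_null_rarely_enters(self):
        entered = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = pd.DataFrame(rng.standard_normal((120, 4)),
                             columns=list("abcd"))
            cls = np.repeat([0, 1], 60)
            rank = lda_rank(x, cls)
            entered += bool(rank.entered)
        # per-step alpha=0.05 over 4 candidates: entry in <= ~20% of nulls
        assert entered / 50 <= 0.30

    def test_single_entered_partial_equals_overall(self):
        x, cls = make_two_class(shift=3.0, seed=2, noise_cols=1)
        rank = lda_rank(x, cls)
        if rank.entered == ["signal"]:
            from plateletscore.multivariate import _wilks_lambda

            lam = _wilks_lambda(x.to_numpy(), np.asarray(cls),
                                [list(x.columns).index("signal")])
            assert rank.partial_lambda["signal"] == pytest.approx(lam, rel=1e-9)

    def test_row_permutation_invariance(self):
        x, cls = make_two_class(shift=1.5, seed=3, noise_cols=2)
        rank_a = lda_rank(x, cls)
        perm = np.random.default_rng(4).permutation(len(x))
        rank_b = lda_rank(x.iloc[perm].reset_index(drop=True), np.asarray(cls)[perm])
        assert rank_a.entered == rank_b.entered
        for v in rank_a.entered:
            assert rank_a.partial_lambda[v] == pytest.approx(
                rank_b.partial_lambda[v], rel=1e-9
            )

    def test_degenerate_inputs_rejected(self):
        x = pd.DataFrame({"a": np.arange(10.0), "b": np.arange(10.0) * 2})
        with pytest.raises(ValueError):
            lda_rank(x, np.zeros(10, dtype=int))  # one class only
        with pytest.raises(ValueError):
            lda_rank(x[["a"]], np.repeat([0, 1], 5))  # single predictor


def cca_brute_force(x1, x2):
    """Dense eigen-decomposition oracle for canonical correlations."""
    z1 = (x1 - x1.mean(0)) / x1.std(0, ddof=1)
    z2 = (x2 - x2.mean(0)) / x2.std(0, ddof=1)
    n = len(z1)
    r11 = z1.T @ z1 / (n - 1)
    r22 = z2.T @ z2 / (n - 1)
    r12 = z1.T @ z2 / (n - 1)
    m = np.linalg.inv(r11) @ r12 @ np.linalg.inv(r22) @ r12.T
    ev = np.sort(np.real(np.linalg.eigvals(m)))[::-1]
    return np.sqrt(np.clip(ev, 0, 1))


class TestCanonical:
    def test_duplicated_set_first_correlation_one(self):
        rng = np.random.default_rng(5)
        x = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("abc"))
        cs = canonical(x, x.copy())
        assert cs.correlations[0] == pytest.approx(1.0, abs=1e-8)

    def test_two_by_two_matches_eigen_oracle(self):
        rng = np.random.default_rng(6)
        z = rng.multivariate_normal(
            np.zeros(4),
            [[1, 0.3, 0.5, 0.1], [0.3, 1, 0.2, 0.4],
             [0.5, 0.2, 1, 0.3], [0.1, 0.4, 0.3, 1]],
            size=500,
        )
        x1, x2 = z[:, :2], z[:, 2:]
        cs = canonical(pd.DataFrame(x1, columns=["a", "b"]),
                       pd.DataFrame(x2, columns=["c", "d"]))
        np.testing.assert_allclose(
            cs.correlations, cca_brute_force(x1, x2), atol=1e-8
        )

    def test_independent_sets_near_zero(self):
        rng = np.random.default_rng(7)
        x1 = pd.DataFrame(rng.standard_normal((5000, 3)), columns=list("abc"))
        x2 = pd.DataFrame(rng.standard_normal((5000, 3)), columns=list("def"))
        cs = canonical(x1, x2)
        assert np.all(cs.correlations < 0.06)

    def test_affine_invariance(self):
        rng = np.random.default_rng(8)
        z = rng.standard_normal((300, 5))
        x1 = pd.DataFrame(z[:, :2] + 0.3 * z[:, 2:4], columns=["a", "b"])
        x2 = pd.DataFrame(z[:, 2:], columns=["c", "d", "e"])
        cs1 = canonical(x1, x2)
        t = np.array([[2.0, 1.0], [0.5, -1.0]])  # invertible
        x1t = pd.DataFrame(x1.to_numpy() @ t + 7.0, columns=["a", "b"])
        cs2 = canonical(x1t, x2)
        np.testing.assert_allclose(cs1.correlations, cs2.correlations, atol=1e-8)

    def test_summary_invariants(self, scored):
        data, _ = scored
        cs = canonical(
            data[["amax_aa", "amax_col", "amax_adp"]],
            data[["plt", "mpv", "pct", "hgb", "hct"]],
        )
        assert np.all(np.diff(cs.correlations) <= 1e-12)
        np.testing.assert_allclose(cs.determination, cs.correlations**2)
        assert 0 < cs.extracted_variance[0] <= 100
        assert cs.total_redundancy[0] <= cs.extracted_variance[0]
        assert cs.total_redundancy[1] <= cs.extracted_variance[1]

    def test_rank_deficiency_named(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal(100)
        x1 = pd.DataFrame({"a": a, "b": 2 * a})
        x2 = pd.DataFrame(rng.standard_normal((100, 2)), columns=["c", "d"])
        with pytest.raises(ValueError, match="rank"):
            canonical(x1, x2)


class TestPanel:
    def test_separable_classes_all_judges_accurate(self):
        rng = np.random.default_rng(10)
        n = 200
        cls = np.repeat([0, 1], n // 2)
        x = pd.DataFrame(
            {
                "u": rng.standard_normal(n) * 0.1 + 5 * cls,
                "v": rng.standard_normal(n) * 0.1 - 5 * cls,
            }
        )
        panel = run_panel(x, cls, seed=0)
        for name, acc in panel.accuracy.items():
            assert acc >= 95.0, name

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(11)
        n = 200
        x = pd.DataFrame(rng.standard_normal((n, 4)), columns=list("abcd"))
        cls = rng.permutation(np.repeat([0, 1], n // 2))
        panel = run_panel(x, cls, seed=1)
        for name, acc in panel.accuracy.items():
            assert 40.0 <= acc <= 60.0, name

    def test_insample_k1_selfmatch(self):
        rng = np.random.default_rng(12)
        x = pd.DataFrame({"a": rng.standard_normal(50),
                          "b": rng.standard_normal(50)})
        cls = rng.integers(0, 2, 50)
        cfg = PanelConfig(evaluation="insample", knn_grid=(1,))
        panel = run_panel(x, cls, cfg, seed=2)
        assert panel.accuracy["knn"] == 100.0

    def test_reproducible_under_seed(self, scored):
        data, _ = scored
        feats = data[["plt", "mpv", "pct", "uric_acid"]]
        cls = data["class_aggregation"].to_numpy()
        cfg = PanelConfig(evaluation="insample")
        a = run_panel(feats, cls, cfg, seed=3)
        b = run_panel(feats, cls, cfg, seed=3)
        pd.testing.assert_frame_equal(a.predictions, b.predictions)

    def test_single_class_rejected(self):
        x = pd.DataFrame({"a": np.arange(10.0), "b": np.arange(10.0) ** 2})
        with pytest.raises(ValueError):
            run_panel(x, np.zeros(10, dtype=int), seed=0)


def synthetic_panel(preds: dict[str, np.ndarray], truth: np.ndarray) -> PanelResult:
    table = pd.DataFrame(preds)
    acc = {c: float(100 * (table[c].to_numpy() == truth).mean()) for c in table}
    return PanelResult(predictions=table, accuracy=acc, truth=truth,
                       config=PanelConfig(), seed=0)


class TestVoting:
    def test_unanimous_truth(self):
        truth = np.array([0, 1, 1, 0, 1])
        panel = synthetic_panel({c: truth.copy() for c in "abc"}, truth)
        assert vote_judges(panel).accuracy == 100.0

    def test_majority_dominates_one_contrarian(self):
        truth = np.array([0, 1] * 10)
        panel = synthetic_panel(
            {"a": truth.copy(), "b": truth.copy(), "c": 1 - truth}, truth
        )
        assert vote_judges(panel).accuracy == 100.0

    def test_tie_abstains_and_counts_incorrect(self):
        truth = np.zeros(4, dtype=int)
        panel = synthetic_panel(
            {"a": np.array([0, 0, 1, 1]), "b": np.array([1, 1, 0, 0])}, truth
        )
        rec = vote_judges(panel)
        assert rec.abstentions == 4
        assert rec.accuracy == 0.0

    def test_three_judges_closed_form(self):
        # independent 70%-accurate judges: majority = p^3 + 3 p^2 (1-p)
        rng = np.random.default_rng(13)
        n = 10000
        truth = rng.integers(0, 2, n)
        preds = {
            c: np.where(rng.random(n) < 0.7, truth, 1 - truth) for c in "abc"
        }
        rec = vote_judges(synthetic_panel(preds, truth))
        assert rec.accuracy == pytest.approx(78.4, abs=1.5)


class TestMars:
    def test_learns_step_function(self):
        rng = np.random.default_rng(14)
        x = rng.uniform(-2, 2, (400, 1))
        y = (x[:, 0] > 0.5).astype(int)
        m = MarsClassifier().fit(x, y)
        assert (m.predict(x) == y).mean() > 0.95

    def test_basis_cap_respected(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal((300, 5))
        y = (x[:, 0] + np.sin(x[:, 1]) > 0).astype(int)
        m = MarsClassifier(max_terms=10).fit(x, y)
        assert len(m.terms_) <= 10
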