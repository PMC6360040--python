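#!/usr/bin/env python
"""Discrimination machinery: stepwise-LDA rankings by partial Wilks'
lambda per variable block, canonical correlations between the aggregometry
set and each explanatory block (with extracted variance and redundancy),
and the leave-one-out classifier panel with the voting consensus."""

from pathlib import Path

import pandas as pd

from plateletscore.cohort import CohortTable
from plateletscore.multivariate import (
    PanelConfig,
    canonical,
    lda_rank,
    run_panel,
    vote_judges,
)

OUT = Path("results")
SEED = 20240917
BLOCKS = ("morphology", "metabolic", "oxidative")


def main() -> None:
    table = CohortTable.from_csv(OUT / "cohort_scored.csv")
    data = table.data
    cls = data["class_global"].to_numpy(dtype=int)

    lda_rows, canon_rows = [], []
    for block in BLOCKS:
        cols = table.variable_sets[block]
        rank = lda_rank(data[cols], cls, grouping="class_global")
        print(f"stepwise LDA [{block}]: entered {rank.entered or 'none'}")
        for v in rank.ranking():
            lda_rows.append({"block": block, "variable": v,
                             "partial_wilks_lambda": rank.partial_lambda[v],
                             "p": rank.partial_p[v]})
        cs = canonical(data[["amax_aa", "amax_col", "amax_adp"]], data[cols])
        canon_rows.append({
            "set1": "aggregometry", "set2": block,
            "canonical_correlation": cs.correlations[0],
            "canonical_determination": cs.determination[0],
            "wilks_lambda": cs.wilks_lambda[0], "p": cs.bartlett_p[0],
            "extracted_variance_set1_pct": cs.extracted_variance[0],
            "extracted_variance_set2_pct": cs.extracted_variance[1],
            "total_redundancy_set1_pct": cs.total_redundancy[0],
            "total_redundancy_set2_pct": cs.total_redundancy[1],
            "best_contributors": "; ".join(cs.contributors2),
        })
        print(f"  canonical r={cs.correlations[0]:.3f} "
              f"(rho2={cs.determination[0]:.3f}, Wilks={cs.wilks_lambda[0]:.3f}, "
              f"p={cs.bartlett_p[0]:.3g}); contributors: "
              f"{', '.join(cs.contributors2) or '-'}")

    pd.DataFrame(lda_rows).to_csv(OUT / "lda_ranking.csv", index=False)
    pd.DataFrame(canon_rows).to_csv(OUT / "canonical.csv", index=False)

    feats = [c for b in BLOCKS for c in table.variable_sets[b]]
    panel = run_panel(data[feats], cls, PanelConfig(evaluation="loo"), seed=SEED)
    consensus = vote_judges(panel)
    preds = panel.predictions.copy()
    preds["consensus"] = consensus.consensus
    preds.insert(0, "subject_id", data["subject_id"].to_numpy())
    preds.to_csv(OUT / "panel_predictions.csv", index=False)

    print(f"\nclassifier panel (leave-one-out, kNN k={panel.knn_k}, "
          f"Chebyshev distance):")
    for name, acc in panel.accuracy.items():
        print(f"  {name:<12s} {acc:.1f}% correct")
    print(f"voting of k judges: {consensus.accuracy:.1f}% correct "
          f"({consensus.abstentions} abstentions)")


if __name__ == "__main__":
    main()
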