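#!/usr/bin/env python
"""Train linear DF classifiers on the best oppositely deregulated pairs.

Builds the 4-, 3- and 2-pair classifiers (each downregulated mRNA paired
with CDKN2A), tunes the basic cutoff (sensitivity ≈ specificity) on
out-of-fold DF values, and reports AUC / sensitivity / specificity with
95% CIs for both contrasts, plus the operating points reachable under the
four alternative diagnostic strategies.
"""

from pathlib import Path

import pandas as pd

from cqtriage import (
    Strategy,
    default_panel,
    feature_matrix,
    make_contrast,
    qc_filter,
    read_cq_table,
    sens_spec,
    train,
    tune_cutoff,
)
from cqtriage.errors import InfeasibleStrategyError
from cqtriage.pairs import PairDef

SEED = 42
RESULTS = Path(__file__).parents[1] / "results"

PAIR_SETS = {
    "clf4": ["MAL-CDKN2A", "TMPRSS4-CDKN2A", "CRNN-CDKN2A", "ECM1-CDKN2A"],
    "clf3": ["MAL-CDKN2A", "TMPRSS4-CDKN2A", "CRNN-CDKN2A"],
    "clf2": ["MAL-CDKN2A", "TMPRSS4-CDKN2A"],
}


def _pairs(names):
    out = []
    for name in names:
        x, _, y = name.partition("-")
        out.append(PairDef(x, y, "DU"))
    return out


def main():
    cohort = read_cq_table(RESULTS / "cohort_wide.csv", "wide", panel=default_panel())
    cohort, _ = qc_filter(cohort)
    (RESULTS / "classifiers").mkdir(parents=True, exist_ok=True)

    report_rows, strategy_rows = [], []
    for clf_id, names in PAIR_SETS.items():
        pairs = _pairs(names)
        labels, retained, _ = make_contrast(cohort, "LSILminus_vs_HSILplus")
        features = feature_matrix(cohort.subset(retained), pairs)
        clf, df_oof = train(features, labels, pairs=pairs, seed=SEED,
                            contrast="LSILminus_vs_HSILplus")
        tuned = tune_cutoff(clf, df_oof, labels, Strategy.BASIC)
        tuned.save(RESULTS / "classifiers" / f"{clf_id}.json")

        for scheme in ("LSILminus_vs_HSILplus", "NILM_vs_CC"):
            lab, kept, _ = make_contrast(cohort, scheme)
            feats = feature_matrix(cohort.subset(kept), pairs)
            m = sens_spec(tuned.df(feats), lab, cutoff=0.0, contrast=scheme)
            report_rows.append({
                "classifier": clf_id, "contrast": scheme, "n_pairs": len(pairs),
                "auc": round(m.auc, 3),
                "auc_lo": round(m.auc_ci[0], 3), "auc_hi": round(m.auc_ci[1], 3),
                "sens": round(m.sensitivity, 2),
                "sens_lo": round(m.sensitivity_ci[0], 2),
                "sens_hi": round(m.sensitivity_ci[1], 2),
                "spec": round(m.specificity, 2),
                "spec_lo": round(m.specificity_ci[0], 2),
                "spec_hi": round(m.specificity_ci[1], 2),
            })

        for strategy in Strategy:
            if strategy is Strategy.BASIC:
                continue
            try:
                alt = tune_cutoff(clf, df_oof, labels, strategy)
                m = sens_spec(alt.df(features), labels, cutoff=0.0)
                strategy_rows.append({
                    "classifier": clf_id, "strategy": strategy.value,
                    "sens": round(m.sensitivity, 1), "spec": round(m.specificity, 1),
                })
            except InfeasibleStrategyError as exc:
                strategy_rows.append({
                    "classifier": clf_id, "strategy": strategy.value,
                    "sens": None, "spec": None, "note": str(exc),
                })

    report = pd.DataFrame(report_rows)
    report.to_csv(RESULTS / "diagnostic_report.csv", index=False)
    pd.DataFrame(strategy_rows).to_csv(RESULTS / "strategy_table.csv", index=False)

    print("diagnostic performance (basic cutoff):")
    print(report.to_string(index=False))
    print(f"\nwrote {RESULTS / 'diagnostic_report.csv'} and strategy_table.csv")


if __name__ == "__main__":
    main()
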